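"""Complete-case filter the discovery cohort and train the circular SOM.

The map is trained on the seven FRS components only (split-by-variable
design): outcome columns never enter the training matrix.  The trained
bundle (grid, standardizer, prototypes, checksum) is saved so later steps
and the external validation reuse it without refitting.
"""

from pathlib import Path

import pandas as pd

from somhte.cohort import ADJUSTMENT_COVARIATES, FRS_COMPONENTS, read_cohort
from somhte.pipeline import complete_case_filter
from somhte.som import fit_som, project_cohort, save_som

ROOT = Path(__file__).resolve().parent.parent / "results"
table = read_cohort(ROOT / "data" / "discovery.csv")
required = list(FRS_COMPONENTS) + list(ADJUSTMENT_COVARIATES)
table, report = complete_case_filter(table, required)
print(f"complete cases: {report['retained']} of {report['total']} "
      f"({report['retained_pct']}%)")
table.to_csv(ROOT / "data" / "discovery_complete.csv", index=False)

som = fit_som(table, FRS_COMPONENTS, rings=5, epochs=50, seed=11)
save_som(som, ROOT / "som_bundle")
assignments = project_cohort(som, table)
pd.DataFrame({"id": table["id"], "district": assignments}).to_csv(
    ROOT / "assignments.csv", index=False)
print(f"trained {som.grid.n_districts}-district map; quantization error "
      f"{som.training_history[0]:.3f} -> {som.training_history[-1]:.3f} over "
      f"{som.epochs} epochs")
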