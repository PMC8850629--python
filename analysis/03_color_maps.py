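"""Color the trained map: district statistics calibrated by random colorings.

Each FRS component and each endpoint's event indicator is summarized per
district and referenced against permutation nulls; the endpoint layers are
display-only (they played no role in training).  Layers whose p-value is
small show regional structure beyond chance.
"""

from pathlib import Path

import pandas as pd

from somhte.cohort import ENDPOINTS, FRS_COMPONENTS, read_cohort
from somhte.mapstats import color_variable, colored_map_frame, render_colored_map
from somhte.som import load_som

N_PERM = 2000  # per-layer random colorings for this desk-scale analysis

ROOT = Path(__file__).resolve().parent.parent / "results"
som = load_som(ROOT / "som_bundle")
table = read_cohort(ROOT / "data" / "discovery_complete.csv")
assignments = pd.read_csv(ROOT / "assignments.csv")["district"].to_numpy()

out = ROOT / "colored"
out.mkdir(exist_ok=True)
layers = list(FRS_COMPONENTS) + [f"{e}_event" for e in ENDPOINTS]
for i, var in enumerate(layers):
    cmap = color_variable(assignments, table[var].to_numpy(dtype=float),
                          som.grid, var, bandwidth=1.0, n_perm=N_PERM,
                          seed=1000 + i)
    colored_map_frame(cmap).to_csv(out / f"{var}.csv", index=False)
    render_colored_map(cmap, som.grid, out / f"{var}.png")
    print(f"{var:>18}: layer p = {cmap.p_value:.4g}")
print(f"colored maps written to {out}")
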