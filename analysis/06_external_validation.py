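"""Transfer the frozen trained map and subgroup split to the validation cohort.

Nothing is refit: the validation cohort is standardized with the discovery
cohort's standardizer, projected onto the stored prototypes, and labeled by
the stored district->subgroup config; balance and the full heterogeneity
analysis are then rerun on the external data alone.
"""

import json
from pathlib import Path

from somhte.pipeline import RunConfig, validate_external

ROOT = Path(__file__).resolve().parent.parent / "results"
config = RunConfig(output_dir=str(ROOT), seed=11)
report = validate_external(
    ROOT / "som_bundle",
    ROOT / "data" / "validation.csv",
    ROOT / "subgroups.yaml",
    config,
    output_dir=ROOT / "external",
)
print("transfer mode:", report["mode"])
print("validation retention:", report["retention"])
print("subgroup sizes:", report["subgroup_sizes"])
print("Q p-values per endpoint:")
for e, q in report["q_summary"].items():
    p = q["p"]
    print(f"  {e:>12}: {'undefined' if p is None else f'{p:.4f}'}")
print(f"external artifacts in {ROOT/'external'}; full report: "
      f"{json.dumps(report['retention'])}")
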