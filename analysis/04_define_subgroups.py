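"""Split the colored map into four contiguous subgroups and check balance.

The contiguity-constrained Ward suggestion stands in for expert visual
boundary drawing; the resulting district->subgroup config is saved so the
identical split can be transferred to the validation cohort.  Within each
subgroup, covariate balance between randomized arms is checked with
standardized mean differences (|SMD| < 0.1 acceptable).
"""

from pathlib import Path

import pandas as pd

from somhte.cohort import ADJUSTMENT_COVARIATES, FRS_COMPONENTS, read_cohort
from somhte.som import load_som
from somhte.subgroups import balance_smd, save_subgroup_config, subgroup_profiles, suggest_subgroups

ROOT = Path(__file__).resolve().parent.parent / "results"
som = load_som(ROOT / "som_bundle")
table = read_cohort(ROOT / "data" / "discovery_complete.csv")
assignments = pd.read_csv(ROOT / "assignments.csv")["district"].to_numpy()

assignment = suggest_subgroups(som, k=4, seed=11)
save_subgroup_config(assignment, ROOT / "subgroups.yaml")
labels = assignment.participant_labels(assignments)
pd.DataFrame({"id": table["id"], "subgroup": labels}).to_csv(
    ROOT / "subgroup_labels.csv", index=False)

profiles = subgroup_profiles(table, labels)
profiles.to_csv(ROOT / "profiles.csv")
print("subgroup sizes:", dict(pd.Series(labels).value_counts()))
print("\nFRS profile per subgroup (mean or %):")
print(profiles.loc[["n"] + list(FRS_COMPONENTS)].round(1).to_string())

covars = list(FRS_COMPONENTS) + list(ADJUSTMENT_COVARIATES)
report = balance_smd(table, labels, covars, threshold=0.1)
report.table.to_csv(ROOT / "balance.csv", index=False)
worst = report.table.sort_values("smd").iloc[-1]
print(f"\nbalance: {int(report.table['flagged'].sum())} of {len(report.table)} "
      f"subgroup-covariate SMDs >= 0.1 (worst {worst['smd']:.3f} for "
      f"{worst['covariate']} in subgroup {worst['subgroup']})")
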