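"""From colored map to discrete participant subgroups.

The primary path is an explicit district -> subgroup configuration (the
reproducible counterpart of expert visual boundary drawing on the colored
maps); a contiguity-constrained agglomerative clustering of the district
prototypes provides an automated suggestion.  Covariate balance between the
randomized arms inside each subgroup is checked with standardized mean
differences, |SMD| < 0.1 counting as acceptable.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .som import SOMGrid, TrainedSOM

_ROMAN = (
    (1000, "M"), (900, "CM"), (500, "D"), (400, "CD"), (100, "C"), (90, "XC"),
    (50, "L"), (40, "XL"), (10, "X"), (9, "IX"), (5, "V"), (4, "IV"), (1, "I"),
)


def _roman(i: int) -> str:
    out = []
    for val, sym in _ROMAN:
        while i >= val:
            out.append(sym)
            i -= val
    return "".join(out)


@dataclass(frozen=True)
class SubgroupAssignment:
    """District -> subgroup labels (every district labeled exactly once)."""

    district_labels: np.ndarray   # (n_districts,) object array of labels
    provenance: str               # "manual-config" | "suggested"

    @property
    def labels(self) -> tuple:
        seen = []
        for lab in self.district_labels:
            if lab not in seen:
                seen.append(lab)
        return tuple(sorted(seen))

    def participant_labels(self, assignments) -> np.ndarray:
        """Each participant inherits the label of their BMU district."""
        return self.district_labels[np.asarray(assignments, dtype=int)]


@dataclass(frozen=True)
class BalanceReport:
    table: pd.DataFrame   # columns: subgroup, covariate, smd, flagged
    threshold: float

    @property
    def all_balanced(self) -> bool:
        return not bool(self.table["flagged"].any())


def load_subgroup_config(source, grid: SOMGrid) -> SubgroupAssignment:
    """Read a district->label map (YAML path or dict) and validate against the grid."""
    if isinstance(source, (str, Path)):
        mapping = yaml.safe_load(Path(source).read_text())
    else:
        mapping = dict(source)
    mapping = {int(k): str(v) for k, v in mapping.items()}
    nd = grid.n_districts
    expected = set(range(nd))
    got = set(mapping)
    if got != expected:
        missing = sorted(expected - got)
        extra = sorted(got - expected)
        raise ValueError(
            f"subgroup config must label every district exactly once; "
            f"missing={missing[:10]}, unknown={extra[:10]}"
        )
    labels = np.array([mapping[i] for i in range(nd)], dtype=object)
    return SubgroupAssignment(district_labels=labels, provenance="manual-config")


def save_subgroup_config(assignment: SubgroupAssignment, path: str | Path) -> None:
    mapping = {int(i): str(lab) for i, lab in enumerate(assignment.district_labels)}
    Path(path).write_text(yaml.safe_dump(mapping))


def _connected(members: np.ndarray, adjacency: np.ndarray) -> bool:
    members = list(members)
    if not members:
        return True
    member_set = set(members)
    seen = {members[0]}
    queue = deque([members[0]])
    while queue:
        i = queue.popleft()
        for j in np.flatnonzero(adjacency[i]):
            if j in member_set and j not in seen:
                seen.add(int(j))
                queue.append(int(j))
    return len(seen) == len(member_set)


def suggest_subgroups(som: TrainedSOM, k: int, seed: int = 0) -> SubgroupAssignment:
    """Contiguity-constrained Ward clustering of district prototypes into k subgroups.

    Merges are restricted to grid-adjacent clusters, so every suggested
    subgroup is a connected patch of the map.  The procedure is
    deterministic; ``seed`` is accepted for interface uniformity and
    provenance only.
    """
    from scipy.sparse import csr_matrix
    from sklearn.cluster import AgglomerativeClustering

    nd = som.grid.n_districts
    if not (1 <= k <= nd):
        raise ValueError(f"k must be in [1, {nd}]")
    if k == 1:
        labels = np.array(["I"] * nd, dtype=object)
        return SubgroupAssignment(district_labels=labels, provenance="suggested")
    model = AgglomerativeClustering(
        n_clusters=k, linkage="ward",
        connectivity=csr_matrix(som.grid.adjacency.astype(int)),
    )
    cluster = model.fit_predict(som.prototypes)
    # stable naming: subgroups numbered by their lowest district id
    order = sorted(range(k), key=lambda c: int(np.flatnonzero(cluster == c)[0]))
    name = {c: _roman(rank + 1) for rank, c in enumerate(order)}
    labels = np.array([name[c] for c in cluster], dtype=object)
    for c in range(k):
        if not _connected(np.flatnonzero(cluster == c), som.grid.adjacency):
            raise RuntimeError("suggested subgroup is not contiguous on the grid")
    return SubgroupAssignment(district_labels=labels, provenance="suggested")


def _is_binary(col: pd.Series) -> bool:
    vals = col.dropna().unique()
    return len(vals) <= 2 and set(np.asarray(vals, dtype=float)) <= {0.0, 1.0}


def subgroup_profiles(table: pd.DataFrame, participant_labels,
                      variables=None) -> pd.DataFrame:
    """Mean (continuous) or percent (binary) per subgroup, plus an overall column.

    Empty subgroups are reported with n = 0 and undefined (NaN) statistics.
    """
    labels = np.asarray(participant_labels, dtype=object)
    if len(labels) != len(table):
        raise ValueError("assignment must cover all participants")
    if variables is None:
        variables = [c for c in table.columns
                     if c not in ("id", "arm") and table[c].dtype.kind in "if"]
    groups = sorted(set(labels))
    rows = {}
    rows["n"] = {}
    for g in groups + ["overall"]:
        mask = np.ones(len(table), bool) if g == "overall" else labels == g
        sub = table.loc[mask]
        rows["n"][g] = int(mask.sum())
        for v in variables:
            rows.setdefault(v, {})
            if len(sub) == 0:
                rows[v][g] = np.nan
            elif _is_binary(table[v]):
                rows[v][g] = 100.0 * float(sub[v].mean())
            else:
                rows[v][g] = float(sub[v].mean())
    return pd.DataFrame(rows).T[groups + ["overall"]]


def smd_continuous(x1: np.ndarray, x0: np.ndarray) -> float:
    """|m1 - m0| / sqrt((s1^2 + s0^2) / 2) with unbiased variances."""
    s1, s0 = np.var(x1, ddof=1), np.var(x0, ddof=1)
    denom = np.sqrt((s1 + s0) / 2.0)
    diff = abs(float(np.mean(x1)) - float(np.mean(x0)))
    if denom == 0:
        return 0.0 if diff == 0 else np.inf
    return diff / denom


def smd_binary(x1: np.ndarray, x0: np.ndarray) -> float:
    """Same pooled-variance form with Bernoulli variances p(1-p)."""
    p1, p0 = float(np.mean(x1)), float(np.mean(x0))
    denom = np.sqrt((p1 * (1 - p1) + p0 * (1 - p0)) / 2.0)
    diff = abs(p1 - p0)
    if denom == 0:
        return 0.0 if diff == 0 else np.inf
    return diff / denom


def balance_smd(table: pd.DataFrame, participant_labels, covariates,
                threshold: float = 0.1, arm_column: str = "arm") -> BalanceReport:
    """Between-arm standardized mean differences per subgroup and covariate."""
    labels = np.asarray(participant_labels, dtype=object)
    records = []
    for g in sorted(set(labels)):
        sub = table.loc[labels == g]
        arms = set(sub[arm_column].unique())
        if len(arms) < 2:
            raise ValueError(f"subgroup {g!r} lacks one of the treatment arms")
        m1 = sub[arm_column] == "intensive"
        for v in covariates:
            x1 = sub.loc[m1, v].to_numpy(dtype=float)
            x0 = sub.loc[~m1, v].to_numpy(dtype=float)
            smd = smd_binary(x1, x0) if _is_binary(table[v]) else smd_continuous(x1, x0)
            records.append({"subgroup": g, "covariate": v, "smd": smd,
                            "flagged": bool(smd >= threshold)})
    return BalanceReport(table=pd.DataFrame(records), threshold=threshold)


def pca_sensitivity(matrix: np.ndarray, n_components: int = 3):
    """PCA of the standardized training matrix (top components, deterministic SVD).

    Returns (scores, loadings, variance_fractions): scores are the projected
    rows, loadings the per-variable component weights (p x n_components),
    fractions the explained-variance shares in nonincreasing order.
    """
    from sklearn.decomposition import PCA

    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[1] < n_components:
        raise ValueError("fewer columns than requested components")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(matrix)
    return scores, pca.components_.T, pca.explained_variance_ratio_
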