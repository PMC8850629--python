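"""District-level map statistics calibrated against permutation nulls.

Each variable is summarized per district as a kernel-smoothed local mean
(continuous) or prevalence (binary).  The regional signal of a layer is its
across-district standard deviation ("amplitude").  Random colorings —
permutations of the variable across participants with map positions held
fixed — give a null distribution of amplitudes that provides both the layer
p-value and a common color scale, so binary and continuous layers are
directly comparable: the district score is the deviation from the grand mean
in units of the mean null amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .som import SOMGrid

#: Default number of random colorings used to calibrate a layer.
DEFAULT_N_PERM = 20_000


@dataclass(frozen=True)
class DistrictLayer:
    variable: str
    values: np.ndarray        # per-district smoothed mean/prevalence (NaN if undefined)
    weights: np.ndarray       # per-district occupancy; sums to n
    bandwidth: float
    defined: np.ndarray       # boolean mask of districts with nonzero total weight
    grand_mean: float


@dataclass(frozen=True)
class NullDistribution:
    variable: str
    n_perm: int
    amplitudes: np.ndarray    # across-district SD of each random coloring
    seed: int


@dataclass(frozen=True)
class ColoredMap:
    variable: str
    values: np.ndarray
    scores: np.ndarray        # null-referenced scale; positive renders red, negative blue
    p_value: float
    defined: np.ndarray


def _kernel(grid: SOMGrid, bandwidth: float) -> np.ndarray:
    if bandwidth == 0:
        return np.eye(grid.n_districts)
    return np.exp(-(grid.distances**2) / (2.0 * bandwidth**2))


def _layer_values(kernel: np.ndarray, sums: np.ndarray, counts: np.ndarray):
    num = kernel @ sums
    den = kernel @ counts
    defined = den > 0
    values = np.full(len(den), np.nan)
    values[defined] = num[defined] / den[defined]
    return values, defined


def district_layer(assignments, values, grid: SOMGrid, bandwidth: float = 1.0) -> DistrictLayer:
    """Kernel-weighted district means of ``values`` over BMU ``assignments``.

    A participant in district b contributes to district d with weight
    exp(-d(b,d)^2 / (2*bandwidth^2)) over the grid distance; bandwidth 0
    reduces to the plain per-district mean.  Districts with zero total
    weight are flagged undefined and excluded from scoring.
    """
    assignments = np.asarray(assignments, dtype=int)
    vals = np.asarray(values, dtype=float)
    if assignments.size == 0:
        raise ValueError("empty input")
    if assignments.shape != vals.shape:
        raise ValueError("assignments and values must have the same length")
    if bandwidth < 0:
        raise ValueError("bandwidth must be >= 0")
    nd = grid.n_districts
    counts = np.bincount(assignments, minlength=nd).astype(float)
    sums = np.bincount(assignments, weights=vals, minlength=nd)
    layer_vals, defined = _layer_values(_kernel(grid, bandwidth), sums, counts)
    return DistrictLayer(
        variable="",
        values=layer_vals,
        weights=counts,
        bandwidth=float(bandwidth),
        defined=defined,
        grand_mean=float(vals.mean()),
    )


def layer_amplitude(layer: DistrictLayer) -> float:
    """Across-district SD of the defined layer values (the regionality summary)."""
    v = layer.values[layer.defined]
    return float(v.std()) if v.size else 0.0


def permutation_nulls(assignments, values, grid: SOMGrid, bandwidth: float = 1.0,
                      n_perm: int = DEFAULT_N_PERM, seed: int = 0) -> NullDistribution:
    """Amplitudes of ``n_perm`` random colorings (values shuffled, positions fixed)."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    assignments = np.asarray(assignments, dtype=int)
    vals = np.asarray(values, dtype=float)
    if assignments.size == 0:
        raise ValueError("empty input")
    rng = np.random.default_rng(seed)
    nd = grid.n_districts
    counts = np.bincount(assignments, minlength=nd).astype(float)
    kernel = _kernel(grid, bandwidth)
    den = kernel @ counts
    defined = den > 0
    amplitudes = np.empty(n_perm)
    v = vals.copy()
    for i in range(n_perm):
        rng.shuffle(v)
        sums = np.bincount(assignments, weights=v, minlength=nd)
        layer = (kernel @ sums)[defined] / den[defined]
        amplitudes[i] = layer.std() if layer.size else 0.0
    return NullDistribution(variable="", n_perm=n_perm, amplitudes=amplitudes, seed=seed)


def color_score(layer: DistrictLayer, null: NullDistribution) -> ColoredMap:
    """Null-referenced district scores and the layer p-value.

    Score = (district value - grand mean) / mean null amplitude, so an affine
    rescaling of a continuous variable leaves the scores unchanged.  The
    p-value is the permutation rank (1 + #{null >= observed}) / (n_perm + 1),
    never 0.
    """
    if layer.variable != null.variable:
        raise ValueError(
            f"layer variable {layer.variable!r} does not match null {null.variable!r}"
        )
    obs = layer_amplitude(layer)
    ref = float(null.amplitudes.mean())
    scores = np.full(len(layer.values), np.nan)
    if ref > 0:
        scores[layer.defined] = (layer.values[layer.defined] - layer.grand_mean) / ref
    else:  # degenerate (e.g. constant variable): no regional signal by construction
        scores[layer.defined] = 0.0
    p = (1.0 + float((null.amplitudes >= obs).sum())) / (null.n_perm + 1.0)
    return ColoredMap(variable=layer.variable, values=layer.values, scores=scores,
                      p_value=p, defined=layer.defined)


def color_variable(assignments, values, grid: SOMGrid, variable: str,
                   bandwidth: float = 1.0, n_perm: int = DEFAULT_N_PERM,
                   seed: int = 0) -> ColoredMap:
    """Layer + permutation nulls + scoring for one variable in one call."""
    layer = district_layer(assignments, values, grid, bandwidth)
    layer = DistrictLayer(variable=variable, values=layer.values, weights=layer.weights,
                          bandwidth=layer.bandwidth, defined=layer.defined,
                          grand_mean=layer.grand_mean)
    null = permutation_nulls(assignments, values, grid, bandwidth, n_perm, seed)
    null = NullDistribution(variable=variable, n_perm=null.n_perm,
                            amplitudes=null.amplitudes, seed=null.seed)
    return color_score(layer, null)


def colored_map_frame(cmap: ColoredMap) -> pd.DataFrame:
    """CSV-ready table: district id, local value, null-referenced score, layer p."""
    return pd.DataFrame({
        "district": np.arange(len(cmap.values)),
        "value": cmap.values,
        "score": cmap.scores,
        "p_value": cmap.p_value,
        "defined": cmap.defined.astype(int),
    })


def render_colored_map(cmap: ColoredMap, grid: SOMGrid, path: str | Path,
                       title: str | None = None) -> None:
    """Render the colored map to SVG/PNG: dark red = highest, dark blue = lowest."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    finite = cmap.scores[np.isfinite(cmap.scores)]
    lim = max(float(np.abs(finite).max()), 1e-9) if finite.size else 1.0
    sc = ax.scatter(grid.coords[:, 0], grid.coords[:, 1], c=cmap.scores,
                    cmap="RdBu_r", vmin=-lim, vmax=lim, s=400, marker="h",
                    edgecolors="grey", linewidths=0.5)
    for i, v in enumerate(cmap.values):
        if np.isfinite(v):
            ax.annotate(f"{v:.3g}", grid.coords[i], ha="center", va="center", fontsize=4)
    ax.set_aspect("equal")
    ax.set_axis_off()
    ax.set_title(title or f"{cmap.variable} (p = {cmap.p_value:.4g})")
    fig.colorbar(sc, ax=ax, shrink=0.7)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
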