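"""Circular batch self-organizing map over a hexagonal district grid.

The map is a disc of hexagonally packed districts (a center cell plus R
concentric rings; ring k holds 6k districts, so 1 + 3R(R+1) in total).
Training is the deterministic batch Kohonen algorithm: every epoch each row
is assigned to its best-matching district (BMU) and each prototype is reset
to the Gaussian-neighborhood-weighted mean of the assigned rows, with the
neighborhood radius decaying linearly from R to 1.  The map is trained on
standardized input variables only — outcome columns are refused at the
standardization step, which is what makes the downstream survival analysis
an honest split-by-variable design.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

_HEX_NEIGHBORS = ((1, 0), (1, -1), (0, -1), (-1, 0), (-1, 1), (0, 1))


@dataclass(frozen=True)
class SOMGrid:
    """Hexagonal disc lattice: ids, ring indices, 2-D coordinates, adjacency, distances."""

    rings: int
    coords: np.ndarray          # (n_districts, 2) planar coordinates
    ring_index: np.ndarray      # (n_districts,) hex distance from center
    adjacency: np.ndarray       # (n_districts, n_districts) boolean, symmetric
    distances: np.ndarray       # (n_districts, n_districts) Euclidean grid distances

    @property
    def n_districts(self) -> int:
        return self.coords.shape[0]


def build_grid(rings: int) -> SOMGrid:
    """Disc of 1 + 3R(R+1) hexagonal districts; ids ordered center-out by ring."""
    if rings < 0:
        raise ValueError("rings must be >= 0")
    cells = []
    for q in range(-rings, rings + 1):
        for r in range(-rings, rings + 1):
            ring = (abs(q) + abs(r) + abs(q + r)) // 2
            if ring <= rings:
                x = q + r / 2.0
                y = r * np.sqrt(3.0) / 2.0
                angle = np.arctan2(y, x) % (2 * np.pi)
                cells.append((ring, angle, q, r, x, y))
    cells.sort(key=lambda c: (c[0], c[1]))
    coords = np.array([[c[4], c[5]] for c in cells])
    ring_index = np.array([c[0] for c in cells], dtype=int)
    axial = {(c[2], c[3]): i for i, c in enumerate(cells)}
    n = len(cells)
    adjacency = np.zeros((n, n), dtype=bool)
    for (q, r), i in axial.items():
        for dq, dr in _HEX_NEIGHBORS:
            j = axial.get((q + dq, r + dr))
            if j is not None:
                adjacency[i, j] = adjacency[j, i] = True
    diff = coords[:, None, :] - coords[None, :, :]
    distances = np.sqrt((diff**2).sum(-1))
    return SOMGrid(rings=rings, coords=coords, ring_index=ring_index,
                   adjacency=adjacency, distances=distances)


@dataclass(frozen=True)
class Standardizer:
    """Per-variable centering/scaling learned from the training cohort."""

    variables: tuple
    center: np.ndarray
    scale: np.ndarray

    def transform(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return (x - self.center) / self.scale

    def inverse(self, z: np.ndarray) -> np.ndarray:
        return np.asarray(z, dtype=float) * self.scale + self.center


_OUTCOME_SUFFIXES = ("_event", "_time")


def standardize_features(table: pd.DataFrame, variables) -> tuple[np.ndarray, Standardizer]:
    """Standardize the named columns to mean 0, SD 1.

    Refuses outcome columns (``*_event``/``*_time``) so the training matrix
    provably excludes the outcome set, refuses missing values (complete-case
    filtering belongs upstream) and zero-variance columns.
    """
    variables = tuple(variables)
    for v in variables:
        if v not in table.columns:
            raise ValueError(f"variable {v!r} not in table")
        if v.endswith(_OUTCOME_SUFFIXES):
            raise ValueError(f"outcome column {v!r} may not enter SOM training")
    x = table[list(variables)].to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("missing values present; apply complete-case filter first")
    center = x.mean(axis=0)
    scale = x.std(axis=0)
    bad = np.where(scale <= 0)[0]
    if bad.size:
        raise ValueError(f"zero-variance variable(s): {[variables[i] for i in bad]}")
    return (x - center) / scale, Standardizer(variables=variables, center=center, scale=scale)


@dataclass(frozen=True)
class TrainedSOM:
    grid: SOMGrid
    prototypes: np.ndarray        # (n_districts, n_variables), standardized space
    standardizer: Standardizer
    training_history: tuple       # quantization error per epoch
    variables: tuple
    seed: int
    epochs: int
    occupancy: np.ndarray = None  # final training BMU counts per district


def _bmu_all(matrix: np.ndarray, prototypes: np.ndarray) -> np.ndarray:
    # argmin over Euclidean distance; ties resolve to the smallest id
    from scipy.spatial.distance import cdist

    return cdist(matrix, prototypes, "sqeuclidean").argmin(axis=1)


def train_som(matrix: np.ndarray, grid: SOMGrid, epochs: int = 50, seed: int = 0) -> TrainedSOM:
    """Batch Kohonen training; deterministic given matrix, grid, epochs and seed.

    Prototypes are initialized on the plane spanned by the top two principal
    components of the training matrix (plus small seeded jitter), giving a
    rotation-meaningful, reproducible starting configuration.  Districts
    that receive zero neighborhood weight in an epoch keep their previous
    prototype.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] == 0:
        raise ValueError("matrix must be a nonempty 2-D array")
    if not np.isfinite(matrix).all():
        raise ValueError("matrix contains non-finite values")
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    n, p = matrix.shape
    nd = grid.n_districts
    rng = np.random.default_rng(seed)

    centered = matrix - matrix.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    scale_r = max(grid.rings, 1)
    sd = s / np.sqrt(n)
    proto = np.zeros((nd, p))
    proto += (grid.coords[:, 0:1] / scale_r) * sd[0] * vt[0][None, :]
    if p >= 2 and len(sd) >= 2:
        proto += (grid.coords[:, 1:2] / scale_r) * sd[1] * vt[1][None, :]
    proto += 0.01 * rng.standard_normal((nd, p))
    proto += matrix.mean(axis=0)

    history = []
    for e in range(epochs):
        if epochs == 1:
            sigma = max(grid.rings, 1.0)
        else:
            sigma = grid.rings + (1.0 - grid.rings) * e / (epochs - 1)
        sigma = max(sigma, 0.5)
        bmu = _bmu_all(matrix, proto)
        h = np.exp(-(grid.distances**2) / (2.0 * sigma**2))
        counts = np.bincount(bmu, minlength=nd).astype(float)
        sums = np.zeros((nd, p))
        np.add.at(sums, bmu, matrix)
        den = h @ counts
        num = h @ sums
        nonzero = den > 1e-12
        proto = proto.copy()
        proto[nonzero] = num[nonzero] / den[nonzero, None]
        bmu_after = _bmu_all(matrix, proto)
        d = np.sqrt(((matrix - proto[bmu_after]) ** 2).sum(-1))
        history.append(float(d.mean()))

    return TrainedSOM(
        grid=grid,
        prototypes=proto,
        standardizer=Standardizer(variables=(), center=np.zeros(p), scale=np.ones(p)),
        training_history=tuple(history),
        variables=(),
        seed=seed,
        epochs=epochs,
        occupancy=np.bincount(bmu_after, minlength=nd).astype(float),
    )


def fit_som(table: pd.DataFrame, variables, rings: int = 5, epochs: int = 50,
            seed: int = 0) -> TrainedSOM:
    """Standardize ``variables`` from ``table``, build the grid, and train."""
    matrix, std = standardize_features(table, variables)
    grid = build_grid(rings)
    som = train_som(matrix, grid, epochs=epochs, seed=seed)
    return TrainedSOM(
        grid=som.grid,
        prototypes=som.prototypes,
        standardizer=std,
        training_history=som.training_history,
        variables=tuple(variables),
        seed=seed,
        epochs=epochs,
        occupancy=som.occupancy,
    )


def assign_bmu(som: TrainedSOM, standardized_row: np.ndarray) -> int:
    """Best-matching district of one standardized row; ties go to the smaller id."""
    row = np.asarray(standardized_row, dtype=float)
    if row.shape != (som.prototypes.shape[1],):
        raise ValueError(
            f"row has {row.shape} values, expected {som.prototypes.shape[1]}"
        )
    d2 = ((som.prototypes - row) ** 2).sum(-1)
    return int(d2.argmin())


def project_cohort(som: TrainedSOM, table: pd.DataFrame) -> np.ndarray:
    """Assign every participant to a district using the TRAINING standardizer.

    The standardizer is never refit, so a map trained on one cohort applies
    unchanged to an external cohort.
    """
    missing = [v for v in som.variables if v not in table.columns]
    if missing:
        raise ValueError(f"table lacks training variables: {missing}")
    x = table[list(som.variables)].to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("missing values present; apply complete-case filter first")
    z = som.standardizer.transform(x)
    return _bmu_all(z, som.prototypes)


def quantization_error(som: TrainedSOM, matrix: np.ndarray) -> float:
    """Mean Euclidean distance from each row to its BMU prototype."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[1] != som.prototypes.shape[1]:
        raise ValueError("matrix width must match the number of training variables")
    bmu = _bmu_all(matrix, som.prototypes)
    return float(np.sqrt(((matrix - som.prototypes[bmu]) ** 2).sum(-1)).mean())


# ---------------------------------------------------------------------------
# Map bundle serialization (YAML descriptor + prototype CSV + checksum)
# ---------------------------------------------------------------------------

def save_som(som: TrainedSOM, directory: str | Path) -> Path:
    """Write the trained map as ``som.yaml`` + ``prototypes.csv`` under ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    proto_path = directory / "prototypes.csv"
    pd.DataFrame(som.prototypes, columns=list(som.variables) or
                 [f"v{i}" for i in range(som.prototypes.shape[1])]).to_csv(
        proto_path, index=False)
    digest = hashlib.sha256(proto_path.read_bytes()).hexdigest()
    doc = {
        "rings": int(som.grid.rings),
        "variables": list(som.variables),
        "seed": int(som.seed),
        "epochs": int(som.epochs),
        "training_history": [float(q) for q in som.training_history],
        "standardizer": {
            "center": [float(c) for c in som.standardizer.center],
            "scale": [float(s) for s in som.standardizer.scale],
        },
        "occupancy": None if som.occupancy is None else [float(c) for c in som.occupancy],
        "prototypes_sha256": digest,
    }
    (directory / "som.yaml").write_text(yaml.safe_dump(doc, sort_keys=False))
    return directory


def load_som(directory: str | Path) -> TrainedSOM:
    """Load a map bundle, verifying the prototype checksum."""
    directory = Path(directory)
    doc = yaml.safe_load((directory / "som.yaml").read_text())
    proto_path = directory / "prototypes.csv"
    digest = hashlib.sha256(proto_path.read_bytes()).hexdigest()
    if digest != doc["prototypes_sha256"]:
        raise ValueError("map bundle integrity check failed: prototype checksum mismatch")
    prototypes = pd.read_csv(proto_path).to_numpy(dtype=float)
    variables = tuple(doc["variables"])
    std = Standardizer(
        variables=variables,
        center=np.asarray(doc["standardizer"]["center"], dtype=float),
        scale=np.asarray(doc["standardizer"]["scale"], dtype=float),
    )
    occ = doc.get("occupancy")
    return TrainedSOM(
        grid=build_grid(int(doc["rings"])),
        prototypes=prototypes,
        standardizer=std,
        training_history=tuple(doc["training_history"]),
        variables=variables,
        seed=int(doc["seed"]),
        epochs=int(doc["epochs"]),
        occupancy=None if occ is None else np.asarray(occ, dtype=float),
    )
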