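"""Synthetic randomized-trial cohorts with planted archetype structure.

Generates SPRINT/ACCORD-like participant tables: a mixture of Framingham-
risk-score (FRS) profile archetypes, 1:1 randomization to intensive vs
standard blood-pressure control, exponential event times with archetype-by-
arm hazard ratios, administrative censoring, and optional MCAR missingness
for complete-case filtering.  The hidden archetype labels and the planted
per-archetype log hazard ratios are retained so downstream recovery tests
have an exact oracle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

#: The seven FRS components used as SOM training variables.
FRS_COMPONENTS = ("female", "age", "tc", "hdl", "sbp", "antihypertensive", "smoker")

#: Continuous vs binary split of the FRS components.
FRS_CONTINUOUS = ("age", "sbp", "tc", "hdl")
FRS_BINARY = ("female", "antihypertensive", "smoker")

#: Additional pretreatment covariates carried for adjustment and balance checks.
ADJUSTMENT_COVARIATES = (
    "race_black",
    "bmi",
    "statin",
    "aspirin",
    "egfr",
    "glucose",
    "triglycerides",
    "uacr",
    "cvd_history",
)

#: The six cardiovascular endpoints, each analyzed with the identical procedure.
ENDPOINTS = ("mi", "non_mi_acs", "stroke", "hf", "cvd_death", "composite")

#: Column holding the hidden archetype label (the planted truth).
TRUTH_COLUMN = "archetype"

ARMS = ("standard", "intensive")

# Cohort-level covariate distributions (means/SDs or prevalences), shared
# across archetypes; these mirror a high-CVD-risk hypertensive population.
_COVARIATE_CONT = {
    "bmi": (29.9, 5.8),
    "egfr": (71.6, 20.7),
    "glucose": (98.9, 13.8),
    "triglycerides": (126.0, 84.0),
    "uacr": (42.5, 166.0),
}
_COVARIATE_BIN = {
    "race_black": 0.319,
    "statin": 0.439,
    "aspirin": 0.510,
    "cvd_history": 0.203,
}


@dataclass(frozen=True)
class ArchetypeSpec:
    """One FRS-profile archetype of the mixture.

    cont_means/cont_sds map the continuous FRS components (age years,
    sbp mmHg, tc mg/dL, hdl mg/dL) to their within-archetype Gaussian
    parameters; bin_prevs maps the binary components (female,
    antihypertensive, smoker) to Bernoulli prevalences.  ``cont_corr`` is an
    optional correlation matrix (ordered as FRS_CONTINUOUS) inducing
    within-archetype correlation between the continuous components.
    """

    label: str
    cont_means: dict
    cont_sds: dict
    bin_prevs: dict
    weight: float
    cont_corr: np.ndarray | None = None

    def validate(self) -> None:
        for v in FRS_CONTINUOUS:
            if v not in self.cont_means or v not in self.cont_sds:
                raise ValueError(f"archetype {self.label!r}: missing continuous component {v!r}")
            if self.cont_sds[v] <= 0:
                raise ValueError(f"archetype {self.label!r}: SD for {v!r} must be > 0")
        for v in FRS_BINARY:
            p = self.bin_prevs.get(v)
            if p is None or not (0.0 <= p <= 1.0):
                raise ValueError(f"archetype {self.label!r}: prevalence for {v!r} must be in [0,1]")
        if not (0.0 <= self.weight <= 1.0):
            raise ValueError(f"archetype {self.label!r}: weight must be in [0,1]")


@dataclass(frozen=True)
class OutcomeSpec:
    """Event-time law for one endpoint.

    base_rate: events per person-year in the standard arm, either a scalar
    or a mapping archetype label -> rate.  log_hr_treatment: log hazard
    ratio of intensive vs standard, scalar or per-archetype mapping.
    Event time is exponential with rate base_rate * exp(log_hr * arm),
    administratively censored at admin_censor_time years.
    """

    endpoint: str
    base_rate: float | dict
    log_hr_treatment: float | dict = 0.0
    admin_censor_time: float = 3.26

    def validate(self, labels: tuple) -> None:
        if self.endpoint not in ENDPOINTS:
            raise ValueError(
                f"unknown endpoint {self.endpoint!r}; expected one of {ENDPOINTS}"
            )
        if self.admin_censor_time <= 0:
            raise ValueError("admin_censor_time must be > 0")
        for lab in labels:
            if self.rate_for(lab) <= 0:
                raise ValueError(f"base_rate must be > 0 (endpoint {self.endpoint!r})")

    def rate_for(self, label: str) -> float:
        if isinstance(self.base_rate, dict):
            return float(self.base_rate[label])
        return float(self.base_rate)

    def log_hr_for(self, label: str) -> float:
        if isinstance(self.log_hr_treatment, dict):
            return float(self.log_hr_treatment[label])
        return float(self.log_hr_treatment)


@dataclass(frozen=True)
class CohortSpec:
    """Full specification of one synthetic randomized cohort."""

    n: int
    archetypes: tuple
    outcomes: tuple
    arm_ratio: float = 0.5
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n < 0:
            raise ValueError("n must be >= 0")
        if not (0.0 < self.arm_ratio < 1.0):
            raise ValueError("arm_ratio must be in (0,1)")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0,1)")
        total = sum(a.weight for a in self.archetypes)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"archetype weights sum to {total}, not 1")
        labels = tuple(a.label for a in self.archetypes)
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate archetype labels")
        for a in self.archetypes:
            a.validate()
        for o in self.outcomes:
            o.validate(labels)

    # -- YAML round trip -------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "n": self.n,
            "arm_ratio": self.arm_ratio,
            "missing_rate": self.missing_rate,
            "seed": self.seed,
            "archetypes": [
                {
                    "label": a.label,
                    "cont_means": {k: float(v) for k, v in a.cont_means.items()},
                    "cont_sds": {k: float(v) for k, v in a.cont_sds.items()},
                    "bin_prevs": {k: float(v) for k, v in a.bin_prevs.items()},
                    "weight": float(a.weight),
                    "cont_corr": None if a.cont_corr is None else np.asarray(a.cont_corr).tolist(),
                }
                for a in self.archetypes
            ],
            "outcomes": [
                {
                    "endpoint": o.endpoint,
                    "base_rate": _plain(o.base_rate),
                    "log_hr_treatment": _plain(o.log_hr_treatment),
                    "admin_censor_time": float(o.admin_censor_time),
                }
                for o in self.outcomes
            ],
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortSpec":
        doc = yaml.safe_load(Path(path).read_text())
        archetypes = tuple(
            ArchetypeSpec(
                label=a["label"],
                cont_means=a["cont_means"],
                cont_sds=a["cont_sds"],
                bin_prevs=a["bin_prevs"],
                weight=a["weight"],
                cont_corr=None if a.get("cont_corr") is None else np.asarray(a["cont_corr"]),
            )
            for a in doc["archetypes"]
        )
        outcomes = tuple(
            OutcomeSpec(
                endpoint=o["endpoint"],
                base_rate=o["base_rate"],
                log_hr_treatment=o.get("log_hr_treatment", 0.0),
                admin_censor_time=o.get("admin_censor_time", 3.26),
            )
            for o in doc["outcomes"]
        )
        return cls(
            n=doc["n"],
            archetypes=archetypes,
            outcomes=outcomes,
            arm_ratio=doc.get("arm_ratio", 0.5),
            missing_rate=doc.get("missing_rate", 0.0),
            seed=doc.get("seed", 0),
        )


def _plain(value):
    """Plain-python scalars/dicts for YAML serialization."""
    if isinstance(value, dict):
        return {k: float(v) for k, v in value.items()}
    return float(value)


def cohort_columns(outcomes: tuple) -> list:
    """Canonical column order of a CohortTable."""
    cols = ["id", "arm"]
    cols += list(FRS_COMPONENTS)
    cols += list(ADJUSTMENT_COVARIATES)
    for o in outcomes:
        cols += [f"{o.endpoint}_event", f"{o.endpoint}_time"]
    cols.append(TRUTH_COLUMN)
    return cols


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a cohort table from ``spec``; byte-identical given the same seed.

    Archetype membership is multinomial on the weights; continuous FRS
    components are Gaussian within archetype (optionally correlated),
    binaries Bernoulli; the arm is Bernoulli(arm_ratio) independent of
    covariates; each endpoint's time is exponential under proportional
    hazards with administrative censoring.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    labels_all = np.array([a.label for a in spec.archetypes])
    weights = np.array([a.weight for a in spec.archetypes], dtype=float)
    weights = weights / weights.sum()

    out = pd.DataFrame(index=pd.RangeIndex(n))
    out["id"] = np.arange(1, n + 1)
    arm_ind = (rng.random(n) < spec.arm_ratio).astype(int)
    out["arm"] = np.where(arm_ind == 1, "intensive", "standard")

    member = rng.choice(len(spec.archetypes), size=n, p=weights)
    archetype = labels_all[member] if n else np.array([], dtype=object)

    cont = np.empty((n, len(FRS_CONTINUOUS)))
    binm = np.empty((n, len(FRS_BINARY)))
    for k, a in enumerate(spec.archetypes):
        mask = member == k
        m = int(mask.sum())
        mu = np.array([a.cont_means[v] for v in FRS_CONTINUOUS])
        sd = np.array([a.cont_sds[v] for v in FRS_CONTINUOUS])
        if a.cont_corr is None:
            cont[mask] = mu + sd * rng.standard_normal((m, len(FRS_CONTINUOUS)))
        else:
            cov = np.outer(sd, sd) * np.asarray(a.cont_corr, dtype=float)
            cont[mask] = rng.multivariate_normal(mu, cov, size=m, method="cholesky")
        prev = np.array([a.bin_prevs[v] for v in FRS_BINARY])
        binm[mask] = (rng.random((m, len(FRS_BINARY))) < prev).astype(float)

    for j, v in enumerate(FRS_BINARY):
        out[v] = binm[:, j].astype(int) if n else np.array([], dtype=int)
    for j, v in enumerate(FRS_CONTINUOUS):
        out[v] = cont[:, j]
    out = out[["id", "arm"] + list(FRS_COMPONENTS)]

    for v, (mu, sd) in _COVARIATE_CONT.items():
        out[v] = mu + sd * rng.standard_normal(n)
    # keep strictly positive scales plausible
    for v in ("egfr", "glucose", "triglycerides"):
        out[v] = np.clip(out[v], 1.0, None)
    out["uacr"] = np.clip(out["uacr"], 0.1, None)
    for v, p in _COVARIATE_BIN.items():
        out[v] = (rng.random(n) < p).astype(int)
    out = out[["id", "arm"] + list(FRS_COMPONENTS) + list(ADJUSTMENT_COVARIATES)]

    for o in spec.outcomes:
        rate = np.array([o.rate_for(a.label) for a in spec.archetypes])[member] if n else np.array([])
        loghr = np.array([o.log_hr_for(a.label) for a in spec.archetypes])[member] if n else np.array([])
        lam = rate * np.exp(loghr * arm_ind)
        raw = rng.exponential(1.0, size=n) / lam if n else np.array([])
        event = (raw <= o.admin_censor_time).astype(int)
        out[f"{o.endpoint}_event"] = event
        out[f"{o.endpoint}_time"] = np.minimum(raw, o.admin_censor_time)

    out[TRUTH_COLUMN] = archetype
    if spec.missing_rate > 0:
        out = inject_missing(out, spec.missing_rate, seed=spec.seed + 1)
    return out


def predictor_columns(table: pd.DataFrame) -> list:
    """FRS components plus adjustment covariates present in ``table``."""
    wanted = list(FRS_COMPONENTS) + list(ADJUSTMENT_COVARIATES)
    return [c for c in wanted if c in table.columns]


def inject_missing(table: pd.DataFrame, rate: float, seed: int) -> pd.DataFrame:
    """Set each predictor cell missing independently with probability ``rate`` (MCAR)."""
    if not (0.0 <= rate < 1.0):
        raise ValueError("rate must be in [0,1)")
    out = table.copy()
    if rate == 0.0:
        return out
    rng = np.random.default_rng(seed)
    cols = predictor_columns(out)
    mask = rng.random((len(out), len(cols))) < rate
    for j, c in enumerate(cols):
        col = out[c].astype(float)
        col[mask[:, j]] = np.nan
        out[c] = col
    return out


def planted_truth(table: pd.DataFrame, spec: CohortSpec | None = None):
    """Hidden archetype labels, and the planted per-archetype log-HRs if a spec is given.

    Returns ``labels`` (a Series aligned with the table) or, when ``spec`` is
    provided, ``(labels, true_log_hrs)`` where ``true_log_hrs[endpoint][label]``
    is the planted treatment log hazard ratio.
    """
    if TRUTH_COLUMN not in table.columns:
        raise ValueError(f"table has no {TRUTH_COLUMN!r} column; not produced by generate_cohort")
    labels = table[TRUTH_COLUMN].copy()
    if spec is None:
        return labels
    true_log_hrs = {
        o.endpoint: {a.label: o.log_hr_for(a.label) for a in spec.archetypes}
        for o in spec.outcomes
    }
    return labels, true_log_hrs


# ---------------------------------------------------------------------------
# Default SPRINT-like specification
# ---------------------------------------------------------------------------

# Archetype mixture mirroring the four map subgroups of a SPRINT-like
# population: I = men with the lowest TC/HDL (highest CVD risk), II = highest
# SBP with little antihypertensive use at baseline, III = women with the
# highest TC/HDL (lowest risk), IV = younger smokers on antihypertensives.
# Weights follow the subgroup share of an 8,773-participant cohort
# (2874/2048/2216/1635); pooled moments approximate the trial's baseline
# table (age 67.9±9.4 y, SBP 139.7±15.8 mmHg, TC 190.4±41.7, HDL 52.9±14.4
# mg/dL, 35.4% female, 90.7% on antihypertensives, 13.5% current smokers).
# Within-archetype SDs are deliberately narrower than the pooled trial SDs:
# the between-archetype spread supplies the remaining variance, so the pooled
# moments match the trial while archetype centroids stay strongly separated
# (~4 or more within-SD on each archetype's defining variables), keeping
# map-based recovery of the planted structure well-posed.  Real cohorts are
# far more overlapping; the separation is a testbed property, not a realism
# claim, and is fully configurable through ArchetypeSpec.
_DEFAULT_ARCHETYPES = (
    ArchetypeSpec(
        label="I",
        cont_means={"age": 71.7, "sbp": 131.9, "tc": 143.6, "hdl": 38.4},
        cont_sds={"age": 5.0, "sbp": 7.0, "tc": 12.0, "hdl": 6.0},
        bin_prevs={"female": 0.03, "antihypertensive": 0.985, "smoker": 0.04},
        weight=2874 / 8773,
    ),
    ArchetypeSpec(
        label="II",
        cont_means={"age": 71.7, "sbp": 165.4, "tc": 192.1, "hdl": 52.2},
        cont_sds={"age": 5.0, "sbp": 7.0, "tc": 12.0, "hdl": 6.0},
        bin_prevs={"female": 0.28, "antihypertensive": 0.65, "smoker": 0.04},
        weight=2048 / 8773,
    ),
    ArchetypeSpec(
        label="III",
        cont_means={"age": 71.7, "sbp": 131.9, "tc": 249.3, "hdl": 72.9},
        cont_sds={"age": 5.0, "sbp": 7.0, "tc": 12.0, "hdl": 6.0},
        bin_prevs={"female": 0.92, "antihypertensive": 0.985, "smoker": 0.04},
        weight=2216 / 8773,
    ),
    ArchetypeSpec(
        label="IV",
        cont_means={"age": 51.3, "sbp": 131.9, "tc": 192.1, "hdl": 52.2},
        cont_sds={"age": 5.0, "sbp": 7.0, "tc": 12.0, "hdl": 6.0},
        bin_prevs={"female": 0.25, "antihypertensive": 0.985, "smoker": 0.55},
        weight=1635 / 8773,
    ),
)

# Crude 3.26-year cumulative incidences per endpoint and archetype, converted
# to exponential rates via rate = -ln(1-p)/t.  Archetype I carries the highest
# event burden, III the lowest, IV the lowest stroke/HF risk.
_INCIDENCE = {
    "mi": {"I": 0.035, "II": 0.030, "III": 0.024, "IV": 0.030},
    "non_mi_acs": {"I": 0.013, "II": 0.011, "III": 0.005, "IV": 0.010},
    "stroke": {"I": 0.024, "II": 0.019, "III": 0.019, "IV": 0.011},
    "hf": {"I": 0.037, "II": 0.023, "III": 0.023, "IV": 0.014},
    "cvd_death": {"I": 0.021, "II": 0.016, "III": 0.009, "IV": 0.012},
    "composite": {"I": 0.101, "II": 0.080, "III": 0.064, "IV": 0.070},
}

_FOLLOW_UP_YEARS = 3.26  # administrative censoring horizon

# Planted treatment effects: intensive control is protective (HR 0.75) for
# every endpoint except non-MI ACS, where the high-SBP/no-medication
# archetype II is harmed (HR 3.62) and the others are null.
_PROTECTIVE_LOG_HR = float(np.log(0.75))
_ACS_LOG_HR = {"I": 0.0, "II": float(np.log(3.62)), "III": 0.0, "IV": 0.0}


def _rates_from_incidence(p_by_label: dict, t: float) -> dict:
    return {lab: float(-np.log(1.0 - p) / t) for lab, p in p_by_label.items()}


def default_sprint_spec(
    n: int = 9361, missing_rate: float = 0.0, seed: int = 20220203
) -> CohortSpec:
    """Four-archetype SPRINT-like cohort spec with planted non-MI-ACS harm in archetype II."""
    outcomes = tuple(
        OutcomeSpec(
            endpoint=e,
            base_rate=_rates_from_incidence(_INCIDENCE[e], _FOLLOW_UP_YEARS),
            log_hr_treatment=_ACS_LOG_HR if e == "non_mi_acs" else _PROTECTIVE_LOG_HR,
            admin_censor_time=_FOLLOW_UP_YEARS,
        )
        for e in ENDPOINTS
    )
    return CohortSpec(
        n=n,
        archetypes=_DEFAULT_ARCHETYPES,
        outcomes=outcomes,
        arm_ratio=0.5,
        missing_rate=missing_rate,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# CSV I/O with seed metadata
# ---------------------------------------------------------------------------

def write_cohort(table: pd.DataFrame, path: str | Path, seed: int | None = None) -> None:
    """Write a cohort CSV plus a ``<path>.meta.json`` sidecar recording the seed."""
    path = Path(path)
    table.to_csv(path, index=False)
    meta = {"n": int(len(table)), "columns": list(table.columns)}
    if seed is not None:
        meta["seed"] = int(seed)
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=1))


def read_cohort(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
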