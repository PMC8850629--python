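"""Per-subgroup treatment effects, heterogeneity testing, and risk arithmetic.

One code path serves every endpoint: a Cox proportional-hazards model of
intensive vs standard treatment (Efron tie handling, Wald intervals) is fit
inside each subgroup, Cochran's Q tests whether the subgroup log hazard
ratios share a common value, and absolute risk reduction (ARR) with the
number needed to harm/treat (NNH/NNT) is computed from crude cumulative
event proportions.  Nelson-Aalen cumulative hazards and baseline t-test /
chi-square comparison tables round out the reporting.  No multiplicity
adjustment is applied across endpoints; results are reported as-is.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: Adjustment sets.  The default follows the methods-text set (sex, age,
#: race, smoking, BMI, antihypertensive use); the forest-figure variant
#: replaces antihypertensive use with statin use.  Model 2 of the
#: sensitivity analysis adjusts for the lipid panel only.
METHODS_ADJUSTMENT = ("female", "age", "race_black", "smoker", "bmi", "antihypertensive")
FIG3_ADJUSTMENT = ("female", "age", "race_black", "smoker", "bmi", "statin")
MODEL2_ADJUSTMENT = ("tc", "hdl", "triglycerides")

_Z95 = 1.959963984540054  # normal 97.5% quantile for 95% Wald intervals


@dataclass(frozen=True)
class CoxFit:
    """Treatment-term Cox fit inside one (sub)cohort."""

    summary: pd.DataFrame        # per-covariate coef, se, hr, ci, p
    log_hr: float                # treatment-term log hazard ratio
    se: float
    hr: float
    ci: tuple
    p: float
    n: int
    events: int
    converged: bool
    monotone: bool               # no events in one arm -> unbounded CI
    adjustment_set: tuple

    @property
    def usable(self) -> bool:
        return self.converged and not self.monotone and np.isfinite(self.se) and self.se > 0


@dataclass(frozen=True)
class RiskDifference:
    arr_pct: float               # 100 * (standard incidence - intensive incidence)
    nnh: float | None            # defined when ARR < 0 (intensive harms)
    nnt: float | None            # defined when ARR > 0 (intensive protects)


@dataclass(frozen=True)
class HTEResult:
    endpoint: str
    fits: dict                   # subgroup label -> CoxFit
    excluded: tuple              # labels excluded from Q (unusable fits)
    q: float
    df: int
    p: float
    risk: pd.DataFrame           # per-subgroup counts, ARR%, NNH/NNT


@dataclass(frozen=True)
class HazardCurve:
    arm: str
    times: np.ndarray
    cumulative_hazard: np.ndarray   # Nelson-Aalen steps, nondecreasing from 0
    at_risk: np.ndarray


def _treatment_indicator(table: pd.DataFrame, arm_column: str = "arm") -> np.ndarray:
    return (table[arm_column] == "intensive").to_numpy(dtype=float)


def fit_cox(table: pd.DataFrame, endpoint: str, treatment_term: str = "arm",
            adjustment_set=METHODS_ADJUSTMENT) -> CoxFit:
    """Cox PH fit of intensive vs standard treatment for one endpoint.

    Maximizes the Efron partial likelihood by Newton iterations and reports
    Wald standard errors and 95% CIs.  With no events in one arm the
    likelihood is monotone in the treatment coefficient: the fit is flagged
    and the CI reported as unbounded rather than fabricating a finite SE.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    dur, ev = f"{endpoint}_time", f"{endpoint}_event"
    for c in (dur, ev):
        if c not in table.columns:
            raise ValueError(f"endpoint column {c!r} missing")
    cols = [dur, ev] + list(adjustment_set)
    df = table[cols].copy()
    df["treatment"] = _treatment_indicator(table, treatment_term)
    if df.isna().any().any():
        raise ValueError("missing values in model columns; filter complete cases first")
    # constant covariates carry no information and break the Newton step
    for c in list(adjustment_set):
        if df[c].nunique() < 2:
            df = df.drop(columns=c)
    n, events = len(df), int(df[ev].sum())
    if events < 2:
        raise ValueError(f"endpoint {endpoint!r}: fewer than 2 events")

    ev_by_arm = df.groupby("treatment")[ev].sum()
    if len(ev_by_arm) < 2 or (ev_by_arm == 0).any():
        empty = pd.DataFrame(columns=["coef", "se", "hr", "ci_low", "ci_high", "p"])
        return CoxFit(summary=empty, log_hr=np.nan, se=np.inf, hr=np.nan,
                      ci=(0.0, np.inf), p=np.nan, n=n, events=events,
                      converged=False, monotone=True,
                      adjustment_set=tuple(adjustment_set))

    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col=dur, event_col=ev,
                    fit_options={"precision": 1e-11, "max_steps": 500})
    except ConvergenceError:
        empty = pd.DataFrame(columns=["coef", "se", "hr", "ci_low", "ci_high", "p"])
        return CoxFit(summary=empty, log_hr=np.nan, se=np.inf, hr=np.nan,
                      ci=(0.0, np.inf), p=np.nan, n=n, events=events,
                      converged=False, monotone=False,
                      adjustment_set=tuple(adjustment_set))

    coef = cph.params_
    se = cph.standard_errors_
    if not np.isfinite(coef).all() or np.abs(coef).max() > 20:
        # quasi-separation: a coefficient ran away although the optimizer stopped
        empty = pd.DataFrame(columns=["coef", "se", "hr", "ci_low", "ci_high", "p"])
        return CoxFit(summary=empty, log_hr=np.nan, se=np.inf, hr=np.nan,
                      ci=(0.0, np.inf), p=np.nan, n=n, events=events,
                      converged=False, monotone=False,
                      adjustment_set=tuple(adjustment_set))
    summary = pd.DataFrame({
        "coef": coef,
        "se": se,
        "hr": np.exp(coef),
        "ci_low": np.exp(coef - _Z95 * se),
        "ci_high": np.exp(coef + _Z95 * se),
        "p": 2.0 * stats.norm.sf(np.abs(coef / se)),
    })
    b, s = float(coef["treatment"]), float(se["treatment"])
    return CoxFit(
        summary=summary, log_hr=b, se=s, hr=float(np.exp(b)),
        ci=(float(np.exp(b - _Z95 * s)), float(np.exp(b + _Z95 * s))),
        p=float(2.0 * stats.norm.sf(abs(b / s))), n=n, events=events,
        converged=True, monotone=False, adjustment_set=tuple(adjustment_set),
    )


def cochran_q(log_hrs, ses):
    """Cochran's Q heterogeneity test over k effect estimates.

    w_i = 1/se_i^2, pooled = sum(w theta)/sum(w), Q = sum(w (theta-pooled)^2),
    p from the upper tail of chi-square with k-1 df.
    """
    theta = np.asarray(log_hrs, dtype=float)
    se = np.asarray(ses, dtype=float)
    if theta.shape != se.shape or theta.ndim != 1:
        raise ValueError("log_hrs and ses must be equal-length vectors")
    k = theta.size
    if k < 2:
        raise ValueError("Cochran's Q needs at least 2 estimates")
    if (se <= 0).any() or not np.isfinite(se).all():
        raise ValueError("standard errors must be positive and finite")
    w = 1.0 / se**2
    pooled = float((w * theta).sum() / w.sum())
    q = float((w * (theta - pooled) ** 2).sum())
    df = k - 1
    p = float(stats.chi2.sf(q, df))
    return q, df, p


def arr_nnh(events_int: int, n_int: int, events_std: int, n_std: int) -> RiskDifference:
    """ARR% = 100*(standard incidence - intensive incidence); NNH/NNT = 1/|ARR|.

    Negative ARR means the intensive arm had more events (harm, NNH);
    positive ARR means benefit (NNT); zero leaves both undefined.
    Incidences are crude cumulative proportions events/n.
    """
    if n_int <= 0 or n_std <= 0:
        raise ValueError("denominators must be > 0")
    if events_int > n_int or events_std > n_std or events_int < 0 or events_std < 0:
        raise ValueError("event counts must lie in [0, n]")
    frac = events_std / n_std - events_int / n_int
    nnh = 1.0 / abs(frac) if frac < 0 else None
    nnt = 1.0 / frac if frac > 0 else None
    return RiskDifference(arr_pct=100.0 * frac, nnh=nnh, nnt=nnt)


def incidence_percent(events: int, n: int, decimals: int = 1) -> float:
    """Crude cumulative incidence as the printed percentage (e.g. 17/1016 -> 1.7)."""
    if n <= 0:
        raise ValueError("denominator must be > 0")
    return round(100.0 * events / n, decimals)


def subgroup_hte(table: pd.DataFrame, participant_labels, endpoint: str,
                 adjustment_set=METHODS_ADJUSTMENT) -> HTEResult:
    """Per-subgroup Cox fits, Cochran's Q across usable subgroups, ARR/NNH per subgroup."""
    labels = np.asarray(participant_labels, dtype=object)
    if len(labels) != len(table):
        raise ValueError("participant labels must cover the whole table")
    fits, excluded, risk_rows = {}, [], []
    ev = f"{endpoint}_event"
    for g in sorted(set(labels)):
        sub = table.loc[labels == g]
        intensive = sub["arm"] == "intensive"
        e_int, n_int = int(sub.loc[intensive, ev].sum()), int(intensive.sum())
        e_std, n_std = int(sub.loc[~intensive, ev].sum()), int((~intensive).sum())
        if n_int and n_std:
            rd = arr_nnh(e_int, n_int, e_std, n_std)
            risk_rows.append({"subgroup": g, "events_intensive": e_int, "n_intensive": n_int,
                              "events_standard": e_std, "n_standard": n_std,
                              "arr_pct": rd.arr_pct, "nnh": rd.nnh, "nnt": rd.nnt})
        try:
            fit = fit_cox(sub, endpoint, adjustment_set=adjustment_set)
        except ValueError:
            excluded.append(g)
            continue
        fits[g] = fit
        if not fit.usable:
            excluded.append(g)
    if excluded:
        warnings.warn(
            f"endpoint {endpoint!r}: subgroups excluded from Q: {sorted(excluded)}",
            stacklevel=2,
        )
    usable = {g: f for g, f in fits.items() if f.usable}
    if len(usable) < 2:
        raise ValueError(
            f"endpoint {endpoint!r}: fewer than 2 usable subgroups; Q undefined"
        )
    q, df, p = cochran_q([f.log_hr for f in usable.values()],
                         [f.se for f in usable.values()])
    return HTEResult(endpoint=endpoint, fits=fits, excluded=tuple(sorted(excluded)),
                     q=q, df=df, p=p, risk=pd.DataFrame(risk_rows))


def cumulative_hazard(table: pd.DataFrame, endpoint: str, mask=None) -> dict:
    """Nelson-Aalen cumulative hazard H(t) = sum d_i/n_i per arm.

    ``mask`` restricts to a subgroup; returns {arm: HazardCurve}.
    """
    from lifelines import NelsonAalenFitter

    sub = table if mask is None else table.loc[np.asarray(mask, dtype=bool)]
    dur, ev = f"{endpoint}_time", f"{endpoint}_event"
    curves = {}
    for arm in ("standard", "intensive"):
        part = sub.loc[sub["arm"] == arm]
        if len(part) == 0:
            raise ValueError(f"no participants in arm {arm!r}")
        naf = NelsonAalenFitter(nelson_aalen_smoothing=False)
        naf.fit(part[dur], event_observed=part[ev])
        ch = naf.cumulative_hazard_.iloc[:, 0]
        at_risk = naf.event_table["at_risk"].reindex(ch.index).to_numpy(dtype=float)
        curves[arm] = HazardCurve(arm=arm, times=ch.index.to_numpy(dtype=float),
                                  cumulative_hazard=ch.to_numpy(dtype=float),
                                  at_risk=at_risk)
    return curves


def baseline_table(table: pd.DataFrame, grouping: str = "arm",
                   variables=None) -> pd.DataFrame:
    """Between-group baseline comparison: pooled-variance t-test for continuous
    variables, Pearson chi-square (no continuity correction) for binaries.
    """
    from .subgroups import _is_binary

    groups = sorted(table[grouping].dropna().unique())
    if len(groups) != 2:
        raise ValueError("baseline table requires exactly two groups")
    g1 = table[table[grouping] == groups[0]]
    g2 = table[table[grouping] == groups[1]]
    if variables is None:
        variables = [c for c in table.columns
                     if c not in ("id", grouping) and table[c].dtype.kind in "if"]
    rows = []
    for v in variables:
        x1, x2 = g1[v].dropna(), g2[v].dropna()
        if _is_binary(table[v]):
            obs = np.array([[x1.sum(), len(x1) - x1.sum()],
                            [x2.sum(), len(x2) - x2.sum()]], dtype=float)
            if (obs.sum(axis=0) == 0).any():
                p = 1.0
            else:
                _, p, _, _ = stats.chi2_contingency(obs, correction=False)
            fmt1 = f"{int(x1.sum())} ({100 * x1.mean():.1f})"
            fmt2 = f"{int(x2.sum())} ({100 * x2.mean():.1f})"
        else:
            if len(x1) < 2 or len(x2) < 2:
                raise ValueError(f"variable {v!r}: group with n < 2 for t-test")
            _, p = stats.ttest_ind(x1, x2, equal_var=True)
            fmt1 = f"{x1.mean():.1f} ± {x1.std(ddof=1):.1f}"
            fmt2 = f"{x2.mean():.1f} ± {x2.std(ddof=1):.1f}"
        rows.append({"variable": v, str(groups[0]): fmt1, str(groups[1]): fmt2,
                     "p": float(p)})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SensitivityResult:
    model1: HTEResult            # no confounders
    model2: HTEResult            # lipid-panel adjustment
    primary: HTEResult | None
    stable: bool                 # heterogeneity call (Q p < alpha) agrees across models
    alpha: float


def sensitivity_models(table: pd.DataFrame, participant_labels, endpoint: str,
                       primary: HTEResult | None = None,
                       alpha: float = 0.05) -> SensitivityResult:
    """Rerun the subgroup HTE with no confounders (model 1) and with the
    lipid panel TC/HDL/triglycerides (model 2); report whether the
    heterogeneity conclusion is stable across models."""
    m1 = subgroup_hte(table, participant_labels, endpoint, adjustment_set=())
    m2 = subgroup_hte(table, participant_labels, endpoint, adjustment_set=MODEL2_ADJUSTMENT)
    calls = [m1.p < alpha, m2.p < alpha]
    if primary is not None:
        calls.append(primary.p < alpha)
    return SensitivityResult(model1=m1, model2=m2, primary=primary,
                             stable=len(set(calls)) == 1, alpha=alpha)


def hte_forest_frame(result: HTEResult) -> pd.DataFrame:
    """Forest-table export: subgroup, HR, CI, p, ARR%, NNH/NNT."""
    rows = []
    risk = result.risk.set_index("subgroup") if len(result.risk) else None
    for g, f in sorted(result.fits.items()):
        row = {"subgroup": g, "n": f.n, "events": f.events, "hr": f.hr,
               "ci_low": f.ci[0], "ci_high": f.ci[1], "p": f.p,
               "usable": f.usable}
        if risk is not None and g in risk.index:
            row["arr_pct"] = risk.loc[g, "arr_pct"]
            row["nnh"] = risk.loc[g, "nnh"]
            row["nnt"] = risk.loc[g, "nnt"]
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["q"] = result.q
    out.attrs["q_p"] = result.p
    return out
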