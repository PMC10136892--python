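"""Progression-free survival: Kaplan-Meier, log-rank, Cox PH.

PFS is time from treatment start to progression or death; subjects lost to
follow-up are censored at last contact. Estimation is delegated to lifelines
(product-limit estimator, Mantel-Cox log-rank, Cox partial likelihood with
Efron tie handling — months-resolution times tie often); this module wraps it
behind the pipeline's result types and adds the threshold-dichotomized
analysis with optional TPS-subgroup restriction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank

from .errors import DegenerateSplitError, NoEventsError


@dataclass
class KmCurve:
    """Product-limit estimate: right-continuous step function S(t)."""

    event_times: np.ndarray      # times where S drops
    survival: np.ndarray         # S after each event time
    at_risk: np.ndarray          # risk-set size just before each event time
    censor_times: np.ndarray
    n: int


@dataclass
class CoxFit:
    beta: float
    hr: float
    ci_low: float
    ci_high: float
    p: float
    n_events: int
    converged: bool


def _check_times(times: np.ndarray) -> None:
    if np.any(times < 0):
        raise ValueError("survival times must be nonnegative")


def km_estimate(times, events) -> KmCurve:
    """Kaplan-Meier product-limit estimator."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    _check_times(times)
    if times.size == 0:
        raise ValueError("need at least one subject")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    ev = kmf.event_table
    drops = ev.index.to_numpy()[ev["observed"].to_numpy() > 0]
    surv = kmf.survival_function_["KM_estimate"]
    survival = np.array([float(surv.loc[t]) for t in drops])
    at_risk = np.array([int(ev.loc[t, "at_risk"]) for t in drops])
    return KmCurve(
        event_times=drops.astype(float),
        survival=survival,
        at_risk=at_risk,
        censor_times=np.sort(times[~events]),
        n=int(times.size),
    )


def survival_at(curve: KmCurve, t: float) -> float:
    """S(t) of the right-continuous step function (post-jump at event times)."""
    if t < 0:
        raise ValueError("t must be nonnegative")
    idx = np.searchsorted(curve.event_times, t, side="right")
    return 1.0 if idx == 0 else float(curve.survival[idx - 1])


def logrank_test(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Mantel-Cox log-rank test (chi-square with 1 df, p-value)."""
    times_a = np.asarray(times_a, float)
    times_b = np.asarray(times_b, float)
    events_a = np.asarray(events_a).astype(bool)
    events_b = np.asarray(events_b).astype(bool)
    if times_a.size == 0 or times_b.size == 0:
        raise ValueError("both groups must be nonempty")
    if not (events_a.any() or events_b.any()):
        raise NoEventsError("no events in either group")
    res = _ll_logrank(times_a, times_b, event_observed_A=events_a,
                      event_observed_B=events_b)
    return float(res.test_statistic), float(res.p_value)


def cox_fit(times, events, covariate, strata=None) -> CoxFit:
    """Cox proportional-hazards fit for a single covariate (Efron ties).

    ``strata`` gives per-stratum baseline hazards (risk sets never cross
    strata). Monotone-likelihood/separation problems are flagged through
    ``converged=False`` after a penalized retry.
    """
    df = pd.DataFrame({
        "time": np.asarray(times, dtype=float),
        "event": np.asarray(events).astype(int),
        "x": np.asarray(covariate, dtype=float),
    })
    _check_times(df["time"].to_numpy())
    if df["event"].sum() < 1:
        raise NoEventsError("Cox fit needs at least one event")
    if df["x"].nunique() < 2:
        raise ValueError("covariate is constant")
    kwargs = {}
    if strata is not None:
        df["stratum"] = np.asarray(strata)
        kwargs["strata"] = ["stratum"]

    converged = True
    fitter = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=Warning)
            fitter.fit(df, duration_col="time", event_col="event", **kwargs)
    except (ConvergenceError, Warning, np.linalg.LinAlgError):
        converged = False
        fitter = CoxPHFitter(penalizer=0.1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitter.fit(df, duration_col="time", event_col="event", **kwargs)

    s = fitter.summary.loc["x"]
    return CoxFit(
        beta=float(s["coef"]),
        hr=float(s["exp(coef)"]),
        ci_low=float(s["exp(coef) lower 95%"]),
        ci_high=float(s["exp(coef) upper 95%"]),
        p=float(s["p"]),
        n_events=int(df["event"].sum()),
        converged=converged,
    )


@dataclass
class DichotomyResult:
    threshold: float
    exposure_side: str           # "le": exposure group is value <= threshold
    n_exposed: int
    n_other: int
    km_exposed: KmCurve
    km_other: KmCurve
    chi2: float
    p_logrank: float
    cox: CoxFit
    subgroup: str | None = None


def dichotomized_pfs_analysis(cohort: pd.DataFrame, feature_values: pd.Series,
                              threshold: float, exposure_side: str = "le",
                              subgroup: str | None = None,
                              tps_col: str = "tps_group",
                              strata_col: str | None = None) -> DichotomyResult:
    """KM pair, log-rank and Cox HR for a threshold-dichotomized feature.

    The exposure (low-risk) group is ``value <= threshold`` when
    ``exposure_side='le'`` and ``value > threshold`` otherwise, so a
    protective feature level yields HR < 1. ``subgroup`` restricts the
    analysis to one TPS level.
    """
    if exposure_side not in ("le", "gt"):
        raise ValueError("exposure_side must be 'le' or 'gt'")
    df = cohort.set_index("patient_id") if "patient_id" in cohort.columns else cohort
    values = feature_values.reindex(df.index)
    if values.isna().any():
        raise ValueError("feature values missing for some patients")
    if subgroup is not None:
        keep = df[tps_col] == subgroup
        df, values = df[keep], values[keep]
        if len(df) == 0:
            raise DegenerateSplitError(f"no patients in subgroup {subgroup!r}")
    exposed = (values <= threshold) if exposure_side == "le" else (values > threshold)
    if exposed.all() or not exposed.any():
        raise DegenerateSplitError(
            f"threshold {threshold:.4f} leaves an empty group"
        )
    t = df["pfs_months"].to_numpy(float)
    e = df["event"].to_numpy(bool)
    ex = exposed.to_numpy(bool)
    chi2, p = logrank_test(t[ex], e[ex], t[~ex], e[~ex])
    strata = df[strata_col].to_numpy() if strata_col is not None else None
    cox = cox_fit(t, e, ex.astype(float), strata=strata)
    return DichotomyResult(
        threshold=float(threshold),
        exposure_side=exposure_side,
        n_exposed=int(ex.sum()),
        n_other=int((~ex).sum()),
        km_exposed=km_estimate(t[ex], e[ex]),
        km_other=km_estimate(t[~ex], e[~ex]),
        chi2=chi2,
        p_logrank=p,
        cox=cox,
        subgroup=subgroup,
    )


def plot_km_pair(result: DichotomyResult, ax=None, labels=("low risk", "high risk")):
    """Optional step-plot of the two dichotomized KM curves (needs matplotlib)."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    for curve, label in ((result.km_exposed, labels[0]),
                         (result.km_other, labels[1])):
        t = np.concatenate([[0.0], curve.event_times])
        s = np.concatenate([[1.0], curve.survival])
        ax.step(t, s, where="post", label=label)
    ax.set_xlabel("months")
    ax.set_ylabel("progression-free survival")
    ax.set_ylim(0, 1.02)
    ax.legend()
    return ax
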