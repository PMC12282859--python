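"""Product-limit estimation and cohort description.

Kaplan-Meier survival with Greenwood variance and pointwise 95% bands
on the log(-log) scale (so bands stay inside [0, 1]), step-function
lookups, the no-interpolation median, and the event/censoring
cross-tabulations used to describe a registry cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .cohort import CATEGORICAL, EVENT_COL, Cohort

__all__ = ["KMCurve", "SurvivalPoint", "km_estimate", "survival_at",
           "median_survival", "cohort_summary"]


@dataclass(frozen=True)
class KMCurve:
    """Kaplan-Meier curve evaluated at the distinct event times.

    ``survival`` is right-continuous and piecewise constant; between
    event times it carries the value of the previous event time.
    """

    times: np.ndarray          # distinct event times, increasing
    at_risk: np.ndarray        # number at risk just before each event time
    events: np.ndarray         # events at each time
    survival: np.ndarray       # S(t) at each event time
    variance: np.ndarray       # Greenwood variance of S(t)
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n: int
    censor_times: np.ndarray   # censoring marks
    t_max: float               # largest observed time (event or censored)

    def __post_init__(self) -> None:
        s = self.survival
        if len(s) and (np.any(np.diff(s) > 1e-12) or s[0] > 1.0 + 1e-12):
            raise ValueError("survival must be non-increasing and start at <= 1")

    @property
    def tail_survival(self) -> float:
        """S at the largest observed time (the plateau value)."""
        return float(self.survival[-1]) if len(self.survival) else 1.0


@dataclass(frozen=True)
class SurvivalPoint:
    t: float
    estimate: float
    ci_lower: float
    ci_upper: float
    extrapolated: bool = False


def km_estimate(cohort: Cohort, alpha: float = 0.05) -> KMCurve:
    """Product-limit estimate with Greenwood variance and log(-log) bands.

    Ties between events and censorings at the same instant follow the
    standard risk-set convention: events precede censorings.
    """
    t = cohort.time
    d = cohort.event
    kmf = KaplanMeierFitter(alpha=alpha)
    kmf.fit(t, event_observed=d)

    table = kmf.event_table
    obs = table["observed"].to_numpy()
    at_risk = table["at_risk"].to_numpy()
    mask = obs > 0
    times = table.index.to_numpy(dtype=float)[mask]
    d_i = obs[mask].astype(float)
    n_i = at_risk[mask].astype(float)

    surv = kmf.survival_function_["KM_estimate"].reindex(times).to_numpy()
    ci = kmf.confidence_interval_.reindex(times)
    lo = ci.iloc[:, 0].to_numpy()
    hi = ci.iloc[:, 1].to_numpy()

    # Greenwood: Var S(t) = S(t)^2 * sum_{t_i <= t} d_i / (n_i (n_i - d_i));
    # a term with n_i == d_i drives S to 0 (variance contribution infinite,
    # clamped to 0 variance at S = 0 as usual).
    with np.errstate(divide="ignore", invalid="ignore"):
        incr = d_i / (n_i * (n_i - d_i))
    incr[~np.isfinite(incr)] = 0.0
    var = surv**2 * np.cumsum(incr)

    return KMCurve(
        times=times,
        at_risk=n_i,
        events=d_i,
        survival=surv,
        variance=var,
        ci_lower=np.clip(lo, 0.0, 1.0),
        ci_upper=np.clip(hi, 0.0, 1.0),
        n=cohort.n,
        censor_times=np.sort(t[d == 0]),
        t_max=float(t.max()),
    )


def survival_at(curve: KMCurve, t: float) -> SurvivalPoint:
    """Step-function value at time ``t`` (right-continuous lookup).

    Beyond the largest observed time the tail value is returned flagged
    as extrapolated.
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    idx = np.searchsorted(curve.times, t, side="right") - 1
    if idx < 0:
        return SurvivalPoint(t, 1.0, 1.0, 1.0)
    return SurvivalPoint(
        t=t,
        estimate=float(curve.survival[idx]),
        ci_lower=float(curve.ci_lower[idx]),
        ci_upper=float(curve.ci_upper[idx]),
        extrapolated=bool(t > curve.t_max),
    )


def median_survival(curve: KMCurve) -> float | None:
    """Smallest event time with S <= 0.5; ``None`` when never reached.

    With a large cured fraction the curve plateaus above 0.5 and the
    median is undefined.
    """
    below = np.nonzero(curve.survival <= 0.5)[0]
    if len(below) == 0:
        return None
    return float(curve.times[below[0]])


def cohort_summary(cohort: Cohort) -> dict:
    """Event/censoring counts overall and per categorical covariate.

    Percentages are row percentages rounded to two decimals, matching
    the usual registry table layout.
    """
    n, n_event = cohort.n, cohort.n_events
    n_cens = n - n_event
    out: dict = {
        "n": n,
        "n_events": n_event,
        "n_censored": n_cens,
        "pct_events": round(100.0 * n_event / n, 2),
        "pct_censored": round(100.0 * n_cens / n, 2),
        "by_covariate": {},
    }
    for cov in cohort.schema:
        if cov.kind != CATEGORICAL:
            continue
        df = cohort.data
        tab = pd.crosstab(df[cov.name].astype(str), df[EVENT_COL]).reindex(
            list(cov.levels), fill_value=0)
        for col in (0, 1):
            if col not in tab.columns:
                tab[col] = 0
        tab = tab[[0, 1]]
        tab.columns = ["censored", "events"]
        total = tab.sum(axis=1)
        with np.errstate(invalid="ignore"):
            tab["pct_censored"] = (100.0 * tab["censored"] / total).round(2)
            tab["pct_events"] = (100.0 * tab["events"] / total).round(2)
        out["by_covariate"][cov.name] = tab
    return out
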