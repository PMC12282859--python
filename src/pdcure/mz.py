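"""Maller-Zhou diagnostics for cure-model assumptions.

Two nonparametric procedures used before fitting a cure model:

* a test for the *presence* of an immune (cured) subpopulation based on
  the Kaplan-Meier tail value p_hat_n = S_KM at the largest observed
  time (H0: everyone is susceptible), and
* a *sufficient follow-up* statistic q_n = N_n / n, where N_n counts
  the uncensored times falling in the half-open window
  (2 t_event_max - t_obs_max, t_event_max].

Both compare against critical values that Maller and Zhou tabulated by
simulation under i.i.d. uniform or exponential censoring with
unit-exponential event times.  Only the two published table entries are
bundled; everything else is simulated here, seeded and reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .cohort import Cohort
from .nonparametric import km_estimate

__all__ = [
    "MZCurePresenceResult",
    "MZFollowupResult",
    "MZNullDistribution",
    "mz_cure_presence_test",
    "mz_followup_test",
    "mz_critical_value",
    "simulate_mz_null",
]

# Published critical values, bundled verbatim:
# (n, censoring model, alpha, statistic) -> critical value
CRITICAL_TABLE = {
    (1000, "exponential", 0.05, "p_hat"): 0.940,
    (1000, "uniform", 0.05, "p_hat"): 0.960,
}


@dataclass(frozen=True)
class MZCurePresenceResult:
    p_hat: float
    n: int
    censor_model: str
    alpha: float
    critical_value: float
    reject_h0: bool | None     # True -> evidence of a cured fraction
    method: str                # 'table' or 'simulate'
    null_summary: dict | None = None


@dataclass(frozen=True)
class MZFollowupResult:
    t_event_max: float
    t_obs_max: float
    delta_n: float
    window: tuple[float, float]    # open left, closed right
    n_window_events: int
    q_n: float
    n: int
    critical_value: float
    sufficient: bool | None
    degenerate: bool = False


@dataclass(frozen=True)
class MZNullDistribution:
    values: np.ndarray
    statistic: str
    n: int
    censor_model: str
    reps: int
    seed: int

    def quantile(self, q: float) -> float:
        if self.reps * min(q, 1 - q) < 5:
            warnings.warn(
                f"only {self.reps} replications for the {q} quantile",
                stacklevel=2,
            )
        return float(np.quantile(self.values, q))


def _km_tail(times: np.ndarray, events: np.ndarray) -> float:
    """S_KM at the largest observed time, fast path for simulation."""
    order = np.argsort(times, kind="stable")
    d = events[order].astype(bool)
    n = len(times)
    at_risk = n - np.arange(n)
    factors = 1.0 - d[at_risk > 0] / at_risk[at_risk > 0]
    return float(np.prod(factors[d])) if d.any() else 1.0


def _qn(times: np.ndarray, events: np.ndarray) -> float:
    ev = events.astype(bool)
    if not ev.any():
        return 0.0
    t_event_max = times[ev].max()
    t_obs_max = times.max()
    left = 2.0 * t_event_max - t_obs_max
    inside = ev & (times > left) & (times <= t_event_max)
    return float(inside.sum()) / len(times)


def _match_censoring_param(censor_model: str, censored_fraction: float) -> float:
    """Censoring parameter giving this censored fraction under H0.

    H0 model: unit-exponential event times.  For Exp(mu) censoring the
    censored fraction is mu/(1+mu); for U(0, B] it is (1-exp(-B))/B.
    """
    cf = float(np.clip(censored_fraction, 1e-6, 1 - 1e-6))
    if censor_model == "exponential":
        return cf / (1.0 - cf)
    if censor_model == "uniform":
        return float(optimize.brentq(
            lambda b: (1.0 - np.exp(-b)) / b - cf, 1e-9, 1e4))
    raise ValueError(f"unknown censoring model {censor_model!r}")


def simulate_mz_null(n: int, censor_model: str, reps: int = 1000,
                     seed: int = 0, statistic: str = "p_hat",
                     mu: float = 1.0, B: float = 2.0) -> MZNullDistribution:
    """Empirical null distribution of p_hat_n or q_n.

    Under H0 there is no cured subpopulation: event times are unit
    exponential and censoring is Exp(mu) or U(0, B] as configured.
    """
    if reps < 100:
        raise ValueError("at least 100 replications required")
    if statistic not in ("p_hat", "q_n"):
        raise ValueError(f"unknown statistic {statistic!r}")
    if censor_model not in ("exponential", "uniform"):
        raise ValueError(f"unknown censoring model {censor_model!r}")
    rng = np.random.default_rng(seed)
    stat = _km_tail if statistic == "p_hat" else _qn
    values = np.empty(reps)
    for r in range(reps):
        t_event = rng.exponential(1.0, size=n)
        if censor_model == "exponential":
            c = rng.exponential(1.0 / mu, size=n)
        else:
            c = B * (1.0 - rng.random(n))
        times = np.minimum(t_event, c)
        events = t_event <= c
        values[r] = stat(times, events)
    return MZNullDistribution(values=values, statistic=statistic, n=n,
                              censor_model=censor_model, reps=reps, seed=seed)


def mz_critical_value(n: int, censor_model: str, alpha: float = 0.05,
                      statistic: str = "p_hat", allow_simulation: bool = True,
                      reps: int = 1000, seed: int = 0,
                      mu: float = 1.0, B: float = 2.0) -> float:
    """Critical value for a Maller-Zhou statistic.

    Published table entries are returned verbatim when covered.  For
    sample sizes above 1000 the tabled p_hat critical value approaches
    1 and is returned as exactly 1.  Anything else falls back to a
    seeded null simulation with a warning.
    """
    if censor_model not in ("exponential", "uniform"):
        raise ValueError(f"unknown censoring model {censor_model!r}")
    key = (n, censor_model, alpha, statistic)
    if key in CRITICAL_TABLE:
        return CRITICAL_TABLE[key]
    if statistic == "p_hat" and n > 1000:
        return 1.0
    if not allow_simulation:
        raise KeyError(f"no bundled critical value for {key} and simulation disabled")
    warnings.warn(
        f"no bundled critical value for {key}; simulating the null",
        stacklevel=2,
    )
    null = simulate_mz_null(n, censor_model, reps=reps, seed=seed,
                            statistic=statistic, mu=mu, B=B)
    q = 1.0 - alpha if statistic == "p_hat" else alpha
    return null.quantile(q)


def mz_cure_presence_test(cohort: Cohort, censor_model: str = "exponential",
                          alpha: float = 0.05, method: str = "simulate",
                          reps: int = 1000, seed: int = 0,
                          mu: float | None = None,
                          B: float | None = None) -> MZCurePresenceResult:
    """Test for the existence of a cured fraction (H0: p = 1, no cure).

    p_hat_n is the Kaplan-Meier estimate at the largest observed time.
    The default decision rule is simulation-based: H0 is rejected when
    p_hat_n exceeds the (1 - alpha) quantile of its simulated null
    distribution, with the censoring parameter matched to the cohort's
    censored fraction.  ``method='table'`` reproduces the published
    lookups instead (decision left undetermined when the bundled table
    does not cover the request).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if cohort.n_events == 0:
        return MZCurePresenceResult(
            p_hat=1.0, n=cohort.n, censor_model=censor_model, alpha=alpha,
            critical_value=np.nan, reject_h0=None, method=method)

    curve = km_estimate(cohort)
    p_hat = curve.tail_survival

    if method == "table":
        crit = mz_critical_value(cohort.n, censor_model, alpha,
                                 statistic="p_hat", allow_simulation=False) \
            if (cohort.n, censor_model, alpha, "p_hat") in CRITICAL_TABLE \
            or cohort.n > 1000 else np.nan
        reject = bool(p_hat > crit) if np.isfinite(crit) else None
        return MZCurePresenceResult(p_hat=p_hat, n=cohort.n,
                                    censor_model=censor_model, alpha=alpha,
                                    critical_value=crit, reject_h0=reject,
                                    method="table")
    if method != "simulate":
        raise ValueError(f"unknown method {method!r}")

    cf = cohort.n_censored / cohort.n
    if censor_model == "exponential":
        mu = _match_censoring_param("exponential", cf) if mu is None else mu
        B = 2.0
    else:
        B = _match_censoring_param("uniform", cf) if B is None else B
        mu = 1.0
    null = simulate_mz_null(cohort.n, censor_model, reps=reps, seed=seed,
                            statistic="p_hat", mu=mu, B=B)
    crit = null.quantile(1.0 - alpha)
    return MZCurePresenceResult(
        p_hat=p_hat, n=cohort.n, censor_model=censor_model, alpha=alpha,
        critical_value=crit, reject_h0=bool(p_hat > crit), method="simulate",
        null_summary={"mean": float(null.values.mean()),
                      "q95": float(np.quantile(null.values, 0.95)),
                      "mu": mu, "B": B, "reps": reps})


def mz_followup_test(cohort: Cohort, critical_value: float | None = None,
                     censor_model: str | None = None, alpha: float = 0.05,
                     reps: int = 1000, seed: int = 0) -> MZFollowupResult:
    """Five-step sufficient-follow-up statistic q_n = N_n / n.

    N_n counts uncensored times strictly inside the half-open window
    (2 t_event_max - t_obs_max, t_event_max].  Follow-up is judged
    sufficient when q_n exceeds the critical value.  When no critical
    value is supplied and a censoring model is named, the critical
    value is the alpha quantile of the simulated null; with neither,
    the decision is left undetermined.
    """
    if cohort.n_events == 0:
        raise ValueError("follow-up test needs at least one event")
    t = cohort.time
    d = cohort.event.astype(bool)
    t_event_max = float(t[d].max())
    t_obs_max = float(t.max())
    delta_n = t_obs_max - t_event_max
    left = 2.0 * t_event_max - t_obs_max
    window = (left, t_event_max)
    degenerate = delta_n == 0.0
    if degenerate:
        n_in, q_n = 0, 0.0
    else:
        inside = d & (t > left) & (t <= t_event_max)
        n_in = int(inside.sum())
        q_n = n_in / cohort.n

    crit = critical_value
    if crit is None and censor_model is not None:
        cf = cohort.n_censored / cohort.n
        param = _match_censoring_param(censor_model, cf)
        kwargs = {"mu": param} if censor_model == "exponential" else {"B": param}
        null = simulate_mz_null(cohort.n, censor_model, reps=reps, seed=seed,
                                statistic="q_n", **kwargs)
        crit = null.quantile(alpha)
    sufficient = None if crit is None else bool(q_n > crit)
    return MZFollowupResult(
        t_event_max=t_event_max, t_obs_max=t_obs_max, delta_n=delta_n,
        window=window, n_window_events=n_in, q_n=q_n, n=cohort.n,
        critical_value=np.nan if crit is None else float(crit),
        sufficient=sufficient, degenerate=degenerate)
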