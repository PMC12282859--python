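"""Likelihoods and maximum-likelihood fitting for cure models.

Three model families for right-censored data with a cured fraction:

* ``mixture``      S_pop(t|x) = pi(x) + (1 - pi(x)) S_u(t|x), Weibull
  latency S_u with proportional-hazards covariate effects and a
  complementary log-log (default) incidence model pi(x);
* ``nonmixture``   (promotion-time) S_pop(t|x) = exp(-exp(a0 + x'b) F_u(t)),
  Weibull F_u; the cure fraction exp(-exp(a0 + x'b)) is approached
  asymptotically;
* ``flexible``     log H_pop(t|x) = g0 + s(log t; gamma) + x'b with s a
  restricted cubic spline; with the cure constraint the basis is built
  from reversed log time so the survival curve plateaus *exactly* at
  pi(x) = exp(-exp(g0 + x'b)) beyond the last knot.

Fitting is quasi-Newton on an unconstrained parameterization (log
shape/scale, cloglog or logit cure linear predictor) with seeded
multistart on failure; the covariance is the inverse of the numerically
differentiated observed information at the optimum.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special
from statsmodels.tools import numdiff

from .cohort import CATEGORICAL, CONTINUOUS, Cohort, CovariateSchema
from .nonparametric import km_estimate
from .splines import SplineBasisSpec, cure_basis, default_knots, rcs_basis

__all__ = [
    "CureModelSpec", "CureModelFit", "EffectEstimate", "CureFraction",
    "Design", "build_design", "build_model_design",
    "loglik_mixture", "loglik_nonmixture", "loglik_flexible",
    "fit_cure_model", "cure_fraction", "effect_table", "predict_survival",
    "effects_frame",
]

_PENALTY = 1e12  # optimizer-safe stand-in for -inf log-likelihood


# --------------------------------------------------------------------------
# design matrices
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Design:
    """Design matrix without intercept: dummies for non-reference levels
    of categorical covariates, mean-centered continuous columns."""

    X: np.ndarray
    columns: tuple[str, ...]
    centers: tuple[float, ...]
    blocks: dict  # covariate name -> tuple of column indices

    @property
    def p(self) -> int:
        return self.X.shape[1]


def build_design(cohort_or_df, schema: CovariateSchema,
                 covariates: tuple[str, ...],
                 centers: dict | None = None) -> Design:
    df = cohort_or_df.data if isinstance(cohort_or_df, Cohort) else cohort_or_df
    cols: list[np.ndarray] = []
    names: list[str] = []
    cents: list[float] = []
    blocks: dict[str, tuple[int, ...]] = {}
    for name in covariates:
        if name not in schema:
            raise KeyError(f"unknown covariate {name!r}")
        cov = schema[name]
        start = len(cols)
        if cov.kind == CATEGORICAL:
            values = df[name].astype(str).to_numpy()
            for level in cov.levels[1:]:
                cols.append((values == level).astype(float))
                names.append(f"{name}[{level}]")
                cents.append(0.0)
        else:
            x = np.asarray(df[name], dtype=float)
            c = float(np.mean(x)) if centers is None else centers.get(name, 0.0)
            cols.append(x - c)
            names.append(name)
            cents.append(c)
        blocks[name] = tuple(range(start, len(cols)))
    X = np.column_stack(cols) if cols else np.empty((len(df), 0))
    return Design(X=X, columns=tuple(names), centers=tuple(cents), blocks=blocks)


def _profile_row(design: Design, schema: CovariateSchema,
                 profile: dict | None) -> np.ndarray:
    """Design row for a covariate profile; ``None`` means the reference
    profile (reference categories, continuous covariates at their
    centering values)."""
    x = np.zeros(design.p)
    if profile is None:
        return x
    for j, (colname, center) in enumerate(zip(design.columns, design.centers)):
        if "[" in colname:
            covname, level = colname[:-1].split("[", 1)
            if covname in profile:
                x[j] = 1.0 if str(profile[covname]) == level else 0.0
        else:
            if colname in profile:
                x[j] = float(profile[colname]) - center
    return x


# --------------------------------------------------------------------------
# specs and fit container
# --------------------------------------------------------------------------

FAMILIES = ("mixture", "nonmixture", "flexible")


@dataclass(frozen=True)
class CureModelSpec:
    family: str
    covariates: tuple[str, ...] = ()
    incidence_covariates: tuple[str, ...] = ()   # mixture only
    cure_link: str = "cloglog"
    spline: SplineBasisSpec | None = None        # flexible; None -> from data
    n_interior_knots: int = 2

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.cure_link not in ("cloglog", "logit"):
            raise ValueError(f"unknown cure link {self.cure_link!r}")
        if self.family != "mixture" and self.incidence_covariates:
            raise ValueError("incidence covariates apply to the mixture family only")
        if self.family == "nonmixture" and self.cure_link != "cloglog":
            raise ValueError("the non-mixture family uses the cloglog cure scale")


@dataclass(frozen=True)
class ModelDesign:
    """Per-cohort structures the likelihoods need (basis precomputed)."""

    time: np.ndarray
    event: np.ndarray
    latency: Design
    incidence: Design | None
    spline: SplineBasisSpec | None
    basis_vals: np.ndarray | None
    basis_ders: np.ndarray | None
    u: np.ndarray | None


def build_model_design(spec: CureModelSpec, cohort: Cohort) -> ModelDesign:
    lat = build_design(cohort, cohort.schema, tuple(spec.covariates))
    inc = None
    if spec.family == "mixture":
        inc = build_design(cohort, cohort.schema, tuple(spec.incidence_covariates))
    spline = None
    vals = ders = u = None
    if spec.family == "flexible":
        spline = spec.spline
        if spline is None:
            spline = default_knots(cohort.time[cohort.event == 1],
                                   n_interior=spec.n_interior_knots,
                                   cure_constraint=True)
        u = np.log(cohort.time)
        vals, ders = (cure_basis if spline.cure_constraint else rcs_basis)(u, spline)
    return ModelDesign(time=cohort.time, event=cohort.event.astype(bool),
                       latency=lat, incidence=inc, spline=spline,
                       basis_vals=vals, basis_ders=ders, u=u)


@dataclass
class CureModelFit:
    spec: CureModelSpec
    params: np.ndarray
    param_names: tuple[str, ...]
    cov: np.ndarray | None
    loglik: float
    n: int
    n_events: int
    converged: bool
    message: str
    design: ModelDesign = field(repr=False)
    schema: CovariateSchema = field(repr=False)

    @property
    def k(self) -> int:
        """Number of free parameters."""
        return len(self.params)

    def _beta_slice(self) -> slice:
        p = self.design.latency.p
        return slice(self.k - p, self.k) if p else slice(self.k, self.k)


# --------------------------------------------------------------------------
# link helpers (cure probability scale)
# --------------------------------------------------------------------------

def _log_pi_terms(eta: np.ndarray, link: str) -> tuple[np.ndarray, np.ndarray]:
    """Return (log pi, log(1 - pi)) stably for the given link."""
    if link == "cloglog":
        x = np.exp(eta)
        log_pi = -x
        log_1m = np.log(-np.expm1(-x))
    else:  # logit
        log_pi = -np.logaddexp(0.0, -eta)
        log_1m = -np.logaddexp(0.0, eta)
    return log_pi, log_1m


def _link_inv(eta: float, link: str) -> float:
    return float(np.exp(-np.exp(eta)) if link == "cloglog" else special.expit(eta))


# --------------------------------------------------------------------------
# log-likelihoods
# --------------------------------------------------------------------------

def _split_mixture(params: np.ndarray, md: ModelDesign):
    p_inc = md.incidence.p if md.incidence is not None else 0
    a0 = params[0]
    b_inc = params[1:1 + p_inc]
    log_shape, log_scale = params[1 + p_inc], params[2 + p_inc]
    beta = params[3 + p_inc:]
    return a0, b_inc, log_shape, log_scale, beta


def loglik_mixture(params, cohort_or_md, design: ModelDesign | None = None,
                   link: str = "cloglog") -> float:
    """Mixture-cure log-likelihood.

    params = [cure intercept, incidence coefs, log shape, log scale,
    latency coefs]; event contribution d log[(1-pi) f_u] and censored
    contribution log[pi + (1-pi) S_u].  Invalid parameters yield -inf
    (never an exception during a fit).
    """
    md = _resolve_md(cohort_or_md, design, "mixture")
    params = np.asarray(params, dtype=float)
    if not np.all(np.isfinite(params)):
        return -np.inf
    a0, b_inc, log_shape, log_scale, beta = _split_mixture(params, md)
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        eta_c = a0 + (md.incidence.X @ b_inc if md.incidence is not None
                      and md.incidence.p else 0.0)
        log_pi, log_1m = _log_pi_terms(np.broadcast_to(eta_c, md.time.shape), link)
        k = np.exp(log_shape)
        logt = np.log(md.time)
        log_z = k * (logt - log_scale) + (md.latency.X @ beta if md.latency.p else 0.0)
        z = np.exp(log_z)
        d = md.event
        ll_event = log_1m[d] + log_shape - logt[d] + log_z[d] - z[d]
        ll_cens = np.logaddexp(log_pi[~d], log_1m[~d] - z[~d])
        out = ll_event.sum() + ll_cens.sum()
    return float(out) if np.isfinite(out) else -np.inf


def loglik_nonmixture(params, cohort_or_md, design: ModelDesign | None = None,
                      link: str = "cloglog") -> float:
    """Non-mixture (promotion-time) log-likelihood.

    S_pop(t|x) = exp(-theta(x) F_u(t)) with theta(x) = exp(a0 + x'b)
    and Weibull F_u, so h(t|x) = theta(x) f_u(t); params =
    [a0, log shape, log scale, coefs].
    """
    md = _resolve_md(cohort_or_md, design, "nonmixture")
    params = np.asarray(params, dtype=float)
    if not np.all(np.isfinite(params)):
        return -np.inf
    a0, log_shape, log_scale = params[0], params[1], params[2]
    beta = params[3:]
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        log_theta = np.broadcast_to(
            a0 + (md.latency.X @ beta if md.latency.p else 0.0), md.time.shape)
        theta = np.exp(log_theta)
        k = np.exp(log_shape)
        logt = np.log(md.time)
        log_z0 = k * (logt - log_scale)
        z0 = np.exp(log_z0)
        F = -np.expm1(-z0)
        d = md.event
        log_f = log_shape - logt + log_z0 - z0
        out = np.sum(log_theta[d] + log_f[d]) - np.sum(theta * F)
    return float(out) if np.isfinite(out) else -np.inf


def loglik_flexible(params, cohort_or_md, design: ModelDesign | None = None,
                    spline: SplineBasisSpec | None = None) -> float:
    """Flexible (spline log-cumulative-hazard) log-likelihood.

    log H(t|x) = g0 + sum_j gamma_j v_j(log t) + x'b; contribution
    d [log s'(log t) - log t + log H] - H.  A non-positive spline slope
    at any event time gives -inf (the hazard must be positive).
    """
    md = _resolve_md(cohort_or_md, design, "flexible", spline)
    params = np.asarray(params, dtype=float)
    if not np.all(np.isfinite(params)):
        return -np.inf
    J = md.basis_vals.shape[1]
    g0, gamma = params[0], params[1:1 + J]
    beta = params[1 + J:]
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        eta = g0 + md.basis_vals @ gamma + (md.latency.X @ beta if md.latency.p else 0.0)
        sprime = md.basis_ders @ gamma
        d = md.event
        if np.any(sprime[d] <= 0.0):
            return -np.inf
        H = np.exp(eta)
        out = np.sum(np.log(sprime[d]) - md.u[d] + eta[d]) - H.sum()
    return float(out) if np.isfinite(out) else -np.inf


def _resolve_md(cohort_or_md, design, family: str,
                spline: SplineBasisSpec | None = None) -> ModelDesign:
    if isinstance(cohort_or_md, ModelDesign):
        return cohort_or_md
    if design is not None:
        return design
    spec = CureModelSpec(family=family, spline=spline)
    return build_model_design(spec, cohort_or_md)


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FitOptions:
    initial: np.ndarray | None = None
    max_iter: int = 500
    gtol: float = 1e-7
    seed: int = 0
    n_starts: int = 5


def _initial_values(spec: CureModelSpec, cohort: Cohort, md: ModelDesign) -> np.ndarray:
    curve = km_estimate(cohort)
    s_tail = float(np.clip(curve.tail_survival, 1e-4, 1.0 - 1e-4))
    t_events = cohort.time[cohort.event == 1]
    if spec.family in ("mixture", "nonmixture"):
        eta0 = (np.log(-np.log(s_tail)) if spec.cure_link == "cloglog"
                else special.logit(s_tail))
        log_scale = float(np.log(np.median(t_events)) + 0.35)
        head = [eta0] + [0.0] * (md.incidence.p if md.incidence is not None else 0) \
            if spec.family == "mixture" else [eta0]
        return np.array(head + [0.0, log_scale] + [0.0] * md.latency.p)
    # flexible: regress cloglog KM on the basis at event times
    s = curve.survival
    keep = (s > 1e-8) & (s < 1.0 - 1e-8)
    u_ev = np.log(curve.times[keep])
    y = np.log(-np.log(s[keep]))
    vals, _ = (cure_basis if md.spline.cure_constraint else rcs_basis)(u_ev, md.spline)
    A = np.column_stack([np.ones(len(u_ev)), vals])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return np.concatenate([coef, np.zeros(md.latency.p)])


def fit_cure_model(spec: CureModelSpec, cohort: Cohort,
                   options: FitOptions | None = None) -> CureModelFit:
    """Maximize the family's log-likelihood by quasi-Newton search.

    Initialization comes from the Kaplan-Meier curve (tail value on the
    cure scale; cloglog regression on the spline basis for the flexible
    family); on failure up to ``n_starts`` seeded perturbed restarts
    are tried and the best optimum kept.  The covariance is the inverse
    numerically differentiated observed information; when it is
    singular the fit is returned with ``cov=None``.  Deterministic
    given the options.
    """
    opts = options or FitOptions()
    if cohort.n_events == 0:
        raise ValueError("cannot fit a cure model with zero events")
    md = build_model_design(spec, cohort)
    rank_X = np.linalg.matrix_rank(np.column_stack(
        [np.ones(cohort.n), md.latency.X])) if md.latency.p else 1
    if rank_X < md.latency.p + 1:
        raise ValueError("latency design matrix is rank deficient")

    if spec.family == "mixture":
        def ll(x): return loglik_mixture(x, md, link=spec.cure_link)
    elif spec.family == "nonmixture":
        def ll(x): return loglik_nonmixture(x, md, link=spec.cure_link)
    else:
        def ll(x): return loglik_flexible(x, md)

    def negll(x: np.ndarray) -> float:
        v = ll(x)
        return -v if np.isfinite(v) else _PENALTY

    x0 = np.asarray(opts.initial, dtype=float) if opts.initial is not None \
        else _initial_values(spec, cohort, md)
    spline_spec = dataclasses.replace(spec, spline=md.spline) \
        if spec.family == "flexible" else spec

    rng = np.random.default_rng(opts.seed)
    best = None
    start = x0
    for attempt in range(opts.n_starts + 1):
        if negll(start) < _PENALTY:
            res = optimize.minimize(negll, start, method="BFGS",
                                    options={"gtol": opts.gtol,
                                             "maxiter": opts.max_iter})
            if best is None or res.fun < best.fun:
                best = res
            if res.fun < _PENALTY and res.success:
                break
        start = x0 + rng.normal(scale=0.3, size=x0.shape) * (1.0 + np.abs(x0))
    if best is None or best.fun >= _PENALTY:
        raise RuntimeError("no valid starting point found for the optimizer")

    xopt = best.x
    converged = bool(best.success or
                     np.max(np.abs(best.jac)) < 1e-3 * max(1.0, abs(best.fun)))
    cov = None
    try:
        hess = numdiff.approx_hess(xopt, negll)
        hess = 0.5 * (hess + hess.T)
        cov = np.linalg.inv(hess)
        cov = 0.5 * (cov + cov.T)
        if not np.all(np.isfinite(cov)) or np.any(np.diag(cov) < 0):
            cov = None
    except np.linalg.LinAlgError:
        cov = None

    names = _param_names(spec, md)
    return CureModelFit(spec=spline_spec, params=xopt, param_names=names,
                        cov=cov, loglik=-float(best.fun), n=cohort.n,
                        n_events=cohort.n_events, converged=converged,
                        message=str(best.message), design=md,
                        schema=cohort.schema)


def _param_names(spec: CureModelSpec, md: ModelDesign) -> tuple[str, ...]:
    beta_names = tuple(f"latency[{c}]" for c in md.latency.columns)
    if spec.family == "mixture":
        inc = tuple(f"cure[{c}]" for c in (md.incidence.columns if md.incidence else ()))
        return ("cure_intercept",) + inc + ("log_shape", "log_scale") + beta_names
    if spec.family == "nonmixture":
        return ("cure_intercept", "log_shape", "log_scale") + beta_names
    J = md.basis_vals.shape[1]
    return ("gamma0",) + tuple(f"gamma{j}" for j in range(1, J + 1)) + beta_names


# --------------------------------------------------------------------------
# derived quantities
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CureFraction:
    estimate: float
    ci_lower: float
    ci_upper: float
    eta: float
    se: float
    ci_available: bool = True


def _cure_eta_and_grad(fit: CureModelFit, profile: dict | None):
    """Linear predictor on the cure scale at a profile, with gradient."""
    md, spec = fit.design, fit.spec
    k = fit.k
    if spec.family == "mixture":
        x = _profile_row(md.incidence, fit.schema, profile)
        grad = np.zeros(k)
        grad[0] = 1.0
        grad[1:1 + md.incidence.p] = x
        eta = fit.params[0] + x @ fit.params[1:1 + md.incidence.p]
        return float(eta), grad
    x = _profile_row(md.latency, fit.schema, profile)
    grad = np.zeros(k)
    grad[0] = 1.0
    grad[fit._beta_slice()] = x
    eta = fit.params[0] + x @ fit.params[fit._beta_slice()]
    return float(eta), grad


def cure_fraction(fit: CureModelFit, profile: dict | None = None,
                  alpha: float = 0.05) -> CureFraction:
    """Cure fraction at a covariate profile with a Wald CI.

    The interval is computed on the linear-predictor (cure link) scale
    and transformed, so the bounds stay inside (0, 1).  For the
    flexible family the plateau value is exp(-exp(g0 + x'b)) -- the
    spline contribution vanishes at and beyond the last knot.
    """
    eta, grad = _cure_eta_and_grad(fit, profile)
    link = fit.spec.cure_link if fit.spec.family == "mixture" else "cloglog"
    est = _link_inv(eta, link)
    if fit.cov is None:
        return CureFraction(est, np.nan, np.nan, eta, np.nan, ci_available=False)
    se = float(np.sqrt(grad @ fit.cov @ grad))
    z = -special.ndtri(alpha / 2.0)
    bounds = sorted((_link_inv(eta - z * se, link), _link_inv(eta + z * se, link)))
    return CureFraction(est, bounds[0], bounds[1], eta, se)


@dataclass(frozen=True)
class EffectEstimate:
    covariate: str
    level: str | None
    coef: float
    se: float
    p_value: float
    hr: float
    ci_lower: float
    ci_upper: float
    cure_ratio: float
    reference: bool = False


def effect_table(fit: CureModelFit, alpha: float = 0.05) -> list[EffectEstimate]:
    """Per-coefficient effects on the latency log-hazard scale.

    HR = exp(beta), CI = exp(beta -/+ z se), Wald p, and the
    conventional per-category cure ratio exp(-exp(beta)).  Reference
    categories are included with beta = 0, HR = 1.
    """
    md = fit.design
    beta = fit.params[fit._beta_slice()]
    ses = np.full(md.latency.p, np.nan)
    if fit.cov is not None and md.latency.p:
        ses = np.sqrt(np.diag(fit.cov)[fit._beta_slice()])
    z = -special.ndtri(alpha / 2.0)
    rows: list[EffectEstimate] = []
    for covname, idxs in md.latency.blocks.items():
        cov = fit.schema[covname]
        if cov.kind == CATEGORICAL:
            rows.append(EffectEstimate(covname, cov.reference, 0.0, 0.0, np.nan,
                                       1.0, 1.0, 1.0,
                                       float(np.exp(-np.exp(0.0))), reference=True))
        for j in idxs:
            b, se = float(beta[j]), float(ses[j])
            level = None
            colname = md.latency.columns[j]
            if "[" in colname:
                level = colname[:-1].split("[", 1)[1]
            wald_p = float(2.0 * special.ndtr(-abs(b / se))) if se > 0 else np.nan
            rows.append(EffectEstimate(
                covariate=covname, level=level, coef=b, se=se, p_value=wald_p,
                hr=float(np.exp(b)),
                ci_lower=float(np.exp(b - z * se)),
                ci_upper=float(np.exp(b + z * se)),
                cure_ratio=float(np.exp(-np.exp(b)))))
    return rows


def effects_frame(rows: list[EffectEstimate]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in rows])


def predict_survival(fit: CureModelFit, t, profile: dict | None = None) -> np.ndarray:
    """Population survival S_pop(t | profile) for the fitted family.

    Monotone non-increasing in t and bounded below by the profile's
    cure fraction (exactly equal to it beyond the plateau).
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t <= 0):
        raise ValueError("t must be positive")
    md, spec = fit.design, fit.spec
    x = _profile_row(md.latency, fit.schema, profile)
    xb = float(x @ fit.params[fit._beta_slice()]) if md.latency.p else 0.0
    if spec.family == "mixture":
        a0, b_inc, log_shape, log_scale, _ = _split_mixture(fit.params, md)
        xi = _profile_row(md.incidence, fit.schema, profile)
        pi = _link_inv(float(a0 + xi @ b_inc), spec.cure_link)
        z = np.exp(np.exp(log_shape) * (np.log(t) - log_scale) + xb)
        return pi + (1.0 - pi) * np.exp(-z)
    if spec.family == "nonmixture":
        a0, log_shape, log_scale = fit.params[:3]
        z0 = np.exp(np.exp(log_shape) * (np.log(t) - log_scale))
        theta = np.exp(a0 + xb)
        return np.exp(-theta * (-np.expm1(-z0)))
    J = md.basis_vals.shape[1]
    g0, gamma = fit.params[0], fit.params[1:1 + J]
    u = np.log(t)
    vals, _ = (cure_basis if md.spline.cure_constraint else rcs_basis)(u, md.spline)
    eta = g0 + vals @ gamma + xb
    return np.exp(-np.exp(eta))
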