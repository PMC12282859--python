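"""Model-building workflow: information criteria, univariate screening,
backward elimination and the end-to-end analysis report.

Categorical covariates enter and leave the model as whole dummy blocks
and are judged by joint Wald chi-square tests.  Backward elimination
removes, at each step, the single covariate with the largest p-value
strictly above the removal threshold, refits, and repeats until every
remaining covariate is below the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort
from .models import (CureModelFit, CureModelSpec, FitOptions, cure_fraction,
                     effect_table, effects_frame, fit_cure_model)

__all__ = [
    "information_criteria", "compare_models", "wald_block_test",
    "univariate_screen", "backward_eliminate", "run_full_analysis",
    "SelectionTrace", "SelectionStep",
]


def information_criteria(fit: CureModelFit) -> dict:
    """AIC = -2 loglik + 2k and BIC = -2 loglik + k log n, exact."""
    aic = -2.0 * fit.loglik + 2.0 * fit.k
    bic = -2.0 * fit.loglik + fit.k * np.log(fit.n)
    return {"AIC": float(aic), "BIC": float(bic)}


def compare_models(fits: dict | list, labels: list[str] | None = None) -> pd.DataFrame:
    """Comparison table ranked by AIC (ties: BIC, then label).

    All fits must come from the same cohort; differing n is refused.
    """
    if isinstance(fits, dict):
        labels = list(fits.keys())
        fits = list(fits.values())
    else:
        labels = labels or [f.spec.family for f in fits]
    ns = {f.n for f in fits}
    if len(ns) > 1:
        raise ValueError(f"fits come from cohorts of differing size: {sorted(ns)}")
    rows = []
    for label, f in zip(labels, fits):
        ic = information_criteria(f)
        rows.append({"model": label, "df": f.k, "loglik": f.loglik,
                     "AIC": ic["AIC"], "BIC": ic["BIC"]})
    table = pd.DataFrame(rows).sort_values(
        ["AIC", "BIC", "model"], kind="stable").reset_index(drop=True)
    table.index = pd.RangeIndex(1, len(table) + 1, name="rank")
    return table


def wald_block_test(fit: CureModelFit, covariate: str) -> float:
    """Joint Wald chi-square p-value for a covariate's dummy block."""
    md = fit.design
    if covariate not in md.latency.blocks:
        raise KeyError(f"covariate {covariate!r} is not in the fitted model")
    if fit.cov is None:
        return np.nan
    local = np.asarray(md.latency.blocks[covariate])
    offset = fit._beta_slice().start
    idx = local + offset
    b = fit.params[idx]
    v = fit.cov[np.ix_(idx, idx)]
    try:
        w = float(b @ np.linalg.solve(v, b))
    except np.linalg.LinAlgError:
        return np.nan
    return float(stats.chi2.sf(w, df=len(idx)))


def univariate_screen(cohort: Cohort, candidates: tuple[str, ...],
                      family: str = "flexible",
                      options: FitOptions | None = None) -> pd.DataFrame:
    """Fit each candidate alone and assemble the screening table.

    One row per non-reference coefficient with Wald p, HR and CI, plus
    the candidate's joint block p-value.  Non-convergent fits are
    reported as such, never dropped silently.
    """
    rows = []
    for cand in candidates:
        if cand not in cohort.schema:
            raise KeyError(f"unknown candidate {cand!r}")
        cov = cohort.schema[cand]
        if cov.kind == "categorical":
            observed = cohort.data[cand].astype(str).nunique()
            if observed < 2:
                raise ValueError(f"candidate {cand!r} has a single observed level")
        spec = CureModelSpec(family=family, covariates=(cand,))
        try:
            fit = fit_cure_model(spec, cohort, options)
        except (RuntimeError, ValueError) as exc:
            rows.append({"covariate": cand, "level": None, "coef": np.nan,
                         "se": np.nan, "p_value": np.nan, "hr": np.nan,
                         "ci_lower": np.nan, "ci_upper": np.nan,
                         "joint_p": np.nan, "converged": False,
                         "note": str(exc)})
            continue
        joint = wald_block_test(fit, cand)
        for r in effect_table(fit):
            if r.reference:
                continue
            rows.append({"covariate": cand, "level": r.level, "coef": r.coef,
                         "se": r.se, "p_value": r.p_value, "hr": r.hr,
                         "ci_lower": r.ci_lower, "ci_upper": r.ci_upper,
                         "joint_p": joint, "converged": fit.converged,
                         "note": ""})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SelectionStep:
    removed: str
    p_value: float
    loglik_before: float
    loglik_after: float


@dataclass
class SelectionTrace:
    remove_above: float
    final_alpha: float
    steps: list[SelectionStep] = field(default_factory=list)
    final_variables: tuple[str, ...] = ()


def backward_eliminate(cohort: Cohort, candidates: tuple[str, ...],
                       remove_above: float = 0.1, final_alpha: float = 0.05,
                       family: str = "flexible",
                       options: FitOptions | None = None
                       ) -> tuple[CureModelFit, SelectionTrace]:
    """Backward elimination by joint Wald p-values.

    Starting from the full model, repeatedly remove the covariate with
    the largest p-value strictly above ``remove_above`` (whole dummy
    blocks at once) and refit, until none remains.  An empty final set
    returns the covariate-free null model.  Deterministic.
    """
    if not candidates:
        raise ValueError("at least one candidate required")
    current = list(candidates)
    trace = SelectionTrace(remove_above=remove_above, final_alpha=final_alpha)

    def fit_set(names: list[str]) -> CureModelFit:
        spec = CureModelSpec(family=family, covariates=tuple(names))
        return fit_cure_model(spec, cohort, options)

    fit = fit_set(current)
    if not fit.converged:
        raise RuntimeError("full model did not converge; elimination aborted")
    while current:
        pvals = {c: wald_block_test(fit, c) for c in current}
        worst = max(pvals, key=lambda c: (np.nan_to_num(pvals[c], nan=1.0)))
        p_worst = pvals[worst]
        effective = 1.0 if np.isnan(p_worst) else p_worst
        if effective <= remove_above:
            break
        current.remove(worst)
        new_fit = fit_set(current) if current else fit_set([])
        trace.steps.append(SelectionStep(removed=worst, p_value=float(effective),
                                         loglik_before=fit.loglik,
                                         loglik_after=new_fit.loglik))
        fit = new_fit
    trace.final_variables = tuple(current)
    return fit, trace


def run_full_analysis(cohort: Cohort, config=None) -> dict:
    """Execute the full analysis sequence and return the report bundle.

    Order: cohort summary; Kaplan-Meier curve with median and
    fixed-time survival; both Maller-Zhou diagnostics; covariate-free
    fits of all three families with the comparison table; univariate
    screening; backward elimination; final effect table and cure
    fraction.  Fully seeded through the analysis configuration.
    """
    from .mz import mz_cure_presence_test, mz_followup_test
    from .nonparametric import cohort_summary, km_estimate, median_survival, survival_at
    from .reporting import AnalysisConfig

    cfg = config or AnalysisConfig()
    opts = FitOptions(seed=cfg.seed)
    bundle: dict = {"seed": cfg.seed, "config": cfg.to_dict()}

    bundle["summary"] = cohort_summary(cohort)
    curve = km_estimate(cohort)
    med = median_survival(curve)
    bundle["km"] = {
        "median_years": med,
        "survival_at": {t: survival_at(curve, t).estimate
                        for t in cfg.survival_times},
        "tail_survival": curve.tail_survival,
        "t_max": curve.t_max,
    }
    bundle["mz_presence"] = mz_cure_presence_test(
        cohort, censor_model=cfg.mz_censor_model, alpha=cfg.alpha,
        reps=cfg.mz_reps, seed=cfg.seed)
    bundle["mz_followup"] = mz_followup_test(
        cohort, censor_model=cfg.mz_censor_model, alpha=cfg.alpha,
        reps=cfg.mz_reps, seed=cfg.seed)

    fits = {}
    for family in ("mixture", "nonmixture", "flexible"):
        fits[family] = fit_cure_model(CureModelSpec(family=family), cohort, opts)
    bundle["null_fits"] = fits
    bundle["comparison"] = compare_models(fits)
    bundle["null_cure_fraction"] = cure_fraction(fits["flexible"])

    candidates = tuple(cfg.candidates) if cfg.candidates else ()
    if candidates:
        bundle["univariate"] = univariate_screen(
            cohort, candidates, family=cfg.family, options=opts)
        final_fit, trace = backward_eliminate(
            cohort, candidates, remove_above=cfg.remove_above,
            final_alpha=cfg.final_alpha, family=cfg.family, options=opts)
        bundle["selection_trace"] = trace
        bundle["final_fit"] = final_fit
        bundle["final_effects"] = effects_frame(effect_table(final_fit))
        bundle["final_cure_fraction"] = cure_fraction(final_fit)
    return bundle
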