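"""Cure-model likelihoods against hand-computed and closed-form values,
family-reduction identities, fitting behavior and derived quantities."""

import dataclasses

import numpy as np
import pytest

from pdcure.models import (CureModelFit, CureModelSpec, FitOptions,
                           build_model_design, cure_fraction, effect_table,
                           effects_frame, fit_cure_model, loglik_flexible,
                           loglik_mixture, loglik_nonmixture, predict_survival)
from pdcure.simulate import (CategoricalSpec, CensoringModel, CureIncidence,
                             Effect, GeneratorConfig, WeibullLatency,
                             generate_cohort, registry_default)
from pdcure.splines import SplineBasisSpec

from conftest import make_cohort

CLOGLOG_HALF = float(np.log(np.log(2.0)))   # eta with pi = 0.5


def weibull_loglik(times, events, shape, scale):
    """Closed-form Weibull log-likelihood (independent oracle)."""
    t = np.asarray(times, float)
    d = np.asarray(events, bool)
    z = (t / scale) ** shape
    log_f = np.log(shape / t[d]) + shape * np.log(t[d] / scale) - z[d]
    return float(log_f.sum() - z[~d].sum())


def random_cohort(seed, n=40):
    rng = np.random.default_rng(seed)
    t = rng.weibull(1.3, n) * 3 + 0.05
    d = rng.integers(0, 2, n)
    d[:3] = 1
    return make_cohort(t, d)


def manual_fit(family, params, cohort=None, spline=None,
               link="cloglog") -> CureModelFit:
    cohort = cohort or make_cohort([1.0], [1])
    spec = CureModelSpec(family=family, spline=spline, cure_link=link)
    md = build_model_design(spec, cohort)
    spec = dataclasses.replace(spec, spline=md.spline)
    return CureModelFit(spec=spec, params=np.asarray(params, float),
                        param_names=("p",) * len(params), cov=None,
                        loglik=0.0, n=cohort.n, n_events=cohort.n_events,
                        converged=True, message="manual", design=md,
                        schema=cohort.schema)


class TestMixtureLikelihood:
    def test_no_cure_limit_is_exponential_density(self):
        # pi ~ 0 via a huge cloglog intercept; unit exponential baseline
        cohort = make_cohort([1.0], [1])
        md = build_model_design(CureModelSpec("mixture"), cohort)
        ll = loglik_mixture([8.0, 0.0, 0.0], md)
        assert ll == pytest.approx(-1.0, abs=1e-12)

    def test_half_cure_censored_hand_value(self):
        cohort = make_cohort([1.0], [0])
        md = build_model_design(CureModelSpec("mixture"), cohort)
        ll = loglik_mixture([CLOGLOG_HALF, 0.0, 0.0], md)
        assert ll == pytest.approx(np.log(0.5 + 0.5 * np.exp(-1)), abs=1e-12)
        assert ll == pytest.approx(-0.37989, abs=1e-5)

    def test_half_cure_event_hand_value(self):
        cohort = make_cohort([1.0], [1])
        md = build_model_design(CureModelSpec("mixture"), cohort)
        ll = loglik_mixture([CLOGLOG_HALF, 0.0, 0.0], md)
        assert ll == pytest.approx(np.log(0.5 * np.exp(-1)), abs=1e-12)
        assert ll == pytest.approx(-1.69315, abs=1e-5)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_zero_cure_reduces_to_weibull(self, seed):
        cohort = random_cohort(seed)
        md = build_model_design(CureModelSpec("mixture"), cohort)
        shape, scale = 1.7, 2.3
        ll = loglik_mixture([9.0, np.log(shape), np.log(scale)], md)
        assert ll == pytest.approx(
            weibull_loglik(cohort.time, cohort.event, shape, scale), abs=1e-8)

    def test_invalid_parameters_give_minus_inf_not_raise(self):
        cohort = make_cohort([1.0], [1])
        md = build_model_design(CureModelSpec("mixture"), cohort)
        assert loglik_mixture([0.0, np.nan, 0.0], md) == -np.inf
        assert loglik_mixture([0.0, 800.0, -800.0], md) == -np.inf


class TestNonmixtureLikelihood:
    def test_censored_hand_value(self):
        cohort = make_cohort([1.0], [0])
        md = build_model_design(CureModelSpec("nonmixture"), cohort)
        ll = loglik_nonmixture([CLOGLOG_HALF, 0.0, 0.0], md)
        assert ll == pytest.approx(np.log(0.5) * (1 - np.exp(-1)), abs=1e-12)
        assert ll == pytest.approx(-0.43815, abs=1e-5)

    def test_event_hand_value(self):
        cohort = make_cohort([1.0], [1])
        md = build_model_design(CureModelSpec("nonmixture"), cohort)
        ll = loglik_nonmixture([CLOGLOG_HALF, 0.0, 0.0], md)
        expected = np.log(-np.log(0.5) * np.exp(-1)) + np.log(0.5) * (1 - np.exp(-1))
        assert ll == pytest.approx(expected, abs=1e-12)
        assert ll == pytest.approx(-1.80466, abs=1e-5)

    def test_early_time_survival_contribution_vanishes(self):
        cohort = make_cohort([1e-9], [0])
        md = build_model_design(CureModelSpec("nonmixture"), cohort)
        assert loglik_nonmixture([0.3, 0.0, 0.0], md) == pytest.approx(0.0, abs=1e-8)


class TestFlexibleLikelihood:
    def test_unit_exponential_reduction(self):
        # 2 unconstrained knots, g0 = 0, g1 = 1 -> H(t) = t
        cohort = make_cohort([1.0], [1])
        spline = SplineBasisSpec((np.log(0.2), np.log(5.0)))
        md = build_model_design(CureModelSpec("flexible", spline=spline), cohort)
        assert loglik_flexible([0.0, 1.0], md) == pytest.approx(-1.0, abs=1e-12)

    @pytest.mark.parametrize("seed,g0,g1", [
        (0, -1.3, 1.4), (1, 0.4, 0.7), (2, -0.2, 2.1), (3, 1.1, 1.0)])
    def test_two_knot_equals_weibull_closed_form(self, seed, g0, g1):
        cohort = random_cohort(seed)
        spline = SplineBasisSpec((np.log(0.01), np.log(50.0)))
        md = build_model_design(CureModelSpec("flexible", spline=spline), cohort)
        shape, scale = g1, np.exp(-g0 / g1)
        assert loglik_flexible([g0, g1], md) == pytest.approx(
            weibull_loglik(cohort.time, cohort.event, shape, scale), abs=1e-8)

    def test_negative_slope_at_event_is_minus_inf(self):
        cohort = make_cohort([1.0, 2.0], [1, 0])
        spline = SplineBasisSpec((np.log(0.2), np.log(5.0)))
        md = build_model_design(CureModelSpec("flexible", spline=spline), cohort)
        assert loglik_flexible([0.0, -1.0], md) == -np.inf


class TestFitting:
    def test_refit_from_optimum_is_stationary(self, registry_cohort):
        fit = fit_cure_model(CureModelSpec("flexible"), registry_cohort,
                             FitOptions(seed=0))
        refit = fit_cure_model(CureModelSpec("flexible"), registry_cohort,
                               FitOptions(seed=0, initial=fit.params))
        np.testing.assert_allclose(refit.params, fit.params, atol=1e-6)
        assert refit.loglik == pytest.approx(fit.loglik, abs=1e-8)

    def test_fit_is_deterministic(self, registry_cohort):
        a = fit_cure_model(CureModelSpec("mixture"), registry_cohort, FitOptions(seed=3))
        b = fit_cure_model(CureModelSpec("mixture"), registry_cohort, FitOptions(seed=3))
        np.testing.assert_array_equal(a.params, b.params)

    def test_zero_events_rejected(self):
        with pytest.raises(ValueError):
            fit_cure_model(CureModelSpec("mixture"),
                           make_cohort([1.0, 2.0], [0, 0]))

    def test_rank_deficient_design_rejected(self, registry_cohort):
        # age twice -> collinear dummies
        with pytest.raises(ValueError, match="rank"):
            fit_cure_model(CureModelSpec(
                "flexible", covariates=("age", "age")), registry_cohort)

    def test_covariate_free_families_have_three_parameters(self, registry_cohort):
        for family in ("mixture", "nonmixture", "flexible"):
            fit = fit_cure_model(CureModelSpec(family), registry_cohort,
                                 FitOptions(seed=0))
            assert fit.k == 3
            assert fit.cov is not None and fit.cov.shape == (3, 3)
            ev = np.linalg.eigvalsh(fit.cov)
            assert np.all(ev > -1e-10)

    def test_no_cure_complete_followup_recovery(self):
        # pi ~ 0 truth with follow-up long enough to observe everyone
        cfg = GeneratorConfig(
            n_subjects=20_000, seed=0,
            cure_model=CureIncidence(intercept=3.0),
            latency_model=WeibullLatency(1.4, 4.0),
            censoring_model=CensoringModel("administrative"),
            study_window_years=60.0)
        cohort = generate_cohort(cfg, seed=9)
        fit = fit_cure_model(CureModelSpec("mixture"), cohort, FitOptions(seed=0))
        assert cure_fraction(fit).estimate < 0.02
        assert np.exp(fit.params[1]) == pytest.approx(1.4, abs=0.05)
        assert np.exp(fit.params[2]) == pytest.approx(4.0, abs=0.1)


class TestCureFraction:
    def test_unit_cloglog_transform(self):
        fit = manual_fit("nonmixture", [0.0, 0.0, 0.0])
        assert cure_fraction(fit).estimate == pytest.approx(np.exp(-1.0))

    @pytest.mark.parametrize("eta,expected", [(0.188, 0.30), (0.043, 0.35)])
    def test_registry_worked_transforms(self, eta, expected):
        fit = manual_fit("nonmixture", [eta, 0.0, 0.0])
        assert round(cure_fraction(fit).estimate, 2) == expected

    def test_ci_inside_unit_interval_and_brackets(self, registry_cohort):
        fit = fit_cure_model(CureModelSpec("flexible"), registry_cohort,
                             FitOptions(seed=0))
        cf = cure_fraction(fit)
        assert 0.0 < cf.ci_lower < cf.estimate < cf.ci_upper < 1.0

    def test_no_covariance_flags_ci_unavailable(self):
        fit = manual_fit("nonmixture", [0.1, 0.0, 0.0])
        cf = cure_fraction(fit)
        assert not cf.ci_available
        assert np.isnan(cf.ci_lower)


@pytest.fixture(scope="module")
def cov_fit():
    cfg = GeneratorConfig(
        n_subjects=3000, seed=0,
        covariate_specs={"grp": CategoricalSpec(("a", "b", "c"),
                                                (0.4, 0.3, 0.3))},
        cure_model=CureIncidence(intercept=CLOGLOG_HALF),
        latency_model=WeibullLatency(1.5, 5.0, (
            Effect("grp", 0.3, level="b"), Effect("grp", 0.6, level="c"))),
        censoring_model=CensoringModel("exponential", mu=0.2),
        study_window_years=18.0)
    cohort = generate_cohort(cfg, seed=1)
    return fit_cure_model(CureModelSpec("mixture", covariates=("grp",)),
                          cohort, FitOptions(seed=0))


class TestEffectTable:
    def test_transforms_are_exact_inverses(self, cov_fit):
        for row in effect_table(cov_fit):
            assert np.log(row.hr) == pytest.approx(row.coef, abs=1e-12)
            assert row.cure_ratio == pytest.approx(
                np.exp(-np.exp(row.coef)), abs=1e-12)

    def test_reference_rows(self, cov_fit):
        rows = effect_table(cov_fit)
        ref = [r for r in rows if r.reference]
        assert len(ref) == 1 and ref[0].level == "a"
        assert ref[0].coef == 0.0 and ref[0].hr == 1.0
        assert ref[0].ci_lower == ref[0].ci_upper == 1.0

    def test_ci_brackets_hr(self, cov_fit):
        for row in effect_table(cov_fit):
            if not row.reference:
                assert row.ci_lower <= row.hr <= row.ci_upper
                assert row.hr > 0 and 0 < row.cure_ratio < 1

    def test_frame_has_one_row_per_level(self, cov_fit):
        frame = effects_frame(effect_table(cov_fit))
        assert list(frame["level"]) == ["a", "b", "c"]


class TestPredictSurvival:
    def test_mixture_hand_value(self):
        # pi = 0.5, unit-exponential latency, t = 1
        fit = manual_fit("mixture", [CLOGLOG_HALF, 0.0, 0.0])
        s = predict_survival(fit, 1.0)
        assert s[0] == pytest.approx(0.5 + 0.5 * np.exp(-1), abs=1e-10)
        assert s[0] == pytest.approx(0.68394, abs=1e-5)

    def test_early_time_tends_to_one_all_families(self, registry_cohort):
        for family in ("mixture", "nonmixture", "flexible"):
            fit = fit_cure_model(CureModelSpec(family), registry_cohort,
                                 FitOptions(seed=0))
            assert predict_survival(fit, 1e-8)[0] == pytest.approx(1.0, abs=1e-3)

    def test_large_time_reaches_cure_fraction(self, registry_cohort):
        for family in ("mixture", "nonmixture", "flexible"):
            fit = fit_cure_model(CureModelSpec(family), registry_cohort,
                                 FitOptions(seed=0))
            pi = cure_fraction(fit).estimate
            assert predict_survival(fit, 1e4)[0] == pytest.approx(pi, abs=1e-6)

    def test_monotone_and_bounded_below_by_cure(self, registry_cohort):
        grid = np.linspace(0.05, 25.0, 200)
        for family in ("mixture", "nonmixture", "flexible"):
            fit = fit_cure_model(CureModelSpec(family), registry_cohort,
                                 FitOptions(seed=0))
            s = predict_survival(fit, grid)
            assert np.all(np.diff(s) <= 1e-10)
            assert np.all(s >= cure_fraction(fit).estimate - 1e-9)

    def test_plateau_exact_beyond_last_knot(self, registry_cohort):
        fit = fit_cure_model(CureModelSpec("flexible"), registry_cohort,
                             FitOptions(seed=0))
        t_plateau = np.exp(fit.spec.spline.knots[-1])
        s = predict_survival(fit, [t_plateau, t_plateau * 2, t_plateau * 10])
        assert s[0] == s[1] == s[2]

    def test_nonpositive_time_rejected(self, registry_cohort):
        fit = fit_cure_model(CureModelSpec("mixture"), registry_cohort,
                             FitOptions(seed=0))
        with pytest.raises(ValueError):
            predict_survival(fit, 0.0)
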