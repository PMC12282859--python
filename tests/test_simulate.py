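"""Synthetic cohort generator: determinism, limits, calibration,
categorization rules and large-sample agreement with analytic summaries."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from pdcure.simulate import (CalibrationError, CategoricalSpec,
                             CategorizationRule, CensoringModel,
                             ContinuousSpec, CureIncidence, Effect,
                             GeneratorConfig, WeibullLatency,
                             apply_categorization, calibrate_generator,
                             expected_event_fraction, generate_cohort,
                             load_config, registry_default, population_median,
                             population_survival, save_config, REGISTRY_TARGETS)
from pdcure.nonparametric import km_estimate

from conftest import make_cohort


def simple_config(**overrides) -> GeneratorConfig:
    base = dict(
        n_subjects=400, seed=0,
        # cure fraction 0.45: strictly below 0.5 so the population
        # median exists (a plateau at exactly 0.5 makes it undefined)
        cure_model=CureIncidence(intercept=float(np.log(-np.log(0.45)))),
        latency_model=WeibullLatency(shape=1.4, scale=4.0),
        censoring_model=CensoringModel("uniform", B=18.0),
        study_window_years=18.0)
    base.update(overrides)
    return GeneratorConfig(**base)


class TestGenerate:
    def test_fixed_seed_determinism(self, registry_config):
        a = generate_cohort(registry_config, seed=7)
        b = generate_cohort(registry_config, seed=7)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_all_cured_limit_has_no_events(self):
        cfg = simple_config(cure_model=CureIncidence(intercept=-30.0))
        cohort = generate_cohort(cfg, seed=3)
        assert cohort.n_events == 0
        assert cohort.data["latent_cured"].all()
        assert np.isinf(cohort.data["latent_time"]).all()

    def test_latent_cured_never_event(self, registry_cohort):
        cured = registry_cohort.data["latent_cured"].to_numpy()
        assert not registry_cohort.event[cured].any()

    def test_registry_default_censored_fraction(self, big_cohort):
        # printed value 71.66%; Monte-Carlo error at n = 50,000 is ~0.2 pt
        assert big_cohort.n_censored / big_cohort.n == pytest.approx(0.7166, abs=0.01)

    def test_row_count_and_positive_times(self, registry_cohort):
        assert registry_cohort.n == 4144
        assert (registry_cohort.time > 0).all()
        assert registry_cohort.time.max() <= 18.0

    def test_event_fraction_matches_numerical_integration(self, big_cohort,
                                                          registry_config):
        analytic = expected_event_fraction(registry_config)
        observed = big_cohort.n_events / big_cohort.n
        # 3.5 binomial standard errors at n = 50,000
        tol = 3.5 * np.sqrt(analytic * (1 - analytic) / big_cohort.n)
        assert observed == pytest.approx(analytic, abs=tol)

    def test_exchangeable_under_reordering(self, registry_cohort):
        rng = np.random.default_rng(0)
        perm = rng.permutation(registry_cohort.n)
        shuffled = registry_cohort.with_data(
            registry_cohort.data.iloc[perm].reset_index(drop=True))
        a, b = km_estimate(registry_cohort), km_estimate(shuffled)
        np.testing.assert_allclose(a.survival, b.survival)
        np.testing.assert_allclose(a.times, b.times)

    def test_unknown_coefficient_covariate_rejected(self):
        with pytest.raises(ValueError, match="unknown covariate"):
            simple_config(latency_model=WeibullLatency(
                1.0, 1.0, (Effect("nope", 0.5),)))

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            simple_config(n_subjects=0)
        with pytest.raises(ValueError):
            simple_config(study_window_years=-1.0)
        with pytest.raises(ValueError):
            CensoringModel("uniform", B=-2.0)
        with pytest.raises(ValueError):
            CategoricalSpec(("a", "b"), (0.7, 0.7))


class TestCalibration:
    def test_censored_fraction_target(self):
        cfg = simple_config(censoring_model=CensoringModel("exponential", mu=0.5))
        cal = calibrate_generator(cfg, {"censored_fraction": 0.7166})
        assert 1.0 - expected_event_fraction(cal) == pytest.approx(0.7166, abs=0.01)
        big = generate_cohort(dataclasses.replace(cal, n_subjects=30_000), seed=2)
        assert 0.7066 <= big.n_censored / big.n <= 0.7266

    def test_cure_fraction_target_sets_km_plateau(self):
        # no censoring before the window end: plateau equals the cure fraction
        cfg = simple_config(n_subjects=20_000,
                            censoring_model=CensoringModel("administrative"),
                            study_window_years=40.0)
        cal = calibrate_generator(cfg, {"cure_fraction": 0.50})
        curve = km_estimate(generate_cohort(cal, seed=4))
        assert curve.tail_survival == pytest.approx(0.50, abs=0.02)

    def test_median_target(self):
        cfg = simple_config()
        cal = calibrate_generator(cfg, {"median_survival_years": 9.98})
        assert population_median(cal) == pytest.approx(9.98, abs=1e-6)
        big = generate_cohort(dataclasses.replace(cal, n_subjects=200_000), seed=5)
        curve = km_estimate(big)
        from pdcure.nonparametric import median_survival
        assert 9.73 <= median_survival(curve) <= 10.23

    def test_idempotent(self, registry_config):
        cal = calibrate_generator(registry_config, REGISTRY_TARGETS)
        again = calibrate_generator(cal, REGISTRY_TARGETS)
        assert again.latency_model.scale == pytest.approx(
            cal.latency_model.scale, abs=1e-6)
        assert again.censoring_model.mu == pytest.approx(
            cal.censoring_model.mu, abs=1e-6)
        assert again.cure_model.intercept == pytest.approx(
            cal.cure_model.intercept, abs=1e-9)

    def test_registry_default_is_calibration_fixed_point(self, registry_config):
        cal = calibrate_generator(registry_config, REGISTRY_TARGETS)
        assert cal.latency_model.scale == pytest.approx(
            registry_config.latency_model.scale, rel=1e-6)
        assert cal.censoring_model.mu == pytest.approx(
            registry_config.censoring_model.mu, rel=1e-6)

    def test_infeasible_target_reports_best(self):
        cfg = simple_config(censoring_model=CensoringModel("administrative"))
        with pytest.raises(CalibrationError) as err:
            calibrate_generator(cfg, {"censored_fraction": 0.7166})
        assert "event_fraction" in err.value.achieved

    def test_no_targets_rejected(self, registry_config):
        with pytest.raises(ValueError):
            calibrate_generator(registry_config, {})


class TestCategorization:
    @pytest.mark.parametrize("covariate,value,expected", [
        ("age", 39.9, "20-40"), ("age", 40.0, "40-60"), ("age", 59.999, "40-60"),
        ("age", 60.0, ">60"), ("age", 22.0, "20-40"),
        ("calcium", 8.19, "<8.2"), ("calcium", 8.2, "8.2-10.2"),
        ("calcium", 10.2, "8.2-10.2"), ("calcium", 10.3, ">10.2"),
        ("ldl", 99.99, "<100"), ("ldl", 100.0, "100-140"),
        ("ldl", 140.0, "100-140"), ("ldl", 140.01, ">140"),
    ])
    def test_boundary_assignment(self, covariate, value, expected):
        others = {"age": 50.0, "calcium": 9.0, "ldl": 120.0}
        others[covariate] = value
        cohort = make_cohort([1.0], [1], **{k: [v] for k, v in others.items()})
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # single row -> empty categories
            out = apply_categorization(cohort)
        assert str(out.data[f"{covariate}_group"].iloc[0]) == expected

    def test_reference_is_lowest_interval(self):
        cohort = make_cohort([1, 2], [1, 0], age=[30.0, 70.0],
                             calcium=[9.0, 9.0], ldl=[120.0, 120.0])
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = apply_categorization(cohort)
        assert out.schema["age_group"].reference == "20-40"
        assert out.schema["age_group"].kind == "categorical"
        # originals retained
        assert "age" in out.schema

    def test_empty_category_warns(self):
        cohort = make_cohort([1, 2], [1, 0], age=[30.0, 35.0])
        rule = CategorizationRule("age_group", "age", (40.0, 60.0),
                                  ("20-40", "40-60", ">60"), (False, False))
        with pytest.warns(UserWarning, match="empty"):
            apply_categorization(cohort, (rule,))

    def test_non_numeric_covariate_rejected(self):
        cohort = make_cohort([1, 2], [1, 0], sex=["m", "f"])
        rule = CategorizationRule("x", "sex", (1.0,), ("a", "b"), (False,))
        with pytest.raises(ValueError, match="not numeric"):
            apply_categorization(cohort, (rule,))


class TestConfigIO:
    def test_yaml_round_trip(self, tmp_path, registry_config):
        path = tmp_path / "profile.yaml"
        save_config(registry_config, path)
        loaded = load_config(path)
        assert loaded == registry_config

    def test_packaged_profile_name(self):
        assert load_config("registry_default") == registry_default()

    def test_unknown_keys_rejected(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("n_subjects: 10\nlatency_model: {shape: 1, scale: 1}\n"
                        "bogus_key: 1\n")
        with pytest.raises(ValueError, match="bogus_key"):
            load_config(path)


def test_population_survival_monotone(registry_config):
    t = np.linspace(0.1, 30, 100)
    s = population_survival(registry_config, t)
    assert np.all(np.diff(s) <= 1e-12)
    assert s[0] <= 1.0 and s[-1] > 0.4
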