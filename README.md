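# pdcure

Cure-fraction survival analysis for peritoneal-dialysis (PD) registry
cohorts — and, more generally, for any right-censored clinical cohort in
which a subpopulation will never experience the event of interest.

PD is a maintenance therapy: a large share of patients never die on PD
(they continue stably, transplant, or switch modality and are censored),
so their Kaplan–Meier curve flattens at a value well above zero. Standard
Cox or fully parametric models assume everyone remains at risk and are
misspecified for such data. `pdcure` implements the cure-model workflow a
registry analyst needs:

- **Kaplan–Meier diagnostics** — product-limit estimation with Greenwood
  variance and log(−log)-scale 95% bands, fixed-time survival, and the
  no-interpolation median.
- **Maller–Zhou tests** — (i) the cured-fraction presence test based on
  the KM tail value p̂ₙ (H₀: *p* = 1, no immune subjects), and (ii) the
  sufficient-follow-up statistic qₙ = Nₙ/n, counting events in the window
  (2·t*₍ₙ₎ − tₙ, t*₍ₙ₎]. Both use simulated nulls (seeded); the two
  published table entries are bundled for lookup mode.
- **Three cure-model families**, fitted by maximum likelihood:
  - *mixture*: S(t|x) = π(x) + (1 − π(x))·S_u(t|x), Weibull latency with
    proportional-hazards effects and a complementary log-log incidence
    model π(x) = exp(−exp(η));
  - *non-mixture* (promotion time): S(t|x) = exp(−exp(α₀ + x′β)·F_u(t)),
    reaching its cure fraction asymptotically;
  - *flexible parametric*: log H(t|x) = γ₀ + s(log t; γ) + x′β with s a
    restricted cubic spline built from reversed log-time so the fitted
    survival plateaus **exactly** at π(x) = exp(−exp(γ₀ + x′β)) beyond the
    last knot.
- **Inference and selection** — cure fractions with CIs transformed from
  the cloglog scale (bounds stay in (0, 1)), hazard-ratio effect tables
  with the conventional per-category cure ratio exp(−exp(β)), AIC/BIC
  comparison, univariate screening, and backward elimination by joint
  Wald tests on whole dummy blocks.
- **A calibrated synthetic registry generator** — cohorts with a latent
  cured subpopulation, Weibull latency, and uniform/exponential/
  administrative censoring, calibrated by deterministic one-dimensional
  searches to hit stated summaries (cure fraction, median survival,
  censored fraction). The packaged `registry_default` profile emulates a
  national PD registry cohort: n = 4,144 adults, 49% cured, median
  survival 9.98 y, 71.66% censored within an 18-year window.

## Worked example

```python
from pdcure import (registry_default, generate_cohort, km_estimate,
                    median_survival, mz_cure_presence_test,
                    CureModelSpec, FitOptions, fit_cure_model,
                    cure_fraction, compare_models)

cohort = generate_cohort(registry_default(), seed=11)   # n = 4,144

curve = km_estimate(cohort)
print(round(median_survival(curve), 2), round(curve.tail_survival, 3))
# 9.09 0.483       <- median ~10 y; the curve plateaus near 0.48

mz = mz_cure_presence_test(cohort, censor_model="exponential", seed=2024)
print(round(mz.p_hat, 3), round(mz.critical_value, 3), mz.reject_h0)
# 0.483 0.169 True  <- the KM tail exceeds the simulated null: cured
#                      subjects are present

fits = {f: fit_cure_model(CureModelSpec(f), cohort, FitOptions(seed=0))
        for f in ("mixture", "nonmixture", "flexible")}
print(compare_models(fits))
#            model  df       loglik          AIC          BIC
# rank
# 1     nonmixture   3 -4055.339125  8116.678250  8135.666501
# 2        mixture   3 -4056.676010  8119.352020  8138.340271
# 3       flexible   3 -4064.800726  8135.601451  8154.589702

cf = cure_fraction(fits["flexible"])
print(f"{cf.estimate:.2f} ({cf.ci_lower:.2f}-{cf.ci_upper:.2f})")
# 0.48 (0.46-0.51)  <- the estimated fraction of patients who will never
#                      fail PD, with a 95% CI on the cloglog scale
```

Each covariate-free family has exactly 3 free parameters, so the AIC
ranking here is a pure likelihood comparison. On this synthetic cohort
(Weibull latency truth) the Weibull-based families fit best; on real
registry data with a non-Weibull hazard the flexible family typically
wins — which is exactly what the comparison table is for.

The numbered scripts under `analysis/` run the full study pipeline on
the simulated registry (cohort generation → KM description →
Maller–Zhou diagnostics → model comparison → covariate selection),
writing their tables under `results/`. Run them in order:

```sh
python analysis/01_simulate_cohort.py
python analysis/02_km_survival.py
...
```

A `pdcure` command-line interface wraps the same steps
(`pdcure simulate`, `km`, `mz-test`, `fit`, `select`, `compare`,
`analyze`); see `pdcure --help`.

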