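import numpy as np
import pandas as pd
import pytest

from pdcure.cohort import Cohort, Covariate, CovariateSchema
from pdcure.simulate import generate_cohort, registry_default


def make_cohort(times, events, **covariates) -> Cohort:
    """Build a small cohort from parallel lists; string covariates become
    categorical (levels sorted, first = reference)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    df = pd.DataFrame({"id": np.arange(1, len(times) + 1),
                       "time_years": times, "event": events})
    covs = []
    for name, values in covariates.items():
        df[name] = values
        if df[name].dtype == object:
            levels = tuple(sorted(set(map(str, values))))
            covs.append(Covariate(name, "categorical", levels))
            df[name] = pd.Categorical(df[name].astype(str), categories=levels)
        else:
            covs.append(Covariate(name, "continuous"))
    return Cohort(data=df, schema=CovariateSchema(tuple(covs)))


@pytest.fixture
def toy_cohort():
    """Times 1 (event), 2 (censored), 3 (event): S(1)=2/3, S(3)=0."""
    return make_cohort([1.0, 2.0, 3.0], [1, 0, 1])


@pytest.fixture
def mz_toy_cohort():
    """Events at 1, 2, 3 and censorings at 4, 5 (follow-up test toy)."""
    return make_cohort([1, 2, 3, 4, 5], [1, 1, 1, 0, 0])


@pytest.fixture(scope="session")
def registry_config():
    return registry_default()


@pytest.fixture(scope="session")
def registry_cohort(registry_config):
    """One registry-emulating cohort of n = 4144 (shared across tests)."""
    return generate_cohort(registry_config, seed=11)


@pytest.fixture(scope="session")
def big_cohort(registry_config):
    """Large cohort (n = 50,000) for law-of-large-numbers checks."""
    import dataclasses
    cfg = dataclasses.replace(registry_config, n_subjects=50_000)
    return generate_cohort(cfg, seed=1)
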