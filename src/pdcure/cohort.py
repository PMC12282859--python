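"""Subject-level right-censored cohort container.

A :class:`Cohort` is the universal input of the package: one row per
subject with a positive follow-up time in years, a binary event
indicator (1 = failure observed, 0 = censored) and covariate columns
described by a :class:`CovariateSchema`.  Cohorts generated by the
synthetic module may additionally carry latent fields (true cure status
and uncensored latent event time) that never exist for real registry
exports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

ID_COL = "id"
TIME_COL = "time_years"
EVENT_COL = "event"

CONTINUOUS = "continuous"
CATEGORICAL = "categorical"


@dataclass(frozen=True)
class Covariate:
    """One covariate column: its name, kind and (if categorical) levels.

    For categorical covariates the first level is the declared reference
    level and is excluded from every design matrix.
    """

    name: str
    kind: str
    levels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in (CONTINUOUS, CATEGORICAL):
            raise ValueError(f"unknown covariate kind {self.kind!r}")
        if self.kind == CATEGORICAL and len(self.levels) < 2:
            raise ValueError(
                f"categorical covariate {self.name!r} needs at least 2 levels"
            )
        if self.kind == CONTINUOUS and self.levels:
            raise ValueError(f"continuous covariate {self.name!r} cannot have levels")

    @property
    def reference(self) -> str:
        if self.kind != CATEGORICAL:
            raise ValueError(f"{self.name!r} is not categorical")
        return self.levels[0]


@dataclass(frozen=True)
class CovariateSchema:
    """Ordered collection of :class:`Covariate` descriptions."""

    covariates: tuple[Covariate, ...] = ()

    def __iter__(self) -> Iterator[Covariate]:
        return iter(self.covariates)

    def __len__(self) -> int:
        return len(self.covariates)

    def __contains__(self, name: str) -> bool:
        return any(c.name == name for c in self.covariates)

    def __getitem__(self, name: str) -> Covariate:
        for c in self.covariates:
            if c.name == name:
                return c
        raise KeyError(name)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.covariates)

    def extended(self, *extra: Covariate) -> "CovariateSchema":
        return CovariateSchema(self.covariates + tuple(extra))


# Latent columns retained only for synthetically generated cohorts.
LATENT_CURED = "latent_cured"
LATENT_TIME = "latent_time"


@dataclass
class Cohort:
    """Right-censored survival cohort with a covariate schema.

    ``data`` holds one row per subject with columns ``id``,
    ``time_years``, ``event`` and one column per schema covariate.
    Complete-case: every subject must carry a value for every covariate.
    """

    data: pd.DataFrame
    schema: CovariateSchema = field(default_factory=CovariateSchema)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.data
        for col in (ID_COL, TIME_COL, EVENT_COL):
            if col not in df.columns:
                raise ValueError(f"cohort data is missing required column {col!r}")
        t = np.asarray(df[TIME_COL], dtype=float)
        if len(t) == 0:
            raise ValueError("empty cohort")
        if not np.all(np.isfinite(t)) or np.any(t <= 0):
            raise ValueError("follow-up times must be strictly positive and finite")
        ev = np.asarray(df[EVENT_COL])
        if not np.isin(ev, [0, 1]).all():
            raise ValueError("event indicator must be 0 (censored) or 1 (event)")
        for cov in self.schema:
            if cov.name not in df.columns:
                raise ValueError(f"covariate {cov.name!r} missing from cohort data")
            col = df[cov.name]
            if col.isna().any():
                raise ValueError(
                    f"covariate {cov.name!r} has missing values (complete-case required)"
                )
            if cov.kind == CATEGORICAL:
                observed = set(col.astype(str).unique())
                unknown = observed - set(cov.levels)
                if unknown:
                    raise ValueError(
                        f"covariate {cov.name!r} has values outside its levels: {unknown}"
                    )
        if LATENT_CURED in df.columns:
            cured = np.asarray(df[LATENT_CURED], dtype=bool)
            if LATENT_TIME in df.columns:
                lt = np.asarray(df[LATENT_TIME], dtype=float)
                if not np.all(np.isinf(lt[cured])):
                    raise ValueError("latent-cured subjects must have infinite latent time")
            if ev[cured].any():
                raise ValueError("latent-cured subjects cannot have an observed event")

    # -- basic accessors -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def time(self) -> np.ndarray:
        return np.asarray(self.data[TIME_COL], dtype=float)

    @property
    def event(self) -> np.ndarray:
        return np.asarray(self.data[EVENT_COL], dtype=int)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    @property
    def n_censored(self) -> int:
        return self.n - self.n_events

    @property
    def has_latent(self) -> bool:
        return LATENT_CURED in self.data.columns

    def covariate(self, name: str) -> pd.Series:
        if name not in self.schema:
            raise KeyError(f"unknown covariate {name!r}")
        return self.data[name]

    def with_data(self, data: pd.DataFrame, schema: CovariateSchema | None = None) -> "Cohort":
        return Cohort(data=data, schema=schema if schema is not None else self.schema,
                      meta=dict(self.meta))
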