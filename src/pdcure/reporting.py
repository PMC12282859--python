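"""Cohort I/O, analysis configuration and report assembly.

Cohorts travel as delimited text (comma-separated, header row, columns
``id``, ``time_years``, ``event``, then covariates; categorical values
as quoted labels).  Reading applies complete-case filtering and logs
the exclusion count.  Reports are rendered deterministically with the
numeric precision used in clinical registry tables (coefficients and
hazard ratios to 3 decimals, cure ratios to 2, information criteria
to 2).
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import (CATEGORICAL, CONTINUOUS, EVENT_COL, ID_COL, LATENT_CURED,
                     LATENT_TIME, TIME_COL, Cohort, Covariate, CovariateSchema)

__all__ = ["read_cohort", "write_cohort", "save_schema", "load_schema",
           "AnalysisConfig", "write_report", "format_value"]

logger = logging.getLogger("pdcure")

_RESERVED = {ID_COL, TIME_COL, EVENT_COL, LATENT_CURED, LATENT_TIME}


def read_cohort(path, schema: CovariateSchema | None = None) -> Cohort:
    """Read a delimited cohort file, complete-case.

    Rows with any missing value are excluded and counted in the log and
    in ``cohort.meta['n_excluded']``.  Without an explicit schema,
    numeric columns become continuous covariates and string columns
    categorical ones with lexicographically sorted levels (first level
    = reference).
    """
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: empty cohort file")
    for col in (TIME_COL, EVENT_COL):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if ID_COL not in df.columns:
        df.insert(0, ID_COL, np.arange(1, len(df) + 1))

    n_total = len(df)
    df = df.dropna()
    n_excluded = n_total - len(df)
    if n_excluded:
        logger.info("read_cohort(%s): excluded %d incomplete of %d records",
                    path, n_excluded, n_total)
    if df.empty:
        raise ValueError(f"{path}: no complete records")

    t = pd.to_numeric(df[TIME_COL], errors="coerce")
    if t.isna().any():
        raise ValueError(f"{path}: non-numeric follow-up time")
    ev = pd.to_numeric(df[EVENT_COL], errors="coerce")
    if ev.isna().any() or not ev.isin([0, 1]).all():
        raise ValueError(f"{path}: event column must contain only 0 and 1")
    df = df.assign(**{TIME_COL: t.astype(float), EVENT_COL: ev.astype(int)})

    if schema is None:
        covs = []
        for col in df.columns:
            if col in _RESERVED:
                continue
            if pd.api.types.is_numeric_dtype(df[col]):
                covs.append(Covariate(col, CONTINUOUS))
            else:
                levels = tuple(sorted(df[col].astype(str).unique()))
                covs.append(Covariate(col, CATEGORICAL, levels))
        schema = CovariateSchema(tuple(covs))
    for cov in schema:
        if cov.kind == CATEGORICAL:
            df[cov.name] = pd.Categorical(df[cov.name].astype(str),
                                          categories=list(cov.levels))
    cohort = Cohort(data=df.reset_index(drop=True), schema=schema,
                    meta={"n_excluded": n_excluded, "source": str(path)})
    return cohort


def write_cohort(cohort: Cohort, path) -> None:
    """Write the delimited cohort format (no missing values permitted)."""
    cols = [ID_COL, TIME_COL, EVENT_COL, *cohort.schema.names]
    df = cohort.data[cols]
    if df.isna().any().any():
        raise ValueError("cohort contains missing values; cannot write")
    df.to_csv(path, index=False, quoting=csv.QUOTE_NONNUMERIC)


def save_schema(schema: CovariateSchema, path) -> None:
    """Persist a covariate schema (JSON sidecar), preserving declared
    level order and hence reference categories across file round-trips."""
    payload = [{"name": c.name, "kind": c.kind, "levels": list(c.levels)}
               for c in schema]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def load_schema(path) -> CovariateSchema:
    with open(path) as fh:
        payload = json.load(fh)
    return CovariateSchema(tuple(
        Covariate(c["name"], c["kind"], tuple(c.get("levels", ())))
        for c in payload))


@dataclass(frozen=True)
class AnalysisConfig:
    """Configuration of the full analysis pipeline (all seeds named)."""

    seed: int = 0
    family: str = "flexible"
    candidates: tuple[str, ...] = ()
    survival_times: tuple[float, ...] = (3.0, 5.0, 10.0)
    alpha: float = 0.05
    remove_above: float = 0.1
    final_alpha: float = 0.05
    mz_censor_model: str = "exponential"
    mz_reps: int = 500
    n_interior_knots: int = 2

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown analysis config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("candidates", "survival_times"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------

_PRECISION = {"coef": 3, "se": 3, "hr": 3, "ci_lower": 3, "ci_upper": 3,
              "p_value": 3, "joint_p": 3, "cure_ratio": 2, "AIC": 2,
              "BIC": 2, "loglik": 2}


def format_value(value, kind: str | None = None) -> str:
    """Render a number at the table precision for its column kind."""
    if value is None:
        return ""
    if isinstance(value, float) and not np.isfinite(value):
        return "" if np.isnan(value) else ("inf" if value > 0 else "-inf")
    digits = _PRECISION.get(kind or "", 4)
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    return f"{value:.{digits}f}"


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, pd.DataFrame):
        return _jsonify(obj.reset_index().to_dict(orient="records"))
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonify(dataclasses.asdict(obj))
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if hasattr(obj, "spec") and hasattr(obj, "params"):   # CureModelFit
        return {"family": obj.spec.family,
                "params": dict(zip(obj.param_names, obj.params.tolist())),
                "loglik": obj.loglik, "k": obj.k, "n": obj.n,
                "converged": obj.converged}
    return obj


def _frame_to_text(df: pd.DataFrame) -> str:
    df = df.copy()
    for col in df.columns:
        kind = col if col in _PRECISION else None
        if pd.api.types.is_float_dtype(df[col]):
            df[col] = df[col].map(lambda v: format_value(v, kind))
    return df.to_string()


def write_report(bundle: dict, path, format: str = "text") -> list[Path]:
    """Serialize a report bundle deterministically.

    ``format`` is one of ``text`` (one human-readable file), ``json``
    (one machine-readable file) or ``csv-set`` (one delimited file per
    table).  Returns the written paths.
    """
    path = Path(path)
    written: list[Path] = []
    if format == "json":
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(_jsonify(bundle), fh, indent=2, sort_keys=True)
            fh.write("\n")
        written.append(path)
    elif format == "text":
        path.parent.mkdir(parents=True, exist_ok=True)
        lines: list[str] = []
        for key in sorted(bundle):
            value = bundle[key]
            lines.append(f"== {key} ==")
            if isinstance(value, pd.DataFrame):
                lines.append(_frame_to_text(value))
            else:
                lines.append(json.dumps(_jsonify(value), indent=2, sort_keys=True))
            lines.append("")
        path.write_text("\n".join(lines))
        written.append(path)
    elif format == "csv-set":
        path.mkdir(parents=True, exist_ok=True)
        for key in sorted(bundle):
            value = bundle[key]
            if isinstance(value, pd.DataFrame):
                out = path / f"{key}.csv"
                value.to_csv(out)
            else:
                out = path / f"{key}.json"
                with open(out, "w") as fh:
                    json.dump(_jsonify(value), fh, indent=2, sort_keys=True)
                    fh.write("\n")
            written.append(out)
    else:
        raise ValueError(f"unknown report format {format!r}")
    return written
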