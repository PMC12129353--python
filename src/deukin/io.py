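"""File formats and run configuration.

Time series travel as delimited text with columns
``time,population,replicate,value``; configs are YAML.  Times may be
recorded in days, in which case the declared labelling period converts
them to scaled time units (stu) on input, with the conversion logged.
Results are written both as full-precision JSON and as a flat CSV row
with an additional two-decimal presentation column.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .enrichment import EnrichmentSchedule
from .errors import DataError
from .fitting import FitResult
from .kinetics import LabelTimeSeries
from .rates import RateSummary

__all__ = [
    "RunConfig",
    "schedule_from_dict",
    "read_timeseries",
    "write_timeseries",
    "write_results",
    "load_config",
    "dump_config",
]

logger = logging.getLogger(__name__)


def schedule_from_dict(spec: dict) -> EnrichmentSchedule:
    """Build an enrichment schedule from config keys
    (shape, tau, f, delta, beta0, normalize)."""
    return EnrichmentSchedule(**spec)


@dataclass
class RunConfig:
    """Fully resolved configuration of one simulate/fit/sweep run.

    Every run emits its resolved config next to the outputs so that the
    run can be repeated identically.
    """

    model: str = "es"
    parameters: dict = field(default_factory=dict)
    schedule: dict = field(default_factory=lambda: {"shape": "step", "tau": 1.0})
    sampling: dict = field(default_factory=lambda: {"start": 0.0, "stop": 2.0, "step": 0.02})
    noise: dict | None = None
    seed: int = 1
    time_unit: str = "stu"
    labelling_period_days: float | None = None
    outputs: dict = field(default_factory=dict)

    def times(self) -> np.ndarray:
        s = self.sampling
        if "times" in s:
            return np.asarray(s["times"], dtype=float)
        return np.round(
            np.arange(s["start"], s["stop"] + 1e-9, s["step"]), 12
        )


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(**raw)


def dump_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)


def read_timeseries(path, labelling_period_days: float | None = None) -> LabelTimeSeries:
    """Read a delimited time series, converting day-scale times to stu.

    The file must have a header with columns
    ``time,population,replicate,value``.  If ``labelling_period_days``
    is given, times are divided by it (days -> stu) and the conversion
    is recorded in the metadata.  Fraction-scale values above 1 are
    allowed (noisy or APE-scale data) but flagged with a warning.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise DataError(f"{path}: file is empty") from exc
    missing = [c for c in LabelTimeSeries.REQUIRED if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        raise DataError(f"{path}: no data rows")
    for col in ("time", "value"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(df.index[bad][0]) + 2  # header is line 1
            raise DataError(f"{path}: non-numeric {col!r} at line {row}")
        if coerced.isna().any():
            row = int(df.index[coerced.isna()][0]) + 2
            raise DataError(f"{path}: missing {col!r} at line {row}")
        df[col] = coerced
    if (df["time"] < 0).any():
        row = int(df.index[df["time"] < 0][0]) + 2
        raise DataError(f"{path}: negative time at line {row}")

    metadata = {"source": str(path), "scale": "fraction"}
    if labelling_period_days is not None:
        df = df.assign(time=df["time"] / labelling_period_days)
        metadata["labelling_period_days"] = labelling_period_days
        logger.info(
            "converted times from days to stu (labelling period = %g days)",
            labelling_period_days,
        )
    flagged = df["value"] > 1.0
    if flagged.any():
        metadata["values_above_one"] = int(flagged.sum())
        logger.warning(
            "%d value(s) above 1: treating data as noisy or APE-scale",
            int(flagged.sum()),
        )
    return LabelTimeSeries(df, metadata=metadata)


def write_timeseries(series: LabelTimeSeries, path) -> None:
    series.data.to_csv(path, index=False, columns=list(LabelTimeSeries.REQUIRED))


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and not np.isfinite(obj):
        return str(obj)
    return obj


def write_results(result, path) -> None:
    """Write a result object as JSON (full precision) plus a flat CSV.

    Accepts :class:`FitResult`, :class:`RateSummary`, a sweep record
    list, or any dataclass/dict.  ``path`` is the JSON target; the CSV
    is written alongside with suffix ``.csv``.
    """
    path = Path(path)
    payload = _jsonable(result)
    path.write_text(json.dumps(payload, indent=2))

    if isinstance(result, list):
        rows = [_flatten(_jsonable(r)) for r in result]
    else:
        rows = [_flatten(payload)]
    df = pd.DataFrame(rows)
    for col in df.columns:
        if pd.api.types.is_float_dtype(df[col]):
            df[f"{col}_2dp"] = df[col].round(2)
    df.to_csv(path.with_suffix(".csv"), index=False)


def _flatten(d: dict, prefix: str = "") -> dict:
    out = {}
    for key, val in d.items():
        name = f"{prefix}{key}"
        if isinstance(val, dict):
            out.update(_flatten(val, prefix=f"{name}."))
        elif isinstance(val, list):
            continue  # residuals and diagnostics stay in the JSON only
        else:
            out[name] = val
    return out
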