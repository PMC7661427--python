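"""File formats: measurement-record CSV, result reports, and run configuration.

The record CSV dialect is a minimal superset of what hierarchical
effort-reduction scenarios need (comma-separated, UTF-8, header required):

    trip_id,haul_id,haul_datetime,haul_catch_kg,length_cm,n_measured,raising_factor

with ``haul_datetime`` in ISO 8601.  Reports are JSON for single results
(reference runs, distances, scenarios) and CSV for tabular results (grids,
bootstrap comparisons, contrast tables); the distance decomposition
(L1 plus the three penalties) is always itemized.
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dissimilarity import AlgorithmParams, DissimilarityResult, GammaSpec
from .lfd import ImportantRange, LengthFrequency, build_lfd
from .reference import ReferenceResult
from .scenarios import MeasurementRecord, ScenarioResult, VarianceComponents
from .simulation import BootstrapComparison, GridResult

__all__ = [
    "RECORD_COLUMNS",
    "RunConfig",
    "read_records",
    "write_records",
    "read_lfd",
    "write_lfd",
    "write_report",
    "load_config",
]

RECORD_COLUMNS = (
    "trip_id",
    "haul_id",
    "haul_datetime",
    "haul_catch_kg",
    "length_cm",
    "n_measured",
    "raising_factor",
)


def read_records(path) -> list[MeasurementRecord]:
    """Parse and validate a measurement-record CSV.

    Errors name the offending column or the (1-based, header excluded) row.
    """
    df = pd.read_csv(
        path, dtype={"trip_id": str, "haul_id": str}, float_precision="round_trip"
    )
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"record file {path} is missing column(s): {', '.join(missing)}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            ts = datetime.fromisoformat(str(row.haul_datetime))
        except ValueError as exc:
            raise ValueError(
                f"row {i}: unparsable haul_datetime {row.haul_datetime!r}"
            ) from exc
        length = int(row.length_cm)
        if length < 0:
            raise ValueError(f"row {i}: negative length_cm {length}")
        try:
            records.append(
                MeasurementRecord(
                    trip_id=str(row.trip_id),
                    haul_id=str(row.haul_id),
                    haul_time=ts,
                    haul_catch_kg=float(row.haul_catch_kg),
                    length_cm=length,
                    n_measured=int(row.n_measured),
                    raising_factor=float(row.raising_factor),
                )
            )
        except ValueError as exc:
            raise ValueError(f"row {i}: {exc}") from exc
    return records


def write_records(records: list[MeasurementRecord], path) -> None:
    import csv

    # repr-exact floats so records survive a write/read cycle unchanged
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(RECORD_COLUMNS)
        for r in records:
            w.writerow(
                [
                    r.trip_id,
                    r.haul_id,
                    r.haul_time.isoformat(),
                    repr(float(r.haul_catch_kg)),
                    r.length_cm,
                    r.n_measured,
                    repr(float(r.raising_factor)),
                ]
            )


def read_lfd(path, origin: int = 0) -> LengthFrequency:
    """Read an LFD from a two-column CSV (``length_cm,count``)."""
    df = pd.read_csv(path)
    for col in ("length_cm", "count"):
        if col not in df.columns:
            raise ValueError(f"LFD file {path} is missing column {col!r}")
    lengths = np.repeat(df["length_cm"].to_numpy(int), df["count"].to_numpy(int))
    return build_lfd(lengths, origin=origin)


def write_lfd(lfd: LengthFrequency, path) -> None:
    pd.DataFrame(
        {"length_cm": lfd.classes, "count": lfd.counts}
    ).to_csv(path, index=False)


def _jsonable(obj):
    if isinstance(obj, (bool, np.bool_)):
        return bool(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, datetime):
        return obj.isoformat()
    if isinstance(obj, LengthFrequency):
        return {
            "origin": obj.origin,
            "class_width": obj.class_width,
            "counts": {str(k): v for k, v in obj.to_dict().items()},
            "total": obj.total,
        }
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_report(result, path) -> None:
    """Serialize a result object: JSON for single results, CSV for tables."""
    path = Path(path)
    if isinstance(result, (GridResult, BootstrapComparison)):
        result.table.to_csv(path, index=False)
        return
    if isinstance(result, pd.DataFrame):
        result.to_csv(path, index=False)
        return
    if isinstance(
        result, (DissimilarityResult, ReferenceResult, ScenarioResult, VarianceComponents)
    ):
        path.write_text(json.dumps(_jsonable(result), indent=2) + "\n")
        return
    raise TypeError(f"don't know how to report a {type(result).__name__}")


@dataclasses.dataclass
class RunConfig:
    """Parameters of a run, loadable from a TOML or YAML file.

    Mirrors :class:`AlgorithmParams` plus the bin origin, a seed and
    optional input/output paths; command-line flags override file values.
    """

    delta: int = 5
    theta: float = 0.9
    epsilon: int = 0
    gamma_mode: str = "zero"
    gamma_value: float = 0.0
    range_low: int | None = None
    range_high: int | None = None
    origin: int = 0
    c1: float = 10.0
    c2: float = 2.0
    c3: float = 1.0
    amplitude_mode: str = "pointwise"
    seed: int | None = None
    input: str | None = None
    output: str | None = None

    def to_params(self) -> AlgorithmParams:
        rng = None
        if self.range_low is not None or self.range_high is not None:
            if self.range_low is None or self.range_high is None:
                raise ValueError("range_low and range_high must be given together")
            rng = ImportantRange(self.range_low, self.range_high)
        return AlgorithmParams(
            delta=self.delta,
            theta=self.theta,
            epsilon=self.epsilon,
            gamma=GammaSpec(self.gamma_mode, self.gamma_value),
            length_range=rng,
            c1=self.c1,
            c2=self.c2,
            c3=self.c3,
            amplitude_mode=self.amplitude_mode,
        )


def load_config(path) -> RunConfig:
    """Load a RunConfig from ``.toml`` / ``.yaml`` / ``.yml``."""
    path = Path(path)
    if path.suffix == ".toml":
        data = tomllib.loads(path.read_text())
    elif path.suffix in (".yaml", ".yml"):
        data = yaml.safe_load(path.read_text()) or {}
    else:
        raise ValueError(f"unsupported config format {path.suffix!r}")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    return RunConfig(**data)
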