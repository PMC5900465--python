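"""Tabular I/O with validation and provenance sidecars.

All tables are plain CSV (comma, UTF-8, header row, "." decimal). Every
file a pipeline stage writes gets a JSON sidecar (``<file>.meta.json``)
recording the stage, seed, and a hash of the configuration, so a run
can be reproduced from its outputs alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any

import pandas as pd

__all__ = [
    "TableValidationError",
    "read_latency_table",
    "write_table",
    "write_sidecar",
    "config_hash",
]

LATENCY_COLUMNS = ["animal_id", "group", "drug", "day", "latency_s", "censored"]
VALID_GROUPS = {"control", "defeated"}


class TableValidationError(ValueError):
    """A table fails schema validation; messages carry 1-based row numbers."""


def _row(i: int) -> int:
    # +2: 1-based counting plus the header line
    return i + 2


def read_latency_table(
    path: str | Path,
    latency_floor: float = 3.0,
    latency_cap: float = 900.0,
) -> pd.DataFrame:
    """Read and validate a daily latency CSV.

    Checks the documented schema: required columns, latencies within
    [floor, cap], the censored flag set exactly at the cap, one row per
    (animal, day), and only defeated animals carrying latencies (controls
    never experience defeat). Errors name the offending line.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in LATENCY_COLUMNS if c not in df.columns]
    if missing:
        raise TableValidationError(f"{path.name}: missing columns {missing}")
    if df.empty:
        return df

    bad_group = df.index[~df["group"].isin(VALID_GROUPS)]
    if len(bad_group):
        i = bad_group[0]
        raise TableValidationError(
            f"{path.name} line {_row(i)}: invalid group {df.loc[i, 'group']!r}"
        )
    ctrl = df.index[df["group"] == "control"]
    if len(ctrl):
        raise TableValidationError(
            f"{path.name} line {_row(ctrl[0])}: control animals must not carry "
            "latency rows"
        )

    lat = pd.to_numeric(df["latency_s"], errors="coerce")
    bad_num = df.index[lat.isna()]
    if len(bad_num):
        i = bad_num[0]
        raise TableValidationError(
            f"{path.name} line {_row(i)}: non-numeric latency "
            f"{df.loc[i, 'latency_s']!r}"
        )
    out_of_range = df.index[(lat < latency_floor) | (lat > latency_cap)]
    if len(out_of_range):
        i = out_of_range[0]
        raise TableValidationError(
            f"{path.name} line {_row(i)}: latency {lat[i]} outside "
            f"[{latency_floor}, {latency_cap}]"
        )

    cens = df["censored"].astype(bool)
    inconsistent = df.index[cens != (lat == latency_cap)]
    if len(inconsistent):
        i = inconsistent[0]
        raise TableValidationError(
            f"{path.name} line {_row(i)}: censored flag must be set exactly "
            f"when latency equals the cap ({latency_cap})"
        )

    dup = df.duplicated(subset=["animal_id", "day"])
    if dup.any():
        i = df.index[dup][0]
        raise TableValidationError(
            f"{path.name} line {_row(i)}: duplicate (animal_id, day) = "
            f"({df.loc[i, 'animal_id']}, {df.loc[i, 'day']})"
        )

    df = df.copy()
    df["latency_s"] = lat
    df["censored"] = cens
    df["day"] = df["day"].astype(int)
    return df


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (str, int, float, bool)) or obj is None:
        return obj
    return str(obj)


def config_hash(config: Any) -> str:
    """Stable short hash of a configuration object."""
    blob = json.dumps(_jsonable(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def write_sidecar(
    path: str | Path, stage: str, seed: int | None, config: Any, **extra: Any
) -> Path:
    """Write ``<path>.meta.json`` with stage name, seed and config hash."""
    path = Path(path)
    meta = {
        "stage": stage,
        "seed": seed,
        "config_hash": config_hash(config),
        "config": _jsonable(config),
        **_jsonable(extra),
    }
    side = path.with_name(path.name + ".meta.json")
    side.write_text(json.dumps(meta, indent=2, sort_keys=True))
    return side
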