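"""CSV/JSON/YAML readers and writers for all domain objects.

Dialects (bit-exact): UTF-8, comma separator, one header row, '.' decimal.

* trace CSV: ``time_s,fluorescence_afu``
* events CSV: ``time_s,kind,aliquot_volume_ul,aliquot_concentration_mM``
* cohort CSV: ``donor_id,group,em_nc_mv,em_cap_mv`` (extra columns kept)
* IVF CSV: ``patient_id,em_cap_mv,oocytes,fertilized_2pn`` or a
  precomputed ``fertilization_rate`` / ``ivf_success`` column
* reports: JSON with sorted keys
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from empredict.calibration import AdditionEvent, FluorescenceTrace
from empredict.errors import DataLoadError, TraceInvariantError

TRACE_COLUMNS = ["time_s", "fluorescence_afu"]
EVENT_COLUMNS = ["time_s", "kind", "aliquot_volume_ul", "aliquot_concentration_mM"]
COHORT_COLUMNS = ["donor_id", "group", "em_nc_mv", "em_cap_mv"]


def _read_csv(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataLoadError(f"{path}: file not found")
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed CSV structure
        raise DataLoadError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataLoadError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")
    return df


def _numeric(df: pd.DataFrame, column: str, path: Path) -> np.ndarray:
    values = pd.to_numeric(df[column], errors="coerce")
    bad = values.index[values.isna() & df[column].notna()]
    if len(bad) or values.isna().any():
        rows = list((values.index[values.isna()] + 2)[:5])  # +2: header + 1-based
        raise DataLoadError(
            f"{path}: column {column!r} has unparseable/missing values at line(s) {rows}"
        )
    return values.to_numpy(dtype=float)


def read_events(path: str | Path) -> list[AdditionEvent]:
    """Load an addition-event log, validating the event invariants."""
    path = Path(path)
    df = _read_csv(path, EVENT_COLUMNS)
    events = []
    for i, row in df.iterrows():
        line = i + 2
        kind = str(row["kind"]).strip()
        if kind not in ("valinomycin", "KCl"):
            raise DataLoadError(f"{path}: line {line}: unknown event kind {kind!r}")
        try:
            events.append(AdditionEvent(
                time=float(row["time_s"]),
                kind=kind,
                aliquot_volume=float(row["aliquot_volume_ul"]),
                aliquot_concentration=float(row["aliquot_concentration_mM"]),
            ))
        except (ValueError, TypeError) as exc:
            raise DataLoadError(f"{path}: line {line}: {exc}") from exc
    kinds = [e.kind for e in sorted(events, key=lambda e: e.time)]
    if "KCl" in kinds and "valinomycin" in kinds:
        if kinds.index("valinomycin") > kinds.index("KCl"):
            raise TraceInvariantError(
                f"{path}: valinomycin must precede all KCl additions"
            )
    return events


def write_events(events: list[AdditionEvent], path: str | Path) -> None:
    pd.DataFrame([
        {
            "time_s": e.time,
            "kind": e.kind,
            "aliquot_volume_ul": e.aliquot_volume,
            "aliquot_concentration_mM": e.aliquot_concentration,
        }
        for e in events
    ]).to_csv(path, index=False)


def read_trace(
    trace_path: str | Path,
    events_path: str | Path | None = None,
    initial_volume: float = 2.0,
    sample_id: str = "",
) -> FluorescenceTrace:
    """Load a fluorescence trace (and optionally its event log)."""
    trace_path = Path(trace_path)
    df = _read_csv(trace_path, TRACE_COLUMNS)
    time = _numeric(df, "time_s", trace_path)
    fluor = _numeric(df, "fluorescence_afu", trace_path)
    if np.any(np.diff(time) <= 0):
        bad = int(np.argmax(np.diff(time) <= 0)) + 3
        raise DataLoadError(f"{trace_path}: time not strictly increasing near line {bad}")
    events = read_events(events_path) if events_path else []
    try:
        return FluorescenceTrace(
            time=time, fluorescence=fluor, events=events,
            initial_volume=initial_volume,
            sample_id=sample_id or trace_path.stem,
        )
    except TraceInvariantError as exc:
        raise DataLoadError(f"{trace_path}: {exc}") from exc


def write_trace(
    trace: FluorescenceTrace,
    trace_path: str | Path,
    events_path: str | Path | None = None,
) -> None:
    pd.DataFrame({
        "time_s": trace.time,
        "fluorescence_afu": trace.fluorescence,
    }).to_csv(trace_path, index=False)
    if events_path is not None:
        write_events(trace.events, events_path)


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Load a donor cohort table with per-condition Em measurements."""
    path = Path(path)
    df = _read_csv(path, COHORT_COLUMNS)
    for col in ("em_nc_mv", "em_cap_mv"):
        _numeric(df, col, path)
    return df


def write_report(report: dict[str, Any], path: str | Path) -> None:
    """Serialize a report as deterministic JSON (sorted keys, 2-space
    indent, trailing newline)."""
    Path(path).write_text(
        json.dumps(report, sort_keys=True, indent=2, default=_jsonable) + "\n",
        encoding="utf-8",
    )


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def config_hash(config: Any) -> str:
    """Stable sha256 of a config (dataclass or dict) for provenance."""
    if dataclasses.is_dataclass(config) and not isinstance(config, type):
        config = dataclasses.asdict(config)
    blob = json.dumps(config, sort_keys=True, default=_jsonable)
    return hashlib.sha256(blob.encode("utf-8")).hexdigest()


def load_config_file(path: str | Path) -> dict[str, Any]:
    """Read a YAML or JSON key-value configuration file."""
    path = Path(path)
    if not path.exists():
        raise DataLoadError(f"{path}: config file not found")
    text = path.read_text(encoding="utf-8")
    try:
        data = yaml.safe_load(text)  # YAML is a superset of JSON
    except yaml.YAMLError as exc:
        raise DataLoadError(f"{path}: cannot parse config ({exc})") from exc
    if not isinstance(data, dict):
        raise DataLoadError(f"{path}: config must be a mapping")
    return data


def save_config_file(config: Any, path: str | Path) -> None:
    if dataclasses.is_dataclass(config) and not isinstance(config, type):
        config = dataclasses.asdict(config)
    Path(path).write_text(yaml.safe_dump(config, sort_keys=True), encoding="utf-8")
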