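"""Traces, light protocols, and report serialization.

A :class:`Trace` is a single-channel time series: modulated chlorophyll
fluorescence (arbitrary units), an electrochromic-shift absorbance change
(expressed as -dI/I), or a TCSPC photon-count histogram. A
:class:`Protocol` annotates a trace with the ordered light phases of the
measuring program (dark, actinic, far-red, saturating pulse, laser flash).

File dialect: traces are delimited text (comma or tab, auto-detected) with
a header naming one time column and one value column; protocols live in a
YAML/JSON sidecar. Time is converted to seconds on ingest regardless of the
declared unit. Phase membership uses half-open intervals [start, end): a
sample sitting exactly on a boundary belongs to the later phase.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import MalformedInputError, SchemaError

CHANNELS = ("fluorescence", "ecs_520", "ecs_546", "ecs_corrected", "tcspc")
PHASE_KINDS = ("dark", "actinic", "far_red", "saturating_pulse", "laser_flash")

#: recognised time-column headers and their conversion factor to seconds
_TIME_UNITS = {"time_s": 1.0, "time_ms": 1e-3, "time_us": 1e-6, "time_ps": 1e-12}
_VALUE_COLUMNS = ("value", "counts")

#: float format preserving full double precision on round trips
_FLOAT_FMT = "%.17g"


@dataclass(frozen=True)
class Trace:
    """A time-stamped single-channel signal.

    Parameters
    ----------
    time
        Sample times in seconds, strictly increasing.
    values
        Signal values (fluorescence a.u., -dI/I, or photon counts).
    channel
        One of ``fluorescence``, ``ecs_520``, ``ecs_546``, ``ecs_corrected``,
        ``tcspc``.
    meta
        Free-form metadata (instrument, TCSPC bin width, ...).
    """

    time: np.ndarray
    values: np.ndarray
    channel: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "values", values)
        if self.channel not in CHANNELS:
            raise MalformedInputError(f"unknown channel {self.channel!r}")
        if time.ndim != 1 or values.ndim != 1 or len(time) != len(values):
            raise MalformedInputError("time and values must be 1-D and equal length")
        if len(time) < 2:
            raise MalformedInputError("a trace needs at least 2 samples")
        if not (np.isfinite(time).all() and np.isfinite(values).all()):
            raise MalformedInputError("trace contains non-finite entries")
        bad = np.nonzero(np.diff(time) <= 0)[0]
        if bad.size:
            # +2: row numbering is 1-based and the offender is the later sample
            raise MalformedInputError(
                f"time not strictly increasing at row {bad[0] + 2}"
            )
        if self.channel == "tcspc":
            if (values < 0).any() or not np.allclose(values, np.round(values)):
                raise MalformedInputError("tcspc counts must be non-negative integers")

    @property
    def span(self) -> tuple[float, float]:
        return float(self.time[0]), float(self.time[-1])

    def value_at(self, t: float) -> float:
        """Signal value at ``t`` by linear interpolation (no extrapolation)."""
        t0, t1 = self.span
        if not (t0 <= t <= t1):
            raise MalformedInputError(f"t={t} outside trace span [{t0}, {t1}]")
        return float(np.interp(t, self.time, self.values))


@dataclass(frozen=True)
class ProtocolPhase:
    """One light phase: [start_s, end_s) at a given intensity.

    ``intensity`` is in umol photons m-2 s-1 for light phases, 0 for dark;
    for ``laser_flash`` it is a unitless flash energy.
    """

    start_s: float
    end_s: float
    kind: str
    intensity: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in PHASE_KINDS:
            raise MalformedInputError(f"unknown phase kind {self.kind!r}")
        if not self.start_s < self.end_s:
            raise MalformedInputError(
                f"phase start {self.start_s} must precede end {self.end_s}"
            )
        if self.intensity < 0:
            raise MalformedInputError("intensity must be >= 0")
        if self.kind == "dark" and self.intensity != 0:
            raise MalformedInputError("dark phases must have intensity 0")

    def contains(self, t: float) -> bool:
        return self.start_s <= t < self.end_s


@dataclass(frozen=True)
class Protocol:
    """An ordered list of phases annotating one trace."""

    phases: tuple[ProtocolPhase, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "phases", tuple(self.phases))

    def of_kind(self, *kinds: str) -> list[ProtocolPhase]:
        return [p for p in self.phases if p.kind in kinds]

    def phase_at(self, t: float) -> ProtocolPhase | None:
        """Latest phase whose half-open interval contains ``t``."""
        hit = None
        for p in self.phases:
            if p.contains(t):
                hit = p
        return hit

    @classmethod
    def from_file(cls, path: str | Path) -> "Protocol":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, Mapping) or "phases" not in raw:
            raise SchemaError(f"{path}: protocol file needs a top-level 'phases' list")
        phases = [
            ProtocolPhase(
                start_s=float(p["start_s"]),
                end_s=float(p["end_s"]),
                kind=str(p["kind"]),
                intensity=float(p.get("intensity", 0.0)),
            )
            for p in raw["phases"]
        ]
        return cls(tuple(phases))

    def to_file(self, path: str | Path) -> None:
        payload = {
            "phases": [
                {
                    "start_s": p.start_s,
                    "end_s": p.end_s,
                    "kind": p.kind,
                    "intensity": p.intensity,
                }
                for p in self.phases
            ]
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def read_trace(path: str | Path, channel: str) -> Trace:
    """Read a delimited-text trace file.

    The header must name one time column (``time_s``/``time_ms``/``time_us``/
    ``time_ps``) and one value column (``value`` or ``counts``). The declared
    time unit is converted to seconds.
    """
    path = Path(path)
    text = path.read_text()
    delimiter = "\t" if "\t" in text.splitlines()[0] else ","
    df = pd.read_csv(path, sep=delimiter)
    time_col = next((c for c in df.columns if c in _TIME_UNITS), None)
    value_col = next((c for c in df.columns if c in _VALUE_COLUMNS), None)
    if time_col is None or value_col is None:
        raise SchemaError(
            f"{path}: expected a time column {sorted(_TIME_UNITS)} and a value "
            f"column {sorted(_VALUE_COLUMNS)}, found {list(df.columns)}"
        )
    time = df[time_col].to_numpy(dtype=float) * _TIME_UNITS[time_col]
    values = df[value_col].to_numpy(dtype=float)
    meta = {"source": str(path), "time_column": time_col}
    return Trace(time=time, values=values, channel=channel, meta=meta)


def write_trace(trace: Trace, path: str | Path) -> None:
    """Write a trace as CSV with full double precision (round-trip safe)."""
    time_col, scale = ("time_ps", 1e12) if trace.channel == "tcspc" else ("time_s", 1.0)
    value_col = "counts" if trace.channel == "tcspc" else "value"
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow([time_col, value_col])
        for t, v in zip(trace.time, trace.values):
            writer.writerow([_FLOAT_FMT % (t * scale), _FLOAT_FMT % v])


def validate_protocol(protocol: Protocol, trace: Trace) -> list[str]:
    """Diagnostic check of a protocol against a trace.

    Returns a (possibly empty) list of human-readable findings; never raises
    and never mutates its inputs.
    """
    findings: list[str] = []
    t0, t1 = trace.span
    starts = [p.start_s for p in protocol.phases]
    if starts != sorted(starts):
        findings.append("phases are not sorted by start time")
    for p in protocol.phases:
        if p.start_s < t0 - 1e-12 or p.end_s > t1 + 1e-12:
            findings.append(
                f"phase {p.kind} [{p.start_s}, {p.end_s}) exceeds trace span "
                f"[{t0}, {t1}]"
            )
    events = protocol.of_kind("saturating_pulse", "laser_flash")
    for a, b in zip(events, events[1:]):
        if b.start_s < a.end_s:
            findings.append(
                f"{a.kind} [{a.start_s}, {a.end_s}) overlaps "
                f"{b.kind} [{b.start_s}, {b.end_s})"
            )
    return findings


def _jsonable(value: Any) -> Any:
    if isinstance(value, (np.floating, np.integer)):
        return value.item()
    if isinstance(value, np.ndarray):
        return value.tolist()
    return value


def write_report(records: Sequence[Mapping[str, Any]] | Mapping[str, Any],
                 path: str | Path) -> None:
    """Write result records deterministically as JSON or CSV (by extension).

    Keys are sorted and floats serialized at full precision, so two writes of
    the same records are byte-identical.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = _deep_jsonable(records)
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        return
    # CSV: flat tabular records
    rows = list(records) if not isinstance(records, Mapping) else [records]
    columns = sorted({k for r in rows for k in r})
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(columns)
        for r in rows:
            out = []
            for c in columns:
                v = _jsonable(r.get(c, ""))
                if isinstance(v, float):
                    v = _FLOAT_FMT % v
                out.append(v)
            writer.writerow(out)


def _deep_jsonable(obj: Any) -> Any:
    if isinstance(obj, Mapping):
        return {str(k): _deep_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_deep_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    v = _jsonable(obj)
    if isinstance(v, float) and not math.isfinite(v):
        return str(v)
    return v


def read_report(path: str | Path) -> Any:
    """Read back a JSON or CSV report written by :func:`write_report`."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        return json.loads(path.read_text())
    df = pd.read_csv(path)
    return df.to_dict(orient="records")
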