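"""Readers and writers for every external file the pipeline touches.

All on-disk formats are plain comma-separated text with fixed dialects:

* **raw recording** — header ``time_s,ax_g,ay_g,az_g``; one tri-axial
  acceleration sample (gravitational units) per row.
* **counts series** — ``#``-prefixed metadata preamble (epoch length,
  start time, wrist side), then header ``epoch_start_s,axis1,axis2,axis3``
  with an optional ``vm`` column.  The vector magnitude is recomputed on
  read and checked against a stored column.
* **annotation export** — ``track,code,onset_ms,offset_ms`` rows exported
  from behavioral-coding software; times in milliseconds at the file
  boundary, seconds everywhere in memory.  Point events (movement bouts)
  carry ``offset == onset``.
* **cohort table** — one wide row per (child, phase) holding every outcome
  column.
* **report** — a rendered group-summary table with significance flags.

Every parser rejects invariant violations with a :class:`FormatError`
naming the offending line; nothing is silently coerced.  Intervals are
half-open ``[onset, offset)`` so abutting intervals tile without double
counting, and all timestamps are session-relative (0 = monitor-on).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

WRIST_SIDES = ("affected", "unaffected")

ARM_USE_CODES = ("bimanual", "unimanual_affected", "unimanual_unaffected")
ASSISTANCE_CODES = ("independent", "assisted", "no_activity")
NAVIGATION_CODES = ("nav",)
BOUT_TRACK = "bout"

TRACK_VOCAB: Mapping[str, tuple[str, ...]] = {
    "navigation": NAVIGATION_CODES,
    "arm_use": ARM_USE_CODES,
    "affected_assistance": ASSISTANCE_CODES,
}

#: tolerance (counts) for stored-vs-recomputed vector magnitude
VM_TOLERANCE = 0.5


class FormatError(ValueError):
    """A file violated its dialect; carries the path and 1-based line number."""

    def __init__(self, path, lineno: int | None, message: str):
        self.path = str(path)
        self.lineno = lineno
        where = f"{self.path}" + (f", line {lineno}" if lineno is not None else "")
        super().__init__(f"{where}: {message}")


# ---------------------------------------------------------------------------
# domain containers


@dataclass(frozen=True)
class Interval:
    """Half-open coded interval ``[onset_s, offset_s)`` with a category code."""

    code: str
    onset_s: float
    offset_s: float

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass
class RawRecording:
    """Raw tri-axial wrist acceleration in gravitational units."""

    wrist_side: str
    sampling_rate_hz: float
    dynamic_range_g: float
    samples: np.ndarray  # shape (n, 4): time_s, ax_g, ay_g, az_g

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.wrist_side not in WRIST_SIDES:
            raise ValueError(f"wrist_side must be one of {WRIST_SIDES}")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.dynamic_range_g <= 0:
            raise ValueError("dynamic_range_g must be positive")
        if self.samples.ndim != 2 or self.samples.shape[1] != 4:
            raise ValueError("samples must have shape (n, 4)")
        t = self.samples[:, 0]
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("non-monotone time")
        if np.any(np.abs(self.samples[:, 1:]) > self.dynamic_range_g + 1e-12):
            raise ValueError("sample exceeds dynamic range")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def duration_s(self) -> float:
        if self.n_samples == 0:
            return 0.0
        # nominal duration: one sample period past the last timestamp
        return float(self.samples[-1, 0] - self.samples[0, 0]) + 1.0 / self.sampling_rate_hz


@dataclass
class CountsSeries:
    """Per-epoch tri-axial activity counts and vector magnitude for one wrist."""

    wrist_side: str
    epoch_len_s: int
    epochs: np.ndarray  # shape (n, 5): epoch_start_s, axis1, axis2, axis3, vm

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.wrist_side not in WRIST_SIDES:
            raise ValueError(f"wrist_side must be one of {WRIST_SIDES}")
        if int(self.epoch_len_s) != self.epoch_len_s or self.epoch_len_s <= 0:
            raise ValueError("epoch_len_s must be a positive integer")
        self.epoch_len_s = int(self.epoch_len_s)
        if self.epochs.ndim != 2 or self.epochs.shape[1] != 5:
            raise ValueError("epochs must have shape (n, 5)")
        if np.any(self.epochs[:, 1:] < 0):
            raise ValueError("negative counts")
        starts = self.epochs[:, 0]
        if len(starts) > 1 and not np.allclose(np.diff(starts), self.epoch_len_s):
            raise ValueError("inconsistent epoch spacing")
        vm = np.sqrt(np.sum(self.epochs[:, 1:4] ** 2, axis=1))
        if np.any(np.abs(vm - self.epochs[:, 4]) > VM_TOLERANCE):
            raise ValueError("vm mismatch with per-axis counts")

    @property
    def n_epochs(self) -> int:
        return len(self.epochs)

    @property
    def starts_s(self) -> np.ndarray:
        return self.epochs[:, 0]

    @property
    def axis_counts(self) -> np.ndarray:
        return self.epochs[:, 1:4]

    @property
    def vm(self) -> np.ndarray:
        return self.epochs[:, 4]

    @property
    def duration_s(self) -> float:
        return self.n_epochs * float(self.epoch_len_s)


@dataclass
class AnnotationStream:
    """Typed, timed behavioral codes for one session's video.

    ``tracks`` maps a track name to its (non-overlapping, half-open)
    interval list; ``bout_events`` are coded point events — affected-arm
    joystick efforts, each one acceleration plus one deceleration.
    """

    session_id: str
    session_duration_s: float
    tracks: dict[str, list[Interval]] = field(default_factory=dict)
    bout_events: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.session_duration_s <= 0:
            raise ValueError("session_duration_s must be positive")
        for track, intervals in self.tracks.items():
            vocab = TRACK_VOCAB.get(track)
            if vocab is None:
                raise ValueError(f"unknown track {track!r}")
            intervals.sort(key=lambda iv: iv.onset_s)
            prev_end = -math.inf
            for iv in intervals:
                if iv.code not in vocab:
                    raise ValueError(f"unknown code {iv.code!r} in track {track}")
                if iv.offset_s <= iv.onset_s:
                    raise ValueError(f"empty or inverted interval in track {track}")
                if iv.onset_s < prev_end - 1e-9:
                    raise ValueError(f"overlap in track {track}")
                if iv.onset_s < -1e-9 or iv.offset_s > self.session_duration_s + 1e-9:
                    raise ValueError(f"interval outside session in track {track}")
                prev_end = iv.offset_s
        for t in self.bout_events:
            if t < 0 or t > self.session_duration_s:
                raise ValueError("bout event outside session")
        self.bout_events = sorted(self.bout_events)


@dataclass
class CohortTable:
    """Wide per-(child, phase) table of all outcome measures."""

    data: pd.DataFrame  # must contain child_id, phase columns

    PHASES = ("early", "late")

    def __post_init__(self) -> None:
        df = self.data
        for col in ("child_id", "phase"):
            if col not in df.columns:
                raise ValueError(f"cohort table missing required column {col!r}")
        bad_phase = set(df["phase"]) - set(self.PHASES)
        if bad_phase:
            raise ValueError(f"unknown phase value(s) {sorted(bad_phase)}")
        if df.duplicated(["child_id", "phase"]).any():
            raise ValueError("duplicate (child_id, phase) row")
        pct_cols = [c for c in df.columns if c.startswith(("pct_", "quest_"))]
        vals = df[pct_cols].to_numpy(float) if pct_cols else np.empty((0, 0))
        if vals.size and (np.nanmin(vals) < -1e-9 or np.nanmax(vals) > 100 + 1e-9):
            raise ValueError("percentage column outside [0, 100]")

    def paired(self, column: str) -> pd.DataFrame:
        """Early/late values side by side for children observed in both phases."""
        wide = self.data.pivot(index="child_id", columns="phase", values=column)
        return wide.dropna().loc[:, list(self.PHASES)]


# ---------------------------------------------------------------------------
# raw recordings

_RAW_HEADER = "time_s,ax_g,ay_g,az_g"


def read_raw_recording(
    path, wrist_side: str, sampling_rate_hz: float = 30.0, dynamic_range_g: float = 8.0
) -> RawRecording:
    """Parse a raw-acceleration CSV into a validated :class:`RawRecording`."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or lines[0].strip() != _RAW_HEADER:
        raise FormatError(path, 1, f"expected header {_RAW_HEADER!r}")
    rows = []
    prev_t = -math.inf
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != 4:
            raise FormatError(path, lineno, f"expected 4 fields, got {len(parts)}")
        try:
            t, ax, ay, az = (float(p) for p in parts)
        except ValueError:
            raise FormatError(path, lineno, f"non-numeric field in {line!r}") from None
        if t <= prev_t:
            raise FormatError(path, lineno, "non-monotone time")
        prev_t = t
        for name, v in (("ax_g", ax), ("ay_g", ay), ("az_g", az)):
            if abs(v) > dynamic_range_g:
                raise FormatError(path, lineno, f"{name}={v} outside ±{dynamic_range_g} g")
        rows.append((t, ax, ay, az))
    arr = np.array(rows, float).reshape(-1, 4)
    return RawRecording(wrist_side, sampling_rate_hz, dynamic_range_g, arr)


def write_raw_recording(recording: RawRecording, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_RAW_HEADER + "\n")
        for t, ax, ay, az in recording.samples:
            fh.write(f"{t:.6f},{ax:.6f},{ay:.6f},{az:.6f}\n")


# ---------------------------------------------------------------------------
# counts series

_COUNTS_HEADER_BASE = ["epoch_start_s", "axis1", "axis2", "axis3"]


def read_counts_csv(path) -> CountsSeries:
    """Parse an activity-counts CSV (``#`` metadata preamble + epoch rows).

    A stored ``vm`` column is checked against the recomputed Euclidean norm
    of the per-axis counts (tolerance ``VM_TOLERANCE``); if absent, vm is
    recomputed.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    meta: dict[str, str] = {}
    body_start = 0
    for lineno, line in enumerate(lines, start=1):
        if line.startswith("#"):
            try:
                key, value = line[1:].split(":", 1)
            except ValueError:
                raise FormatError(path, lineno, f"malformed preamble line {line!r}") from None
            meta[key.strip()] = value.strip()
            body_start = lineno
        else:
            break
    for key in ("epoch_len_s", "wrist_side"):
        if key not in meta:
            raise FormatError(path, None, f"preamble missing {key!r}")
    try:
        epoch_len = int(meta["epoch_len_s"])
    except ValueError:
        raise FormatError(path, None, f"non-integer epoch_len_s {meta['epoch_len_s']!r}") from None
    wrist_side = meta["wrist_side"]
    if wrist_side not in WRIST_SIDES:
        raise FormatError(path, None, f"unknown wrist_side {wrist_side!r}")

    if body_start >= len(lines):
        raise FormatError(path, None, "missing header row")
    header_lineno = body_start + 1
    header = [h.strip() for h in lines[body_start].split(",")]
    if header[:4] != _COUNTS_HEADER_BASE or header[4:] not in ([], ["vm"]):
        raise FormatError(path, header_lineno, f"unexpected header {lines[body_start]!r}")
    has_vm = header[4:] == ["vm"]

    rows = []
    for lineno, line in enumerate(lines[header_lineno:], start=header_lineno + 1):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != len(header):
            raise FormatError(path, lineno, f"expected {len(header)} fields, got {len(parts)}")
        try:
            vals = [float(p) for p in parts]
        except ValueError:
            raise FormatError(path, lineno, f"non-numeric field in {line!r}") from None
        if any(v < 0 for v in vals[1:]):
            raise FormatError(path, lineno, "negative counts")
        vm_computed = math.sqrt(vals[1] ** 2 + vals[2] ** 2 + vals[3] ** 2)
        if has_vm and abs(vals[4] - vm_computed) > VM_TOLERANCE:
            raise FormatError(
                path, lineno, f"vm mismatch: stored {vals[4]}, recomputed {vm_computed:.3f}"
            )
        rows.append(vals[:4] + [vm_computed])
    arr = np.array(rows, float).reshape(-1, 5)
    if len(arr) > 1 and not np.allclose(np.diff(arr[:, 0]), epoch_len):
        raise FormatError(path, None, "inconsistent epoch spacing")
    try:
        return CountsSeries(wrist_side, epoch_len, arr)
    except ValueError as exc:
        raise FormatError(path, None, str(exc)) from None


def write_counts_csv(series: CountsSeries, path, start_time_s: float = 0.0) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# epoch_len_s: {series.epoch_len_s}\n")
        fh.write(f"# start_time_s: {start_time_s:g}\n")
        fh.write(f"# wrist_side: {series.wrist_side}\n")
        fh.write(",".join(_COUNTS_HEADER_BASE + ["vm"]) + "\n")
        for start, a1, a2, a3, vm in series.epochs:
            fh.write(f"{start:g},{a1:.4f},{a2:.4f},{a3:.4f},{vm:.4f}\n")


# ---------------------------------------------------------------------------
# annotation exports

_ANNOT_HEADER = "track,code,onset_ms,offset_ms"


def read_annotation_export(path) -> AnnotationStream:
    """Parse a behavioral-coding export into an :class:`AnnotationStream`.

    Dialect: optional ``# session_id:`` / ``# session_duration_s:`` preamble,
    then ``track,code,onset_ms,offset_ms`` rows.  Interval tracks use the
    controlled vocabularies in :data:`TRACK_VOCAB`; rows on the ``bout``
    track are point events with ``offset_ms == onset_ms``.  If no duration
    is declared, the largest offset is used.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    meta: dict[str, str] = {}
    body_start = 0
    for lineno, line in enumerate(lines, start=1):
        if line.startswith("#"):
            key, _, value = line[1:].partition(":")
            meta[key.strip()] = value.strip()
            body_start = lineno
        else:
            break
    if body_start >= len(lines) or lines[body_start].strip() != _ANNOT_HEADER:
        raise FormatError(path, body_start + 1, f"expected header {_ANNOT_HEADER!r}")

    tracks: dict[str, list[Interval]] = {}
    bouts: list[float] = []
    max_offset = 0.0
    for lineno, line in enumerate(lines[body_start + 1 :], start=body_start + 2):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != 4:
            raise FormatError(path, lineno, f"expected 4 fields, got {len(parts)}")
        track, code = parts[0].strip(), parts[1].strip()
        try:
            onset_s = float(parts[2]) / 1000.0
            offset_s = float(parts[3]) / 1000.0
        except ValueError:
            raise FormatError(path, lineno, f"non-numeric time in {line!r}") from None
        if offset_s < onset_s:
            raise FormatError(path, lineno, "offset before onset")
        max_offset = max(max_offset, offset_s)
        if track == BOUT_TRACK:
            bouts.append(onset_s)
            continue
        vocab = TRACK_VOCAB.get(track)
        if vocab is None:
            raise FormatError(path, lineno, f"unknown track {track!r}")
        if code not in vocab:
            raise FormatError(path, lineno, f"unknown code {code!r} for track {track}")
        if offset_s == onset_s:
            raise FormatError(path, lineno, f"zero-length interval in track {track}")
        tracks.setdefault(track, []).append(Interval(code, onset_s, offset_s))

    session_id = meta.get("session_id", path.stem)
    duration = float(meta["session_duration_s"]) if "session_duration_s" in meta else max_offset
    try:
        return AnnotationStream(session_id, duration, tracks, bouts)
    except ValueError as exc:
        raise FormatError(path, None, str(exc)) from None


def write_annotation_export(stream: AnnotationStream, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# session_id: {stream.session_id}\n")
        fh.write(f"# session_duration_s: {stream.session_duration_s:g}\n")
        fh.write(_ANNOT_HEADER + "\n")
        for track in sorted(stream.tracks):
            for iv in stream.tracks[track]:
                fh.write(f"{track},{iv.code},{iv.onset_s * 1000:g},{iv.offset_s * 1000:g}\n")
        for t in stream.bout_events:
            fh.write(f"{BOUT_TRACK},{BOUT_TRACK},{t * 1000:g},{t * 1000:g}\n")


# ---------------------------------------------------------------------------
# cohort tables


def read_cohort_csv(path) -> CohortTable:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(path, None, str(exc)) from None
    try:
        return CohortTable(df)
    except ValueError as exc:
        raise FormatError(path, None, str(exc)) from None


def write_cohort_csv(table: CohortTable, path) -> None:
    table.data.to_csv(path, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# rendered report


def format_mean_se(mean: float, se: float, decimals: int = 2) -> str:
    """Render a ``mean (SE)`` cell, e.g. ``79.29 (4.21)``."""
    return f"{mean:.{decimals}f} ({se:.{decimals}f})"


def format_median_iqr(median: float, q1: float, q3: float, decimals: int = 2) -> str:
    return f"{median:.{decimals}f} ({q1:.{decimals}f} to {q3:.{decimals}f})"


def significance_flag(p: float, alpha: float = 0.05, trend_alpha: float = 0.1) -> str:
    """``*`` at p ≤ alpha, ``†`` for a trend below trend_alpha, else empty."""
    if p <= alpha:
        return "*"
    if p < trend_alpha:
        return "†"
    return ""


def write_report(rows: Sequence[Mapping[str, object]], path, fmt: str = "csv") -> None:
    """Write a rendered group-summary report.

    Each row mapping must provide ``outcome``, ``early`` and ``late``
    (pre-rendered cells) and may provide ``p``/``flag``/``test``/``effect``.
    """
    required = ("outcome", "early", "late")
    for i, row in enumerate(rows):
        for col in required:
            if col not in row:
                raise ValueError(f"report row {i} missing required column {col!r}")
    df = pd.DataFrame(rows)
    path = Path(path)
    if fmt == "csv":
        df.to_csv(path, index=False, lineterminator="\n")
    elif fmt == "markdown":
        path.write_text(df.to_markdown(index=False) + "\n")
    else:
        raise ValueError(f"unknown report format {fmt!r}")
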