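"""Wrist accelerometry → bilateral arm-use metrics.

The measurement chain mirrors standard practice in upper-extremity (UE)
rehabilitation accelerometry: raw tri-axial acceleration is reduced to
per-epoch *activity counts*, combined into a vector magnitude (VM),
classified against children's counts-per-minute intensity cut-points at
60-s epochs, and compared across wrists at 1-s epochs through two
asymmetry metrics:

* **use ratio** — hours of affected-arm activity divided by hours of
  unaffected-arm activity (1 = equal duration of use);
* **magnitude ratio** — natural log of the per-epoch affected/unaffected
  VM ratio (0 = equal intensity), summarized by median and IQR because
  the per-epoch distribution is heavily skewed.

The vendor raw→counts conversion is proprietary; :func:`raw_to_counts`
implements an open surrogate (band-pass filter, dead-band, amplitude
quantization, per-epoch rectified integration) with its constants
documented below.  Pipelines that start from exported counts never touch
the surrogate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import signal

from .io_formats import CountsSeries, RawRecording

__all__ = [
    "IntensityCutpoints",
    "CountScale",
    "IntensityBreakdown",
    "BilateralSessionMetrics",
    "raw_to_counts",
    "counts_to_acceleration",
    "vector_magnitude",
    "reepoch",
    "classify_intensity",
    "use_ratio",
    "magnitude_ratio",
    "session_inclusion_filter",
    "child_phase_summary",
]

INTENSITY_LEVELS = ("sedentary", "light", "moderate", "vigorous")

#: clamp value for the log magnitude ratio when exactly one arm shows
#: zero counts in an epoch (convention from the UE-accelerometry
#: literature on bilateral magnitude ratios)
LOG_RATIO_CLAMP = 7.0


@dataclass(frozen=True)
class IntensityCutpoints:
    """Children's activity-intensity cut-points in counts/minute.

    An epoch at exactly a band maximum belongs to the lower band
    (e.g. 149 counts/min is sedentary), matching the closed printed
    ranges 0–149 / 150–499 / 500–3999 / ≥4000.
    """

    sedentary_max: float = 149.0
    light_max: float = 499.0
    moderate_max: float = 3999.0

    def __post_init__(self) -> None:
        if not (0 <= self.sedentary_max < self.light_max < self.moderate_max):
            raise ValueError("cut-points must be non-negative and strictly increasing")

    @property
    def band_edges(self) -> tuple[float, float, float]:
        return (self.sedentary_max, self.light_max, self.moderate_max)


@dataclass(frozen=True)
class CountScale:
    """Linear count → acceleration scale: 1 count = 0.001664 g = 0.0163072 m/s²."""

    g_per_count: float = 0.001664
    g_mps2: float = 9.8

    @property
    def mps2_per_count(self) -> float:
        return self.g_per_count * self.g_mps2


@dataclass(frozen=True)
class IntensityBreakdown:
    """Percent of classified 60-s epochs in each intensity band (sums to 100)."""

    pct_sedentary: float
    pct_light: float
    pct_moderate: float
    pct_vigorous: float

    def __post_init__(self) -> None:
        vals = self.as_tuple()
        if any(v < -1e-9 or v > 100 + 1e-9 for v in vals):
            raise ValueError("percentages must lie in [0, 100]")
        if abs(sum(vals) - 100.0) > 1e-6:
            raise ValueError("percentages must sum to 100")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.pct_sedentary, self.pct_light, self.pct_moderate, self.pct_vigorous)

    def as_dict(self) -> dict[str, float]:
        return dict(zip([f"pct_{l}" for l in INTENSITY_LEVELS], self.as_tuple()))


@dataclass
class BilateralSessionMetrics:
    """Use-ratio and magnitude-ratio summary for one session."""

    hours_use_affected: float
    hours_use_unaffected: float
    use_ratio: float | None  # None when undefined (no unaffected-arm use)
    magnitude_ratio_median: float | None
    magnitude_ratio_q1: float | None
    magnitude_ratio_q3: float | None
    n_epochs_used: int
    undefined_reason: str | None = None


# ---------------------------------------------------------------------------
# raw → counts surrogate

# Surrogate constants (the vendor algorithm is closed-source):
#  - Butterworth band-pass 0.25–2.5 Hz, order 3: keeps volitional arm
#    movement, rejects the DC/gravity component and high-frequency noise.
#  - dead-band 0.05 g: filtered amplitudes below this contribute nothing.
#  - quantization step 0.001664 g (the printed count scale).
# Epoch counts are the per-sample quantized rectified amplitudes integrated
# over the epoch (sum divided by the sampling rate), so counts are
# independent of sampling rate for a fixed underlying signal.
_BANDPASS_HZ = (0.25, 2.5)
_FILTER_ORDER = 3
_DEADBAND_G = 0.05
_QUANT_STEP_G = 0.001664
_MIN_SAMPLING_HZ = 20.0


def raw_to_counts(raw: RawRecording, epoch_len_s: int = 1) -> CountsSeries:
    """Convert raw acceleration to per-axis activity counts per epoch.

    A trailing partial epoch is dropped.  All-zero input yields all-zero
    counts (dead-band), and scaling the input amplitude up never decreases
    any epoch's counts (the chain is monotone in amplitude).
    """
    if raw.n_samples == 0:
        raise ValueError("empty recording")
    fs = raw.sampling_rate_hz
    if fs < _MIN_SAMPLING_HZ:
        raise ValueError(f"sampling rate {fs} Hz below minimum {_MIN_SAMPLING_HZ} Hz")
    samples_per_epoch = int(round(epoch_len_s * fs))
    n_epochs = raw.n_samples // samples_per_epoch
    if n_epochs == 0:
        raise ValueError("recording shorter than one epoch")

    sos = signal.butter(
        _FILTER_ORDER, _BANDPASS_HZ, btype="bandpass", fs=fs, output="sos"
    )
    acc = raw.samples[:, 1:4]
    filtered = signal.sosfilt(sos, acc, axis=0)
    rect = np.abs(filtered)
    rect = np.where(rect < _DEADBAND_G, 0.0, rect)
    quantized = np.floor(rect / _QUANT_STEP_G)

    t0 = raw.samples[0, 0]
    used = quantized[: n_epochs * samples_per_epoch]
    per_epoch = used.reshape(n_epochs, samples_per_epoch, 3).sum(axis=1) / fs
    starts = t0 + np.arange(n_epochs) * float(epoch_len_s)
    vm = np.sqrt((per_epoch**2).sum(axis=1))
    epochs = np.column_stack([starts, per_epoch, vm])
    return CountsSeries(raw.wrist_side, int(epoch_len_s), epochs)


def counts_to_acceleration(counts, scale: CountScale = CountScale()) -> np.ndarray | float:
    """Convert activity counts to acceleration in m/s² (1 count = 0.0163072 m/s²)."""
    arr = np.asarray(counts, dtype=float)
    if np.any(arr < 0):
        raise ValueError("negative counts")
    out = arr * scale.mps2_per_count
    return float(out) if out.ndim == 0 else out


def vector_magnitude(axis1, axis2, axis3) -> np.ndarray | float:
    """Euclidean norm of the three per-axis counts of an epoch."""
    a1, a2, a3 = (np.asarray(a, dtype=float) for a in (axis1, axis2, axis3))
    if np.any(a1 < 0) or np.any(a2 < 0) or np.any(a3 < 0):
        raise ValueError("negative counts")
    out = np.sqrt(a1**2 + a2**2 + a3**2)
    return float(out) if out.ndim == 0 else out


def reepoch(series: CountsSeries, target_len_s: int) -> CountsSeries:
    """Re-aggregate a counts series to a longer epoch length.

    Per-axis counts are summed within each target epoch and the vector
    magnitude recomputed on the summed axes (the VM of a sum is not the
    sum of VMs).  Disaggregation is not defined for counts and raises.
    A trailing partial target epoch is dropped.
    """
    target_len_s = int(target_len_s)
    if target_len_s == series.epoch_len_s:
        return CountsSeries(series.wrist_side, series.epoch_len_s, series.epochs.copy())
    if target_len_s < series.epoch_len_s:
        raise ValueError(
            f"cannot disaggregate {series.epoch_len_s}-s epochs to {target_len_s} s"
        )
    if target_len_s % series.epoch_len_s != 0:
        raise ValueError(
            f"target epoch {target_len_s} s is not a multiple of {series.epoch_len_s} s"
        )
    factor = target_len_s // series.epoch_len_s
    n_out = series.n_epochs // factor
    if n_out == 0:
        raise ValueError("series shorter than one target epoch")
    axes = series.axis_counts[: n_out * factor].reshape(n_out, factor, 3).sum(axis=1)
    t0 = series.starts_s[0] if series.n_epochs else 0.0
    starts = t0 + np.arange(n_out) * float(target_len_s)
    vm = np.sqrt((axes**2).sum(axis=1))
    return CountsSeries(series.wrist_side, target_len_s, np.column_stack([starts, axes, vm]))


def classify_intensity(
    series: CountsSeries,
    cutpoints: IntensityCutpoints = IntensityCutpoints(),
    use_vm: bool = True,
) -> tuple[np.ndarray, IntensityBreakdown]:
    """Label each 60-s epoch by intensity band and tabulate the breakdown.

    Classification uses the VM counts/min by default; ``use_vm=False``
    classifies on the first (vertical) axis instead, matching the original
    uniaxial formulation of the children's cut-points.
    """
    if series.epoch_len_s != 60:
        raise ValueError(f"intensity classification requires 60-s epochs, got {series.epoch_len_s}")
    cpm = series.vm if use_vm else series.axis_counts[:, 0]
    edges = cutpoints.band_edges
    idx = np.digitize(cpm, [e + 0.0 for e in edges], right=True)  # band max → lower band
    labels = np.array(INTENSITY_LEVELS, dtype=object)[idx]
    n = len(cpm)
    if n == 0:
        raise ValueError("no epochs to classify")
    pcts = [100.0 * np.sum(idx == k) / n for k in range(4)]
    return labels, IntensityBreakdown(*pcts)


def use_ratio(
    affected: CountsSeries,
    unaffected: CountsSeries,
    activity_threshold: float = 0.0,
) -> BilateralSessionMetrics:
    """Hours-of-use ratio between arms from paired 1-s counts series.

    A 1-s epoch counts as "use" when its VM exceeds ``activity_threshold``
    (default 0 counts).  Values < 1 indicate greater use of the
    unaffected/dominant arm.  The magnitude-ratio fields of the returned
    record are left unset; see :func:`magnitude_ratio`.
    """
    _check_paired_grids(affected, unaffected)
    sec = float(affected.epoch_len_s)
    hours_aff = float(np.sum(affected.vm > activity_threshold)) * sec / 3600.0
    hours_un = float(np.sum(unaffected.vm > activity_threshold)) * sec / 3600.0
    if hours_un == 0:
        return BilateralSessionMetrics(
            hours_aff, hours_un, None, None, None, None, 0,
            undefined_reason="no unaffected-arm use above threshold",
        )
    return BilateralSessionMetrics(
        hours_aff, hours_un, hours_aff / hours_un, None, None, None, affected.n_epochs
    )


def magnitude_ratio(
    affected: CountsSeries, unaffected: CountsSeries
) -> tuple[np.ndarray, dict[str, float], int]:
    """Per-epoch natural-log VM ratio (affected/unaffected) with median/IQR.

    Epochs where both arms show zero VM are excluded; epochs where exactly
    one arm is zero are clamped to ±:data:`LOG_RATIO_CLAMP`.  Returns the
    retained per-epoch series, a ``{median, q1, q3}`` summary, and the
    number of retained epochs.  Raises when no epoch is retained.
    """
    _check_paired_grids(affected, unaffected)
    a, u = affected.vm, unaffected.vm
    both_zero = (a == 0) & (u == 0)
    keep = ~both_zero
    a, u = a[keep], u[keep]
    with np.errstate(divide="ignore"):
        ratio = np.where(
            a == 0, -LOG_RATIO_CLAMP, np.where(u == 0, LOG_RATIO_CLAMP, np.log(np.divide(a, np.where(u == 0, 1.0, u))))
        )
    ratio = np.clip(ratio, -LOG_RATIO_CLAMP, LOG_RATIO_CLAMP)
    if len(ratio) == 0:
        raise ValueError("magnitude ratio undefined: no epochs with activity on either arm")
    q1, med, q3 = np.percentile(ratio, [25, 50, 75])
    return ratio, {"median": float(med), "q1": float(q1), "q3": float(q3)}, int(len(ratio))


def _check_paired_grids(a: CountsSeries, b: CountsSeries) -> None:
    if a.epoch_len_s != b.epoch_len_s:
        raise ValueError("epoch lengths differ between arms")
    if a.n_epochs != b.n_epochs or not np.allclose(a.starts_s, b.starts_s):
        raise ValueError("epoch grids differ between arms")


# ---------------------------------------------------------------------------
# inclusion filtering and phase aggregation


@dataclass(frozen=True)
class SessionRecord:
    """Minimal per-session availability metadata for inclusion filtering."""

    child_id: str
    phase: str  # early | late
    session_id: str
    has_affected: bool = True
    has_unaffected: bool = True


@dataclass
class InclusionResult:
    """Who enters which analysis, with logged exclusion reasons."""

    bilateral_children: list[str]
    affected_only_children: list[str]
    exclusions: dict[str, list[str]] = field(default_factory=dict)


def session_inclusion_filter(
    sessions: Iterable[SessionRecord], min_sessions: int = 3
) -> InclusionResult:
    """Apply the ≥ ``min_sessions``-per-phase wear-compliance rule.

    A child enters bilateral (use-/magnitude-ratio) analyses only when both
    phases hold at least ``min_sessions`` sessions with both-wrist data,
    and enters affected-arm-only (intensity) analyses when both phases
    hold at least ``min_sessions`` sessions with affected-wrist data.
    """
    by_child: dict[str, list[SessionRecord]] = {}
    for rec in sessions:
        if rec.phase not in ("early", "late"):
            raise ValueError(f"unknown phase {rec.phase!r}")
        by_child.setdefault(rec.child_id, []).append(rec)

    bilateral, affected_only, exclusions = [], [], {}
    for child in sorted(by_child):
        recs = by_child[child]
        reasons = []
        ok_bilateral = ok_affected = True
        for phase in ("early", "late"):
            n_both = sum(1 for r in recs if r.phase == phase and r.has_affected and r.has_unaffected)
            n_aff = sum(1 for r in recs if r.phase == phase and r.has_affected)
            if n_aff < min_sessions:
                ok_affected = False
                reasons.append(
                    f"insufficient {phase} sessions with affected-wrist data "
                    f"({n_aff} < {min_sessions})"
                )
            if n_both < min_sessions:
                ok_bilateral = False
                if n_aff >= min_sessions:
                    reasons.append(
                        f"insufficient {phase} sessions with both-wrist data "
                        f"({n_both} < {min_sessions})"
                    )
        if ok_affected:
            affected_only.append(child)
        if ok_bilateral:
            bilateral.append(child)
        if reasons:
            exclusions[child] = reasons
    return InclusionResult(bilateral, affected_only, exclusions)


def child_phase_summary(
    session_values: Sequence[float], metric: str = "mean"
) -> float:
    """Collapse session-level values to one per-child phase value.

    Unweighted mean across sessions; magnitude-ratio medians are collapsed
    by the median instead (``metric="median"``), keeping the summary on the
    same robust scale as the per-session statistic.
    """
    vals = np.asarray(list(session_values), dtype=float)
    if vals.size == 0:
        raise ValueError("empty phase: no session values")
    if metric == "mean":
        return float(np.mean(vals))
    if metric == "median":
        return float(np.median(vals))
    raise ValueError(f"unknown aggregation {metric!r}")
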