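"""Video-coded outcome measures of affected-arm use during navigation.

All metrics are restricted — by half-open interval intersection — to the
*navigation* portion of a session (the time the ride-on toy is in motion):

* percent of navigation time in bimanual vs unimanual joystick activity,
  and their ratio (higher = more bimanual relative to unimanual use);
* the independent / assisted / no-activity breakdown of affected-arm
  activity (the assistance track must cover navigation);
* the rate of affected-arm movement bouts per navigation minute.

Bouts enter as coded point events (one acceleration + one deceleration per
bout, coded by a human rater), not signal-detected episodes.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_formats import AnnotationStream

__all__ = [
    "VideoSessionMetrics",
    "navigation_gate",
    "bimanual_unimanual",
    "independence_breakdown",
    "bout_rate",
    "compute_video_metrics",
]

#: maximum tolerated gap (s) in the assistance track's cover of navigation
COVERAGE_TOLERANCE_S = 0.5


@dataclass
class VideoSessionMetrics:
    navigation_s: float
    pct_bimanual: float
    pct_unimanual: float
    bim_unim_ratio: float | None  # None when no unimanual time (undefined, not inf)
    pct_independent: float
    pct_assisted: float
    pct_no_activity: float
    bout_count: int
    bout_rate_per_min: float


def _merge(intervals: list[tuple[float, float]]) -> list[tuple[float, float]]:
    """Union of half-open intervals as a sorted disjoint list."""
    out: list[tuple[float, float]] = []
    for a, b in sorted(intervals):
        if out and a <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], b))
        else:
            out.append((a, b))
    return out


def _intersect_len(ivs: list[tuple[float, float]], gates: list[tuple[float, float]]) -> float:
    total = 0.0
    for a, b in ivs:
        for ga, gb in gates:
            lo, hi = max(a, ga), min(b, gb)
            if hi > lo:
                total += hi - lo
    return total


def navigation_gate(stream: AnnotationStream) -> tuple[list[tuple[float, float]], float]:
    """Union of navigation intervals and its total duration in seconds."""
    nav = stream.tracks.get("navigation", [])
    if not nav:
        raise ValueError("empty navigation track")
    gates = _merge([(iv.onset_s, iv.offset_s) for iv in nav])
    return gates, sum(b - a for a, b in gates)


def bimanual_unimanual(stream: AnnotationStream) -> tuple[float, float, float | None]:
    """(pct_bimanual, pct_unimanual, bimanual−unimanual ratio) over navigation.

    Unimanual time pools both unimanual codes (affected-only and
    unaffected-only use).  A session with zero unimanual time has an
    undefined ratio, returned as ``None`` rather than infinity.
    """
    gates, nav_s = navigation_gate(stream)
    arm = stream.tracks.get("arm_use", [])
    bim = _intersect_len([(iv.onset_s, iv.offset_s) for iv in arm if iv.code == "bimanual"], gates)
    uni = _intersect_len(
        [(iv.onset_s, iv.offset_s) for iv in arm if iv.code.startswith("unimanual")], gates
    )
    ratio = bim / uni if uni > 0 else None
    return 100.0 * bim / nav_s, 100.0 * uni / nav_s, ratio


def independence_breakdown(stream: AnnotationStream) -> tuple[float, float, float]:
    """Percent of navigation in independent / assisted / no-activity bouts.

    The affected-assistance track must cover navigation; a gap larger than
    :data:`COVERAGE_TOLERANCE_S` raises, naming the gap.  Percentages are
    renormalized over the covered time so they sum to exactly 100.
    """
    gates, nav_s = navigation_gate(stream)
    track = stream.tracks.get("affected_assistance", [])
    ivs = [(iv.onset_s, iv.offset_s) for iv in track]
    covered = _merge(ivs)
    # locate the largest uncovered stretch of navigation
    gap_total = nav_s - _intersect_len(covered, gates)
    if gap_total > COVERAGE_TOLERANCE_S:
        gap = _largest_gap(covered, gates)
        raise ValueError(
            f"assistance coverage gap of {gap_total:.2f} s in navigation "
            f"(largest at [{gap[0]:.2f}, {gap[1]:.2f}))"
        )
    secs = {}
    for code in ("independent", "assisted", "no_activity"):
        secs[code] = _intersect_len(
            [(iv.onset_s, iv.offset_s) for iv in track if iv.code == code], gates
        )
    total = sum(secs.values())
    if total == 0:
        raise ValueError("assistance track empty over navigation")
    return tuple(100.0 * secs[c] / total for c in ("independent", "assisted", "no_activity"))


def _largest_gap(covered, gates):
    best = (0.0, 0.0)
    for ga, gb in gates:
        pos = ga
        for a, b in covered:
            if a > pos and min(a, gb) - pos > best[1] - best[0] and pos < gb:
                best = (pos, min(a, gb))
            pos = max(pos, b)
            if pos >= gb:
                break
        if pos < gb and gb - pos > best[1] - best[0]:
            best = (pos, gb)
    return best


def bout_rate(stream: AnnotationStream) -> tuple[int, float]:
    """Count of coded movement bouts inside navigation, and bouts per
    navigation minute."""
    gates, nav_s = navigation_gate(stream)
    if nav_s == 0:
        raise ValueError("zero navigation time")
    count = sum(1 for t in stream.bout_events if any(a <= t < b for a, b in gates))
    return count, count / (nav_s / 60.0)


def compute_video_metrics(stream: AnnotationStream) -> VideoSessionMetrics:
    """All per-session video metrics in one pass."""
    _, nav_s = navigation_gate(stream)
    pct_bim, pct_uni, ratio = bimanual_unimanual(stream)
    pct_ind, pct_ass, pct_no = independence_breakdown(stream)
    n_bouts, rate = bout_rate(stream)
    return VideoSessionMetrics(
        navigation_s=nav_s,
        pct_bimanual=pct_bim,
        pct_unimanual=pct_uni,
        bim_unim_ratio=ratio,
        pct_independent=pct_ind,
        pct_assisted=pct_ass,
        pct_no_activity=pct_no,
        bout_count=n_bouts,
        bout_rate_per_min=rate,
    )
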