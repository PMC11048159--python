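"""Synthetic dual-wrist accelerometry and video-annotation generator.

Emulates the statistical structure the analysis assumes, with known
ground truth, so every pipeline stage can be exercised without external
data:

* per session, each 60-s block draws an intensity state (sedentary /
  light / moderate / vigorous) from a phase-specific mixture, the
  unaffected-arm counts/min are drawn uniformly within the state's
  cut-point band, and 1-s counts are apportioned with multiplicative
  noise truncated at zero;
* the affected arm carries a multiplicative intensity deficit
  (``asymmetry_scale``) relative to the unaffected arm, and a fraction of
  epochs is zeroed to hit a target active-time ratio;
* coded video streams tile a configurable navigation fraction with
  arm-use and assistance intervals (expected bimanual share and
  independence mixture configurable) and overlay a Poisson process of
  movement bouts restricted to navigation;
* per-child QUEST sub-domain scores with a configurable pre→post gain;
* a cohort-level driver writes the full file tree through
  :mod:`wristmetrics.io_formats`, including deliberately wear-
  non-compliant children to exercise the session-inclusion filter.

Counts are emitted as continuous values (vendor integer quantization is
not emulated).  Every stream of randomness is a named substream of the
master seed — keyed by (child, phase, session, stream) — so any subset of
the cohort regenerates identically.

Defaults describe a plausible ride-on-toy training cohort: 11 children,
5 sessions per week-long phase, 25-min sessions, an intensity mixture
dominated by moderate activity that shifts a further ~6 percentage points
toward moderate from early to late sessions, near-equal active time on
the two arms with a ~20% intensity deficit on the affected side, and a
bimanual share of navigation rising from 50% to 65%.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import io_formats
from .accelerometry import INTENSITY_LEVELS, SessionRecord
from .io_formats import AnnotationStream, CountsSeries, Interval, RawRecording

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "SimulatedCountsSession",
    "simulate_counts_session",
    "simulate_raw_session",
    "simulate_annotations",
    "simulate_cohort",
]

#: counts/min sampling band per intensity state (vigorous capped at 8000)
STATE_BANDS = ((0.0, 149.0), (150.0, 499.0), (500.0, 3999.0), (4000.0, 8000.0))

#: fixed unit direction distributing VM counts over the three axes
_AXIS_WEIGHTS = np.array([2.0 / 3.0, 1.0 / 3.0, 2.0 / 3.0])

#: raw-mode amplitude scale: g of oscillation amplitude per (count/s)
_RAW_G_PER_CPS = 0.01


def _normalized(p: Sequence[float], name: str) -> tuple[float, ...]:
    arr = np.asarray(p, float)
    if np.any(arr < 0):
        raise ValueError(f"{name} has negative entries")
    s = arr.sum()
    if abs(s - 1.0) > 1e-9:
        raise ValueError(f"{name} must sum to 1 (got {s})")
    return tuple(arr)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the simulated cohort (see module docstring)."""

    n_children: int = 11
    sessions_per_phase: int = 5
    session_len_s: int = 1500
    intensity_mix_early: tuple[float, ...] = (0.0453, 0.1293, 0.7929, 0.0325)
    intensity_mix_late: tuple[float, ...] = (0.0152, 0.1148, 0.8553, 0.0147)
    asymmetry_scale: float = 0.8
    #: SD of zero-mean log-scale per-session jitter on the asymmetry scale
    asymmetry_jitter_sd: float = 0.05
    active_time_ratio: float = 1.0
    #: SD of zero-mean log-scale per-session jitter on the active-time ratio
    active_ratio_jitter_sd: float = 0.02
    bimanual_prop_early: float = 0.5
    bimanual_prop_late: float = 0.65
    independence_mix: tuple[float, float, float] = (0.70, 0.11, 0.19)
    bout_rate_per_min: float = 39.6
    noise_cv: float = 0.25
    navigation_fraction: float = 0.5
    arm_noise: str = "shared"  # shared: affected = s × unaffected exactly
    quest_pre_means: tuple[float, float, float, float] = (60.9, 63.3, 72.0, 71.7)
    quest_pre_sd: float = 12.0
    quest_gain_means: tuple[float, float, float, float] = (4.3, 6.7, 6.6, 12.9)
    quest_gain_sd: float = 5.5
    #: children emitted with only 2 early sessions (fail the ≥3 rule)
    n_short_early_children: int = 3
    #: further children emitted without unaffected-wrist files
    n_unaffected_missing_children: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_children < 1 or self.sessions_per_phase < 1:
            raise ValueError("cohort dimensions must be positive")
        if self.session_len_s % 60 != 0:
            raise ValueError("session_len_s must be a multiple of 60")
        if not 1200 <= self.session_len_s <= 1800:
            raise ValueError("session_len_s must lie in [1200, 1800] (20–30 min)")
        for name in ("intensity_mix_early", "intensity_mix_late"):
            object.__setattr__(self, name, _normalized(getattr(self, name), name))
        object.__setattr__(
            self, "independence_mix", _normalized(self.independence_mix, "independence_mix")
        )
        if self.asymmetry_scale <= 0 or self.bout_rate_per_min < 0:
            raise ValueError("rates and scales must be positive")
        if self.active_time_ratio <= 0:
            raise ValueError("active_time_ratio must be positive")
        if self.asymmetry_jitter_sd < 0 or self.active_ratio_jitter_sd < 0:
            raise ValueError("jitter SDs must be non-negative")
        if not (0 <= self.bimanual_prop_early <= 1 and 0 <= self.bimanual_prop_late <= 1):
            raise ValueError("bimanual proportions must lie in [0, 1]")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if not 0 < self.navigation_fraction <= 1:
            raise ValueError("navigation_fraction must lie in (0, 1]")
        if self.arm_noise not in ("shared", "independent"):
            raise ValueError("arm_noise must be 'shared' or 'independent'")

    def intensity_mix(self, phase: str) -> tuple[float, ...]:
        return self.intensity_mix_early if phase == "early" else self.intensity_mix_late

    def bimanual_prop(self, phase: str) -> float:
        return self.bimanual_prop_early if phase == "early" else self.bimanual_prop_late

    def rng(self, child: int, phase: str, session: int, stream: str) -> np.random.Generator:
        """Named substream: any (child, phase, session, stream) regenerates
        identically regardless of what else is drawn."""
        phase_idx = {"early": 0, "late": 1}[phase]
        stream_idx = int.from_bytes(hashlib.sha256(stream.encode()).digest()[:4], "big")
        ss = np.random.SeedSequence(
            entropy=self.seed, spawn_key=(child, phase_idx, session, stream_idx)
        )
        return np.random.default_rng(ss)


@dataclass
class GroundTruth:
    """What the generator actually realized, for parameter-recovery checks."""

    states: np.ndarray | None = None  # per-60-s-block intensity index
    asymmetry_scale: float | None = None
    active_time_ratio: float | None = None
    bimanual_prop_configured: float | None = None
    bimanual_share_realized: float | None = None
    independence_mix: tuple[float, ...] | None = None
    bout_count: int | None = None
    navigation_s: float | None = None

    def state_percentages(self) -> dict[str, float]:
        n = len(self.states)
        return {
            f"pct_{lvl}": 100.0 * float(np.sum(self.states == k)) / n
            for k, lvl in enumerate(INTENSITY_LEVELS)
        }


@dataclass
class SimulatedCountsSession:
    affected_1s: CountsSeries
    unaffected_1s: CountsSeries
    affected_60s: CountsSeries
    unaffected_60s: CountsSeries
    truth: GroundTruth


def _axes_from_vm(starts: np.ndarray, vm: np.ndarray) -> np.ndarray:
    axes = vm[:, None] * _AXIS_WEIGHTS[None, :]
    return np.column_stack([starts, axes, vm])


def _aggregate_60(series: CountsSeries) -> CountsSeries:
    from .accelerometry import reepoch

    return reepoch(series, 60)


def simulate_counts_session(
    config: GeneratorConfig, child: int, phase: str, session: int = 0
) -> SimulatedCountsSession:
    """Simulate one session's paired 1-s and 60-s counts series.

    Per 60-s block a state is drawn from the phase's intensity mixture and
    the unaffected counts/min uniformly within the state's band; 1-s
    counts get multiplicative truncated-normal noise (CV ``noise_cv``).
    Affected 1-s counts are ``asymmetry_scale ×`` the unaffected counts
    epoch-wise (or independently re-noised under
    ``arm_noise="independent"``); epochs are then zeroed on one arm to hit
    ``active_time_ratio``.
    """
    n_blocks = config.session_len_s // 60
    n_sec = config.session_len_s
    rng = config.rng(child, phase, session, "counts")

    states = rng.choice(4, size=n_blocks, p=config.intensity_mix(phase))
    lows = np.array([STATE_BANDS[s][0] for s in states])
    highs = np.array([STATE_BANDS[s][1] for s in states])
    cpm = rng.uniform(lows, highs)
    base = np.repeat(cpm / 60.0, 60)  # per-second target counts

    def noise() -> np.ndarray:
        if config.noise_cv == 0:
            return np.ones(n_sec)
        return np.clip(rng.normal(1.0, config.noise_cv, size=n_sec), 0.0, None)

    # per-session realizations: zero-mean log-scale jitter around the
    # configured asymmetry scale and active-time ratio
    s_session = config.asymmetry_scale * (
        float(np.exp(rng.normal(0.0, config.asymmetry_jitter_sd)))
        if config.asymmetry_jitter_sd > 0 else 1.0
    )
    ratio = config.active_time_ratio * (
        float(np.exp(rng.normal(0.0, config.active_ratio_jitter_sd)))
        if config.active_ratio_jitter_sd > 0 else 1.0
    )

    unaff = base * noise()
    if config.arm_noise == "shared":
        aff = s_session * unaff
    else:
        aff = s_session * base * noise()

    if ratio < 1.0:
        k = int(round((1.0 - ratio) * n_sec))
        idx = rng.choice(n_sec, size=k, replace=False)
        aff[idx] = 0.0
    elif ratio > 1.0:
        k = int(round((1.0 - 1.0 / ratio) * n_sec))
        idx = rng.choice(n_sec, size=k, replace=False)
        unaff[idx] = 0.0

    starts = np.arange(n_sec, dtype=float)
    aff_1s = CountsSeries("affected", 1, _axes_from_vm(starts, aff))
    unaff_1s = CountsSeries("unaffected", 1, _axes_from_vm(starts, unaff))
    truth = GroundTruth(
        states=states,
        asymmetry_scale=s_session,
        active_time_ratio=ratio,
    )
    return SimulatedCountsSession(
        aff_1s, unaff_1s, _aggregate_60(aff_1s), _aggregate_60(unaff_1s), truth
    )


def simulate_raw_session(
    config: GeneratorConfig,
    child: int,
    phase: str,
    session: int = 0,
    sampling_rate_hz: float = 30.0,
) -> tuple[RawRecording, RawRecording, GroundTruth]:
    """Simulate paired raw 30-Hz recordings realizing the counts profile.

    The raw signal is a band-limited oscillation (0.5–2 Hz, inside the
    surrogate counts filter pass-band) whose per-second amplitude scales
    with the session's target counts profile, so the downstream counts
    preserve the per-state intensity ordering.
    """
    sim = simulate_counts_session(config, child, phase, session)
    rng = config.rng(child, phase, session, "raw")
    n_sec = config.session_len_s
    fs = sampling_rate_hz
    n_samp = int(round(n_sec * fs))
    t = np.arange(n_samp) / fs

    freq = rng.uniform(0.5, 2.0)
    phase_off = rng.uniform(0, 2 * np.pi, size=3)
    carrier = np.sin(2 * np.pi * freq * t[:, None] + phase_off[None, :])

    recs = []
    for series, side in ((sim.affected_1s, "affected"), (sim.unaffected_1s, "unaffected")):
        amp_per_sec = _RAW_G_PER_CPS * series.vm  # g per 1-s slot
        amp = np.repeat(amp_per_sec, int(fs))[:n_samp]
        acc = np.clip(amp[:, None] * _AXIS_WEIGHTS[None, :] * carrier, -8.0, 8.0)
        samples = np.column_stack([t, acc])
        recs.append(RawRecording(side, fs, 8.0, samples))
    return recs[0], recs[1], sim.truth


def _tile_intervals(
    rng: np.random.Generator,
    segments: list[tuple[float, float]],
    codes: Sequence[str],
    probs: Sequence[float],
    mean_len_s: float = 10.0,
) -> list[Interval]:
    """Tile segments with abutting intervals, codes i.i.d. from ``probs``.

    Interval lengths are exponential (mean ``mean_len_s``) independent of
    the code, so the expected duration share of each code equals its
    probability.
    """
    out = []
    for a, b in segments:
        pos = a
        while pos < b - 1e-9:
            length = min(rng.exponential(mean_len_s) + 0.5, b - pos)
            code = codes[rng.choice(len(codes), p=list(probs))]
            out.append(Interval(code, pos, pos + length))
            pos += length
    return out


def simulate_annotations(
    config: GeneratorConfig, child: int, phase: str, session: int = 0
) -> tuple[AnnotationStream, GroundTruth]:
    """Simulate one session's coded video stream.

    Navigation occupies ``navigation_fraction`` of the session in 120-s
    cycles.  Within navigation, the arm-use track alternates bimanual and
    unimanual intervals (expected bimanual share = the phase's
    ``bimanual_prop``), the assistance track covers navigation with codes
    from ``independence_mix``, and bout events arrive as a Poisson process
    at ``bout_rate_per_min``.
    """
    rng = config.rng(child, phase, session, "annotations")
    total = float(config.session_len_s)
    cycle = 120.0
    nav_segments: list[tuple[float, float]] = []
    pos = 0.0
    while pos < total - 1e-9:
        seg_len = min(cycle, total - pos) * config.navigation_fraction
        if seg_len > 1.0:
            nav_segments.append((pos, pos + seg_len))
        pos += cycle
    nav_s = sum(b - a for a, b in nav_segments)

    bim_p = config.bimanual_prop(phase)
    arm_codes = ("bimanual", "unimanual_affected", "unimanual_unaffected")
    arm_probs = (bim_p, (1 - bim_p) / 2, (1 - bim_p) / 2)
    arm_use = _tile_intervals(rng, nav_segments, arm_codes, arm_probs)
    assist = _tile_intervals(
        rng, nav_segments, ("independent", "assisted", "no_activity"), config.independence_mix
    )

    bouts: list[float] = []
    for a, b in nav_segments:
        lam = config.bout_rate_per_min * (b - a) / 60.0
        n = rng.poisson(lam)
        bouts.extend(np.sort(rng.uniform(a, b, size=n)))

    stream = AnnotationStream(
        session_id=f"child{child:02d}_{phase}_s{session:02d}",
        session_duration_s=total,
        tracks={
            "navigation": [Interval("nav", a, b) for a, b in nav_segments],
            "arm_use": arm_use,
            "affected_assistance": assist,
        },
        bout_events=bouts,
    )
    bim_realized = sum(iv.duration_s for iv in arm_use if iv.code == "bimanual") / nav_s
    truth = GroundTruth(
        bimanual_prop_configured=bim_p,
        bimanual_share_realized=float(bim_realized),
        independence_mix=config.independence_mix,
        bout_count=len(bouts),
        navigation_s=float(nav_s),
    )
    return stream, truth


# ---------------------------------------------------------------------------
# cohort-level driver


@dataclass
class SimulatedCohort:
    """In-memory cohort bundle: sessions, annotations, QUEST, ground truth."""

    config: GeneratorConfig
    sessions: list[SessionRecord]
    counts: dict[tuple[str, str, str], SimulatedCountsSession]
    annotations: dict[tuple[str, str, str], AnnotationStream]
    quest: dict[str, dict[str, tuple[float, float, float, float]]]
    truths: dict[tuple[str, str, str], GroundTruth]


def _child_id(i: int) -> str:
    return f"c{i + 1:02d}"


def simulate_cohort(config: GeneratorConfig, out_dir=None) -> SimulatedCohort:
    """Simulate the whole cohort; optionally write the file tree.

    The last ``n_short_early_children`` children receive only 2 early
    sessions (failing the ≥3-session wear rule everywhere); the
    ``n_unaffected_missing_children`` before them lack unaffected-wrist
    files (retained for affected-arm-only analyses).  With the defaults
    (11 children, 3 + 1) this reproduces an 8-of-11 affected-arm /
    7-of-11 bilateral analysis set.

    When ``out_dir`` is given, writes
    ``children/<child>/<phase>/<session>/counts_*.csv`` and
    ``annotations.csv`` plus a ``quest.csv`` cohort file, all through the
    io_formats dialects; regeneration under the same seed is
    byte-identical.
    """
    sessions: list[SessionRecord] = []
    counts, annots, truths = {}, {}, {}
    quest: dict[str, dict[str, tuple]] = {}

    n = config.n_children
    short_early = set(range(max(0, n - config.n_short_early_children), n))
    un_missing = set(
        range(
            max(0, n - config.n_short_early_children - config.n_unaffected_missing_children),
            max(0, n - config.n_short_early_children),
        )
    )

    quest_subs = ("dissociated", "grasps", "weight_bearing", "protective_extension")
    for i in range(n):
        cid = _child_id(i)
        qrng = config.rng(i, "early", 0, "quest")
        pre = np.clip(
            qrng.normal(config.quest_pre_means, config.quest_pre_sd), 0, 100
        )
        post = np.clip(
            pre + qrng.normal(config.quest_gain_means, config.quest_gain_sd), 0, 100
        )
        quest[cid] = {"early": tuple(pre), "late": tuple(post)}

        for phase in ("early", "late"):
            n_sessions = config.sessions_per_phase
            if i in short_early and phase == "early":
                n_sessions = min(2, config.sessions_per_phase)
            for s in range(n_sessions):
                sid = f"s{s + 1:02d}"
                key = (cid, phase, sid)
                sim = simulate_counts_session(config, i, phase, s)
                stream, truth_a = simulate_annotations(config, i, phase, s)
                counts[key] = sim
                annots[key] = stream
                t = sim.truth
                t.bimanual_prop_configured = truth_a.bimanual_prop_configured
                t.bimanual_share_realized = truth_a.bimanual_share_realized
                t.bout_count = truth_a.bout_count
                t.navigation_s = truth_a.navigation_s
                truths[key] = t
                sessions.append(
                    SessionRecord(cid, phase, sid, True, i not in un_missing)
                )

    cohort = SimulatedCohort(config, sessions, counts, annots, quest, truths)
    if out_dir is not None:
        _write_cohort_tree(cohort, Path(out_dir))
    return cohort


def _write_cohort_tree(cohort: SimulatedCohort, root: Path) -> None:
    root.mkdir(parents=True, exist_ok=True)
    un_missing_children = {
        rec.child_id for rec in cohort.sessions if not rec.has_unaffected
    }
    for (cid, phase, sid), sim in cohort.counts.items():
        d = root / "children" / cid / phase / sid
        d.mkdir(parents=True, exist_ok=True)
        io_formats.write_counts_csv(sim.affected_1s, d / "counts_affected.csv")
        if cid not in un_missing_children:
            io_formats.write_counts_csv(sim.unaffected_1s, d / "counts_unaffected.csv")
        io_formats.write_annotation_export(cohort.annotations[(cid, phase, sid)], d / "annotations.csv")
    rows = ["child_id,phase," + ",".join(f"quest_{s}" for s in
            ("dissociated", "grasps", "weight_bearing", "protective_extension"))]
    for cid in sorted(cohort.quest):
        for phase in ("early", "late"):
            vals = cohort.quest[cid][phase]
            rows.append(f"{cid},{phase}," + ",".join(f"{v:.4f}" for v in vals))
    (root / "quest.csv").write_text("\n".join(rows) + "\n")
    manifest = {
        "config": asdict(cohort.config),
        "n_sessions": len(cohort.sessions),
    }
    (root / "generator_manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
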