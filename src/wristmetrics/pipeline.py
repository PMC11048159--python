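"""End-to-end orchestration: simulate or ingest → metrics → cohort → stats.

The run products are plain-text files under the output directory:
per-session and per-child-phase metric CSVs, the assembled cohort table,
the rendered group report with significance flags, a machine-readable
test-results CSV, and a reproducibility manifest (config hash, seed,
package version).  Metric outputs are byte-reproducible under a fixed
seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd

from . import __version__, accelerometry, io_formats, video_metrics
from .accelerometry import SessionRecord, session_inclusion_filter
from .io_formats import CohortTable
from .stats import CohortAnalysis, CohortResults, StatConfig, paired_t
from .synthetic import GeneratorConfig, SimulatedCohort, simulate_cohort

log = logging.getLogger("wristmetrics")

__all__ = [
    "RunConfig",
    "run",
    "reconcile_tables",
    "session_metrics_frame",
    "child_phase_frame",
    "assemble_cohort",
]


@dataclass
class RunConfig:
    mode: str = "simulate"  # simulate | ingest
    input_dir: str | None = None  # required in ingest mode
    output_dir: str = "wristmetrics_out"
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    stat_config: StatConfig = field(default_factory=StatConfig)
    activity_threshold: float = 0.0
    min_sessions: int = 3
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "ingest"):
            raise ValueError("mode must be 'simulate' or 'ingest'")
        if self.mode == "ingest" and not self.input_dir:
            raise ValueError("ingest mode requires input_dir")
        if self.mode == "simulate":
            if self.seed is None:
                self.seed = self.generator.seed
            else:
                self.generator = dataclasses.replace(self.generator, seed=self.seed)


# ---------------------------------------------------------------------------
# per-session metrics


def _accel_session_metrics(
    affected_1s, unaffected_1s, activity_threshold: float
) -> dict[str, float]:
    out: dict[str, float] = {}
    aff_60 = accelerometry.reepoch(affected_1s, 60)
    _, breakdown = accelerometry.classify_intensity(aff_60)
    out.update(breakdown.as_dict())
    if unaffected_1s is not None:
        use = accelerometry.use_ratio(affected_1s, unaffected_1s, activity_threshold)
        out["use_ratio"] = use.use_ratio if use.use_ratio is not None else np.nan
        _, summary, n_used = accelerometry.magnitude_ratio(affected_1s, unaffected_1s)
        out["magnitude_ratio_median"] = summary["median"]
        out["magnitude_ratio_q1"] = summary["q1"]
        out["magnitude_ratio_q3"] = summary["q3"]
        out["n_epochs_used"] = n_used
    return out


def _video_session_metrics(stream) -> dict[str, float]:
    m = video_metrics.compute_video_metrics(stream)
    return {
        "navigation_s": m.navigation_s,
        "pct_bimanual": m.pct_bimanual,
        "pct_unimanual": m.pct_unimanual,
        "bim_unim_ratio": m.bim_unim_ratio if m.bim_unim_ratio is not None else np.nan,
        "pct_independent": m.pct_independent,
        "pct_assisted": m.pct_assisted,
        "pct_no_activity": m.pct_no_activity,
        "bout_count": m.bout_count,
        "bout_rate_per_min": m.bout_rate_per_min,
    }


def session_metrics_frame(
    cohort: SimulatedCohort | None = None,
    input_dir: str | Path | None = None,
    activity_threshold: float = 0.0,
) -> tuple[pd.DataFrame, list[SessionRecord]]:
    """Per-session metric rows from an in-memory simulation or a file tree."""
    rows = []
    records: list[SessionRecord] = []
    if cohort is not None:
        records = list(cohort.sessions)
        for rec in records:
            key = (rec.child_id, rec.phase, rec.session_id)
            sim = cohort.counts[key]
            unaff = sim.unaffected_1s if rec.has_unaffected else None
            row = {"child_id": rec.child_id, "phase": rec.phase, "session_id": rec.session_id}
            row.update(_accel_session_metrics(sim.affected_1s, unaff, activity_threshold))
            row.update(_video_session_metrics(cohort.annotations[key]))
            rows.append(row)
    else:
        root = Path(input_dir) / "children"
        if not root.is_dir():
            raise FileNotFoundError(f"ingest: no 'children' directory under {input_dir}")
        for sdir in sorted(root.glob("*/*/*")):
            cid, phase, sid = sdir.parts[-3:]
            aff_path = sdir / "counts_affected.csv"
            un_path = sdir / "counts_unaffected.csv"
            ann_path = sdir / "annotations.csv"
            has_aff, has_un = aff_path.exists(), un_path.exists()
            records.append(SessionRecord(cid, phase, sid, has_aff, has_un))
            row = {"child_id": cid, "phase": phase, "session_id": sid}
            if has_aff:
                aff = io_formats.read_counts_csv(aff_path)
                unaff = io_formats.read_counts_csv(un_path) if has_un else None
                try:
                    row.update(_accel_session_metrics(aff, unaff, activity_threshold))
                except (ValueError, io_formats.FormatError) as exc:
                    raise RuntimeError(f"accelerometry: {sdir}: {exc}") from exc
            if ann_path.exists():
                try:
                    stream = io_formats.read_annotation_export(ann_path)
                    row.update(_video_session_metrics(stream))
                except (ValueError, io_formats.FormatError) as exc:
                    raise RuntimeError(f"video_metrics: {sdir}: {exc}") from exc
            elif not ann_path.exists() and has_aff:
                raise RuntimeError(f"video_metrics: file not found: {ann_path}")
            rows.append(row)
    return pd.DataFrame(rows), records


# the cohort-table columns each inclusion tier is allowed to contribute to
_BILATERAL_COLS = ("use_ratio", "magnitude_ratio_median", "magnitude_ratio_q1", "magnitude_ratio_q3")
_AFFECTED_COLS = ("pct_sedentary", "pct_light", "pct_moderate", "pct_vigorous")
_VIDEO_COLS = (
    "pct_bimanual", "pct_unimanual", "bim_unim_ratio",
    "pct_independent", "pct_assisted", "pct_no_activity",
    "bout_count", "bout_rate_per_min", "navigation_s",
)


def child_phase_frame(
    session_df: pd.DataFrame,
    records: list[SessionRecord],
    min_sessions: int = 3,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Collapse session metrics to per-(child, phase) rows under the
    ≥ ``min_sessions`` wear-compliance rule.

    Intensity columns need affected-wrist compliance; use/magnitude
    ratios need both-wrist compliance.  Video metrics have no wear rule
    (all coded sessions contribute).  Session-level values are averaged
    within child × phase (magnitude-ratio medians by the median).
    """
    inclusion = session_inclusion_filter(records, min_sessions)
    rows = []
    for (cid, phase), grp in session_df.groupby(["child_id", "phase"], sort=True):
        row: dict[str, object] = {"child_id": cid, "phase": phase}
        for col in session_df.columns:
            if col in ("child_id", "phase", "session_id"):
                continue
            vals = grp[col].dropna()
            if not len(vals):
                continue
            if col in _AFFECTED_COLS and cid not in inclusion.affected_only_children:
                continue
            if col in _BILATERAL_COLS and cid not in inclusion.bilateral_children:
                continue
            agg = "median" if col.startswith("magnitude_ratio") else "mean"
            row[col] = accelerometry.child_phase_summary(vals, agg)
        rows.append(row)
    return pd.DataFrame(rows), inclusion.exclusions


def assemble_cohort(
    child_phase_df: pd.DataFrame, quest_df: pd.DataFrame | None = None
) -> CohortTable:
    """Join per-child-phase metrics with QUEST sub-domain scores."""
    df = child_phase_df
    if quest_df is not None:
        df = df.merge(quest_df, on=["child_id", "phase"], how="outer")
    return CohortTable(df.sort_values(["child_id", "phase"]).reset_index(drop=True))


# ---------------------------------------------------------------------------
# full run


def run(config: RunConfig) -> CohortResults:
    """Execute the configured pipeline and write the output tree."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO, format="%(name)s %(levelname)s %(message)s")

    quest_df = None
    if config.mode == "simulate":
        log.info("stage simulate: seed=%s", config.generator.seed)
        cohort = simulate_cohort(config.generator, out_dir=out / "data")
        session_df, records = session_metrics_frame(
            cohort, activity_threshold=config.activity_threshold
        )
        quest_rows = []
        for cid, phases in cohort.quest.items():
            for phase, vals in phases.items():
                quest_rows.append({
                    "child_id": cid, "phase": phase,
                    "quest_dissociated": vals[0], "quest_grasps": vals[1],
                    "quest_weight_bearing": vals[2], "quest_protective_extension": vals[3],
                })
        quest_df = pd.DataFrame(quest_rows)
    else:
        log.info("stage ingest: %s", config.input_dir)
        session_df, records = session_metrics_frame(
            input_dir=config.input_dir, activity_threshold=config.activity_threshold
        )
        quest_path = Path(config.input_dir) / "quest.csv"
        if quest_path.exists():
            quest_df = pd.read_csv(quest_path)

    log.info("stage metrics: %d sessions", len(session_df))
    session_df.to_csv(out / "session_metrics.csv", index=False, lineterminator="\n", float_format="%.6f")
    phase_df, exclusions = child_phase_frame(session_df, records, config.min_sessions)
    phase_df.to_csv(out / "child_phase_metrics.csv", index=False, lineterminator="\n", float_format="%.6f")
    (out / "exclusions.json").write_text(json.dumps(exclusions, indent=2) + "\n")

    log.info("stage analyze: %d child-phase rows", len(phase_df))
    cohort_table = assemble_cohort(phase_df, quest_df)
    io_formats.write_cohort_csv(cohort_table, out / "cohort.csv")
    results = CohortAnalysis(cohort_table, config.stat_config).fit()
    results.write_report(out / "report.csv")
    results.write_report(out / "report.md", fmt="markdown")
    results.tests_frame().to_csv(out / "test_results.csv", index=False, lineterminator="\n")

    manifest = {
        "version": __version__,
        "mode": config.mode,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(
            json.dumps(dataclasses.asdict(config), sort_keys=True, default=str).encode()
        ).hexdigest(),
        "n_sessions": len(session_df),
        "n_children": int(session_df["child_id"].nunique()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    log.info("run complete: %s", out)
    return results


# ---------------------------------------------------------------------------
# published-table reconciliation


def reconcile_tables(
    per_child: pd.DataFrame, reference: pd.DataFrame | None = None
) -> dict[str, pd.DataFrame]:
    """Recompute group rows from a wide per-child intensity table and map
    them onto published-style summary rows.

    ``per_child`` holds one row per child with ``pct_<band>_<phase>``
    columns.  Returns the recomputed ``group`` frame (mean, SE per band
    and phase, plus the early-vs-late paired t), and — when ``reference``
    rows (label, early_mean, early_se, late_mean, late_se) are supplied —
    a ``mapping`` frame assigning each recomputed band to its
    nearest-match reference label.  The mapping is reported, never
    silently applied.
    """
    bands = sorted({
        c[len("pct_"):-len("_early")] for c in per_child.columns if c.endswith("_early")
    })
    if not bands:
        raise ValueError("no pct_<band>_early columns found")
    group_rows = []
    for band in bands:
        early = pd.to_numeric(per_child[f"pct_{band}_early"], errors="raise").to_numpy(float)
        late = pd.to_numeric(per_child[f"pct_{band}_late"], errors="raise").to_numpy(float)
        res = paired_t(early, late)
        group_rows.append({
            "band": band,
            "early_mean": early.mean(),
            "early_se": early.std(ddof=1) / np.sqrt(len(early)),
            "late_mean": late.mean(),
            "late_se": late.std(ddof=1) / np.sqrt(len(late)),
            "t": res.statistic,
            "df": res.df,
            "p": res.p_value,
        })
    group = pd.DataFrame(group_rows)
    out = {"group": group}
    if reference is not None:
        mapping_rows = []
        for _, g in group.iterrows():
            dist = (
                (reference["early_mean"] - g["early_mean"]).abs()
                + (reference["late_mean"] - g["late_mean"]).abs()
            )
            j = int(dist.idxmin())
            mapping_rows.append({
                "band": g["band"],
                "matched_label": reference.loc[j, "label"],
                "mean_abs_gap": float(dist.min()) / 2.0,
                "label_agrees": reference.loc[j, "label"] == g["band"],
            })
        out["mapping"] = pd.DataFrame(mapping_rows)
    return out
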