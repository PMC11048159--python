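"""Small example datasets bundled with the package.

``load_example_intensity_table`` returns per-child percent-time-by-
intensity data for the affected arm of eight children with hemiplegia,
measured by wrist accelerometry during early and late ride-on-toy
training sessions and classified with the children's counts/min
cut-points.  ``load_example_group_summary`` returns the corresponding
published-style group summary rows (mean (SE) per band and phase).

The two tables disagree on band labels: the group-summary rows carry the
intensity labels in the *reverse* order of the per-child columns
(summary "sedentary" ↔ per-child "vigorous", "light" ↔ "moderate", and
vice versa).  :func:`wristmetrics.pipeline.reconcile_tables` recovers
this mapping by nearest-match on the recomputed group means; it is the
worked reconciliation example used throughout the docs and tests.
"""

from __future__ import annotations

import io

import pandas as pd

_INTENSITY_CSV = """\
child_id,pct_sedentary_early,pct_sedentary_late,pct_light_early,pct_light_late,pct_moderate_early,pct_moderate_late,pct_vigorous_early,pct_vigorous_late
c01,1.14,0,98.86,97.73,0,2.273,0,0
c02,0,0,78,80.18,19.95,19.82,2.05,0
c03,0,1.25,83.69,91.84,12.82,6.912,3.49,0
c04,0,0,76.55,86.36,16.48,9.468,6.97,4.17
c05,0.69,0,70.56,74.39,24.49,22.18,4.26,3.43
c06,0,0,60.04,75.95,22.04,19.52,17.9,4.53
c07,14.6,0,76.22,88.43,7.678,11.57,1.52,0
c08,9.61,10.5,90.39,89.49,0,0,0,0
"""

_GROUP_SUMMARY_CSV = """\
label,early_mean,early_se,late_mean,late_se
sedentary,4.53,2.08,1.52,0.75
light,12.93,3.38,11.47,2.96
moderate,79.3,4.21,85.5,2.86
vigorous,3.25,1.99,1.47,1.3
"""


def load_example_intensity_table() -> pd.DataFrame:
    """Per-child affected-arm intensity percentages, early vs late sessions."""
    return pd.read_csv(io.StringIO(_INTENSITY_CSV))


def load_example_group_summary() -> pd.DataFrame:
    """Published-style group mean (SE) rows matching the per-child table
    (band labels reversed; see module docstring)."""
    return pd.read_csv(io.StringIO(_GROUP_SUMMARY_CSV))
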