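"""Worked-example data: a six-reader emergency-CTA reading study.

These tables summarize a crossed two-session reading study in which six
readers of three experience levels rated 119 emergency ECG-gated CT
angiograms (67 adjudicated myocardial infarctions: 22 STEMI, 45 NSTEMI;
52 without infarction) for hypodense myocardium, once with deviation-map
overlays and once without.  They serve three purposes here:

* worked examples for the aggregation and reclassification arithmetic,
* default operating points for the simulated reader panel, so that the
  synthetic pipeline reproduces a realistic reader mix out of the box,
* regression anchors for the reporting layer's rounding conventions.

All proportions are stored as percentages exactly as printed in the study
report; convert to proportions before feeding them to simulation code.
"""

from __future__ import annotations

import pandas as pd

from .mrmc import ConfusionCounts, ReclassTable
from .phantom import ReaderOperatingPoint

__all__ = [
    "READER_METRICS",
    "SUBGROUP_SENSITIVITY",
    "RECLASS_EXAMPLE",
    "REPORT_CONFUSION",
    "STUDY_COHORT_MIX",
    "default_reader_panel",
]

#: Cohort case mix of the study: (STEMI, NSTEMI, no infarction).
STUDY_COHORT_MIX = (22, 45, 52)

#: Per-reader diagnostic metrics (percent) with and without colormap
#: overlays, plus each reader's net reclassification index (percent).
READER_METRICS = pd.DataFrame(
    [
        # reader, experience, condition, sens, spec, acc, ppv, npv, nri_pct
        ("reader1", "junior resident", "without_colormap", 46.3, 92.3, 66.4, 88.6, 57.1, -6),
        ("reader1", "junior resident", "with_colormap", 46.4, 84.6, 62.8, 80.0, 54.3, -6),
        ("reader2", "junior resident", "without_colormap", 55.2, 55.8, 55.5, 61.7, 49.2, 8),
        ("reader2", "junior resident", "with_colormap", 62.7, 55.8, 59.7, 64.6, 53.7, 8),
        ("reader3", "experienced resident", "without_colormap", 28.4, 94.2, 57.1, 86.4, 50.5, 7),
        ("reader3", "experienced resident", "with_colormap", 43.3, 80.8, 59.7, 74.4, 52.5, 7),
        ("reader4", "experienced resident", "without_colormap", 29.9, 76.9, 50.4, 62.5, 46.0, 21),
        ("reader4", "experienced resident", "with_colormap", 52.2, 63.5, 57.1, 64.8, 50.8, 21),
        ("reader5", "expert", "without_colormap", 13.4, 92.3, 47.9, 69.2, 45.3, 35),
        ("reader5", "expert", "with_colormap", 44.9, 75.0, 57.8, 70.5, 50.6, 35),
        ("reader6", "expert", "without_colormap", 28.4, 86.5, 53.8, 73.1, 48.4, 1),
        ("reader6", "expert", "with_colormap", 26.1, 90.4, 53.7, 78.3, 48.0, 1),
    ],
    columns=[
        "reader_id",
        "experience",
        "condition",
        "sensitivity",
        "specificity",
        "accuracy",
        "ppv",
        "npv",
        "nri_pct",
    ],
)

#: Per-reader subgroup sensitivity and PPV (percent) by infarct type.
SUBGROUP_SENSITIVITY = pd.DataFrame(
    [
        ("STEMI", "reader1", "with_colormap", 63.6, 35.0),
        ("STEMI", "reader1", "without_colormap", 50.0, 31.4),
        ("STEMI", "reader2", "with_colormap", 63.6, 21.5),
        ("STEMI", "reader2", "without_colormap", 54.5, 20.0),
        ("STEMI", "reader3", "with_colormap", 50.0, 28.2),
        ("STEMI", "reader3", "without_colormap", 31.8, 31.8),
        ("STEMI", "reader4", "with_colormap", 59.1, 24.1),
        ("STEMI", "reader4", "without_colormap", 31.8, 21.9),
        ("STEMI", "reader5", "with_colormap", 36.4, 18.2),
        ("STEMI", "reader5", "without_colormap", 13.6, 18.2),
        ("STEMI", "reader6", "with_colormap", 22.7, 21.7),
        ("STEMI", "reader6", "without_colormap", 22.7, 19.2),
        ("NSTEMI", "reader1", "with_colormap", 38.3, 45.0),
        ("NSTEMI", "reader1", "without_colormap", 44.4, 57.1),
        ("NSTEMI", "reader2", "with_colormap", 62.2, 43.1),
        ("NSTEMI", "reader2", "without_colormap", 55.6, 41.7),
        ("NSTEMI", "reader3", "with_colormap", 40.0, 46.2),
        ("NSTEMI", "reader3", "without_colormap", 26.7, 54.5),
        ("NSTEMI", "reader4", "with_colormap", 48.9, 40.7),
        ("NSTEMI", "reader4", "without_colormap", 28.9, 40.6),
        ("NSTEMI", "reader5", "with_colormap", 48.9, 52.3),
        ("NSTEMI", "reader5", "without_colormap", 13.3, 46.2),
        ("NSTEMI", "reader6", "with_colormap", 27.7, 56.5),
        ("NSTEMI", "reader6", "without_colormap", 31.1, 53.8),
    ],
    columns=["subgroup", "reader_id", "condition", "sensitivity", "ppv"],
)

#: Reader 4's reclassification table.  Its published stated totals
#: (49 events / 70 non-events) disagree with the cell sums (50 / 69); both
#: are retained, and nri() exposes both variants.  The stated totals are
#: the denominators that reproduce the published NRI of 0.21.
RECLASS_EXAMPLE = ReclassTable(
    up_event=22,
    down_event=7,
    up_nonevent=11,
    down_nonevent=4,
    stay_abnormal_event=13,
    stay_normal_event=8,
    stay_abnormal_nonevent=25,
    stay_normal_nonevent=29,
    n_event=49,
    n_nonevent=70,
)

#: Clinical-routine radiology reports of the same 119 patients: an infarct
#: was stated in 7 reports, all true (4 STEMI, 3 NSTEMI), none falsely.
REPORT_CONFUSION = ConfusionCounts(tp=7, fp=0, fn=60, tn=52)


def default_reader_panel() -> list[ReaderOperatingPoint]:
    """Operating points for the default simulated panel.

    Each simulated reader adopts the sensitivity/specificity a real reader
    showed under each condition, so the synthetic pipeline's panel spans
    the same range of behavior as the study's human readers.
    """
    return [
        ReaderOperatingPoint(
            reader_id=row.reader_id,
            condition=row.condition,
            sensitivity=row.sensitivity / 100.0,
            specificity=row.specificity / 100.0,
        )
        for row in READER_METRICS.itertuples()
    ]
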