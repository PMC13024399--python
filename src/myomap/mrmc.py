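"""Multi-reader multi-case (MRMC) design and statistics.

The study design is a fully crossed two-session crossover: readers are
split into two groups and cases into two groups; in the first session each
reader group reads one case group with colormap overlays and the other
without, and after a washout interval the assignment is crossed, so every
reader reads every case exactly once under each condition.

The statistics are those conventionally reported for such a reading study:
per-reader sensitivity / specificity / accuracy / PPV / NPV against the
adjudicated case status, McNemar's test on the paired with/without ratings
(exact binomial for small discordant counts, continuity-corrected
chi-square otherwise), pairwise Cohen's kappa between readers, the binary
net reclassification index (NRI) between conditions, subgroup (STEMI /
NSTEMI) sensitivity and PPV, territory-level pooled metrics, and a
Wilcoxon signed-rank comparison of paired reading times.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import cohen_kappa_score
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

__all__ = [
    "CONDITIONS",
    "CERTAINTY_LEVELS",
    "ReadingRecord",
    "DesignAssignment",
    "ConfusionCounts",
    "DiagnosticMetrics",
    "ReclassTable",
    "allocate_design",
    "confusion",
    "metrics",
    "mcnemar",
    "discordant_counts",
    "kappa",
    "weighted_kappa",
    "kappa_matrix",
    "nri",
    "reclass_from_records",
    "format_reclass_table",
    "aggregate",
    "subgroup_metrics",
    "territory_metrics",
    "time_compare",
]

CONDITIONS = ("with_colormap", "without_colormap")
CERTAINTY_LEVELS = ("def_no", "prob_no", "intermediate", "prob_yes", "def_yes")
POSITIVE_ADJUDICATIONS = ("STEMI", "NSTEMI")

#: Discordant-pair count below which McNemar's test is computed exactly.
MCNEMAR_EXACT_THRESHOLD = 25


@dataclass(frozen=True)
class ReadingRecord:
    """One reader x case x condition observation."""

    reader_id: str
    case_id: str
    condition: str
    hypodense: str  # yes | no
    certainty: str
    territory: str
    time_s: float
    session: int = 0

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.hypodense not in ("yes", "no"):
            raise ValueError(f"hypodense must be 'yes' or 'no', got {self.hypodense!r}")
        if self.certainty not in CERTAINTY_LEVELS:
            raise ValueError(f"unknown certainty {self.certainty!r}")
        if self.hypodense == "no" and self.territory != "none":
            raise ValueError("a 'no' rating cannot carry a territory")


def records_frame(records: Sequence[ReadingRecord]) -> pd.DataFrame:
    """Reading records as a tidy table (the working representation)."""
    return pd.DataFrame([r.__dict__ for r in records])


@dataclass
class DesignAssignment:
    """The crossed two-session MRMC assignment.

    ``sessions`` has one row per reading slot: session, reader_id, case_id,
    condition.  ``reader_groups`` / ``case_groups`` record the partitions.
    """

    reader_groups: tuple[list, list]
    case_groups: tuple[list, list]
    sessions: pd.DataFrame

    def expand(self) -> pd.DataFrame:
        return self.sessions.copy()


def allocate_design(readers: Sequence, cases: Sequence, seed: int = 0) -> DesignAssignment:
    """Build the crossed two-session design.

    Readers are randomly split into two groups (I and II); cases are split
    in listed order (group A = first half, rounded up, group B = the rest).
    Session 1 shows group A with colormaps to reader group I and without to
    group II, and vice versa for group B; session 2 crosses the conditions.
    The expansion has exactly ``len(readers) * len(cases) * 2`` slots, each
    reader x case pair appearing once per condition.
    """
    readers = list(readers)
    cases = list(cases)
    if len(readers) < 2 or len(cases) < 2:
        raise ValueError("need at least 2 readers and 2 cases")
    rng = np.random.default_rng(np.random.SeedSequence(int(seed)))
    order = rng.permutation(len(readers))
    half_r = (len(readers) + 1) // 2
    group_i = [readers[i] for i in sorted(order[:half_r])]
    group_ii = [readers[i] for i in sorted(order[half_r:])]
    half_c = (len(cases) + 1) // 2
    group_a, group_b = cases[:half_c], cases[half_c:]

    rows = []
    for session in (1, 2):
        for reader_group, with_cases, without_cases in (
            (group_i, group_a, group_b),
            (group_ii, group_b, group_a),
        ):
            if session == 2:  # crossed assignment after the washout
                with_cases, without_cases = without_cases, with_cases
            for reader in reader_group:
                rows.extend(
                    (session, reader, case, "with_colormap") for case in with_cases
                )
                rows.extend(
                    (session, reader, case, "without_colormap") for case in without_cases
                )
    sessions = pd.DataFrame(rows, columns=["session", "reader_id", "case_id", "condition"])
    return DesignAssignment((group_i, group_ii), (group_a, group_b), sessions)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")
        if self.total == 0:
            raise ValueError("empty confusion table")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


class DiagnosticMetrics(NamedTuple):
    """Standard 2x2 diagnostic proportions; NaN marks an undefined ratio."""

    sensitivity: float
    specificity: float
    accuracy: float
    ppv: float
    npv: float


def _case_positive(truth: pd.DataFrame) -> pd.Series:
    return truth.set_index("case_id").adjudication.isin(POSITIVE_ADJUDICATIONS)


def confusion(records: pd.DataFrame, truth: pd.DataFrame) -> ConfusionCounts:
    """2x2 counts for one reader x condition slice of reading records.

    A reading is positive when hypodense == 'yes'; a case is positive when
    adjudicated STEMI or NSTEMI.  Requires exactly one record per case.
    """
    if records.case_id.duplicated().any():
        raise ValueError("duplicate case in records slice (pass one reader x condition)")
    positive = _case_positive(truth)
    missing = set(positive.index) - set(records.case_id)
    if missing:
        raise ValueError(f"records missing {len(missing)} cases, e.g. {sorted(missing)[:3]}")
    rated_yes = records.set_index("case_id").hypodense.eq("yes")
    rated_yes = rated_yes.reindex(positive.index)
    tp = int((rated_yes & positive).sum())
    fp = int((rated_yes & ~positive).sum())
    fn = int((~rated_yes & positive).sum())
    tn = int((~rated_yes & ~positive).sum())
    return ConfusionCounts(tp, fp, fn, tn)


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


def metrics(c: ConfusionCounts) -> DiagnosticMetrics:
    """Sensitivity, specificity, accuracy, PPV and NPV from 2x2 counts.

    Computed at full precision as proportions; any presentation rounding
    belongs to the reporting layer.  Ratios with a zero denominator are
    returned as NaN rather than silently as 0.
    """
    return DiagnosticMetrics(
        sensitivity=_ratio(c.tp, c.tp + c.fn),
        specificity=_ratio(c.tn, c.tn + c.fp),
        accuracy=_ratio(c.tp + c.tn, c.total),
        ppv=_ratio(c.tp, c.tp + c.fp),
        npv=_ratio(c.tn, c.tn + c.fn),
    )


class McNemarResult(NamedTuple):
    statistic: float
    p_value: float
    method: str  # "exact" | "chi2_cc"


def mcnemar(b: int, c: int) -> McNemarResult:
    """McNemar's test on the two discordant-pair counts.

    Exact two-sided binomial when b + c < 25, chi-square with continuity
    correction otherwise.  b and c are the two kinds of discordant pairs of
    the paired with/without ratings (their roles are symmetric).
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be non-negative")
    n = b + c
    if n == 0:
        return McNemarResult(0.0, 1.0, "exact")
    if n < MCNEMAR_EXACT_THRESHOLD:
        res = _sm_mcnemar([[0, b], [c, 0]], exact=True)
        return McNemarResult(float(res.statistic), min(1.0, float(res.pvalue)), "exact")
    res = _sm_mcnemar([[0, b], [c, 0]], exact=False, correction=True)
    return McNemarResult(float(res.statistic), float(res.pvalue), "chi2_cc")


def discordant_counts(
    with_records: pd.DataFrame,
    without_records: pd.DataFrame,
    truth: pd.DataFrame,
    stratum: str = "cases",
) -> tuple[int, int]:
    """Discordant pairs of one reader's with/without ratings.

    ``stratum="cases"`` restricts to adjudicated-positive cases (the paired
    comparison behind sensitivity), ``"noncases"`` to negatives (behind
    specificity).  Returns (yes-with & no-without, no-with & yes-without).
    """
    if stratum not in ("cases", "noncases"):
        raise ValueError("stratum must be 'cases' or 'noncases'")
    positive = _case_positive(truth)
    keep = positive[positive] if stratum == "cases" else positive[~positive]
    w = with_records.set_index("case_id").hypodense.reindex(keep.index)
    wo = without_records.set_index("case_id").hypodense.reindex(keep.index)
    if w.isna().any() or wo.isna().any():
        raise ValueError("records do not cover the stratum's cases under both conditions")
    b = int(((w == "yes") & (wo == "no")).sum())
    c = int(((w == "no") & (wo == "yes")).sum())
    return b, c


def kappa(r1: Sequence, r2: Sequence) -> float:
    """Unweighted Cohen's kappa between two raters on the same cases.

    NaN when the chance-corrected denominator is zero (both raters constant
    and identical), which is undefined rather than perfect agreement.
    """
    r1 = list(r1)
    r2 = list(r2)
    if len(r1) != len(r2) or not r1:
        raise ValueError("rating vectors must be non-empty and equally long")
    if len(set(r1)) == 1 and set(r1) == set(r2):
        return float("nan")
    return float(cohen_kappa_score(r1, r2))


def weighted_kappa(r1: Sequence, r2: Sequence, levels: Sequence = CERTAINTY_LEVELS) -> float:
    """Linearly weighted kappa on ordered categories (the certainty scale)."""
    r1 = list(r1)
    r2 = list(r2)
    if len(r1) != len(r2) or not r1:
        raise ValueError("rating vectors must be non-empty and equally long")
    if len(set(r1)) == 1 and set(r1) == set(r2):
        return float("nan")
    return float(cohen_kappa_score(r1, r2, labels=list(levels), weights="linear"))


def kappa_matrix(records: pd.DataFrame, condition: str) -> pd.DataFrame:
    """Pairwise Cohen's kappa of the binary ratings across all readers."""
    sub = records[records.condition == condition]
    pivot = sub.pivot_table(
        index="case_id", columns="reader_id", values="hypodense", aggfunc="first"
    )
    readers = list(pivot.columns)
    out = pd.DataFrame(np.eye(len(readers)), index=readers, columns=readers)
    for i, a in enumerate(readers):
        for b in readers[i + 1 :]:
            k = kappa(pivot[a], pivot[b])
            out.loc[a, b] = out.loc[b, a] = k
    return out


@dataclass(frozen=True)
class ReclassTable:
    """Paired with/without classifications stratified by case status.

    'Up' means reclassified from normal without colormaps to abnormal with
    colormaps; 'down' the reverse.  The ``stay_*`` counts are the concordant
    cells, kept so the full 2x2-per-stratum table can be printed.  The
    denominators ``n_event`` / ``n_nonevent`` default to the cell sums but
    may be supplied explicitly when a published table's stated totals are
    to be used as-is (see :func:`nri`).
    """

    up_event: int
    down_event: int
    up_nonevent: int
    down_nonevent: int
    stay_abnormal_event: int = 0
    stay_normal_event: int = 0
    stay_abnormal_nonevent: int = 0
    stay_normal_nonevent: int = 0
    n_event: int | None = None
    n_nonevent: int | None = None

    def cell_sum_event(self) -> int:
        return (
            self.up_event + self.down_event + self.stay_abnormal_event + self.stay_normal_event
        )

    def cell_sum_nonevent(self) -> int:
        return (
            self.up_nonevent
            + self.down_nonevent
            + self.stay_abnormal_nonevent
            + self.stay_normal_nonevent
        )

    def denominators(self) -> tuple[int, int]:
        ne = self.n_event if self.n_event is not None else self.cell_sum_event()
        nn = self.n_nonevent if self.n_nonevent is not None else self.cell_sum_nonevent()
        return ne, nn


def nri(t: ReclassTable, use_stated_denominators: bool = True) -> float:
    """Binary net reclassification index of with- vs. without-colormap reads.

    NRI = (up_event - down_event) / n_event
        + (down_nonevent - up_nonevent) / n_nonevent

    Each stratum term lies in [-1, 1], so the sum lies in [-2, 2]; the
    conventional clinical reading treats the value as the net fraction of
    patients correctly reclassified by the new test.  With
    ``use_stated_denominators=False`` the cell sums are used as denominators
    regardless of any explicitly supplied totals.
    """
    if use_stated_denominators:
        n_event, n_nonevent = t.denominators()
    else:
        n_event, n_nonevent = t.cell_sum_event(), t.cell_sum_nonevent()
    if n_event <= 0 or n_nonevent <= 0:
        raise ValueError("NRI requires positive event and non-event denominators")
    return (t.up_event - t.down_event) / n_event + (
        t.down_nonevent - t.up_nonevent
    ) / n_nonevent


def reclass_from_records(
    with_records: pd.DataFrame, without_records: pd.DataFrame, truth: pd.DataFrame
) -> ReclassTable:
    """Build one reader's reclassification table from paired records."""
    positive = _case_positive(truth)
    w = with_records.set_index("case_id").hypodense.reindex(positive.index)
    wo = without_records.set_index("case_id").hypodense.reindex(positive.index)
    if w.isna().any() or wo.isna().any():
        raise ValueError("records do not cover all cases under both conditions")
    up = (w == "yes") & (wo == "no")
    down = (w == "no") & (wo == "yes")
    stay_ab = (w == "yes") & (wo == "yes")
    stay_no = (w == "no") & (wo == "no")
    return ReclassTable(
        up_event=int((up & positive).sum()),
        down_event=int((down & positive).sum()),
        up_nonevent=int((up & ~positive).sum()),
        down_nonevent=int((down & ~positive).sum()),
        stay_abnormal_event=int((stay_ab & positive).sum()),
        stay_normal_event=int((stay_no & positive).sum()),
        stay_abnormal_nonevent=int((stay_ab & ~positive).sum()),
        stay_normal_nonevent=int((stay_no & ~positive).sum()),
    )


def format_reclass_table(t: ReclassTable) -> str:
    """Printable reclassification table: per cell, events over non-events."""
    ne, nn = t.denominators()
    lines = [
        "                      CT alone",
        "                      abnormal   normal    total",
        "colormap abnormal   "
        f"{t.stay_abnormal_event:>8}  {t.up_event:>7}  {t.stay_abnormal_event + t.up_event:>7}",
        "                    "
        f"{t.stay_abnormal_nonevent:>8}  {t.up_nonevent:>7}  "
        f"{t.stay_abnormal_nonevent + t.up_nonevent:>7}",
        "colormap normal     "
        f"{t.down_event:>8}  {t.stay_normal_event:>7}  {t.down_event + t.stay_normal_event:>7}",
        "                    "
        f"{t.down_nonevent:>8}  {t.stay_normal_nonevent:>7}  "
        f"{t.down_nonevent + t.stay_normal_nonevent:>7}",
        f"events: cell sum {t.cell_sum_event()}, denominator used {ne}",
        f"non-events: cell sum {t.cell_sum_nonevent()}, denominator used {nn}",
    ]

    def _fmt(stated: bool) -> str:
        try:
            return f"{nri(t, stated):.2f}"
        except ValueError:
            return "undefined (empty stratum)"

    lines += [
        f"NRI (stated denominators) = {_fmt(True)}",
        f"NRI (cell-sum denominators) = {_fmt(False)}",
    ]
    if (ne, nn) != (t.cell_sum_event(), t.cell_sum_nonevent()):
        lines.append(
            "note: stated totals differ from the cell sums; both NRI variants are shown"
        )
    return "\n".join(lines)


def aggregate(per_reader: Sequence[float]) -> float:
    """Unweighted arithmetic mean of per-reader values (metrics or NRIs)."""
    values = np.asarray(list(per_reader), dtype=float)
    if values.size == 0:
        raise ValueError("need at least one reader")
    return float(values.mean())


class SubgroupMetrics(NamedTuple):
    sensitivity: float
    ppv: float


def subgroup_metrics(
    records: pd.DataFrame, truth: pd.DataFrame, subgroup: str
) -> SubgroupMetrics:
    """Sensitivity and PPV of one reader x condition for STEMI or NSTEMI.

    Readers rate hypodense myocardium, not infarct type, so specificity is
    not meaningful per subgroup: sensitivity is restricted to subgroup
    cases, and PPV counts subgroup true positives over *all* positive calls.
    """
    if subgroup not in POSITIVE_ADJUDICATIONS:
        raise ValueError(f"subgroup must be one of {POSITIVE_ADJUDICATIONS}")
    t = truth.set_index("case_id")
    in_subgroup = t.adjudication.eq(subgroup)
    if not in_subgroup.any():
        raise ValueError(f"no {subgroup} cases in the truth table")
    rated_yes = records.set_index("case_id").hypodense.eq("yes").reindex(t.index)
    if rated_yes.isna().any():
        raise ValueError("records do not cover all cases")
    tp_sub = int((rated_yes & in_subgroup).sum())
    n_sub = int(in_subgroup.sum())
    all_pos_calls = int(rated_yes.sum())
    return SubgroupMetrics(
        sensitivity=_ratio(tp_sub, n_sub), ppv=_ratio(tp_sub, all_pos_calls)
    )


def territory_metrics(records: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    """Per-territory diagnostic metrics pooled over all readers.

    A reading counts as territory-T-positive only when it is a 'yes' *and*
    assigns territory T; a case is territory-T-positive when its culprit
    territory is T.  Pooling is over all reader x case readings of the
    given records (pass a one-condition slice for per-condition tables).
    """
    t = truth.set_index("case_id")
    merged = records.merge(
        t[["territory"]].rename(columns={"territory": "culprit"}),
        left_on="case_id",
        right_index=True,
        how="left",
    )
    if merged.culprit.isna().any():
        raise ValueError("truth table missing culprit territories for some cases")
    rows = {}
    for terr in ("RCA", "LAD", "CX"):
        called = (merged.hypodense == "yes") & (merged.territory == terr)
        is_case = merged.culprit == terr
        c = ConfusionCounts(
            tp=int((called & is_case).sum()),
            fp=int((called & ~is_case).sum()),
            fn=int((~called & is_case).sum()),
            tn=int((~called & ~is_case).sum()),
        )
        rows[terr] = metrics(c)._asdict()
    return pd.DataFrame(rows).T


class TimeCompareResult(NamedTuple):
    median_with: float
    iqr_with: tuple[float, float]
    median_without: float
    iqr_without: tuple[float, float]
    p_value: float


def time_compare(
    times_with: Sequence[float], times_without: Sequence[float]
) -> TimeCompareResult:
    """Medians, IQRs and a Wilcoxon signed-rank p for paired reading times.

    Inputs must be aligned reader x case pairs.  The signed-rank test is
    used because times are paired and right-skewed; identical pairs (all
    zero differences) yield p = 1.
    """
    tw = np.asarray(times_with, dtype=float)
    two = np.asarray(times_without, dtype=float)
    if tw.shape != two.shape or tw.ndim != 1 or tw.size == 0:
        raise ValueError("paired time vectors must be non-empty and equally long")
    diffs = tw - two
    if np.all(diffs == 0):
        p = 1.0
    else:
        p = float(stats.wilcoxon(tw, two, zero_method="wilcox").pvalue)
    q = lambda x: (float(np.quantile(x, 0.25)), float(np.quantile(x, 0.75)))
    return TimeCompareResult(
        median_with=float(np.median(tw)),
        iqr_with=q(tw),
        median_without=float(np.median(two)),
        iqr_without=q(two),
        p_value=p,
    )
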