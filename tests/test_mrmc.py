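"""MRMC design and statistics: confusion metrics, McNemar, kappa, NRI,
subgroup/territory pooling and reading-time comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from myomap.mrmc import (
    ConfusionCounts,
    ReclassTable,
    aggregate,
    allocate_design,
    confusion,
    discordant_counts,
    kappa,
    kappa_matrix,
    mcnemar,
    metrics,
    nri,
    reclass_from_records,
    subgroup_metrics,
    territory_metrics,
    time_compare,
    weighted_kappa,
)
from myomap.phantom import ReaderOperatingPoint, sample_truth, simulate_readers


def _records(rows):
    return pd.DataFrame(
        rows,
        columns=["reader_id", "case_id", "condition", "hypodense", "certainty", "territory", "time_s"],
    )


def _truth(rows):
    return pd.DataFrame(rows, columns=["case_id", "adjudication", "territory"])


class TestAllocateDesign:
    def test_two_by_two_design_is_balanced(self):
        design = allocate_design(["r1", "r2"], ["c1", "c2"], seed=0)
        table = design.expand()
        assert len(table) == 8
        per_pair = table.groupby(["reader_id", "case_id"]).condition.nunique()
        assert per_pair.eq(2).all()

    def test_study_scale_slot_count(self):
        readers = [f"r{i}" for i in range(6)]
        cases = [f"c{i}" for i in range(119)]
        table = allocate_design(readers, cases, seed=1).expand()
        assert len(table) == 1428

    def test_no_reader_sees_a_case_twice_per_session(self):
        table = allocate_design(
            [f"r{i}" for i in range(4)], [f"c{i}" for i in range(10)], seed=2
        ).expand()
        assert not table.duplicated(["session", "reader_id", "case_id"]).any()
        # each reader reads every case once per session
        counts = table.groupby(["session", "reader_id"]).case_id.nunique()
        assert counts.eq(10).all()

    def test_conditions_crossed_between_sessions(self):
        table = allocate_design(["r1", "r2"], [f"c{i}" for i in range(6)], seed=3).expand()
        s1 = table[table.session == 1].set_index(["reader_id", "case_id"]).condition
        s2 = table[table.session == 2].set_index(["reader_id", "case_id"]).condition
        assert (s1 != s2.loc[s1.index]).all()


class TestConfusionAndMetrics:
    truth5 = _truth(
        [("c1", "STEMI", "RCA"), ("c2", "NSTEMI", "LAD"), ("c3", "STEMI", "CX"),
         ("c4", "none", "none"), ("c5", "none", "none")]
    )

    def test_perfect_reader(self):
        rows = [
            ("r", f"c{i}", "with_colormap", "yes", "def_yes", t, 20.0)
            for i, t in zip((1, 2, 3), ("RCA", "LAD", "CX"))
        ] + [
            ("r", f"c{i}", "with_colormap", "no", "def_no", "none", 20.0)
            for i in (4, 5)
        ]
        c = confusion(_records(rows), self.truth5)
        assert (c.tp, c.fp, c.fn, c.tn) == (3, 0, 0, 2)
        m = metrics(c)
        assert m == (1.0, 1.0, 1.0, 1.0, 1.0)

    def test_all_no_reader_on_study_mix(self):
        truth = sample_truth(22, 45, 52, seed=0)
        rows = [("r", cid, "with_colormap", "no", "def_no", "none", 10.0)
                for cid in truth.case_id]
        c = confusion(_records(rows), truth)
        assert (c.tp, c.fp, c.fn, c.tn) == (0, 0, 67, 52)

    def test_missing_cases_rejected(self):
        rows = [("r", "c1", "with_colormap", "yes", "def_yes", "RCA", 5.0)]
        with pytest.raises(ValueError, match="missing"):
            confusion(_records(rows), self.truth5)

    @pytest.mark.parametrize("seed", range(5))
    def test_metrics_match_ratio_oracle(self, seed):
        rng = np.random.default_rng(seed)
        tp, fp, fn, tn = rng.integers(1, 50, size=4)
        m = metrics(ConfusionCounts(int(tp), int(fp), int(fn), int(tn)))
        assert m.sensitivity == pytest.approx(tp / (tp + fn))
        assert m.specificity == pytest.approx(tn / (tn + fp))
        assert m.accuracy == pytest.approx((tp + tn) / (tp + fp + fn + tn))
        assert m.ppv == pytest.approx(tp / (tp + fp))
        assert m.npv == pytest.approx(tn / (tn + fn))
        # identities
        assert m.accuracy * (tp + fp + fn + tn) == pytest.approx(tp + tn)
        assert m.sensitivity * (tp + fn) == pytest.approx(tp)

    def test_zero_denominator_flags_nan_not_zero(self):
        m = metrics(ConfusionCounts(tp=0, fp=0, fn=0, tn=5))
        assert np.isnan(m.sensitivity)
        assert np.isnan(m.ppv)
        assert m.specificity == 1.0


class TestMcNemar:
    def test_no_discordance_gives_p_one(self):
        assert mcnemar(0, 0).p_value == 1.0

    def test_exact_p_matches_binomial_tail_oracle(self):
        # two-sided exact p for (12, 2): 2 * P(X <= 2 | n=14, p=1/2)
        result = mcnemar(12, 2)
        assert result.method == "exact"
        expected = 2 * stats.binom.cdf(2, 14, 0.5)
        assert result.p_value == pytest.approx(expected)
        assert result.p_value == pytest.approx(0.012939453125)

    def test_symmetric_discordance_gives_p_one(self):
        assert mcnemar(10, 10).p_value == 1.0

    def test_large_counts_use_continuity_corrected_chi2(self):
        result = mcnemar(30, 10)
        assert result.method == "chi2_cc"
        expected = stats.chi2.sf((abs(30 - 10) - 1) ** 2 / 40, df=1)
        assert result.p_value == pytest.approx(expected)

    def test_discordant_counts_from_paired_records(self):
        truth = _truth([("c1", "STEMI", "RCA"), ("c2", "NSTEMI", "LAD"),
                        ("c3", "none", "none")])
        w = _records([("r", "c1", "with_colormap", "yes", "def_yes", "RCA", 1.0),
                      ("r", "c2", "with_colormap", "yes", "def_yes", "LAD", 1.0),
                      ("r", "c3", "with_colormap", "yes", "def_yes", "CX", 1.0)])
        wo = _records([("r", "c1", "without_colormap", "no", "def_no", "none", 1.0),
                       ("r", "c2", "without_colormap", "yes", "def_yes", "LAD", 1.0),
                       ("r", "c3", "without_colormap", "no", "def_no", "none", 1.0)])
        assert discordant_counts(w, wo, truth, "cases") == (1, 0)
        assert discordant_counts(w, wo, truth, "noncases") == (1, 0)


class TestKappa:
    def test_identical_ratings_give_one(self):
        r = ["yes", "no", "yes", "no", "yes"]
        assert kappa(r, r) == 1.0

    def test_constant_rater_against_mixed_gives_zero(self):
        a = ["yes"] * 10
        b = ["yes"] * 6 + ["no"] * 4
        assert kappa(a, b) == pytest.approx(0.0)

    def test_two_by_two_counts_match_hand_formula(self):
        # agreement table (20, 5; 10, 15): po=0.7, pe=0.5, kappa=0.4
        a = ["y"] * 25 + ["n"] * 25
        b = ["y"] * 20 + ["n"] * 5 + ["y"] * 10 + ["n"] * 15
        assert kappa(a, b) == pytest.approx(0.4)

    def test_undefined_when_both_constant_identical(self):
        assert np.isnan(kappa(["yes"] * 5, ["yes"] * 5))

    def test_weighted_kappa_on_ordered_certainty(self):
        a = ["def_no", "prob_no", "intermediate", "prob_yes", "def_yes"]
        assert weighted_kappa(a, a) == 1.0
        shifted = ["prob_no", "intermediate", "prob_yes", "def_yes", "def_yes"]
        assert -1.0 <= weighted_kappa(a, shifted) < 1.0

    def test_kappa_matrix_is_symmetric_with_unit_diagonal(self):
        truth = sample_truth(5, 5, 5, seed=1)
        readers = ["r1", "r2", "r3"]
        design = allocate_design(readers, list(truth.case_id), seed=0)
        points = [ReaderOperatingPoint(r, c, 0.7, 0.7)
                  for r in readers for c in ("with_colormap", "without_colormap")]
        records = simulate_readers(truth, points, design, seed=2)
        km = kappa_matrix(records, "with_colormap")
        assert list(km.index) == readers
        np.testing.assert_allclose(np.diag(km), 1.0)
        np.testing.assert_allclose(km.values, km.values.T)
        assert (km.values >= -1 - 1e-12).all() and (km.values <= 1 + 1e-12).all()


class TestNRI:
    def test_no_reclassification_is_zero(self):
        t = ReclassTable(0, 0, 0, 0, n_event=10, n_nonevent=10)
        assert nri(t) == 0.0

    def test_theoretical_maximum_is_two(self):
        t = ReclassTable(up_event=10, down_event=0, up_nonevent=0, down_nonevent=20,
                         n_event=10, n_nonevent=20)
        assert nri(t) == 2.0

    def test_stated_vs_cell_sum_denominators(self):
        from myomap.datasets import RECLASS_EXAMPLE

        assert round(nri(RECLASS_EXAMPLE, use_stated_denominators=True), 2) == 0.21
        assert round(nri(RECLASS_EXAMPLE, use_stated_denominators=False), 2) == 0.20

    def test_reclass_from_records_counts_directions(self):
        truth = _truth([("c1", "STEMI", "RCA"), ("c2", "NSTEMI", "LAD"),
                        ("c3", "none", "none"), ("c4", "none", "none")])
        w = _records([("r", "c1", "with_colormap", "yes", "def_yes", "RCA", 1.0),
                      ("r", "c2", "with_colormap", "no", "def_no", "none", 1.0),
                      ("r", "c3", "with_colormap", "yes", "prob_yes", "CX", 1.0),
                      ("r", "c4", "with_colormap", "no", "def_no", "none", 1.0)])
        wo = _records([("r", "c1", "without_colormap", "no", "def_no", "none", 1.0),
                       ("r", "c2", "without_colormap", "yes", "def_yes", "LAD", 1.0),
                       ("r", "c3", "without_colormap", "no", "def_no", "none", 1.0),
                       ("r", "c4", "without_colormap", "yes", "prob_yes", "RCA", 1.0)])
        t = reclass_from_records(w, wo, truth)
        assert (t.up_event, t.down_event, t.up_nonevent, t.down_nonevent) == (1, 1, 1, 1)
        assert t.denominators() == (2, 2)
        assert nri(t) == 0.0

    def test_range_bound(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            up_e, down_e, up_n, down_n = rng.integers(0, 10, size=4)
            t = ReclassTable(int(up_e), int(down_e), int(up_n), int(down_n),
                             n_event=20, n_nonevent=20)
            assert -2.0 <= nri(t) <= 2.0


class TestAggregateAndSubgroups:
    def test_single_reader_aggregate_is_identity(self):
        assert aggregate([0.42]) == 0.42

    def test_subgroup_sensitivity_restricted_and_ppv_over_all_calls(self):
        truth = _truth([("c1", "STEMI", "RCA"), ("c2", "NSTEMI", "LAD"),
                        ("c3", "none", "none")])
        rows = [("r", "c1", "with_colormap", "yes", "def_yes", "RCA", 1.0),
                ("r", "c2", "with_colormap", "yes", "def_yes", "LAD", 1.0),
                ("r", "c3", "with_colormap", "yes", "def_yes", "CX", 1.0)]
        sm = subgroup_metrics(_records(rows), truth, "STEMI")
        assert sm.sensitivity == 1.0
        assert sm.ppv == pytest.approx(1 / 3)  # 1 STEMI TP over 3 positive calls

    def test_subgroup_matches_recount_oracle_on_simulated_panel(self):
        truth = sample_truth(10, 15, 15, seed=4)
        readers = ["r1", "r2"]
        design = allocate_design(readers, list(truth.case_id), seed=1)
        points = [ReaderOperatingPoint(r, c, 0.6, 0.8)
                  for r in readers for c in ("with_colormap", "without_colormap")]
        records = simulate_readers(truth, points, design, seed=6)
        sub = records[(records.reader_id == "r1") & (records.condition == "with_colormap")]
        sm = subgroup_metrics(sub, truth, "NSTEMI")
        merged = sub.merge(truth, on="case_id", suffixes=("", "_t"))
        nstemi = merged[merged.adjudication == "NSTEMI"]
        assert sm.sensitivity == pytest.approx(nstemi.hypodense.eq("yes").mean())
        tp = nstemi.hypodense.eq("yes").sum()
        assert sm.ppv == pytest.approx(tp / merged.hypodense.eq("yes").sum())

    def test_empty_subgroup_rejected(self):
        truth = _truth([("c1", "NSTEMI", "LAD"), ("c2", "none", "none")])
        rows = [("r", "c1", "with_colormap", "no", "def_no", "none", 1.0),
                ("r", "c2", "with_colormap", "no", "def_no", "none", 1.0)]
        with pytest.raises(ValueError, match="STEMI"):
            subgroup_metrics(_records(rows), truth, "STEMI")


class TestTerritoryMetrics:
    def test_perfect_panel_has_unit_territory_sensitivity(self):
        truth = sample_truth(4, 4, 4, seed=2)
        readers = ["r1", "r2"]
        design = allocate_design(readers, list(truth.case_id), seed=0)
        points = [ReaderOperatingPoint(r, c, 1.0, 1.0)
                  for r in readers for c in ("with_colormap", "without_colormap")]
        records = simulate_readers(truth, points, design, seed=1)
        tm = territory_metrics(records[records.condition == "with_colormap"], truth)
        present = truth[truth.territory != "none"].territory.unique()
        for terr in present:
            assert tm.loc[terr, "sensitivity"] == 1.0

    def test_always_lad_reader_misses_other_territories(self):
        truth = _truth([("c1", "STEMI", "RCA"), ("c2", "NSTEMI", "CX"),
                        ("c3", "NSTEMI", "LAD"), ("c4", "none", "none")])
        rows = [("r", cid, "with_colormap", "yes", "def_yes", "LAD", 1.0)
                for cid in ("c1", "c2", "c3")]
        rows.append(("r", "c4", "with_colormap", "no", "def_no", "none", 1.0))
        tm = territory_metrics(_records(rows), truth)
        assert tm.loc["RCA", "sensitivity"] == 0.0
        assert tm.loc["CX", "sensitivity"] == 0.0
        assert tm.loc["LAD", "sensitivity"] == 1.0

    def test_pooled_counts_match_recount_oracle(self):
        truth = sample_truth(6, 6, 6, seed=8)
        readers = ["r1", "r2", "r3"]
        design = allocate_design(readers, list(truth.case_id), seed=2)
        points = [ReaderOperatingPoint(r, c, 0.7, 0.7)
                  for r in readers for c in ("with_colormap", "without_colormap")]
        records = simulate_readers(truth, points, design, seed=3)
        sub = records[records.condition == "with_colormap"]
        tm = territory_metrics(sub, truth)
        merged = sub.merge(truth.rename(columns={"territory": "culprit"}), on="case_id")
        for terr in ("RCA", "LAD", "CX"):
            called = (merged.hypodense == "yes") & (merged.territory == terr)
            is_case = merged.culprit == terr
            if is_case.sum():
                assert tm.loc[terr, "sensitivity"] == pytest.approx(
                    (called & is_case).sum() / is_case.sum()
                )


class TestTimeCompare:
    def test_identical_times_give_p_one(self):
        t = [10.0, 20.0, 30.0]
        result = time_compare(t, t)
        assert result.p_value == 1.0
        assert result.median_with == result.median_without

    def test_constant_shift_moves_median(self, rng):
        base = rng.lognormal(np.log(25), 0.5, size=60)
        result = time_compare(base + 5.0, base)
        assert result.median_with == pytest.approx(result.median_without + 5.0)
        assert result.p_value < 0.001

    def test_power_against_half_sd_shift(self):
        """Monte-Carlo power at the study's pair count: > 80% at d = 0.5 SD."""
        rng = np.random.default_rng(2024)
        n, reps, shift = 119, 200, 0.5
        rejections = 0
        for _ in range(reps):
            without = rng.normal(27.0, 1.0, size=n)
            with_ = without - shift + rng.normal(0, 0.5, size=n)
            if time_compare(with_, without).p_value < 0.05:
                rejections += 1
        assert rejections / reps > 0.8

    def test_unpaired_lengths_rejected(self):
        with pytest.raises(ValueError):
            time_compare([1.0, 2.0], [1.0])


class TestEndToEndRecovery:
    def test_panel_sensitivity_difference_converges(self):
        """The pipeline's mean with-vs-without sensitivity difference
        converges to the operating-point difference (5,000 cases)."""
        truth = sample_truth(1400, 1400, 2200, seed=31)
        readers = ["r1", "r2"]
        design = allocate_design(readers, list(truth.case_id), seed=1)
        sens_with, sens_without = 0.6, 0.4
        points = []
        for r in readers:
            points.append(ReaderOperatingPoint(r, "with_colormap", sens_with, 0.8))
            points.append(ReaderOperatingPoint(r, "without_colormap", sens_without, 0.8))
        records = simulate_readers(truth, points, design, seed=41)
        diffs = []
        n_pos = int(truth.adjudication.isin(["STEMI", "NSTEMI"]).sum())
        for r in readers:
            emp = {}
            for cond in ("with_colormap", "without_colormap"):
                sub = records[(records.reader_id == r) & (records.condition == cond)]
                c = confusion(sub, truth)
                emp[cond] = metrics(c).sensitivity
            diffs.append(emp["with_colormap"] - emp["without_colormap"])
        var_single = (sens_with * (1 - sens_with) + sens_without * (1 - sens_without)) / n_pos
        sd_mean = np.sqrt(var_single / len(readers))
        assert abs(np.mean(diffs) - (sens_with - sens_without)) <= 3 * sd_mean
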