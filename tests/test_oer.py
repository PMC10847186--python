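"""OER engine: summaries, cutoff ladder, binning, percentages, classification."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from panelscope.identify import detect_panels
from panelscope.oer import (
    BIN_LABELS,
    CUTOFF_KEYS,
    CutoffLadder,
    PanelScoreSummary,
    assign_bin,
    bin_subsets,
    build_cutoffs,
    classify_panel,
    compute_oer,
    evaluate_all,
    read_oer_table,
    round_percentage,
    summarize_panel,
    write_oer_table,
)
from panelscope.panels import GenePanel, PanelRegistry
from panelscope.qc import normalize
from panelscope.simulate import PanelPlan, SimulationConfig, simulate, truth_registry

from conftest import labeled, normalized


def ladder_from(q1, q3, degenerate=False):
    return CutoffLadder(
        cutoffs={k: (q3 - q1) / 10 * (k / 10) + q1 for k in CUTOFF_KEYS}, degenerate=degenerate
    )


class TestSummarize:
    def test_single_cell_own_subset_degenerate_range(self):
        adata = normalized([[5.0], [1.0]], ["own", "other"], genes=["X"])
        s = summarize_panel(adata, GenePanel(name="P", genes=("X",)), "own")
        assert s.q1 == s.q3 == 5.0

    def test_q1_q3_are_min_max_of_own_cells(self):
        adata = normalized([[1.0], [2.0], [3.0], [9.0]], ["o", "o", "o", "x"], genes=["X"])
        s = summarize_panel(adata, GenePanel(name="P", genes=("X",)), "o")
        assert (s.q1, s.q3) == (1.0, 3.0)
        assert s.scores["o"] == pytest.approx(2.0)

    def test_quartile_mode_uses_percentiles(self):
        vals = [[float(v)] for v in range(1, 6)] + [[0.0]]
        adata = normalized(vals, ["o"] * 5 + ["x"], genes=["X"])
        s = summarize_panel(adata, GenePanel(name="P", genes=("X",)), "o", quartile=True)
        assert (s.q1, s.q3) == (2.0, 4.0)

    def test_subset_means_match_brute_force(self, rng):
        values = rng.normal(2, 1, size=(40, 6))
        labels = [f"s{i % 4}" for i in range(40)]
        adata = normalized(values, labels)
        panel = GenePanel(name="P", genes=("G1", "G3", "G4"))
        s = summarize_panel(adata, panel, "s0")
        for sub in "s0 s1 s2 s3".split():
            cells = [i for i, l in enumerate(labels) if l == sub]
            expected = np.mean([values[i, [1, 3, 4]].mean() for i in cells])
            assert s.scores[sub] == pytest.approx(expected)

    def test_absent_own_subset_is_error(self):
        adata = normalized([[1.0]], ["a"], genes=["X"])
        with pytest.raises(ValueError, match="absent"):
            summarize_panel(adata, GenePanel(name="P", genes=("X",)), "nope")

    def test_unnormalized_matrix_is_error(self):
        adata = labeled(np.array([[1]]), ["a"], genes=["X"])
        with pytest.raises(ValueError, match="normalized"):
            summarize_panel(adata, GenePanel(name="P", genes=("X",)), "a")


class TestCutoffLadder:
    def test_unit_range_formula(self):
        s = PanelScoreSummary(panel="P", own_subset="o", scores={"o": 5.0}, q1=0.0, q3=10.0)
        ladder = build_cutoffs(s)
        assert [ladder[k] for k in CUTOFF_KEYS] == [1, 2, 3, 4, 5, 6]
        assert not ladder.degenerate

    def test_offset_range_arithmetic(self):
        s = PanelScoreSummary(panel="P", own_subset="o", scores={"o": 3.0}, q1=2.0, q3=7.0)
        assert build_cutoffs(s)[30] == pytest.approx(3.5)

    def test_degenerate_range_flags_and_collapses(self):
        s = PanelScoreSummary(panel="P", own_subset="o", scores={"o": 4.0}, q1=4.0, q3=4.0)
        ladder = build_cutoffs(s)
        assert ladder.degenerate
        assert all(ladder[k] == 4.0 for k in CUTOFF_KEYS)

    def test_nonfinite_bounds_are_error(self):
        with pytest.raises(ValueError, match="non-finite"):
            PanelScoreSummary(panel="P", own_subset="o", scores={"o": 1.0}, q1=np.nan, q3=1.0)

    @given(st.floats(-100, 100), st.floats(0, 100))
    def test_cutoffs_monotone_nondecreasing(self, q1, span):
        ladder = ladder_from(q1, q1 + span)
        vals = [ladder[k] for k in CUTOFF_KEYS]
        assert all(a <= b + 1e-12 for a, b in zip(vals, vals[1:]))


class TestBinning:
    @pytest.mark.parametrize(
        "score,expected",
        [
            (0.5, "<10"),
            (1.0, "<10"),  # equals cutoff_10: strictly-greater rule
            (2.0, "10-20"),  # equals cutoff_20
            (3.5, "30-40"),
            (6.0, "50-60"),
            (6.5, ">60"),
        ],
    )
    def test_boundary_assignment(self, score, expected):
        assert assign_bin(score, ladder_from(0.0, 10.0)) == expected

    @given(st.lists(st.floats(-2, 12), min_size=1, max_size=30))
    def test_matches_brute_force_interval_rule(self, scores):
        ladder = ladder_from(0.0, 10.0)
        cuts = [ladder[k] for k in CUTOFF_KEYS]
        for s in scores:
            expected = sum(s > c for c in cuts)
            assert assign_bin(s, ladder) == BIN_LABELS[expected]

    def test_every_population_in_exactly_one_bin(self):
        summary = PanelScoreSummary(
            panel="P",
            own_subset="o",
            scores={"o": 9.0, "a": 0.5, "b": 3.3, "c": 7.0},
            q1=0.0,
            q3=10.0,
        )
        counts, assignment = bin_subsets(summary, build_cutoffs(summary))
        assert sum(counts.values()) == 4
        assert assignment == {"o": ">60", "a": "<10", "b": "30-40", "c": ">60"}

    def test_force_self_top_pins_own_population(self):
        summary = PanelScoreSummary(
            panel="P", own_subset="o", scores={"o": 0.5, "a": 0.5}, q1=0.0, q3=10.0
        )
        counts, assignment = bin_subsets(summary, build_cutoffs(summary), force_self_top=True)
        assert assignment["o"] == ">60" and assignment["a"] == "<10"
        assert counts[">60"] == 1

    def test_degenerate_ladder_splits_at_q1(self):
        summary = PanelScoreSummary(
            panel="P", own_subset="o", scores={"o": 4.0, "lo": 3.0, "hi": 5.0}, q1=4.0, q3=4.0
        )
        _, assignment = bin_subsets(summary, build_cutoffs(summary))
        assert assignment == {"o": "<10", "lo": "<10", "hi": ">60"}


class TestComputeOER:
    # reference rows: printed percentages of the healthy-blood tables
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((31, 0, 0, 0, 0, 0, 1), ((96.88, 0, 0, 0, 0, 0), 3.12, 3.12)),
            ((13, 5, 7, 3, 1, 1, 2), ((40.62, 15.62, 21.88, 9.38, 3.12, 3.12), 21.88, 6.25)),
            ((8, 6, 1, 0, 1, 7, 9), ((25, 18.75, 3.12, 0, 3.12, 21.88), 53.12, 28.12)),
        ],
    )
    def test_reference_rows(self, counts, expected):
        prof = compute_oer("P", counts, 32)
        intervals, gt30, gt60 = expected
        assert tuple(prof.oer[b] for b in BIN_LABELS[:-1]) == intervals
        assert (prof.oer_gt30, prof.oer_gt60) == (gt30, gt60)

    def test_half_to_even_rounding(self):
        assert round_percentage(31, 32) == 96.88  # 96.875 rounds up to even
        assert round_percentage(1, 32) == 3.12  # 3.125 rounds down to even
        assert round_percentage(7, 32) == 21.88
        assert round_percentage(3, 32) == 9.38

    def test_count_sum_mismatch_is_error(self):
        with pytest.raises(ValueError, match="sum to"):
            compute_oer("P", (1, 0, 0, 0, 0, 0, 0), 32)
        prof = compute_oer("P", (26, 0, 0, 0, 0, 0, 5), 32, strict=False)
        assert prof.oer_gt60 == 15.62

    @given(
        st.lists(st.integers(0, 40), min_size=7, max_size=7).filter(lambda c: sum(c) > 0)
    )
    def test_percentages_sum_to_100_and_cumulative_consistency(self, counts):
        n = sum(counts)
        prof = compute_oer("P", counts, n)
        total = sum(prof.oer[b] for b in BIN_LABELS[:-1]) + prof.oer_gt60
        assert total == pytest.approx(100.0, abs=0.05)
        assert prof.n_gt30 == sum(prof.counts[b] for b in ("30-40", "40-50", "50-60", ">60"))
        assert prof.oer_gt30 == round_percentage(prof.n_gt30, n)
        assert prof.n_gt60 <= prof.n_gt30 <= n


class TestClassify:
    @pytest.mark.parametrize(
        "n30,n60,expected",
        [(1, 1, "specific"), (7, 2, "associate"), (17, 9, "reference"), (3, 3, "associate")],
    )
    def test_reference_membership_at_n32(self, n30, n60, expected):
        prof = compute_oer("P", {"<10": 32 - n30, "30-40": n30 - n60, ">60": n60}, 32)
        assert classify_panel(prof).label == expected

    def test_exact_mode_uses_unrounded_threshold(self):
        prof = compute_oer("P", {"<10": 29, "30-40": 0, ">60": 3}, 32)
        assert classify_panel(prof, threshold_mode="exact").label == "specific"
        assert classify_panel(prof, threshold_mode="count").label == "associate"

    def test_specific_and_reference_disjoint(self):
        # specific implies n_>60 <= n_>30 below threshold, so never reference
        for n30 in range(4):
            for n60 in range(n30 + 1):
                prof = compute_oer("P", {"<10": 32 - n30, "30-40": n30 - n60, ">60": n60}, 32)
                cls = classify_panel(prof)
                if cls.label == "specific":
                    assert prof.n_gt60 <= prof.n_gt30 < 32 * 0.1

    def test_threshold_fields(self):
        prof = compute_oer("P", {"<10": 32}, 32)
        cls = classify_panel(prof)
        assert cls.threshold == pytest.approx(3.2)
        assert cls.threshold_count == 3


class TestEvaluateAll:
    def _planted(self, seed=0, n_subsets=20):
        subsets = tuple((f"s{i}", 50) for i in range(n_subsets))
        panels = {
            f"P{i}": PanelPlan(genes=(2 * i, 2 * i + 1), subsets=(f"s{i}",), fold_change=50)
            for i in range(n_subsets)
        }
        cfg = SimulationConfig(n_genes=3 * n_subsets, subsets=subsets, panels=panels, seed=seed)
        adata, _ = simulate(cfg)
        adata = normalize(adata)
        reg = truth_registry(cfg)
        return adata, reg

    def test_planted_panel_classified_specific(self):
        adata, reg = self._planted()
        det = detect_panels(adata, reg)
        result = evaluate_all(adata, reg, det)
        assert result.n_total == 20
        assert result.classifications["P0"].label == "specific"
        assert result.own_subsets["P0"] == "s0"

    def test_constant_high_scoring_panel_is_reference(self):
        # own subset spans scores 1..3; every other population mean (5.0)
        # exceeds cutoff(60%) = 2.2, the degenerate-free reference situation
        values = [[1.0], [2.0], [3.0]] + [[5.0]] * 20
        labels = ["own"] * 3 + [f"x{i}" for i in range(20)]
        adata = normalized(values, labels, genes=["X"])
        reg = PanelRegistry()
        reg.add(GenePanel(name="P", genes=("X",)))
        summary = summarize_panel(adata, reg["P"], "own")
        ladder = build_cutoffs(summary)
        counts, _ = bin_subsets(summary, ladder)
        prof = compute_oer("P", counts, sum(counts.values()))
        assert classify_panel(prof).label == "reference"

    def test_panel_order_invariance(self):
        adata, reg = self._planted(seed=3)
        det = detect_panels(adata, reg)
        table_fwd = evaluate_all(adata, reg, det).to_frame()
        reg_rev = PanelRegistry()
        for name in reversed(reg.names):
            reg_rev.add(reg[name])
        det_rev = detect_panels(adata, reg_rev, positivity_threshold=0.10)
        table_rev = evaluate_all(adata, reg_rev, det_rev).to_frame()
        assert table_fwd.equals(table_rev)

    def test_zero_detected_panels_is_error(self):
        adata, reg = self._planted(seed=1, n_subsets=12)
        det = detect_panels(adata, reg, positivity_threshold=1.0)
        with pytest.raises(ValueError, match="zero detected"):
            evaluate_all(adata, reg, det)

    def test_table_roundtrip_through_tsv(self, tmp_path):
        adata, reg = self._planted(seed=2, n_subsets=12)
        det = detect_panels(adata, reg)
        result = evaluate_all(adata, reg, det)
        path = tmp_path / "oer.tsv"
        write_oer_table(result, path)
        reread = read_oer_table(path)
        assert len(reread) == len(result.profiles)
        for prof, label in reread:
            orig = result.profiles[prof.panel]
            assert prof.counts == orig.counts
            assert prof.oer == orig.oer
            assert label == result.classifications[prof.panel].label
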