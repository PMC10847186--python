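"""Positivity rule, panel detection, multi-assignment resolution, group tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, strategies as st

from panelscope.identify import (
    compare_groups,
    count_positive_cells,
    detect_panels,
    exact_ranksum_pvalue,
    resolve_multi_assignment,
)
from panelscope.oer import compute_oer
from panelscope.panels import GenePanel, PanelRegistry

from conftest import labeled


def brute_force_positive(counts, labels, gene_idx, positive_min=0.0):
    """Per-cell double loop oracle for the all-markers-positive rule."""
    out: dict[str, int] = {}
    for i, lab in enumerate(labels):
        positive = all(counts[i, j] > positive_min for j in gene_idx)
        out.setdefault(lab, 0)
        out[lab] += int(positive)
    return out


class TestCountPositive:
    def test_single_gene_single_count_is_positive(self):
        adata = labeled(np.array([[1]]), ["a"], genes=["X"])
        panel = GenePanel(name="P", genes=("X",))
        assert count_positive_cells(adata, panel)["a"] == 1

    def test_all_markers_required(self):
        adata = labeled(np.array([[5, 0]]), ["a"], genes=["X", "Y"])
        panel = GenePanel(name="P", genes=("X", "Y"))
        assert count_positive_cells(adata, panel)["a"] == 0

    def test_low_direction_genes_ignored(self):
        adata = labeled(np.array([[5, 0]]), ["a"], genes=["X", "Y"])
        panel = GenePanel(name="P", genes=("X", "Y"), directions=("high", "low"))
        assert count_positive_cells(adata, panel)["a"] == 1

    def test_matches_brute_force_on_random_matrices(self, rng):
        for _ in range(10):
            n_sub = rng.integers(2, 6)
            counts = rng.integers(0, 3, size=(n_sub * 10, 8))
            labels = [f"s{i // 10}" for i in range(n_sub * 10)]
            adata = labeled(counts, labels)
            gene_idx = sorted(rng.choice(8, size=3, replace=False))
            panel = GenePanel(name="P", genes=tuple(f"G{j}" for j in gene_idx))
            got = count_positive_cells(adata, panel)
            expected = brute_force_positive(counts, labels, gene_idx)
            for sub in got.index:
                assert got[sub] == expected.get(sub, 0)

    @given(st.floats(min_value=0, max_value=4), st.floats(min_value=0, max_value=4))
    def test_raising_positive_min_never_increases_counts(self, lo, hi):
        lo, hi = sorted((lo, hi))
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 5, size=(30, 4))
        adata = labeled(counts, ["a"] * 15 + ["b"] * 15)
        panel = GenePanel(name="P", genes=("G0", "G1"))
        low = count_positive_cells(adata, panel, positive_min=lo)
        high = count_positive_cells(adata, panel, positive_min=hi)
        assert (high <= low).all()

    def test_missing_gene_is_error(self):
        adata = labeled(np.array([[1]]), ["a"], genes=["X"])
        with pytest.raises(ValueError, match="absent"):
            count_positive_cells(adata, GenePanel(name="P", genes=("NOPE",)))


class TestDetectPanels:
    def _registry(self):
        reg = PanelRegistry()
        reg.add(GenePanel(name="P", genes=("G0", "G1")))
        return reg

    def test_fully_expressing_subset_detected(self):
        counts = np.vstack([np.ones((10, 2), int), np.zeros((10, 2), int)])
        adata = labeled(counts, ["hit"] * 10 + ["miss"] * 10)
        det = detect_panels(adata, self._registry(), positivity_threshold=0.10)
        by = det.set_index("subset")
        assert bool(by.loc["hit", "detected"]) and not bool(by.loc["miss", "detected"])

    def test_positivity_at_threshold_is_not_detected(self):
        # 9 positive cells out of 100 in every subset; threshold 0.10 is strict
        counts = np.zeros((200, 2), dtype=int)
        for start in (0, 100):
            counts[start : start + 9] = 1
        adata = labeled(counts, ["a"] * 100 + ["b"] * 100)
        det = detect_panels(adata, self._registry(), positivity_threshold=0.10)
        assert not det["detected"].any()
        det2 = detect_panels(adata, self._registry(), positivity_threshold=0.08)
        assert det2["detected"].all()

    def test_detected_count_monotone_in_threshold(self, rng):
        counts = rng.integers(0, 2, size=(120, 6))
        adata = labeled(counts, [f"s{i % 4}" for i in range(120)])
        reg = PanelRegistry()
        for k in range(3):
            reg.add(GenePanel(name=f"P{k}", genes=(f"G{2 * k}", f"G{2 * k + 1}")))
        previous = None
        for thr in np.linspace(0, 1, 11):
            det = detect_panels(adata, reg, positivity_threshold=thr)
            n = det.groupby("panel")["detected"].any().sum()
            if previous is not None:
                assert n <= previous
            previous = n


class TestResolveMultiAssignment:
    def _detections(self, panels, subset="s0"):
        return pd.DataFrame(
            {
                "panel": panels,
                "subset": [subset] * len(panels),
                "positive_cells": [5] * len(panels),
                "subset_size": [10] * len(panels),
                "positivity": [0.5] * len(panels),
                "detected": [True] * len(panels),
            }
        )

    def _profiles(self, spec):
        return {
            name: compute_oer(name, {"<10": n - g30, "30-40": g30 - g60, ">60": g60}, n)
            for name, (n, g30, g60) in spec.items()
        }

    def test_most_specific_candidate_wins(self):
        profiles = self._profiles({"A": (32, 1, 1), "B": (32, 7, 2)})
        assert resolve_multi_assignment(self._detections(["A", "B"]), profiles) == {"s0": "A"}

    def test_single_candidate_is_identity(self):
        profiles = self._profiles({"A": (32, 5, 2)})
        assert resolve_multi_assignment(self._detections(["A"]), profiles) == {"s0": "A"}

    def test_full_tie_breaks_lexicographically_and_order_invariant(self):
        profiles = self._profiles({"B": (32, 3, 1), "A": (32, 3, 1)})
        for order in itertools.permutations(["A", "B"]):
            assert resolve_multi_assignment(self._detections(list(order)), profiles) == {"s0": "A"}

    def test_missing_profile_is_error(self):
        with pytest.raises(KeyError, match="no OER profile"):
            resolve_multi_assignment(self._detections(["A"]), {})


class TestCompareGroups:
    def _table(self, a_vals, b_vals, panel="P"):
        rows = []
        for i, v in enumerate(a_vals):
            rows.append({"sample": f"a{i}", "group": "A", "panel": panel, "proportion": v})
        for i, v in enumerate(b_vals):
            rows.append({"sample": f"b{i}", "group": "B", "panel": panel, "proportion": v})
        return pd.DataFrame(rows)

    def test_identical_groups_give_p_one(self):
        out = compare_groups(self._table([0.2, 0.2, 0.2], [0.2, 0.2, 0.2]), "A", "B")
        assert out.loc[0, "p_value"] == 1.0

    def test_complete_separation_gives_exact_minimal_p(self):
        # 3 vs 3, fully separated: 2 extreme assignments out of C(6,3)=20
        out = compare_groups(self._table([0.1, 0.1, 0.1], [0.9, 0.9, 0.9]), "A", "B")
        assert out.loc[0, "p_value"] == pytest.approx(0.1)

    def test_swapping_groups_flips_direction_not_p(self):
        table = self._table([0.1, 0.2, 0.15], [0.5, 0.6, 0.4])
        ab = compare_groups(table, "A", "B")
        ba = compare_groups(table, "B", "A")
        assert ab.loc[0, "p_value"] == ba.loc[0, "p_value"]
        assert ab.loc[0, "effect"] == -ba.loc[0, "effect"]
        assert {ab.loc[0, "direction"], ba.loc[0, "direction"]} == {"up", "down"}

    def test_single_sample_group_is_error(self):
        with pytest.raises(ValueError, match=">=2 samples"):
            compare_groups(self._table([0.1], [0.2, 0.3]), "A", "B")

    def test_exact_enumeration_matches_scipy_when_tie_free(self, rng):
        for _ in range(20):
            x = rng.normal(size=4)
            y = rng.normal(size=5)
            ours = exact_ranksum_pvalue(x, y)
            ref = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
            assert ours == pytest.approx(float(ref))

    def test_bh_correction_column(self):
        table = pd.concat(
            [self._table([0.1, 0.1, 0.1], [0.9, 0.9, 0.9], panel=f"P{i}") for i in range(4)]
        )
        out = compare_groups(table, "A", "B", bh_correct=True)
        assert "p_adjusted" in out.columns
        assert (out["p_adjusted"] >= out["p_value"]).all()
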