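import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from atacdiff.genomics_io import ExpressionTable, ValidationError
from atacdiff.integration_targets import (
    TargetFilterSpec,
    etv1_target_selection,
    high_confidence_targets,
    overlap_hypergeometric,
    percent_of,
    prioritize_tfs,
)
from atacdiff.motif_analysis import EnrichmentResult


class TestHighConfidenceTargets:
    SPEC = TargetFilterSpec()

    def _call(self, directions, flags, genes, expr, folds):
        return high_confidence_targets(directions, flags, genes, expr, folds,
                                       self.SPEC)

    def test_all_cuts_pass(self):
        result = self._call(["open-in-cancer"], [True], ["G1"],
                            {"G1": 6.0}, {"G1": 1.4})
        assert result.genes == {"G1"}
        assert result.provenance == {"G1": [0]}

    def test_reduction_exactly_at_cut_dropped(self):
        result = self._call(["open-in-cancer"], [True], ["G1"],
                            {"G1": 6.0}, {"G1": 1.3})
        assert result.genes == set()

    def test_expression_floor_strict(self):
        result = self._call(["open-in-cancer"], [True], ["G1"],
                            {"G1": 5.0}, {"G1": 2.0})
        assert result.genes == set()

    def test_wrong_direction_or_no_motif_dropped(self):
        result = self._call(
            ["open-in-normal", "open-in-cancer"], [True, False],
            ["G1", "G2"], {"G1": 9.0, "G2": 9.0}, {"G1": 2.0, "G2": 2.0},
        )
        assert result.genes == set()

    def test_missing_expression_counted(self):
        result = self._call(["open-in-cancer"], [True], ["G1"], {}, {"G1": 2.0})
        assert result.genes == set()
        assert result.missing_expression == 1

    def test_monotone_in_cuts(self):
        """Loosening any cut never removes a gene."""
        rng = np.random.default_rng(0)
        n = 50
        directions = rng.choice(["open-in-cancer", "open-in-normal"], size=n)
        flags = rng.random(n) < 0.6
        genes = [f"G{i}" for i in range(n)]
        expr = {g: float(rng.uniform(0, 20)) for g in genes}
        folds = {g: float(rng.uniform(0.5, 3)) for g in genes}
        strict = TargetFilterSpec(expression_floor=8.0, reduction_cut=1.8)
        loose = TargetFilterSpec(expression_floor=2.0, reduction_cut=1.1)
        got_strict = high_confidence_targets(directions, flags, genes, expr,
                                             folds, strict).genes
        got_loose = high_confidence_targets(directions, flags, genes, expr,
                                            folds, loose).genes
        assert got_strict <= got_loose


class TestEtv1Selection:
    @pytest.mark.parametrize(
        "is_open,ap1,ets,kept",
        [
            (True, True, False, True),    # open + AP1 only
            (True, False, True, True),    # open + ETS only
            (True, True, True, True),     # open + both
            (False, True, True, False),   # closed
            (True, False, False, False),  # open, no motif
        ],
    )
    def test_or_both_semantics(self, is_open, ap1, ets, kept):
        result = etv1_target_selection(["G1"], [is_open], [ap1], [ets])
        assert (result == {"G1"}) is kept

    def test_unassigned_peaks_skipped(self):
        assert etv1_target_selection([None], [True], [True], [True]) == set()


def hypergeom_enumerate(size_a, size_b, universe, min_overlap):
    """Exhaustive oracle: enumerate every draw of A from the universe."""
    items = range(universe)
    b = set(itertools.islice(items, size_b))
    total = hits = 0
    for draw in itertools.combinations(items, size_a):
        total += 1
        if len(b & set(draw)) >= min_overlap:
            hits += 1
    return hits / total


class TestOverlapHypergeometric:
    def test_identical_full_sets_give_p_one(self):
        universe = {"a", "b", "c"}
        p, ov = overlap_hypergeometric(universe, universe, 3)
        assert ov == 3
        assert p == pytest.approx(1.0)

    def test_small_worked_example(self):
        # |A| = |B| = 2, universe 4, overlap 2: 1 of C(4,2)=6 draws
        a, b = {"w", "x"}, {"w", "x"}
        p, ov = overlap_hypergeometric(a, b, 4)
        assert ov == 2
        assert p == pytest.approx(1.0 / 6.0)

    def test_inconsistent_sizes_rejected(self):
        with pytest.raises(ValidationError):
            overlap_hypergeometric({"a", "b", "c"}, {"a"}, 2)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.data())
    def test_matches_exhaustive_enumeration(self, data):
        universe = data.draw(st.integers(2, 12))
        size_a = data.draw(st.integers(1, universe))
        size_b = data.draw(st.integers(1, universe))
        max_ov = min(size_a, size_b)
        min_ov_possible = max(0, size_a + size_b - universe)
        overlap = data.draw(st.integers(min_ov_possible, max_ov))
        items = [f"i{k}" for k in range(universe)]
        b = set(items[:size_b])
        a = set(items[:overlap]) | set(items[size_b:size_b + size_a - overlap])
        assert len(a) == size_a and len(a & b) == overlap
        p, ov = overlap_hypergeometric(a, b, universe)
        expected = hypergeom_enumerate(size_a, size_b, universe, ov)
        assert p == pytest.approx(expected, rel=1e-9, abs=1e-12)


def _enrichment(motif_id, neglog10_p):
    return EnrichmentResult(motif_id, 10, 20, 0.1, 5.0, 10.0 ** (-neglog10_p))


class TestPrioritizeTfs:
    CANCER = ["c1", "c2"]
    NORMAL = ["n1", "n2"]

    def test_fold_exactly_threshold_is_significant(self):
        table = ExpressionTable(
            pd.DataFrame([[15.0, 15.0, 10.0, 10.0]], index=["TF1"],
                         columns=["c1", "c2", "n1", "n2"]), unit="FPKM")
        rows = prioritize_tfs([_enrichment("M1", 5.0)], table, {"M1": ["TF1"]},
                              self.CANCER, self.NORMAL, pseudocount=0.0)
        assert rows[0].significant
        assert 2 ** rows[0].log2_expression_fold == pytest.approx(1.5)

    def test_opposite_direction_not_significant(self):
        table = ExpressionTable(
            pd.DataFrame([[5.0, 5.0, 10.0, 10.0]], index=["TF1"],
                         columns=["c1", "c2", "n1", "n2"]), unit="FPKM")
        rows = prioritize_tfs([_enrichment("M1", 5.0)], table, {"M1": ["TF1"]},
                              self.CANCER, self.NORMAL)
        assert not rows[0].significant  # 2-fold down while regions open in cancer

    def test_unmapped_motif_gets_missing_y(self):
        table = ExpressionTable(
            pd.DataFrame([[1.0, 1.0, 1.0, 1.0]], index=["TF1"],
                         columns=["c1", "c2", "n1", "n2"]), unit="FPKM")
        rows = prioritize_tfs([_enrichment("M9", 2.0)], table, {},
                              self.CANCER, self.NORMAL)
        assert rows[0].log2_expression_fold is None
        assert not rows[0].significant

    def test_mean_of_means_aggregation(self):
        table = ExpressionTable(
            pd.DataFrame([[40.0, 40.0, 10.0, 10.0], [10.0, 10.0, 10.0, 10.0]],
                         index=["TF1", "TF2"],
                         columns=["c1", "c2", "n1", "n2"]), unit="FPKM")
        rows = prioritize_tfs([_enrichment("M1", 5.0)], table,
                              {"M1": ["TF1", "TF2"]},
                              self.CANCER, self.NORMAL, pseudocount=0.0)
        # mean of per-TF means: (40+10)/2 vs (10+10)/2 = 2.5-fold
        assert 2 ** rows[0].log2_expression_fold == pytest.approx(2.5)

    def test_rows_sorted_by_enrichment_and_input_order_invariant(self):
        table = ExpressionTable(
            pd.DataFrame([[10.0, 10.0, 10.0, 10.0]], index=["TF1"],
                         columns=["c1", "c2", "n1", "n2"]), unit="FPKM")
        enr = [_enrichment("A", 2.0), _enrichment("B", 7.0), _enrichment("C", 4.0)]
        mapping = {m: ["TF1"] for m in "ABC"}
        fwd = prioritize_tfs(enr, table, mapping, self.CANCER, self.NORMAL)
        rev = prioritize_tfs(enr[::-1], table, mapping, self.CANCER, self.NORMAL)
        assert [r.motif_id for r in fwd] == ["B", "C", "A"]
        assert fwd == rev


class TestPercentOf:
    @pytest.mark.parametrize(
        "num,den,expected",
        [(121, 398, 30), (75, 121, 62), (233, 738, 32), (130, 956, 14)],
    )
    def test_published_ratios(self, num, den, expected):
        assert percent_of(num, den) == expected

    def test_round_half_up(self):
        assert percent_of(1, 8) == 13   # 12.5 rounds up
        assert percent_of(1, 200) == 1  # 0.5 rounds up

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValidationError):
            percent_of(1, 0)
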