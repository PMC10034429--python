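"""Needleman–Wunsch alignment and the composite scoring function."""

import itertools
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_force_min_cost
from essalign.align import (
    Alignment,
    align_pair,
    alignment_score,
    format_score,
    gap_penalty_pair,
    homogeneity,
    localize_trim,
    nw_align,
    optimal_cost,
)
from essalign.labels import GAP, format_ess
from essalign.scoring import SubstitutionMatrix, build_matrix
import numpy as np


def total_cost(alignment, matrix, gap_cost=1.0):
    return sum(
        gap_cost if GAP in (x, y) else matrix.loc(x, y)
        for x, y in zip(alignment.aligned1, alignment.aligned2)
    )


class TestWorkedExample:
    def test_printed_gap_placement(self, worked_example, worked_matrix):
        ess1, ess2 = worked_example
        a = nw_align(ess1, ess2, worked_matrix)
        assert format_ess(a.aligned1) == "2.7.1:5.3.1:5.3.1:2.7.1:4.1.2:1.2.1"
        assert format_ess(a.aligned2) == "-.-.-:5.3.1:5.3.1:-.-.-:4.2.1:-.-.-"

    def test_score_components(self, worked_example, worked_matrix):
        ess1, ess2 = worked_example
        a = nw_align(ess1, ess2, worked_matrix)
        assert a.homogeneity == pytest.approx((3 + 11 / 26) / 6)
        assert a.gap_penalty == pytest.approx(0.5)
        assert format_score(a.score) == "0.56698"

    def test_localized_score(self, worked_example, worked_matrix):
        ess1, ess2 = worked_example
        trimmed = align_pair(ess1, ess2, worked_matrix, localize=True)
        # columns spanned by the shorter ESS: 5.3.1/5.3.1, 5.3.1/5.3.1,
        # 2.7.1/gap, 4.1.2/4.2.1
        assert len(trimmed) == 4
        expected = 0.95 * ((0 + 0 + 1 + 11 / 26) / 4) + 0.05 * 0.5
        assert trimmed.score == pytest.approx(expected)


class TestNWAlign:
    def test_identity_alignment_costs_nothing(self, small_matrix, small_alphabet):
        seq = [small_alphabet[i % len(small_alphabet)] for i in range(7)]
        a = nw_align(seq, seq, small_matrix)
        assert GAP not in a.aligned1 + a.aligned2
        assert a.score == 0.0
        assert optimal_cost(seq, seq, small_matrix) == 0.0

    def test_alignment_recovers_inputs(self, small_matrix, small_alphabet):
        rng = random.Random(7)
        for _ in range(50):
            s1 = rng.choices(small_alphabet, k=rng.randint(1, 8))
            s2 = rng.choices(small_alphabet, k=rng.randint(1, 8))
            a = nw_align(s1, s2, small_matrix)
            assert [x for x in a.aligned1 if x != GAP] == s1
            assert [x for x in a.aligned2 if x != GAP] == s2
            assert not any(
                x == GAP and y == GAP for x, y in zip(a.aligned1, a.aligned2)
            )

    def test_traceback_cost_equals_dp_cost(self, small_matrix, small_alphabet):
        rng = random.Random(11)
        for _ in range(50):
            s1 = rng.choices(small_alphabet, k=rng.randint(1, 8))
            s2 = rng.choices(small_alphabet, k=rng.randint(1, 8))
            a = nw_align(s1, s2, small_matrix)
            assert total_cost(a, small_matrix) == pytest.approx(
                optimal_cost(s1, s2, small_matrix)
            )

    def test_matches_enumeration_oracle_small(self, small_matrix, small_alphabet):
        seqs = [
            list(t)
            for n in (1, 2, 3)
            for t in itertools.product(small_alphabet[:3], repeat=n)
        ]
        for s1 in seqs:
            for s2 in seqs:
                assert optimal_cost(s1, s2, small_matrix) == pytest.approx(
                    brute_force_min_cost(s1, s2, small_matrix)
                )

    def test_all_gap_upper_bound(self, small_matrix, small_alphabet):
        rng = random.Random(3)
        for _ in range(30):
            s1 = rng.choices(small_alphabet, k=rng.randint(1, 8))
            s2 = rng.choices(small_alphabet, k=rng.randint(1, 8))
            assert optimal_cost(s1, s2, small_matrix) <= len(s1) + len(s2)

    def test_zero_matrix_cost_is_length_difference(self, small_alphabet):
        labels = small_alphabet + ["9.9.9"]
        zero = SubstitutionMatrix(
            labels, np.zeros((len(labels), len(labels)))
        )
        rng = random.Random(5)
        for _ in range(20):
            s1 = rng.choices(small_alphabet, k=rng.randint(1, 8))
            s2 = rng.choices(small_alphabet, k=rng.randint(1, 8))
            assert optimal_cost(s1, s2, zero) == pytest.approx(
                abs(len(s1) - len(s2))
            )

    def test_lowering_substitution_never_raises_cost(
        self, small_matrix, small_alphabet
    ):
        rng = random.Random(13)
        for _ in range(20):
            s1 = rng.choices(small_alphabet, k=rng.randint(2, 6))
            s2 = rng.choices(small_alphabet, k=rng.randint(2, 6))
            before = optimal_cost(s1, s2, small_matrix)
            values = small_matrix.values.copy()
            i = rng.randrange(len(small_alphabet))
            j = rng.randrange(len(small_alphabet))
            if i == j:
                continue
            values[i, j] = values[j, i] = values[i, j] / 2.0
            lowered = SubstitutionMatrix(small_matrix.labels, values)
            assert optimal_cost(s1, s2, lowered) <= before + 1e-12

    def test_empty_sequence_rejected(self, small_matrix):
        with pytest.raises(ValueError):
            nw_align([], ["2.7.1"], small_matrix)

    def test_unknown_label_named_in_error(self, small_matrix):
        with pytest.raises(KeyError, match="8.8.8"):
            nw_align(["8.8.8"], ["2.7.1"], small_matrix)


class TestScoreComponents:
    def test_homogeneity_of_identity_is_zero(self, small_matrix):
        a = ["2.7.1", "5.3.1"]
        assert homogeneity(a, a, small_matrix) == 0.0

    def test_fully_gapped_columns_score_one(self, small_matrix):
        a1 = ["2.7.1", "5.3.1", GAP, GAP]
        a2 = [GAP, GAP, "2.7.1", "5.3.1"]
        assert homogeneity(a1, a2, small_matrix) == 1.0

    @pytest.mark.parametrize(
        "aligned,expected",
        [
            (["2.7.1", "5.3.1", "2.7.1"], 0.0),  # gapless
            ([GAP, "2.7.1", "5.3.1", GAP], 0.0),  # terminal gaps excluded
            (["2.7.1", GAP, GAP, GAP, "5.3.1"], 1 / 3),  # one block of 3
            (["2.7.1", GAP, "5.3.1", GAP, "2.7.1"], 1.0),  # two isolated gaps
            ([GAP, "2.7.1", GAP, GAP, "5.3.1", GAP], 1 / 2),  # mixed
        ],
    )
    def test_per_sequence_gap_ratio(self, aligned, expected):
        gapless = ["2.7.1"] * len(aligned)
        assert gap_penalty_pair(aligned, gapless) == pytest.approx(expected / 2)

    def test_fully_mismatched_gapless_scores_095(self):
        m = build_matrix(["1.1.1", "2.2.2"])
        a = nw_align(["1.1.1"] * 4, ["2.2.2"] * 4, m)
        assert a.homogeneity == 1.0
        assert a.gap_penalty == 0.0
        assert a.score == pytest.approx(0.95)

    def test_alignment_score_matches_components(self, worked_example, worked_matrix):
        a = nw_align(*worked_example, worked_matrix)
        assert alignment_score(a) == pytest.approx(
            0.95 * a.homogeneity + 0.05 * a.gap_penalty
        )

    def test_format_score_truncates(self):
        assert format_score(0.5669871794871795) == "0.56698"
        assert format_score(0.0) == "0.00000"
        assert format_score(1.0) == "1.00000"


class TestLocalizeTrim:
    def test_trim_is_identity_when_short_seq_spans_all(self, small_matrix):
        a = nw_align(["2.7.1", "5.3.1"], ["2.7.1", "5.3.1"], small_matrix)
        t = localize_trim(a, small_matrix)
        assert t == a

    def test_equal_length_gapless_identity(self, small_matrix, small_alphabet):
        s1 = small_alphabet[:4]
        s2 = list(reversed(small_alphabet[:4]))
        a = nw_align(s1, s2, small_matrix)
        if GAP not in a.aligned1 + a.aligned2:
            assert localize_trim(a, small_matrix) == a

    def test_trim_never_lengthens_and_rescoring_consistent(
        self, small_matrix, small_alphabet
    ):
        rng = random.Random(23)
        for _ in range(30):
            s1 = rng.choices(small_alphabet, k=rng.randint(2, 9))
            s2 = rng.choices(small_alphabet, k=rng.randint(2, 9))
            a = nw_align(s1, s2, small_matrix)
            t = localize_trim(a, small_matrix)
            assert len(t) <= len(a)
            assert t.score == pytest.approx(
                0.95 * t.homogeneity + 0.05 * t.gap_penalty
            )


label_strategy = st.sampled_from(["2.7.1", "2.7.2", "2.4.1", "5.3.1"])
seq_strategy = st.lists(label_strategy, min_size=1, max_size=8)


class TestScoreProperties:
    @given(s1=seq_strategy, s2=seq_strategy)
    @settings(max_examples=150, deadline=None)
    def test_symmetry_and_bounds(self, small_matrix, s1, s2):
        a = nw_align(s1, s2, small_matrix)
        b = nw_align(s2, s1, small_matrix)
        assert a.score == pytest.approx(b.score)
        assert 0.0 <= a.score <= 1.0
        assert 0.0 <= a.homogeneity <= 1.0
        assert 0.0 <= a.gap_penalty <= 1.0

    @given(s=seq_strategy)
    @settings(max_examples=100, deadline=None)
    def test_self_alignment_is_zero(self, small_matrix, s):
        assert nw_align(s, s, small_matrix).score == 0.0


class TestAlignmentContainer:
    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            Alignment(("2.7.1",), ("2.7.1", "5.3.1"), 0, 0, 0)

    def test_gap_vs_gap_rejected(self, small_matrix):
        with pytest.raises(ValueError):
            Alignment.from_gapped([GAP, "2.7.1"], [GAP, "2.7.1"], small_matrix)
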