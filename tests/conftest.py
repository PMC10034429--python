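"""Shared fixtures and the independent alignment oracle."""

from __future__ import annotations

import pytest

from essalign.labels import GAP
from essalign.scoring import build_matrix, matrix_for


def enumerate_alignments(s1, s2):
    """Yield every monotone gapped alignment of two sequences.

    Plain recursion over the three column choices — no memoisation, no
    dynamic programming — so this is an independent oracle for the NW
    implementation, usable only at small lengths.
    """
    if not s1 and not s2:
        yield ([], [])
        return
    if s1 and s2:
        for a1, a2 in enumerate_alignments(s1[1:], s2[1:]):
            yield ([s1[0]] + a1, [s2[0]] + a2)
    if s1:
        for a1, a2 in enumerate_alignments(s1[1:], s2):
            yield ([s1[0]] + a1, [GAP] + a2)
    if s2:
        for a1, a2 in enumerate_alignments(s1, s2[1:]):
            yield ([GAP] + a1, [s2[0]] + a2)


def brute_force_min_cost(s1, s2, matrix, gap_cost=1.0):
    """Minimum total dissimilarity over all enumerated alignments."""
    best = None
    for a1, a2 in enumerate_alignments(list(s1), list(s2)):
        cost = 0.0
        for x, y in zip(a1, a2):
            cost += gap_cost if GAP in (x, y) else matrix.loc(x, y)
        if best is None or cost < best:
            best = cost
    return best


@pytest.fixture(scope="session")
def worked_example():
    """The documented CLI pair example: inputs and printed outputs."""
    ess1 = "2.7.1:5.3.1:5.3.1:2.7.1:4.1.2:1.2.1".split(":")
    ess2 = "5.3.1:5.3.1:4.2.1".split(":")
    return ess1, ess2


@pytest.fixture(scope="session")
def worked_matrix(worked_example):
    return matrix_for(worked_example)


@pytest.fixture(scope="session")
def small_matrix():
    """Matrix over a 4-label alphabet spanning all dissimilarity tiers."""
    return build_matrix(["2.7.1", "2.7.2", "2.4.1", "5.3.1"])


@pytest.fixture(scope="session")
def small_alphabet(small_matrix):
    return [lab for lab in small_matrix.labels if lab != "9.9.9"]
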