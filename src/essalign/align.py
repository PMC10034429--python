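"""Global pairwise alignment of enzymatic step sequences.

The aligner is a minimizing Needleman–Wunsch: cell (i, j) of the DP
matrix holds the least total dissimilarity of aligning the first i
steps of one ESS against the first j steps of the other,

    M[i][j] = min( M[i-1][j-1] + S(ec_i, ec_j),
                   M[i][j-1]   + gap,
                   M[i-1][j]   + gap )

with gap cost 1, the maximum dissimilarity of two EC numbers.  Low
scores therefore mean similar sequences.  Gaps are written ``"-.-.-"``.

An alignment is summarised by a composite score in [0, 1]:

    score = 0.95 * H + 0.05 * GP

where H (homogeneity) is the mean per-column dissimilarity, a column
pairing a step with a gap counting as the maximum 1, and GP penalises
scattered gaps: for each sequence the number of internal gap blocks is
divided by its internal gap-character count (terminal gap runs are left
out of GP, though they do count in H), and GP is the mean of the two
ratios, a gapless sequence contributing 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .labels import GAP
from .scoring import SubstitutionMatrix

H_WEIGHT = 0.95
GP_WEIGHT = 0.05
DEFAULT_GAP_COST = 1.0


@dataclass(frozen=True)
class Alignment:
    """Two equal-length gapped label sequences plus score components."""

    aligned1: tuple[str, ...]
    aligned2: tuple[str, ...]
    homogeneity: float
    gap_penalty: float
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned1) != len(self.aligned2):
            raise ValueError("aligned sequences must have equal length")

    def __len__(self) -> int:
        return len(self.aligned1)

    @classmethod
    def from_gapped(
        cls, aligned1, aligned2, matrix: SubstitutionMatrix
    ) -> "Alignment":
        """Score a pre-gapped pair of sequences."""
        a1 = tuple(aligned1)
        a2 = tuple(aligned2)
        if len(a1) != len(a2):
            raise ValueError("aligned sequences must have equal length")
        if any(x == GAP and y == GAP for x, y in zip(a1, a2)):
            raise ValueError("gap-vs-gap columns are not allowed")
        h = homogeneity(a1, a2, matrix)
        gp = gap_penalty_pair(a1, a2)
        return cls(a1, a2, h, gp, composite_score(h, gp))


def homogeneity(aligned1, aligned2, matrix: SubstitutionMatrix) -> float:
    """Mean per-column dissimilarity; any gap column contributes 1.

    Terminal gaps are included — H sees the full alignment length.
    """
    n = len(aligned1)
    if n == 0:
        raise ValueError("empty alignment")
    total = 0.0
    for x, y in zip(aligned1, aligned2):
        total += 1.0 if GAP in (x, y) else matrix.loc(x, y)
    return total / n


def _internal_gap_stats(aligned) -> tuple[int, int]:
    """(gap blocks, gap characters) between the first and last residue.

    Gap runs hanging off either end of the sequence are not counted.
    """
    residue_pos = [i for i, x in enumerate(aligned) if x != GAP]
    if not residue_pos:
        return 0, 0
    lo, hi = residue_pos[0], residue_pos[-1]
    blocks = 0
    chars = 0
    in_block = False
    for x in aligned[lo : hi + 1]:
        if x == GAP:
            chars += 1
            if not in_block:
                blocks += 1
                in_block = True
        else:
            in_block = False
    return blocks, chars


def gap_penalty_pair(aligned1, aligned2) -> float:
    """Mean over both sequences of (internal gap blocks / internal gaps).

    A sequence with no internal gaps contributes 0.  The ratio equals 1
    when every internal gap stands alone and falls toward 0 as gaps
    coalesce into fewer, longer blocks.
    """
    contributions = []
    for aligned in (aligned1, aligned2):
        blocks, chars = _internal_gap_stats(aligned)
        contributions.append(blocks / chars if chars else 0.0)
    return sum(contributions) / len(contributions)


def composite_score(h: float, gp: float) -> float:
    return H_WEIGHT * h + GP_WEIGHT * gp


def alignment_score(alignment: Alignment) -> float:
    """Composite dissimilarity 0.95*H + 0.05*GP of an alignment."""
    return composite_score(alignment.homogeneity, alignment.gap_penalty)


def format_score(score: float, decimals: int = 5) -> str:
    """Render a score the way the CLI reports it: truncated, not rounded.

    The reference outputs print 0.5669872... as ``0.56698``, so the
    final digit is floored toward zero.
    """
    scale = 10**decimals
    return f"{math.floor(score * scale + 1e-12) / scale:.{decimals}f}"


def nw_align(
    seq1,
    seq2,
    matrix: SubstitutionMatrix,
    gap_cost: float = DEFAULT_GAP_COST,
) -> Alignment:
    """Minimizing global alignment of two ungapped ESS.

    Traceback ties are broken deterministically, preferring a
    substitution column over a gap in the second sequence over a gap in
    the first.
    """
    s1 = list(seq1)
    s2 = list(seq2)
    if not s1 or not s2:
        raise ValueError("cannot align an empty sequence")
    if any(x == GAP for x in s1 + s2):
        raise ValueError("input sequences must not contain gap labels")
    # canonical input order: co-optimal tracebacks are resolved the same
    # way for (X, Y) and (Y, X), making the score exactly symmetric
    if tuple(s2) < tuple(s1):
        mirror = nw_align(s2, s1, matrix, gap_cost)
        return Alignment(
            mirror.aligned2,
            mirror.aligned1,
            mirror.homogeneity,
            mirror.gap_penalty,
            mirror.score,
        )
    n, m = len(s1), len(s2)
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        M[i][0] = i * gap_cost
    for j in range(1, m + 1):
        M[0][j] = j * gap_cost
    for i in range(1, n + 1):
        row = M[i]
        prev = M[i - 1]
        a = s1[i - 1]
        for j in range(1, m + 1):
            row[j] = min(
                prev[j - 1] + matrix.loc(a, s2[j - 1]),
                row[j - 1] + gap_cost,
                prev[j] + gap_cost,
            )
    aligned1: list[str] = []
    aligned2: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if (
            i > 0
            and j > 0
            and math.isclose(
                M[i][j], M[i - 1][j - 1] + matrix.loc(s1[i - 1], s2[j - 1])
            )
        ):
            aligned1.append(s1[i - 1])
            aligned2.append(s2[j - 1])
            i -= 1
            j -= 1
        elif i > 0 and math.isclose(M[i][j], M[i - 1][j] + gap_cost):
            aligned1.append(s1[i - 1])
            aligned2.append(GAP)
            i -= 1
        else:
            aligned1.append(GAP)
            aligned2.append(s2[j - 1])
            j -= 1
    aligned1.reverse()
    aligned2.reverse()
    return Alignment.from_gapped(aligned1, aligned2, matrix)


def optimal_cost(
    seq1, seq2, matrix: SubstitutionMatrix, gap_cost: float = DEFAULT_GAP_COST
) -> float:
    """Total DP cost M[n][m] of the optimal alignment (no traceback)."""
    s1 = list(seq1)
    s2 = list(seq2)
    if not s1 or not s2:
        raise ValueError("cannot align an empty sequence")
    m = len(s2)
    prev = [j * gap_cost for j in range(m + 1)]
    for i, a in enumerate(s1, start=1):
        cur = [i * gap_cost] + [0.0] * m
        for j in range(1, m + 1):
            cur[j] = min(
                prev[j - 1] + matrix.loc(a, s2[j - 1]),
                cur[j - 1] + gap_cost,
                prev[j] + gap_cost,
            )
        prev = cur
    return prev[m]


def localize_trim(alignment: Alignment, matrix: SubstitutionMatrix) -> Alignment:
    """Trim the alignment to the coverage of the shorter input and rescore.

    Columns outside the span from the first to the last residue of the
    sequence with fewer residues are dropped; when both inputs have the
    same number of residues the intersection of their spans is used.  H
    and GP are recomputed on the remaining columns, so gap runs that
    become terminal inside the window drop out of GP.
    """
    spans = []
    counts = []
    for aligned in (alignment.aligned1, alignment.aligned2):
        pos = [i for i, x in enumerate(aligned) if x != GAP]
        if not pos:
            raise ValueError("alignment has a fully gapped sequence")
        spans.append((pos[0], pos[-1]))
        counts.append(len(pos))
    if counts[0] < counts[1]:
        lo, hi = spans[0]
    elif counts[1] < counts[0]:
        lo, hi = spans[1]
    else:
        lo = max(spans[0][0], spans[1][0])
        hi = min(spans[0][1], spans[1][1])
        if lo > hi:
            raise ValueError("sequence spans do not overlap; nothing to trim to")
    return Alignment.from_gapped(
        alignment.aligned1[lo : hi + 1], alignment.aligned2[lo : hi + 1], matrix
    )


def align_pair(
    seq1,
    seq2,
    matrix: SubstitutionMatrix,
    gap_cost: float = DEFAULT_GAP_COST,
    localize: bool = False,
) -> Alignment:
    """Align and score, optionally with the localize trim applied."""
    alignment = nw_align(seq1, seq2, matrix, gap_cost)
    if localize:
        alignment = localize_trim(alignment, matrix)
    return alignment
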