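"""Shuffled-null score distributions and significance thresholds.

How low must an alignment score be before two ESS are more similar
than chance?  The null model shuffles the EC-number content of the
entire database globally — every token is reassigned at random into
sequences of the original lengths — so each replicate preserves the
database-wide EC composition and every sequence length exactly while
destroying any within-sequence order or family structure.  (A
per-sequence permutation would keep each sequence's own composition
and with it most of the family signal, which would make the null far
too conservative.)

Real all-vs-all scores are then compared against an ensemble of such
replicates (default 10).  The report gives mean ± SD per replicate and
full curves of cumulative score density for real and null data plus
the fraction of sequences left partnerless at each candidate cutoff,
and recommends the largest threshold where the real data remain denser
than the null mean and sequence loss stays under a cap (default 1%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .batch import ScoredPair

DEFAULT_REPLICATES = 10
DEFAULT_LOSS_CAP = 0.01
#: rule-of-thumb cutoff derived from a KEGG-wide database
REFERENCE_THRESHOLD = 0.27


def shuffle_database(
    sequences: list[list[str]], seed: int
) -> list[list[str]]:
    """Globally shuffle EC tokens across a database of sequences.

    The returned database has the same number of sequences, each of its
    original length, and exactly the same overall EC-label multiset.
    """
    if not sequences:
        raise ValueError("cannot shuffle an empty database")
    rng = np.random.default_rng(seed)
    tokens = [lab for seq in sequences for lab in seq]
    order = rng.permutation(len(tokens))
    shuffled_tokens = [tokens[i] for i in order]
    out = []
    pos = 0
    for seq in sequences:
        out.append(shuffled_tokens[pos : pos + len(seq)])
        pos += len(seq)
    return out


def make_null_ensemble(
    sequences: list[list[str]],
    n_replicates: int = DEFAULT_REPLICATES,
    base_seed: int = 0,
) -> list[list[list[str]]]:
    """``n_replicates`` shuffled databases, replicate r seeded base_seed + r."""
    return [
        shuffle_database(sequences, base_seed + r) for r in range(n_replicates)
    ]


@dataclass
class ThresholdReport:
    """Curves and summaries backing a recommended significance cutoff."""

    grid: np.ndarray
    real_density: np.ndarray  # fraction of real pairs scoring <= t
    null_density: np.ndarray  # same, averaged over null replicates
    loss_fraction: np.ndarray  # fraction of sequences with no partner <= t
    null_stats: list[tuple[float, float]]  # (mean, sd) per replicate
    recommended_threshold: float | None
    separable: bool
    loss_cap: float
    reference_threshold: float = REFERENCE_THRESHOLD

    def summary_table(self) -> str:
        lines = ["replicate\tmean\tsd"]
        for r, (mean, sd) in enumerate(self.null_stats):
            lines.append(f"{r}\t{mean:.5f}\t{sd:.5f}")
        rec = (
            f"{self.recommended_threshold:.3f}"
            if self.recommended_threshold is not None
            else "none (real and null not separable)"
        )
        lines.append(f"recommended_threshold\t{rec}")
        lines.append(f"reference_threshold\t{self.reference_threshold}")
        return "\n".join(lines)


def _ecdf(scores: np.ndarray, grid: np.ndarray) -> np.ndarray:
    if scores.size == 0:
        return np.zeros_like(grid)
    scores = np.sort(scores)
    return np.searchsorted(scores, grid, side="right") / scores.size


def threshold_report(
    real_pairs: list[ScoredPair],
    n_sequences: int,
    null_score_sets: list[np.ndarray],
    loss_cap: float = DEFAULT_LOSS_CAP,
    grid: np.ndarray | None = None,
) -> ThresholdReport:
    """Derive a significance threshold from real vs shuffled-null scores.

    ``real_pairs`` must be the unfiltered all-vs-all result (threshold
    1.0) so the cumulative curves are unbiased.  The recommendation is
    the largest grid point below the null band (every replicate's
    mean − SD) where (a) the real cumulative density
    strictly exceeds the null-mean cumulative density and (b) fewer
    than ``loss_cap`` of the ``n_sequences`` have no partner at or
    below the cutoff.  With ``loss_cap`` = 1 criterion (b) never binds.
    """
    if not real_pairs:
        raise ValueError("no real alignment scores supplied")
    if not null_score_sets:
        raise ValueError("no null score distributions supplied")
    if grid is None:
        grid = np.round(np.arange(0.0, 1.0001, 0.005), 3)
    real_scores = np.array([p.score for p in real_pairs], dtype=float)
    real_density = _ecdf(real_scores, grid)
    null_arrays = [np.asarray(s, dtype=float) for s in null_score_sets]
    null_density = np.mean([_ecdf(arr, grid) for arr in null_arrays], axis=0)
    null_stats = [(float(arr.mean()), float(arr.std(ddof=1))) for arr in null_arrays]

    # best (lowest) score seen per sequence, for the loss criterion
    best: dict[int, float] = {}
    for pair in real_pairs:
        for sid in (pair.id1, pair.id2):
            if pair.score < best.get(sid, np.inf):
                best[sid] = pair.score
    best_values = np.sort(np.array(list(best.values()), dtype=float))
    partnered = np.searchsorted(best_values, grid, side="right") / n_sequences
    loss_fraction = 1.0 - partnered

    # a significant cutoff must sit below the null score band (mean - SD
    # of every replicate), not merely below the null maximum
    band_edge = min(mean - sd for mean, sd in null_stats)
    ok = (
        (real_density > null_density)
        & (loss_fraction < loss_cap)
        & (grid < band_edge)
    )
    if ok.any():
        recommended = float(grid[np.nonzero(ok)[0][-1]])
        separable = True
    else:
        separable = bool((real_density > null_density).any())
        recommended = None
    return ThresholdReport(
        grid=grid,
        real_density=real_density,
        null_density=null_density,
        loss_fraction=loss_fraction,
        null_stats=null_stats,
        recommended_threshold=recommended,
        separable=separable,
        loss_cap=loss_cap,
    )
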