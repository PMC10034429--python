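"""All-vs-all and database-vs-database ESS alignment.

Every unordered pair within one sequence set (or every cross pair
between two sets) is aligned, and pairs scoring at or below a
significance threshold (default 0.27) are emitted as (id1, id2, score)
rows, optionally with the gapped alignments.  Work is partitioned into
contiguous row blocks handed to a process pool; because each block's
result is merged back in block order, the emitted set and its ordering
are identical for any worker count.  Results are streamed to the output
file rather than accumulated, since permissive thresholds on large
databases can produce very large result sets.
"""

from __future__ import annotations

import multiprocessing as mp
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

from .align import align_pair, format_score
from .labels import format_ess
from .scoring import DEFAULT_WEIGHTS, SubstitutionMatrix, WeightConfig, matrix_for

DEFAULT_THRESHOLD = 0.27


@dataclass(frozen=True)
class ScoredPair:
    id1: int
    id2: int
    score: float
    alignment: tuple[str, str] | None = None


# worker state, set once per process by the pool initializer
_STATE: dict = {}


def _init_worker(seqs1, seqs2, matrix, localize, emit_alignments, threshold):
    _STATE.update(
        seqs1=seqs1,
        seqs2=seqs2,
        matrix=matrix,
        localize=localize,
        emit_alignments=emit_alignments,
        threshold=threshold,
    )


def _align_block(rows: Sequence[int]) -> list[ScoredPair]:
    seqs1 = _STATE["seqs1"]
    seqs2 = _STATE["seqs2"]
    matrix = _STATE["matrix"]
    out: list[ScoredPair] = []
    for i in rows:
        id1, labels1 = seqs1[i]
        if seqs2 is None:  # all-vs-all within one set: j > i only
            partners = seqs1[i + 1 :]
        else:
            partners = seqs2
        for id2, labels2 in partners:
            alignment = align_pair(
                labels1, labels2, matrix, localize=_STATE["localize"]
            )
            if alignment.score <= _STATE["threshold"]:
                gapped = (
                    (format_ess(alignment.aligned1), format_ess(alignment.aligned2))
                    if _STATE["emit_alignments"]
                    else None
                )
                out.append(ScoredPair(id1, id2, alignment.score, gapped))
    return out


def _blocks(n_rows: int, n_blocks: int) -> list[list[int]]:
    n_blocks = max(1, min(n_blocks, n_rows))
    size, extra = divmod(n_rows, n_blocks)
    blocks = []
    start = 0
    for b in range(n_blocks):
        stop = start + size + (1 if b < extra else 0)
        blocks.append(list(range(start, stop)))
        start = stop
    return blocks


def dbalign(
    seqs1: Sequence[tuple[int, Sequence[str]]],
    seqs2: Sequence[tuple[int, Sequence[str]]] | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    nproc: int = 1,
    localize: bool = False,
    emit_alignments: bool = False,
    weights: WeightConfig = DEFAULT_WEIGHTS,
    matrix: SubstitutionMatrix | None = None,
) -> Iterator[ScoredPair]:
    """Yield scored pairs at or below ``threshold``.

    With one sequence set, all C(k, 2) unordered pairs are aligned
    (self-pairs excluded); with two sets, every cross pair including
    identical ids.  The yielded set does not depend on ``nproc``.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    seqs1 = [(int(i), list(s)) for i, s in seqs1]
    seqs2 = None if seqs2 is None else [(int(i), list(s)) for i, s in seqs2]
    if matrix is None:
        all_seqs = [s for _, s in seqs1] + ([s for _, s in seqs2] if seqs2 else [])
        matrix = matrix_for(all_seqs, weights)
    n_rows = len(seqs1)
    if n_rows == 0:
        return
    if nproc <= 1:
        _init_worker(seqs1, seqs2, matrix, localize, emit_alignments, threshold)
        for block in _blocks(n_rows, 1):
            yield from _align_block(block)
        return
    # many small blocks so uneven row costs balance across workers
    blocks = _blocks(n_rows, nproc * 4)
    with mp.Pool(
        nproc,
        initializer=_init_worker,
        initargs=(seqs1, seqs2, matrix, localize, emit_alignments, threshold),
    ) as pool:
        for result in pool.imap(_align_block, blocks):
            yield from result


def write_scores(
    pairs: Iterable[ScoredPair], destination, emit_alignments: bool = False
) -> int:
    """Stream pairs to a tab-separated file; returns the row count."""
    n = 0
    own = isinstance(destination, (str, bytes)) or hasattr(destination, "__fspath__")
    handle = open(destination, "w") if own else destination
    try:
        header = ["ess1", "ess2", "score"]
        if emit_alignments:
            header += ["alignment1", "alignment2"]
        handle.write("\t".join(header) + "\n")
        for pair in pairs:
            row = [str(pair.id1), str(pair.id2), format_score(pair.score)]
            if emit_alignments:
                row += list(pair.alignment or ("", ""))
            handle.write("\t".join(row) + "\n")
            n += 1
    finally:
        if own:
            handle.close()
    return n
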