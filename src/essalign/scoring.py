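"""Entropy-based dissimilarity of EC numbers.

Two closely related measures are provided.  ``ecs_dissimilarity`` is the
general column form: each of the three EC levels is treated as an
alignment column, its Shannon entropy is computed over the symbols
present, and the three entropies are combined as a weighted mean.  For a
pair of EC numbers every per-level entropy is 0 (same symbol) or 1
(different symbols), so the pairwise value reduces to a weighted count
of mismatched levels.

``matrix_entry`` adds the hierarchy override used to build the pairwise
substitution matrix S: a mismatch at a level forces every deeper level
to count as mismatched as well, because EC sublevels are only comparable
within the same parent class.  With the default weights (15, 10, 1) the
possible pairwise values are 0, 1/26, 11/26 and 1.

The sentinel ``9.9.9`` (no EC assigned) is similar only to itself and
maximally dissimilar (1) to every other label.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .labels import GAP, UNASSIGNED, ec_sort_key, is_ec3


@dataclass(frozen=True)
class WeightConfig:
    """Per-level weights for the three EC classification levels."""

    w1: float = 15.0
    w2: float = 10.0
    w3: float = 1.0

    def __post_init__(self) -> None:
        if min(self.w1, self.w2, self.w3) < 0 or self.w1 + self.w2 + self.w3 <= 0:
            raise ValueError("weights must be non-negative with a positive sum")

    @property
    def total(self) -> float:
        return self.w1 + self.w2 + self.w3

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.w1, self.w2, self.w3)


DEFAULT_WEIGHTS = WeightConfig()


def column_entropy(symbols: Sequence[str]) -> float:
    """Shannon entropy (base 2) of a multiset of level symbols.

    For two symbols this is 0 when they are equal and 1 when they
    differ, which is the simplification the pairwise matrix relies on.
    """
    if len(symbols) == 0:
        raise ValueError("entropy of an empty column is undefined")
    n = len(symbols)
    counts = Counter(symbols)
    return -sum((c / n) * math.log2(c / n) for c in counts.values())


def _check_scorable(label: str) -> None:
    if label == GAP:
        raise ValueError("gap labels are handled by the aligner, not the scorer")
    if not is_ec3(label):
        raise ValueError(f"not a three-level EC label: {label!r}")


def ecs_dissimilarity(
    ec_list: Sequence[str], weights: WeightConfig = DEFAULT_WEIGHTS
) -> float:
    """Weighted mean per-level entropy of a column of EC numbers.

    ``ec_list`` holds the EC labels aligned in one column (two for a
    pairwise alignment, more for a multiple alignment).  Gap labels are
    rejected; the aligner accounts for gaps separately.
    """
    if not ec_list:
        raise ValueError("empty EC column")
    for label in ec_list:
        _check_scorable(label)
    levels = [label.split(".") for label in ec_list]
    w = weights.as_tuple()
    num = sum(
        w[lvl] * column_entropy([parts[lvl] for parts in levels]) for lvl in range(3)
    )
    return num / weights.total


def matrix_entry(
    ec1: str, ec2: str, weights: WeightConfig = DEFAULT_WEIGHTS
) -> float:
    """Hierarchy-overridden pairwise dissimilarity in [0, 1].

    A first-level mismatch scores 1 outright; a second-level mismatch
    counts levels 2 and 3 as mismatched; otherwise only the third level
    can differ.  ``9.9.9`` scores 1 against everything but itself.
    """
    _check_scorable(ec1)
    _check_scorable(ec2)
    if ec1 == ec2:
        return 0.0
    if UNASSIGNED in (ec1, ec2):
        return 1.0
    l1 = ec1.split(".")
    l2 = ec2.split(".")
    if l1[0] != l2[0]:
        return 1.0
    if l1[1] != l2[1]:
        return (weights.w2 + weights.w3) / weights.total
    return weights.w3 / weights.total


class SubstitutionMatrix:
    """Symmetric EC dissimilarity lookup over a fixed label universe.

    Values live in [0, 1] with a zero diagonal.  Backed by a dense numpy
    array with a label index; ``loc`` raises a ``KeyError`` naming any
    label absent from the universe.
    """

    def __init__(self, labels: Sequence[str], values: np.ndarray):
        self.labels = list(labels)
        self._index = {lab: i for i, lab in enumerate(self.labels)}
        self.values = np.asarray(values, dtype=float)
        if self.values.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match label count")

    def __contains__(self, label: str) -> bool:
        return label in self._index

    def loc(self, ec1: str, ec2: str) -> float:
        try:
            i = self._index[ec1]
        except KeyError:
            raise KeyError(f"EC label not in substitution matrix: {ec1!r}") from None
        try:
            j = self._index[ec2]
        except KeyError:
            raise KeyError(f"EC label not in substitution matrix: {ec2!r}") from None
        return float(self.values[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="ec")

    @classmethod
    def read_tsv(cls, path) -> "SubstitutionMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        frame.columns = [str(c) for c in frame.columns]
        return cls([str(i) for i in frame.index], frame.to_numpy())


def build_matrix(
    labels: Iterable[str], weights: WeightConfig = DEFAULT_WEIGHTS
) -> SubstitutionMatrix:
    """Precompute the full symmetric matrix over ``labels`` plus ``9.9.9``.

    The label universe is whatever EC numbers occur in the data at hand;
    the matrix is cheap to regenerate and is not a fixed-size constant.
    """
    seen = set()
    ordered = []
    for lab in labels:
        _check_scorable(lab)
        if lab in seen:
            raise ValueError(f"duplicate label: {lab!r}")
        seen.add(lab)
        ordered.append(lab)
    ordered = sorted(ordered, key=ec_sort_key)
    if UNASSIGNED not in seen:
        ordered.append(UNASSIGNED)
    n = len(ordered)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = matrix_entry(ordered[i], ordered[j], weights)
    return SubstitutionMatrix(ordered, values)


def matrix_for(
    sequences: Iterable[Sequence[str]], weights: WeightConfig = DEFAULT_WEIGHTS
) -> SubstitutionMatrix:
    """Build a substitution matrix covering every label used in ``sequences``."""
    universe = {lab for seq in sequences for lab in seq}
    return build_matrix(universe, weights)
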