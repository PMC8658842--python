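"""Three-pair seed guess generation.

Three matched feature pairs are the minimum that pins down an
unambiguous rigid 3D transformation, so every refinement run starts
from a "guess" of exactly three label-compatible pairs. Guesses are
ranked by the sum of their dissimilarity-matrix entries (smaller is
better); generation is fully deterministic with lexicographic
tie-breaking.
"""

from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass
from typing import Iterator

import numpy as np
from scipy.optimize import linear_sum_assignment

from .encoding import DissimilarityMatrix
from .errors import NoSeedError
from .model import Pharmacophore

#: Guess-budget presets: "fast" favours runtime, "accurate" hit recall.
PRESETS = {"fast": 20, "accurate": 300}

_BIG = 1e9  # stand-in cost for invalid entries in the assignment solve


@dataclass(frozen=True)
class SeedGuess:
    """Exactly three (i, j) feature pairs plus their summed dissimilarity."""

    pairs: tuple[tuple[int, int], ...]
    score: float

    def __post_init__(self):
        if len(self.pairs) != 3:
            raise ValueError("a seed guess holds exactly three pairs")


def single_best_guess(M: DissimilarityMatrix) -> SeedGuess:
    """Best three pairs taken from one optimal assignment over the matrix.

    Solves the assignment over the whole matrix (invalid entries
    prohibitive) and keeps the three assigned pairs with the smallest
    dissimilarity, tie-broken by (cost, i, j).
    """
    vals = M.values
    if min(vals.shape) < 3:
        raise NoSeedError("need at least three features on each side")
    costs = np.where(np.isfinite(vals), vals, _BIG)
    rows, cols = linear_sum_assignment(costs)
    assigned = [
        (float(vals[i, j]), int(i), int(j))
        for i, j in zip(rows, cols)
        if np.isfinite(vals[i, j])
    ]
    if len(assigned) < 3:
        raise NoSeedError(
            "fewer than three label-compatible pairs in the optimal assignment"
        )
    assigned.sort()
    best = assigned[:3]
    pairs = tuple(sorted((i, j) for _, i, j in best))
    return SeedGuess(pairs=pairs, score=float(sum(c for c, _, _ in best)))


def _feasible_triples(
    entries: list[tuple[int, int, float]]
) -> Iterator[tuple[float, tuple[tuple[int, int], ...]]]:
    """All one-to-one triples over valid entries (rows and columns distinct)."""
    for (i1, j1, c1), (i2, j2, c2), (i3, j3, c3) in itertools.combinations(
        entries, 3
    ):
        if i1 == i2 or i1 == i3 or i2 == i3:
            continue
        if j1 == j2 or j1 == j3 or j2 == j3:
            continue
        yield c1 + c2 + c3, ((i1, j1), (i2, j2), (i3, j3))


def top_m_guesses(M: DissimilarityMatrix, m: int) -> list[SeedGuess]:
    """The ``m`` lowest-scoring feasible three-pair combinations, ascending.

    Every unordered combination of three valid entries with distinct
    rows and distinct columns is considered once. Returns fewer than
    ``m`` guesses when fewer feasible combinations exist; ties are
    broken by lexicographic pair indices.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    entries = M.finite_entries()
    # heap of the m best (score, pairs); invert for max-heap behaviour
    heap: list[tuple[float, tuple]] = []
    for score, pairs in _feasible_triples(entries):
        key = (-score, tuple(-x for p in pairs for x in p))
        if len(heap) < m:
            heapq.heappush(heap, (key, score, pairs))
        elif key > heap[0][0]:
            heapq.heapreplace(heap, (key, score, pairs))
    ranked = sorted(((s, p) for _, s, p in heap), key=lambda x: (x[0], x[1]))
    return [SeedGuess(pairs=p, score=s) for s, p in ranked]


def all_guesses(A: Pharmacophore, B: Pharmacophore) -> Iterator[SeedGuess]:
    """Every label-compatible three-pair combination, lexicographic order.

    Used for exhaustive alignment; no dissimilarity matrix is needed,
    so scores are reported as 0.
    """
    types_a, types_b = A.types, B.types
    compatible = [
        (i, j)
        for i in range(len(types_a))
        for j in range(len(types_b))
        if types_a[i] == types_b[j]
    ]
    for (i1, j1), (i2, j2), (i3, j3) in itertools.combinations(compatible, 3):
        if i1 == i2 or i1 == i3 or i2 == i3:
            continue
        if j1 == j2 or j1 == j3 or j2 == j3:
            continue
        yield SeedGuess(pairs=((i1, j1), (i2, j2), (i3, j3)), score=0.0)
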