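"""Neighbourhood-distance feature encoding and the dissimilarity matrix.

Each feature is encoded by the labelled distances to every other feature
of its own pharmacophore. Two encodings of same-typed features are
compared by optimally assigning neighbour to neighbour (an assignment
problem): a neighbour pair with unequal labels costs 1; otherwise the
absolute distance difference is divided by the larger of the two
intra-pharmacophore pairs' summed positional tolerances and clamped at
1. Unequal neighbour counts are reconciled by padding with full-cost
dummies. The total assignment cost, normalised by the size of the
larger pharmacophore, is the pseudo-cost of pairing the two features;
type-incompatible feature pairs are marked invalid (infinite).

All entries are rigid-motion invariant since only internal distances
enter, which is what makes the matrix usable for seeding an alignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import pdist, squareform

from .model import Pharmacophore

#: Sentinel marking a type-incompatible (invalid) feature pair.
INVALID = np.inf


@dataclass(frozen=True)
class FeatureEncoding:
    """Labelled neighbourhood-distance profile of one feature.

    ``labels[k]``, ``distances[k]`` and ``tolerances[k]`` describe the
    k-th neighbour (every other feature of the same pharmacophore);
    ``owner_tolerance`` is the tolerance of the encoded feature itself.
    """

    owner_type: str
    owner_tolerance: float
    labels: tuple[str, ...]
    distances: np.ndarray
    tolerances: np.ndarray

    def __len__(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class DissimilarityMatrix:
    """|A| x |B| pseudo-cost grid; INVALID marks type-incompatible pairs."""

    values: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def finite_entries(self) -> list[tuple[int, int, float]]:
        """(i, j, cost) for every valid entry, in row-major order."""
        out = []
        vals = self.values
        for i in range(vals.shape[0]):
            for j in range(vals.shape[1]):
                v = vals[i, j]
                if np.isfinite(v):
                    out.append((i, j, float(v)))
        return out


def encode_features(P: Pharmacophore) -> list[FeatureEncoding]:
    """Encode every feature of ``P`` by its labelled neighbour distances."""
    n = len(P)
    if n == 0:
        return []
    pos = P.positions
    tol = P.tolerances
    types = P.types
    dmat = squareform(pdist(pos)) if n > 1 else np.zeros((1, 1))
    encodings = []
    for i in range(n):
        idx = [k for k in range(n) if k != i]
        encodings.append(
            FeatureEncoding(
                owner_type=types[i],
                owner_tolerance=float(tol[i]),
                labels=tuple(types[k] for k in idx),
                distances=dmat[i, idx].copy(),
                tolerances=tol[idx].copy(),
            )
        )
    return encodings


def encoding_dissimilarity(
    ea: FeatureEncoding, eb: FeatureEncoding, normalizer: int
) -> float:
    """Pseudo-cost in [0, 1) for pairing two encoded features.

    Returns INVALID when the owner types differ. ``normalizer`` must be
    the feature count of the larger pharmacophore.
    """
    if normalizer <= 0:
        raise ValueError("normalizer must be a positive integer")
    if ea.owner_type != eb.owner_type:
        return INVALID
    na, nb = len(ea), len(eb)
    side = max(na, nb)
    if side == 0:
        return 0.0
    grid = np.ones((side, side))
    if na and nb:
        # D[p, q] = larger of the two intra-model pairs' summed tolerances
        sum_a = ea.owner_tolerance + ea.tolerances  # (na,)
        sum_b = eb.owner_tolerance + eb.tolerances  # (nb,)
        denom = np.maximum(sum_a[:, None], sum_b[None, :])
        diff = np.abs(ea.distances[:, None] - eb.distances[None, :])
        cost = np.minimum(1.0, diff / denom)
        label_mismatch = np.array(
            [[la != lb for lb in eb.labels] for la in ea.labels]
        )
        cost[label_mismatch] = 1.0
        grid[:na, :nb] = cost
    rows, cols = linear_sum_assignment(grid)
    return float(grid[rows, cols].sum()) / normalizer


def build_dissimilarity_matrix(
    A: Pharmacophore, B: Pharmacophore
) -> DissimilarityMatrix:
    """Pairwise pseudo-costs between all features of A (rows) and B (columns)."""
    enc_a = encode_features(A)
    enc_b = encode_features(B)
    normalizer = max(len(A), len(B))
    vals = np.empty((len(A), len(B)))
    for i, ea in enumerate(enc_a):
        for j, eb in enumerate(enc_b):
            vals[i, j] = encoding_dissimilarity(ea, eb, normalizer)
    return DissimilarityMatrix(vals)
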