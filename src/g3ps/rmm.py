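"""RM baseline aligner: distance-histogram encoding + Hungarian + Kabsch.

The classic pipeline this package's greedy aligner is compared against.
Each feature is abstracted by per-neighbour-type histograms of
distances (smoothed so that near-bin-boundary distances still look
similar), a histogram-overlap cost matrix feeds the Hungarian
assignment, the assigned pairs are superposed with Kabsch, and pairs
violating their tolerance are removed before the assignment is
repeated until a stable alignment remains. Omitted features are
handled combinatorially: every subset of the query with up to #o
features removed is tried in turn, which is where this method's
runtime explodes — the effort counter exposed here makes that visible
without wall-clock timing.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .errors import AmbiguousAlignmentError, DegenerateGeometryError
from .model import (
    AlignmentResult,
    AlignmentStats,
    PairSet,
    Pharmacophore,
    rmsd_of_pairs,
)
from .postfilter import PostFilterConfig, apply_postfilters
from .refine import kabsch

_BIG = 1e9

#: Default triangular smoothing kernel (mass-conserving, symmetric).
DEFAULT_KERNEL = (0.25, 0.5, 0.25)


@dataclass
class RMMConfig:
    """Histogram and pipeline knobs of the RM baseline.

    bin_width : histogram bin width, angstrom (default 1.0).
    hist_range : distance range covered by the histograms, angstrom.
    smoothing_kernel : odd-length kernel summing to 1; empty disables
        smoothing.
    postfilters : post-filter settings applied before accepting a
        candidate alignment (None = no post-filtering).
    """

    bin_width: float = 1.0
    hist_range: tuple[float, float] = (0.0, 20.0)
    smoothing_kernel: tuple[float, ...] = DEFAULT_KERNEL
    postfilters: PostFilterConfig | None = None


@dataclass(frozen=True)
class DistanceHistogramEncoding:
    """Per-neighbour-type binned distance counts for one feature."""

    owner_type: str
    histograms: dict[str, np.ndarray]
    smoothed: bool


def _smooth(h: np.ndarray, kernel: tuple[float, ...]) -> np.ndarray:
    if not kernel or len(kernel) == 1:
        return h
    half = len(kernel) // 2
    padded = np.pad(h, half, mode="symmetric")
    return np.convolve(padded, np.asarray(kernel, dtype=float), mode="valid")


def rmm_encode(
    P: Pharmacophore, config: RMMConfig | None = None
) -> list[DistanceHistogramEncoding]:
    """Encode each feature by smoothed per-type distance histograms."""
    config = config or RMMConfig()
    if config.bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    lo, hi = config.hist_range
    edges = np.arange(lo, hi + config.bin_width, config.bin_width)
    pos = P.positions
    types = P.types
    n = len(P)
    out = []
    for i in range(n):
        hists: dict[str, np.ndarray] = {}
        for k in range(n):
            if k == i:
                continue
            d = float(np.linalg.norm(pos[i] - pos[k]))
            h = hists.setdefault(types[k], np.zeros(len(edges) - 1))
            b = min(int(np.searchsorted(edges, d, side="right")) - 1,
                    len(edges) - 2)
            h[max(b, 0)] += 1.0
        smoothed = bool(config.smoothing_kernel)
        if smoothed:
            hists = {t: _smooth(h, config.smoothing_kernel)
                     for t, h in hists.items()}
        out.append(DistanceHistogramEncoding(types[i], hists, smoothed))
    return out


def histogram_cost(
    ea: DistanceHistogramEncoding, eb: DistanceHistogramEncoding
) -> float:
    """Histogram-overlap dissimilarity in [0, 1]; BIG for type mismatch.

    Per shared neighbour type: 1 - sum(min(h1, h2)) / max(mass1, mass2, 1),
    averaged over the union of neighbour types present in either encoding.
    """
    if ea.owner_type != eb.owner_type:
        return _BIG
    types = set(ea.histograms) | set(eb.histograms)
    if not types:
        return 0.0
    total = 0.0
    for t in sorted(types):
        h1 = ea.histograms.get(t)
        h2 = eb.histograms.get(t)
        if h1 is None or h2 is None:
            total += 1.0
            continue
        overlap = float(np.minimum(h1, h2).sum())
        denom = max(float(h1.sum()), float(h2.sum()), 1.0)
        total += 1.0 - overlap / denom
    return total / len(types)


def _assign(cost: np.ndarray) -> list[tuple[int, int]]:
    rows, cols = linear_sum_assignment(np.where(cost >= _BIG, _BIG, cost))
    return [(int(i), int(j)) for i, j in zip(rows, cols) if cost[i, j] < _BIG]


def rmm_align(
    A: Pharmacophore,
    B: Pharmacophore,
    omitted: int = 0,
    config: RMMConfig | None = None,
) -> AlignmentResult:
    """RM baseline alignment of B onto query A.

    Tries every combination of query features with k = 0..omitted
    features removed (larger subsets first). For each reduced query:
    encode, build the histogram cost matrix, Hungarian-assign, Kabsch
    the assigned pairs, drop tolerance-violating pairs and repeat until
    stable or fewer than three pairs remain. The first combination
    producing a valid alignment (all surviving pairs within tolerance,
    count >= |A| - omitted, post-filters passed) is returned.
    ``result.stats.kabsch_calls`` counts superposition invocations — the
    effort proxy that grows combinatorially with the omitted budget.
    """
    config = config or RMMConfig()
    nA = len(A)
    if nA - omitted < 3:
        raise AmbiguousAlignmentError(
            f"query has {nA} features and {omitted} may be omitted; at "
            "least three matched pairs are required"
        )
    stats = AlignmentStats()
    enc_b = rmm_encode(B, config)
    required = nA - omitted

    for k in range(0, omitted + 1):
        for subset in itertools.combinations(range(nA), nA - k):
            res = _rmm_align_subset(A, B, list(subset), enc_b, config, stats)
            if res is None or res.match_count < max(required, 3):
                continue
            if config.postfilters is not None:
                res = apply_postfilters(
                    res, A, B, config.postfilters, max(required, 3)
                )
                if not res.valid:
                    continue
            res.stats = stats
            return res
    return AlignmentResult.empty(stats)


def _rmm_align_subset(
    A: Pharmacophore,
    B: Pharmacophore,
    subset: list[int],
    enc_b,
    config: RMMConfig,
    stats: AlignmentStats,
) -> AlignmentResult | None:
    sub = Pharmacophore(
        name=A.name, features=[A.features[i] for i in subset]
    )
    enc_a = rmm_encode(sub, config)
    cost = np.array(
        [[histogram_cost(ea, eb) for eb in enc_b] for ea in enc_a]
    ).reshape(len(subset), len(B))

    posA, posB = A.positions, B.positions
    rows_pool = list(range(len(subset)))
    cols_pool = list(range(len(B)))
    while True:
        if len(rows_pool) < 3 or len(cols_pool) < 3:
            return None
        sub_cost = cost[np.ix_(rows_pool, cols_pool)]
        local = _assign(sub_cost)
        pairs = [(subset[rows_pool[r]], cols_pool[c]) for r, c in local]
        if len(pairs) < 3:
            return None
        ii = [i for i, _ in pairs]
        jj = [j for _, j in pairs]
        try:
            t = kabsch(posA[ii], posB[jj])
            stats.kabsch_calls += 1
        except DegenerateGeometryError:
            return None
        d = np.linalg.norm(posA[ii] - t.apply(posB[jj]), axis=1)
        thr = np.array(
            [max(A.features[i].tolerance, B.features[j].tolerance)
             for i, j in pairs]
        )
        bad = d >= thr
        if not bad.any():
            ps = PairSet(pairs)
            return AlignmentResult(
                transform=t,
                matched=ps,
                match_count=len(ps),
                rmsd=rmsd_of_pairs(A, B, ps, t),
                valid=True,
                stats=stats,
            )
        # remove violating pairs' features from the pools and re-assign
        bad_rows = {subset.index(pairs[x][0]) for x in np.nonzero(bad)[0]}
        bad_cols = {pairs[x][1] for x in np.nonzero(bad)[0]}
        rows_pool = [r for r in rows_pool if r not in bad_rows]
        cols_pool = [c for c in cols_pool if c not in bad_cols]
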