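"""Kabsch superposition and the greedy match-maximising refinement loop.

The aligner grows a matched pair set from a three-pair seed in the
spirit of iterative closest point, but with the objective changed from
minimising RMSD to maximising the number of feature pairs that lie
within their positional tolerances. A boolean "forbidden" matrix F
tracks which pairs can no longer be considered; every iteration marks
at least one new entry, which guarantees termination after at most
|A|*|B| iterations.

When adding the geometrically closest eligible pair breaks some pair's
tolerance under the re-fitted transform, a pure-translation rescue is
attempted first: the matched pairs define a ball-intersection
feasibility problem (each pair's residual must be movable inside its
tolerance radius by one shared translation), solved as a convex minimax
program. Only if that fails is the candidate pair forbidden.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy.optimize import minimize

from .encoding import build_dissimilarity_matrix
from .errors import (
    AmbiguousAlignmentError,
    DegenerateGeometryError,
    NoSeedError,
    UnderdeterminedError,
)
from .guesses import PRESETS, SeedGuess, all_guesses, top_m_guesses
from .model import (
    AlignmentResult,
    AlignmentStats,
    PairSet,
    Pharmacophore,
    RigidTransform,
    rmsd_of_pairs,
)

_DEGENERATE_REL = 1e-9


def kabsch(pointsA: np.ndarray, pointsB: np.ndarray) -> RigidTransform:
    """Optimal proper rigid superposition of B points onto A points.

    Returns the rotation + translation minimising the RMSD of the
    transformed B points to their A counterparts. Reflections are
    corrected via the determinant sign of the SVD solution, so the
    result is always a proper rotation.

    Raises
    ------
    UnderdeterminedError
        Fewer than three point pairs.
    DegenerateGeometryError
        Collinear or coincident points (the rotation about the
        degenerate axis is ambiguous).
    """
    pa = np.asarray(pointsA, dtype=float).reshape(-1, 3)
    pb = np.asarray(pointsB, dtype=float).reshape(-1, 3)
    if pa.shape != pb.shape:
        raise ValueError("point lists must have equal length")
    if pa.shape[0] < 3:
        raise UnderdeterminedError(
            f"need at least 3 point pairs, got {pa.shape[0]}"
        )
    ca = pa.mean(axis=0)
    cb = pb.mean(axis=0)
    qa = pa - ca
    qb = pb - cb
    H = qb.T @ qa
    U, S, Vt = np.linalg.svd(H)
    # rank < 2 <=> points (in at least one set) collinear or coincident
    scale = max(S[0], 1.0)
    if S[1] <= _DEGENERATE_REL * scale:
        raise DegenerateGeometryError(
            "point configuration is collinear or coincident"
        )
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return RigidTransform(R, ca - R @ cb)


def _batched_kabsch(pa: np.ndarray, pb: np.ndarray):
    """Vectorised Kabsch over a batch of mappings.

    ``pa``, ``pb``: (M, k, 3). Returns rotations (M, 3, 3) and
    translations (M, 3); degenerate members get a best-effort rotation
    (no error), which is adequate for oracle-style maximisation.
    """
    ca = pa.mean(axis=1, keepdims=True)
    cb = pb.mean(axis=1, keepdims=True)
    qa = pa - ca
    qb = pb - cb
    H = np.einsum("mki,mkj->mij", qb, qa)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(np.einsum("mij,mjk->mik", Vt.transpose(0, 2, 1),
                                        U.transpose(0, 2, 1))))
    D = np.zeros((pa.shape[0], 3, 3))
    D[:, 0, 0] = 1.0
    D[:, 1, 1] = 1.0
    D[:, 2, 2] = d
    R = np.einsum("mij,mjk,mkl->mil", Vt.transpose(0, 2, 1), D,
                  U.transpose(0, 2, 1))
    t = ca[:, 0, :] - np.einsum("mij,mj->mi", R, cb[:, 0, :])
    return R, t


def translation_rescue(
    residuals: np.ndarray, radii: np.ndarray
) -> np.ndarray | None:
    """Find a shared translation putting every residual inside its radius.

    ``residuals[k]`` is A_k - t(B_k) for each matched pair, ``radii[k]``
    the pair's tolerance bound. Seeks delta with
    ``|residuals[k] - delta| < radii[k]`` for all k — i.e. a point in
    the open intersection of balls centred at the residuals. Returns
    the translation (to be *added* to the transform) or None when the
    intersection is empty.
    """
    c = np.asarray(residuals, dtype=float).reshape(-1, 3)
    r = np.asarray(radii, dtype=float).ravel()

    def _ok(delta):
        return bool(np.all(np.linalg.norm(c - delta, axis=1) < r))

    # cheap necessary condition: any two balls disjoint => no intersection
    diff = c[:, None, :] - c[None, :, :]
    gap = np.linalg.norm(diff, axis=2) - (r[:, None] + r[None, :])
    if np.any(gap >= 0):
        return None
    # cheap sufficient candidates before invoking the solver
    for cand in (c.mean(axis=0), *c):
        if _ok(cand):
            return cand
    # convex minimax: min_delta max_k (|c_k - delta| - r_k), via epigraph SLSQP
    x0 = np.append(c.mean(axis=0), np.max(np.linalg.norm(
        c - c.mean(axis=0), axis=1) - r))

    def objective(x):
        return x[3]

    def constraint(x):
        return x[3] - (np.linalg.norm(c - x[:3], axis=1) - r)

    sol = minimize(
        objective,
        x0,
        method="SLSQP",
        constraints=[{"type": "ineq", "fun": constraint}],
        options={"maxiter": 100, "ftol": 1e-10},
    )
    delta = sol.x[:3]
    if _ok(delta):
        return delta
    return None


@dataclass
class AlignConfig:
    """Configuration of the G3PS aligner.

    guesses : number of seed guesses refined (ignored when exhaustive).
    exhaustive : refine every label-compatible three-pair combination.
    omitted : allowed unmatched query features (#o); used for the
        validity verdict and, when ``early_exit`` is on, for stopping.
    early_exit : stop as soon as a refinement reaches |A| - omitted
        matches. Off by default so that the work performed never
        depends on the omitted budget.
    """

    guesses: int = PRESETS["fast"]
    exhaustive: bool = False
    omitted: int = 0
    early_exit: bool = False

    @classmethod
    def preset(cls, name: str, **kw) -> "AlignConfig":
        return cls(guesses=PRESETS[name], **kw)


def refine(
    A: Pharmacophore,
    B: Pharmacophore,
    seed: SeedGuess,
    config: AlignConfig | None = None,
    stats: AlignmentStats | None = None,
) -> AlignmentResult:
    """Greedy refinement of one three-pair seed into a maximal match.

    Starts from the Kabsch superposition of the seed pairs, then
    repeatedly tries to add the closest unforbidden pair, re-fitting
    the transform each time and falling back to the translation rescue
    before rejecting a candidate. Terminates when the forbidden matrix
    is saturated, when every query feature is matched, or (with
    ``early_exit``) when |A| - omitted matches are collected.
    """
    config = config or AlignConfig()
    stats = stats if stats is not None else AlignmentStats()
    stats.refinements += 1

    nA, nB = len(A), len(B)
    posA, posB = A.positions, B.positions
    tolA, tolB = A.tolerances, B.tolerances
    maxtol = np.maximum(tolA[:, None], tolB[None, :])
    typesA, typesB = A.types, B.types

    pairs = list(seed.pairs)
    rows = [i for i, _ in pairs]
    cols = [j for _, j in pairs]

    transform = kabsch(posA[rows], posB[cols])
    stats.kabsch_calls += 1

    # F: True = pair no longer considered
    F = np.array(
        [[typesA[i] != typesB[j] for j in range(nB)] for i in range(nA)],
        dtype=bool,
    ).reshape(nA, nB)
    F[rows, :] = True
    F[:, cols] = True

    tposB = transform.apply(posB)

    def _violations(plist, t_posB) -> bool:
        ii = [i for i, _ in plist]
        jj = [j for _, j in plist]
        d = np.linalg.norm(posA[ii] - t_posB[jj], axis=1)
        return bool(np.any(d >= maxtol[ii, jj]))

    while not F.all():
        marked_before = int(F.sum())
        # closest eligible pair under the current transform
        dists = np.linalg.norm(posA[:, None, :] - tposB[None, :, :], axis=2)
        dists[F] = np.inf
        flat = int(np.argmin(dists))  # row-major => lexicographic tie-break
        i, j = divmod(flat, nB)
        ptest = (int(i), int(j))
        Ptest = pairs + [ptest]
        rws = [p for p, _ in Ptest]
        cls_ = [q for _, q in Ptest]
        try:
            t_new = kabsch(posA[rws], posB[cls_])
            stats.kabsch_calls += 1
        except DegenerateGeometryError:
            t_new = None
        accepted = False
        if t_new is not None:
            new_tposB = t_new.apply(posB)
            if not _violations(Ptest, new_tposB):
                accepted = True
            else:
                residuals = posA[rws] - new_tposB[cls_]
                radii = maxtol[rws, cls_]
                delta = translation_rescue(residuals, radii)
                if delta is not None:
                    t_new = t_new.translated(delta)
                    new_tposB = t_new.apply(posB)
                    if not _violations(Ptest, new_tposB):
                        accepted = True
        if accepted:
            pairs = Ptest
            transform = t_new
            tposB = new_tposB
            F[i, :] = True
            F[:, j] = True
        else:
            F[i, j] = True
        stats.iterations += 1
        assert int(F.sum()) > marked_before, "forbidden matrix must grow"
        if len(pairs) >= nA:
            break
        if config.early_exit and len(pairs) >= nA - config.omitted:
            break

    # report only pairs that satisfy the predicate under the final transform
    ii = [i for i, _ in pairs]
    jj = [j for _, j in pairs]
    d = np.linalg.norm(posA[ii] - tposB[jj], axis=1)
    ok = d < maxtol[ii, jj]
    matched = PairSet(p for p, good in zip(pairs, ok) if good)
    result = AlignmentResult(
        transform=transform,
        matched=matched,
        match_count=len(matched),
        rmsd=rmsd_of_pairs(A, B, matched, transform),
        valid=bool(ok.all()),
        stats=stats,
    )
    return result


def align(
    A: Pharmacophore,
    B: Pharmacophore,
    config: AlignConfig | None = None,
) -> AlignmentResult:
    """Align target B onto query A, maximising the matched feature count.

    Generates seed guesses (ranked by the dissimilarity matrix, or all
    of them in exhaustive mode), refines each one, and returns the best
    result: largest match count, ties broken by smaller RMSD, then by
    guess rank. Guesses whose three pairs are all contained in an
    already-found solution are skipped, and the scan stops early once
    no larger match is possible (match count equals min(|A|, |B|)).

    Raises
    ------
    AmbiguousAlignmentError
        When |A| - omitted < 3: fewer than three required matches
        cannot define an unambiguous rigid alignment.
    """
    config = config or AlignConfig()
    if len(A) - config.omitted < 3:
        raise AmbiguousAlignmentError(
            f"query has {len(A)} features and {config.omitted} may be "
            "omitted; at least three matched pairs are required"
        )
    stats = AlignmentStats()
    if config.exhaustive:
        guesses: Iterable[SeedGuess] = all_guesses(A, B)
    else:
        if min(len(A), len(B)) < 3:
            return AlignmentResult.empty(stats)
        M = build_dissimilarity_matrix(A, B)
        try:
            guesses = top_m_guesses(M, config.guesses)
        except NoSeedError:
            guesses = []

    best: AlignmentResult | None = None
    found_pair_sets: list[frozenset] = []
    max_possible = min(len(A), len(B))
    target = max_possible
    if config.early_exit:
        target = min(target, len(A) - config.omitted)

    for guess in guesses:
        gset = set(guess.pairs)
        if any(gset <= s for s in found_pair_sets):
            continue
        try:
            res = refine(A, B, guess, config, stats)
        except DegenerateGeometryError:
            continue  # measure-zero seed geometry; try the next guess
        if res.match_count >= 3:
            found_pair_sets.append(res.matched.as_set())
        if (
            best is None
            or res.match_count > best.match_count
            or (res.match_count == best.match_count and res.rmsd < best.rmsd)
        ):
            best = res
        if best is not None and best.match_count >= target:
            break

    if best is None:
        return AlignmentResult.empty(stats)
    best.stats = stats
    return best


def brute_force_best_match(
    A: Pharmacophore,
    B: Pharmacophore,
    min_size: int = 3,
    translation_polish: bool = True,
) -> int:
    """Exhaustive subset-superposition oracle for small pharmacophores.

    For every label-consistent one-to-one mapping of size >= min_size,
    fit the mapping with Kabsch and count how many of its pairs satisfy
    the tolerance predicate; return the maximum count found. With
    ``translation_polish`` (default), a mapping whose Kabsch fit leaves
    violations also counts in full if keeping the Kabsch rotation and
    freeing the translation can satisfy every pair (the same
    ball-intersection condition the aligner's translation rescue uses) —
    without this, the greedy aligner can legitimately beat the oracle.
    Exponential in the feature count; intended for n <= ~7 cross-checks.
    """
    import itertools

    posA, posB = A.positions, B.positions
    maxtol = np.maximum(A.tolerances[:, None], B.tolerances[None, :])
    typesA, typesB = A.types, B.types
    compatible = [
        (i, j)
        for i in range(len(A))
        for j in range(len(B))
        if typesA[i] == typesB[j]
    ]
    best = 0
    for k in range(min_size, min(len(A), len(B)) + 1):
        mappings = []
        for combo in itertools.combinations(compatible, k):
            rows = [i for i, _ in combo]
            cols = [j for _, j in combo]
            if len(set(rows)) < k or len(set(cols)) < k:
                continue
            mappings.append(combo)
        if not mappings:
            continue
        arr = np.array(mappings)  # (M, k, 2)
        pa = posA[arr[:, :, 0]]
        pb = posB[arr[:, :, 1]]
        R, t = _batched_kabsch(pa, pb)
        pb_t = np.einsum("mij,mkj->mki", R, pb) + t[:, None, :]
        d = np.linalg.norm(pa - pb_t, axis=2)
        thr = maxtol[arr[:, :, 0], arr[:, :, 1]]
        counts = (d < thr).sum(axis=1)
        best = max(best, int(counts.max()))
        if translation_polish and best < k:
            resid = pa - pb_t  # (M, k, 3)
            # necessary condition: all residual balls pairwise intersect
            gap = (
                np.linalg.norm(resid[:, :, None, :] - resid[:, None, :, :],
                               axis=3)
                - (thr[:, :, None] + thr[:, None, :])
            )
            cand = np.nonzero((counts < k) & np.all(gap < 0, axis=(1, 2)))[0]
            for m in cand:
                if translation_rescue(resid[m], thr[m]) is not None:
                    best = k
                    break
    return best
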