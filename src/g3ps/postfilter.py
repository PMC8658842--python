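"""Post-processing of alignments: exclusion-volume dodging and direction checks.

An otherwise good alignment whose molecule atoms barely clash with an
exclusion sphere need not be discarded outright: up to a small number
of extra translations are tried to "dodge" the spheres, after which
every matched pair's tolerance must be re-validated. Directed features
(H-bond vectors, ring plane normals) are checked last: a matched pair
whose directions diverge beyond the angular tolerance is unmatched,
and the alignment is discarded if that drops the match count below the
caller's minimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize

from .model import (
    AlignmentResult,
    PairSet,
    Pharmacophore,
    RigidTransform,
    exclusion_ok,
    rmsd_of_pairs,
)

_EPS = 1e-3  # clearance margin pushed beyond each sphere radius, angstrom


@dataclass
class PostFilterConfig:
    """Knobs of the post-processing stage.

    max_dodge_translations : attempts to translate out of exclusion
        clashes before giving up (default 3).
    direction_angle_tolerance : maximal angle, degrees, between a query
        feature direction and the rotated target direction (default 45).
    enforce_exclusions : turn the exclusion check (and dodging) on/off.
    plane_normal_types : feature types whose direction is a plane
        normal, compared up to sign (aromatic rings by default).
    """

    max_dodge_translations: int = 3
    direction_angle_tolerance: float = 45.0
    enforce_exclusions: bool = True
    plane_normal_types: frozenset[str] = field(
        default_factory=lambda: frozenset({"AR"})
    )

    def __post_init__(self):
        if self.max_dodge_translations < 0:
            raise ValueError("max_dodge_translations must be >= 0")
        if not 0 < self.direction_angle_tolerance <= 180:
            raise ValueError("direction_angle_tolerance must be in (0, 180]")


def _clash_list(
    atoms: np.ndarray, exclusions, t: RigidTransform
) -> list[tuple[int, int, float]]:
    """(atom index, sphere index, penetration depth) for all collisions."""
    out = []
    if atoms.shape[0] == 0:
        return out
    ta = t.apply(atoms)
    for s_idx, sph in enumerate(exclusions):
        d = np.linalg.norm(ta - sph.center, axis=1)
        for a_idx in np.nonzero(d <= sph.radius)[0]:
            out.append((int(a_idx), s_idx, float(sph.radius - d[a_idx])))
    return out


def _dodge_translation(
    atoms: np.ndarray, exclusions, t: RigidTransform, clashes
) -> np.ndarray:
    """Minimum-norm translation pushing every clashing atom clear.

    Each clashing (atom, sphere) pair must end at radius + eps
    clearance; solved as a smallest-norm point outside the clashing
    balls (non-convex — SLSQP from a push-out initial point).
    """
    ta = t.apply(atoms)
    centers = np.array([exclusions[s].center for _, s, _ in clashes])
    hard_radii = np.array([exclusions[s].radius for _, s, _ in clashes])
    radii = hard_radii + _EPS  # solver target leaves an eps margin
    points = np.array([ta[a] for a, _, _ in clashes])

    # initial guess: resolve the deepest clash radially
    deepest = int(np.argmax([dep for _, _, dep in clashes]))
    v = points[deepest] - centers[deepest]
    nv = np.linalg.norm(v)
    direction = v / nv if nv > 1e-9 else np.array([1.0, 0.0, 0.0])
    needed = radii[deepest] - nv
    x0 = direction * needed

    def _ok(delta):
        # verify against the hard radii (strict clearance), not the target
        d = np.linalg.norm(points + delta - centers, axis=1)
        return bool(np.all(d > hard_radii))

    if _ok(x0):
        return x0

    def constraint(delta):
        return np.linalg.norm(points + delta - centers, axis=1) - radii

    sol = minimize(
        lambda x: float(x @ x),
        x0,
        jac=lambda x: 2 * x,
        method="SLSQP",
        constraints=[{"type": "ineq", "fun": constraint}],
        options={"maxiter": 200, "ftol": 1e-12},
    )
    if _ok(sol.x):
        return sol.x
    # fall back to a larger radial push
    return direction * (needed + max(radii))


def _revalidate(
    res: AlignmentResult,
    A: Pharmacophore,
    B: Pharmacophore,
    t: RigidTransform,
) -> tuple[PairSet, float]:
    posB_t = t.apply(B.positions)
    keep = []
    for i, j in res.matched:
        d = float(np.linalg.norm(A.features[i].position - posB_t[j]))
        if d < max(A.features[i].tolerance, B.features[j].tolerance):
            keep.append((i, j))
    ps = PairSet(keep)
    return ps, rmsd_of_pairs(A, B, ps, t)


def dodge_exclusions(
    res: AlignmentResult,
    A: Pharmacophore,
    B: Pharmacophore,
    cfg: PostFilterConfig | None = None,
    min_matches: int = 3,
) -> AlignmentResult:
    """Resolve exclusion-volume clashes by up to a few extra translations.

    A clash-free result is returned unchanged. Otherwise candidate
    translations (each the minimum-norm displacement clearing the
    current clash set) are applied, up to ``cfg.max_dodge_translations``
    times; once clash-free, every matched pair is re-validated against
    its tolerance and pairs now violating are dropped. If clashes
    persist, or the surviving match count falls below ``min_matches``,
    the result is marked invalid.
    """
    cfg = cfg or PostFilterConfig()
    if not cfg.enforce_exclusions:
        return res
    atoms = B.atom_array()
    if exclusion_ok(atoms, A.exclusions, res.transform):
        return res
    t = res.transform
    for _ in range(cfg.max_dodge_translations):
        clashes = _clash_list(atoms, A.exclusions, t)
        if not clashes:
            break
        delta = _dodge_translation(atoms, A.exclusions, t, clashes)
        t = t.translated(delta)
    if not exclusion_ok(atoms, A.exclusions, t):
        return replace(res, valid=False)
    matched, rmsd = _revalidate(res, A, B, t)
    valid = res.valid and len(matched) >= min_matches
    return AlignmentResult(
        transform=t,
        matched=matched,
        match_count=len(matched),
        rmsd=rmsd,
        valid=valid,
        stats=res.stats,
    )


def check_directions(
    res: AlignmentResult,
    A: Pharmacophore,
    B: Pharmacophore,
    cfg: PostFilterConfig | None = None,
    min_matches: int = 3,
) -> AlignmentResult:
    """Unmatch pairs whose feature directions diverge after alignment.

    Applies only to pairs where both features carry a direction; the
    target direction is rotated by the alignment before the angle is
    measured. Plane-normal feature types compare up to sign. If the
    surviving match count drops below ``min_matches``, the alignment is
    discarded (marked invalid).
    """
    cfg = cfg or PostFilterConfig()
    R = res.transform
    keep = []
    changed = False
    cos_tol = np.cos(np.deg2rad(cfg.direction_angle_tolerance))
    for i, j in res.matched:
        fa, fb = A.features[i], B.features[j]
        if fa.direction is None or fb.direction is None:
            keep.append((i, j))
            continue
        db = R.rotate(fb.direction)
        c = float(np.clip(np.dot(fa.direction, db), -1.0, 1.0))
        if fa.type in cfg.plane_normal_types:
            c = abs(c)
        if c >= cos_tol:
            keep.append((i, j))
        else:
            changed = True
    if not changed:
        return res
    matched = PairSet(keep)
    valid = res.valid and len(matched) >= min_matches
    return AlignmentResult(
        transform=res.transform,
        matched=matched,
        match_count=len(matched),
        rmsd=rmsd_of_pairs(A, B, matched, res.transform),
        valid=valid,
        stats=res.stats,
    )


def apply_postfilters(
    res: AlignmentResult,
    A: Pharmacophore,
    B: Pharmacophore,
    cfg: PostFilterConfig | None = None,
    min_matches: int = 3,
) -> AlignmentResult:
    """Exclusion dodging followed by the direction check."""
    cfg = cfg or PostFilterConfig()
    out = dodge_exclusions(res, A, B, cfg, min_matches)
    if not out.valid:
        return out
    return check_directions(out, A, B, cfg, min_matches)
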