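"""Synthetic pharmacophore generators for testing and benchmarking.

Everything here is reproducible from a seed and generated in memory;
no external data files are involved. The generators emulate the shape
of ligand-derived pharmacophores (a handful of features of a few
types, ~1-2 angstrom tolerances, ~10 angstrom spatial extent) without
deriving them from real molecules.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

import numpy as np

from .errors import FixtureError
from .model import (
    ExclusionSphere,
    Feature,
    PairSet,
    Pharmacophore,
    RigidTransform,
)

DEFAULT_ALPHABET = ("H", "AR", "HBA", "HBD")
MIN_SEPARATION = 1.5  # angstrom, between generated feature centres


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one random pharmacophore fixture.

    Defaults emulate typical screening-model conditions: a 10 angstrom
    bounding box, tolerance radii drawn from [1.0, 2.0] angstrom, and a
    four-letter type alphabet.
    """

    n_features: int
    type_alphabet: tuple[str, ...] = DEFAULT_ALPHABET
    bbox: float = 10.0
    tolerance_range: tuple[float, float] = (1.0, 2.0)
    noise_sigma: float = 0.0
    seed: int = 0


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix from a normalised quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def random_rigid_transform(
    rng: np.random.Generator, translation_extent: float = 5.0
) -> RigidTransform:
    return RigidTransform(
        _random_rotation(rng),
        rng.uniform(-translation_extent, translation_extent, size=3),
    )


def random_pharmacophore(spec: FixtureSpec) -> Pharmacophore:
    """Random pharmacophore with pairwise feature separation >= 1.5 A.

    Positions are uniform in the bounding box (rejection-sampled for
    the separation constraint), types uniform over the alphabet and
    tolerances uniform over the configured range. Identical specs
    produce identical fixtures.
    """
    if spec.n_features < 1:
        raise ValueError("n_features must be >= 1")
    rng = np.random.default_rng(spec.seed)
    positions: list[np.ndarray] = []
    attempts = 0
    while len(positions) < spec.n_features:
        if attempts >= 10_000:
            raise FixtureError(
                f"could not place {spec.n_features} features with "
                f"{MIN_SEPARATION} A separation in a {spec.bbox} A box"
            )
        cand = rng.uniform(0.0, spec.bbox, size=3)
        attempts += 1
        if all(np.linalg.norm(cand - p) >= MIN_SEPARATION for p in positions):
            positions.append(cand)
    lo, hi = spec.tolerance_range
    feats = [
        Feature(
            type=str(rng.choice(spec.type_alphabet)),
            position=p,
            tolerance=float(rng.uniform(lo, hi)),
        )
        for p in positions
    ]
    return Pharmacophore(name=f"random-{spec.seed}", features=feats)


def perturbed_copy(
    P: Pharmacophore,
    rigid: bool = True,
    noise_sigma: float = 0.0,
    drop_k: int = 0,
    seed: int = 0,
) -> tuple[Pharmacophore, PairSet]:
    """Rigidly moved, noised, feature-dropped copy with its ground truth.

    Applies a random rigid transform (when ``rigid``), adds isotropic
    Gaussian positional noise, then deletes ``drop_k`` random features.
    Returns the copy and the surviving ground-truth correspondence
    (original index, copy index).
    """
    if drop_k >= len(P):
        raise ValueError("drop_k must be smaller than the feature count")
    rng = np.random.default_rng(seed)
    t = random_rigid_transform(rng) if rigid else RigidTransform.identity()
    keep = sorted(rng.choice(len(P), size=len(P) - drop_k, replace=False))
    feats = []
    for new_idx, orig_idx in enumerate(keep):
        f = P.features[orig_idx]
        pos = t.apply(f.position)
        if noise_sigma > 0:
            pos = pos + rng.normal(scale=noise_sigma, size=3)
        direction = t.rotate(f.direction) if f.direction is not None else None
        feats.append(dc_replace(f, position=pos, direction=direction))
    atoms = t.apply(P.atoms) if P.atoms is not None else None
    copy = Pharmacophore(
        name=P.name + "-copy", features=feats, exclusions=[], atoms=atoms
    )
    truth = PairSet((int(orig), new) for new, orig in enumerate(keep))
    return copy, truth


def clash_scenario(
    fixable: bool,
) -> tuple[Pharmacophore, Pharmacophore]:
    """Deterministic exclusion-clash fixture (query, target).

    The target is an exact copy of the query's features (the identity
    alignment matches all of them with zero RMSD) plus one molecule
    atom that collides with the query's exclusion sphere. In the
    fixable variant the atom sits 0.1 A inside the sphere while every
    matched pair has well over 0.5 A of tolerance slack, so a small
    translation saves the alignment; in the unfixable variant the
    sphere is so large that any clearing translation breaks all
    tolerances.
    """
    feats = [
        Feature("H", (0.0, 0.0, 0.0), 1.0),
        Feature("AR", (4.0, 0.0, 0.0), 1.0),
        Feature("HBA", (0.0, 4.0, 0.0), 1.0),
        Feature("HBD", (2.0, 2.0, 3.0), 1.0),
    ]
    if fixable:
        # atom 0.1 A inside a 1.0 A sphere placed away from the features
        sphere = ExclusionSphere((8.0, 8.0, 0.0), 1.0)
        atom = np.array([[8.9, 8.0, 0.0]])
    else:
        # atom at the feature centroid, deep inside a 3 A sphere: clearing
        # it needs a ~3 A shift, far beyond the 1.0 A tolerances
        centroid = np.mean([f.position for f in feats], axis=0)
        sphere = ExclusionSphere(centroid, 3.0)
        atom = np.array([centroid])
    query = Pharmacophore(name="clash-query", features=feats,
                          exclusions=[sphere])
    target = Pharmacophore(name="clash-target", features=list(feats),
                           atoms=atom)
    return query, target


def mirror_copy(P: Pharmacophore, seed: int = 0) -> Pharmacophore:
    """Mirror image of ``P`` (reflection through the yz-plane), then a
    random rigid move. All internal distances are preserved, so every
    distance-based encoding sees it as identical to ``P``, but no
    proper rotation can superpose a chiral arrangement onto it."""
    rng = np.random.default_rng(seed)
    t = random_rigid_transform(rng)
    M = np.diag([-1.0, 1.0, 1.0])
    feats = [
        dc_replace(
            f,
            position=t.apply(M @ f.position),
            direction=None if f.direction is None else t.rotate(M @ f.direction),
        )
        for f in P.features
    ]
    return Pharmacophore(name=P.name + "-mirror", features=feats)


def rmm_suboptimal_fixture() -> tuple[Pharmacophore, Pharmacophore]:
    """Hand-built case where the histogram/Hungarian baseline underperforms.

    The query is a chiral arrangement of same-type features; the target
    is its mirror image. Internal distances — hence all distance-based
    encodings — are identical, so the baseline's assignment picks the
    identity pairing, whose Kabsch fit cannot satisfy the tolerances
    for a chiral set, and the iterative removal collapses the match.
    The greedy aligner, seeding from many three-pair combinations,
    still finds the best achievable sub-alignment.
    """
    feats = [
        Feature("H", (0.0, 0.0, 0.0), 1.0),
        Feature("H", (5.0, 0.0, 0.0), 1.0),
        Feature("H", (0.0, 6.0, 0.0), 1.0),
        Feature("H", (1.0, 2.0, 5.0), 1.0),
        Feature("H", (4.0, 4.0, 2.5), 1.0),
    ]
    query = Pharmacophore(name="chiral-query", features=feats)
    target = mirror_copy(query, seed=7)
    return query, target


@dataclass
class ScreeningSuite:
    """A query plus a labelled library of actives and decoys."""

    query: Pharmacophore
    library: list[Pharmacophore]
    labels: list[bool] = field(default_factory=list)  # True = planted active


def screening_library(
    n_actives: int = 50,
    n_decoys: int = 150,
    n_features: int = 6,
    noise_sigma: float = 0.2,
    drop_k: int = 0,
    seed: int = 0,
) -> ScreeningSuite:
    """Synthetic screening suite with known ground-truth hit labels.

    Actives are rigid, noised (optionally feature-dropped) copies of
    the query; decoys are unrelated random pharmacophores over the
    same type alphabet and extent.
    """
    rng = np.random.default_rng(seed)
    query = random_pharmacophore(
        FixtureSpec(n_features=n_features, seed=int(rng.integers(2**31)))
    )
    library: list[Pharmacophore] = []
    labels: list[bool] = []
    for a in range(n_actives):
        copy, _ = perturbed_copy(
            query,
            rigid=True,
            noise_sigma=noise_sigma,
            drop_k=drop_k,
            seed=int(rng.integers(2**31)),
        )
        copy.name = f"active{a:04d}"
        library.append(copy)
        labels.append(True)
    for d in range(n_decoys):
        dec = random_pharmacophore(
            FixtureSpec(n_features=n_features, seed=int(rng.integers(2**31)))
        )
        dec.name = f"decoy{d:04d}"
        library.append(dec)
        labels.append(False)
    return ScreeningSuite(query=query, library=library, labels=labels)
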