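"""Pharmacophore domain types and the geometric matching predicates.

A pharmacophore is an ordered collection of labelled 3D feature points.
Each feature carries a positional tolerance radius: two features of the
same type *match* under an alignment when the distance between their
centres is strictly smaller than the larger of the two tolerances.
Exclusion spheres are "anti-features": no atom of the aligned molecule
may come within (or onto) their radius.

All coordinates are Cartesian angstroms in a right-handed frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import G3PSError

# Well-known feature type codes. Codes compare by exact string equality and
# user-defined codes are allowed everywhere; XV marks exclusion volumes in
# external files and never participates in feature matching.
FEATURE_CODES = ("H", "AR", "HBA", "HBD", "PI", "NI")
EXCLUSION_CODE = "XV"


def _as_vec3(x) -> np.ndarray:
    v = np.asarray(x, dtype=float)
    if v.shape != (3,):
        raise ValueError(f"expected a 3-vector, got shape {v.shape}")
    return v


@dataclass(frozen=True)
class Feature:
    """A labelled 3D point with a positional tolerance radius.

    Parameters
    ----------
    type : str
        Feature type code (e.g. ``"HBA"``); compared by string equality.
    position : array-like of 3 floats
        Feature centre, angstroms.
    tolerance : float
        Positional tolerance radius (> 0), angstroms.
    direction : array-like of 3 floats, optional
        Unit direction vector (H-bond direction, ring plane normal, ...).
    optional : bool
        User-designated "optional" flag; stored and round-tripped but not
        treated specially by the aligners beyond the global omitted-feature
        budget.
    """

    type: str
    position: np.ndarray
    tolerance: float
    direction: np.ndarray | None = None
    optional: bool = False

    def __post_init__(self):
        object.__setattr__(self, "position", _as_vec3(self.position))
        if not self.tolerance > 0:
            raise ValueError(f"tolerance must be > 0, got {self.tolerance}")
        if self.direction is not None:
            d = _as_vec3(self.direction)
            n = np.linalg.norm(d)
            if abs(n - 1.0) > 1e-6:
                if n == 0:
                    raise ValueError("direction vector must be non-zero")
                d = d / n
            object.__setattr__(self, "direction", d)

    def __eq__(self, other):
        if not isinstance(other, Feature):
            return NotImplemented
        if self.type != other.type or self.tolerance != other.tolerance:
            return False
        if self.optional != other.optional:
            return False
        if not np.array_equal(self.position, other.position):
            return False
        if (self.direction is None) != (other.direction is None):
            return False
        if self.direction is not None and not np.array_equal(
            self.direction, other.direction
        ):
            return False
        return True


@dataclass(frozen=True)
class ExclusionSphere:
    """A spherical exclusion volume: centre and radius in angstroms."""

    center: np.ndarray
    radius: float

    def __post_init__(self):
        object.__setattr__(self, "center", _as_vec3(self.center))
        if not self.radius > 0:
            raise ValueError(f"radius must be > 0, got {self.radius}")

    def __eq__(self, other):
        if not isinstance(other, ExclusionSphere):
            return NotImplemented
        return self.radius == other.radius and np.array_equal(
            self.center, other.center
        )


@dataclass
class Pharmacophore:
    """An ordered feature list plus exclusion spheres and optional atoms.

    ``atoms`` are the heavy-atom coordinates of the underlying molecule;
    they are what exclusion spheres are checked against. An empty atom
    list makes every exclusion check vacuously pass.
    """

    name: str = ""
    features: list[Feature] = field(default_factory=list)
    exclusions: list[ExclusionSphere] = field(default_factory=list)
    atoms: np.ndarray | None = None

    def __post_init__(self):
        if self.atoms is not None:
            a = np.asarray(self.atoms, dtype=float)
            if a.size == 0:
                a = None
            else:
                a = a.reshape(-1, 3)
            self.atoms = a

    def __len__(self) -> int:
        return len(self.features)

    @property
    def positions(self) -> np.ndarray:
        """(n, 3) array of feature centres."""
        if not self.features:
            return np.zeros((0, 3))
        return np.array([f.position for f in self.features])

    @property
    def tolerances(self) -> np.ndarray:
        return np.array([f.tolerance for f in self.features])

    @property
    def types(self) -> list[str]:
        return [f.type for f in self.features]

    def atom_array(self) -> np.ndarray:
        return np.zeros((0, 3)) if self.atoms is None else self.atoms


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion x -> R @ x + t (no scaling, no reflection)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = _as_vec3(self.translation)
        if R.shape != (3, 3):
            raise ValueError("rotation must be a 3x3 matrix")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation matrix is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation matrix has negative determinant (reflection)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform one 3-vector or an (n, 3) array of points."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def rotate(self, vectors: np.ndarray) -> np.ndarray:
        """Rotate direction vectors (no translation)."""
        return np.asarray(vectors, dtype=float) @ self.rotation.T

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def translated(self, delta: np.ndarray) -> "RigidTransform":
        """The same motion followed by an extra translation ``delta``."""
        return RigidTransform(self.rotation, self.translation + _as_vec3(delta))


@dataclass(frozen=True)
class PairSet:
    """One-to-one matched feature index pairs (i into query A, j into target B)."""

    pairs: tuple[tuple[int, int], ...]

    def __init__(self, pairs: Iterable[tuple[int, int]]):
        p = tuple((int(i), int(j)) for i, j in pairs)
        rows = [i for i, _ in p]
        cols = [j for _, j in p]
        if len(set(rows)) != len(rows) or len(set(cols)) != len(cols):
            raise G3PSError("pair set is not one-to-one")
        object.__setattr__(self, "pairs", p)

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def rows(self) -> list[int]:
        return [i for i, _ in self.pairs]

    def cols(self) -> list[int]:
        return [j for _, j in self.pairs]

    def as_set(self) -> frozenset[tuple[int, int]]:
        return frozenset(self.pairs)


@dataclass
class AlignmentResult:
    """Outcome of aligning target B onto query A.

    ``transform`` maps B's frame onto A's frame. ``matched`` holds only
    pairs that satisfy the match predicate under ``transform``;
    ``match_count == len(matched)``. ``valid`` is the overall verdict
    after whatever post-filters the caller applied.
    """

    transform: RigidTransform
    matched: PairSet
    match_count: int
    rmsd: float
    valid: bool
    stats: "AlignmentStats | None" = None

    @classmethod
    def empty(cls, stats=None) -> "AlignmentResult":
        return cls(RigidTransform.identity(), PairSet(()), 0, 0.0, False, stats)


@dataclass
class AlignmentStats:
    """Hardware-independent effort counters for benchmarking."""

    refinements: int = 0
    kabsch_calls: int = 0
    iterations: int = 0

    def merge(self, other: "AlignmentStats") -> None:
        self.refinements += other.refinements
        self.kabsch_calls += other.kabsch_calls
        self.iterations += other.iterations


# ---------------------------------------------------------------------------
# Matching predicates


def features_match(a: Feature, b: Feature, t: RigidTransform) -> bool:
    """True iff ``a`` and the transformed ``b`` form a matching pair.

    Same type and centre distance *strictly* below the larger of the two
    tolerance radii. ``a`` is in the query frame; ``b`` is transformed
    by ``t`` before the distance is evaluated.
    """
    if a.type != b.type:
        return False
    d = float(np.linalg.norm(a.position - t.apply(b.position)))
    return d < max(a.tolerance, b.tolerance)


def exclusion_ok(
    atoms: np.ndarray | Sequence,
    exclusions: Sequence[ExclusionSphere],
    t: RigidTransform,
) -> bool:
    """True iff every transformed atom clears every exclusion sphere.

    The clearance condition is strict: an atom exactly on the sphere
    surface counts as a collision. An empty atom list passes vacuously.
    """
    a = np.asarray(atoms, dtype=float).reshape(-1, 3)
    if a.shape[0] == 0 or not exclusions:
        return True
    ta = t.apply(a)
    for sph in exclusions:
        d = np.linalg.norm(ta - sph.center, axis=1)
        if not np.all(d > sph.radius):
            return False
    return True


def rmsd_of_pairs(
    A: Pharmacophore, B: Pharmacophore, pairs: Iterable[tuple[int, int]],
    t: RigidTransform,
) -> float:
    pl = list(pairs)
    if not pl:
        return 0.0
    pa = A.positions[[i for i, _ in pl]]
    pb = t.apply(B.positions[[j for _, j in pl]])
    return float(np.sqrt(np.mean(np.sum((pa - pb) ** 2, axis=1))))


def classify_fit(
    A: Pharmacophore, B: Pharmacophore, res: AlignmentResult, omitted: int = 0
) -> str:
    """Classify an alignment as 'full', 'maximum', 'partial' or 'none'.

    full: every feature of both models is paired; maximum: every query
    feature is paired into a larger target; partial: at least
    |A| - omitted query features are paired; none otherwise.
    """
    mc = res.match_count
    nA, nB = len(A), len(B)
    if mc == nA == nB:
        return "full"
    if mc == nA < nB:
        return "maximum"
    if nA - omitted <= mc < nA:
        return "partial"
    return "none"
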