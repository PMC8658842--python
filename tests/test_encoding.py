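"""Neighbourhood encoding and dissimilarity matrix, against a brute-force
permutation oracle for the neighbour assignment."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from g3ps import (
    INVALID,
    build_dissimilarity_matrix,
    encode_features,
    encoding_dissimilarity,
)
from g3ps.synthetic import random_rigid_transform
from g3ps.model import Feature, Pharmacophore

from conftest import make_random


def brute_force_dissimilarity(ea, eb, normalizer: int) -> float:
    """Independent oracle: exhaustive minimum over padded permutations."""
    if ea.owner_type != eb.owner_type:
        return INVALID
    na, nb = len(ea), len(eb)
    side = max(na, nb)
    if side == 0:
        return 0.0
    grid = np.ones((side, side))
    for p in range(na):
        for q in range(nb):
            if ea.labels[p] != eb.labels[q]:
                continue
            D = max(ea.owner_tolerance + ea.tolerances[p],
                    eb.owner_tolerance + eb.tolerances[q])
            grid[p, q] = min(1.0, abs(ea.distances[p] - eb.distances[q]) / D)
    best = min(
        sum(grid[r, c] for r, c in enumerate(perm))
        for perm in itertools.permutations(range(side))
    )
    return best / normalizer


class TestEncodeFeatures:
    def test_single_feature_has_no_neighbours(self):
        p = Pharmacophore(features=[Feature("H", (0, 0, 0), 1.0)])
        (enc,) = encode_features(p)
        assert len(enc) == 0

    def test_two_features_see_each_other(self):
        p = Pharmacophore(features=[
            Feature("H", (0, 0, 0), 1.0),
            Feature("AR", (3.0, 0, 0), 1.0),
        ])
        ea, eb = encode_features(p)
        assert ea.labels == ("AR",) and eb.labels == ("H",)
        assert ea.distances[0] == pytest.approx(3.0)

    def test_neighbour_count_is_n_minus_one(self):
        p = make_random(4, seed=9)
        assert all(len(e) == 3 for e in encode_features(p))


class TestEncodingDissimilarity:
    def test_identical_features_cost_zero(self):
        p = make_random(5, seed=1)
        enc = encode_features(p)
        for e in enc:
            assert encoding_dissimilarity(e, e, 5) == pytest.approx(0.0)

    def test_type_mismatch_is_invalid(self):
        p = Pharmacophore(features=[
            Feature("H", (0, 0, 0), 1.0),
            Feature("AR", (3.0, 0, 0), 1.0),
        ])
        ea, eb = encode_features(p)
        assert encoding_dissimilarity(ea, eb, 2) == INVALID

    def test_large_distance_difference_clamps_to_one(self):
        # neighbour distances differ by 10 A with tolerance sums 3.0:
        # the per-pair cost clamps to exactly 1
        a = Pharmacophore(features=[
            Feature("H", (0, 0, 0), 1.5),
            Feature("H", (2.0, 0, 0), 1.5),
        ])
        b = Pharmacophore(features=[
            Feature("H", (0, 0, 0), 1.5),
            Feature("H", (12.0, 0, 0), 1.5),
        ])
        M = build_dissimilarity_matrix(a, b)
        # each entry: single neighbour pair at clamped cost 1, / normalizer 2
        assert M.values[0, 0] == pytest.approx(0.5)

    def test_normalizer_must_be_positive(self):
        p = make_random(3, seed=2)
        ea = encode_features(p)[0]
        with pytest.raises(ValueError):
            encoding_dissimilarity(ea, ea, 0)


class TestDissimilarityMatrix:
    @given(st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None)
    def test_entries_bounded_and_sentinel_iff_type_mismatch(self, seed):
        rng = np.random.default_rng(seed)
        A = make_random(int(rng.integers(1, 6)), seed=seed)
        B = make_random(int(rng.integers(1, 6)), seed=seed + 1)
        M = build_dissimilarity_matrix(A, B)
        for i in range(len(A)):
            for j in range(len(B)):
                v = M.values[i, j]
                if A.types[i] != B.types[j]:
                    assert v == INVALID
                else:
                    assert 0.0 <= v <= 1.0

    def test_self_comparison_zero_diagonal(self):
        A = make_random(5, seed=3)
        M = build_dissimilarity_matrix(A, A)
        assert np.allclose(np.diag(M.values), 0.0)

    def test_rigid_transform_invariance(self):
        # encodings use internal distances only, so a moved copy has the
        # same matrix and a zero diagonal under the identity pairing
        A = make_random(5, seed=4)
        t = random_rigid_transform(np.random.default_rng(8))
        moved = Pharmacophore(features=[
            Feature(f.type, t.apply(f.position), f.tolerance)
            for f in A.features
        ])
        M = build_dissimilarity_matrix(A, moved)
        assert np.allclose(np.diag(M.values), 0.0, atol=1e-12)

    def test_all_type_disjoint_all_sentinel(self):
        a = Pharmacophore(features=[Feature("H", (3.0 * i, 0, 0), 1.0)
                                    for i in range(3)])
        b = Pharmacophore(features=[Feature("AR", (3.0 * i, 0, 0), 1.0)
                                    for i in range(3)])
        M = build_dissimilarity_matrix(a, b)
        assert np.all(np.isinf(M.values))

    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_matches_permutation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        A = make_random(4, seed=seed, type_alphabet=("H", "AR"))
        B = make_random(5, seed=seed + 100, type_alphabet=("H", "AR"))
        enc_a, enc_b = encode_features(A), encode_features(B)
        M = build_dissimilarity_matrix(A, B)
        for i, ea in enumerate(enc_a):
            for j, eb in enumerate(enc_b):
                expected = brute_force_dissimilarity(ea, eb, 5)
                if expected == INVALID:
                    assert M.values[i, j] == INVALID
                else:
                    assert M.values[i, j] == pytest.approx(expected, abs=1e-12)
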