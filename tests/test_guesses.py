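"""Seed-guess generation against exhaustive enumeration oracles."""

import itertools

import numpy as np
import pytest

from g3ps import (
    DissimilarityMatrix,
    Feature,
    NoSeedError,
    Pharmacophore,
    all_guesses,
    build_dissimilarity_matrix,
    single_best_guess,
    top_m_guesses,
)
from g3ps.synthetic import random_rigid_transform

from conftest import make_random


def enumerate_triples(values: np.ndarray):
    """Oracle: all feasible three-pair combinations with their scores."""
    entries = [
        (i, j, values[i, j])
        for i in range(values.shape[0])
        for j in range(values.shape[1])
        if np.isfinite(values[i, j])
    ]
    out = []
    for combo in itertools.combinations(entries, 3):
        rows = {i for i, _, _ in combo}
        cols = {j for _, j, _ in combo}
        if len(rows) < 3 or len(cols) < 3:
            continue
        out.append((sum(c for _, _, c in combo),
                    tuple((i, j) for i, j, _ in combo)))
    return out


class TestSingleBestGuess:
    def test_identical_pharmacophores_zero_cost_diagonal_pairs(self):
        A = make_random(5, seed=21)
        g = single_best_guess(build_dissimilarity_matrix(A, A))
        assert g.score == pytest.approx(0.0, abs=1e-12)
        assert all(i == j for i, j in g.pairs)

    def test_unique_zero_permutation_recovered(self):
        vals = np.full((3, 3), 0.8)
        np.fill_diagonal(vals, 0.0)
        g = single_best_guess(DissimilarityMatrix(vals))
        assert set(g.pairs) == {(0, 0), (1, 1), (2, 2)}

    def test_all_sentinel_raises(self):
        vals = np.full((3, 3), np.inf)
        with pytest.raises(NoSeedError):
            single_best_guess(DissimilarityMatrix(vals))


class TestTopMGuesses:
    @pytest.mark.parametrize("seed", [31, 32, 33, 34])
    def test_matches_enumeration_oracle(self, seed):
        A = make_random(4, seed=seed)
        B = make_random(5, seed=seed + 50)
        M = build_dissimilarity_matrix(A, B)
        oracle = sorted(enumerate_triples(M.values))
        got = top_m_guesses(M, 10**6)
        assert len(got) == len(oracle)
        for guess, (score, _) in zip(got, oracle):
            assert guess.score == pytest.approx(score, abs=1e-12)

    def test_m_one_is_global_minimum(self):
        A = make_random(5, seed=35)
        B = make_random(5, seed=36)
        M = build_dissimilarity_matrix(A, B)
        top = top_m_guesses(M, 1)
        if top:
            best_single = single_best_guess(M)
            assert top[0].score <= best_single.score + 1e-12

    def test_returns_fewer_when_fewer_feasible(self):
        vals = np.full((3, 3), np.inf)
        np.fill_diagonal(vals, 0.1)
        got = top_m_guesses(DissimilarityMatrix(vals), 300)
        assert len(got) == 1  # only the diagonal triple is feasible

    def test_scores_ascending(self):
        A = make_random(6, seed=37)
        B = make_random(6, seed=38)
        got = top_m_guesses(build_dissimilarity_matrix(A, B), 50)
        scores = [g.score for g in got]
        assert scores == sorted(scores)


class TestAllGuesses:
    def test_distinct_types_single_combination(self):
        feats = [
            Feature("H", (0, 0, 0), 1.0),
            Feature("AR", (4, 0, 0), 1.0),
            Feature("HBA", (0, 4, 0), 1.0),
        ]
        A = Pharmacophore(features=feats)
        B = Pharmacophore(features=list(feats))
        assert len(list(all_guesses(A, B))) == 1

    def test_same_type_triples_count_permutations(self):
        feats = [Feature("H", (3.0 * i, 0, 0), 1.0) for i in range(3)]
        A = Pharmacophore(features=feats)
        B = Pharmacophore(features=list(feats))
        assert len(list(all_guesses(A, B))) == 6  # 3! one-to-one maps

    def test_no_shared_types_empty(self):
        A = Pharmacophore(features=[Feature("H", (3.0 * i, 0, 0), 1.0)
                                    for i in range(3)])
        B = Pharmacophore(features=[Feature("NI", (3.0 * i, 0, 0), 1.0)
                                    for i in range(3)])
        assert list(all_guesses(A, B)) == []

    def test_guess_list_rigid_invariant(self):
        A = make_random(5, seed=39)
        B = make_random(5, seed=40)
        t = random_rigid_transform(np.random.default_rng(41))
        moved = Pharmacophore(features=[
            Feature(f.type, t.apply(f.position), f.tolerance)
            for f in B.features
        ])
        ref = [g.pairs for g in all_guesses(A, B)]
        got = [g.pairs for g in all_guesses(A, moved)]
        assert ref == got
        # ranked guesses are also invariant: the matrix uses internal
        # distances only
        Mr = build_dissimilarity_matrix(A, B)
        Mg = build_dissimilarity_matrix(A, moved)
        ref2 = [(g.pairs, round(g.score, 10)) for g in top_m_guesses(Mr, 20)]
        got2 = [(g.pairs, round(g.score, 10)) for g in top_m_guesses(Mg, 20)]
        assert ref2 == got2
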