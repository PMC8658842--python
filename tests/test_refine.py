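"""Kabsch superposition, translation rescue, and the greedy refinement loop."""

import numpy as np
import pytest

from g3ps import (
    AlignConfig,
    AmbiguousAlignmentError,
    DegenerateGeometryError,
    Feature,
    Pharmacophore,
    SeedGuess,
    UnderdeterminedError,
    align,
    brute_force_best_match,
    kabsch,
    refine,
    translation_rescue,
)
from g3ps.synthetic import perturbed_copy, random_rigid_transform

from conftest import make_random


class TestKabsch:
    def test_identity_on_equal_points(self):
        pts = np.random.default_rng(0).uniform(-5, 5, size=(5, 3))
        t = kabsch(pts, pts)
        assert np.allclose(t.rotation, np.eye(3), atol=1e-9)
        assert np.allclose(t.translation, 0.0, atol=1e-9)

    def test_recovers_known_rigid_map(self):
        pts = np.random.default_rng(1).uniform(-5, 5, size=(6, 3))
        Rz = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        moved = pts @ Rz.T + np.array([1.0, 2.0, 3.0])
        t = kabsch(pts, moved)
        back = t.apply(moved)
        assert np.allclose(back, pts, atol=1e-9)

    def test_beats_random_transforms_on_noisy_cloud(self):
        # Monte-Carlo lower bound: the closed-form fit is at least as good
        # as 1000 random rigid placements
        rng = np.random.default_rng(2)
        pts = rng.uniform(-5, 5, size=(5, 3))
        t_true = random_rigid_transform(rng)
        moved = t_true.apply(pts) + rng.normal(scale=0.1, size=(5, 3))
        t = kabsch(pts, moved)
        best_rmsd = np.sqrt(np.mean(np.sum((pts - t.apply(moved)) ** 2, 1)))
        for _ in range(1000):
            tr = random_rigid_transform(rng, translation_extent=8.0)
            r = np.sqrt(np.mean(np.sum((pts - tr.apply(moved)) ** 2, 1)))
            assert best_rmsd <= r + 1e-12

    def test_underdetermined_raises(self):
        pts = np.zeros((2, 3))
        with pytest.raises(UnderdeterminedError):
            kabsch(pts, pts)

    def test_collinear_raises(self):
        pts = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [3.5, 0, 0]])
        with pytest.raises(DegenerateGeometryError):
            kabsch(pts, pts)


class TestTranslationRescue:
    def test_no_violation_returns_feasible_delta(self):
        resid = np.zeros((3, 3))
        radii = np.ones(3)
        delta = translation_rescue(resid, radii)
        assert delta is not None
        assert np.all(np.linalg.norm(resid - delta, axis=1) < radii)

    def test_single_violation_with_slack_succeeds(self):
        # one pair 0.2 A outside its ball, others with 0.5 A slack
        resid = np.array([[1.2, 0, 0], [0.1, 0, 0], [-0.1, 0, 0]])
        radii = np.array([1.0, 0.6, 0.6])
        delta = translation_rescue(resid, radii)
        assert delta is not None
        assert np.all(np.linalg.norm(resid - delta, axis=1) < radii)
        # oracle: a coarse grid search also finds a feasible point
        grid = np.linspace(-0.6, 0.6, 25)
        found = any(
            np.all(np.linalg.norm(resid - np.array([x, y, z]), axis=1) < radii)
            for x in grid for y in grid for z in grid
        )
        assert found

    def test_opposite_violations_fail(self):
        # two balls pushed apart further than their combined radii
        resid = np.array([[3.0, 0, 0], [-3.0, 0, 0], [0.0, 0, 0]])
        radii = np.array([1.0, 1.0, 1.0])
        assert translation_rescue(resid, radii) is None


def _seed_for(A, B, pairs=((0, 0), (1, 1), (2, 2))):
    return SeedGuess(pairs=tuple(pairs), score=0.0)


class TestRefine:
    def test_exact_copy_full_match(self):
        A = make_random(6, seed=50)
        B, _ = perturbed_copy(A, seed=51)
        res = refine(A, B, _seed_for(A, B))
        assert res.match_count == 6
        assert res.rmsd < 1e-6
        assert res.valid

    def test_noise_below_half_tolerance_full_match(self):
        # noise < min tolerance / 2 guarantees every ground-truth pair
        # stays within threshold under the true inverse transform
        A = make_random(6, seed=52, tolerance_range=(1.2, 2.0))
        B, truth = perturbed_copy(A, noise_sigma=0.1, seed=53)
        res = refine(A, B, _seed_for(A, B))
        assert res.match_count == 6

    def test_pair_set_one_to_one(self):
        A = make_random(6, seed=55)
        B = make_random(6, seed=56)
        guesses = list(__import__("g3ps").all_guesses(A, B))
        assert guesses
        res = refine(A, B, guesses[0])
        rows = res.matched.rows()
        cols = res.matched.cols()
        assert len(set(rows)) == len(rows)
        assert len(set(cols)) == len(cols)

    def test_iteration_count_bounded_by_grid(self):
        # each iteration marks >= 1 forbidden entry, so iterations can
        # never exceed |A| * |B| (termination argument)
        A = make_random(7, seed=56)
        B = make_random(7, seed=57)
        guesses = list(__import__("g3ps").all_guesses(A, B))
        if not guesses:
            pytest.skip("no compatible seed")
        res = refine(A, B, guesses[0])
        assert res.stats.iterations <= len(A) * len(B)


class TestAlign:
    def test_exact_copy_fast_preset(self):
        A = make_random(6, seed=60)
        B, _ = perturbed_copy(A, seed=61)
        res = align(A, B, AlignConfig.preset("fast"))
        assert res.match_count == 6 and res.rmsd < 1e-6

    def test_omitted_budget_guard(self):
        A = make_random(5, seed=62)
        with pytest.raises(AmbiguousAlignmentError):
            align(A, A, AlignConfig(omitted=3))

    def test_no_shared_types_gives_empty_result(self):
        A = Pharmacophore(features=[Feature("H", (3.0 * i, 0, 0), 1.0)
                                    for i in range(3)])
        B = Pharmacophore(features=[Feature("NI", (3.0 * i, 0, 0), 1.0)
                                    for i in range(3)])
        res = align(A, B)
        assert res.match_count == 0 and not res.valid

    def test_deterministic(self):
        A = make_random(6, seed=63)
        B = make_random(6, seed=64)
        r1 = align(A, B, AlignConfig(guesses=50))
        r2 = align(A, B, AlignConfig(guesses=50))
        assert r1.match_count == r2.match_count
        assert r1.matched.pairs == r2.matched.pairs
        assert np.array_equal(r1.transform.rotation, r2.transform.rotation)

    @pytest.mark.parametrize("seed", [70, 71, 72])
    def test_rigid_invariance_of_match_count(self, seed):
        A = make_random(5, seed=seed)
        B = make_random(5, seed=seed + 10)
        t = random_rigid_transform(np.random.default_rng(seed + 20))
        moved = Pharmacophore(features=[
            Feature(f.type, t.apply(f.position), f.tolerance)
            for f in B.features
        ])
        cfg = AlignConfig(exhaustive=True)
        assert align(A, B, cfg).match_count == align(A, moved, cfg).match_count

    def test_exhaustive_at_least_fast(self):
        for seed in range(80, 85):
            A = make_random(6, seed=seed)
            B = make_random(6, seed=seed + 100)
            fast = align(A, B, AlignConfig(guesses=20)).match_count
            full = align(A, B, AlignConfig(exhaustive=True)).match_count
            assert full >= fast

    def test_exhaustive_never_exceeds_oracle(self):
        for seed in range(90, 100):
            A = make_random(5, seed=seed)
            B = make_random(5, seed=seed + 200)
            got = align(A, B, AlignConfig(exhaustive=True)).match_count
            oracle = brute_force_best_match(A, B)
            assert got <= oracle

    def test_mirror_seed_never_reflected(self):
        # a mirror-image target can never be matched by a reflection:
        # det(R) stays +1 and only a threshold-satisfying subset matches
        from g3ps import mirror_copy

        A = make_random(6, seed=66, type_alphabet=("H",))
        B = mirror_copy(A, seed=67)
        res = align(A, B, AlignConfig(exhaustive=True))
        assert np.linalg.det(res.transform.rotation) == pytest.approx(1.0)

    def test_refinement_effort_independent_of_omitted(self):
        A = make_random(6, seed=68)
        B = make_random(6, seed=69)
        counts = []
        for omitted in (0, 1, 2, 3):
            res = align(A, B, AlignConfig(guesses=20, omitted=omitted))
            counts.append(res.stats.refinements)
        assert len(set(counts)) == 1
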