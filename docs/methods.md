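# Methods

This note records the model, the algorithmic and numerical choices,
and what the synthetic benchmarks do and do not demonstrate.

## Matching model

A pharmacophore is an ordered list of labelled feature points in
Cartesian angstroms, each with a positional tolerance radius
`thresh > 0`, optionally a unit direction vector, plus exclusion
spheres and (optionally) the underlying molecule's atom coordinates.
A pair `(A_i, B_j)` matches under a rigid transform `T` iff the labels
are equal and `dist(A_i, T(B_j)) < max(thresh(A_i), thresh(B_j))`.
Both this inequality and the exclusion clearance
`dist(T(a), centre) > radius` are **strict**: boundary contact fails a
match and counts as a clash. Matched pair sets are one-to-one. Only
proper rigid motions are allowed; the Kabsch solver corrects
reflections via the determinant sign, so `det(R) = +1` always.

Alignment quality is primarily the matched-pair count; RMSD over the
matched pairs breaks ties only. Fit classes: *full* (everything
paired), *maximum* (all query features paired into a larger target),
*partial* (at least `|A| - #o` query features paired, `#o` being the
omitted-feature budget), else *none*.

## Seeding

Feature encodings use only intra-model distances, so they are
invariant under any rigid motion of either model. The pairwise
pseudo-cost between same-typed features solves a linear assignment
over neighbour pairs with per-pair cost
`min(1, |d_p - d_q| / max(tol_i + tol_p, tol_j + tol_q))` (1 for
unequal neighbour labels). Unequal neighbour counts are reconciled by
padding the grid with cost-1 dummies — an unmatchable neighbour is
maximally different. The total is normalised by the larger model's
feature count, so all valid entries lie in `[0, 1)`; type-incompatible
entries carry an infinite sentinel and are never selected.
`scipy.optimize.linear_sum_assignment` is the assignment solver
throughout (any optimal LAP algorithm satisfies the contract).

Seed guesses are three-pair combinations with distinct rows, distinct
columns and no sentinel, ranked by the sum of their three entries and
tie-broken lexicographically. Presets: *fast* = 20 guesses,
*accurate* = 300. Exhaustive mode enumerates every label-compatible
combination (`O(n^6)` but cheap at screening sizes). The whole
pipeline is deterministic — there is no RNG anywhere in the aligners.

## Refinement

Each seed is fitted with Kabsch; the forbidden matrix `F` starts with
all type-incompatible entries plus the seed's rows and columns marked.
Per iteration the unforbidden pair with the smallest centre distance
under the current transform is tried (ties resolved by row-major
order): the enlarged pair set is re-fitted, and *every* pair is
re-validated — the previous alignment is restored on failure, so the
whole set must stay feasible, not just the newcomer. Acceptance marks
the pair's row and column; rejection marks the single entry. Since
every iteration marks at least one new entry, the loop terminates
within `|A|·|B|` iterations (asserted at run time).

**Translation rescue.** Before rejecting a candidate, a pure
translation `δ` is sought with `|r_k - δ| < ρ_k` for every pair's
residual `r_k` and tolerance bound `ρ_k` — a point in the open
intersection of balls. This convex minimax problem is solved by a
pairwise-disjointness precheck, cheap candidate points (centroid and
ball centres), then an SLSQP epigraph formulation; the returned `δ` is
verified against the strict inequalities before use. The rescue is
attempted only inside the improvement loop, not on the raw seed fit.

Results report only pairs satisfying the predicate under the final
transform; if some seed pair never satisfied it, the result carries
`valid = False` with the honest surviving count. Degenerate seed
geometry (collinear/coincident, detected when the second singular
value of the centred point matrix falls below 1e-9 of the largest)
raises an error from `refine`; the multi-guess driver skips such
seeds rather than aborting, since they are a measure-zero accident of
seed enumeration.

The guess loop skips seeds wholly contained in an already-found
solution and stops early once the match count reaches
`min(|A|, |B|)`, which no later guess can beat. This sacrifices the
RMSD tie-break against later equal-sized matches — a deliberate trade,
since the count is the primary objective and the early stop keeps
screening effort low. An opt-in `early_exit` stops refinement at
`|A| - #o` matches; it is **off by default** (including in screening)
so that the work performed never depends on the omitted budget — the
property the effort benchmarks measure.

## Post-processing

Exclusion dodging applies up to `max_dodge_translations` (default 3)
candidate translations; each is the minimum-norm displacement pushing
every currently clashing atom to `radius + 1e-3 Å` clearance (deepest
clash resolved radially, multi-clash cases via SLSQP on `min |δ|²`
with clearance constraints; verification is against the hard radii).
After the clash set is cleared, all matched pairs are re-validated and
violators dropped; the result is invalid if clashes persist or the
count falls below the caller's minimum. Direction filtering removes
matched pairs whose query direction and rotated target direction
diverge beyond `direction_angle_tolerance` (default 45°, a
configurable choice); aromatic plane normals compare up to sign. Pairs
lacking a direction on either side pass unchecked.

## Baseline aligner

`rmm_align` re-implements the classic pipeline for head-to-head match
and effort comparisons: per-feature, per-neighbour-type distance
histograms (bin width 1 Å over 0–20 Å, defaults configurable),
smoothed with a mass-conserving triangular kernel `[0.25, 0.5, 0.25]`
(symmetric-padded boundaries); histogram-overlap cost
`1 − Σ min(h₁,h₂) / max(Σh₁, Σh₂, 1)` averaged over the union of
neighbour types — the specific overlap metric is our documented
choice, as is treating "removing violating pairs" as removing those
features from the assignment pools before re-running
Hungarian + Kabsch until stable or fewer than three pairs remain.
Omitted features are handled combinatorially: each query subset with
up to `#o` removals (larger first) is re-encoded — the reduced model
*is* the query being aligned — and the first subset yielding a valid
alignment wins. The Kabsch-invocation counter is the effort proxy;
wall-clock comparisons are out of scope. This is a faithful-behaviour
baseline, not a bit-exact reproduction of any particular product.

## Synthetic benchmarks

The fixture generator draws feature positions uniformly in a 10 Å box
with ≥ 1.5 Å pairwise separation, types uniformly from
`{H, AR, HBA, HBD}`, and tolerances uniformly from `[1.0, 2.0] Å` —
magnitudes typical of ligand-derived screening models. Perturbed
copies apply a random rigid motion, isotropic Gaussian noise and
optional feature deletions, returning the surviving ground-truth
correspondence. Screening suites plant 50 noised actives among 150
unrelated decoys (200 entries). Benchmark problem sizes: 200 recovery
cases (n = 4..8 exact; n = 5..8 for noisy cases with up to two
dropped features, since n = 4 minus two would fall below the
three-pair minimum), 100 oracle-comparison pairs with n ≤ 6.

What these fixtures do **not** emulate: feature-count and type
distributions of real ligands, correlated conformer ensembles,
directional features in bulk, or decoys with realistic chemical
similarity to the query. Passing benchmarks therefore demonstrates
the geometric and algorithmic properties of the aligners, not virtual
screening enrichment on real targets.

## Oracle

The exhaustive cross-check enumerates every label-consistent
one-to-one mapping of size ≥ 3, fits each with (batched) Kabsch and
counts its tolerance-satisfying pairs. Because the greedy aligner may
legitimately finish on a rescue step — Kabsch rotation plus an extra
translation — a mapping is also credited in full when keeping its
Kabsch rotation and freeing the translation satisfies all pairs (the
same ball-intersection condition as the rescue). Without this polish
the greedy search can exceed the oracle, which would invalidate it as
an upper bound; `translation_polish=False` recovers the plain variant.

## Known limitations

- Direction vectors are not used during refinement, only as a
  post-filter; alignments that could be steered by directionality may
  need more guesses.
- The dodge translations are minimum-norm constructions; a clash
  fixable only by a rotation or a non-minimal translation is given up.
- Effort counters, not wall-clock time, are the performance metric;
  absolute speed depends on vectorisation and is not benchmarked.
- Per-feature "optional" flags are stored and round-tripped but not
  treated specially beyond the global omitted-feature budget.
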