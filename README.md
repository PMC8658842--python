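# g3ps — match-count-maximising pharmacophore alignment

`g3ps` aligns 3D pharmacophore models — labelled feature points
(hydrophobic, aromatic, H-bond acceptor/donor, ionizable, ...) with
positional tolerance radii, optional direction vectors and exclusion
volume spheres — so that the **number of geometrically matched feature
pairs is maximised**, rather than the RMSD minimised or a volume
overlap maximised. It is written for computational chemists running
pharmacophore-based virtual screens, where an aligner that minimises
RMSD will happily superpose three features perfectly and miss the hit
that matches all seven within their tolerances.

## The algorithm

Two features `A_i`, `B_j` *match* under a rigid transform `T` when

    label(A_i) = label(B_j)   and   dist(A_i, T(B_j)) < max(thresh(A_i), thresh(B_j))

where `thresh` is each feature's positional tolerance radius. The
aligner searches for the proper rigid motion (rotation + translation,
no scaling or reflection) maximising the number of matching pairs;
among equal counts, smaller RMSD of the matched pairs wins.

The greedy three-point search works in two stages:

1. **Seeding.** Each feature is encoded by the labelled distances to
   every other feature of its own model; encodings are compared by an
   optimal neighbour assignment (distance differences scaled by summed
   tolerances and clamped at 1), giving an `|A| x |B|` dissimilarity
   matrix. The `m` lowest-scoring feasible three-pair combinations —
   three pairs being the minimum that fixes an unambiguous 3D
   transform — become seed guesses (`m` = 20 for the *fast* preset,
   300 for *accurate*; `--exhaustive` tries every combination).
2. **Greedy refinement.** Each seed is superposed with the Kabsch
   algorithm, then the closest not-yet-forbidden pair is repeatedly
   added, the transform re-fitted, and every collected pair re-checked
   against its tolerance; if a check fails, a pure-translation rescue
   (a convex ball-intersection feasibility problem) is attempted
   before the candidate is forbidden. A monotone "forbidden" matrix
   guarantees termination.

Post-processing can *dodge* shallow exclusion-volume clashes with up
to three minimal translations (re-validating all matched pairs
afterwards) and unmatch pairs whose direction vectors diverge beyond
an angular tolerance.

Because the search never enumerates feature subsets, its effort is
independent of the allowed number of omitted features `#o` — unlike
the classic distance-histogram/Hungarian baseline (`rmm_align`), also
implemented here for comparison, whose work grows with `sum_k C(|A|, k)`.

## Worked example

```python
from g3ps import (FixtureSpec, random_pharmacophore, perturbed_copy,
                  write_pharmacophore)
q = random_pharmacophore(FixtureSpec(n_features=6, seed=4))
q.name = "query"
write_pharmacophore(q, "query.json")
t, _ = perturbed_copy(q, seed=55)       # exact rigid copy
write_pharmacophore(t, "target.json")
```

```text
$ g3ps align query.json target.json --preset fast --report json
{
  "query": "query",
  "target": "query-copy",
  "match_count": 6,
  "rmsd": 0.0,
  "valid": true,
  "fit": "full",
  ...
}
```

All six feature pairs are recovered with zero residual and the fit is
classified *full* (every feature of both models is paired; *maximum* =
the whole query fits a larger target, *partial* = at least
`|query| - #o` pairs). Screening a ten-entry library (five noised
copies, half with one feature deleted, plus five unrelated decoys)
with one omitted feature allowed:

```text
$ g3ps screen query.json library.jsonl --preset fast --omitted 1 --out hits.tsv
5 hit(s) from 10 entries (105 refinements, 334 superpositions)
  mol0:0  matched=6 rmsd=0.3456
  mol1:0  matched=5 rmsd=0.2481
  mol2:0  matched=6 rmsd=0.3355
  mol3:0  matched=5 rmsd=0.3053
  mol4:0  matched=6 rmsd=0.2619
```

Every planted copy is a hit (the feature-dropped ones match 5 of 6,
within the omitted budget) and no decoy is; the refinement and
superposition counts are the hardware-independent effort metrics. The
same run with `--algorithm rmm` screens with the baseline aligner.

## File formats

Native JSON (lossless) and a line-oriented `.phar` text dialect with
4-decimal fixed precision:

```text
NAME example
HBA 1.0000 2.0000 3.0000 1.5000 1 0.0000 0.0000 1.0000
H 4.0000 0.0000 0.0000 1.0000 0 0.0000 0.0000 0.0000
EXCL 8.0000 8.0000 0.0000 1.0000
ATOM 8.9000 8.0000 0.0000
$$$$
```

Feature records are `CODE x y z tolerance hasDir nx ny nz`; `EXCL` is
an exclusion sphere, `ATOM` a molecule atom, `$$$$` ends a record.
Concatenated records (or a JSON-lines file) form a screening library;
entries named `molecule:conformer` are grouped per molecule.

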