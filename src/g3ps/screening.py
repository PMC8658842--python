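"""Virtual screening driver: align a library against a query pharmacophore.

A library entry is a hit when its best valid alignment matches at
least |query| - omitted features after all post-filters. Multi-conformer
libraries name entries ``molecule:conformer``; a molecule counts once,
represented by its best conformer. Per-entry effort counters
(refinement and Kabsch invocations) are reported as a
hardware-independent runtime proxy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .errors import G3PSError
from .model import AlignmentResult, Pharmacophore, RigidTransform
from .postfilter import PostFilterConfig, apply_postfilters
from .refine import AlignConfig, align
from .rmm import RMMConfig, rmm_align


@dataclass
class ScreenConfig:
    """Screening run configuration.

    algorithm : 'g3ps' (greedy three-point search) or 'rmm' (baseline).
    guesses / exhaustive : seed budget for the greedy aligner.
    omitted : allowed unmatched query features (#o).
    postfilters : exclusion/direction post-filtering (None = off).
    per_conformer : report one hit row per conformer instead of one
        per molecule.
    """

    algorithm: str = "g3ps"
    guesses: int = 20
    exhaustive: bool = False
    omitted: int = 0
    postfilters: PostFilterConfig | None = None
    per_conformer: bool = False
    rmm: RMMConfig = field(default_factory=RMMConfig)


@dataclass
class ScreeningHit:
    """One accepted library molecule (best conformer)."""

    target_name: str
    conformer_id: str | None
    match_count: int
    rmsd: float
    transform: RigidTransform


@dataclass
class ScreenMetrics:
    """Effort counters aggregated over the run."""

    entries: int = 0
    refinements: int = 0
    kabsch_calls: int = 0
    per_entry_refinements: list[int] = field(default_factory=list)
    per_entry_kabsch: list[int] = field(default_factory=list)
    per_entry_hit: list[bool] = field(default_factory=list)
    skipped: int = 0


def _split_name(name: str) -> tuple[str, str | None]:
    if ":" in name:
        mol, conf = name.split(":", 1)
        return mol, conf
    return name, None


def _align_entry(
    query: Pharmacophore, entry: Pharmacophore, cfg: ScreenConfig
) -> AlignmentResult:
    if cfg.algorithm == "g3ps":
        return align(
            query,
            entry,
            AlignConfig(
                guesses=cfg.guesses,
                exhaustive=cfg.exhaustive,
                omitted=cfg.omitted,
            ),
        )
    if cfg.algorithm == "rmm":
        return rmm_align(query, entry, cfg.omitted, cfg.rmm)
    raise ValueError(f"unknown algorithm {cfg.algorithm!r}")


def screen(
    query: Pharmacophore,
    library: Iterable[Pharmacophore],
    config: ScreenConfig | None = None,
) -> tuple[list[ScreeningHit], ScreenMetrics]:
    """Screen ``library`` against ``query``; return hits and run metrics.

    Hits require a valid alignment with match count >= |query| - omitted
    (post-filters applied when configured). Entries that fail to align
    for geometric reasons are simply non-hits; entries that raise a
    parse-level error are counted in ``metrics.skipped``.
    """
    config = config or ScreenConfig()
    required = len(query) - config.omitted
    if required < 3:
        from .errors import AmbiguousAlignmentError

        raise AmbiguousAlignmentError(
            f"query has {len(query)} features and {config.omitted} may be "
            "omitted; at least three matched pairs are required"
        )
    metrics = ScreenMetrics()
    best_by_mol: dict[str, ScreeningHit] = {}
    order: list[str] = []
    hits_rows: list[ScreeningHit] = []

    for entry in library:
        metrics.entries += 1
        try:
            res = _align_entry(query, entry, config)
        except G3PSError:
            metrics.skipped += 1
            continue
        if res.stats is not None:
            metrics.refinements += res.stats.refinements
            metrics.kabsch_calls += res.stats.kabsch_calls
            metrics.per_entry_refinements.append(res.stats.refinements)
            metrics.per_entry_kabsch.append(res.stats.kabsch_calls)
        if config.postfilters is not None and res.match_count >= 3:
            res = apply_postfilters(
                res, query, entry, config.postfilters, max(required, 3)
            )
        is_hit = res.valid and res.match_count >= required
        metrics.per_entry_hit.append(is_hit)
        if not is_hit:
            continue
        mol, conf = _split_name(entry.name)
        hit = ScreeningHit(
            target_name=mol,
            conformer_id=conf,
            match_count=res.match_count,
            rmsd=res.rmsd,
            transform=res.transform,
        )
        if config.per_conformer:
            hits_rows.append(hit)
            continue
        prev = best_by_mol.get(mol)
        if prev is None:
            best_by_mol[mol] = hit
            order.append(mol)
        elif (hit.match_count, -hit.rmsd) > (prev.match_count, -prev.rmsd):
            best_by_mol[mol] = hit

    if config.per_conformer:
        return hits_rows, metrics
    return [best_by_mol[m] for m in order], metrics


def write_hits_tsv(hits: list[ScreeningHit], path) -> None:
    """Write a hit table: molecule, conformer, match_count, rmsd, matrix."""
    lines = ["molecule\tconformer\tmatch_count\trmsd\tmatrix"]
    for h in hits:
        flat = list(h.transform.rotation.ravel()) + list(h.transform.translation)
        mat = ",".join(f"{v:.4f}" for v in flat)
        lines.append(
            f"{h.target_name}\t{h.conformer_id or ''}\t{h.match_count}"
            f"\t{h.rmsd:.4f}\t{mat}"
        )
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + "\n")
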