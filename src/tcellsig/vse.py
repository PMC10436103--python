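"""Variant-set enrichment (VSE) of risk loci within accessible-region sets.

Risk variants are expanded into LD blocks (the associated variant set, AVS);
significance of their overlap with a region set is judged against matched
random variant sets: null families of catalog LD blocks size-matched to the
AVS blocks.  The enrichment score of a variant set against a region set is
the number of blocks with at least one variant inside a region; the add-one
empirical p-value compares the observed score with the null score
distribution, Bonferroni-corrected across region sets.

The variant catalog is a DataFrame with columns chrom, pos (0-based),
variant_id, block_id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .atac import GenomicInterval

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("chrom", "pos", "variant_id", "block_id")


def _check_catalog(catalog: pd.DataFrame) -> None:
    missing = set(REQUIRED_COLUMNS) - set(catalog.columns)
    if missing:
        raise ValueError(f"variant catalog missing columns {sorted(missing)}")
    if catalog["variant_id"].duplicated().any():
        raise ValueError("duplicate variant ids in catalog")
    if (catalog["pos"] < 0).any():
        raise ValueError("variant positions must be >= 0")


def variants_in_regions(
    catalog: pd.DataFrame, regions: Sequence[GenomicInterval]
) -> np.ndarray:
    """Boolean per catalog row: position inside any half-open region."""
    inside = np.zeros(len(catalog), dtype=bool)
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in regions:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    pos = catalog["pos"].to_numpy(np.int64)
    chroms = catalog["chrom"].to_numpy()
    for chrom, ivs in by_chrom.items():
        ivs = sorted(ivs, key=lambda x: x.start)
        starts = np.array([i.start for i in ivs], dtype=np.int64)
        ends = np.array([i.end for i in ivs], dtype=np.int64)
        mask = chroms == chrom
        j = np.searchsorted(starts, pos[mask], side="right") - 1
        hit = (j >= 0) & (pos[mask] < ends[np.clip(j, 0, None)])
        inside[np.flatnonzero(mask)] = hit
    return inside


@dataclass
class AssociatedVariantSet:
    """Disjoint LD blocks, each a frozenset of variant ids."""

    blocks: dict[str, frozenset[str]]  # block label -> variant ids
    unmapped: list[str] = field(default_factory=list)

    def __post_init__(self):
        seen: set[str] = set()
        for label, members in self.blocks.items():
            if not members:
                raise ValueError(f"block {label} is empty")
            if seen & members:
                raise ValueError("AVS blocks must be disjoint")
            seen |= members

    @property
    def sizes(self) -> list[int]:
        return [len(m) for m in self.blocks.values()]


@dataclass
class MatchedNullSet:
    """One size-matched random block family; provenance maps wanted -> got sizes."""

    blocks: dict[str, frozenset[str]]
    provenance: list[tuple[int, int]]


@dataclass
class VSEResult:
    region_set_id: str
    observed_score: int
    null_scores: np.ndarray
    enrichment_p: float
    bonferroni_p: float
    significant: bool
    z_score: float | None = None


def build_avs(
    risk_variants: Sequence[str],
    catalog: pd.DataFrame,
    ld_pairs: pd.DataFrame | None = None,
    r2_threshold: float = 0.8,
) -> AssociatedVariantSet:
    """Expand risk variants into disjoint LD blocks.

    ``ld_pairs`` has columns variant_a, variant_b, r2.  Each risk variant
    seeds a block with every catalog variant linked at r2 >= threshold;
    blocks sharing a variant are merged (union-find).  Risk variants absent
    from the catalog are reported in ``unmapped``, not fatal.
    """
    _check_catalog(catalog)
    known = set(catalog["variant_id"])
    unmapped = [v for v in risk_variants if v not in known]
    if unmapped:
        logger.warning("%d risk variants absent from catalog", len(unmapped))
    seeds = [v for v in risk_variants if v in known]

    neighbors: dict[str, set[str]] = {}
    if ld_pairs is not None and len(ld_pairs):
        strong = ld_pairs[ld_pairs["r2"] >= r2_threshold]
        for a, b in zip(strong["variant_a"], strong["variant_b"]):
            if a in known and b in known:
                neighbors.setdefault(a, set()).add(b)
                neighbors.setdefault(b, set()).add(a)

    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent.get(x, x) != x:
            parent[x] = parent.get(parent[x], parent[x])
            x = parent[x]
        return x

    def union(x: str, y: str) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[rx] = ry

    members: dict[str, set[str]] = {}
    for v in seeds:
        members[v] = {v} | neighbors.get(v, set())
        for m in members[v]:
            parent.setdefault(m, m)
        for m in members[v]:
            union(v, m)
    merged: dict[str, set[str]] = {}
    for v in seeds:
        merged.setdefault(find(v), set()).update(members[v])
    blocks = {
        f"avs{i + 1}": frozenset(mem)
        for i, (_, mem) in enumerate(sorted(merged.items()))
    }
    return AssociatedVariantSet(blocks=blocks, unmapped=unmapped)


def avs_from_blocks(catalog: pd.DataFrame, block_ids: Sequence[str]) -> AssociatedVariantSet:
    """AVS whose blocks are catalog LD blocks chosen by id."""
    _check_catalog(catalog)
    grouped = catalog.groupby("block_id")["variant_id"].apply(frozenset)
    missing = [b for b in block_ids if b not in grouped.index]
    if missing:
        raise ValueError(f"unknown block ids: {missing[:3]}")
    return AssociatedVariantSet(blocks={b: grouped[b] for b in block_ids})


def sample_matched_null(
    avs: AssociatedVariantSet,
    catalog: pd.DataFrame,
    n_null: int = 500,
    seed: int | None = None,
) -> list[MatchedNullSet]:
    """Draw ``n_null`` random block families size-matched to the AVS.

    Candidate blocks are catalog LD blocks sharing no variant with the AVS.
    Each AVS block is matched by a random candidate of equal variant count
    when available, else of nearest count (logged in the provenance);
    within one null family blocks are drawn without replacement.
    """
    _check_catalog(catalog)
    avs_variants = frozenset().union(*avs.blocks.values())
    grouped = catalog.groupby("block_id")["variant_id"].apply(frozenset)
    candidates = {
        b: mem for b, mem in grouped.items() if not (mem & avs_variants)
    }
    if len(candidates) < len(avs.blocks):
        raise ValueError("catalog too small: fewer candidate blocks than AVS blocks")
    cand_ids = np.array(sorted(candidates))
    cand_sizes = np.array([len(candidates[b]) for b in cand_ids])
    wanted = sorted(avs.sizes, reverse=True)

    rng = np.random.default_rng(seed)
    null_sets: list[MatchedNullSet] = []
    for _ in range(n_null):
        taken = np.zeros(len(cand_ids), dtype=bool)
        blocks: dict[str, frozenset[str]] = {}
        provenance: list[tuple[int, int]] = []
        for size in wanted:
            free = ~taken
            exact = free & (cand_sizes == size)
            pool = np.flatnonzero(exact)
            if pool.size == 0:
                dist = np.where(free, np.abs(cand_sizes - size), np.iinfo(np.int64).max)
                best = dist.min()
                pool = np.flatnonzero(free & (np.abs(cand_sizes - size) == best))
            k = int(rng.choice(pool))
            taken[k] = True
            bid = str(cand_ids[k])
            blocks[f"null_{bid}"] = candidates[bid]
            got = int(cand_sizes[k])
            provenance.append((size, got))
            if got != size:
                logger.info("no candidate block of size %d; matched %d", size, got)
        null_sets.append(MatchedNullSet(blocks=blocks, provenance=provenance))
    return null_sets


def overlap_score(
    blocks: Mapping[str, frozenset[str]],
    catalog: pd.DataFrame,
    regions: Sequence[GenomicInterval],
) -> int:
    """Number of blocks with >= 1 variant inside any region."""
    inside = variants_in_regions(catalog, regions)
    in_set = set(catalog.loc[inside, "variant_id"])
    return sum(1 for mem in blocks.values() if mem & in_set)


def _block_hits(
    catalog: pd.DataFrame, regions: Sequence[GenomicInterval]
) -> set[str]:
    inside = variants_in_regions(catalog, regions)
    return set(catalog.loc[inside, "variant_id"])


def vse(
    avs: AssociatedVariantSet,
    region_sets: Mapping[str, Sequence[GenomicInterval]],
    catalog: pd.DataFrame,
    n_null: int = 500,
    alpha: float = 0.01,
    seed: int | None = None,
    normal_approximation: bool = False,
) -> dict[str, VSEResult]:
    """Run variant-set enrichment of the AVS against each named region set.

    One family of ``n_null`` matched null sets is shared across region sets so
    the per-set p-values are comparable.  ``enrichment_p`` is the add-one
    empirical upper-tail p; Bonferroni correction multiplies by the number of
    region sets; ``significant`` means Bonferroni p < alpha.  With
    ``normal_approximation`` a z-score of the observed score against the null
    mean/sd is attached for score-distribution displays.
    """
    if not region_sets:
        raise ValueError("need >= 1 region set")
    if n_null < 100:
        raise ValueError("need n_null >= 100")
    null_sets = sample_matched_null(avs, catalog, n_null=n_null, seed=seed)
    n_sets = len(region_sets)
    results: dict[str, VSEResult] = {}
    for name, regions in region_sets.items():
        hit_variants = _block_hits(catalog, regions)
        observed = sum(1 for mem in avs.blocks.values() if mem & hit_variants)
        null_scores = np.array([
            sum(1 for mem in ns.blocks.values() if mem & hit_variants)
            for ns in null_sets
        ])
        p = (1 + int((null_scores >= observed).sum())) / (1 + n_null)
        bonf = min(1.0, p * n_sets)
        z = None
        if normal_approximation:
            sd = null_scores.std(ddof=1)
            z = float((observed - null_scores.mean()) / sd) if sd > 0 else 0.0
        results[name] = VSEResult(
            region_set_id=name,
            observed_score=int(observed),
            null_scores=null_scores,
            enrichment_p=p,
            bonferroni_p=bonf,
            significant=bonf < alpha,
            z_score=z,
        )
    return results


def snp_hit_matrix(
    avs: AssociatedVariantSet,
    region_sets: Mapping[str, Sequence[GenomicInterval]],
    catalog: pd.DataFrame,
) -> pd.DataFrame:
    """Block x region-set presence table (True = block has a variant inside)."""
    cols = {}
    for name, regions in region_sets.items():
        hit_variants = _block_hits(catalog, regions)
        cols[name] = [bool(mem & hit_variants) for mem in avs.blocks.values()]
    return pd.DataFrame(cols, index=list(avs.blocks))
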