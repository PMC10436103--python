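"""Synthetic data generators for the whole pipeline.

Every input the analysis consumes can be generated here with the statistical
structure the method assumes, together with the planted ground truth needed
for recovery testing:

* replicate ATAC peak landscapes for in-vitro polarized CD4 T-cell subtypes
  (Treg, Th1, Th2, pTh17, rTh17 by default) over a shared-site backbone, with
  per-replicate site dropout and an effector baseline carrying shared sites
  only;
* negative-binomial accessibility counts with lognormal library-size factors
  and planted fold changes;
* mixtures of subtype signature profiles at Dirichlet-random proportions with
  element-wise multiplicative lognormal noise;
* an LD-block-structured variant catalog with risk blocks optionally planted
  inside a chosen region set;
* clustered single-cell counts with planted marker genes and a mitochondrial
  gene subset (``MT-`` prefix);
* bulk TPM profiles as convex cell-type mixtures with a planted cytotoxic
  effect inside the CD4 component of the inflamed group.

All generators are pure functions of ``(config, seed)``: each one draws from
its own salted stream derived from ``config.seed``, so adding a generator
call never perturbs the output of another.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .atac import GenomicInterval, PeakCallSet

SUBTYPE_NAMES = ("Treg", "Th1", "Th2", "pTh17", "rTh17")
EFFECTOR = "effector"

CYTOTOXIC_GENES = ("GZMA", "GZMB", "GNLY", "IFNG", "PRF1")

# fixed salts: one independent stream per generator
_SALTS = {
    "landscape": 11,
    "counts": 12,
    "mixtures": 13,
    "ld": 14,
    "risk": 15,
    "sc": 16,
    "bulk": 17,
}


def _rng(seed: int, generator: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _SALTS[generator]]))


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of every generator; defaults are the study-scale conditions.

    Subtype landscape: 5 polarized subtypes, 3 replicates each (plus an
    effector baseline of shared sites only), dropout 0.1 per replicate per
    specific site.  Counts: NB dispersion 0.05, lognormal library factors
    (sigma 0.3).  Mixtures: flat Dirichlet(1), multiplicative lognormal noise
    sigma 0.1.  LD genome: 200 blocks of 1-20 variants.  Single cell: three
    clusters, planted markers at log2FC 2, 5% mitochondrial counts.  Bulk:
    15 samples per group, cytotoxic effect of 1 (log2) in the inflamed CD4
    component.
    """

    seed: int = 0
    # subtype peak landscape
    n_subtypes: int = 5
    n_replicates_per_subtype: int = 3
    n_shared_sites: int = 1000
    n_specific_sites_per_subtype: int = 600
    dropout_rate: float = 0.1
    site_width: int = 500
    site_spacing: int = 2000
    # accessibility counts
    nb_dispersion: float = 0.05
    base_mean: float = 100.0
    background_fold: float = 8.0
    library_sigma: float = 0.3
    da_fraction: float = 0.0
    da_log2fc: float = 0.0
    da_group: str | None = None
    # mixtures
    n_mixtures: int = 100
    noise_sigma: float = 0.1
    dirichlet_alpha: float | Sequence[float] = 1.0
    # LD genome / risk variants
    n_blocks: int = 200
    block_size_range: tuple[int, int] = (1, 20)
    variant_spacing: int = 1000
    n_risk_loci: int = 30
    enrichment_delta: float = 0.0
    target_region_set: str = "target"
    # single cell
    cluster_sizes: tuple[int, ...] = (200, 200, 100)
    n_genes: int = 1000
    n_markers_per_cluster: int = 20
    marker_log2fc: float = 2.0
    n_mito_genes: int = 10
    mito_fraction: float = 0.05
    sc_base_mean: float = 0.5
    # bulk
    bulk_n_per_group: int = 15
    bulk_n_genes: int = 400
    bulk_effect: float = 1.0
    bulk_cd4_alpha: tuple[float, ...] = (4.0, 3.0, 3.0)  # CD4, CD8, epithelial

    def __post_init__(self):
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        alpha = np.atleast_1d(np.asarray(self.dirichlet_alpha, dtype=float))
        if (alpha <= 0).any():
            raise ValueError("dirichlet_alpha must be positive")
        if self.n_replicates_per_subtype < 1 or self.n_subtypes < 1:
            raise ValueError("counts used as denominators must be >= 1")
        if self.block_size_range[0] < 1:
            raise ValueError("block sizes must be >= 1")
        if not (0 <= self.mito_fraction < 1):
            raise ValueError("mito_fraction must be in [0, 1)")
        if self.marker_log2fc < 0:
            raise ValueError("marker_log2fc must be >= 0 (markers are up in their cluster)")


@dataclass
class GroundTruth:
    """Planted structure emitted by the generators, consumed by recovery tests."""

    true_proportions: pd.DataFrame | None = None          # mixtures x subtypes
    planted_da_sites: dict[str, float] = field(default_factory=dict)  # key -> log2FC
    planted_specific_sites: dict[str, list[GenomicInterval]] = field(default_factory=dict)
    shared_sites: list[GenomicInterval] = field(default_factory=list)
    enriched_block_ids: list[str] = field(default_factory=list)
    planted_markers: dict[str, list[str]] = field(default_factory=dict)  # cluster -> genes
    planted_bulk_effect: float = 0.0
    true_cd4_fraction: pd.Series | None = None

    def __post_init__(self):
        if self.true_proportions is not None:
            arr = self.true_proportions.to_numpy(float)
            if (arr < 0).any() or not np.allclose(arr.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError("true proportions must lie on the simplex")
        specifics = list(self.planted_specific_sites.values())
        seen: set[GenomicInterval] = set()
        for sites in specifics:
            s = set(sites)
            if s & seen:
                raise ValueError("planted specific sites must be disjoint across subtypes")
            seen |= s


def subtype_names(n: int) -> list[str]:
    if n <= len(SUBTYPE_NAMES):
        return list(SUBTYPE_NAMES[:n])
    return list(SUBTYPE_NAMES) + [f"S{i}" for i in range(len(SUBTYPE_NAMES), n)]


# ---------------------------------------------------------------------------
# 1. Subtype peak landscapes
# ---------------------------------------------------------------------------

def gen_subtype_peak_landscape(
    config: SimulationConfig,
) -> tuple[list[PeakCallSet], GroundTruth]:
    """Replicate peak calls per polarized subtype plus an effector baseline.

    Shared sites appear in every replicate of every condition (effector
    included).  Each subtype-specific site appears in each replicate of its
    own subtype with probability ``1 - dropout_rate`` and never elsewhere.
    Sites are laid out non-overlapping on one synthetic chromosome.
    """
    if config.n_replicates_per_subtype < 3:
        raise ValueError("need >= 3 replicates per subtype for consensus calling")
    rng = _rng(config.seed, "landscape")
    subtypes = subtype_names(config.n_subtypes)

    def site(i: int) -> GenomicInterval:
        start = i * config.site_spacing
        return GenomicInterval("chr1", start, start + config.site_width)

    if config.site_width >= config.site_spacing:
        raise ValueError("site_width must be smaller than site_spacing (interval collision)")

    n_shared = config.n_shared_sites
    shared = [site(i) for i in range(n_shared)]
    specific: dict[str, list[GenomicInterval]] = {}
    pos = n_shared
    for sub in subtypes:
        specific[sub] = [site(i) for i in range(pos, pos + config.n_specific_sites_per_subtype)]
        pos += config.n_specific_sites_per_subtype

    call_sets: list[PeakCallSet] = []
    for sub in subtypes:
        for rep in range(config.n_replicates_per_subtype):
            keep = rng.random(len(specific[sub])) >= config.dropout_rate
            ivs = sorted(shared + [iv for iv, k in zip(specific[sub], keep) if k])
            call_sets.append(PeakCallSet(f"{sub}_rep{rep + 1}", sub, tuple(ivs)))
    for rep in range(config.n_replicates_per_subtype):
        call_sets.append(PeakCallSet(f"{EFFECTOR}_rep{rep + 1}", EFFECTOR, tuple(sorted(shared))))

    truth = GroundTruth(planted_specific_sites=specific, shared_sites=shared)
    return call_sets, truth


# ---------------------------------------------------------------------------
# 2. Accessibility counts
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw with Var = mu + dispersion * mu^2."""
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean / shape)
    return rng.poisson(lam)


def gen_accessibility_counts(
    landscape: Sequence[PeakCallSet],
    truth: GroundTruth,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Peak x sample NB count matrix over the landscape's site catalog.

    A site called in a replicate has expected signal ``base_mean``; an absent
    site falls to ``base_mean / background_fold``.  Per-sample library-size
    factors are lognormal(0, library_sigma).  When ``da_fraction > 0``, that
    fraction of shared sites is shifted by ``da_log2fc`` in the replicates of
    ``da_group`` and recorded in the returned ground truth.
    """
    if config.nb_dispersion <= 0:
        raise ValueError("nb_dispersion must be positive")
    rng = _rng(config.seed, "counts")
    catalog = sorted({iv for pcs in landscape for iv in pcs.intervals})
    keys = [iv.key for iv in catalog]
    row_of = {iv: i for i, iv in enumerate(catalog)}
    n_sites, n_samples = len(catalog), len(landscape)

    base = config.base_mean * np.exp(rng.normal(0.0, 0.25, size=n_sites))
    background = base / config.background_fold
    lib = np.exp(rng.normal(0.0, config.library_sigma, size=n_samples))

    planted: dict[str, float] = {}
    if config.da_fraction > 0 and config.da_log2fc != 0:
        n_da = int(round(config.da_fraction * len(truth.shared_sites)))
        da_idx = rng.choice(len(truth.shared_sites), size=n_da, replace=False)
        for i in da_idx:
            planted[truth.shared_sites[i].key] = config.da_log2fc
    da_group = config.da_group
    if planted and da_group is None:
        da_group = landscape[0].subtype

    mean = np.empty((n_sites, n_samples))
    for j, pcs in enumerate(landscape):
        present = np.zeros(n_sites, dtype=bool)
        present[[row_of[iv] for iv in pcs.intervals]] = True
        mu = np.where(present, base, background)
        if planted and pcs.subtype == da_group:
            key_row = {k: i for i, k in enumerate(keys)}
            for key, lfc in planted.items():
                mu[key_row[key]] *= 2.0**lfc
        mean[:, j] = mu * lib[j]
    counts = _nb_draw(rng, mean, config.nb_dispersion)
    df = pd.DataFrame(counts, index=keys, columns=[p.sample_id for p in landscape])
    return df, replace(truth, planted_da_sites=planted)


# ---------------------------------------------------------------------------
# 3. Mixtures of subtype signatures
# ---------------------------------------------------------------------------

def gen_mixtures(
    signature_matrix: pd.DataFrame,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Synthetic bulk profiles from randomly selected subtype proportions.

    Each profile is ``S @ p`` with ``p ~ Dirichlet(alpha)``, multiplied
    element-wise by lognormal(0, noise_sigma) noise.  Returns the feature x
    mixture profile matrix and the true proportions (mixtures x subtypes).
    """
    S = signature_matrix.to_numpy(float)
    if (S < 0).any():
        raise ValueError("signature matrix must be non-negative")
    n_features, n_subtypes = S.shape
    if n_subtypes < 2:
        raise ValueError("need >= 2 subtypes")
    alpha = np.broadcast_to(
        np.atleast_1d(np.asarray(config.dirichlet_alpha, dtype=float)), (n_subtypes,)
    )
    if (alpha <= 0).any():
        raise ValueError("dirichlet_alpha must be positive")
    rng = _rng(config.seed, "mixtures")
    props = rng.dirichlet(alpha, size=config.n_mixtures)
    clean = props @ S.T  # mixtures x features
    noise = np.exp(rng.normal(0.0, config.noise_sigma, size=clean.shape)) \
        if config.noise_sigma > 0 else 1.0
    profiles = pd.DataFrame(
        (clean * noise).T,
        index=signature_matrix.index,
        columns=[f"mix{i + 1}" for i in range(config.n_mixtures)],
    )
    truth = GroundTruth(
        true_proportions=pd.DataFrame(
            props, index=profiles.columns, columns=signature_matrix.columns
        )
    )
    return profiles, truth


# ---------------------------------------------------------------------------
# 4. LD genome and risk variants
# ---------------------------------------------------------------------------

def gen_ld_genome(config: SimulationConfig) -> pd.DataFrame:
    """Variant catalog partitioned into disjoint LD blocks.

    Returns a DataFrame with columns chrom, pos, variant_id, block_id;
    positions sorted, blocks contiguous and non-overlapping on one synthetic
    chromosome.
    """
    lo, hi = config.block_size_range
    if lo < 1 or hi < lo:
        raise ValueError("invalid block_size_range")
    rng = _rng(config.seed, "ld")
    sizes = rng.integers(lo, hi + 1, size=config.n_blocks)
    rows = []
    pos = 0
    for b, size in enumerate(sizes):
        for _ in range(size):
            rows.append(("chr1", pos, f"rs{pos}", f"block{b}"))
            pos += config.variant_spacing
        pos += config.variant_spacing  # gap between blocks
    return pd.DataFrame(rows, columns=["chrom", "pos", "variant_id", "block_id"])


def _blocks_in_regions(
    catalog: pd.DataFrame, regions: Sequence[GenomicInterval]
) -> np.ndarray:
    """Block ids (unique order) with >= 1 variant inside any region."""
    from .vse import variants_in_regions

    inside = variants_in_regions(catalog, regions)
    return catalog.loc[inside, "block_id"].unique()


def gen_risk_variants(
    ld_genome: pd.DataFrame,
    region_sets: Mapping[str, Sequence[GenomicInterval]],
    config: SimulationConfig,
) -> tuple[list[str], GroundTruth]:
    """Choose risk blocks with excess probability of lying in the target set.

    Each risk block lands inside the target region set with probability
    ``background_rate + enrichment_delta`` (background = fraction of catalog
    blocks overlapping the set).  Returns the chosen risk block ids and the
    ground truth listing which of them overlap the target set.
    """
    if config.target_region_set not in region_sets:
        raise ValueError(f"target region set {config.target_region_set!r} not provided")
    blocks = ld_genome["block_id"].unique()
    if config.n_risk_loci > len(blocks):
        raise ValueError("n_risk_loci exceeds the number of catalog blocks")
    inside = set(_blocks_in_regions(ld_genome, region_sets[config.target_region_set]))
    bg_rate = len(inside) / len(blocks)
    p_in = bg_rate + config.enrichment_delta
    if p_in > 1 + 1e-12:
        raise ValueError("enrichment_delta pushes the overlap probability above 1")
    if config.enrichment_delta > 0 and not inside:
        raise ValueError("no catalog block overlaps the target set; cannot enrich")

    rng = _rng(config.seed, "risk")
    in_blocks = [b for b in blocks if b in inside]
    out_blocks = [b for b in blocks if b not in inside]
    rng.shuffle(in_blocks)
    rng.shuffle(out_blocks)
    chosen: list[str] = []
    for _ in range(config.n_risk_loci):
        take_in = rng.random() < p_in
        if take_in and in_blocks:
            chosen.append(in_blocks.pop())
        elif out_blocks:
            chosen.append(out_blocks.pop())
        else:
            chosen.append(in_blocks.pop())
    truth = GroundTruth(enriched_block_ids=[b for b in chosen if b in inside])
    return chosen, truth


# ---------------------------------------------------------------------------
# 5. Single-cell counts
# ---------------------------------------------------------------------------

def gen_sc_counts(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.Series, GroundTruth]:
    """Clustered gene x cell NB counts with planted markers and mito genes.

    Gene means are lognormal around ``sc_base_mean``; each cluster's markers
    are upregulated by ``marker_log2fc`` (log2) in that cluster only; the
    ``MT-`` genes are scaled so they contribute ``mito_fraction`` of counts in
    expectation; per-cell library factors are lognormal(0, library_sigma).
    """
    if len(config.cluster_sizes) < 2:
        raise ValueError("need >= 2 clusters")
    if config.marker_log2fc < 0:
        raise ValueError("marker_log2fc must be >= 0")
    rng = _rng(config.seed, "sc")
    n_mito = config.n_mito_genes
    n_reg = config.n_genes - n_mito
    genes = [f"G{i + 1}" for i in range(n_reg)] + [f"MT-{i + 1}" for i in range(n_mito)]
    clusters = [f"C{i}" for i in range(len(config.cluster_sizes))]

    base = config.sc_base_mean * np.exp(rng.normal(0.0, 1.0, size=config.n_genes))
    mito_mask = np.array([g.startswith("MT-") for g in genes])
    # scale mito means so that E[mito counts] / E[total counts] = mito_fraction
    if mito_mask.any():
        non_mito_total = base[~mito_mask].sum()
        if config.mito_fraction == 0:
            base[mito_mask] = 0.0
        else:
            target = config.mito_fraction / (1 - config.mito_fraction) * non_mito_total
            base[mito_mask] *= target / base[mito_mask].sum()

    needed = config.n_markers_per_cluster * len(clusters)
    if needed > n_reg:
        raise ValueError(
            f"{needed} marker genes requested but only {n_reg} non-mitochondrial "
            "genes available; disjoint marker sets impossible"
        )
    markers: dict[str, list[str]] = {}
    taken: set[int] = set()
    non_mito_idx = np.flatnonzero(~mito_mask)
    for c in clusters:
        avail = np.array([i for i in non_mito_idx if i not in taken])
        idx = rng.choice(avail, size=config.n_markers_per_cluster, replace=False)
        taken |= set(int(i) for i in idx)
        markers[c] = [genes[i] for i in idx]

    labels, cols = [], []
    blocks = []
    for c, size in zip(clusters, config.cluster_sizes):
        mu = np.tile(base[:, None], (1, size))
        idx = [genes.index(g) for g in markers[c]]
        mu[idx, :] *= 2.0**config.marker_log2fc
        lib = np.exp(rng.normal(0.0, config.library_sigma, size=size))
        blocks.append(_nb_draw(rng, mu * lib, config.nb_dispersion * 4))
        labels += [c] * size
        cols += [f"{c}_cell{i + 1}" for i in range(size)]
    counts = pd.DataFrame(np.concatenate(blocks, axis=1), index=genes, columns=cols)
    truth = GroundTruth(planted_markers=markers)
    return counts, pd.Series(labels, index=cols, name="cluster"), truth


# ---------------------------------------------------------------------------
# 6. Bulk TPM
# ---------------------------------------------------------------------------

def gen_bulk_tpm(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series, GroundTruth]:
    """Bulk TPM matrix as cell-type mixtures with a planted cytotoxic effect.

    Three cell-type profiles (CD4, CD8, Epithelial) mix at Dirichlet-random
    fractions per sample; inflamed-group samples carry a ``bulk_effect``
    (log2) upshift of the cytotoxic genes inside their CD4 component.
    Columns are rescaled to sum to 1e6 (TPM).  Returns (tpm, cell-type
    profile matrix, group labels, ground truth with true CD4 fractions).
    """
    rng = _rng(config.seed, "bulk")
    cell_types = ["CD4", "CD8", "Epithelial"]
    n_genes = config.bulk_n_genes
    genes = list(CYTOTOXIC_GENES) + [f"B{i + 1}" for i in range(n_genes - len(CYTOTOXIC_GENES))]

    profiles = np.exp(rng.normal(2.0, 1.0, size=(n_genes, len(cell_types))))
    # give each cell type a marker block so deconvolution is identifiable
    n_mark = 40
    for k in range(len(cell_types)):
        lo = len(CYTOTOXIC_GENES) + k * n_mark
        profiles[lo : lo + n_mark, k] *= 20.0
    # cytotoxic genes live mostly in the T-cell compartments
    cyto = slice(0, len(CYTOTOXIC_GENES))
    profiles[cyto, 2] *= 0.05
    profile_df = pd.DataFrame(profiles, index=genes, columns=cell_types)

    groups, cols, fracs_list = [], [], []
    tpm_cols = []
    alpha = np.asarray(config.bulk_cd4_alpha, dtype=float)
    for group in ("noninflamed", "inflamed"):
        for i in range(config.bulk_n_per_group):
            frac = rng.dirichlet(alpha)
            prof = profiles.copy()
            if group == "inflamed" and config.bulk_effect != 0:
                prof[cyto, 0] = prof[cyto, 0] * 2.0**config.bulk_effect
            sample = prof @ frac
            if config.noise_sigma > 0:
                sample = sample * np.exp(rng.normal(0.0, config.noise_sigma, size=n_genes))
            tpm_cols.append(sample / sample.sum() * 1e6)
            cols.append(f"{group}_{i + 1}")
            groups.append(group)
            fracs_list.append(frac[0])
    tpm = pd.DataFrame(np.column_stack(tpm_cols), index=genes, columns=cols)
    labels = pd.Series(groups, index=cols, name="group")
    truth = GroundTruth(
        planted_bulk_effect=config.bulk_effect,
        true_cd4_fraction=pd.Series(fracs_list, index=cols, name="cd4_fraction"),
    )
    return tpm, profile_df, labels, truth
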