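"""Single-cell signature scoring: QC, CP10K normalization, mean-centered
signature scores, marker derivation, overlap and co-expression analysis,
cytotoxic-cell classification and preranked gene-set enrichment.

The central quantity is the mean-centered expression

    Er[i, j] = E[i, j] - mean_j(E[i, .])

for gene i in cell j, computed on log(CP10K + 1) values (natural log); a
cell's score for a gene signature is the mean Er over the signature genes
present in the matrix.  Marker tables come from cluster-vs-rest Welch t
tests with Benjamini-Hochberg correction, following the convention of
computing log2 fold changes on expm1-back-transformed group means with a
pseudocount of 1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

CP10K_TOTAL = 10_000.0
MITO_PREFIX = "MT-"

# manually defined signatures of classical markers
CYTOTOXICITY_SIGNATURE = ("GZMA", "GZMB", "GNLY", "IFNG", "PRF1")
TH1_SIGNATURE = ("TNF", "STAT1", "STAT4", "CXCR3", "IFNG")
TH17_SIGNATURE = ("CCR6", "STAT3", "RORA", "IL17A", "RORC")


@dataclass(frozen=True)
class GeneSignature:
    name: str
    genes: tuple[str, ...]

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"signature {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"signature {self.name!r} has duplicate genes")


CYTOTOXIC = GeneSignature("cytotoxicity", CYTOTOXICITY_SIGNATURE)
TH1 = GeneSignature("Th1", TH1_SIGNATURE)
TH17 = GeneSignature("Th17", TH17_SIGNATURE)


@dataclass
class ScoreVector:
    """Per-cell signature scores plus the fraction of signature genes found."""

    name: str
    scores: pd.Series
    coverage: float

    def __post_init__(self):
        if not (0 < self.coverage <= 1):
            raise ValueError("coverage must be in (0, 1]")


# ---------------------------------------------------------------------------
# QC and normalization
# ---------------------------------------------------------------------------

def qc_filter(
    counts: pd.DataFrame,
    min_genes: int = 200,
    max_mito_fraction: float = 1.0,
    mito_genes: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Remove low-quality cells.

    Keeps cells with at least ``min_genes`` genes detected (count > 0) and at
    most ``max_mito_fraction`` of counts in mitochondrial genes (``MT-``
    prefix unless ``mito_genes`` given).  Returns the filtered matrix and a
    report with per-criterion removal counts.
    """
    if min_genes < 0 or max_mito_fraction < 0:
        raise ValueError("thresholds must be >= 0")
    if mito_genes is None:
        mito_genes = [g for g in counts.index if str(g).startswith(MITO_PREFIX)]
    detected = (counts > 0).sum(axis=0)
    totals = counts.sum(axis=0)
    mito = counts.loc[counts.index.intersection(mito_genes)].sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = (mito / totals).fillna(0.0)
    low_genes = detected < min_genes
    high_mito = mito_frac > max_mito_fraction
    keep = ~(low_genes | high_mito)
    if not keep.any():
        raise ValueError("QC removed every cell; review min_genes / max_mito_fraction")
    report = {
        "n_input": int(counts.shape[1]),
        "n_kept": int(keep.sum()),
        "removed_low_genes": int(low_genes.sum()),
        "removed_high_mito": int(high_mito.sum()),
        "removed_total": int((~keep).sum()),
    }
    return counts.loc[:, keep], report


def normalize_cp10k(counts: pd.DataFrame) -> pd.DataFrame:
    """log(CP10K + 1): counts scaled to 10,000 per cell, natural-log transformed."""
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        bad = list(totals.index[totals == 0])[:3]
        raise ValueError(f"all-zero cells present (run QC first): {bad}")
    return np.log1p(counts / totals * CP10K_TOTAL)


def center_genes(matrix: pd.DataFrame) -> pd.DataFrame:
    """Mean-center each gene across cells: Er = E - rowmean(E)."""
    if matrix.shape[1] < 2:
        raise ValueError("centering needs >= 2 cells")
    return matrix.sub(matrix.mean(axis=1), axis=0)


def score_signature(centered: pd.DataFrame, signature: GeneSignature) -> ScoreVector:
    """Per-cell mean Er over the signature genes present in the matrix.

    Genes absent from the matrix are dropped (coverage records the fraction
    found); zero coverage is an error naming the missing genes.
    """
    present = [g for g in signature.genes if g in centered.index]
    if not present:
        raise ValueError(
            f"no gene of signature {signature.name!r} found in matrix: "
            f"{list(signature.genes)}"
        )
    coverage = len(present) / len(signature.genes)
    if coverage < 1:
        logger.info("signature %s: %d/%d genes present",
                    signature.name, len(present), len(signature.genes))
    scores = centered.loc[present].mean(axis=0)
    return ScoreVector(name=signature.name, scores=scores, coverage=coverage)


# ---------------------------------------------------------------------------
# Marker derivation
# ---------------------------------------------------------------------------

def _welch_t(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Welch two-sided t-test p-values; ties with zero variance -> 1."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    zero_var = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    equal_mean = np.isclose(a.mean(axis=1), b.mean(axis=1))
    p = np.where(zero_var & equal_mean, 1.0, p)
    p = np.where(zero_var & ~equal_mean, 0.0, p)
    return np.nan_to_num(p, nan=1.0)


def _log2fc_backtransformed(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """log2 FC of expm1-back-transformed group means, pseudocount 1 (a over b)."""
    return np.log2((np.expm1(a).mean(axis=1) + 1) / (np.expm1(b).mean(axis=1) + 1))


def find_markers(
    normalized: pd.DataFrame,
    cluster_labels: Mapping[str, str] | pd.Series,
    lfc_threshold: float = 0.5,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Cluster-vs-rest marker genes on log-normalized expression.

    Per cluster, each gene gets a Welch two-sided t test against all other
    cells; BH correction runs across genes within the cluster; reported
    markers satisfy |log2FC| > lfc_threshold and adjusted p < fdr_threshold.
    Columns: cluster, gene, log2_fold_change, p_value, fdr, direction.
    """
    labels = pd.Series(dict(cluster_labels) if not isinstance(cluster_labels, pd.Series)
                       else cluster_labels)[normalized.columns]
    clusters = sorted(labels.unique())
    if len(clusters) < 2:
        raise ValueError("need >= 2 clusters")
    rows = []
    X = normalized.to_numpy(float)
    for c in clusters:
        mask = (labels == c).to_numpy()
        if mask.sum() < 3:
            raise ValueError(f"cluster {c!r} has < 3 cells")
        a, b = X[:, mask], X[:, ~mask]
        p = _welch_t(a, b)
        lfc = _log2fc_backtransformed(a, b)
        fdr = multipletests(p, method="fdr_bh")[1]
        sig = (np.abs(lfc) > lfc_threshold) & (fdr < fdr_threshold)
        for i in np.flatnonzero(sig):
            rows.append((c, normalized.index[i], float(lfc[i]), float(p[i]),
                         float(fdr[i]), "up" if lfc[i] > 0 else "down"))
    return pd.DataFrame(
        rows, columns=["cluster", "gene", "log2_fold_change", "p_value", "fdr", "direction"]
    )


def derive_reference_signatures(
    reference: pd.DataFrame,
    subset_labels: Mapping[str, str] | pd.Series,
    lfc_threshold: float = 1.0,
    fdr_threshold: float = 0.05,
) -> dict[str, GeneSignature]:
    """Subset-specific gene signatures from a labelled reference matrix.

    Each subset is compared to all other samples with a two-sided t test;
    a subset's signature is the genes with log2 FC > lfc_threshold (up only)
    and BH-adjusted p < fdr_threshold.  A gene may appear in several
    signatures.  Subsets with an empty result map to no signature.
    """
    labels = pd.Series(dict(subset_labels) if not isinstance(subset_labels, pd.Series)
                       else subset_labels)[reference.columns]
    X = reference.to_numpy(float)
    signatures: dict[str, GeneSignature] = {}
    for subset in sorted(labels.unique()):
        mask = (labels == subset).to_numpy()
        if mask.sum() < 3:
            raise ValueError(f"subset {subset!r} has < 3 samples")
        a, b = X[:, mask], X[:, ~mask]
        p = _welch_t(a, b)
        lfc = np.log2((a.mean(axis=1) + 1) / (b.mean(axis=1) + 1))
        fdr = multipletests(p, method="fdr_bh")[1]
        genes = tuple(reference.index[(lfc > lfc_threshold) & (fdr < fdr_threshold)])
        if genes:
            signatures[subset] = GeneSignature(name=subset, genes=genes)
        else:
            logger.info("subset %s: no signature genes at the thresholds", subset)
    return signatures


# ---------------------------------------------------------------------------
# Overlap, co-expression, classification
# ---------------------------------------------------------------------------

def hypergeom_overlap(
    sig_a: Sequence[str], sig_b: Sequence[str], universe_size: int
) -> tuple[float, int]:
    """Upper-tail hypergeometric p of the overlap between two gene sets.

    P(X >= overlap) with X ~ Hypergeom(universe_size, |a|, |b|).
    """
    a, b = set(sig_a), set(sig_b)
    if len(a) > universe_size or len(b) > universe_size:
        raise ValueError("signature larger than the gene universe")
    overlap = len(a & b)
    if overlap > min(len(a), len(b)):
        raise ValueError("overlap exceeds the smaller set: duplicated ids?")
    p = float(stats.hypergeom.sf(overlap - 1, universe_size, len(a), len(b)))
    return p, overlap


def coexpression_fraction(
    score_a: ScoreVector,
    score_b: ScoreVector,
    threshold: float = 0.0,
    group_labels: pd.Series | None = None,
) -> float | pd.Series:
    """Fraction of cells with both signature scores above ``threshold``."""
    if not score_a.scores.index.equals(score_b.scores.index):
        raise ValueError("score vectors are not aligned on the same cells")
    both = (score_a.scores > threshold) & (score_b.scores > threshold)
    if group_labels is not None:
        return both.groupby(group_labels[both.index]).mean()
    return float(both.mean())


def classify_cytotoxic(
    normalized: pd.DataFrame,
    signature: GeneSignature = CYTOTOXIC,
    min_genes_detected: int = 2,
) -> pd.Series:
    """Boolean per cell: co-expresses the cytotoxic program.

    A cell is positive when at least ``min_genes_detected`` signature genes
    have nonzero normalized expression AND its signature score (on the
    centered matrix) is positive.
    """
    present = [g for g in signature.genes if g in normalized.index]
    if not present:
        raise ValueError(f"signature genes absent from matrix: {signature.genes}")
    detected = (normalized.loc[present] > 0).sum(axis=0) >= min_genes_detected
    score = score_signature(center_genes(normalized), signature).scores > 0
    return (detected & score).rename("cytotoxic")


# ---------------------------------------------------------------------------
# Preranked GSEA
# ---------------------------------------------------------------------------

def preranked_gsea(
    ranked_stats: pd.Series,
    gene_set: Sequence[str],
    weight_exponent: float = 1.0,
    n_permutations: int = 1000,
    seed: int | None = None,
) -> dict:
    """Running-sum enrichment of a gene set in a ranked gene list.

    Genes are ordered by decreasing statistic.  Walking down the list, a hit
    adds |stat|^weight (normalized over hits) and every position subtracts
    the uniform 1/N; the enrichment score (ES) is the maximum deviation from
    zero.  The null distribution comes from random gene-label sets of the
    same size; NES = ES / mean(|null ES| of the same sign) and the p-value is
    the add-one empirical tail probability among same-sign null scores.
    """
    if ranked_stats.index.duplicated().any():
        raise ValueError("duplicate gene ids in ranking")
    genes_in_set = [g for g in set(gene_set) if g in ranked_stats.index]
    if not genes_in_set:
        raise ValueError("gene set shares no genes with the ranking")
    n = len(ranked_stats)
    k = len(genes_in_set)
    if k == n:
        raise ValueError("gene set covers the whole ranking: no misses to walk")

    order = ranked_stats.sort_values(ascending=False)
    stat = np.abs(order.to_numpy(float)) ** weight_exponent
    hit = order.index.isin(genes_in_set)

    def es_of(hit_mask: np.ndarray) -> float:
        w = np.where(hit_mask, stat, 0.0)
        total = w.sum()
        inc = w / total if total > 0 else hit_mask / hit_mask.sum()
        running = np.cumsum(inc - 1.0 / n)
        i = int(np.argmax(np.abs(running)))
        return float(running[i])

    es = es_of(hit)

    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        mask = np.zeros(n, dtype=bool)
        mask[rng.choice(n, size=k, replace=False)] = True
        null[i] = es_of(mask)
    same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
    denom = np.abs(same_sign).mean() if same_sign.size else np.nan
    nes = es / denom if denom and not np.isnan(denom) else np.nan
    p = (1 + int((np.abs(same_sign) >= abs(es)).sum())) / (1 + same_sign.size)
    return {"es": es, "nes": float(nes), "p_value": float(p),
            "n_genes": n, "n_hits": k}
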