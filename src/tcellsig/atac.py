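"""Chromatin-accessibility signature construction for CD4 T-cell subtypes.

This module works on ATAC-seq peak calls (0-based, half-open BED intervals) and
peak-by-sample accessibility matrices.  It builds a merged peak catalog across
samples, calls consensus sites per condition (a site must be detected in a
minimum fraction of replicates), derives the gained / lost / subtype-specific
site sets of each in-vitro polarized subtype relative to an effector baseline,
runs a simplified negative-binomial differential-accessibility test, annotates
peaks against gene models and links peaks to genes (promoter / exon overlap,
plus correlation-based distal linking).

Coordinates are 0-based half-open throughout; an overlap of >= 1 bp counts as
detection.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

# Promoter window, in bp around the TSS (upstream, downstream on the coding strand)
PROMOTER_UPSTREAM = 2500
PROMOTER_DOWNSTREAM = 500

# Default consensus fraction: a site must be called in >= 2/3 of replicates
DEFAULT_MIN_FRACTION = 2.0 / 3.0


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

class GenomicInterval(NamedTuple):
    """A 0-based half-open genomic interval [start, end)."""

    chrom: str
    start: int
    end: int

    def validate(self) -> "GenomicInterval":
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"malformed interval {self.chrom}:{self.start}-{self.end}")
        return self

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def parse_interval_key(key: str) -> GenomicInterval:
    chrom, span = key.rsplit(":", 1)
    start, end = span.split("-")
    return GenomicInterval(chrom, int(start), int(end)).validate()


@dataclass(frozen=True)
class PeakCallSet:
    """Peak calls of one replicate sample: sorted, non-overlapping intervals."""

    sample_id: str
    subtype: str
    intervals: tuple[GenomicInterval, ...]

    def __post_init__(self):
        prev: GenomicInterval | None = None
        for iv in self.intervals:
            try:
                iv.validate()
            except ValueError as exc:
                raise ValueError(f"sample {self.sample_id}: {exc}") from exc
            if prev is not None and prev.chrom == iv.chrom:
                if iv.start < prev.start:
                    raise ValueError(f"sample {self.sample_id}: intervals not sorted")
                if iv.start < prev.end:
                    raise ValueError(
                        f"sample {self.sample_id}: overlapping intervals "
                        f"{prev.key} and {iv.key}"
                    )
            prev = iv


@dataclass
class AccessibilityMatrix:
    """Peak catalog x samples matrix of non-negative accessibility values.

    ``data`` rows are indexed by interval keys ("chrom:start-end") in catalog
    order; values may be raw read counts or fold enrichment over background.
    """

    catalog: list[GenomicInterval]
    data: pd.DataFrame

    def __post_init__(self):
        if list(self.data.index) != [iv.key for iv in self.catalog]:
            raise ValueError("data index must match catalog order")
        if (self.data.values < 0).any():
            raise ValueError("accessibility values must be non-negative")
        if self.data.columns.duplicated().any():
            raise ValueError("duplicate sample ids")

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    tss: int
    exons: tuple[GenomicInterval, ...] = ()

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: unknown strand {self.strand!r}")

    def promoter_window(
        self,
        upstream: int = PROMOTER_UPSTREAM,
        downstream: int = PROMOTER_DOWNSTREAM,
    ) -> GenomicInterval:
        """Promoter interval: ``upstream`` bp 5' of the TSS to ``downstream`` bp 3'.

        On the minus strand the window is mirrored around the TSS base.
        Clipped at coordinate 0.
        """
        if self.strand == "+":
            start, end = self.tss - upstream, self.tss + downstream
        else:
            start, end = self.tss - downstream + 1, self.tss + upstream + 1
        return GenomicInterval(self.chrom, max(0, start), max(1, end))

    @property
    def span(self) -> GenomicInterval:
        if self.exons:
            lo = min(e.start for e in self.exons)
            hi = max(e.end for e in self.exons)
            return GenomicInterval(self.chrom, min(lo, self.tss), max(hi, self.tss + 1))
        return GenomicInterval(self.chrom, self.tss, self.tss + 1)


# ---------------------------------------------------------------------------
# Interval set algebra
# ---------------------------------------------------------------------------

def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union-merge intervals: transitively overlapping runs collapse to one.

    Output is sorted by (chrom, start) and non-overlapping.  Bookended
    intervals ([10,20) and [20,30)) merge into one covered run, matching
    per-base-pair coverage semantics.
    """
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in ivs:
        iv.validate()
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            merged[-1] = GenomicInterval(last.chrom, last.start, max(last.end, iv.end))
        else:
            merged.append(iv)
    return merged


def merge_catalog(peak_call_sets: Sequence[PeakCallSet]) -> list[GenomicInterval]:
    """Merged union of peaks across all samples (the peak catalog)."""
    all_ivs: list[GenomicInterval] = []
    for pcs in peak_call_sets:
        for iv in pcs.intervals:
            if iv.start >= iv.end:
                raise ValueError(f"sample {pcs.sample_id}: malformed interval {iv}")
            all_ivs.append(iv)
    return merge_intervals(all_ivs)


class _IntervalIndex:
    """Per-chromosome start-sorted arrays with prefix-max ends.

    An interval overlaps the query iff some stored interval has
    start < q.end and end > q.start; with starts sorted, the prefix maximum
    of ends answers that in one binary search, whether or not the stored
    intervals overlap each other.
    """

    def __init__(self, intervals: Iterable[GenomicInterval]):
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        grouped: dict[str, list[GenomicInterval]] = {}
        for iv in intervals:
            grouped.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in grouped.items():
            ivs = sorted(ivs, key=lambda x: x.start)
            starts = np.array([i.start for i in ivs], dtype=np.int64)
            ends = np.maximum.accumulate(np.array([i.end for i in ivs], dtype=np.int64))
            self._by_chrom[chrom] = (starts, ends)

    def overlaps(self, iv: GenomicInterval) -> bool:
        entry = self._by_chrom.get(iv.chrom)
        if entry is None:
            return False
        starts, max_ends = entry
        j = int(np.searchsorted(starts, iv.end, side="left")) - 1
        return j >= 0 and bool(max_ends[j] > iv.start)


def _overlap_flags(catalog: Sequence[GenomicInterval],
                   intervals: Iterable[GenomicInterval]) -> np.ndarray:
    """Boolean per catalog interval: does any query interval overlap it."""
    idx = _IntervalIndex(intervals)
    return np.array([idx.overlaps(iv) for iv in catalog], dtype=bool)


def consensus_sites(
    peak_call_sets: Sequence[PeakCallSet],
    min_fraction: float = DEFAULT_MIN_FRACTION,
    catalog: Sequence[GenomicInterval] | None = None,
) -> list[GenomicInterval]:
    """Catalog sites detected in at least ``ceil(min_fraction * n)`` replicates.

    ``catalog`` defaults to the merged union of the replicates themselves; pass
    a shared catalog when consensus sets of different conditions must live on
    common coordinates.
    """
    if not peak_call_sets:
        raise ValueError("at least one replicate required")
    if not (0 < min_fraction <= 1):
        raise ValueError("min_fraction must be in (0, 1]")
    if catalog is None:
        catalog = merge_catalog(peak_call_sets)
    n = len(peak_call_sets)
    required = math.ceil(min_fraction * n)
    counts = np.zeros(len(catalog), dtype=int)
    for pcs in peak_call_sets:
        counts += _overlap_flags(catalog, pcs.intervals)
    return [iv for iv, c in zip(catalog, counts) if c >= required]


def gained_lost(
    subtype_consensus: Iterable[GenomicInterval],
    effector_consensus: Iterable[GenomicInterval],
) -> tuple[list[GenomicInterval], list[GenomicInterval]]:
    """Sites gained (subtype not effector) and lost (effector not subtype).

    Both inputs must come from the same catalog so that identical sites share
    identical coordinates; the difference is exact set difference.
    """
    sub = set(subtype_consensus)
    eff = set(effector_consensus)
    gained = sorted(sub - eff)
    lost = sorted(eff - sub)
    return gained, lost


def subtype_specific(
    gained_by_subtype: Mapping[str, Iterable[GenomicInterval]],
) -> dict[str, list[GenomicInterval]]:
    """Gained sites unique to each subtype (gained by no other subtype)."""
    if len(gained_by_subtype) < 2:
        raise ValueError("need gained sets for at least 2 subtypes")
    sets = {k: set(v) for k, v in gained_by_subtype.items()}
    specific: dict[str, list[GenomicInterval]] = {}
    for sub, g in sets.items():
        others: set[GenomicInterval] = set()
        for o, og in sets.items():
            if o != sub:
                others |= og
        specific[sub] = sorted(g - others)
    return specific


def pairwise_jaccard(
    sets_by_subtype: Mapping[str, Iterable],
) -> pd.DataFrame:
    """Symmetric Jaccard similarity |A n B| / |A u B| between subtype sets.

    Two empty sets get similarity 0 (logged), including on the diagonal.
    """
    names = list(sets_by_subtype)
    sets = {k: set(v) for k, v in sets_by_subtype.items()}
    mat = pd.DataFrame(0.0, index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i:]:
            union = sets[a] | sets[b]
            if not union:
                logger.info("jaccard(%s, %s): both sets empty, similarity := 0", a, b)
                val = 0.0
            else:
                val = len(sets[a] & sets[b]) / len(union)
            mat.loc[a, b] = mat.loc[b, a] = val
    return mat


# ---------------------------------------------------------------------------
# Differential accessibility (simplified NB Wald test)
# ---------------------------------------------------------------------------

def tmm_factors(counts: pd.DataFrame, trim_m: float = 0.3, trim_a: float = 0.05) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors (geometric mean 1).

    The reference sample is the one whose upper-quartile/library-size ratio is
    closest to the mean ratio.  M (log ratio) and A (log abundance) values of
    peaks expressed in both samples are doubly trimmed before averaging.
    """
    lib = counts.sum(axis=0).astype(float)
    if (lib == 0).any():
        raise ValueError("sample with zero total counts")
    uq = counts.apply(lambda c: np.quantile(c[c > 0], 0.75) if (c > 0).any() else 0.0)
    ratio = uq / lib
    ref = (ratio - ratio.mean()).abs().idxmin()
    ref_cpm = counts[ref].to_numpy(float) / lib[ref]
    factors = {}
    for s in counts.columns:
        if s == ref:
            factors[s] = 1.0
            continue
        cpm = counts[s].to_numpy(float) / lib[s]
        ok = (cpm > 0) & (ref_cpm > 0)
        if ok.sum() < 10:
            factors[s] = 1.0
            continue
        m = np.log2(cpm[ok] / ref_cpm[ok])
        a = 0.5 * np.log2(cpm[ok] * ref_cpm[ok])
        keep = np.ones(m.size, dtype=bool)
        for vals, trim in ((m, trim_m), (a, trim_a)):
            lo, hi = np.quantile(vals, [trim, 1 - trim])
            keep &= (vals >= lo) & (vals <= hi)
        factors[s] = float(2 ** np.mean(m[keep])) if keep.any() else 1.0
    f = pd.Series(factors)[counts.columns]
    return f / np.exp(np.mean(np.log(f)))


@dataclass
class DifferentialResult:
    """Per-peak differential accessibility table.

    ``table`` columns: log2_fold_change, p_value, fdr, direction, significant.
    ``contrast`` records which group label the fold change is "up" in.
    """

    table: pd.DataFrame
    contrast: tuple[str, str]  # (baseline, comparison)


def differential_accessibility(
    counts: AccessibilityMatrix | pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    min_abs_log2fc: float = 1.0,
    fdr_threshold: float = 0.05,
    prior_df: float = 20.0,
    pseudocount: float = 0.5,
) -> DifferentialResult:
    """Simplified negative-binomial Wald test between two sample groups.

    Counts are TMM-normalized; a per-peak dispersion is estimated by the
    method of moments and shrunk toward the common (median) dispersion with
    ``prior_df`` prior degrees of freedom; the Wald statistic tests the log2
    fold change (comparison over baseline group, labels in sorted order) with
    a delta-method standard error; Benjamini-Hochberg FDR across peaks.
    All-zero peaks get p = 1 and are excluded from the FDR ranking.
    """
    df = counts.data if isinstance(counts, AccessibilityMatrix) else counts
    g = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
    g = g[df.columns]
    levels = sorted(g.unique())
    if len(levels) != 2:
        raise ValueError(f"exactly two groups required, got {levels}")
    base, comp = levels
    cols_a = g.index[g == base]
    cols_b = g.index[g == comp]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("each group needs >= 2 samples for a dispersion estimate")
    vals = df.to_numpy(float)
    if not np.allclose(vals, np.round(vals)):
        raise ValueError("differential accessibility expects integer read counts")

    factors = tmm_factors(df)
    eff_lib = df.sum(axis=0).astype(float) * factors
    scale = float(np.exp(np.mean(np.log(eff_lib))))
    norm = df / eff_lib * scale

    a = norm[cols_a].to_numpy(float)
    b = norm[cols_b].to_numpy(float)
    na, nb = a.shape[1], b.shape[1]
    mu_a, mu_b = a.mean(axis=1), b.mean(axis=1)
    var_a, var_b = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        phi_raw = ((na - 1) * (var_a - mu_a) / mu_a**2
                   + (nb - 1) * (var_b - mu_b) / mu_b**2) / (na + nb - 2)
    expressed = (mu_a + mu_b) > 0
    phi_raw = np.clip(np.nan_to_num(phi_raw, nan=0.0, posinf=0.0), 0.0, None)
    common = float(np.median(phi_raw[expressed])) if expressed.any() else 0.0
    resid_df = na + nb - 2
    phi = (prior_df * common + resid_df * phi_raw) / (prior_df + resid_df)

    lfc = np.log2((mu_b + pseudocount) / (mu_a + pseudocount))
    var_log_a = (1.0 / (mu_a + pseudocount) + phi) / na
    var_log_b = (1.0 / (mu_b + pseudocount) + phi) / nb
    se_lfc = np.sqrt(var_log_a + var_log_b) / np.log(2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se_lfc > 0, lfc / se_lfc, 0.0)
    p = 2 * stats.norm.sf(np.abs(z))
    p[~expressed] = 1.0

    fdr = np.ones_like(p)
    if expressed.any():
        fdr[expressed] = multipletests(p[expressed], method="fdr_bh")[1]
    direction = np.where(lfc > 0, f"up_in_{comp}", np.where(lfc < 0, f"up_in_{base}", "none"))
    significant = (fdr < fdr_threshold) & (np.abs(lfc) >= min_abs_log2fc) & expressed
    table = pd.DataFrame(
        {
            "log2_fold_change": lfc,
            "p_value": p,
            "fdr": fdr,
            "direction": direction,
            "significant": significant,
        },
        index=df.index,
    )
    return DifferentialResult(table=table, contrast=(base, comp))


# ---------------------------------------------------------------------------
# Peak annotation and peak-to-gene linking
# ---------------------------------------------------------------------------

def _overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def annotate_peaks(
    catalog: Sequence[GenomicInterval],
    gene_models: Sequence[GeneModel],
) -> pd.Series:
    """Classify each peak as promoter, exon, intron or intergenic.

    Promoter windows span 2.5 kb upstream to 0.5 kb downstream of the TSS
    (strand-aware); precedence promoter > exon > intron > intergenic, where
    intron means inside a gene span without touching an exon or promoter.
    """
    promoters = _IntervalIndex(g.promoter_window() for g in gene_models)
    exons = _IntervalIndex(e for g in gene_models for e in g.exons)
    spans = _IntervalIndex(g.span for g in gene_models)
    labels = []
    for iv in catalog:
        if promoters.overlaps(iv):
            labels.append("promoter")
        elif exons.overlaps(iv):
            labels.append("exon")
        elif spans.overlaps(iv):
            labels.append("intron")
        else:
            labels.append("intergenic")
    return pd.Series(labels, index=[iv.key for iv in catalog], name="feature_class")


def peak_to_gene_links(
    catalog: Sequence[GenomicInterval],
    gene_models: Sequence[GeneModel],
    accessibility: AccessibilityMatrix | None = None,
    corr_threshold: float = 0.7,
    max_distance: int = 500_000,
) -> pd.DataFrame:
    """Associate peaks with genes.

    Promoter and exon links require literal overlap.  Distal links follow the
    correlation strategy of linking distal elements to promoters: a peak within
    ``max_distance`` of a gene's TSS is linked when the Pearson correlation
    (across samples) between its accessibility and the mean accessibility of
    the gene's promoter peaks reaches ``corr_threshold``.  Distal linking
    needs an accessibility matrix with >= 8 samples, otherwise it is disabled
    with a warning.  Returns columns: peak, gene_id, link_class, correlation.
    """
    records: list[tuple[str, str, str, float]] = []
    do_distal = accessibility is not None and len(accessibility.samples) >= 8
    if accessibility is not None and not do_distal:
        warnings.warn("fewer than 8 samples: distal linking disabled", stacklevel=2)
    sig = accessibility.data.to_numpy(float) if accessibility is not None else None
    row_of = {iv.key: i for i, iv in enumerate(catalog)}

    for gene in gene_models:
        prom = gene.promoter_window()
        prom_rows: list[int] = []
        linked_here: set[str] = set()
        for iv in catalog:
            if _overlaps(iv, prom):
                records.append((iv.key, gene.gene_id, "promoter", float("nan")))
                linked_here.add(iv.key)
                prom_rows.append(row_of[iv.key])
        for iv in catalog:
            if iv.key not in linked_here and any(_overlaps(iv, e) for e in gene.exons):
                records.append((iv.key, gene.gene_id, "exon", float("nan")))
                linked_here.add(iv.key)
        if not do_distal:
            continue
        if not prom_rows:
            logger.info("gene %s has no promoter peak: no distal links", gene.gene_id)
            continue
        prom_signal = sig[prom_rows].mean(axis=0)
        if np.std(prom_signal) == 0:
            continue
        for iv in catalog:
            if iv.key in linked_here or iv.chrom != gene.chrom:
                continue
            dist = max(iv.start - gene.tss, gene.tss - (iv.end - 1), 0)
            if dist > max_distance:
                continue
            peak_signal = sig[row_of[iv.key]]
            if np.std(peak_signal) == 0:
                continue
            r = float(np.corrcoef(peak_signal, prom_signal)[0, 1])
            if r >= corr_threshold:
                records.append((iv.key, gene.gene_id, "distal", r))
    return pd.DataFrame(records, columns=["peak", "gene_id", "link_class", "correlation"])


# ---------------------------------------------------------------------------
# Region-set summaries and rank tests
# ---------------------------------------------------------------------------

def mean_fold_enrichment(
    accessibility: AccessibilityMatrix,
    region_set: Sequence[GenomicInterval],
    samples: Sequence[str] | None = None,
) -> pd.Series:
    """Per-sample arithmetic mean signal over the rows of ``region_set``."""
    if len(region_set) == 0:
        raise ValueError("empty region set")
    keys = [iv.key for iv in region_set]
    missing = set(keys) - set(accessibility.data.index)
    if missing:
        raise ValueError(f"region set contains intervals outside the catalog: {sorted(missing)[:3]}")
    sub = accessibility.data.loc[keys]
    if samples is not None:
        sub = sub[list(samples)]
    return sub.mean(axis=0)


def rank_compare(
    values_a: Sequence[float],
    values_b: Sequence[float],
    paired: bool = False,
) -> tuple[float, float]:
    """Two-sided rank test between two groups of accessibility summaries.

    Paired mode runs the Wilcoxon signed-rank test on matched samples;
    unpaired mode the Mann-Whitney rank-sum test.  All-tied inputs yield
    p = 1 with a warning.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need >= 3 observations per group")
    if paired:
        if len(a) != len(b):
            raise ValueError("paired test needs equal-length groups")
        if np.all(a == b):
            warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
            return 0.0, 1.0
        stat, p = stats.wilcoxon(a, b, alternative="two-sided")
        return float(stat), float(p)
    if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
        warnings.warn("all observations tied; p = 1", stacklevel=2)
        return float(len(a) * len(b) / 2), 1.0
    stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(stat), float(p)
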