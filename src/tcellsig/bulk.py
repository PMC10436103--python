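"""Cytotoxic-CD4 scoring of bulk tissue transcriptomes.

To score a cytotoxic CD4 T-cell signature in whole-tissue RNA-seq while
controlling for signal from other compartments, each sample's TPM profile is
first weighted by its estimated CD4 T-cell fraction (from the deconvolution
engine against an immune signature matrix with labelled CD4 columns; samples
whose deconvolution permutation p exceeds a threshold are excluded), then
log2(x + 1) transformed, mean-centered per gene across the retained samples,
and summarized as the mean centered value over the signature genes.  Group
comparisons use a Welch two-sided t test (two groups) or one-way ANOVA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .deconvolution import deconvolve
from .singlecell import GeneSignature

logger = logging.getLogger(__name__)

TPM_TOTAL = 1e6


def validate_tpm(tpm: pd.DataFrame, rtol: float = 1e-6) -> pd.DataFrame:
    if (tpm.values < 0).any():
        raise ValueError("TPM values must be non-negative")
    sums = tpm.sum(axis=0)
    if not np.allclose(sums, TPM_TOTAL, rtol=rtol):
        bad = list(sums.index[~np.isclose(sums, TPM_TOTAL, rtol=rtol)])[:3]
        raise ValueError(f"TPM columns must sum to 1e6: {bad}")
    return tpm


@dataclass
class FractionEstimates:
    """Per-sample CD4 fraction, deconvolution p-value and exclusion flag."""

    table: pd.DataFrame  # columns: cd4_fraction, p_value, excluded
    p_exclusion: float

    @property
    def retained(self) -> pd.Index:
        return self.table.index[~self.table["excluded"]]


def estimate_cd4_fraction(
    bulk: pd.DataFrame,
    immune_signature: pd.DataFrame,
    cd4_columns: Sequence[str],
    p_exclusion: float = 0.05,
    n_permutations: int = 0,
    engine: str = "nnls",
    seed: int = 0,
) -> FractionEstimates:
    """Deconvolve each bulk sample and sum the CD4-labelled proportions.

    The CD4 fraction of a sample is the sum of proportions over
    ``cd4_columns`` of the immune signature.  With ``n_permutations > 0``,
    samples whose permutation p exceeds ``p_exclusion`` are flagged excluded;
    with 0 permutations no sample is excluded (p is NaN).
    """
    missing = [c for c in cd4_columns if c not in immune_signature.columns]
    if missing or not cd4_columns:
        raise ValueError(f"no CD4-labelled signature column among {list(cd4_columns)}")
    common = immune_signature.index.intersection(bulk.index)
    if len(common) == 0:
        raise ValueError("bulk matrix shares no genes with the immune signature")
    S = immune_signature.loc[common]
    rows = []
    seeds = np.random.SeedSequence([seed, 7]).generate_state(bulk.shape[1])
    for i, sample in enumerate(bulk.columns):
        res = deconvolve(
            bulk.loc[common, sample], S, engine=engine,
            n_permutations=n_permutations, seed=int(seeds[i] % (2**31)),
        )
        frac = float(res.proportions[list(cd4_columns)].sum())
        p = res.p_value if res.p_value is not None else np.nan
        rows.append((sample, frac, p))
    table = pd.DataFrame(rows, columns=["sample", "cd4_fraction", "p_value"]).set_index("sample")
    table["excluded"] = table["p_value"] > p_exclusion
    n_excluded = int(table["excluded"].sum())
    if n_excluded:
        logger.info("%d samples excluded at deconvolution p > %g", n_excluded, p_exclusion)
    return FractionEstimates(table=table, p_exclusion=p_exclusion)


def cd4_weighted_expression(
    bulk: pd.DataFrame, fractions: FractionEstimates
) -> pd.DataFrame:
    """Multiply each retained sample's TPM column by its CD4 fraction."""
    missing = set(bulk.columns) - set(fractions.table.index)
    if missing:
        raise ValueError(f"no fraction estimate for samples: {sorted(missing)[:3]}")
    excluded = [s for s in bulk.columns if bool(fractions.table.loc[s, "excluded"])]
    if excluded:
        raise ValueError(
            f"excluded samples requested: {excluded[:3]}; drop them first"
        )
    fr = fractions.table.loc[bulk.columns, "cd4_fraction"]
    return bulk * fr


@dataclass
class ScoredSamples:
    scores: pd.Series
    groups: pd.Series
    coverage: float


def tissue_score(
    weighted: pd.DataFrame,
    signature: GeneSignature,
    group_labels: Mapping[str, str] | pd.Series | None = None,
) -> ScoredSamples:
    """Cytotoxic tissue score: mean per-gene-centered log2(x+1) over signature genes.

    Centering uses only the samples present in ``weighted`` (i.e. the
    retained ones), so each gene's centered values average to zero across
    retained samples.
    """
    if weighted.shape[1] < 2:
        raise ValueError("need >= 2 retained samples")
    present = [g for g in signature.genes if g in weighted.index]
    if not present:
        raise ValueError(f"no signature gene present in the matrix: {signature.genes}")
    logx = np.log2(weighted + 1.0)
    centered = logx.sub(logx.mean(axis=1), axis=0)
    scores = centered.loc[present].mean(axis=0)
    groups = (
        pd.Series(dict(group_labels) if not isinstance(group_labels, pd.Series) else group_labels)
        [weighted.columns]
        if group_labels is not None
        else pd.Series("all", index=weighted.columns)
    )
    return ScoredSamples(scores=scores, groups=groups,
                         coverage=len(present) / len(signature.genes))


def compare_score_groups(scored: ScoredSamples, mode: str = "auto") -> dict:
    """Compare tissue scores between groups.

    ``two_group`` runs a Welch two-sided t test, ``multi_group`` a one-way
    ANOVA F test; ``auto`` picks by the number of groups.  Identical groups
    with zero variance yield p = 1 by convention.
    """
    levels = sorted(scored.groups.unique())
    if mode == "auto":
        mode = "two_group" if len(levels) == 2 else "multi_group"
    arrays = [scored.scores[scored.groups == g].to_numpy(float) for g in levels]
    for g, arr in zip(levels, arrays):
        if len(arr) < 3:
            raise ValueError(f"group {g!r} has < 3 samples")
    summary = {g: {"n": len(a), "mean": float(a.mean())} for g, a in zip(levels, arrays)}
    if mode == "two_group":
        if len(levels) != 2:
            raise ValueError("two_group mode needs exactly two groups")
        a, b = arrays
        if a.var() == 0 and b.var() == 0:
            p = 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
            return {"mode": mode, "statistic": 0.0, "p_value": p, "groups": summary}
        t, p = stats.ttest_ind(a, b, equal_var=False)
        return {"mode": mode, "statistic": float(t), "p_value": float(p), "groups": summary}
    if mode != "multi_group":
        raise ValueError(f"unknown mode {mode!r}")
    f, p = stats.f_oneway(*arrays)
    return {"mode": mode, "statistic": float(f), "p_value": float(p), "groups": summary}
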