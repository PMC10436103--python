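"""Interval set algebra, consensus/gained/lost calling, differential
accessibility, peak annotation and peak-gene linking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tcellsig import atac
from tcellsig.atac import GeneModel, GenomicInterval, PeakCallSet


def iv(start, end, chrom="chr1"):
    return GenomicInterval(chrom, start, end)


def pcs(sample, intervals, subtype="x"):
    return PeakCallSet(sample, subtype, tuple(sorted(intervals)))


def brute_force_union(intervals, chrom_len=10_000):
    """Per-base-pair membership oracle for interval union on one chromosome."""
    covered = np.zeros(chrom_len, dtype=bool)
    for i in intervals:
        covered[i.start:i.end] = True
    out, start = [], None
    for p in range(chrom_len + 1):
        on = p < chrom_len and covered[p]
        if on and start is None:
            start = p
        elif not on and start is not None:
            out.append(GenomicInterval("chr1", start, p))
            start = None
    return out


intervals_strategy = st.lists(
    st.tuples(st.integers(0, 9_000), st.integers(1, 900)).map(
        lambda t: GenomicInterval("chr1", t[0], t[0] + t[1])
    ),
    min_size=0,
    max_size=40,
)


class TestMergeCatalog:
    def test_overlapping_intervals_merge(self):
        sets = [pcs("a", [iv(10, 20)]), pcs("b", [iv(15, 25)])]
        assert atac.merge_catalog(sets) == [iv(10, 25)]

    def test_disjoint_intervals_preserved(self):
        sets = [pcs("a", [iv(10, 20), iv(30, 40)])]
        assert atac.merge_catalog(sets) == [iv(10, 20), iv(30, 40)]

    def test_matches_brute_force_union_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(3):
            sets = []
            for s in range(3):
                starts = np.sort(rng.choice(9_000, size=200, replace=False))
                raw = [iv(int(a), int(a) + int(rng.integers(1, 60))) for a in starts]
                sets.append(pcs(f"s{s}", atac.merge_intervals(raw)))
            merged = atac.merge_catalog(sets)
            expected = brute_force_union([i for p in sets for i in p.intervals])
            assert merged == expected

    def test_malformed_interval_reports_sample(self):
        with pytest.raises(ValueError, match="bad_sample"):
            PeakCallSet("bad_sample", "x", (GenomicInterval("chr1", 20, 10),))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(intervals_strategy)
    def test_idempotent_and_matches_oracle(self, intervals):
        merged = atac.merge_intervals(intervals)
        assert atac.merge_intervals(merged) == merged
        assert merged == brute_force_union(intervals)


class TestConsensus:
    def setup_method(self):
        self.site = iv(100, 200)
        self.other = iv(400, 500)

    def _reps(self, presence):
        return [
            pcs(f"r{i}", [self.site] * p + [self.other], subtype="c")
            for i, p in enumerate(presence)
        ]

    def test_two_of_three_included(self):
        # a site detected in 2/3 of samples meets the published consensus rule
        reps = self._reps([1, 1, 0])
        cons = atac.consensus_sites(reps, min_fraction=2 / 3)
        assert self.site in cons

    def test_one_of_three_excluded(self):
        cons = atac.consensus_sites(self._reps([1, 0, 0]), min_fraction=2 / 3)
        assert self.site not in cons

    def test_intersection_limit(self):
        assert self.site in atac.consensus_sites(self._reps([1, 1, 1]), min_fraction=1.0)
        assert self.site not in atac.consensus_sites(self._reps([1, 1, 0]), min_fraction=1.0)

    def test_empty_replicates_rejected(self):
        with pytest.raises(ValueError):
            atac.consensus_sites([], min_fraction=0.5)

    def test_monotone_in_min_fraction(self):
        reps = self._reps([1, 1, 0])
        sizes = [
            len(atac.consensus_sites(reps, min_fraction=f))
            for f in (0.1, 1 / 3, 2 / 3, 1.0)
        ]
        assert sizes == sorted(sizes, reverse=True)


class TestGainedLost:
    def test_empty_effector(self):
        sub = [iv(0, 10), iv(20, 30)]
        gained, lost = atac.gained_lost(sub, [])
        assert gained == sub and lost == []

    def test_identical_sets_yield_nothing(self):
        sub = [iv(0, 10)]
        gained, lost = atac.gained_lost(sub, sub)
        assert gained == [] and lost == []

    def test_set_difference_enumeration(self):
        shared = [iv(i * 100, i * 100 + 50) for i in range(4)]
        sub_only = [iv(1000 + i * 100, 1000 + i * 100 + 50) for i in range(5)]
        eff_only = [iv(2000 + i * 100, 2000 + i * 100 + 50) for i in range(3)]
        gained, lost = atac.gained_lost(shared + sub_only, shared + eff_only)
        assert len(gained) == 5 and len(lost) == 3
        assert set(gained) == set(sub_only) and set(lost) == set(eff_only)

    def test_gained_disjoint_from_effector(self):
        rng = np.random.default_rng(0)
        all_sites = [iv(i * 100, i * 100 + 50) for i in range(50)]
        sub = [s for s in all_sites if rng.random() < 0.6]
        eff = [s for s in all_sites if rng.random() < 0.6]
        gained, lost = atac.gained_lost(sub, eff)
        assert not set(gained) & set(eff)
        assert len(gained) + len(set(sub) & set(eff)) == len(sub)


class TestSubtypeSpecific:
    def test_unique_site_is_specific(self):
        out = atac.subtype_specific({"a": [iv(0, 10)], "b": [iv(20, 30)]})
        assert out == {"a": [iv(0, 10)], "b": [iv(20, 30)]}

    def test_shared_gain_in_neither(self):
        shared = iv(0, 10)
        out = atac.subtype_specific({"a": [shared, iv(20, 30)], "b": [shared]})
        assert out["a"] == [iv(20, 30)] and out["b"] == []

    def test_specific_sets_pairwise_disjoint(self, small_pipeline):
        specific = small_pipeline["specific"]
        subs = list(specific)
        for i, a in enumerate(subs):
            for b in subs[i + 1:]:
                assert not set(specific[a]) & set(specific[b])


class TestPairwiseJaccard:
    def test_identical_and_disjoint(self):
        m = atac.pairwise_jaccard({"a": [1, 2], "b": [1, 2], "c": [3]})
        assert m.loc["a", "b"] == 1.0
        assert m.loc["a", "c"] == 0.0
        assert np.allclose(m.values, m.values.T)
        assert (np.diag(m.values) == 1.0).all()

    def test_hand_enumerated_value(self):
        a = set(range(4))
        b = set(range(2, 8))
        m = atac.pairwise_jaccard({"a": a, "b": b})
        assert m.loc["a", "b"] == pytest.approx(2 / 8)

    def test_both_empty_defined_as_zero(self):
        m = atac.pairwise_jaccard({"a": [], "b": []})
        assert m.loc["a", "b"] == 0.0


class TestDifferentialAccessibility:
    @staticmethod
    def _nb(rng, mean, phi):
        return rng.poisson(rng.gamma(1 / phi, mean * phi))

    def test_identical_columns_nothing_significant(self):
        rng = np.random.default_rng(1)
        col = rng.poisson(50.0, size=100)
        df = pd.DataFrame({f"s{i}": col for i in range(6)}, dtype=int)
        groups = {f"s{i}": "A" if i < 3 else "B" for i in range(6)}
        res = atac.differential_accessibility(df, groups)
        assert np.allclose(res.table.log2_fold_change, 0.0)
        assert not res.table.significant.any()

    def test_all_zero_row_excluded_from_fdr(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.poisson(40.0, size=(50, 6)),
                          columns=[f"s{i}" for i in range(6)])
        df.iloc[0] = 0
        groups = {f"s{i}": "A" if i < 3 else "B" for i in range(6)}
        res = atac.differential_accessibility(df, groups)
        assert res.table.iloc[0].p_value == 1.0
        assert not res.table.iloc[0].significant

    def test_small_group_rejected(self):
        df = pd.DataFrame(np.ones((5, 3), dtype=int), columns=list("abc"))
        with pytest.raises(ValueError, match="2 samples"):
            atac.differential_accessibility(df, {"a": "A", "b": "B", "c": "B"})

    def test_planted_sites_recovered(self):
        # one simulation at the stated effect size; the 50-replicate
        # sensitivity/FDR sweep lives in the acceptance suite
        rng = np.random.default_rng(3)
        n, n_da = 400, 40
        base = np.exp(rng.normal(np.log(80), 0.4, size=n))
        mean_a = np.tile(base[:, None], (1, 6))
        mean_b = mean_a.copy()
        mean_b[:n_da] *= 8.0  # log2 FC = 3
        counts = np.hstack([self._nb(rng, mean_a, 0.05), self._nb(rng, mean_b, 0.05)])
        df = pd.DataFrame(counts, columns=[f"s{i}" for i in range(12)])
        groups = {f"s{i}": "A" if i < 6 else "B" for i in range(12)}
        res = atac.differential_accessibility(df, groups)
        called = set(np.flatnonzero(res.table.significant.to_numpy()))
        sens = len(called & set(range(n_da))) / n_da
        assert sens >= 0.9
        assert res.table.log2_fold_change.iloc[:n_da].mean() == pytest.approx(3.0, abs=0.6)


class TestAnnotatePeaks:
    genes = [
        GeneModel("g_plus", "chr1", "+", 10_000,
                  (iv(10_000, 10_400), iv(12_000, 12_300))),
        GeneModel("g_minus", "chr2", "-", 50_000, (iv(48_000, 50_001),)),
    ]

    def test_promoter_window_overlap(self):
        # 2.5 kb upstream to 0.5 kb downstream of the TSS
        labels = atac.annotate_peaks([iv(7_400, 7_600)], self.genes)
        assert labels.iloc[0] == "promoter"

    def test_exon_outside_promoter(self):
        labels = atac.annotate_peaks([iv(12_000, 12_100)], self.genes)
        assert labels.iloc[0] == "exon"

    def test_intron_and_intergenic(self):
        labels = atac.annotate_peaks(
            [iv(11_000, 11_100), iv(500_000, 500_100), iv(100, 200, chrom="chrX")],
            self.genes,
        )
        assert list(labels) == ["intron", "intergenic", "intergenic"]

    def test_minus_strand_promoter_mirrored(self):
        # upstream of a minus-strand gene lies at larger coordinates
        labels = atac.annotate_peaks([iv(52_000, 52_100, chrom="chr2")], self.genes)
        assert labels.iloc[0] == "promoter"

    def test_unknown_strand_rejected(self):
        with pytest.raises(ValueError, match="strand"):
            GeneModel("bad", "chr1", "*", 0)


class TestPeakGeneLinks:
    def _matrix(self, catalog, values):
        keys = [i.key for i in catalog]
        return atac.AccessibilityMatrix(
            catalog=catalog,
            data=pd.DataFrame(values, index=keys,
                              columns=[f"s{i}" for i in range(values.shape[1])]),
        )

    def test_promoter_link_regardless_of_correlation(self):
        gene = GeneModel("g", "chr1", "+", 10_000)
        catalog = [iv(9_000, 9_200)]
        rng = np.random.default_rng(0)
        links = atac.peak_to_gene_links(
            catalog, [gene], self._matrix(catalog, rng.random((1, 10)))
        )
        assert list(links.link_class) == ["promoter"]

    def test_exact_copy_distal_peak_linked(self):
        gene = GeneModel("g", "chr1", "+", 10_000)
        rng = np.random.default_rng(1)
        prom_sig = rng.random(10)
        catalog = [iv(9_000, 9_200), iv(100_000, 100_200)]
        mat = self._matrix(catalog, np.vstack([prom_sig, prom_sig]))
        links = atac.peak_to_gene_links(catalog, [gene], mat)
        distal = links[links.link_class == "distal"]
        assert len(distal) == 1
        assert distal.correlation.iloc[0] == pytest.approx(1.0)

    def test_planted_correlations_recovered_no_decoys(self):
        rng = np.random.default_rng(2)
        hits = decoys = 0
        for _ in range(20):
            gene = GeneModel("g", "chr1", "+", 10_000)
            prom = rng.normal(size=12)
            correlated = 0.9 * prom + np.sqrt(1 - 0.81) * rng.normal(size=12)
            decoy = rng.normal(size=12)
            catalog = [iv(9_000, 9_200), iv(60_000, 60_200), iv(80_000, 80_200)]
            # affine shift keeps the signals positive without touching r
            vals = 10.0 + 2.0 * np.vstack([prom, correlated, decoy])
            links = atac.peak_to_gene_links(catalog, [gene], self._matrix(catalog, vals),
                                            corr_threshold=0.7)
            distal = set(links[links.link_class == "distal"].peak)
            hits += catalog[1].key in distal
            decoys += catalog[2].key in distal
        assert hits >= 17 and decoys <= 1

    def test_few_samples_disable_distal(self):
        gene = GeneModel("g", "chr1", "+", 10_000)
        catalog = [iv(9_000, 9_200), iv(100_000, 100_200)]
        mat = self._matrix(catalog, np.ones((2, 4)))
        with pytest.warns(UserWarning, match="distal"):
            links = atac.peak_to_gene_links(catalog, [gene], mat)
        assert "distal" not in set(links.link_class)


class TestMeanFoldEnrichment:
    def _mat(self, values):
        catalog = [iv(i * 100, i * 100 + 50) for i in range(values.shape[0])]
        return atac.AccessibilityMatrix(
            catalog=catalog,
            data=pd.DataFrame(values, index=[c.key for c in catalog],
                              columns=[f"s{j}" for j in range(values.shape[1])]),
        ), catalog

    def test_single_region_returns_row(self):
        mat, catalog = self._mat(np.array([[1.0, 2.0], [3.0, 4.0]]))
        out = atac.mean_fold_enrichment(mat, [catalog[1]])
        assert list(out) == [3.0, 4.0]

    def test_constant_matrix(self):
        mat, catalog = self._mat(np.full((4, 3), 2.5))
        assert (atac.mean_fold_enrichment(mat, catalog) == 2.5).all()

    def test_hand_computed_means(self):
        mat, catalog = self._mat(np.array([[1.0, 4.0], [2.0, 5.0], [6.0, 9.0]]))
        out = atac.mean_fold_enrichment(mat, catalog[:2])
        assert list(out) == [1.5, 4.5]

    def test_empty_region_set_rejected(self):
        mat, _ = self._mat(np.ones((2, 2)))
        with pytest.raises(ValueError):
            atac.mean_fold_enrichment(mat, [])


class TestRankCompare:
    def test_identical_groups_p_one(self):
        with pytest.warns(UserWarning):
            _, p = atac.rank_compare([1, 1, 1], [1, 1, 1])
        assert p == 1.0

    def test_unpaired_matches_exact_permutation(self):
        # enumeration over all 20 label assignments gives two-sided p = 2/20
        _, p = atac.rank_compare([1, 2, 3], [10, 20, 30])
        assert p == pytest.approx(0.1)

    def test_paired_all_positive_signed_rank(self):
        # all 6 differences positive: 2 of 64 sign patterns are as extreme
        _, p = atac.rank_compare([5, 6, 7, 8, 9, 10], [1, 2, 3, 4, 5, 6], paired=True)
        assert p == pytest.approx(2 / 64)

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            atac.rank_compare([1, 2], [3, 4, 5])
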