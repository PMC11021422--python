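"""Densities, stratification, meta-profiles, 5'SS profiles, Spearman."""

import dataclasses
import itertools

import numpy as np
import pandas as pd
import pytest

from finechrom.formats_io import ChromSizes, GeneModel, pairs_frame
from finechrom.profiles import (
    gene_contact_density, metagene_profile, spearman, splice_site_profile,
    stratify_by_percentile,
)
from finechrom.synthetic_data import simulate_contacts


def _gene(gid="g", chrom="chr1", start=10_000, end=12_000, strand="+"):
    return GeneModel(gid, chrom, start, end, strand, [(start, end)])


class TestGeneContactDensity:
    def test_formula(self):
        # 10 internal contacts, 2 kb gene, 10^6 library -> 5.0
        recs = [("chr1", 10_100 + i, "+", "chr1", 11_500 + i, "-", 60, 60)
                for i in range(10)]
        density = gene_contact_density(pairs_frame(recs), [_gene()],
                                       library_total=1_000_000)
        assert density["g"] == pytest.approx(5.0)

    def test_zero_for_contactless_gene(self):
        recs = [("chr1", 100, "+", "chr1", 2_000, "-", 60, 60)]
        density = gene_contact_density(pairs_frame(recs), [_gene()],
                                       library_total=1_000)
        assert density["g"] == 0.0

    def test_depth_normalization(self):
        recs = [("chr1", 10_100, "+", "chr1", 11_500, "-", 60, 60)]
        d1 = gene_contact_density(pairs_frame(recs), [_gene()],
                                  library_total=1_000_000)
        d2 = gene_contact_density(pairs_frame(recs), [_gene()],
                                  library_total=2_000_000)
        assert d1["g"] == pytest.approx(2 * d2["g"])

    def test_one_end_outside_not_counted(self):
        recs = [("chr1", 10_100, "+", "chr1", 50_000, "-", 60, 60)]
        density = gene_contact_density(pairs_frame(recs), [_gene()],
                                       library_total=1_000)
        assert density["g"] == 0.0

    def test_zero_library_errors(self):
        with pytest.raises(ValueError):
            gene_contact_density(pairs_frame([]), [_gene()], library_total=0)


class TestStratify:
    def test_sizes(self):
        vals = pd.Series(np.arange(100.0), index=[f"g{i:03d}" for i in range(100)])
        top, bottom = stratify_by_percentile(vals, pct=10)
        assert len(top) == 10 and len(bottom) == 10
        assert set(top) == {f"g{i:03d}" for i in range(90, 100)}

    def test_all_equal_is_deterministic(self):
        vals = pd.Series(np.ones(20), index=[f"g{i:02d}" for i in range(20)])
        t1, b1 = stratify_by_percentile(vals, pct=10)
        t2, b2 = stratify_by_percentile(vals, pct=10)
        assert t1 == t2 and b1 == b2

    def test_disjoint_for_half_or_less(self):
        rng = np.random.default_rng(0)
        vals = pd.Series(rng.standard_normal(37),
                         index=[f"g{i:02d}" for i in range(37)])
        top, bottom = stratify_by_percentile(vals, pct=50)
        assert not set(top) & set(bottom)

    @pytest.mark.parametrize("pct", [0, -1, 60])
    def test_invalid_pct_errors(self, pct):
        vals = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError):
            stratify_by_percentile(vals, pct=pct)


class TestMetageneProfile:
    def test_top_group_above_bottom_on_planted_enrichment(
            self, small_config, small_genome, small_truth):
        """Genes with high activity factors carry more gene-body contacts at
        every scaled-body bin."""
        chromsizes, genes, _ = small_genome
        pairs = simulate_contacts(chromsizes, genes, small_truth,
                                  small_config, "22C", n_pairs=400_000)
        factor = pd.Series(small_truth.activity_factor)
        top, bottom = stratify_by_percentile(factor, pct=20)
        prof = metagene_profile(pairs, genes, {"top": top, "bottom": bottom},
                                n_body_bins=20)
        assert prof.profiles["top"].mean() > prof.profiles["bottom"].mean()

    def test_minus_strand_signal_oriented_to_tss(self):
        cs = ChromSizes({"chr1": 50_000})
        g = GeneModel("gm", "chr1", 10_000, 20_000, "-", [(10_000, 20_000)])
        # ends concentrated near the genomic END = the TSS of a minus gene
        recs = [("chr1", 19_500 + (i % 100), "+", "chr1", 30_000, "-", 60, 60)
                for i in range(200)]
        prof = metagene_profile(pairs_frame(recs), [g], {"all": ["gm"]},
                                n_body_bins=10)
        assert prof.profiles["all"][0] > prof.profiles["all"][-1]

    def test_short_gene_excluded(self):
        cs_gene = GeneModel("tiny", "chr1", 100, 150, "+", [(100, 150)])
        ok_gene = _gene("ok")
        recs = [("chr1", 10_100, "+", "chr1", 11_000, "-", 60, 60)]
        prof = metagene_profile(pairs_frame(recs), [cs_gene, ok_gene],
                                {"grp": ["tiny", "ok"]}, n_body_bins=100)
        assert prof.group_sizes["grp"] == 1

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            metagene_profile(pairs_frame([]), [_gene()], {"grp": []})


class TestSpliceSiteProfile:
    def test_planted_downstream_peak(self, small_config, small_genome,
                                     small_truth):
        """The pausing component puts the peak downstream of the first 5'SS,
        covering the ~25 bp pausing offset."""
        chromsizes, genes, _ = small_genome
        pairs = simulate_contacts(chromsizes, genes, small_truth,
                                  small_config, "22C", n_pairs=200_000)
        prof = splice_site_profile(pairs, genes, first_only=True,
                                   zscore=False)
        down = (prof.offsets >= 0) & (prof.offsets < 50)
        far = prof.offsets >= 100
        assert prof.profiles["all"][down].mean() > \
            2 * prof.profiles["all"][far].mean()
        peak = prof.offsets[np.argmax(prof.profiles["all"])]
        assert 0 <= peak <= 50

    def test_zscore_contract(self, small_config, small_genome, small_truth):
        chromsizes, genes, _ = small_genome
        pairs = {c: simulate_contacts(chromsizes, genes, small_truth,
                                      small_config, c, n_pairs=100_000)
                 for c in ("22C", "cold3h")}
        prof = splice_site_profile(pairs, genes, first_only=True)
        assert prof.zscored
        for vals in prof.profiles.values():
            assert vals.mean() == pytest.approx(0.0, abs=1e-12)
            assert vals.std() == pytest.approx(1.0, abs=1e-12)

    def test_condition_ordering_recovered(self, small_config, small_genome,
                                          small_truth):
        chromsizes, genes, _ = small_genome
        pairs = {c: simulate_contacts(chromsizes, genes, small_truth,
                                      small_config, c, seed=500 + i,
                                      n_pairs=150_000)
                 for i, c in enumerate(("22C", "cold3h", "cold12h"))}
        prof = splice_site_profile(pairs, genes, first_only=True)
        sel = (prof.offsets >= 0) & (prof.offsets <= 50)
        z = {c: p[sel].mean() for c, p in prof.profiles.items()}
        assert z["22C"] > z["cold12h"] > z["cold3h"]

    def test_first_only_anchor_subset(self, small_genome):
        _, genes, _ = small_genome
        multi = [g for g in genes if len(g.exons) >= 3][:5]
        all_sites = sum(len(g.five_prime_splice_sites()) for g in multi)
        first_sites = sum(1 for g in multi if g.five_prime_splice_sites())
        assert first_sites < all_sites
        recs = [("chr1", 1_000, "+", "chr1", 5_000, "-", 60, 60)]
        p_first = splice_site_profile(pairs_frame(recs), multi,
                                      first_only=True, zscore=False)
        p_all = splice_site_profile(pairs_frame(recs), multi,
                                    first_only=False, zscore=False)
        assert p_first.group_sizes["all"] == first_sites
        assert p_all.group_sizes["all"] == all_sites

    def test_no_multiexon_genes_errors(self):
        with pytest.raises(ValueError):
            splice_site_profile(pairs_frame([]), [_gene()])


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman([1, 2, 3], [3, 6, 9])[0] == pytest.approx(1.0)

    def test_reversed_is_minus_one(self):
        assert spearman([1, 2, 3], [9, 6, 3])[0] == pytest.approx(-1.0)

    def test_ties_match_brute_force_midranks(self):
        def midranks(v):
            v = np.asarray(v, dtype=float)
            out = np.empty(len(v))
            for i, x in enumerate(v):
                less = np.sum(v < x)
                equal = np.sum(v == x)
                out[i] = less + (equal + 1) / 2.0
            return out

        rng = np.random.default_rng(1)
        for _ in range(20):
            x = rng.integers(0, 4, 12).astype(float)
            y = rng.integers(0, 4, 12).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            rs, _ = spearman(x, y)
            rx, ry = midranks(x), midranks(y)
            want = np.corrcoef(rx, ry)[0, 1]
            assert rs == pytest.approx(want, abs=1e-12)

    def test_matches_scipy_for_large_n(self):
        from scipy import stats
        rng = np.random.default_rng(2)
        x = rng.standard_normal(60)
        y = x + rng.standard_normal(60)
        rs, p = spearman(x, y)
        ref = stats.spearmanr(x, y)
        assert rs == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_exact_permutation_small_n(self):
        # monotone n=4: one-in-24 orderings ties the maximum on each side
        rs, p = spearman([1, 2, 3, 4], [2, 4, 6, 8])
        assert rs == pytest.approx(1.0)
        assert p == pytest.approx(2 / 24)

    def test_constant_vector_errors(self):
        with pytest.raises(ValueError):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])
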