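"""Linker splitting, filtering, binning, VC normalization, decay, replicates."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from finechrom.contact_processing import (
    ContactMatrix, DEFAULT_LINKER, bin_contacts, decay_curve, filter_pairs,
    pairs_from_linker_reads, replicate_correlation, split_linker_read,
    vc_normalize,
)
from finechrom.formats_io import ChromSizes, pairs_frame
from finechrom.synthetic_data import simulate_contacts, simulate_linker_reads


class TestSplitLinkerRead:
    FLANK1 = "ACGTACGTACGTACGTACGT"
    FLANK2 = "TTTTCCCCTTTTCCCCTTTT"

    def test_splits_at_linker(self):
        read = self.FLANK1 + DEFAULT_LINKER + self.FLANK2
        assert split_linker_read(read) == (self.FLANK1, self.FLANK2)

    def test_no_linker_returns_none(self):
        assert split_linker_read("ACGT" * 30) is None

    def test_short_flank_returns_none(self):
        read = "ACGTA" + DEFAULT_LINKER + self.FLANK2
        assert split_linker_read(read) is None

    def test_empty_linker_errors(self):
        with pytest.raises(ValueError):
            split_linker_read("ACGT" * 30, linker_seq="")

    def test_one_mismatch_tolerance_behind_flag(self):
        mutated = "A" + DEFAULT_LINKER[1:]
        read = self.FLANK1 + mutated + self.FLANK2
        assert split_linker_read(read) is None
        assert split_linker_read(read, max_mismatches=1) == \
            (self.FLANK1, self.FLANK2)

    def test_split_recovers_simulated_non_decoy_pairs(
            self, small_config, small_genome, small_truth):
        """Composition invariant: read simulation then linker splitting gives
        back exactly the non-decoy pairs."""
        chromsizes, genes, _ = small_genome
        cfg = dataclasses.replace(small_config, decoy_fraction=0.25)
        pairs = simulate_contacts(chromsizes, genes, small_truth, cfg, "22C",
                                  n_pairs=1_000).head(400)
        reads = simulate_linker_reads(pairs, cfg)
        recovered = pairs_from_linker_reads(reads, chromsizes)
        want = pairs[["chrom1", "pos1", "chrom2", "pos2"]].sort_values(
            ["chrom1", "pos1", "chrom2", "pos2"]).reset_index(drop=True)
        got = recovered[["chrom1", "pos1", "chrom2", "pos2"]].sort_values(
            ["chrom1", "pos1", "chrom2", "pos2"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(got, want)


class TestFilterPairs:
    def test_mapq_below_threshold_dropped(self, toy_chromsizes):
        pairs = pairs_frame([("chr1", 10, "+", "chr1", 5_000, "+", 9, 30)])
        out, rep = filter_pairs(pairs, mapq_min=10, min_distance=400)
        assert len(out) == 0 and rep.n_low_mapq == 1

    def test_mapq_10_kept(self):
        pairs = pairs_frame([("chr1", 10, "+", "chr1", 5_000, "+", 10, 30)])
        out, _ = filter_pairs(pairs, mapq_min=10, min_distance=400)
        assert len(out) == 1

    def test_exact_duplicates_collapsed(self):
        rec = ("chr1", 10, "+", "chr1", 5_000, "-", 30, 30)
        out, rep = filter_pairs(pairs_frame([rec, rec]), min_distance=400)
        assert len(out) == 1 and rep.n_duplicates == 1

    def test_strand_differs_is_not_a_duplicate(self):
        out, rep = filter_pairs(pairs_frame([
            ("chr1", 10, "+", "chr1", 5_000, "-", 30, 30),
            ("chr1", 10, "+", "chr1", 5_000, "+", 30, 30),
        ]), min_distance=400)
        assert len(out) == 2 and rep.n_duplicates == 0

    def test_short_range_intra_dropped(self):
        pairs = pairs_frame([("chr1", 100, "+", "chr1", 250, "+", 30, 30)])
        out, rep = filter_pairs(pairs, min_distance=400)
        assert len(out) == 0 and rep.n_short_range == 1

    def test_report_counts_sum_to_input_minus_output(self, toy_pairs):
        out, rep = filter_pairs(toy_pairs, mapq_min=10, min_distance=400)
        assert rep.n_input - rep.n_output == \
            rep.n_low_mapq + rep.n_short_range + rep.n_duplicates


class TestBinContacts:
    def test_bin_index_is_floor_division(self, toy_chromsizes):
        pairs = pairs_frame([("chr1", 150, "+", "chr1", 450, "+", 30, 30)])
        m = bin_contacts(pairs, 200, toy_chromsizes)
        assert m.intra("chr1")[0, 2] == 1

    def test_total_conserved(self, toy_chromsizes, small_config, small_genome,
                             small_truth):
        chromsizes, genes, _ = small_genome
        pairs = simulate_contacts(chromsizes, genes, small_truth,
                                  small_config, "22C", n_pairs=5_000)
        m = bin_contacts(pairs, 200, chromsizes)
        assert m.total == len(pairs)

    def test_non_positive_resolution_errors(self, toy_chromsizes, toy_pairs):
        with pytest.raises(ValueError):
            bin_contacts(toy_pairs, 0, toy_chromsizes)


def matrix_from_dense(dense, chrom="chr1", resolution=200):
    dense = np.asarray(dense, dtype=float)
    n = dense.shape[0]
    cs = ChromSizes({chrom: n * resolution})
    m = ContactMatrix(resolution=resolution, chromsizes=cs)
    m.maps[(chrom, chrom)] = sp.csr_matrix(np.triu(dense))
    return m


class TestVcNormalize:
    def test_hand_computed_example(self):
        # full-matrix row sums 2 and 8; M'01 = 2/(2*8) = 0.125 before rescale
        m = matrix_from_dense([[0, 2], [0, 6]])
        out = vc_normalize(m)
        raw01 = 2 / (2 * 8)
        raw11 = 6 / (8 * 8)
        scale = 8 / (raw01 + raw11)
        assert out.intra("chr1")[0, 1] == pytest.approx(raw01 * scale)

    def test_total_mass_preserved(self):
        rng = np.random.default_rng(0)
        m = matrix_from_dense(rng.integers(0, 20, (6, 6)))
        out = vc_normalize(m)
        assert out.intra("chr1").sum() == pytest.approx(m.intra("chr1").sum(),
                                                        rel=1e-9)

    def test_uniform_matrix_unchanged_up_to_scale(self):
        m = matrix_from_dense(np.full((5, 5), 3.0))
        out = vc_normalize(m)
        a = m.intra("chr1").toarray()
        b = out.intra("chr1").toarray()
        ratio = b[a > 0] / a[a > 0]
        assert np.allclose(ratio, ratio[0])

    def test_idempotent_on_equal_coverage_matrix(self):
        # with equal row sums VC divides every entry by the same factor, so a
        # second pass changes nothing beyond the preserved global scale
        dense = np.array([[1.0, 2.0, 3.0],
                          [0.0, 1.0, 3.0],
                          [0.0, 0.0, 0.0]])   # symmetrized rows: 6, 6, 6
        m = matrix_from_dense(dense)
        once = vc_normalize(m)
        twice = vc_normalize(once)
        assert np.allclose(once.intra("chr1").toarray(),
                           twice.intra("chr1").toarray())

    def test_repeated_passes_contract_coverage_nonuniformity(self):
        def spread(mat):
            m = mat.intra("chr1")
            sym = (m + m.T - sp.diags(m.diagonal())).toarray()
            rows = sym.sum(axis=1)
            return rows.max() / rows.min()

        rng = np.random.default_rng(1)
        m = matrix_from_dense(rng.integers(1, 30, (8, 8)))
        once = vc_normalize(m)
        twice = vc_normalize(once)
        assert spread(once) < spread(m)
        assert spread(twice) < spread(once)

    def test_all_zero_matrix_returned_unchanged(self, caplog):
        m = matrix_from_dense(np.zeros((3, 3)))
        out = vc_normalize(m)
        assert out.intra("chr1").nnz == 0


class TestDecayCurve:
    def test_no_contacts_in_range_errors(self):
        pairs = pairs_frame([("chr1", 0, "+", "chr2", 10, "+", 30, 30)])
        with pytest.raises(ValueError):
            decay_curve(pairs)

    def test_single_distance_refuses_fit(self):
        pairs = pairs_frame(
            [("chr1", i * 10, "+", "chr1", i * 10 + 2_000, "+", 30, 30)
             for i in range(50)])
        with pytest.raises(ValueError, match="occupied"):
            decay_curve(pairs)

    def test_depth_invariance(self, small_config, small_genome, small_truth):
        chromsizes, genes, _ = small_genome
        pairs = simulate_contacts(chromsizes, genes, small_truth,
                                  small_config, "22C", n_pairs=100_000)
        full = decay_curve(pairs, d_max=500_000)
        half = decay_curve(pairs.head(len(pairs) // 2), d_max=500_000)
        occ = (full.density > 0) & (half.density > 0)
        # densities per contact per bp: equal up to sampling noise
        assert np.corrcoef(np.log(full.density[occ]),
                           np.log(half.density[occ]))[0, 1] > 0.99
        assert half.alpha == pytest.approx(full.alpha, abs=0.05)


class TestReplicateCorrelation:
    def test_matrix_vs_itself_is_one(self):
        rng = np.random.default_rng(2)
        m = matrix_from_dense(rng.poisson(3, (20, 20)))
        overall, per = replicate_correlation(m, m)
        assert overall == pytest.approx(1.0)

    def test_independent_matrices_near_zero(self):
        rng = np.random.default_rng(3)
        a = matrix_from_dense(rng.poisson(3, (60, 60)))
        b = matrix_from_dense(rng.poisson(3, (60, 60)))
        overall, _ = replicate_correlation(a, b)
        assert abs(overall) < 0.1

    def test_same_process_replicates_highly_correlated(
            self, small_config, small_genome, small_truth):
        chromsizes, genes, _ = small_genome
        reps = []
        for seed in (101, 102):
            pairs = simulate_contacts(chromsizes, genes, small_truth,
                                      small_config, "22C", seed=seed,
                                      n_pairs=300_000)
            reps.append(bin_contacts(pairs, 10_000, chromsizes))
        overall, per = replicate_correlation(reps[0], reps[1])
        assert overall > 0.9
        assert (per["pearson_r"] > 0).all()

    def test_mismatched_resolution_errors(self):
        a = matrix_from_dense(np.eye(4), resolution=200)
        b = matrix_from_dense(np.eye(4), resolution=400)
        with pytest.raises(ValueError):
            replicate_correlation(a, b)
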