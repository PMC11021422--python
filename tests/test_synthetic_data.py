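"""Generator determinism, planted-structure recovery, and read simulation."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from finechrom.synthetic_data import (
    SimulationConfig, generate_genome, plant_loops, simulate_contacts,
    simulate_activity_and_expression, simulate_linker_reads,
)
from finechrom.formats_io import write_annotation_gff3
from finechrom.contact_processing import DEFAULT_LINKER
from finechrom.coexpression import pair_expression_correlation
from finechrom.profiles import spearman, gene_contact_density


class TestGenome:
    def test_fixed_seed_is_byte_identical(self, small_config, tmp_path):
        outs = []
        for i in range(2):
            _, genes, _ = generate_genome(small_config)
            p = tmp_path / f"run{i}.gff3"
            write_annotation_gff3(genes, p)
            outs.append(p.read_bytes())
        assert outs[0] == outs[1]

    def test_multiexon_fraction_supplies_splice_anchors(self, small_config,
                                                        small_genome):
        _, genes, _ = small_genome
        with_ss = sum(g.first_five_prime_ss() is not None for g in genes)
        assert with_ss >= small_config.multiexon_fraction * len(genes) * 0.8

    def test_genes_non_overlapping(self, small_genome):
        _, genes, _ = small_genome
        by_chrom = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        for gl in by_chrom.values():
            gl = sorted(gl, key=lambda g: g.start)
            assert all(a.end <= b.start for a, b in zip(gl[:-1], gl[1:]))

    def test_too_small_genome_errors(self):
        cfg = SimulationConfig(seed=0, n_chroms=1, chrom_length=20_000,
                               n_genes=100, n_loops=1, n_hotspots=0)
        with pytest.raises(ValueError, match="too small"):
            generate_genome(cfg)

    def test_planted_anchors_inside_genome(self, small_config, small_genome,
                                           small_truth):
        chromsizes, _, _ = small_genome
        res = small_config.resolution
        for row in small_truth.loops.itertuples():
            assert 0 <= row.bin1 < row.bin2
            assert row.bin2 * res < chromsizes[row.chrom]


class TestContacts:
    def test_unknown_condition_errors(self, small_config, small_genome,
                                      small_truth):
        chromsizes, genes, _ = small_genome
        with pytest.raises(ValueError, match="unknown condition"):
            simulate_contacts(chromsizes, genes, small_truth, small_config,
                              "hot45C")

    def test_determinism(self, small_config, small_genome, small_truth):
        chromsizes, genes, _ = small_genome
        a = simulate_contacts(chromsizes, genes, small_truth, small_config,
                              "22C", n_pairs=20_000)
        b = simulate_contacts(chromsizes, genes, small_truth, small_config,
                              "22C", n_pairs=20_000)
        pd.testing.assert_frame_equal(a, b)

    def test_decay_slope_matches_configured_alpha(self, small_config,
                                                  small_genome, small_truth):
        """Log-log regression on the binned distance histogram recovers the
        configured decay exponent (independent fit, not decay_curve)."""
        chromsizes, genes, _ = small_genome
        cfg = dataclasses.replace(small_config, rate_body=0.0, rate_base=0.0,
                                  rate_pause=0.0, inter_fraction=0.0)
        pairs = simulate_contacts(chromsizes, genes, small_truth, cfg, "22C",
                                  n_pairs=300_000)
        intra = pairs[pairs.chrom1 == pairs.chrom2]
        d = (intra.pos2 - intra.pos1).to_numpy()
        d = d[(d >= 1_000) & (d < 400_000)]
        edges = np.logspace(3, np.log10(400_000), 30)
        hist, _ = np.histogram(d, bins=edges)
        centers = np.sqrt(edges[:-1] * edges[1:])
        dens = hist / np.diff(edges)
        occ = hist > 0
        slope = stats.linregress(np.log(centers[occ]), np.log(dens[occ])).slope
        assert slope == pytest.approx(-cfg.alpha, abs=0.1)

    def test_cold3h_has_fewer_pause_window_pairs(self, small_config,
                                                 small_genome, small_truth):
        """Same seed: background identical, only the 5'SS pausing component
        shrinks with the condition weight."""
        chromsizes, genes, _ = small_genome
        counts = {}
        for cond in ("22C", "cold3h"):
            pairs = simulate_contacts(chromsizes, genes, small_truth,
                                      small_config, cond, n_pairs=100_000)
            n = 0
            for g in genes:
                ss = g.first_five_prime_ss()
                if ss is None:
                    continue
                lo, hi = (ss, ss + 50) if g.strand == "+" else (ss - 50, ss)
                for col_c, col_p in (("chrom1", "pos1"), ("chrom2", "pos2")):
                    sel = (pairs[col_c] == g.chrom) & \
                        (pairs[col_p] >= lo) & (pairs[col_p] < hi)
                    n += int(sel.sum())
            counts[cond] = n
        assert counts["cold3h"] < counts["22C"]

    def test_fold1_loops_add_nothing_beyond_background(self, small_config,
                                                       small_genome):
        """fold = total enrichment: fold=1 anchors stay exactly at the
        background rate, fold=8 adds pairs at the same anchors."""
        chromsizes, genes, _ = small_genome
        cfg1 = dataclasses.replace(small_config, loop_fold=1.0)
        cfg8 = dataclasses.replace(small_config, loop_fold=8.0)
        truth1 = plant_loops(cfg1, chromsizes, genes)
        truth8 = plant_loops(cfg8, chromsizes, genes)
        # same seed => same anchors, only the fold differs
        assert (truth1.loops[["chrom", "bin1", "bin2"]].values
                == truth8.loops[["chrom", "bin1", "bin2"]].values).all()
        a = simulate_contacts(chromsizes, genes, truth1, cfg1, "22C",
                              n_pairs=50_000)
        b = simulate_contacts(chromsizes, genes, truth8, cfg8, "22C",
                              n_pairs=50_000)
        assert len(a) < len(b)
        # every extra pair in the fold=8 run sits at a planted anchor bin pair
        res = small_config.resolution
        keys = truth8.loop_keys()

        def anchor_counts(pairs):
            intra = pairs[pairs.chrom1 == pairs.chrom2]
            hits = [(c, p1 // res, p2 // res) in keys
                    for c, p1, p2 in zip(intra.chrom1, intra.pos1, intra.pos2)]
            return sum(hits)

        assert anchor_counts(b) - anchor_counts(a) == len(b) - len(a)


class TestActivityExpression:
    def test_rho_out_of_range_errors(self, small_config, small_genome,
                                     small_truth):
        chromsizes, genes, _ = small_genome
        cfg = dataclasses.replace(small_config, expression_rho=1.0)
        with pytest.raises(ValueError, match="rho"):
            simulate_activity_and_expression(chromsizes, genes, small_truth,
                                             cfg)

    @pytest.mark.parametrize("rho,tol", [(0.0, 0.1), (0.9, 0.1)])
    def test_planted_pair_correlation_recovered(self, small_config,
                                                small_genome, rho, tol):
        chromsizes, genes, _ = small_genome
        cfg = dataclasses.replace(small_config, expression_rho=rho)
        truth = plant_loops(cfg, chromsizes, genes)
        _, expr = simulate_activity_and_expression(chromsizes, genes, truth,
                                                   cfg)
        rs = pair_expression_correlation(expr, truth.coexpressed_pairs)
        assert np.mean(rs) == pytest.approx(rho, abs=tol)

    def test_activity_contact_coupling_recovered(self, small_config,
                                                 small_genome, small_truth):
        """Spearman(per-gene contact density, activity signal) lands near the
        configured coupling target."""
        chromsizes, genes, _ = small_genome
        tracks, _ = simulate_activity_and_expression(
            chromsizes, genes, small_truth, small_config)
        pairs = simulate_contacts(chromsizes, genes, small_truth,
                                  small_config, "22C", n_pairs=1_000_000)
        density = gene_contact_density(pairs, genes)
        activity = pd.Series({g.gene_id: tracks["22C"].mean_over(
            g.chrom, g.start, g.end) for g in genes})
        rs, _ = spearman(density.loc[activity.index], activity)
        assert rs == pytest.approx(small_config.activity_coupling, abs=0.15)

    def test_zero_coupling_gives_zero_spearman(self, small_config,
                                               small_genome, small_truth):
        chromsizes, genes, _ = small_genome
        cfg = dataclasses.replace(small_config, activity_coupling=0.0)
        tracks, _ = simulate_activity_and_expression(chromsizes, genes,
                                                     small_truth, cfg)
        activity = pd.Series({g.gene_id: tracks["22C"].mean_over(
            g.chrom, g.start, g.end) for g in genes})
        dens = pd.Series(small_truth.expected_density)
        rs, _ = spearman(dens.loc[activity.index], activity)
        assert abs(rs) < 0.15


class TestLinkerReads:
    def test_no_decoys_every_read_has_linker_once(self, small_config,
                                                  small_genome, small_truth):
        chromsizes, genes, _ = small_genome
        cfg = dataclasses.replace(small_config, decoy_fraction=0.0)
        pairs = simulate_contacts(chromsizes, genes, small_truth, cfg, "22C",
                                  n_pairs=500).head(200)
        reads = simulate_linker_reads(pairs, cfg)
        assert len(reads) == len(pairs)
        for _, seq in reads:
            assert seq.count(DEFAULT_LINKER) == 1

    def test_read_names_encode_coordinates(self, small_config, small_genome,
                                           small_truth):
        chromsizes, genes, _ = small_genome
        cfg = dataclasses.replace(small_config, decoy_fraction=0.0)
        pairs = simulate_contacts(chromsizes, genes, small_truth, cfg, "22C",
                                  n_pairs=500).head(50)
        reads = simulate_linker_reads(pairs, cfg)
        for (name, _), row in zip(reads, pairs.itertuples(index=False)):
            left, right, _ = name.split("|")
            assert left == f"{row.chrom1}:{row.pos1}:{row.strand1}"
            assert right == f"{row.chrom2}:{row.pos2}:{row.strand2}"

    def test_decoy_count_is_binomial(self, small_config, small_genome,
                                     small_truth):
        chromsizes, genes, _ = small_genome
        cfg = dataclasses.replace(small_config, decoy_fraction=0.3)
        pairs = simulate_contacts(chromsizes, genes, small_truth, cfg, "22C",
                                  n_pairs=2_000).head(1_000)
        reads = simulate_linker_reads(pairs, cfg)
        n_decoys = sum(DEFAULT_LINKER not in seq for _, seq in reads)
        # 300 +- 4 binomial sd
        assert abs(n_decoys - 300) < 4 * np.sqrt(1_000 * 0.3 * 0.7)
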