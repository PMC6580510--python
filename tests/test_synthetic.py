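import numpy as np
import pytest
from scipy import stats as sps

from coldchrom.annotation import SizingError
from coldchrom.bivalent import ChannelError
from coldchrom.synthetic import (
    SimConfig,
    SimulationError,
    generate_annotation,
    nucleosome_centers,
    simulate_chip,
    simulate_dnase,
    simulate_expression,
)

SMALL = dict(n_chroms=1, chrom_length=400_000, n_genes=40,
             dnase_depth=60_000, chip_depth=60_000)


class TestSimConfig:
    def test_validation(self):
        with pytest.raises(SimulationError):
            SimConfig(carryover_rate=0.6)
        with pytest.raises(SimulationError):
            SimConfig(chrom_length=0)
        with pytest.raises(SimulationError):
            SimConfig(gene_length_range=(50, 40))


class TestGenerateAnnotation:
    def test_empty_gene_set(self):
        ann, labels = generate_annotation(SimConfig(n_genes=0, seed=1))
        assert len(ann) == 0 and len(labels.table) == 0

    def test_deterministic(self):
        cfg = SimConfig(seed=1, **{k: v for k, v in SMALL.items()})
        ann1, lab1 = generate_annotation(cfg)
        ann2, lab2 = generate_annotation(cfg)
        assert [(g.gene_id, g.tss, g.tts, tuple(g.exons)) for g in ann1.genes] == \
               [(g.gene_id, g.tss, g.tts, tuple(g.exons)) for g in ann2.genes]
        assert lab1.table.drop(columns="body_bumps").equals(
            lab2.table.drop(columns="body_bumps"))
        assert list(lab1.table["body_bumps"]) == list(lab2.table["body_bumps"])

    def test_gene_spacing_at_least_2kb(self):
        ann, _ = generate_annotation(SimConfig(seed=2, n_genes=50,
                                               n_chroms=1, chrom_length=1_000_000))
        for chrom in ann.chrom_sizes:
            genes = ann.genes_on(chrom)
            for g1, g2 in zip(genes, genes[1:]):
                assert g2.start - g1.end >= 2000

    def test_chromosome_too_short_raises(self):
        with pytest.raises(SizingError):
            generate_annotation(SimConfig(n_chroms=1, chrom_length=50_000,
                                          n_genes=40))

    def test_truth_invariants(self, sim_genome):
        _, labels = sim_genome
        t = labels.table
        silenced = t["expression_class"] == "silenced"
        assert (t.loc[silenced, ["fpkm_RT", "fpkm_cold", "fpkm_leaf"]] == 0).all().all()
        assert not (t["bivalent_planted"] & silenced).any()
        # strand-consistent TSS/TTS already enforced by GeneModel

    def test_genes_have_exons_inside_body(self, sim_genome):
        ann, _ = sim_genome
        for g in ann.genes:
            assert len(g.exons) >= 1
            assert g.exons[0][0] >= g.start and g.exons[-1][1] <= g.end


class TestSimulateDnase:
    def test_zero_depth_empty_track(self):
        cfg = SimConfig(seed=3, dnase_depth=0, **{k: v for k, v in SMALL.items()
                                                  if k != "dnase_depth"})
        ann, labels = generate_annotation(cfg)
        track = simulate_dnase(cfg, ann, labels, "RT", 1)
        assert track.library_size == 0

    def test_unknown_condition_raises(self, sim_cfg, sim_genome):
        ann, labels = sim_genome
        with pytest.raises(SimulationError):
            simulate_dnase(sim_cfg, ann, labels, "hot", 1)

    def test_depth_conservation(self, sim_cfg, dnase_tracks):
        for track in dnase_tracks.values():
            assert track.library_size == sim_cfg.dnase_depth

    def test_replicates_differ_but_conditions_reproduce(self, sim_cfg, sim_genome):
        ann, labels = sim_genome
        a = simulate_dnase(sim_cfg, ann, labels, "RT", 1)
        b = simulate_dnase(sim_cfg, ann, labels, "RT", 1)
        c = simulate_dnase(sim_cfg, ann, labels, "RT", 2)
        assert all(np.array_equal(a.cuts[k], b.cuts[k]) for k in a.cuts)
        assert any(not np.array_equal(a.cuts[k], c.cuts[k]) for k in a.cuts)

    def test_cold_gene_body_gains_cuts_across_seeds(self):
        wins = 0
        n_seeds = 20
        for seed in range(n_seeds):
            cfg = SimConfig(seed=100 + seed, **SMALL)
            ann, labels = generate_annotation(cfg)
            planted = labels.table[labels.table["genic_dhs_cold_only"]]
            gid = planted.index[0]
            g = ann[gid]
            rt = simulate_dnase(cfg, ann, labels, "RT", 1)
            cold = simulate_dnase(cfg, ann, labels, "cold", 1)
            if cold.count_in(g.chrom, g.start, g.end) > rt.count_in(g.chrom, g.start, g.end):
                wins += 1
        # sign test: under no effect, wins ~ Binomial(20, 0.5)
        assert sps.binomtest(wins, n_seeds, 0.5, alternative="greater").pvalue < 0.01

    def test_background_region_poisson_bound(self):
        cfg = SimConfig(seed=7, n_chroms=1, chrom_length=200_000, n_genes=0,
                        dnase_depth=100_000)
        ann, labels = generate_annotation(cfg)
        track = simulate_dnase(cfg, ann, labels, "RT", 1)
        lam = cfg.dnase_depth / cfg.chrom_length  # all mass reverts to background
        count = track.count_in("chr1", 50_000, 60_000)
        assert abs(count - lam * 10_000) <= 4 * np.sqrt(lam * 10_000)


class TestSimulateChip:
    def test_unknown_channel_raises(self, sim_cfg, sim_genome):
        ann, labels = sim_genome
        with pytest.raises(ChannelError):
            simulate_chip(sim_cfg, ann, labels, "H3K9me2", "RT")

    def test_depth_conservation(self, sim_cfg, chip_tracks):
        for track in chip_tracks.values():
            assert track.library_size == sim_cfg.chip_depth

    def test_input_uniform_over_grid(self):
        cfg = SimConfig(seed=8, n_chroms=1, chrom_length=500_000, n_genes=50,
                        chip_depth=100_000)
        ann, labels = generate_annotation(cfg)
        track = simulate_chip(cfg, ann, labels, "input", "RT")
        centers = nucleosome_centers(cfg, "chr1")
        mids = track.event_positions("chr1")
        # assign midpoints to nearest nucleosome; expect uniform occupancy
        idx = np.clip(np.searchsorted(centers, mids), 0, centers.size - 1)
        near = np.where((idx > 0) & (np.abs(mids - centers[idx - 1])
                                     < np.abs(mids - centers[idx])), idx - 1, idx)
        occ = np.bincount(near, minlength=centers.size)
        chi2 = ((occ - occ.mean()) ** 2 / occ.mean()).sum()
        p = sps.chi2.sf(chi2, centers.size - 1)
        assert p > 0.01

    def test_bivalent_gene_sequential_enrichment_across_seeds(self):
        wins = 0
        n_seeds = 15
        for seed in range(n_seeds):
            cfg = SimConfig(seed=200 + seed, **SMALL)
            ann, labels = generate_annotation(cfg)
            gid = sorted(labels.bivalent)[0]
            g = ann[gid]
            seq = simulate_chip(cfg, ann, labels, "K4-K27", "cold")
            noab = simulate_chip(cfg, ann, labels, "K4-noAb", "cold")
            if seq.count_in(g.chrom, g.start, g.end) > noab.count_in(g.chrom, g.start, g.end):
                wins += 1
        assert sps.binomtest(wins, n_seeds, 0.5, alternative="greater").pvalue < 0.01

    def test_k4_only_gene_reverse_order_matches_background(self, sim_cfg, sim_genome):
        ann, labels = sim_genome
        chip = simulate_chip(sim_cfg, ann, labels, "K27-K4", "cold")
        k4_only = sorted(labels.active - labels.bivalent)
        g = ann[k4_only[0]]
        body_n = chip.count_in(g.chrom, g.start, g.end)
        # flanking intergenic window of equal total length
        flank_n = (chip.count_in(g.chrom, g.start - g.length // 2 - 300, g.start - 300)
                   + chip.count_in(g.chrom, g.end + 300,
                                   g.end + 300 + (g.length - g.length // 2)))
        res = sps.poisson_means_test(body_n, g.length, flank_n, g.length)
        assert res.pvalue > 0.01


class TestSimulateExpression:
    def test_silenced_zero_everywhere(self, sim_genome, expression_tables):
        _, labels = sim_genome
        expr, _, _ = expression_tables
        silenced = sorted(labels.genes_in_class("silenced"))
        assert (expr.loc[silenced] == 0).all().all()

    def test_up_genes_fold_change_direction_and_size(self, sim_genome,
                                                     expression_tables):
        _, labels = sim_genome
        expr, _, _ = expression_tables
        up = sorted(labels.genes_in_class("up"))
        fc = expr.loc[up, "cold"] / expr.loc[up, "RT"]
        assert (fc > 1).all()
        assert fc.median() >= 1.5
        down = sorted(labels.genes_in_class("down"))
        fc_down = expr.loc[down, "RT"] / expr.loc[down, "cold"]
        assert (fc_down > 1).all()
        assert fc_down.median() >= 1.5

    def test_caller_intersection_is_exactly_planted(self, sim_genome,
                                                    expression_tables):
        from coldchrom.stats import intersect_de

        _, labels = sim_genome
        _, de_a, de_b = expression_tables
        planted = labels.genes_in_class("up") | labels.genes_in_class("down")
        assert set(intersect_de(de_a, de_b)["gene_id"]) == planted

    def test_each_caller_has_private_false_positives(self, sim_genome,
                                                     expression_tables):
        _, labels = sim_genome
        _, de_a, de_b = expression_tables
        planted = labels.genes_in_class("up") | labels.genes_in_class("down")
        fp_a = set(de_a.loc[de_a["fdr"] < 0.01, "gene_id"]) - planted
        fp_b = set(de_b.loc[de_b["fdr"] < 0.01, "gene_id"]) - planted
        assert fp_a and fp_b
        assert not fp_a & fp_b

    def test_deterministic(self, sim_cfg, sim_genome):
        _, labels = sim_genome
        e1, a1, b1 = simulate_expression(sim_cfg, labels)
        e2, a2, b2 = simulate_expression(sim_cfg, labels)
        assert e1.equals(e2) and a1.equals(a2) and b1.equals(b2)
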