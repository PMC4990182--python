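import json

import numpy as np
import pytest
from scipy import stats

from polyadapt import io_formats as io
from polyadapt import synthetic_data as syn


def small_config(seed, **kw):
    defaults = dict(n_samples=40, n_chrom=2, variants_per_chrom=30,
                    n_genes=10)
    defaults.update(kw)
    return syn.SimulationConfig(seed=seed, **defaults)


class TestPanel:
    def test_determinism(self):
        a = syn.simulate_panel(small_config(9))
        b = syn.simulate_panel(small_config(9))
        np.testing.assert_array_equal(a.haplotypes, b.haplotypes)
        np.testing.assert_array_equal(a.dosages, b.dosages)

    def test_seed_sensitivity(self):
        a = syn.simulate_panel(small_config(1))
        b = syn.simulate_panel(small_config(2))
        assert not np.array_equal(a.dosages, b.dosages)

    def test_dosages_consistent_with_haplotypes(self):
        p = syn.simulate_panel(small_config(3))
        np.testing.assert_array_equal(p.dosages,
                                      p.haplotypes[0::2] + p.haplotypes[1::2])

    def test_sweep_carrier_fraction(self):
        cfg = small_config(4, sweeps=(syn.SweepConfig("rs1_15",
                                                      derived_freq=0.5),))
        p = syn.simulate_panel(cfg)
        core = p._index["rs1_15"]
        assert p.haplotypes[:, core].sum() == 40  # 0.5 * 80 haplotypes

    def test_too_few_carriers_rejected(self):
        cfg = small_config(5, n_samples=1,
                           sweeps=(syn.SweepConfig("rs1_15",
                                                   derived_freq=0.4),))
        with pytest.raises(ValueError, match="carrier"):
            syn.simulate_panel(cfg)

    def test_allele_frequencies_within_maf_range(self):
        cfg = small_config(6, n_samples=500, maf_range=(0.3, 0.4))
        p = syn.simulate_panel(cfg)
        freqs = p.haplotypes.mean(axis=0)
        assert freqs.min() > 0.2 and freqs.max() < 0.5


class TestSummaryStats:
    def test_null_effect_gives_uniform_p(self):
        # mu_alt = 0: planted-gene p-values indistinguishable from uniform
        pooled = []
        for seed in range(10):
            cfg = small_config(seed, planted_genes=("G1_2",), alt_effect=0.0)
            panel = syn.simulate_panel(cfg)
            ann = syn.make_gene_annotation(cfg)
            recs = syn.simulate_summary_stats(cfg, panel, ann)
            gene = next(g for g in ann if g.gene_id == "G1_2")
            pooled += [r.p_gwas for r in recs
                       if r.chrom == gene.chrom
                       and gene.start <= r.pos <= gene.end]
        assert stats.kstest(pooled, "uniform").pvalue > 0.01

    def test_strong_effect_gives_small_p(self):
        medians = []
        for seed in range(10):
            cfg = small_config(seed, planted_genes=("G1_2",), alt_effect=4.0)
            panel = syn.simulate_panel(cfg)
            ann = syn.make_gene_annotation(cfg)
            recs = syn.simulate_summary_stats(cfg, panel, ann)
            gene = next(g for g in ann if g.gene_id == "G1_2")
            ps = [r.p_gwas for r in recs
                  if r.chrom == gene.chrom and gene.start <= r.pos <= gene.end]
            medians.append(np.median(ps))
        assert np.median(medians) < 1e-3

    def test_no_planted_genes_all_uniform(self):
        cfg = small_config(7)
        panel = syn.simulate_panel(cfg)
        recs = syn.simulate_summary_stats(cfg, panel,
                                          syn.make_gene_annotation(cfg))
        ps = [r.p_gwas for r in recs]
        assert stats.kstest(ps, "uniform").pvalue > 0.001


class TestPpi:
    def test_clique_when_q_in_one(self):
        cfg = small_config(1, planted_module=("G1_1", "G1_2", "G1_3"),
                           module_q_in=1.0)
        g = syn.simulate_ppi(cfg, [f"G1_{i}" for i in range(1, 11)])
        for a in cfg.planted_module:
            for b in cfg.planted_module:
                if a != b:
                    assert g.has_edge(a, b)

    def test_q_in_zero_adds_nothing(self):
        genes = [f"G1_{i}" for i in range(1, 11)]
        base = syn.simulate_ppi(small_config(2), genes)
        planted = syn.simulate_ppi(
            small_config(2, planted_module=tuple(genes[:3]),
                         module_q_in=0.0), genes)
        assert set(base.edges()) == set(planted.edges())

    def test_heavy_tailed_degrees(self):
        # preferential attachment: hubs far above the median degree
        for seed in range(10):
            cfg = syn.SimulationConfig(seed=seed, n_genes=600)
            genes = [f"G{i}" for i in range(600)]
            g = syn.simulate_ppi(cfg, genes)
            degrees = np.array([d for _, d in g.degree()])
            assert degrees.max() > 3 * np.median(degrees)

    def test_connected(self):
        import networkx as nx

        g = syn.simulate_ppi(small_config(3), [f"G{i}" for i in range(50)])
        assert nx.is_connected(g)


class TestPlantEpistasis:
    def test_zero_error_copies_exactly(self):
        cfg = small_config(1)
        panel = syn.simulate_panel(cfg)
        pair = syn.PlantedPair("rs1_5", "rs2_5", copy_error=0.0)
        out = syn.plant_epistasis(panel, (pair,), seed=0)
        np.testing.assert_array_equal(out.column("rs2_5"),
                                      out.column("rs1_5"))

    def test_half_error_attenuates_correlation(self):
        cfg = small_config(2, n_samples=10_000)
        panel = syn.simulate_panel(cfg)
        pair = syn.PlantedPair("rs1_5", "rs2_5", copy_error=0.5)
        out = syn.plant_epistasis(panel, (pair,), seed=1)
        r = np.corrcoef(out.column("rs1_5"), out.column("rs2_5"))[0, 1]
        assert r == pytest.approx(0.5, abs=0.05)

    def test_short_cis_pair_rejected(self):
        cfg = small_config(3)
        panel = syn.simulate_panel(cfg)
        pair = syn.PlantedPair("rs1_5", "rs1_6")
        with pytest.raises(ValueError, match="10"):
            syn.plant_epistasis(panel, (pair,), seed=0)

    def test_original_panel_untouched(self):
        cfg = small_config(4)
        panel = syn.simulate_panel(cfg)
        before = panel.dosages.copy()
        syn.plant_epistasis(panel, (syn.PlantedPair("rs1_5", "rs2_5", 0.0),),
                            seed=0)
        np.testing.assert_array_equal(panel.dosages, before)

    def test_haplotypes_stay_consistent(self):
        cfg = small_config(5)
        panel = syn.simulate_panel(cfg)
        out = syn.plant_epistasis(panel,
                                  (syn.PlantedPair("rs1_5", "rs2_5", 0.2),),
                                  seed=0)
        np.testing.assert_array_equal(
            out.dosages, out.haplotypes[0::2] + out.haplotypes[1::2])


class TestBundle:
    def test_fixture_round_trip(self, tmp_path):
        cfg = small_config(11, planted_genes=("G1_2",),
                           planted_module=("G1_2", "G1_3"),
                           n_background_terms=5)
        paths = syn.write_fixture_bundle(cfg, tmp_path)
        bundle = syn.generate_bundle(cfg)

        panel = io.read_genotypes_vcf(paths["vcf"])
        np.testing.assert_array_equal(panel.dosages, bundle.panel.dosages)
        np.testing.assert_array_equal(panel.haplotypes,
                                      bundle.panel.haplotypes)

        stats_back = io.read_summary_stats(paths["summary"])
        assert stats_back == sorted(
            bundle.summary_stats,
            key=lambda r: (r.chrom, r.pos, r.variant_id))

        assert io.read_gene_bed(paths["bed"]) == bundle.annotation
        assert set(io.read_ppi_edges(paths["ppi"]).edges()) == \
               set(bundle.ppi.edges())
        assert io.read_gmt(paths["gmt"]).terms == bundle.gmt.terms

        ihs = io.read_ihs_table(paths["ihs"])
        assert len(ihs) == len(bundle.ihs_table)

    def test_truth_manifest_lists_planted_entities(self, tmp_path):
        cfg = syn.default_config(13)
        paths = syn.write_fixture_bundle(cfg, tmp_path)
        truth = json.loads(paths["truth"].read_text())
        assert truth["planted_genes"] == list(cfg.planted_genes)
        assert truth["planted_module"] == list(cfg.planted_module)
        assert len(truth["planted_pairs"]) == len(cfg.planted_pairs)
        assert truth["true_term"] == syn.TRUE_TERM_ID

    def test_different_seeds_different_dosages(self):
        a = syn.generate_bundle(small_config(1))
        b = syn.generate_bundle(small_config(2))
        assert not np.array_equal(a.panel.dosages, b.panel.dosages)
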