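"""Generator contracts: determinism, LD structure, z-score sampling model."""

import numpy as np
import pytest
from scipy import stats as st

from pleiogene.synthetic import (
    PlantedLocus,
    SimConfig,
    TruthTable,
    benchmark_config,
    simulate_gene_annotation,
    simulate_reference_panel,
    simulate_sumstats,
)


def small_cfg(**kw):
    base = dict(n_individuals=300, n_blocks=2, snps_per_block=8,
                ancestral_haplotypes_per_block=5, seed=1, blocks_per_gene=1,
                traits=("t",))
    base.update(kw)
    return SimConfig(**base)


class TestPanelGeneration:
    def test_same_seed_is_bit_identical(self):
        a = simulate_reference_panel(small_cfg())
        b = simulate_reference_panel(small_cfg())
        assert np.array_equal(a.genotypes, b.genotypes)
        assert a.markers.equals(b.markers)

    def test_different_seed_differs(self):
        a = simulate_reference_panel(small_cfg())
        b = simulate_reference_panel(small_cfg(seed=2))
        assert not np.array_equal(a.genotypes, b.genotypes)

    @pytest.mark.parametrize(
        "kw", [dict(n_blocks=0), dict(n_individuals=1), dict(maf_range=(0.0, 0.5)),
               dict(maf_range=(0.2, 0.7)), dict(ancestral_haplotypes_per_block=0)]
    )
    def test_degenerate_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            small_cfg(**kw)

    def test_single_ancestral_haplotype_is_monomorphic(self):
        cfg = small_cfg(ancestral_haplotypes_per_block=1, mutation_rate=0.0)
        panel = simulate_reference_panel(cfg)
        assert panel.is_monomorphic().all()
        # every individual identical and homozygous within each block
        assert np.all((panel.genotypes == 0) | (panel.genotypes == 2))
        assert (panel.genotypes == panel.genotypes[0]).all()

    def test_between_block_ld_is_negligible(self):
        cfg = small_cfg(n_individuals=2000, seed=5)
        panel = simulate_reference_panel(cfg)
        a = panel.genotypes[:, 0].astype(float)
        b = panel.genotypes[:, cfg.snps_per_block].astype(float)
        r = np.corrcoef(a, b)[0, 1]  # brute-force Pearson on dosage vectors
        assert r**2 < 0.05
        assert panel.ld_r2("rs0", f"rs{cfg.snps_per_block}") == pytest.approx(r**2)

    def test_positions_one_based_and_unique_ids(self):
        panel = simulate_reference_panel(small_cfg())
        assert (panel.markers["pos"] >= 1).all()
        assert panel.markers["snp_id"].is_unique


class TestGeneAnnotation:
    def test_planted_genes_present_and_overlapping_pair_identical(self):
        cfg = SimConfig(n_individuals=100, n_blocks=6, snps_per_block=4,
                        seed=0, blocks_per_gene=3, traits=("t",))
        panel = simulate_reference_panel(cfg)
        genes = simulate_gene_annotation(cfg, panel)
        names = set(genes["name"])
        assert {"GENE0", "GENE1", "GENE0-AS"} <= names
        g0 = genes[genes["name"] == "GENE0"].iloc[0]
        g0as = genes[genes["name"] == "GENE0-AS"].iloc[0]
        assert (g0["start"], g0["end"]) == (g0as["start"], g0as["end"])
        assert g0as["strand"] == "-"
        assert (genes["start"] >= 1).all()

    def test_genes_separated_by_more_than_10kb(self):
        cfg = SimConfig(n_individuals=100, n_blocks=6, snps_per_block=4,
                        seed=0, blocks_per_gene=3, traits=("t",))
        panel = simulate_reference_panel(cfg)
        genes = simulate_gene_annotation(cfg, panel).drop_duplicates(["start", "end"])
        for chrom, sub in genes.groupby("chrom"):
            sub = sub.sort_values("start")
            gaps = sub["start"].to_numpy()[1:] - sub["end"].to_numpy()[:-1]
            assert (gaps > 10_000).all()


class TestSumstats:
    def test_null_z_is_calibrated(self):
        cfg = SimConfig(n_individuals=500, n_blocks=50, snps_per_block=20,
                        ancestral_haplotypes_per_block=8, seed=9,
                        blocks_per_gene=1, traits=("t",))
        panel = simulate_reference_panel(cfg)
        df, _ = simulate_sumstats(panel, None, "t", 20_000, seed=9)
        frac = (df["P"] < 0.05).mean()
        n = len(df)
        assert n >= 900
        # binomial 99.9% envelope around 0.05 (SNPs within a block are
        # correlated, so allow a generous multiple of the iid width)
        assert abs(frac - 0.05) < 6 * np.sqrt(0.05 * 0.95 / n) + 0.01

    def test_p_matches_two_sided_normal_of_z(self):
        cfg = small_cfg()
        panel = simulate_reference_panel(cfg)
        df, _ = simulate_sumstats(panel, None, "t", 10_000, seed=2)
        z = df["BETA"] / df["SE"]
        assert np.allclose(df["P"], 2 * st.norm.sf(np.abs(z)), rtol=1e-10)

    def test_neighbor_mean_z_is_r_times_lambda(self):
        cfg = small_cfg(n_individuals=1500, seed=4)
        panel = simulate_reference_panel(cfg)
        causal = "rs3"
        truth = TruthTable((PlantedLocus("II", "G", ((causal, "t", 6.0),)),))
        R = panel.ld_matrix([causal, "rs4"])
        r = R[0, 1]
        zs = []
        for s in range(200):
            df, _ = simulate_sumstats(panel, truth, "t", 50_000, seed=1000 + s)
            row = df.set_index("SNP").loc["rs4"]
            zs.append(row["BETA"] / row["SE"])
        zs = np.array(zs)
        assert abs(zs.mean() - r * 6.0) < 3 * zs.std(ddof=1) / np.sqrt(len(zs))

    def test_z_correlation_across_seeds_approaches_panel_r(self):
        cfg = small_cfg(n_individuals=1500, seed=4)
        panel = simulate_reference_panel(cfg)
        ids = list(panel.snp_ids)
        R = panel.ld_matrix(ids)
        targets = {}
        iu = np.triu_indices(len(ids), 1)
        for want in (0.0, 0.5, 0.9):
            k = np.argmin(np.abs(R[iu] - want))
            targets[want] = (ids[iu[0][k]], ids[iu[1][k]], R[iu][k])
        Z = []
        for s in range(200):
            df, _ = simulate_sumstats(panel, None, "t", 50_000, seed=2000 + s)
            df = df.set_index("SNP")
            Z.append((df["BETA"] / df["SE"]).reindex(ids).to_numpy())
        Z = np.array(Z)
        for want, (a, b, r_panel) in targets.items():
            ia, ib = ids.index(a), ids.index(b)
            r_emp = np.corrcoef(Z[:, ia], Z[:, ib])[0, 1]
            assert abs(r_emp - r_panel) < 0.15, f"target {want}"

    def test_unknown_causal_snp_rejected(self):
        cfg = small_cfg()
        panel = simulate_reference_panel(cfg)
        truth = TruthTable((PlantedLocus("II", "G", (("rs_nope", "t", 6.0),)),))
        with pytest.raises(KeyError):
            simulate_sumstats(panel, truth, "t", 1000, seed=0)

    def test_null_regions_rarely_reach_selection_threshold(self):
        hits = 0
        n_seeds = 20
        for s in range(n_seeds):
            cfg = SimConfig(n_individuals=400, n_blocks=40, snps_per_block=20,
                            ancestral_haplotypes_per_block=8, seed=300 + s,
                            blocks_per_gene=1, traits=("t",))
            panel = simulate_reference_panel(cfg)
            df, _ = simulate_sumstats(panel, None, "t", 20_000, seed=300 + s)
            hits += df["P"].min() > 1e-5
        assert hits >= 0.9 * n_seeds


class TestBenchmarkConfig:
    def test_planted_scenario_counts(self):
        cfg = benchmark_config(seed=0)
        truth = TruthTable(cfg.planted_loci)
        counts = truth.to_frame()["scenario"].value_counts().to_dict()
        assert counts == {"I": 6, "II": 6, "III": 6, "mixed": 4}

    def test_causal_snps_exist_in_panel(self):
        cfg = benchmark_config(seed=0, n_regions=5, n_individuals=200)
        panel = simulate_reference_panel(cfg)
        truth = TruthTable(cfg.planted_loci)
        assert truth.causal_ids() <= set(panel.snp_ids)

    def test_sumstats_determinism_bytewise(self, bench_study):
        from pleiogene import synthetic

        cfg, panel, genes_df, truth, stats, _ = bench_study
        again, _ = synthetic.simulate_sumstats(
            panel, truth, cfg.traits[0], cfg.gwas_n_per_trait, cfg.seed,
            decoys_per_filter=cfg.decoys_per_filter)
        assert stats[cfg.traits[0]].equals(again)
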