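"""Conditional/joint selection: algebraic identities and oracle agreement."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as st

from pleiogene import cojo
from pleiogene.synthetic import (
    PlantedLocus,
    SimConfig,
    TruthTable,
    simulate_reference_panel,
    simulate_sumstats,
)

from conftest import make_panel


def records_from(panel, freq, beta, se, n=10_000):
    m = len(freq)
    z = np.asarray(beta) / np.asarray(se)
    return pd.DataFrame(
        {
            "SNP": list(panel.snp_ids)[:m],
            "CHR": panel.markers["chrom"].to_numpy()[:m],
            "BP": panel.markers["pos"].to_numpy()[:m],
            "FREQ": freq,
            "BETA": beta,
            "SE": se,
            "P": np.maximum(2 * st.norm.sf(np.abs(z)), 1e-300),
            "N": n,
        }
    )


def simulate_individual_region(seed, n=5000, m=10):
    """Individual-level genotypes + phenotype with 1-2 planted effects and
    marginal single-SNP statistics — the exact-regression oracle's input."""
    cfg = SimConfig(n_individuals=n, n_blocks=1, snps_per_block=m,
                    ancestral_haplotypes_per_block=25, seed=seed,
                    blocks_per_gene=1, traits=("t",), mutation_rate=0.02)
    panel = simulate_reference_panel(cfg)
    rng = np.random.default_rng([seed, 7])
    X = panel.genotypes.astype(float)
    keep = X.std(axis=0) > 0
    X, mk = X[:, keep], panel.markers[keep]
    m = X.shape[1]
    f = X.mean(axis=0) / 2
    causal = rng.choice(m, size=rng.integers(1, 3), replace=False)
    beta_true = np.zeros(m)
    for c in causal:
        beta_true[c] = rng.choice([-1, 1]) * 7.5 / np.sqrt(n * 2 * f[c] * (1 - f[c]))
    y = X @ beta_true + rng.standard_normal(n)
    Xc, yc = X - X.mean(axis=0), y - y.mean()
    sxx = (Xc**2).sum(axis=0)
    b = Xc.T @ yc / sxx
    resid_var = np.array([np.var(yc - b[j] * Xc[:, j], ddof=2) for j in range(m)])
    se = np.sqrt(resid_var * n / (n - 2) / sxx)
    p = 2 * st.norm.sf(np.abs(b / se))
    rec = pd.DataFrame({"SNP": mk["snp_id"].to_numpy(), "CHR": mk["chrom"].to_numpy(),
                        "BP": mk["pos"].to_numpy(), "FREQ": f, "BETA": b, "SE": se,
                        "P": np.maximum(p, 1e-300), "N": n})
    return panel, rec, Xc, yc, set(mk["snp_id"].to_numpy()[causal])


class TestJointFit:
    def test_single_record_equals_marginal(self, toy_panel):
        rec = records_from(toy_panel, [0.3], [0.05], [0.01])
        out = cojo.joint_fit(rec, toy_panel)
        assert out.loc[0, "BETA_J"] == pytest.approx(0.05)
        assert out.loc[0, "P_J"] == pytest.approx(rec.loc[0, "P"], rel=0.02)

    def test_orthogonal_records_keep_marginal_estimates(self):
        rng = np.random.default_rng(0)
        g = np.stack([rng.integers(0, 3, 4000), rng.integers(0, 3, 4000)], axis=1)
        panel = make_panel(g)
        r = panel.ld_r("s0", "s1")
        assert abs(r) < 0.05
        rec = records_from(panel, [0.5, 0.5], [0.03, -0.02], [0.01, 0.01])
        out = cojo.joint_fit(rec, panel)
        # r is not exactly 0 in a finite panel; agreement is near-exact
        assert np.allclose(out["BETA_J"], rec["BETA"], atol=2e-3)
        assert np.allclose(out["SE_J"], rec["SE"], rtol=0.02)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exact_regression_on_individual_data(self, seed):
        panel, rec, Xc, yc, _ = simulate_individual_region(seed)
        out = cojo.joint_fit(rec, panel)
        exact, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
        assert np.max(np.abs(out["BETA_J"].to_numpy() - exact)) < 0.05

    def test_collinear_system_names_offenders(self):
        g = np.tile(np.array([[0, 0], [1, 1], [2, 2]]), (30, 1))
        panel = make_panel(g)
        rec = records_from(panel, [0.5, 0.5], [0.03, 0.03], [0.01, 0.01])
        with pytest.raises(cojo.CollinearityError) as err:
            cojo.joint_fit(rec, panel)
        assert "s0" in str(err.value) and "s1" in str(err.value)


class TestConditionalP:
    def test_empty_selected_set_gives_marginal_p(self, toy_panel):
        rec = records_from(toy_panel, [0.3, 0.4], [0.05, 0.01], [0.01, 0.01])
        res = cojo.conditional_p("s0", [], rec, toy_panel)
        assert res["p"] == pytest.approx(rec.loc[0, "P"], rel=0.02)

    def test_perfect_ld_candidate_flagged_collinear(self):
        g = np.tile(np.array([[0, 0], [1, 1], [2, 2]]), (30, 1))
        panel = make_panel(g)
        rec = records_from(panel, [0.5, 0.5], [0.03, 0.03], [0.01, 0.01])
        res = cojo.conditional_p("s1", ["s0"], rec, panel)
        assert res["collinear"]

    def test_orthogonal_candidate_keeps_marginal_p(self):
        rng = np.random.default_rng(1)
        g = np.stack([rng.integers(0, 3, 4000), rng.integers(0, 3, 4000)], axis=1)
        panel = make_panel(g)
        # betas of the same small scale: the conditioning shift through the
        # finite-panel residual r (~0.02) is then second order
        rec = records_from(panel, [0.5, 0.5], [0.01, 0.01], [0.01, 0.01])
        res = cojo.conditional_p("s1", ["s0"], rec, panel)
        assert res["p"] == pytest.approx(rec.loc[1, "P"], rel=0.1)


def planted_region(seed, n_causal=2, lam=6.0):
    cfg = SimConfig(n_individuals=1000, n_blocks=3, snps_per_block=12,
                    ancestral_haplotypes_per_block=8, seed=seed,
                    blocks_per_gene=3, traits=("t",))
    panel = simulate_reference_panel(cfg)
    causal = ("rs6", "rs18")[:n_causal]
    truth = TruthTable((PlantedLocus("II", "GENE0",
                                     tuple((c, "t", lam) for c in causal)),))
    df, _ = simulate_sumstats(panel, truth, "t", 50_000, seed=seed)
    return panel, df, causal


class TestSelectSignals:
    def test_single_causal_region_yields_one_signal(self):
        panel, df, causal = planted_region(seed=0, n_causal=1, lam=8.0)
        sigs = cojo.select_signals(df, panel, trait="t")
        assert len(sigs) == 1
        sig = sigs[0]
        r2 = 1.0 if sig.snp_id == causal[0] else panel.ld_r2(sig.snp_id, causal[0])
        assert r2 > 0.5  # the causal SNP or a close proxy

    def test_two_block_heterogeneity_recovers_both(self):
        found = 0
        for seed in range(6):
            panel, df, causal = planted_region(seed=100 + seed)
            sigs = cojo.select_signals(df, panel, trait="t")
            hit = 0
            for c in causal:
                hit += any(
                    s.snp_id == c or panel.ld_r2(s.snp_id, c) > 0.3 for s in sigs
                )
            found += hit == 2
        assert found >= 5

    def test_final_signals_mutually_quasi_independent(self):
        panel, df, _ = planted_region(seed=3)
        params = cojo.CojoParams()
        sigs = cojo.select_signals(df, panel, params, trait="t")
        for i, a in enumerate(sigs):
            for b in sigs[i + 1:]:
                assert panel.ld_r2(a.snp_id, b.snp_id) < params.collinearity_r2
        assert all(s.p_j < params.p_select for s in sigs) or len(sigs) == 1

    def test_threshold_monotonicity_on_coincident_paths(self):
        panel, df, _ = planted_region(seed=5)
        strict = cojo.select_signals(df, panel, cojo.CojoParams(p_select=1e-6), "t")
        loose = cojo.select_signals(df, panel, cojo.CojoParams(p_select=1e-4), "t")
        strict_ids = {s.snp_id for s in strict}
        loose_ids = {s.snp_id for s in loose}
        if strict_ids <= loose_ids:  # greedy paths coincide
            assert len(loose_ids) >= len(strict_ids)
        else:  # paths diverged; the invariant is not asserted
            pytest.skip("greedy paths diverged on this seed")

    def test_null_false_signal_rate_matches_bonferroni_expectation(self):
        # expectation: n_snps * p_select false signals per null run
        total = 0
        n_seeds, n_snps = 60, 2000
        for s in range(n_seeds):
            cfg = SimConfig(n_individuals=300, n_blocks=20, snps_per_block=100,
                            ancestral_haplotypes_per_block=16, seed=700 + s,
                            blocks_per_gene=1, traits=("t",), mutation_rate=0.02)
            panel = simulate_reference_panel(cfg)
            df, _ = simulate_sumstats(panel, None, "t", 20_000, seed=700 + s)
            total += len(cojo.select_signals(df, panel, trait="t"))
        lam = n_seeds * n_snps * 1e-5  # = 1.2 expected in total
        assert total <= lam + 3 * np.sqrt(lam) + 1
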