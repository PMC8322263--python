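"""Brown combined p-values: identities, calibration and gene selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as hst
from scipy import stats as st

from pleiogene.brown import (
    brown_score,
    fdr_adjust_within_trait,
    gene_score_threshold,
    score_all_genes,
    select_pleiotropic_genes,
)
from pleiogene.genes import Gene, assign_snps_to_genes, merge_gene_blocks

from conftest import make_panel


class TestBrownScore:
    def test_single_test_identity(self):
        s = brown_score([0.01], np.eye(1))
        assert s.p_brown == pytest.approx(0.01, abs=1e-12)
        assert s.c == pytest.approx(1.0) and s.f == pytest.approx(2.0)

    def test_equals_fisher_when_independent(self):
        p = np.array([0.01, 0.2, 0.5, 0.9])
        fisher = st.chi2.sf(-2 * np.log(p).sum(), 2 * len(p))
        assert brown_score(p, np.eye(4)).p_brown == pytest.approx(fisher, abs=1e-12)

    def test_duplicate_test_identity_at_perfect_correlation(self):
        R = np.array([[1.0, 1.0], [1.0, 1.0]])
        s = brown_score([0.03, 0.03], R)
        # cov(1) = 3.263+0.710+0.027 = 4 exactly -> c = 2, f = 2
        assert s.c == pytest.approx(2.0, abs=1e-12)
        assert s.f == pytest.approx(2.0, abs=1e-12)
        assert s.p_brown == pytest.approx(0.03, abs=1e-10)
        s_neg = brown_score([0.03, 0.03], -R + 2 * np.eye(2))
        assert s_neg.p_brown == pytest.approx(s.p_brown, abs=1e-12)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(hst.integers(0, 10_000))
    def test_reorder_invariance(self, seed):
        rng = np.random.default_rng(seed)
        k = rng.integers(2, 7)
        A = rng.standard_normal((k, 2))
        R = np.corrcoef(A @ A.T + np.eye(k))
        p = rng.uniform(1e-6, 1, k)
        perm = rng.permutation(k)
        a = brown_score(p, R).p_brown
        b = brown_score(p[perm], R[np.ix_(perm, perm)]).p_brown
        assert a == pytest.approx(b, rel=1e-12)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            brown_score([0.0, 0.5], np.eye(2))
        with pytest.raises(ValueError):
            brown_score([], np.eye(0))

    def test_null_calibration_under_strong_ld(self):
        # correlated-null z-scores, k = 10, |r| up to ~0.9
        rng = np.random.default_rng(5)
        k, reps = 10, 2000
        A = rng.standard_normal((k, 2)) * 1.2
        S = A @ A.T + np.diag(rng.uniform(0.1, 0.6, k))
        d = np.sqrt(np.diag(S))
        R = S / np.outer(d, d)
        w, v = np.linalg.eigh(R)
        R = (v * np.clip(w, 1e-6, None)) @ v.T
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
        L = np.linalg.cholesky(R)
        Z = (L @ rng.standard_normal((k, reps))).T
        P = 2 * st.norm.sf(np.abs(Z))
        hits = sum(brown_score(P[i], R).p_brown < 0.05 for i in range(reps))
        assert 0.03 < hits / reps < 0.08  # tighter band tested at 10k reps


def bh_oracle(p):
    """Independent Benjamini–Hochberg step-up implementation."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        q[i] = prev
    return q


class TestFdr:
    def test_single_gene_q_equals_p(self):
        df = pd.DataFrame({"group": ["g"], "trait": ["t"], "p_brown": [0.02]})
        out = fdr_adjust_within_trait(df)
        assert out.loc[0, "q"] == pytest.approx(0.02)

    def test_all_equal_p_all_equal_q(self):
        df = pd.DataFrame({"group": list("abc"), "trait": "t", "p_brown": 0.01})
        out = fdr_adjust_within_trait(df)
        assert np.allclose(out["q"], 0.01)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(hst.integers(0, 10_000))
    def test_matches_step_up_oracle_per_trait(self, seed):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame({
            "group": [f"g{i}" for i in range(12)],
            "trait": ["t1"] * 6 + ["t2"] * 6,
            "p_brown": rng.uniform(1e-8, 1, 12),
        })
        out = fdr_adjust_within_trait(df)
        for trait, sub in out.groupby("trait"):
            assert np.allclose(sub["q"], bh_oracle(sub["p_brown"]))
        assert (out["q"] >= out["p_brown"] - 1e-15).all()


class TestScoreThreshold:
    def test_27_traits_truncates_to_0_0018(self):
        assert gene_score_threshold(27) == pytest.approx(0.0018, abs=1e-12)

    @pytest.mark.parametrize("n,expected", [(1, 0.05), (2, 0.025), (10, 0.005)])
    def test_simple_cases(self, n, expected):
        assert gene_score_threshold(n) == pytest.approx(expected)


def region_fixture():
    """Panel of 4 markers, one gene over the first three."""
    rng = np.random.default_rng(2)
    n = 500
    g0 = rng.integers(0, 3, n)
    g1 = np.where(rng.random(n) < 0.8, g0, rng.integers(0, 3, n))
    g2 = rng.integers(0, 3, n)
    g3 = rng.integers(0, 3, n)
    panel = make_panel(np.stack([g0, g1, g2, g3], axis=1),
                       pos=[1000, 2000, 3000, 200_000])
    gene = Gene("G", 1, 500, 3500)
    assignments, _ = assign_snps_to_genes(
        pd.DataFrame({"SNP": ["s0", "s1", "s2"], "CHR": 1,
                      "BP": [1000, 2000, 3000]}), [gene])
    groups = merge_gene_blocks(assignments, [gene])
    return panel, groups


def trait_table(ps, chrom="1"):
    return pd.DataFrame({
        "SNP": [f"s{i}" for i in range(len(ps))],
        "CHR": chrom,
        "BP": [1000, 2000, 3000, 200_000][: len(ps)],
        "P": ps,
    })


class TestScoreAllGenes:
    def test_single_snp_group_reduces_to_snp_p(self):
        panel, _ = region_fixture()
        gene = Gene("G1", 1, 150_000, 250_000)
        assignments, _ = assign_snps_to_genes(
            pd.DataFrame({"SNP": ["s3"], "CHR": 1, "BP": [200_000]}), [gene])
        groups = merge_gene_blocks(assignments, [gene])
        scores = score_all_genes(groups, {"t": trait_table([0.5, 0.5, 0.5, 0.004])},
                                 panel)
        assert len(scores) == 1
        assert scores.loc[0, "p_brown"] == pytest.approx(0.004)

    def test_snp_order_irrelevant(self):
        panel, groups = region_fixture()
        t = trait_table([0.01, 0.2, 0.05])
        a = score_all_genes(groups, {"t": t}, panel)
        b = score_all_genes(groups, {"t": t.iloc[::-1].reset_index(drop=True)}, panel)
        assert a.loc[0, "p_brown"] == pytest.approx(b.loc[0, "p_brown"])

    def test_absent_snps_dropped(self):
        panel, groups = region_fixture()
        t = trait_table([0.01, 0.2, 0.05])
        t.loc[len(t)] = ["not_in_panel", "1", 2500, 0.001]
        scores = score_all_genes(groups, {"t": t}, panel)
        assert scores.loc[0, "k"] == 3


class TestSelectPleiotropic:
    def make_scores(self, q1, q2, min_p):
        return pd.DataFrame({
            "group": "G", "trait": ["t1", "t2"], "k": 3, "X": 1.0, "c": 1.0,
            "f": 6.0, "p_brown": [q1, q2], "min_p": min_p,
            "min_p_snp": ["s0", "s2"], "q": [q1, q2],
        })

    def test_two_trait_gene_with_good_minp_selected(self):
        panel, _ = region_fixture()
        scores = self.make_scores(1e-4, 1e-4, [1e-7, 1e-7])
        out = select_pleiotropic_genes(scores, {}, panel, 0.0018, 5.7e-6)
        assert len(out) == 1
        assert out.loc[0, "category"] == "independent_markers"

    def test_single_trait_gene_excluded(self):
        panel, _ = region_fixture()
        scores = self.make_scores(1e-4, 0.5, [1e-7, 1e-7])
        out = select_pleiotropic_genes(scores, {}, panel, 0.0018, 5.7e-6)
        assert out.empty

    def test_minp_filter_applies(self):
        panel, _ = region_fixture()
        scores = self.make_scores(1e-4, 1e-4, [1e-5, 1e-5])  # worse than 5.7e-6
        out = select_pleiotropic_genes(scores, {}, panel, 0.0018, 5.7e-6)
        assert out.loc[0, "category"] == "minp_fail"

    def test_marker_confirmed_wins_over_ld_categories(self):
        panel, _ = region_fixture()
        scores = self.make_scores(1e-4, 1e-4, [1e-7, 1e-7])
        out = select_pleiotropic_genes(scores, {"G": "I"}, panel, 0.0018, 5.7e-6)
        assert out.loc[0, "category"] == "marker_confirmed"

    def test_dependent_markers_category(self):
        panel, _ = region_fixture()
        scores = self.make_scores(1e-4, 1e-4, [1e-7, 1e-7])
        scores["min_p_snp"] = ["s0", "s1"]  # strong LD pair
        out = select_pleiotropic_genes(scores, {}, panel, 0.0018, 5.7e-6)
        assert out.loc[0, "category"] == "dependent_markers"
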