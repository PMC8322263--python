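"""LD-corrected Brown gene scores and cross-trait pleiotropic-gene selection.

Brown's method extends Fisher's combined test X = −2 Σ ln p_i to
correlated p-values by moment-matching X to a scaled chi-square c·χ²_f:
E[X] = 2k and Var[X] = 4k + 2 Σ_{i<j} cov_ij, with the covariance of
(−2 ln p_i, −2 ln p_j) approximated from the test-statistic correlation ρ
by the Kost–McDermott polynomial cov(a) = 3.263a + 0.710a² + 0.027a³.

GWAS p-values are two-sided, i.e. functions of z², and the correlation
between the underlying χ² statistics is ρ², so the polynomial is applied
to a = ρ² by default (``cov_mode="two_sided"``); a = |ρ| reproduces the
classical one-sided form (``cov_mode="one_sided"``) but is markedly
conservative on two-sided inputs.  Both forms reach exactly 4 at |ρ| = 1,
recovering the duplicate-test identity, and reduce to Fisher's method at
ρ = 0.  Panel genotype correlation proxies ρ, the standard practice for
gene scores from summary statistics.  Scores are FDR-adjusted
within each trait (Benjamini–Hochberg); a gene is called pleiotropic when
its adjusted score passes the study threshold (0.05 / number of traits,
truncated to four decimals: 0.05/27 → 0.0018) in at least two traits and
its best SNP also passes the experiment-wide marker threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import floor

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genes import FLANK_BP, GeneGroup, collect_region_snps
from .panel import GenotypePanel, MonomorphicMarkerError

__all__ = [
    "BrownScore",
    "brown_score",
    "score_all_genes",
    "fdr_adjust_within_trait",
    "gene_score_threshold",
    "select_pleiotropic_genes",
]

P_FLOOR = 1e-300
_KOST = (3.263, 0.710, 0.027)

CATEGORIES = (
    "marker_confirmed",
    "independent_markers",
    "dependent_markers",
    "mixed",
    "minp_fail",
)


@dataclass(frozen=True)
class BrownScore:
    """Combined p-value for one gene and one trait."""

    k: int          # number of SNPs combined
    X: float        # Fisher statistic -2 sum ln p
    c: float        # scale of the matched chi-square
    f: float        # effective degrees of freedom
    p_brown: float


def _kost_cov(r: np.ndarray, cov_mode: str = "two_sided") -> np.ndarray:
    if cov_mode == "two_sided":
        a = np.asarray(r) ** 2
    elif cov_mode == "one_sided":
        a = np.abs(r)
    else:
        raise ValueError(f"unknown cov_mode {cov_mode!r}")
    return a * (_KOST[0] + _KOST[1] * a + _KOST[2] * a**2)


def brown_score(pvalues, R: np.ndarray, cov_mode: str = "two_sided") -> BrownScore:
    """Brown combined p-value for correlated tests.

    ``R`` is the signed correlation matrix matching the order of
    ``pvalues`` (only the magnitude of r enters the covariance, so sign
    flips are irrelevant).  p-values must lie in (0, 1]; callers floor
    zeros.  With k = 1 the score is the input p; with R = I it reduces
    exactly to Fisher's method.  See the module docstring for
    ``cov_mode``.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]; floor zeros first")
    R = np.atleast_2d(np.asarray(R, dtype=float))
    if R.shape != (p.size, p.size):
        raise ValueError("R shape does not match the number of p-values")
    k = p.size
    X = float(-2.0 * np.sum(np.log(p)))
    mean = 2.0 * k
    iu = np.triu_indices(k, 1)
    var = 4.0 * k + 2.0 * float(np.sum(_kost_cov(R[iu], cov_mode)))
    c = var / (2.0 * mean)
    f = 2.0 * mean**2 / var
    p_brown = float(stats.chi2.sf(X / c, f))
    return BrownScore(k=k, X=X, c=c, f=f, p_brown=max(p_brown, P_FLOOR))


def score_all_genes(
    groups: list[GeneGroup],
    sumstats_by_trait: dict[str, pd.DataFrame],
    panel: GenotypePanel,
    flank_bp: int = FLANK_BP,
) -> pd.DataFrame:
    """One Brown score per (group, trait) over all QC'd SNPs in the block
    ± flank present in both the sumstats and the panel.

    Returns a long table with columns ``group trait k X c f p_brown min_p
    min_p_snp``; (group, trait) cells with no usable SNP are absent.
    Monomorphic or missing panel markers are dropped before scoring.
    """
    rows = []
    for group in groups:
        region = collect_region_snps(group, sumstats_by_trait, flank_bp)
        for trait, df in region.items():
            in_panel = df["SNP"].isin(panel.snp_ids)
            df = df.loc[in_panel]
            if not len(df):
                continue
            ids = list(df["SNP"])
            poly = ~panel.is_monomorphic(ids)
            df = df.loc[poly]
            if not len(df):
                continue
            ids = list(df["SNP"])
            R = panel.ld_matrix(ids)
            p = np.maximum(df["P"].to_numpy(float), P_FLOOR)
            score = brown_score(p, R)
            imin = int(np.argmin(p))
            rows.append(
                {
                    "group": group.name,
                    "trait": trait,
                    "k": score.k,
                    "X": score.X,
                    "c": score.c,
                    "f": score.f,
                    "p_brown": score.p_brown,
                    "min_p": float(p[imin]),
                    "min_p_snp": ids[imin],
                }
            )
    return pd.DataFrame(
        rows,
        columns=["group", "trait", "k", "X", "c", "f", "p_brown", "min_p", "min_p_snp"],
    )


def fdr_adjust_within_trait(scores: pd.DataFrame) -> pd.DataFrame:
    """Benjamini–Hochberg step-up within each trait; appends a ``q`` column."""
    out = scores.copy()
    out["q"] = np.nan
    for trait, sub in out.groupby("trait"):
        q = multipletests(sub["p_brown"].to_numpy(), method="fdr_bh")[1]
        out.loc[sub.index, "q"] = q
    return out


def gene_score_threshold(n_traits: int, decimals: int = 4) -> float:
    """Study threshold for the FDR-adjusted gene score: 0.05 / n_traits,
    truncated to ``decimals`` decimals (0.05/27 → 0.0018)."""
    if n_traits < 1:
        raise ValueError("n_traits must be >= 1")
    raw = 0.05 / n_traits
    scale = 10**decimals
    truncated = floor(raw * scale) / scale
    return truncated if truncated > 0 else raw


def select_pleiotropic_genes(
    scores: pd.DataFrame,
    classifications: dict[str, str],
    panel: GenotypePanel,
    q_thresh: float,
    minp_thresh: float,
    dependence_r2: float = 0.2,
) -> pd.DataFrame:
    """Cross-trait gene selection with the marker-level follow-up filter.

    A gene qualifies when its FDR-adjusted Brown score passes ``q_thresh``
    in at least two traits.  Genes whose minimal SNP p-value across the
    qualifying traits exceeds ``minp_thresh`` fall into ``minp_fail``;
    survivors are categorized as ``marker_confirmed`` when the marker-based
    analysis already classified the group, else by the LD between the
    per-trait top SNPs across qualifying trait pairs:
    ``independent_markers`` (all r² < 0.2), ``dependent_markers``
    (all ≥ 0.2) or ``mixed``.
    """
    if "q" not in scores.columns:
        raise ValueError("scores must be FDR-adjusted first")
    rows = []
    for group, sub in scores.groupby("group"):
        qual = sub.loc[sub["q"] < q_thresh]
        if len(qual) < 2:
            continue
        traits = tuple(sorted(qual["trait"]))
        min_p = float(qual["min_p"].min())
        if min_p > minp_thresh:
            category = "minp_fail"
        elif classifications.get(group) in ("I", "II", "III", "mixed"):
            category = "marker_confirmed"
        else:
            top = dict(zip(qual["trait"], qual["min_p_snp"]))
            r2s = []
            for a, b in combinations(sorted(top), 2):
                if top[a] == top[b]:
                    r2s.append(1.0)
                    continue
                try:
                    r2s.append(panel.ld_r2(top[a], top[b]))
                except MonomorphicMarkerError:
                    continue
            if r2s and all(r < dependence_r2 for r in r2s):
                category = "independent_markers"
            elif r2s and all(r >= dependence_r2 for r in r2s):
                category = "dependent_markers"
            else:
                category = "mixed"
        rows.append(
            {
                "group": group,
                "traits": ";".join(traits),
                "n_traits": len(traits),
                "min_p": min_p,
                "category": category,
            }
        )
    return pd.DataFrame(rows, columns=["group", "traits", "n_traits", "min_p", "category"])
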