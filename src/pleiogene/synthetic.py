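"""Synthetic multi-trait GWAS study generator with planted truth.

Builds the three inputs the analysis pipeline consumes — a diploid
reference panel with block-structured LD, a gene annotation covering the
planted loci, and per-trait GWAS summary statistics — together with a
machine-readable truth table, so that signal selection, scenario
classification, gene scores and haplotype placement can all be tested
against known ground truth.

The model
---------
* The panel is a mosaic of per-block ancestral haplotypes: each LD block
  has a small pool of ancestral haplotypes with Dirichlet-distributed
  population weights, and every chromosome copy of every individual draws
  one pool member per block independently (plus a small per-site mutation
  rate).  This yields strong within-block LD and essentially zero LD
  between blocks.
* Summary statistics are generated directly on the z-score scale: within
  each LD block, z ~ MVN(R·λ, R) where R is the panel's signed dosage
  correlation matrix (eigenvalue-floored for positive definiteness) and λ
  the planted noncentrality vector.  β = z·SE with SE = 1/sqrt(2f(1−f)n),
  which is exactly the sampling model the conditional-selection stage
  assumes, so parameter-recovery tests are sharp.
* Planted loci realize the cross-trait scenarios: gene-level pleiotropy
  (LD-independent variants, different traits), allelic heterogeneity
  (LD-independent variants, one trait), SNP-level pleiotropy (one variant
  shared across traits), and mixed loci carrying both.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .panel import GenotypePanel, regularize_corr

__all__ = [
    "SimConfig",
    "PlantedLocus",
    "TruthTable",
    "simulate_reference_panel",
    "simulate_gene_annotation",
    "simulate_sumstats",
    "simulate_study",
    "benchmark_config",
]

SCENARIOS = ("I", "II", "III", "mixed", "null")
AUTOSOMES = tuple(range(1, 23))
# strand-unambiguous allele pairs only, so panel markers never trip the
# ambiguous-SNP QC filter by construction
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]

SUMSTATS_COLUMNS = ["SNP", "CHR", "BP", "A1", "A2", "FREQ", "BETA", "SE", "P", "N", "INFO"]
DECOY_REASONS = ("low_info", "low_maf", "ambiguous", "indel", "non_autosome")


@dataclass(frozen=True)
class PlantedLocus:
    """A causal locus: scenario label, host gene, and (snp, trait, λ) triples."""

    scenario: str
    gene_name: str
    causal_snps: tuple  # of (snp_id, trait, lambda)

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")


@dataclass
class SimConfig:
    n_individuals: int = 2000
    n_blocks: int = 6
    snps_per_block: int = 16
    block_span_bp: int = 20_000
    ancestral_haplotypes_per_block: int = 8
    maf_range: tuple[float, float] = (0.15, 0.5)
    traits: tuple[str, ...] = ("traitA",)
    gwas_n_per_trait: int = 50_000
    planted_loci: tuple[PlantedLocus, ...] = ()
    seed: int = 0
    # layout / nuisance knobs
    blocks_per_gene: int = 3
    inter_block_gap_bp: int = 2_000
    mutation_rate: float = 0.005
    antisense_duplicate: bool = True
    decoys_per_filter: int = 0

    def __post_init__(self):
        if self.n_individuals < 2:
            raise ValueError("n_individuals must be >= 2")
        if self.n_blocks < 1 or self.snps_per_block < 1:
            raise ValueError("need at least one block and one SNP per block")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.ancestral_haplotypes_per_block < 1:
            raise ValueError("ancestral_haplotypes_per_block must be >= 1")
        if self.block_span_bp < self.snps_per_block:
            raise ValueError("block_span_bp too small for snps_per_block")
        self.traits = tuple(self.traits)
        self.planted_loci = tuple(self.planted_loci)

    @property
    def n_genes(self) -> int:
        return self.n_blocks // self.blocks_per_gene


@dataclass
class TruthTable:
    """One row per planted locus, with helpers to build λ vectors."""

    loci: tuple[PlantedLocus, ...]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for loc in self.loci:
            rows.append(
                {
                    "gene_name": loc.gene_name,
                    "scenario": loc.scenario,
                    "causal": ";".join(f"{s}:{t}:{l:g}" for s, t, l in loc.causal_snps),
                }
            )
        return pd.DataFrame(rows, columns=["gene_name", "scenario", "causal"])

    def scenario_of_gene(self) -> dict[str, str]:
        return {loc.gene_name: loc.scenario for loc in self.loci}

    def causal_ids(self, trait: str | None = None) -> set[str]:
        return {
            s
            for loc in self.loci
            for s, t, _ in loc.causal_snps
            if trait is None or t == trait
        }

    def lambda_vector(self, trait: str, panel: GenotypePanel) -> np.ndarray:
        lam = np.zeros(panel.n_markers)
        for loc in self.loci:
            for snp, t, value in loc.causal_snps:
                if t != trait:
                    continue
                if snp not in panel:
                    raise KeyError(f"unknown causal SNP id {snp!r}")
                lam[panel.indices([snp])[0]] += value
        return lam


# ---------------------------------------------------------------------------
# layout


def _block_layout(config: SimConfig) -> pd.DataFrame:
    """Chromosome/start for every block; genes occupy consecutive block
    triples, each layout unit 20 Mb from its neighbours on a chromosome."""
    rows = []
    bpg = config.blocks_per_gene
    covered = config.n_genes * bpg
    for b in range(config.n_blocks):
        if b < covered:
            unit, local = divmod(b, bpg)
            gene = unit
        else:
            unit = config.n_genes + (b - covered)
            local, gene = 0, -1
        chrom = AUTOSOMES[unit % len(AUTOSOMES)]
        slot = unit // len(AUTOSOMES)
        start = 1_000_000 + slot * 20_000_000 + local * (
            config.block_span_bp + config.inter_block_gap_bp
        )
        rows.append({"block": b, "chrom": chrom, "start": start, "gene": gene})
    return pd.DataFrame(rows)


def snp_id_for(config: SimConfig, block: int, snp_in_block: int) -> str:
    """Deterministic marker naming, usable before the panel is built."""
    return f"rs{block * config.snps_per_block + snp_in_block}"


# ---------------------------------------------------------------------------
# panel


def simulate_reference_panel(config: SimConfig) -> GenotypePanel:
    """Mosaic-of-ancestral-haplotypes diploid panel (see module docstring).

    Deterministic under ``config.seed``: the same config yields a
    bit-identical panel.
    """
    rng = np.random.default_rng([config.seed, 101])
    layout = _block_layout(config)
    m, K, N = config.snps_per_block, config.ancestral_haplotypes_per_block, config.n_individuals
    lo, _hi = config.maf_range
    spacing = max(config.block_span_bp // m, 1)

    marker_rows = []
    geno_cols = []
    for _, blk in layout.iterrows():
        # ancestral pool with population weights; resample sites whose pooled
        # frequency falls outside the target MAF band
        w = rng.dirichlet(np.full(K, 3.0)) if K > 1 else np.array([1.0])
        H = np.zeros((K, m), dtype=np.int8)
        for j in range(m):
            p = rng.uniform(config.maf_range[0], config.maf_range[1])
            col = (rng.random(K) < p).astype(np.int8)
            if K > 1:
                for _try in range(50):
                    pooled = float(w @ col)
                    if lo <= pooled <= 1 - lo:
                        break
                    col = (rng.random(K) < 0.5).astype(np.int8)
            H[:, j] = col
        choice = rng.choice(K, size=(N, 2), p=w)
        haps = H[choice]  # (N, 2, m)
        if config.mutation_rate > 0:
            flips = rng.random(haps.shape) < config.mutation_rate
            haps = haps ^ flips
        geno_cols.append(haps.sum(axis=1).astype(np.int8))

        for j in range(m):
            a, b = _ALLELE_PAIRS[rng.integers(len(_ALLELE_PAIRS))]
            marker_rows.append(
                {
                    "snp_id": snp_id_for(config, int(blk["block"]), j),
                    "chrom": int(blk["chrom"]),
                    "pos": int(blk["start"] + j * spacing),
                    "allele_a": a,
                    "allele_b": b,
                    "block": int(blk["block"]),
                }
            )
    markers = pd.DataFrame(marker_rows)
    genotypes = np.concatenate(geno_cols, axis=1)
    # order markers by (chrom, pos) as a panel requires
    order = np.lexsort((markers["pos"].to_numpy(), markers["chrom"].to_numpy()))
    return GenotypePanel(markers.iloc[order], genotypes[:, order])


# ---------------------------------------------------------------------------
# genes


def simulate_gene_annotation(config: SimConfig, panel: GenotypePanel) -> pd.DataFrame:
    """Gene table covering the planted loci (1-based inclusive coordinates).

    Each gene spans ``blocks_per_gene`` consecutive LD blocks; one fully
    overlapping antisense duplicate of the first gene is emitted (it covers
    the identical markers and must merge into a gene_block downstream), and
    genes sit far apart (>10 kb), leaving any leftover blocks unannotated.
    """
    layout = _block_layout(config)
    rows = []
    for g in range(config.n_genes):
        blocks = layout[layout["gene"] == g]
        sub = panel.markers[panel.markers["block"].isin(blocks["block"])]
        start = max(int(sub["pos"].min()) - 500, 1)
        end = int(sub["pos"].max()) + 500
        rows.append(
            {
                "chrom": int(blocks["chrom"].iloc[0]),
                "start": start,
                "end": end,
                "name": f"GENE{g}",
                "score": 0,
                "strand": "+",
            }
        )
    if rows and config.antisense_duplicate:
        first = dict(rows[0])
        first["name"] = rows[0]["name"] + "-AS"
        first["strand"] = "-"
        rows.append(first)
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])


# ---------------------------------------------------------------------------
# summary statistics


def _trait_rng(seed: int, trait: str) -> np.random.Generator:
    return np.random.default_rng([seed, 202, zlib.crc32(trait.encode()) & 0x7FFFFFFF])


def simulate_sumstats(
    panel: GenotypePanel,
    truth: TruthTable | None,
    trait: str,
    n: int,
    seed: int,
    info_range: tuple[float, float] = (0.9, 1.0),
    decoys_per_filter: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Marginal GWAS summary statistics for one trait.

    Returns ``(sumstats, decoys)``: the sumstats table (columns
    ``SNP CHR BP A1 A2 FREQ BETA SE P N INFO``, effect allele = panel
    allele B) and a table labelling injected QC-failure decoy rows
    (empty when ``decoys_per_filter`` is 0).  Monomorphic panel markers
    are not reported (a real GWAS would not emit them).
    """
    rng = _trait_rng(seed, trait)
    lam = (
        truth.lambda_vector(trait, panel)
        if truth is not None
        else np.zeros(panel.n_markers)
    )
    if "block" in panel.markers.columns:
        block_ids = panel.markers["block"].to_numpy()
    else:
        block_ids = panel.markers["chrom"].to_numpy()

    f_panel = panel.freq()
    poly = (f_panel > 0) & (f_panel < 1)
    z = np.zeros(panel.n_markers)
    for b in np.unique(block_ids):
        idx = np.flatnonzero((block_ids == b) & poly)
        if idx.size == 0:
            continue
        g = panel.genotypes[:, idx].astype(float)
        R = np.corrcoef(g, rowvar=False) if idx.size > 1 else np.array([[1.0]])
        R = regularize_corr(np.atleast_2d(R))
        L = np.linalg.cholesky(R)
        mean = R @ lam[idx]
        z[idx] = mean + L @ rng.standard_normal(idx.size)

    keep = np.flatnonzero(poly)
    f_hat = rng.binomial(2 * n, f_panel[keep]) / (2.0 * n)
    f_hat = np.clip(f_hat, 1.0 / (4 * n), 1 - 1.0 / (4 * n))
    se = 1.0 / np.sqrt(2.0 * f_hat * (1.0 - f_hat) * n)
    zk = z[keep]
    df = pd.DataFrame(
        {
            "SNP": panel.markers["snp_id"].to_numpy()[keep],
            "CHR": panel.markers["chrom"].astype(str).to_numpy()[keep],
            "BP": panel.markers["pos"].to_numpy()[keep],
            "A1": panel.markers["allele_b"].to_numpy()[keep],
            "A2": panel.markers["allele_a"].to_numpy()[keep],
            "FREQ": f_hat,
            "BETA": zk * se,
            "SE": se,
            "P": np.maximum(2.0 * stats.norm.sf(np.abs(zk)), 1e-300),
            "N": n,
            "INFO": rng.uniform(info_range[0], info_range[1], size=keep.size),
        }
    )
    decoys = _make_decoys(rng, trait, n, decoys_per_filter)
    if len(decoys):
        df = pd.concat([df, decoys.drop(columns="reason")], ignore_index=True)
    return df, decoys


def _make_decoys(rng, trait: str, n: int, per_filter: int) -> pd.DataFrame:
    """Rows engineered to fail exactly one QC filter each, labelled."""
    rows = []
    for reason in DECOY_REASONS:
        for i in range(per_filter):
            z = rng.standard_normal()
            f = rng.uniform(0.15, 0.5)
            se = 1.0 / np.sqrt(2 * f * (1 - f) * n)
            row = {
                "SNP": f"decoy_{reason}_{trait}_{i}",
                "CHR": str(rng.integers(1, 23)),
                "BP": int(rng.integers(1, 1_000_000)),
                "A1": "A",
                "A2": "G",
                "FREQ": f,
                "BETA": z * se,
                "SE": se,
                "P": max(2 * stats.norm.sf(abs(z)), 1e-300),
                "N": n,
                "INFO": rng.uniform(0.9, 1.0),
                "reason": reason,
            }
            if reason == "low_info":
                row["INFO"] = rng.uniform(0.5, 0.89)
            elif reason == "low_maf":
                row["FREQ"] = rng.uniform(0.01, 0.09)
            elif reason == "ambiguous":
                row["A1"], row["A2"] = ("A", "T") if rng.random() < 0.5 else ("C", "G")
            elif reason == "indel":
                row["A1"], row["A2"] = ("I", "D") if rng.random() < 0.5 else ("AT", "A")
            elif reason == "non_autosome":
                row["CHR"] = "X"
            rows.append(row)
    return pd.DataFrame(rows, columns=SUMSTATS_COLUMNS + ["reason"])


def simulate_study(config: SimConfig):
    """Panel + genes + truth + per-trait sumstats (+ decoy labels) in one call."""
    panel = simulate_reference_panel(config)
    genes = simulate_gene_annotation(config, panel)
    truth = TruthTable(config.planted_loci)
    sumstats, decoys = {}, {}
    for trait in config.traits:
        sumstats[trait], decoys[trait] = simulate_sumstats(
            panel,
            truth,
            trait,
            config.gwas_n_per_trait,
            config.seed,
            decoys_per_filter=config.decoys_per_filter,
        )
    return panel, genes, truth, sumstats, decoys


# ---------------------------------------------------------------------------
# benchmark


def benchmark_config(
    seed: int,
    n_traits: int = 3,
    n_regions: int = 30,
    lam: float = 6.0,
    gwas_n: int = 50_000,
    n_individuals: int = 2000,
    snps_per_block: int = 16,
    decoys_per_filter: int = 0,
) -> SimConfig:
    """The standard recovery benchmark: 30 gene regions on 3 traits.

    Region classes mirror the archetypes seen in real cross-trait scans:
    6 gene-level pleiotropy loci (three LD-independent variants, one per
    trait), 6 allelic-heterogeneity loci (three independent variants, one
    trait), 6 SNP-level pleiotropy loci (one variant shared by all traits),
    4 mixed loci (a shared variant plus two independent ones), and 8 null
    regions.  Every causal variant carries noncentrality λ (default 6).
    Classes use as many variants as their definitions allow so that the
    class label is robust to the ~6% per-signal dropout expected at the
    1e-5 selection threshold (Φ(λ − 4.42) ≈ 0.94 per variant).
    """
    traits = tuple(f"trait{chr(ord('A') + i)}" for i in range(n_traits))
    bpg = 3
    config = SimConfig(
        n_individuals=n_individuals,
        n_blocks=n_regions * bpg + 2,
        snps_per_block=snps_per_block,
        traits=traits,
        gwas_n_per_trait=gwas_n,
        seed=seed,
        blocks_per_gene=bpg,
        decoys_per_filter=decoys_per_filter,
    )
    mid = snps_per_block // 2

    def snp(region: int, block_in_gene: int) -> str:
        return snp_id_for(config, region * bpg + block_in_gene, mid)

    n_each = n_regions // 5  # 6 each of I/II/III at the default 30
    n_mixed = min(4, max(n_regions - 3 * n_each, 0))  # default: 4 mixed + 8 null
    loci = []
    r = 0
    for _ in range(n_each):  # Scenario I: one independent variant per trait
        causal = tuple((snp(r, b), traits[b % n_traits], lam) for b in range(3))
        loci.append(PlantedLocus("I", f"GENE{r}", causal))
        r += 1
    for k in range(n_each):  # Scenario II: three independent variants, one trait
        t = traits[k % n_traits]
        causal = tuple((snp(r, b), t, lam) for b in range(3))
        loci.append(PlantedLocus("II", f"GENE{r}", causal))
        r += 1
    for _ in range(n_each):  # Scenario III: one variant shared by all traits
        causal = tuple((snp(r, 1), t, lam) for t in traits)
        loci.append(PlantedLocus("III", f"GENE{r}", causal))
        r += 1
    for _ in range(n_mixed):  # mixed: shared variant + two independent ones
        causal = tuple((snp(r, 0), t, lam) for t in traits) + (
            (snp(r, 1), traits[0], lam),
            (snp(r, 2), traits[1 % n_traits], lam),
        )
        loci.append(PlantedLocus("mixed", f"GENE{r}", causal))
        r += 1
    return SimConfig(
        n_individuals=n_individuals,
        n_blocks=config.n_blocks,
        snps_per_block=snps_per_block,
        traits=traits,
        gwas_n_per_trait=gwas_n,
        planted_loci=tuple(loci),
        seed=seed,
        blocks_per_gene=bpg,
        decoys_per_filter=decoys_per_filter,
    )


# ---------------------------------------------------------------------------
# writers


def write_sumstats(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


def write_genes_bed(genes: pd.DataFrame, path) -> None:
    genes.to_csv(path, sep="\t", index=False, header=False)


def write_truth(truth: TruthTable, path) -> None:
    truth.to_frame().to_csv(path, sep="\t", index=False)
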