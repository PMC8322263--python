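"""Gene binning: SNP→gene assignment with ±10 kb flanks and gene_block merging.

Selected signals are annotated to genes when they fall within the gene
boundaries extended by 10 kb on each side (1-based inclusive).  Genes that
are fully overlapping or antisense — and therefore carry the identical
combination of annotated markers — are merged into gene_blocks whose span
runs from the minimum member start to the maximum member end.  Region SNP
sets (every QC'd SNP inside a block ± flank, per trait) feed both the
pruning-based Bonferroni threshold and the Brown gene scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "Gene",
    "GeneGroup",
    "read_gene_table",
    "assign_snps_to_genes",
    "merge_gene_blocks",
    "collect_region_snps",
]

FLANK_BP = 10_000


@dataclass(frozen=True)
class Gene:
    name: str
    chrom: object
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"gene {self.name}: start > end")


@dataclass
class GeneGroup:
    """A gene or a gene_block of merged genes with its assigned markers."""

    name: str
    genes: tuple[Gene, ...]
    chrom: object
    start: int
    end: int
    snp_ids: frozenset[str]

    @property
    def is_block(self) -> bool:
        return len(self.genes) > 1


def read_gene_table(path) -> list[Gene]:
    """Read a 6-column BED-like gene table (chrom start end name score
    strand), coordinates 1-based inclusive as used throughout."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"name": str, "strand": str},
    )
    return [
        Gene(r.name, r.chrom, int(r.start), int(r.end), r.strand)
        for r in df.itertuples(index=False)
    ]


def genes_from_frame(df: pd.DataFrame) -> list[Gene]:
    return [
        Gene(str(r["name"]), r["chrom"], int(r["start"]), int(r["end"]), str(r["strand"]))
        for _, r in df.iterrows()
    ]


def assign_snps_to_genes(
    snps: pd.DataFrame,
    genes: list[Gene],
    flank_bp: int = FLANK_BP,
) -> tuple[dict[str, list[str]], list[str]]:
    """Assign SNPs (columns ``SNP CHR BP``) to every gene whose flanked
    interval covers them; bounds inclusive.

    Returns ``(assignments, unannotated)``: gene name → sorted snp ids,
    plus the ids assigned to no gene.
    """
    chrom = snps["CHR"].astype(str).to_numpy()
    pos = snps["BP"].to_numpy()
    ids = snps["SNP"].to_numpy()
    assignments: dict[str, list[str]] = {}
    hit = pd.Series(False, index=range(len(snps)))
    for gene in genes:
        mask = (
            (chrom == str(gene.chrom))
            & (pos >= gene.start - flank_bp)
            & (pos <= gene.end + flank_bp)
        )
        if mask.any():
            assignments[gene.name] = sorted(ids[mask])
            hit |= mask
    unannotated = sorted(ids[~hit.to_numpy()])
    return assignments, unannotated


def merge_gene_blocks(
    assignments: dict[str, list[str]],
    genes: list[Gene],
) -> list[GeneGroup]:
    """Merge genes carrying the identical assigned-marker combination.

    Identity of the marker set is the merge key (transitive by
    construction); genes with a unique set pass through as singleton
    groups, genes with no assigned markers are dropped.  The block span is
    the minimum start to the maximum end over members.
    """
    by_name = {g.name: g for g in genes}
    buckets: dict[tuple, list[Gene]] = {}
    for name, snp_list in assignments.items():
        if not snp_list:
            continue
        key = (by_name[name].chrom, tuple(sorted(snp_list)))
        buckets.setdefault(key, []).append(by_name[name])
    groups = []
    for (chrom, snp_key), members in buckets.items():
        members = tuple(sorted(members, key=lambda g: (g.start, g.name)))
        groups.append(
            GeneGroup(
                name="|".join(g.name for g in members),
                genes=members,
                chrom=chrom,
                start=min(g.start for g in members),
                end=max(g.end for g in members),
                snp_ids=frozenset(snp_key),
            )
        )
    groups.sort(key=lambda gr: (str(gr.chrom), gr.start, gr.name))
    return groups


def collect_region_snps(
    group: GeneGroup,
    sumstats_by_trait: dict[str, pd.DataFrame],
    flank_bp: int = FLANK_BP,
) -> dict[str, pd.DataFrame]:
    """Every QC'd SNP (not only signals) inside the block ± flank, per
    trait, with p-values — inputs to pruning and Brown scoring."""
    out = {}
    for trait, df in sumstats_by_trait.items():
        mask = (
            (df["CHR"].astype(str) == str(group.chrom))
            & (df["BP"] >= group.start - flank_bp)
            & (df["BP"] <= group.end + flank_bp)
        )
        out[trait] = df.loc[mask, ["SNP", "CHR", "BP", "P"]].reset_index(drop=True)
    return out
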