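"""Haplotype blocks and haplotype frequencies from unphased genotypes.

Blocks are defined by the four-gamete rule: adjacent markers are joined
while at most three of the four possible two-locus haplotypes are present
above a frequency cutoff, up to a maximum block span.  Haplotype
frequencies within a block are maximum-likelihood estimates from an EM
algorithm over unphased diploid genotypes; the report lists common
haplotypes (>10% by default) and places trait-associated alleles on them,
flagging the configuration where two focal alleles ride on disjoint
haplotypes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import GenotypePanel

__all__ = [
    "HaploBlock",
    "HaplotypeEstimate",
    "HaplotypeReport",
    "four_gamete_blocks",
    "estimate_haplotypes",
    "haplotype_report",
]

# enumeration guard: 2 phase options per het site, 4 per missing site
_MAX_AMBIGUITY_BITS = 18


@dataclass(frozen=True)
class HaploBlock:
    chrom: object
    start: int
    end: int
    snp_ids: tuple[str, ...]

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self.snp_ids


@dataclass(frozen=True)
class HaplotypeEstimate:
    """One haplotype over a block's markers, as allele letters, with its
    EM-estimated population frequency."""

    alleles: str
    frequency: float


@dataclass
class HaplotypeReport:
    block: HaploBlock
    haplotypes: list[HaplotypeEstimate]          # frequency > freq_min only
    placements: dict[str, dict]                  # focal snp -> allele/trait/haplotype idx
    different_haplotypes: list[tuple[str, str]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for snp, info in self.placements.items():
            rows.append(
                {
                    "snp_id": snp,
                    "trait": info["trait"],
                    "allele": info["allele"],
                    "haplotypes": ",".join(str(i) for i in info["haplotypes"]) or "-",
                }
            )
        return pd.DataFrame(rows)


def _pair_freqs(panel: GenotypePanel, snp_i: str, snp_j: str) -> np.ndarray:
    """EM two-locus haplotype frequencies, order (00, 01, 10, 11)."""
    est = estimate_haplotypes(panel, [snp_i, snp_j], _raw=True)
    out = np.zeros(4)
    for hap, f in est:
        out[(hap >> 1) * 2 + (hap & 1)] = f
    return out


def four_gamete_blocks(
    panel: GenotypePanel,
    snp_ids,
    window_bp: int = 500_000,
    gamete_freq_min: float = 0.01,
) -> list[HaploBlock]:
    """Partition consecutive markers into four-gamete-rule haploblocks.

    Adjacent markers stay in one block while the estimated two-locus
    haplotype frequencies show at most three gametes at frequency
    >= ``gamete_freq_min`` and the block span stays <= ``window_bp``.
    The returned blocks partition the input markers (singletons allowed).
    """
    ids = list(snp_ids)
    idx = panel.indices(ids)
    sub = panel.markers.iloc[idx]
    order = np.lexsort((sub["pos"].to_numpy(), sub["chrom"].to_numpy()))
    ids = [ids[i] for i in order]
    chrom = sub["chrom"].to_numpy()[order]
    pos = sub["pos"].to_numpy()[order]

    blocks: list[HaploBlock] = []
    cur = [0]
    for k in range(1, len(ids)):
        joined = False
        if chrom[k] == chrom[cur[0]] and pos[k] - pos[cur[0]] <= window_bp:
            f = _pair_freqs(panel, ids[k - 1], ids[k])
            if int(np.sum(f >= gamete_freq_min)) <= 3:
                joined = True
        if joined:
            cur.append(k)
        else:
            blocks.append(
                HaploBlock(chrom[cur[0]], int(pos[cur[0]]), int(pos[cur[-1]]),
                           tuple(ids[i] for i in cur))
            )
            cur = [k]
    blocks.append(
        HaploBlock(chrom[cur[0]], int(pos[cur[0]]), int(pos[cur[-1]]),
                   tuple(ids[i] for i in cur))
    )
    return blocks


def _compatible_pairs(gvec: np.ndarray) -> list[tuple[int, int]]:
    """All unordered haplotype pairs (as bitmasks) consistent with one
    individual's genotype vector; missing sites range over all four
    two-allele configurations."""
    per_site: list[list[tuple[int, int]]] = []
    bits = 0
    for g in gvec:
        if g == 0:
            per_site.append([(0, 0)])
        elif g == 2:
            per_site.append([(1, 1)])
        elif g == 1:
            per_site.append([(0, 1), (1, 0)])
            bits += 1
        else:  # missing
            per_site.append([(0, 0), (0, 1), (1, 0), (1, 1)])
            bits += 2
    if bits > _MAX_AMBIGUITY_BITS:
        raise ValueError(
            f"phase ambiguity too large ({bits} bits) for EM enumeration"
        )
    pairs = set()
    for combo in itertools.product(*per_site):
        h1 = h2 = 0
        for a, b in combo:
            h1 = (h1 << 1) | a
            h2 = (h2 << 1) | b
        pairs.add((min(h1, h2), max(h1, h2)))
    return sorted(pairs)


def estimate_haplotypes(
    panel: GenotypePanel,
    snp_ids,
    max_iter: int = 500,
    tol: float = 1e-6,
    _raw: bool = False,
):
    """EM maximum-likelihood haplotype frequencies over <= 25 markers.

    Initialization is uniform over the haplotypes compatible with at least
    one individual; convergence when the largest frequency change drops
    below ``tol`` (or after ``max_iter`` iterations).  Missing genotypes
    are summed over compatible configurations in the E step.
    """
    ids = list(snp_ids)
    k = len(ids)
    if k == 0 or k > 25:
        raise ValueError("estimate_haplotypes requires 1-25 markers")
    G = panel.dosages(ids)

    ind_pairs = [_compatible_pairs(G[i]) for i in range(G.shape[0])]
    hap_universe = sorted({h for pairs in ind_pairs for p in pairs for h in p})
    hmap = {h: i for i, h in enumerate(hap_universe)}
    H = len(hap_universe)
    freqs = np.full(H, 1.0 / H)

    pair_idx = [
        (np.array([hmap[a] for a, _ in pairs]), np.array([hmap[b] for _, b in pairs]))
        for pairs in ind_pairs
    ]
    n = len(pair_idx)
    for _ in range(max_iter):
        counts = np.zeros(H)
        for ia, ib in pair_idx:
            w = freqs[ia] * freqs[ib] * np.where(ia == ib, 1.0, 2.0)
            tot = w.sum()
            if tot <= 0:
                w = np.full(len(ia), 1.0 / len(ia))
            else:
                w = w / tot
            np.add.at(counts, ia, w)
            np.add.at(counts, ib, w)
        new = counts / (2.0 * n)
        if np.max(np.abs(new - freqs)) < tol:
            freqs = new
            break
        freqs = new

    result = sorted(zip(hap_universe, freqs), key=lambda t: (-t[1], t[0]))
    if _raw:
        return result
    sub = panel.markers.iloc[panel.indices(ids)]
    a_allele = sub["allele_a"].to_numpy()
    b_allele = sub["allele_b"].to_numpy()
    out = []
    for hap, f in result:
        letters = "".join(
            b_allele[j] if (hap >> (k - 1 - j)) & 1 else a_allele[j] for j in range(k)
        )
        out.append(HaplotypeEstimate(letters, float(f)))
    return out


def haplotype_report(
    panel: GenotypePanel,
    block: HaploBlock,
    focal: list[tuple[str, str, str]],
    freq_min: float = 0.10,
) -> HaplotypeReport:
    """Place trait-associated alleles on the block's common haplotypes.

    ``focal`` lists ``(snp_id, trait, trait_increasing_allele)`` with every
    snp inside the block.  Only haplotypes with frequency > ``freq_min``
    are reported.  For every focal pair whose flagged alleles sit on
    disjoint sets of reported haplotypes the pair is flagged — the
    configuration where alleles associated with different phenotypes ride
    on different haplotypes.
    """
    for snp_id, _, _ in focal:
        if snp_id not in block:
            raise ValueError(f"focal SNP {snp_id} outside block")
    all_haps = estimate_haplotypes(panel, list(block.snp_ids))
    common = [h for h in all_haps if h.frequency > freq_min]
    pos_of = {s: i for i, s in enumerate(block.snp_ids)}
    placements: dict[str, dict] = {}
    for snp_id, trait, allele in focal:
        j = pos_of[snp_id]
        carriers = [i for i, h in enumerate(common) if h.alleles[j] == allele]
        placements[snp_id] = {"trait": trait, "allele": allele, "haplotypes": carriers}
    flagged = []
    snps = [s for s, _, _ in focal]
    for a, b in itertools.combinations(snps, 2):
        ha, hb = set(placements[a]["haplotypes"]), set(placements[b]["haplotypes"])
        if ha and hb and not (ha & hb):
            flagged.append((a, b))
    return HaplotypeReport(block, common, placements, flagged)
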