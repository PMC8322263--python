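"""Reference genotype panel and all linkage-disequilibrium quantities.

The panel is the single source of LD information for every stage of the
analysis: pairwise r/r² between markers, region correlation matrices used
for conditional regression and for Brown gene scores, and windowed
pairwise pruning used to derive the experiment-wide Bonferroni threshold.

Genotypes are stored as allele-B dosages (0/1/2, -1 = missing) in an
individuals × markers ``int8`` matrix; the marker map is a
:class:`pandas.DataFrame` with 1-based positions.  PLINK 1 binary
(.bed/.bim/.fam) I/O is implemented here directly (SNP-major 2-bit codec).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypePanel",
    "MonomorphicMarkerError",
    "ld_r",
    "ld_r2",
    "ld_matrix",
    "regularize_corr",
    "prune_pairwise",
    "read_plink",
]

MISSING = -1

_MARKER_COLUMNS = ("snp_id", "chrom", "pos", "allele_a", "allele_b")


class MonomorphicMarkerError(ValueError):
    """LD is undefined for a marker with zero dosage variance."""

    def __init__(self, snp_ids):
        self.snp_ids = list(np.atleast_1d(snp_ids))
        super().__init__(f"monomorphic marker(s): {', '.join(map(str, self.snp_ids))}")


@dataclass
class GenotypePanel:
    """Diploid reference panel: marker map plus allele-B dosage matrix.

    Parameters
    ----------
    markers
        One row per marker with columns ``snp_id, chrom, pos, allele_a,
        allele_b`` (extra columns are carried along untouched). Positions
        are 1-based and must be nondecreasing within a chromosome.
    genotypes
        ``(n_individuals, n_markers)`` int8 array of allele-B dosages;
        ``-1`` marks a missing genotype.
    """

    markers: pd.DataFrame
    genotypes: np.ndarray
    _index: pd.Index = field(init=False, repr=False)

    def __post_init__(self) -> None:
        missing_cols = [c for c in _MARKER_COLUMNS if c not in self.markers.columns]
        if missing_cols:
            raise ValueError(f"marker table lacks columns: {missing_cols}")
        self.markers = self.markers.reset_index(drop=True)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2 or self.genotypes.shape[1] != len(self.markers):
            raise ValueError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.markers)} markers"
            )
        if self.markers["snp_id"].duplicated().any():
            dup = self.markers.loc[self.markers["snp_id"].duplicated(), "snp_id"]
            raise ValueError(f"duplicate marker ids: {sorted(set(dup))[:5]}")
        for _, grp in self.markers.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing:
                raise ValueError("positions must be nondecreasing within chromosome")
        self._index = pd.Index(self.markers["snp_id"])

    # -- basic accessors ---------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[1]

    @property
    def snp_ids(self) -> pd.Index:
        return self._index

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def indices(self, snp_ids: Iterable[str]) -> np.ndarray:
        idx = self._index.get_indexer(list(snp_ids))
        if (idx < 0).any():
            missing = [s for s, i in zip(snp_ids, idx) if i < 0]
            raise KeyError(f"markers not in panel: {missing[:5]}")
        return idx

    def dosages(self, snp_ids: Iterable[str] | None = None) -> np.ndarray:
        """Dosage columns for the given markers (all markers by default)."""
        if snp_ids is None:
            return self.genotypes
        return self.genotypes[:, self.indices(snp_ids)]

    def freq(self, snp_ids: Iterable[str] | None = None) -> np.ndarray:
        """Allele-B frequency per marker, missing genotypes excluded."""
        g = self.dosages(snp_ids).astype(float)
        g[g == MISSING] = np.nan
        with np.errstate(invalid="ignore"):
            return np.nanmean(g, axis=0) / 2.0

    def maf(self, snp_ids: Iterable[str] | None = None) -> np.ndarray:
        f = self.freq(snp_ids)
        return np.minimum(f, 1.0 - f)

    def is_monomorphic(self, snp_ids: Iterable[str] | None = None) -> np.ndarray:
        g = self.dosages(snp_ids).astype(float)
        g[g == MISSING] = np.nan
        with np.errstate(invalid="ignore"):
            v = np.nanvar(g, axis=0)
        return ~(v > 0)

    def subset(self, snp_ids: Sequence[str]) -> "GenotypePanel":
        idx = self.indices(snp_ids)
        order = np.sort(idx)
        return GenotypePanel(self.markers.iloc[order].copy(), self.genotypes[:, order])

    # -- LD ----------------------------------------------------------------

    def ld_r(self, snp_i: str, snp_j: str) -> float:
        """Signed Pearson correlation of dosages, pairwise-deleting missing."""
        gi, gj = self.dosages([snp_i, snp_j]).astype(float).T
        keep = (gi != MISSING) & (gj != MISSING)
        gi, gj = gi[keep], gj[keep]
        bad = [s for s, g in ((snp_i, gi), (snp_j, gj)) if g.size < 2 or np.var(g) == 0]
        if bad:
            raise MonomorphicMarkerError(bad)
        return float(np.corrcoef(gi, gj)[0, 1])

    def ld_r2(self, snp_i: str, snp_j: str) -> float:
        return self.ld_r(snp_i, snp_j) ** 2

    def ld_matrix(self, snp_ids: Sequence[str]) -> np.ndarray:
        """Signed correlation matrix over the given markers (input order).

        Missing genotypes are handled by pairwise deletion.  Raises
        :class:`MonomorphicMarkerError` listing every offending marker.
        """
        snp_ids = list(snp_ids)
        if not snp_ids:
            raise ValueError("empty marker list")
        g = self.dosages(snp_ids).astype(float)
        g[g == MISSING] = np.nan
        with np.errstate(invalid="ignore"):
            v = np.nanvar(g, axis=0)
        mono = [s for s, vi in zip(snp_ids, v) if not vi > 0]
        if mono:
            raise MonomorphicMarkerError(mono)
        if np.isnan(g).any():
            r = np.ma.corrcoef(np.ma.masked_invalid(g), rowvar=False).filled(0.0)
        else:
            r = np.corrcoef(g, rowvar=False)
        r = np.asarray(r, dtype=float)
        if r.ndim == 0:  # single marker
            r = np.array([[1.0]])
        np.fill_diagonal(r, 1.0)
        return np.clip(r, -1.0, 1.0)

    # -- PLINK 1 binary ----------------------------------------------------

    def write_plink(self, prefix: str | Path) -> None:
        """Write .bed/.bim/.fam. The bim A1 allele is the counted allele B."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        bim = pd.DataFrame(
            {
                "chrom": self.markers["chrom"],
                "snp_id": self.markers["snp_id"],
                "cm": 0,
                "pos": self.markers["pos"],
                "a1": self.markers["allele_b"],
                "a2": self.markers["allele_a"],
            }
        )
        bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
        fam = pd.DataFrame(
            {
                "fid": [f"ind{i}" for i in range(self.n_individuals)],
                "iid": [f"ind{i}" for i in range(self.n_individuals)],
                "pat": 0,
                "mat": 0,
                "sex": 0,
                "pheno": -9,
            }
        )
        fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)
        with open(prefix.with_suffix(".bed"), "wb") as fh:
            fh.write(bytes([0x6C, 0x1B, 0x01]))  # magic + SNP-major
            fh.write(_pack_bed(self.genotypes))


def _pack_bed(genotypes: np.ndarray) -> bytes:
    # dosage of bim-A1 -> 2-bit code: 2 -> 00, het -> 10, 0 -> 11, missing -> 01
    code_of = np.array([3, 2, 0], dtype=np.uint8)
    n_ind, n_snp = genotypes.shape
    n_pad = (-n_ind) % 4
    out = np.empty((n_snp, (n_ind + n_pad) // 4), dtype=np.uint8)
    codes = np.where(genotypes.T == MISSING, 1, code_of[np.clip(genotypes.T, 0, 2)])
    codes = codes.astype(np.uint8)
    if n_pad:
        pad = np.zeros((n_snp, n_pad), dtype=np.uint8)  # pad with hom code 00
        codes = np.concatenate([codes, pad], axis=1)
    codes = codes.reshape(n_snp, -1, 4)
    out = (
        codes[:, :, 0]
        | (codes[:, :, 1] << 2)
        | (codes[:, :, 2] << 4)
        | (codes[:, :, 3] << 6)
    )
    return out.tobytes()


def read_plink(prefix: str | Path) -> GenotypePanel:
    """Read a PLINK 1 binary fileset written in SNP-major order."""
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
        dtype={"snp_id": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None)
    n_ind, n_snp = len(fam), len(bim)
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if raw[:3].tolist() != [0x6C, 0x1B, 0x01]:
        raise ValueError(f"{prefix}.bed is not a SNP-major PLINK 1 bed file")
    body = raw[3:]
    bytes_per_snp = (n_ind + 3) // 4
    codes = body.reshape(n_snp, bytes_per_snp)
    shifts = np.arange(4) * 2
    two_bit = (codes[:, :, None] >> shifts[None, None, :]) & 0b11
    two_bit = two_bit.reshape(n_snp, -1)[:, :n_ind]
    dosage_of = np.array([2, MISSING, 1, 0], dtype=np.int8)  # code -> A1 dosage
    genotypes = dosage_of[two_bit].T
    markers = pd.DataFrame(
        {
            "snp_id": bim["snp_id"],
            "chrom": bim["chrom"],
            "pos": bim["pos"],
            "allele_a": bim["a2"],
            "allele_b": bim["a1"],
        }
    )
    return GenotypePanel(markers, genotypes)


# -- module-level operation wrappers --------------------------------------


def ld_r(panel: GenotypePanel, snp_i: str, snp_j: str) -> float:
    return panel.ld_r(snp_i, snp_j)


def ld_r2(panel: GenotypePanel, snp_i: str, snp_j: str) -> float:
    return panel.ld_r2(snp_i, snp_j)


def ld_matrix(panel: GenotypePanel, snp_ids: Sequence[str]) -> np.ndarray:
    return panel.ld_matrix(snp_ids)


def regularize_corr(R: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Return the nearest unit-diagonal PSD matrix with eigenvalues >= floor.

    Eigenvalues are clipped at ``floor`` and the matrix rescaled back to a
    unit diagonal, guaranteeing a valid covariance for MVN sampling and an
    invertible system for joint regression.
    """
    R = np.asarray(R, dtype=float)
    w, v = np.linalg.eigh((R + R.T) / 2.0)
    if w.min() >= floor:
        return R
    w = np.clip(w, floor, None)
    R2 = (v * w) @ v.T
    d = np.sqrt(np.diag(R2))
    R2 = R2 / np.outer(d, d)
    np.fill_diagonal(R2, 1.0)
    return R2


def prune_pairwise(
    panel: GenotypePanel,
    snp_ids: Sequence[str],
    window_bp: int = 10_000_000,
    r2_thresh: float = 0.2,
) -> tuple[list[str], int]:
    """Windowed pairwise LD pruning of a marker set.

    Scanning position order, while any same-chromosome pair closer than
    ``window_bp`` shows r² > ``r2_thresh``, the member with the smaller MAF
    is removed (tie: the one at the larger position).  The first violating
    pair in position order is always resolved first, which makes the result
    deterministic and independent of the input ordering.  Monomorphic
    markers carry no LD evidence and are always retained.

    Returns the retained ids (position order) and their count — the count
    feeds the experiment-wide Bonferroni threshold.
    """
    snp_ids = list(dict.fromkeys(snp_ids))
    if not snp_ids:
        return [], 0
    idx = panel.indices(snp_ids)
    sub = panel.markers.iloc[idx]
    order = np.lexsort((sub["pos"].to_numpy(), sub["chrom"].to_numpy()))
    ids = [snp_ids[i] for i in order]
    chrom = sub["chrom"].to_numpy()[order]
    pos = sub["pos"].to_numpy()[order]
    maf = panel.maf(ids)
    g = panel.dosages(ids).astype(float)
    g[g == MISSING] = np.nan
    with np.errstate(invalid="ignore"):
        v = np.nanvar(g, axis=0)
    poly = v > 0
    if np.isnan(g).any():
        r = np.ma.corrcoef(np.ma.masked_invalid(g), rowvar=False).filled(0.0)
    else:
        gp = g[:, poly]
        r = np.zeros((len(ids), len(ids)))
        if poly.sum() >= 2:
            r[np.ix_(poly, poly)] = np.corrcoef(gp, rowvar=False)
    r2 = np.asarray(r, dtype=float) ** 2

    alive = np.ones(len(ids), dtype=bool)
    while True:
        victim = None
        alive_idx = np.flatnonzero(alive)
        for a_pos, i in enumerate(alive_idx):
            if not poly[i]:
                continue
            for j in alive_idx[a_pos + 1 :]:
                if chrom[j] != chrom[i] or pos[j] - pos[i] > window_bp:
                    break
                if poly[j] and r2[i, j] > r2_thresh:
                    if maf[i] < maf[j]:
                        victim = i
                    elif maf[j] < maf[i]:
                        victim = j
                    else:  # tie: drop the larger position
                        victim = j
                    break
            if victim is not None:
                break
        if victim is None:
            break
        alive[victim] = False
    retained = [ids[i] for i in np.flatnonzero(alive)]
    return retained, len(retained)
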