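"""Reading, quality control and panel harmonization of GWAS summary statistics.

QC follows the standard recommendations for conditional analysis of
summary statistics against an external LD reference: drop poorly imputed
markers (INFO < 0.9), low-frequency markers (MAF < 0.1), strand-ambiguous
SNPs (A/T, C/G), insertions/deletions, non-autosomal records and
duplicated ids.  Harmonization orients every record to the panel's
counted allele, flipping β and the effect-allele frequency when the
alleles are reported in the opposite order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import GenotypePanel

__all__ = [
    "MANDATORY_COLUMNS",
    "QCParams",
    "QCReport",
    "read_sumstats",
    "qc_filter",
    "harmonize_to_panel",
]

MANDATORY_COLUMNS = ["SNP", "CHR", "BP", "A1", "A2", "FREQ", "BETA", "SE", "P", "N"]
_NUMERIC = ["BP", "FREQ", "BETA", "SE", "P", "N", "INFO"]
_BASES = {"A", "C", "G", "T"}
_AMBIGUOUS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass
class QCParams:
    info_min: float = 0.9
    maf_min: float = 0.1
    freq_tol: float = 0.2


@dataclass
class QCReport:
    """Row accounting across QC and harmonization; removed + retained =
    input rows at each stage."""

    input_rows: int = 0
    removed: dict = field(default_factory=dict)
    retained: int = 0

    def add(self, reason: str, count: int) -> None:
        if count:
            self.removed[reason] = self.removed.get(reason, 0) + int(count)

    @property
    def total_removed(self) -> int:
        return sum(self.removed.values())

    def to_dict(self) -> dict:
        return {
            "input_rows": self.input_rows,
            "removed": dict(self.removed),
            "retained": self.retained,
        }


def read_sumstats(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a whitespace/tab-delimited summary-statistics table.

    ``column_map`` maps file column names to the canonical names
    (``SNP CHR BP A1 A2 FREQ BETA SE P N [INFO]``).  Rows with unparseable
    numeric fields are dropped (count in ``df.attrs['n_unparseable']``);
    a missing mandatory column raises a ``ValueError`` naming it.
    """
    df = pd.read_csv(path, sep=r"\s+", dtype=str)
    if column_map:
        df = df.rename(columns=column_map)
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing mandatory column: {col}")
    if "INFO" not in df.columns:
        df["INFO"] = "1"  # no imputation score reported: treated as genotyped
    for col in _NUMERIC:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    ok = df[_NUMERIC].notna().all(axis=1)
    n_bad = int((~ok).sum())
    df = df.loc[ok].reset_index(drop=True)
    df["BP"] = df["BP"].astype(np.int64)
    df["N"] = df["N"].astype(np.int64)
    df["A1"] = df["A1"].str.upper()
    df["A2"] = df["A2"].str.upper()
    df["CHR"] = df["CHR"].astype(str).str.removeprefix("chr")
    df.attrs["n_unparseable"] = n_bad
    return df[MANDATORY_COLUMNS + ["INFO"]].copy()


def _autosome(chrom: pd.Series) -> pd.Series:
    num = pd.to_numeric(chrom, errors="coerce")
    return num.between(1, 22) & (num == num.round())


def qc_filter(df: pd.DataFrame, params: QCParams | None = None) -> tuple[pd.DataFrame, QCReport]:
    """Apply the marker-level QC filters; returns (retained table, report).

    The retained set is the conjunction of all predicates, so filter order
    cannot change it; each removed row is counted once, under the first
    failing filter in the order low_info, low_maf, ambiguous, indel,
    non_autosome, duplicate.
    """
    params = params or QCParams()
    report = QCReport(input_rows=len(df))
    a1, a2 = df["A1"], df["A2"]
    fails = {
        "low_info": df["INFO"] < params.info_min,
        "low_maf": np.minimum(df["FREQ"], 1 - df["FREQ"]) < params.maf_min,
        "ambiguous": pd.Series(list(zip(a1, a2)), index=df.index).isin(_AMBIGUOUS),
        "indel": ~(a1.isin(_BASES) & a2.isin(_BASES)),
        "non_autosome": ~_autosome(df["CHR"]),
        "duplicate": df["SNP"].duplicated(keep=False),
    }
    removed = pd.Series(False, index=df.index)
    for reason, mask in fails.items():
        report.add(reason, int((mask & ~removed).sum()))
        removed |= mask
    out = df.loc[~removed].reset_index(drop=True)
    report.retained = len(out)
    return out, report


def harmonize_to_panel(
    df: pd.DataFrame,
    panel: GenotypePanel,
    freq_tol: float = 0.2,
    report: QCReport | None = None,
) -> tuple[pd.DataFrame, QCReport]:
    """Orient records to the panel's allele B and drop unmatchable ones.

    Matching is by snp id.  A record whose (A1, A2) equals the panel's
    (alleleB, alleleA) is kept as is; the reversed order flips the sign of
    β and the effect-allele frequency; any other allele combination is
    dropped (``allele_mismatch``), as are records absent from the panel
    and records whose frequency disagrees with the panel by more than
    ``freq_tol`` after orientation.  |β| and p are untouched.
    """
    report = report or QCReport(input_rows=len(df))
    idx = panel.snp_ids.get_indexer(df["SNP"])
    present = idx >= 0
    report.add("not_in_panel", int((~present).sum()))
    sub = df.loc[present].reset_index(drop=True)
    pidx = idx[present]
    pa = panel.markers["allele_a"].to_numpy()[pidx]
    pb = panel.markers["allele_b"].to_numpy()[pidx]
    a1 = sub["A1"].to_numpy()
    a2 = sub["A2"].to_numpy()
    direct = (a1 == pb) & (a2 == pa)
    flipped = (a1 == pa) & (a2 == pb)
    report.add("allele_mismatch", int((~direct & ~flipped).sum()))
    keep = direct | flipped
    sub = sub.loc[keep].reset_index(drop=True)
    flip = flipped[keep]
    sub.loc[flip, "BETA"] = -sub.loc[flip, "BETA"]
    sub.loc[flip, "FREQ"] = 1.0 - sub.loc[flip, "FREQ"]
    sub.loc[flip, ["A1", "A2"]] = sub.loc[flip, ["A2", "A1"]].to_numpy()

    pfreq = panel.freq(sub["SNP"])
    ok = np.abs(sub["FREQ"].to_numpy() - pfreq) <= freq_tol
    report.add("freq_mismatch", int((~ok).sum()))
    out = sub.loc[ok].reset_index(drop=True)
    report.retained = len(out)
    return out, report
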