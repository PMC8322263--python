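"""End-to-end pipeline: simulate/load → QC → select → bin → classify → score → haplotypes.

A single declarative config drives the run; every stage parameter has the
study defaults (INFO 0.9, MAF 0.1, p_select 1e-5, ±10 kb flanks, 10 Mb /
r² 0.2 pruning, dependence r² 0.2, 5% FWER, 500 kb / >10% haplotypes) and
one seed feeds all randomness, so a rerun with the same config is
byte-identical.  Outputs are plain TSV/BED/JSON plus a manifest recording
parameters and per-stage row counts.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import pandas as pd
import yaml

from . import brown, cojo, genes, haplotypes, scenarios, sumstats, synthetic
from .panel import prune_pairwise, read_plink

__all__ = ["RunConfig", "run_pipeline", "load_config"]

log = logging.getLogger("pleiogene")


@dataclass
class RunConfig:
    """Validated pipeline configuration (YAML-serializable).

    Either ``synthetic`` (a :class:`~pleiogene.synthetic.SimConfig` mapping)
    or explicit input ``paths`` (per-trait sumstats, panel prefix, gene BED)
    must be given.
    """

    out: str = "pleiogene_run"
    seed: int = 0
    synthetic: dict | None = None
    paths: dict | None = None
    info_min: float = 0.9
    maf_min: float = 0.1
    freq_tol: float = 0.2
    p_select: float = 1e-5
    select_window_bp: int = 10_000_000
    collinearity_r2: float = 0.9
    flank_bp: int = 10_000
    prune_window_bp: int = 10_000_000
    prune_r2: float = 0.2
    dependence_r2: float = 0.2
    fwer: float = 0.05
    genomewide_alpha: float = 5e-8
    q_decimals: int = 4
    haplo_enabled: bool = True
    haplo_window_bp: int = 500_000
    haplo_freq_min: float = 0.10
    haplo_gamete_freq_min: float = 0.01

    def __post_init__(self):
        if self.synthetic is None and self.paths is None:
            raise ValueError("config needs either 'synthetic' or 'paths'")

    @classmethod
    def from_mapping(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ValueError(f"unknown config keys: {unknown}")
        return cls(**data)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_mapping(data)


def _sim_config(cfg: RunConfig) -> synthetic.SimConfig:
    data = dict(cfg.synthetic or {})
    data.setdefault("seed", cfg.seed)
    if data.pop("benchmark", False):
        keep = {"seed", "n_traits", "n_regions", "lam", "gwas_n", "n_individuals",
                "snps_per_block", "decoys_per_filter"}
        extra = set(data) - keep
        if extra:
            raise ValueError(f"unknown benchmark keys: {sorted(extra)}")
        return synthetic.benchmark_config(**data)
    loci = tuple(
        synthetic.PlantedLocus(p["scenario"], p["gene_name"],
                               tuple(map(tuple, p["causal_snps"])))
        for p in data.pop("planted_loci", [])
    )
    return synthetic.SimConfig(planted_loci=loci, **data)


def _load_inputs(cfg: RunConfig, outdir: Path):
    """Return (panel, gene list, truth-or-None, raw sumstats per trait)."""
    if cfg.synthetic is not None:
        sim = _sim_config(cfg)
        panel, gene_df, truth, stats_by_trait, _ = synthetic.simulate_study(sim)
        panel.write_plink(outdir / "panel")
        synthetic.write_genes_bed(gene_df, outdir / "genes.bed")
        synthetic.write_truth(truth, outdir / "truth.tsv")
        for trait, df in stats_by_trait.items():
            synthetic.write_sumstats(df, outdir / f"sumstats_{trait}.raw.tsv")
        return panel, genes.genes_from_frame(gene_df), truth, stats_by_trait
    paths = cfg.paths or {}
    panel = read_plink(paths["panel"])
    gene_list = genes.read_gene_table(paths["genes"])
    stats_by_trait = {
        trait: sumstats.read_sumstats(p, paths.get("column_map"))
        for trait, p in paths["sumstats"].items()
    }
    return panel, gene_list, None, stats_by_trait


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage in order and return the run manifest.

    Any stage failure aborts with the stage name in the exception message;
    outputs of completed stages are retained in ``cfg.out``.
    """
    outdir = Path(cfg.out)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "parameters": _param_dict(cfg), "stages": {}}
    stage = "inputs"
    t0 = time.perf_counter()
    try:
        panel, gene_list, truth, raw_stats = _load_inputs(cfg, outdir)
        manifest["stages"]["inputs"] = {
            "n_panel_markers": panel.n_markers,
            "n_individuals": panel.n_individuals,
            "n_genes": len(gene_list),
            "traits": sorted(raw_stats),
        }
        _tick(stage, t0)

        stage = "qc"
        t0 = time.perf_counter()
        qc_params = sumstats.QCParams(cfg.info_min, cfg.maf_min, cfg.freq_tol)
        clean: dict[str, pd.DataFrame] = {}
        qc_reports = {}
        for trait in sorted(raw_stats):
            filtered, report = sumstats.qc_filter(raw_stats[trait], qc_params)
            harmonized, report = sumstats.harmonize_to_panel(
                filtered, panel, cfg.freq_tol, report
            )
            report.input_rows = len(raw_stats[trait])
            clean[trait] = harmonized
            qc_reports[trait] = report.to_dict()
            harmonized.to_csv(outdir / f"sumstats_{trait}.qc.tsv", sep="\t", index=False)
        (outdir / "qc_report.json").write_text(json.dumps(qc_reports, indent=2, sort_keys=True))
        manifest["stages"]["qc"] = qc_reports
        _tick(stage, t0)

        stage = "select"
        t0 = time.perf_counter()
        params = cojo.CojoParams(cfg.p_select, cfg.select_window_bp, cfg.collinearity_r2)
        all_signals: list[cojo.Signal] = []
        for trait in sorted(clean):
            sig = cojo.select_signals(clean[trait], panel, params, trait=trait)
            all_signals.extend(sig)
        sig_frame = cojo.signals_to_frame(all_signals)
        sig_frame.to_csv(outdir / "signals.tsv", sep="\t", index=False)
        manifest["stages"]["select"] = {
            "n_signals": len(all_signals),
            "per_trait": sig_frame.groupby("trait").size().to_dict() if len(sig_frame) else {},
        }
        _tick(stage, t0)

        stage = "bin"
        t0 = time.perf_counter()
        sig_snps = sig_frame.rename(columns={"snp_id": "SNP", "chrom": "CHR", "pos": "BP"})
        sig_snps = sig_snps.drop_duplicates("SNP")
        assignments, unannotated = genes.assign_snps_to_genes(
            sig_snps[["SNP", "CHR", "BP"]], gene_list, cfg.flank_bp
        )
        groups = genes.merge_gene_blocks(assignments, gene_list)
        pd.Series(unannotated, name="SNP").to_csv(outdir / "unannotated_snps.tsv",
                                                  sep="\t", index=False)
        group_rows = pd.DataFrame(
            [
                {
                    "group": g.name,
                    "chrom": g.chrom,
                    "start": g.start,
                    "end": g.end,
                    "n_genes": len(g.genes),
                    "n_signal_snps": len(g.snp_ids),
                }
                for g in groups
            ]
        )
        group_rows.to_csv(outdir / "gene_groups.tsv", sep="\t", index=False)
        manifest["stages"]["bin"] = {
            "n_assigned_snps": int(len(sig_snps) - len(unannotated)),
            "n_unannotated_snps": len(unannotated),
            "n_groups": len(groups),
        }
        _tick(stage, t0)

        stage = "classify"
        t0 = time.perf_counter()
        by_group_signals = _signals_by_group(groups, all_signals)
        multi = [g for g in groups if _n_distinct(by_group_signals[g.name]) >= 2]
        region_snp_ids: set[str] = set()
        for g in multi:
            per_trait = genes.collect_region_snps(g, clean, cfg.flank_bp)
            for df in per_trait.values():
                region_snp_ids.update(df["SNP"])
        region_snp_ids &= set(panel.snp_ids)
        if region_snp_ids:
            _, pruned_count = prune_pairwise(
                panel, sorted(region_snp_ids), cfg.prune_window_bp, cfg.prune_r2
            )
            alpha = scenarios.compute_experiment_threshold(pruned_count)
        else:
            pruned_count, alpha = 0, cfg.fwer
        grid = {
            "genomewide": cfg.genomewide_alpha,
            "experiment": alpha,
            "selection": cfg.p_select,
        }
        class_by_thresh = {}
        for label, thr in grid.items():
            ts = scenarios.ThresholdSet(cfg.p_select, min(thr, 0.05), cfg.dependence_r2)
            class_by_thresh[label] = [
                scenarios.classify_region(g, by_group_signals[g.name], panel, ts)
                for g in multi
            ]
        classifications = class_by_thresh["experiment"]
        table1 = scenarios.tabulate_scenarios(class_by_thresh)
        table1.to_csv(outdir / "scenario_counts.tsv", sep="\t")
        _write_classifications(classifications, outdir / "classifications.tsv")
        matrix = scenarios.trait_pair_matrix(classifications, sorted(clean))
        matrix.to_csv(outdir / "trait_pair_matrix.tsv", sep="\t")
        manifest["stages"]["classify"] = {
            "n_multi_signal_groups": len(multi),
            "n_region_snps": len(region_snp_ids),
            "pruned_count": pruned_count,
            "experiment_alpha": alpha,
            "scenario_counts": {k: int(v) for k, v in table1["experiment"].items()},
        }
        _tick(stage, t0)

        stage = "score"
        t0 = time.perf_counter()
        scores = brown.score_all_genes(groups, clean, panel, cfg.flank_bp)
        scores = brown.fdr_adjust_within_trait(scores)
        scores.to_csv(outdir / "gene_scores.tsv", sep="\t", index=False)
        q_thresh = brown.gene_score_threshold(len(clean), cfg.q_decimals)
        scenario_of = {c.group: c.scenario for c in classifications}
        selection = brown.select_pleiotropic_genes(
            scores, scenario_of, panel, q_thresh, alpha, cfg.dependence_r2
        )
        selection.to_csv(outdir / "pleiotropic_genes.tsv", sep="\t", index=False)
        manifest["stages"]["score"] = {
            "n_scores": len(scores),
            "q_thresh": q_thresh,
            "n_selected": len(selection),
            "categories": selection.groupby("category").size().to_dict()
            if len(selection)
            else {},
        }
        _tick(stage, t0)

        stage = "haplo"
        t0 = time.perf_counter()
        n_reports = 0
        if cfg.haplo_enabled:
            n_reports = _haplotype_reports(
                cfg, panel, classifications, by_group_signals, groups, outdir
            )
        manifest["stages"]["haplo"] = {"n_reports": n_reports}
        _tick(stage, t0)
    except Exception as err:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err

    if truth is not None:
        manifest["truth"] = {
            "planted": truth.to_frame()["scenario"].value_counts().to_dict()
        }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _param_dict(cfg: RunConfig) -> dict:
    d = asdict(cfg)
    return d


def _tick(stage: str, t0: float) -> None:
    log.info("stage %-8s done in %.2fs", stage, time.perf_counter() - t0)


def _signals_by_group(groups, all_signals) -> dict[str, list]:
    out = {g.name: [] for g in groups}
    for g in groups:
        members = g.snp_ids
        for s in all_signals:
            if s.snp_id in members:
                out[g.name].append(s)
    return out


def _n_distinct(signals) -> int:
    return len({(s.trait, s.snp_id) for s in signals})


def _write_classifications(classifications, path) -> None:
    rows = []
    for c in classifications:
        pair_txt = ";".join(
            f"{p['snp_i']}({p['trait_i']})~{p['snp_j']}({p['trait_j']}):r2={p['r2']:.3f}"
            for p in c.pairs
        )
        rows.append(
            {
                "group": c.group,
                "scenario": c.scenario,
                "traits": ";".join(c.traits),
                "pairs": pair_txt,
            }
        )
    pd.DataFrame(rows, columns=["group", "scenario", "traits", "pairs"]).to_csv(
        path, sep="\t", index=False
    )


def _haplotype_reports(cfg, panel, classifications, by_group_signals, groups, outdir) -> int:
    """Fig.-2-style reports for gene-level pleiotropy regions: place each
    trait's top allele on the block haplotypes."""
    by_name = {g.name: g for g in groups}
    rows = []
    for c in classifications:
        if c.scenario not in ("I", "mixed"):
            continue
        group = by_name[c.group]
        sig = sorted(by_group_signals[c.group], key=lambda s: s.p_j)
        focal_by_trait = {}
        for s in sig:  # best signal per trait
            focal_by_trait.setdefault(s.trait, s)
        focal_sigs = list(focal_by_trait.values())
        region_ids = _block_marker_window(panel, group, focal_sigs)
        if len(region_ids) < 2:
            continue
        blocks = haplotypes.four_gamete_blocks(
            panel, region_ids, cfg.haplo_window_bp, cfg.haplo_gamete_freq_min
        )
        for block in blocks:
            focal = []
            for s in focal_sigs:
                if s.snp_id in block:
                    allele = _trait_increasing_allele(panel, s)
                    focal.append((s.snp_id, s.trait, allele))
            if len(focal) < 1:
                continue
            rep = haplotypes.haplotype_report(panel, block, focal, cfg.haplo_freq_min)
            for snp, info in rep.placements.items():
                rows.append(
                    {
                        "group": c.group,
                        "block": f"{block.chrom}:{block.start}-{block.end}",
                        "snp_id": snp,
                        "trait": info["trait"],
                        "allele": info["allele"],
                        "haplotypes": ",".join(map(str, info["haplotypes"])) or "-",
                        "n_common_haplotypes": len(rep.haplotypes),
                        "different_haplotypes": ";".join(
                            f"{a}~{b}" for a, b in rep.different_haplotypes
                        ),
                    }
                )
    frame = pd.DataFrame(
        rows,
        columns=[
            "group", "block", "snp_id", "trait", "allele",
            "haplotypes", "n_common_haplotypes", "different_haplotypes",
        ],
    )
    frame.to_csv(outdir / "haplotype_report.tsv", sep="\t", index=False)
    return len(frame)


def _block_marker_window(panel, group, focal_sigs, pad: int = 0) -> list[str]:
    """All polymorphic panel markers spanning the group's focal signals."""
    if not focal_sigs:
        return []
    chrom = group.chrom
    lo = min(s.pos for s in focal_sigs) - pad
    hi = max(s.pos for s in focal_sigs) + pad
    sub = panel.markers[
        (panel.markers["chrom"].astype(str) == str(chrom))
        & (panel.markers["pos"] >= lo)
        & (panel.markers["pos"] <= hi)
    ]
    ids = [s for s in sub["snp_id"] if not panel.is_monomorphic([s])[0]]
    return ids


def _trait_increasing_allele(panel, signal) -> str:
    """Allele whose dosage increases the trait, from the harmonized β sign
    (effect allele is panel allele B)."""
    row = panel.markers.iloc[panel.indices([signal.snp_id])[0]]
    return str(row["allele_b"] if signal.beta_j >= 0 else row["allele_a"])
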