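"""End-to-end orchestration: simulate → bind → DE → integrate → motif → report.

Every stage reads and writes plain-text files (narrowPeak, FASTA, TSV, JSON),
so subcommands can be re-run independently on the files an earlier stage
wrote. A run is a pure function of (config, seed): the report JSON and all
gene lists are byte-identical across repeated runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import binding, census, expression, motif, simulate, stats
from .annotation import GeneAnnotation, IntervalSet, load_annotation, write_annotation

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and parameters for a pipeline run; defaults are the study's."""

    # inputs; None means "simulate"
    annotation: str | None = None
    fasta: str | None = None
    flag_peaks: list[str] = field(default_factory=list)
    control_peaks: list[str] = field(default_factory=list)
    expression: str | None = None
    panel: str | None = None
    blacklist: str | None = None
    cgi: str | None = None
    # parameters (defaults as published)
    flank: int = 1000
    min_replicates: int = 2
    expressed_threshold: float = 1.0
    de_alpha: float = 0.05
    motif_pattern: str = "CNCCTCAG"
    n_permutations: int = 10_000
    seed: int = 0
    simulation: simulate.SimulationConfig | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulation = simulate.SimulationConfig(**sim)
        return cfg

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        return d


def _config_hash(cfg: PipelineConfig) -> str:
    payload = json.dumps(cfg.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> dict[str, Any]:
    """Run every stage and write stage outputs plus a RunReport JSON.

    Returns the report dictionary. With no input paths configured, a synthetic
    cohort is generated (seeded from cfg.seed) and written to ``outdir`` so
    the file-facing entry points are exercised end to end.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "provenance": {"config_hash": _config_hash(cfg), "seed": cfg.seed}
    }

    truth = None
    if cfg.annotation is None:
        sim_cfg = cfg.simulation or simulate.SimulationConfig(seed=cfg.seed)
        genome = simulate.make_genome(sim_cfg)
        flag_reps, control_reps = simulate.simulate_peaks(genome.annotation, genome.truth, sim_cfg)
        matrix, _ = simulate.simulate_expression(genome.annotation, genome.truth, sim_cfg)
        truth = genome.truth

        simulate.write_fasta(genome.sequence, outdir / "genome.fa", name=sim_cfg.chrom_name)
        write_annotation(genome.annotation, outdir / "annotation.tsv")
        genome.blacklist.to_bed(outdir / "blacklist.bed")
        genome.cgi.to_bed(outdir / "cgi.bed")
        for i, peaks in enumerate(flag_reps, 1):
            binding.write_narrowpeak(peaks, outdir / f"flag_rep{i}.narrowPeak")
        for i, peaks in enumerate(control_reps, 1):
            binding.write_narrowpeak(peaks, outdir / f"control_rep{i}.narrowPeak")
        matrix.to_tsv(outdir / "expression.tsv")
        genome.truth.to_json(outdir / "ground_truth.json")

        cfg = dataclasses.replace(
            cfg,
            annotation=str(outdir / "annotation.tsv"),
            fasta=str(outdir / "genome.fa"),
            flag_peaks=[str(outdir / f"flag_rep{i}.narrowPeak") for i in range(1, len(flag_reps) + 1)],
            control_peaks=[str(outdir / f"control_rep{i}.narrowPeak") for i in range(1, len(control_reps) + 1)],
            expression=str(outdir / "expression.tsv"),
            blacklist=str(outdir / "blacklist.bed"),
        )

    ann = load_annotation(cfg.annotation)
    report["n_genes"] = len(ann.genes)

    # --- binding ---------------------------------------------------------
    blacklist = IntervalSet.from_bed(cfg.blacklist, label="blacklist") if cfg.blacklist else None
    flag_sets, flag_fracs = [], []
    for i, path in enumerate(cfg.flag_peaks, 1):
        peaks = binding.read_narrowpeak(path, condition="FLAG", replicate_id=f"flag{i}")
        if blacklist is not None:
            peaks = binding.filter_blacklist(peaks, blacklist)
        flag_sets.append(binding.genes_with_promoter_peak(peaks, ann, flank=cfg.flank))
        flag_fracs.append(binding.promoter_fraction(peaks, ann, flank=cfg.flank))
    control_sets, control_fracs = [], []
    for i, path in enumerate(cfg.control_peaks, 1):
        peaks = binding.read_narrowpeak(path, condition="control", replicate_id=f"control{i}")
        if blacklist is not None:
            peaks = binding.filter_blacklist(peaks, blacklist)
        control_sets.append(binding.genes_with_promoter_peak(peaks, ann, flank=cfg.flank))
        if peaks:
            control_fracs.append(binding.promoter_fraction(peaks, ann, flank=cfg.flank))

    bound, call_table = binding.call_bound_genes(flag_sets, control_sets, cfg.min_replicates)
    binding.write_binding_calls(call_table, outdir / "binding_calls.tsv")
    binding.write_gene_list(bound, outdir / "bound_genes.txt")
    report["binding"] = {
        "n_bound": len(bound),
        "flag_promoter_fraction": flag_fracs,
        "control_promoter_fraction": control_fracs,
    }

    # --- expression -------------------------------------------------------
    matrix = expression.ExpressionMatrix.read_tsv(cfg.expression)
    expressed = expression.expressed_genes(matrix, threshold=cfg.expressed_threshold)
    de = expression.simple_de_test(matrix, "KO", "high", alpha=cfg.de_alpha)
    de.to_csv(outdir / "de_ko_vs_high.tsv", sep="\t", index=False, float_format="%.6g")
    cls = expression.classify_and_tabulate(bound, de, expressed)
    cls.per_gene.to_csv(outdir / "classification.tsv", sep="\t", index=False)
    binding.write_gene_list(cls.activated, outdir / "activated_genes.txt")

    n_up = int((de.loc[de["gene_id"].isin(expressed), "direction"] == "up").sum())
    n_down = int((de.loc[de["gene_id"].isin(expressed), "direction"] == "down").sum())
    report["expression"] = {
        "n_expressed": len(expressed),
        "n_up": n_up,
        "n_down": n_down,
        "n_activated": len(cls.activated),
        "fraction_up_bound": cls.fraction_up_bound,
        "fraction_up_unbound": cls.fraction_up_unbound,
        "fraction_activated_of_up": cls.fraction_activated_of_up,
        "odds_ratio": cls.fisher.odds_ratio if cls.fisher else None,
        "fisher_p": cls.fisher.p if cls.fisher else None,
    }

    # low-vs-high concordance when low samples exist
    if len(matrix.samples_in_group("low")) >= 2:
        de_low = expression.simple_de_test(matrix, "low", "high", alpha=cfg.de_alpha)
        report["expression"]["fold_change_concordance_r"] = expression.fold_change_concordance(
            de, de_low
        )

    # --- overlap statistics ----------------------------------------------
    universe = expressed
    up_set = set(de.loc[de["direction"] == "up", "gene_id"]) & universe
    down_set = set(de.loc[de["direction"] == "down", "gene_id"]) & universe
    bound_expressed = bound & universe
    overlaps = {}
    for name, gene_set in (("up", up_set), ("down", down_set)):
        if gene_set and bound_expressed:
            ov = stats.hypergeom_overlap(
                len(universe), len(bound_expressed), len(gene_set), len(gene_set & bound_expressed)
            )
            overlaps[name] = {
                "overlap": ov.overlap,
                "fold": ov.fold,
                "log10_p_over": ov.log10_p_over,
                "log10_p_under": ov.log10_p_under,
            }
    report["overlap"] = overlaps

    # --- motif dose -------------------------------------------------------
    if cfg.fasta:
        import pyfaidx

        fasta = pyfaidx.Fasta(cfg.fasta)
        pattern = motif.DegenerateMotif(cfg.motif_pattern)
        counts = motif.promoter_motif_table(ann, fasta, pattern, flank=cfg.flank)
        counts.to_csv(outdir / "promoter_motif_counts.tsv", sep="\t", header=True)

        pooled = []
        for i, path in enumerate(cfg.flag_peaks, 1):
            pooled.extend(binding.read_narrowpeak(path, "FLAG", f"flag{i}"))
        if blacklist is not None:
            pooled = binding.filter_blacklist(pooled, blacklist)
        summits = [(p.chrom, p.summit) for p in pooled]
        window_counts = motif.summit_window_counts(summits, fasta, pattern)
        scores = np.array([p.score for p in pooled])
        pd.DataFrame(
            {"chrom": [c for c, _ in summits], "summit": [s for _, s in summits],
             "motif_count": window_counts, "score": scores}
        ).to_csv(outdir / "summit_motif_counts.tsv", sep="\t", index=False, float_format="%.6g")
        if window_counts.size >= 10 and window_counts.max() > window_counts.min():
            rho, perm_p = motif.motif_score_correlation(
                window_counts, scores, n_permutations=cfg.n_permutations, rng=cfg.seed
            )
            report["motif"] = {"summit_spearman_rho": rho, "summit_permutation_p": perm_p}
        else:
            report["motif"] = {}

        fc = de.set_index("gene_id")["log2fc"]
        strata = motif.stratify_by_motif_count(fc, counts)
        strata.to_csv(outdir / "motif_dose_strata.tsv", sep="\t", float_format="%.6g")
        report["motif"]["expression_strata_monotone"] = strata.attrs["monotone_medians"]

    # --- ground-truth recovery -------------------------------------------
    if truth is not None:
        true_bound = truth.bound_genes
        true_unbound = set(truth.motif_count) - true_bound
        tp = len(bound & true_bound)
        fp = len(bound & true_unbound)
        called_act = cls.activated
        true_act = true_bound  # every bound gene has a positive planted effect
        report["recovery"] = {
            "bound_sensitivity": tp / len(true_bound) if true_bound else float("nan"),
            "bound_fpr": fp / len(true_unbound) if true_unbound else float("nan"),
            "activated_sensitivity": len(called_act & true_act) / len(true_act)
            if true_act
            else float("nan"),
            "activated_precision": len(called_act & true_act) / len(called_act)
            if called_act
            else float("nan"),
        }

    report_path = outdir / "run_report.json"
    report_path.write_text(json.dumps(report, indent=1, sort_keys=True, default=float))
    return report
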