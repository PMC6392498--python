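"""Synthetic genomes, replicated promoter peaks, and staged expression matrices.

The generator emits the statistical structure the downstream integration
assumes, so the whole pipeline is testable without sequencing data:

* a random genome with genes on a single chromosome, each with a
  non-overlapping 2-kb promoter window;
* CNCCTCAG motif instances planted near the TSS of "bound" genes — a gene is
  bound iff it carries at least one planted motif, so binding, peak score and
  expression amplification all share one motif dose;
* replicated FLAG peak calls (per-replicate sensitivity, summit jitter,
  score = base + increment x motif count + noise) plus spurious non-promoter
  peaks; control replicates carry spurious peaks only;
* KO / low-STRA8 / high-STRA8 expression in which bound genes are amplified by
  2^(increment x motif count) in high samples (half the log-effect in low),
  with a separate downregulated gene set, multiplicative lognormal noise, and
  columns renormalized to TPM;
* a nine-tissue panel with planted testis-biased genes.

Peaks are generated directly at the peak-caller output contract (narrowPeak
records); no read-level simulation is attempted. All generators are pure
functions of (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .annotation import GeneAnnotation, IntervalSet, Transcript
from .binding import Peak
from .expression import ExpressionMatrix
from .motif import DegenerateMotif, IUPAC, reverse_complement

TISSUES = ("brain", "colon", "heart", "kidney", "liver", "lung", "muscle", "spleen", "testis")

# conditional distribution of motif count given >= 1 planted motif: most bound
# promoters carry one or two motifs, with a thin tail out to eight
_POSITIVE_COUNT_PROBS = {1: 0.49, 2: 0.29, 3: 0.12, 4: 0.05, 5: 0.035, 6: 0.008, 7: 0.004, 8: 0.003}


def default_motif_count_distribution(frac_bound: float) -> dict[int, float]:
    """P(0) = 1 − frac_bound; positive counts share the remaining mass."""
    dist = {0: 1.0 - frac_bound}
    dist.update({k: v * frac_bound for k, v in _POSITIVE_COUNT_PROBS.items()})
    return dist


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the study design: three FLAG and three control ChIP
    replicates at 0.9 per-replicate sensitivity, a quarter of genes bound,
    and KO:3 / low:2 / high:2 expression samples.
    """

    n_genes: int = 1000
    chrom_length: int = 3_200_000
    chrom_name: str = "chr1"
    n_flag_reps: int = 3
    n_control_reps: int = 3
    frac_bound: float = 0.25
    motif_count_distribution: dict[int, float] | None = None
    per_replicate_sensitivity: float = 0.9
    spurious_peak_rate: float = 45.0
    summit_jitter_sd: float = 30.0
    # peak score model: base + per-motif increment + Normal noise, floored
    score_base: float = 50.0
    score_per_motif: float = 20.0
    score_noise_sd: float = 10.0
    score_floor: float = 1.0
    peak_halfwidth: int = 200
    # expression model (log2 scale); the downregulated set is sized so the
    # transcript mass it loses roughly balances the mass the amplified genes
    # gain, keeping TPM closure from shifting unchanged genes
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 1.5
    log2fc_per_motif: float = 0.4
    n_downregulated: int = 250
    downregulation_log2fc: float = -2.5
    expression_noise_sd: float = 0.06
    groups: dict[str, int] = field(default_factory=lambda: {"KO": 3, "low": 2, "high": 3})
    # placement
    flank: int = 1000
    motif_cluster_halfwidth: int = 250
    cgi_prob_bound: float = 0.97
    cgi_prob_unbound: float = 0.5
    cgi_halfwidth: int = 300
    n_blacklist: int = 5
    blacklist_length: int = 1000
    motif: str = "CNCCTCAG"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.motif_count_distribution is None:
            self.motif_count_distribution = default_motif_count_distribution(self.frac_bound)
        total = sum(self.motif_count_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"motif_count_distribution sums to {total}, not 1")
        for p in (self.per_replicate_sensitivity, self.frac_bound, *self.motif_count_distribution.values()):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(self.seed).spawn(stream + 1)[stream])


@dataclass
class GroundTruth:
    """Planted truth for recovery checks."""

    bound_genes: set[str]
    motif_count: dict[str, int]
    true_log2fc: dict[str, float]
    downregulated_genes: set[str]

    def __post_init__(self) -> None:
        if self.bound_genes & self.downregulated_genes:
            raise ValueError("bound and downregulated gene sets must be disjoint")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "bound_genes": sorted(self.bound_genes),
            "motif_count": dict(sorted(self.motif_count.items())),
            "true_log2fc": dict(sorted(self.true_log2fc.items())),
            "downregulated_genes": sorted(self.downregulated_genes),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            set(d["bound_genes"]),
            {k: int(v) for k, v in d["motif_count"].items()},
            {k: float(v) for k, v in d["true_log2fc"].items()},
            set(d["downregulated_genes"]),
        )


@dataclass
class SyntheticGenome:
    sequence: str
    annotation: GeneAnnotation
    truth: GroundTruth
    cgi: IntervalSet
    blacklist: IntervalSet


def _instantiate_motif(pattern: str, rng: np.random.Generator) -> str:
    return "".join(c if c in "ACGT" else rng.choice(list(IUPAC[c])) for c in pattern)


def make_genome(cfg: SimulationConfig) -> SyntheticGenome:
    """Random genome with planted promoter motifs; deterministic in cfg.seed."""
    rng = cfg.rng(0)
    spacing = cfg.chrom_length // cfg.n_genes
    if spacing < 2 * cfg.flank + 2 * cfg.motif_cluster_halfwidth:
        raise ValueError(
            f"chrom_length {cfg.chrom_length} cannot pack {cfg.n_genes} genes "
            f"with non-overlapping {2 * cfg.flank} bp promoters"
        )
    seq = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=cfg.chrom_length)

    counts_support = np.array(sorted(cfg.motif_count_distribution))
    counts_probs = np.array([cfg.motif_count_distribution[k] for k in counts_support], dtype=float)
    counts_probs = counts_probs / counts_probs.sum()

    motif_len = len(cfg.motif)
    transcripts, motif_count, bound = [], {}, set()
    for i in range(cfg.n_genes):
        gene = f"gene{i:05d}"
        tss = i * spacing + spacing // 2
        strand = "+" if rng.random() < 0.5 else "-"
        transcripts.append(Transcript(f"{gene}.t1", gene, cfg.chrom_name, strand, tss))
        count = int(rng.choice(counts_support, p=counts_probs))
        motif_count[gene] = count
        if count > 0:
            bound.add(gene)
        # plant non-overlapping instances clustered around the TSS
        lo = tss - cfg.motif_cluster_halfwidth
        hi = tss + cfg.motif_cluster_halfwidth - motif_len
        placed: list[int] = []
        attempts = 0
        while len(placed) < count:
            pos = int(rng.integers(lo, hi + 1))
            if all(abs(pos - q) >= motif_len for q in placed):
                placed.append(pos)
            attempts += 1
            if attempts > 1000:
                raise RuntimeError("could not place motifs without overlap")
        for pos in placed:
            instance = _instantiate_motif(cfg.motif, rng)
            if rng.random() < 0.5:
                instance = reverse_complement(instance)
            seq[pos : pos + motif_len] = np.frombuffer(instance.encode(), dtype="S1")

    ann = GeneAnnotation(transcripts, chrom_lengths={cfg.chrom_name: cfg.chrom_length})

    cgi_intervals = []
    for t in ann.transcripts:
        p = cfg.cgi_prob_bound if t.gene_id in bound else cfg.cgi_prob_unbound
        if rng.random() < p:
            cgi_intervals.append(
                (cfg.chrom_name, max(0, t.tss - cfg.cgi_halfwidth), t.tss + cfg.cgi_halfwidth)
            )
    cgi = IntervalSet(cgi_intervals, label="CGI")

    blacklist_intervals = []
    for _ in range(cfg.n_blacklist):
        start = _draw_non_promoter_position(rng, cfg, margin=cfg.blacklist_length)
        blacklist_intervals.append((cfg.chrom_name, start, start + cfg.blacklist_length))
    blacklist = IntervalSet(blacklist_intervals, label="blacklist")

    # downregulated genes drawn from the motif-free (unbound) genes
    unbound = sorted(set(motif_count) - bound)
    n_down = min(cfg.n_downregulated, len(unbound))
    down = set(rng.choice(unbound, size=n_down, replace=False)) if n_down else set()
    true_log2fc = {
        g: cfg.log2fc_per_motif * motif_count[g]
        if g in bound
        else (cfg.downregulation_log2fc if g in down else 0.0)
        for g in motif_count
    }
    truth = GroundTruth(bound, motif_count, true_log2fc, down)
    return SyntheticGenome(seq.tobytes().decode(), ann, truth, cgi, blacklist)


def _draw_non_promoter_position(
    rng: np.random.Generator, cfg: SimulationConfig, margin: int = 0
) -> int:
    """Uniform position whose [pos, pos+margin) clears every promoter window."""
    spacing = cfg.chrom_length // cfg.n_genes
    for _ in range(10_000):
        pos = int(rng.integers(0, cfg.chrom_length - margin))
        offset = pos % spacing
        center = spacing // 2
        lo = center - cfg.flank - margin
        hi = center + cfg.flank
        if not (lo < offset < hi) and pos // spacing < cfg.n_genes:
            return pos
    raise RuntimeError("could not draw a non-promoter position")


def simulate_peaks(
    ann: GeneAnnotation, truth: GroundTruth, cfg: SimulationConfig
) -> tuple[list[list[Peak]], list[list[Peak]]]:
    """Replicated FLAG and control peak calls.

    Each bound gene yields a FLAG peak per replicate with probability
    ``per_replicate_sensitivity``; summits jitter around the TSS; scores follow
    base + increment x motif count + noise, floored at a positive value.
    Spurious peaks (Poisson per replicate) land at uniform non-promoter
    positions so planted truth stays clean; controls carry only spurious peaks.
    """
    rng = cfg.rng(1)
    tss_of = {t.gene_id: t.tss for t in ann.transcripts}
    hw = cfg.peak_halfwidth

    def spurious_peaks(replicate: str, condition: str) -> list[Peak]:
        n = rng.poisson(cfg.spurious_peak_rate)
        out = []
        for _ in range(n):
            pos = _draw_non_promoter_position(rng, cfg, margin=0)
            score = max(cfg.score_floor, cfg.score_base + rng.normal(0, cfg.score_noise_sd))
            start = max(0, pos - hw)
            out.append(Peak(cfg.chrom_name, start, pos + hw, pos, score, replicate, condition))
        return out

    flag_reps: list[list[Peak]] = []
    for r in range(cfg.n_flag_reps):
        rep_name = f"flag{r + 1}"
        peaks: list[Peak] = []
        for gene in sorted(truth.bound_genes):
            if rng.random() >= cfg.per_replicate_sensitivity:
                continue
            summit = int(round(tss_of[gene] + rng.normal(0, cfg.summit_jitter_sd)))
            summit = int(np.clip(summit, tss_of[gene] - cfg.flank + 1, tss_of[gene] + cfg.flank - 1))
            score = max(
                cfg.score_floor,
                cfg.score_base
                + cfg.score_per_motif * truth.motif_count[gene]
                + rng.normal(0, cfg.score_noise_sd),
            )
            start = max(0, summit - hw)
            peaks.append(Peak(cfg.chrom_name, start, summit + hw, summit, score, rep_name, "FLAG"))
        peaks.extend(spurious_peaks(rep_name, "FLAG"))
        flag_reps.append(sorted(peaks, key=lambda p: p.start))

    control_reps = [
        sorted(spurious_peaks(f"control{r + 1}", "control"), key=lambda p: p.start)
        for r in range(cfg.n_control_reps)
    ]
    return flag_reps, control_reps


def simulate_expression(
    ann: GeneAnnotation,
    truth: GroundTruth,
    cfg: SimulationConfig,
    groups: Mapping[str, int] | None = None,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """KO / low / high TPM matrix with motif-dose amplification in high samples.

    high samples multiply bound genes by 2^(increment x motif count) and
    downregulated genes by 2^(downregulation log2FC); low samples receive half
    of every log effect; KO samples are baseline. Per-sample multiplicative
    lognormal noise; columns renormalized to sum 1e6.
    """
    rng = cfg.rng(2)
    groups = dict(groups or cfg.groups)
    genes = sorted(ann.genes)
    base_log2 = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, size=len(genes))
    effect = np.array([truth.true_log2fc.get(g, 0.0) for g in genes])
    scale = {"KO": 0.0, "low": 0.5, "high": 1.0}

    columns, names = [], []
    for group, n in groups.items():
        if group not in scale:
            raise ValueError(f"unknown group {group!r}; expected KO/low/high")
        for r in range(n):
            noise = rng.normal(0.0, cfg.expression_noise_sd, size=len(genes))
            columns.append(2.0 ** (base_log2 + scale[group] * effect + noise))
            names.append(f"{group}.{r + 1}")
    data = pd.DataFrame(np.column_stack(columns), index=genes, columns=names)
    matrix = ExpressionMatrix(data).renormalized()

    de_truth = pd.DataFrame(
        {
            "gene_id": genes,
            "true_log2fc": effect,
            "bound": [g in truth.bound_genes for g in genes],
            "downregulated": [g in truth.downregulated_genes for g in genes],
        }
    )
    return matrix, de_truth


def simulate_tissue_panel(
    ann: GeneAnnotation,
    n_biased: int,
    cfg: SimulationConfig,
    n_replicates: int = 3,
    bias_factor: float = 10.0,
    noise_sd: float = 0.0,
) -> tuple[ExpressionMatrix, set[str]]:
    """Nine-tissue panel with ``n_biased`` genes planted as testis-biased.

    A biased gene's testis value is ``bias_factor`` x the sum of its other
    eight tissue values; balanced genes are equal across tissues. Optional
    multiplicative lognormal noise (log2 sd) perturbs each column.
    """
    if n_biased > len(ann.genes):
        raise ValueError("n_biased exceeds the number of genes")
    rng = cfg.rng(3)
    genes = sorted(ann.genes)
    biased = set(rng.choice(genes, size=n_biased, replace=False)) if n_biased else set()
    base = 2.0 ** rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, size=len(genes))
    columns, names = [], []
    for tissue in TISSUES:
        for r in range(n_replicates):
            values = base.copy()
            if tissue == "testis":
                mask = np.array([g in biased for g in genes])
                values[mask] = bias_factor * 8.0 * base[mask]
            if noise_sd > 0:
                values = values * 2.0 ** rng.normal(0.0, noise_sd, size=len(genes))
            columns.append(values)
            names.append(f"{tissue}.{r + 1}")
    data = pd.DataFrame(np.column_stack(columns), index=genes, columns=names)
    return ExpressionMatrix(data).renormalized(), biased


def simulate_promoter_counts(
    truth: GroundTruth,
    cfg: SimulationConfig,
    mean_depth: float = 20.0,
    input_rate: float = 10.0,
) -> tuple[dict[str, int], dict[str, int]]:
    """Poisson promoter read counts with rate proportional to the expected peak
    score, plus a flat input-chromatin rate; feeds the rpm-subtraction step."""
    rng = cfg.rng(4)
    chip, inputs = {}, {}
    for gene in sorted(truth.motif_count):
        expected_score = cfg.score_base + cfg.score_per_motif * truth.motif_count[gene]
        rate = input_rate + mean_depth * expected_score / cfg.score_base * (gene in truth.bound_genes)
        chip[gene] = int(rng.poisson(rate))
        inputs[gene] = int(rng.poisson(input_rate))
    return chip, inputs


def write_fasta(sequence: str, path: str | Path, name: str = "chr1", width: int = 80) -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(sequence), width):
            fh.write(sequence[i : i + width] + "\n")
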