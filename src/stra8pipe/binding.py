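"""Replicated ChIP peaks to gene-level binding calls.

Implements the promoter-assignment and consensus logic: blacklist filtering,
summit-to-TSS assignment within a 1-kb flank, removal of genes hit in any
control replicate, and the >= min_replicates consensus that defines the bound
set. Also the rpm/input-subtraction arithmetic for promoter read density.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .annotation import GeneAnnotation, IntervalSet, promoter_window

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Peak:
    """One called peak with its summit (absolute 0-based position) and score."""

    chrom: str
    start: int
    end: int
    summit: int
    score: float
    replicate_id: str = ""
    condition: str = "FLAG"

    def __post_init__(self) -> None:
        if not (self.start <= self.summit < self.end):
            raise ValueError(
                f"summit {self.summit} outside peak [{self.start}, {self.end})"
            )


@dataclass(frozen=True)
class BindingCall:
    gene_id: str
    n_flag_replicates_with_peak: int
    control_hit: bool
    bound: bool


def read_narrowpeak(
    path: str | Path, condition: str = "FLAG", replicate_id: str = ""
) -> list[Peak]:
    """Read ENCODE narrowPeak (BED6+4). Summit = start + 10th column offset.

    A summit offset of −1 (absent) falls back to the interval midpoint with a
    logged warning. Plain BED with >= 3 columns is accepted; score defaults 0.
    """
    peaks: list[Peak] = []
    n_fallback = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            score = float(parts[6]) if len(parts) >= 7 else (float(parts[4]) if len(parts) >= 5 else 0.0)
            offset = int(parts[9]) if len(parts) >= 10 else -1
            if offset < 0:
                summit = (start + end) // 2
                n_fallback += 1
            else:
                summit = start + offset
            peaks.append(Peak(chrom, start, end, summit, score, replicate_id, condition))
    if n_fallback:
        logger.warning("%s: %d peaks without summit; used interval midpoints", path, n_fallback)
    return peaks


def write_narrowpeak(peaks: Sequence[Peak], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\tpeak_{i}\t0\t.\t{p.score:.4f}\t-1\t-1\t{p.summit - p.start}\n"
            )


def filter_blacklist(peaks: Iterable[Peak], blacklist: IntervalSet) -> list[Peak]:
    """Drop peaks whose [start, end) overlaps any blacklist interval; order kept."""
    return [p for p in peaks if not blacklist.overlaps(p.chrom, p.start, p.end)]


def _tss_window_trees(ann: GeneAnnotation, flank: int) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for t in ann.transcripts:
        w = promoter_window(t, flank=flank, chrom_lengths=ann.chrom_lengths)
        trees.setdefault(t.chrom, IntervalTree()).addi(w.start, w.end, (t.transcript_id, t.gene_id))
    return trees


def assign_peaks_to_tss(
    peaks: Sequence[Peak], ann: GeneAnnotation, flank: int = 1000
) -> list[set[tuple[str, str]]]:
    """Per peak, the set of (transcript_id, gene_id) whose TSS lies within
    ``flank`` of the peak summit. Assignment uses the summit only; a summit
    within range of several TSSs is assigned to all of them.
    """
    if len(ann) == 0:
        raise ValueError("annotation is empty")
    trees = _tss_window_trees(ann, flank)
    assignments: list[set[tuple[str, str]]] = []
    for p in peaks:
        tree = trees.get(p.chrom)
        hits = tree.at(p.summit) if tree is not None else set()
        assignments.append({iv.data for iv in hits})
    return assignments


def genes_with_promoter_peak(
    peaks: Sequence[Peak], ann: GeneAnnotation, flank: int = 1000
) -> set[str]:
    """Genes whose promoter (summit within ``flank`` of a TSS) has >= 1 peak."""
    out: set[str] = set()
    for assigned in assign_peaks_to_tss(peaks, ann, flank=flank):
        out.update(g for _, g in assigned)
    return out


def promoter_fraction(peaks: Sequence[Peak], ann: GeneAnnotation, flank: int = 1000) -> float:
    """Fraction of peaks assigned to >= 1 transcript. Errors on an empty peak list."""
    if len(peaks) == 0:
        raise ValueError("promoter fraction undefined for an empty peak list")
    assignments = assign_peaks_to_tss(peaks, ann, flank=flank)
    return sum(bool(a) for a in assignments) / len(peaks)


def call_bound_genes(
    flag_reps: Sequence[set[str]],
    control_reps: Sequence[set[str]],
    min_replicates: int = 2,
) -> tuple[set[str], pd.DataFrame]:
    """Replicate-consensus binding calls with any-control-replicate removal.

    bound = (gene in >= min_replicates FLAG replicate gene sets) AND (gene in
    no control replicate gene set). Returns the bound set plus a per-gene
    table of BindingCall fields for every gene seen in any replicate.
    """
    if min_replicates > len(flag_reps):
        raise ValueError(
            f"min_replicates={min_replicates} exceeds {len(flag_reps)} FLAG replicates"
        )
    control_union: set[str] = set().union(*control_reps) if control_reps else set()
    all_genes = sorted(set().union(*flag_reps, control_union) if flag_reps else control_union)
    rows = []
    bound: set[str] = set()
    for gene in all_genes:
        n_hits = sum(gene in rep for rep in flag_reps)
        in_control = gene in control_union
        is_bound = n_hits >= min_replicates and not in_control
        if is_bound:
            bound.add(gene)
        rows.append(
            {
                "gene_id": gene,
                "n_flag_replicates_with_peak": n_hits,
                "control_hit": in_control,
                "bound": is_bound,
            }
        )
    table = pd.DataFrame(rows, columns=["gene_id", "n_flag_replicates_with_peak", "control_hit", "bound"])
    return bound, table


def promoter_read_density(
    promoter_counts: Mapping[str, float],
    library_size: float,
    input_counts: Mapping[str, float],
    input_library_size: float,
) -> dict[str, float]:
    """Input-subtracted reads-per-million at each gene's promoter.

    value = count/library_size * 1e6 − input_count/input_library_size * 1e6.
    Negative values are permitted (not clipped). Transcript-level counts must
    be summed to gene level before calling.
    """
    if library_size <= 0 or input_library_size <= 0:
        raise ValueError("library sizes must be > 0")
    out: dict[str, float] = {}
    for gene, count in promoter_counts.items():
        inp = input_counts.get(gene, 0.0)
        if count < 0 or inp < 0:
            raise ValueError(f"negative count for gene {gene!r}")
        out[gene] = count / library_size * 1e6 - inp / input_library_size * 1e6
    return out


def write_binding_calls(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(g + "\n")
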