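"""Genomic coordinate frame: transcripts, promoter windows, interval sets.

All internal coordinates are 0-based, half-open. GTF input (1-based, closed)
is converted on load; BED input is native. The TSS of a + strand transcript is
its start; of a − strand transcript, its last base (GTF ``end − 1``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

VALID_STRANDS = {"+", "-"}


@dataclass(frozen=True)
class Transcript:
    """One transcript anchored by its TSS (0-based genomic position)."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    tss: int
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.tss < 0:
            raise ValueError(f"tss must be >= 0, got {self.tss}")


@dataclass(frozen=True)
class PromoterWindow:
    """Symmetric window around a transcript's TSS, clipped at chromosome ends."""

    gene_id: str
    transcript_id: str
    chrom: str
    start: int
    end: int
    flank: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("empty promoter window")


class GeneAnnotation:
    """Container of transcripts indexed by gene, with optional chromosome sizes."""

    def __init__(
        self,
        transcripts: Iterable[Transcript],
        chrom_lengths: Mapping[str, int] | None = None,
    ) -> None:
        self.transcripts: list[Transcript] = list(transcripts)
        seen: set[str] = set()
        for t in self.transcripts:
            if t.transcript_id in seen:
                raise ValueError(f"duplicate transcript_id {t.transcript_id!r}")
            seen.add(t.transcript_id)
        self.gene_index: dict[str, list[Transcript]] = {}
        for t in self.transcripts:
            self.gene_index.setdefault(t.gene_id, []).append(t)
        self.chrom_lengths = dict(chrom_lengths) if chrom_lengths else None
        if self.chrom_lengths is not None:
            for t in self.transcripts:
                length = self.chrom_lengths.get(t.chrom)
                if length is not None and t.tss >= length:
                    raise ValueError(
                        f"TSS {t.tss} of {t.transcript_id} beyond {t.chrom} length {length}"
                    )

    def __len__(self) -> int:
        return len(self.transcripts)

    @property
    def genes(self) -> list[str]:
        return list(self.gene_index)

    def transcripts_of(self, gene_id: str) -> list[Transcript]:
        try:
            return self.gene_index[gene_id]
        except KeyError:
            raise KeyError(f"unknown gene {gene_id!r}") from None


class IntervalSet:
    """A labelled set of genomic intervals with fast point/range overlap queries."""

    def __init__(self, intervals: Iterable[tuple[str, int, int]], label: str = "other") -> None:
        self.intervals: list[tuple[str, int, int]] = []
        self.label = label
        self._trees: dict[str, IntervalTree] = {}
        for chrom, start, end in intervals:
            if start >= end:
                raise ValueError(f"start must be < end, got [{start}, {end})")
            self.intervals.append((chrom, int(start), int(end)))
            self._trees.setdefault(chrom, IntervalTree()).addi(start, end)

    def __len__(self) -> int:
        return len(self.intervals)

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """True iff any interval shares >= 1 base with [start, end) on chrom."""
        tree = self._trees.get(chrom)
        return bool(tree.overlap(start, end)) if tree is not None else False

    def contains_point(self, chrom: str, pos: int) -> bool:
        tree = self._trees.get(chrom)
        return bool(tree.at(pos)) if tree is not None else False

    @classmethod
    def from_bed(cls, path: str | Path, label: str = "other") -> "IntervalSet":
        intervals = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValueError(f"{path}:{lineno}: BED line has < 3 columns")
                intervals.append((parts[0], int(parts[1]), int(parts[2])))
        return cls(intervals, label=label)

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom, start, end in self.intervals:
                fh.write(f"{chrom}\t{start}\t{end}\n")


def _parse_gtf_attributes(attr_field: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in attr_field.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def load_annotation(
    path: str | Path,
    biotype_filter: str | None = "protein_coding",
    tss_overrides: Mapping[str, int] | None = None,
    chrom_lengths: Mapping[str, int] | None = None,
) -> GeneAnnotation:
    """Load transcript annotation from GTF (Ensembl dialect) or the TSV dialect.

    The TSV dialect has a header ``transcript_id gene_id chrom strand tss [biotype]``
    with 0-based TSS. GTF coordinates are converted: TSS = start − 1 on +, end − 1
    on −. Records failing ``biotype_filter`` are dropped; records with unknown
    strand are rejected with a counted warning.

    ``tss_overrides`` maps transcript_id to a manually curated **1-based** TSS
    (converted to 0-based on load), for annotations with hand-added start sites.
    """
    path = Path(path)
    if path.suffix.lower() in {".gtf", ".gff"}:
        transcripts = _load_gtf(path, biotype_filter)
    else:
        transcripts = _load_tsv(path, biotype_filter)
    if tss_overrides:
        transcripts = [
            t
            if t.transcript_id not in tss_overrides
            else Transcript(
                t.transcript_id, t.gene_id, t.chrom, t.strand,
                int(tss_overrides[t.transcript_id]) - 1, t.biotype,
            )
            for t in transcripts
        ]
    return GeneAnnotation(transcripts, chrom_lengths=chrom_lengths)


def _load_gtf(path: Path, biotype_filter: str | None) -> list[Transcript]:
    transcripts: list[Transcript] = []
    n_bad_strand = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise ValueError(f"{path}:{lineno}: malformed GTF row ({len(parts)} columns)")
            if parts[2] != "transcript":
                continue
            try:
                start_1b, end_1b = int(parts[3]), int(parts[4])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            strand = parts[6]
            if strand not in VALID_STRANDS:
                n_bad_strand += 1
                continue
            attrs = _parse_gtf_attributes(parts[8])
            biotype = attrs.get("transcript_biotype", attrs.get("gene_biotype", ""))
            if biotype_filter is not None and biotype != biotype_filter:
                continue
            tss = start_1b - 1 if strand == "+" else end_1b - 1
            transcripts.append(
                Transcript(attrs["transcript_id"], attrs["gene_id"], parts[0], strand, tss, biotype)
            )
    if n_bad_strand:
        logger.warning("%s: rejected %d records with unknown strand", path, n_bad_strand)
    return transcripts


def _load_tsv(path: Path, biotype_filter: str | None) -> list[Transcript]:
    transcripts: list[Transcript] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for col in ("transcript_id", "gene_id", "chrom", "strand", "tss"):
            if col not in idx:
                raise ValueError(f"{path}: missing column {col!r}")
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < len(header):
                raise ValueError(f"{path}:{lineno}: malformed row")
            biotype = parts[idx["biotype"]] if "biotype" in idx else "protein_coding"
            if biotype_filter is not None and biotype != biotype_filter:
                continue
            transcripts.append(
                Transcript(
                    parts[idx["transcript_id"]],
                    parts[idx["gene_id"]],
                    parts[idx["chrom"]],
                    parts[idx["strand"]],
                    int(parts[idx["tss"]]),
                    biotype,
                )
            )
    return transcripts


def write_annotation(ann: GeneAnnotation, path: str | Path) -> None:
    """Write the TSV annotation dialect (0-based TSS)."""
    with open(path, "w") as fh:
        fh.write("transcript_id\tgene_id\tchrom\tstrand\ttss\tbiotype\n")
        for t in ann.transcripts:
            fh.write(f"{t.transcript_id}\t{t.gene_id}\t{t.chrom}\t{t.strand}\t{t.tss}\t{t.biotype}\n")


def promoter_window(
    t: Transcript, flank: int = 1000, chrom_lengths: Mapping[str, int] | None = None
) -> PromoterWindow:
    """[tss − flank, tss + flank), clipped at chromosome bounds when known.

    The window is strand-independent: + and − transcripts with the same TSS
    yield identical windows.
    """
    if flank <= 0:
        raise ValueError("flank must be > 0")
    start = max(0, t.tss - flank)
    end = t.tss + flank
    if chrom_lengths is not None and t.chrom in chrom_lengths:
        end = min(end, chrom_lengths[t.chrom])
    return PromoterWindow(t.gene_id, t.transcript_id, t.chrom, start, end, flank)


def has_cgi_promoter(
    gene_id: str, ann: GeneAnnotation, cgi: IntervalSet, flank: int = 1000
) -> bool:
    """True iff a CpG island overlaps the 2-kb TSS window of any transcript of the gene."""
    for t in ann.transcripts_of(gene_id):
        w = promoter_window(t, flank=flank, chrom_lengths=ann.chrom_lengths)
        if cgi.overlaps(w.chrom, w.start, w.end):
            return True
    return False
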