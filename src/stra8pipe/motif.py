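"""IUPAC degenerate-motif scanning and motif dose-response analyses.

The scanner implements "perfect match" semantics for a degenerate pattern such
as CNCCTCAG: each literal position must match exactly, an N (or other
ambiguity code) in the pattern matches the corresponding set of plain bases,
and an N in the *subject* sequence matches nothing. Overlapping matches are
all reported. Both-strand scanning also matches the reverse complement of the
pattern on the given sequence, reported as strand "-" at the forward
coordinate of the match start.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneAnnotation, promoter_window
from .stats import mann_whitney, spearman_permutation

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(pattern: str) -> str:
    """Reverse complement of a nucleotide or IUPAC pattern string."""
    return pattern.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class DegenerateMotif:
    """An IUPAC pattern, default the STRA8 core motif CNCCTCAG."""

    pattern: str = "CNCCTCAG"

    def __post_init__(self) -> None:
        pat = self.pattern.upper()
        bad = set(pat) - set(IUPAC)
        if bad or not pat:
            raise ValueError(f"invalid IUPAC code(s) {sorted(bad)} in pattern {self.pattern!r}")
        object.__setattr__(self, "pattern", pat)

    def __len__(self) -> int:
        return len(self.pattern)

    def _regex(self, pattern: str) -> re.Pattern[str]:
        # lookahead so overlapping matches are all reported
        return re.compile("(?=(" + "".join(f"[{IUPAC[c]}]" for c in pattern) + "))")

    @property
    def forward_regex(self) -> re.Pattern[str]:
        return self._regex(self.pattern)

    @property
    def reverse_regex(self) -> re.Pattern[str]:
        return self._regex(reverse_complement(self.pattern))


def scan_motif(
    seq: str, motif: DegenerateMotif | str = "CNCCTCAG", both_strands: bool = True
) -> list[tuple[int, str]]:
    """All (position, strand) matches of the motif in ``seq`` (0-based starts)."""
    if isinstance(motif, str):
        motif = DegenerateMotif(motif)
    seq = seq.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"sequence contains non-nucleotide characters {sorted(bad)}")
    hits = [(m.start(), "+") for m in motif.forward_regex.finditer(seq)]
    if both_strands:
        hits += [(m.start(), "-") for m in motif.reverse_regex.finditer(seq)]
    return sorted(hits)


def count_motifs(seq: str, motif: DegenerateMotif | str = "CNCCTCAG", both_strands: bool = True) -> int:
    return len(scan_motif(seq, motif, both_strands=both_strands))


def count_promoter_motifs(
    gene_id: str,
    ann: GeneAnnotation,
    sequences: Mapping[str, object],
    motif: DegenerateMotif | str = "CNCCTCAG",
    flank: int = 1000,
    both_strands: bool = True,
) -> int:
    """Motif count in the 2-kb TSS window; max over the gene's transcripts.

    ``sequences`` maps chromosome name to an indexable sequence (a plain string
    or a ``pyfaidx.Fasta`` record). Windows extending past the sequence end are
    clipped.
    """
    if isinstance(motif, str):
        motif = DegenerateMotif(motif)
    best = 0
    for t in ann.transcripts_of(gene_id):
        record = sequences[t.chrom]
        w = promoter_window(t, flank=flank, chrom_lengths=ann.chrom_lengths)
        seq = str(record[w.start : w.end])
        best = max(best, count_motifs(seq, motif, both_strands=both_strands))
    return best


def promoter_motif_table(
    ann: GeneAnnotation,
    sequences: Mapping[str, object],
    motif: DegenerateMotif | str = "CNCCTCAG",
    flank: int = 1000,
) -> pd.Series:
    """Per-gene promoter motif counts for every gene in the annotation."""
    if isinstance(motif, str):
        motif = DegenerateMotif(motif)
    counts = {g: count_promoter_motifs(g, ann, sequences, motif, flank=flank) for g in ann.genes}
    return pd.Series(counts, name="promoter_motif_count").sort_index()


def summit_window_counts(
    summits: Sequence[tuple[str, int]],
    sequences: Mapping[str, object],
    motif: DegenerateMotif | str = "CNCCTCAG",
    halfwidth: int = 50,
) -> np.ndarray:
    """Motif counts in the 100-bp windows [summit − 50, summit + 50) around summits."""
    if isinstance(motif, str):
        motif = DegenerateMotif(motif)
    counts = []
    for chrom, summit in summits:
        record = sequences[chrom]
        start = max(0, summit - halfwidth)
        seq = str(record[start : summit + halfwidth])
        counts.append(count_motifs(seq, motif))
    return np.asarray(counts, dtype=int)


def motif_score_correlation(
    summit_counts: Sequence[int],
    scores: Sequence[float],
    n_permutations: int = 10_000,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float]:
    """Spearman rho between summit-window motif counts and peak scores.

    The p-value comes from seeded permutations of the score vector,
    p = (1 + #{|rho*| >= |rho|}) / (1 + n_permutations).
    """
    counts = np.asarray(summit_counts, dtype=float)
    if counts.size < 10:
        raise ValueError("need at least 10 peaks")
    if n_permutations < 100:
        raise ValueError("need at least 100 permutations")
    return spearman_permutation(counts, scores, n_permutations=n_permutations, rng=rng)


def stratify_by_motif_count(
    values: Mapping[str, float] | pd.Series,
    counts: Mapping[str, int] | pd.Series,
    max_stratum: int = 5,
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """Distribution summaries of ``values`` per motif-count stratum 0..max_stratum.

    Genes with more than ``max_stratum`` motifs are pooled into the top
    stratum. Returns one row per stratum with n, median, quartiles, the
    Mann-Whitney p against the previous stratum (NaN where either stratum is
    empty), and a shared ``monotone_medians`` flag saying whether the
    non-empty stratum medians are non-decreasing.
    """
    values = pd.Series(values, dtype=float)
    counts = pd.Series(counts, dtype=int)
    shared = values.index.intersection(counts.index)
    values, counts = values[shared], counts.clip(upper=max_stratum)[shared]
    rows = []
    prev: np.ndarray | None = None
    for stratum in range(max_stratum + 1):
        v = values[counts == stratum].to_numpy()
        p_adj = np.nan
        if v.size and prev is not None and prev.size:
            _, p_adj = mann_whitney(v, prev, alternative=alternative)
        rows.append(
            {
                "stratum": stratum,
                "n": v.size,
                "median": np.median(v) if v.size else np.nan,
                "q1": np.percentile(v, 25) if v.size else np.nan,
                "q3": np.percentile(v, 75) if v.size else np.nan,
                "p_vs_previous": p_adj,
            }
        )
        if v.size:
            prev = v
    out = pd.DataFrame(rows).set_index("stratum")
    medians = out["median"].dropna().to_numpy()
    out.attrs["monotone_medians"] = bool(np.all(np.diff(medians) >= 0)) if medians.size else False
    return out
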