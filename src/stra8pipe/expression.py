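"""Expression-side integration: TPM aggregation, expressed filter, plumbing DE,
bound x DE classification, fold-change concordance, and the testis-bias rule.

The differential-expression stage is a deliberately simple stand-in — a Welch
t-test on log2(TPM+1) with Benjamini-Hochberg adjustment — chosen because the
analysis of interest is the integration of binding with expression, not the DE
engine; externally computed DE tables (e.g. from a count-based model) can be
loaded with :func:`read_de_table` and dropped in anywhere a DE table is used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .annotation import GeneAnnotation
from .stats import FisherResult, bh_fdr, fisher_exact

TPM_TOTAL = 1e6

DE_COLUMNS = ["gene_id", "log2fc", "p", "q", "direction"]


@dataclass
class ExpressionMatrix:
    """Gene x sample abundance table with TPM semantics and sample group labels.

    ``groups`` maps sample name to its group (KO / low / high, or a tissue
    name). Sample names of the form ``group.rep`` are parsed automatically.
    """

    data: pd.DataFrame
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.data.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        if not self.groups:
            self.groups = {s: str(s).rsplit(".", 1)[0] for s in self.data.columns}

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s, g in self.groups.items() if g == group]

    def renormalized(self) -> "ExpressionMatrix":
        """Rescale every column to sum to 1e6 (TPM semantics)."""
        sums = self.data.sum(axis=0)
        if (sums <= 0).any():
            raise ValueError("cannot renormalize a column with zero total")
        return ExpressionMatrix(self.data * (TPM_TOTAL / sums), dict(self.groups))

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")

    @classmethod
    def read_tsv(cls, path: str | Path, groups: Mapping[str, str] | None = None) -> "ExpressionMatrix":
        data = pd.read_csv(path, sep="\t", index_col=0)
        return cls(data, dict(groups) if groups else {})


def gene_tpm(transcript_tpm: pd.DataFrame, ann: GeneAnnotation) -> ExpressionMatrix:
    """Sum transcript-level TPM to gene level and renormalize columns to 1e6.

    Every transcript row must map to a gene in the annotation; orphans raise an
    error listing their IDs.
    """
    tx_to_gene = {t.transcript_id: t.gene_id for t in ann.transcripts}
    orphans = [tx for tx in transcript_tpm.index if tx not in tx_to_gene]
    if orphans:
        raise ValueError(f"transcripts not in annotation: {orphans}")
    gene_ids = transcript_tpm.index.map(tx_to_gene)
    summed = transcript_tpm.groupby(gene_ids).sum()
    return ExpressionMatrix(summed).renormalized()


def expressed_genes(
    m: ExpressionMatrix, threshold: float = 1.0, strict: bool = False
) -> set[str]:
    """Genes whose value reaches ``threshold`` in at least one sample.

    The comparison is >= by default (the legend-stated rule); ``strict=True``
    switches to a strict > comparison.
    """
    values = m.data.to_numpy()
    hit = (values > threshold) if strict else (values >= threshold)
    mask = hit.any(axis=1)
    return set(m.data.index[mask])


def simple_de_test(
    m: ExpressionMatrix, group1: str, group2: str, alpha: float = 0.05
) -> pd.DataFrame:
    """Welch t-test per gene on log2(TPM+1), group2 over group1, BH-adjusted.

    log2fc = mean(log2(group2+1)) − mean(log2(group1+1)). Genes constant in
    both groups get p = 1. ``direction`` is up/down for q < alpha by the sign
    of log2fc, otherwise ns.
    """
    s1 = m.samples_in_group(group1)
    s2 = m.samples_in_group(group2)
    if len(s1) < 2 or len(s2) < 2:
        raise ValueError(f"need >= 2 samples per group ({group1}: {len(s1)}, {group2}: {len(s2)})")
    x1 = np.log2(m.data[s1].to_numpy() + 1.0)
    x2 = np.log2(m.data[s2].to_numpy() + 1.0)
    log2fc = x2.mean(axis=1) - x1.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = sps.ttest_ind(x2, x1, axis=1, equal_var=False)
    p = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
    q = bh_fdr(p)
    direction = np.where(q < alpha, np.where(log2fc > 0, "up", "down"), "ns")
    direction = np.where((q < alpha) & (log2fc == 0), "ns", direction)
    return pd.DataFrame(
        {
            "gene_id": m.data.index,
            "log2fc": log2fc,
            "p": p,
            "q": q,
            "direction": direction,
        }
    ).reset_index(drop=True)


def read_de_table(path: str | Path, alpha: float = 0.05) -> pd.DataFrame:
    """Load an externally computed DE table (gene_id, log2fc, p, q)."""
    de = pd.read_csv(path, sep="\t")
    missing = {"gene_id", "log2fc", "p", "q"} - set(de.columns)
    if missing:
        raise ValueError(f"DE table missing columns {sorted(missing)}")
    if "direction" not in de.columns:
        de["direction"] = np.where(
            de["q"] < alpha, np.where(de["log2fc"] > 0, "up", "down"), "ns"
        )
    return de[DE_COLUMNS]


@dataclass
class ClassificationResult:
    """Bound x DE classification over the expressed-gene universe."""

    per_gene: pd.DataFrame  # gene_id, expressed, bound, up, down, activated
    table: list[list[int]]  # [[bound_up, bound_down], [unbound_up, unbound_down]]
    activated: set[str]
    bound_down: set[str]
    fraction_up_bound: float
    fraction_up_unbound: float
    fraction_activated_of_up: float
    fisher: FisherResult | None
    degenerate: bool

    @property
    def counts(self) -> dict[str, int]:
        (bu, bd), (uu, ud) = self.table
        return {
            "bound_up": bu,
            "bound_down": bd,
            "unbound_up": uu,
            "unbound_down": ud,
            "n_de_expressed": bu + bd + uu + ud,
        }


def classify_and_tabulate(
    bound: set[str], de: pd.DataFrame, expressed: set[str]
) -> ClassificationResult:
    """Cross gene-level binding with DE direction, restricted to expressed genes.

    The 2x2 table counts differentially expressed, expressed genes only, split
    bound/unbound x up/down. A zero margin makes the odds ratio Haldane-
    corrected and sets the ``degenerate`` flag.
    """
    de = de[de["gene_id"].isin(expressed)]
    sig = de[de["direction"] != "ns"]
    is_bound = sig["gene_id"].isin(bound)
    is_up = sig["direction"] == "up"
    bu = int((is_bound & is_up).sum())
    bd = int((is_bound & ~is_up).sum())
    uu = int((~is_bound & is_up).sum())
    ud = int((~is_bound & ~is_up).sum())
    table = [[bu, bd], [uu, ud]]
    activated = set(sig.loc[is_bound & is_up, "gene_id"])
    bound_down = set(sig.loc[is_bound & ~is_up, "gene_id"])
    degenerate = min(bu + bd, uu + ud, bu + uu, bd + ud) == 0
    fisher = fisher_exact(table) if (bu + bd + uu + ud) > 0 else None

    per_gene = pd.DataFrame({"gene_id": sorted(expressed)})
    per_gene["expressed"] = True
    per_gene["bound"] = per_gene["gene_id"].isin(bound)
    dirmap = dict(zip(de["gene_id"], de["direction"]))
    per_gene["up"] = per_gene["gene_id"].map(lambda g: dirmap.get(g) == "up")
    per_gene["down"] = per_gene["gene_id"].map(lambda g: dirmap.get(g) == "down")
    per_gene["activated"] = per_gene["bound"] & per_gene["up"]

    n_up = bu + uu
    return ClassificationResult(
        per_gene=per_gene,
        table=table,
        activated=activated,
        bound_down=bound_down,
        fraction_up_bound=bu / (bu + bd) if (bu + bd) else math.nan,
        fraction_up_unbound=uu / (uu + ud) if (uu + ud) else math.nan,
        fraction_activated_of_up=bu / n_up if n_up else math.nan,
        fisher=fisher,
        degenerate=degenerate,
    )


def fold_change_concordance(de_a: pd.DataFrame, de_b: pd.DataFrame) -> float:
    """Pearson r of log2 fold changes over the genes tested in both tables."""
    merged = de_a.merge(de_b, on="gene_id", suffixes=("_a", "_b"))
    if len(merged) < 3:
        raise ValueError("need >= 3 shared genes")
    a = merged["log2fc_a"].to_numpy()
    b = merged["log2fc_b"].to_numpy()
    if np.all(a == a[0]) or np.all(b == b[0]):
        raise ValueError("fold changes are constant; correlation undefined")
    return float(sps.pearsonr(a, b).statistic)


def testis_bias(panel: ExpressionMatrix, testis: str = "testis") -> pd.Series:
    """Flag genes whose testis TPM exceeds half the summed TPM over all tissues.

    Per-tissue values are medians across that tissue's replicate columns. The
    inequality is strict, so an all-zero gene is not biased.
    """
    tissues = sorted(set(panel.groups.values()))
    if testis not in tissues:
        raise ValueError(f"no sample labelled {testis!r} in the panel")
    medians = pd.DataFrame(
        {t: panel.data[panel.samples_in_group(t)].median(axis=1) for t in tissues}
    )
    total = medians.sum(axis=1)
    biased = medians[testis] > 0.5 * total
    biased.name = "testis_biased"
    return biased
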