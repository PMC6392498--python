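# stra8pipe

Integration analysis for transcription-factor target calling at meiotic
initiation in the mouse testis. The package reconstructs, as a tested and
reusable pipeline, the chain of analyses by which promoter-binding
(ChIP-seq) and staged expression (RNA-seq) data define the gene program
amplified by STRA8 — the retinoic-acid-induced factor required for germ
cells to enter meiosis — together with the CNCCTCAG motif dose-response, the
testis-bias classifier, and the closed-form estimate of how rare
meiosis-initiating cells are in an unperturbed adult testis.

It is written for computational biologists who want to re-run or adapt this
kind of promoter-centric TF-target analysis: every stage is an ordinary
function over standard text formats (narrowPeak, FASTA, GTF/TSV, BED, TSV
matrices), and a synthetic-data generator emits cohorts with the same
statistical structure so the whole pipeline is testable without any
sequencing data.

## The analysis

**Bound genes.** Peaks from each FLAG ChIP replicate are blacklist-filtered
and assigned to transcripts whose TSS lies within 1 kb of the peak *summit*
(a summit near several TSSs is assigned to all of them). A gene is *bound*
if its promoter has a peak in ≥ 2 of 3 FLAG replicates and in no control
replicate:

    bound(g)  ⇔  |{r : g ∈ FLAG_r}| ≥ 2  ∧  g ∉ ⋃ control_r

**Activated genes.** Expression is gene-level TPM; a gene is *expressed* if
TPM ≥ 1 in any sample. Differential expression between knockout and
high-STRA8 preleptotene samples (Welch t on log2(TPM+1), Benjamini–Hochberg
q < 0.05) crosses with the bound set: *activated* = bound ∧ upregulated.
The bound × up/down contingency table is summarized with a Fisher exact
test, odds ratio and Woolf CI; set overlaps use one-tailed hypergeometric
tests computed in log space (genome-scale overlaps reach p < 10⁻³²⁰).

**Motif dose.** The degenerate core motif CNCCTCAG is scanned on both
strands (perfect-match IUPAC semantics, overlapping hits counted). Per-gene
promoter counts (2-kb TSS window, max over transcripts) and 100-bp
summit-window counts feed dose-response analyses: Spearman correlation of
summit motif count with peak score (permutation p), and per-stratum
medians of binding signal or expression fold change with Mann-Whitney
comparisons between adjacent strata.

**Cell census.** A closed-form chain over published stereology constants
estimates what fraction of adult-testis cells are STRA8-expressing
preleptotene spermatocytes, and the enrichment achieved by synchronizing
spermatogenesis:

    f = (spermatocytes / total cells) × (STRA8 duration / spermatocyte lifespan)

## Worked example

```bash
stra8pipe census --mode paper
```

```
total cells per testis:            133.3 x 10^6
spermatocytes, of all cells:       18.8%
preleptotene lifespan:             40 hr
preleptotene, of spermatocytes:    12.3%
preleptotene, of all cells:        2.3%
preleptotene cells per testis:     3.1 x 10^6
STRA8 expression duration:         25 hr
STRA8+, of preleptotene:           62.5%
STRA8+ preleptotene per testis:    1.88 x 10^6
STRA8+ preleptotene, of all cells: 1.4%
observed 2S fraction:              44%
synchronization enrichment:        31-fold
```

Reading the chain: spermatocytes are 18.8% of the 133.3 million cells per
testis; a preleptotene spermatocyte lives ~40 of the 326 spermatocyte hours
(12.3%), so preleptotene cells are 2.3% of the testis; STRA8 is expressed
for ~25 of those 40 hours (62.5%), leaving ~1.4% of all cells as
STRA8-positive preleptotene spermatocytes. A synchronized testis in which
44% of cells are STRA8-positive preleptotene is therefore 31-fold enriched
for meiosis-initiating cells. `--mode unrounded` carries full precision
(1.44%, 30.6-fold) instead of reproducing the printed rounding.

An end-to-end synthetic run:

```bash
stra8pipe run --seed 17 --outdir out/
```

simulates a 1000-gene cohort (three FLAG + three control ChIP replicates,
KO/low/high expression), then calls bound genes, tests DE, classifies
activated genes, counts promoter motifs, and writes gene lists plus
`out/run_report.json` with recovery metrics against the planted truth
(typically: bound-set sensitivity ≈ 0.97 with zero false positives, FLAG
promoter fraction ≈ 83% vs 0% in controls, summit motif–score Spearman
ρ ≈ 0.4 with permutation p ≈ 1e-4). Two runs with the same seed are
byte-identical.

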