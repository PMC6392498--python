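# Methods

## Coordinate frame and promoter definitions

All internal coordinates are 0-based half-open; GTF input (1-based closed)
is converted on load, BED is native. The TSS of a + strand transcript is its
start, of a − strand transcript its last base. "Within 1 kb of the TSS" is
implemented as the half-open window [tss − 1000, tss + 1000): a summit at
exactly +1000 bp downstream is *not* assigned. Interval overlap means ≥ 1
shared base. Multi-transcript genes use any/max semantics: a gene has a CGI
promoter if *any* transcript's 2-kb window overlaps a CpG island, and its
promoter motif count is the *max* over transcripts. Manually curated TSS
overrides are accepted as a 1-based table and converted on load.

## Binding calls

Peak assignment uses the summit only; a peak whose summit is within 1 kb of
several TSSs is assigned to every one of them, and a gene counts once per
replicate however many of its transcripts were hit. Control filtering is
any-replicate removal (a gene seen in any control replicate can never be
bound) and is applied together with the ≥ min_replicates consensus
(default 2 of 3). Peaks on contigs absent from the annotation are retained
and count in promoter-fraction denominators. narrowPeak summits are read
from the 10th column; an absent summit (−1) falls back to the interval
midpoint with a logged warning. Promoter read density is
count/library × 10⁶ minus the same quantity for input chromatin; negative
values are reported, not clipped.

## Differential expression (plumbing)

The DE stage is deliberately simple: Welch t per gene on log2(TPM + 1),
log2FC as the difference of group means on that scale, BH adjustment across
all tested genes, q < 0.05 for direction calls. It is a *behavioural*
stand-in — the analysis of interest is the integration of binding with
expression, not the DE engine — and externally computed DE tables
(gene_id, log2fc, p, q) can be loaded and dropped in anywhere a DE table is
consumed. Genes constant in both groups get p = 1. The expressed filter is
TPM ≥ 1 in at least one sample; the threshold and the strictness of the
comparison are configurable.

The bound × direction contingency table is restricted to expressed,
differentially expressed genes (the alternative — all DE genes regardless
of expression — changes little because DE calls already imply expression).
The odds ratio is the sample ratio with a Woolf log-interval CI; a zero
cell triggers the Haldane–Anscombe 0.5 correction for the ratio and CI
(flagged), while the Fisher p stays exact. Note the Woolf interval is not
the conditional-likelihood interval R reports, so intervals can differ in
the second decimal on large tables.

## Statistics

Hypergeometric and binomial tail probabilities are accumulated in log space
from log-pmfs (logsumexp), so overlaps at genome scale report finite
log10 p (values like −322) even where the plain p underflows to zero.
Two-tailed Fisher sums tables with probability ≤ the observed table's.
Mann-Whitney uses average ranks for ties; for |x| + |y| ≤ 16 the p-value is
an exact enumeration over group assignments (which handles ties without
approximation), larger samples use the tie- and continuity-corrected normal
approximation. The `alternative` argument refers to the first sample.
Permutation p-values are (1 + #extreme)/(1 + N) with a seeded generator.
BH q-values use the standard step-up with monotonicity enforcement.

## Motif scanning

Perfect-match semantics for a degenerate pattern: literal positions must
match exactly; an ambiguity code in the pattern matches its IUPAC base set;
an N in the subject sequence matches nothing. Both strands are scanned by
default (the reverse-complement pattern is matched on the given sequence
and reported as strand "−" at the forward coordinate); overlapping matches
are all counted, and the naive character-by-character scanner in the test
suite defines the reference behaviour. The summit window is
[summit − 50, summit + 50). Position-weight-matrix scoring and de novo
discovery are out of scope: the motif is an input, default CNCCTCAG.

## Synthetic cohorts

The generator emits the output contracts of the upstream tools (narrowPeak
records, TPM matrices), not reads; peak calling, alignment and transcript
quantification are outside the pipeline's scope. Defaults are the study
conditions: 1000 genes, a quarter of them bound, three FLAG and three
control ChIP replicates at 0.9 per-replicate sensitivity, KO/low/high
expression samples.

Design choices, made once for internal consistency:

* **Binding is motif-borne.** A gene is bound iff it carries ≥ 1 planted
  CNCCTCAG instance; the default motif-count distribution puts
  P(0) = 1 − frac_bound and concentrates positive counts at 1–2 with a thin
  tail to 8, so binding, peak score (base 50 + 20/motif + N(0,10)) and
  expression amplification share a single motif dose, which is the model
  the analysis is designed to detect.
* **Motifs cluster near the TSS** (±250 bp), so 100-bp summit windows
  (summit jitter sd 30 bp) intersect part of the planted dose and the
  summit-count/score correlation is positive but well below 1 — the
  qualitative regime of the real data (ρ ≈ 0.2–0.4).
* **Spurious peaks are rejection-sampled out of promoter windows**, in both
  FLAG and control replicates, so planted truth stays clean: the binding
  false-positive rate is structurally ~0 and the control promoter fraction
  is 0 rather than the small positive value uniform placement would give.
  This is a documented simplification. The spurious rate (45/replicate)
  sets the FLAG promoter fraction near the published ~83%.
* **Expression closure is mass-balanced.** TPM columns sum to 10⁶, so
  amplifying a quarter of genes would otherwise deflate every other gene
  and corrupt the planted null. Amplification is therefore modest
  (0.4 log2 per motif; median activated gene ~1.5-fold) and the
  downregulated set (250 motif-free genes at −2.5 log2) removes roughly the
  transcript mass the amplified genes add — mirroring the near-equal up and
  down counts observed at this transition. Residual closure shift is
  < 0.05 log2. Sample noise is multiplicative lognormal (0.06 log2);
  KO:3 / low:2 / high:3 samples (one more high replicate than the study's
  two, keeping the plumbing t-test powered the way the study's count-based
  model was); low samples receive half of every log effect.
* **The tissue panel** plants biased genes with testis value 10× the sum of
  the other eight tissues, three replicate columns per tissue. Under TPM
  closure a planted biased fraction above ~ (f−1)/(8f−1) ≈ 12% of genes
  cannot survive renormalization; tests plant ≤ 10%.

What passing tests show — and do not show. The generator reproduces the
*structure* the integration logic assumes (replicated promoter-localized
peaks, dose-dependent scores, amplification-not-switching expression). It
does not model read-level artifacts, GC bias, peak-caller behaviour,
overdispersed counts, batch effects, or realistic biological replicate
variance; recovery metrics here validate the set logic and statistics, not
DE power on real data.

## Cell census

All census counts and stage constants are configuration with the published
values as defaults, so the calculator generalizes to other markers or
stages. Preleptotene lifespan = Σ stage duration × presence fraction
(later half of VI, all of VII, first half of VIII → 40.05 h); STRA8
duration additionally weights by the STRA8-positive tubule fraction
(0/0.71/1.0 → 25.03 h). Two rounding modes: `unrounded` (default) carries
full precision, under which the chain collapses algebraically to
spermatocyte_fraction × duration / lifespan_total (asserted to 1e−12);
`paper` rounds each printed intermediate — including rounding the
preleptotene count to 3.0 × 10⁶ before the 62.5% multiplication — solely to
reproduce the published numbers digit for digit. The report exposes both
the all-preleptotene fraction (2.3%) and the STRA8-positive preleptotene
fraction (~1.4%) explicitly, because the two are easy to conflate.

## Problem sizes and determinism

Default synthetic runs use 1000 genes on a 3.2-Mb chromosome, 10⁴
permutations for correlation p-values; the consensus closed-form check uses
2000 genes (~500 bound). Every generator is a pure function of
(config, seed) via `numpy.random.default_rng` with spawned child streams
per stage, and pipeline outputs (gene lists, reports) are written in sorted
order so identical (config, seed) runs are byte-identical.

## Known limitations

* The plumbing DE test is not a count model; on real overdispersed data it
  will be miscalibrated and real DESeq2-style output should be supplied.
* Welch-based direction calls inherit TPM compositional effects; strongly
  unbalanced global shifts will masquerade as widespread DE (the generator
  avoids this by construction, real data may not).
* The exact Mann-Whitney path enumerates up to 16 pooled observations;
  beyond that the normal approximation is used even in the far tail.
* Degenerate-motif counting treats strands independently; palindromic
  patterns can double-count a physically single site. The naive oracle
  defines this as the reference behaviour.
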