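# Methods

## Model and scope

`tescope` treats a paired-omics experiment as two genes × samples
matrices measured on the same biological material: a *translatome* layer
(ribosome-associated RNA quantified like RNA-seq — full-length capture,
no P-site or codon-level signal) and a *transcriptome* layer (total RNA).
Samples carry a condition label (e.g. young/aged, control/knockdown) with
replicates; the canonical design is two conditions × three biological
replicates.

The analysis rests on one modeling assumption: in the cells of interest
transcription is largely inactive, so regulation acts on translation.
Translational efficiency

TE_g = mean(TPM_g, translatome) / mean(TPM_g, transcriptome)

is computed per condition on condition-mean TPMs rather than as a mean of
per-replicate ratios: with three replicates and occasional zeros in the
numerator, the ratio of means is markedly more stable than the mean of
ratios, and zeros remain representable (TE = 0 is legal; the numerator
gets no pseudocount). The denominator is bounded away from zero by the
eligibility rule: a gene enters the TE analysis only if its transcriptome
TPM exceeds `expr_tpm_min` (default 1, strict inequality) in at least one
replicate of that condition. The any-replicate convention mirrors the
expressed-gene filter used for detection; a condition-mean variant is
available (`rule="mean"`), and eligibility is assessed per condition so
that condition-specific genes are reported rather than silently dropped.

## Thresholds

All cutoffs live in a single `Thresholds` object threaded through every
stage:

| parameter | default | unit | role |
|---|---|---|---|
| `expr_tpm_min` | 1 | TPM | expressed/eligible gene filter (strict) |
| `fc_up`, `fc_down` | 1.5, 0.67 | ratio | up/down bounds for DE and TE change |
| `alpha` | 0.05 | probability | raw p cutoff paired with the FC bound |
| `te_high`, `te_low` | 2, 0.5 | ratio | high-/low-TE bins |
| `papcpe_window` | 100 | nt | max CPE–PAS gap for a papCPE |
| `concordant_log2fc` | −0.58 | log2 ratio | final cascade stage (≈ FC 0.67) |
| `proteome_fc_up/down` | 1.2, 0.83 | ratio | single-replicate proteome calls |

## Differential expression and regulation classes

Fold change is computed on condition means of TPM with a pseudocount of
0.01 TPM in numerator and denominator (avoids division by zero; small
enough not to distort genes above the expression filter). Significance is
a two-sided Welch (unequal-variance) t-test on log2(TPM+1); Welch was
chosen over the pooled-variance test for robustness at n = 3, where
variance equality is untestable. No multiple-testing correction is
applied by default — the caller implements the classic volcano rule (raw
p < α together with the FC bound), and a Benjamini–Hochberg option is
available but off. Proteome tables, when supplied, are consumed as
precomputed fold changes with the 1.2/0.83 bounds and no test: one
replicate supports no variance estimate.

"Transcriptionally constant" is operationalized as direction
`unchanged`, i.e. *either* the FC bound or the significance condition
failing; the four regulation classes are then I = up/up, II =
down/unchanged, III = up/unchanged, IV = down/down, everything else
`none`. The partition is total and disjoint by construction.

TE up/down calls use the fold-change bound alone, with no significance
test: a TE value is already a ratio of averaged quantities and carries no
natural per-gene variance estimate at this design size.

## log2(TPM+1), correlation, PCA

log2(TPM+1) is the working transform for replicate correlation, PCA and
the t-tests. The pseudocount of 1 TPM bounds the transform at zero and
damps dropout noise in few-cell samples; it is configurable in spirit
(the transform is applied in one place per module). PCA is an SVD of the
centered (not variance-scaled) samples × genes matrix; component signs
are fixed by making each component's largest-magnitude gene loading
positive, so outputs are deterministic across BLAS implementations.

## Motif scanning and papCPE

The scanner matches IUPAC patterns on the sense strand of the 3'UTR in
DNA alphabet (T, not U — FASTA convention; 3'UTR motifs are
strand-defined). Default patterns are CPE = {TTTTAT, TTTTAAT} and PAS =
{AATAAA, ATTAAA}; the consensus sets in the literature vary, so the
defaults are deliberately minimal and fully configurable. All
occurrences, including overlapping ones, are reported; an N in the
sequence matches nothing. The implementation compiles each pattern to a
lookahead regex; tests verify exact agreement with a brute-force
position-by-position comparison.

"Within 100 bp" is ambiguous for extended matches, so the CPE–PAS gap is
defined as the number of nucleotides strictly between the two matches
(`max(0, larger start − smaller end)`; touching or overlapping motifs
have gap 0). A papCPE call is `min gap over all CPE–PAS pairs ≤ window`,
which makes the call monotone in the window size.

## Gene-set statistics

*Preranked GSEA.* Genes are ranked by score descending with ties broken
by gene id (determinism). Member genes increment the running sum by
|score|^w normalized over member scores (w = 1 by default, the classic
weighted statistic; w = 0 gives the unweighted Kolmogorov–Smirnov-like
form); non-members decrement by 1/(N − N_hit). ES is the extremum of the
running sum. The null is built from random same-size gene sets — a
gene-permutation null, the standard choice in preranked mode where only
the ranked list exists. p uses the add-one estimator over same-sign null
scores; NES divides ES by the mean |null ES| of the same sign; the
leading edge is the members at or before the extremum (after it for
negative ES). Default 1,000 permutations; the seed is a required argument
in the CLI.

*Over-representation.* Two-tailed Fisher exact test on the 2×2 table
restricted to the declared universe, BH-corrected across sets (the
correction method for ORA is a documented choice; the stratified group
tests use Bonferroni where a post hoc family is explicit). Odds ratios
use the Haldane +0.5 correction when any cell is zero. RBP enrichment
reduces each RBP's motif-occurrence column to a gene set and reuses the
same machinery.

*Stratified comparisons.* Two groups: Welch t-test. Four groups (2×2
flags, e.g. m6A × papCPE): one-way ANOVA plus all six pairwise Welch
comparisons with Bonferroni factor 6. With two groups, classic ANOVA
satisfies F = t² against the pooled t-test; tests pin this equivalence.

## The candidate cascade

Stage 1 intersects genes with differential TE (*any* direction — the
fraction of stage-1 genes that are concordantly down is itself a
reported quantity, so stage 1 must admit both directions) in both
contrasts with the m6A set and the RIP consensus; stage 2 keeps TE-down
in both; stage 3 keeps translational log2 FC strictly below
`concordant_log2fc` in both. The RIP consensus is the strict intersection
of replicate target lists by default (`min_support` configurable).
Stages are nested by construction and the final set is monotone in the
log2 FC cut. Cross-species overlaps optionally match by uppercased
symbol; within-set symbols that collide after uppercasing are dropped
with a logged count rather than merged.

## Synthetic cohorts

The generator emulates the structure the analysis assumes, not any real
dataset's gene-level values:

* baseline abundance 2^N(5, 2) (TPM-scale), baseline TE 2^N(0, 1);
* transcription constant: the transcriptome mean is identical across
  conditions; the translatome mean is abundance × TE;
* the aging/perturbation effect multiplies TE by 2^shift (default
  shift = −1) for an *affected* subset: m6A-flagged genes (55% of genes)
  with baseline TE > 2, each affected with probability 0.8;
* counts are negative binomial with variance μ + φμ² (φ = 0.1, constant
  across genes; φ = 0 falls back to Poisson), with length-biased means —
  expected reads ∝ abundance × length — scaled to a 10⁶ library, so TPM
  normalization round-trips the abundances;
* RIP replicates observe m6A genes with sensitivity 0.8 and non-m6A
  genes at a 5% false-positive rate, independently per replicate; the
  truth table marks m6A genes as the true targets;
* 3'UTRs (200–1500 nt) are uniform-background sequences with accidental
  CPE/PAS occurrences scrubbed by redrawing, then planted motifs: a PAS
  near the 3' end, a CPE within the papCPE window when the papCPE flag is
  set and farther than the window otherwise (the PAS is omitted in UTRs
  too short to honor a cpe-without-papcpe constraint). The final sequence
  is validated by re-annotation and redrawn on mismatch, so the
  flag → sequence → flag round trip is exact; the cost is that
  backgrounds are not i.i.d. uniform.

A second contrast over the same biology (the reader-knockdown analog)
reuses a cohort's truth table (`shared_truth=`): baselines and flags are
kept, the affected subset and all noise are redrawn, so the two contrasts
suppress overlapping subsets of the m6A high-TE genes — the situation the
cascade is designed for.

Everything derives from a single `numpy` Generator seed; two runs with
the same parameters are bit-identical.

### What the generator does and does not show

Because transcription is exactly constant and noise is exactly NB,
passing recovery tests demonstrates the pipeline's correctness and
calibration under its own assumptions — not robustness to batch effects,
dropout inflation, length-dependent capture bias beyond the linear term,
or ortholog mapping noise, none of which are simulated. Two measured
properties of the simulated conditions are worth knowing when reading
test output:

* **Compositional offset.** TPM is a relative measure: when affected
  genes lose translatome mass in the perturbed condition, every other
  gene's translatome TPM rises by a common factor, so measured log2 TE
  changes equal the planted shift plus log2(Σ expr·TE_baseline /
  Σ expr·TE_perturbed) (~ +0.13 at defaults). The noise-free-limit test
  asserts against this computable expectation; the recovered median for
  affected genes at defaults is ≈ −0.87 for a planted −1.
* **Null call rate.** With φ = 0.1 and three replicates the null standard
  deviation of log2 TE change is ≈ 0.54, so roughly 29% of genes exceed
  the 1.5/0.67 fold-change bounds by noise alone (symmetrically up and
  down). Single-contrast TE direction calls at this design size are
  therefore noisy screens; the cascade's replication requirement (both
  contrasts, plus set intersections) is what drives its false-discovery
  rate to < 0.1% of genes in null runs.

## Numerical and I/O conventions

Tables are tab-separated UTF-8 with a decimal point, written with 6
significant digits (round-trips bit-exactly at that precision). JSON
reports fix floats at 10 significant digits, making pipeline re-runs
byte-identical given identical inputs and seed. Gene ids are opaque,
case-sensitive strings except in the explicit cross-species matching
mode. Motif hits export as BED6 (0-based half-open, score 0, strand +).
TPM columns must sum to 10⁶ within relative 10⁻⁶; all-zero samples are
propagated as all-zero with a warning rather than rejected. Degenerate
statistics are explicit errors (zero-variance correlation inputs, empty
ANOVA cells, a gene set covering the whole ranking) rather than NaNs.

## Problem sizes

Default test and acceptance runs use 2,000-gene cohorts with three
replicates per condition (the canonical design) and 300-gene cohorts for
the noise-free-limit check; exhaustive GSEA enumeration uses 5-gene
rankings where the null is fully enumerable, and the motif-scanner
equivalence check uses one hundred 1 kb sequences. These sizes make every
oracle exactly computable while exercising the same code paths as larger
inputs.

## Known limitations

* TE inherits TPM's compositional nature; strong global translational
  shifts move all TEs and are not distinguishable from uniform efficiency
  changes without external normalization (not implemented).
* No NB-GLM differential framework: with three replicates the paper-style
  volcano rule is the intended behavior, and raw p-values are reported as
  such.
* The CPE/PAS consensus sets are minimal defaults, not a curated motif
  database; users with access to curated CPE annotations can supply them
  directly and skip the scanner.
* Cross-species matching by uppercased symbol is a heuristic, not
  orthology; one-to-many collisions are dropped.
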