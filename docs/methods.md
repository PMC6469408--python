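# Methods

This note documents the statistical models, conventions and design choices
behind each module, what the synthetic-data generators do and do not
emulate, and the numerical decisions a maintainer would want to know.

## Relative expression (ΔCq)

Expression of a target gene is quantified as ΔCq = Cq(reference) −
Cq(target), in cycles, so one unit is a twofold change and higher ΔCq means
higher relative expression.  Two reference genes (RpL32, RpS18) are assayed
per target; empirically they act additively — ΔCq is shifted by a constant
when switching reference — which the two-way gene × reference ANOVA
(`two_way_anova`) makes checkable: a pure reference main effect with a null
interaction.

**Pooling the references.** The per-gene one-way ANOVA across sample
classes (`anova_per_gene`) pools the two references by centering ΔCq within
each reference gene before fitting, and charges one residual degree of
freedom per centered reference mean beyond the first.  Under a balanced
layout this is algebraically identical to the additive
`class + reference` two-way fit (a test asserts this against the statsmodels
fit), so the F test for the class effect keeps its nominal size — the
simulated type-I error at α = 0.05 is 0.053 over 1000 null datasets.
Analysing each reference separately is available via
`pool_references=False` after subsetting.

**Scheffé post-hoc.** For classes *i*, *j* with means m_i, m_j and the
pooled residual MSE on df_e degrees of freedom,

    S = (m_i − m_j)² / (MSE · (1/n_i + 1/n_j) · (k − 1)),
    p = P(F(k−1, df_e) ≥ S),

valid simultaneously for all contrasts, hence never less conservative than
the unprotected pairwise F test (property-tested).  With MSE = 0 the p-value
degenerates to 0 for unequal and 1 for equal means, with a warning.

**FDR family.** All Scheffé pairwise p-values across all genes of one
experiment are corrected jointly by Benjamini–Hochberg (delegated to
statsmodels `multipletests`); a per-gene family is available via
`fdr_scope="per-gene"`.  Joint correction is the more conservative reading
of a global "FDR for all tests" policy.  Significance threshold: q < 0.05
(configurable).

**Compact letter display.** Insert-and-absorb: start with one letter set
holding all classes; for each significant pair split every set containing
both, then absorb subsets.  The construction guarantees classes share a
letter iff they are not significantly different; this is verified
exhaustively against the iff-condition for every symmetric matrix on up to
5 classes.  Letters are assigned in first-use order of the class ordering.

**Counts.** Fecundity summaries use the n−1 sample SD; a single-count class
reports SE 0 with a warning.  Primer efficiency comes from the standard
curve slope as 10^(−1/slope) − 1; it is reported, never enforced as a
filter.

## Candidate filtering

Fertile classes are exactly {BC1p, BC1b, BC4, F8y, F8y+, F8se}; F8se+ males
are sterile (the introgressed non-sepia X carries the *Overdrive* sterility
allele) and never count toward fertile misregulation.  A (gene, class) is
*misregulated* iff its q-value differs from **both** parental species.  The
exclusion rule: a gene is excluded iff misregulated in ≥ 1 fertile class
AND at least one such class is not significantly different from sterile F1
males.  A gene whose misregulated fertile classes *all* differ from sterile
F1 is retained by the letter of the rule but annotated `review` — the rule
only licenses exclusion through the F1-matching condition.  GA24206 is the
stress case: its introgression class (F8y+) differs from sterile F1, but
its backcross classes do not, so the same rule excludes it through the BC
branch without special-casing.  The sterile-F1 comparisons use the same
Scheffé + FDR machinery and threshold as the parental comparisons.

Because the published table prints the parental-comparison flags but shows
the sterile-F1 comparisons only graphically, the embedded flags encode the
minimal assignment consistent with the reported outcome (every misregulated
fertile class F1-like except GA24206/F8y+); `datasets.py` marks these as
reconstructed.

## Tissue enrichment

The enrichment call uses the magnitude ratio |ΔCq(T)|/|ΔCq(AG)| rounded to
two decimals; the tissue label follows the sign of ΔCq(T) − ΔCq(AG); the
fold change is the reciprocal of the **rounded** ratio when the ratio is
below 1 and the ratio itself otherwise, so fold ≥ 1 always.  The rounded
reciprocal is deliberate: it is the only convention that reproduces the
published rows (1/0.04 = 25.00 where the unrounded reciprocal gives 27.9).
Both rounded and unrounded values are emitted, plus a clearly-labelled
linear fold 2^(ΔCq(T) − ΔCq(AG)) — the magnitude ratio is a log-scale
artifact, not a linear expression ratio.  One published row (GA19543,
printed 0.65/1.54) recomputes to 0.66/1.52 from its printed means,
evidently because it was derived from unrounded means; it is flagged in the
tests, not corrected.  Extremes filters: a gene is dropped when all
available tissue ΔCq < −10 (too low) or all > −5 (too high, housekeeping
behaviour), thresholds configurable.  Ties (ΔCq(T) = ΔCq(AG)) return an
explicit unclassified call.

## Substitution mapping

Coordinates are TSS-relative with **no position 0** (−1 abuts +1), so an
interval −1123..+518 spans exactly 1641 positions; internal computations
use the 1-based ungapped index of the reference-species (species a)
sequence, with `tss_to_index`/`index_to_tss` as the bijection.

Event calling walks the alignment columns: one SNV per mismatched non-gap
column; maximal runs of gap columns in one species collapse to a single
indel event at the leftmost affected species-a base (insertions anchor at
the preceding species-a base).  Counting an indel once regardless of length
matters: the four-base GA30092 deletion at −728..−725 is one event, which
the 7/1710 = 0.004 proportion requires.  Ambiguity codes are skipped with a
warning.

The conspecific-strain polymorphism screen is abstracted to desk scale: an
event is a shared polymorphism (not fixed) iff the species-b allele is
observed among species-a strains at that site.  Evidence is either a
per-site allele table or raw reads; a read contributes evidence only if its
global identity against its best-matching window of the fragment exceeds
90% (exhaustive window scan, no heuristic seeding).

Domain labels: annotated features outrank distance windows (CDS, then
5'UTR/transcript, then neighbouring-gene annotations), with a promoter
overlap noted as e.g. `CDS/P`; otherwise P = −200..+200, PP = −500..−201
(−500 inclusive), PD strictly < −500, else `other`.

**Dataset note.** The published GA30092 record prints the sequenced
interval −1,139..+528 (1667 positions) alongside an alignment length of
1,710.  The printed length is used for the substitution proportion (0.004
requires it); the interval is used for coordinate mapping.

## Hotspot clustering test

For the i-th of n events (sorted, 1-based) at index x_i on N positions,
G_i = i/n − x_i/N measures the gap between the events' empirical CDF and
the uniform CDF; the statistic is T = max over ranks i < j of (G_j − G_i),
with the maximizing pair delimiting the hotspot (reported inclusively:
j − i + 1 events).  T is compared against Monte Carlo draws of n indices
sampled without replacement from 1..N (default 100,000 replicates).

Numerical and design choices:

* **One-tailed positive convention.** T is the signed maximum increment,
  not max |ΔG| — the a-priori hypothesis is an *excess* of substitutions in
  a sub-interval.  A two-tailed |ΔG| mode sits behind `two_tailed=True`.
  T may be ≤ 0 for super-dispersed configurations and is reported as-is.
* **p-value.** Add-one permutation convention
  p = (1 + #{T* ≥ T}) / (n_sim + 1), so p > 0 always; the raw exceedance
  count is also reported.  Ties in T are broken toward the smallest (i, j).
* **Exact oracle.** `exact_null_enumeration` enumerates all n-subsets
  (integer arithmetic on the common denominator n·N, so equal values
  aggregate exactly) up to C(N, n) ≤ 10⁶; Monte Carlo tails are tested
  against it within binomial error.
* **Calibration.** Under the null the p-value is uniform: 20,000 null draws
  scored against a shared 100,000-replicate null give KS distance ≈ 0.011
  from U(0,1).  These sizes were chosen so the Monte Carlo noise of the
  measurement itself (≈ 0.9/√n_outer) sits well below the 0.02 bound being
  checked.
* **Regions.** Tests run both per domain window (P, PP, PD, CDS) and on the
  whole fragment, and both are always reported — for GA22690 the
  whole-fragment test is significant (p ≈ 0.018) with its maximizer
  extending to −289, while the promoter-distal restriction pinpoints the
  −751..−525 interval (8 events) as the maximal-ΔG window; which region a
  published significance call refers to is ambiguous, so neither is
  preferred silently.  Across regions/genes, BH-FDR q-values are attached
  (configurable off).  Single-event regions are skipped (no ΔG exists).
* **Indels** participate as point events at their leftmost index; whether
  the −1052 single-base deletion belongs in GA22690's n is not documented
  upstream — it is included by default (n = 15).
* All randomness flows through one seeded NumPy generator; seeds are logged
  in every result.  Sampling uses the n-smallest-keys trick on uniform
  matrices, chunked at 10,000 replicates (≈ 130 MB peak for N = 1641).

## Synthetic data

`generate_cq_table` draws independent Gaussian noise with sd
`replicate_sd/√2` on each Cq so ΔCq has exactly the scenario sd; the second
reference gene is shifted by `reference_offset` (default 0.8 cycles),
reproducing the constant-sign reference effect.  Defaults: sd 0.3 cycles,
5 replicates per class × reference — the assay guarantees at least three
biological replicates but does not publish within-group variances, so these
are documented assumptions, not reported values.

Sterile-F1 class means are not published (figure-only); the study-structured
scenario (`study_expression_scenario`) sets them to the mean of the gene's
first misregulated fertile class (making that class F1-like, as reported)
and, for never-misregulated genes, to 6 cycles below the gene's lowest
class mean.  The latter choice makes the end-to-end recovery of the
10-gene retained set robust: at sd 0.3 the Scheffé test is powerful enough
to flag some unstarred cells (e.g. GA19543's BC classes sit ≈ 2.2 cycles
from both parents), and a distant F1 mean ensures such incidental flags
yield "retained (review)" rather than spurious exclusion.  The generator
emulates group means, additive reference structure and Gaussian replicate
noise — not amplification chemistry, primer efficiency variation, plate
effects, or correlated replicates; passing tests therefore validate the
statistical pipeline, not qPCR pre-processing.

`generate_sequence_pair` plants Bernoulli background substitutions, a
uniform cluster of extra events, optional single-column deletions, and
shared-polymorphism structure in 100-bp strain reads (the ≥90% identity
contract is exercised by corrupting reads in tests).  Multi-column indels
are exercised through fixture alignments rather than the generator.
`generate_fecundity` draws negative-binomial counts (variance
m + dispersion·m², Poisson at dispersion 0, six vials per class by
default) — offspring counts are typically overdispersed and no dispersion
is published.

## Problem sizes in the test suite

The suite runs in about half a minute on one core: Monte Carlo nulls at
2,000–100,000 replicates depending on the assertion, 200-seed power checks
(planted 8-event cluster: 94% rejection; planted 5-cycle se/se+ shift:
~100% recovery), 1000-simulation ANOVA calibration, and 12-seed end-to-end
screen recovery (12/12 at sd 0.3, n = 5).

## Known limitations

* The raw per-replicate Cq, fecundity and trace data of the original assays
  are not redistributed; printed summary tables and flags are embedded
  instead, with the sterile-F1 flags reconstructed from figure-level
  statements (see above).
* The two-way ANOVA on real data (F with >1200 denominator df) cannot be
  reproduced from summary tables; the package verifies its two-way ANOVA
  against a sum-of-squares oracle and checks the additive-reference
  structure by simulation instead.
* The polymorphism screen is a desk-scale abstraction of a BLASTn search
  against 43 strain read sets; it implements the same ≥90% identity
  matching contract but no alignment seeding or read-mapping heuristics.
* The unbalanced-layout behaviour of the pooled per-gene ANOVA is
  approximate (centering equals the additive fit only under balance).
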