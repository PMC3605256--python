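# Methods

This note records the statistical models, the conventions chosen where
the underlying methods literature leaves room, and what the synthetic
generators do and do not emulate.

## Coordinates and interval conventions

All intervals are 0-based half-open internally (BED convention). Readers
accept 1-based inclusive tables via `dialect="one_based"`. Reciprocal
overlap of two intervals is `min(ovl/len(a), ovl/len(b))`; it is 0 across
chromosomes, symmetric, and equals 1 only for identical intervals.
Abutting half-open intervals have overlap 0.

## Consensus calling

A CNV event in one sample is retained when calls from at least
`min_algorithms` (default 2) distinct algorithms agree at the
reciprocal-overlap threshold (default 0.5). Grouping is deterministic:
same-class calls are sorted by position; the first unassigned call seeds
a group and the largest set of calls pairwise compatible with each other
(all pairs ≥ threshold) containing the seed is taken, ties broken by
position order. The consensus span is the **intersection** of the
supporting calls — the conservative choice, since every supporting
algorithm asserts at least that much — with the union retained as
metadata. Gains and losses never merge.

## CNVR clustering and frequency

Cross-sample clustering is single-linkage and seeded: calls sorted by
position, the first unassigned call opens a region, and any same-class
call with reciprocal overlap ≥ 0.5 against the current region envelope is
absorbed until the region stops growing. Comparing against the growing
envelope (rather than the fixed seed) is the default because it is the
common CNVR-construction practice; `envelope=False` switches to
seed-anchored comparison. The choice matters only for chains of partially
overlapping calls.

Region frequency is carriers over **all** samples of the sheet supplied —
cases and controls combined — and should be computed per platform batch,
since probe content determines what is callable. The rare stratum uses a
strict inequality (frequency < 5%), and size strata use the region
envelope length.

## NAHR classification

An event is a candidate recurrent NAHR rearrangement when it is ≥ 100 kb
and each breakpoint lies within one member of a homologous
segmental-duplication pair, extended by a slack of 20 kb per side. The
slack absorbs array breakpoint uncertainty, which is set by probe
spacing; 20 kb is a generous bound for the platforms this pipeline
targets and is configurable.

## Exact 2×2 association

Fisher exact p-values condition on both table margins. The two-sided rule
is minimum-likelihood (sum the probabilities of all tables no more likely
than the observed one) — the dominant software convention. The one-sided
p sums the case-enrichment tail. Odds ratios come in two flavours because
published reports mix them: the sample cross-product `ad/bc` and the
conditional MLE of the noncentral hypergeometric likelihood. The exact
conditional (Cornfield) interval — obtained by inverting the exact test —
is the default companion of the conditional MLE and is what exact-test
software prints; Woolf intervals `exp(log OR ± 1.96·√(1/a+1/b+1/c+1/d))`
are provided for the sample OR. The conditional MLE always lies closer to
the null than the sample OR and converges to it as cells grow; both facts
are property-tested. Zero-cell tables default to reporting OR = ∞ (or 0)
together with the finite exact conditional bound, which remains
informative; Haldane-Anscombe (+0.5 per cell) and strict-error policies
are available.

## Burden regression and cross-cohort combination

Per-sample burden is regressed on case status by maximum-likelihood
logistic regression (IRLS via statsmodels), with the sample sheet's
eigenvector covariates included by default; collinear covariates are
dropped with a warning. Perfect or quasi-separation is detected (failed
convergence, |β| > 15, or SE > 50) and **flagged** on the result rather
than silently returned; a Firth-penalized fit (Jeffreys-prior score
correction) is available behind `firth_on_separation=True`. The default
is flag-and-report because a penalized estimate silently substituted for
a diverged one changes the estimand.

Cohorts typed on different platforms are combined by inverse-variance
meta-analysis of the per-cohort log-odds (fixed effects, or
DerSimonian–Laird random effects with the usual τ² moment estimator), or
by a single pooled fit with cohort indicator covariates. Meta-analysis of
per-cohort fits stands in for a mixed-effects logistic model with cohort
as a random factor: the two agree asymptotically, and the meta form is
fully deterministic and unit-testable. With identical cohorts the fixed
combination halves the variance; under heterogeneity the random-effects
interval is wider — both covered by tests.

## Permutation locus testing

The per-locus statistic is the case-carrier count. Nominal p-values use
the add-one rule `(1 + #{perm ≥ obs}) / (n_perm + 1)`, so no p is ever
zero. Genomewide correction is max-T: each locus's observed statistic is
referred to the permutation distribution of the maximum statistic over
all loci, which controls family-wise error under the complete null and
is the standard array-era correction. Labels are permuted **within
cohort** by default: cohort and platform are confounded in multi-center
designs, and unrestricted shuffling would let platform-specific
callability masquerade as association. Gene-set burden permutes within
platform for the same reason, and platforms with zero probe coverage of
the set are excluded.

## Inbreeding from HBD segments

HBD segments with ≥ 50% reciprocal overlap with a same-sample deletion
call are removed before estimation: a hemizygous deletion exposes the
single remaining haplotype as a run of homozygosity. F is the
segment-based estimator — total autosomal HBD length over total autosomal
manifest length. Sex chromosomes are excluded (the male X is hemizygous);
no minimum segment length is imposed by default (`min_segment`
configurable) and the manifest length, not the assayed SNP span, is the
denominator — both choices are recorded here because callers and studies
differ. The classification ladder F > 0.5% / 1.6% / 6.25% uses strict
inequalities; counts along the ladder are necessarily non-increasing.
UPD flagging requires ≥ 90% HBD coverage of a chromosome; true isodisomy
gives coverage near 1, and the margin tolerates segment fragmentation.

## Variant prioritization

Normalization ranges are configuration, not code: phyloP [−14, 6],
GERP [−12.3, 6.17], PolyPhen2 [0, 1], LRT [0, 1] ascending, SIFT [0, 1]
descending (low raw = damaging, so the normalized value is flipped).
Out-of-range raw values are clamped and logged. A missing annotation is
treated as benign (0) by default — the conservative direction for
ranking — with a drop-the-variant policy available via the normalization
configuration (`missing_policy="drop"`). Panel variants use their own genotype ploidy
when present (the generator emits heterozygous panel genotypes); genes
absent from the panel take `P_max = 0`, so panel-novel genes rank
highest, which is the intent of the population rescaling. Ranking is a
total order — descending `P_pop`, descending `P_ind`, then variant id —
making output independent of input order.

## Synthetic generators

*CNV cohorts.* The toy genome is 22 autosomes × 10 Mb + X (8 Mb) +
Y (3 Mb): large enough to contrast chromosome compartments, small enough
for seconds-scale simulation. Default cohorts are 83/62, 179/974 and
61/100 cases/controls on three platforms (323 cases, 1136 controls).
Rare events are Poisson per genome (autosomal gain and loss 1.0 each,
X 0.15 each, Y 0.05 each) with log-normal sizes (median 30 kb,
σ_log 1.2, populating both sides of the 100 kb stratum boundary); common
polymorphic regions (20 loci, frequencies 5–40%) overlay them. Case
status follows `logit P(case) = α_cohort + Σ β·count` with a default
injected per-event log-OR of log(1.10) on rare autosomal deletions;
individuals are then sampled to the target case/control counts, which
preserves β under retrospective sampling. Each true event is emitted per
algorithm with sensitivities (1.0, 0.9, 0.9) and N(0, 2 kb) breakpoint
jitter, so 2-of-3 consensus recovers ~99% of events and attenuation is
negligible relative to the sampling error.

*HBD tracts.* Autozygous segments are placed as a Poisson process on the
concatenated autosomes (real-scale ~2.87 Gb manifest — a 10 Mb toy genome
would truncate tracts whose expected length, 100/(2g) cM ≈ 16.7 cM for
first cousins at 1 cM/Mb, exceeds a toy chromosome), with exponential
lengths and expected genome fraction equal to the target F (1/16 for
first cousins). Segments spilling over a chromosome boundary are split,
preserving covered length. Short background homozygosity (F ≈ 0.001,
mean 0.5 Mb) reproduces the L-shaped length distribution of real HBD
callsets. Whole-chromosome UPD is injected by construction.

*Exomes.* Annotation scores are drawn benign-skewed (Beta(0.8, 3) in
normalized space) and mapped to raw annotator scales; 5% of subject
genotypes are homozygous; MAFs are Beta(0.5, 5)/2 so the 10% filter is
exercised. The planted hit is homozygous with all normalized scores in
[0.95, 1], in a gene absent from the panel, with MAFs below 5% — its
`(P_pop, P_ind)` strictly dominates the background with overwhelming
probability, and the acceptance run verifies 100/100.

What the generators do **not** emulate: LD structure and genotype-level
data (HBD is simulated at segment level, not through a haplotype HMM),
array probe placement and intensity noise (sensitivity and jitter are
abstract channel parameters), platform-specific callability differences
beyond cohort labels, and realistic gene/annotation correlation
structure. Passing recovery tests therefore demonstrates correctness of
the estimators under their stated models, not robustness to array
artifacts.

## Problem sizes and runtime

Acceptance-scale runs use: 100 replicates of the full
simulate → consensus → cluster → filter → logistic → meta pipeline at
study scale (~1 s each); 500 null permutation families of 20 loci × 200
permutations for FWER; 200 null logistic fits at n = 500/500 for CI
coverage; 500 first-cousin samples for F recovery; 20 UPD injections; and
100 seeded exomes. The exhaustive Fisher oracle covers all 46 375
margin-distinct 2×2 tables with total ≤ 30. The full test suite runs in
a few minutes on one CPU.

## Known limitations

- The exact conditional CI is computed by inverting the exact test
  (scipy); for extremely unbalanced tables with huge margins it can be
  slow relative to the Woolf interval.
- The max-T statistic (raw case-carrier count) gives loci with higher
  total carrier counts more influence on the max than rarer loci;
  family-wise error control holds regardless, but power is not
  equalized across loci.
- Mixed-effects logistic regression is approximated by meta-analysis of
  per-cohort fits; with very small cohorts (sparse counts) the per-cohort
  Wald SEs that feed the meta-combination can be unstable, which is when
  the pooled stratified alternative is preferable.
- `consensus_merge` falls back from exact maximum-clique grouping to
  greedy absorption when a single call overlaps more than 16 others —
  beyond anything a per-sample callset produces in practice.
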