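# Methods

## The design and its statistical encoding

The analysis targets a 7-group factorial of resynthesized *Capsella*
lineages — two diploid parents (Co2 = *C. orientalis*, maternal;
Cg2 = *C. grandiflora*), their diploid hybrid (F2), two autotetraploids
(Co4, Cg4), and two allotetraploids differing in the order of events
(Allo-d: hybridize then duplicate; Allo-h: duplicate then hybridize) — with
two tissues (flower, leaf), six independent lines per group, one sequenced
individual per line (84 RNA samples), and six phenotyped individuals per
line (252 plants). Ploidy and hybrid state are derived from the group
label everywhere; they are never free columns that could drift out of sync.

Two questions shape every stage: does WGD by itself change expression or
fitness, and does hybridization do so additively (midparent) or
nonadditively (dominance/transgression)?

## Synthetic data generator

`allohybrid.simulate` produces counts, metadata, phenotypes, and per-gene
truth. Gene g has a baseline log2 mean b_g ~ N(4, 2). A fraction
`pi_ped` (default 0.25) of genes diverge between the parents by
d_g ~ N(0, 1.5) truncated to |d| ≥ 1 (log2), split symmetrically:
Co2 = b + d/2, Cg2 = b − d/2. Hybrid modes are drawn per gene over all
genes (defaults: additive 0.17, ELD toward either parent 0.03 + 0.03,
transgressive 0.0001 + 0.0001, remainder conserved); modes that require a
parental difference (additive, both ELD modes) force the gene into the
diverged set, and conserved genes are additionally diverged with the
residual probability so the overall diverged fraction equals `pi_ped`
(when `pi_ped` is too small to accommodate the divergence-requiring modes,
the excess is demoted to conserved — `pi_ped = 0` therefore yields a fully
exchangeable transcriptome). Hybrid expected means follow the mode
exactly: midparent for additive/conserved, the matched parent for ELD, and
max/min(parents) ± 1.5 log2 for TRE. By default
`wgd_effect_fraction = 0`, so Co4 ≡ Co2, Cg4 ≡ Cg2 and
F2 ≡ Allo-d ≡ Allo-h in expectation — the generator's null is the design's
central empirical finding, and `wgd_effect_fraction` / `wgd_logfc` exist to
break it. A per-gene leaf-vs-flower offset ~ N(0, 1) makes tissue the
dominant axis of variation, as in real data. An optional per-line random
effect defaults to σ = 0 (no within-vs-between-line variance decomposition
is asserted by the design).

**Counts.** Each sample draws a library size ~ lognormal(log 2e7, 0.15)
read pairs. Per-gene NB dispersions are lognormal(log 0.05, 0.5). Rather
than drawing independent NB counts — which would violate the fixed library
size — each feature receives an intensity (expected mean × a gamma
multiplier with the gene's dispersion) and reads are allocated
multinomially. This is the Poisson–gamma representation of the NB
conditioned on the total: sample totals equal the drawn library sizes
exactly, and marginal per-gene counts are NB to excellent approximation
(the dispersion-recovery tests confirm estimates centered on the configured
values). TE features (400, classes weighted LTR 0.45 / Helitron 0.20 /
SINE 0.10 / LINE 0.15 / other 0.10, lognormal per-feature weights) are
scaled per sample so the expected TE read share equals the sample's lane
fraction (defaults 5.3%, 1.5%, 4.8%); lanes are assigned in balanced
blocks (two samples per lane within every group × tissue).

**Phenotypes.** Pollen viability and normal-seed counts are beta-binomial
around the configured group proportions with intra-class correlation
ρ = 0.02, so a quasi-binomial fit sees dispersion > 1, as proportion data
from real plants do. Viability defaults are the observed group means
(Co2 0.985, Cg2 0.966, F2 0.827, Allo-d 0.813, Allo-h 0.878, Co4 0.831,
Cg4 0.914); normal-seed defaults for hybrids are 0.57 / 0.70 / 0.78
(F2 / Allo-d / Allo-h), and the nonhybrid values (Co2 0.95, Cg2 0.93,
Co4 0.80, Cg4 0.85) were chosen so that WGD lowers seed quality in
nonhybrids while raising it in hybrids — the interaction the design
detects. Each individual is scored on ≥ 300 pollen grains per flower
across 2 flowers and ~10 fruits × Poisson(20) seeds. Quantitative traits
(stem length, flowering time, pollen per flower) are normal around group
means ordered Co < hybrids < Cg with a tetraploid offset and Allo-d
flowering later than Allo-h.

## Normalization

TPM uses annotated feature length with no fragment-length correction;
TE rows are excluded from gene TPM by default. CPM supports a prior count
scaled by relative library size (prior_g = prior × lib_s / mean lib;
denominator grows by twice the prior), so log-CPM is comparable across
depths; prior 0 gives plain CPM whose columns sum to exactly 1e6. Both
expression filters are strict inequalities (TPM > 2, CPM > 1), so values
exactly at the threshold are excluded.

TMM scaling factors follow the canonical trimmed weighted-mean-of-M-values
procedure: reference = sample whose upper-quartile/library-size ratio is
closest to the mean of that ratio; genes zero in either sample are dropped;
M-values are trimmed 30% from each tail and A-values 5% from each tail
(rank-based, average ranks for ties); surviving M-values are averaged with
inverse asymptotic binomial variance weights; factors are rescaled to
geometric mean 1. The implementation agrees with edgeR 4.0.16
`calcNormFactors` to ~1e-10 on a frozen fixture. Note one property users
sometimes assume is only approximate: multiplying a single column by a
constant changes factors slightly (≲1%), because the precision weights mix
obs and ref count magnitudes and are not scale-free.

Downsampling to a common group-average library size is implemented as
binomial thinning: every cell of a sample in group g is kept with
probability target/mean_g (target = smallest group mean, probability
capped at 1). Thinning never increases a count, preserves within-sample
proportions in expectation, and is seeded. This is a reconstruction of the
goal stated for the original pipeline ("similar average number of mapped
reads per group"); the original script is not public.

## Differential expression

Per tissue, a single NB group-means model (`~ 0 + group`, log link) is
fitted per gene with log TMM-effective-library-size offsets. Because the
design matrix is group-indicator, the MLE separates by group into
one-dimensional Newton problems (score Σ(y−μ)/(1+αμ), information
Σμ/(1+αμ)), vectorized across genes.

Dispersions are estimated on a 49-point log-spaced grid (1e-4 to 4, plus a
Poisson point) by Cox–Reid adjusted profile likelihood (the 0.5·log det
X'WX correction removes most of the downward MLE bias at n = 6 per group);
the common dispersion maximizes the summed APL; per-gene estimates are
shrunk as (prior_df·common + df·raw)/(prior_df + df) with prior_df = 10.
Grid resolution (~19% between neighbors) is finer than the sampling noise
of per-gene estimates at these sample sizes. On simulated truth, median
shrunken estimates land within the (0.07, 0.13) window for true α = 0.1
and below 0.02 for Poisson data.

Pairwise contrasts are likelihood-ratio tests with the shrunken dispersion
held fixed: separate means for A and B versus a shared mean, χ²₁ reference.
In the Poisson limit this reproduces the two-group deviance test to 1e-6.
log2FC comes from fitted group CPMs with the 0.5 prior count (capping at
±20 for genes expressed in one group only). DEGs require |log2FC| >
log2(2) **and** BH FDR < 0.05, with BH computed across all tested genes and
applied per contrast. The alternative reading — BH within the
fold-change-passing subset — is available as a config switch but is not the
default: fold-change selection under the null enriches small p-values, so
BH within the selected subset calls a handful of false DEGs in every
realization, while the default mode yields a median of zero DEGs between
identically distributed groups at the design's sample size (and never more
than the handful the design tolerates).

## Expression-pattern classification

The 10-category decision table is a single explicit constant on the status
triple (hybrid vs Co2, hybrid vs Cg2, Co2 vs Cg2), constructed from the
verbal definitions: hybrid significantly above (below) both parents →
transgressive up (down), regardless of the parental contrast; hybrid
indistinguishable from exactly one parent and shifted in that parent's
direction relative to the other → complete ELD of the matched parent (high
or low by the parental contrast's sign); hybrid strictly between two
differing parents (significant against both, in opposite directions
consistent with the parental difference) → additive intermediate; all
statuses null → no change; parents differ but the hybrid resolves against
neither → unresolved parental difference; the remaining 12 incoherent
triples (possible under test noise) → ambiguous, reported rather than
dropped. Additivity is required to be strict (significant difference from
*both* parents); a more permissive "non-extreme" reading would absorb most
unresolved and ambiguous triples and was not adopted. Exchanging the
parents (swap the hybrid contrasts, negate the parental one) maps
ELD_P1 ↔ ELD_P2 and fixes every other category — enumerated exhaustively
in the tests. Enumerating all 27 triples yields exactly 10 distinct
labels with multiplicities 3/3/1/2/1/1/1/1/2/12.

Classification is threshold-based and inherits a known bias: an additively
expressed gene whose parents differ by just over the fold-change threshold
(|d| slightly above 2 log2, so the hybrid sits ~1 log2 from each parent)
is called dominant whenever noise pushes one hybrid-parent contrast across
the threshold and not the other. At the generator defaults (|d| ≥ 1,
17% additive) this inflates observed complete ELD to ~10% against a 6%
truth; with parental divergence ≥ 2 log2 and no additive class the
recovery is exact to ~0.1 percentage point (the configuration used for the
recovery test). Real-data ELD percentages should be read with the same
caveat.

## Extreme expression

Within a tissue, the 42 individuals are ranked per gene by CPM (genes with
CPM > 1 in ≥ 2 individuals); ranks 1 and 42 are extreme. Ties are broken
by a per-gene seeded random permutation, which preserves the exchangeable
null expectation of 2G/N extreme genes per individual exactly and makes
the conservation identity (Σ rank-1 counts = Σ rank-N counts = G) hold on
every run; a drop-tied-extremes mode exists for sensitivity analysis. Raw
CPM is the default (TMM-effective sizes optional). The optional
restriction to genes not differentially expressed between the parents
(FC < 1.2 **or** FDR > 0.05; untested genes count as non-significant)
removes the midparent effect that otherwise depresses hybrids'
extreme counts.

## TE abundance

TE abundance is numerator/denominator count data (reads on TEs / reads on
TEs or genes, per sample, optionally one class), tested with quasi-binomial
logit GLMs. Proportions at sequencing depth carry overdispersion orders of
magnitude above binomial (per-sample TE load varies biologically), which
the Pearson dispersion absorbs; the lane is included as a fixed batch
factor. The same binomial thinning used for expression is applied first so
group library-size differences cannot masquerade as TE effects.

## Phenotype statistics

One-way ANOVA is the classical between/within decomposition (F = t² for
two groups, to 1e-10). Tukey HSD uses the studentized range distribution
with the Tukey–Kramer correction for unbalanced groups; significance is
decided against the α critical value (reported p-values invert the same
test). The compact letter display uses the insert–absorb algorithm;
letters are named a, b, c, … in order of the highest-mean group containing
them, making the display a deterministic function of the pairwise
significance matrix.

Quasi-binomial GLMs fit the binomial-logit model by IRLS (point estimates
identical to the plain binomial fit) and scale uncertainty by
φ = Pearson χ²/df. Term tests are type II analysis-of-deviance F-tests:
each main effect is tested against the model containing the other main
effects *and any interaction not involving it*, interactions are tested
last; F = (Δdeviance/Δdf)/φ with the full model's φ and residual df. This
matches R's `car::Anova(type = 2, test.statistic = "F")` to the printed
precision on a frozen fixture (a type III option was considered and
dropped: with the balanced designs used here the two coincide for the
interaction, and type II has strictly more power for main effects).
Pollen viability is analyzed per individual by summing the two flowers'
counts — the binomial-consistent equivalent of averaging per-flower
proportions. Selfed seed set is reported descriptively only.

## Ordination

The leading-logFC distance between two samples is the root-mean-square of
the `top` (default 500) largest squared log2-CPM differences, re-ranked for
every pair; classical (Torgerson) MDS double-centers −D²/2 and scales
eigenvectors by the square roots of the eigenvalues (axis signs are
arbitrary; exactly Euclidean inputs are reproduced to 1e-9). PCA operates
on gene-centered log2(TMM-adjusted TPM + 1) via SVD. The TPM > 2 filter is
recomputed within each tissue subset by default.

## Problem sizes and seeds

The simulation-based checks run at the design's sample size (n = 6 per
group, 42 samples per tissue) with feature counts chosen per question:
the full 10,000 genes where genome-scale multiplicity matters (null DEG
behavior over 20 seeds, ELD/TRE recovery), 2,000 genes for
dispersion-recovery distributions, 400 genes + 80 TEs over 100 replicates
for the TE GLM error rates, and 1,000 replicates for the scalar
calibrations (quasi-binomial interaction type I, Tukey family-wise error).
All stochastic steps take explicit seeds; the pipeline derives per-stage
seeds from one global seed as (seed × 1000003 + crc32(stage)) mod 2³¹, so
stages are individually reproducible and a rerun yields bit-identical
output hashes.

## Known limitations

- The synthetic generator draws lines as exchangeable replicates (no
  line-level variance component by default) and models TE expression at
  the class level with lognormal weights; it contains no sequences, no
  positional genome structure, and no homeolog resolution (total
  expression of both homeologs, as in the upstream counting). Passing
  tests therefore validate the statistical machinery under the design's
  distributional assumptions, not read-level artifacts such as mapping
  bias between diverged subgenomes.
- The decision table reconstructs the 10 categories from their verbal
  definitions; it is isolated behind a single constant so an alternative
  scheme can be swapped in.
- Dispersion estimation is grid-based profile likelihood with linear
  shrinkage; it is deliberately not a numerical replica of edgeR's
  empirical-Bayes machinery (simulation calibration, not package
  equality, is the correctness criterion).
- Real-data users must match their upstream counting choices (union mode,
  multi-mapping TE resolution) to the count matrices they supply; counting
  is out of scope here.
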