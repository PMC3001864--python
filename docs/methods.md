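# Methods

This note records the models implemented in `crossqtl`, the defaults and
why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical decisions a maintainer would want to know.

## Meiosis model and genotype probabilities

Gametes are modelled under the Haldane map function,
r = ½(1 − e^(−2d/100)) for d in cM, i.e. crossovers form a Poisson
process with no interference. The simulator realises this law directly
at the markers: a gamete's allele at the first marker is Bernoulli(½)
and flips between adjacent markers with probability equal to the
interval's recombination fraction. Because the crossover process is
Markov, this marker-restricted chain is exactly equivalent to drawing
Poisson crossover counts with uniform positions and reading off
parities — it is the same model, vectorised.

Conditional genotype probabilities use a three-state HMM per chromosome:
prior (¼, ½, ¼); transitions from two independent meioses, e.g.
P(AA→AA) = (1−r)², P(AA→AB) = 2r(1−r), P(AB→AB) = (1−r)² + r²; emissions
give the observed class probability 1 − ε and ε/2 to each other class.
The grid holds all markers plus pseudomarkers every `step` cM (default
2 cM). Defaults: ε = 0.001, a small buffer for genotyping error; both
are configurable. The forward–backward recursion is scaled per locus and
is checked in the tests against exhaustive enumeration of both gametes'
allele paths on chains of up to four markers (agreement to 1e−10).

Map estimation keeps markers in their given physical order and estimates
each adjacent pair's recombination fraction by bounded maximum
likelihood on the exact F2 two-locus genotype table, which marginalises
the double-heterozygote phase ambiguity; cM positions follow by inverse
Haldane and accumulation. Monomorphic markers are skipped with a
warning since their recombination fraction is undefined.

## Genome scans and permutation FDR

Haley–Knott regression fits y on [1, L_A, L_D] at every grid locus, with
L_A = P(AA) − P(BB) and L_D = P(AB), and
LOD = (n/2)·log10(RSS₀/RSS₁) against the intercept-only model.
Expression traits are first regressed on gender and the residuals
scanned; on balanced designs this tracks a scan with gender as an
additive covariate to within 0.2 LOD (tested). Numerical choices: a
perfect fit (RSS₁ ≈ 0) is capped at LOD 300 and flagged so results stay
finite and serialisable; a rank-deficient design drops the dominance
column with a flag; constant traits score 0 (the RSS₀ ≈ 0 case is
detected relative to the trait's scale). Permutations shuffle whole
individuals against the intact genotype rows, preserving genome-wide
linkage — the standard QTL permutation unit.

Two FDR estimators are provided. Clinical traits use trait-by-trait
nulls (default 1,000 permutations): peak LODs are converted to add-one
p-values, p = (1 + #{null ≥ obs})/(P + 1), permuted peaks are converted
the same way against the trait's own null, and
FDR(t) = mean_b #{p_perm(b) ≤ t} / max(1, #{p_obs ≤ t}), monotonized
q-value-style (running minimum over increasingly lenient thresholds).
Expression traits use a null pooled across reporters from a few
(default 5) whole-matrix permutations:
FDR(λ) = (average permuted count ≥ λ)/(observed count ≥ λ), reported as
1 when no observed peak exceeds λ. A caveat worth knowing: at the single
most extreme attained threshold any permutation-count estimator is
highly variable (with one discovery the estimate is roughly
exponential around its mean), so FDR estimates at thresholds carrying
only one or two discoveries should be read with caution; in the bulk
region (≳10 discoveries) the estimator is accurate and conservative on
null data (tested).

Default significance thresholds: LOD 4.3 for clinical traits, LOD 5 for
expression traits, 3.0 suggestive — all configuration keys.

## eQTL catalog, hotspots, replication

Catalog entries are collapsed to one per (reporter, chromosome, tissue)
at the maximum LOD. The *cis* call uses an inclusive ±20 Mb window on
the same chromosome; peak Mb positions are linearly interpolated between
flanking markers' physical coordinates, since QTL live on the genetic
map while the cis window is physical. Bins are half-open
[start, start + size), anchored at 0 per chromosome, counting unique
reporters. The uniform expectation divides the catalog total by all
mapped bins. The Poisson upper tail is computed in log space (with a
log-sum-exp fallback where scipy's survival function underflows) and
floored at the smallest positive double; the empirical p compares the
observed bin count to the genome-wide maximum bin count of each permuted
catalog with the add-one rule. Replication in a second cohort supports
two rules: max LOD ≥ 2 anywhere on the stated chromosome, and
LOD ≥ 3 with the max-LOD position inside a stated cM interval. The
hotspot signature is summarised by the first principal component of the
standardized signature submatrix, sign-oriented so the sum of reporter
loadings is positive, and correlated with each trait (Pearson r,
two-sided t-approximation p).

Tissue-sharing fractions use (reporter, chromosome) keys with a union
denominator by default; a conditional-on-first-catalog denominator is
available by flag, since either convention is defensible.

## Likelihood-based causality model selection

Overlaps are collected where a trait peak and an expression peak
(both LOD ≥ 2) on the same chromosome have intersecting LOD > 1 support
regions; the test marker L is the genotyped marker nearest the midpoint
of the two peak positions (ties to the lower cM).

Given the genotype posterior w_i at L, the three models factor as
P(R|L)·P(C|R) (causal), P(C|L)·P(R|C) (reactive), and P(R|L)·P(C|L)
(independent); the shared P(L) factor cancels and is omitted. Genotype-
conditional terms are three-mean, common-variance normal mixtures over
w_i, maximised by EM (tolerance 1e−8, ≤ 500 iterations, deterministic);
trait-conditional terms are closed-form linear regressions with MLE
variance. Parameter counts are 7, 7 and 8; the smallest
AIC = 2k − 2 log L̂ wins. `no_call` is returned for AIC ties below
1e−9, degenerate fits (zero residual variance), constant inputs, or
fewer than 30 complete triplets. A hard-call mode replaces the posterior
with its argmax; with error-free genotypes the two modes agree
(tested). The independent model is implemented without a residual-
correlation parameter; adding one (k = 9) is a straightforward
sensitivity variant but is not the default because the extra parameter
is unidentifiable exactly when the independence structure holds.

A built-in calibration harness simulates triplets under each generative
model (1:2:1 genotypes, additive effect 1.0 residual-SD, unit noise,
n = 300 by default) and tabulates verdict rates; at these conditions the
matching verdict is essentially always selected (≥ 99% over 500
replicates per model), comfortably above the ≥ 80/80/70% working
thresholds used in the tests.

Causal-gene enrichment uses the fold
(causal-in-signature/signature)/(causal-on-array/array) with a one-sided
Fisher exact p, cross-checked against exhaustive hypergeometric
summation.

## Co-expression networks

The top quartile of reporters by cross-individual variance enters the
network ("most differentially expressed" has no unique definition; a
median-absolute-deviation ranking is available by flag). The network is
unsigned, a_ij = |r_ij|^β (a signed variant is a flag), and β is the
smallest integer in 1–20 whose connectivity histogram gives a log-log
R² above 0.8 over 10 equal-width bins on log k; if no candidate
crosses, the argmax-R² candidate is used with a warning. The plain
log-log fit is implemented; a truncated-power-law variant would alter
the index but not the machinery. Topological overlap is
ω_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i, k_j) + 1 − a_ij), ω_ii = 1.
Modules come from average-linkage clustering of 1 − ω with a static
branch cut at an absolute height of 0.99: topological-overlap
dissimilarities of unrelated genes pile up immediately below 1, so the
fixed cut just under 1 isolates coherent branches, whereas a cut at a
height *quantile* is dominated by those near-1 merges and collapses
everything into one module. Branches of at least 20 genes are coloured
from a fixed palette (turquoise, blue, brown, …) in descending size
order so colour labels are reproducible; the rest are grey. With all
pairwise dissimilarities equal and below the cut, everything forms one
module (or all grey below the minimum size). Module eigengenes are
standardized within-module first principal components, sign-oriented to
correlate positively with the average module gene. Set-in-module
enrichment uses fold = (|set∩module|/|module|)/(|set|/|universe|) with
an upper-tail hypergeometric p. Knockout signatures are per-reporter
two-group one-way ANOVA at α = 0.05 by default (the threshold is a
parameter; genes constant and equal in both groups report p = 1).

## eSNP enrichment

The eligible universe keeps SNPs within 1,000,000 bp of a gene with MAF
strictly above 0.04. Null sets match the eSNP set's profile over MAF
deciles × 4 distance-to-gene bins (bin edges from the set's own
quantiles); matching on linkage-disequilibrium structure is not
implemented — it would require a reference panel. Each resample draws
without replacement per stratum; since only the count of sub-threshold
SNPs per stratum enters the fraction, the count is drawn from its exact
hypergeometric law, which is identical in distribution to enumerating
SNP identities and makes the default 100,000 resamples cheap. Strata
with too few universe SNPs borrow from the nearest stratum with spare
capacity, with a warning. The test reports Z, the one-sided normal-tail
p, the 2.5/97.5 percentile band of the null, and the add-one empirical
resampling p alongside (the normal-tail p has resolution beyond the
resample count; where both are informative they agree within Monte
Carlo error, as the tests check).

## Synthetic study generators

`simulate_study` produces genotypes, expression, traits and a SNP table
with a ground-truth sidecar. Defaults emulate the structure of a
two-strain mouse intercross study: 360 F2 individuals (300 in the
scaled hotspot benchmark), 19 autosomes with mouse-like genetic lengths,
markers every 5 cM, 2% genotypes missing completely at random, a fixed
2 Mb/cM physical scale so the ±20 Mb cis window is exercisable, balanced
binary gender with reporter-specific gender effects (SD 0.3), and unit
residual SD. The expression layer plants a 200-reporter trans hotspot at
35 cM on chromosome 8 (additive effect 1.0 residual-SD, a quarter of the
reporters with negative sign), 100 cis reporters (effect 1.5) at their
own locations, and 1,700 pure-noise reporters. Driving genotypes are
taken at the marker nearest the configured position, and missing
genotypes are imputed from the 1:2:1 prior when effects are applied so
the missingness pattern carries no signal. Clinical traits realise three
architectures relative to the hotspot transcripts: causal (trait =
signature score + noise, where the score is the mean of standardized
hotspot-reporter expressions), reactive (trait from genotype, then its
linked reporters re-generated from the trait), and independent (trait
from genotype with its own noise). The SNP generator gives non-eSNPs
uniform association p and plants P(p < 0.05) = π (default 0.10) in the
eSNP set, with uniform MAF and exponential distance-to-gene.

`simulate_modular_expression` provides block-structured expression
(shared latent factor per module, expected within-module correlation
0.8) for network benchmarks, because locus-driven co-expression at the
study's effect sizes yields pairwise correlations around 0.3 — too weak
for module detection, and not what real transcriptome-wide modular
structure looks like.

What the generators do **not** emulate: crossover interference,
X-chromosome dosage, litter/cage and batch effects, heavy-tailed or
heteroskedastic expression noise, realistic LD between SNPs, and
transcriptome-wide correlation beyond the planted blocks. Passing tests
therefore demonstrate correctness of the statistical machinery under
its stated model, not robustness to every artefact of real microarray
data.

## Problem sizes used in tests and the acceptance script

Calibration and benchmark runs use deliberately scaled problems chosen
to exercise the full machinery: 500 causality triplets per model at
n = 300; a hotspot study with 300 individuals, 2,000 reporters and 5
whole-matrix permutations; FDR calibration with 100 null traits and 200
permutations; eSNP calibration with 200 repeated experiments at 2,000
resamples each; network recovery with 5 planted 30-gene modules among
100 noise genes. These sizes give stable statistics while keeping a full
run to a couple of minutes.
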