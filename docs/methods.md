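# Methods

## The workflow being modeled

The package implements the computational side of a two-stage plasma
miRNA biomarker study in early colorectal cancer. Stage one is a
discovery screen: small-RNA sequencing of a few case and control plasma
libraries, normalized and ranked by fold change, with candidates pruned
by variability, absolute abundance, and assay availability. Stage two is
validation: each surviving miRNA is absolutely quantified by droplet
digital PCR (ddPCR) in a larger cohort, and each patient's value is
classified against the range spanned by tumor-free controls. Panels are
then summarized by per-patient dysregulation counts, ≥k coverage, a
coverage comparison between panels, and KRAS-stratified group tests.

## ddPCR quantification

A well partitions the reaction into N droplets; each droplet is negative
with probability exp(−λ) when λ is the mean target copies per droplet.
The maximum-likelihood estimate from an endpoint read is
λ̂ = −ln(N_neg/N_tot), converted to concentration by
c = λ̂ / V_d × dilution, with V_d the droplet volume in µL. V_d defaults
to 0.85 nL — the de-facto convention for the instrument class this
models; it is a parameter, not a constant, because nominal droplet
volumes differ across chemistries. Saturated wells (no negatives) raise
an error rather than returning infinity: the concentration is simply not
estimable and the well must be re-run diluted. Confidence intervals use
the Wilson score interval on the negative fraction, propagated through
the strictly decreasing map p ↦ −ln p (the interval endpoints therefore
swap); the score interval is preferred because it behaves sensibly at
extreme fractions, and the method is configurable. Monte-Carlo
round-trip tests bound the relative bias of the whole chain below 1%
over 1–5000 copies/µL at 20,000 droplets.

## Normalization and the training screen

Size factors are median-of-ratios: for each library, the median over
miRNAs (restricted to rows positive in every library) of the ratio of
its count to the row's geometric mean. We additionally rescale the
factors to geometric mean 1. This unit-product convention changes
nothing for symmetric designs, leaves the worked two-sample example
(factors 1/√2, √2 for a doubled column) intact, and gives the clean
equivariance property that scaling one library's counts by c scales its
factor by exactly c relative to every other library.

Fold changes are ratios of normalized group means with a pseudocount
(default 0.5) added to each mean, reported as a magnitude ≥ 1 plus an
UP/DOWN direction — matching how thresholds like "FC > 2" are stated in
bench practice, rather than log2 units. The screen is deliberately a
fold-change ranking with no per-miRNA hypothesis test: at 3-versus-5
libraries a dispersion-estimated test has essentially no power, and the
orthogonal ddPCR validation stage is the arbiter.

Candidate filters are a conjunction, with exclusions tagged by the first
failing rule in the fixed order FC → VARIABILITY → ABUNDANCE → ASSAY
(the surviving set is order-independent). Numerical conventions: the FC
cut is strict (fc > threshold); the abundance cut excludes strictly
below 0.2 copies/µL, so exactly 0.2 survives. The variability rule is a
control-group coefficient of variation (sample SD / mean) with default
ceiling 2.5. A caveat worth stating: for n non-negative values the
sample-SD CV is bounded by √n — √3 ≈ 1.73 for three controls — so with a
three-control training set the default ceiling of 2.5 can never trigger; it becomes active with larger control sets (the
eight-value worked example in the tests has CV 2.83) or a lower
configurable threshold. A candidate with no ddPCR measurement is tagged
MISSING and excluded — absence of an absolute quantification is not
evidence of abundance.

PCA is centered (optionally log(x+pseudocount)-transformed) via singular
value decomposition; hierarchical clustering uses average linkage on
correlation distance 1 − r, with zero-variance rows dropped.

## Dysregulation calling

The classification rule: UP strictly above the control maximum, DOWN
strictly below the control minimum, NORMAL otherwise. Ties at a bound
are NORMAL — exceedance means "higher/lower than" the extremes. MISSING
measurements are never imputed and do not count; zero copies/µL is a
legitimate value and triggers DOWN whenever the control minimum is
positive. An alternative caller compares against the control mean with a
fold margin (default 2.0; margin 1 degenerates to a strict comparison
with the mean). The margin default is a package choice: the variant
analysis it mirrors is described only qualitatively in the source
workflow, so the margin is exposed as a parameter rather than fixed.

Because the rule is a range-exceedance heuristic, its false-positive
behaviour matters: under an exchangeable continuous null a new sample is
equally likely to land in any of the n+1 rank gaps of n controls, so the
per-miRNA flag rate is 2/(n+1) — about 0.29 per miRNA with six controls,
which is why per-patient counts and ≥k coverage, not single-miRNA calls,
carry the diagnostic weight. `null_specificity` estimates this rate by
simulation and the tests verify it against the closed form for
n ∈ {3, 6, 10}.

## Cohort statistics

Mann–Whitney U uses the exact null distribution when the pooled sample
is ≤ 12 and tie-free, otherwise the normal approximation with tie
correction; a fully constant pooled sample returns p = 1 with a warning.
Spearman is computed on mid-ranks, with full permutation enumeration of
the pairing for n ≤ 8 and the t-approximation above. The signature
comparison uses the pooled two-proportion z-test without continuity
correction; pooling (rather than unpooled variance or a corrected
statistic) is the variant that reproduces the conventional hand
calculation for flagged counts such as 31/35 vs 23/35 (z = 2.277,
p = 0.023). The two panels share their denominator, so this is a
conservative convenience test, not an exact paired analysis. No
multiple-testing correction is applied anywhere; results carry the
number of tests performed so readers can correct as they see fit.

miRNA set grouping standardizes log levels per miRNA, takes a PCA across
patients, and k-means-clusters the miRNAs on biplot-style loadings
(component weights scaled by the component standard deviation) over the
first three components by default. The scaling matters: unscaled unit-
norm loadings let low-variance trailing components dominate distances
and can split perfectly co-regulated pairs. Within-set pairwise Spearman
correlations are reported alongside so co-regulation claims are
inspectable.

KRAS stratification is binary MUT/WT on case samples only; individual
variant classes are carried in metadata but not modeled — typical
per-variant counts in cohorts of this size are single digits.

## Synthetic cohorts

The generator emulates the study conditions the pipeline assumes: a
6-control/35-case ddPCR cohort whose first 3 + 5 samples form the nested
NGS training set, ~2,000 miRNAs, a planted 9-miRNA signature (5 up,
4 down) with true fold change 4, a 3-miRNA KRAS-responsive subset
(fold change 4 in mutants, mutant fraction 16/27), 20% multiplicative
ddPCR noise, negative-binomial counts with dispersion 0.2 and log-uniform
size factors in [0.5, 2], and a 10% low-abundance stratum below
0.2 copies/µL to exercise the abundance filter. Baseline abundances are
log-uniform over 0.5–500 copies/µL and NGS count means are proportional
to them (20 expected reads per copy/µL at unit size factor), keeping the
two platforms consistent. Noise is multiplicative log-normal because
plasma miRNA abundances span orders of magnitude and negative values are
impossible. Where the emulated study reports no distributional detail,
these defaults are conventional choices for plasma small-RNA data, fixed
once; they are not fitted to any dataset.

What the generator does *not* emulate: hemolysis and pre-analytical
variation, correlated miRNA families, droplet rain/gating ambiguity,
batch effects between platforms, and any relation between KRAS status
and overall tumor burden. Passing recovery tests therefore demonstrate
that the pipeline's inference is correct under its own model — planted
effects of the stated size are found, nulls are flagged at the analytic
rate — not that real cohorts of this size would yield equally clean
signatures.

An `affected_fraction` parameter lets validation runs include
effect-free patients (the separation experiments use 0.5) while the
default of 1.0 matches the assumption that every case carries the
signature.

## Numerical and design notes

- One `numpy` Generator seeded by the config drives all simulation
  randomness; identical configs reproduce cohorts bit-for-bit.
- Exact-test cutoffs (pooled n ≤ 12 for U, n ≤ 8 for Spearman) keep full
  enumeration below ~10⁵ evaluations.
- Degenerate inputs fail loudly with typed exceptions (saturated wells,
  constant vectors, empty strata, unformable control ranges) rather than
  returning NaN.
- Validation experiment sizes (20 seeds for recovery, 10⁵ replicates for
  the null rate, 2×10⁴ wells per concentration for the round trip) are
  chosen so Monte-Carlo error is several-fold smaller than the margins
  being checked.
- File outputs carry a `#` header with the tool version and a hash of
  the producing configuration; all readers skip comment lines. The
  simulation truth table uses literal `NULL`/`NA` category labels, and
  its reader disables default NA-string coercion accordingly.
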