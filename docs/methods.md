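# Methods

## Model and scope

`mratlas` implements two-sample summary-data Mendelian randomization: the
per-SNP associations with the exposure (β̂Xⱼ, seXⱼ, per 1-SD trait units)
and with the outcome (β̂Yⱼ, seYⱼ, log-odds) come from non-overlapping
cohorts, and under the instrumental-variable assumptions (relevance, no
confounding of the SNP-outcome relation, no effect on the outcome except
through the exposure) each ratio βYⱼ/βXⱼ estimates the same causal log-OR
per SD. The package's job is everything around and including that
estimate: selecting and harmonizing instruments, pooling outcome cohorts,
estimating the causal effect four ways, stress-testing the third assumption
(horizontal pleiotropy), quantifying power, and assembling grid-scale
results with nested multiple-testing tiers.

## Instrument selection and strength

Candidates must pass P < 5×10⁻⁸ (strict) and MAF > 0.01 (strict); rows
without a frequency pass the MAF filter and are re-checked at
harmonization. Clumping is greedy: take the lowest-p remaining candidate
(ties broken lexicographically on SNP id for reproducibility), discard
candidates with r² ≥ 0.001 against it, repeat. When the panel carries
positions, discarding can be restricted to a window around the lead;
the default window is 10,000 kb. A 10 kb reading of the same window
specification would make r²-pruning essentially positional and is
inconsistent with pruning at r² < 0.001, but both are expressible through
`clump_window_kb`; with no positions the window is ignored and pruning is
purely r²-based (the conservative choice).

Per-SNP variance explained uses the standardized-trait identity
R²ⱼ = 2fⱼ(1−fⱼ)βⱼ²; a SNP without a frequency falls back to
β²/(β² + n·se²) and is flagged. Per-SNP F is the Wald chi-square (β/se)²;
the overall F is (R²/(1−R²))·((n−k−1)/k) over the clumped set. Both per-SNP
and overall F are reported because usage in the field varies. The
individual-level check in the test suite (n = 20,000 simulated genotypes)
confirms the summary formulas to within 5%.

The confounder screen is advisory: instruments with P < 10⁻⁵ in any
supplied confounder GWAS (BMI, adiposity, activity, smoking, ...) are
flagged and reported, never removed. The screen threshold is read as
P < 10⁻⁵; a greater-than flag threshold is not meaningful.

## Harmonization

Outcome records are re-expressed on the exposure's effect allele. Swapping
alleles negates β and mirrors the frequency (eaf → 1−eaf); p, se and n are
untouched. Strand complementation is attempted only after direct label
matching fails, and never for palindromic pairs, where a complement is
indistinguishable from a swap.

Palindromic SNPs (A/T or C/G) are oriented by frequency concordance: the
outcome record is flipped, if necessary, so its effect-allele frequency
falls on the same side of 0.5 as the exposure's. Orientation is attempted
only when both MAFs are ≤ 0.42; above that (or with a missing frequency on
either side) the SNP is declared non-inferable and sent to the proxy path.
A frequency of exactly 0.5 is undecidable and the SNP is dropped.

Proxy replacement: a SNP absent from the outcome, or a non-inferable
palindrome, is replaced by the highest-r² panel neighbour with r² > 0.8
(strict) that exists in the outcome and is not itself a non-inferable
palindrome. Because only r² (not phase) is available, the proxy's outcome
effect is oriented by the same frequency-concordance rule against the
*original* exposure record, whose exposure effect the instrument keeps —
the minor-with-minor allele coupling this assumes is standard at r² > 0.8.
Proxies whose orientation cannot be established this way are skipped in
favour of the next candidate. Every input SNP ends in exactly one of
`instruments` or `dropped` (with a reason string); this conservation is
asserted property-style in the tests.

Cohort meta-analysis happens before exposure-outcome harmonization: outcome
cohorts are pooled per SNP by fixed-effect inverse variance on the log-OR
scale (no genomic-control correction), with the first cohort fixing the
allele orientation and later cohorts aligned by labels or, for palindromes,
by frequency; SNPs carried by only a subset of cohorts are pooled over the
cohorts that have them.

## Estimators

* **Wald ratio** (k = 1): βY/βX with first-order SE seY/|βX|, normal p.
* **IVW**: weighted regression of βY on βX through the origin, weights
  1/seY². "Random effects" is the multiplicative form: the fixed-effect SE
  1/√(ΣwβX²) is inflated by max(1, √(Q/(k−1))), so the model reduces to
  fixed effects when Cochran's Q is at or below its degrees of freedom and
  reduces exactly to the Wald ratio at k = 1. P-values are normal.
* **Weighted median** (k ≥ 3): ratio estimates sorted ascending, cumulative
  standardized weights sⱼ = (Σᵢ≤ⱼwᵢ − wⱼ/2)/Σw with wⱼ = (βXⱼ/seYⱼ)² (the
  first-order inverse variance of the ratio), estimate interpolated at
  s = 0.5. The SE is the standard deviation of the estimate over 1,000
  parametric-bootstrap replicates (effects redrawn from normal(β̂, se));
  the bootstrap seed is mandatory, making the SE bit-reproducible.
* **MR-Egger** (k ≥ 3): weighted least squares of βY on βX with a free
  intercept, weights 1/seY², instruments re-oriented so all βX ≥ 0 first.
  The slope is the causal estimate; the intercept estimates average
  directional pleiotropy. SEs carry the same max(1, √(Q/(k−2))) inflation
  and inference uses t(k−2) — with two estimated coefficients on a handful
  of SNPs the t correction is material. The inference distribution is
  recorded on every result (`reference` field).

With fewer instruments than a method needs, the pipeline records an
explicit not-available marker (rendered "NA"), distinct from an error.
All four estimators are invariant to simultaneous sign flips of
(βX, βY) per instrument; this is asserted on random sets.

## Sensitivity battery

Cochran's Q uses the ratio-estimate form with weights (βX/seY)², which is
identical to the weighted residual sum of squares of the origin-constrained
IVW fit; I² = max(0, (Q−df)/Q)·100.

MR-PRESSO follows the published resampling scheme. Observed statistic:
RSS = Σⱼ wⱼ(βYⱼ − βXⱼ·b̂₍₋ⱼ₎)² with leave-one-out IVW slopes b̂₍₋ⱼ₎ and
wⱼ = 1/seYⱼ². Null distribution: n_sim = 1,000 parametric draws
β*Yⱼ ~ N(βXⱼ·b̂₍₋ⱼ₎, seYⱼ), β*Xⱼ ~ N(βXⱼ, seXⱼ), each scored with its own
leave-one-out slopes. The global p is the exceedance proportion, floored at
1/n_sim and labelled "<1/n_sim" when no draw exceeds (a Monte-Carlo p
cannot be zero). Per-SNP outlier p-values compare each SNP's observed
residual contribution with its simulated contributions and are
Bonferroni-corrected by k; flagged SNPs trigger an outlier-corrected IVW
estimate and a distortion test that compares the correction against
removing random instrument subsets of the same size.

**Known conservatism of the global test.** The simulation means
βXⱼ·b̂₍₋ⱼ₎ embed the observed leave-one-out slopes, which are partly fitted
noise. When instrument influence wⱼβXⱼ² is spread evenly, the per-SNP
deviations of those slopes from the full-set slope are negligible and the
test is close to nominal (measured 0.035–0.05 at α = 0.05 on
equal-influence designs). When influence is unequal — the realistic case
where effect magnitudes vary widely and SEs depend on allele frequency, as
in this package's generator defaults — those deviations inject j-specific
signal into the simulated RSS, inflating the null distribution: measured
type-I error is 0.01–0.03 instead of 0.05. The distortion is always
conservative (the test under-rejects, never over-rejects), so detected
pleiotropy remains trustworthy; power for weak global pleiotropy is
correspondingly reduced. The outlier test is unaffected in practice: a
planted 10-SE outlier is recovered in ≥ 90% of replicates at defaults.

## Meta-analysis, power, tiers

Fixed-effect meta: βpool = Σwᵢβᵢ/Σwᵢ, se = 1/√Σwᵢ, wᵢ = 1/seᵢ²; the pooled
SE never exceeds any cohort SE and the pooled β lies in the convex hull of
cohort βs (property-tested).

Binary-outcome power for the IVW estimate uses the normal approximation:
the IVW z-statistic has non-centrality λ = √(n·R²·φ(1−φ))·|ln OR| for n
participants with case fraction φ and instrument variance explained R², so
two-sided power at level α is Φ(λ − z₁₋α/₂) + Φ(−λ − z₁₋α/₂). This equals
α exactly at OR = 1. The formula models the fixed-effect IVW test, as the
standard MR power calculators do; the multiplicative random-effects floor
makes realized power of the pipeline's default IVW slightly lower
(≈ 0.04–0.06 at mid-power), which is why the simulation oracle
(`empirical_power`) uses the fixed-effect p-value by default and exposes the
random-effects variant behind a flag. Agreement between formula and
simulation is within ±0.01 over a 3×3 (n, OR) grid at 2,000 replicates per
cell. The minimum detectable OR at 80% power is found by bisection on
ln(OR) (relative tolerance 10⁻⁶) and reported as ">10" when even OR = 10 is
underpowered; the protective bound is its reciprocal by symmetry.

Significance tiers are nested: nominal (p < 0.05), per-exposure Bonferroni
(p < 0.05/n_exposures), per-pair Bonferroni (p < 0.05/(n_exposures ×
n_outcomes in the family)). For a 14-exposure, 22-outcome family these
print (to 2 significant figures, as reported) as 0.0036 and 0.00016. Pair
families are sized per outcome family, configurable per run. Atlas rows are
ordered by ascending IVW p within family; single-instrument pairs are
ranked by their Wald ratio, which the IVW reduces to.

## Synthetic-data generator

The generator draws summary statistics directly (no individual-level
genotypes): effect-allele frequencies fⱼ ~ U(0.05, 0.95); causal exposure
effects with normal raw magnitudes rescaled so Σ2fⱼ(1−fⱼ)βXⱼ² equals the
target R² (default 0.02, inside the 0.6–4.6% range typical of biomarker
instrument sets); exposure estimates β̂X ~ N(βX, 1/√(2f(1−f)nX)) with
nX = 100,000; binary-outcome effects βY = b·βX + αⱼ with cohort SEs
1/√(2f(1−f)·n·φ(1−φ)) for two biobank-scale cohorts (300k at 10% cases,
220k at 6%). Pleiotropic offsets αⱼ afflict a configurable fraction of
instruments (default 0.3) with magnitude scaled to the median outcome SE
(default 1.5× — comparable to, but larger than, sampling noise, so the
scenario is detectable without being trivial): mean-zero normal for
balanced, positive-mean for directional; the `outlier` preset plants a
single 10-SE offset. Null SNPs (default 40) have βX = 0. LD blocks are
equicorrelated clusters (default two r² = 0.9 partners per causal SNP,
sharing the lead's frequency and carrying √r²-attenuated effects), which
exercises clumping and the proxy path. Palindromic SNPs (default 20%) get
MAFs drawn from U(0.30, 0.50), straddling the 0.42 inferability limit on
both sides; outcome tables flip allele coding for a configurable fraction
of SNPs (default 30%) and strand labels for 10%.

Five independent random streams (structure, effects, exposure noise,
outcome noise, presentation) are spawned from the single seed, so changing
a presentation fraction (coding/strand flips) leaves the underlying effects
byte-identical — the basis of the end-to-end invariance check, which
demands exact equality of estimates between a fully flipped and a flip-free
dataset.

What the generator does *not* emulate: sampling correlation between LD
partners' estimates (each SNP's noise is drawn independently), population
stratification, sample overlap between exposure and outcome cohorts,
allele-frequency differences between cohorts, and mis-reported effect
columns. Passing calibration on this generator therefore demonstrates
estimator correctness under the two-sample MR sampling model, not
robustness to those real-data pathologies.

## Replicated experiments and sizes

The validation experiments (shared by `tests/test_acceptance.py`,
`scripts/acceptance.py` and `analysis/03–04`) use: 500 replicates for
type-I calibration, intercept uniformity, parameter recovery and coverage;
2,000 vectorized replicates per power-grid cell; 200 replicates for outlier
recall; 1,000 random instrument sets for oracle equivalence; MR-PRESSO with
500 null draws inside replicated experiments (1,000 at single-run
defaults). These sizes keep the full suite around two minutes on one CPU
while holding Monte-Carlo SEs near or below 0.01 on rates.

Recovery and coverage experiments instrument the pair with the generator's
known causal SNPs rather than re-running significance selection: selecting
on the same data that feeds estimation adds winner's-curse bias of about
−0.007 on the log-OR (≈ 3 Monte-Carlo SEs at 500 replicates), which is a
property of selection, not of the estimators under test. Selection,
clumping and harmonization are exercised end-to-end by the pipeline tests
and by the calibration experiments, where the null effect makes selection
harmless.

## Numerical choices and degenerate inputs

p/β/se consistency is checked on read with a 20% relative tolerance on the
implied two-sided normal p (warn, never drop — catches unit errors while
tolerating legacy rounding). LD matrices must be symmetric within 10⁻¹²
with unit diagonal. Zero exposure effect makes the Wald ratio an error;
all-equal exposure effects make the Egger design collinear (error); every
instrument flagged as a PRESSO outlier is a degenerate-set error. Empty
instrument sets after harmonization yield reason-coded atlas rows, never a
crashed grid. Greedy-clump ties break lexicographically; the weighted
median clamps to the extreme ratios when the 0.5 quantile falls outside the
cumulative-weight range. Seeds are mandatory for every stochastic
procedure, and per-pair seeds in grid runs are spawned deterministically
from the run seed.

## Limitations

Single-SNP and two-SNP pairs support no pleiotropy diagnostics (as with
any MR implementation); the proxy orientation rule assumes minor-allele
coupling and will mis-sign proxies in anti-phased LD; the MR-PRESSO global
test is conservative under unequal instrument influence (above); power
calculations assume the fixed-effect IVW and one aggregate R² per exposure;
no FDR procedures, mode-based estimators, Steiger filtering, bidirectional
or nonlinear MR are provided.
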