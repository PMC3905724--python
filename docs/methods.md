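# Methods

This note records the models implemented in `isoshare`, the defaults and
numerical choices, and what the synthetic cohorts do and do not emulate.

## Forward isolate simulator (`isoshare.simulate`)

**Model.** Discrete non-overlapping generations descend from `n_founders`
unrelated founders. Each offspring draws two distinct parents uniformly at
random (selfing disallowed, monogamy not enforced — the simplest
exchangeable mating model). Each transmitted gamete is a mosaic of the
parent's two haplotypes with crossover breakpoints drawn as a Poisson
process at rate 1 per Morgan along the genetic map (Haldane model, no
interference) and a fair coin for the starting phase. Haplotypes are
represented as ancestry mosaics over founder haplotypes, so genotypes are an
exact function of founder alleles and the recombination history, and true
IBD segments around the focal allele are read off the mosaics rather than
inferred.

**Focal allele.** Exactly one founder haplotype carries the derived allele
at the focal marker (nearest marker to the chromosome midpoint). When a
target final frequency is set, whole replicates are rejection-resampled
until the realised frequency falls within `freq_tol` of the target (bounded
by `max_attempts`, with a clear error on exhaustion). Conditioning on the
realised frequency is the only selection applied; the within-run drift
dynamics are untouched, and with the target disabled the allele-frequency
trajectory is a martingale (verified by a 200-replicate t-test in the
suite).

**Defaults.** 40 founders, 8–10 generations with geometric growth,
uniform 1 cM/Mb map over 10 Mb, background marker minor-allele frequencies
uniform on (0.1, 0.5) (informative, array-like markers), genotype error 1%
(miscalls uniform over the two wrong dosage values), missingness 0. The
demography is illustrative — the real villages' history (a
sixteenth-century settlement of a few hundred people) is not documented at
parameter level, so defaults were chosen once to produce the qualitative
isolate signature: extensive haplotype sharing, a rare allele at ~2%, deep
cryptic relatedness.

**Traits.** `trait = mean + β·copies + polygenic + residual`, the polygenic
component drawn with covariance proportional to the supplied kinship matrix
(normalised to unit mean diagonal; non-PSD matrices rejected). β is either
given directly or derived from a target variance fraction via
`VE = 2f(1−f)β_std²` at the realised allele frequency. Defaults mirror a
serum HDL scale (mean 1.265, SD 0.35 mmol/l) with VE 2.9% and polygenic
h² 0.3.

**What the simulator does not emulate.** Mutation, selection, migration and
population merging; sex chromosomes; realistic site-frequency spectra
(background markers are common by construction); genotyping-batch artefacts
beyond uniform error; age/sex covariate structure. Tests passing on these
cohorts therefore certify the algorithms under the stated model, not
performance on any real cohort.

## Staged genotype QC (`isoshare.qc`)

Stages run in a fixed order: call-rate prefilter at 0.90 on both axes →
sample call rate 0.98 → heterozygosity outliers, computed separately over
rare (MAF < 1%) and common (MAF ≥ 1%) variants → variant call rate 0.95 and
Hardy–Weinberg exact filter at p < 1e-4 → final variant call rate 0.99 →
removal of samples that are sole minor-allele carriers at more than 100
variants → final Hardy–Weinberg pass. All inequalities are strict; filters
only drop rows/columns and never edit genotype values; monomorphic variants
have Hardy–Weinberg p = 1 by convention and are never removed by that
filter.

The heterozygosity-outlier cut-off is ±3 SD by default. An SD-based rule
re-estimates its own reference distribution, so repeated application keeps
trimming the tails; the pipeline is a fixed point only with respect to its
threshold-based filters.

## Phenotype preparation (`isoshare.traits`)

Fixed order: unit harmonisation → Friedewald LDL (`LDL = TC − HDL − TG/5`,
computed in mg/dl, missing where TG > 400 mg/dl) → 5-SD outlier removal
(single pass, strict inequality, mean/SD from the non-missing input) →
transformation → dichotomisation (HDL ≥ 60 mg/dl high, < 40 mg/dl low).
The inverse-normal transform uses Blom normal scores
`Φ⁻¹((r − 3/8)/(n + 1/4))` with average ranks for ties; conversion factors
are 38.67 mg/dl per mmol/l for cholesterol fractions and 88.57 for
triglycerides.

## Linear mixed model (`isoshare.lmm`)

Kinship is the centered genotype relatedness matrix `K = WWᵀ/p` with columns
`x − 2f` and per-variant mean imputation of missing calls (for this
computation only).

The association model `y = Wα + xβ + u + ε`, `u ~ N(0, σ_g²K)`,
`ε ~ N(0, σ_e²I)` is fitted by full maximum likelihood: after rotating by
the eigenvectors of K the covariance is diagonal in `λ = σ_g²/σ_e²`, and the
profile likelihood of `log10 λ` is maximised on [−5, 5] by a 21-point coarse
grid followed by bounded scalar minimisation in the bracketing interval
(verified against a 1,001-point grid to 1e-4 in log-likelihood). ML rather
than REML is used so that likelihood-ratio statistics of nested models are
directly comparable; p-values are `χ²(1)` on `2(ll_alt − ll_null)` with the
null re-optimised without the variant. Standard errors come from the GLS
information at the optimum with the ML variance estimate (slightly
downward-biased at small n, as usual for ML). The eigendecomposition is
computed once per kinship matrix and complete-case pattern and cached;
exactly diagonal kinship skips the decomposition. Rows with missing trait,
covariate or dosage are dropped, not imputed. Binary traits are analysed by
the same linear mixed model on the 0/1 scale (a linear probability model
under kinship); the effect is reported as a per-allele risk difference and,
for presentation, exponentiated with a Wald 95% interval. A singular design
(e.g. conditioning a variant on itself) falls back to the pseudoinverse with
a collinearity warning.

Calibration at study scale is part of the acceptance suite: type-I error at
nominal 0.05 over 1,000 null replicates (n = 300 with genuine kinship
structure) within the binomial confidence band, and ±2·se coverage of a true
per-allele effect of 0.882 standardised units at MAF 0.019, h² = 0.3
(n = 2,000, 200 replicates).

## Surrogate-parent haplotype sharing (`isoshare.sharing`)

**Hidden chain.** For a target individual the hidden state is a pair of
surrogate parents drawn from a candidate set (by default all samples, or all
with kinship < 0.2 to the target when a kinship matrix is supplied). The
state is implemented as an ordered (left, right) slot pair with symmetric
emissions, which is the same model as an unordered pair plus a deterministic
tie-break; slots may coincide after switches.

**Emission.** Each surrogate transmits one allele drawn uniformly from its
genotype (dosage g transmits the alternate allele with probability g/2;
missing surrogate genotypes transmit either allele with probability 1/2).
The implied true target genotype is observed through a miscall channel with
error ε (default 1%), uniform over the two wrong dosage values; missing
target genotypes emit probability 1.

**Transition.** Between adjacent variants separated by d Morgans each slot
independently switches with probability `1 − exp(−switch_rate·d)`
(`switch_rate` 1 per Morgan by default, exposed because the proportionality
constant between map distance and surrogate turnover is a modelling choice)
and redraws uniformly from the candidate set.

**Decoding.** Viterbi in log space throughout. The factorised transition
allows each step in O(states) using row/column/global maxima (both-stay,
one-switch, both-switch cases). Ties break deterministically toward keeping
the current surrogates and toward the lowest candidate index. The decoder is
verified against exhaustive path enumeration on randomised instances with up
to 5 variants and 4 candidates.

**Segments.** The shared segment around a focal position is the maximal run
of variants over which the focal-side slot is unchanged, reported in closed
1-based coordinates at the outermost compatible variants (never extrapolated
into untyped gaps; BED export converts to 0-based half-open). The
independent cross-check, `maximal_identity_pair`, scans outward from the
focal variant and returns the longest interval containing it with at most
`max_mismatch` opposite-homozygote sites — the only genotype configuration
incompatible with sharing one haplotype.

**Generations to the common ancestor.** If the target and its nearest
genealogical neighbour coalesce G generations back, 2G meioses separate
them, so the shared segment extends left and right by independent
Exponential(2G per Morgan) distances and its total length is
Gamma(2, 2G). The MLE is `Ĝ = 1/mean(lengths in Morgans)`; since
`2G·n·mean ~ Gamma(2n, 1)`, the confidence interval is
`[q_{α/2}, q_{1−α/2}]/(2n·mean)` with Gamma(2n) quantiles. The estimator is
scale-consistent and recovers G = 4.1 within [3.6, 4.6] in ≥95% of
replicates of 500 lengths.

**Carrier comparison.** Carrier vs non-carrier segment lengths at the focal
grid point are compared with the two-sample Kolmogorov–Smirnov test
(scipy's exact small-sample method where applicable). Excess carrier
sharing is the per-grid-point difference of mean carrier and mean
non-carrier lengths, binned by genetic distance from the focal site; a decay
rate is fitted by least squares on the log of the positive excess and left
undefined when no bin is positive.

## Variant-level statistics (`isoshare.variant_stats`)

- **Hardy–Weinberg exact test:** conditional on allele counts, the
  probability of each heterozygote configuration is computed by log-gamma
  weights and the two-sided p sums configurations no more probable than the
  observed one (a 1e-12 relative tolerance guards floating ties).
  Monomorphic → p = 1. Verified against exact-integer enumeration for every
  table with up to 50 samples.
- **EM linkage disequilibrium:** two-locus haplotype frequencies start at
  linkage equilibrium and iterate over the double-heterozygote phase split
  until the largest frequency change is below 1e-10 (cap 1,000 iterations);
  the log-likelihood is asserted non-decreasing at every step. D′ = |D|/Dmax
  with the sign-appropriate Dmax; r² = D²/(f_A f_a f_B f_b). Deterministic,
  so no seed.
- **Pairwise IBD:** method-of-moments on identity-by-state counts given
  sample allele frequencies, clamped and normalised to the simplex;
  π̂ = P(IBD1)/2 + P(IBD2). No small-sample allele-frequency correction is
  applied (cohort frequencies are assumed well estimated).
- **Fisher's method:** `X² = −2Σln p` on `χ²(2k)`; permutation-invariant,
  identity for k = 1.
- **Power:** the per-individual non-centrality of a single-variant test
  equals the variance explained, giving
  `N = ⌈(z_{1−α/2} + z_{power})²/VE⌉` with genome-wide α = 5×10⁻⁸ by
  default. This is a normal-approximation design calculation; treat its
  output as order-of-magnitude.
- **Allele age:** the neutral (Kimura–Ohta) expected age of an allele at
  frequency p, `−4·Ne·p·ln(p)/(1−p)` generations, with Ne = 10,000 and
  25 years per generation by default. It is a frequency-only stand-in for
  haplotype-based dating and is reported with that caveat.
- **Span arithmetic:** closed-coordinate spans in bp with kb floored
  (571,082 bp reports as 571 kb).

## Problem sizes

The test suite and acceptance script are sized for a single CPU: simulated
cohorts of 200–1,267 samples with 40–300 markers; 1,000 null and 200 effect
replicates for LMM calibration (n = 300 and 2,000); 200 randomised Viterbi
enumeration instances (≤5 variants, ≤4 candidates); exhaustive
Hardy–Weinberg verification to 50 samples; 1,000 random LD tables. These
sizes keep full runs in the tens of seconds while leaving every statistical
check well-powered.

## Known limitations

- The surrogate-parent HMM scales as O(candidates²) per variant; for
  cohorts beyond a few hundred candidates, restrict the candidate set (the
  kinship cap does this naturally).
- ML standard errors are slightly anticonservative at small n; the LRT, not
  the Wald ratio, is the primary test.
- The binary-trait model is a linear probability model, not logistic; rare
  outcomes with strong covariate effects can yield fitted probabilities
  outside [0, 1].
- The power and allele-age models are deliberately simple closed forms and
  should not be quoted beyond order of magnitude.
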