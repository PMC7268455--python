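# Methods

This note documents the statistical model behind each module, the defaults
and why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself compute.

## Data model and units

A summary-statistics table carries, per SNP: identifier, chromosome,
1-based position, effect and other allele (A/C/G/T, upper-cased on read),
effect-allele frequency in (0,1), per-allele effect `beta` (log odds for
binary traits, SD units for continuous traits), its standard error,
two-sided p-value and sample size. Canonical column names are
`SNP CHR POS EA OA EAF BETA SE P N`; a user column map handles other
dialects. Hard invariants (positive SE, distinct valid alleles, frequency
and p-value in range) drop the offending row and are counted per reason;
the p-value-vs-(beta/se) consistency check only warns, because public GWAS
files are rounded. p = 0 is floored to the smallest positive double since
downstream code takes logs and normal quantiles. Duplicated identifiers
keep the first occurrence (the provenance of duplicates in source GWAS is
generally unknowable from the file alone).

## Synthetic two-sample generator

For SNP *j*: frequency p*ⱼ* ~ U(0.05, 0.95); instrument effect
γ*ⱼ* ~ N(μ_γ, σ_γ); direct (pleiotropic) outcome effect α*ⱼ* per model —
`none` (0), `balanced` (mean 0), `directional` (mean ≠ 0), or
`inside_violating` (correlation ρ with γ, violating InSIDE); optionally only
a fraction `pleio_frac` of SNPs carry pleiotropy (invalid instruments).
The true outcome effect is Γ*ⱼ* = β·γ*ⱼ* + α*ⱼ*. Observed effects add
independent Gaussian noise at the SE implied by the per-allele variance
approximation `se = 1/sqrt(2p(1−p)n)`, with binary traits scaled by
`1/sqrt(cf(1−cf))` for case fraction cf. This matches how real GWAS SEs
scale with frequency and sample size, and makes consortium splitting obey
exact variance arithmetic. Everything is generated directly on the summary
scale — no individual-level sampling — for speed; an individual-level path
exists only for the genotype panel below.

Defaults mirror a desk-scale glioma-type study: 50 instrument SNPs, an
exposure GWAS of n = 100,000, and a case-control outcome GWAS of n = 11,240
with 5739 cases (case fraction 0.51). Instrument strengths default to
γ ~ N(0.04, 0.01), which puts individual SNPs near genome-wide significance
at that exposure sample size.

`split_consortia` decomposes one GWAS into sub-studies conditionally: study
*i* gets SE/√fraction and effect `beta + ξᵢ − Σwξ/Σw` with ξᵢ drawn at the
sub-study SE and w the inverse-variance weights. Each split then has the
correct marginal sampling variance while the fixed-effects meta-analysis of
the splits reproduces the pooled GWAS *exactly* — the natural consistency
requirement for testing the meta-analysis module. (Adding independent noise
without the centering term would inflate the pooled-after-meta variance by
~50% and show up directly as λGC ≈ 1.5 on null data.)

The LD panel uses an exchangeable copy model per block: each haplotype
allele copies a latent block haplotype with probability `within_r2^0.25`,
else draws fresh at the block frequency; all within-block dosage pairs then
correlate at r² ≈ the target, and r² = 1 duplicates columns exactly. SNPs
within a block share the block's frequency — mixing frequencies inside a
block would distort the target correlation. This panel supports clumping
and PRS tests; it does not emulate realistic human LD maps, recombination
hotspots, or allele-frequency/LD coupling.

LD-score inputs draw χ²*ⱼ* = z², z ~ N(√(E[χ²]−1), 1) with
E[χ²] = intercept + N·h²·ℓ*ⱼ*/M — the sampling model of a GWAS z statistic
(a mean below 1 falls back to a scaled central χ²). LD scores are uniform
on (1, 200).

**What passing tests do and do not show.** The generator reproduces the
*statistical* structure the estimators assume (independent samples,
per-allele SE scaling, pleiotropy configurations, block LD). It does not
model sample overlap, population stratification, imputation error,
winner's-curse selection of instruments, liability-scale subtleties of the
binary outcome, or realistic LD. Calibration and recovery results therefore
validate the implementation, not robustness of MR to those real-data
complications.

## Meta-analysis, λGC, LDSC

Fixed-effects inverse-variance combination: w = 1/se², pooled beta the
weighted mean, pooled SE `1/sqrt(Σw)`, across-study heterogeneity
Q = Σw(β−β̄)². Alleles are aligned to the first study's frame by the same
swap/flip rules as instrument harmonization; irreconcilable SNPs are
excluded and logged. λGC = median(χ²)/0.4549 (the 1-df χ² median).

LDSC regresses χ² on ℓ; slope·M/N estimates h², the intercept absorbs
confounding/inflation. Default weighting is inverse squared predicted mean
(1/(2(1+sℓ)²)), iterated twice from an OLS start — the standard variance
stabilisation for heavy-tailed χ²; plain OLS is available and is exact on
noiseless toy input. SEs come from a delete-one block jackknife over 200
contiguous blocks (fewer when M < 200). The weighting/jackknife settings
are package choices; published analyses rarely state them.

## Instruments

Selection keeps rows with P strictly below 5e-8 (the conventional
genome-wide threshold); clumping is greedy — keep the lowest-p remaining
SNP, discard all remaining SNPs with r² ≥ 0.001 against it — with
deterministic tie-breaks (p, chromosome, position, id) and missing LD pairs
treated as r² = 0 with a logged warning. Strict inequalities at both
thresholds. Harmonization matches by identifier: identical coding keeps the
pair; swapped coding negates the outcome beta and complements its
frequency; strand-complement codings are resolved the same way for
unambiguous SNPs. Palindromic (A/T, C/G) SNPs are kept only if both
datasets' aligned frequencies fall on the same side of 0.5 and outside
(0.42, 0.58) — a widely used frequency-inference rule; the limit is a
parameter. No LD-proxy search is attempted for SNPs missing from the
outcome; they are dropped and audited. Instrument variance explained uses
the per-SNP pseudo-r² z²/(z²+n), summed across (post-clumping,
approximately independent) SNPs.

## Estimators

Formulas as in the README. Numerical conventions:

- 95% CIs are beta ± z₀.₉₇₅·se everywhere except where a bootstrap is the
  stated SE source; p-values are two-sided normal.
- The multiplicative random-effects inflation √max(1, Q/(J−1)) is floored
  at 1 — overdispersion never *shrinks* an SE (standard conservative
  convention). Same for Egger with Q′/(J−2).
- Egger orients every pair to γ ≥ 0 before fitting (required for the
  intercept's interpretation), refuses J < 3, and rejects collinear designs
  (no spread in instrument strengths) via a condition-number check.
- WME weights are γ²/se(Γ)² (inverse first-order ratio variance); the
  estimate interpolates between the two ratios whose cumulative midpoint
  weights straddle 0.5. SEs for WME and MBE come from a seeded parametric
  bootstrap (resampling γ̂, Γ̂ from their sampling normals; normal-theory
  SE from the bootstrap SD; 1000 draws by default).
- MBE bandwidth is φ·0.9·min(sd, 1.4826·MAD)·J^(−1/5) with φ = 1;
  the KDE argmax is located on a fixed 1024-point grid spanning the ratio
  range ± 3 bandwidths. A degenerate (zero) bandwidth falls back to the
  weighted median. The NOME-assumption MBE variant is out of scope.
- Binary-exposure odds ratios are raised to the power ln 2 (per doubling of
  exposure odds); the code stores the exact constant, which prints as 0.693
  at three decimals.

## Sensitivity battery

Cochran's Q uses the ratio form (identical algebraically to the weighted
regression residual around the fixed-effects IVW); Rucker's Q′ is the
weighted residual sum of squares of the Egger fit, so Q′ ≤ Q always, and
Q − Q′ with 1 df flags directional pleiotropy. Radial IVW regresses
β√w on √w through the origin — the slope *is* the fixed-effects IVW — and
flags SNP j when its contribution q*ⱼ* exceeds the χ²₁ upper-α point with α
Bonferroni-divided by J (configurable off). Leave-one-out re-runs the
multiplicative random-effects IVW. Steiger compares instrument variance
explained in exposure vs outcome via Fisher's r-to-z with 1/(n−3)
variances; for a binary outcome the z-based quantity is a pseudo-r² on the
log-odds scale and the result is flagged accordingly (a liability-scale
correction is out of scope).

Concordance labels: a sensitivity estimator is `uncertain` when its p ≥
0.05; otherwise `agree` when its effect direction matches IVW *and* the two
95% CIs overlap, else `disagree`. "Magnitude agrees" has no standard
definition; CI overlap is the documented operationalisation, with a
sign-only mode available.

## PRS, power, tiers

The summary-statistic PRS association is, by construction, the instrument
pipeline at a relaxed threshold (P < 1e-5, clumped at r² < 0.001) followed
by *fixed-effects* IVW; at the strict threshold it reproduces the strict
instrument's fixed-effects IVW bit for bit. It assumes no pleiotropy and is
correspondingly more susceptible to false positives — its type-I error is
only calibrated under no pleiotropy.

Analytic power treats the IVW z statistic as normal with mean
`b = sqrt(n·R²·cf(1−cf))·|β|` for a binary outcome (case fraction cf;
omitting cf gives the continuous-outcome version `b = sqrt(n·R²)·|β|`).
Two-sided power at level α is Φ(b−z₁₋α/₂) + Φ(−b−z₁₋α/₂), which equals α
at β = 0 and is monotone in n, R² and |β|. The two-tail form (rather than
the common one-tail approximation) is what matches the empirical rejection
rate of the two-sided fixed-effects IVW test, and the formula is
cross-validated against simulation rather than against any publication's
text. Family-wise thresholds: strict = 0.05/m (full precision is reported;
for m = 36 this is 1.389e-3, often quoted rounded to 1e-3), suggestive
band [strict, 0.05).

## Study runner

`run_study` meta-analyses the outcome consortia once, then per exposure:
select → clump → harmonize → multiplicative random-effects IVW → OR scale →
tier. Rows at the suggestive tier or better (or all rows, with
`force_sensitivity`) get Egger/WME/MBE concordance labels and Cochran's Q;
every row gets Steiger and post-hoc power (at the row's own IVW estimate).
Exposures whose instrument cannot be built become `skipped` rows with the
reason, never a crash. All bootstrap seeds derive from the config seed plus
the exposure index, so identical configs produce identical output bytes.
Subtype analyses (e.g. all-glioma / glioblastoma / non-glioblastoma) are
separate configs over different outcome files, not a special code path.
There is no console-script CLI: the library functions plus the `examples/`
scripts are the interface, matching how such analyses are driven in
practice.

## Validation scenarios (sizes chosen as package defaults)

- Null calibration: 1000 replicates of the default null scenario (J = 50,
  β = 0); the multiplicative random-effects floor makes the test slightly
  conservative, so empirical rates run a little below 0.05.
- Recovery: β = 0.3 with strong instruments (γ ~ N(0.1, 0.03),
  n_exp = 200,000) over 200 replicates — strong instruments keep
  weak-instrument (regression-dilution) bias in Egger well below the
  Monte-Carlo resolution.
- Pleiotropy robustness: 40% invalid instruments with directional
  α ~ N(0.04, 0.01) and large samples on both sides (500,000), so the
  contamination is well separated from ratio noise — the regime in which
  the weighted median's validity condition holds. The WME's mean stays
  within its reported uncertainty of the truth while the IVW mean shifts by
  several of its own SEs; the residual small WME bias is the known
  finite-sample quantile shift of a weighted median under asymmetric
  contamination and shrinks with the noise scale.
- Steiger: instrument R² ≈ 0.02 (γ ~ N(0.032, 0.008), n_exp = 100,000)
  against the outcome's pseudo-R² ≈ β²R², 500 replicates.
- Power cross-check: analytic power evaluated at the ensemble-mean realized
  R² vs the fixed-effects IVW rejection rate over 2000 replicates (the
  formula models fixed-effects precision; the MRE variant is by design more
  conservative).
- LDSC: h² = 0.3, intercept 1, N = 20,000, M = 50,000 in the acceptance
  script (10,000 in tests), recovered within block-jackknife SEs.

## Known limitations

Proxy-SNP lookup, MR-PRESSO, multivariable MR, contamination-mixture
estimators, bivariate LDSC genetic correlation, funnel plots and I² are not
implemented. The Steiger pseudo-r² for binary outcomes is uncorrected for
liability scale. The generator's limitations are listed above; in
particular, instrument selection on the *same* exposure data that is then
used for estimation (winner's curse) is faithful to real practice but means
selected γ̂ are slightly inflated in weak-instrument regimes.
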