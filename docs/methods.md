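# Methods

## Model and procedure

The package evaluates paired (pre/post) cohorts of four visual-function
examinations and produces, per subject, a single composite efficacy score.
The analysis sequence is:

1. **Difference scores.** For each subject, post-minus-pre differences of
   amblyopic-eye logMAR acuity, the *interocular* binocular-rivalry balance
   gap, horizontal perceptual eye position (PEP, degrees) and ordinal
   stereo level. Differencing (rather than using post-treatment state)
   encodes that efficacy depends on where a patient started: a mild case
   completely cured moves little and scores modestly by design.
2. **Screening.** Each indicator's differences get a paired *t* test
   (two-sided, sample SD with n−1 denominator). Vertical PEP is carried
   through parsing and reporting but never coupled: its change is not
   reliably different from zero in the reference cohort (|t| ≈ 1.5,
   p ≈ 0.14), and the package keeps that exclusion as the default.
3. **CRITIC weighting** on the m×4 difference matrix: Z-score
   standardization, variation coefficients v_j, Pearson correlation R,
   independence coefficients η_j = Σ_k(1−|r_kj|) (the k = j self-term is
   included and contributes 0, so η_j ∈ [0, n−1]), information volumes
   D_j = |v_j|η_j, weights ω_j = D_j/ΣD_j.
4. **Coupling index.** Differences are benefit-oriented (acuity, rivalry
   gap and PEP are cost-type and negated; stereo is benefit-type), min–max
   normalised per column across the cohort being scored, and combined as
   CI_i = Σ_j ω_j u_ij.

## Assumptions

- Exactly one pre and one post battery per subject; no imputation beyond
  flagging a missing cell.
- The interocular rivalry gap is the *absolute* level difference |L−R|,
  making the index invariant to which eye is amblyopic. A signed
  (amblyopic-minus-fellow) gap is equally defensible on the available
  evidence; the absolute form was chosen because cohort files need not
  label the amblyopic eye.
- Pearson correlation, and hence CRITIC, treats the ordinal scales
  (rivalry levels, stereo levels) as interval-valued.

## Design choices where the design was open

- **Variation-coefficient convention.** The coefficient is defined as
  s_j/x̄_j, but every value in the reference summary tabulation equals
  x̄_j/s_j (e.g. −0.38/0.26 = −1.46). Both are implemented behind a
  `convention` switch; the default `"table"` reproduces the tabulated
  column exactly and is what the weights chain uses. The discrepancy is
  visible in every report (the convention is recorded on the result).
- **Magnitude policy.** Three of the four reference v values are negative;
  a literal product v_j·η_j would make information volumes and weights
  negative. The default takes |v_j|; a `"signed"` mode exists for fidelity
  experiments and is tested but not recommended.
- **Coupling formula.** The reference analysis reports per-subject coupling
  indices without stating the formula. This package's default — cohort
  min–max normalisation of benefit-oriented differences under CRITIC
  weights — is the normalisation native to the CRITIC literature and
  yields [0,1] scores of the same order as the reported ones (0.13–0.52).
  The reported values are therefore *not* reproduction targets; the
  orderings narrated for the validation cohort (S1 maximal; S5 below S4)
  are, and both hold under the defaults. A Z-score normalisation is
  available as an alternative.
- **Reference weights are constants, not targets.** The published weights
  (0.2154, 0.2575, 0.1724, 0.3547; 0.2221, 0.2643, 0.1633, 0.3504 with the
  validation subjects added) are not derivable from the published summary
  statistics under either convention or magnitude policy — the full chain
  from the tabulated summaries gives (0.4266, 0.2263, 0.1439, 0.2032) —
  so they live in `visioncouple.reference` purely for comparison, and a
  test asserts the non-derivability so the discrepancy stays visible.
- **Validation fixture.** One cell of the packaged validation cohort (S1's
  pre-treatment right-eye rivalry level) is not reliably recoverable from
  its source tabulation; it ships empty and flagged, and the loader can
  fill it with level 8, the only value consistent with that subject's
  recorded post-treatment levels and left-eye trajectory.

## Synthetic cohorts

Only first/second moments and the 4×4 correlation of the reference
difference scores are published, so the generator is the minimal-assumption
Gaussian model: correlated standard normals through a Cholesky factor of
the target correlation, rescaled to target SDs and means. Defaults are the
reference cohort's tabulated values (means −0.38, −1.48, −0.60, 0.85; SDs
0.26, 2.02, 1.31, 1.26; n = 46 in the emulated study). Discretized mode
snaps draws to each scale's legal grid (0.1-logMAR steps; integer levels
with stereo in [−4,4] and rivalry gap in [−7,7]) post hoc rather than via
ordinal latent thresholds — simpler, at the cost of a small correlation
bias that tests bound below 0.1 absolute at n = 10000.
`generate_cohort` further realises each difference as a legal pre/post
record pair (pre logMAR on the 0.1 grid in [0.1, 1.0], eye levels 1–8 with
a phase-stable fellow eye, PEP in [0, 3]°, stereo 0–4), clipping the
difference to what the grids admit; the realised (clipped) difference
matrix is returned and recovered exactly by the difference-score code.
Vertical PEP drifts by N(−0.07, 0.31) per subject, emulating the slight
non-significant decrease of the reference cohort.

What synthetic cohorts do **not** emulate: treatment-duration, age and
adherence effects; non-Gaussian tails; any dependence between a subject's
baseline severity and their difference scores. Passing recovery tests
shows the pipeline is correct under the published moment structure, not
that the Gaussian model captures real amblyopia cohorts.

## Numerical choices

- Sample (n−1) SDs everywhere; two-sided p-values from Student's t.
- Correlations computed on the standardized matrix (equal, to rounding, to
  raw-data Pearson correlation; a test asserts entrywise agreement at
  1e−12) and clipped into [−1, 1] against floating-point excursions.
- Degenerate inputs fail loudly with dedicated error classes: zero-variance
  columns (standardization, correlation, paired t), all-zero information
  volumes, constant columns under min–max normalisation, cohorts smaller
  than 3 subjects, non-positive-definite target correlations.
- Ranking ties break lexicographically by subject id for determinism.
- Numbers serialise at full precision; rounding is display-only.

## Problem sizes used in validation

Moment/correlation recovery is checked at n = 10000 (means within ±0.05,
SDs within 3%, correlations within ±0.03) and the acuity–rivalry
correlation additionally at n = 5000 (±0.03); the Monte-Carlo band of the
rivalry |t| at n = 46 is checked across 200 seeds; oracle equivalence of
the CRITIC chain against an independent loop-based implementation is
checked on random 8×4 matrices at 1e−10.

## Known limitations

- Equal-interval treatment of ordinal scales is an approximation; with
  only five stereo levels the difference scores are coarse.
- Min–max coupling scores are cohort-relative: indices from different
  cohorts are not directly comparable.
- The generator's post-hoc discretization slightly attenuates target
  correlations for the integer-valued indicators.
- One-sided clinical covariates (age, treatment duration, adherence) are
  out of scope.
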