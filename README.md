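# visioncouple

Quantifying amblyopia treatment efficacy from a *battery* of visual-function
examinations rather than from visual acuity alone.

Amblyopia therapy (here: dichoptic push–pull perceptual training) changes
several aspects of vision at once — acuity of the amblyopic eye, interocular
suppression, cortical eye-position control, stereopsis — and these changes do
not track each other across patients. `visioncouple` implements a composite
per-subject efficacy score that couples four pre/post difference scores with
objective weights, for ophthalmology researchers and biostatisticians
analysing paired treatment cohorts.

## The method

For each subject, four post-minus-pre difference scores are formed:

| indicator | scale | improvement |
|---|---|---|
| visual acuity (amblyopic eye) | logMAR | negative Δ |
| binocular rivalry balance point | interocular level gap, 0–7 | negative Δ |
| horizontal perceptual eye position | degrees | negative Δ |
| stereoacuity | ordinal level 0–4 (none…100″) | positive Δ |

Each indicator is screened with a paired *t* test, *t* = d̄ / (s_d/√n).
Weights then come from the **CRITIC** algorithm (Criteria Importance Through
Inter-criteria Correlation), computed from the cohort's m×n difference
matrix X = (x_ij):

1. Z-score standardize: x*_ij = (x_ij − x̄_j)/s_j, with sample SD s_j;
2. variation coefficient v_j (contrast intensity) — the definitional form
   s_j/x̄_j and the tabulated reciprocal form x̄_j/s_j are both available;
3. Pearson correlation matrix R = (r_kl) of the indicators;
4. independence coefficient η_j = Σ_k (1 − |r_kl|) (conflict);
5. information volume D_j = |v_j|·η_j and weights ω_j = D_j / Σ D_j.

Finally each subject's **coupling index** is CI_i = Σ_j ω_j·u_ij, where u_ij
are the benefit-oriented difference scores (cost-type indicators negated)
min–max normalised per column across the cohort, so CI ∈ [0, 1] with 1 =
best-in-cohort on every indicator.

Because no raw per-subject data accompany the reference cohort, the package
includes a seeded Gaussian generator that reproduces its tabulated means,
SDs and 4×4 correlation structure, in continuous or grid-discretized form,
down to fully legal pre/post examination records.

## Worked example

```python
from visioncouple import load_validation_cohort, run_full_report

report = run_full_report(load_validation_cohort())
print(report.critic.weights_by_label())
for rank, s in enumerate(report.ranking(), start=1):
    print(rank, s.subject_id, round(s.ci, 4))
```

On the packaged 8-subject validation cohort this prints

```
CRITIC weights:
  visual_acuity   0.4301
  brbp            0.2395
  horizontal_pep  0.2468
  stereoacuity    0.0836

coupling-index ranking:
  1. S1  CI = 0.7664
  2. S2  CI = 0.6234
  3. S4  CI = 0.5326
  4. S3  CI = 0.4308
  5. S5  CI = 0.3225
  6. S7  CI = 0.2477
  7. S8  CI = 0.2435
  8. S6  CI = 0.1562
```

S1 — who improved on all four indicators at once (logMAR 1.00→0.10, rivalry
gap 4→1, PEP 1.2°→0.64°, stereo 400″→200″) — tops the ranking, and S5, a
milder case that was nearly balanced before treatment, scores below S4
despite a similar post-treatment battery: the index rewards *change*, not
final state. The scripts in `examples/` walk through each capability
(scale encodings, the weighting chain, cohort scoring, parameter recovery).

A thin CLI mirrors the library: `visioncouple simulate|weights|score|report`
(CSV cohorts in, JSON reports out; see `--help`).

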