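# Methods

This note documents the generative model behind the synthetic cohort, the
definition of every derived index and statistic, the numerical conventions,
and the design choices that were genuinely open. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Stimulation protocol

Twenty tonic heat stimuli, 30 s at target temperature with 30 s
inter-stimulus interval at a 35 °C baseline, ramped at 1 °C/s, in the fixed
pseudorandomized order

    36 44 48 46 46 44 36 48 46 48 36 44 48 44 36 46 36 44 48 46   (°C)

Each of {36, 44, 46, 48} appears five times. 36 °C is the non-noxious
control. The order makes the 46 °C target appear once after 36 °C
(low-contrast), three times after 48 °C (high-contrast) and once after
46 °C (neither condition) — that asymmetry is what the contrast indexes
exploit. The analysis window is the 30-s plateau; t = 0 is plateau onset
and the ramp duration is carried on each trace as `window_onset_s`, so a
ramp-inclusive reanalysis remains one flag away. Whether the original
window included the ramp seconds is not decidable from the protocol
description alone; plateau-onset is the convention implemented.

## Trace model (synthetic cohort)

### Traits

Facet scores are simulated directly on the T-score scale (mean 50, SD 10)
— item-level questionnaire simulation would add nothing testable. Each
domain contributes one latent factor; facet z-scores are
`z = sqrt(r) g_d + sqrt(1-r) e` with within-domain correlation r = 0.4 and
zero cross-domain correlation. A domain score is the **sum** of its six
facets (NEO scoring convention; the aggregation is then standardized
wherever a domain z-score is needed).

Attachment prototype ratings arise from a unit-variance latent
`lat_p = Σ_d w_pd z(domain_d) [+ β_C5→sec z(C5) for secure] + resid·ε`,
mapped to the 7-point scale by `round(4 + 1.5·lat)` and clipped to [1, 7].
Loadings whose systematic variance exceeds 1 raise a configuration error
naming the prototype. The secure-N, secure-E and preoccupied-N loadings
are calibrated (below); the dismissing and fearful defaults (low
extraversion; high neuroticism with low extraversion, respectively) are
plausible values in the same convention and carry no calibrated claim.

### Ratings

During stimulus j at temperature T, participant i's rating is

    V(t) = clip_[0,100][ μ(T) + s_i(T)·t + shift_ij + offset_i + ε(t) ]

* `μ(T)` — plateau baseline rating, nondecreasing in T, ≈ 0 at 36 °C.
* `s_i(T) = s0(T)·(1 + h·u_i) + β_N6→tai·z(N6) − β_C5→tai·z(C5)` —
  sensitization slope (VAS/s); `u_i ~ N(0,1)` is a participant factor with
  heterogeneity h = 0.8, shared across temperatures (sensitization-prone
  individuals are so at every level). The control temperature gets slope 0.
* `shift_ij = ±γ_i/2` on 46 °C trials only: + after 36 °C, − after 48 °C,
  so the measured contrast magnitude estimates γ_i. The generative
  mechanism is an assimilation-style rating shift on the plateau, not a
  slope change — the phenomenon constrains the sign pattern, not the
  mechanism, and a shift is the simplest form that reproduces it.
  `γ_i = γ0 + β_N6→con·z(N6) + β_sec→con·z(secure latent) + σ_γ η_i`.
* `offset_i ~ N(0, 8²)` on noxious trials — between-participant
  responsiveness offset.
* `ε(t)` — stationary AR(1) rating jitter (marginal SD 5) plus white
  measurement noise (SD 2). The AR coefficient is specified as the lag-1
  autocorrelation at the 100 Hz reference rate (0.98, correlation time
  ≈ 0.5 s) and converted to other rates as `φ(dt) = 0.98^(dt/0.01)`, which
  makes every epoch-mean variance — hence every calibrated population
  correlation — invariant to the simulation rate.

The between-participant dispersion terms (`u_i`, `offset_i`, `σ_γ`) are
required for the couplings to have well-defined population correlations
below 1; without them a trait coupling, however small, would dominate the
index variance.

Traces default to 100 Hz, a decimated stand-in for 1000 Hz hardware, with
a config switch (`sample_rate_hz`); simulation studies in the test suite
run at 10 Hz, which the suite itself shows changes epoch means by < 0.1
VAS units. Reproducibility: one master seed; participant i draws from
streams keyed `(i, purpose)`, so enlarging a cohort never reshuffles
earlier participants, and a single trace simulated alone is bit-identical
to the same trace inside a cohort run.

### Calibration

Coupling constants are not free knobs: they were fixed once by iterated
large-cohort simulation so that measured *population* quantities match the
study's anchor values, then frozen into `GeneratorConfig` defaults:

| quantity (population) | target |
|---|---|
| group epoch means at 44 °C (A, C) | 7.52, 12.20 |
| group epoch means at 48 °C (A, C) | 24.62, 62.73 |
| mean TAI at 46 °C | 18.2 |
| low/high-contrast condition means | 30.45 / 12.31 |
| Spearman ρ(N6, contrast magnitude) | +0.15 |
| Spearman ρ(C5, TAI@46) | −0.14 |
| Spearman ρ(N6, TAI@46) | +0.12 |
| Spearman ρ(secure, N), ρ(secure, E), ρ(preoccupied, N) | −0.30, +0.41, +0.40 |

Calibration is empirical (simulate, compare, rescale) because the 0/100
clamping and the 1–7 rating discretization attenuate correlations in a way
no closed form captures. One deliberate non-target: the generator routes
self-discipline's contrast effect purely through the mediated
C5 → secure → γ path, and a purely mediated effect cannot be made as large
as the anchor ρ(C5, ΔV) ≈ −0.11 without an implausibly large C5–secure
correlation; the direct N6 path takes calibration precedence.

Two scenario constructors encode mediation ground truths with deliberately
strong couplings (standardized a ≈ 0.55, b ≈ −0.40, or direct ≈ 0.35):
at n = 534 the causal-steps classifier cannot reach ≥ 90 % correct
classification at anchor-sized effects (the step-1 test alone has < 70 %
power at |c| ≈ 0.11), so classifier validation and anchor-sized effect
recovery are separate studies with separate configs.

### NRS reports and exclusion

Honest post-session reports are `NRS = mean 46 °C VAS / 10 + N(0, 0.5)`
clipped to [0, 10]. Exactly `n_discrepant` participants (default 4 of
538, selected deterministically from the master seed) are planted with a
±4.5-point offset. The exclusion filter removes participants with
`|VAS/10 − NRS| > 3.0`; the threshold is a config knob logged into every
report, since "significant discrepancy" admits no unique value. Missing
NRS ⇒ excluded with a distinct `missing_nrs` reason code.

## Signal processing

Denoising is a 1-s centered moving average (window shrinks symmetrically
at the edges: constant traces are fixed points and the output never leaves
the min/max envelope) followed by decimation to 10 Hz. This preserves the
10-s epoch statistics up to edge effects smaller than one window while
suppressing rating jitter. Epoch bounds are half-open on A and B and
closed at 30 s — a sample at exactly t = 10 s belongs to epoch B (tested)
— preventing double counting under the "0–10 / 10–20 / 20–30" phrasing.
An epoch with no samples after preprocessing rejects the whole stimulus,
which propagates to the exclusion reporting; there is no interpolation
across epochs.

## Indexes

Per-participant TAI at a temperature aggregates its five repetitions by
unweighted mean. The contrast-condition rating is the full 30-s window
mean taken as the equal-weight mean of the three epoch means ("average
pain intensity" fixes no window). With only one low-contrast trial in the
printed sequence the low-contrast mean is a single-trial estimate — a
protocol property, not an implementation choice; it inflates that
condition's sampling noise and is why the condition means, not per-trial
values, enter all statistics. Missing conditions yield missing markers
(NaN), never zeros. The sensitivity median split sends ties at the median
to the low group (deterministic); an all-identical cohort degenerates to
all-low with a warning.

## Statistics

All implemented directly (scipy supplies only t/F/normal tails, and the
Shapiro–Wilk routine used as the normality gate):

* **Spearman**: Pearson correlation of mid-ranks; ties get average ranks;
  p from t = ρ√((n−2)/(1−ρ²)) on n−2 df, two-sided; |ρ| = 1 ⇒ p = 0 by
  convention; constant input ⇒ undefined marker. Pairwise deletion, so n
  drifts across battery cells. (n ≥ 3 is accepted; the ±1 convention
  covers the 3-point edge case.)
* **BH-FDR**: q(i) = min_{j≥i} m·p(j)/j on the sorted scale, capped at 1.
  m counts the valid (non-missing) p-values of the family; the number of
  missing markers excluded is reported alongside. Families mirror the
  per-figure reporting structure: one family per (index × instrument) —
  35 NEO predictors, or 4 attachment prototypes. q < .05 is "significant",
  .05 ≤ q < .10 "trend".
* **Paired t**: zero-variance differences take a dedicated branch (t = 0,
  p = 1 if the mean difference is 0; ±∞ marker with p = 0 otherwise), each
  with a warning. Pairwise epoch contrasts are reported uncorrected.
* **Wilcoxon rank-sum**: mid-ranks, tie-corrected variance, 0.5 continuity
  correction; for combined n ≤ 12 the exact two-sided p by full
  enumeration of rank assignments is returned alongside (it is the oracle
  for the approximation).
* **RM-ANOVA + GG**: one-way within-subject F with the subject effect
  removed, listwise deletion; ε from the eigenvalues of the covariance of
  k−1 orthonormal contrast scores, clamped to [1/(k−1), 1]; corrected dfs
  ε(k−1) and ε(k−1)(n−1). The factorial temperature × epoch design is
  analyzed as per-temperature univariate RM-ANOVAs (the reported df
  pattern, e.g. df2 = 1066ε at n = 534, is the univariate one); no
  doubly-multivariate MANOVA is attempted.
* **Mediation**: three OLS fits on one complete-case sample; variables are
  z-standardized for classification (unstandardized B reported alongside);
  classification at α = .05 — "none" if a or b fails, else
  "no-total-effect" if c fails, else "partial"/"full" by c′. First-order
  Sobel SE only (no Aroian/Goodman variants); a percentile bootstrap CI
  for a·b is available as an optional extra diagnostic. No covariates
  (age/sex) enter by default. The identity c = c′ + a·b is asserted to
  1e−10 on every fit.

## Simulation-study problem sizes

The test suite's Monte Carlo studies use the 10 Hz trace rate and: 300
null cohorts of n = 100 (FDR control), 200 cohorts of n = 534 (effect-size
recovery and battery power), and 150 cohorts of n = 534 per mediation
scenario. `scripts/acceptance.py` uses 600 null replicates. Under the
all-null generator, BH yields E[V/max(R,1)] = α·m₀/m = .05 under
independence and ≤ .05 under the positive within-domain dependence used
here, so the measured value fluctuates around .05 with Monte Carlo SE
≈ √(.05·.95/R); the suite therefore tests against .05 + 2·SE.

## What the generator does and does not emulate

It reproduces the protocol's trial structure, clamped continuous rating
dynamics with realistic between-participant dispersion, trait→behavior
couplings of calibrated population size, and inconsistent-reporter
planting. It does **not** model thermode/skin physics, item-response
measurement of the questionnaires, age/sex effects, rating lag or
motor dynamics of the lever, or any coupling between overall sensitivity
and contrast susceptibility beyond what the shared trait structure
induces. Passing tests therefore certify the *pipeline* — index
arithmetic, error control, classifier behavior under known ground truth —
not any claim about human data.

## Known limitations

* The TAI couplings are additive in slope units while between-participant
  slope dispersion scales with s0(T); trait–TAI correlations are therefore
  calibrated at 46 °C and are larger at 44 °C / smaller at 48 °C than a
  temperature-invariant-ρ model would give.
* The low-contrast condition rests on a single trial per participant, so
  its mean carries one trial's AR-noise variance (~1 VAS unit SD).
* Clamping at 0 compresses the high-contrast condition's lower tail
  (floor-skew), which is realistic but makes analytic effect-size algebra
  inexact — hence the empirical calibration.
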