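# Methods

`haircort` analyses longitudinal hair cortisol: six 2-cm hair segments per
person, each integrating roughly two months of cortisol exposure (hair grows
~1 cm/month), giving a retrospective one-year time series at two-month
resolution. The package has two halves: an analysis pipeline (decline
correction → Fourier spectrum with a permutation null → cosinor
seasonality), and mechanistic models of the HPA axis whose simulated
cortisol is pushed through the *identical* pipeline. A synthetic cohort
generator makes every stage testable without any dataset.

## Synthetic cohort generator

Each participant i with segment midpoints t (years before collection) is

    C_i(t) = B_i · exp(−α_i t) · S(month(t)) · F_i(t) · ε

| component | default | meaning |
|---|---|---|
| `B_i` | lognormal, ln-sd 0.75 | between-person baseline (pg/mg). The expected log-range of 55 normal draws is ≈ 4.6 sd, so 0.75 gives a ~30-fold max/min cohort spread. |
| `α_i` | Normal(2.2, 0.5²) yr⁻¹, truncated at 0 | exponential decline of measured cortisol along the hair |
| `S` | 1 + 0.15·cos(2π(m − 1.5)/12) | seasonal factor, 15% amplitude, late-winter peak |
| `F_i` | CV 0.22 | slow biological fluctuations (see below) |
| `ε` | lognormal, CV 0.14 | multiplicative assay noise, σ_ln = √ln(1 + CV²) |

Noise is multiplicative/lognormal throughout because concentrations are
positive and assay error scales with level. The segment's time coordinate
is the *midpoint* of its growth window (the unbiased average position);
growth rate is fixed at 1 cm/month, with no per-person variation.

`F_i` supports three spectra, all specified as a log-scale Gaussian-ish
process scaled so the multiplicative factor has the requested CV:

- `single_frequency(f)` — a cosine at f (default 1 yr⁻¹) with a random
  phase per participant. This is the **default**, because the generator's
  job is to emulate the observed data, whose defining feature is a dominant
  detectable 1 yr⁻¹ component.
- `white` — independent per segment; used for null-calibration studies.
- `one_over_f` — spectral synthesis (harmonics of a 4-year period,
  amplitudes ∝ 1/f, random phases), window-averaged analytically over each
  2-month segment via the sinc attenuation. Note that almost all 1/f power
  lies below 1 yr⁻¹, where the decline correction removes it: such cohorts
  have realistic long-memory physiology but a *low* detectable residual CV.

Collection dates are uniform over a configurable calendar interval (the
actual distribution in real cohorts is unknown); the seasonal recovery
tests depend on dates spanning the year.

## Decline correction

Per participant, OLS of ln C on t: `ln C_j = ln B − α t_j + r_j`. The fit
is in log space (multiplicative model, positive data); residuals are
exactly zero-mean and orthogonal to the trend, which later makes the
correction idempotent — a property the permutation null relies on. A
nonlinear fit on the linear scale is deliberately not the default.

Fluctuation size is summarised as the per-participant CV of the normalized
series exp(r), averaged over the cohort, with assay noise removed in
quadrature: `cv_corr = √(cv_raw² − cv_assay²)`. If the assay CV reaches
the raw CV the subtraction raises instead of returning zero — that
indicates miscalibration, not absence of signal.

A **non-parametric variant** subtracts the across-cohort median log profile
per segment position and re-centres each row. It is a stated
reconstruction, clearly swappable, and has a known limitation: it cannot
remove *individual* deviations in decline slope, so cohorts with real
between-person slope spread retain genuine trend power in its residuals.

## Spectrum and permutation null

Six points spanning one year resolve frequencies 1, 2, 3 yr⁻¹. Amplitudes
follow the convention that recovers a sampled cosine's amplitude exactly:
A_k = 2|X_k|/N for 0 < k < N/2 and A_{N/2} = |X_{N/2}|/N at Nyquist. A
consequence worth remembering: for featureless noise the Nyquist bin's
expected amplitude is about half that of the doubled bins, so cross-bin
comparisons of noise levels should be made on a common (doubled) scale.

The cohort statistic is the mean over participants of per-participant
amplitudes of the *log*-residuals. Bootstrap SEM resamples participants
with replacement. The null permutes each participant's corrected series
and re-applies the identical correction; because the correction refits a
trend to the shuffled series, the null's 1 yr⁻¹ amplitude is suppressed
relative to its higher frequencies — the same artifact the observed
spectrum carries. Two numerical choices matter:

1. **Power matching.** Re-projecting a permuted residual series removes on
   average 1/(n−1) of its variance (the permutation regenerates a trend
   component that the refit then removes). Left uncorrected, the null is
   ~10% low in amplitude at every bin and the test is anticonservative —
   on white-noise cohorts the observed mean left the null 95% CI far more
   often than nominal. Each shuffled-and-recorrected series is therefore
   rescaled to its pre-permutation norm; measured per-bin coverage is then
   94–97%.
2. **Add-one p.** The permutation p at 1 yr⁻¹ is (1 + #{null ≥ obs})/(1 +
   n_shuffle), so 1,000 repeats bound p at ~0.001. The parametric p is the
   one-sided normal upper tail of the observed mean under the null repeats'
   mean/sd; Cohen's d uses the same standardisation. Cliff's delta compares
   the bootstrap distribution of the observed 1 yr⁻¹ mean against the null
   repeats (the two-sample choice is configurable; ties count zero).

Zero-variance series are excluded with a warning; fewer than 40 shuffles or
5 participants is an error.

## Cosinor seasonality

A single cohort-level 12-month cosinor is fitted to the pooled
(month-of-year, log-residual) points; per-individual cosinors are not
identifiable from six points in the presence of a 1 yr⁻¹ fluctuation.
Months are fractional, derived from the collection date minus the segment
midpoint offset.

The default fit is **decline-aware**: the cos/sin regressors are passed
through each participant's detrending projector before the pooled OLS
(Frisch–Waugh), making it equivalent to a joint fit of log-concentration on
per-participant intercept + slope plus shared harmonics. This matters: a
12-month cosine observed through exactly one year of hair is partly
absorbed by the exponential trend fit, and the plain residual cosinor
recovers only ~⅔ of a known injected amplitude. The plain pooled version
remains available.

Deseasonalization divides the concentrations by the fitted seasonal factor
and re-runs the decline correction (keeping the zero-mean residual
invariant), then recomputes CVs and the spectrum. The quadrature prediction
for the CV drop, √(cv² − A²/2), ignores the overlap between the harmonic
and the per-participant trends, so it is accurate to ~5–10% here — the
tolerance the tests use.

## HPA models

Dimensionless, unit fixed point. Stress input u drives CRH (x1) → ACTH
(x2) → cortisol (x3); cortisol divides the upstream production terms (the
normalized strong-feedback limit; the feedback exponent is configurable).
The gland-mass variant multiplies secretion by pituitary-corticotroph mass
P and adrenal-cortex mass A, which grow log-linearly in their driving
hormone's deviation from baseline: dP/dt = bP·P·(x1 − 1),
dA/dt = bA·A·(x2 − 1).

At quasi-steady state for the hormones (valid since a ≫ b), the slow
subsystem in (ln P, ln A) has Jacobian [[−bP/3, −bP/3], [bA/3, −2bA/3]];
for bP = bA = b the eigenvalues are (b/3)(−3 ± i√3)/2 — a damped
oscillation with period 4π√3/b ≈ 21.77/b days and damping ratio √3/2.
Tissue turnover of 17 days therefore gives a ~370-day (≈ 1-year) period:
week-scale cell turnover, year-scale resonance, linked by the 2π in
period = 2π/frequency. The damping ratio is structurally ≥ √3/2 for equal
turnover rates (minimum ≈ 0.82 at bP = 2bA), so the resonance is a broad
low-frequency shoulder, not a sharp peak.

Numerics: Euler–Maruyama on log-state (positivity by construction),
default dt = 0.02 day with the stiffness guard dt < 0.1/max(a); hormone
rates default to 4 day⁻¹ — a few-hour timescale, and by the
fast-parameter-irrelevance property (verified in tests by driving a 10×
faster parameterization with the same stress path) their exact value does
not shape the slow spectrum. The stress input is an Ornstein–Uhlenbeck
process, mean 1, clipped below at 0.01: true white noise into a positive
ODE is ill-defined, so "white" means correlation time ≪ the resonance
period. Defaults σ = 0.8, τ = 7 days were calibrated once so that the
gland-mass model's two-month-averaged cortisol fluctuates with CV ≈ 0.19,
emulating the ~22% non-seasonal fluctuation scale of real hair data. Both
the slow gland response and the in-band broadband floor scale as σ²τ, so
this choice sets the overall scale but *not* the model's spectral contrast,
which is structural.

`virtual_hair` averages x3 over consecutive 2-month windows, slices
non-overlapping 6-segment blocks into virtual participants (segment 1 =
most recent), and by default imposes the empirical decline (2.2 yr⁻¹) and
14% assay noise so the simulated cohorts pass through the pipeline exactly
as real data would.

### What model discrimination can and cannot show

The classic cascade has only hour-scale timescales: its virtual-hair
spectrum is statistically indistinguishable from the shuffled null at all
three frequencies (verified over replicate cohorts). The gland-mass model
concentrates power at and below 1 yr⁻¹; its corrected 1/3 amplitude ratio
is ~2–2.5 and its 1 yr⁻¹ amplitude exceeds the calibrated null's 97.5%
line in only roughly half of 55-participant cohorts. The broad (heavily
damped) resonance, the decline correction eating part of the 1 yr⁻¹ band,
and 55-participant sampling noise together make single-cohort exceedance a
coin-weighted outcome rather than a near-certainty; with the *uncorrected*
(power-deflated) null the exceedance looks much stronger, but that null
fails calibration on featureless data. The tests encode both facts
honestly: classic-model indistinguishability passes; the gland-mass
near-certain-exceedance check is expected to fail and documents why.

## What the synthetic cohorts do not capture

Per-individual hair growth rates, segment-boundary mixing, washout/UV
degradation beyond a single exponential, non-stationary stressor
distributions, and any coupling between baseline level and fluctuation
size. Passing tests therefore demonstrate correctness of the estimators
and calibration of the inference under the stated generative model, not
biological validity of that model.

## Problem sizes used in tests and the acceptance script

Cohorts are 55 participants × 6 segments unless a test needs otherwise;
null calibration uses 50–100 replicate cohorts at 300–500 shuffles; model
discrimination uses 20 replicate cohorts per variant at 500 shuffles;
decline-recovery bias uses 100–200 cohorts. These sizes keep every
Monte-Carlo estimate's sampling error well below the tolerance it is
checked against.
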