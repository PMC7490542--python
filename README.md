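# haircort

Analysis of longitudinal hair cortisol and of the HPA-axis feedback
mechanisms that could generate its slow fluctuations.

Hair grows about 1 cm/month and passively records cortisol, so six 2-cm
segments give a retrospective one-year cortisol time series per person at
two-month resolution. Two obstacles stand between the raw measurements and
the physiology: measured cortisol declines roughly exponentially with
distance from the scalp, and the assay carries ~14% multiplicative noise.
This package implements the complete analysis chain:

1. **Decline correction** — per person, OLS of ln C on segment time:
   `ln C_j = ln B − α t_j + r_j`, yielding the baseline B, the decline
   coefficient α (yr⁻¹) and log-residuals r that carry the fluctuations.
   A non-parametric (median-profile) variant is included.
2. **Spectrum** — per-person DFT amplitudes of the residuals at 1, 2,
   3 yr⁻¹, averaged over the cohort, with bootstrap SEM and a shuffled
   null: each person's corrected series is permuted, re-corrected
   identically, and power-matched, giving percentile CIs, permutation and
   parametric p-values, Cohen's d and Cliff's delta.
3. **Cosinor seasonality** — a cohort-level 12-month cosinor
   (`r ~ cos 2πm/12 + sin 2πm/12`, m = calendar month of each segment)
   fitted with decline-aware regressors; amplitude, acrophase, and the
   fluctuation CV after removing the seasonal factor.
4. **HPA models** — stochastic simulations of the classic hormone cascade
   (CRH → ACTH → cortisol with cortisol negative feedback) and of the
   gland-mass model, in which hormones also act as growth factors for the
   pituitary corticotrophs (mass P) and adrenal cortex (mass A). The slow
   P–A loop linearizes to eigenvalues (b/3)(−3 ± i√3)/2 for equal
   turnover rates b, i.e. a damped oscillation with period 4π√3/b:
   17-day tissue turnover ⇒ ~370-day period. Simulated cortisol is
   converted to virtual hair segments and analysed by the identical
   pipeline.
5. **Synthetic cohorts** — a generator with ~30-fold lognormal baseline
   spread, exponential decline (2.2 ± 0.5 yr⁻¹), 14% assay noise, 15%
   seasonality and 22% slow fluctuations with selectable frequency
   content, used throughout the tests.

## Worked example

```sh
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_decline_correction.py
python analysis/03_spectrum.py --seed 1
python analysis/04_seasonality.py --seed 1
python analysis/05_hpa_models.py --seed 1
```

prints (abridged):

```
decline: alpha = 2.13 +/- 0.09 /yr, baseline spread 32-fold
raw CV 22.1% -> noise-corrected 17.1%
freq  mean_amp  boot_sem  null_mean  null_95CI
1/yr  0.221   0.017    0.150   [0.132, 0.168]
2/yr  0.133   0.009    0.180   [0.160, 0.199]
3/yr  0.057   0.005    0.081   [0.067, 0.098]
1/yr vs null: p = 0.000999 (permutation), d = 7.6, Cliff's delta = 1.00
seasonal amplitude 13.1%, peak at month 1.8
linearized resonance: period 370.0 d (0.99/yr), damping ratio 0.866
classic:    amplitudes [0.096, 0.105, 0.053], 1/yr within null 97.5% CI
gland_mass: amplitudes [0.136, 0.158, 0.071], ratio 1/3 = 1.91
```

Reading this: the fitted decline (2.13 ± 0.09 yr⁻¹) recovers the
generator's 2.2; the 1 yr⁻¹ amplitude (0.221) sits far above the null's
97.5% line (0.168) while the null itself is *suppressed* at 1 yr⁻¹
relative to 2 yr⁻¹ — the decline refit removes slow structure from
shuffled data too, so low-frequency dominance must beat that handicap to
be called significant. The cosinor recovers the injected 15% seasonality
(13.1% here), and the gland-mass model — unlike the classic cascade —
concentrates spectral weight at low frequency, with the ~1-year timescale
emerging from week-scale tissue turnover via period = 2π/frequency.

The same pipeline runs on real data: any CSV with columns
`participant_id, collection_date, segment_index, cortisol_pg_per_mg`
can be passed to `analysis/02...04` via `--cohort`, or use
`haircort.pipeline.run(RunConfig(cohort_csv=...))` for an end-to-end
report with full provenance (config hash, seeds, versions).

## Layout

```
src/haircort/    cohort.py (generator, CSV i/o), decline.py, spectrum.py,
                 cosinor.py, hpa.py, pipeline.py, plots.py
analysis/        numbered drivers reproducing each stage, writing results/
tests/           unit + property tests and end-to-end acceptance checks
docs/methods.md  model, estimators, numerical choices, limitations
```
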