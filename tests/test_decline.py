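import math
from dataclasses import replace
from datetime import date

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from haircort import (CohortParams, HairSeries, cohort_decline_summary,
                      fit_cohort, fit_decline, fluctuation_cv, generate_cohort,
                      noise_corrected_cv, nonparametric_correct)
from haircort.cohort import CohortError
from haircort.decline import (DegenerateSubtractionError, InsufficientDataError)


class TestFitDecline:
    def test_noiseless_exponential_recovered_exactly(self, clean_exponential_series):
        fit = fit_decline(clean_exponential_series)
        assert fit.baseline == pytest.approx(10.0, rel=1e-10)
        assert fit.alpha == pytest.approx(2.2, rel=1e-10)
        np.testing.assert_allclose(fit.log_residuals, 0.0, atol=1e-12)
        assert fit.fit_r2 == pytest.approx(1.0)

    def test_residuals_zero_mean(self, default_fits):
        for f in default_fits:
            assert abs(f.log_residuals.mean()) < 1e-10

    @given(scale=st.floats(0.01, 100.0), seed=st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_scale_equivariance(self, scale, seed):
        rng = np.random.default_rng(seed)
        conc = np.exp(rng.normal(1.0, 0.5, size=6))
        s = HairSeries("a", date(2020, 1, 1), conc)
        f1 = fit_decline(s)
        f2 = fit_decline(replace(s, concentrations=conc * scale))
        assert f2.baseline == pytest.approx(f1.baseline * scale, rel=1e-9)
        assert f2.alpha == pytest.approx(f1.alpha, rel=1e-9, abs=1e-9)
        np.testing.assert_allclose(f2.log_residuals, f1.log_residuals, atol=1e-9)

    def test_too_few_segments_rejected(self):
        s = HairSeries("a", date(2020, 1, 1), np.array([1.0, 2.0]))
        with pytest.raises(InsufficientDataError):
            fit_decline(s)

    def test_vectorised_cohort_fit_matches_single(self, default_cohort):
        fits = fit_cohort(default_cohort)
        for s, fc in zip(default_cohort[:5], fits[:5]):
            f1 = fit_decline(s)
            assert fc.alpha == pytest.approx(f1.alpha, rel=1e-12)
            assert fc.baseline == pytest.approx(f1.baseline, rel=1e-12)


class TestCohortSummary:
    def test_hand_computed_mean_and_sem(self, clean_exponential_series):
        t = clean_exponential_series.segment_midpoint_years
        fits = [fit_decline(HairSeries(str(a), date(2020, 1, 1),
                                       5.0 * np.exp(-a * t)))
                for a in (2.0, 3.0)]
        mean, sem, fold = cohort_decline_summary(fits)
        assert mean == pytest.approx(2.5)
        assert sem == pytest.approx(0.5)  # sd = 0.7071, / sqrt(2)
        assert fold == pytest.approx(1.0)

    def test_identical_fits_zero_sem(self, clean_exponential_series):
        fit = fit_decline(clean_exponential_series)
        _, sem, _ = cohort_decline_summary([fit, fit, fit])
        assert sem == 0.0

    def test_single_fit_rejected(self, clean_exponential_series):
        with pytest.raises(InsufficientDataError):
            cohort_decline_summary([fit_decline(clean_exponential_series)])

    def test_recovery_on_one_cohort_within_2_sem(self):
        p = CohortParams(decay_mean=2.2, decay_sd=0.5, seasonal_amplitude=0.0,
                         fluctuation_spectrum="white", rng_seed=11)
        mean, sem, _ = cohort_decline_summary(fit_cohort(generate_cohort(p)))
        # fitted alphas scatter around the generator truth
        assert abs(mean - 2.2) < 2 * math.sqrt(sem ** 2 + 0.5 ** 2 / 55)


class TestFluctuationCv:
    def test_quadrature_identity_at_zero_assay(self, default_fits):
        stats = fluctuation_cv(default_fits, 0.0)
        assert stats.mean_cv_noise_corrected == stats.mean_cv_raw

    def test_corrected_below_raw(self, default_fits):
        stats = fluctuation_cv(default_fits, 0.10)
        assert stats.mean_cv_noise_corrected < stats.mean_cv_raw
        assert np.all(stats.per_participant_cv >= 0)

    def test_degenerate_subtraction_raises(self, default_fits):
        with pytest.raises(DegenerateSubtractionError):
            fluctuation_cv(default_fits, 5.0)

    def test_quadrature_closed_form(self):
        assert noise_corrected_cv(0.28, 0.14) == pytest.approx(0.14 * math.sqrt(3))


class TestNonparametric:
    def test_shared_exponential_gives_zero_residuals(self, clean_exponential_series):
        cohort = [replace(clean_exponential_series, participant_id=f"P{i}",
                          concentrations=clean_exponential_series.concentrations * c)
                  for i, c in enumerate([0.5, 1.0, 2.0, 7.0])]
        fits = nonparametric_correct(cohort)
        for f in fits:
            np.testing.assert_allclose(f.log_residuals, 0.0, atol=1e-12)

    def test_mixed_segment_counts_rejected(self, clean_exponential_series):
        short = HairSeries("s", date(2020, 1, 1), np.ones(4))
        with pytest.raises(CohortError, match="mixed"):
            nonparametric_correct([clean_exponential_series, short])

    def test_single_frequency_cohort_keeps_1_per_year_dominant(self):
        from haircort.cohort import cohort_matrix
        from haircort.decline import nonparametric_residuals
        from haircort.spectrum import cohort_spectrum
        p = CohortParams(seasonal_amplitude=0.0, rng_seed=21)
        cohort = generate_cohort(p)
        fits = nonparametric_correct(cohort)
        _, logc, _ = cohort_matrix(cohort)
        res = cohort_spectrum(fits, n_boot=100, n_shuffle=200, seed=3,
                              logc=logc, corrector=nonparametric_residuals)
        assert res.mean_amplitude[0] > res.null_ci_high[0]
        assert res.amp_ratio_1_over_3 > 1.0

    def test_white_noise_cohorts_match_null(self):
        from haircort.cohort import cohort_matrix
        from haircort.decline import nonparametric_residuals
        from haircort.spectrum import cohort_spectrum
        inside = 0
        n_runs = 40
        for k in range(n_runs):
            # shared decline (decay_sd = 0): the median-profile correction
            # cannot remove individual slope deviations, which would be a
            # real (not spurious) slow component
            p = CohortParams(seasonal_amplitude=0.0, decay_sd=0.0,
                             fluctuation_spectrum="white", rng_seed=400 + k)
            cohort = generate_cohort(p)
            fits = nonparametric_correct(cohort)
            _, logc, _ = cohort_matrix(cohort)
            res = cohort_spectrum(fits, n_boot=20, n_shuffle=200, seed=500 + k,
                                  logc=logc, corrector=nonparametric_residuals)
            inside += (res.null_ci_low[0] <= res.mean_amplitude[0]
                       <= res.null_ci_high[0])
        # nominal per-bin coverage ~95%; allow binomial noise at n = 40
        assert inside >= 0.85 * n_runs
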