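import math
from dataclasses import replace

import numpy as np
import pytest

from haircort import (HPAParams, fit_cohort, linearize, sensitivity_scan,
                      simulate, step_response_period, virtual_hair)
from haircort.hpa import (DAYS_PER_YEAR, HPAConfigError, simulate_qss)
from haircort.spectrum import cohort_spectrum


def short_params(**kw):
    base = dict(t_total=120.0, burn_in=200.0, seed=0)
    base.update(kw)
    return HPAParams(**base)


class TestSimulate:
    def test_zero_noise_stays_at_fixed_point(self):
        for variant in ("classic", "gland_mass"):
            traj = simulate(short_params(model_variant=variant, input_sigma=0.0))
            for arr in (traj.x1, traj.x2, traj.x3, traj.u):
                np.testing.assert_allclose(arr, 1.0, atol=1e-12)
            if variant == "gland_mass":
                np.testing.assert_allclose(traj.P, 1.0, atol=1e-12)
                np.testing.assert_allclose(traj.A, 1.0, atol=1e-12)

    def test_positivity_along_trajectory(self):
        traj = simulate(short_params(input_sigma=1.0, t_total=400.0, seed=3))
        for arr in (traj.x1, traj.x2, traj.x3, traj.P, traj.A):
            assert np.all(arr > 0)

    def test_fixed_seed_bit_reproducible(self):
        p = short_params(seed=5)
        t1, t2 = simulate(p), simulate(p)
        np.testing.assert_array_equal(t1.x3, t2.x3)
        np.testing.assert_array_equal(t1.u, t2.u)

    def test_stiff_step_size_rejected(self):
        with pytest.raises(HPAConfigError, match="dt"):
            HPAParams(a3=20.0, dt=0.02).validate()

    def test_short_burn_in_rejected_for_gland_mass(self):
        with pytest.raises(HPAConfigError, match="burn_in"):
            HPAParams(burn_in=10.0).validate()

    def test_qss_reduction_agrees_when_hormones_fast(self):
        # hormone rates ~100x the gland turnover rates: the full model's
        # gland-mass trajectories should track the QSS reduction closely
        p = HPAParams(a1=6.0, a2=6.0, a3=6.0, dt=0.01, input_sigma=0.5,
                      input_tau=3.0, t_total=2 * DAYS_PER_YEAR, burn_in=100.0,
                      seed=7)
        rng = np.random.default_rng(0)
        n_steps = int(round((p.burn_in + p.t_total) / p.dt)) + 2
        rho = math.exp(-p.dt / p.input_tau)
        eps = rng.standard_normal(n_steps)
        u = np.empty(n_steps)
        u[0] = 1.0
        for i in range(1, n_steps):
            u[i] = 1.0 + (u[i - 1] - 1.0) * rho \
                + p.input_sigma * math.sqrt(1 - rho * rho) * eps[i]
        u = np.maximum(u, 0.01)
        full = simulate(p, u_path=u)
        qss = simulate_qss(p, u_path=u)
        for a, b in ((full.P, qss.P), (full.A, qss.A)):
            rms = math.sqrt(np.mean((a - b) ** 2)) / math.sqrt(np.mean(b ** 2))
            assert rms < 0.05


class TestLinearize:
    def test_closed_form_period_for_equal_turnover(self):
        b = 1.0 / 17.0
        lin = linearize(HPAParams(bP=b, bA=b))
        assert lin.resonance_period == pytest.approx(4 * math.pi * math.sqrt(3) / b,
                                                     abs=1e-8)
        assert lin.damping_ratio == pytest.approx(math.sqrt(3) / 2, abs=1e-12)

    def test_eigenvalues_conjugate_pair(self):
        lin = linearize(HPAParams())
        lam = np.sort_complex(lin.eigenvalues)
        assert lam[0] == pytest.approx(np.conj(lam[1]))
        np.testing.assert_allclose(
            lam[1], (1 / 17.0 / 3.0) * (-3 + 1j * math.sqrt(3)) / 2, atol=1e-12)

    def test_turnover_rescaling_scales_frequency(self):
        lin1 = linearize(HPAParams())
        lin2 = linearize(HPAParams(bP=3.0 / 17, bA=3.0 / 17, burn_in=200.0))
        assert lin2.resonance_frequency == pytest.approx(3 * lin1.resonance_frequency)

    def test_period_frequency_identity(self):
        lin = linearize(HPAParams())
        assert lin.resonance_period * lin.resonance_frequency == \
            pytest.approx(DAYS_PER_YEAR)

    def test_classic_variant_rejected(self):
        with pytest.raises(HPAConfigError, match="classic"):
            linearize(HPAParams(model_variant="classic"))

    def test_asymmetric_turnover_step_response_matches_eigenvalues(self):
        p = HPAParams(bP=1 / 10.0, bA=1 / 60.0, burn_in=300.0)
        lin = linearize(p)
        period = step_response_period(p)
        assert abs(period - lin.resonance_period) / lin.resonance_period < 0.10


class TestVirtualHair:
    def test_constant_trajectory_flat_segments(self):
        traj = simulate(short_params(input_sigma=0.0, t_total=DAYS_PER_YEAR))
        hair = virtual_hair(traj, decay_alpha=0.0, assay_cv=0.0)
        assert len(hair) == 1
        np.testing.assert_allclose(hair[0].concentrations, 1.0, atol=1e-12)

    def test_too_short_trajectory_rejected(self):
        traj = simulate(short_params(input_sigma=0.0, t_total=100.0))
        with pytest.raises(HPAConfigError, match="block"):
            virtual_hair(traj)

    def test_replicate_trajectories_become_participants(self):
        traj = simulate(short_params(t_total=DAYS_PER_YEAR, n_traj=7, seed=2))
        hair = virtual_hair(traj, seed=0)
        assert len(hair) == 7
        assert len({s.participant_id for s in hair}) == 7

    def test_imposed_decay_recovered_by_decline_fit(self):
        traj = simulate(short_params(input_sigma=0.0, t_total=DAYS_PER_YEAR))
        hair = virtual_hair(traj, decay_alpha=2.2, assay_cv=0.0)
        from haircort import fit_decline
        fit = fit_decline(hair[0])
        assert fit.alpha == pytest.approx(2.2, rel=1e-6)


class TestFastParameterIrrelevance:
    def test_hormone_rates_do_not_shape_slow_spectrum(self):
        # multiply a1..a3 by 10 (and shrink dt accordingly) while driving
        # both runs with the same stress sample path: virtual-hair cohort
        # mean amplitudes change by well under 10%
        n_traj = 24
        dt_fine = 0.002
        base = HPAParams(t_total=DAYS_PER_YEAR, burn_in=200.0, n_traj=n_traj)
        n_fine = int(round((base.burn_in + base.t_total) / dt_fine)) + 2
        rng = np.random.default_rng(99)
        rho = math.exp(-dt_fine / base.input_tau)
        u = np.empty((n_fine, n_traj))
        u[0] = 1.0
        noise = rng.standard_normal((n_fine, n_traj))
        sd = base.input_sigma * math.sqrt(1 - rho * rho)
        for i in range(1, n_fine):
            u[i] = 1.0 + (u[i - 1] - 1.0) * rho + sd * noise[i]
        u = np.maximum(u, 0.01)

        amps = {}
        for label, (a, dt, path) in {
                "slow": (4.0, 0.02, u[::10]),
                "fast": (40.0, dt_fine, u)}.items():
            p = replace(base, a1=a, a2=a, a3=a, dt=dt)
            hair = virtual_hair(simulate(p, u_path=path),
                                decay_alpha=0.0, assay_cv=0.0, seed=1)
            res = cohort_spectrum(fit_cohort(hair), n_boot=50, n_shuffle=50,
                                  seed=2)
            amps[label] = res.mean_amplitude
        rel = np.abs(amps["fast"] - amps["slow"]) / amps["slow"]
        assert np.all(rel < 0.10)


class TestSensitivityScan:
    def test_grid_produces_expected_rows_and_dominance(self):
        df = sensitivity_scan([(17.0, 17.0), (30.0, 30.0)], reps=1,
                              n_participants=30, n_boot=50, n_shuffle=100,
                              seed=4)
        assert list(df["tP_days"]) == [17.0, 30.0]
        assert np.all(np.isfinite(df["amp_ratio_1_over_3"]))
        assert np.all(df["amp_ratio_1_over_3"] > 1.0)

    def test_empty_grid_rejected(self):
        with pytest.raises(HPAConfigError, match="empty"):
            sensitivity_scan([], reps=1)
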