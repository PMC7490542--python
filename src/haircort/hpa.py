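"""HPA-axis models: classic hormone cascade and gland-mass feedback.

Dimensionless formulation with the normal operating point at 1 for every
state variable.  Stress input u drives CRH (x1); CRH drives ACTH (x2);
ACTH drives cortisol (x3); cortisol inhibits both upstream hormones
(1/x3 feedback, the normalized strong-feedback limit):

classic (hormone half-lives of hours only)::

    dx1/dt = a1 (u / x3 - x1)
    dx2/dt = a2 (x1 / x3 - x2)
    dx3/dt = a3 (x2 - x3)

gland_mass additionally lets the hormones act as growth factors for the
secreting tissues - pituitary corticotroph functional mass P and adrenal
cortex functional mass A - which multiply the secretion terms::

    dx2/dt = a2 (P x1 / x3 - x2)        dP/dt = bP P (x1 - 1)
    dx3/dt = a3 (A x2 - x3)             dA/dt = bA A (x2 - 1)

The P-A loop has tissue-turnover rates bP, bA of order weeks, and its
linearization around the fixed point yields a damped resonance with period
4 pi sqrt(3) / b (for bP = bA = b): turnover times of a few weeks give a
period of about one year.

Stress input is an Ornstein-Uhlenbeck process with mean 1 (white on the
slow timescales of interest), integrated together with the state by
Euler-Maruyama on log-state variables, which preserves positivity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import date

import numpy as np

from .cohort import HairSeries, lognormal_sigma

__all__ = [
    "HPAParams",
    "HPATrajectory",
    "LinearAnalysis",
    "HPAConfigError",
    "IntegrationError",
    "simulate",
    "simulate_qss",
    "linearize",
    "virtual_hair",
    "step_response_period",
    "sensitivity_scan",
]

DAYS_PER_YEAR = 365.25
DAYS_PER_MONTH = DAYS_PER_YEAR / 12.0
U_FLOOR = 0.01


class HPAConfigError(ValueError):
    pass


class IntegrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class HPAParams:
    """Rates in day^-1, times in days.  Defaults put hormone turnover on the
    few-hour scale (their exact values do not affect the slow spectrum) and
    tissue turnover at 17 days, for which the linearized resonance period is
    ~370 days."""

    a1: float = 4.0
    a2: float = 4.0
    a3: float = 4.0
    bP: float = 1.0 / 17.0
    bA: float = 1.0 / 17.0
    input_sigma: float = 0.8
    input_tau: float = 7.0
    model_variant: str = "gland_mass"   # classic | gland_mass
    dt: float = 0.02
    t_total: float = 6.0 * DAYS_PER_YEAR
    burn_in: float = 200.0
    seed: int = 0
    n_traj: int = 1                     # independent replicate trajectories
    record_every: float = 0.25          # days between stored samples

    def validate(self) -> None:
        for name in ("a1", "a2", "a3", "bP", "bA"):
            if getattr(self, name) <= 0:
                raise HPAConfigError(f"{name} must be > 0")
        if self.model_variant not in ("classic", "gland_mass"):
            raise HPAConfigError(f"unknown model_variant {self.model_variant!r}")
        amax = max(self.a1, self.a2, self.a3)
        if self.dt >= 0.1 / amax:
            raise HPAConfigError(
                f"dt = {self.dt} too large for fastest rate {amax}/day "
                f"(need dt < {0.1 / amax:.4g})")
        if self.input_sigma < 0 or self.input_tau <= 0:
            raise HPAConfigError("input_sigma >= 0 and input_tau > 0 required")
        if self.model_variant == "gland_mass" and self.burn_in < 5.0 / min(self.bP, self.bA):
            raise HPAConfigError(
                f"burn_in must be >= 5/min(bP,bA) = {5.0 / min(self.bP, self.bA):.1f} days")
        if self.t_total <= 0 or self.n_traj < 1:
            raise HPAConfigError("t_total > 0 and n_traj >= 1 required")


@dataclass(frozen=True)
class HPATrajectory:
    """Recorded time courses after burn-in.  State arrays have shape
    (n_samples,) for a single trajectory or (n_samples, n_traj)."""

    times: np.ndarray    # days, starting at 0 after burn-in
    u: np.ndarray
    x1: np.ndarray
    x2: np.ndarray
    x3: np.ndarray
    P: np.ndarray | None
    A: np.ndarray | None
    params: HPAParams

    @property
    def n_traj(self) -> int:
        return 1 if self.x3.ndim == 1 else self.x3.shape[1]


def _make_u_updater(p: HPAParams, rng, n):
    """Exact-discretization OU step for the stress input, clipped below."""
    rho = math.exp(-p.dt / p.input_tau)
    noise_sd = p.input_sigma * math.sqrt(1.0 - rho * rho)

    def step(u):
        u = 1.0 + (u - 1.0) * rho + noise_sd * rng.standard_normal(n)
        return np.maximum(u, U_FLOOR)

    return step


def simulate(params: HPAParams, u_path: np.ndarray | None = None) -> HPATrajectory:
    """Integrate the model by Euler-Maruyama on log-state.

    ``u_path``, if given, replaces the OU input: an array of shape
    (n_steps,) or (n_steps, n_traj) of stress values per integration step
    (burn-in steps included).  Raises :class:`IntegrationError` (reporting
    the time) if the state leaves the positive orthant numerically.
    """
    p = params
    p.validate()
    rng = np.random.default_rng(p.seed)
    gland = p.model_variant == "gland_mass"

    n_steps = int(round((p.burn_in + p.t_total) / p.dt))
    burn_steps = int(round(p.burn_in / p.dt))
    stride = max(1, int(round(p.record_every / p.dt)))
    rec_idx = np.arange(burn_steps, n_steps + 1, stride)
    n_rec = rec_idx.size
    n = p.n_traj

    if u_path is not None:
        u_path = np.asarray(u_path, dtype=float)
        if u_path.shape[0] < n_steps:
            raise HPAConfigError(
                f"u_path has {u_path.shape[0]} steps, need {n_steps}")
        u_step = None
    else:
        u_step = _make_u_updater(p, rng, n)

    lx = np.zeros((3, n))                      # ln x1, ln x2, ln x3
    lP = np.zeros(n)
    lA = np.zeros(n)
    if u_path is not None:
        u = np.broadcast_to(np.atleast_1d(u_path[0]), (n,)).astype(float)
    else:
        u = np.ones(n)

    out = {k: np.empty((n_rec, n)) for k in ("u", "x1", "x2", "x3")}
    if gland:
        out["P"] = np.empty((n_rec, n))
        out["A"] = np.empty((n_rec, n))

    rec_pos = {int(s): j for j, s in enumerate(rec_idx)}
    dt = p.dt
    for step in range(n_steps + 1):
        j = rec_pos.get(step)
        if j is not None:
            x = np.exp(lx)
            out["u"][j] = u
            out["x1"][j], out["x2"][j], out["x3"][j] = x
            if gland:
                out["P"][j] = np.exp(lP)
                out["A"][j] = np.exp(lA)
        if step == n_steps:
            break
        x1, x2, x3 = np.exp(lx)
        if gland:
            lx[0] += p.a1 * (u / (x3 * x1) - 1.0) * dt
            lx[1] += p.a2 * (np.exp(lP) * x1 / (x3 * x2) - 1.0) * dt
            lx[2] += p.a3 * (np.exp(lA) * x2 / x3 - 1.0) * dt
            lP += p.bP * (x1 - 1.0) * dt
            lA += p.bA * (x2 - 1.0) * dt
        else:
            lx[0] += p.a1 * (u / (x3 * x1) - 1.0) * dt
            lx[1] += p.a2 * (x1 / (x3 * x2) - 1.0) * dt
            lx[2] += p.a3 * (x2 / x3 - 1.0) * dt
        if not np.all(np.isfinite(lx)) or (gland and not
                                           (np.all(np.isfinite(lP)) and np.all(np.isfinite(lA)))):
            raise IntegrationError(
                f"state left the positive orthant at t = {step * dt - p.burn_in:.2f} days")
        if u_path is not None:
            u = np.broadcast_to(np.atleast_1d(u_path[step + 1] if step + 1 < u_path.shape[0]
                                              else u_path[-1]), (n,)).astype(float)
        else:
            u = u_step(u)

    times = (rec_idx - burn_steps) * dt

    def sq(a):
        return a[:, 0] if n == 1 else a

    return HPATrajectory(
        times=times,
        u=sq(out["u"]), x1=sq(out["x1"]), x2=sq(out["x2"]), x3=sq(out["x3"]),
        P=sq(out["P"]) if gland else None,
        A=sq(out["A"]) if gland else None,
        params=p,
    )


def simulate_qss(params: HPAParams, u_path: np.ndarray) -> HPATrajectory:
    """Quasi-steady-state reduction of the gland-mass model.

    Hormones are slaved to the gland masses and input:
    x3 = (A P u)^(1/3), x1 = u / x3, x2 = x3 / A; only (ln P, ln A) are
    integrated.  Valid when hormone rates are much faster than bP, bA.
    """
    p = params
    if p.model_variant != "gland_mass":
        raise HPAConfigError("QSS reduction applies to the gland_mass variant")
    p.validate()
    u_path = np.asarray(u_path, dtype=float)
    n_steps = int(round((p.burn_in + p.t_total) / p.dt))
    burn_steps = int(round(p.burn_in / p.dt))
    stride = max(1, int(round(p.record_every / p.dt)))
    rec_idx = np.arange(burn_steps, n_steps + 1, stride)
    n = p.n_traj

    lP = np.zeros(n)
    lA = np.zeros(n)
    rec = {k: np.empty((rec_idx.size, n)) for k in ("u", "x1", "x2", "x3", "P", "A")}
    rec_pos = {int(s): j for j, s in enumerate(rec_idx)}
    for step in range(n_steps + 1):
        u = np.broadcast_to(np.atleast_1d(u_path[min(step, u_path.shape[0] - 1)]), (n,))
        x3 = np.exp((lA + lP + np.log(u)) / 3.0)
        x1 = u / x3
        x2 = x3 / np.exp(lA)
        j = rec_pos.get(step)
        if j is not None:
            rec["u"][j] = u
            rec["x1"][j], rec["x2"][j], rec["x3"][j] = x1, x2, x3
            rec["P"][j], rec["A"][j] = np.exp(lP), np.exp(lA)
        if step == n_steps:
            break
        lP = lP + p.bP * (x1 - 1.0) * p.dt
        lA = lA + p.bA * (x2 - 1.0) * p.dt

    def sq(a):
        return a[:, 0] if n == 1 else a

    return HPATrajectory(
        times=(rec_idx - burn_steps) * p.dt,
        u=sq(rec["u"]), x1=sq(rec["x1"]), x2=sq(rec["x2"]), x3=sq(rec["x3"]),
        P=sq(rec["P"]), A=sq(rec["A"]), params=p,
    )


@dataclass(frozen=True)
class LinearAnalysis:
    eigenvalues: np.ndarray        # day^-1, slow (ln P, ln A) subsystem
    resonance_frequency: float     # yr^-1: Im(lambda) / 2 pi, converted
    resonance_period: float        # days: 2 pi / |Im(lambda)|
    damping_ratio: float           # -Re(lambda) / |lambda|


def linearize(params: HPAParams) -> LinearAnalysis:
    """Eigen-analysis of the slow gland subsystem at quasi-steady state.

    With hormones slaved (u = 1): x1 = (A P)^(-1/3), x2 = P^(1/3) A^(-2/3),
    so in (p, q) = (ln P, ln A):

        dp/dt = bP (exp(-(p+q)/3) - 1)
        dq/dt = bA (exp((p-2q)/3) - 1)

    and the Jacobian at the all-ones fixed point is
    [[-bP/3, -bP/3], [bA/3, -2 bA/3]].  For bP = bA = b the eigenvalues are
    (b/3)(-3 +/- i sqrt(3))/2, i.e. resonance period 4 pi sqrt(3) / b.
    """
    p = params
    if p.model_variant != "gland_mass":
        raise HPAConfigError("classic variant has no slow subsystem to linearize")
    J = np.array([[-p.bP / 3.0, -p.bP / 3.0],
                  [p.bA / 3.0, -2.0 * p.bA / 3.0]])
    lam = np.linalg.eigvals(J)
    im = np.abs(lam.imag).max()
    if im > 0:
        period = 2.0 * math.pi / im
        freq = DAYS_PER_YEAR / period
        lead = lam[np.argmax(lam.imag)]
        zeta = float(-lead.real / abs(lead))
    else:
        period = math.inf
        freq = 0.0
        zeta = 1.0
    return LinearAnalysis(lam, float(freq), float(period), zeta)


def virtual_hair(
    trajectory: HPATrajectory,
    n_segments: int = 6,
    segment_months: float = 2.0,
    decay_alpha: float = 2.2,
    assay_cv: float = 0.14,
    seed=None,
    base_date: date = date(2020, 1, 1),
) -> list[HairSeries]:
    """Turn simulated cortisol into virtual hair-segment series.

    x3 is averaged over consecutive ``segment_months`` windows; each
    non-overlapping block of ``n_segments`` windows becomes one virtual
    participant (multiple replicate trajectories each contribute their own
    blocks).  Optional exponential decline along the hair (``decay_alpha``,
    yr^-1) and multiplicative lognormal assay noise mimic real measurements;
    set them to 0 to get the bare model output.
    """
    rng = np.random.default_rng(seed)
    t = trajectory.times
    x3 = trajectory.x3 if trajectory.x3.ndim == 2 else trajectory.x3[:, None]
    seg_days = segment_months * DAYS_PER_MONTH
    block_days = n_segments * seg_days
    dt_rec = t[1] - t[0] if t.size > 1 else 0.0
    n_blocks = int((t[-1] + dt_rec) // block_days)  # half-open to the last sample
    if n_blocks < 1:
        raise HPAConfigError(
            f"trajectory spans {t[-1]:.0f} days < one {block_days:.0f}-day block")

    # segment 1 is scalp-proximal = most recent window before block end
    t_mid_years = (np.arange(1, n_segments + 1) - 0.5) * segment_months / 12.0
    decay = np.exp(-decay_alpha * t_mid_years)
    series = []
    for traj in range(x3.shape[1]):
        for blk in range(n_blocks):
            end = (blk + 1) * block_days
            conc = np.empty(n_segments)
            for j in range(n_segments):
                lo = np.searchsorted(t, end - (j + 1) * seg_days)
                hi = np.searchsorted(t, end - j * seg_days)
                conc[j] = x3[lo:hi, traj].mean()
            conc = conc * decay
            if assay_cv > 0:
                s = lognormal_sigma(assay_cv)
                conc = conc * np.exp(rng.normal(-0.5 * s * s, s, size=n_segments))
            series.append(HairSeries(
                participant_id=f"V{traj + 1:03d}B{blk + 1:02d}",
                collection_date=base_date,
                concentrations=conc,
                segment_length_cm=2.0,
                growth_rate_cm_per_month=2.0 / segment_months,
            ))
    return series


def step_response_period(params: HPAParams, step_to: float = 1.5,
                         t_total: float | None = None) -> float:
    """Damped-oscillation period of cortisol after a step in stress input.

    Runs the noise-free gland-mass model with u stepped from 1 to
    ``step_to`` at t = 0 and measures the period as twice the spacing of
    consecutive zero crossings of x3 around its new steady state (= step_to,
    since the gland loop makes x1, x2 perfectly adapt).
    """
    if params.model_variant != "gland_mass":
        raise HPAConfigError("step response period requires the gland_mass variant")
    lin = linearize(params)
    horizon = t_total if t_total is not None else 2.2 * lin.resonance_period
    burn = 5.0 / min(params.bP, params.bA)
    p = replace(params, input_sigma=0.0, burn_in=burn, t_total=horizon,
                n_traj=1, record_every=min(params.record_every, 0.25))
    # u = 1 during burn-in (the system sits at its fixed point), stepped to
    # step_to at recorded t = 0
    n_steps = int(round((burn + horizon) / p.dt)) + 2
    u_path = np.full(n_steps, float(step_to))
    u_path[: int(round(burn / p.dt))] = 1.0
    traj = simulate(p, u_path=u_path)
    dev = traj.x3 - step_to
    # skip the fast hormone transient before looking for crossings
    skip = np.searchsorted(traj.times, 5.0 / min(params.a1, params.a2, params.a3))
    dev = dev[skip:]
    tt = traj.times[skip:]
    sign = np.sign(dev)
    cross = np.nonzero(np.diff(sign) != 0)[0]
    if cross.size < 2:
        raise IntegrationError("fewer than two zero crossings: period unresolved")
    # linear interpolation of crossing times
    tc = []
    for i in cross[:3]:
        f = dev[i] / (dev[i] - dev[i + 1])
        tc.append(tt[i] + f * (tt[i + 1] - tt[i]))
    return 2.0 * float(np.mean(np.diff(tc)))


def sensitivity_scan(
    turnover_times,
    reps: int = 3,
    base_params: HPAParams | None = None,
    n_participants: int = 55,
    n_boot: int = 200,
    n_shuffle: int = 200,
    seed: int = 0,
):
    """Scan tissue turnover times (tP, tA in days): for each grid point and
    replicate, simulate, build virtual hair, run the correction + spectrum
    pipeline, and report the 1/3 amplitude ratio and whether the 1 yr^-1
    amplitude exceeds the null 97.5% CI.  Returns a pandas DataFrame.
    """
    import pandas as pd

    from .decline import fit_cohort
    from .spectrum import cohort_spectrum

    grid = list(turnover_times)
    if not grid:
        raise HPAConfigError("empty turnover-time grid")
    base = base_params or HPAParams()
    rows = []
    ss = np.random.SeedSequence(seed)
    for (tP, tA) in grid:
        for rep in range(reps):
            child = ss.spawn(1)[0]
            s1, s2, s3 = child.generate_state(3) % (2 ** 31)
            p = replace(base, model_variant="gland_mass",
                        bP=1.0 / tP, bA=1.0 / tA,
                        burn_in=max(base.burn_in, 5.0 * max(tP, tA)),
                        t_total=DAYS_PER_YEAR, n_traj=n_participants,
                        seed=int(s1))
            traj = simulate(p)
            cohort = virtual_hair(traj, seed=int(s2))
            res = cohort_spectrum(fit_cohort(cohort), n_boot=n_boot,
                                  n_shuffle=n_shuffle, seed=int(s3))
            rows.append({
                "tP_days": tP, "tA_days": tA, "rep": rep,
                "amp_ratio_1_over_3": res.amp_ratio_1_over_3,
                "a1_above_null": bool(res.mean_amplitude[0] > res.null_ci_high[0]),
                "mean_amp_1": res.mean_amplitude[0],
                "null_ci_high_1": res.null_ci_high[0],
            })
    return pd.DataFrame(rows)
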