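"""Fourier spectrum of decline-corrected hair cortisol.

Six segments over one year resolve exactly three frequencies: 1, 2 and
3 yr^-1 (periods of 12, 6 and 4 months).  The cohort statistic is the mean
over participants of the per-participant DFT amplitude at each frequency.
Uncertainty comes from bootstrapping participants; significance from a
shuffled null in which each participant's raw segment values are permuted
and the *entire* correction + spectrum pipeline is re-run, so the null
inherits the low-frequency suppression that the decline fit introduces.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .decline import DeclineFit, exponential_residuals

__all__ = [
    "SpectrumResult",
    "SpectrumError",
    "dft_amplitudes",
    "amplitude_matrix",
    "cohort_spectrum",
    "effect_sizes",
    "cliffs_delta",
    "cohens_d",
]


class SpectrumError(ValueError):
    pass


def dft_amplitudes(x: np.ndarray) -> np.ndarray:
    """One-sided DFT amplitudes of a real series of even length N.

    With X_k = sum_n x_n exp(-2 pi i k n / N), returns
    A_k = 2|X_k|/N for 0 < k < N/2 and A_{N/2} = |X_{N/2}|/N (Nyquist).
    When the N points span one year, bin k has frequency k yr^-1.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise SpectrumError("series must be 1-d")
    n = x.size
    if n < 4 or n % 2:
        raise SpectrumError(f"series length must be even and >= 4, got {n}")
    X = np.fft.rfft(x)
    amps = 2.0 * np.abs(X[1:]) / n
    amps[-1] /= 2.0  # Nyquist bin is not doubled
    return amps


def amplitude_matrix(resid: np.ndarray) -> np.ndarray:
    """Row-wise :func:`dft_amplitudes` for a residual matrix (n, N)."""
    n = resid.shape[1]
    if n < 4 or n % 2:
        raise SpectrumError(f"series length must be even and >= 4, got {n}")
    X = np.fft.rfft(resid, axis=1)
    amps = 2.0 * np.abs(X[:, 1:]) / n
    amps[:, -1] /= 2.0
    return amps


@dataclass(frozen=True)
class SpectrumResult:
    frequencies: np.ndarray          # yr^-1: 1 .. N/2
    mean_amplitude: np.ndarray
    bootstrap_sem: np.ndarray
    null_mean: np.ndarray
    null_ci_low: np.ndarray          # 2.5 percentile of null cohort means
    null_ci_high: np.ndarray         # 97.5 percentile
    p_parametric: float              # one-sided normal upper tail, 1 yr^-1 bin
    p_nonparametric: float           # add-one permutation p, 1 yr^-1 bin
    cohens_d: float                  # (observed - null mean) / null sd
    cliffs_delta: float              # bootstrap-of-observed vs null repeats
    amp_ratio_1_over_3: float        # lowest over highest frequency amplitude
    amp_ratio_sem: float
    n_participants: int
    n_boot: int
    n_shuffle: int
    excluded: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "frequencies_per_year": self.frequencies.tolist(),
            "mean_amplitude": self.mean_amplitude.tolist(),
            "bootstrap_sem": self.bootstrap_sem.tolist(),
            "null_mean": self.null_mean.tolist(),
            "null_ci_low": self.null_ci_low.tolist(),
            "null_ci_high": self.null_ci_high.tolist(),
            "p_parametric": self.p_parametric,
            "p_nonparametric": self.p_nonparametric,
            "cohens_d": self.cohens_d,
            "cliffs_delta": self.cliffs_delta,
            "amp_ratio_1_over_3": self.amp_ratio_1_over_3,
            "amp_ratio_sem": self.amp_ratio_sem,
            "n_participants": self.n_participants,
            "n_boot": self.n_boot,
            "n_shuffle": self.n_shuffle,
            "excluded": list(self.excluded),
        }


def _reconstruct_logc(fits: list[DeclineFit]) -> tuple[np.ndarray, np.ndarray]:
    t = fits[0].t_years
    logc = np.vstack([
        math.log(f.baseline) - f.alpha * t + f.log_residuals for f in fits])
    return logc, t


def cohort_spectrum(
    fits: list[DeclineFit],
    n_boot: int = 1000,
    n_shuffle: int = 1000,
    seed=None,
    *,
    logc: np.ndarray | None = None,
    corrector=exponential_residuals,
) -> SpectrumResult:
    """Cohort mean Fourier amplitudes with bootstrap SEM and shuffled null.

    ``corrector`` maps a log-concentration matrix to log-residuals and is
    applied identically to the observed data and to every shuffle repeat.
    ``logc`` overrides the matrix reconstructed from ``fits`` (needed when
    the fits come from a correction that is not the exponential one).
    """
    if len(fits) < 5:
        raise SpectrumError(f"need >= 5 participants, got {len(fits)}")
    if n_shuffle < 40:
        raise SpectrumError("n_shuffle < 40: 95% CI percentiles undefined")
    rng = np.random.default_rng(seed)

    if logc is None:
        logc, t = _reconstruct_logc(fits)
    else:
        logc = np.asarray(logc, dtype=float)
        t = fits[0].t_years

    ids = [f.participant_id for f in fits]
    var = logc.var(axis=1)
    excluded = [ids[i] for i in np.nonzero(var == 0.0)[0]]
    if excluded:
        warnings.warn(f"excluding zero-variance series: {excluded}", stacklevel=2)
        keep = var > 0.0
        logc = logc[keep]
        if logc.shape[0] < 5:
            raise SpectrumError("fewer than 5 usable participants after exclusion")

    n, m = logc.shape
    resid = corrector(logc, t)
    per_part = amplitude_matrix(resid)               # (n, m/2)
    observed = per_part.mean(axis=0)
    nfreq = observed.size
    freqs = np.arange(1, nfreq + 1, dtype=float)

    boot_idx = rng.integers(0, n, size=(n_boot, n))
    boot_means = per_part[boot_idx].mean(axis=1)     # (n_boot, nfreq)
    boot_sem = boot_means.std(axis=0, ddof=1)

    # Null: permute each participant's decline-corrected values and re-run
    # the identical correction.  The correction is idempotent (residuals are
    # orthogonal to the design), so observed and null go through the same
    # code path; refitting the trend on shuffled series is what suppresses
    # the null's 1 yr^-1 amplitude relative to its higher frequencies.
    # Each re-corrected series is rescaled to its pre-permutation power:
    # the second projection would otherwise remove ~1/(n-1) of the variance
    # and bias the null low at every frequency (anticonservative test).
    null_means = np.empty((n_shuffle, nfreq))
    for r in range(n_shuffle):
        shuffled = rng.permuted(resid, axis=1)
        recorr = corrector(shuffled, t)
        power_in = np.linalg.norm(shuffled, axis=1)
        power_out = np.linalg.norm(recorr, axis=1)
        recorr = recorr * (power_in / np.where(power_out > 0, power_out, 1.0))[:, None]
        null_means[r] = amplitude_matrix(recorr).mean(axis=0)
    null_mean = null_means.mean(axis=0)
    null_lo = np.percentile(null_means, 2.5, axis=0)
    null_hi = np.percentile(null_means, 97.5, axis=0)

    obs1, null1 = observed[0], null_means[:, 0]
    null_sd = null1.std(ddof=1)
    z = (obs1 - null1.mean()) / null_sd
    p_param = float(sps.norm.sf(z))
    p_nonparam = (1.0 + np.count_nonzero(null1 >= obs1)) / (1.0 + n_shuffle)
    d = float(z)
    delta = cliffs_delta(boot_means[:, 0], null1)

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = float(observed[0] / observed[-1])
        boot_ratio = boot_means[:, 0] / boot_means[:, -1]
    ratio_sem = float(np.nanstd(boot_ratio, ddof=1))

    return SpectrumResult(
        frequencies=freqs,
        mean_amplitude=observed,
        bootstrap_sem=boot_sem,
        null_mean=null_mean,
        null_ci_low=null_lo,
        null_ci_high=null_hi,
        p_parametric=p_param,
        p_nonparametric=float(p_nonparam),
        cohens_d=d,
        cliffs_delta=delta,
        amp_ratio_1_over_3=ratio,
        amp_ratio_sem=ratio_sem,
        n_participants=n,
        n_boot=n_boot,
        n_shuffle=n_shuffle,
        excluded=excluded,
    )


def cohens_d(a, b) -> float:
    """Pooled-sd standardized mean difference (n-1 weights)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise SpectrumError("samples must be non-empty")
    va = a.var(ddof=1) if a.size > 1 else 0.0
    vb = b.var(ddof=1) if b.size > 1 else 0.0
    pooled = math.sqrt(((a.size - 1) * va + (b.size - 1) * vb)
                       / (a.size + b.size - 2))
    if pooled == 0:
        raise SpectrumError("zero pooled sd: Cohen's d undefined")
    return float((a.mean() - b.mean()) / pooled)


def cliffs_delta(a, b) -> float:
    """(#{a > b} - #{a < b}) / (n_a n_b) over all pairs; ties contribute 0."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise SpectrumError("samples must be non-empty")
    # O(n log n) via ranks rather than the n_a*n_b outer comparison
    greater = np.searchsorted(np.sort(b), a, side="left").sum()
    less_eq = np.searchsorted(np.sort(b), a, side="right").sum()
    wins = greater
    losses = a.size * b.size - less_eq
    return float((wins - losses) / (a.size * b.size))


def effect_sizes(sample_a, sample_b) -> tuple[float, float]:
    """Cohen's d (pooled sd) and Cliff's delta between two samples."""
    return cohens_d(sample_a, sample_b), cliffs_delta(sample_a, sample_b)
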