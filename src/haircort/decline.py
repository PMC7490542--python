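"""Exponential decline correction of hair cortisol.

Measured cortisol decreases systematically with distance from the scalp.
Each participant's series is corrected by ordinary least squares of
log-concentration on segment midpoint time t (years before collection):

    ln C_j = ln B - alpha * t_j + r_j

``B`` is the fitted baseline at the scalp (t = 0), ``alpha`` the decline
coefficient (yr^-1) and ``r_j`` the log-residuals that carry the biological
fluctuations analysed downstream.  A non-parametric variant subtracts the
across-cohort median log profile instead of a per-individual exponential.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .cohort import HairSeries, cohort_matrix

__all__ = [
    "DeclineFit",
    "FluctuationStats",
    "InsufficientDataError",
    "DegenerateSubtractionError",
    "fit_decline",
    "fit_cohort",
    "cohort_decline_summary",
    "fluctuation_cv",
    "noise_corrected_cv",
    "nonparametric_correct",
    "exponential_residuals",
    "nonparametric_residuals",
]


class InsufficientDataError(ValueError):
    pass


class DegenerateSubtractionError(ValueError):
    """Assay CV at or above the raw fluctuation CV: nothing left to explain."""


@dataclass(frozen=True)
class DeclineFit:
    participant_id: str
    baseline: float            # pg/mg, fitted value at the scalp (t = 0)
    alpha: float               # yr^-1
    t_years: np.ndarray        # segment midpoint times used in the fit
    log_residuals: np.ndarray  # r_j = ln C_j - (ln B - alpha t_j); OLS => mean 0
    fit_r2: float

    @property
    def normalized(self) -> np.ndarray:
        """Decline-corrected concentrations relative to the fitted trend."""
        return np.exp(self.log_residuals)


@dataclass(frozen=True)
class FluctuationStats:
    per_participant_cv: np.ndarray
    mean_cv_raw: float
    assay_cv: float
    mean_cv_noise_corrected: float


def _ols_log_linear(logc: np.ndarray, t: np.ndarray):
    """Row-wise OLS of logc (n x m) on [1, t]; returns intercepts, slopes,
    residual matrix and R^2 per row.  Closed-form normal equations so the
    same code path serves single fits and the 1,000-repeat shuffle null."""
    X = np.column_stack([np.ones_like(t), t])
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = logc @ X @ xtx_inv.T              # (n, 2): [intercept, slope]
    resid = logc - beta @ X.T
    ss_res = np.sum(resid ** 2, axis=1)
    centered = logc - logc.mean(axis=1, keepdims=True)
    ss_tot = np.sum(centered ** 2, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 1.0)
    return beta[:, 0], beta[:, 1], resid, r2


def exponential_residuals(logc: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Log-residual matrix of the per-row exponential (log-linear OLS) fit.

    This is the corrector applied identically to observed and shuffled data.
    """
    return _ols_log_linear(logc, t)[2]


def fit_decline(series: HairSeries) -> DeclineFit:
    if series.n_segments < 3:
        raise InsufficientDataError(
            f"{series.participant_id}: need >= 3 segments, got {series.n_segments}")
    t = series.segment_midpoint_years
    logc = np.log(series.concentrations)[None, :]
    b0, b1, resid, r2 = _ols_log_linear(logc, t)
    return DeclineFit(
        participant_id=series.participant_id,
        baseline=float(np.exp(b0[0])),
        alpha=float(-b1[0]),
        t_years=t,
        log_residuals=resid[0],
        fit_r2=float(r2[0]),
    )


def fit_cohort(cohort: list[HairSeries]) -> list[DeclineFit]:
    """Vectorised :func:`fit_decline` over a uniform-length cohort."""
    ids, logc, t = cohort_matrix(cohort)
    if t.size < 3:
        raise InsufficientDataError("need >= 3 segments")
    b0, b1, resid, r2 = _ols_log_linear(logc, t)
    return [
        DeclineFit(pid, float(np.exp(b0[i])), float(-b1[i]), t, resid[i], float(r2[i]))
        for i, pid in enumerate(ids)
    ]


def cohort_decline_summary(fits: list[DeclineFit]):
    """Mean and SEM of alpha across participants, and the fold range
    (max/min) of fitted baselines."""
    if len(fits) < 2:
        raise InsufficientDataError("need >= 2 fits for a cohort summary")
    alphas = np.array([f.alpha for f in fits])
    baselines = np.array([f.baseline for f in fits])
    mean_alpha = float(alphas.mean())
    sem_alpha = float(alphas.std(ddof=1) / math.sqrt(alphas.size))
    fold = float(baselines.max() / baselines.min())
    return mean_alpha, sem_alpha, fold


def noise_corrected_cv(mean_cv_raw: float, assay_cv: float) -> float:
    """Quadrature subtraction of assay noise from a raw fluctuation CV."""
    if assay_cv < 0:
        raise ValueError("assay_cv must be >= 0")
    if assay_cv >= mean_cv_raw:
        raise DegenerateSubtractionError(
            f"assay CV {assay_cv} >= raw fluctuation CV {mean_cv_raw:.4f}")
    return math.sqrt(mean_cv_raw ** 2 - assay_cv ** 2)


def fluctuation_cv(fits: list[DeclineFit], assay_cv: float) -> FluctuationStats:
    """Per-participant CV (sd/mean of the normalized series), cohort mean,
    and quadrature subtraction of the assay noise:

        cv_corrected = sqrt(mean_cv_raw^2 - assay_cv^2)
    """
    if not fits:
        raise InsufficientDataError("no fits")
    if assay_cv < 0:
        raise ValueError("assay_cv must be >= 0")
    cvs = np.array([f.normalized.std(ddof=1) / f.normalized.mean() for f in fits])
    mean_raw = float(cvs.mean())
    if assay_cv == 0:
        return FluctuationStats(cvs, mean_raw, 0.0, mean_raw)
    corrected = noise_corrected_cv(mean_raw, assay_cv)
    return FluctuationStats(cvs, mean_raw, assay_cv, corrected)


def nonparametric_residuals(logc: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Median-profile corrector: subtract the across-cohort median log
    concentration per segment position, then centre each row."""
    prof = np.median(logc, axis=0)
    resid = logc - prof[None, :]
    return resid - resid.mean(axis=1, keepdims=True)


def nonparametric_correct(cohort: list[HairSeries]) -> list[DeclineFit]:
    """Decline correction without a per-individual parametric model.

    The common decline shape is taken as the across-cohort median log
    profile per segment position; each individual's log series minus that
    profile, centred to zero mean, is the residual series.  The result is
    packaged as :class:`DeclineFit` objects (alpha from the median profile's
    own log-linear slope, shared by all participants) so the downstream
    spectrum pipeline is agnostic to the correction method.
    """
    ids, logc, t = cohort_matrix(cohort)
    resid = nonparametric_residuals(logc, t)
    prof = np.median(logc, axis=0)
    b0, b1, _, _ = _ols_log_linear(prof[None, :], t)
    shared_alpha = float(-b1[0])
    fits = []
    for i, pid in enumerate(ids):
        level = float(np.exp(logc[i].mean() - prof.mean() + b0[0]))
        fits.append(DeclineFit(pid, level, shared_alpha, t, resid[i], float("nan")))
    return fits
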