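"""Cosinor (12-month) seasonality of decline-corrected cortisol.

Each hair segment is dated by its midpoint (collection date minus the
segment's growth offset at 1 cm/month), giving a calendar month-of-year in
[0, 12).  A single cohort-level cosinor is fitted by OLS to the pooled
log-residuals:

    r = mesor + beta_c cos(2 pi m / 12) + beta_s sin(2 pi m / 12)

amplitude = sqrt(beta_c^2 + beta_s^2) (~ fractional amplitude of the
multiplicative seasonal factor, for small amplitudes) and the acrophase is
the month of peak.  A per-individual cosinor is not identifiable from six
points in the presence of a 1 yr^-1 fluctuation, so the fit is pooled; the
decline fit has already centred each individual's residuals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .cohort import HairSeries
from .decline import DeclineFit, FluctuationStats, fluctuation_cv

__all__ = [
    "CosinorFit",
    "CosinorError",
    "fit_cosinor",
    "seasonal_points",
    "fit_cohort_cosinor",
    "deseasonalize",
]

MONTHS = 12.0


class CosinorError(ValueError):
    pass


@dataclass(frozen=True)
class CosinorFit:
    mesor: float            # log-residual intercept
    amplitude: float        # >= 0, fraction (log scale ~ fractional)
    acrophase_month: float  # month of peak, in [0, 12)
    beta_cos: float
    beta_sin: float
    residual_cv: float      # cohort CV after removing the seasonal term
    n_points: int

    def predict(self, month: np.ndarray) -> np.ndarray:
        w = 2.0 * math.pi * np.asarray(month, dtype=float) / MONTHS
        return self.mesor + self.beta_cos * np.cos(w) + self.beta_sin * np.sin(w)


def fit_cosinor(months, log_residuals) -> CosinorFit:
    """OLS cosinor on pooled (month-of-year, log-residual) points.

    Requires >= 3 distinct sampling months spanning more than 1/3 of a year;
    raises :class:`CosinorError` if the harmonic regressors are not
    identifiable (e.g. all samples in the same month).
    """
    m = np.asarray(months, dtype=float)
    r = np.asarray(log_residuals, dtype=float)
    if m.shape != r.shape or m.ndim != 1:
        raise CosinorError("months and log_residuals must be equal-length 1-d")
    distinct = np.unique(np.round(m % MONTHS, 6))
    if distinct.size < 3:
        raise CosinorError("need >= 3 distinct calendar times")
    gaps = np.diff(np.concatenate([distinct, [distinct[0] + MONTHS]]))
    circular_span = MONTHS - gaps.max()
    if circular_span <= MONTHS / 3:
        raise CosinorError("calendar times must span more than 1/3 of a year")

    w = 2.0 * math.pi * m / MONTHS
    X = np.column_stack([np.ones_like(w), np.cos(w), np.sin(w)])
    if np.linalg.matrix_rank(X) < 3:
        raise CosinorError("cosinor design matrix is rank deficient")
    beta, *_ = np.linalg.lstsq(X, r, rcond=None)
    mesor, bc, bs = (float(v) for v in beta)
    amplitude = math.hypot(bc, bs)
    acrophase = (math.atan2(bs, bc) * MONTHS / (2.0 * math.pi)) % MONTHS
    resid = r - X @ beta
    norm = np.exp(resid)
    cv = float(norm.std(ddof=1) / norm.mean())
    return CosinorFit(mesor, amplitude, acrophase, bc, bs, cv, m.size)


def seasonal_points(cohort: list[HairSeries], fits: list[DeclineFit]):
    """Pool (month-of-year, log-residual) pairs over all segments.

    Returns (months, residuals, per-participant month matrix) with rows
    aligned to ``fits``.
    """
    if len(cohort) != len(fits):
        raise CosinorError("cohort and fits differ in length")
    by_id = {s.participant_id: s for s in cohort}
    month_rows, resid_rows = [], []
    for f in fits:
        s = by_id.get(f.participant_id)
        if s is None:
            raise CosinorError(f"no series for fit {f.participant_id}")
        month_rows.append(s.segment_month_of_year)
        resid_rows.append(f.log_residuals)
    month_mat = np.vstack(month_rows)
    resid_mat = np.vstack(resid_rows)
    return month_mat.ravel(), resid_mat.ravel(), month_mat


def fit_cohort_cosinor(
    cohort: list[HairSeries],
    fits: list[DeclineFit],
    decline_aware: bool = True,
) -> CosinorFit:
    """Cohort-level cosinor of decline-corrected cortisol.

    With ``decline_aware`` (default), the harmonic regressors are passed
    through each participant's detrending projector before the pooled OLS
    (Frisch-Waugh), which makes the fit equivalent to a joint regression of
    log-concentration on per-participant intercept + slope plus shared
    cos/sin terms.  The plain residual cosinor underestimates the seasonal
    amplitude by ~1/3 here, because a 12-month cosine sampled over exactly
    one year of hair is partly absorbed by each individual's exponential
    trend; the projected fit is unbiased.
    """
    months, resid, month_mat = seasonal_points(cohort, fits)
    if not decline_aware:
        return fit_cosinor(months, resid)

    t = fits[0].t_years
    X = np.column_stack([np.ones_like(t), t])
    R = np.eye(t.size) - X @ np.linalg.inv(X.T @ X) @ X.T
    w = 2.0 * math.pi * month_mat / MONTHS
    Z = np.column_stack([(np.cos(w) @ R.T).ravel(), (np.sin(w) @ R.T).ravel()])
    if np.linalg.matrix_rank(Z) < 2:
        raise CosinorError("cosinor design matrix is rank deficient")
    beta, *_ = np.linalg.lstsq(Z, resid, rcond=None)
    bc, bs = (float(v) for v in beta)
    amplitude = math.hypot(bc, bs)
    acrophase = (math.atan2(bs, bc) * MONTHS / (2.0 * math.pi)) % MONTHS
    fitted = Z @ beta
    norm = np.exp(resid - fitted)
    cv = float(norm.std(ddof=1) / norm.mean())
    # mesor of the residuals is 0 by construction of the decline fit
    return CosinorFit(0.0, amplitude, acrophase, bc, bs, cv, resid.size)


def deseasonalize(
    fits: list[DeclineFit],
    cosinor: CosinorFit,
    cohort: list[HairSeries],
    assay_cv: float = 0.14,
) -> tuple[list[DeclineFit], FluctuationStats]:
    """Remove the fitted multiplicative seasonal factor and re-run the
    decline correction, then recompute the fluctuation CV with assay-noise
    subtraction.

    Dividing the concentrations by exp(seasonal term) before refitting keeps
    the residuals exactly zero-mean (the decline-fit invariant), which a
    plain subtraction of the harmonic from the old residuals would not.
    """
    from .decline import fit_cohort

    _, _, month_mat = seasonal_points(cohort, fits)
    w = 2.0 * math.pi * month_mat / MONTHS
    seasonal = cosinor.beta_cos * np.cos(w) + cosinor.beta_sin * np.sin(w)
    by_id = {s.participant_id: s for s in cohort}
    ordered = [by_id[f.participant_id] for f in fits]
    adjusted = [replace(s, concentrations=s.concentrations * np.exp(-seasonal[i]))
                for i, s in enumerate(ordered)]
    out = fit_cohort(adjusted)
    stats = fluctuation_cv(out, assay_cv)
    return out, stats
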