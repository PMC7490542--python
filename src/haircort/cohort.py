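"""Synthetic hair-cortisol cohorts.

A cohort is a list of :class:`HairSeries`, one per participant.  Each series
holds the cortisol concentration (pg/mg) of consecutive 2-cm hair segments,
segment 1 being closest to the scalp (most recent growth).  With hair growing
at ~1 cm/month, six 2-cm segments cover about one year retrospectively.

The generator composes, per participant ``i`` and segment midpoint time ``t``
(years before collection):

    C_i(t) = B_i * exp(-alpha_i * t) * S(month(t)) * F_i(t) * eps

where ``B_i`` is a lognormal between-person baseline, ``alpha_i`` the
exponential decline coefficient of cortisol along the hair, ``S`` a cosinor
seasonal factor, ``F_i`` a slow multiplicative biological-fluctuation process
with selectable frequency content, and ``eps`` multiplicative assay noise.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field, replace
from datetime import date, timedelta

import numpy as np

__all__ = [
    "CohortParams",
    "HairSeries",
    "CohortError",
    "CohortParseError",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "cohort_matrix",
    "month_fraction",
    "lognormal_sigma",
]

MONTHS_PER_YEAR = 12.0


class CohortError(ValueError):
    """Invalid cohort parameters or series."""


class CohortParseError(CohortError):
    """Malformed cohort CSV."""


def lognormal_sigma(cv: float) -> float:
    """Log-scale sd of a lognormal with coefficient of variation ``cv``."""
    return math.sqrt(math.log1p(cv * cv))


def month_fraction(d: date) -> float:
    """Continuous month-of-year in [0, 12) for a calendar date."""
    return (d - date(d.year, 1, 1)).days / 365.25 * MONTHS_PER_YEAR


@dataclass(frozen=True)
class HairSeries:
    """One participant's ordered hair-segment cortisol series.

    ``concentrations[0]`` is the scalp-proximal segment (most recent).
    Segment midpoint times are years *before* the collection date.
    """

    participant_id: str
    collection_date: date
    concentrations: np.ndarray
    segment_length_cm: float = 2.0
    growth_rate_cm_per_month: float = 1.0

    def __post_init__(self):
        c = np.asarray(self.concentrations, dtype=float)
        object.__setattr__(self, "concentrations", c)
        if c.ndim != 1 or c.size < 1:
            raise CohortError(f"{self.participant_id}: concentrations must be a 1-d series")
        if not np.all(c > 0):
            raise CohortError(f"{self.participant_id}: concentrations must be strictly positive")
        if self.growth_rate_cm_per_month <= 0:
            raise CohortError("growth_rate_cm_per_month must be > 0")

    @property
    def n_segments(self) -> int:
        return self.concentrations.size

    @property
    def segment_midpoint_years(self) -> np.ndarray:
        """Midpoint of segment i sits (i - 1/2) segment-lengths from the scalp."""
        i = np.arange(1, self.n_segments + 1)
        months = self.segment_length_cm * (i - 0.5) / self.growth_rate_cm_per_month
        return months / MONTHS_PER_YEAR

    @property
    def segment_month_of_year(self) -> np.ndarray:
        """Calendar month-of-year of each segment midpoint, in [0, 12)."""
        m0 = month_fraction(self.collection_date)
        return (m0 - self.segment_midpoint_years * MONTHS_PER_YEAR) % MONTHS_PER_YEAR


@dataclass(frozen=True)
class CohortParams:
    """Generator settings; defaults reproduce the cohort structure the
    analysis assumes (n = 55, six 2-cm segments, ~30-fold baseline spread,
    decline 2.2 yr^-1, assay CV 14%, seasonality 15%, slow fluctuations 22%).
    """

    n_participants: int = 55
    n_segments: int = 6
    segment_length_cm: float = 2.0
    growth_rate_cm_per_month: float = 1.0
    baseline_median: float = 10.0          # pg/mg
    # ln-scale sd; the expected log-range of 55 normal draws is ~4.6 sd,
    # so 0.75 puts the cohort max/min baseline ratio near 30-fold
    baseline_log_sd: float = 0.75
    decay_mean: float = 2.2                # yr^-1
    decay_sd: float = 0.5                  # yr^-1, truncated at 0
    assay_cv: float = 0.14
    seasonal_amplitude: float = 0.15       # fraction of baseline
    seasonal_acrophase_month: float = 1.5  # late winter peak
    fluctuation_cv: float = 0.22
    # single_frequency at 1 yr^-1 emulates the observed dominant year-scale
    # fluctuation; white and one_over_f cover featureless / broadband content
    fluctuation_spectrum: str = "single_frequency"
    fluctuation_frequency: float = 1.0     # yr^-1, for single_frequency only
    collection_start: date = date(2019, 1, 1)
    collection_end: date = date(2019, 12, 31)
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 1:
            raise CohortError("n_participants must be >= 1")
        if self.n_segments < 4:
            raise CohortError("n_segments must be >= 4 (DFT needs >= 2 nonzero frequencies)")
        if self.segment_length_cm <= 0:
            raise CohortError("segment_length_cm must be > 0")
        if self.growth_rate_cm_per_month <= 0:
            raise CohortError("growth_rate_cm_per_month must be > 0")
        for name in ("baseline_log_sd", "decay_sd", "assay_cv",
                     "seasonal_amplitude", "fluctuation_cv"):
            if getattr(self, name) < 0:
                raise CohortError(f"{name} must be >= 0")
        if self.baseline_median <= 0:
            raise CohortError("baseline_median must be > 0")
        if self.fluctuation_spectrum not in ("white", "one_over_f", "single_frequency"):
            raise CohortError(
                f"fluctuation_spectrum must be white, one_over_f or single_frequency, "
                f"got {self.fluctuation_spectrum!r}")
        if self.fluctuation_spectrum == "single_frequency" and self.fluctuation_frequency <= 0:
            raise CohortError("fluctuation_frequency must be > 0")
        if self.collection_end < self.collection_start:
            raise CohortError("collection_end must be >= collection_start")


# --- fluctuation processes -------------------------------------------------
#
# All processes produce a zero-mean log-scale signal g at the segment
# midpoints, with population sd sigma = sqrt(ln(1 + cv^2)) so that the
# multiplicative factor exp(g) has coefficient of variation ~ cv.

_ONE_OVER_F_PERIOD_MONTHS = 48.0   # synthesis period: power down to 0.25 yr^-1
_ONE_OVER_F_K_MAX = 96             # highest harmonic: 24 yr^-1


def _fluct_white(rng, n_series, t_months, sigma):
    return rng.normal(0.0, sigma, size=(n_series, t_months.size))


def _fluct_single_frequency(rng, n_series, t_months, sigma, freq_per_year):
    # Random phase per participant; over phase, var(a*cos) = a^2/2.
    a = math.sqrt(2.0) * sigma
    phi = rng.uniform(0.0, 2.0 * math.pi, size=(n_series, 1))
    omega = 2.0 * math.pi * freq_per_year / MONTHS_PER_YEAR
    return a * np.cos(omega * t_months[None, :] + phi)


def _fluct_one_over_f(rng, n_series, t_months, sigma, window_months):
    """Spectral synthesis of 1/f log-fluctuations, window-averaged per segment.

    Harmonics of a long (4-year) period with amplitude proportional to 1/f and
    i.i.d. phases; averaging over the segment window attenuates harmonic k by
    sinc(pi*k*w/T), which is folded into the closed-form variance used to
    scale the process to the requested sd.
    """
    T = _ONE_OVER_F_PERIOD_MONTHS
    k = np.arange(1, _ONE_OVER_F_K_MAX + 1)
    amp = 1.0 / k
    x = math.pi * k * window_months / T
    sinc = np.sin(x) / x
    var_unscaled = float(np.sum((amp * sinc) ** 2) / 2.0)
    scale = sigma / math.sqrt(var_unscaled)
    phi = rng.uniform(0.0, 2.0 * math.pi, size=(n_series, k.size))
    arg = 2.0 * math.pi * np.einsum("k,t->tk", k, t_months) / T  # (t, k)
    g = np.einsum("k,ntk->nt",
                  amp * sinc * scale,
                  np.cos(arg[None, :, :] + phi[:, None, :]))
    return g


def generate_cohort(params: CohortParams) -> list[HairSeries]:
    """Draw a synthetic cohort; bit-reproducible for a fixed ``rng_seed``."""
    params.validate()
    p = params
    rng = np.random.default_rng(p.rng_seed)
    n, m = p.n_participants, p.n_segments

    t_years = HairSeries(
        "template", p.collection_start, np.ones(m),
        p.segment_length_cm, p.growth_rate_cm_per_month).segment_midpoint_years
    t_months = t_years * MONTHS_PER_YEAR
    window_months = p.segment_length_cm / p.growth_rate_cm_per_month

    baselines = p.baseline_median * np.exp(rng.normal(0.0, p.baseline_log_sd, size=n))
    alphas = rng.normal(p.decay_mean, p.decay_sd, size=n) if p.decay_sd > 0 \
        else np.full(n, p.decay_mean)
    alphas = np.clip(alphas, 0.0, None)

    span_days = (p.collection_end - p.collection_start).days
    offsets = rng.integers(0, span_days + 1, size=n)
    dates = [p.collection_start + timedelta(days=int(d)) for d in offsets]

    if p.fluctuation_cv > 0:
        sig = lognormal_sigma(p.fluctuation_cv)
        if p.fluctuation_spectrum == "white":
            g = _fluct_white(rng, n, t_months, sig)
        elif p.fluctuation_spectrum == "single_frequency":
            g = _fluct_single_frequency(rng, n, t_months, sig, p.fluctuation_frequency)
        else:
            g = _fluct_one_over_f(rng, n, t_months, sig, window_months)
    else:
        g = np.zeros((n, m))

    if p.assay_cv > 0:
        s_eps = lognormal_sigma(p.assay_cv)
        log_eps = rng.normal(-0.5 * s_eps * s_eps, s_eps, size=(n, m))
    else:
        log_eps = np.zeros((n, m))

    cohort = []
    for i in range(n):
        m0 = month_fraction(dates[i])
        month = (m0 - t_months) % MONTHS_PER_YEAR
        seasonal = 1.0 + p.seasonal_amplitude * np.cos(
            2.0 * math.pi * (month - p.seasonal_acrophase_month) / MONTHS_PER_YEAR)
        conc = (baselines[i] * np.exp(-alphas[i] * t_years) * seasonal
                * np.exp(g[i]) * np.exp(log_eps[i]))
        cohort.append(HairSeries(
            participant_id=f"P{i + 1:03d}",
            collection_date=dates[i],
            concentrations=conc,
            segment_length_cm=p.segment_length_cm,
            growth_rate_cm_per_month=p.growth_rate_cm_per_month,
        ))
    return cohort


# --- CSV i/o ---------------------------------------------------------------

_CSV_FIELDS = ["participant_id", "collection_date", "segment_index", "cortisol_pg_per_mg"]


def write_cohort(cohort: list[HairSeries], path) -> None:
    """Long-format CSV: participant_id, collection_date (ISO 8601),
    segment_index (1 = scalp-proximal), cortisol_pg_per_mg."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_CSV_FIELDS)
        for s in cohort:
            for j, c in enumerate(s.concentrations, start=1):
                w.writerow([s.participant_id, s.collection_date.isoformat(), j, repr(float(c))])


def read_cohort(path, expected_segments: int | None = None) -> list[HairSeries]:
    """Read a cohort CSV; raises :class:`CohortParseError` (with the row
    number) on malformed rows, non-positive concentrations, or duplicate
    (participant, segment) pairs.  Participants whose segment count differs
    from ``expected_segments`` (or from the cohort mode) trigger a warning."""
    rows: dict[str, dict] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = [f for f in _CSV_FIELDS if f not in (reader.fieldnames or [])]
        if missing:
            raise CohortParseError(f"missing columns: {missing}")
        for lineno, row in enumerate(reader, start=2):
            try:
                pid = row["participant_id"]
                d = date.fromisoformat(row["collection_date"])
                j = int(row["segment_index"])
                c = float(row["cortisol_pg_per_mg"])
            except (KeyError, TypeError, ValueError) as exc:
                raise CohortParseError(f"row {lineno}: malformed ({exc})") from exc
            if c <= 0:
                raise CohortParseError(f"row {lineno}: non-positive cortisol {c}")
            if j < 1:
                raise CohortParseError(f"row {lineno}: segment_index must be >= 1")
            entry = rows.setdefault(pid, {"date": d, "segments": {}})
            if entry["date"] != d:
                raise CohortParseError(f"row {lineno}: conflicting collection_date for {pid}")
            if j in entry["segments"]:
                raise CohortParseError(f"row {lineno}: duplicate segment {j} for {pid}")
            entry["segments"][j] = c
    if not rows:
        raise CohortParseError("empty cohort file")

    counts = [len(e["segments"]) for e in rows.values()]
    # modal segment count; ties resolved toward the larger count
    expected = expected_segments or max(sorted(set(counts)),
                                        key=lambda c: (counts.count(c), c))
    cohort = []
    for pid, entry in rows.items():
        idx = sorted(entry["segments"])
        if idx != list(range(1, len(idx) + 1)):
            raise CohortParseError(f"participant {pid}: non-contiguous segment indices {idx}")
        if len(idx) != expected:
            warnings.warn(
                f"participant {pid} has {len(idx)} segments, expected {expected}",
                stacklevel=2)
        cohort.append(HairSeries(
            participant_id=pid,
            collection_date=entry["date"],
            concentrations=np.array([entry["segments"][j] for j in idx]),
        ))
    return cohort


def cohort_matrix(cohort: list[HairSeries]):
    """Stack a uniform-length cohort into arrays.

    Returns ``(ids, log_conc, t_years)`` with ``log_conc`` of shape
    (n_participants, n_segments) and ``t_years`` the shared midpoint times.
    """
    if not cohort:
        raise CohortError("empty cohort")
    m = cohort[0].n_segments
    if any(s.n_segments != m for s in cohort):
        raise CohortError("mixed segment counts in cohort")
    ids = [s.participant_id for s in cohort]
    logc = np.log(np.vstack([s.concentrations for s in cohort]))
    return ids, logc, cohort[0].segment_midpoint_years
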