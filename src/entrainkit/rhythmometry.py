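"""Cosinor rhythmometry and the χ²-periodogram.

Cosinor: least-squares fit of a single cosine at a fixed trial period τ,

    y(t) = M + β_c·cos(2πt/τ) + β_s·sin(2πt/τ),

giving the mesor M (rhythm-adjusted mean), amplitude A = √(β_c²+β_s²)
(half peak-to-trough) and acrophase φ (time of the fitted peak).  The
acrophase is reported in zeitgeber-time hours of the fitted peak rather
than the negative-radians convention of the classical cosinor literature.

χ²-periodogram: for each trial period the series is folded into that many
phase columns and the between-column variance of column means is compared
with the total variance; the rhythm's period is taken at the highest peak
of the statistic over the trial-period grid (20–25 h at 5-min resolution
by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, FitError, ParameterError
from .io import BinnedSeries
from .simulate import ExpressionCourse


@dataclass(frozen=True)
class CosinorFit:
    """Single-component cosinor estimates at a fixed trial period.

    ``acrophase_zt_hours`` is NaN (flagged undefined) when the input is
    constant; ``percent_rhythm`` is the fraction of variance explained.
    """

    trial_period_hours: float
    mesor: float
    amplitude: float
    acrophase_zt_hours: float
    residual_variance: float
    n_points: int
    percent_rhythm: float

    @property
    def acrophase_defined(self) -> bool:
        return bool(np.isfinite(self.acrophase_zt_hours))


@dataclass(frozen=True)
class PeriodogramResult:
    """χ²-periodogram curve and its peak."""

    trial_periods_hours: np.ndarray
    qp_values: np.ndarray
    peak_period_hours: float
    df_per_period: np.ndarray
    significance_threshold: np.ndarray  # χ² 0.99 quantile per trial period


# ----------------------------------------------------------------------
# cosinor
# ----------------------------------------------------------------------

def _cosinor_arrays(series) -> tuple[np.ndarray, np.ndarray]:
    """Time (hours, on the unwrapped ZT axis) and value arrays."""
    if isinstance(series, BinnedSeries):
        # unwrapped ZT: within one regime segment ZT advances 1 h per hour
        t = series.zt_hours[0] + np.arange(len(series)) * series.epoch_hours
        return t, series.counts.astype(float)
    if isinstance(series, ExpressionCourse):
        return series.sample_times_hours, series.values
    t, y = series
    return np.asarray(t, dtype=float), np.asarray(y, dtype=float)


def cosinor_fit(series, trial_period_hours: float = 24.0) -> CosinorFit:
    """Least-squares single-cosine fit at a fixed trial period.

    Accepts a :class:`BinnedSeries` (fitted on its ZT axis so the
    acrophase is directly a ZT), an :class:`ExpressionCourse` (times are
    hours post-synchronization), or a plain ``(times, values)`` pair.

    Raises
    ------
    FitError
        Fewer than 4 points, less than one full trial period spanned, or
        fewer than 3 distinct phases sampled.
    """
    if trial_period_hours <= 0:
        raise ParameterError("trial period must be positive")
    t, y = _cosinor_arrays(series)
    if t.size < 4:
        raise FitError("cosinor needs at least 4 points")
    tau = trial_period_hours
    sparse = t.size < 16  # sparse expression-style sampling
    span = t.max() - t.min()
    step = span / (t.size - 1)  # one more sample closes the period
    if not sparse and span + step < tau - 1e-9:
        raise FitError("series must span at least one full trial period")
    phases = np.unique(np.round(np.mod(t, tau) / tau, 6))
    if phases.size < 3:
        raise FitError("need samples at ≥ 3 distinct phases of the trial period")

    omega = 2 * np.pi / tau
    design = np.column_stack([np.ones_like(t), np.cos(omega * t),
                              np.sin(omega * t)])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    mesor, beta_c, beta_s = (float(c) for c in coef)
    amplitude = float(np.hypot(beta_c, beta_s))
    resid = y - design @ coef
    rvar = float(resid @ resid) / max(t.size - 3, 1)
    sst = float(np.sum((y - y.mean()) ** 2))
    pr = 1.0 - float(resid @ resid) / sst if sst > 0 else 0.0

    if amplitude < 1e-12 * max(1.0, abs(mesor)) or sst == 0.0:
        acro = float("nan")  # constant input: peak time undefined
        amplitude = 0.0
    else:
        # y = A·cos(ω t − ψ) peaks at t = ψ/ω (+ kτ); map into [0, 24)
        psi = np.arctan2(beta_s, beta_c)
        acro = float(np.mod(psi / omega, tau) % 24.0)
    return CosinorFit(
        trial_period_hours=tau,
        mesor=mesor,
        amplitude=amplitude,
        acrophase_zt_hours=acro,
        residual_variance=rvar,
        n_points=int(t.size),
        percent_rhythm=max(pr, 0.0),
    )


def cosinor_per_cycle(series: BinnedSeries,
                      trial_period_hours: float = 24.0) -> list[CosinorFit]:
    """One cosinor fit per whole trial-period cycle of the series."""
    per_cycle = int(round(trial_period_hours / series.epoch_hours))
    n_cycles = len(series) // per_cycle
    if n_cycles < 1:
        raise FitError("series shorter than one trial period")
    out = []
    for k in range(n_cycles):
        sl = slice(k * per_cycle, (k + 1) * per_cycle)
        t = series.zt_hours[0] + np.arange(len(series))[sl] * series.epoch_hours
        out.append(cosinor_fit((t, series.counts[sl].astype(float)),
                               trial_period_hours))
    return out


# ----------------------------------------------------------------------
# χ²-periodogram
# ----------------------------------------------------------------------

def chi_square_periodogram(
    series: BinnedSeries,
    period_min_hours: float = 20.0,
    period_max_hours: float = 25.0,
    step_seconds: float = 300.0,
    whole_cycles: bool = False,
) -> PeriodogramResult:
    """Folded-variance (χ²) periodogram over a trial-period grid.

    For each trial period P (an integer number of epochs) the series is
    folded into P phase columns with means M_h, column counts K_h and
    grand mean M̄.  The default statistic uses every point and weights
    each column by its count (the one-way-ANOVA between-column sum of
    squares):

        Qp = N · Σ_h K_h (M_h − M̄)² / Σ_i (x_i − M̄)².

    Since the within-column variance is non-negative, Qp ≤ N with
    equality exactly when every column is constant, so on noiseless
    periodic input the grid argmax is the true period; and the noise
    expectation of the numerator, Σ_h K_h·σ²/K_h = P·σ², varies smoothly
    along the period grid.  With ``whole_cycles`` the series is instead
    truncated to the largest whole number of cycles K per trial period
    and Qp = N_used·Σ_h(M_h − M̄)²/Σ_i(x_i − M̄)² with N_used = K·P
    (equal column counts); the cycle count then changes discontinuously
    along the grid, which inflates Qp on the long-period side of such
    steps on short records, so the all-points fold is the default.  The
    peak is the grid argmax of Qp; ties are broken toward the period
    closest to 24 h, then toward the smaller period.  A χ²(P−1) 0.99
    quantile per trial period is reported for reference but plays no
    role in peak selection.
    """
    dt_s = series.epoch_seconds
    if step_seconds % dt_s > 1e-9 and dt_s % step_seconds > 1e-9:
        raise ParameterError("epoch length must divide the period step")
    x = series.counts.astype(float)
    n = x.size
    if n * dt_s / 3600.0 < 2 * period_max_hours:
        raise ParameterError(
            "series must span at least two cycles of the longest trial period"
        )
    if np.ptp(x) == 0:
        raise DegenerateInputError("constant series has no periodicity")

    p_lo = int(round(period_min_hours * 3600 / dt_s))
    p_hi = int(round(period_max_hours * 3600 / dt_s))
    step = max(1, int(round(step_seconds / dt_s)))
    periods_epochs = np.arange(p_lo, p_hi + 1, step)

    qp = np.empty(len(periods_epochs))
    for i, p in enumerate(periods_epochs):
        if whole_cycles:
            k = n // p
            used = x[: k * p]
            col_means = used.reshape(k, p).mean(axis=0)
            grand = used.mean()
            num = float(np.sum((col_means - grand) ** 2))
            n_used = k * p
        else:
            cols = np.arange(n) % p
            counts = np.bincount(cols, minlength=p)
            col_means = np.bincount(cols, weights=x, minlength=p) / counts
            used = x
            grand = x.mean()
            num = float(np.sum(counts * (col_means - grand) ** 2))
            n_used = n
        denom = float(np.sum((used - grand) ** 2))
        qp[i] = n_used * num / denom if denom > 0 else 0.0

    hours = periods_epochs * dt_s / 3600.0
    best = qp.max()
    tied = np.flatnonzero(np.isclose(qp, best, rtol=0, atol=1e-12))
    # deterministic tie-break: closest to 24 h, then the smaller period
    order = sorted(tied, key=lambda j: (abs(hours[j] - 24.0), hours[j]))
    peak = float(hours[order[0]])
    df = periods_epochs - 1
    return PeriodogramResult(
        trial_periods_hours=hours,
        qp_values=qp,
        peak_period_hours=peak,
        df_per_period=df,
        significance_threshold=stats.chi2.ppf(0.99, df),
    )
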