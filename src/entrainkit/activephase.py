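"""Active-phase detection: smoothed above-mean activity bouts per LD cycle.

The procedure mirrors standard rodent actigraphy practice: 5-min binned
counts are smoothed with a sliding Gaussian window of 4 h total width,
epochs above the individual's window mean are classified "active", runs
of active epochs separated by gaps of at most 1 h are merged into one
bout, and each bout is assigned to an LD cycle.  Onset and offset are the
ZT of the bout's first epoch start and of the epoch after its last; the
duration is their difference on the unwrapped axis (offsets running past
lights-on exceed 24).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .io import BinnedSeries
from .schedules import LightSchedule

logger = logging.getLogger("entrainkit")

#: half-cycle window boundaries for assigning a bout to an LD cycle:
#: a bout belongs to the cycle whose dark onset D satisfies
#: midpoint ∈ [D − 6 h, D + 18 h); the 6-h lead keeps anticipatory
#: onsets attached to the coming night
CYCLE_LEAD_HOURS = 6.0


@dataclass(frozen=True)
class SmoothedSeries:
    """Gaussian-smoothed activity on the same axis as its source."""

    animal_id: str
    epoch_seconds: float
    start_hours: float
    values: np.ndarray
    zt_hours: np.ndarray
    regime: np.ndarray
    span_hours: float
    sigma_hours: float

    @property
    def epoch_hours(self) -> float:
        return self.epoch_seconds / 3600.0

    @property
    def times_hours(self) -> np.ndarray:
        return self.start_hours + np.arange(len(self.values)) * self.epoch_hours

    def __len__(self) -> int:
        return int(len(self.values))


@dataclass(frozen=True)
class ActivePhase:
    """One above-mean activity bout assigned to one LD cycle.

    ``onset_zt_hours``/``offset_zt_hours`` are unwrapped relative to the
    bout's cycle (dark onset = ZT 12 exactly), so the offset may exceed
    24 when activity runs past lights-on and
    ``duration_hours = offset − onset`` stays linear.  ``offset_zt_mod24``
    gives the wrapped value for plotting.
    """

    animal_id: str
    cycle_index: int
    onset_zt_hours: float
    offset_zt_hours: float
    duration_hours: float
    secondary: bool = False

    @property
    def onset_zt_mod24(self) -> float:
        return self.onset_zt_hours % 24.0

    @property
    def offset_zt_mod24(self) -> float:
        return self.offset_zt_hours % 24.0


def _gaussian_kernel(epoch_hours: float, span_hours: float,
                     sigma_hours: float) -> np.ndarray:
    half = int(round(span_hours / 2.0 / epoch_hours))
    k = np.arange(-half, half + 1) * epoch_hours
    w = np.exp(-0.5 * (k / sigma_hours) ** 2)
    return w / w.sum()


def gaussian_smooth(
    series: BinnedSeries,
    span_hours: float = 4.0,
    sigma_hours: float | None = None,
    restart_on_regime_change: bool = True,
) -> SmoothedSeries:
    """Weighted average with a sliding truncated-Gaussian window.

    The kernel's total span is ``span_hours`` (±span/2) with
    σ = span/4 by default, i.e. truncation at 2σ; weights are
    renormalized to sum to one at record edges (and, by default, at
    LD/DD regime boundaries, which are treated as record edges so the
    free-running smoothing never borrows entrained epochs).
    """
    dt = series.epoch_hours
    span_epochs = span_hours / dt
    if abs(span_epochs - round(span_epochs)) > 1e-9 or \
            int(round(span_epochs)) % 2:
        raise ParameterError("span must be an even multiple of the epoch length")
    if span_epochs < 3:
        raise ParameterError("span must cover at least 3 epochs")
    if sigma_hours is None:
        sigma_hours = span_hours / 4.0
    kernel = _gaussian_kernel(dt, span_hours, sigma_hours)

    x = series.counts.astype(float)
    out = np.empty_like(x)
    if restart_on_regime_change and len(series):
        changes = np.flatnonzero(series.regime[1:] != series.regime[:-1]) + 1
        bounds = [0, *changes.tolist(), len(x)]
    else:
        bounds = [0, len(x)]
    for a, b in zip(bounds[:-1], bounds[1:]):
        seg = x[a:b]
        num = np.convolve(seg, kernel, mode="same")
        den = np.convolve(np.ones_like(seg), kernel, mode="same")
        out[a:b] = num / den
    return SmoothedSeries(
        animal_id=series.animal_id,
        epoch_seconds=series.epoch_seconds,
        start_hours=series.start_hours,
        values=out,
        zt_hours=series.zt_hours,
        regime=series.regime,
        span_hours=span_hours,
        sigma_hours=sigma_hours,
    )


def classify_active_epochs(
    smoothed: SmoothedSeries,
) -> tuple[np.ndarray, float]:
    """Boolean mask of epochs above the individual's window mean.

    The threshold — the mean of the smoothed series over the analysis
    window — is returned alongside the mask.  A zero-variance window
    yields an all-inactive mask with a warning.
    """
    v = smoothed.values
    threshold = float(v.mean()) if v.size else float("nan")
    if v.size and np.ptp(v) <= 1e-12 * max(abs(threshold), 1.0):
        warnings.warn("zero-variance window: no epochs classified active",
                      stacklevel=2)
        return np.zeros(v.size, dtype=bool), threshold
    return v > threshold, threshold


def _merged_runs(mask: np.ndarray, max_gap_epochs: int) -> list[tuple[int, int]]:
    """Half-open [start, stop) index runs of True, gaps ≤ max_gap merged."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    runs: list[tuple[int, int]] = []
    start = prev = int(idx[0])
    for i in idx[1:]:
        if i - prev - 1 <= max_gap_epochs:
            prev = int(i)
        else:
            runs.append((start, prev + 1))
            start = prev = int(i)
    runs.append((start, prev + 1))
    return runs


def detect_active_phases(
    mask: np.ndarray,
    smoothed: SmoothedSeries,
    schedule: LightSchedule,
    max_gap_hours: float = 1.0,
) -> list[ActivePhase]:
    """Merge active runs into bouts and assign one per LD cycle.

    Runs separated by inactive gaps of at most ``max_gap_hours``
    (inclusive) merge into one candidate bout.  Each bout is assigned to
    the cycle whose window (dark onset − 6 h, dark onset + 18 h]
    contains its midpoint; when several bouts land in one cycle the
    longest is that cycle's active phase and the rest are flagged
    ``secondary``.  An all-inactive mask yields an empty list.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.size != len(smoothed):
        raise ParameterError("mask must align with the smoothed series")
    dt = smoothed.epoch_hours
    max_gap_epochs = int(np.floor(max_gap_hours / dt + 1e-9))
    runs = _merged_runs(mask, max_gap_epochs)
    if not runs:
        return []

    times = smoothed.times_hours
    t_end = smoothed.start_hours + len(smoothed) * dt
    # include dark onsets slightly beyond the window so late bouts attach
    darks = schedule.dark_onsets(
        max(schedule.start, smoothed.start_hours - CYCLE_LEAD_HOURS),
        min(schedule.end, t_end + 24.0 - CYCLE_LEAD_HOURS),
    )
    phases: list[ActivePhase] = []
    for start, stop in runs:
        onset_t = float(times[start])
        offset_t = float(times[start] + (stop - start) * dt)
        mid = 0.5 * (onset_t + offset_t)
        cand = np.flatnonzero(
            (mid >= darks - CYCLE_LEAD_HOURS)
            & (mid < darks + 24.0 - CYCLE_LEAD_HOURS)
        )
        if cand.size == 0:
            continue
        c = int(cand[0])
        dark = float(darks[c])
        phases.append(
            ActivePhase(
                animal_id=smoothed.animal_id,
                cycle_index=c,
                onset_zt_hours=12.0 + onset_t - dark,
                offset_zt_hours=12.0 + offset_t - dark,
                duration_hours=offset_t - onset_t,
            )
        )
    # keep the longest bout per cycle as primary
    out: list[ActivePhase] = []
    for c in sorted({p.cycle_index for p in phases}):
        group = sorted(
            (p for p in phases if p.cycle_index == c),
            key=lambda p: -p.duration_hours,
        )
        out.append(group[0])
        out.extend(
            ActivePhase(p.animal_id, p.cycle_index, p.onset_zt_hours,
                        p.offset_zt_hours, p.duration_hours, secondary=True)
            for p in group[1:]
        )
    return out


@dataclass(frozen=True)
class ActivePhaseSummary:
    """Per-animal means over cycles of onset/offset/duration."""

    animal_id: str
    mean_onset_zt: float
    mean_offset_zt: float
    mean_duration_hours: float
    n_cycles: int


def active_phase_summary(phases: list[ActivePhase]) -> ActivePhaseSummary:
    """Average primary phases over cycles (unwrapped ZT axis).

    With a phase in every cycle the mean duration equals mean offset −
    mean onset; an empty input yields a count-0 summary with NaN means.
    """
    primary = [p for p in phases if not p.secondary]
    if not primary:
        animal = phases[0].animal_id if phases else ""
        return ActivePhaseSummary(animal, float("nan"), float("nan"),
                                  float("nan"), 0)
    onsets = np.array([p.onset_zt_hours for p in primary])
    offsets = np.array([p.offset_zt_hours for p in primary])
    return ActivePhaseSummary(
        animal_id=primary[0].animal_id,
        mean_onset_zt=float(onsets.mean()),
        mean_offset_zt=float(offsets.mean()),
        mean_duration_hours=float((offsets - onsets).mean()),
        n_cycles=len(primary),
    )
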