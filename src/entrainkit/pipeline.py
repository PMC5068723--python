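"""End-to-end study orchestration.

Segments a recording into the experiment's named conditions (baseline
entrainment, free-running DD, forced resynchronization, phase advance),
runs every metric — cosinor amplitude/acrophase, χ²-periodogram period,
DFA scaling exponent, active-phase onset/offset/duration — per animal per
condition, and emits tidy tables ready for external group-level
statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .activephase import (active_phase_summary, classify_active_epochs,
                          detect_active_phases, gaussian_smooth)
from .dfa import dfa
from .errors import EntrainkitError, ProtocolError
from .io import BinnedSeries, EventStream, bin_events
from .rhythmometry import chi_square_periodogram, cosinor_fit
from .schedules import DD, LD, LightSchedule

logger = logging.getLogger("entrainkit")

BASELINE_CYCLES = 3        # LD cycles analyzed under steady entrainment
ACCLIMATION_CYCLES = 3     # LD cycles excluded before baseline
DD_WINDOW_HOURS = 72.0     # last 72 h of DD are analyzed
FORCED_SYNC_CYCLES = 3     # first cycles after LD resumes

#: DFA fit range (epochs of 5 min) used for the study's scaling exponent:
#: 30 min – 6 h.  Sub-circadian scales isolate the intrinsic fluctuation
#: structure: a smooth entrained rhythm is locally linear there and is
#: removed by the per-window detrending, whereas the sharp on/off
#: transitions of rigid photic masking inflate mid-scale fluctuations —
#: which is exactly the entrainment signature the exponent is meant to
#: pick up.  The full scale ladder (up to N/4) is still computed and
#: reported by :func:`entrainkit.dfa.dfa` for sensitivity analyses.
STUDY_DFA_FIT_RANGE = (6, 72)


@dataclass(frozen=True)
class ExperimentSegments:
    """Named half-open absolute-hour windows of one recording."""

    acclimation: tuple[float, float] | None = None
    baseline_ld: tuple[float, float] | None = None
    free_running_dd: tuple[float, float] | None = None
    forced_sync_ld: tuple[float, float] | None = None
    phase_advance_cycles: tuple[tuple[float, float], ...] = ()

    def analysis_windows(self) -> dict[str, tuple[float, float]]:
        out: dict[str, tuple[float, float]] = {}
        if self.baseline_ld:
            out["baseline_LD"] = self.baseline_ld
        if self.free_running_dd:
            out["free_running_DD"] = self.free_running_dd
        if self.forced_sync_ld:
            out["forced_sync"] = self.forced_sync_ld
        for k, w in enumerate(self.phase_advance_cycles):
            out[f"phase_advance_cycle_{k}"] = w
        return out


@dataclass(frozen=True)
class PhaseShiftDesign:
    """Phase-advance experiment layout (default: 6-h advance)."""

    shift_hours: float = 6.0
    n_pre_cycles: int = 3
    n_post_cycles: int = 5

    def __post_init__(self) -> None:
        if not 0 < self.shift_hours < 24:
            raise ProtocolError("shift must lie in (0, 24) h")
        if self.n_post_cycles < 3:
            raise ProtocolError("need at least 3 post-shift cycles")


# ----------------------------------------------------------------------
# segmentation
# ----------------------------------------------------------------------

def segment_experiment(
    schedule: LightSchedule,
    protocol: str = "dd_reentrain",
) -> ExperimentSegments:
    """Derive the protocol's named analysis windows from the schedule.

    ``baseline``: acclimation + baseline within one LD stretch.
    ``dd_reentrain``: adds the last 72 h of DD and the first 3 cycles of
    resumed LD.  ``phase_advance``: per-cycle windows after the shift.
    Acclimation is excluded from every analysis window.
    """
    segs = schedule.segments
    cycle = segs[0].cycle_length_hours
    need = (ACCLIMATION_CYCLES + BASELINE_CYCLES) * cycle

    if protocol in ("baseline", "dd_reentrain"):
        ld0 = segs[0]
        if ld0.regime != LD or ld0.end - ld0.start < need - 1e-9:
            raise ProtocolError(
                f"first LD segment must cover ≥ {need} h "
                f"(acclimation + baseline), has {ld0.end - ld0.start} h"
            )
        accl = (ld0.start, ld0.start + ACCLIMATION_CYCLES * cycle)
        base = (accl[1], accl[1] + BASELINE_CYCLES * cycle)
        if protocol == "baseline":
            return ExperimentSegments(acclimation=accl, baseline_ld=base)
        dd = next((s for s in segs if s.regime == DD), None)
        if dd is None or dd.end - dd.start < DD_WINDOW_HOURS - 1e-9:
            raise ProtocolError("protocol needs a DD segment of ≥ 72 h")
        dd_win = (dd.end - DD_WINDOW_HOURS, dd.end)
        resync = next(
            (s for s in segs if s.regime == LD and s.start >= dd.end - 1e-9),
            None,
        )
        if resync is None or \
                resync.end - resync.start < FORCED_SYNC_CYCLES * cycle - 1e-9:
            raise ProtocolError(
                f"protocol needs ≥ {FORCED_SYNC_CYCLES} LD cycles after DD"
            )
        sync = (resync.start, resync.start + FORCED_SYNC_CYCLES * cycle)
        return ExperimentSegments(
            acclimation=accl, baseline_ld=base,
            free_running_dd=dd_win, forced_sync_ld=sync,
        )

    if protocol == "phase_advance":
        if len(segs) < 2:
            raise ProtocolError("phase-advance protocol needs a shifted segment")
        pre, post = segs[0], segs[1]
        n_pre = int((pre.end - pre.start) // cycle)
        n_post = int(round((post.end - post.start) / cycle))
        if n_post < 2:
            raise ProtocolError("need ≥ 2 post-shift cycles")
        accl = (pre.start, pre.start + min(ACCLIMATION_CYCLES, n_pre) * cycle)
        base_hi = pre.start + n_pre * cycle
        base = (max(accl[1], base_hi - BASELINE_CYCLES * cycle), base_hi)
        cycles = tuple(
            (post.start + k * cycle, post.start + (k + 1) * cycle)
            for k in range(n_post)
        )
        return ExperimentSegments(
            acclimation=accl, baseline_ld=base, phase_advance_cycles=cycles
        )

    raise ProtocolError(f"unknown protocol {protocol!r}")


# ----------------------------------------------------------------------
# metric battery
# ----------------------------------------------------------------------

def _metrics_for_window(
    binned: BinnedSeries,
    schedule: LightSchedule,
    window_name: str,
) -> dict[str, float]:
    """All metrics for one animal × window; failures become NaN."""
    is_dd = window_name == "free_running_DD"
    row: dict[str, float] = {}
    period = np.nan
    try:
        pg = chi_square_periodogram(binned)
        period = pg.peak_period_hours
    except EntrainkitError as exc:
        logger.info("periodogram skipped for %s/%s: %s", binned.animal_id,
                    window_name, exc)
    row["period_hours"] = period

    try:
        tau = period if is_dd and np.isfinite(period) else 24.0
        fit = cosinor_fit(binned, tau)
        row["amplitude"] = fit.amplitude
        row["acrophase_zt"] = fit.acrophase_zt_hours
        row["mesor"] = fit.mesor
        row["percent_rhythm"] = fit.percent_rhythm
    except EntrainkitError as exc:
        logger.warning("cosinor failed for %s/%s: %s", binned.animal_id,
                       window_name, exc)
        row.update(amplitude=np.nan, acrophase_zt=np.nan, mesor=np.nan,
                   percent_rhythm=np.nan)

    try:
        row["scaling_exponent"] = dfa(
            binned, fit_range=STUDY_DFA_FIT_RANGE
        ).scaling_exponent
    except EntrainkitError as exc:
        logger.warning("DFA failed for %s/%s: %s", binned.animal_id,
                       window_name, exc)
        row["scaling_exponent"] = np.nan

    if not is_dd:
        try:
            sm = gaussian_smooth(binned)
            mask, _ = classify_active_epochs(sm)
            phases = detect_active_phases(mask, sm, schedule)
            summ = active_phase_summary(phases)
            row.update(
                onset_zt=summ.mean_onset_zt,
                offset_zt=summ.mean_offset_zt,
                duration_hours=summ.mean_duration_hours,
                n_cycles=summ.n_cycles,
            )
        except EntrainkitError as exc:
            logger.warning("active-phase failed for %s/%s: %s",
                           binned.animal_id, window_name, exc)
            row.update(onset_zt=np.nan, offset_zt=np.nan,
                       duration_hours=np.nan, n_cycles=0)
    else:
        row.update(onset_zt=np.nan, offset_zt=np.nan,
                   duration_hours=np.nan, n_cycles=0)
    return row


def run_all_metrics(
    streams: dict[str, EventStream],
    schedule: LightSchedule,
    segments: ExperimentSegments,
    epoch_seconds: float = 300.0,
    groups: dict[str, str] | None = None,
) -> pd.DataFrame:
    """The full metric battery: one row per animal × analysis window.

    LD windows are fitted at τ = 24 h; the DD window at the periodogram
    peak.  A failing submodule leaves NaNs in its columns and the batch
    continues.
    """
    rows = []
    for animal_id, stream in streams.items():
        for name, window in segments.analysis_windows().items():
            binned = bin_events(stream, epoch_seconds, window, schedule)
            row = {"animal_id": animal_id,
                   "group": (groups or {}).get(animal_id, ""),
                   "window": name,
                   "window_start_hours": window[0],
                   "window_end_hours": window[1]}
            row.update(_metrics_for_window(binned, schedule, name))
            rows.append(row)
    return pd.DataFrame(rows)


def phase_shift_response(
    streams: dict[str, EventStream],
    schedule: LightSchedule,
    design: PhaseShiftDesign = PhaseShiftDesign(),
    epoch_seconds: float = 300.0,
) -> pd.DataFrame:
    """Per-cycle active-phase metrics and cosinor acrophase around a shift.

    Pre-shift cycles are indexed −n..−1 on the old schedule, post-shift
    cycles 0.. on the new one; ZT refers to the governing schedule of
    each cycle.
    """
    segs = schedule.segments
    if len(segs) < 2 or segs[1].lights_on_anchor == segs[0].lights_on_anchor:
        raise ProtocolError("schedule contains no phase shift")
    pre, post = segs[0], segs[1]
    cycle = pre.cycle_length_hours
    n_post = int((post.end - post.start) // cycle)
    if n_post < 2:
        raise ProtocolError("need ≥ 2 post-shift cycles in the recording")
    n_pre = min(design.n_pre_cycles, int((pre.end - pre.start) // cycle))
    n_post = min(design.n_post_cycles, n_post)

    windows: list[tuple[int, float, float]] = []
    pre_last = pre.start + int((pre.end - pre.start) // cycle) * cycle
    for k in range(n_pre):
        hi = pre_last - k * cycle
        windows.append((-(k + 1), hi - cycle, hi))
    for k in range(n_post):
        windows.append((k, post.start + k * cycle,
                        post.start + (k + 1) * cycle))

    rows = []
    for animal_id, stream in streams.items():
        for cyc_idx, lo, hi in sorted(windows):
            binned = bin_events(stream, epoch_seconds, (lo, hi), schedule)
            row: dict[str, float] = {"animal_id": animal_id,
                                     "cycle": cyc_idx}
            try:
                fit = cosinor_fit(binned, 24.0)
                row["acrophase_zt"] = fit.acrophase_zt_hours
                row["amplitude"] = fit.amplitude
            except EntrainkitError:
                row["acrophase_zt"] = np.nan
                row["amplitude"] = np.nan
            try:
                sm = gaussian_smooth(binned)
                mask, _ = classify_active_epochs(sm)
                phases = [p for p in detect_active_phases(mask, sm, schedule)
                          if not p.secondary]
                if phases:
                    best = max(phases, key=lambda p: p.duration_hours)
                    row.update(onset_zt=best.onset_zt_hours,
                               offset_zt=best.offset_zt_hours,
                               duration_hours=best.duration_hours)
                else:
                    row.update(onset_zt=np.nan, offset_zt=np.nan,
                               duration_hours=np.nan)
            except EntrainkitError:
                row.update(onset_zt=np.nan, offset_zt=np.nan,
                           duration_hours=np.nan)
            rows.append(row)
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# actogram
# ----------------------------------------------------------------------

def export_actogram(
    binned: BinnedSeries,
    schedule: LightSchedule,
    bin_minutes: float = 15.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Double-plotted actogram matrix (days × 2 cycles of 15-min bins).

    Row ``d`` concatenates day ``d`` and day ``d+1``; the second half of
    row ``d`` therefore equals the first half of row ``d+1``.  Returns
    ``(matrix, light_track)`` where ``light_track`` marks lit bins of the
    first plotted day (1 = lights on).
    """
    factor = bin_minutes * 60.0 / binned.epoch_seconds
    if abs(factor - round(factor)) > 1e-9 or factor < 1:
        raise ProtocolError("actogram bin must be a multiple of the epoch")
    f = int(round(factor))
    n = (len(binned) // f) * f
    coarse = binned.counts[:n].reshape(-1, f).sum(axis=1)
    per_day = int(round(24 * 60 / bin_minutes))
    days = coarse.size // per_day
    if days < 2:
        raise ProtocolError("actogram needs at least 2 days of data")
    daily = coarse[: days * per_day].reshape(days, per_day)
    matrix = np.hstack([daily[:-1], daily[1:]])
    t0 = binned.start_hours + np.arange(per_day) * bin_minutes / 60.0
    light = (~np.atleast_1d(schedule.is_dark(np.minimum(t0, schedule.end - 1e-6)))
             ).astype(int)
    return matrix, np.concatenate([light, light])
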