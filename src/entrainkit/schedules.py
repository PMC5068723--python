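"""Light schedules and zeitgeber-time (ZT) arithmetic.

A :class:`LightSchedule` is an ordered, contiguous sequence of segments,
each either a light–dark cycle (``LD``) or constant darkness (``DD``).
Absolute time is measured in hours from the start of the experiment
(``t = 0``); by the builders' convention ``t = 0`` coincides with a
lights-on, i.e. ZT 0.  Under a 12:12 LD cycle the light phase spans
ZT 0–12 and the dark phase ZT 12–24.

For DD segments the ZT axis is extrapolated from the phase anchor of the
last preceding LD segment, so "subjective" light and dark keep their ZT
meaning while the lights stay off.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, RangeError

LD = "LD"
DD = "DD"


@dataclass(frozen=True)
class Segment:
    """One homogeneous stretch of the lighting protocol.

    Parameters
    ----------
    start, end:
        Absolute hours; half-open interval ``[start, end)``.
    regime:
        ``"LD"`` or ``"DD"``.
    lights_on_anchor:
        Absolute hour of a lights-on event defining ZT 0 for this
        segment (for DD, the anchor inherited from the last LD segment).
    photoperiod_hours:
        Length of the light phase per cycle.
    cycle_length_hours:
        Zeitgeber period (24 h for a standard LD cycle).
    """

    start: float
    end: float
    regime: str
    lights_on_anchor: float
    photoperiod_hours: float = 12.0
    cycle_length_hours: float = 24.0

    def __post_init__(self) -> None:
        if self.regime not in (LD, DD):
            raise ConfigurationError(f"unknown regime {self.regime!r}")
        if not self.end > self.start:
            raise ConfigurationError("segment must have positive duration")
        if not 0.0 < self.photoperiod_hours < self.cycle_length_hours:
            raise ConfigurationError(
                "photoperiod must lie strictly inside the cycle length"
            )


@dataclass(frozen=True)
class LightSchedule:
    """Contiguous, time-ordered lighting segments with ZT arithmetic.

    Attributes
    ----------
    segments:
        Ordered tuple of :class:`Segment`; must tile ``[start, end)``
        without gaps or overlaps.
    t0_clock_hours:
        Wall-clock hour-of-day corresponding to ``t = 0`` (used only
        when exporting absolute timestamps; the analyses are clock-free).
        Defaults to 6.0 — lights on at 06:00.
    """

    segments: tuple[Segment, ...]
    t0_clock_hours: float = 6.0

    # cached arrays for vectorized lookup
    _starts: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.segments:
            raise ConfigurationError("schedule has no segments")
        for a, b in zip(self.segments, self.segments[1:]):
            if not np.isclose(a.end, b.start):
                raise ConfigurationError(
                    "segments must be contiguous and time-ordered"
                )
        object.__setattr__(
            self, "_starts", np.array([s.start for s in self.segments])
        )

    # ------------------------------------------------------------------
    @property
    def start(self) -> float:
        return self.segments[0].start

    @property
    def end(self) -> float:
        return self.segments[-1].end

    @property
    def duration_hours(self) -> float:
        return self.end - self.start

    def segment_at(self, t: float) -> Segment:
        """Segment containing absolute hour ``t`` (end-inclusive at the tail)."""
        self._check_range(np.asarray([t]))
        idx = int(np.searchsorted(self._starts, t, side="right") - 1)
        return self.segments[idx]

    def _check_range(self, t: np.ndarray) -> None:
        if t.size and (t.min() < self.start - 1e-9 or t.max() > self.end + 1e-9):
            raise RangeError(
                f"time outside schedule [{self.start}, {self.end}] h"
            )

    def _segment_indices(self, t: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self._starts, t, side="right") - 1
        return np.clip(idx, 0, len(self.segments) - 1)

    # ------------------------------------------------------------------
    def zt_of(self, t):
        """Zeitgeber time of absolute hour(s) ``t``.

        ZT = hours since the most recent (possibly extrapolated)
        lights-on, modulo the cycle length of the governing segment.
        """
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        self._check_range(t_arr)
        idx = self._segment_indices(t_arr)
        anchors = np.array([s.lights_on_anchor for s in self.segments])[idx]
        cycles = np.array([s.cycle_length_hours for s in self.segments])[idx]
        zt = np.mod(t_arr - anchors, cycles)
        return float(zt[0]) if np.isscalar(t) or np.ndim(t) == 0 else zt

    def regime_of(self, t):
        """Regime label ("LD"/"DD") of absolute hour(s) ``t``."""
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        self._check_range(t_arr)
        idx = self._segment_indices(t_arr)
        regimes = np.array([s.regime for s in self.segments])[idx]
        return str(regimes[0]) if np.isscalar(t) or np.ndim(t) == 0 else regimes

    def is_dark(self, t):
        """True where the lights are physically off (all of DD is dark)."""
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        zt = np.atleast_1d(self.zt_of(t_arr))
        idx = self._segment_indices(t_arr)
        photo = np.array([s.photoperiod_hours for s in self.segments])[idx]
        dd = np.array([s.regime == DD for s in self.segments])[idx]
        dark = dd | (zt >= photo)
        return bool(dark[0]) if np.isscalar(t) or np.ndim(t) == 0 else dark

    def dark_onsets(self, t_start: float, t_end: float) -> np.ndarray:
        """Absolute hours of dark onsets (ZT = photoperiod) in ``[t_start, t_end)``.

        DD segments contribute *subjective* dark onsets on the
        extrapolated ZT axis, so active phases can still be assigned to
        circadian cycles under free-running conditions.
        """
        onsets: list[float] = []
        for seg in self.segments:
            lo, hi = max(seg.start, t_start), min(seg.end, t_end)
            if hi <= lo:
                continue
            first = seg.lights_on_anchor + seg.photoperiod_hours
            k0 = int(np.ceil((lo - first) / seg.cycle_length_hours - 1e-9))
            d = first + k0 * seg.cycle_length_hours
            while d < hi - 1e-9:
                if d >= lo - 1e-9:
                    onsets.append(d)
                d += seg.cycle_length_hours
        return np.array(sorted(onsets))

    # ------------------------------------------------------------------
    # builders
    # ------------------------------------------------------------------
    @classmethod
    def standard_ld(
        cls,
        days: float,
        photoperiod_hours: float = 12.0,
        cycle_length_hours: float = 24.0,
        t0_clock_hours: float = 6.0,
    ) -> "LightSchedule":
        """A single uninterrupted LD segment starting at lights-on."""
        seg = Segment(0.0, days * cycle_length_hours, LD, 0.0,
                      photoperiod_hours, cycle_length_hours)
        return cls((seg,), t0_clock_hours)

    @classmethod
    def dd_protocol(
        cls,
        ld_days: int = 6,
        dd_days: int = 14,
        resync_days: int = 3,
        photoperiod_hours: float = 12.0,
        cycle_length_hours: float = 24.0,
        t0_clock_hours: float = 6.0,
    ) -> "LightSchedule":
        """Baseline LD, constant darkness, then LD resumed in phase.

        Matches the free-running / forced-resynchronization protocol:
        LD for ``ld_days`` (acclimation + baseline), DD for ``dd_days``,
        then the original LD cycle resumes for ``resync_days``.
        """
        c = cycle_length_hours
        t1, t2 = ld_days * c, (ld_days + dd_days) * c
        t3 = t2 + resync_days * c
        segs = (
            Segment(0.0, t1, LD, 0.0, photoperiod_hours, c),
            Segment(t1, t2, DD, 0.0, photoperiod_hours, c),
            Segment(t2, t3, LD, 0.0, photoperiod_hours, c),
        )
        return cls(segs, t0_clock_hours)

    @classmethod
    def phase_advance_protocol(
        cls,
        pre_days: int = 6,
        shift_hours: float = 6.0,
        post_days: int = 5,
        photoperiod_hours: float = 12.0,
        cycle_length_hours: float = 24.0,
        t0_clock_hours: float = 6.0,
    ) -> "LightSchedule":
        """LD baseline followed by a phase *advance* of the LD cycle.

        The advance is realized by truncating one dark phase: the first
        lights-on of the new schedule occurs ``shift_hours`` earlier than
        the old schedule would have produced it.  The ZT axis follows the
        new schedule from its first lights-on.
        """
        c = cycle_length_hours
        if not 0.0 < shift_hours < c:
            raise ConfigurationError("shift must lie in (0, cycle length)")
        t_shift = pre_days * c - shift_hours  # first new lights-on
        segs = (
            Segment(0.0, t_shift, LD, 0.0, photoperiod_hours, c),
            Segment(t_shift, t_shift + post_days * c, LD, t_shift,
                    photoperiod_hours, c),
        )
        return cls(segs, t0_clock_hours)
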