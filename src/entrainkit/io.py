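"""Event-stream containers, CSV round-trip, and epoch binning.

The raw input of the pipeline is an RFID homecage visit log: one row per
visit with an animal id, a timestamp and an antenna id.  A visit is the
interval during which an animal is detected continuously by one antenna;
here each visit contributes one event at its onset.  Internally all times
are float hours relative to the schedule origin (``t = 0`` = first
lights-on); ISO-8601 timestamps are materialized only at the CSV boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError, RangeError
from .schedules import LightSchedule

logger = logging.getLogger("entrainkit")

#: default origin used when rendering absolute timestamps; 06:00 so that
#: t = 0 is a lights-on under the default clock convention
DEFAULT_ORIGIN = datetime(2024, 1, 1, 6, 0, 0)


@dataclass(frozen=True)
class EventStream:
    """Time-ordered visit events for one animal.

    ``times_hours`` are visit onsets in hours since the schedule origin;
    ``antenna_ids`` are parallel integer labels.  Duplicate
    (timestamp, antenna) pairs are collapsed on construction.
    """

    animal_id: str
    times_hours: np.ndarray
    antenna_ids: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times_hours, dtype=float)
        a = np.asarray(self.antenna_ids)
        if t.shape != a.shape:
            raise ParameterError("times and antenna ids must be parallel")
        order = np.argsort(t, kind="stable")
        t, a = t[order], a[order]
        keep = np.ones(t.size, dtype=bool)
        if t.size > 1:
            keep[1:] = ~((np.diff(t) == 0.0) & (a[1:] == a[:-1]))
        object.__setattr__(self, "times_hours", t[keep])
        object.__setattr__(self, "antenna_ids", a[keep])

    def __len__(self) -> int:
        return int(self.times_hours.size)


@dataclass(frozen=True)
class CsvDialect:
    """Declares how an event CSV is laid out.

    ``origin`` maps absolute timestamps to the schedule's hour axis
    (hour 0 = ``origin``); ``timestamp_format`` is a strptime pattern or
    ``None`` for ISO-8601.
    """

    delimiter: str = ","
    timestamp_format: str | None = None
    animal_column: str = "animal_id"
    time_column: str = "timestamp"
    antenna_column: str = "antenna_id"
    origin: datetime = DEFAULT_ORIGIN


@dataclass(frozen=True)
class BinnedSeries:
    """Equal-epoch activity counts on a light-schedule-aware time axis.

    ``counts[k]`` is the number of visit onsets in the half-open epoch
    ``[start_hours + k*dt, start_hours + (k+1)*dt)``; ``zt_hours[k]`` and
    ``regime[k]`` are the zeitgeber time and the LD/DD flag of the epoch
    *start*.
    """

    animal_id: str
    epoch_seconds: float
    start_hours: float
    counts: np.ndarray
    zt_hours: np.ndarray
    regime: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if not (len(c) == len(self.zt_hours) == len(self.regime)):
            raise ParameterError("counts/zt/regime must have equal length")
        if c.size and c.min() < 0:
            raise ParameterError("counts must be non-negative")

    @property
    def epoch_hours(self) -> float:
        return self.epoch_seconds / 3600.0

    @property
    def times_hours(self) -> np.ndarray:
        """Absolute hour of each epoch start."""
        return self.start_hours + np.arange(len(self.counts)) * self.epoch_hours

    def __len__(self) -> int:
        return int(len(self.counts))

    def slice_hours(self, t0: float, t1: float) -> "BinnedSeries":
        """Sub-series covering epochs whose start lies in ``[t0, t1)``."""
        t = self.times_hours
        m = (t >= t0 - 1e-9) & (t < t1 - 1e-9)
        return replace(
            self,
            start_hours=float(t[m][0]) if m.any() else t0,
            counts=self.counts[m],
            zt_hours=self.zt_hours[m],
            regime=self.regime[m],
        )

    def to_frame(self) -> pd.DataFrame:
        """Tidy representation: one row per epoch."""
        return pd.DataFrame(
            {
                "animal_id": self.animal_id,
                "epoch_start_hours": self.times_hours,
                "zt": self.zt_hours,
                "regime": self.regime,
                "count": self.counts,
            }
        )


# ----------------------------------------------------------------------
# CSV round-trip
# ----------------------------------------------------------------------

def write_events(
    streams: dict[str, EventStream] | list[EventStream],
    path: str | Path,
    dialect: CsvDialect = CsvDialect(),
) -> None:
    """Write event streams as a single tidy CSV with ISO-8601 timestamps."""
    if isinstance(streams, dict):
        streams = list(streams.values())
    frames = []
    for s in streams:
        ts = pd.Timestamp(dialect.origin) + pd.to_timedelta(
            s.times_hours, unit="h"
        )
        frames.append(
            pd.DataFrame(
                {
                    dialect.animal_column: s.animal_id,
                    dialect.time_column: ts.strftime("%Y-%m-%dT%H:%M:%S.%f"),
                    dialect.antenna_column: s.antenna_ids,
                }
            )
        )
    pd.concat(frames).to_csv(path, sep=dialect.delimiter, index=False)


def read_events(
    path: str | Path, dialect: CsvDialect = CsvDialect()
) -> dict[str, EventStream]:
    """Parse an event CSV into one :class:`EventStream` per animal.

    Rows whose timestamp cannot be parsed under the declared dialect are
    dropped; the drop count is logged.  A file with zero parseable rows
    raises :class:`FormatError` naming the line of the first failure.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=dialect.delimiter, dtype=str)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise FormatError(f"{path}: {exc}") from exc
    for col in (dialect.animal_column, dialect.time_column,
                dialect.antenna_column):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    ts = pd.to_datetime(
        df[dialect.time_column], format=dialect.timestamp_format,
        errors="coerce",
    )
    bad = ts.isna()
    if bad.all():
        first = int(bad.idxmax()) + 2  # header is line 1
        raise FormatError(
            f"{path}: no parseable timestamps (first failure at line {first})"
        )
    if bad.any():
        logger.warning(
            "%s: dropped %d rows with unparseable timestamps", path,
            int(bad.sum()),
        )
    df = df.loc[~bad].copy()
    hours = (
        (ts[~bad] - pd.Timestamp(dialect.origin)).dt.total_seconds() / 3600.0
    )
    df["_hours"] = hours.to_numpy()
    out: dict[str, EventStream] = {}
    for animal, grp in df.groupby(dialect.animal_column, sort=True):
        out[str(animal)] = EventStream(
            str(animal),
            grp["_hours"].to_numpy(),
            pd.to_numeric(grp[dialect.antenna_column], errors="coerce")
            .fillna(-1)
            .astype(int)
            .to_numpy(),
        )
    return out


# ----------------------------------------------------------------------
# binning
# ----------------------------------------------------------------------

def bin_events(
    stream: EventStream,
    epoch_seconds: float,
    window: tuple[float, float],
    schedule: LightSchedule,
) -> BinnedSeries:
    """Bin visit onsets into equal half-open epochs over ``window`` (hours).

    The window must be aligned to the epoch grid and the epoch length
    must divide 24 h evenly, so that epochs tile whole LD cycles.
    """
    dt = epoch_seconds / 3600.0
    t0, t1 = window
    if epoch_seconds <= 0 or abs(round(86400 / epoch_seconds) * epoch_seconds
                                 - 86400) > 1e-6:
        raise ParameterError("epoch length must divide 24 h evenly")
    for edge in (t0, t1):
        if abs(round(edge / dt) * dt - edge) > 1e-9:
            raise ParameterError("window must be aligned to the epoch grid")
    if t0 < schedule.start - 1e-9 or t1 > schedule.end + 1e-9 or t1 <= t0:
        raise RangeError("window outside the recorded schedule")
    n = int(round((t1 - t0) / dt))
    edges = t0 + np.arange(n + 1) * dt
    counts, _ = np.histogram(stream.times_hours, bins=edges)
    starts = edges[:-1]
    return BinnedSeries(
        animal_id=stream.animal_id,
        epoch_seconds=epoch_seconds,
        start_hours=t0,
        counts=counts.astype(int),
        zt_hours=np.atleast_1d(schedule.zt_of(starts)),
        regime=np.atleast_1d(schedule.regime_of(starts)),
    )
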