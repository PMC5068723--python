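"""Synthetic actigraphy and clock-gene expression generator.

Generates ground-truth-known visit event streams under arbitrary light
schedules, with the statistical structure the downstream analyses assume:

* a circadian modulation of the visit rate (cosine, entrained to the
  schedule or free-running in DD, with exponential phase relaxation
  after schedule disruptions);
* a photic gate (activity permitted from shortly before dark onset until
  shortly after light onset; disabled in DD);
* multiplicative long-range-correlated noise (exponentiated fractional
  Gaussian noise with tunable Hurst exponent);
* events drawn as an inhomogeneous Poisson point process by thinning.

Phenotype presets encode the qualitative contrasts between healthy
controls, rigidly photic-gated animals ("dex"-like: no anticipation of
dark onset, activity suppressed immediately at lights-on, fast
re-entrainment) and low-amplitude but normally entrained animals
("mehg"-like).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import ConfigurationError, ParameterError
from .io import EventStream
from .schedules import LD, LightSchedule

#: phase-error scale (hours) over which anticipatory behavior matures;
#: anticipation/offset-lag are expressed fully only once the internal
#: oscillator is aligned with the schedule (see docs/methods.md)
ANTICIPATION_MATURITY_HOURS = 1.0

#: Gaussian sigma (hours) of the sharp dark-onset activity surge
BURST_SIGMA_HOURS = 0.1

#: photic-masking floor while the oscillator is misaligned: light then
#: suppresses activity directly, regardless of the preset's entrained
#: masking strength
MISALIGNED_GATE_FLOOR = 0.05

#: e-folding time (hours) of rhythm coherence during free-running DD:
#: the expressed circadian modulation dissipates slowly without a
#: zeitgeber and is rebuilt during re-entrainment
DD_DESYNC_TAU_HOURS = 168.0

#: coherence never decays below this floor — the free-running rhythm
#: stays detectable throughout a two-week DD exposure
COHERENCE_FLOOR = 0.2

#: coherence is rebuilt more slowly than phase re-locks: the oscillator
#: finds the right phase first, full rhythm amplitude returns later
COHERENCE_REBUILD_FACTOR = 6.0


# ----------------------------------------------------------------------
# fractional Gaussian noise
# ----------------------------------------------------------------------

def fgn_autocovariance(lags, hurst: float):
    """Exact autocovariance of unit-variance fGn: γ(k) = ½(|k+1|^{2H} − 2|k|^{2H} + |k−1|^{2H})."""
    k = np.abs(np.asarray(lags, dtype=float))
    h2 = 2.0 * hurst
    return 0.5 * ((k + 1) ** h2 - 2 * k ** h2 + np.abs(k - 1) ** h2)


def generate_fractional_noise(
    n: int, hurst: float, rng: np.random.Generator | int
) -> np.ndarray:
    """Exact fractional Gaussian noise via circulant embedding.

    Returns a zero-mean series of length ``n`` with unit theoretical
    variance whose DFA-1 scaling exponent equals ``hurst``.  ``hurst``
    = 0.5 reduces to white noise.  Sampling is exact (Davies–Harte):
    the circulant covariance ring is diagonalized by the FFT and a
    complex Gaussian vector with those eigenvalue weights is transformed
    back.
    """
    if not 0.0 < hurst < 1.0:
        raise ParameterError(f"hurst must lie in (0, 1), got {hurst}")
    if n < 1:
        raise ParameterError("series length must be positive")
    rng = np.random.default_rng(rng) if not isinstance(
        rng, np.random.Generator) else rng
    if abs(hurst - 0.5) < 1e-12:
        return rng.standard_normal(n)
    # embedding size: power of two ≥ 2(n−1); enlarge if the ring is not PSD
    m = 1 << max(1, (2 * max(n - 1, 1) - 1).bit_length())
    while True:
        row = np.concatenate(
            [fgn_autocovariance(np.arange(m // 2 + 1), hurst),
             fgn_autocovariance(np.arange(m // 2 - 1, 0, -1), hurst)]
        )
        lam = np.fft.fft(row).real
        if lam.min() > -1e-8 * lam.max():
            lam = np.clip(lam, 0.0, None)
            break
        m <<= 1  # pragma: no cover - PSD for all H in (0,1) at this size
    half = m // 2
    v = np.empty(m, dtype=complex)
    v[0] = math.sqrt(lam[0]) * rng.standard_normal()
    v[half] = math.sqrt(lam[half]) * rng.standard_normal()
    re = rng.standard_normal(half - 1)
    im = rng.standard_normal(half - 1)
    inner = np.sqrt(lam[1:half] / 2.0) * (re + 1j * im)
    v[1:half] = inner
    v[half + 1:] = np.conj(inner[::-1])
    x = np.fft.fft(v).real / math.sqrt(m)
    return x[:n]


# ----------------------------------------------------------------------
# phenotype presets
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class PhenotypePreset:
    """Generative parameters for one simulated animal class.

    Parameters
    ----------
    intrinsic_period_hours:
        Free-running circadian period expressed in DD (~23.7 h in mice).
    entrained_period_hours:
        Period the oscillator tends to under LD; 24 h when entrainment
        is stable.
    rhythm_amplitude:
        Relative modulation depth of the circadian rate component, in
        [0, 1].
    acrophase_zt_hours:
        ZT of the circadian modulation peak (middle of the dark phase,
        ZT 18, for a nocturnal animal).
    anticipation_hours:
        How far the photic gate opens before dark onset once entrained
        (0 = rigid gating).
    offset_lag_hours:
        How far gated activity persists past lights-on.
    hurst_exponent:
        Long-range-correlation parameter of the multiplicative noise.
    mean_rate:
        Expected visits per hour at unit modulation.
    reentrainment_rate_cycles:
        e-folding time, in LD cycles, of the oscillator's phase error
        after a schedule disruption (→0 = instant re-locking).
    gate_floor:
        Relative activity permitted outside the gate window once
        entrained (masking strength: small = strong photic suppression;
        while the oscillator is misaligned, masking is strong for every
        phenotype).
    noise_sigma:
        Log-scale of the multiplicative noise; calibrated so the DFA
        exponent of binned counts tracks ``hurst_exponent``.
    onset_burst:
        Relative peak height of the brief activity surge at dark onset
        (the lights-off burst of nocturnal rodents); 0 disables it.
    """

    name: str
    intrinsic_period_hours: float = 23.7
    entrained_period_hours: float = 24.0
    rhythm_amplitude: float = 0.6
    acrophase_zt_hours: float = 18.0
    anticipation_hours: float = 1.5
    offset_lag_hours: float = 1.0
    hurst_exponent: float = 0.8
    mean_rate: float = 240.0
    reentrainment_rate_cycles: float = 2.5
    gate_floor: float = 0.25
    noise_sigma: float = 0.45
    onset_burst: float = 2.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.rhythm_amplitude <= 1.0:
            raise ParameterError("rhythm_amplitude must lie in [0, 1]")
        if not 0.0 < self.hurst_exponent < 1.0:
            raise ParameterError("hurst_exponent must lie in (0, 1)")
        if self.mean_rate <= 0:
            raise ParameterError("mean_rate must be positive")
        for name in ("anticipation_hours", "offset_lag_hours",
                     "reentrainment_rate_cycles", "noise_sigma",
                     "onset_burst"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")
        if not 0.0 <= self.gate_floor <= 1.0:
            raise ParameterError("gate_floor must lie in [0, 1]")
        if not 0.0 <= self.acrophase_zt_hours < 24.0:
            raise ParameterError("acrophase_zt_hours must lie in [0, 24)")


CONTROL = PhenotypePreset("control", acrophase_zt_hours=17.0, gate_floor=0.7,
                          reentrainment_rate_cycles=4.0)
DEX = PhenotypePreset(
    "dex",
    rhythm_amplitude=0.8,
    acrophase_zt_hours=18.0,
    anticipation_hours=0.0,
    offset_lag_hours=0.1,
    reentrainment_rate_cycles=0.3,
    gate_floor=0.02,
)
#: aged variant whose steady-entrainment period drifts short of 24 h
DEX_AGED = replace(DEX, name="dex_aged", entrained_period_hours=23.6)
MEHG = replace(CONTROL, name="mehg", rhythm_amplitude=0.3)

PRESETS: dict[str, PhenotypePreset] = {
    p.name: p for p in (CONTROL, DEX, DEX_AGED, MEHG)
}


@dataclass(frozen=True)
class SimulationConfig:
    """Schedule, animal roster and sampling resolution for one run."""

    schedule: LightSchedule
    animals: tuple[tuple[str, PhenotypePreset], ...]
    epoch_seconds: float = 300.0
    rng_seed: int = 0
    n_antennas: int = 4

    def __post_init__(self) -> None:
        if not self.animals:
            raise ConfigurationError("no animals configured")
        if self.epoch_seconds <= 0:
            raise ConfigurationError("epoch_seconds must be positive")


# ----------------------------------------------------------------------
# oscillator / rate model
# ----------------------------------------------------------------------

def _oscillator_phase(
    schedule: LightSchedule, preset: PhenotypePreset, t: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Internal circadian time ζ(t), |phase error| and rhythm coherence.

    Under LD the oscillator advances at 24/entrained_period hours of
    subjective time per hour and relaxes exponentially toward the
    schedule's ZT with time constant ``reentrainment_rate_cycles``
    cycles; in DD it free-runs at the intrinsic period.  The phase error
    is the wrapped difference schedule-ZT − ζ (zero in DD by convention:
    there is no zeitgeber to be in error against).
    """
    dt = float(t[1] - t[0]) if len(t) > 1 else 0.0
    zt = np.atleast_1d(schedule.zt_of(t))
    regimes = np.atleast_1d(schedule.regime_of(t))
    cyc = np.array([schedule.segment_at(float(x)).cycle_length_hours
                    for x in t[:1]])  # builders use one cycle length
    cycle = float(cyc[0]) if cyc.size else 24.0

    zeta = np.empty(len(t))
    err = np.zeros(len(t))
    coh = np.ones(len(t))
    tau_r = preset.reentrainment_rate_cycles * cycle
    pull = 1.0 if tau_r < 1e-9 else 1.0 - math.exp(-dt / tau_r)
    rebuild = 1.0 if tau_r < 1e-9 else 1.0 - math.exp(
        -dt / (COHERENCE_REBUILD_FACTOR * tau_r))
    decay = math.exp(-dt / DD_DESYNC_TAU_HOURS)
    zeta[0] = zt[0] if regimes[0] == LD else 0.0
    for i in range(len(t)):
        if i > 0:
            if regimes[i] == LD:
                zeta[i] = zeta[i - 1] + dt * cycle / preset.entrained_period_hours
                coh[i] = coh[i - 1] + rebuild * (1.0 - coh[i - 1])
            else:
                zeta[i] = zeta[i - 1] + dt * cycle / preset.intrinsic_period_hours
                coh[i] = max(coh[i - 1] * decay, COHERENCE_FLOOR)
        if regimes[i] == LD:
            e = (zt[i] - zeta[i] + cycle / 2) % cycle - cycle / 2
            zeta[i] += pull * e
            err[i] = abs((zt[i] - zeta[i] + cycle / 2) % cycle - cycle / 2)
    return zeta % cycle, err, coh


def _ramp(x: np.ndarray, half_width) -> np.ndarray:
    """Raised-cosine step from 0 to 1 over ``[-half_width, +half_width]``.

    A zero half-width degenerates to the hard step ``x >= 0``.
    """
    x = np.asarray(x, dtype=float)
    hw = np.broadcast_to(np.asarray(half_width, dtype=float), x.shape)
    soft = hw > 0
    u = np.where(soft, np.clip(x / np.where(soft, hw, 1.0), -1.0, 1.0),
                 np.where(x >= 0, 1.0, -1.0))
    return 0.5 * (1.0 + np.sin(0.5 * np.pi * u))


def _rate_on_grid(
    schedule: LightSchedule,
    preset: PhenotypePreset,
    t: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Expected visit rate (visits/h) at grid times ``t``."""
    zeta, err, coh = _oscillator_phase(schedule, preset, t)
    cycle = 24.0
    # rhythm coherence dissipates slowly in DD and is rebuilt during
    # re-entrainment; the expressed modulation amplitude scales with it
    amp = preset.rhythm_amplitude * coh
    modulation = 1.0 + amp * np.cos(
        2 * np.pi * (zeta - preset.acrophase_zt_hours) / cycle
    )

    regimes = np.atleast_1d(schedule.regime_of(t))
    zt = np.atleast_1d(schedule.zt_of(t))
    gate = np.ones(len(t))
    burst = np.zeros(len(t))
    ld = regimes == LD
    if ld.any():
        photo = schedule.segments[0].photoperiod_hours
        maturity = np.exp(-err[ld] / ANTICIPATION_MATURITY_HOURS)
        ant = preset.anticipation_hours * maturity
        off = preset.offset_lag_hours * maturity
        z = zt[ld]
        # raised-cosine edges: anticipatory ramp-up centred ``ant`` before
        # dark onset (half-width ant) and ramp-down centred ``off`` after
        # lights-on (half-width off); zero widths give a hard box, the
        # rigid-masking phenotype
        up = _ramp(z - (photo - ant), ant)            # 0 → 1 around dark onset
        down = 1.0 - _ramp(z - off, np.maximum(off, 1e-6))  # 1 → 0 after lights-on
        openness = np.maximum(up, down)
        # masking is strong whenever the oscillator is misaligned; the
        # preset's (weaker) entrained masking applies only once re-locked
        floor = (preset.gate_floor * maturity
                 + MISALIGNED_GATE_FLOOR * (1.0 - maturity))
        gate[ld] = floor + (1.0 - floor) * openness
        # lights-off surge: a brief sharp activity burst at dark onset
        dz = (z - photo + 12.0) % 24.0 - 12.0
        burst[ld] = preset.onset_burst * np.exp(
            -0.5 * (dz / BURST_SIGMA_HOURS) ** 2
        )

    sig = preset.noise_sigma
    noise = np.exp(
        sig * generate_fractional_noise(len(t), preset.hurst_exponent, rng)
        - sig * sig / 2.0
    )
    return preset.mean_rate * (modulation * gate + burst) * noise


def simulate_activity(
    config: SimulationConfig,
) -> dict[str, EventStream]:
    """Simulate one visit event stream per configured animal.

    Events are drawn as an inhomogeneous Poisson process by thinning a
    homogeneous process at the grid's peak rate; the rate is piecewise
    constant at the configured epoch resolution.  A fixed
    ``config.rng_seed`` yields bit-identical event streams.
    """
    sched = config.schedule
    dt = config.epoch_seconds / 3600.0
    n = int(round(sched.duration_hours / dt))
    if n < 1:
        raise ConfigurationError("schedule too short for one epoch")
    t_grid = sched.start + np.arange(n) * dt

    streams: dict[str, EventStream] = {}
    seeds = np.random.SeedSequence(config.rng_seed).spawn(len(config.animals))
    for (animal_id, preset), seed in zip(config.animals, seeds):
        rng = np.random.default_rng(seed)
        rate = _rate_on_grid(sched, preset, t_grid, rng)
        lam = float(rate.max())
        total = sched.duration_hours
        n_cand = rng.poisson(lam * total)
        cand = np.sort(rng.uniform(sched.start, sched.end, n_cand))
        idx = np.clip(((cand - sched.start) / dt).astype(int), 0, n - 1)
        accept = rng.uniform(0, 1, n_cand) < rate[idx] / lam
        times = cand[accept]
        antennas = rng.integers(0, config.n_antennas, times.size)
        streams[animal_id] = EventStream(animal_id, times, antennas)
    return streams


# ----------------------------------------------------------------------
# clock-gene expression time courses
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class ExpressionCourse:
    """Sparse relative-expression time course for one replicate culture."""

    gene: str
    sample_times_hours: np.ndarray
    values: np.ndarray
    group: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.sample_times_hours, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape:
            raise ParameterError("times and values must be parallel")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ParameterError("sample times must be strictly increasing")
        if v.size and v.min() <= 0:
            raise ParameterError("expression values must be positive")
        object.__setattr__(self, "sample_times_hours", t)
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class ExpressionParams:
    """Damped-cosine generative model for a synchronized culture.

    value(t) = mesor + amplitude·exp(−damping·t)·cos(2π(t − acrophase)/24)
    plus Gaussian noise, truncated positive.  Times are hours after
    synchronization.
    """

    mesor: float = 1.0
    amplitude: float = 0.5
    acrophase_hours: float = 20.0
    damping_per_hour: float = 0.02
    noise_sd: float = 0.05
    period_hours: float = 24.0

    def __post_init__(self) -> None:
        if self.amplitude < 0 or self.mesor < 0:
            raise ParameterError("amplitude and mesor must be non-negative")


#: fibroblast presets: controls show robust oscillations, the
#: "dex"-like group attenuated and faster-damping ones
EXPRESSION_PRESETS = {
    "control": ExpressionParams(),
    "dex": ExpressionParams(amplitude=0.18, damping_per_hour=0.05),
}


def simulate_expression(
    params: ExpressionParams,
    sample_times_hours=np.arange(6.0, 36.1, 6.0),
    replicates: int = 3,
    rng: np.random.Generator | int = 0,
    gene: str = "Bmal1",
    group: str = "",
    time_window: tuple[float, float] = (6.0, 36.0),
) -> list[ExpressionCourse]:
    """Simulate sparse post-synchronization expression time courses."""
    t = np.asarray(sample_times_hours, dtype=float)
    lo, hi = time_window
    if t.min() < lo - 1e-9 or t.max() > hi + 1e-9:
        raise ParameterError(
            f"sample times must lie within [{lo}, {hi}] h post-synchronization"
        )
    if replicates < 1:
        raise ParameterError("replicates must be ≥ 1")
    rng = np.random.default_rng(rng) if not isinstance(
        rng, np.random.Generator) else rng
    courses = []
    for _ in range(replicates):
        clean = params.mesor + params.amplitude * np.exp(
            -params.damping_per_hour * t
        ) * np.cos(2 * np.pi * (t - params.acrophase_hours)
                   / params.period_hours)
        noisy = clean + (params.noise_sd * rng.standard_normal(t.size)
                         if params.noise_sd > 0 else 0.0)
        courses.append(
            ExpressionCourse(gene, t, np.maximum(noisy, 1e-6), group)
        )
    return courses
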