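import numpy as np
import pytest

import entrainkit as ek


@pytest.fixture(scope="session")
def ld6():
    """Six LD cycles, lights on at t=0 (ZT 0)."""
    return ek.LightSchedule.standard_ld(6)


@pytest.fixture(scope="session")
def ld3():
    return ek.LightSchedule.standard_ld(3)


@pytest.fixture(scope="session")
def dd_protocol_schedule():
    """6 LD + 14 DD + 3 LD resynchronization cycles."""
    return ek.LightSchedule.dd_protocol()


@pytest.fixture(scope="session")
def control_streams_6d(ld6):
    """Control-preset event streams for 10 seeds under 6 LD days."""
    out = []
    for seed in range(10):
        cfg = ek.SimulationConfig(ld6, (("c", ek.CONTROL),), rng_seed=seed)
        out.append(ek.simulate_activity(cfg)["c"])
    return out


@pytest.fixture(scope="session")
def dex_binned_3d(ld3):
    """DEX-preset 5-min binned counts over 3 LD cycles, 10 seeds."""
    out = []
    for seed in range(10):
        cfg = ek.SimulationConfig(ld3, (("d", ek.DEX),), rng_seed=seed)
        stream = ek.simulate_activity(cfg)["d"]
        out.append(ek.bin_events(stream, 300, (0.0, 72.0), ld3))
    return out


def make_binned(counts, schedule, epoch_seconds=300.0, start_hours=0.0,
                animal_id="test"):
    """Wrap a plain count array in a BinnedSeries on the given schedule."""
    counts = np.asarray(counts)
    dt = epoch_seconds / 3600.0
    starts = start_hours + np.arange(len(counts)) * dt
    return ek.BinnedSeries(
        animal_id=animal_id,
        epoch_seconds=epoch_seconds,
        start_hours=start_hours,
        counts=counts,
        zt_hours=np.atleast_1d(schedule.zt_of(starts)),
        regime=np.atleast_1d(schedule.regime_of(starts)),
    )
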