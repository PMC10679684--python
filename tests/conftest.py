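import numpy as np
import pytest

from mea3d.geometry import ArrayRecording, DeviceLayout, ElectrodeAddress, SpikeTrain


@pytest.fixture(scope="session")
def layout():
    return DeviceLayout()


def make_recording(layout, times_fn, duration=1800.0, well=1, div=45,
                   condition="baseline"):
    """Build a single-well recording with per-address spike times from
    ``times_fn(address) -> array``."""
    trains = [
        SpikeTrain(a, np.asarray(times_fn(a), dtype=float), duration=duration)
        for a in layout.addresses()
        if a.well == well
    ]
    return ArrayRecording(well=well, div=div, condition=condition,
                         trains=trains, layout=layout)


@pytest.fixture
def uniform_recording(layout):
    """Every electrode fires the same 100 regular spikes over 30 min."""
    times = np.linspace(5.0, 1795.0, 100)
    return make_recording(layout, lambda a: times)


def random_train(rng, n, duration):
    return np.sort(rng.uniform(0.0, duration, size=n))


@pytest.fixture
def addr():
    return ElectrodeAddress(1, 1, 1)
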