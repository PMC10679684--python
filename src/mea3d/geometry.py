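"""Device geometry for the 3-well, 10-probe x 8-electrode 3D MEA.

Each well holds one array of 10 vertically actuated polymer probes with 8
thin-film electrodes per probe (80 electrodes per array, 240 per device).
The acquisition system digitizes 256 channels; 240 of them are wired to
device electrodes, so analysis starts by remapping raw channel indices onto
(well, probe, electrode) addresses.  Vertical electrode pairs define four
250-um-thick tissue cross sections: electrodes 1-2 -> "bottom", 3-4 ->
"middle1", 5-6 -> "middle2", 7-8 -> "top".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SECTIONS = ("bottom", "middle1", "middle2", "top")

#: electrode index (1-based) -> cross-section label
_ELECTRODE_SECTION = {
    1: "bottom", 2: "bottom",
    3: "middle1", 4: "middle1",
    5: "middle2", 6: "middle2",
    7: "top", 8: "top",
}


class UnmappedChannelError(KeyError):
    """Raised when a raw acquisition channel is not wired to any electrode."""


def assign_cross_section(electrode: int) -> str:
    """Map a 1-based electrode index on a probe to its cross-section label.

    Electrodes are numbered from the substrate up; each vertical pair samples
    one 250 um slab of the hydrogel tissue.

    Parameters
    ----------
    electrode : int
        Electrode index on the probe, 1..8.

    Returns
    -------
    str
        One of ``"bottom"``, ``"middle1"``, ``"middle2"``, ``"top"``.
    """
    try:
        return _ELECTRODE_SECTION[int(electrode)]
    except (KeyError, TypeError, ValueError):
        raise ValueError(f"electrode index must be in 1..8, got {electrode!r}")


@dataclass(frozen=True, order=True)
class ElectrodeAddress:
    """Physical location of one electrode: well, probe, electrode (all 1-based)."""

    well: int
    probe: int
    electrode: int

    def __post_init__(self) -> None:
        if not 1 <= self.well:
            raise ValueError(f"well must be >= 1, got {self.well}")
        if not 1 <= self.probe:
            raise ValueError(f"probe must be >= 1, got {self.probe}")
        if not 1 <= self.electrode <= 8:
            raise ValueError(f"electrode must be in 1..8, got {self.electrode}")

    @property
    def section(self) -> str:
        return assign_cross_section(self.electrode)


def _default_electrode_z(section_span_um: float) -> np.ndarray:
    # electrodes sit at the centers of 125-um half-bins: 125, 375, ... 1875 um
    half = section_span_um / 2.0
    return half / 2.0 + half * np.arange(8)


@dataclass(frozen=True)
class DeviceLayout:
    """Geometry and channel wiring of one recording device.

    Attributes
    ----------
    n_wells, probes_per_well, electrodes_per_probe : int
        Device format; defaults give the 3 x 10 x 8 = 240-electrode device.
    electrode_z_um : tuple of float
        Height of each electrode (1..8) above the substrate, strictly
        increasing.  Defaults place electrode pairs at the centers of
        successive 250 um cross-section bins.
    section_span_um : float
        Vertical thickness of one cross section (two electrodes).
    channel_map : dict[int, ElectrodeAddress]
        Raw acquisition channel -> electrode address.  Defaults to a fixed,
        documented wiring that uses channels 0..239 of the 256-channel
        acquisition format in (well, probe, electrode) lexicographic order and
        leaves channels 240..255 unused.  Real hardware wiring is
        instrument-specific and should be supplied from a config file.
    """

    n_wells: int = 3
    probes_per_well: int = 10
    electrodes_per_probe: int = 8
    section_span_um: float = 250.0
    electrode_z_um: tuple = ()
    channel_map: dict = field(default_factory=dict, hash=False)

    def __post_init__(self) -> None:
        if self.electrodes_per_probe % 2 != 0:
            raise ValueError("electrodes_per_probe must pair into cross sections")
        z = (np.asarray(self.electrode_z_um, dtype=float)
             if len(self.electrode_z_um)
             else _default_electrode_z(self.section_span_um)[: self.electrodes_per_probe])
        if len(z) != self.electrodes_per_probe:
            raise ValueError("electrode_z_um length must equal electrodes_per_probe")
        if np.any(np.diff(z) <= 0):
            raise ValueError("electrode_z_um must be strictly increasing")
        object.__setattr__(self, "electrode_z_um", tuple(float(v) for v in z))
        cmap = dict(self.channel_map) if self.channel_map else self._default_channel_map()
        addrs = list(cmap.values())
        if len(set(addrs)) != len(addrs):
            raise ValueError("channel_map must be injective")
        if len(addrs) != self.n_electrodes:
            raise ValueError(
                f"channel_map covers {len(addrs)} electrodes, expected {self.n_electrodes}"
            )
        object.__setattr__(self, "channel_map", cmap)

    # -- derived sizes -----------------------------------------------------
    @property
    def electrodes_per_well(self) -> int:
        return self.probes_per_well * self.electrodes_per_probe

    @property
    def n_electrodes(self) -> int:
        return self.n_wells * self.electrodes_per_well

    def _default_channel_map(self) -> dict:
        cmap = {}
        ch = 0
        for w in range(1, self.n_wells + 1):
            for p in range(1, self.probes_per_well + 1):
                for e in range(1, self.electrodes_per_probe + 1):
                    cmap[ch] = ElectrodeAddress(w, p, e)
                    ch += 1
        return cmap

    # -- operations --------------------------------------------------------
    def remap_channel(self, raw_channel: int) -> ElectrodeAddress:
        """Translate a raw acquisition channel index into an electrode address."""
        try:
            return self.channel_map[int(raw_channel)]
        except KeyError:
            raise UnmappedChannelError(
                f"acquisition channel {raw_channel} is not wired to any electrode"
            ) from None

    def channel_of(self, address: ElectrodeAddress) -> int:
        """Inverse of :meth:`remap_channel`."""
        for ch, addr in self.channel_map.items():
            if addr == address:
                return ch
        raise KeyError(f"address {address} not present in channel map")

    def addresses(self) -> list[ElectrodeAddress]:
        """All electrode addresses in (well, probe, electrode) order."""
        return sorted(self.channel_map.values())

    def section_of(self, address: ElectrodeAddress) -> str:
        return assign_cross_section(address.electrode)

    def electrode_z(self, electrode: int) -> float:
        return self.electrode_z_um[electrode - 1]


def remap_channels(raw_channels, layout: DeviceLayout) -> list[ElectrodeAddress]:
    """Remap an iterable of raw channel indices to electrode addresses."""
    return [layout.remap_channel(c) for c in raw_channels]


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted extracellular spike timestamps (s) of one electrode.

    ``times`` are threshold-crossing event times on ``[0, duration]``; this
    is multi-unit activity, not sorted single units.
    """

    address: ElectrodeAddress
    times: np.ndarray
    duration: float = 1800.0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=np.float64)
        if t.ndim != 1:
            raise ValueError("spike times must be a 1-D array")
        if t.size and (np.any(np.diff(t) < 0)):
            raise ValueError("spike times must be non-decreasing")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if t.size and (t[0] < 0 or t[-1] > self.duration):
            raise ValueError("spike times must lie within [0, duration]")
        object.__setattr__(self, "times", t)

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    @property
    def firing_rate(self) -> float:
        return self.n_spikes / self.duration

    def restrict(self, t0: float, t1: float) -> "SpikeTrain":
        """Spikes in [t0, t1), re-referenced to t0."""
        sel = self.times[(self.times >= t0) & (self.times < t1)]
        return SpikeTrain(self.address, sel - t0, duration=t1 - t0)


CONDITIONS = (
    "baseline",
    "BIC",
    "AP5+BIC",
    "CNQX+AP5+BIC",
    "vehicle_0.037",
    "vehicle_0.10",
    "vehicle_0.27",
)


@dataclass
class ArrayRecording:
    """One 30-min recording of a single 80-electrode array (one well)."""

    well: int
    div: int
    condition: str
    trains: list
    layout: DeviceLayout = field(default_factory=DeviceLayout)

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"condition {self.condition!r} not one of {CONDITIONS}"
            )
        expect = self.layout.electrodes_per_well
        if len(self.trains) != expect:
            raise ValueError(f"expected {expect} trains, got {len(self.trains)}")
        durs = {t.duration for t in self.trains}
        if len(durs) > 1:
            raise ValueError("all trains must share one recording duration")
        seen = {t.address for t in self.trains}
        if len(seen) != len(self.trains):
            raise ValueError("duplicate electrode address among trains")
        self.trains = sorted(self.trains, key=lambda t: t.address)

    @property
    def duration(self) -> float:
        return self.trains[0].duration

    def train(self, probe: int, electrode: int) -> SpikeTrain:
        for t in self.trains:
            if t.address.probe == probe and t.address.electrode == electrode:
                return t
        raise KeyError((probe, electrode))
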