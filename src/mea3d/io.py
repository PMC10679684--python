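"""HDF5 spike-data I/O and YAML layout configuration.

Schema (one file per device recording)::

    /wells/{w}/                          group per well, attrs: div, condition
    /wells/{w}/electrodes/{p}_{e}/spike_times   float64 seconds, sorted
    root attrs: duration_s, sampling_hz

Timestamps are stored as float64 seconds; round trips are lossless well
below the 1 us resolution of a 10 kHz acquisition.
"""

from __future__ import annotations

import os

import h5py
import numpy as np
import yaml

from .geometry import ArrayRecording, DeviceLayout, ElectrodeAddress, SpikeTrain


class SchemaError(ValueError):
    """The HDF5 file does not conform to the documented spike-data schema."""


def write_recording(recordings, path, sampling_hz: float = 10_000.0) -> None:
    """Write one or more :class:`ArrayRecording` (one per well) to HDF5."""
    if isinstance(recordings, ArrayRecording):
        recordings = [recordings]
    durations = {r.duration for r in recordings}
    if len(durations) != 1:
        raise ValueError("all recordings in one file must share a duration")
    with h5py.File(path, "w") as f:
        f.attrs["duration_s"] = float(recordings[0].duration)
        f.attrs["sampling_hz"] = float(sampling_hz)
        wells = f.create_group("wells")
        for rec in recordings:
            g = wells.create_group(str(rec.well))
            g.attrs["div"] = int(rec.div)
            g.attrs["condition"] = rec.condition
            eg = g.create_group("electrodes")
            for train in rec.trains:
                a = train.address
                eg.create_dataset(
                    f"{a.probe}_{a.electrode}",
                    data=np.asarray(train.times, dtype=np.float64),
                )


def read_recording(path, layout: DeviceLayout | None = None) -> list:
    """Read all wells of a spike-data HDF5 file into :class:`ArrayRecording`s."""
    if layout is None:
        layout = DeviceLayout()
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    recordings = []
    with h5py.File(path, "r") as f:
        if "wells" not in f or "duration_s" not in f.attrs:
            raise SchemaError("missing /wells group or duration_s attribute")
        duration = float(f.attrs["duration_s"])
        for w_name in sorted(f["wells"], key=int):
            g = f["wells"][w_name]
            if "electrodes" not in g:
                raise SchemaError(f"well {w_name} lacks an electrodes group")
            trains = []
            for key, ds in g["electrodes"].items():
                try:
                    p, e = (int(x) for x in key.split("_"))
                except ValueError:
                    raise SchemaError(f"bad electrode key {key!r}") from None
                times = np.asarray(ds[()], dtype=np.float64)
                if times.size and np.any(np.diff(times) < 0):
                    raise SchemaError(
                        f"unsorted spike timestamps for well {w_name} electrode {key}"
                    )
                addr = ElectrodeAddress(int(w_name), p, e)
                try:
                    trains.append(SpikeTrain(addr, times, duration=duration))
                except ValueError as exc:
                    raise SchemaError(str(exc)) from None
            if len(trains) != layout.electrodes_per_well:
                raise SchemaError(
                    f"well {w_name} has {len(trains)} electrodes, expected "
                    f"{layout.electrodes_per_well}"
                )
            recordings.append(
                ArrayRecording(
                    well=int(w_name),
                    div=int(g.attrs.get("div", -1)),
                    condition=str(g.attrs.get("condition", "baseline")),
                    trains=trains,
                    layout=layout,
                )
            )
    return recordings


def layout_from_yaml(path) -> DeviceLayout:
    """Build a :class:`DeviceLayout` from a YAML config.

    Recognized keys: ``n_wells``, ``probes_per_well``, ``electrodes_per_probe``,
    ``section_span_um``, ``electrode_z_um`` (list) and ``channel_map`` (mapping
    of raw channel -> [well, probe, electrode]).
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    cmap = {
        int(ch): ElectrodeAddress(*[int(v) for v in addr])
        for ch, addr in (cfg.pop("channel_map", {}) or {}).items()
    }
    return DeviceLayout(channel_map=cmap, **cfg)


def layout_to_yaml(layout: DeviceLayout, path) -> None:
    cfg = {
        "n_wells": layout.n_wells,
        "probes_per_well": layout.probes_per_well,
        "electrodes_per_probe": layout.electrodes_per_probe,
        "section_span_um": layout.section_span_um,
        "electrode_z_um": list(layout.electrode_z_um),
        "channel_map": {
            ch: [a.well, a.probe, a.electrode]
            for ch, a in sorted(layout.channel_map.items())
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
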