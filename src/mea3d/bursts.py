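"""Silent-electrode filtering and per-electrode spike/burst features.

Burst detection is an ISI-threshold scan: a candidate burst opens when an
interspike interval drops to ``max_begin_isi`` (0.1 s) or less, and extends
while intervals stay within ``max_end_isi`` (0.2 s).  Candidates closer than
the minimum interburst interval (0.5 s) are merged, and merged candidates
must still contain at least 6 spikes and last at least 0.05 s.  Electrodes
with fewer than 10 spikes over the recording are silent: they are excluded
from active analysis and carry zero for every feature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import ArrayRecording, SpikeTrain, assign_cross_section


@dataclass(frozen=True)
class BurstParams:
    max_begin_isi: float = 0.1
    max_end_isi: float = 0.2
    min_ibi: float = 0.5
    min_duration: float = 0.05
    min_spikes: int = 6
    silent_threshold: int = 10  # spikes per recording below which an electrode is silent

    def __post_init__(self) -> None:
        if not 0 < self.max_begin_isi <= self.max_end_isi:
            raise ValueError("need 0 < max_begin_isi <= max_end_isi")
        if self.min_ibi <= 0 or self.min_duration <= 0:
            raise ValueError("min_ibi and min_duration must be positive")
        if self.min_spikes < 2:
            raise ValueError("min_spikes must be >= 2")
        if self.silent_threshold < 0:
            raise ValueError("silent_threshold must be >= 0")


@dataclass(frozen=True)
class Burst:
    start: float
    end: float
    n_spikes: int

    @property
    def duration(self) -> float:
        return self.end - self.start


def filter_silent(recording: ArrayRecording, params: BurstParams | None = None):
    """Split a recording's trains into active and silent electrodes.

    Returns ``(active_trains, removed_addresses)``; an electrode is removed
    when it fired fewer than ``silent_threshold`` spikes over the recording.
    The removed list is preserved so features can be zero-filled.
    """
    params = params or BurstParams()
    active, removed = [], []
    for train in recording.trains:
        if train.n_spikes < params.silent_threshold:
            removed.append(train.address)
        else:
            active.append(train)
    return active, removed


def detect_bursts(train: SpikeTrain, params: BurstParams | None = None) -> list:
    """ISI-scan burst detection on one spike train.

    Candidate runs are opened by an ISI <= ``max_begin_isi`` and extended
    while ISIs stay <= ``max_end_isi``; runs separated by less than
    ``min_ibi`` are merged (iteratively), and only merged runs with at least
    ``min_spikes`` spikes and ``min_duration`` length are returned.
    """
    params = params or BurstParams()
    t = train.times
    if t.size < 2:
        return []
    isi = np.diff(t)

    # scan: candidates as (first_spike_idx, last_spike_idx) inclusive
    candidates = []
    i = 0
    n_isi = isi.size
    while i < n_isi:
        if isi[i] <= params.max_begin_isi:
            j = i + 1
            while j < n_isi and isi[j] <= params.max_end_isi:
                j += 1
            candidates.append((i, j))  # spikes i .. j
            i = j + 1
        else:
            i += 1

    # merge candidates whose gap (start of next minus end of previous) < min_ibi
    merged = []
    for c in candidates:
        if merged and t[c[0]] - t[merged[-1][1]] < params.min_ibi:
            merged[-1] = (merged[-1][0], c[1])
        else:
            merged.append(list(c))

    bursts = []
    for a, b in merged:
        n_sp = b - a + 1
        dur = t[b] - t[a]
        if n_sp >= params.min_spikes and dur >= params.min_duration:
            bursts.append(Burst(start=float(t[a]), end=float(t[b]), n_spikes=n_sp))
    return bursts


def compute_features(
    recording: ArrayRecording,
    params: BurstParams | None = None,
) -> pd.DataFrame:
    """Per-electrode feature table for one recording.

    One row per layout electrode with spike count, firing rate (Hz), mean
    ISI (s, over all consecutive spike pairs), burst count, bursts per
    minute and mean burst duration (s).  Silent electrodes get zeros and
    ``active=False``.
    """
    params = params or BurstParams()
    active, removed = filter_silent(recording, params)
    removed_set = set(removed)
    duration = recording.duration
    rows = []
    for train in recording.trains:
        a = train.address
        silent = a in removed_set
        if silent:
            feats = dict(
                n_spikes=0, firing_rate=0.0, mean_isi=0.0,
                n_bursts=0, bursts_per_minute=0.0, mean_burst_duration=0.0,
            )
        else:
            bursts = detect_bursts(train, params)
            isi = np.diff(train.times)
            feats = dict(
                n_spikes=train.n_spikes,
                firing_rate=train.n_spikes / duration,
                mean_isi=float(isi.mean()) if isi.size else 0.0,
                n_bursts=len(bursts),
                bursts_per_minute=len(bursts) / (duration / 60.0),
                mean_burst_duration=(
                    float(np.mean([b.duration for b in bursts])) if bursts else 0.0
                ),
            )
        rows.append(
            dict(
                well=a.well, probe=a.probe, electrode=a.electrode,
                section=assign_cross_section(a.electrode),
                active=not silent, **feats,
            )
        )
    return pd.DataFrame(rows)


FEATURE_COLUMNS = (
    "n_spikes", "firing_rate", "mean_isi",
    "n_bursts", "bursts_per_minute", "mean_burst_duration",
)
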