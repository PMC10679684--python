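"""Synthetic 3D-culture generator.

Produces spike recordings, longitudinal (DIV) series, receptor-antagonist
treatment effects, raw voltage traces and nuclei-count z-stacks with the
statistical structure the downstream analysis assumes:

* per-electrode activity = homogeneous Poisson background + section-level
  burst events.  Burst events are a marked Poisson process per cross
  section; each event recruits each of the section's electrodes with a
  Bernoulli coupling probability, and a recruited electrode emits a run of
  >= 6 spikes at the configured intra-burst ISI (jittered).  Shared parent
  events across sections generate between-section synchrony.
* activity grows with culture age along a logistic curve per section
  (sparse before the onset DIV, saturating at the plateau DIV), emulating
  cultures that become active around two weeks in vitro and plateau around
  four.
* treatments scale firing rate, burst rate and coupling multiplicatively
  per section.
* nuclei counts per 10-um z-slice follow a bottom-heavy profile: most cells
  settle in the lower half of the gel before it polymerizes.

All generators are deterministic given a seed.  Defaults are synthetic and
documented, not fitted to any experimental dataset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    SECTIONS,
    ArrayRecording,
    DeviceLayout,
    SpikeTrain,
    assign_cross_section,
)

_MIN_BURST_SPIKES = 6


def _as_section_array(value, name: str) -> np.ndarray:
    arr = np.broadcast_to(np.asarray(value, dtype=float), (len(SECTIONS),)).copy()
    if np.any(arr < 0):
        raise ValueError(f"{name} must be non-negative, got {arr}")
    return arr


def logistic_growth(div, onset_div, plateau_div) -> np.ndarray:
    """Activity scale factor in [0, 1] as a function of culture age.

    The curve passes 5% of plateau at ``onset_div`` and 95% at
    ``plateau_div``; activity is effectively absent before onset and
    saturated after the plateau.
    """
    onset = np.asarray(onset_div, dtype=float)
    plateau = np.asarray(plateau_div, dtype=float)
    if np.any(plateau <= onset):
        raise ValueError("plateau_div must exceed onset_div")
    mid = (onset + plateau) / 2.0
    k = 2.0 * math.log(19.0) / (plateau - onset)
    return 1.0 / (1.0 + np.exp(-k * (np.asarray(div, dtype=float) - mid)))


@dataclass(frozen=True)
class CultureConfig:
    """Parameters of the synthetic culture (per section, bottom -> top).

    Attributes
    ----------
    firing_rate_hz : array-like (4,)
        Target per-electrode firing rate at plateau, background plus burst
        spikes combined.  The Poisson background rate is reduced by the
        expected burst contribution so the total matches this value.
    burst_rate_per_min : array-like (4,)
        Section-level burst-event rate at plateau.
    within_coupling : array-like (4,)
        Probability that a section-level burst event recruits any given
        electrode of that section.
    between_coupling : float
        Fraction of burst events shared across sections (shared parent
        events); 0 = sections burst independently.
    intra_burst_isi_s : float
        Nominal spacing of spikes inside an emitted burst.
    spikes_per_burst_mean : float
        Mean spikes per emitted burst; the count is 6 + Poisson(mean - 6).
    onset_div, plateau_div : array-like (4,)
        Logistic growth-curve anchors per section.
    """

    firing_rate_hz: tuple = (2.0, 1.4, 1.8, 1.6)
    burst_rate_per_min: tuple = (10.0, 7.0, 10.0, 8.0)
    within_coupling: tuple = (0.7, 0.6, 0.7, 0.7)
    between_coupling: float = 0.4
    intra_burst_isi_s: float = 0.05
    spikes_per_burst_mean: float = 12.0
    burst_jitter_s: float = 0.010
    onset_div: tuple = (14.0, 17.0, 14.0, 17.0)
    plateau_div: tuple = (32.0, 32.0, 38.0, 38.0)

    def __post_init__(self) -> None:
        for name in ("firing_rate_hz", "burst_rate_per_min", "within_coupling"):
            arr = _as_section_array(getattr(self, name), name)
            object.__setattr__(self, name, tuple(arr))
        if not 0.0 <= self.between_coupling <= 1.0:
            raise ValueError("between_coupling must be in [0, 1]")
        if np.any(np.asarray(self.within_coupling) > 1.0):
            raise ValueError("within_coupling probabilities must be <= 1")
        if self.intra_burst_isi_s <= 0:
            raise ValueError("intra_burst_isi_s must be positive")
        if self.spikes_per_burst_mean < _MIN_BURST_SPIKES:
            raise ValueError(
                f"spikes_per_burst_mean must be >= {_MIN_BURST_SPIKES}"
            )
        onset = _as_section_array(self.onset_div, "onset_div")
        plateau = _as_section_array(self.plateau_div, "plateau_div")
        if np.any(plateau <= onset):
            raise ValueError("plateau_div must exceed onset_div per section")
        object.__setattr__(self, "onset_div", tuple(onset))
        object.__setattr__(self, "plateau_div", tuple(plateau))

    def growth_factor(self, div) -> np.ndarray:
        """Per-section logistic scale at culture age ``div``."""
        return logistic_growth(
            div, np.asarray(self.onset_div), np.asarray(self.plateau_div)
        )


@dataclass(frozen=True)
class TreatmentEffect:
    """Per-condition, per-section multiplicative factors (bottom -> top).

    Keys are condition labels; missing conditions (including all vehicle
    conditions by default) act as identity.  Factors scale, respectively,
    the background firing rate, the burst-event rate and the electrode
    recruitment (coupling) probability.
    """

    firing: dict = field(default_factory=dict)
    burst: dict = field(default_factory=dict)
    coupling: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("firing", "burst", "coupling"):
            clean = {
                cond: tuple(_as_section_array(v, f"{name}[{cond}]"))
                for cond, v in getattr(self, name).items()
            }
            object.__setattr__(self, name, clean)

    def factors(self, condition: str):
        ones = np.ones(len(SECTIONS))
        return (
            np.asarray(self.firing.get(condition, ones), dtype=float),
            np.asarray(self.burst.get(condition, ones), dtype=float),
            np.asarray(self.coupling.get(condition, ones), dtype=float),
        )

    @classmethod
    def null(cls) -> "TreatmentEffect":
        return cls()

    @classmethod
    def disinhibition_preset(cls) -> "TreatmentEffect":
        """Synthetic antagonist phenomenology: GABA_A block (BIC) disinhibits
        lower sections but reduces coordinated firing at the top; adding the
        NMDA antagonist (AP-5) trims activity mildly; adding the AMPA/kainate
        antagonist (CNQX) silences roughly half of the network."""
        return cls(
            firing={
                "BIC": (1.6, 1.4, 1.2, 0.7),
                "AP5+BIC": (1.2, 1.1, 0.9, 0.6),
                "CNQX+AP5+BIC": (0.4, 0.35, 0.3, 0.25),
            },
            burst={
                "BIC": (1.5, 1.4, 1.2, 0.8),
                "AP5+BIC": (1.1, 1.0, 0.9, 0.7),
                "CNQX+AP5+BIC": (0.35, 0.3, 0.3, 0.2),
            },
            coupling={
                "BIC": (1.3, 1.3, 1.2, 0.9),
                "AP5+BIC": (1.0, 0.95, 0.9, 0.8),
                "CNQX+AP5+BIC": (0.5, 0.45, 0.4, 0.35),
            },
        )


# ---------------------------------------------------------------------------
# expected-rate bookkeeping (used by tests to form analytic standard errors)
# ---------------------------------------------------------------------------

def _spike_count_moments(mean_spikes: float):
    # S = 6 + Poisson(mean - 6): E[S] = mean, Var[S] = mean - 6
    mu = mean_spikes
    var = mean_spikes - _MIN_BURST_SPIKES
    return mu, var + mu * mu  # (E[S], E[S^2])


def effective_rates(
    config: CultureConfig,
    div: float = 45.0,
    condition: str = "baseline",
    effects: TreatmentEffect | None = None,
):
    """Per-section (background_rate, event_rate_hz, coupling) after growth
    and treatment scaling.  Background is the configured total rate minus
    the expected burst contribution, floored at zero."""
    effects = effects or TreatmentEffect.null()
    f_fire, f_burst, f_coup = effects.factors(condition)
    g = config.growth_factor(div)
    total = np.asarray(config.firing_rate_hz) * g * f_fire
    ev_rate = np.asarray(config.burst_rate_per_min) / 60.0 * g * f_burst
    coupling = np.clip(np.asarray(config.within_coupling) * f_coup, 0.0, 1.0)
    mu_s, _ = _spike_count_moments(config.spikes_per_burst_mean)
    background = np.clip(total - ev_rate * coupling * mu_s, 0.0, None)
    return background, ev_rate, coupling


def expected_section_rate(
    config: CultureConfig,
    div: float = 45.0,
    condition: str = "baseline",
    effects: TreatmentEffect | None = None,
    duration: float = 1800.0,
    electrodes_per_section: int = 20,
):
    """Expected per-electrode firing rate per section and the analytic SE of
    the section-mean rate.

    The SE accounts for the compound-Poisson clustering of burst spikes:
    shared section events correlate electrodes, so the variance of the
    section total is ``n*lam_bg*T + lam_ev*T*E[X^2]`` with
    ``X = sum_i Bern(p) * S_i`` the spikes one event adds to the section.
    """
    bg, ev, p = effective_rates(config, div, condition, effects)
    mu_s, s2 = _spike_count_moments(config.spikes_per_burst_mean)
    n = electrodes_per_section
    mean_rate = bg + ev * p * mu_s
    # event-level moments of X
    ex = n * p * mu_s
    var_x = n * (p * s2 - p * p * mu_s * mu_s)
    ex2 = var_x + ex * ex
    var_total = n * bg * duration + ev * duration * ex2
    se = np.sqrt(var_total) / (n * duration)
    return mean_rate, se


# ---------------------------------------------------------------------------
# recording simulation
# ---------------------------------------------------------------------------

def _poisson_times(rng, rate_hz: float, duration: float) -> np.ndarray:
    n = rng.poisson(rate_hz * duration)
    return np.sort(rng.uniform(0.0, duration, size=n))


def simulate_recording(
    config: CultureConfig,
    div: float = 45.0,
    condition: str = "baseline",
    effects: TreatmentEffect | None = None,
    seed: int | np.random.SeedSequence = 0,
    layout: DeviceLayout | None = None,
    well: int = 1,
    duration: float = 1800.0,
) -> ArrayRecording:
    """Simulate one 80-electrode array recording.

    Spikes per electrode are a homogeneous Poisson background plus bursts
    emitted when section-level events recruit the electrode.  A fraction
    ``between_coupling`` of events are shared parents that reach every
    section simultaneously, generating between-section synchrony.
    """
    layout = layout or DeviceLayout()
    rng = np.random.default_rng(seed)
    bg, ev_rate, coupling = effective_rates(config, div, condition, effects)

    # shared parents fire at kappa * min section rate so every section keeps
    # its configured total event rate exactly
    shared_rate = config.between_coupling * float(ev_rate.min())
    shared = _poisson_times(rng, shared_rate, duration)
    events_by_section = [
        np.sort(
            np.concatenate(
                [shared, _poisson_times(rng, max(r - shared_rate, 0.0), duration)]
            )
        )
        for r in ev_rate
    ]

    isi = config.intra_burst_isi_s
    jit = config.burst_jitter_s
    extra_mean = config.spikes_per_burst_mean - _MIN_BURST_SPIKES

    trains = []
    for addr in (a for a in layout.addresses() if a.well == well):
        s_idx = SECTIONS.index(assign_cross_section(addr.electrode))
        spikes = [_poisson_times(rng, bg[s_idx], duration)]
        events = events_by_section[s_idx]
        if events.size and coupling[s_idx] > 0:
            recruited = events[rng.random(events.size) < coupling[s_idx]]
            for t0 in recruited:
                n_sp = _MIN_BURST_SPIKES + rng.poisson(extra_mean)
                start = t0 + abs(rng.normal(0.0, jit))
                offsets = isi * np.arange(n_sp) * (
                    1.0 + rng.uniform(-0.1, 0.1, size=n_sp)
                )
                spikes.append(start + np.sort(offsets))
        times = np.concatenate(spikes)
        times = np.sort(times[(times >= 0.0) & (times <= duration)])
        trains.append(SpikeTrain(addr, times, duration=duration))

    return ArrayRecording(
        well=well, div=int(round(div)), condition=condition,
        trains=trains, layout=layout,
    )


def simulate_longitudinal(
    config: CultureConfig,
    div_list,
    seed: int | np.random.SeedSequence = 0,
    **kwargs,
) -> list:
    """One recording per DIV, with per-section activity following the
    configured logistic growth curves."""
    div_list = list(div_list)
    if sorted(div_list) != div_list:
        raise ValueError("div_list must be sorted")
    ss = np.random.SeedSequence(seed) if isinstance(seed, int) else seed
    children = ss.spawn(len(div_list))
    return [
        simulate_recording(config, div=d, seed=c, **kwargs)
        for d, c in zip(div_list, children)
    ]


def simulate_treatment_series(
    config: CultureConfig,
    effects: TreatmentEffect | None = None,
    seed: int | np.random.SeedSequence = 0,
    div: float = 45.0,
    n_vehicle_wells: int = 3,
    **kwargs,
):
    """Sequential-antagonist experiment on one chemical well plus matched
    vehicle wells.

    Returns ``(chem, vehicles)``: ``chem`` maps each chemical condition
    (baseline, BIC, AP5+BIC, CNQX+AP5+BIC) to a recording of the treated
    well; ``vehicles`` is a list of per-well dicts keyed by the vehicle
    conditions (baseline, vehicle_0.037, vehicle_0.10, vehicle_0.27).
    """
    effects = effects if effects is not None else TreatmentEffect.disinhibition_preset()
    ss = np.random.SeedSequence(seed) if isinstance(seed, int) else seed
    chem_conditions = ["baseline", "BIC", "AP5+BIC", "CNQX+AP5+BIC"]
    veh_conditions = ["baseline", "vehicle_0.037", "vehicle_0.10", "vehicle_0.27"]
    children = iter(ss.spawn(len(chem_conditions) + n_vehicle_wells * len(veh_conditions)))
    chem = {
        cond: simulate_recording(
            config, div=div, condition=cond, effects=effects,
            seed=next(children), well=1, **kwargs,
        )
        for cond in chem_conditions
    }
    vehicles = []
    for w in range(n_vehicle_wells):
        vehicles.append({
            cond: simulate_recording(
                config, div=div, condition=cond, effects=effects,
                seed=next(children), well=min(w + 1, 3), **kwargs,
            )
            for cond in veh_conditions
        })
    return chem, vehicles


# ---------------------------------------------------------------------------
# nuclei z-stacks and raw traces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DensityConfig:
    """Synthetic nuclei distribution over the gel depth.

    ``shape='bottom_heavy'`` uses an exponential density with length scale
    half the gel height, placing ~73% of cells in the bottom half (cells
    settle before the gel polymerizes); ``'uniform'`` spreads them evenly.
    """

    total_cells: int = 6000
    gel_height_um: float = 1354.0
    slice_um: float = 10.0
    field_area_mm2: float = 0.44
    shape: str = "bottom_heavy"

    def __post_init__(self) -> None:
        if self.total_cells < 0:
            raise ValueError("total_cells must be >= 0")
        if self.gel_height_um <= 0 or self.slice_um <= 0:
            raise ValueError("gel height and slice thickness must be positive")
        if self.shape not in ("bottom_heavy", "uniform"):
            raise ValueError(f"unknown density shape {self.shape!r}")

    @property
    def slice_edges_um(self) -> np.ndarray:
        n = int(np.ceil(self.gel_height_um / self.slice_um))
        return self.slice_um * np.arange(n + 1)


def simulate_density_stack(dcfg: DensityConfig, seed: int = 0):
    """Nuclei counts per 10-um z-slice (multinomial sample of the profile).

    Returns ``(slice_edges_um, counts)`` with ``len(counts) ==
    len(slice_edges_um) - 1``.
    """
    rng = np.random.default_rng(seed)
    edges = dcfg.slice_edges_um
    centers = (edges[:-1] + np.minimum(edges[1:], dcfg.gel_height_um)) / 2.0
    widths = np.minimum(edges[1:], dcfg.gel_height_um) - edges[:-1]
    if dcfg.shape == "uniform":
        weights = widths.astype(float)
    else:
        scale = dcfg.gel_height_um / 2.0
        weights = widths * np.exp(-centers / scale)
    weights = weights / weights.sum()
    counts = rng.multinomial(dcfg.total_cells, weights)
    return edges, counts


def simulate_raw_trace(
    train: SpikeTrain,
    noise_sd: float = 5.0,
    spike_amp: float = -50.0,
    sampling_hz: float = 10_000.0,
    seed: int = 0,
) -> np.ndarray:
    """Synthetic extracellular voltage trace (uV): Gaussian noise plus a
    stereotyped biphasic waveform (sharp negative lobe, smaller positive
    rebound) inserted at each spike time.
    """
    if spike_amp >= 0:
        raise ValueError("spike_amp must be negative (extracellular convention)")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if sampling_hz < 2000.0:
        raise ValueError("sampling_hz too low to resolve the ~1 ms waveform")
    rng = np.random.default_rng(seed)
    n = int(round(train.duration * sampling_hz))
    trace = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else np.zeros(n)

    # ~1.2 ms biphasic template, unit negative peak
    half = max(int(round(0.0006 * sampling_hz)), 3)
    k = np.arange(2 * half)
    w = np.where(
        k < half,
        -np.sin(np.pi * k / half),
        0.3 * np.sin(np.pi * (k - half) / half),
    )
    template = np.abs(spike_amp) * w

    if train.times.size and train.times[-1] > train.duration:
        raise ValueError("spike times beyond trace duration")
    for t in train.times:
        i0 = int(round(t * sampling_hz))
        i1 = min(i0 + template.size, n)
        trace[i0:i1] += template[: i1 - i0]
    return trace
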