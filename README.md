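# mea3d

Depth-resolved analysis of extracellular recordings from **3D
multi-electrode arrays (3D MEAs)** embedded in hydrogel-based neural
tissue — human iPSC-derived neurons co-cultured with astrocytes in an
ECM-collagen gel.  Unlike planar MEAs, which sample only the surface of a
3D culture, these devices carry 10 vertically actuated polymer probes per
well with 8 thin-film electrodes each (80 electrodes per array, 240 per
3-well device), so spiking can be resolved along the vertical (z) axis of
the tissue.

The package is written for electrophysiologists and tissue engineers who
need to turn time-stamped spike data from such devices into
depth-resolved, density-corrected, network-level readouts:

* **Cross sections.**  Vertical electrode pairs partition the tissue into
  four 250 µm slabs — *bottom* (electrodes 1–2), *middle 1* (3–4),
  *middle 2* (5–6), *top* (7–8).  Spike/burst features are summarized per
  slab and corrected for the non-uniform cell density over depth.
* **Synchrony.**  Pairwise network coordination is measured with the
  SPIKE-distance, a parameter-free, time-resolved dissimilarity
  *D* ∈ [0, 1] between two spike trains; the synchrony score is *S* = 1 −
  *D* (1 = fully synchronous).  Optionally the distance is normalized by
  the mean distance of rate-matched Poisson surrogates, which removes the
  measure's bias toward higher synchrony for denser trains.
* **Pharmacology.**  Sequential receptor antagonists — bicuculline (BIC,
  GABA_A), AP-5 (NMDA), CNQX (AMPA/kainate), each added on top of the
  previous — let networks be classified by their synaptic dependence.
  Every electrode pair ("edge") is tracked across conditions and
  categorized as high synchrony (*S* ≥ 0.40), low (*S* < 0.40), or
  inactive, with counts normalized to the edges visible under BIC
  disinhibition.

Because raw recordings of this kind are rarely shared, the package
includes a first-class synthetic-culture generator
(`mea3d.synthetic`) that reproduces the statistical structure the
analysis assumes — layered arrays, bottom-heavy cell density, logistic
growth of activity over days in vitro (DIV), correlated bursting within
and between cross sections, and multiplicative treatment effects — so
every stage is testable end to end.

## Methods at a glance

* Spike detection: bandpass 4–4000 Hz at 10 kHz, threshold at −6.5 × SD of
  baseline noise (robust MAD estimate), 1 ms refractory.
* Burst detection (ISI scan): a burst opens at an inter-spike interval
  ≤ 0.1 s, extends while ISIs ≤ 0.2 s, merges across gaps < 0.5 s, and
  must contain ≥ 6 spikes over ≥ 0.05 s.  Electrodes with < 10 spikes per
  30-min recording are silent and zero-filled.
* SPIKE-distance: with auxiliary spikes at 0 and *T*, the instantaneous
  dissimilarity is
  `S_n(t) = (Δt_P x_F + Δt_F x_P) / x_ISI` per train and
  `S(t) = (S_1 x_ISI,2 + S_2 x_ISI,1) / (2 ⟨x_ISI⟩²)` for the pair;
  *D* is the exact time average of the piecewise-linear `S(t)`.
* Density normalization: per-section densities from 10 µm nuclei-count
  z-slices; constants `c_s = d_bottom / d_s` (bottom ≡ 1) multiply each
  section's features.
* Layer correlations: Pearson *r* between per-DIV section trajectories,
  separately for the growth (DIV 14–28) and plateau (DIV 32–45) phases.

## Worked example

```python
import numpy as np
import mea3d

# a mature (45 DIV) synthetic culture, one well, 10 min
cfg = mea3d.CultureConfig()
rec = mea3d.simulate_recording(cfg, div=45, seed=42, duration=600.0)

feats = mea3d.compute_features(rec)          # one row per electrode
summary = mea3d.aggregate(feats)             # per cross section
print(summary[["n_active", "firing_rate_mean", "bursts_per_minute_mean"]].round(3))

edges, counts = mea3d.simulate_density_stack(mea3d.DensityConfig(), seed=42)
prof = mea3d.DensityProfile.from_counts(edges, counts, field_area_mm2=0.44)
print(np.round(prof.constants, 3))
print(mea3d.apply_density_normalization(summary, prof.constants)[
    ["firing_rate_mean"]].round(3))
```

prints

```
         n_active  firing_rate_mean  bursts_per_minute_mean
section
bottom         20             1.917                   5.900
middle1        20             1.585                   4.655
middle2        20             1.653                   5.525
top            20             1.720                   5.600
full           80             1.719                   5.420
[1.    1.516 2.106 1.605]
         firing_rate_mean
section
bottom              1.917
middle1             2.403
middle2             3.481
top                 2.760
full                1.719
```

All 80 electrodes are active; raw firing rates are fairly even across
depth (1.6–1.9 Hz, ~5 bursts/min).  The bottom-heavy nuclei stack gives
normalization constants of 1 / 1.52 / 2.11 / 1.61 (fold-difference in cell
density relative to the bottom), so per unit cell density the upper
sections are the most active — the middle-2 slab reaches 3.48 Hz after
correction despite having the fewest cells.

Pairwise synchrony and treatment tracking follow the same pattern:

```python
m = mea3d.pairwise_matrix(rec, mea3d.SynchronyParams(seed=42))
print(m.section_block_means())              # 4x4 within/between-section means
```

A CLI mirrors the library (`mea3d simulate|validate|remap|detect|features|
sections|synchrony|run`); `mea3d run config.yaml` executes the full
pipeline and writes a manifest with the seed and parameter hash.

## Layout

```
src/mea3d/
  geometry.py    device layout, channel remapping, cross sections, spike trains
  io.py          HDF5 spike-data schema, YAML layout configs
  synthetic.py   synthetic cultures, growth curves, treatments, traces, z-stacks
  detection.py   bandpass + robust-threshold spike detection
  bursts.py      silent-electrode filter, ISI-scan burst detection, features
  sections.py    section aggregation, density normalization, layer correlations
  synchrony.py   SPIKE-distance engine, surrogate normalization, matrices
  treatments.py  vehicle fold changes, edge categories, tracking, shift fits
  pipeline.py    end-to-end orchestration with manifest
  cli.py         click CLI
```

See `docs/methods.md` for the modeling assumptions, parameter defaults and
numerical choices.
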