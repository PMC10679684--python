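# Methods notes

This note records the models, parameter conventions and numerical choices
behind `mea3d`, and what the synthetic-culture tests do and do not
establish about real recordings.

## Device model and cross sections

The device is modeled as 3 wells × 10 probes × 8 electrodes (240
channels used of a 256-channel acquisition format).  The physical wiring
of acquisition channels to electrodes is instrument-specific and not
derivable from first principles, so the 256→240 map is a configurable
lookup table; the shipped default assigns channels 0–239 in
(well, probe, electrode) lexicographic order and leaves 240–255 unused.
This default is an arbitrary but fixed, documented choice — real rigs
should supply their wiring as YAML.

Electrode *e* ∈ 1..8 on a probe belongs to cross section ⌈e/2⌉ of four
250 µm slabs (bottom, middle 1, middle 2, top).  Default electrode
heights are the centers of successive 125 µm half-bins (125, 375, …,
1875 µm), i.e., each electrode pair straddles the center of its slab.
Probe-tilt effects on electrode height are out of scope; heights are
only used for documentation and density binning, never for analysis
weights.

Timestamps are float64 seconds; indices are 1-based to match bench
labeling conventions.  The HDF5 schema
(`/wells/{w}/electrodes/{p}_{e}/spike_times`) round-trips losslessly far
below the 1 µs resolution of a 10 kHz acquisition.

## Spike detection

Raw traces are bandpassed 4–4000 Hz (2nd-order Butterworth) and spikes
are downward crossings of −6.5 × SD of baseline noise with a 1 ms
refractory.  Two deliberate choices:

* **Zero-phase filtering** (`sosfiltfilt`): the band is standard but the
  filter implementation is not dictated by the acquisition convention;
  zero-phase avoids biasing spike timestamps by the filter group delay.
  Note that forward–backward application means white noise retains the
  band's power squared, so the post-filter SD of synthetic white noise is
  ~14 % below the raw SD — tests compare against the filtered trace's
  true SD, not the generator's input SD.
* **Robust SD** via the scaled median absolute deviation (×1.4826),
  computed on the filtered signal.  The plain sample SD is inflated by
  the spikes themselves (visibly so at 1 % contamination); MAD is nearly
  unbiased for Gaussian noise and insensitive to sparse deflections.  The
  raw SD remains selectable (`robust_sd=False`) for parity with
  instruments that threshold on the plain SD.

Only the negative threshold is applied (extracellular spikes present as
negative deflections at the electrode).

## Burst detection

ISI-threshold scan with the standard five parameters: max beginning ISI
0.1 s, max ending ISI 0.2 s, min inter-burst interval 0.5 s, min duration
0.05 s, min 6 spikes.  Interpretation choices, since the scan itself is a
convention rather than a published algorithm:

* A candidate opens when an ISI ≤ 0.1 s occurs (that ISI is the burst's
  first interval) and extends while ISIs stay ≤ 0.2 s.
* Candidates separated by < 0.5 s are merged *before* the spike-count and
  duration filters are applied, and the filters are evaluated on the
  merged candidate jointly.  Merging first preserves long composite
  bursts, which is what a minimum inter-burst interval semantically
  demands.  Returned bursts therefore always satisfy ≥ 6 spikes, ≥ 0.05 s
  duration, and ≥ 0.5 s separation.
* The mean ISI feature is computed over all consecutive spike pairs of
  the train, not restricted to bursts.

The scan is validated against an independent brute-force enumeration
(maximal runs + fixed-point merging) on 1000+ random trains.

Electrodes with fewer than 10 spikes per recording are silent: excluded
from active-only averages and zero-filled (`active=False`) in the feature
table, so arrays keep their full 80-row shape.

## SPIKE-distance and synchrony

With auxiliary spikes at *t* = 0 and *t* = *T* on both trains, each train
*n* contributes at time *t*: preceding/following spikes `t_P`, `t_F`,
local quantities `x_P = t − t_P`, `x_F = t_F − t`, `x_ISI = t_F − t_P`,
and nearest-spike offsets `Δt_P`, `Δt_F` from `t_P`, `t_F` to the other
train.  Then

    S_n(t) = (Δt_P·x_F + Δt_F·x_P) / x_ISI
    S(t)   = (S_1·x_ISI,2 + S_2·x_ISI,1) / (2·((x_ISI,1 + x_ISI,2)/2)²)
    D      = (1/T) ∫ S(t) dt

Between consecutive events of the merged pair, every quantity except
`x_P`, `x_F` is constant, so `S(t)` is **linear on each inter-event
interval** and the integral is computed exactly with one trapezoid per
interval — no quadrature error.  A dense-grid (1 ms) sampler kept in the
test suite as an independent oracle agrees to < 10⁻³ on hundreds of
random pairs; time-rescaling invariance holds to 10⁻⁹.  Identical trains
give *D* = 0 exactly.  Empty trains are an error (the measure is
undefined), and pairs are only scored when both electrodes pass the
10-spike activity rule.

**Surrogate normalization.**  The raw measure assigns denser train pairs
systematically lower distances.  The default score is
`S = 1 − D/D̄_rand`, where `D̄_rand` is the mean distance over 20
spike-count-matched homogeneous Poisson pairs with the same duration and
the same edge correction, sub-seeded deterministically per electrode
pair.  By construction a pair indistinguishable from independent Poisson
firing scores ≈ 0 (mean within sampling error of 0) and identical trains
score exactly 1.  The alternative `(1 − D)/(1 − D̄_rand)` form is
available as `method="similarity"`; results in this package default to
the ratio form because it zeroes the Poisson baseline rather than
rescaling it.  Scores are clipped to [0, 1].

Section block means average all non-missing pair scores within each
(section, section) block of the 4 × 4 grid; the time-resolved profile
restricts trains to consecutive windows, scores all within-section pairs
with spikes in the window, and averages per section.

A full 80-electrode, 30-min matrix (3160 pairs, surrogate normalization
on) completes in roughly two minutes on one CPU; the test suite asserts a
10-minute ceiling.

## Cell-density normalization

Nuclei counts per 10 µm confocal z-slice are binned into the four 250 µm
sections by slice center (counts above the top section fold into it; no
extrapolation), divided by the field-of-view area to give cells/mm², and
referenced to the bottom: `c_s = d_bottom / d_s`, bottom ≡ 1.  Features
multiply by `c_s`, expressing activity per unit cell density.  The
constants are scale-invariant in total cell count and undefined (an
error) when any section has zero density.  A single average density
profile is applied to all wells; per-well matched profiles can be passed
explicitly if available.

## Growth phases and layer correlations

Per-DIV section means are correlated (Pearson by default; the choice of
coefficient is a convention, Spearman is selectable) within the growth
(DIV 14–28) and plateau (DIV 32–45) windows, requiring ≥ 3 timepoints per
phase.  A constant trajectory has undefined correlation and is reported
as NaN, never coerced to 0.

## Treatment tracking

Antagonists are cumulative: BIC, then AP-5 + BIC, then CNQX + AP-5 + BIC,
with vehicle wells at the matching DMSO concentrations (0.037 / 0.10 /
0.27 %).  Feature effects are reported as
`(chem/chem_baseline) / mean(vehicle/vehicle_baseline)` so the DMSO trend
cancels; the vehicle group maps to 1 identically, and zero baselines
yield NaN with a warning rather than a silent 0.

Edges are categorized per condition: high (score ≥ 0.40), low (< 0.40),
inactive (either electrode under 10 spikes in that condition — the
silent-electrode rule reused as the edge-activity rule, a documented
choice since no separate definition exists).  Category counts are
normalized to the number of BIC-active edges (so per-condition fractions
need not sum to 1), transition flags mark edges that became active or
inactive relative to baseline, and synchrony shifts are fit by OLS with
the condition score as response and the BIC score as predictor (swap via
argument); fits with < 2 common edges or zero predictor spread are
reported missing.  Whether normalized or unnormalized scores feed the
edge analysis follows the synchrony parameters used to build the
matrices and is recorded there.

## Synthetic cultures

The generator is a minimal mechanism that produces the structure the
analysis measures, not a biophysical model:

* Per electrode: homogeneous Poisson background + bursts from
  section-level marked Poisson event processes.  Each event recruits each
  electrode of its section with probability `within_coupling`; a
  recruited electrode emits `6 + Poisson(mean − 6)` spikes at the
  intra-burst ISI (±10 % jitter) after a |N(0, 10 ms)| onset delay.
* Between-section synchrony comes from shared parent events: a fraction
  `between_coupling` of the slowest section's event rate is drawn as
  global parents that reach every section; the remainder is private per
  section, so each section keeps its configured total event rate exactly.
* The background rate is the configured total firing rate minus the
  expected burst contribution (floored at 0), so the *configured* rate is
  the *expected* rate; `expected_section_rate` also returns the analytic
  SE of a section-mean rate including the compound-Poisson clustering
  term, which the recovery tests use.
* Growth: per-section logistic in DIV anchored at 5 % (onset) and 95 %
  (plateau); defaults onset 14–17, plateau 32–38 by section.
* Defaults describe a mature, burst-dominated culture: total rates
  1.4–2.0 Hz per electrode by section, 7–10 burst events/min,
  recruitment 0.6–0.7, ~12 spikes/burst — i.e., most spikes occur inside
  coordinated bursts with sparse tonic firing between them, which is the
  regime in which depth-resolved synchrony analysis is informative.  All
  defaults are synthetic and documented, not fitted to any dataset.
* Nuclei stacks: multinomial over 10 µm slices of a 1354 µm gel with an
  exponential (length scale = half the gel height) bottom-heavy default
  (~73 % of cells in the lower half), 0.44 mm² field of view, 6000 cells.
* Raw traces: Gaussian noise plus a ~1.2 ms biphasic template (sharp
  negative lobe, 30 % positive rebound) at each spike time.

What the generator does **not** emulate: refractoriness and ISI structure
of real neurons, burst-shape adaptation, electrode-specific amplitudes
and noise, probe-angle geometry, well-to-well onset variability (the
generator exposes per-section onsets but defaults to common ones), or
non-stationarity within a recording.  Passing tests therefore establish
that the pipeline measures what it claims on data with known structure —
not that real cultures have that structure.

## Problem sizes in the test suite

The validation suites run at sizes chosen to exercise the full device
format while keeping the suite fast: 500 random pairs (≤ 60 spikes, 20 s)
for the distance-engine oracle; 1000 random trains for the burst oracle;
50 replicates of 200 s, 80-electrode recordings (unnormalized scores) for
the block-structure recovery; one full 80-electrode, 30-min recording
with surrogate normalization for the end-to-end matrix; 30-min
recordings for rate-recovery checks.

## Known limitations

* The exact integrator assumes finite spike times; coincident spikes
  across trains are handled by merging grid points, but truly identical
  trains are the only case with *D* exactly 0.
* Surrogate normalization can clip genuinely anti-synchronous pairs
  (D > D̄_rand) to 0; the unclipped value is recoverable by computing
  `spike_distance` and `surrogate_distance` directly.
* Density normalization multiplies SEMs by the same constant as means,
  i.e., it treats the constant as exact and propagates no uncertainty
  from the nuclei counts.
* The pipeline analyzes threshold-crossing multi-unit activity; no spike
  sorting is attempted, so "electrode" and "unit" are conflated
  throughout, as is standard for MEA burst/synchrony screens.
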