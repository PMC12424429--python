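# smtrap

Single-molecule trajectory analysis for membrane proteins imaged by
video-rate TIRF microscopy: short-timescale diffusion coefficients
(D<sub>200ms</sub>), transient-trapping detection and statistics, dual-color
colocalization, and membrane-recruitment quantification — together with a
seeded synthetic-trajectory generator so that every stage can be validated
by parameter recovery without any raw imaging data.

The package is written for single-particle-tracking (SPT) practitioners: it
starts from tidy trajectory tables (one localization per row) as produced by
any spot tracker, and reproduces the analysis used to characterize the
activation-dependent trapping of the small GTPase KRAS and its partners
(the exchange factor SOS1 and the kinase BRAF) in the plasma membrane.

## The quantities it computes

**Diffusion.** For a trajectory of N positions at frame interval δt the mean
square displacement at lag n averages the squared displacements over all
N−n overlapping windows,

    MSD(nδt) = ⟨[x(t+nδt) − x(t)]² + [y(t+nδt) − y(t)]²⟩ .

D<sub>200ms</sub> is the slope/4 of an ordinary least-squares line (with
intercept) through the MSD values at the 167, 200 and 233 ms lags
(n = 5, 6, 7 at video rate). Localization noise σ adds 4σ² to the intercept
but not to the slope. Trajectories with D<sub>200ms</sub> below a threshold
calibrated as the 95th-percentile D<sub>200ms</sub> of immobilized reference
molecules (0.009 μm²/s in the reference calibration) are classed immobile.

**Transient trapping.** A trapping event is ≥5 consecutive frames (166.7 ms)
confined within a 100-nm-diameter zone (50-nm radius about the event
centroid), found by a greedy grow-and-verify scan. Zone size is the radial
SD of the event's positions about the centroid, corrected for localization
precision in quadrature (√(raw² − 2σ²)) and reported as an area in
multiples of π nm². Per cell, the temporal fraction is the percentage of
tracked time inside events and the frequency is events per second of
tracked time.

**Colocalization.** All inter-channel pair distances per frame are binned
into 50-nm annuli (0–500 nm), normalized by annulus area; the
colocalization index is the 0–50 nm density over the 400–500 nm density
(1 under spatial independence). Two molecules within 240 nm in a frame are
scored colocalized; maximal runs of such frames form colocalization events.

**Recruitment.** Per cell, background-subtracted spot intensities of
molecules persisting ≥10 frames are summed and expressed relative to a
reference time point; the PS-probe assay is summarized as spot count /
(whole-cell intensity × area).

**Simulator.** A two-state (free / trapped) continuous-time Markov process
with exponential dwells, Brownian free motion (per-axis step variance
2·D·δt), Gaussian confinement about a fixed trap center, per-axis
localization noise, and geometric photobleach truncation. Closed-form
truncation oracles — mean detected dwell T + τ and detectable time fraction
e^(−T/τ)(1 + T/τ) — let a preset's occupancy be calibrated so the detector
should recover a chosen temporal fraction.

## Worked example

```python
import smtrap as sm

preset = sm.get_preset("wt_post2")      # activated-KRAS-like condition
preset.n_cells, preset.trajectories_per_cell = 4, 100
tracks = sm.simulate_experiment(preset, seed=1)

res = sm.TrappingModel(tracks, sm.DetectorParams(), sigma_axis=14.0).fit()
print(res.summary())
```

prints

```
Transient-trapping analysis
----------------------------------------------
detector             50 nm radius, >= 5 frames
trajectories         393 (>= 10 frames)
cells                4
events               765
mean duration        305.0 ms
mean temporal frac.  8.69 %
mean frequency       0.285 events/s
duration-size rho    0.044
```

The detector finds 765 confinement events in 393 trajectories; their mean
duration (~305 ms) and the mean per-cell temporal fraction (~8.7%) recover
the preset's generative inputs (trap dwell 171 ms above the 166.7 ms
threshold residency; occupancy calibrated for a detected fraction near 8%),
and zone size is uncorrelated with duration (ρ ≈ 0) because the generator
draws them independently. The same objects work on real tracker output via
`sm.read_tracks("tracks.csv", dt=1/30)`.

A diffusion summary for the same data:

```python
print(sm.DiffusionModel(tracks).fit().summary())
```

```
Diffusion analysis (D_200ms, 3-lag MSD fit)
----------------------------------------------
condition            KRAS WT-like, 2 min after EGF stimulation (trapping peak)
trajectories         393
median D_200ms       0.4008 um^2/s
immobile threshold   0.0090 um^2/s
immobile fraction    0.25 %
```

(The median sits below the preset's free-state D = 0.45 μm²/s because
trapped episodes slow the 200-ms-scale displacement — the same shift the
imaging experiments detect on activation.)

There is also a CLI for shell pipelines:

```sh
smtrap simulate --preset wt_post2 --seed 42 --out tracks.csv
smtrap analyze trap tracks.csv --radius-nm 50 --min-frames 5 \
       --sigma-nm 14.0 --out events.csv --cell-out cells.csv
smtrap report tracks.csv
```

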