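# eprsim

A headless, deterministic-seedable 3D particle simulator of fluorophore
biodistribution for fluorescence-guided surgery (FGS), together with the
tumor-to-background ratio (TBR) arithmetic used to quantify longitudinal
in-vivo imaging series.

## The problem

Intraoperative fluorescence imaging only works if, at the moment of
surgery, the tumor is brighter than the surrounding tissue. Whether that
happens depends on the interplay of uptake and clearance kinetics in the
tumor region of interest (ROI) and the normal-tissue background (the
imaging field of view, FOV), on the enhanced permeability and retention
(EPR) effect that preferentially accumulates macromolecular agents in
tumors, and on whether the probe is *always-on* (emitting everywhere, so
contrast requires background clearance) or *bio-responsive* (off in
circulation, switching on irreversibly after tumor uptake).

`eprsim` models this with non-interacting particles in a box chamber:

* particles are released at an injection site in batches of 100 every
  5 frames, each with a random direction into the chamber, and advance
  along rectilinear trajectories one velocity vector per frame;
* chamber walls reflect; the ROI sphere reflects from the inside (the
  tumor retains) and is freely entered from the outside;
* an optional EPR shell around the ROI slows particles (speed multiplier
  `1 − viscosity`: 0.1× in the shell vs 0.845× in the ROI and 1× in the
  FOV, with default viscosities 0.9 and 0.155), bends their trajectories
  toward the tumor, and returns particles that strike its boundary from
  inside to the FOV with probability 0.5, otherwise reflecting them back;
* per-compartment clearance removes randomly selected particles to a
  clearance site every 20 frames (FOV) / 40 frames (ROI), after
  configurable initial delays — a minimal model of excretion and
  metabolism;
* every 30 frames the percentage of administered fluorophore in the FOV,
  in the ROI, and cleared is recorded.

The TBR module works on summarized total radiant efficiency (TRE) values:
`TBR(t) = tumor TRE / mean of three equal-area background TREs`, with
threshold-2 crossing times, above-threshold intervals, and fold-change
retention ratios, plus a closed-form synthetic time-course generator so
the arithmetic is testable without animal data.

## Worked example

Six presets (`sim1` … `sim6`) span the canonical scenarios: fast vs slow
clearance, always-on vs responsive emission, EPR off vs on. Compare the
moderate-clearance always-on scenario with and without the EPR zone:

```sh
$ eprsim run --preset sim2
peak_roi_pct=27.75
peak_roi_frame=990
crossover_frame=960
contrast_window=(1320, 3330)
detect_onset_frame=None

$ eprsim run --preset sim5 --out-csv sim5.csv
peak_roi_pct=62.35
peak_roi_frame=750
crossover_frame=450
contrast_window=(840, 5730)
detect_onset_frame=None
```

`sim5` differs from `sim2` only in having the EPR zone enabled. Enabling
it raises peak tumor uptake from 27.8% to 62.4% of the administered dose,
moves the FOV/ROI crossover earlier (frame 450 vs 960), and more than
doubles the contrast window — the interval during which the background
has fully cleared while fluorophore remains in the tumor. Responsive-mode
presets (`sim3`, `sim4`, `sim6`) share trajectories bit-for-bit with
their always-on twins and additionally report `detect_onset_frame`, the
first sample with a switched-on particle in the tumor.

The TBR pipeline on a synthetic noise-free time course:

```sh
$ eprsim synth-tbr --out-csv records.csv --noise-cv 0 --seed 1
$ eprsim tbr --in-csv records.csv
first_time_above_threshold=24.0
intervals_above_threshold=[(24.0, 168.0)]
```

The generated tumor and background curves are dark for the first hour
(off-to-on switching), rise to a peak near 12 h, and the background
clears faster than the tumor, so the TBR crosses the clinically relevant
threshold of 2 at the 24 h acquisition and stays above it to the end of
the week-long series.

Python API:

```python
import dataclasses
from eprsim import preset, run

cfg = dataclasses.replace(preset("sim6"), seed=3)
result = run(cfg)
print(result.summary.peak_roi_pct, result.summary.detect_onset_frame)
```

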