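# Methods

## Model

`eprsim` is an agent-based kinetic model of contrast-agent
biodistribution, deliberately qualitative: it illustrates how uptake,
clearance, the EPR effect and off-to-on emission interact to produce (or
fail to produce) imaging contrast. It does not model blood flow, photon
transport, or physical units — coordinates are dimensionless
chamber-lengths and the frame is the time unit.

The scene is an axis-aligned box (half-extents `(1, 0.6, 0.6)` by
default) with two concentric spheres at the origin: the tumor ROI
(radius 0.15) and the EPR sphere (radius 0.30) whose shell is the zone
of leaky vasculature. The injection site sits at the centre of the
`x = −1` wall; the clearance site is a parking point outside the chamber
where removed particles become inert. All of this is configurable; the
defaults were chosen so the spheres sit well inside the chamber and the
injection point is distant from the tumor.

### Particle lifecycle

Each particle is `reservoir → active → cleared`, with two monotone
flags: `entered_epr` and `entered_roi` (the latter also switches
emission on, irreversibly, in responsive mode). Batches of
`batch_size = 100` activate every `release_cadence = 5` frames with
directions drawn uniformly on the hemisphere facing the chamber
interior (the exact release distribution is a modelling choice; uniform
hemisphere is the least-informative option for a point source on a
wall).

### Motion and collisions

Per frame each active particle moves `base_speed × (1 − viscosity)`
along its direction, where the viscosity is 0 in the FOV, 0.9 in the
EPR shell and 0.155 in the ROI, giving the speed multipliers 1, 0.1 and
0.845. Crossings within a step are resolved continuously (parametric
`t` along the segment, earliest surface first), with per-surface
policies: walls and the ROI boundary seen from inside reflect
specularly; the ROI boundary crossed from outside is transparent and
sets tumor uptake; the EPR boundary struck from inside flips a coin
(escape probability 0.5 → pass into the FOV, else reflect); the EPR
boundary crossed from outside is transparent. After a pass-through the
remainder of the step is rescaled by the ratio of the new and old
region multipliers. Grazing contacts with `t` within 1e−9 of the end of
the step are deferred to the next frame so no contact is processed
twice; candidate hits with `t < 1e−9` are ignored so a particle sitting
on a surface it just interacted with is not re-collided. The region
label is carried in state and updated by crossing events rather than
re-derived from positions, which keeps particles that end a frame
exactly on a sphere in their correct compartment.

Inside the EPR shell, a gravity-like attraction rotates the direction
vector toward the tumor centre by at most `attraction_strength = 0.2`
rad/frame. It is a pure rotation — speeds stay exactly
`base_speed × multiplier` — so the printed multipliers remain exact
invariants. The strength of the attraction is not quantified by the
scenario definitions; 0.2 rad/frame was chosen as a clearly dominant
but not instantaneous bias (full alignment within ~8 frames for a
worst-case heading), and together with the 0.5 escape rule it makes the
majority of shell entrants reach the ROI, which is the qualitative
behaviour the zone exists to produce.

### Clearance

Compartment clearance is an event schedule, not a continuous rate:
after `delay` frames, every `cadence` frames (20 for FOV, 40 for ROI)
up to `rate` particles are selected uniformly at random from the
compartment pool and parked at the clearance site. The first event
fires at `frame = delay` exactly, then on an arithmetic progression.
`rate` is interpreted as particles removed per event; the preset values
(50/25/10) are relative arbitrary units under this interpretation.
EPR-shell particles belong to the FOV pool for clearance, and by
default also to the FOV trace of the chart
(`count_epr_as_fov_in_series = True`; switching it off charts the shell
with the tumor signal instead — the normalization identity is preserved
either way).

### Randomness and determinism

One seeded `numpy` generator drives everything, consumed in a fixed
order per frame: release directions, escape coin flips in collision
order, FOV clearance selection, ROI clearance selection. Runs are
bit-reproducible given the config. Emission never consumes randomness,
which is why always-on and responsive twins share trajectories exactly.

## Sampling and summary metrics

The chart samples at frame 0 and every `sample_cadence = 30` frames
thereafter, so `F` frames yield `⌊F/30⌋ + 1` samples. Percentages are
of the administered total (not of particles currently present), so both
the FOV and ROI curves decay to zero as clearance completes; the
implicit reservoir share closes the identity
`%FOV + %ROI + %cleared + %reservoir = 100`.

Summary definitions, evaluated at sample resolution:

* **peak** — maximum `%ROI`, earliest frame on ties;
* **crossover** — first sample with `%ROI ≥ %FOV`, except that samples
  with both traces at zero (before release, or after complete
  clearance) never count: a crossover of two empty compartments says
  nothing about contrast;
* **contrast window** — the first maximal run of samples with
  `%FOV = 0` and `%ROI > 0`;
* **detection onset** — responsive runs only: first sample with at
  least one switched-on particle in the ROI.

## Engine defaults and problem sizes

`n_particles = 2000`, `base_speed = 0.02` chamber-lengths/frame and
`max_frames = 6000` were chosen together so that a run traverses all
three phases — release (complete by frame 100), uptake, and clearance
to empty — with the preset delay/rate schedules. The engine is
vectorized over particles (struct-of-arrays state, batched crossing
solver), so a full 2000 × 6000 run takes a few seconds on one core; the
unit-test suite uses a few hundred particles and frames, and the
end-to-end suite runs the presets at full scale, with ten paired seeds
for the EPR-on/EPR-off comparison.

## TBR analysis

`TBR = tumor TRE / mean(three background TREs)`; threshold crossings
and above-threshold intervals are computed at the acquired time points
with no interpolation, since imaging happens at discrete acquisitions;
a fold-change ratio requires both of its time points to be present in
the series for the same reason. When tumor and all backgrounds are
exactly zero (a dark off-state probe before onset), the TBR series
records 0 — no signal anywhere is no contrast — while a zero background
against a nonzero tumor raises, because that ratio is genuinely
undefined.

The synthetic generator exists to exercise this arithmetic. Tumor and
background follow
`A · (1 − e^(−k_up·τ)) · e^(−k_cl·τ)` with `τ = max(t − delay, 0)`:
zero through the onset delay (1 h by default, the off-state silence), a
saturating rise, and exponential clearance. Defaults `k_up = 0.3/h`,
`k_cl,tumor = 0.012/h`, `k_cl,bg = 0.04/h`, background amplitude 0.95×
tumor, amplitude `5e9` (p/sec)/(µW/cm²) put the tumor peak near 12 h and
the threshold-2 crossing at the 24 h acquisition of the default
week-long schedule, with the TBR rising monotonically over the tail
because the background clears faster. Multiplicative lognormal noise
(CV 0.1 by default, mean 1) models acquisition variability. A single
exponential clearance is a deliberate simplification — real washout is
multi-phasic, and this tail ratio grows without bound — so the
generator supports qualitative tests (silence, monotone late growth,
suffix threshold intervals), not pharmacokinetic inference.

## What the synthetic data does and does not show

The particle model and the generator reproduce the *shapes* that
matter: background-first loading, delayed tumor uptake, clearance-rate
orderings, EPR-driven uptake amplification, off-to-on contrast without
background clearance. Passing tests therefore demonstrate internal
consistency of the mechanics and arithmetic, not calibration to any
tissue: absolute times, percentages and TBR magnitudes in this package
carry no physical units and cannot be compared numerically to animal
data.

## Numerical choices and degenerate inputs

* Crossing solver: slab method for walls, quadratic roots for spheres;
  ties between surfaces at identical `t` resolve wall → ROI → EPR
  (measure-zero, affects only event order).
* Reflection uses `v − 2(v·n)n` with outward unit normals; norm
  preserved to machine precision.
* Attraction handles the antiparallel singularity by rotating within an
  arbitrary fixed plane.
* A collision-resolution pass is capped at 32 sub-steps per particle per
  frame (unreachable at default speeds); any particle found outside the
  chamber afterwards aborts the run with a diagnostic rather than
  continuing silently.
* `n_particles = 0` is valid and yields an identically zero series;
  empty series are rejected by `summarize` and `threshold_crossings`.
* Config JSON is strict: full field set required (including `seed`),
  unknown keys rejected, canonical serialization (sorted keys) makes
  save → load → save byte-identical.

## Known limitations

Rectilinear motion is not blood flow; there is no vascular tree,
perfusion gradient, binding kinetics, or photon attenuation. Clearance
selects particles uniformly, ignoring position within the compartment.
The EPR shell is a sharp sphere rather than a perfusion-limited
gradient. Injection and clearance are point sites, not tube volumes.
These are all faithful to the model's role as a visual, mechanistic
illustration rather than a predictive pharmacokinetic tool.
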