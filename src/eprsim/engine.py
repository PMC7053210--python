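"""Frame-stepped particle kinetics for contrast-agent biodistribution.

The model: ``n_particles`` fluorophore particles start in a reservoir at the
injection site and are activated in batches of ``batch_size`` every
``release_cadence`` frames, each with an independent random direction into
the chamber interior.  Active particles move along rectilinear trajectories,
one velocity-vector step per frame; they never interact with each other.
Region-dependent viscosity rescales speed (multiplier ``1 - viscosity``):
particles in the EPR shell travel at 0.1x the FOV speed and particles in
the tumor ROI at 0.845x under the default viscosities of 0.9 and 0.155.

Collision rules per frame, resolved continuously along the step segment:

* chamber wall — specular reflection;
* ROI sphere hit from inside — specular reflection (the tumor retains);
* ROI sphere crossed from outside — pass through; the particle has entered
  the tumor (in responsive mode its emission switches on, irreversibly);
* EPR sphere hit from inside (zone enabled) — a fair-by-default coin:
  escape back into the FOV with probability ``epr_escape_prob`` (0.5),
  otherwise specular reflection back into the shell;
* EPR sphere crossed from outside — pass through into the zone.

Inside the EPR shell a gravity-like attraction turns each particle's
direction toward the tumor centre by at most ``attraction_strength`` radians
per frame; it rotates the direction and never rescales speed.

Clearance models excretion/metabolism: after a per-compartment initial
delay, every ``fov_clear_cadence`` (resp. ``roi_clear_cadence``) frames up
to ``fov_rate`` (``roi_rate``) particles are selected uniformly at random
from the compartment pool and parked, inert, at the clearance site.  For
clearance purposes EPR-shell particles count as FOV.

A single seeded generator drives all randomness, consumed in a fixed order
per frame: release directions, then escape coin flips in collision order,
then FOV clearance selection, then ROI clearance selection.  Two runs with
the same config are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Iterator

import numpy as np

from .geometry import (
    Geometry,
    Region,
    REGION_EPR,
    REGION_FOV,
    REGION_ROI,
    SURF_EPR,
    SURF_ROI,
    first_crossings,
)

__all__ = [
    "SimulationConfig",
    "SimulationState",
    "EventLog",
    "RunResult",
    "ConfigError",
    "EngineInvariantError",
    "speed_multiplier",
    "release_step",
    "motion_step",
    "clearance_step",
    "advance_frame",
    "run",
    "new_state",
    "estimate_epr_escape_fraction",
]

# particle lifecycle status codes
STATUS_RESERVOIR, STATUS_ACTIVE, STATUS_CLEARED = 0, 1, 2

MODES = ("always_on", "responsive")

# cap on collision sub-steps per frame; with default speeds a particle meets
# at most a couple of surfaces per frame, so this is never reached in practice
_MAX_COLLISION_ITERS = 32


class ConfigError(ValueError):
    """Invalid simulation configuration; the message names the field."""


class EngineInvariantError(RuntimeError):
    """A particle escaped the chamber: collision handling failed."""


@dataclass(frozen=True)
class SimulationConfig:
    """Every tunable of the engine.

    Defaults are the moderate-clearance study condition (background delay
    250 frames / 25 particles per event, tumor delay 750 / 10) with the EPR
    zone off and an always-on fluorophore; the shipped presets override
    only the fields their scenario changes.
    """

    n_particles: int = 2000
    batch_size: int = 100
    release_cadence: int = 5
    base_speed: float = 0.02
    epr_enabled: bool = False
    mode: str = "always_on"
    viscosity_epr: float = 0.9
    viscosity_roi: float = 0.155
    epr_escape_prob: float = 0.5
    attraction_strength: float = 0.2
    fov_delay: int = 250
    fov_rate: int = 25
    roi_delay: int = 750
    roi_rate: int = 10
    fov_clear_cadence: int = 20
    roi_clear_cadence: int = 40
    sample_cadence: int = 30
    max_frames: int = 6000
    seed: int = 0
    #: whether EPR-shell particles count toward the FOV trace of the
    #: sampled distribution series (they always do for clearance)
    count_epr_as_fov_in_series: bool = True
    geometry: Geometry = field(default_factory=Geometry)

    def validate(self) -> "SimulationConfig":
        def _require(cond: bool, name: str, why: str):
            if not cond:
                raise ConfigError(f"{name}: {why}")

        _require(self.n_particles >= 0, "n_particles", "must be >= 0")
        _require(self.batch_size >= 1, "batch_size", "must be >= 1")
        _require(self.release_cadence >= 1, "release_cadence", "must be >= 1")
        _require(self.base_speed > 0, "base_speed", "must be > 0")
        _require(self.mode in MODES, "mode", f"must be one of {MODES}")
        _require(0 <= self.viscosity_epr < 1, "viscosity_epr", "must be in [0, 1)")
        _require(0 <= self.viscosity_roi < 1, "viscosity_roi", "must be in [0, 1)")
        _require(0 <= self.epr_escape_prob <= 1, "epr_escape_prob", "must be in [0, 1]")
        _require(self.attraction_strength >= 0, "attraction_strength", "must be >= 0")
        for name in ("fov_delay", "roi_delay"):
            _require(getattr(self, name) >= 0, name, "must be >= 0")
        for name in ("fov_rate", "roi_rate"):
            _require(getattr(self, name) >= 0, name, "must be >= 0")
        for name in ("fov_clear_cadence", "roi_clear_cadence", "sample_cadence"):
            _require(getattr(self, name) >= 1, name, "must be >= 1")
        _require(self.max_frames >= 0, "max_frames", "must be >= 0")
        _require(isinstance(self.seed, (int, np.integer)), "seed", "must be an integer")
        _require(isinstance(self.geometry, Geometry), "geometry", "must be a Geometry")
        return self

    def speed_in(self, region_code: int) -> float:
        return self.base_speed * _multipliers(self)[region_code]


def _multipliers(config: SimulationConfig) -> np.ndarray:
    return np.array([1.0, 1.0 - config.viscosity_epr, 1.0 - config.viscosity_roi])


def speed_multiplier(region: Region | int, config: SimulationConfig) -> float:
    """Speed scale for a region: 1 in the FOV, ``1 - viscosity`` elsewhere."""
    code = region.value if isinstance(region, Region) else region
    lookup = {Region.FOV.value: 0, Region.EPR.value: 1, Region.ROI.value: 2}
    idx = lookup[code] if isinstance(code, str) else int(code)
    return float(_multipliers(config)[idx])


@dataclass
class EventLog:
    """Timestamped record of discrete engine events, for audit and tests."""

    releases: list = field(default_factory=list)  # (frame, n_activated)
    clearances: list = field(default_factory=list)  # (frame, "fov"|"roi", n_removed)
    sample_frames: list = field(default_factory=list)
    epr_boundary_hits: int = 0  # inside-surface collisions with the EPR sphere
    epr_escapes: int = 0  # of those, Bernoulli escapes back into the FOV


@dataclass
class SimulationState:
    """Mutable per-frame state of one simulation (struct of arrays)."""

    frame: int
    positions: np.ndarray  # (N, 3)
    directions: np.ndarray  # (N, 3) unit vectors (undefined while in reservoir)
    status: np.ndarray  # (N,) int8 lifecycle codes
    region: np.ndarray  # (N,) int8 region codes (valid for active particles)
    entered_roi: np.ndarray  # (N,) bool, monotone
    entered_epr: np.ndarray  # (N,) bool, monotone
    rng: np.random.Generator
    log: EventLog = field(default_factory=EventLog)

    @property
    def counts(self) -> tuple[int, int, int]:
        """(n_reservoir, n_active, n_cleared)."""
        return (
            int(np.sum(self.status == STATUS_RESERVOIR)),
            int(np.sum(self.status == STATUS_ACTIVE)),
            int(np.sum(self.status == STATUS_CLEARED)),
        )

    def emitting_mask(self, mode: str) -> np.ndarray:
        """Which particles currently fluoresce.

        Always-on probes emit whenever active; responsive (off-to-on)
        probes emit only after tumor uptake has switched them on.
        """
        active = self.status == STATUS_ACTIVE
        if mode == "responsive":
            return active & self.entered_roi
        return active


def new_state(config: SimulationConfig) -> SimulationState:
    """Fresh state: all particles in the reservoir at the injection site."""
    n = config.n_particles
    inj = np.asarray(config.geometry.injection_site, dtype=float)
    return SimulationState(
        frame=0,
        positions=np.tile(inj, (n, 1)),
        directions=np.tile(np.array([1.0, 0.0, 0.0]), (n, 1)),
        status=np.full(n, STATUS_RESERVOIR, dtype=np.int8),
        region=np.full(n, REGION_FOV, dtype=np.int8),
        entered_roi=np.zeros(n, dtype=bool),
        entered_epr=np.zeros(n, dtype=bool),
        rng=np.random.default_rng(config.seed),
    )


# ---------------------------------------------------------------------------
# release


def _interior_directions(k: int, geometry: Geometry, rng: np.random.Generator) -> np.ndarray:
    """k unit vectors uniform on the hemisphere facing the chamber interior."""
    d = rng.standard_normal((k, 3))
    norms = np.linalg.norm(d, axis=1, keepdims=True)
    norms[norms < 1e-12] = 1.0
    d /= norms
    hemi = geometry.inward_release_axis()
    if hemi is not None:
        axis, sign = hemi
        d[:, axis] = sign * np.abs(d[:, axis])
    return d


def release_step(state: SimulationState, config: SimulationConfig) -> SimulationState:
    """Activate the next batch when the frame is on the release cadence."""
    if state.frame % config.release_cadence != 0:
        return state
    reservoir = np.flatnonzero(state.status == STATUS_RESERVOIR)
    if reservoir.size == 0:
        return state
    k = min(config.batch_size, reservoir.size)
    idx = reservoir[:k]
    state.status[idx] = STATUS_ACTIVE
    state.positions[idx] = np.asarray(config.geometry.injection_site)
    state.directions[idx] = _interior_directions(k, config.geometry, state.rng)
    state.region[idx] = REGION_FOV
    state.log.releases.append((state.frame, k))
    return state


# ---------------------------------------------------------------------------
# motion


def _attract_toward_center(
    dirs: np.ndarray, pos: np.ndarray, center: np.ndarray, max_angle: float
) -> np.ndarray:
    """Rotate unit directions toward ``center`` by at most ``max_angle`` rad.

    Pure rotation: the returned vectors are unit length.  Particles exactly
    at the centre, or already aligned, are left unchanged; antiparallel
    directions rotate within an arbitrary fixed plane.
    """
    to_c = center - pos
    dist = np.linalg.norm(to_c, axis=1)
    ok = dist > 1e-12
    u = np.zeros_like(to_c)
    u[ok] = to_c[ok] / dist[ok, None]
    cosang = np.clip(np.einsum("ij,ij->i", dirs, u), -1.0, 1.0)
    ang = np.arccos(cosang)
    out = dirs.copy()

    snap = ok & (ang <= max_angle)
    out[snap] = u[snap]

    rot = ok & (ang > max_angle)
    if rot.any():
        d = dirs[rot]
        uu = u[rot]
        # perpendicular component of the target direction within the
        # rotation plane; degenerate only when antiparallel
        perp = uu - cosang[rot, None] * d
        pn = np.linalg.norm(perp, axis=1)
        bad = pn < 1e-12
        if bad.any():
            alt = np.cross(d[bad], np.array([1.0, 0.0, 0.0]))
            alt_n = np.linalg.norm(alt, axis=1)
            fix = alt_n < 1e-12
            if fix.any():
                alt[fix] = np.cross(d[bad][fix], np.array([0.0, 1.0, 0.0]))
                alt_n[fix] = np.linalg.norm(alt[fix], axis=1)
            perp[bad] = alt / alt_n[:, None]
            pn[bad] = 1.0
        perp /= pn[:, None]
        out[rot] = d * np.cos(max_angle) + perp * np.sin(max_angle)
        out[rot] /= np.linalg.norm(out[rot], axis=1, keepdims=True)
    return out


def motion_step(state: SimulationState, config: SimulationConfig) -> SimulationState:
    """Advance every active particle one frame, resolving all crossings."""
    act = np.flatnonzero(state.status == STATUS_ACTIVE)
    if act.size == 0:
        return state
    geom = config.geometry
    center = geom._c
    mults = _multipliers(config)

    pos = state.positions[act].copy()
    dirs = state.directions[act].copy()
    # state.region is authoritative: it is set at release and updated by
    # every crossing event, which keeps particles sitting exactly on a
    # sphere after a reflection in their correct compartment
    region = state.region[act].copy()

    if config.epr_enabled and config.attraction_strength > 0:
        in_epr = region == REGION_EPR
        if in_epr.any():
            dirs[in_epr] = _attract_toward_center(
                dirs[in_epr], pos[in_epr], center, config.attraction_strength
            )

    remaining = dirs * (config.base_speed * mults[region])[:, None]

    pending = np.arange(act.size)
    for _ in range(_MAX_COLLISION_ITERS):
        if pending.size == 0:
            break
        batch = first_crossings(pos[pending], remaining[pending], geom, config.epr_enabled)

        done = pending[~batch.has_hit]
        pos[done] += remaining[done]
        remaining[done] = 0.0

        hit = batch.has_hit
        if not hit.any():
            pending = pending[:0]
            break
        idx = pending[hit]
        t = batch.t[hit]
        surf = batch.surface[hit]
        normal = batch.normal[hit]
        entering = batch.entering[hit]
        pos[idx] = batch.point[hit]
        leftover = (1.0 - t)[:, None] * remaining[idx]

        reflect = np.zeros(idx.size, dtype=bool)
        new_region = region[idx].copy()

        wall = surf < SURF_ROI
        reflect |= wall

        roi = surf == SURF_ROI
        roi_enter = roi & entering
        roi_exit = roi & ~entering
        reflect |= roi_exit
        new_region[roi_enter] = REGION_ROI
        state.entered_roi[act[idx[roi_enter]]] = True

        epr = surf == SURF_EPR
        epr_enter = epr & entering
        epr_exit = epr & ~entering
        new_region[epr_enter] = REGION_EPR
        state.entered_epr[act[idx[epr_enter]]] = True
        if epr_exit.any():
            n_exit = int(epr_exit.sum())
            coins = state.rng.random(n_exit) < config.epr_escape_prob
            state.log.epr_boundary_hits += n_exit
            state.log.epr_escapes += int(coins.sum())
            escape_idx = np.flatnonzero(epr_exit)
            new_region[escape_idx[coins]] = REGION_FOV
            reflect_back = np.zeros(idx.size, dtype=bool)
            reflect_back[escape_idx[~coins]] = True
            reflect |= reflect_back

        if reflect.any():
            n_r = normal[reflect]
            dots = np.einsum("ij,ij->i", leftover[reflect], n_r)
            leftover[reflect] -= 2.0 * dots[:, None] * n_r
            ddots = np.einsum("ij,ij->i", dirs[idx[reflect]], n_r)
            dirs[idx[reflect]] -= 2.0 * ddots[:, None] * n_r

        changed = new_region != region[idx]
        if changed.any():
            scale = mults[new_region[changed]] / mults[region[idx[changed]]]
            leftover[changed] *= scale[:, None]
            region[idx[changed]] = new_region[changed]

        remaining[idx] = leftover
        pending = idx

    if not geom.contains(pos).all():
        bad = np.flatnonzero(~geom.contains(pos))
        raise EngineInvariantError(
            f"frame {state.frame}: {bad.size} particle(s) left the chamber, e.g. {pos[bad[0]]}"
        )

    state.positions[act] = pos
    state.directions[act] = dirs
    state.region[act] = region
    return state


# ---------------------------------------------------------------------------
# clearance


def _clearance_due(frame: int, delay: int, cadence: int) -> bool:
    return frame >= delay and (frame - delay) % cadence == 0


def _clear_pool(state: SimulationState, pool: np.ndarray, rate: int, site: np.ndarray,
                label: str) -> None:
    k = min(rate, pool.size)
    if k <= 0:
        return
    chosen = state.rng.choice(pool, size=k, replace=False)
    state.status[chosen] = STATUS_CLEARED
    state.positions[chosen] = site
    state.log.clearances.append((state.frame, label, int(k)))


def clearance_step(state: SimulationState, config: SimulationConfig) -> SimulationState:
    """Scheduled removal of random particles from each compartment.

    No event fires before the compartment's delay; thereafter events fall
    exactly on ``delay, delay + cadence, delay + 2*cadence, ...``.  The FOV
    pool includes EPR-shell particles.
    """
    site = np.asarray(config.geometry.clearance_site)
    active = state.status == STATUS_ACTIVE
    if _clearance_due(state.frame, config.fov_delay, config.fov_clear_cadence):
        pool = np.flatnonzero(active & (state.region != REGION_ROI))
        _clear_pool(state, pool, config.fov_rate, site, "fov")
    if _clearance_due(state.frame, config.roi_delay, config.roi_clear_cadence):
        active = state.status == STATUS_ACTIVE  # FOV event may have fired
        pool = np.flatnonzero(active & (state.region == REGION_ROI))
        _clear_pool(state, pool, config.roi_rate, site, "roi")
    return state


# ---------------------------------------------------------------------------
# frame composition and runs


def advance_frame(state: SimulationState, config: SimulationConfig) -> SimulationState:
    """One frame: release, motion, clearance, then the frame counter ticks."""
    release_step(state, config)
    motion_step(state, config)
    clearance_step(state, config)
    state.frame += 1
    return state


@dataclass
class RunResult:
    """Sampled distribution series, its summary, and the final engine state."""

    series: "DistributionSeries"
    summary: "SummaryMetrics"
    final_state: SimulationState

    def __iter__(self) -> Iterator:
        return iter((self.series, self.summary))


def run(config: SimulationConfig) -> RunResult:
    """Execute ``max_frames`` frames and return the sampled series + summary.

    Deterministic given ``config.seed``: identical configs give
    bit-identical trajectories, event logs and series.
    """
    from .metrics import DistributionSeries, make_sample, summarize

    config.validate()
    state = new_state(config)
    samples = [make_sample(state, config)]
    state.log.sample_frames.append(0)
    for _ in range(config.max_frames):
        advance_frame(state, config)
        if state.frame % config.sample_cadence == 0:
            samples.append(make_sample(state, config))
            state.log.sample_frames.append(state.frame)
    series = DistributionSeries(samples=samples, mode=config.mode,
                                n_particles=config.n_particles)
    return RunResult(series=series, summary=summarize(series), final_state=state)


# ---------------------------------------------------------------------------
# instrumented escape-probability measurement


def estimate_epr_escape_fraction(
    n_events: int = 10_000,
    seed: int = 0,
    config: SimulationConfig | None = None,
) -> tuple[float, int]:
    """Empirical escape fraction over forced EPR inside-surface collisions.

    Confines particles to the EPR shell with attraction disabled and drives
    them radially outward so every few frames each one strikes the EPR
    boundary from inside, exercising the engine's Bernoulli escape path.
    Particles are re-armed (teleported back to mid-shell, aimed outward)
    after every frame so collisions accumulate until at least ``n_events``
    have been counted.  Returns ``(escape_fraction, n_events_observed)``.
    """
    if config is None:
        config = SimulationConfig()
    geom = config.geometry
    # outward step 1.5x the mid-shell -> boundary distance, so every
    # re-armed particle strikes the EPR sphere from inside each frame
    shell_mid = 0.5 * (geom.roi_radius + geom.epr_radius)
    cfg = replace(
        config,
        n_particles=512,
        epr_enabled=True,
        attraction_strength=0.0,
        base_speed=1.5 * (geom.epr_radius - shell_mid) / (1.0 - config.viscosity_epr),
        seed=seed,
    )
    cfg.validate()
    state = new_state(cfg)
    n = cfg.n_particles
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x5EED)).generate_state(1)[0])
    radial = rng.standard_normal((n, 3))
    radial /= np.linalg.norm(radial, axis=1, keepdims=True)
    center = geom._c

    def _rearm():
        state.status[:] = STATUS_ACTIVE
        state.positions[:] = center + shell_mid * radial
        state.directions[:] = radial
        state.region[:] = REGION_EPR

    while state.log.epr_boundary_hits < n_events:
        _rearm()
        motion_step(state, cfg)
        state.frame += 1
    hits = state.log.epr_boundary_hits
    return state.log.epr_escapes / hits, hits
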