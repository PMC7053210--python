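"""Engine kinetics: release, motion, clearance, and whole-run invariants."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from eprsim.engine import (
    STATUS_ACTIVE,
    STATUS_CLEARED,
    STATUS_RESERVOIR,
    ConfigError,
    SimulationConfig,
    advance_frame,
    clearance_step,
    estimate_epr_escape_fraction,
    motion_step,
    new_state,
    release_step,
    run,
    speed_multiplier,
)
from eprsim.geometry import REGION_EPR, REGION_FOV, REGION_ROI, Region

from conftest import make_config, place_particles


class TestSpeedMultiplier:
    @pytest.mark.parametrize(
        "region, expected",
        [(Region.FOV, 1.0), (Region.EPR, 0.1), (Region.ROI, 0.845)],
    )
    def test_default_viscosities(self, region, expected):
        cfg = SimulationConfig()
        assert speed_multiplier(region, cfg) == pytest.approx(expected, abs=1e-12)

    def test_custom_viscosity(self):
        cfg = make_config(viscosity_epr=0.5)
        assert speed_multiplier(Region.EPR, cfg) == pytest.approx(0.5)


class TestRelease:
    def test_first_frame_releases_one_batch(self):
        cfg = make_config(n_particles=2000)
        state = new_state(cfg)
        release_step(state, cfg)
        assert state.counts == (1900, 100, 0)
        assert state.log.releases == [(0, 100)]

    def test_off_cadence_frame_releases_nothing(self):
        cfg = make_config(n_particles=2000)
        state = new_state(cfg)
        state.frame = 3
        release_step(state, cfg)
        assert state.counts == (2000, 0, 0)

    def test_reservoir_smaller_than_batch_drains_fully(self):
        cfg = make_config(n_particles=40)
        state = new_state(cfg)
        state.frame = 5
        release_step(state, cfg)
        assert state.counts == (0, 40, 0)

    def test_release_directions_point_into_interior(self):
        # injection on the x = -1 wall: every released direction has x >= 0
        cfg = make_config(n_particles=500, batch_size=500)
        state = new_state(cfg)
        release_step(state, cfg)
        dirs = state.directions[state.status == STATUS_ACTIVE]
        assert np.all(dirs[:, 0] >= 0)
        np.testing.assert_allclose(np.linalg.norm(dirs, axis=1), 1.0, atol=1e-12)


class TestMotion:
    def test_free_flight_advances_by_velocity(self, placed):
        cfg = make_config(n_particles=1, base_speed=0.01)
        state = placed(cfg, [[0.5, 0.3, 0.0]], [[1.0, 0.0, 0.0]])
        motion_step(state, cfg)
        np.testing.assert_allclose(state.positions[0], [0.51, 0.3, 0.0], atol=1e-12)

    def test_speed_scaling_per_region(self, placed):
        """Displacement norms: base_speed in the FOV, 0.1x in the EPR shell,
        0.845x in the ROI, exact to 1e-9 relative (attraction off)."""
        cfg = make_config(n_particles=3, epr_enabled=True, attraction_strength=0.0,
                          base_speed=0.002)
        pos = [[0.6, 0.0, 0.0], [0.22, 0.0, 0.0], [0.0, 0.0, 0.0]]
        dirs = [[0.0, 1.0, 0.0]] * 3
        state = placed(cfg, pos, dirs)
        before = state.positions.copy()
        motion_step(state, cfg)
        norms = np.linalg.norm(state.positions - before, axis=1)
        np.testing.assert_allclose(norms, [0.002, 0.0002, 0.00169], rtol=1e-9)

    def test_wall_reflection_preserves_speed(self, placed):
        cfg = make_config(n_particles=1, base_speed=0.05)
        state = placed(cfg, [[0.98, 0.0, 0.0]], [[1.0, 0.0, 0.0]])
        motion_step(state, cfg)
        # 0.02 out to the wall, 0.03 back
        np.testing.assert_allclose(state.positions[0], [0.97, 0.0, 0.0], atol=1e-12)
        np.testing.assert_allclose(state.directions[0], [-1.0, 0.0, 0.0], atol=1e-12)

    def test_roi_boundary_reflects_from_inside(self, placed):
        cfg = make_config(n_particles=1, base_speed=0.02)
        state = placed(cfg, [[0.14, 0.0, 0.0]], [[1.0, 0.0, 0.0]])
        assert state.region[0] == REGION_ROI
        motion_step(state, cfg)
        assert state.region[0] == REGION_ROI
        assert np.linalg.norm(state.positions[0]) < cfg.geometry.roi_radius + 1e-12
        np.testing.assert_allclose(state.directions[0], [-1.0, 0.0, 0.0], atol=1e-12)

    def test_roi_entry_sets_uptake_flag(self, placed):
        cfg = make_config(n_particles=1, base_speed=0.02, mode="responsive")
        state = placed(cfg, [[0.16, 0.0, 0.0]], [[-1.0, 0.0, 0.0]])
        assert not state.entered_roi[0]
        motion_step(state, cfg)
        assert state.entered_roi[0]
        assert state.region[0] == REGION_ROI
        assert state.emitting_mask("responsive")[0]

    def test_epr_escape_fraction_matches_binomial(self):
        """Forced inside-surface collisions escape at the configured 50%
        rate, within 3 binomial standard errors."""
        frac, n = estimate_epr_escape_fraction(4000, seed=11)
        assert n >= 4000
        se = np.sqrt(0.25 / n)
        assert abs(frac - 0.5) <= 3 * se

    def test_epr_escape_prob_zero_always_reflects(self):
        cfg = make_config(epr_escape_prob=0.0)
        frac, n = estimate_epr_escape_fraction(1000, seed=3, config=cfg)
        assert frac == 0.0


class TestClearance:
    def _active_state(self, cfg, n_in_roi=0):
        rng = np.random.default_rng(0)
        n = cfg.n_particles
        pos = np.empty((n, 3))
        pos[:] = [0.7, 0.2, 0.1]
        pos[:n_in_roi] = np.asarray(cfg.geometry.roi_center) + [0.05, 0.0, 0.0]
        dirs = rng.standard_normal((n, 3))
        return place_particles(cfg, pos, dirs)

    def test_no_event_before_delay(self):
        cfg = make_config(fov_delay=250, fov_rate=50)
        state = self._active_state(cfg)
        state.frame = 249
        clearance_step(state, cfg)
        assert state.counts[2] == 0

    def test_events_follow_delay_plus_cadence(self):
        cfg = make_config(n_particles=2000, fov_delay=250, fov_rate=25,
                          fov_clear_cadence=20, roi_rate=0, max_frames=320)
        state = self._active_state(cfg)
        for frame in range(320):
            state.frame = frame
            clearance_step(state, cfg)
        assert state.log.clearances == [
            (250, "fov", 25), (270, "fov", 25), (290, "fov", 25), (310, "fov", 25)
        ]

    def test_roi_pool_exhaustion_clears_all(self):
        cfg = make_config(n_particles=10, roi_delay=0, roi_rate=10, fov_rate=0)
        state = self._active_state(cfg, n_in_roi=3)
        state.frame = 0
        clearance_step(state, cfg)
        assert state.log.clearances == [(0, "roi", 3)]
        assert np.sum((state.status == STATUS_ACTIVE) & (state.region == REGION_ROI)) == 0

    def test_cleared_particles_parked_at_clearance_site(self):
        cfg = make_config(n_particles=10, fov_delay=0, fov_rate=4)
        state = self._active_state(cfg)
        state.frame = 0
        clearance_step(state, cfg)
        cleared = state.status == STATUS_CLEARED
        assert cleared.sum() == 4
        np.testing.assert_allclose(
            state.positions[cleared],
            np.tile(cfg.geometry.clearance_site, (4, 1)),
        )

    def test_epr_shell_particles_cleared_with_fov_pool(self):
        cfg = make_config(n_particles=5, epr_enabled=True, fov_delay=0, fov_rate=5)
        r = 0.5 * (cfg.geometry.roi_radius + cfg.geometry.epr_radius)
        pos = np.tile([r, 0.0, 0.0], (5, 1))
        state = place_particles(cfg, pos, np.tile([0.0, 1.0, 0.0], (5, 1)))
        assert np.all(state.region == REGION_EPR)
        state.frame = 0
        clearance_step(state, cfg)
        assert state.counts[2] == 5


class TestRuns:
    def test_frame_counter_and_conservation(self, config):
        state = new_state(config)
        for k in range(1, 101):
            advance_frame(state, config)
            assert state.frame == k
            assert sum(state.counts) == config.n_particles

    def test_determinism_bitwise(self):
        cfg = make_config(seed=42, epr_enabled=True, fov_delay=100, roi_delay=150)
        a, b = run(cfg), run(cfg)
        assert a.series.to_dataframe().equals(b.series.to_dataframe())
        np.testing.assert_array_equal(a.final_state.positions, b.final_state.positions)
        np.testing.assert_array_equal(a.final_state.status, b.final_state.status)

    def test_particles_do_not_interact(self):
        """The trajectory of the first batch is unchanged by the presence of
        later batches (no clearance, so the only randomness is release)."""
        small = make_config(n_particles=100, fov_rate=0, roi_rate=0, max_frames=300)
        big = dataclasses.replace(small, n_particles=200).validate()
        ra, rb = run(small), run(big)
        np.testing.assert_array_equal(
            ra.final_state.positions[:100], rb.final_state.positions[:100]
        )

    def test_monotone_flags(self):
        cfg = make_config(epr_enabled=True, fov_delay=50, roi_delay=80, max_frames=400)
        state = new_state(cfg)
        prev_roi = state.entered_roi.copy()
        prev_cleared = state.status == STATUS_CLEARED
        for _ in range(cfg.max_frames):
            advance_frame(state, cfg)
            roi = state.entered_roi
            cleared = state.status == STATUS_CLEARED
            assert np.all(roi >= prev_roi)
            assert np.all(cleared >= prev_cleared)
            prev_roi, prev_cleared = roi.copy(), cleared.copy()

    def test_mode_equivalence_trajectories(self):
        """Always-on and responsive runs share trajectories bit-for-bit;
        only the emission flags differ."""
        base = make_config(epr_enabled=True, fov_delay=60, roi_delay=90)
        resp = dataclasses.replace(base, mode="responsive").validate()
        ra, rb = run(base), run(resp)
        np.testing.assert_array_equal(ra.final_state.positions, rb.final_state.positions)
        da, db = ra.series.to_dataframe(), rb.series.to_dataframe()
        for col in ("frame", "pct_fov", "pct_roi", "pct_cleared"):
            np.testing.assert_array_equal(da[col].to_numpy(), db[col].to_numpy())

    def test_zero_particles_gives_flat_series(self):
        cfg = make_config(n_particles=0, max_frames=90)
        res = run(cfg)
        df = res.series.to_dataframe()
        assert (df[["pct_fov", "pct_roi", "pct_cleared"]].to_numpy() == 0).all()

    def test_epr_funnel_majority_reaches_roi(self):
        """With attraction and the 50% escape rule, most particles that
        enter the EPR shell go on to enter the tumor ROI."""
        entered_epr = entered_roi_too = 0
        for seed in range(3):
            cfg = make_config(n_particles=300, epr_enabled=True, seed=seed,
                              max_frames=2000, fov_delay=2000, roi_delay=2000)
            state = run(cfg).final_state
            entered_epr += int(state.entered_epr.sum())
            entered_roi_too += int((state.entered_epr & state.entered_roi).sum())
        assert entered_epr > 100
        assert entered_roi_too > entered_epr / 2

    def test_invalid_config_rejected_before_stepping(self):
        with pytest.raises(ConfigError, match="viscosity_epr"):
            run(SimulationConfig(viscosity_epr=1.5))
        with pytest.raises(ConfigError, match="mode"):
            run(SimulationConfig(mode="blinking"))
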