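"""Stepper contracts: boundaries, overlap resolution, conservation,
determinism and parameter schedules."""

import dataclasses

import numpy as np
import pytest

from fclsim.brownian_engine import (
    ConfigError,
    ParameterSchedule,
    SimulationConfig,
    apply_schedule,
    diffusion_step,
    reflect_into_domain,
    reject_out_of_domain_association,
    run_simulation,
    step,
)
from fclsim.fixtures_io import random_initial_condition
from fclsim.model_core import DiffusionSpec
from fclsim.reaction_kinetics import RateTable


class TestReflectIntoDomain:
    @pytest.mark.parametrize(
        "x, expected",
        [
            (0.5, 0.5),  # interior unchanged
            (1.2, 0.8),  # 2L - pos at the far wall
            (-0.3, 0.3),  # mirror at zero
            (2.5, 0.5),  # two mirrors
            (0.0, 0.0),
            (1.0, 1.0),
        ],
    )
    def test_mirror_values(self, x, expected):
        L = 1.0
        out = reflect_into_domain(np.array([x, 0.5, 0.5]), L)
        assert out[0] == pytest.approx(expected * L, abs=1e-12)
        assert np.all((out >= 0) & (out <= L))

    def test_non_finite_rejected(self):
        from fclsim.brownian_engine import SimulationAbortError

        with pytest.raises(SimulationAbortError):
            reflect_into_domain(np.array([np.nan, 0, 0]), 1.0)


class TestDomainRejection:
    def test_inside_accepted_outside_rejected(self):
        L = 100.0
        assert not reject_out_of_domain_association(np.array([[50.0, 50, 50]]), L)
        assert reject_out_of_domain_association(np.array([[50.0, 50, -1.0]]), L)
        assert reject_out_of_domain_association(np.array([[101.0, 50, 50]]), L)
        # exactly on a face: accepted (closed domain)
        assert not reject_out_of_domain_association(np.array([[0.0, 100.0, 50]]), L)


class TestDiffusionStep:
    def test_zero_diffusion_is_frozen(self, rng):
        spec = DiffusionSpec.isotropic(0.0, 0.0)
        delta, rot = diffusion_step(spec, 3.0, rng)
        assert np.all(delta == 0.0)
        assert rot.magnitude() == 0.0

    def test_membrane_spec_confined(self, rng):
        spec = DiffusionSpec((5.0, 5.0, 0.0), (0.0, 0.0, 0.2))
        for _ in range(50):
            delta, rot = diffusion_step(spec, 3.0, rng)
            assert delta[2] == 0.0
            rv = rot.as_rotvec()
            assert rv[0] == 0.0 and rv[1] == 0.0

    def test_msd_matches_2Ddt(self, pure_diffusion_config):
        """Per-axis MSD of a free clathrin over many steps is 2 D dt."""
        cfg = dataclasses.replace(
            pure_diffusion_config,
            n_clathrin=1,
            box_edge=1e6,  # effectively unbounded: no reflections
            duration=3.0 * 10_000,
            frame_interval=3.0,
        )
        traj = run_simulation(cfg)
        pos = np.array([f.pos[0] for f in traj.frames])
        disp = np.diff(pos, axis=0)
        d_coeff = cfg.clathrin_diffusion.d_trans[0]
        expected = 2.0 * d_coeff * cfg.dt
        msd = np.mean(disp**2, axis=0)
        se = np.std(disp**2, axis=0) / np.sqrt(len(disp))
        assert np.all(np.abs(msd - expected) < 3.0 * se)


class TestStepInvariants:
    def test_conservation_and_bounds(self, tiny_config, rng):
        cfg = dataclasses.replace(tiny_config, debug_checks=True)
        state = random_initial_condition(cfg, rng)
        total0 = state.ap2_pool.total
        eff = apply_schedule(cfg, None, 0.0)
        for _ in range(400):
            step(state, cfg, rng, eff)  # debug_checks asserts invariants
        assert state.n_clathrin == cfg.n_clathrin
        assert state.ap2_pool.total == total0
        assert state.time == pytest.approx(400 * cfg.dt)

    def test_pure_diffusion_keeps_bond_graph(self, pure_diffusion_config, rng):
        cfg = pure_diffusion_config
        state = random_initial_condition(cfg, rng)
        before = state.leg_partner.copy()
        pos0 = state.pos.copy()
        eff = apply_schedule(cfg, None, 0.0)
        for _ in range(300):
            step(state, cfg, rng, eff)
        np.testing.assert_array_equal(state.leg_partner, before)
        assert not np.allclose(state.pos, pos0)  # but they did move

    def test_ap2_members_stay_on_membrane(self, tiny_config, rng):
        cfg = dataclasses.replace(tiny_config, duration=3.0 * 2000)
        state = random_initial_condition(cfg, rng)
        eff = apply_schedule(cfg, None, 0.0)
        geom = cfg.geometry
        for k in range(2000):
            step(state, cfg, rng, eff)
            hosts = np.flatnonzero(state.ap2_id >= 0)
            if len(hosts):
                z = state.site_coords(geom)[hosts, geom.AP2_SITE, 2]
                assert np.max(np.abs(z)) < 1e-6

    def test_determinism_bit_identical(self, tiny_config):
        t1 = run_simulation(tiny_config)
        t2 = run_simulation(tiny_config)
        assert len(t1.frames) == len(t2.frames)
        for f1, f2 in zip(t1.frames, t2.frames):
            np.testing.assert_array_equal(f1.pos, f2.pos)
            np.testing.assert_array_equal(f1.quat, f2.quat)
            np.testing.assert_array_equal(f1.cc_bonds, f2.cc_bonds)
            np.testing.assert_array_equal(f1.ap2_id, f2.ap2_id)

    def test_zero_duration_single_frame(self, tiny_config):
        cfg = dataclasses.replace(tiny_config, duration=0.0)
        traj = run_simulation(cfg)
        assert len(traj.frames) == 1
        assert traj.frames[0].time == 0.0


class TestSchedule:
    def _schedule(self):
        return ParameterSchedule(
            (
                (0.0, {"n_ap2": 200, "k_cc_gated_mult": 50.0, "d_clat_mult": 0.02}),
                (1.8e9, {}),  # revert at 30 min
            )
        )

    def test_piecewise_values(self):
        cfg = SimulationConfig(n_ap2=100)
        sched = self._schedule()
        before = apply_schedule(cfg, ParameterSchedule(((10.0, {"n_ap2": 7}),)), 5.0)
        assert before.n_ap2 == cfg.n_ap2  # baseline before the first breakpoint

        during = apply_schedule(cfg, sched, 60.0)
        assert during.n_ap2 == 200
        assert during.rates.k_cc_gated == pytest.approx(50 * cfg.rates.k_cc_gated)
        assert during.clathrin_diffusion.d_trans[0] == pytest.approx(
            0.02 * cfg.clathrin_diffusion.d_trans[0]
        )

        after = apply_schedule(cfg, sched, 1.8e9 + 3.0)
        assert after.n_ap2 == 100
        assert after.rates.k_cc_gated == cfg.rates.k_cc_gated
        assert after.clathrin_diffusion == cfg.clathrin_diffusion

    def test_unknown_override_rejected(self):
        with pytest.raises(ConfigError):
            ParameterSchedule(((0.0, {"bogus_field": 2}),))

    def test_non_increasing_times_rejected(self):
        with pytest.raises(ConfigError):
            ParameterSchedule(((5.0, {}), (5.0, {})))

    def test_ap2_increase_enters_free_pool(self, tiny_config, rng):
        sched = ParameterSchedule(((30.0, {"n_ap2": tiny_config.n_ap2 + 5}),))
        cfg = dataclasses.replace(
            tiny_config, schedule=sched, duration=300.0, debug_checks=True
        )
        traj = run_simulation(cfg)
        assert traj.frames[-1].pool_total == tiny_config.n_ap2 + 5

    def test_ap2_decrease_never_force_unbinds(self, tiny_config, rng):
        sched = ParameterSchedule(((30.0, {"n_ap2": 0}),))
        cfg = dataclasses.replace(
            tiny_config, schedule=sched, duration=600.0, debug_checks=True
        )
        traj = run_simulation(cfg)
        last = traj.frames[-1]
        bound = int(np.sum(last.ap2_id >= 0))
        # total never drops below what is still bound; free pool is empty
        assert last.pool_total >= bound
        assert last.pool_total - bound == 0 or last.pool_pending > 0


class TestOverlapContract:
    def test_no_pair_below_excluded_diameter(self, tiny_config, rng):
        cfg = dataclasses.replace(tiny_config, n_clathrin=20, box_edge=150.0)
        state = random_initial_condition(cfg, rng)
        eff = apply_schedule(cfg, None, 0.0)
        excl = cfg.geometry.excluded_diameter
        for _ in range(500):
            step(state, cfg, rng, eff)
            d2 = np.sum(
                (state.pos[:, None, :] - state.pos[None, :, :]) ** 2, axis=-1
            )
            np.fill_diagonal(d2, np.inf)
            assert d2.min() >= (excl - 1e-6) ** 2

    def test_max_retries_zero_keeps_state_valid(self, tiny_config, rng):
        cfg = dataclasses.replace(
            tiny_config, max_retries=0, n_clathrin=20, box_edge=120.0, debug_checks=True
        )
        state = random_initial_condition(cfg, rng)
        eff = apply_schedule(cfg, None, 0.0)
        for _ in range(200):
            step(state, cfg, rng, eff)  # debug_checks enforces the contract
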