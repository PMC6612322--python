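"""Unit tests for cell mechanics, cycle, fate, growth, and division."""

import numpy as np
import pytest

from egfrsim import mechanics as mech
from egfrsim.config import Config, MutationProfile


class TestRepulsionForce:
    def test_closed_form(self):
        # f = K (h0 - h) / (h - (h0 - h1)) = 1 * (10 - 7.5) / (7.5 - 5) = 1
        assert mech.repulsion_force(7.5, h0=10.0, h1=5.0, K=1.0) == pytest.approx(1.0)

    def test_zero_outside_contact(self):
        assert mech.repulsion_force(10.0, 10.0, 5.0, 1.0) == 0.0
        assert mech.repulsion_force(12.0, 10.0, 5.0, 1.0) == 0.0

    def test_monotone_decreasing_in_h(self):
        hs = np.linspace(5.01, 9.99, 50)
        fs = [mech.repulsion_force(h, 10.0, 5.0, 2.0) for h in hs]
        assert all(a > b for a, b in zip(fs, fs[1:]))

    def test_diverges_near_core(self):
        assert mech.repulsion_force(5.0 + 1e-6, 10.0, 5.0, 1.0) > 1e5

    def test_incompressibility_violation(self):
        with pytest.raises(ValueError):
            mech.repulsion_force(5.0, 10.0, 5.0, 1.0)
        with pytest.raises(ValueError):
            mech.repulsion_force(4.0, 10.0, 5.0, 1.0)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            mech.repulsion_force(7.5, 10.0, 12.0, 1.0)
        with pytest.raises(ValueError):
            mech.repulsion_force(7.5, 10.0, 5.0, 0.0)


class TestMotion:
    def test_velocity_friction_decay(self, cfg):
        cell = mech.make_cell(0, np.zeros(3), cfg, master_seed=1)
        cell.vel = np.array([1.0, 0.0, 0.0])
        dt, n = 0.005, 200
        for _ in range(n):
            mech.integrate_motion([cell], dt, cfg)
        # v_n = v0 / (1 + mu dt)^n -> v0 exp(-mu t)
        expected = 1.0 / (1.0 + cfg.mechanics.mu * dt) ** n
        assert cell.vel[0] == pytest.approx(expected, rel=1e-12)
        assert abs(expected - np.exp(-cfg.mechanics.mu * n * dt)) < 0.03

    def test_overlapping_pair_pushed_apart_symmetrically(self, cfg):
        a = mech.make_cell(0, np.zeros(3), cfg, master_seed=1)
        b = mech.make_cell(1, np.array([8.0, 0.0, 0.0]), cfg, master_seed=1)
        mech.integrate_motion([a, b], 0.005, cfg)
        assert a.vel[0] < 0 < b.vel[0]
        assert a.vel[0] == pytest.approx(-b.vel[0])
        assert np.allclose(a.vel[1:], 0) and np.allclose(b.vel[1:], 0)

    def test_hard_core_invariant(self, cfg):
        # cells launched at each other never penetrate the incompressible cores
        a = mech.make_cell(0, np.zeros(3), cfg, master_seed=1)
        b = mech.make_cell(1, np.array([10.5, 0.0, 0.0]), cfg, master_seed=1)
        a.vel = np.array([20.0, 0.0, 0.0])
        b.vel = np.array([-20.0, 0.0, 0.0])
        core = 2.0 * cfg.cell.r_cell - 2.0 * cfg.cell.r_nucleus
        for _ in range(2000):
            margin = mech.integrate_motion([a, b], 0.005, cfg)
            h = np.linalg.norm(a.pos - b.pos)
            assert h > core
            if margin != np.inf:
                assert margin > 0

    def test_overdamped_option(self, cfg):
        cfg.mechanics.overdamped = True
        a = mech.make_cell(0, np.zeros(3), cfg, master_seed=1)
        b = mech.make_cell(1, np.array([8.0, 0.0, 0.0]), cfg, master_seed=1)
        mech.integrate_motion([a, b], 0.005, cfg)
        f = mech.repulsion_force(8.0, 10.0, 5.0, cfg.mechanics.K)
        assert a.vel[0] == pytest.approx(-f / (cfg.mechanics.m * cfg.mechanics.mu))

    def test_empty_and_validation(self, cfg):
        assert mech.integrate_motion([], 0.005, cfg) == np.inf
        with pytest.raises(ValueError):
            mech.integrate_motion([], 0.0, cfg)


class TestCycleAndFate:
    def test_apoptosis_below_threshold(self, cfg):
        cell = mech.make_cell(0, np.zeros(3), cfg, master_seed=1)
        cell.cycle_clock = cfg.cycle.g1_duration - 0.004
        assert mech.advance_cycle_and_fate(cell, 0.005, cfg) == "apoptosis"
        assert cell.phase == mech.PHASE_DYING

    def test_commit_above_threshold(self, cfg):
        cell = mech.make_cell(0, np.zeros(3), cfg, master_seed=1)
        tf_idx = np.flatnonzero(cell.interior.species == 3)
        cell.interior.active[tf_idx[: cfg.cycle.n_tf_star + 1]] = True
        cell.interior.t_off[tf_idx[: cfg.cycle.n_tf_star + 1]] = 1e9
        cell.cycle_clock = cfg.cycle.g1_duration - 0.004
        assert mech.advance_cycle_and_fate(cell, 0.005, cfg) == "committed"
        assert cell.phase == mech.PHASE_COMMITTED

    def test_threshold_is_strict(self, cfg):
        cell = mech.make_cell(0, np.zeros(3), cfg, master_seed=1)
        tf_idx = np.flatnonzero(cell.interior.species == 3)
        cell.interior.active[tf_idx[: cfg.cycle.n_tf_star]] = True  # exactly N*
        cell.cycle_clock = cfg.cycle.g1_duration - 0.004
        assert mech.advance_cycle_and_fate(cell, 0.005, cfg) == "apoptosis"

    def test_divide_when_cycle_complete(self, cfg):
        cell = mech.make_cell(0, np.zeros(3), cfg, master_seed=1)
        cell.phase = mech.PHASE_COMMITTED
        cell.cycle_clock = cell.cycle_length - 0.004
        assert mech.advance_cycle_and_fate(cell, 0.005, cfg) == "divide"

    def test_checkpoint_fires_once(self, cfg):
        cell = mech.make_cell(0, np.zeros(3), cfg, master_seed=1)
        cell.cycle_clock = cfg.cycle.g1_duration + 1.0
        cell.phase = mech.PHASE_COMMITTED
        assert mech.advance_cycle_and_fate(cell, 0.005, cfg) == "none"


class TestGrowth:
    def test_linear_volume_doubling(self, cfg):
        cell = mech.make_cell(0, np.zeros(3), cfg, master_seed=1)
        cell.phase = mech.PHASE_COMMITTED
        v0 = cell.volume
        cell.cycle_clock = cell.cycle_length
        mech.grow(cell, cfg)
        assert cell.volume == pytest.approx(2.0 * v0, rel=1e-9)
        # halfway through growth: 1.5x volume
        cell.cycle_clock = 0.5 * (cfg.cycle.g1_duration + cell.cycle_length)
        mech.grow(cell, cfg)
        assert cell.volume == pytest.approx(1.5 * v0, rel=1e-9)

    def test_g1_cell_does_not_grow(self, cfg):
        cell = mech.make_cell(0, np.zeros(3), cfg, master_seed=1)
        r0 = cell.radius
        cell.cycle_clock = 100.0
        mech.grow(cell, cfg)
        assert cell.radius == r0


class TestDivision:
    def _grown_cell(self, cfg, profile=None):
        cell = mech.make_cell(0, np.zeros(3), cfg, master_seed=1, profile=profile)
        cell.phase = mech.PHASE_COMMITTED
        cell.cycle_clock = cell.cycle_length
        mech.grow(cell, cfg)
        return cell

    def test_daughter_geometry(self, cfg):
        cell = self._grown_cell(cfg)
        d1, d2 = mech.divide(cell, cfg, master_seed=1, new_ids=(1, 2))
        assert d1.radius == d2.radius == cell.birth_radius
        gap = np.linalg.norm(d1.pos - d2.pos)
        assert gap == pytest.approx(2.0 * cell.birth_radius)
        assert np.allclose(0.5 * (d1.pos + d2.pos), cell.pos)
        assert d1.phase == d2.phase == mech.PHASE_G1
        assert d1.cycle_clock == d2.cycle_clock == 0.0

    def test_molecule_conservation_without_replenishment(self, cfg):
        cfg.cycle.replenish_daughters = False
        cell = self._grown_cell(cfg)
        d1, d2 = mech.divide(cell, cfg, master_seed=1, new_ids=(1, 2))
        assert list(d1.interior.counts() + d2.interior.counts()) == [200, 60, 300, 50]

    def test_replenished_daughters_have_full_complement(self, cfg):
        cell = self._grown_cell(cfg)
        d1, d2 = mech.divide(cell, cfg, master_seed=1, new_ids=(1, 2))
        assert list(d1.interior.counts()) == [200, 60, 300, 50]
        assert list(d2.interior.counts()) == [200, 60, 300, 50]

    def test_daughters_inherit_genotype_and_receptor_count(self, cfg):
        prof = MutationProfile(kras=True, n_egfr=12)
        cell = self._grown_cell(cfg, profile=prof)
        d1, d2 = mech.divide(cell, cfg, master_seed=1, new_ids=(1, 2))
        for d in (d1, d2):
            assert d.profile is prof
            assert d.receptors.m == 12
            assert d.interior.rates[0] == pytest.approx(0.001)


class TestMakeCell:
    def test_cycle_length_within_jitter(self, cfg):
        lengths = [
            mech.make_cell(i, np.zeros(3), cfg, master_seed=5).cycle_length
            for i in range(100)
        ]
        lo = cfg.cycle.cycle_mean - cfg.cycle.cycle_jitter
        hi = cfg.cycle.cycle_mean + cfg.cycle.cycle_jitter
        assert all(lo <= L <= hi for L in lengths)
        assert abs(np.mean(lengths) - cfg.cycle.cycle_mean) < cfg.cycle.cycle_jitter / 2

    def test_receptor_count_from_profile(self, cfg):
        cell = mech.make_cell(0, np.zeros(3), cfg, master_seed=1,
                              profile=MutationProfile(n_egfr=24))
        assert cell.receptors.m == 24
        cell = mech.make_cell(0, np.zeros(3), cfg, master_seed=1)
        assert cell.receptors.m == cfg.receptors.n_egfr
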