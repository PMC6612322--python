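"""Unit tests for the per-cell Brownian-Dynamics cascade."""

import numpy as np
import pytest

from egfrsim import intracellular as ic
from egfrsim._kernels import SP_ERK, SP_RAF, SP_RAS, SP_TF
from egfrsim.config import Config, IntracellularConfig, MutationProfile


def fresh(cfg: Config, rng, profile=None) -> ic.CellInterior:
    return ic.init_cell_molecules(
        cfg.cell.r_cell, cfg.cell.r_nucleus, cfg.intracellular, rng, profile
    )


class TestInitialisation:
    def test_counts(self, cfg, rng):
        cell = fresh(cfg, rng)
        assert cell.n == 610
        assert list(cell.counts()) == [200, 60, 300, 50]
        assert not cell.active.any()

    def test_compartments(self, cfg, rng):
        cell = fresh(cfg, rng)
        r = np.linalg.norm(cell.pos, axis=1)
        tf = cell.species == SP_TF
        assert np.all(r[tf] <= cfg.cell.r_nucleus + 1e-12)
        assert np.all(r[~tf] >= cfg.cell.r_nucleus - 1e-12)
        assert np.all(r <= cfg.cell.r_cell + 1e-12)

    def test_invalid_geometry(self, cfg, rng):
        with pytest.raises(ValueError):
            ic.init_cell_molecules(2.0, 3.0, cfg.intracellular, rng)


class TestMutation:
    def test_multipliers(self):
        base = np.array([0.1, 0.1, 0.1, 1 / 15])
        rates = ic.apply_mutation(MutationProfile(kras=True), base)
        assert rates[SP_RAS] == pytest.approx(0.001)
        assert rates[SP_RAF] == pytest.approx(0.1)
        rates = ic.apply_mutation(MutationProfile(braf=True), base)
        assert rates[SP_RAF] == pytest.approx(0.001)
        rates = ic.apply_mutation(MutationProfile(kras=True, braf=True), base)
        assert rates[SP_RAS] == pytest.approx(0.001)
        assert rates[SP_RAF] == pytest.approx(0.001)
        assert rates[SP_ERK] == pytest.approx(0.1)
        assert rates[SP_TF] == pytest.approx(1 / 15)

    def test_normal_unchanged(self):
        base = np.array([0.1, 0.2, 0.3, 0.4])
        assert np.array_equal(ic.apply_mutation(MutationProfile(), base), base)

    def test_invalid_rates(self):
        with pytest.raises(ValueError):
            ic.apply_mutation(MutationProfile(), np.array([0.1, 0.0, 0.1, 0.1]))


class TestStepInterior:
    def test_conservation_and_confinement(self, cfg, rng):
        cell = fresh(cfg, rng)
        rec_c = np.array([[0.0, 0.0, cfg.cell.r_cell - cfg.receptors.r_rec]])
        rec_on = np.array([True])
        for k in range(400):
            ic.step_interior(cell, rec_c, rec_on, cfg.receptors.r_rec, 0.005,
                             k * 0.005, rng)
        assert cell.n == 610
        assert list(cell.counts()) == [200, 60, 300, 50]
        r = np.linalg.norm(cell.pos, axis=1)
        assert np.all(r <= cfg.cell.r_cell + 1e-9)
        tf = cell.species == SP_TF
        assert np.all(r[tf] <= cfg.cell.r_nucleus + 1e-9)
        # non-ERK cytoplasmic species never enter the nucleus
        cyt = (cell.species == SP_RAS) | (cell.species == SP_RAF)
        assert np.all(r[cyt] >= cfg.cell.r_nucleus - 1e-9)

    def test_quiescent_interior_skipped(self, cfg, rng):
        cell = fresh(cfg, rng)
        before = cell.pos.copy()
        ic.step_interior(cell, np.zeros((0, 3)), np.zeros(0, bool),
                         cfg.receptors.r_rec, 0.005, 0.0, rng)
        # nothing active, no receptor: the uniform state is invariant, step skipped
        assert np.array_equal(cell.pos, before)

    def test_cascade_fires_from_receptor(self, cfg, rng):
        cell = fresh(cfg, rng)
        rec_c = np.array([[0.0, 0.0, cfg.cell.r_cell - cfg.receptors.r_rec]])
        rec_on = np.array([True])
        for k in range(2000):
            ic.step_interior(cell, rec_c, rec_on, cfg.receptors.r_rec, 0.005,
                             k * 0.005, rng)
        counts = cell.active_counts()
        assert counts[SP_RAS] > 0
        assert counts[SP_RAF] > 0
        assert counts[SP_ERK] > 0
        assert counts[SP_TF] > 0

    def test_no_activation_without_receptor(self, cfg, rng):
        cell = fresh(cfg, rng)
        for k in range(200):
            ic.step_interior(cell, np.zeros((0, 3)), np.zeros(0, bool),
                             cfg.receptors.r_rec, 0.005, k * 0.005, rng)
        assert not cell.active.any()

    def test_switch_off_at_assigned_time(self, cfg, rng):
        cell = fresh(cfg, rng)
        i = int(np.flatnonzero(cell.species == SP_RAS)[0])
        cell.active[i] = True
        cell.t_off[i] = 0.5
        ic.step_interior(cell, np.zeros((0, 3)), np.zeros(0, bool),
                         cfg.receptors.r_rec, 0.005, 0.0, rng)
        assert cell.active[i]
        ic.step_interior(cell, np.zeros((0, 3)), np.zeros(0, bool),
                         cfg.receptors.r_rec, 0.005, 0.5, rng)
        assert not cell.active[i]


class TestWellMixedOracle:
    def test_pair_activation_matches_mass_action(self, cfg):
        """In the well-mixed limit (step length >> cell size) the BD pair
        reaction is mass-action with rate = P(overlap) / dt, with
        P(overlap) = v_react / V_cytoplasm for uniformly re-mixed positions."""
        rng = np.random.default_rng(97531)
        params = IntracellularConfig(d_protein=5000.0)  # rms step ~7 µm >> cell
        cell = ic.init_cell_molecules(cfg.cell.r_cell, cfg.cell.r_nucleus,
                                      params, rng)
        # one permanently active Ras; count activated Raf over time
        i = int(np.flatnonzero(cell.species == SP_RAS)[0])
        cell.active[i] = True
        cell.t_off[i] = 1e12
        # make deactivation negligible so the count is a pure birth process
        cell.rates[:] = 1e-9
        dt, t_end = 0.005, 5.0
        for k in range(int(t_end / dt)):
            ic.step_interior(cell, np.zeros((0, 3)), np.zeros(0, bool),
                             cfg.receptors.r_rec, dt, k * dt, rng)
        d_pp = 2.0 * params.r_bd
        v_react = 4.0 / 3.0 * np.pi * d_pp**3
        v_cyt = 4.0 / 3.0 * np.pi * (cfg.cell.r_cell**3 - cfg.cell.r_nucleus**3)
        k_pair = (v_react / v_cyt) / dt  # per-pair activation rate, 1/min
        n_raf = 60
        expected = n_raf * (1.0 - np.exp(-k_pair * t_end))
        observed = cell.active_counts()[SP_RAF]
        sd = np.sqrt(n_raf * (1 - np.exp(-k_pair * t_end)) * np.exp(-k_pair * t_end))
        # allow boundary-clipping bias (~5%) plus 3 sigma of binomial noise
        assert abs(observed - expected) < 0.1 * expected + 3 * sd


class TestDivision:
    def test_halving_conserves_and_splits_evenly(self, cfg, rng):
        mother = fresh(cfg, rng)
        # activate a few molecules so states are inherited
        idx = rng.choice(mother.n, size=40, replace=False)
        mother.active[idx] = True
        mother.t_off[idx] = 100.0
        n_active = int(mother.active.sum())
        d1, d2 = ic.halve_on_division(mother, rng)
        c1, c2 = d1.counts(), d2.counts()
        assert list(c1 + c2) == [200, 60, 300, 50]
        for sp in range(4):
            assert abs(int(c1[sp]) - int(c2[sp])) <= 1
        assert int(d1.active.sum() + d2.active.sum()) == n_active

    def test_halving_redraws_positions_in_domains(self, cfg, rng):
        mother = fresh(cfg, rng)
        d1, _ = ic.halve_on_division(mother, rng)
        r = np.linalg.norm(d1.pos, axis=1)
        tf = d1.species == SP_TF
        assert np.all(r[tf] <= cfg.cell.r_nucleus + 1e-12)
        assert np.all(r[~tf] >= cfg.cell.r_nucleus - 1e-12)

    def test_replenish_tops_up(self, cfg, rng):
        mother = fresh(cfg, rng)
        d1, d2 = ic.halve_on_division(mother, rng)
        ic.replenish(d1, cfg.intracellular, rng)
        assert list(d1.counts()) == [200, 60, 300, 50]
        # replenished molecules are inactive
        assert int(d1.active.sum()) <= int(mother.active.sum())

    def test_replenish_full_complement_is_noop(self, cfg, rng):
        cell = fresh(cfg, rng)
        before = cell.pos.copy()
        ic.replenish(cell, cfg.intracellular, rng)
        assert cell.n == 610
        assert np.array_equal(cell.pos, before)
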