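"""Force-field unit tests: pair, bond, bending, and wall terms."""

import math

import numpy as np
import pytest

from glycodpd.engine import (AngleSpec, BondSpec, DegeneratePairError,
                             ParticleState, PairInteractionTable,
                             SimulationBox, compute_angle_forces,
                             compute_bond_forces, compute_pair_forces,
                             wall_forces)

BOX = SimulationBox(np.array([10.0, 10.0, 10.0]), (True, True, True))


def two_beads(r, species=(0, 0), vel=None):
    pos = np.array([[5.0, 5.0, 5.0], [5.0 + r, 5.0, 5.0]])
    v = np.zeros((2, 3)) if vel is None else np.asarray(vel, float)
    return ParticleState(pos, v, np.array(species))


def deterministic_pair_force(state):
    """F^C + F^D only: a huge dt drives the fluctuation-dissipation
    amplitude sqrt(2 beta kBT / dt) to zero without touching C or D."""
    table = PairInteractionTable(dt=1e12)
    return compute_pair_forces(state, table, BOX, rng_seed=0)


class TestPairForces:
    def test_beyond_cutoff_all_terms_vanish(self):
        state = two_beads(1.2, vel=[[0, 0, 0], [-1, 0, 0]])
        f = compute_pair_forces(state, PairInteractionTable(), BOX, 1)
        assert np.all(f == 0.0)

    def test_conservative_magnitude_at_half_cutoff(self):
        # a_ww w(r) = 25 * 0.5 = 12.5, repulsive along the pair axis
        f = deterministic_pair_force(two_beads(0.5))
        assert f[0, 0] == pytest.approx(-12.5)
        assert f[1, 0] == pytest.approx(12.5)
        assert np.allclose(f[:, 1:], 0.0)

    def test_species_repulsion_table(self):
        # glycocalyx-water pairs repel at a_gw = 26.3, g-g at 30
        f_gw = deterministic_pair_force(two_beads(0.5, species=(0, 1)))
        f_gg = deterministic_pair_force(two_beads(0.5, species=(1, 2)))
        assert f_gw[1, 0] == pytest.approx(26.3 * 0.5)
        assert f_gg[1, 0] == pytest.approx(30.0 * 0.5)

    def test_dissipative_opposes_approach(self):
        # closing speed 1 along the axis: |F^D| = beta w^2 = 4.5 * 0.25
        closing = two_beads(0.5, vel=[[1.0, 0, 0], [0.0, 0, 0]])
        static = two_beads(0.5)
        fd = (deterministic_pair_force(closing)
              - deterministic_pair_force(static))
        assert fd[0, 0] == pytest.approx(-4.5 * 0.25)
        assert fd[1, 0] == pytest.approx(+4.5 * 0.25)

    def test_random_force_moments(self):
        # var(F^R_x) = (2 beta kBT / dt) w^2 at r = 0.5
        state = two_beads(0.5)
        table = PairInteractionTable()
        n = 100_000
        fx = np.empty(n)
        for s in range(n):
            f = compute_pair_forces(state, table, BOX, rng_seed=s)
            fx[s] = f[0, 0] + 12.5  # remove conservative part
        expected_var = 2 * 4.5 / 0.001 * 0.25
        assert abs(fx.mean()) < 3 * math.sqrt(expected_var / n)
        assert fx.var() == pytest.approx(expected_var, rel=0.02)

    def test_newtons_third_law_many_body(self):
        rng = np.random.default_rng(3)
        n = 120
        state = ParticleState(rng.uniform(0, 10, (n, 3)),
                              rng.normal(size=(n, 3)),
                              rng.integers(0, 3, n))
        f = compute_pair_forces(state, PairInteractionTable(), BOX, 9)
        assert np.abs(f.sum(axis=0)).max() < 1e-10

    def test_force_continuity_at_cutoff(self):
        f_in = compute_pair_forces(two_beads(0.999999),
                                   PairInteractionTable(), BOX, 4)
        assert np.abs(f_in).max() < 0.01

    def test_coincident_pair_is_degenerate(self):
        with pytest.raises(DegeneratePairError):
            compute_pair_forces(two_beads(0.0), PairInteractionTable(),
                                BOX, 1)

    def test_symmetric_per_pair_draws(self):
        # same seed and step: forces are a pure function of the pair set
        state = two_beads(0.5)
        f1 = compute_pair_forces(state, PairInteractionTable(), BOX, 7,
                                 step=3)
        f2 = compute_pair_forces(state, PairInteractionTable(), BOX, 7,
                                 step=3)
        assert np.array_equal(f1, f2)
        assert np.allclose(f1[0], -f1[1])


class TestBondForces:
    def test_equilibrium_length_no_force(self):
        f, e = compute_bond_forces(two_beads(0.5), [BondSpec(0, 1)])
        assert np.all(f == 0.0) and e == 0.0

    def test_stretched_bond_values(self):
        # |F| = 2 k_s (r - b0) = 2 * 100 * 0.1; E = 100 * 0.01
        f, e = compute_bond_forces(two_beads(0.6), [BondSpec(0, 1)])
        assert f[0, 0] == pytest.approx(20.0)
        assert f[1, 0] == pytest.approx(-20.0)
        assert e == pytest.approx(1.0)

    def test_compressed_bond_pushes_apart(self):
        f, _ = compute_bond_forces(two_beads(0.4), [BondSpec(0, 1)])
        assert f[0, 0] < 0 < f[1, 0]

    def test_zero_length_bond_degenerate(self):
        with pytest.raises(DegeneratePairError):
            compute_bond_forces(two_beads(0.0), [BondSpec(0, 1)])


def bent_trimer(dphi):
    """Three beads with bond length 0.5 and bend angle pi - dphi."""
    pos = np.array([
        [0.0, 0.0, 0.0],
        [0.5, 0.0, 0.0],
        [0.5 + 0.5 * math.cos(dphi), 0.5 * math.sin(dphi), 0.0]])
    return ParticleState(pos, np.zeros((3, 3)), np.zeros(3, dtype=np.int64))


class TestAngleForces:
    def test_straight_trimer_is_equilibrium(self):
        f, e = compute_angle_forces(bent_trimer(0.0), [AngleSpec(0, 1, 2)])
        assert e == pytest.approx(0.0, abs=1e-12)
        assert np.abs(f).max() < 1e-8

    def test_bending_energy_value(self):
        # E = (k_E / 2) dphi^2 = 231 * 0.01 at the baseline stiffness
        _, e = compute_angle_forces(bent_trimer(0.1), [AngleSpec(0, 1, 2)])
        assert e == pytest.approx(2.31, rel=1e-6)

    def test_forces_sum_and_torque_free(self):
        state = bent_trimer(0.3)
        f, _ = compute_angle_forces(state, [AngleSpec(0, 1, 2)])
        assert np.abs(f.sum(axis=0)).max() < 1e-12
        torque = np.cross(state.pos - state.pos[1], f).sum(axis=0)
        assert np.abs(torque).max() < 1e-12

    def test_matches_numerical_gradient(self):
        spec = AngleSpec(0, 1, 2)
        state = bent_trimer(0.25)
        f, _ = compute_angle_forces(state, [spec])
        h = 1e-6
        for p in range(3):
            for d in range(3):
                sp = state.copy()
                sp.pos[p, d] += h
                _, ep = compute_angle_forces(sp, [spec])
                sm = state.copy()
                sm.pos[p, d] -= h
                _, em = compute_angle_forces(sm, [spec])
                assert f[p, d] == pytest.approx(-(ep - em) / (2 * h),
                                                abs=1e-4)

    def test_degenerate_arm(self):
        pos = np.array([[0.0, 0, 0], [0.0, 0, 0], [0.5, 0, 0]])
        state = ParticleState(pos, np.zeros((3, 3)), np.zeros(3, dtype=int))
        with pytest.raises(DegeneratePairError):
            compute_angle_forces(state, [AngleSpec(0, 1, 2)])


class TestWallForces:
    BOXW = SimulationBox(np.array([10.0, 10.0, 10.0]))  # y walled

    def one_at(self, y):
        return ParticleState(np.array([[5.0, y, 5.0]]), np.zeros((1, 3)),
                             np.zeros(1, dtype=np.int64))

    def test_far_from_walls_no_force(self):
        f = wall_forces(self.one_at(5.0), self.BOXW)
        assert np.all(f == 0.0)

    def test_contact_maximal_repulsion_perpendicular(self):
        f = wall_forces(self.one_at(0.0), self.BOXW)
        assert f[0, 1] == pytest.approx(25.0)
        assert f[0, 0] == f[0, 2] == 0.0

    def test_top_wall_mirrors(self):
        f = wall_forces(self.one_at(9.5), self.BOXW)
        assert f[0, 1] == pytest.approx(-12.5)

    def test_continuous_at_range_edge(self):
        f = wall_forces(self.one_at(0.999999), self.BOXW)
        assert abs(f[0, 1]) < 1e-4

    def test_periodic_box_rejects_walls(self):
        with pytest.raises(ValueError):
            wall_forces(self.one_at(5.0), BOX)
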