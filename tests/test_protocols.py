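"""Run recipes: equilibration, drives, timed events, scaled fixture tiers."""

import numpy as np
import pytest

from glycodpd.engine import DRIVEN, FREE, TETHERED
from glycodpd.model import CaseConfig, build_case, case_config
from glycodpd.protocols import (Event, RunSchedule, build_system, equilibrate,
                                make_mini_case, run_production)


def tiny_config(**kw):
    base = dict(case_id="tiny", d0=4.0, d1=2.0, n_eg_chains=3, eg_beads=6,
                half_kE=27, n_rbc_chains=3, rbc_beads=6, drive_speed=0.1,
                box=(8.0, 6.0, 4.0), t_equil=1.0, t_prod=2.0,
                frame_interval=0.25, seed=3)
    base.update(kw)
    return CaseConfig(**base)


class TestEvents:
    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            Event(time=1.0, kind="explode")

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            Event(time=-1.0, kind="release_chain", chain=0)

    def test_missing_chain_reference(self):
        system = build_system(tiny_config())
        equilibrate(system, 0.0)
        ev = Event(time=0.5, kind="release_chain", chain=99)
        with pytest.raises(ValueError):
            run_production(system, events=[ev])


class TestSchedule:
    def test_spans_must_be_nonnegative(self):
        with pytest.raises(ValueError):
            RunSchedule(t_equil=-1.0)

    def test_frame_interval_must_divide_span(self):
        with pytest.raises(ValueError):
            RunSchedule(t_prod=10.0, frame_interval=3.0)


class TestEquilibrate:
    def test_zero_span_returns_unchanged(self):
        system = build_system(tiny_config())
        p0 = system.state.pos.copy()
        equilibrate(system, 0.0)
        assert np.array_equal(system.state.pos, p0)
        assert system.restart is not None

    def test_restart_checkpoint_reused_for_stiffness_sweep(self):
        # the stiffness sweep starts every variant from one equilibrated
        # conformation: restoring the checkpoint reproduces it bit-exactly
        system = build_system(tiny_config())
        equilibrate(system, 1.0)
        conf = system.state.pos.copy()
        system.sim.step(500)
        system.sim.restore(system.restart)
        assert np.array_equal(system.state.pos, conf)
        system.topology.set_bending_constant(2 * 347.0)
        assert np.all(system.topology.bonded.angle_kE == 694.0)
        assert np.array_equal(system.state.pos, conf)


class TestProduction:
    def test_driven_ends_move_at_prescribed_speed(self):
        system = build_system(tiny_config())
        equilibrate(system, 0.5)
        topo = system.topology
        anchors = [topo.chains[c].anchor_index for c in topo.rbc_chains]
        x0 = system.state.pos[anchors, 0].copy()
        traj = run_production(system)
        cfg = system.config
        for k, f in enumerate(traj.frames):
            expect = (x0 + cfg.drive_speed * f.time) % cfg.box[0]
            assert np.allclose(f.pos[anchors, 0], expect, atol=1e-9)
            assert np.allclose(f.vel[anchors, 0], cfg.drive_speed
                               if f.time > 0 else f.vel[anchors, 0])

    def test_release_event_removes_tether_and_lifts(self):
        cfg = tiny_config(events=[dict(time=1.0, kind="release_chain",
                                       chain="eg_center",
                                       displacement=[0.0, 1.0, 0.0])])
        system = build_system(cfg)
        equilibrate(system, 0.5)
        topo = system.topology
        center = topo.eg_chains[len(topo.eg_chains) // 2]
        anchor = topo.chains[center].anchor_index
        y_before = None
        traj = run_production(system)
        for f in traj.frames:
            if f.time < 1.0:
                assert f.pos[anchor, 1] == pytest.approx(0.0)
                y_before = f.pos[topo.chains[center].beads, 1].mean()
        assert system.state.role[anchor] == FREE
        assert topo.chains[center].spec.anchor_mode == "released"
        y_after = traj.frames[-1].pos[topo.chains[center].beads, 1].mean()
        assert y_after > y_before

    def test_velocity_pulse_applies_then_expires(self):
        cfg = tiny_config(drive_speed=0.0,
                          events=[dict(time=0.0, kind="velocity_pulse",
                                       chains="eg_tips",
                                       velocity=[0.2, 0.0, 0.0],
                                       duration=0.5)])
        system = build_system(cfg)
        equilibrate(system, 0.5)
        topo = system.topology
        tips = [topo.chains[c].tip_index for c in topo.eg_chains]
        traj = run_production(system)
        for f in traj.frames:
            if 0.0 < f.time <= 0.5:
                assert np.allclose(f.vel[tips, 0], 0.2)
        assert np.all(system.state.role[tips] == FREE)
        # tips were dragged forward during the pulse
        assert (traj.frames[2].pos[tips, 0]
                > traj.frames[0].pos[tips, 0]).all()

    def test_undriven_run_is_statistically_stationary(self):
        cfg = tiny_config(drive_speed=0.0, t_prod=3.0)
        system = build_system(cfg)
        equilibrate(system, 1.0)
        traj = run_production(system)
        v = np.concatenate([f.vel[system.state.free_mask]
                            for f in traj.frames])
        assert np.abs(v.mean(axis=0)).max() < 0.02

    def test_frames_carry_provenance(self):
        system = build_system(tiny_config())
        equilibrate(system, 0.0)
        traj = run_production(system)
        assert traj.meta["case_id"] == "tiny"
        assert len(traj.meta["config_hash"]) == 16
        assert len(traj) == int(2.0 / 0.25) + 1


class TestScaledTiers:
    def test_mini_contract(self):
        cfg = make_mini_case("A", scale="mini")
        assert cfg.box == (20.0, 20.0, 10.0)
        assert cfg.n_eg_chains == cfg.n_rbc_chains == 4
        assert cfg.eg_beads == 20
        assert cfg.t_equil == 20.0 and cfg.t_prod == 60.0
        assert 11_000 < cfg.n_total_beads < 13_000

    def test_micro_variants_mirror_the_matrix(self):
        a = make_mini_case("A", scale="micro")
        assert make_mini_case("B", scale="micro").n_eg_chains \
            == 2 * a.n_eg_chains
        assert make_mini_case("C", scale="micro").d1 == 2 * a.d1
        assert make_mini_case("D", scale="micro").eg_beads \
            == a.eg_beads // 2
        assert make_mini_case("F", scale="micro").d0 < a.d0
        assert make_mini_case("A3", scale="micro").n_rbc_chains == 1
        # printed speed ratios preserved under the tier drive scaling
        assert make_mini_case("A2", scale="micro").drive_speed \
            == pytest.approx(4 * a.drive_speed)
        assert make_mini_case("A1", scale="micro").drive_speed \
            == pytest.approx(0.1 * a.drive_speed)

    def test_event_cases_have_events(self):
        g = make_mini_case("G", scale="micro")
        assert g.events[0]["kind"] == "release_chain"
        assert g.events[0]["time"] == pytest.approx(g.t_prod / 2)
        h = make_mini_case("H", scale="micro")
        assert h.events[0]["kind"] == "velocity_pulse"
        assert h.n_eg_chains == 5 and h.n_rbc_chains == 3
        assert h.drive_speed == 0.0

    def test_unknown_case_rejected(self):
        with pytest.raises(KeyError):
            make_mini_case("Z")

    def test_two_compartment_case_drives_solvent(self):
        cfg = make_mini_case("0", scale="micro")
        assert cfg.n_rbc_chains == 0
        assert cfg.body_force_x > 0  # the "slow" preset
        # strong forcing so the impulse dominates tether-exchange noise
        cfg.body_force_x = 0.05
        cfg.t_equil, cfg.t_prod = 1.0, 2.0
        system = build_system(cfg)
        equilibrate(system)
        p0 = system.sim.total_momentum()[0]
        run_production(system)
        # before the flow fully couples to the tethered brush, the
        # body-force impulse n_w f t shows up as total x momentum
        expect = cfg.n_water_beads * cfg.body_force_x * cfg.t_prod
        gained = system.sim.total_momentum()[0] - p0
        assert gained == pytest.approx(expect, rel=0.4)

    def test_full_case_zero_config_matches_flow_preset(self):
        cfg = case_config("0")
        assert cfg.n_rbc_chains == 0 and cfg.body_force_x > 0
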