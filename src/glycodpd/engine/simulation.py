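"""Time integration: modified velocity-Verlet stepping, checkpoints, diagnostics.

The integrator is the Groot-Warren modified velocity-Verlet with prediction
parameter lambda (default 0.65): positions advance with the stored force, the
dissipative force is evaluated once per step at predicted velocities, then the
velocity corrector uses the mean of old and new forces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import _kernels
from .forces import bonded_exclusion_keys, use_cell_list
from .types import (FREE, AngleSpec, BondSpec, DegeneratePairError,
                    ParticleState, PairInteractionTable, SimulationBox,
                    StateCorruptionError, angles_to_arrays, bonds_to_arrays)

_EMPTY_I2 = np.empty((0, 2), dtype=np.int64)
_EMPTY_I3 = np.empty((0, 3), dtype=np.int64)
_EMPTY_F = np.empty(0, dtype=np.float64)


@dataclass
class BondedTerms:
    """Flattened bond and angle tables consumed by the kernels."""

    bonds: np.ndarray = field(default_factory=lambda: _EMPTY_I2.copy())
    bond_ks: np.ndarray = field(default_factory=lambda: _EMPTY_F.copy())
    bond_b0: np.ndarray = field(default_factory=lambda: _EMPTY_F.copy())
    angles: np.ndarray = field(default_factory=lambda: _EMPTY_I3.copy())
    angle_kE: np.ndarray = field(default_factory=lambda: _EMPTY_F.copy())
    angle_phi0: np.ndarray = field(default_factory=lambda: _EMPTY_F.copy())

    @classmethod
    def from_specs(cls, bonds: Sequence[BondSpec] = (),
                   angles: Sequence[AngleSpec] = ()) -> "BondedTerms":
        bi, ks, b0 = bonds_to_arrays(bonds)
        ai, kE, p0 = angles_to_arrays(angles)
        return cls(bi, ks, b0, ai, kE, p0)


def maxwell_velocities(n: int, rng: np.random.Generator, kBT: float = 1.0,
                       mass: np.ndarray | float = 1.0) -> np.ndarray:
    """Maxwell-Boltzmann velocities with the net momentum removed."""
    m = np.broadcast_to(np.asarray(mass, dtype=np.float64), (n,))
    v = rng.normal(0.0, 1.0, size=(n, 3)) * np.sqrt(kBT / m)[:, None]
    v -= (m[:, None] * v).sum(axis=0) / m.sum()
    return v


def kinetic_temperature(state: ParticleState) -> float:
    """Reduced kinetic temperature sum(m v^2) / (3 N_free) over free beads."""
    free = state.free_mask
    nfree = int(free.sum())
    if nfree == 0:
        raise ValueError("no free particles: temperature undefined")
    v2 = (state.vel[free] ** 2).sum(axis=1)
    return float((state.mass[free] * v2).sum() / (3.0 * nfree))


class Simulation:
    """A DPD system plus integrator state.

    Parameters
    ----------
    state, box, table : the particle state, domain, and pair-interaction set.
    bonded : BondedTerms with the chain bonds and bends (empty = pure solvent).
    seed : master seed of the counter-based pair RNG; together with the
        configuration it fixes the trajectory bit-for-bit on one thread.
    lam : velocity-prediction parameter of the modified velocity-Verlet.
    a_wall : wall repulsion amplitude (defaults to a_ww); only used when the
        box is walled.
    body_force : (n_species, 3) constant force per species (e.g. to drive the
        solvent in the two-compartment setup).
    exclude_bonded : drop 1-2 bonded pairs from the C/D/R pair sum.
    """

    def __init__(self, state: ParticleState, box: SimulationBox,
                 table: PairInteractionTable | None = None,
                 bonded: BondedTerms | None = None, seed: int = 0,
                 lam: float = 0.65, a_wall: float | None = None,
                 body_force: np.ndarray | None = None,
                 exclude_bonded: bool = False,
                 track_solvent_forces: bool = False):
        self.state = state
        self.box = box
        self.table = table if table is not None else PairInteractionTable()
        self.bonded = bonded if bonded is not None else BondedTerms()
        self.seed = int(seed)
        self.lam = float(lam)
        self.a_wall = float(a_wall) if a_wall is not None else float(
            self.table.a[0, 0])
        nspecies = self.table.a.shape[0]
        if body_force is None:
            body_force = np.zeros((nspecies, 3))
        self.body_force = np.ascontiguousarray(body_force, dtype=np.float64)
        #: counter-flowing x body force by z half (viscosity calibration)
        self.poiseuille_fx = 0.0
        self.excl_keys = (bonded_exclusion_keys(self.bonded.bonds, state.n)
                          if exclude_bonded else np.empty(0, dtype=np.int64))
        self.track_solvent_forces = bool(track_solvent_forces)
        self.step_index = 0
        self.frc = np.zeros((state.n, 3))
        self.solvent_frc = np.zeros((state.n, 3))
        self._vpred = np.zeros((state.n, 3))
        self._fnew = np.zeros((state.n, 3))
        self._forces_ready = False

    # -- time -----------------------------------------------------------
    @property
    def dt(self) -> float:
        return self.table.dt

    @property
    def time(self) -> float:
        return self.step_index * self.dt

    def steps_for(self, span: float) -> int:
        return int(round(span / self.dt))

    # -- forces ---------------------------------------------------------
    def _eval_forces(self):
        s = self.state
        ndegen = _kernels.total_forces(
            s.pos, s.vel, s.species, s.role, self.table.a, self.table.beta,
            self.table.rc, self.table.kBT, self.table.dt, self.box.lengths,
            self.box.periodic_arr, self.box.walled, self.a_wall,
            self.bonded.bonds, self.bonded.bond_ks, self.bonded.bond_b0,
            self.bonded.angles, self.bonded.angle_kE, self.bonded.angle_phi0,
            self.body_force, self.poiseuille_fx, np.int64(self.step_index),
            np.int64(self.seed), self.frc, self.solvent_frc,
            self.track_solvent_forces, self.excl_keys, self._use_cells())
        if ndegen:
            raise DegeneratePairError(f"{ndegen} degenerate interaction(s)")
        self._forces_ready = True

    def _use_cells(self) -> bool:
        return use_cell_list(self.box, self.table.rc, self.state.n)

    def invalidate_forces(self):
        """Call after externally mutating positions/roles/topology."""
        self._forces_ready = False

    # -- stepping -------------------------------------------------------
    def step(self, nsteps: int = 1):
        """Advance nsteps of dt; free beads integrate, tethered beads stay,
        driven beads move kinematically at their prescribed velocity."""
        if nsteps <= 0:
            return self
        if not self._forces_ready:
            self._eval_forces()
        s = self.state
        ndegen, ok = _kernels.run_nsteps(
            s.pos, s.vel, self.frc, s.species, s.role, s.mass, s.drive,
            self.table.a, self.table.beta, self.table.rc, self.table.kBT,
            self.table.dt, self.lam, self.box.lengths, self.box.periodic_arr,
            self.box.walled, self.a_wall,
            self.bonded.bonds, self.bonded.bond_ks, self.bonded.bond_b0,
            self.bonded.angles, self.bonded.angle_kE, self.bonded.angle_phi0,
            self.body_force, self.poiseuille_fx, self.excl_keys,
            np.int64(self.seed), np.int64(self.step_index), np.int64(nsteps),
            self.track_solvent_forces, self.solvent_frc,
            self._use_cells(), self._vpred, self._fnew)
        self.step_index += nsteps
        if ndegen:
            raise DegeneratePairError(f"{ndegen} degenerate interaction(s)")
        if not ok:
            raise StateCorruptionError(
                f"non-finite state after step {self.step_index}")
        return self

    def run(self, span: float):
        """Advance a time span (in tau)."""
        return self.step(self.steps_for(span))

    # -- diagnostics ----------------------------------------------------
    def kinetic_temperature(self) -> float:
        return kinetic_temperature(self.state)

    def total_momentum(self) -> np.ndarray:
        return (self.state.mass[:, None] * self.state.vel).sum(axis=0)

    # -- checkpointing --------------------------------------------------
    def checkpoint(self) -> dict:
        """Everything needed to resume bit-exactly (the RNG state is the
        step counter)."""
        s = self.state
        return {
            "pos": s.pos.copy(), "vel": s.vel.copy(), "frc": self.frc.copy(),
            "role": s.role.copy(), "drive": s.drive.copy(),
            "step_index": self.step_index, "seed": self.seed,
        }

    def restore(self, chk: dict):
        s = self.state
        s.pos[:] = chk["pos"]
        s.vel[:] = chk["vel"]
        self.frc[:] = chk["frc"]
        s.role[:] = chk["role"]
        s.drive[:] = chk["drive"]
        self.step_index = int(chk["step_index"])
        self.seed = int(chk["seed"])
        self._forces_ready = True
        return self


# -- equilibrium fluctuation sampling of the bonded potentials ------------

def sample_dimer_bond(k_s: float = 100.0, b0: float = 0.5, kBT: float = 1.0,
                      n_samples: int = 100_000, seed: int = 0,
                      dt: float = 0.004, gamma: float = 2.0,
                      sample_every: int = 4) -> np.ndarray:
    """Thermal bond-length samples of an isolated dimer (Langevin dynamics).

    At equilibrium the length fluctuates with width ~ sqrt(kBT / (2 k_s)).
    """
    pos = np.array([[0.0, 0.0, 0.0], [b0, 0.0, 0.0]])
    vel = np.zeros((2, 3))
    mass = np.ones(2)
    bonds = np.array([[0, 1]], dtype=np.int64)
    out = np.empty((n_samples, 2, 3))
    got = _kernels.langevin_sample(
        pos, vel, mass, bonds, np.array([k_s]), np.array([b0]),
        _EMPTY_I3, _EMPTY_F, _EMPTY_F, kBT, gamma, dt,
        n_samples * sample_every + sample_every, sample_every,
        np.int64(seed), False, out)
    d = out[:got, 1] - out[:got, 0]
    return np.linalg.norm(d, axis=1)


def sample_trimer_angle(k_E: float = 462.0, k_s: float = 100.0,
                        b0: float = 0.5, kBT: float = 1.0,
                        n_samples: int = 100_000, seed: int = 0,
                        dt: float = 0.004, gamma: float = 2.0,
                        sample_every: int = 4) -> np.ndarray:
    """Signed thermal bend-angle deviations (phi - pi) of an isolated trimer.

    Sampled in the x-y plane so the angle measure is flat and the equilibrium
    width is sqrt(kBT / k_E) exactly; the sign comes from the z cross-product
    of the two arm vectors.
    """
    pos = np.array([[0.0, 0.0, 0.0], [b0, 0.0, 0.0], [2 * b0, 0.0, 0.0]])
    vel = np.zeros((3, 3))
    mass = np.ones(3)
    bonds = np.array([[0, 1], [1, 2]], dtype=np.int64)
    angles = np.array([[0, 1, 2]], dtype=np.int64)
    out = np.empty((n_samples, 3, 3))
    got = _kernels.langevin_sample(
        pos, vel, mass, bonds, np.array([k_s, k_s]), np.array([b0, b0]),
        angles, np.array([k_E]), np.array([np.pi]), kBT, gamma, dt,
        n_samples * sample_every + sample_every, sample_every,
        np.int64(seed), True, out)
    a = out[:got, 0] - out[:got, 1]
    b = out[:got, 2] - out[:got, 1]
    ra = np.linalg.norm(a, axis=1)
    rb = np.linalg.norm(b, axis=1)
    c = np.clip((a * b).sum(axis=1) / (ra * rb), -1.0, 1.0)
    phi = np.arccos(c)
    sign = np.sign(a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0])
    sign[sign == 0] = 1.0
    return sign * (np.pi - phi)
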