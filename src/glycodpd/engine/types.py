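"""Core domain types of the DPD engine, all in reduced units."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: species codes
WATER, EG_BEAD, RBC_BEAD = 0, 1, 2
SPECIES_NAMES = ("water", "eg_bead", "rbc_bead")

#: role codes
FREE, TETHERED, DRIVEN = 0, 1, 2
ROLE_NAMES = ("free", "tethered", "driven")


class DegeneratePairError(RuntimeError):
    """Two interacting particles coincide; the force direction is undefined."""


class StateCorruptionError(RuntimeError):
    """Non-finite coordinates or velocities were produced."""


@dataclass
class SimulationBox:
    """Orthorhombic domain; y is the walled (non-periodic) axis by default.

    Walls sit at y = 0 and y = Ly and push beads back along +/-y with a soft
    linear ramp inside one cutoff of the plane.
    """

    lengths: np.ndarray
    periodic: tuple[bool, bool, bool] = (True, False, True)

    def __post_init__(self):
        self.lengths = np.asarray(self.lengths, dtype=np.float64)
        if self.lengths.shape != (3,) or np.any(self.lengths <= 0):
            raise ValueError("box needs three positive lengths")

    @property
    def volume(self) -> float:
        return float(np.prod(self.lengths))

    @property
    def walled(self) -> bool:
        return not self.periodic[1]

    def wrap(self, pos: np.ndarray) -> np.ndarray:
        """Wrap periodic axes into [0, L); non-periodic axes untouched."""
        out = np.array(pos, dtype=np.float64, copy=True)
        for d in range(3):
            if self.periodic[d]:
                out[:, d] %= self.lengths[d]
        return out

    def min_image(self, dvec: np.ndarray) -> np.ndarray:
        dvec = np.array(dvec, dtype=np.float64, copy=True)
        for d in range(3):
            if self.periodic[d]:
                L = self.lengths[d]
                dvec[..., d] -= L * np.floor(dvec[..., d] / L + 0.5)
        return dvec

    def contains(self, pos: np.ndarray) -> bool:
        y = pos[:, 1]
        return bool(np.all(y >= 0.0) and np.all(y <= self.lengths[1]))

    @property
    def periodic_arr(self) -> np.ndarray:
        return np.asarray(self.periodic, dtype=np.bool_)


@dataclass
class PairInteractionTable:
    """Soft-repulsion maxima a_ij by species pair plus thermostat constants.

    Defaults are the glycocalyx/water set: a_ww = 25, a_gw = 26.3, a_gg = 30
    (both glycocalyx species count as g), beta = 4.5 for all pairs, r_c = 1,
    k_B T = 1, dt = 0.001 tau.  The random-force amplitude is fixed by the
    fluctuation-dissipation relation sigma = sqrt(2 beta k_B T / dt).
    """

    a: np.ndarray = field(default_factory=lambda: np.array(
        [[25.0, 26.3, 26.3],
         [26.3, 30.0, 30.0],
         [26.3, 30.0, 30.0]]))
    beta: np.ndarray = field(default_factory=lambda: np.full((3, 3), 4.5))
    rc: float = 1.0
    kBT: float = 1.0
    dt: float = 0.001

    def __post_init__(self):
        self.a = np.asarray(self.a, dtype=np.float64)
        self.beta = np.asarray(self.beta, dtype=np.float64)
        if not np.allclose(self.a, self.a.T):
            raise ValueError("a_ij must be symmetric")
        if np.any(self.beta <= 0):
            raise ValueError("beta must be positive")
        if self.dt <= 0 or self.rc <= 0 or self.kBT <= 0:
            raise ValueError("rc, kBT, dt must be positive")

    @property
    def sigma(self) -> np.ndarray:
        """Random-force amplitudes sqrt(2 beta k_B T / dt)."""
        return np.sqrt(2.0 * self.beta * self.kBT / self.dt)


@dataclass
class BondSpec:
    """Harmonic bond with energy k_s (r - b0)^2 (no 1/2 prefactor)."""

    i: int
    j: int
    k_s: float = 100.0
    b0: float = 0.5

    def __post_init__(self):
        if self.k_s <= 0 or self.b0 <= 0:
            raise ValueError("k_s and b0 must be positive")


@dataclass
class AngleSpec:
    """Harmonic bend with energy (k_E/2)(phi - phi0)^2, phi0 = pi by default."""

    i: int
    j: int  # central bead
    k: int
    k_E: float = 462.0
    phi0: float = np.pi

    def __post_init__(self):
        if self.k_E < 0:
            raise ValueError("k_E must be non-negative")


def bonds_to_arrays(bonds: Sequence[BondSpec]):
    idx = np.array([[b.i, b.j] for b in bonds], dtype=np.int64).reshape(-1, 2)
    ks = np.array([b.k_s for b in bonds], dtype=np.float64)
    b0 = np.array([b.b0 for b in bonds], dtype=np.float64)
    return idx, ks, b0


def angles_to_arrays(angles: Sequence[AngleSpec]):
    idx = np.array([[t.i, t.j, t.k] for t in angles],
                   dtype=np.int64).reshape(-1, 3)
    kE = np.array([t.k_E for t in angles], dtype=np.float64)
    phi0 = np.array([t.phi0 for t in angles], dtype=np.float64)
    return idx, kE, phi0


@dataclass
class ParticleState:
    """Positions, velocities, species and role tags of all beads."""

    pos: np.ndarray
    vel: np.ndarray
    species: np.ndarray
    role: np.ndarray | None = None
    mass: np.ndarray | None = None
    drive: np.ndarray | None = None  # prescribed velocity of driven beads

    def __post_init__(self):
        self.pos = np.ascontiguousarray(self.pos, dtype=np.float64)
        self.vel = np.ascontiguousarray(self.vel, dtype=np.float64)
        n = self.pos.shape[0]
        if self.pos.shape != (n, 3) or self.vel.shape != (n, 3):
            raise ValueError("pos and vel must be (N, 3)")
        self.species = np.ascontiguousarray(self.species, dtype=np.int64)
        if self.species.shape != (n,):
            raise ValueError("species must be (N,)")
        if self.role is None:
            self.role = np.zeros(n, dtype=np.int64)
        self.role = np.ascontiguousarray(self.role, dtype=np.int64)
        if self.mass is None:
            self.mass = np.ones(n, dtype=np.float64)
        self.mass = np.ascontiguousarray(self.mass, dtype=np.float64)
        if self.drive is None:
            self.drive = np.zeros((n, 3), dtype=np.float64)
        self.drive = np.ascontiguousarray(self.drive, dtype=np.float64)
        if not np.all(np.isfinite(self.pos)) or not np.all(np.isfinite(self.vel)):
            raise StateCorruptionError("non-finite coordinates or velocities")

    @property
    def n(self) -> int:
        return self.pos.shape[0]

    @property
    def free_mask(self) -> np.ndarray:
        return self.role == FREE

    def copy(self) -> "ParticleState":
        return ParticleState(self.pos.copy(), self.vel.copy(),
                             self.species.copy(), self.role.copy(),
                             self.mass.copy(), self.drive.copy())
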