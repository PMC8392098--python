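"""Functional force evaluation: pair (C/D/R), bonded, bending, and wall terms."""

from __future__ import annotations

from typing import Sequence

import numpy as np

from . import _kernels
from .types import (AngleSpec, BondSpec, DegeneratePairError, ParticleState,
                    PairInteractionTable, SimulationBox, StateCorruptionError,
                    angles_to_arrays, bonds_to_arrays)

_EMPTY_EXCL = np.empty(0, dtype=np.int64)
_NO_SF = np.empty((0, 3), dtype=np.float64)


def use_cell_list(box: SimulationBox, rc: float, n: int) -> bool:
    """Cell lists need >= 3 cells along every periodic axis; else brute-force."""
    if n < 200:
        return False
    for d in range(3):
        if box.periodic[d] and box.lengths[d] < 3.0 * rc:
            return False
    return True


def compute_pair_forces(state: ParticleState, table: PairInteractionTable,
                        box: SimulationBox, rng_seed: int, step: int = 0,
                        track_solvent: bool = False,
                        exclusions: np.ndarray | None = None):
    """Conservative + dissipative + random pair forces of one configuration.

    Per-pair Gaussian draws are keyed by (rng_seed, step, i, j) so the same
    arguments always give the same forces and alpha_ij = alpha_ji holds.
    Returns the (N, 3) force array, or (forces, solvent_forces) when
    track_solvent is set (solvent_forces = pair force on each non-water bead
    from water beads only).
    """
    if not np.all(np.isfinite(state.vel)):
        raise StateCorruptionError("non-finite velocities")
    n = state.n
    f = np.zeros((n, 3))
    sf = np.zeros((n, 3)) if track_solvent else _NO_SF
    excl = _EMPTY_EXCL if exclusions is None else exclusions
    args = (state.pos, state.vel, state.species, table.a, table.beta,
            table.rc, table.kBT, table.dt, box.lengths, box.periodic_arr,
            np.int64(step), np.int64(rng_seed), f, sf, track_solvent, excl)
    if use_cell_list(box, table.rc, n):
        ndegen = _kernels.pair_forces_cells(*args)
    else:
        ndegen = _kernels.pair_forces_brute(*args)
    if ndegen:
        raise DegeneratePairError(f"{ndegen} coincident pair(s)")
    return (f, sf) if track_solvent else f


def compute_bond_forces(state: ParticleState, bonds: Sequence[BondSpec],
                        box: SimulationBox | None = None):
    """Forces and total energy of harmonic bonds E = k_s (r - b0)^2."""
    idx, ks, b0 = bonds_to_arrays(bonds)
    f = np.zeros((state.n, 3))
    L, per = _box_arrays(box)
    e, ndegen = _kernels.bond_forces(state.pos, idx, ks, b0, L, per, f)
    if ndegen:
        raise DegeneratePairError(f"{ndegen} zero-length bond(s)")
    return f, e


def compute_angle_forces(state: ParticleState, angles: Sequence[AngleSpec],
                         box: SimulationBox | None = None):
    """Forces and total energy of harmonic bends E = (k_E/2)(phi - phi0)^2."""
    idx, kE, phi0 = angles_to_arrays(angles)
    f = np.zeros((state.n, 3))
    L, per = _box_arrays(box)
    e, ndegen = _kernels.angle_forces(state.pos, idx, kE, phi0, L, per, f)
    if ndegen:
        raise DegeneratePairError(f"{ndegen} degenerate angle arm(s)")
    return f, e


def wall_forces(state: ParticleState, box: SimulationBox,
                a_wall: float = 25.0, rc: float = 1.0) -> np.ndarray:
    """Soft perpendicular repulsion from the y = 0 and y = Ly wall planes."""
    if not box.walled:
        raise ValueError("box has no walls (y is periodic)")
    f = np.zeros((state.n, 3))
    _kernels.wall_forces(state.pos, box.lengths[1], a_wall, rc, f)
    if not box.contains(state.pos):
        import warnings
        warnings.warn("particles beyond the wall plane (integration blow-up?)",
                      RuntimeWarning, stacklevel=2)
    return f


def bonded_exclusion_keys(bond_idx: np.ndarray, n: int) -> np.ndarray:
    """Sorted i*N+j keys (i<j) of 1-2 bonded pairs, for the exclusion flag."""
    if bond_idx.size == 0:
        return _EMPTY_EXCL
    lo = np.minimum(bond_idx[:, 0], bond_idx[:, 1]).astype(np.int64)
    hi = np.maximum(bond_idx[:, 0], bond_idx[:, 1]).astype(np.int64)
    return np.sort(lo * np.int64(n) + hi)


def _box_arrays(box: SimulationBox | None):
    if box is None:
        return (np.full(3, 1e12), np.zeros(3, dtype=np.bool_))
    return box.lengths, box.periodic_arr
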