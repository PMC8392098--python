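"""Near-field flow statistics: velocity binning, orientation dispersion,
Kolmogorov-Smirnov comparisons, shear profiles, viscosity calibration,
lifting force.

The canonical full-scale grid is 16 x 9 x 1 cuboid meshes of 5 x 5 x 40 r_c
over the 80 x 45 x 40 domain; scaled-down runs use geometrically similar
grids.  Per-bin orientation is the x-y projection angle theta = atan2(vy, vx).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ..engine import (ParticleState, PairInteractionTable, Simulation,
                      SimulationBox, maxwell_velocities)
from ..model import ChainTopology
from ..trajectory import Trajectory


@dataclass
class FlowFieldGrid:
    """Binned mean-velocity field; empty bins are flagged and excluded."""

    edges: tuple[np.ndarray, np.ndarray, np.ndarray]
    mean_vel: np.ndarray   # (nx, ny, nz, 3)
    counts: np.ndarray     # (nx, ny, nz) pooled samples per bin

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.counts.shape

    @property
    def occupied(self) -> np.ndarray:
        return self.counts > 0

    @property
    def theta(self) -> np.ndarray:
        """x-y projection angle of each occupied bin, flattened."""
        occ = self.occupied
        return np.arctan2(self.mean_vel[occ][:, 1], self.mean_vel[occ][:, 0])

    @property
    def y_centers(self) -> np.ndarray:
        e = self.edges[1]
        return 0.5 * (e[1:] + e[:-1])

    def momentum_sum(self) -> np.ndarray:
        """sum(bin mean x bin count): equals the pooled velocity sum."""
        return (self.mean_vel * self.counts[..., None]).sum(axis=(0, 1, 2))


@dataclass
class ShearProfile:
    """Mean v_x(y) and its central-difference shear rate / stress."""

    y: np.ndarray
    vx: np.ndarray
    shear_rate: np.ndarray          # dvx/dy, 1/tau
    viscosity: float | None = None
    stress: np.ndarray | None = None  # f = gamma dvx/dy


def grid_edges(box: SimulationBox, shape=(16, 9, 1),
               bin_size=None) -> tuple[np.ndarray, ...]:
    if bin_size is not None:
        shape = []
        for d in range(3):
            k = box.lengths[d] / bin_size[d]
            if abs(k - round(k)) > 1e-9:
                raise ValueError(
                    f"bin size {bin_size[d]} does not tile axis {d} "
                    f"(L = {box.lengths[d]})")
            shape.append(int(round(k)))
    return tuple(np.linspace(0.0, box.lengths[d], shape[d] + 1)
                 for d in range(3))


def bin_velocities(traj: Trajectory, shape=(16, 9, 1), bin_size=None,
                   species: int | None = None,
                   window: float | None = None) -> FlowFieldGrid:
    """Time-and-particle mean velocity per cuboid mesh.

    window restricts to the last ``window`` tau of the trajectory (the
    headline analyses average over the last 400 tau at full scale).
    species filters to one bead species (None = all beads).
    """
    sub = traj if window is None else traj.last(window)
    if len(sub) == 0:
        raise ValueError("no frames in the requested window")
    edges = grid_edges(traj.box, shape, bin_size)
    nshape = tuple(len(e) - 1 for e in edges)
    vsum = np.zeros(nshape + (3,))
    cnt = np.zeros(nshape, dtype=np.int64)
    L = traj.box.lengths
    for f in sub.frames:
        pos, vel = f.pos, f.vel
        if species is not None:
            m = traj.species == species
            pos, vel = pos[m], vel[m]
        idx = []
        for d in range(3):
            i = np.floor(pos[:, d] / L[d] * nshape[d]).astype(np.int64)
            idx.append(np.clip(i, 0, nshape[d] - 1))
        flat = np.ravel_multi_index(idx, nshape)
        np.add.at(cnt.ravel(), flat, 1)
        for c in range(3):
            np.add.at(vsum.reshape(-1, 3)[:, c], flat, vel[:, c])
    mean = np.zeros_like(vsum)
    occ = cnt > 0
    mean[occ] = vsum[occ] / cnt[occ, None]
    return FlowFieldGrid(edges, mean, cnt)


@dataclass
class OrientationStats:
    theta: np.ndarray
    mean_direction: float
    resultant_length: float
    circular_std: float


def orientation_stats(source) -> OrientationStats:
    """Circular summary of per-bin flow orientations.

    Accepts a FlowFieldGrid (uses occupied bins) or a raw theta sample.
    Dispersion is the circular standard deviation sqrt(-2 ln R).
    """
    theta = source.theta if isinstance(source, FlowFieldGrid) \
        else np.asarray(source, dtype=np.float64)
    if theta.size == 0:
        raise ValueError("no occupied bins / empty angle sample")
    z = np.exp(1j * theta).mean()
    r = np.abs(z)
    circ_std = np.sqrt(max(0.0, -2.0 * np.log(max(r, 1e-300))))
    return OrientationStats(theta, float(np.angle(z)), float(r),
                            float(circ_std))


def compare_orientations(theta_a, theta_b):
    """Two-sample Kolmogorov-Smirnov test on orientation samples.

    Returns (D, p).  D is the ECDF supremum distance in [0, 1].
    """
    a = np.asarray(theta_a, dtype=np.float64)
    b = np.asarray(theta_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 samples per side")
    res = stats.ks_2samp(a, b)
    return float(res.statistic), float(res.pvalue)


def shear_profile(grid: FlowFieldGrid, viscosity: float | None = None,
                  region: tuple[float, float] | None = None) -> ShearProfile:
    """v_x(y) profile and central-difference shear rate from a binned field.

    Each y level pools its x,z bins weighted by occupancy.  When a region
    (y_lo, y_hi) is given the profile is restricted to bins whose centers
    fall inside it.  Stress f = gamma dvx/dy requires a viscosity.
    """
    y = grid.y_centers
    w = grid.counts.sum(axis=(0, 2)).astype(np.float64)
    vxsum = (grid.mean_vel[..., 0] * grid.counts).sum(axis=(0, 2))
    sel = w > 0
    if region is not None:
        sel &= (y >= region[0]) & (y <= region[1])
    y, w, vxsum = y[sel], w[sel], vxsum[sel]
    if len(y) < 3:
        raise ValueError("need at least 3 occupied y-bins")
    vx = vxsum / w
    rate = np.gradient(vx, y)
    stress = None if viscosity is None else viscosity * rate
    return ShearProfile(y, vx, rate, viscosity, stress)


def shear_rate_series(traj: Trajectory, region: tuple[float, float],
                      species: int | None = 0, frame_stride: int = 1):
    """Per-frame least-squares slope of v_x vs y over beads in a y-region.

    Returns (times, rates, mean, standard_error); the near-surface check of
    the propulsion analysis asks whether this mean is consistent with zero.
    frame_stride thins the frames so the standard error is computed from
    approximately decorrelated samples.
    """
    times, rates = [], []
    for f in traj.frames[::frame_stride]:
        m = (f.pos[:, 1] >= region[0]) & (f.pos[:, 1] <= region[1])
        if species is not None:
            m &= traj.species == species
        if m.sum() < 10:
            continue
        y = f.pos[m, 1]
        vx = f.vel[m, 0]
        slope = np.polyfit(y, vx, 1)[0]
        times.append(f.time)
        rates.append(slope)
    rates = np.asarray(rates)
    if len(rates) < 2:
        raise ValueError("not enough frames with beads in the region")
    mean = float(rates.mean())
    se = float(rates.std(ddof=1) / np.sqrt(len(rates)))
    return np.asarray(times), rates, mean, se


def calibrate_viscosity(seed: int = 0, box_lengths=(8.0, 8.0, 8.0),
                        body_force: float = 0.1, density: float = 3.0,
                        t_warm: float = 20.0, t_sample: float = 30.0,
                        table: PairInteractionTable | None = None) -> float:
    """Dynamic viscosity of the DPD solvent by the periodic-Poiseuille
    method.

    A fully periodic solvent box is driven by a counter-flowing body force
    (+f along x in the lower z half, -f in the upper); the steady response
    in each half is the parabola v_x = (rho f / 2 gamma) z(h - z) with
    h = Lz/2, so gamma = rho f / (2 A) with A the fitted amplitude.  The
    readout uses velocity statistics only, which average far better at
    small scale than any instantaneous stress measurement.
    """
    rng = np.random.default_rng(seed)
    table = table if table is not None else PairInteractionTable()
    L = np.asarray(box_lengths, dtype=np.float64)
    n = int(round(density * np.prod(L)))
    pos = rng.uniform(0, 1, size=(n, 3)) * L
    species = np.zeros(n, dtype=np.int64)
    vel = maxwell_velocities(n, rng, table.kBT)
    state = ParticleState(pos, vel, species)
    box = SimulationBox(L, (True, True, True))
    sim = Simulation(state, box, table, seed=seed)
    sim.poiseuille_fx = float(body_force)
    sim.run(t_warm)

    h = L[2] / 2.0
    nsamp = max(1, int(round(t_sample / 0.25)))
    num = 0.0
    den = 0.0
    for _ in range(nsamp):
        sim.run(0.25)
        z = state.pos[:, 2]
        fold = np.where(z < h, z, z - h)
        sign = np.where(z < h, 1.0, -1.0)
        phi = fold * (h - fold)
        num += float((phi * sign * state.vel[:, 0]).sum())
        den += float((phi * phi).sum())
    amplitude = num / den
    if amplitude <= 0:
        raise RuntimeError("no steady flow established")
    return float(density * body_force / (2.0 * amplitude))


def lifting_force(traj: Trajectory, topo: ChainTopology, chain_id: int,
                  window: float | None = None) -> float:
    """Time- and bead-averaged y-component of the solvent pair force on one
    chain's beads.  Requires the run to have streamed per-bead forces."""
    sub = traj if window is None else traj.last(window)
    ch = topo.chains[chain_id]
    vals = []
    for f in sub.frames:
        if f.forces is None:
            raise ValueError("per-bead forces were not recorded for this run")
        vals.append(f.forces[ch.start:ch.stop, 1].mean())
    if not vals:
        raise ValueError("no frames in window")
    return float(np.mean(vals))
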