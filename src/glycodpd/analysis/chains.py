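"""Per-chain deformation observables: deflection, RMSD, interface, settling.

Deflection is measured at the free-end (tip) bead of a tethered chain against
a reference frame (by default the first stored production frame, i.e. the end
of equilibration).  The deformation RMSD between two consecutive stored
structures follows the printed normalisation

    RMSD = ( sum_i w_i ||x_i - y_i||^2 / (N_b sum_i w_i) )^(1/2)

which carries an extra 1/N_b relative to the conventional form; the
conventional form is available behind ``printed_form=False`` (orderings are
unaffected, absolute values scale by sqrt(N_b)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import make_interp_spline

from ..model import ChainTopology
from ..trajectory import Trajectory


@dataclass
class ChainMetrics:
    """Per-chain time series of the deformation observables."""

    times: np.ndarray                 # (T,)
    chain_ids: list[int]
    deflection: np.ndarray            # (C, T) tip x deflection, r_c
    relative_deflection: np.ndarray   # (C, T) deflection / l0
    tip_height_change: np.ndarray     # (C, T) tip (y - y_ref) / l0
    window: float = 100.0


def _chain_coords(traj: Trajectory, topo: ChainTopology, cid: int):
    ch = topo.chains[cid]
    return np.stack([f.pos[ch.start:ch.stop] for f in traj.frames])


def tip_deflection(traj: Trajectory, topo: ChainTopology, chain_id: int,
                   reference_index: int = 0,
                   allow_released: bool = False) -> np.ndarray:
    """Tip x-displacement series relative to the reference frame.

    Periodic x is unwrapped by minimum image, so a tip that crosses the box
    edge keeps a continuous deflection.  A released chain has no defined tip
    deflection and is rejected unless allow_released is set.
    """
    ch = topo.chains[chain_id]
    if ch.spec.anchor_mode == "released" and not allow_released:
        raise ValueError(f"chain {chain_id} was released: tip deflection "
                         "undefined after the release event")
    tips = np.array([f.pos[ch.tip_index] for f in traj.frames])
    dx = tips[:, 0] - tips[reference_index, 0]
    Lx = traj.box.lengths[0]
    if traj.box.periodic[0]:
        dx -= Lx * np.floor(dx / Lx + 0.5)
    return dx


def relative_deflection(traj: Trajectory, topo: ChainTopology,
                        chain_ids: list[int] | None = None,
                        reference_index: int = 0) -> np.ndarray:
    """Dimensionless tip deflection dx/l0 averaged over the given chains."""
    if chain_ids is None:
        chain_ids = topo.eg_chains
    if len(chain_ids) == 0:
        raise ValueError("empty chain set")
    series = [tip_deflection(traj, topo, c, reference_index)
              / topo.chains[c].l0 for c in chain_ids]
    return np.mean(series, axis=0)


def central_chains(topo: ChainTopology, n: int = 2) -> list[int]:
    """The n central EG chains (fast-drive analyses restrict to these)."""
    eg = topo.eg_chains
    mid = len(eg) / 2
    order = sorted(eg, key=lambda c: abs(eg.index(c) + 0.5 - mid))
    return sorted(order[:n])


def rmsd(frame_a: np.ndarray, frame_b: np.ndarray,
         weights: np.ndarray | None = None, printed_form: bool = True,
         box=None) -> float:
    """Deformation RMSD between two structures of one chain."""
    a = np.asarray(frame_a, dtype=np.float64)
    b = np.asarray(frame_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"mismatched bead counts: {a.shape} vs {b.shape}")
    nb = a.shape[0]
    w = np.ones(nb) if weights is None else np.asarray(weights, np.float64)
    if w.shape != (nb,):
        raise ValueError("weights must have one entry per bead")
    d = a - b
    if box is not None:
        d = box.min_image(d)
    sq = (d ** 2).sum(axis=1)
    denom = (nb * w.sum()) if printed_form else w.sum()
    return float(np.sqrt((w * sq).sum() / denom))


def windowed_rmsd(traj: Trajectory, topo: ChainTopology,
                  chain_ids: list[int] | None = None, window: float = 100.0,
                  weights: np.ndarray | None = None,
                  printed_form: bool = True, frame_stride: int = 1):
    """Consecutive-structure RMSD averaged per window and across chains.

    "Consecutive structures" are stored frames frame_stride apart (stride 1 =
    every saved frame; the canonical full-scale cadence is 1 tau).  Returns
    (window_end_times, averaged_rmsd) with one value per full window.
    """
    if chain_ids is None:
        chain_ids = topo.eg_chains
    sel = np.arange(0, len(traj.frames), frame_stride)
    times = traj.times[sel]
    if len(times) < 2:
        raise ValueError("need at least two frames")
    dt_frame = times[1] - times[0]
    if window < dt_frame - 1e-9:
        raise ValueError("window shorter than the frame interval")
    per_frame = np.zeros(len(times) - 1)
    for cid in chain_ids:
        coords = _chain_coords(traj, topo, cid)[sel]
        for k in range(len(times) - 1):
            per_frame[k] += rmsd(coords[k + 1], coords[k], weights,
                                 printed_form, traj.box)
    per_frame /= len(chain_ids)
    mid = 0.5 * (times[1:] + times[:-1])
    t0 = times[0]
    nwin = int(np.floor((times[-1] - t0) / window + 1e-9))
    ends = np.array([t0 + (k + 1) * window for k in range(nwin)])
    vals = np.array([per_frame[(mid >= e - window) & (mid < e)].mean()
                     for e in ends])
    return ends, vals


def interface_spline(tip_points: np.ndarray, n_samples: int = 200):
    """Cubic B-spline through the free-end (x, y) points, ordered by x.

    Interpolates at the tips; degrades to a lower order (with a warning)
    when fewer than 4 tips are available.  Returns (xs, ys) samples.
    """
    pts = np.asarray(tip_points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] < 2:
        raise ValueError("tip_points must be (n, 2+)")
    x, y = pts[:, 0], pts[:, 1]
    if np.any(np.diff(x) <= 0):
        raise ValueError("tip x coordinates must be strictly increasing")
    k = 3
    if len(x) <= k:
        k = len(x) - 1
        warnings.warn(f"only {len(x)} tips: using spline order {k}",
                      RuntimeWarning, stacklevel=2)
    spl = make_interp_spline(x, y, k=k)
    xs = np.linspace(x[0], x[-1], n_samples)
    return xs, spl(xs)


def settling_time(series: np.ndarray, times: np.ndarray,
                  tolerance: float) -> float:
    """First time after which the series stays within tolerance of its
    final plateau (mean of the last fifth).  NaN (with a warning) when the
    tail has not settled to a plateau."""
    s = np.asarray(series, dtype=np.float64)
    t = np.asarray(times, dtype=np.float64)
    ntail = max(2, len(s) // 5)
    plateau = s[-ntail:].mean()
    if np.abs(s[-ntail:] - plateau).max() > 3 * tolerance:
        warnings.warn("series has not reached a plateau: settling time "
                      "undefined", RuntimeWarning, stacklevel=2)
        return float("nan")
    ok = np.abs(s - plateau) <= tolerance
    # last index where it was outside tolerance
    outside = np.nonzero(~ok)[0]
    if len(outside) == 0:
        return float(t[0])
    if outside[-1] == len(s) - 1:
        warnings.warn("series never settles within tolerance",
                      RuntimeWarning, stacklevel=2)
        return float("nan")
    return float(t[outside[-1] + 1])


def mean_chain_height(traj: Trajectory, topo: ChainTopology,
                      chain_ids: list[int] | None = None,
                      window: float | None = None) -> float:
    """Mean bead height (y) of the given chains, time-averaged over the
    last ``window`` tau (whole trajectory when None)."""
    if chain_ids is None:
        chain_ids = topo.eg_chains
    sub = traj if window is None else traj.last(window)
    vals = []
    for f in sub.frames:
        for cid in chain_ids:
            ch = topo.chains[cid]
            vals.append(f.pos[ch.start:ch.stop, 1].mean())
    return float(np.mean(vals))


def compute_chain_metrics(traj: Trajectory, topo: ChainTopology,
                          chain_ids: list[int] | None = None,
                          window: float = 100.0) -> ChainMetrics:
    if chain_ids is None:
        chain_ids = topo.eg_chains
    times = traj.times
    defl, rel, dy = [], [], []
    for cid in chain_ids:
        ch = topo.chains[cid]
        d = tip_deflection(traj, topo, cid)
        tips_y = np.array([f.pos[ch.tip_index, 1] for f in traj.frames])
        defl.append(d)
        rel.append(d / ch.l0)
        dy.append((tips_y - tips_y[0]) / ch.l0)
    return ChainMetrics(times, list(chain_ids), np.array(defl),
                        np.array(rel), np.array(dy), window)
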