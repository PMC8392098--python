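"""Trajectory containers and persistence.

On-disk formats: an HDF5 container (lossless, one file per run), and XYZ /
LAMMPS-dump text dialects for interchange.  Dump column order is
``id type x y z vx vy vz``; the integer TIMESTEP field encodes time at the
canonical dt = 0.001 tau.  All values on disk are reduced DPD units.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd
import yaml

from .engine import ParticleState, SimulationBox

_DT_CANON = 0.001
SCHEMA_VERSION = 1


class TrajectoryParseError(ValueError):
    """Malformed trajectory text; carries the byte offset of the failure."""

    def __init__(self, msg: str, offset: int | None = None):
        if offset is not None:
            msg = f"{msg} (byte offset {offset})"
        super().__init__(msg)
        self.offset = offset


@dataclass
class TrajectoryFrame:
    """One stored snapshot; per-bead solvent forces are optional."""

    time: float
    pos: np.ndarray
    vel: np.ndarray
    forces: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.pos.shape[0]


@dataclass
class Trajectory:
    """Frames plus the per-run constants (box, tags, provenance)."""

    box: SimulationBox
    species: np.ndarray
    role: np.ndarray
    frames: list[TrajectoryFrame] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def append(self, frame: TrajectoryFrame):
        if self.frames:
            if frame.n != self.frames[0].n:
                raise ValueError("particle count changed within a run")
            if frame.time <= self.frames[-1].time:
                raise ValueError("frame times must increase")
        self.frames.append(frame)

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i) -> TrajectoryFrame:
        return self.frames[i]

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    def window(self, t_lo: float, t_hi: float) -> "Trajectory":
        """Sub-trajectory with t_lo <= t <= t_hi (inclusive)."""
        sel = [f for f in self.frames if t_lo - 1e-9 <= f.time <= t_hi + 1e-9]
        return Trajectory(self.box, self.species, self.role, sel, self.meta)

    def last(self, span: float) -> "Trajectory":
        t1 = self.frames[-1].time
        return self.window(t1 - span, t1)


def config_hash(cfg_dict: dict) -> str:
    return hashlib.sha256(
        yaml.safe_dump(cfg_dict, sort_keys=True).encode()).hexdigest()[:16]


# -- XYZ ------------------------------------------------------------------

_SPECIES_SYM = ("W", "G", "R")


def write_xyz(traj: Trajectory, path):
    """Plain XYZ (species symbol + coordinates); positions only."""
    with open(path, "w") as fh:
        for f in traj.frames:
            fh.write(f"{f.n}\n")
            fh.write(f"time={f.time:.6f} box="
                     + ",".join(f"{x:g}" for x in traj.box.lengths) + "\n")
            for sp, (x, y, z) in zip(traj.species, f.pos):
                fh.write(f"{_SPECIES_SYM[sp]} {x:.8f} {y:.8f} {z:.8f}\n")


def read_xyz(path) -> Trajectory:
    frames = []
    species = None
    box = None
    with open(path) as fh:
        while True:
            off = fh.tell()
            line = fh.readline()
            if not line:
                break
            try:
                n = int(line)
            except ValueError:
                raise TrajectoryParseError("expected atom count", off)
            comment = fh.readline()
            t, L = _parse_xyz_comment(comment)
            syms, pos = [], np.empty((n, 3))
            for k in range(n):
                off = fh.tell()
                parts = fh.readline().split()
                if len(parts) < 4:
                    raise TrajectoryParseError("truncated frame", off)
                syms.append(parts[0])
                pos[k] = [float(v) for v in parts[1:4]]
            if species is None:
                species = np.array([_SPECIES_SYM.index(s) if s in _SPECIES_SYM
                                    else 0 for s in syms], dtype=np.int64)
                box = SimulationBox(L) if L is not None else SimulationBox(
                    np.maximum(pos.max(axis=0), 1.0))
            frames.append(TrajectoryFrame(t, pos, np.zeros_like(pos)))
    if species is None:
        raise TrajectoryParseError("empty XYZ file", 0)
    return Trajectory(box, species, np.zeros_like(species), frames)


def _parse_xyz_comment(comment: str):
    t, L = 0.0, None
    for tok in comment.split():
        if tok.startswith("time="):
            t = float(tok[5:])
        elif tok.startswith("box="):
            L = np.array([float(v) for v in tok[4:].split(",")])
    return t, L


# -- LAMMPS dump ----------------------------------------------------------

def write_lammps_dump(traj: Trajectory, path):
    """Text dump, columns ``id type x y z vx vy vz`` (ids and types 1-based)."""
    per = traj.box.periodic
    bounds = " ".join("pp" if p else "ff" for p in per)
    with open(path, "w") as fh:
        for f in traj.frames:
            fh.write("ITEM: TIMESTEP\n")
            fh.write(f"{int(round(f.time / _DT_CANON))}\n")
            fh.write("ITEM: NUMBER OF ATOMS\n")
            fh.write(f"{f.n}\n")
            fh.write(f"ITEM: BOX BOUNDS {bounds}\n")
            for d in range(3):
                fh.write(f"0.0 {traj.box.lengths[d]:.8f}\n")
            fh.write("ITEM: ATOMS id type x y z vx vy vz\n")
            for i in range(f.n):
                x, y, z = f.pos[i]
                vx, vy, vz = f.vel[i]
                fh.write(f"{i + 1} {traj.species[i] + 1} "
                         f"{x:.8f} {y:.8f} {z:.8f} "
                         f"{vx:.8f} {vy:.8f} {vz:.8f}\n")


_REQUIRED_COLS = ("id", "type", "x", "y", "z", "vx", "vy", "vz")


def iter_lammps_dump(path):
    """Stream frames one at a time (constant memory in the frame count)."""
    with open(path) as fh:
        while True:
            off = fh.tell()
            line = fh.readline()
            if not line:
                return
            if line.strip() != "ITEM: TIMESTEP":
                raise TrajectoryParseError(
                    f"expected 'ITEM: TIMESTEP', got {line.strip()!r}", off)
            step = int(fh.readline())
            if fh.readline().strip() != "ITEM: NUMBER OF ATOMS":
                raise TrajectoryParseError("expected atom-count header",
                                           fh.tell())
            n = int(fh.readline())
            header = fh.readline()
            if not header.startswith("ITEM: BOX BOUNDS"):
                raise TrajectoryParseError("expected box bounds", fh.tell())
            per = tuple(tok == "pp" for tok in header.split()[3:6])
            L = np.empty(3)
            for d in range(3):
                lo, hi = (float(v) for v in fh.readline().split()[:2])
                L[d] = hi - lo
            cols_line = fh.readline()
            if not cols_line.startswith("ITEM: ATOMS"):
                raise TrajectoryParseError("expected atom table", fh.tell())
            cols = cols_line.split()[2:]
            missing = [c for c in _REQUIRED_COLS if c not in cols]
            if missing:
                raise TrajectoryParseError(
                    f"missing column(s): {', '.join(missing)}", fh.tell())
            idx = {c: cols.index(c) for c in cols}
            pos = np.empty((n, 3))
            vel = np.empty((n, 3))
            types = np.empty(n, dtype=np.int64)
            extras = {c: np.empty(n) for c in cols
                      if c not in _REQUIRED_COLS}
            for _ in range(n):
                off = fh.tell()
                parts = fh.readline().split()
                if len(parts) != len(cols):
                    raise TrajectoryParseError("truncated atom row", off)
                i = int(parts[idx["id"]]) - 1
                if i < 0 or i >= n:
                    raise TrajectoryParseError(f"atom id {i + 1} out of range",
                                               off)
                types[i] = int(parts[idx["type"]]) - 1
                for d, c in enumerate(("x", "y", "z")):
                    pos[i, d] = float(parts[idx[c]])
                for d, c in enumerate(("vx", "vy", "vz")):
                    vel[i, d] = float(parts[idx[c]])
                for c in extras:
                    extras[c][i] = float(parts[idx[c]])
            yield (step * _DT_CANON, pos, vel, types,
                   SimulationBox(L, per), extras)


def read_lammps_dump(path) -> Trajectory:
    frames = []
    species, box = None, None
    for t, pos, vel, types, b, _extras in iter_lammps_dump(path):
        if species is None:
            species, box = types, b
        frames.append(TrajectoryFrame(t, pos, vel))
    if species is None:
        raise TrajectoryParseError("empty dump file", 0)
    return Trajectory(box, species, np.zeros_like(species), frames)


# -- HDF5 container -------------------------------------------------------

def write_h5(traj: Trajectory, path):
    """Lossless hierarchical container (frames, tags, provenance)."""
    with h5py.File(path, "w") as h5:
        h5.attrs["schema_version"] = SCHEMA_VERSION
        h5.attrs["meta"] = json.dumps(traj.meta, sort_keys=True)
        h5["box/lengths"] = traj.box.lengths
        h5["box/periodic"] = np.asarray(traj.box.periodic, dtype=np.bool_)
        h5["species"] = traj.species
        h5["role"] = traj.role
        h5["times"] = traj.times
        g = h5.create_group("frames")
        for k, f in enumerate(traj.frames):
            fg = g.create_group(f"{k:06d}")
            fg.attrs["time"] = f.time
            fg["pos"] = f.pos
            fg["vel"] = f.vel
            if f.forces is not None:
                fg["forces"] = f.forces


def read_h5(path) -> Trajectory:
    with h5py.File(path, "r") as h5:
        box = SimulationBox(h5["box/lengths"][...],
                            tuple(bool(p) for p in h5["box/periodic"][...]))
        traj = Trajectory(box, h5["species"][...], h5["role"][...],
                          meta=json.loads(h5.attrs.get("meta", "{}")))
        for key in sorted(h5["frames"]):
            fg = h5["frames"][key]
            traj.append(TrajectoryFrame(
                float(fg.attrs["time"]), fg["pos"][...], fg["vel"][...],
                fg["forces"][...] if "forces" in fg else None))
    return traj


# -- metrics tables -------------------------------------------------------

def write_metrics(table: pd.DataFrame, path):
    """Tidy metrics table to CSV or JSON (by suffix); schema versioned."""
    path = str(path)
    if path.endswith(".json"):
        payload = {"schema_version": SCHEMA_VERSION,
                   "columns": list(table.columns),
                   "data": table.to_dict(orient="records")}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
    elif path.endswith(".csv"):
        table.to_csv(path, index=False)
    else:
        raise ValueError(f"unknown metrics format for {path!r}")


def read_metrics(path) -> pd.DataFrame:
    path = str(path)
    if path.endswith(".json"):
        with open(path) as fh:
            payload = json.load(fh)
        return pd.DataFrame(payload["data"], columns=payload.get("columns"))
    if path.endswith(".csv"):
        return pd.read_csv(path)
    raise ValueError(f"unknown metrics format for {path!r}")


def frame_from_state(state: ParticleState, time: float,
                     forces: np.ndarray | None = None) -> TrajectoryFrame:
    return TrajectoryFrame(time, state.pos.copy(), state.vel.copy(),
                           None if forces is None else forces.copy())
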