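"""Builders for the two- and three-compartment glycocalyx systems.

The three-compartment geometry is two opposing bead-spring brushes in explicit
DPD solvent: a lower array of endothelial-glycocalyx (EG) chains tethered to
the y = 0 wall, and an upper array representing the red-blood-cell (RBC)
glycocalyx whose top beads are dragged at a constant x velocity along the
anchor plane y = d0.  The case matrix covers chain density (d1), chain length,
bending stiffness, brush separation (d0), drive speed, and shedding events.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import yaml
from scipy.spatial import cKDTree

from .engine import (DRIVEN, EG_BEAD, FREE, RBC_BEAD, TETHERED, WATER,
                     BondedTerms, ParticleState, PairInteractionTable,
                     SimulationBox, maxwell_velocities)

#: Full-scale case matrix: brush separation d0, anchor spacing d1, EG chain
#: count, beads per EG chain, half bending constant k_E/2, drive speed of the
#: RBC ends (r_c/tau), RBC chain count (mirrors the EG row where unprinted).
CASE_MATRIX: dict[str, dict] = {
    "0":  dict(d0=None, d1=5.0, n_eg=12, eg_beads=60, half_kE=231,
               drive=0.0, n_rbc=0, remarks="EG in flow"),
    "A":  dict(d0=32.5, d1=5.0, n_eg=12, eg_beads=60, half_kE=231,
               drive=0.05, n_rbc=12, remarks="normal condition"),
    "A1": dict(d0=32.5, d1=5.0, n_eg=12, eg_beads=60, half_kE=231,
               drive=0.005, n_rbc=12, remarks="slow RBCs"),
    "A2": dict(d0=32.5, d1=5.0, n_eg=12, eg_beads=60, half_kE=231,
               drive=0.2, n_rbc=12, remarks="fast RBCs"),
    "A3": dict(d0=32.5, d1=5.0, n_eg=12, eg_beads=60, half_kE=231,
               drive=0.05, n_rbc=1, remarks="RBC glycocalyx shedding"),
    "B":  dict(d0=32.5, d1=2.5, n_eg=24, eg_beads=60, half_kE=231,
               drive=0.05, n_rbc=12, remarks="dense EG"),
    "C":  dict(d0=32.5, d1=10.0, n_eg=6, eg_beads=60, half_kE=231,
               drive=0.05, n_rbc=12, remarks="rarefied EG"),
    "D":  dict(d0=32.5, d1=5.0, n_eg=12, eg_beads=30, half_kE=231,
               drive=0.05, n_rbc=12, remarks="short chains"),
    "E1": dict(d0=32.5, d1=5.0, n_eg=12, eg_beads=60, half_kE=347,
               drive=0.05, n_rbc=12, remarks="stiffer EG"),
    "E2": dict(d0=32.5, d1=5.0, n_eg=12, eg_beads=60, half_kE=115,
               drive=0.05, n_rbc=12, remarks="softer EG"),
    "E3": dict(d0=32.5, d1=5.0, n_eg=12, eg_beads=60, half_kE=462,
               drive=0.05, n_rbc=12, remarks="stiffer EG"),
    "E4": dict(d0=32.5, d1=5.0, n_eg=12, eg_beads=60, half_kE=693,
               drive=0.05, n_rbc=12, remarks="stiffer EG"),
    "F":  dict(d0=27.5, d1=5.0, n_eg=12, eg_beads=60, half_kE=231,
               drive=0.05, n_rbc=12, remarks="close RBC-EG"),
    "G":  dict(d0=32.5, d1=5.0, n_eg=12, eg_beads=60, half_kE=231,
               drive=0.05, n_rbc=12, remarks="release chain 7"),
    "H":  dict(d0=32.5, d1=5.0, n_eg=5, eg_beads=60, half_kE=231,
               drive=0.0, n_rbc=3, remarks="EG propels RBC"),
}

FULL_DOMAIN = (80.0, 45.0, 40.0)


@dataclass
class ChainSpec:
    """One bead-spring chain: geometry, stiffness, and anchoring."""

    n_beads: int
    b0: float = 0.5
    k_s: float = 100.0
    k_E: float = 462.0
    anchor_mode: str = "tethered"  # tethered | driven | released
    anchor: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: int = +1  # +1 grows along +y (EG), -1 grows along -y (RBC)
    drive_velocity: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if self.n_beads < 2:
            raise ValueError("a chain needs at least 2 beads")
        if self.anchor_mode not in ("tethered", "driven", "released"):
            raise ValueError(f"unknown anchor mode {self.anchor_mode!r}")

    @property
    def l0(self) -> float:
        """Contour length (N_b - 1) b0."""
        return (self.n_beads - 1) * self.b0


@dataclass
class Chain:
    label: str           # "EG" | "RBC"
    start: int           # first global bead index
    spec: ChainSpec

    @property
    def n_beads(self) -> int:
        return self.spec.n_beads

    @property
    def stop(self) -> int:
        return self.start + self.n_beads

    @property
    def beads(self) -> np.ndarray:
        return np.arange(self.start, self.stop)

    @property
    def anchor_index(self) -> int:
        return self.start

    @property
    def tip_index(self) -> int:
        """Free-end bead (top of an EG chain, bottom of an RBC chain)."""
        return self.stop - 1

    @property
    def l0(self) -> float:
        return self.spec.l0


class ChainTopology:
    """Ordered chains with their derived bond and angle tables."""

    def __init__(self, chains: Sequence[Chain]):
        self.chains = list(chains)
        bonds, ks, b0, angles, kE, phi0 = [], [], [], [], [], []
        for ch in self.chains:
            s = ch.spec
            for k in range(ch.start, ch.stop - 1):
                bonds.append((k, k + 1))
                ks.append(s.k_s)
                b0.append(s.b0)
            for k in range(ch.start, ch.stop - 2):
                angles.append((k, k + 1, k + 2))
                kE.append(s.k_E)
                phi0.append(np.pi)
        self.bonded = BondedTerms(
            np.array(bonds, dtype=np.int64).reshape(-1, 2),
            np.array(ks), np.array(b0),
            np.array(angles, dtype=np.int64).reshape(-1, 3),
            np.array(kE), np.array(phi0))

    def __len__(self) -> int:
        return len(self.chains)

    @property
    def n_beads(self) -> int:
        return sum(c.n_beads for c in self.chains)

    @property
    def eg_chains(self) -> list[int]:
        return [i for i, c in enumerate(self.chains) if c.label == "EG"]

    @property
    def rbc_chains(self) -> list[int]:
        return [i for i, c in enumerate(self.chains) if c.label == "RBC"]

    def set_bending_constant(self, k_E: float):
        """Swap the bending constant everywhere (stiffness sweeps reuse one
        equilibrated conformation)."""
        self.bonded.angle_kE[:] = k_E
        for c in self.chains:
            c.spec.k_E = k_E


@dataclass
class CaseConfig:
    """One case of the study matrix plus protocol spans; the unit of
    reproducibility (same config + seed => identical trajectory)."""

    case_id: str
    d0: float | None
    d1: float
    n_eg_chains: int
    eg_beads: int
    half_kE: float
    n_rbc_chains: int
    rbc_beads: int = 60
    rbc_d1: float | None = None  # RBC anchor spacing (defaults to d1)
    drive_speed: float = 0.05
    box: tuple[float, float, float] = FULL_DOMAIN
    density: float = 3.0
    b0: float = 0.5
    k_s: float = 100.0
    t_equil: float = 200.0
    t_prod: float = 1600.0
    frame_interval: float = 1.0
    body_force_x: float = 0.0  # on water beads (two-compartment flow)
    events: list = field(default_factory=list)  # dicts, see protocols.Event
    seed: int = 0

    @property
    def k_E(self) -> float:
        return 2.0 * self.half_kE

    @property
    def volume(self) -> float:
        return float(np.prod(self.box))

    @property
    def n_chain_beads(self) -> int:
        return (self.n_eg_chains * self.eg_beads
                + self.n_rbc_chains * self.rbc_beads)

    @property
    def n_total_beads(self) -> int:
        return int(round(self.density * self.volume))

    @property
    def n_water_beads(self) -> int:
        return self.n_total_beads - self.n_chain_beads

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CaseConfig":
        d = dict(d)
        d["box"] = tuple(d["box"])
        return cls(**d)

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CaseConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def case_config(case_id: str, seed: int = 0) -> CaseConfig:
    """Full-scale configuration of one printed case row."""
    if case_id not in CASE_MATRIX:
        raise KeyError(f"unknown case {case_id!r}")
    row = CASE_MATRIX[case_id]
    cfg = CaseConfig(
        case_id=case_id, d0=row["d0"], d1=row["d1"], n_eg_chains=row["n_eg"],
        eg_beads=row["eg_beads"], half_kE=row["half_kE"],
        n_rbc_chains=row["n_rbc"], rbc_d1=5.0, drive_speed=row["drive"],
        seed=seed)
    if case_id == "G":
        cfg.t_prod = 1600.0
        cfg.events = [dict(time=800.0, kind="release_chain",
                           chain="eg_center", displacement=[0.0, 2.0, 0.0])]
    elif case_id == "H":
        cfg.events = [dict(time=0.0, kind="velocity_pulse", chains="eg_tips",
                           velocity=[0.05, 0.0, 0.0], duration=5.0)]
    elif case_id == "0":
        # "slow" flow preset; see protocols.flow_body_force / FLOW_PRESETS
        cfg.body_force_x = 12.0 * 0.85 * 0.01 / (3.0 * 45.0 ** 2)
    return cfg


def validate_config(cfg: CaseConfig) -> list[str]:
    """Report (never raise) every constraint the config violates."""
    v = []
    Lx, Ly, Lz = cfg.box
    if min(cfg.box) <= 0:
        v.append("box: all lengths must be positive")
    if cfg.density <= 0:
        v.append("density: must be positive")
    if cfg.d1 <= 0:
        v.append("d1: anchor spacing must be positive")
    if cfg.n_eg_chains < 1:
        v.append("n_eg_chains: need at least one EG chain")
    if cfg.eg_beads < 2:
        v.append("eg_beads: a chain needs >= 2 beads")
    if (cfg.n_eg_chains - 1) * cfg.d1 > Lx:
        v.append(f"d1: EG row span {(cfg.n_eg_chains - 1) * cfg.d1} "
                 f"exceeds Lx = {Lx}")
    eg_l0 = (cfg.eg_beads - 1) * cfg.b0
    if eg_l0 >= Ly:
        v.append(f"eg_beads: contour length {eg_l0} does not fit Ly = {Ly}")
    if cfg.n_rbc_chains > 0:
        if cfg.d0 is None or cfg.d0 <= 0:
            v.append("d0: must be positive when RBC chains are present")
        else:
            if cfg.d0 > Ly:
                v.append(f"d0: anchor plane {cfg.d0} outside Ly = {Ly}")
            rd1 = cfg.rbc_d1 if cfg.rbc_d1 is not None else cfg.d1
            if (cfg.n_rbc_chains - 1) * rd1 > Lx:
                v.append("rbc_d1: RBC row span exceeds Lx")
    if cfg.n_water_beads < 0:
        v.append("density: chain beads alone exceed density * volume")
    if cfg.half_kE < 0:
        v.append("half_kE: must be non-negative")
    if cfg.drive_speed < 0:
        v.append("drive_speed: must be non-negative")
    return v


def build_chain(spec: ChainSpec, wall_margin: float = 0.5):
    """Initial bead coordinates of one chain grown from its anchor.

    EG chains grow straight upward (+y) from the wall; RBC chains grow
    downward (-y) from the drive plane and, if longer than the gap (the
    close-separation cases), fold into a "J" running along +x one
    wall_margin above the wall.  Returns an (N_b, 3) coordinate array.
    """
    pos = np.tile(np.asarray(spec.anchor, dtype=np.float64), (spec.n_beads, 1))
    if spec.direction >= 0:
        pos[:, 1] += spec.b0 * np.arange(spec.n_beads)
        return pos
    y0 = spec.anchor[1]
    n_down = min(spec.n_beads, int((y0 - wall_margin) / spec.b0) + 1)
    k = np.arange(spec.n_beads)
    pos[:, 1] = np.maximum(y0 - spec.b0 * k, y0 - spec.b0 * (n_down - 1))
    pos[:, 0] += spec.b0 * np.maximum(k - (n_down - 1), 0)
    return pos


def build_case(cfg: CaseConfig, fill_solvent: bool = True):
    """Assemble one case: returns (ParticleState, ChainTopology, SimulationBox).

    EG chains form a single row along x at z = Lz/2 with spacing d1, anchors
    on the y = 0 wall; RBC chains form a centered row on the plane y = d0 with
    the same spacing.  Solvent beads fill the domain to the target number
    density with jittered insertion (no bead closer than 0.1 r_c to a chain
    bead); velocities are Maxwell-Boltzmann with zero net momentum.
    """
    problems = validate_config(cfg)
    if problems:
        raise ValueError("invalid case config: " + "; ".join(problems))
    Lx, Ly, Lz = cfg.box
    box = SimulationBox(np.array([Lx, Ly, Lz]))
    rng = np.random.default_rng(cfg.seed)

    chains, coords = [], []
    start = 0
    x0 = 0.5 * (Lx - (cfg.n_eg_chains - 1) * cfg.d1)
    for i in range(cfg.n_eg_chains):
        spec = ChainSpec(cfg.eg_beads, cfg.b0, cfg.k_s, cfg.k_E,
                         anchor_mode="tethered",
                         anchor=(x0 + i * cfg.d1, 0.0, Lz / 2), direction=+1)
        chains.append(Chain("EG", start, spec))
        coords.append(build_chain(spec))
        start += spec.n_beads
    if cfg.n_rbc_chains > 0:
        rd1 = cfg.rbc_d1 if cfg.rbc_d1 is not None else cfg.d1
        x0r = 0.5 * (Lx - (cfg.n_rbc_chains - 1) * rd1)
        for i in range(cfg.n_rbc_chains):
            spec = ChainSpec(cfg.rbc_beads, cfg.b0, cfg.k_s, cfg.k_E,
                             anchor_mode="driven",
                             anchor=(x0r + i * rd1, cfg.d0, Lz / 2),
                             direction=-1,
                             drive_velocity=(cfg.drive_speed, 0.0, 0.0))
            chains.append(Chain("RBC", start, spec))
            coords.append(build_chain(spec))
            start += spec.n_beads
    topo = ChainTopology(chains)
    chain_pos = np.concatenate(coords, axis=0)

    species = np.empty(start, dtype=np.int64)
    role = np.zeros(start, dtype=np.int64)
    for ch in chains:
        species[ch.start:ch.stop] = EG_BEAD if ch.label == "EG" else RBC_BEAD
        if ch.spec.anchor_mode == "tethered":
            role[ch.anchor_index] = TETHERED
        elif ch.spec.anchor_mode == "driven":
            role[ch.anchor_index] = DRIVEN
    # break the lattice symmetry of opposing straight chains (exactly
    # overlapping beads have no defined force direction); anchors stay put
    jit = rng.uniform(-0.05, 0.05, size=chain_pos.shape)
    jit[role != FREE] = 0.0
    chain_pos = chain_pos + jit
    chain_pos[:, 1] = np.clip(chain_pos[:, 1], 0.0, Ly)

    if fill_solvent and cfg.n_water_beads > 0:
        nw = cfg.n_water_beads
        wpos = rng.uniform(0.0, 1.0, size=(nw, 3)) * np.array([Lx, Ly, Lz])
        tree = cKDTree(chain_pos)
        for _ in range(100):
            d, _i = tree.query(wpos, k=1)
            bad = d < 0.1
            if not bad.any():
                break
            wpos[bad] = rng.uniform(0.0, 1.0, size=(int(bad.sum()), 3)) \
                * np.array([Lx, Ly, Lz])
        pos = np.concatenate([chain_pos, wpos], axis=0)
        species = np.concatenate([species, np.full(nw, WATER, dtype=np.int64)])
        role = np.concatenate([role, np.zeros(nw, dtype=np.int64)])
    else:
        pos = chain_pos

    n = pos.shape[0]
    vel = np.zeros((n, 3))
    free = role == FREE
    vel[free] = maxwell_velocities(int(free.sum()), rng)
    drive = np.zeros((n, 3))
    state = ParticleState(pos, vel, species, role, drive=drive)
    return state, topo, box


def default_table(cfg: CaseConfig | None = None) -> PairInteractionTable:
    return PairInteractionTable()
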