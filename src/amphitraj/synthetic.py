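"""Synthetic membrane-system generator with planted, known ground truth.

The generator emulates — at toy scale and with pseudo-atoms, not physics —
the kind of system the analyses in this package are meant for: a tetrameric
membrane protein whose four subunits each carry an S1–S4 helix bundle plus
linker/loop/pore regions, embedded in a two-leaflet lipid patch, with
amphipathic fatty-acid-like ligands (carboxyl head bead ``O1``/``O2``/``C1``
plus a C2..C22 tail with explicit pseudo-hydrogens).

Planted, recoverable truths:

* **tail flexibility** — tail conformations are resampled every frame from a
  trans/gauche dihedral model whose gauche probability scales with the
  ``flexibility`` parameter; 0 gives an all-trans chain (every C–C–C–C
  dihedral exactly 180°), 1 a highly disordered chain.  Pseudo-hydrogens sit
  perpendicular to the local C–C–C plane, so deuterium order parameters are
  exactly −0.5 for the all-trans chain oriented along the membrane normal.
* **contacts** — listed ``(chain, residue, ligand, part, intervals)`` contacts
  are realised by positional override: during a planted interval the ligand
  is laid out all-trans pointing radially away from the protein with the
  anchor atom (head ``O1`` or terminal tail carbon) placed at
  ``contact_distance`` from the residue's side-chain bead.  Outside planted
  intervals every ligand is kept at least ``2 × contact_cutoff`` away from
  the protein, so a contact analysis must recover exactly the planted set.
* **lateral diffusion** — ligand head positions follow a seeded 2-D Brownian
  walk with the planted diffusion constant (``planted_D``, cm²/s).

All randomness flows through one ``numpy`` generator seeded from
``GeneratorConfig.seed``; identical configs give bitwise-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import yaml

from .core import Atom, Frame, Role, Topology, Trajectory

__all__ = [
    "GeneratorConfig",
    "PlantedContact",
    "GroundTruth",
    "generate_system",
    "generate_fatty_acid_pair",
    "generate_state_pair",
]

# geometry constants (Å / degrees); pseudo-atom scale, not a force field
_BOND_CC = 1.53
_ANGLE_CCC = 111.0
_BOND_CH = 1.09
_HELIX_RISE = 2.5
_CB_OFFSET = 2.0
_SUBUNIT_RADIUS = 16.0
_HELIX_LOCAL = {"S1": (6.5, 6.5), "S2": (-6.5, 6.5), "S3": (-6.5, -6.5), "S4": (6.5, -6.5)}
_PORE_LOCAL = (5.0, 0.0)
_CM2S_TO_A2NS = 1e7  # 1 cm²/s = 1e16 Å²/s = 1e7 Å²/ns

_HELIX_NAMES = ("LEU", "ILE", "VAL", "ALA", "PHE", "MET")
_LINKER_NAMES = ("SER", "ASN", "GLU", "ASP")
_LOOP_NAMES = ("SER", "THR", "GLN")
_PORE_NAMES = ("GLY", "TYR", "VAL", "LEU", "ALA", "TRP")

_REGION_ORDER = ("S1", "S1-S2_loop", "S2", "S3", "S3-S4_linker", "S4", "pore")


@dataclass
class PlantedContact:
    chain_id: str
    residue_id: int
    ligand_id: int
    part: str  # "head" or "tail"
    intervals: list[tuple[float, float]]  # ns, inclusive

    def __post_init__(self):
        if self.part not in ("head", "tail"):
            raise ValueError(f"part must be 'head' or 'tail', got {self.part!r}")
        self.intervals = [(float(a), float(b)) for a, b in self.intervals]
        for a, b in self.intervals:
            if b < a:
                raise ValueError(f"interval ({a}, {b}) reversed")


@dataclass
class GeneratorConfig:
    n_subunits: int = 4
    residues_per_region: dict[str, int] = field(
        default_factory=lambda: {
            "S1": 6, "S1-S2_loop": 3, "S2": 6, "S3": 6,
            "S3-S4_linker": 4, "S4": 6, "pore": 6,
        }
    )
    n_ligands: int = 8
    n_lipids: int = 32
    tail_length: int = 22
    flexibility: float = 0.8
    planted_contacts: list[PlantedContact] = field(default_factory=list)
    planted_D: float = 4e-9  # cm²/s, lateral
    box: tuple[float, float, float] = (120.0, 120.0, 80.0)
    n_frames: int = 500
    dt_ns: float = 1.0
    seed: int = 0
    contact_distance: float = 3.0  # Å, anchor-to-residue distance while planted
    contact_cutoff: float = 3.5  # Å, criterion the planted system is built for
    first_resid: int = 301
    ligand_resname: str = "DHA"

    def __post_init__(self):
        if not 0.0 <= self.flexibility <= 1.0:
            raise ValueError("flexibility must be in [0, 1]")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.tail_length < 4:
            raise ValueError("tail_length must be >= 4")
        total = self.n_frames * self.dt_ns
        for pc in self.planted_contacts:
            for a, b in pc.intervals:
                if a < 0 or b > total + 1e-9:
                    raise ValueError(
                        f"planted interval ({a}, {b}) outside [0, {total}] ns"
                    )
            if not 0 <= pc.ligand_id < self.n_ligands:
                raise ValueError(f"planted contact references ligand {pc.ligand_id}")


@dataclass
class GroundTruth:
    """Planted truths serialized alongside every generated system."""

    planted_contacts: list[PlantedContact]
    planted_D_cm2_s: float
    flexibility: float
    seed: int
    residence_intervals: dict[int, list[tuple[float, float]]]
    contact_distance: float

    def to_yaml(self, path) -> None:
        data = {
            "planted_contacts": [asdict(pc) for pc in self.planted_contacts],
            "planted_D_cm2_s": float(self.planted_D_cm2_s),
            "flexibility": float(self.flexibility),
            "seed": int(self.seed),
            "residence_intervals": {
                int(k): [[float(a), float(b)] for a, b in v]
                for k, v in self.residence_intervals.items()
            },
            "contact_distance": float(self.contact_distance),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh)

    @classmethod
    def from_yaml(cls, path) -> "GroundTruth":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(
            planted_contacts=[PlantedContact(**pc) for pc in data["planted_contacts"]],
            planted_D_cm2_s=data["planted_D_cm2_s"],
            flexibility=data["flexibility"],
            seed=data["seed"],
            residence_intervals={
                int(k): [tuple(iv) for iv in v]
                for k, v in data["residence_intervals"].items()
            },
            contact_distance=data["contact_distance"],
        )


# --- dihedral chain building --------------------------------------------

def _build_chains(dihedrals_deg: np.ndarray, n_atoms: int) -> np.ndarray:
    """Batched internal→Cartesian chain build (NeRF).

    ``dihedrals_deg``: (batch, n_atoms - 3) torsions in degrees.  Bond length
    and angle fixed at 1.53 Å / 111°.  Returns (batch, n_atoms, 3).
    """
    batch = dihedrals_deg.shape[0]
    theta = math.radians(_ANGLE_CCC)
    d = _BOND_CC
    pos = np.zeros((batch, n_atoms, 3))
    pos[:, 1] = (d, 0.0, 0.0)
    pos[:, 2] = pos[:, 1] + (d * -math.cos(theta), d * math.sin(theta), 0.0)
    phi = np.radians(dihedrals_deg)
    for i in range(3, n_atoms):
        b1 = pos[:, i - 2] - pos[:, i - 3]
        b2 = pos[:, i - 1] - pos[:, i - 2]
        bc = b2 / np.linalg.norm(b2, axis=1, keepdims=True)
        n = np.cross(b1, bc)
        n /= np.linalg.norm(n, axis=1, keepdims=True)
        m = np.cross(n, bc)
        p = phi[:, i - 3]
        disp = (
            bc * (-d * math.cos(theta))
            + m * (d * math.sin(theta) * np.cos(p))[:, None]
            + n * (d * math.sin(theta) * np.sin(p))[:, None]
        )
        pos[:, i] = pos[:, i - 1] + disp
    return pos


def _all_trans(n_atoms: int) -> np.ndarray:
    return _build_chains(np.full((1, max(n_atoms - 3, 0)), 180.0), n_atoms)[0]


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix mapping unit vector a onto unit vector b (Rodrigues)."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # 180°: rotate about any axis perpendicular to a
        axis = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-6:
            axis = np.cross(a, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        return 2.0 * np.outer(axis, axis) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def _hydrogen_positions(tail: np.ndarray, c1: np.ndarray) -> np.ndarray:
    """Pseudo-hydrogen pairs perpendicular to the local C–C–C plane.

    ``tail``: (..., n_c, 3) carbon positions C2..Cn; ``c1``: (..., 3) position
    of the head carbon bonded to C2.  Returns (..., n_c, 2, 3).
    """
    prev = np.concatenate([c1[..., None, :], tail[..., :-1, :]], axis=-2)
    nxt = tail[..., 1:, :]
    b_in = tail[..., :-1, :] - prev[..., :-1, :]
    b_out = nxt - tail[..., :-1, :]
    normals = np.cross(b_in, b_out)
    # terminal carbon reuses the preceding normal
    normals = np.concatenate([normals, normals[..., -1:, :]], axis=-2)
    norm = np.linalg.norm(normals, axis=-1, keepdims=True)
    # collinear guard: fall back to a vector ⟂ to the chain bond and z
    bad = norm[..., 0] < 1e-8
    if np.any(bad):
        bonds = np.concatenate([b_in, b_in[..., -1:, :]], axis=-2)
        alt = np.cross(bonds, np.array([0.0, 0.0, 1.0]))
        alt_norm = np.linalg.norm(alt, axis=-1, keepdims=True)
        alt = np.where(alt_norm > 1e-8, alt, np.array([1.0, 0.0, 0.0]))
        normals = np.where(bad[..., None], alt, normals)
        norm = np.linalg.norm(normals, axis=-1, keepdims=True)
    unit = normals / norm
    h_a = tail + _BOND_CH * unit
    h_b = tail - _BOND_CH * unit
    return np.stack([h_a, h_b], axis=-2)


# --- protein / lipid scaffolds ------------------------------------------

def _chain_letters(n: int) -> list[str]:
    return [chr(ord("A") + i) for i in range(n)]


def _build_protein(config: GeneratorConfig):
    """Static protein beads: per residue one backbone (CA) and one
    side-chain (CB) bead, CB pointing radially outward.  Returns
    (atoms, coords, region_map, extracellular)."""
    cx, cy, cz = config.box[0] / 2, config.box[1] / 2, config.box[2] / 2
    atoms: list[Atom] = []
    coords: list[np.ndarray] = []
    region_map: dict[str, set] = {}
    extracellular: set = set()
    idx = 0
    for k, chain in enumerate(_chain_letters(config.n_subunits)):
        ang = 2 * math.pi * k / config.n_subunits
        ca_, sa_ = math.cos(ang), math.sin(ang)
        sub_x = cx + _SUBUNIT_RADIUS * ca_
        sub_y = cy + _SUBUNIT_RADIUS * sa_

        def local_to_global(lx, ly):
            return (sub_x + lx * ca_ - ly * sa_, sub_y + lx * sa_ + ly * ca_)

        resid = config.first_resid
        region_xy: dict[str, tuple[float, float]] = {}
        for region in _REGION_ORDER:
            n_res = config.residues_per_region.get(region, 0)
            if n_res == 0:
                continue
            if region in _HELIX_LOCAL:
                x, y = local_to_global(*_HELIX_LOCAL[region])
                region_xy[region] = (x, y)
                z0 = cz - (n_res - 1) / 2 * _HELIX_RISE
                positions = [(x, y, z0 + i * _HELIX_RISE) for i in range(n_res)]
                names = _HELIX_NAMES
            elif region == "pore":
                x, y = local_to_global(*_PORE_LOCAL)
                # pore helices sit toward the symmetry axis
                x = cx + (x - cx) * 0.35
                y = cy + (y - cy) * 0.35
                z0 = cz - (n_res - 1) / 2 * _HELIX_RISE
                positions = [(x, y, z0 + i * _HELIX_RISE) for i in range(n_res)]
                names = _PORE_NAMES
            else:
                a_lab, b_lab = ("S1", "S2") if region == "S1-S2_loop" else ("S3", "S4")
                ax, ay = region_xy.get(a_lab, local_to_global(*_HELIX_LOCAL[a_lab]))
                bx, by = region_xy.get(b_lab, local_to_global(*_HELIX_LOCAL[b_lab]))
                n_hel = max(config.residues_per_region.get(a_lab, 4), 2)
                z_top = cz + (n_hel - 1) / 2 * _HELIX_RISE + 4.0
                positions = []
                for i in range(n_res):
                    f = (i + 1) / (n_res + 1)
                    positions.append((ax + f * (bx - ax), ay + f * (by - ay), z_top))
                names = _LINKER_NAMES if region == "S3-S4_linker" else _LOOP_NAMES
            members = region_map.setdefault(region, set())
            loop_like = region in ("S3-S4_linker", "S1-S2_loop")
            for i, (x, y, z) in enumerate(positions):
                rname = names[i % len(names)]
                # helix side-chain beads face out radially; loop/linker beads
                # face away from the subunit centre (perpendicular to the
                # inter-helix chord) so neighbouring shells stay separated
                rx, ry = (x - sub_x, y - sub_y) if loop_like else (x - cx, y - cy)
                rn = math.hypot(rx, ry)
                if rn < 1e-6:
                    rx, ry = x - cx, y - cy
                    rn = math.hypot(rx, ry) or 1.0
                cbx, cby = x + _CB_OFFSET * rx / rn, y + _CB_OFFSET * ry / rn
                for aname, pos in (("CA", (x, y, z)), ("CB", (cbx, cby, z))):
                    atoms.append(
                        Atom(idx, aname, "C", resid, rname, chain, Role.protein)
                    )
                    coords.append(np.array(pos))
                    idx += 1
                members.add((chain, resid))
                if z > cz + 0.1:
                    extracellular.add((chain, resid))
                resid += 1
    return atoms, coords, region_map, extracellular


def _build_lipids(config: GeneratorConfig, start_index: int, protein_radius: float):
    cx, cy, cz = config.box[0] / 2, config.box[1] / 2, config.box[2] / 2
    spacing = 8.0
    slots = []
    nx = int(config.box[0] // spacing)
    ny = int(config.box[1] // spacing)
    for i in range(nx):
        for j in range(ny):
            x = (i + 0.5) * spacing
            y = (j + 0.5) * spacing
            if math.hypot(x - cx, y - cy) >= protein_radius + 6.0:
                slots.append((x, y))
    if len(slots) < max(config.n_lipids, 1):
        raise ValueError(
            f"box too small for {config.n_lipids} lipids (only {len(slots)} grid slots)"
        )
    atoms: list[Atom] = []
    coords: list[np.ndarray] = []
    idx = start_index
    for m in range(config.n_lipids):
        x, y = slots[m % len(slots)]
        top = m % 2 == 0
        z_head = cz + 17.0 if top else cz - 17.0
        dz = -4.0 if top else 4.0
        beads = [("P", z_head), ("C1", z_head + dz), ("C2", z_head + 2 * dz), ("C3", z_head + 3 * dz)]
        for name, z in beads:
            atoms.append(Atom(idx, name, element_of(name), m + 1, "POP", "M", Role.lipid))
            coords.append(np.array([x, y, z]))
            idx += 1
    return atoms, coords


def element_of(name: str) -> str:
    from .core import element_from_name

    return element_from_name(name)


def _planted_layout(pc, cb, center_xy, prot_xyz, p_atoms, config, axis, n_tail):
    """Deterministic clash-free ligand layout for a planted contact frame.

    The anchor atom (head ``O1`` or the terminal tail carbon) sits exactly
    ``contact_distance`` from the residue's side-chain bead along the
    outward radial; the all-trans chain leaves the anchor along a direction
    chosen, from a fixed candidate list of tilt/azimuth combinations, so
    that every non-anchor atom stays at least ``contact_cutoff`` + margin
    from every protein atom outside the target residue.
    """
    cx, cy = center_xy
    out = np.array([cb[0] - cx, cb[1] - cy, 0.0])
    out /= np.linalg.norm(out[:2])
    zhat = np.array([0.0, 0.0, 1.0])
    flat = _all_trans(n_tail)
    flat -= flat[0]
    other = np.array(
        [
            xyz
            for a, xyz in zip(p_atoms, prot_xyz)
            if not (a.chain_id == pc.chain_id and a.residue_id == pc.residue_id)
        ]
    )
    margin = 0.3
    clear = config.contact_cutoff + margin

    def rotz(vec, deg):
        az = math.radians(deg)
        ca_, sa_ = math.cos(az), math.sin(az)
        return np.array(
            [vec[0] * ca_ - vec[1] * sa_, vec[0] * sa_ + vec[1] * ca_, vec[2]]
        )

    def tilted(deg_tilt, deg_az):
        t = math.radians(deg_tilt)
        return math.cos(t) * rotz(out, deg_az) + math.sin(t) * zhat

    for a_tilt in (0.0, 35.0, 55.0, -35.0, 70.0, 90.0):
        for a_az in (0.0, 30.0, -30.0, 60.0, -60.0, 90.0, -90.0):
            approach = tilted(a_tilt, a_az)
            target = cb + config.contact_distance * approach
            if len(other):
                d_anchor = np.linalg.norm(other - target, axis=1).min()
                if d_anchor < clear:
                    continue
            for c_tilt in (-45.0, -60.0, -30.0, 45.0, 60.0, 0.0, -75.0, 75.0):
                for c_az in (0.0, 25.0, -25.0, 50.0, -50.0, 90.0, -90.0):
                    direction = tilted(c_tilt, c_az)
                    if pc.part == "head":
                        rot = _rotation_between(axis, direction)
                        o1_c = target
                        c1_c = target + 1.4 * direction
                        perp = np.cross(zhat, direction)
                        if np.linalg.norm(perp) < 1e-6:
                            perp = np.array([1.0, 0.0, 0.0])
                        o2_c = o1_c + 1.2 * perp / np.linalg.norm(perp)
                        c2_c = c1_c + _BOND_CC * direction
                        tail_pos = c2_c + flat @ rot.T
                    else:
                        rot = _rotation_between(axis, -direction)
                        tail_c = flat @ rot.T
                        tail_pos = target + (tail_c - tail_c[-1])
                        d21 = tail_pos[0] - tail_pos[1]
                        d21 /= np.linalg.norm(d21)
                        c1_c = tail_pos[0] + 1.5 * d21
                        o1_c = c1_c + 1.4 * d21
                        o2_c = o1_c + np.array([0.0, 0.0, 1.2])
                    pts = np.vstack([o1_c, o2_c, c1_c, tail_pos])
                    if len(other):
                        # non-anchor atoms must stay clear of everything;
                        # the anchor only of non-target residues
                        non_anchor = pts[:-1] if pc.part == "tail" else pts[1:]
                        d = np.linalg.norm(
                            non_anchor[:, None, :] - other[None], axis=-1
                        )
                        if d.min() < clear:
                            continue
                    lo = pts.min(axis=0)
                    hi = pts.max(axis=0)
                    if np.any(lo < 2.0) or np.any(hi > np.asarray(config.box) - 2.0):
                        continue
                    return o1_c, o2_c, c1_c, tail_pos
    raise ValueError(
        f"cannot find a clash-free planted layout for residue "
        f"({pc.chain_id!r}, {pc.residue_id}); choose a more exposed residue"
    )


# --- the generator -------------------------------------------------------

def generate_system(config: GeneratorConfig):
    """Generate (Topology, Trajectory, GroundTruth) with planted truths."""
    rng = np.random.default_rng(config.seed)
    box = np.asarray(config.box, dtype=np.float64)
    cx, cy, cz = box / 2
    n_tail = config.tail_length - 1  # carbons C2..C_tail_length
    total_time = config.n_frames * config.dt_ns

    # -- static scaffold
    if config.n_subunits > 0:
        p_atoms, p_coords, region_map, extracellular = _build_protein(config)
    else:
        p_atoms, p_coords, region_map, extracellular = [], [], {}, set()
    prot_xyz = np.array(p_coords).reshape(-1, 3) if p_coords else np.empty((0, 3))
    prot_radius = (
        float(np.max(np.hypot(prot_xyz[:, 0] - cx, prot_xyz[:, 1] - cy)))
        if len(prot_xyz)
        else 0.0
    )
    l_atoms, l_coords = (
        _build_lipids(config, len(p_atoms), prot_radius)
        if config.n_lipids > 0
        else ([], [])
    )

    # -- validate planted contacts against the scaffold
    residue_cb: dict[tuple[str, int], np.ndarray] = {}
    for a, c in zip(p_atoms, p_coords):
        if a.name == "CB":
            residue_cb[(a.chain_id, a.residue_id)] = c
    for pc in config.planted_contacts:
        if (pc.chain_id, pc.residue_id) not in residue_cb:
            raise ValueError(
                f"planted contact targets nonexistent residue "
                f"({pc.chain_id!r}, {pc.residue_id})"
            )

    # -- ligand topology
    lig_atoms: list[Atom] = []
    idx = len(p_atoms) + len(l_atoms)
    tail_names = [f"C{i}" for i in range(2, config.tail_length + 1)]
    per_lig_names = ["O1", "O2", "C1"] + tail_names
    for t in tail_names:
        per_lig_names += [f"H{t[1:]}A", f"H{t[1:]}B"]
    for li in range(config.n_ligands):
        for name in per_lig_names:
            lig_atoms.append(
                Atom(idx, name, element_of(name), li + 1, config.ligand_resname, "L", Role.ligand)
            )
            idx += 1
    n_per_lig = len(per_lig_names)

    topology = Topology(
        p_atoms + l_atoms + lig_atoms,
        region_map=region_map,
        extracellular=extracellular,
    )

    # -- per-frame ligand coordinates
    times = np.arange(config.n_frames) * config.dt_ns
    sigma = math.sqrt(2.0 * config.planted_D * _CM2S_TO_A2NS * config.dt_ns)
    clearance = 2.0 * config.contact_cutoff
    r_reflect = prot_radius + clearance + 5.0
    r_max = min(box[0], box[1]) / 2 - 10.0
    if config.n_subunits > 0 and r_reflect >= r_max:
        raise ValueError("box too small for ligand placement around the protein")

    canon = _all_trans(n_tail)
    axis = canon[-1] - canon[0]
    rot_down = _rotation_between(axis, np.array([0.0, 0.0, -1.0]))
    z_head = cz + 15.0

    contact_by_lig: dict[int, list[PlantedContact]] = {}
    for pc in config.planted_contacts:
        contact_by_lig.setdefault(pc.ligand_id, []).append(pc)

    lig_xyz = np.empty((config.n_frames, config.n_ligands, n_per_lig, 3))
    gauche_p = 0.5 * config.flexibility

    for li in range(config.n_ligands):
        # head xy Brownian walk (reflected off the protein clearance radius)
        if config.n_subunits > 0:
            ang0 = rng.uniform(0, 2 * math.pi)
            rad0 = rng.uniform(r_reflect + 2.0, r_max)
            x0, y0 = cx + rad0 * math.cos(ang0), cy + rad0 * math.sin(ang0)
        else:
            x0, y0 = rng.uniform(0, box[0]), rng.uniform(0, box[1])
        steps = rng.normal(0.0, sigma, size=(config.n_frames - 1, 2))
        track = np.concatenate([[[x0, y0]], steps]).cumsum(axis=0)
        if config.n_subunits > 0:
            # radial reflection keeps distractors clear of the protein
            rel = track - (cx, cy)
            r = np.hypot(rel[:, 0], rel[:, 1])
            inside = r < r_reflect
            if np.any(inside):
                scale = np.where(inside, (2 * r_reflect - r) / np.maximum(r, 1e-9), 1.0)
                track = (cx, cy) + rel * scale[:, None]
        track[:, 0] %= box[0]
        track[:, 1] %= box[1]

        # per-frame torsional resampling; common random numbers across
        # flexibility values so the monotonicity contrast is seed-paired
        u = rng.random((config.n_frames, max(n_tail - 3, 0)))
        u_sign = rng.random((config.n_frames, max(n_tail - 3, 0)))
        azimuth = rng.uniform(0, 2 * math.pi, size=config.n_frames)
        tilt_angle = rng.normal(0.0, 1.0, size=config.n_frames)
        tilt_azim = rng.uniform(0, 2 * math.pi, size=config.n_frames)
        dihedrals = np.where(
            u < gauche_p, np.where(u_sign < 0.5, 60.0, -60.0), 180.0
        )
        chains = _build_chains(dihedrals, n_tail)  # (n_frames, n_tail, 3)
        chains = chains - chains[:, :1]
        chains = chains @ rot_down.T
        # whole-chain axis wobble about a horizontal axis, scaled with
        # flexibility: emulates molecular-axis fluctuation so even the
        # conformationally rigid first carbons disorder with flexibility
        theta = np.radians(20.0 * config.flexibility) * tilt_angle
        ax = np.stack(
            [np.cos(tilt_azim), np.sin(tilt_azim), np.zeros_like(tilt_azim)], axis=1
        )
        k_cross = np.zeros((config.n_frames, 3, 3))
        k_cross[:, 0, 1], k_cross[:, 0, 2] = -ax[:, 2], ax[:, 1]
        k_cross[:, 1, 0], k_cross[:, 1, 2] = ax[:, 2], -ax[:, 0]
        k_cross[:, 2, 0], k_cross[:, 2, 1] = -ax[:, 1], ax[:, 0]
        eye = np.eye(3)[None]
        r_tilt = (
            eye
            + np.sin(theta)[:, None, None] * k_cross
            + (1 - np.cos(theta))[:, None, None] * (k_cross @ k_cross)
        )
        cos_a, sin_a = np.cos(azimuth), np.sin(azimuth)
        rz = np.zeros((config.n_frames, 3, 3))
        rz[:, 0, 0], rz[:, 0, 1] = cos_a, -sin_a
        rz[:, 1, 0], rz[:, 1, 1] = sin_a, cos_a
        rz[:, 2, 2] = 1.0
        r_full = rz @ r_tilt
        chains = np.einsum("fij,faj->fai", r_full, chains)

        # head offsets share the chain's rigid-body orientation so the
        # C1-C2 bond (and hence the first C-H normals) wobble with it
        o1 = np.column_stack([track, np.full(config.n_frames, z_head)])
        c1 = o1 + np.einsum("fij,j->fi", r_full, np.array([0.0, 0.0, -1.4]))
        o2 = o1 + np.einsum("fij,j->fi", r_full, np.array([1.2, 0.0, 0.3]))
        c2_base = c1 + np.einsum("fij,j->fi", r_full, np.array([0.0, 0.0, -_BOND_CC]))
        tail = c2_base[:, None, :] + chains

        # planted-contact frames: deterministic all-trans outward layout
        for pc in contact_by_lig.get(li, []):
            cb = residue_cb[(pc.chain_id, pc.residue_id)]
            mask = np.zeros(config.n_frames, dtype=bool)
            for a, b in pc.intervals:
                mask |= (times >= a - 1e-9) & (times <= b + 1e-9)
            if not np.any(mask):
                continue
            o1_c, o2_c, c1_c, tail_pos = _planted_layout(
                pc, cb, (cx, cy), prot_xyz, p_atoms, config, axis, n_tail
            )
            o1[mask] = o1_c
            o2[mask] = o2_c
            c1[mask] = c1_c
            tail[mask] = tail_pos

        # clearance enforcement for atoms of non-contact frames that lean in
        if config.n_subunits > 0 and len(prot_xyz):
            rad_atoms = np.hypot(tail[..., 0] - cx, tail[..., 1] - cy)
            risky = rad_atoms.min(axis=1) < prot_radius + clearance
            contact_mask = np.zeros(config.n_frames, dtype=bool)
            for pc in contact_by_lig.get(li, []):
                for a, b in pc.intervals:
                    contact_mask |= (times >= a - 1e-9) & (times <= b + 1e-9)
            risky &= ~contact_mask
            for fi in np.flatnonzero(risky):
                pts = np.vstack([o1[fi], o2[fi], c1[fi], tail[fi]])
                d = np.linalg.norm(pts[:, None, :] - prot_xyz[None], axis=-1).min()
                if d < clearance:
                    rel = np.array([o1[fi, 0] - cx, o1[fi, 1] - cy])
                    rel /= max(np.linalg.norm(rel), 1e-9)
                    shift = np.array([*((clearance - d + 1.0) * rel), 0.0])
                    o1[fi] += shift
                    o2[fi] += shift
                    c1[fi] += shift
                    tail[fi] += shift

        hyd = _hydrogen_positions(tail, c1)  # (n_frames, n_tail, 2, 3)
        block = np.concatenate(
            [
                o1[:, None],
                o2[:, None],
                c1[:, None],
                tail,
                hyd.reshape(config.n_frames, -1, 3),
            ],
            axis=1,
        )
        lig_xyz[:, li] = block

    # -- assemble frames
    static = np.array(p_coords + l_coords).reshape(-1, 3) if (p_coords or l_coords) else np.empty((0, 3))
    frames = []
    for fi in range(config.n_frames):
        coords = np.vstack([static, lig_xyz[fi].reshape(-1, 3)])
        frames.append(Frame(time_ns=float(times[fi]), coordinates=coords, box=box.copy()))
    trajectory = Trajectory(topology, frames)

    residence = {
        li: sorted((a, b) for pc in pcs for a, b in pc.intervals)
        for li, pcs in contact_by_lig.items()
    }
    truth = GroundTruth(
        planted_contacts=list(config.planted_contacts),
        planted_D_cm2_s=config.planted_D,
        flexibility=config.flexibility,
        seed=config.seed,
        residence_intervals=residence,
        contact_distance=config.contact_distance,
    )
    return topology, trajectory, truth


def generate_fatty_acid_pair(
    flexibility_sat: float,
    flexibility_poly: float,
    n_frames: int,
    seed: int,
    **kwargs,
):
    """Paired single-ligand membrane patches differing only in tail disorder.

    Emulates simulating one saturated-like and one polyunsaturated-like fatty
    acid in separate lipid patches; the pair shares the seed so contrasts in
    chain descriptors are driven by the flexibility parameter alone.
    Returns ``((topology, trajectory, truth)_sat, (…)_poly)``.
    """
    if not flexibility_sat < flexibility_poly:
        raise ValueError("flexibility_sat must be < flexibility_poly")
    common = dict(
        n_subunits=0,
        n_ligands=1,
        n_lipids=kwargs.pop("n_lipids", 16),
        n_frames=n_frames,
        seed=seed,
        box=kwargs.pop("box", (80.0, 80.0, 80.0)),
        **kwargs,
    )
    sat = generate_system(
        GeneratorConfig(flexibility=flexibility_sat, ligand_resname="DA", **common)
    )
    poly = generate_system(
        GeneratorConfig(flexibility=flexibility_poly, ligand_resname="DHA", **common)
    )
    return sat, poly


def generate_state_pair(
    seed: int,
    head_offset: float = 0.5,
    base_distance: float = 3.0,
    n_frames: int = 200,
    **kwargs,
):
    """Two systems mimicking two conformational states of the protein whose
    planted head-to-residue gap differs by ``head_offset`` Å (one planted
    head contact per subunit, spanning the whole trajectory).

    Returns ``(near_system, far_system)`` where the "near" state's head
    anchors sit ``head_offset`` Å closer to their target residues.
    """
    cfg0 = GeneratorConfig(seed=seed, n_frames=n_frames, **kwargs)
    total = n_frames * cfg0.dt_ns
    # one planted head contact per subunit, on an S4 residue
    s4_start = cfg0.first_resid + sum(
        cfg0.residues_per_region.get(r, 0)
        for r in ("S1", "S1-S2_loop", "S2", "S3", "S3-S4_linker")
    )
    contacts = [
        PlantedContact(chain, s4_start + 2, li, "head", [(0.0, total)])
        for li, chain in enumerate(_chain_letters(cfg0.n_subunits))
    ]
    near = generate_system(
        GeneratorConfig(
            seed=seed,
            n_frames=n_frames,
            planted_contacts=contacts,
            contact_distance=base_distance,
            **kwargs,
        )
    )
    far = generate_system(
        GeneratorConfig(
            seed=seed,
            n_frames=n_frames,
            planted_contacts=[PlantedContact(**asdict(pc)) for pc in contacts],
            contact_distance=base_distance + head_offset,
            **kwargs,
        )
    )
    return near, far
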