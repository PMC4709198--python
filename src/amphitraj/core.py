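"""Core data model: topology, frames, trajectories, periodic geometry.

Internal units are fixed throughout the package: Ångström for lengths and
nanoseconds for times.  Unit conversion happens only at the I/O boundary
(e.g. GRO nanometres, trajectory picosecond timestamps).

Boxes are orthorhombic only; triclinic input is rejected at the reader level.
Atom indices are 0-based; residue ids are taken verbatim from input files so
that region maps can be declared in the author numbering of the structure.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Role",
    "Atom",
    "Topology",
    "Frame",
    "Trajectory",
    "ParseError",
    "TopologyError",
    "minimum_image_displacement",
    "minimum_image_distance",
    "DEFAULT_ROLE_MAP",
    "RESIDUE_CLASSES",
    "residue_class",
    "element_from_name",
]


class ParseError(ValueError):
    """Raised when an input file does not conform to its format."""


class TopologyError(ValueError):
    """Raised for inconsistencies between a topology and dependent data."""


class Role(str, enum.Enum):
    protein = "protein"
    lipid = "lipid"
    ligand = "ligand"
    ion = "ion"
    solvent = "solvent"


#: Residue-name → role dictionary shipped with the package; overridable
#: wherever a reader accepts ``role_map``.
DEFAULT_ROLE_MAP: dict[str, Role] = {
    **{
        name: Role.protein
        for name in (
            "ALA ARG ASN ASP CYS GLN GLU GLY HIS HSD HSE ILE LEU LYS MET "
            "PHE PRO SER THR TRP TYR VAL"
        ).split()
    },
    **{name: Role.lipid for name in ("POPC", "POPE", "POPS", "DPPC", "DOPC", "POP", "PC")},
    **{name: Role.ligand for name in ("DHA", "DA", "LIG", "FA")},
    **{name: Role.ion for name in ("NA", "CL", "SOD", "CLA", "K", "POT", "CA2", "MG")},
    **{name: Role.solvent for name in ("SOL", "HOH", "TIP3", "WAT", "SPC")},
}

#: Three-way chemical partition used to annotate contact tables.  The split
#: follows the usual hydropathy-based convention (aliphatics/aromatics
#: hydrophobic; amides, hydroxyls and histidine polar; Asp/Glu/Lys/Arg
#: charged).
RESIDUE_CLASSES: dict[str, str] = {
    **{n: "hydrophobic" for n in "ALA VAL LEU ILE PHE MET TRP CYS GLY PRO".split()},
    **{n: "polar" for n in "SER THR ASN GLN TYR HIS HSD HSE".split()},
    **{n: "charged" for n in "ARG LYS ASP GLU".split()},
}


def residue_class(residue_name: str) -> str:
    return RESIDUE_CLASSES.get(residue_name.upper(), "other")


def element_from_name(name: str) -> str:
    """Guess an element symbol from an atom name (PDB-style heuristics).

    Leading digits are stripped (``1HB`` → H); two-letter elements common in
    biomolecular systems are recognised before falling back to the first
    alphabetic character.
    """
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        raise ValueError(f"cannot infer element from atom name {name!r}")
    upper = stripped.upper()
    for two in ("CL", "NA", "MG", "BR", "FE", "ZN"):
        if upper.startswith(two) and len(upper) <= 3:
            return two.capitalize()
    return upper[0]


@dataclass(frozen=True)
class Atom:
    index: int
    name: str
    element: str
    residue_id: int
    residue_name: str
    chain_id: str
    role: Role

    def __post_init__(self):
        if not self.element:
            raise ValueError(f"atom {self.index} ({self.name}) has empty element")


class Topology:
    """Ordered atom collection with chain, region, and role structure.

    Parameters
    ----------
    atoms
        Atoms in file order; ``atom.index`` must equal the position.
    region_map
        Mapping of region label (``S1`` … ``S4``, ``S3-S4_linker``,
        ``S1-S2_loop``, ``pore``) to a set of ``(chain_id, residue_id)``.
    extracellular
        Set of ``(chain_id, residue_id)`` lying in the extracellular half of
        their region; typically declared as residue ranges in config.
    """

    def __init__(
        self,
        atoms: Sequence[Atom],
        region_map: Mapping[str, Iterable[tuple[str, int]]] | None = None,
        extracellular: Iterable[tuple[str, int]] | None = None,
    ):
        self.atoms: list[Atom] = list(atoms)
        for i, a in enumerate(self.atoms):
            if a.index != i:
                raise TopologyError(f"atom at position {i} has index {a.index}")
        # columnar views used by every numeric analysis
        self.names = np.array([a.name for a in self.atoms], dtype=object)
        self.elements = np.array([a.element for a in self.atoms], dtype=object)
        self.residue_ids = np.array([a.residue_id for a in self.atoms], dtype=np.int64)
        self.residue_names = np.array([a.residue_name for a in self.atoms], dtype=object)
        self.chain_ids = np.array([a.chain_id for a in self.atoms], dtype=object)
        self.roles = np.array([a.role.value for a in self.atoms], dtype=object)

        known = {(a.chain_id, a.residue_id) for a in self.atoms}
        self.region_map: dict[str, set[tuple[str, int]]] = {}
        for label, members in (region_map or {}).items():
            members = {(str(c), int(r)) for c, r in members}
            missing = members - known
            if missing:
                raise TopologyError(
                    f"region {label!r} references residues absent from topology: "
                    f"{sorted(missing)[:5]}"
                )
            self.region_map[label] = members
        self._check_regions_disjoint()
        self.extracellular: set[tuple[str, int]] = {
            (str(c), int(r)) for c, r in (extracellular or ())
        }

    def _check_regions_disjoint(self) -> None:
        per_chain: dict[str, dict[tuple[str, int], str]] = {}
        for label, members in self.region_map.items():
            for key in members:
                seen = per_chain.setdefault(key[0], {})
                if key in seen:
                    raise TopologyError(
                        f"residue {key} assigned to both regions {seen[key]!r} and {label!r}"
                    )
                seen[key] = label

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def subunits(self) -> dict[str, list[int]]:
        """chain_id → ordered residue ids (first-appearance order)."""
        out: dict[str, list[int]] = {}
        for a in self.atoms:
            lst = out.setdefault(a.chain_id, [])
            if not lst or lst[-1] != a.residue_id:
                if a.residue_id not in lst:
                    lst.append(a.residue_id)
        return out

    def region_of(self, chain_id: str, residue_id: int) -> str:
        for label, members in self.region_map.items():
            if (chain_id, residue_id) in members:
                return label
        return "unassigned"

    def is_extracellular(self, chain_id: str, residue_id: int) -> bool:
        return (chain_id, residue_id) in self.extracellular

    def heavy_mask(self) -> np.ndarray:
        return np.array([e.upper() != "H" for e in self.elements], dtype=bool)

    def with_regions(
        self,
        region_map: Mapping[str, Iterable[tuple[str, int]]],
        extracellular: Iterable[tuple[str, int]] | None = None,
    ) -> "Topology":
        return Topology(self.atoms, region_map=region_map, extracellular=extracellular)


@dataclass
class Frame:
    """One trajectory frame: time (ns), coordinates (Å), orthorhombic box (Å)."""

    time_ns: float
    coordinates: np.ndarray  # (n_atoms, 3) float64, Å
    box: np.ndarray  # (3,) float64, Å

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=np.float64)
        self.box = np.asarray(self.box, dtype=np.float64).reshape(3)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must be (n_atoms, 3)")
        if np.any(self.box <= 0):
            raise ValueError(f"box edges must be positive, got {self.box}")
        if self.time_ns < 0:
            raise ValueError("frame time must be >= 0")


class Trajectory:
    """Time-ordered frames over a fixed topology.

    Coordinates are also exposed as a single ``(n_frames, n_atoms, 3)`` array
    (``.xyz``) because every analysis in the package is vectorised over
    frames.
    """

    def __init__(self, topology: Topology, frames: Sequence[Frame]):
        if not frames:
            raise ValueError("trajectory needs at least one frame")
        n = topology.n_atoms
        for i, f in enumerate(frames):
            if f.coordinates.shape[0] != n:
                raise TopologyError(
                    f"frame {i} has {f.coordinates.shape[0]} atoms, topology has {n}"
                )
        times = np.array([f.time_ns for f in frames], dtype=np.float64)
        if np.any(np.diff(times) <= 0):
            raise ValueError("frame times must be strictly increasing")
        self.topology = topology
        self.frames = list(frames)
        self.times = times
        self.xyz = np.stack([f.coordinates for f in frames])
        self.boxes = np.stack([f.box for f in frames])

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def dt_ns(self) -> float:
        """Nominal frame spacing (first interval; 0.0 for single frames)."""
        if self.n_frames < 2:
            return 0.0
        return float(self.times[1] - self.times[0])

    def frame_durations(self) -> np.ndarray:
        """Per-frame time weight: interval to the next frame; the last frame
        carries the preceding interval. Sums to n·dt on a uniform grid."""
        if self.n_frames == 1:
            return np.array([0.0])
        d = np.diff(self.times)
        return np.concatenate([d, d[-1:]])

    @property
    def total_time_ns(self) -> float:
        return float(self.frame_durations().sum())


def minimum_image_displacement(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Displacement a−b wrapped into the primary orthorhombic image.

    Broadcasts over leading axes; ``box`` edges must be positive.
    """
    box = np.asarray(box, dtype=np.float64)
    if np.any(box <= 0):
        raise ValueError("box edges must be positive")
    d = np.asarray(a, dtype=np.float64) - np.asarray(b, dtype=np.float64)
    return d - box * np.round(d / box)


def minimum_image_distance(a, b, box) -> np.ndarray | float:
    """Minimum-image Euclidean distance between points ``a`` and ``b`` (Å)."""
    d = minimum_image_displacement(a, b, box)
    out = np.sqrt(np.sum(d * d, axis=-1))
    return float(out) if out.ndim == 0 else out
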