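"""Structure and trajectory I/O.

PDB/GRO structures and XTC/DCD/TRR trajectories are read and written through
MDAnalysis; this module converts to the package's own data model (Å, ns,
orthorhombic boxes) and assigns roles from a residue-name dictionary.

A plain-text trajectory dialect is provided for human-readable fixtures::

    t=<time ns> box=<lx> <ly> <lz>
    <x> <y> <z>          # one line per atom, Å
    ...                  # repeated per frame

The dialect carries no atom metadata; a topology must be supplied on read.
"""

from __future__ import annotations

import os
import warnings
from typing import Mapping, Sequence

import numpy as np

from .core import (
    DEFAULT_ROLE_MAP,
    Atom,
    Frame,
    ParseError,
    Role,
    Topology,
    TopologyError,
    Trajectory,
    element_from_name,
)

__all__ = [
    "read_structure",
    "read_trajectory",
    "write_structure",
    "write_trajectory",
]

_PS_PER_NS = 1000.0


def _role_for(resname: str, role_map: Mapping[str, Role]) -> Role:
    role = role_map.get(resname.upper())
    if role is None:
        warnings.warn(
            f"unknown residue name {resname!r}: assigning role 'ligand'",
            stacklevel=3,
        )
        return Role.ligand
    return Role(role)


def _check_orthorhombic(dimensions, path) -> np.ndarray:
    if dimensions is None or np.all(np.asarray(dimensions)[:3] == 0):
        raise ParseError(f"{path}: no periodic box information")
    dims = np.asarray(dimensions, dtype=np.float64)
    angles = dims[3:6] if dims.size >= 6 else np.array([90.0, 90.0, 90.0])
    if not np.allclose(angles, 90.0, atol=1e-3):
        raise ParseError(
            f"{path}: triclinic box (angles {angles}); only orthorhombic boxes "
            "are supported"
        )
    return dims[:3].copy()


def read_structure(
    path: str | os.PathLike,
    format: str | None = None,
    role_map: Mapping[str, Role] | None = None,
) -> tuple[Topology, Frame]:
    """Read a PDB or GRO structure into a Topology and a coordinate Frame.

    Coordinates are returned in Å (GRO nanometres are converted by the
    reader).  The frame box falls back to a generous bounding box when the
    file records none (common for hand-written PDB fixtures).
    """
    import MDAnalysis as mda

    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    fmt = (format or os.path.splitext(path)[1].lstrip(".")).upper()
    if fmt not in ("PDB", "GRO"):
        raise ValueError(f"unsupported structure format {fmt!r} (PDB or GRO)")
    role_map = {k.upper(): Role(v) for k, v in (role_map or DEFAULT_ROLE_MAP).items()}

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            u = mda.Universe(path, format=fmt)
        except Exception as exc:  # MDAnalysis raises assorted exception types
            raise ParseError(f"{path}: failed to parse as {fmt}: {exc}") from exc

    ag = u.atoms
    n = len(ag)
    names = [str(x) for x in ag.names]
    if hasattr(ag, "chainIDs"):
        chains = [str(c) if str(c).strip() else "A" for c in ag.chainIDs]
    elif hasattr(ag, "segids"):
        chains = [str(c) if str(c).strip() and str(c) != "SYSTEM" else "A" for c in ag.segids]
    else:
        chains = ["A"] * n
    resids = [int(r) for r in ag.resids]
    resnames = [str(r) for r in ag.resnames]

    atoms = [
        Atom(
            index=i,
            name=names[i],
            element=element_from_name(names[i]),
            residue_id=resids[i],
            residue_name=resnames[i],
            chain_id=chains[i],
            role=_role_for(resnames[i], role_map),
        )
        for i in range(n)
    ]
    topology = Topology(atoms)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        coords = np.asarray(ag.positions, dtype=np.float64)  # MDAnalysis: Å
        dims = u.dimensions
        time_ns = float(getattr(u.trajectory.ts, "time", 0.0) or 0.0) / _PS_PER_NS
    if dims is None or np.all(np.asarray(dims)[:3] == 0):
        # no box record (common in hand-written fixtures): generous fallback
        span = coords.max(axis=0) - coords.min(axis=0) + 100.0
        box = np.maximum(span, 100.0)
    else:
        box = _check_orthorhombic(dims, path)
    return topology, Frame(time_ns=max(time_ns, 0.0), coordinates=coords, box=box)


def read_trajectory(
    path: str | os.PathLike,
    topology: Topology,
    format: str | None = None,
    dt_ns: float = 1.0,
) -> Trajectory:
    """Read XTC/DCD/TRR (via MDAnalysis) or the plaintext dialect.

    ``dt_ns`` supplies frame spacing for formats whose timestamps are absent
    or degenerate (typical of DCD files written without time metadata).
    """
    path = os.fspath(path)
    fmt = (format or os.path.splitext(path)[1].lstrip(".")).upper()
    if fmt in ("TXT", "PLAINTEXT", "AMPHITXT"):
        return _read_plaintext(path, topology)
    if fmt not in ("XTC", "DCD", "TRR"):
        raise ValueError(f"unsupported trajectory format {fmt!r}")

    import MDAnalysis as mda
    from MDAnalysis.coordinates.core import reader  # noqa: F401  (format registry)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(topology.n_atoms, trajectory=True)
        try:
            u.load_new(path, format=fmt)
        except Exception as exc:
            raise ParseError(f"{path}: failed to read {fmt} trajectory: {exc}") from exc
        if u.trajectory.n_atoms != topology.n_atoms:
            raise TopologyError(
                f"{path}: trajectory has {u.trajectory.n_atoms} atoms, "
                f"topology has {topology.n_atoms}"
            )
        frames = []
        times = []
        for ts in u.trajectory:
            box = _check_orthorhombic(ts.dimensions, path)
            frames.append((np.asarray(ts.positions, dtype=np.float64), box))
            times.append(float(ts.time) / _PS_PER_NS)
    times = np.asarray(times)
    if fmt == "DCD" or (len(times) > 1 and np.any(np.diff(times) <= 0)):
        # DCD time metadata is unreliable; rebuild a uniform grid
        times = np.arange(len(times), dtype=np.float64) * dt_ns
    return Trajectory(
        topology,
        [Frame(time_ns=t, coordinates=c, box=b) for t, (c, b) in zip(times, frames)],
    )


def _read_plaintext(path: str, topology: Topology) -> Trajectory:
    frames: list[Frame] = []
    n = topology.n_atoms
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.startswith("t="):
            raise ParseError(f"{path}:{i + 1}: expected frame header 't=... box=...'")
        try:
            t_part, box_part = line.split("box=")
            time_ns = float(t_part.split("=")[1])
            box = np.array([float(x) for x in box_part.split()], dtype=np.float64)
            if box.size != 3:
                raise ValueError
        except ValueError as exc:
            raise ParseError(f"{path}:{i + 1}: malformed frame header {line!r}") from exc
        coords = np.empty((n, 3))
        if len(lines) - (i + 1) < n:
            raise ParseError(f"{path}:{i + 1}: truncated frame (need {n} atom lines)")
        for j in range(n):
            row = lines[i + 1 + j].split()
            if len(row) != 3:
                raise ParseError(f"{path}:{i + 2 + j}: expected 'x y z'")
            coords[j] = [float(v) for v in row]
        frames.append(Frame(time_ns=time_ns, coordinates=coords, box=box))
        i += 1 + n
    if not frames:
        raise ParseError(f"{path}: no frames found")
    if np.any(np.diff([f.time_ns for f in frames]) <= 0):
        raise ParseError(f"{path}: frame times not strictly increasing")
    return Trajectory(topology, frames)


def write_structure(
    path: str | os.PathLike,
    topology: Topology,
    frame: Frame,
) -> None:
    """Write a PDB structure file (via MDAnalysis)."""
    import MDAnalysis as mda

    n = topology.n_atoms
    n_res_keys: list[tuple[str, int]] = []
    res_index = np.empty(n, dtype=np.int64)
    for i, a in enumerate(topology.atoms):
        key = (a.chain_id, a.residue_id)
        if not n_res_keys or n_res_keys[-1] != key:
            n_res_keys.append(key)
        res_index[i] = len(n_res_keys) - 1
    n_res = len(n_res_keys)
    seg_ids = sorted({c for c, _ in n_res_keys})
    seg_index = np.array([seg_ids.index(c) for c, _ in n_res_keys])

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(
            n,
            n_residues=n_res,
            n_segments=len(seg_ids),
            atom_resindex=res_index,
            residue_segindex=seg_index,
            trajectory=True,
        )
        u.add_TopologyAttr("names", [a.name for a in topology.atoms])
        u.add_TopologyAttr("elements", [a.element for a in topology.atoms])
        first_atom = {}
        for i, a in enumerate(topology.atoms):
            first_atom.setdefault((a.chain_id, a.residue_id), a)
        res_atoms = [first_atom[k] for k in n_res_keys]
        u.add_TopologyAttr("resnames", [a.residue_name for a in res_atoms])
        u.add_TopologyAttr("resids", [a.residue_id for a in res_atoms])
        u.add_TopologyAttr("chainIDs", [a.chain_id for a in topology.atoms])
        u.add_TopologyAttr("segids", seg_ids)
        u.atoms.positions = np.asarray(frame.coordinates, dtype=np.float32)
        u.dimensions = np.array([*frame.box, 90.0, 90.0, 90.0], dtype=np.float32)
        u.atoms.write(os.fspath(path))


def write_trajectory(
    path: str | os.PathLike,
    trajectory: Trajectory,
    format: str | None = None,
) -> None:
    """Write a trajectory in the plaintext dialect or DCD/XTC/TRR."""
    path = os.fspath(path)
    fmt = (format or os.path.splitext(path)[1].lstrip(".")).upper()
    if fmt in ("TXT", "PLAINTEXT", "AMPHITXT"):
        with open(path, "w") as fh:
            for f in trajectory.frames:
                fh.write(
                    f"t={f.time_ns:.9g} box={f.box[0]:.9g} {f.box[1]:.9g} {f.box[2]:.9g}\n"
                )
                np.savetxt(fh, f.coordinates, fmt="%.9g")
        return
    if fmt not in ("DCD", "XTC", "TRR"):
        raise ValueError(f"unsupported trajectory format {fmt!r}")

    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        n = trajectory.topology.n_atoms
        u = mda.Universe.empty(n, trajectory=True)
        with mda.Writer(path, n_atoms=n, format=fmt) as w:
            for f in trajectory.frames:
                u.atoms.positions = np.asarray(f.coordinates, dtype=np.float32)
                u.dimensions = np.array([*f.box, 90.0, 90.0, 90.0], dtype=np.float32)
                u.trajectory.ts.time = f.time_ns * _PS_PER_NS
                w.write(u.atoms)
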