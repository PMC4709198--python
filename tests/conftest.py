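import numpy as np
import pytest

from amphitraj.core import Atom, Frame, Role, Topology, Trajectory
from amphitraj.schema import default_fatty_acid_schema
from amphitraj.synthetic import GeneratorConfig, PlantedContact, generate_system


@pytest.fixture(scope="session")
def schema22():
    return default_fatty_acid_schema(22)


@pytest.fixture(scope="session")
def small_system():
    """Tetramer + lipids + 4 ligands, 50 frames, no planted contacts."""
    return generate_system(GeneratorConfig(n_frames=50, n_ligands=4, seed=42))


@pytest.fixture(scope="session")
def planted_system():
    """100-frame system with three planted contacts (two above, one below a
    30 ns persistence threshold)."""
    contacts = [
        PlantedContact("A", 318, 0, "tail", [(0.0, 60.0)]),
        PlantedContact("B", 327, 1, "head", [(10.0, 80.0)]),
        PlantedContact("C", 305, 2, "head", [(0.0, 20.0)]),
    ]
    cfg = GeneratorConfig(n_frames=100, planted_contacts=contacts, seed=5)
    return generate_system(cfg), contacts


def make_topology(spec):
    """Build a Topology from (name, resid, resname, chain, role) tuples."""
    atoms = [
        Atom(i, name, name[0], resid, resname, chain, Role(role))
        for i, (name, resid, resname, chain, role) in enumerate(spec)
    ]
    return Topology(atoms)


def make_trajectory(topology, coords_per_frame, box=(100.0, 100.0, 100.0), dt=1.0):
    frames = [
        Frame(time_ns=i * dt, coordinates=np.asarray(c, dtype=float), box=np.asarray(box))
        for i, c in enumerate(coords_per_frame)
    ]
    return Trajectory(topology, frames)
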