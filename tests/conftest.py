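import numpy as np
import pytest

from porescope.model_io import Atom, Frame, MolecularSystem, Trajectory
from porescope.pore_frame import PoreFrame


def make_atoms(n, name="X", element="C", residue="RES"):
    return [Atom(i + 1, name, element, residue, i + 1) for i in range(n)]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def single_particle_traj(z_values, dt_ns=0.1, x=0.0, y=0.0):
    """Trajectory of one fixed center atom (index 0) and one tracked particle
    (index 1) whose z follows ``z_values``."""
    atoms = [
        Atom(1, "CEN", "C", "CEN", 1),
        Atom(2, "P", "P", "PO4", 2, role_tags=frozenset({"phosphorus_terminal"})),
    ]
    system = MolecularSystem(atoms)
    frames = [
        Frame(k * dt_ns, np.array([[0.0, 0.0, 0.0], [x, y, float(z)]]))
        for k, z in enumerate(z_values)
    ]
    return Trajectory(system, frames, dt_ns)


def center_pore(traj_or_system, **kwargs):
    return PoreFrame((0,), **kwargs)
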