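"""Pore-axis reaction coordinate and slab decomposition.

The axial coordinate z of a tracked particle is the signed projection of
(particle - center) onto the pore axis, where the center is the geometric
mean of designated backbone-carbon atoms and z > 0 points to the cytosolic
side.  All profiles and event detectors bin this coordinate into half-open
slabs [lo, hi).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_io import Frame, MolecularSystem, Trajectory

__all__ = [
    "PoreFrame",
    "default_slab_edges",
    "pore_center",
    "z_of",
    "z_series",
    "radial_distance",
    "slab_index",
]

#: default axial extent of the binned region, in angstroms
Z_RANGE_DEFAULT = (-22.0, 22.0)


def default_slab_edges(slab_width_A: float = 1.0,
                       z_range: tuple = Z_RANGE_DEFAULT) -> np.ndarray:
    lo, hi = z_range
    n = int(round((hi - lo) / slab_width_A))
    return lo + slab_width_A * np.arange(n + 1)


@dataclass
class PoreFrame:
    """Reference frame of the pore: center selection, axis, slab grid."""

    center_atom_indices: tuple
    axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    pore_half_length_A: float = 15.0
    slab_edges_A: np.ndarray = field(default_factory=default_slab_edges)

    def __post_init__(self) -> None:
        self.center_atom_indices = tuple(self.center_atom_indices)
        if not self.center_atom_indices:
            raise ValueError("center atom selection is empty")
        self.axis = np.asarray(self.axis, dtype=float)
        norm = np.linalg.norm(self.axis)
        if norm == 0:
            raise ValueError("axis must be nonzero")
        self.axis = self.axis / norm
        self.slab_edges_A = np.asarray(self.slab_edges_A, dtype=float)
        if np.any(np.diff(self.slab_edges_A) <= 0):
            raise ValueError("slab edges must be strictly increasing")

    @classmethod
    def from_reference_residues(
        cls,
        system: MolecularSystem,
        residue_numbers,
        backbone_atoms: str = "CA,C",
        **kwargs,
    ) -> "PoreFrame":
        """Build from reference residue numbers using their backbone carbons
        (``backbone_atoms``: "CA,C" for both, "CA" for alpha carbons only)."""
        names = [s.strip() for s in backbone_atoms.split(",")]
        idxs = system.select(residue_numbers, names)
        if not idxs:
            raise ValueError(
                f"no atoms named {names} found in residues {list(residue_numbers)}"
            )
        return cls(tuple(idxs), **kwargs)


def pore_center(frame: Frame, pore: PoreFrame) -> np.ndarray:
    """Arithmetic mean of the center-selection atom coordinates."""
    return frame.coords[list(pore.center_atom_indices)].mean(axis=0)


def z_of(frame: Frame, pore: PoreFrame, particle_atom_index: int) -> float:
    """Signed axial coordinate of one atom, in angstroms."""
    delta = frame.coords[particle_atom_index] - pore_center(frame, pore)
    return float(np.dot(delta, pore.axis))


def z_series(traj: Trajectory, pore: PoreFrame, particle_atom_index: int) -> np.ndarray:
    return np.array([z_of(f, pore, particle_atom_index) for f in traj.frames])


def radial_distance(frame: Frame, pore: PoreFrame, atom_indices) -> np.ndarray:
    """Distance of atoms from the pore axis (perpendicular component)."""
    center = pore_center(frame, pore)
    delta = frame.coords[np.asarray(atom_indices, dtype=int)] - center
    axial = delta @ pore.axis
    perp = delta - np.outer(axial, pore.axis)
    return np.linalg.norm(perp, axis=1)


def slab_index(z: float, slab_edges) -> int | None:
    """Half-open binning [edge_i, edge_{i+1}); ties go to the upper bin.
    Returns None outside the grid."""
    edges = np.asarray(slab_edges, dtype=float)
    i = int(np.searchsorted(edges, z, side="right")) - 1
    if i < 0 or i >= len(edges) - 1:
        return None
    return i
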