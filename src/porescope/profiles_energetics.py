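"""Slice-averaged profiles along the pore axis and Boltzmann-inversion energetics.

Profiles are computed on a fixed half-open slab grid (default [-22, 22] A).
The free-energy profile is the Boltzmann inversion
``dG(z) = -RT ln(C(z) / C_bulk)`` of a concentration profile; bins that were
never visited carry ``None`` rather than a fabricated barrier height.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model_io import Trajectory
from .pore_frame import PoreFrame, default_slab_edges, pore_center, slab_index, z_series

__all__ = [
    "ZProfile",
    "Thermo",
    "SelectivityResult",
    "occupancy_histogram",
    "interaction_profile",
    "pairing_profile",
    "concentration_profile",
    "free_energy_profile",
    "estimate_bulk_concentration",
    "block_standard_error",
    "selectivity_ratio",
]

#: gas constant in kcal/(mol K)
R_KCAL_PER_MOL_K = 0.0019872041

QUANTITIES = (
    "occupancy_fraction",
    "n_int",
    "n_pairing",
    "concentration",
    "free_energy_kcal",
)


@dataclass
class ZProfile:
    """A binned quantity along z. ``values`` may contain None for empty bins."""

    bin_edges_A: np.ndarray
    values: list
    se: list | None
    n_samples: np.ndarray
    quantity: str

    def __post_init__(self) -> None:
        self.bin_edges_A = np.asarray(self.bin_edges_A, dtype=float)
        self.values = list(self.values)
        self.n_samples = np.asarray(self.n_samples, dtype=int)
        if self.quantity not in QUANTITIES:
            raise ValueError(f"unknown quantity {self.quantity!r}")
        nbins = len(self.bin_edges_A) - 1
        if len(self.values) != nbins or len(self.n_samples) != nbins:
            raise ValueError("values/n_samples length must equal number of bins")
        if self.se is not None and len(self.se) != nbins:
            raise ValueError("se length must equal number of bins")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_A[:-1] + self.bin_edges_A[1:])


@dataclass(frozen=True)
class Thermo:
    """Temperature and the derived RT in kcal/mol."""

    temperature_K: float = 300.0

    def __post_init__(self) -> None:
        if self.temperature_K <= 0:
            raise ValueError("temperature must be positive")

    @property
    def RT_kcal(self) -> float:
        return R_KCAL_PER_MOL_K * self.temperature_K


@dataclass(frozen=True)
class SelectivityResult:
    n_anion_avg: float
    n_cation_avg: float
    ratio: float
    pore_region: str


# ---------------------------------------------------------------------------

def _z_and_bins(traj: Trajectory, atom_index: int, pore: PoreFrame,
                slab_width_A: float):
    edges = default_slab_edges(slab_width_A,
                               (pore.slab_edges_A[0], pore.slab_edges_A[-1]))
    zs = z_series(traj, pore, atom_index)
    bins = [slab_index(z, edges) for z in zs]
    return edges, zs, bins


def occupancy_histogram(traj: Trajectory, tracked_atom: int, pore: PoreFrame,
                        slab_width_A: float = 1.0) -> ZProfile:
    """Fraction of snapshots with the tracked atom's z in each slab."""
    if traj.n_frames == 0:
        raise ValueError("trajectory has no frames")
    edges, _, bins = _z_and_bins(traj, tracked_atom, pore, slab_width_A)
    counts = np.zeros(len(edges) - 1, dtype=int)
    for b in bins:
        if b is not None:
            counts[b] += 1
    values = (counts / traj.n_frames).tolist()
    return ZProfile(edges, values, None, counts, "occupancy_fraction")


def interaction_profile(traj: Trajectory, contact_records, residue_id: str,
                        tracked_atom: int, pore: PoreFrame,
                        slab_width_A: float = 1.0,
                        criterion: str | None = None) -> ZProfile:
    """N_int: fraction of in-slab snapshots in which the contact with
    ``residue_id`` is formed, per slab.  Unvisited slabs carry None."""
    edges, _, bins = _z_and_bins(traj, tracked_atom, pore, slab_width_A)
    contact_frames = {
        r.frame_index
        for r in contact_records
        if r.partner_b == residue_id and (criterion is None or r.criterion == criterion)
    }
    nbins = len(edges) - 1
    visited = np.zeros(nbins, dtype=int)
    formed = np.zeros(nbins, dtype=int)
    for k, b in enumerate(bins):
        if b is None:
            continue
        visited[b] += 1
        if k in contact_frames:
            formed[b] += 1
    values = [formed[i] / visited[i] if visited[i] > 0 else None for i in range(nbins)]
    return ZProfile(edges, values, None, visited, "n_int")


def pairing_profile(traj: Trajectory, cation_pairing_records, tracked_atom: int,
                    pore: PoreFrame, slab_width_A: float = 1.0) -> ZProfile:
    """Mean number of distinct simultaneously paired cations, per slab."""
    edges, _, bins = _z_and_bins(traj, tracked_atom, pore, slab_width_A)
    paired_by_frame: dict = {}
    for r in cation_pairing_records:
        paired_by_frame.setdefault(r.frame_index, set()).add(r.partner_b)
    nbins = len(edges) - 1
    visited = np.zeros(nbins, dtype=int)
    total = np.zeros(nbins, dtype=float)
    for k, b in enumerate(bins):
        if b is None:
            continue
        visited[b] += 1
        total[b] += len(paired_by_frame.get(k, ()))
    values = [total[i] / visited[i] if visited[i] > 0 else None for i in range(nbins)]
    return ZProfile(edges, values, None, visited, "n_pairing")


def concentration_profile(traj: Trajectory, species_atoms: Sequence[int],
                          pore: PoreFrame, slab_width_A: float = 1.0,
                          radial_cutoff_A: float = 12.0) -> ZProfile:
    """Time-averaged number density (atoms/A^3) in cylindrical slabs of the
    given radius around the pore axis."""
    if radial_cutoff_A <= 0:
        raise ValueError("radial cutoff must be positive")
    edges = default_slab_edges(slab_width_A,
                               (pore.slab_edges_A[0], pore.slab_edges_A[-1]))
    nbins = len(edges) - 1
    counts = np.zeros(nbins, dtype=float)
    idx = np.asarray(list(species_atoms), dtype=int)
    axis = pore.axis
    for f in traj.frames:
        center = pore_center(f, pore)
        delta = f.coords[idx] - center
        zvals = delta @ axis
        perp = delta - np.outer(zvals, axis)
        rad = np.linalg.norm(perp, axis=1)
        inside = rad < radial_cutoff_A
        for z in zvals[inside]:
            b = slab_index(float(z), edges)
            if b is not None:
                counts[b] += 1
    slab_volume = math.pi * radial_cutoff_A**2 * slab_width_A
    n_samples = counts.astype(int)
    values = (counts / traj.n_frames / slab_volume).tolist()
    return ZProfile(edges, values, None, n_samples, "concentration")


def free_energy_profile(conc_profile: ZProfile, c_bulk: float,
                        thermo: Thermo = Thermo()) -> ZProfile:
    """Boltzmann inversion of a concentration profile, in kcal/mol.

    Bins with zero concentration map to None (an unresolved, effectively
    infinite barrier) instead of a clipped number.
    """
    if c_bulk <= 0:
        raise ValueError("bulk concentration must be positive")
    if conc_profile.quantity != "concentration":
        raise ValueError("input must be a concentration profile")
    rt = thermo.RT_kcal
    values = []
    se = None
    if conc_profile.se is not None:
        se = []
    for i, c in enumerate(conc_profile.values):
        if c is None or c <= 0:
            values.append(None)
            if se is not None:
                se.append(None)
            continue
        values.append(-rt * math.log(c / c_bulk))
        if se is not None:
            s = conc_profile.se[i]
            se.append(None if s is None else rt * s / c)
    return ZProfile(conc_profile.bin_edges_A, values, se,
                    conc_profile.n_samples, "free_energy_kcal")


def estimate_bulk_concentration(traj: Trajectory, species_atoms: Sequence[int],
                                pore: PoreFrame, bulk_z_range: tuple,
                                radial_cutoff_A: float = 12.0) -> float:
    """Time-averaged species density (atoms/A^3) in the designated bulk
    cylinder slice ``bulk_z_range`` = (z_lo, z_hi)."""
    z_lo, z_hi = bulk_z_range
    if z_hi <= z_lo or radial_cutoff_A <= 0:
        raise ValueError("bulk region has zero volume")
    idx = np.asarray(list(species_atoms), dtype=int)
    axis = pore.axis
    total = 0
    for f in traj.frames:
        center = pore_center(f, pore)
        delta = f.coords[idx] - center
        zvals = delta @ axis
        perp = delta - np.outer(zvals, axis)
        rad = np.linalg.norm(perp, axis=1)
        total += int(np.sum((zvals >= z_lo) & (zvals < z_hi) & (rad < radial_cutoff_A)))
    volume = math.pi * radial_cutoff_A**2 * (z_hi - z_lo)
    return total / traj.n_frames / volume


def block_standard_error(per_frame_series: Sequence[float], n_blocks: int):
    """(mean of block means, SE) over contiguous near-equal blocks."""
    series = np.asarray(per_frame_series, dtype=float)
    if n_blocks < 2:
        raise ValueError("need at least 2 blocks")
    if len(series) < n_blocks:
        raise ValueError(f"series of length {len(series)} shorter than {n_blocks} blocks")
    blocks = np.array_split(series, n_blocks)
    means = np.array([b.mean() for b in blocks])
    return float(means.mean()), float(means.std(ddof=1) / math.sqrt(n_blocks))


def selectivity_ratio(traj: Trajectory, anion_atoms: Sequence[int],
                      cation_atoms: Sequence[int], pore: PoreFrame,
                      z_max_A: float = 15.0,
                      radial_cutoff_A: float = 12.0) -> SelectivityResult:
    """Ratio of time-averaged simultaneous pore occupancies, anions/cations.

    The pore region is the cylinder |z| <= z_max_A, radius radial_cutoff_A.
    """
    axis = pore.axis

    def mean_occupancy(idx_list) -> float:
        idx = np.asarray(list(idx_list), dtype=int)
        if idx.size == 0:
            return 0.0
        total = 0
        for f in traj.frames:
            center = pore_center(f, pore)
            delta = f.coords[idx] - center
            zvals = delta @ axis
            perp = delta - np.outer(zvals, axis)
            rad = np.linalg.norm(perp, axis=1)
            total += int(np.sum((np.abs(zvals) <= z_max_A) & (rad < radial_cutoff_A)))
        return total / traj.n_frames

    n_anion = mean_occupancy(anion_atoms)
    n_cation = mean_occupancy(cation_atoms)
    if n_cation == 0:
        raise ValueError("time-averaged cation occupancy is zero; ratio undefined")
    return SelectivityResult(
        n_anion, n_cation, n_anion / n_cation,
        f"|z| <= {z_max_A} A, r < {radial_cutoff_A} A",
    )
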