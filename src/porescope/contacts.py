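"""Geometric interaction criteria and contact-lifetime classification.

Six detectors are provided, each mirroring one literal distance/angle rule:

========================  ========================================================
electrostatic             phosphate O to Lys/Arg side-chain N, <= 4.0 A (inclusive)
cation_pairing            phosphate O to cation, < 4.0 A (strict)
pi_pi                     ring-center distance < 6 A and inter-plane angle < 30 deg
cation_pi                 ring center to side-chain N < 6 A and NH-vector/plane
                          angle > 60 deg
guanidinium_stack         ring center to guanidinium center < 6 A and inter-plane
                          angle < 30 deg
hbond                     donor-heavy to acceptor < 3.5 A and D-H-A angle > 120 deg
========================  ========================================================

All plane/plane and vector/plane angles are folded into [0, 90] degrees.
Boundary inclusivity follows the wording of each rule and is fixed in
:class:`InteractionCriteria`.  Distances use the minimum-image convention
whenever the frame carries an orthorhombic box.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .model_io import Frame

__all__ = [
    "InteractionCriteria",
    "ContactRecord",
    "ContactTimeline",
    "LifetimeStats",
    "pair_distances",
    "ring_plane",
    "detect_electrostatic",
    "detect_cation_pairing",
    "detect_pi_pi",
    "detect_cation_pi",
    "detect_guanidinium_stack",
    "detect_hbond",
    "build_timelines",
    "classify_longlived",
]

CRITERIA_NAMES = (
    "electrostatic",
    "cation_pairing",
    "pi_pi",
    "cation_pi",
    "guanidinium_stack",
    "hbond",
)


@dataclass(frozen=True)
class InteractionCriteria:
    """Distance/angle thresholds; inclusivity is part of the contract.

    ``electrostatic_max_A`` is the only inclusive bound ("or less"); every
    other comparison is strict.
    """

    electrostatic_max_A: float = 4.0          # inclusive
    pairing_max_A: float = 4.0                # strict
    pipi_max_A: float = 6.0                   # strict
    pipi_max_angle_deg: float = 30.0          # strict
    cationpi_max_A: float = 6.0               # strict
    cationpi_min_angle_deg: float = 60.0      # strict
    guanidinium_stack_max_angle_deg: float = 30.0  # strict
    hbond_heavy_max_A: float = 3.5            # strict
    hbond_min_angle_deg: float = 120.0        # strict
    longlived_min_ns: float = 5.0             # strict

    def __post_init__(self) -> None:
        for name in (
            "electrostatic_max_A",
            "pairing_max_A",
            "pipi_max_A",
            "cationpi_max_A",
            "hbond_heavy_max_A",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in (
            "pipi_max_angle_deg",
            "cationpi_min_angle_deg",
            "guanidinium_stack_max_angle_deg",
            "hbond_min_angle_deg",
        ):
            a = getattr(self, name)
            if not 0 < a < 180:
                raise ValueError(f"{name} must lie in (0, 180)")


@dataclass(frozen=True)
class ContactRecord:
    frame_index: int
    criterion: str
    partner_a: str
    partner_b: str
    distance_A: float
    angle_deg: float | None = None


# ---------------------------------------------------------------------------
# geometry helpers

def _displacement(a: np.ndarray, b: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    d = b - a
    if box is not None:
        d = d - box * np.round(d / box)
    return d


def pair_distances(coords_a: np.ndarray, coords_b: np.ndarray,
                   box: np.ndarray | None = None) -> np.ndarray:
    """All pairwise distances (n_a, n_b), minimum image if a box is given."""
    d = coords_b[None, :, :] - coords_a[:, None, :]
    if box is not None:
        d = d - box * np.round(d / box)
    return np.linalg.norm(d, axis=-1)


def _folded_angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    """Angle between two directions folded into [0, 90] degrees."""
    c = abs(float(np.dot(u, v)) / (np.linalg.norm(u) * np.linalg.norm(v)))
    return math.degrees(math.acos(min(1.0, c)))


def ring_plane(frame: Frame, ring_triplet: Sequence[int],
               masses: Sequence[float] | None = None):
    """(center, unit normal) of the plane through three ring atoms.

    Center is the mass-weighted mean (equal masses by default); normal is
    the unit cross product of the two edge vectors.
    """
    idx = list(ring_triplet)
    if len(idx) != 3:
        raise ValueError("ring triplet must contain exactly 3 atoms")
    p = frame.coords[idx]
    if masses is None:
        center = p.mean(axis=0)
    else:
        m = np.asarray(masses, dtype=float)
        center = (p * m[:, None]).sum(axis=0) / m.sum()
    n = np.cross(p[1] - p[0], p[2] - p[0])
    norm = np.linalg.norm(n)
    if norm < 1e-8:
        raise ValueError("collinear ring atoms: plane undefined")
    return center, n / norm


def _as_groups(sel) -> dict:
    """Normalize a selection to {group_id: [atom indices]}."""
    if isinstance(sel, Mapping):
        return {str(k): list(v) for k, v in sel.items()}
    return {"group": list(sel)}


# ---------------------------------------------------------------------------
# detectors

def detect_electrostatic(frame: Frame, phosphate_oxygens, basic_nitrogens,
                         criteria: InteractionCriteria = InteractionCriteria(),
                         frame_index: int = 0) -> list:
    """One record per (ligand group, residue) whose minimal O-N distance is
    <= the inclusive electrostatic cutoff."""
    ogroups = _as_groups(phosphate_oxygens)
    ngroups = _as_groups(basic_nitrogens)
    if not ogroups or any(not v for v in ogroups.values()):
        raise ValueError("empty phosphate-oxygen selection")
    if not ngroups or any(not v for v in ngroups.values()):
        raise ValueError("empty nitrogen selection")
    out = []
    for lig, oidx in ogroups.items():
        for res, nidx in ngroups.items():
            dmin = pair_distances(frame.coords[oidx], frame.coords[nidx], frame.box).min()
            if dmin <= criteria.electrostatic_max_A:
                out.append(ContactRecord(frame_index, "electrostatic", lig, res, float(dmin)))
    return out


def detect_cation_pairing(frame: Frame, phosphate_oxygens, cations,
                          criteria: InteractionCriteria = InteractionCriteria(),
                          frame_index: int = 0) -> list:
    """One record per (phosphate group, cation) with min O-cation distance
    strictly below the pairing cutoff."""
    ogroups = _as_groups(phosphate_oxygens)
    if isinstance(cations, Mapping):
        cats = {str(k): int(v) for k, v in cations.items()}
    else:
        cats = {f"cation{j}": int(i) for j, i in enumerate(cations)}
    if not ogroups or any(not v for v in ogroups.values()):
        raise ValueError("empty phosphate-oxygen selection")
    if not cats:
        raise ValueError("empty cation selection")
    out = []
    for lig, oidx in ogroups.items():
        ocoords = frame.coords[oidx]
        for cid, ci in cats.items():
            dmin = pair_distances(ocoords, frame.coords[[ci]], frame.box).min()
            if dmin < criteria.pairing_max_A:
                out.append(ContactRecord(frame_index, "cation_pairing", lig, cid, float(dmin)))
    return out


def detect_pi_pi(frame: Frame, ring_a_triplet, ring_b_triplet,
                 criteria: InteractionCriteria = InteractionCriteria(),
                 frame_index: int = 0, partner_a: str = "ring_a",
                 partner_b: str = "ring_b"):
    ca, na = ring_plane(frame, ring_a_triplet)
    cb, nb = ring_plane(frame, ring_b_triplet)
    dist = float(np.linalg.norm(_displacement(ca, cb, frame.box)))
    angle = _folded_angle_deg(na, nb)
    if dist < criteria.pipi_max_A and angle < criteria.pipi_max_angle_deg:
        return ContactRecord(frame_index, "pi_pi", partner_a, partner_b, dist, angle)
    return None


def detect_cation_pi(frame: Frame, ring_triplet, nh_pairs,
                     criteria: InteractionCriteria = InteractionCriteria(),
                     frame_index: int = 0, partner_a: str = "ring",
                     partner_b: str = "residue") -> list:
    """Ring center within the cutoff of at least one side-chain N, and at
    least one N-H vector tilted out of the ring plane beyond the angle bound.

    ``nh_pairs``: list of (nitrogen_index, hydrogen_index) tuples; the
    vector/plane angle is 90 deg minus the folded vector/normal angle.
    """
    if not nh_pairs:
        raise ValueError("residue provides no N-H pairs")
    center, normal = ring_plane(frame, ring_triplet)
    best_d = None
    dist_ok = False
    for n_idx, _ in nh_pairs:
        d = float(np.linalg.norm(_displacement(center, frame.coords[n_idx], frame.box)))
        best_d = d if best_d is None else min(best_d, d)
        if d < criteria.cationpi_max_A:
            dist_ok = True
    best_angle = 0.0
    for n_idx, h_idx in nh_pairs:
        nh = _displacement(frame.coords[n_idx], frame.coords[h_idx], frame.box)
        plane_angle = 90.0 - _folded_angle_deg(nh, normal)
        best_angle = max(best_angle, plane_angle)
    if dist_ok and best_angle > criteria.cationpi_min_angle_deg:
        return [ContactRecord(frame_index, "cation_pi", partner_a, partner_b,
                              best_d, best_angle)]
    return []


def detect_guanidinium_stack(frame: Frame, ring_triplet, guanidinium_triplet,
                             criteria: InteractionCriteria = InteractionCriteria(),
                             frame_index: int = 0, partner_a: str = "ring",
                             partner_b: str = "arg"):
    if len(list(guanidinium_triplet)) != 3:
        raise ValueError("guanidinium plane requires exactly 3 atoms (NE, NH1, NH2)")
    ca, na = ring_plane(frame, ring_triplet)
    cg, ng = ring_plane(frame, guanidinium_triplet)
    dist = float(np.linalg.norm(_displacement(ca, cg, frame.box)))
    angle = _folded_angle_deg(na, ng)
    if dist < criteria.cationpi_max_A and angle < criteria.guanidinium_stack_max_angle_deg:
        return ContactRecord(frame_index, "guanidinium_stack", partner_a, partner_b,
                             dist, angle)
    return None


def detect_hbond(frame: Frame, donors, acceptors,
                 criteria: InteractionCriteria = InteractionCriteria(),
                 frame_index: int = 0) -> list:
    """Donors are (heavy, hydrogen) index pairs; acceptors heavy-atom indices
    or a {name: index} mapping."""
    if isinstance(acceptors, Mapping):
        accs = {str(k): int(v) for k, v in acceptors.items()}
    else:
        accs = {f"acceptor{j}": int(i) for j, i in enumerate(acceptors)}
    out = []
    for d_idx, h_idx in donors:
        dh = _displacement(frame.coords[d_idx], frame.coords[h_idx], frame.box)
        if np.linalg.norm(dh) > 1.2:
            raise ValueError(
                f"donor pair ({d_idx}, {h_idx}): |D-H| = {np.linalg.norm(dh):.2f} A > 1.2 A"
            )
        for aid, a_idx in accs.items():
            da = _displacement(frame.coords[d_idx], frame.coords[a_idx], frame.box)
            dist = float(np.linalg.norm(da))
            if dist >= criteria.hbond_heavy_max_A:
                continue
            hd = -dh
            ha = _displacement(frame.coords[h_idx], frame.coords[a_idx], frame.box)
            cosang = float(np.dot(hd, ha)) / (np.linalg.norm(hd) * np.linalg.norm(ha))
            angle = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
            if angle > criteria.hbond_min_angle_deg:
                out.append(ContactRecord(frame_index, "hbond", f"donor{d_idx}",
                                         aid, dist, angle))
    return out


# ---------------------------------------------------------------------------
# timelines

@dataclass
class ContactTimeline:
    """(partner_a, partner_b, criterion) -> sorted unique frame indices."""

    frames_by_pair: dict = field(default_factory=dict)

    def add(self, record: ContactRecord) -> None:
        key = (record.partner_a, record.partner_b, record.criterion)
        self.frames_by_pair.setdefault(key, set()).add(record.frame_index)

    def sorted_frames(self, key) -> list:
        return sorted(self.frames_by_pair.get(key, ()))


@dataclass(frozen=True)
class LifetimeStats:
    max_run_ns: float
    is_longlived: bool
    n_runs: int


def build_timelines(records) -> ContactTimeline:
    tl = ContactTimeline()
    for r in records:
        tl.add(r)
    return tl


def _run_lengths(frames: Sequence[int]) -> list:
    runs, length = [], 0
    prev = None
    for f in frames:
        if prev is not None and f == prev + 1:
            length += 1
        else:
            if length:
                runs.append(length)
            length = 1
        prev = f
    if length:
        runs.append(length)
    return runs


def classify_longlived(timeline: ContactTimeline, dt_ns: float,
                       criteria: InteractionCriteria = InteractionCriteria()) -> dict:
    """Per contact pair: maximal contiguous run duration (k frames -> k*dt)
    and whether it strictly exceeds the long-lived threshold."""
    out = {}
    for key in timeline.frames_by_pair:
        runs = _run_lengths(timeline.sorted_frames(key))
        max_run = max(runs) * dt_ns if runs else 0.0
        out[key] = LifetimeStats(max_run, max_run > criteria.longlived_min_ns, len(runs))
    return out
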