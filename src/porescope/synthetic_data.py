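"""Ground-truth-known synthetic inputs: toy pores, Brownian-dynamics
trajectories, and hand-placed contact-criterion fixtures.

The Brownian generator integrates overdamped Langevin dynamics,
``dr = -(D/RT) grad(U) dt + sqrt(2 D dt) eta``, with reflecting walls on a
cylinder of the pore radius and on the box z-faces.  Its stationary law is
the Boltzmann distribution of the axial potential U(z) — exactly the
assumption Boltzmann-inversion free-energy profiles rely on — so parameter
recovery closes the loop between generator and analysis.

U(z) is a sum of Gaussian wells/barriers evaluated everywhere (smooth
forces); specs whose Gaussians have not decayed at the pore mouth violate
the continuity contract and are rejected.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .model_io import Atom, Frame, MolecularSystem, Trajectory
from .profiles_energetics import R_KCAL_PER_MOL_K

__all__ = [
    "GaussianTerm",
    "SpeciesSpec",
    "SyntheticSpec",
    "GroundTruth",
    "ContactFixture",
    "build_toy_pore",
    "simulate_bd",
    "generate",
    "make_contact_fixture",
    "run_fixture_detectors",
]


@dataclass(frozen=True)
class GaussianTerm:
    """One Gaussian well (negative amplitude) or barrier (positive)."""

    amplitude_kcal: float
    center_z_A: float
    width_A: float

    def __post_init__(self) -> None:
        if self.width_A <= 0:
            raise ValueError("Gaussian width must be positive")


@dataclass(frozen=True)
class SpeciesSpec:
    name: str
    charge: int
    count: int
    diffusion_A2_per_ns: float = 100.0
    potential_scale: float = 1.0   # multiplier on U(z) felt by this species

    def __post_init__(self) -> None:
        if self.count < 0 or self.diffusion_A2_per_ns < 0:
            raise ValueError("count and diffusion coefficient must be >= 0")


@dataclass
class SyntheticSpec:
    seed: int
    box_A: tuple = (40.0, 40.0, 80.0)
    pore_half_length_A: float = 15.0
    pore_radius_A: float = 12.0
    potential: list = field(default_factory=list)
    timestep_ns: float = 0.005
    n_frames: int = 1000
    save_every: int = 1
    species: list = field(default_factory=list)
    temperature_K: float = 300.0
    basic_site_z: tuple = ()
    aromatic_site_z: tuple = ()

    def __post_init__(self) -> None:
        if self.timestep_ns <= 0:
            raise ValueError("timestep must be positive")
        if self.n_frames < 1 or self.save_every < 1:
            raise ValueError("n_frames and save_every must be >= 1")

    @property
    def RT_kcal(self) -> float:
        return R_KCAL_PER_MOL_K * self.temperature_K

    def u_of_z(self, z):
        z = np.asarray(z, dtype=float)
        u = np.zeros_like(z)
        for g in self.potential:
            u += g.amplitude_kcal * np.exp(-((z - g.center_z_A) ** 2) / (2 * g.width_A**2))
        return u

    def du_dz(self, z):
        z = np.asarray(z, dtype=float)
        du = np.zeros_like(z)
        for g in self.potential:
            du += (
                g.amplitude_kcal
                * (-(z - g.center_z_A) / g.width_A**2)
                * np.exp(-((z - g.center_z_A) ** 2) / (2 * g.width_A**2))
            )
        return du

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSpec":
        d = dict(d)
        d["potential"] = [GaussianTerm(**g) for g in d.get("potential", [])]
        d["species"] = [SpeciesSpec(**s) for s in d.get("species", [])]
        for key in ("box_A", "basic_site_z", "aromatic_site_z"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class GroundTruth:
    """What the generator knows: the potential, the per-species bulk density
    of the stationary law, and the density-ratio-derived selectivity."""

    u_of_z: Callable
    true_bulk_density: dict
    expected_ratio: float | None


# ---------------------------------------------------------------------------
# toy pore construction

def _wall_atoms(spec: SyntheticSpec, serial0: int):
    atoms, coords = [], []
    serial = serial0
    resnum = 1
    n_ring = 12
    z_rows = np.arange(-spec.pore_half_length_A, spec.pore_half_length_A + 1e-9, 5.0)
    for z in z_rows:
        for k in range(n_ring):
            th = 2 * math.pi * k / n_ring
            atoms.append(Atom(serial, "DUM", "C", "POR", resnum, "W"))
            coords.append(
                [spec.pore_radius_A * math.cos(th), spec.pore_radius_A * math.sin(th), z]
            )
            serial += 1
        resnum += 1
    return atoms, coords, serial


def build_toy_pore(spec: SyntheticSpec):
    """Cylindrical shell of inert pseudo-atoms, decorated with basic sites
    (NZ + bonded H, tagged) and aromatic triplets, plus one atom per mobile
    species particle.  Returns (system, base_coords)."""
    atoms, coords, serial = _wall_atoms(spec, 1)
    groups: dict = {}
    resnum = 1000
    site_positions = []
    r_site = max(spec.pore_radius_A - 4.0, 1.0)
    basic_indices = []
    for z in spec.basic_site_z:
        pos = np.array([r_site, 0.0, float(z)])
        for prev in site_positions:
            if np.linalg.norm(pos - prev) < 1.0:
                raise ValueError(f"overlapping decoration placements at z={z}")
        site_positions.append(pos)
        i_n = len(atoms)
        atoms.append(Atom(serial, "NZ", "N", "LYS", resnum, "A",
                          frozenset({"sidechain_nitrogen", "donor_heavy"})))
        coords.append(pos.tolist())
        serial += 1
        atoms.append(Atom(serial, "HZ1", "H", "LYS", resnum, "A",
                          frozenset({"hydrogen"})))
        coords.append((pos + np.array([-1.0, 0.0, 0.0])).tolist())
        serial += 1
        groups[f"basic_site_{resnum}"] = (i_n, i_n + 1)
        basic_indices.append(i_n)
        resnum += 1
    if basic_indices:
        groups["basic_sites"] = tuple(basic_indices)
    for z in spec.aromatic_site_z:
        center = np.array([-r_site, 0.0, float(z)])
        for prev in site_positions:
            if np.linalg.norm(center - prev) < 1.0:
                raise ValueError(f"overlapping decoration placements at z={z}")
        site_positions.append(center)
        tri = []
        for k in range(3):
            th = 2 * math.pi * k / 3
            tri.append(len(atoms))
            atoms.append(Atom(serial, f"CR{k + 1}", "C", "PHE", resnum, "A",
                              frozenset({"ring_atom"})))
            coords.append((center + 0.8 * np.array([math.cos(th), math.sin(th), 0.0])).tolist())
            serial += 1
        groups[f"ring_{resnum}"] = tuple(tri)
        resnum += 1
    for sp in spec.species:
        tag = "cation" if sp.charge > 0 else ("anion" if sp.charge < 0 else None)
        tags = frozenset({tag}) if tag else frozenset()
        idxs = []
        for _ in range(sp.count):
            idxs.append(len(atoms))
            atoms.append(Atom(serial, sp.name[:4].upper(), sp.name[:2].capitalize(),
                              "ION", resnum, "I", tags))
            coords.append([0.0, 0.0, 0.0])
            serial += 1
            resnum += 1
        groups[sp.name] = tuple(idxs)
    system = MolecularSystem(atoms, groups)
    return system, np.array(coords, dtype=float)


# ---------------------------------------------------------------------------
# Brownian dynamics

def _check_continuity(spec: SyntheticSpec, tol: float = 0.05) -> None:
    u_edge = np.abs(spec.u_of_z(np.array([-spec.pore_half_length_A,
                                          spec.pore_half_length_A])))
    if np.any(u_edge > tol):
        raise ValueError(
            f"potential does not decay at the pore mouth: |U| = {u_edge.max():.3f} "
            f"kcal/mol at |z| = {spec.pore_half_length_A} A (tolerance {tol})"
        )


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    span = hi - lo
    y = np.mod(x - lo, 2 * span)
    y = np.where(y > span, 2 * span - y, y)
    return y + lo


def _ground_truth(spec: SyntheticSpec) -> GroundTruth:
    lz = spec.box_A[2]
    area = math.pi * spec.pore_radius_A**2
    zg = np.linspace(-lz / 2, lz / 2, 4001)
    rt = spec.RT_kcal
    bulk = {}
    pore_fraction = {}
    for sp in spec.species:
        w = np.exp(-sp.potential_scale * spec.u_of_z(zg) / rt)
        norm = np.trapezoid(w, zg)
        bulk[sp.name] = sp.count / (area * norm)
        inside = np.abs(zg) <= spec.pore_half_length_A
        pore_fraction[sp.name] = np.trapezoid(w[inside], zg[inside]) / norm
    n_an = sum(sp.count * pore_fraction[sp.name] for sp in spec.species if sp.charge < 0)
    n_cat = sum(sp.count * pore_fraction[sp.name] for sp in spec.species if sp.charge > 0)
    ratio = (n_an / n_cat) if n_cat > 0 else None
    return GroundTruth(spec.u_of_z, bulk, ratio)


def simulate_bd(system: MolecularSystem, spec: SyntheticSpec,
                base_coords: np.ndarray | None = None):
    """Overdamped Euler-Maruyama trajectory of all mobile species.

    Returns (Trajectory, GroundTruth); bit-identical for identical seed+spec.
    """
    if spec.potential:
        _check_continuity(spec)
        w_min = min(g.width_A for g in spec.potential)
        for sp in spec.species:
            if sp.diffusion_A2_per_ns * spec.timestep_ns > 0.1 * w_min**2:
                warnings.warn(
                    f"species {sp.name}: D*dt = "
                    f"{sp.diffusion_A2_per_ns * spec.timestep_ns:.3g} A^2 is not "
                    f"small vs narrowest Gaussian width^2 = {w_min**2:.3g} A^2",
                    stacklevel=2,
                )
    if base_coords is None:
        base_coords = np.zeros((system.n_atoms, 3))
    base_coords = np.asarray(base_coords, dtype=float).copy()

    mobile_idx, d_coef, scale = [], [], []
    rng_master = np.random.default_rng(spec.seed)
    lz = spec.box_A[2]
    radius = spec.pore_radius_A
    for i_sp, sp in enumerate(spec.species):
        idxs = list(system.topology_groups.get(sp.name, ()))
        if len(idxs) != sp.count:
            raise ValueError(
                f"species {sp.name}: topology group has {len(idxs)} atoms, "
                f"spec says {sp.count}"
            )
        # per-species substream for initial placement, derived from the master seed
        sub = np.random.default_rng([spec.seed, i_sp])
        r = radius * np.sqrt(sub.uniform(0, 1, sp.count))
        th = sub.uniform(0, 2 * math.pi, sp.count)
        z0 = sub.uniform(-lz / 2, lz / 2, sp.count)
        base_coords[idxs, 0] = r * np.cos(th)
        base_coords[idxs, 1] = r * np.sin(th)
        base_coords[idxs, 2] = z0
        mobile_idx.extend(idxs)
        d_coef.extend([sp.diffusion_A2_per_ns] * sp.count)
        scale.extend([sp.potential_scale] * sp.count)

    mobile_idx = np.asarray(mobile_idx, dtype=int)
    d_coef = np.asarray(d_coef, dtype=float)
    scale = np.asarray(scale, dtype=float)
    rt = spec.RT_kcal
    dt = spec.timestep_ns
    sigma = np.sqrt(2.0 * d_coef * dt)
    mobility = d_coef / rt * dt
    max_step = min(spec.box_A) / 2

    pos = base_coords[mobile_idx].copy()
    frames = [Frame(0.0, base_coords.copy(), np.asarray(spec.box_A, dtype=float))]
    dt_frame = dt * spec.save_every
    n_steps = (spec.n_frames - 1) * spec.save_every
    for step in range(1, n_steps + 1):
        drift_z = -mobility * scale * spec.du_dz(pos[:, 2])
        noise = rng_master.standard_normal((len(pos), 3)) * sigma[:, None]
        disp = noise
        disp[:, 2] += drift_z
        if np.any(np.abs(disp) > max_step):
            raise RuntimeError(
                "divergent BD step: displacement exceeds half the box; "
                "reduce the timestep"
            )
        pos = pos + disp
        pos[:, 2] = _reflect(pos[:, 2], -lz / 2, lz / 2)
        rad = np.hypot(pos[:, 0], pos[:, 1])
        over = rad > radius
        if np.any(over):
            folded = 2 * radius - rad[over]
            ratio = folded / rad[over]
            pos[over, 0] *= ratio
            pos[over, 1] *= ratio
        if step % spec.save_every == 0:
            snap = base_coords.copy()
            snap[mobile_idx] = pos
            frames.append(Frame(step * dt, snap, np.asarray(spec.box_A, dtype=float)))
    traj = Trajectory(system, frames, dt_frame)
    return traj, _ground_truth(spec)


def generate(spec: SyntheticSpec):
    """build_toy_pore + simulate_bd in one call."""
    system, coords = build_toy_pore(spec)
    traj, truth = simulate_bd(system, spec, coords)
    return system, traj, truth


# ---------------------------------------------------------------------------
# contact fixtures

@dataclass
class ContactFixture:
    """A hand-placed geometry with enumerated expected detector hits.

    ``selections`` holds whatever the corresponding detector needs;
    ``expected`` is the set of (criterion, partner_a, partner_b) that must
    be reported.  Distance boundaries are realized exactly; irrational
    angle boundaries (30/60/120 deg) are realized just inside/outside so
    strict comparisons are unambiguous in floating point.
    """

    kind: str
    system: MolecularSystem
    frame: Frame
    selections: dict
    expected: set


def _atoms_at(named_points):
    atoms, coords = [], []
    for k, (name, element, xyz) in enumerate(named_points):
        atoms.append(Atom(k + 1, name, element, "FIX", k + 1, "A"))
        coords.append(xyz)
    return MolecularSystem(atoms), Frame(0.0, np.array(coords, dtype=float))


def _triangle(center, tilt_deg: float = 0.0, radius: float = 0.8):
    """Equilateral triangle whose centroid is exactly ``center`` (z-wise)
    and whose plane is tilted about the x-axis by ``tilt_deg``."""
    t = math.radians(tilt_deg)
    rot = np.array([[1, 0, 0],
                    [0, math.cos(t), -math.sin(t)],
                    [0, math.sin(t), math.cos(t)]])
    pts = []
    for k in range(3):
        th = 2 * math.pi * k / 3
        p = radius * np.array([math.cos(th), math.sin(th), 0.0])
        pts.append(np.asarray(center, dtype=float) + rot @ p)
    return pts


def make_contact_fixture(kind: str):
    """Fixture geometries straddling each criterion's thresholds.

    kind in {electrostatic, pairing, pipi, cationpi, guanidinium, hbond,
    boundary_cases}; boundary_cases returns the list of all six.
    """
    if kind == "boundary_cases":
        return [make_contact_fixture(k) for k in
                ("electrostatic", "pairing", "pipi", "cationpi", "guanidinium", "hbond")]
    if kind == "electrostatic":
        system, frame = _atoms_at([
            ("NZ", "N", [0.0, 0.0, 0.0]),
            ("O1", "O", [3.9, 0.0, 0.0]),
            ("O1", "O", [0.0, 4.0, 0.0]),
            ("O1", "O", [0.0, 0.0, 4.1]),
        ])
        sel = {"oxygens": {"lig39": [1], "lig40": [2], "lig41": [3]},
               "nitrogens": {"LYS1": [0]}}
        expected = {("electrostatic", "lig39", "LYS1"),
                    ("electrostatic", "lig40", "LYS1")}   # 4.0 A inclusive
        return ContactFixture(kind, system, frame, sel, expected)
    if kind == "pairing":
        system, frame = _atoms_at([
            ("O1", "O", [0.0, 0.0, 0.0]),
            ("NA", "Na", [3.5, 0.0, 0.0]),
            ("NA", "Na", [0.0, 3.999, 0.0]),
            ("NA", "Na", [4.0, 0.0, 0.0]),    # exactly at the strict bound
            ("NA", "Na", [0.0, 0.0, 4.5]),
        ])
        sel = {"oxygens": {"phos": [0]},
               "cations": {"na35": 1, "na3999": 2, "na40": 3, "na45": 4}}
        expected = {("cation_pairing", "phos", "na35"),
                    ("cation_pairing", "phos", "na3999")}
        return ContactFixture(kind, system, frame, sel, expected)
    if kind == "pipi":
        pts = []
        tris = {}

        def add_ring(name, center, tilt):
            start = len(pts)
            for p in _triangle(center, tilt):
                pts.append((f"C{len(pts)}", "C", p.tolist()))
            tris[name] = (start, start + 1, start + 2)

        add_ring("base", [0, 0, 0], 0.0)
        add_ring("parallel4", [0, 0, 4.0], 0.0)        # hit: 4 A, 0 deg
        add_ring("perp4", [0, 0, -4.0], 90.0)          # miss: 90 deg
        add_ring("tilt29", [0, 5.9, 0], 29.0)          # hit: < 6 A, 29 deg
        add_ring("tilt31", [0, -5.9, 0], 31.0)         # miss: 31 deg
        add_ring("far6", [0, 0, 6.0], 0.0)             # miss: exactly 6 A (strict)
        system, frame = _atoms_at(pts)
        expected = {("pi_pi", "base", "parallel4"), ("pi_pi", "base", "tilt29")}
        return ContactFixture(kind, system, frame,
                              {"ring_a": tris["base"], "partners": {
                                  k: v for k, v in tris.items() if k != "base"}},
                              expected)
    if kind == "cationpi":
        pts = []
        tri = []
        for p in _triangle([0, 0, 0], 0.0):
            tri.append(len(pts))
            pts.append((f"C{len(pts)}", "C", p.tolist()))
        cases = {}

        def add_nh(name, n_xyz, h_xyz):
            i = len(pts)
            pts.append(("NZ", "N", list(n_xyz)))
            pts.append(("HZ", "H", list(h_xyz)))
            cases[name] = [(i, i + 1)]

        add_nh("normal90", [0, 0, 5.0], [0, 0, 6.0])       # hit: plane angle 90
        add_nh("inplane0", [5.0, 0, 0], [6.0, 0, 0])       # miss: plane angle 0
        add_nh("far60", [0, 0, 6.0], [0, 0, 7.0])          # miss: exactly 6 A (strict)
        a59 = math.radians(59.0)
        add_nh("ang59", [0, 4.0, 1.0],
               [math.cos(a59), 4.0, 1.0 + math.sin(a59)])  # miss: 59 < 60
        a61 = math.radians(61.0)
        add_nh("ang61", [0, -4.0, 1.0],
               [math.cos(a61), -4.0, 1.0 + math.sin(a61)])  # hit: 61 > 60
        system, frame = _atoms_at(pts)
        expected = {("cation_pi", "ring", "normal90"), ("cation_pi", "ring", "ang61")}
        return ContactFixture(kind, system, frame,
                              {"ring": tuple(tri), "cases": cases}, expected)
    if kind == "guanidinium":
        pts = []
        tris = {}

        def add_tri(name, center, tilt):
            start = len(pts)
            el = "C" if name == "base" else "N"
            for p in _triangle(center, tilt):
                pts.append((f"{el}{len(pts)}", el, p.tolist()))
            tris[name] = (start, start + 1, start + 2)

        add_tri("base", [0, 0, 0], 0.0)
        add_tri("stack38", [0, 0, 3.8], 0.0)     # hit: coplanar stack
        add_tri("tilt45", [0, 0, -3.8], 45.0)    # miss: 45 deg
        add_tri("tilt299", [0, 5.9, 0], 29.9)    # hit: 29.9 deg at 5.9 A
        add_tri("far6", [0, 0, 6.0], 0.0)        # miss: exactly 6 A (strict)
        system, frame = _atoms_at(pts)
        expected = {("guanidinium_stack", "ring", "stack38"),
                    ("guanidinium_stack", "ring", "tilt299")}
        return ContactFixture(kind, system, frame,
                              {"ring": tris["base"], "partners": {
                                  k: v for k, v in tris.items() if k != "base"}},
                              expected)
    if kind == "hbond":
        a121 = math.radians(180.0 - 121.0)
        a119 = math.radians(180.0 - 119.0)
        pts = [
            ("OD", "O", [0.0, 0.0, 0.0]),                 # donor heavy (linear case)
            ("HD", "H", [1.0, 0.0, 0.0]),
            ("OA", "O", [2.9, 0.0, 0.0]),                 # hit: linear, 2.9 A
            ("OA", "O", [-3.6, 0.0, 0.0]),                # (unused direction)
            ("OD", "O", [0.0, 10.0, 0.0]),                # donor heavy (distance cases)
            ("HD", "H", [1.0, 10.0, 0.0]),
            ("OA", "O", [3.6, 10.0, 0.0]),                # miss: 3.6 A
            ("OA", "O", [3.5, 10.0, 0.0]),                # miss: exactly 3.5 A (strict)
            ("OD", "O", [0.0, 20.0, 0.0]),                # donor heavy (angle cases)
            ("HD", "H", [1.0, 20.0, 0.0]),
            ("OA", "O", [1.0 + 2.4 * math.cos(a121), 20.0 + 2.4 * math.sin(a121), 0.0]),
            ("OA", "O", [1.0 + 2.4 * math.cos(a119), 20.0 - 2.4 * math.sin(a119), 0.0]),
        ]
        system, frame = _atoms_at(pts)
        sel = {
            "donors": [(0, 1), (4, 5), (8, 9)],
            "acceptors": {"lin29": 2, "far36": 6, "at35": 7, "ang121": 10, "ang119": 11},
        }
        expected = {("hbond", "donor0", "lin29"), ("hbond", "donor8", "ang121")}
        return ContactFixture(kind, system, frame, sel, expected)
    raise ValueError(f"unknown fixture kind {kind!r}")


def run_fixture_detectors(fixture: ContactFixture, criteria=None) -> set:
    """Run the package detectors on a fixture; returns the found
    (criterion, partner_a, partner_b) set for comparison with ``expected``."""
    from . import contacts as C

    if criteria is None:
        criteria = C.InteractionCriteria()
    f, sel = fixture.frame, fixture.selections
    found = set()
    if fixture.kind == "electrostatic":
        recs = C.detect_electrostatic(f, sel["oxygens"], sel["nitrogens"], criteria)
        found = {(r.criterion, r.partner_a, r.partner_b) for r in recs}
    elif fixture.kind == "pairing":
        recs = C.detect_cation_pairing(f, sel["oxygens"], sel["cations"], criteria)
        found = {(r.criterion, r.partner_a, r.partner_b) for r in recs}
    elif fixture.kind == "pipi":
        for name, tri in sel["partners"].items():
            r = C.detect_pi_pi(f, sel["ring_a"], tri, criteria,
                               partner_a="base", partner_b=name)
            if r is not None:
                found.add((r.criterion, r.partner_a, r.partner_b))
    elif fixture.kind == "cationpi":
        for name, nh_pairs in sel["cases"].items():
            for r in C.detect_cation_pi(f, sel["ring"], nh_pairs, criteria,
                                        partner_a="ring", partner_b=name):
                found.add((r.criterion, r.partner_a, r.partner_b))
    elif fixture.kind == "guanidinium":
        for name, tri in sel["partners"].items():
            r = C.detect_guanidinium_stack(f, sel["ring"], tri, criteria,
                                           partner_a="ring", partner_b=name)
            if r is not None:
                found.add((r.criterion, r.partner_a, r.partner_b))
    elif fixture.kind == "hbond":
        recs = C.detect_hbond(f, sel["donors"], sel["acceptors"], criteria)
        found = {(r.criterion, r.partner_a, r.partner_b) for r in recs}
    else:
        raise ValueError(f"unknown fixture kind {fixture.kind!r}")
    return found
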