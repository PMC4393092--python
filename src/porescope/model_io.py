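"""Data model and readers/writers for structures, trajectories, MSAs, I/V data and profiles.

Structure input is PDB (ATOM/HETATM, standard columns) or nothing at all when
systems are built programmatically.  Trajectories come either as CHARMM/NAMD
DCD (via MDAnalysis) or as a human-writable plain-text dialect::

    natoms N dt_ns X
    frame I time_ns T [box a b c]
    x y z          # N lines, one per atom, in system atom order

Coordinates are in angstroms throughout, times in nanoseconds.
"""

from __future__ import annotations

import fnmatch
import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ROLE_TAGS",
    "Atom",
    "MolecularSystem",
    "Frame",
    "Trajectory",
    "MsaRecord",
    "Msa",
    "IVSeries",
    "TaggingRules",
    "default_tagging_rules",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "read_msa",
    "read_iv",
    "write_profile",
    "read_profile",
    "ParseError",
]

ROLE_TAGS = frozenset(
    {
        "backbone_carbon",
        "sidechain_nitrogen",
        "phosphate_oxygen",
        "phosphorus_terminal",
        "ring_atom",
        "donor_heavy",
        "hydrogen",
        "cation",
        "anion",
    }
)


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


@dataclass(frozen=True)
class Atom:
    """A named atom with residue identity and functional role tags."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    chain: str = "A"
    role_tags: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.serial < 1:
            raise ValueError(f"atom serial must be >= 1, got {self.serial}")
        unknown = set(self.role_tags) - ROLE_TAGS
        if unknown:
            raise ValueError(f"unknown role tags: {sorted(unknown)}")
        if "hydrogen" in self.role_tags and self.element.upper() != "H":
            raise ValueError(
                f"atom {self.serial} ({self.name}): 'hydrogen' tag on element "
                f"{self.element!r}"
            )

    @property
    def residue_id(self) -> str:
        return f"{self.residue_name}:{self.residue_number}:{self.chain}"


@dataclass
class MolecularSystem:
    """Ordered atom list plus named index groups (e.g. ring triplets)."""

    atoms: list
    topology_groups: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            dup = sorted({s for s in serials if serials.count(s) > 1})
            raise ValueError(f"duplicate atom serial(s): {dup}")
        n = len(self.atoms)
        for gname, idxs in self.topology_groups.items():
            for i in idxs:
                if not 0 <= i < n:
                    raise ValueError(
                        f"topology group {gname!r}: index {i} out of range (n={n})"
                    )

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def indices_with_tag(self, tag: str) -> list:
        return [i for i, a in enumerate(self.atoms) if tag in a.role_tags]

    def select(self, residue_numbers: Iterable[int], atom_names: Iterable[str]) -> list:
        rset, aset = set(residue_numbers), set(atom_names)
        return [
            i
            for i, a in enumerate(self.atoms)
            if a.residue_number in rset and a.name in aset
        ]


@dataclass
class Frame:
    """One trajectory snapshot: per-atom coordinates and an optional box."""

    time_ns: float
    coords: np.ndarray
    box: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError(f"coords must be (n, 3), got {self.coords.shape}")
        if self.time_ns < 0:
            raise ValueError("time_ns must be >= 0")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (3,) or np.any(self.box <= 0):
                raise ValueError("box must be 3 positive lengths")


@dataclass
class Trajectory:
    system: MolecularSystem
    frames: list
    dt_ns: float

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("trajectory must hold at least one frame")
        if self.dt_ns <= 0:
            raise ValueError("dt_ns must be positive")
        n = self.system.n_atoms
        times = []
        for k, f in enumerate(self.frames):
            if f.coords.shape[0] != n:
                raise ValueError(
                    f"frame {k}: {f.coords.shape[0]} atoms, system has {n}"
                )
            times.append(f.time_ns)
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)


@dataclass(frozen=True)
class MsaRecord:
    id: str
    aligned_seq: str


@dataclass
class Msa:
    records: list
    reference_id: str

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("empty alignment")
        lengths = {len(r.aligned_seq) for r in self.records}
        if len(lengths) != 1:
            raise ValueError(f"ragged alignment: lengths {sorted(lengths)}")
        if self.reference_id not in {r.id for r in self.records}:
            raise ValueError(f"reference id {self.reference_id!r} not in alignment")

    @property
    def length(self) -> int:
        return len(self.records[0].aligned_seq)

    def record(self, rec_id: str) -> MsaRecord:
        for r in self.records:
            if r.id == rec_id:
                return r
        raise KeyError(rec_id)


@dataclass
class IVSeries:
    voltage_mV: np.ndarray
    current_pA: np.ndarray

    def __post_init__(self) -> None:
        self.voltage_mV = np.asarray(self.voltage_mV, dtype=float)
        self.current_pA = np.asarray(self.current_pA, dtype=float)
        if self.voltage_mV.shape != self.current_pA.shape:
            raise ValueError("voltage and current must have equal length")
        if len(np.unique(self.voltage_mV)) < 2:
            raise ValueError("need at least 2 distinct voltages")


# ---------------------------------------------------------------------------
# tagging rules

@dataclass
class TaggingRules:
    """Ordered (residue-pattern, atom-pattern) -> tags rules; fnmatch globs.

    All matching rules apply (tags are unioned).  Residue/atom patterns are
    matched case-sensitively against the PDB residue and atom names.
    """

    rules: list = field(default_factory=list)

    def add(self, residue_pattern: str, atom_pattern: str, *tags: str) -> "TaggingRules":
        unknown = set(tags) - ROLE_TAGS
        if unknown:
            raise ValueError(f"unknown role tags: {sorted(unknown)}")
        self.rules.append((residue_pattern, atom_pattern, frozenset(tags)))
        return self

    def tags_for(self, residue_name: str, atom_name: str, element: str) -> frozenset:
        tags = set()
        for rpat, apat, rtags in self.rules:
            if fnmatch.fnmatchcase(residue_name, rpat) and fnmatch.fnmatchcase(
                atom_name, apat
            ):
                tags |= rtags
        if element.upper() == "H":
            tags.add("hydrogen")
            tags.discard("donor_heavy")
        return frozenset(tags)


def default_tagging_rules() -> TaggingRules:
    """Built-in templates: Lys/Arg side-chain nitrogens, backbone carbons and
    per-residue phosphate templates (terminal P by name, gamma for ATP)."""
    t = TaggingRules()
    t.add("LYS", "NZ", "sidechain_nitrogen")
    for n in ("NE", "NH1", "NH2"):
        t.add("ARG", n, "sidechain_nitrogen")
    t.add("*", "CA", "backbone_carbon")
    t.add("*", "C", "backbone_carbon")
    # phosphate-bearing ligand templates
    for o in ("O1G", "O2G", "O3G", "O1B", "O2B", "O3B", "O1A", "O2A", "O3A"):
        t.add("ATP", o, "phosphate_oxygen")
    t.add("ATP", "PG", "phosphorus_terminal")
    for o in ("O1B", "O2B", "O3B", "O1A", "O2A", "O3A"):
        t.add("ADP", o, "phosphate_oxygen")
    t.add("ADP", "PB", "phosphorus_terminal")
    for o in ("O1P", "O2P", "O3P"):
        t.add("AMP", o, "phosphate_oxygen")
    t.add("AMP", "P", "phosphorus_terminal")
    for res in ("PO4", "PI", "H2P", "HPO"):
        for o in ("O1", "O2", "O3", "O4"):
            t.add(res, o, "phosphate_oxygen")
        t.add(res, "P", "phosphorus_terminal")
    return t


# ---------------------------------------------------------------------------
# PDB

def _infer_element(atom_name: str) -> str:
    s = atom_name.strip()
    if not s:
        return ""
    if s[0].isdigit():
        s = s.lstrip("0123456789")
    if s[:1].upper() == "H":
        return "H"
    return s[:1].upper()


def read_structure(path: str, tagging_rules: TaggingRules | None = None) -> MolecularSystem:
    """Parse a PDB file (ATOM/HETATM records) into a tagged MolecularSystem."""
    if tagging_rules is None:
        tagging_rules = default_tagging_rules()
    atoms = []
    seen = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec not in ("ATOM", "HETATM"):
                continue
            try:
                serial = int(line[6:11])
                name = line[12:16].strip()
                residue_name = line[17:20].strip()
                chain = line[21:22].strip() or "A"
                residue_number = int(line[22:26])
                float(line[30:38]); float(line[38:46]); float(line[46:54])
            except ValueError as exc:
                raise ParseError(f"{path}: malformed PDB record at line {lineno}: {exc}") from exc
            element = line[76:78].strip() if len(line) >= 78 else ""
            if not element:
                element = _infer_element(name)
            if serial in seen:
                raise ParseError(f"{path}: duplicate atom serial {serial} at line {lineno}")
            seen.add(serial)
            tags = tagging_rules.tags_for(residue_name, name, element)
            atoms.append(
                Atom(serial, name, element, residue_name, residue_number, chain, tags)
            )
    return MolecularSystem(atoms)


def read_structure_coords(path: str) -> np.ndarray:
    """Coordinates of the ATOM/HETATM records of a PDB file, in file order."""
    coords = []
    with open(path) as fh:
        for line in fh:
            if line[:6].strip() in ("ATOM", "HETATM"):
                coords.append([float(line[30:38]), float(line[38:46]), float(line[46:54])])
    return np.array(coords, dtype=float)


def write_structure(system: MolecularSystem, path: str, coords: np.ndarray | None = None) -> None:
    if coords is None:
        coords = np.zeros((system.n_atoms, 3))
    coords = np.asarray(coords, dtype=float)
    with open(path, "w") as fh:
        for a, xyz in zip(system.atoms, coords):
            name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
            fh.write(
                f"ATOM  {a.serial:5d} {name:<4.4s} {a.residue_name:<3.3s} "
                f"{a.chain:1.1s}{a.residue_number:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                f"  1.00  0.00          {a.element:>2.2s}\n"
            )
        fh.write("END\n")


# ---------------------------------------------------------------------------
# trajectories

def _infer_traj_format(path: str) -> str:
    return "dcd" if os.path.splitext(path)[1].lower() == ".dcd" else "text"


def read_trajectory(system: MolecularSystem, path: str, format: str | None = None) -> Trajectory:
    fmt = format or _infer_traj_format(path)
    if fmt == "text":
        return _read_text_trajectory(system, path)
    if fmt == "dcd":
        return _read_dcd_trajectory(system, path)
    raise ValueError(f"unknown trajectory format {fmt!r}")


def write_trajectory(traj: Trajectory, path: str, format: str | None = None) -> None:
    fmt = format or _infer_traj_format(path)
    if fmt == "text":
        _write_text_trajectory(traj, path)
    elif fmt == "dcd":
        _write_dcd_trajectory(traj, path)
    else:
        raise ValueError(f"unknown trajectory format {fmt!r}")


def _read_text_trajectory(system: MolecularSystem, path: str) -> Trajectory:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or not lines[0].startswith("natoms"):
        raise ParseError(f"{path}: missing 'natoms N dt_ns X' header at line 1")
    head = lines[0].split()
    try:
        natoms, dt_ns = int(head[1]), float(head[3])
    except (IndexError, ValueError) as exc:
        raise ParseError(f"{path}: malformed header at line 1: {lines[0]!r}") from exc
    if natoms != system.n_atoms:
        raise ValueError(
            f"{path}: file has {natoms} atoms, system has {system.n_atoms}"
        )
    frames = []
    i = 1
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        parts = lines[i].split()
        if parts[0] != "frame":
            raise ParseError(f"{path}: expected 'frame' record at line {i + 1}")
        try:
            time_ns = float(parts[3])
        except (IndexError, ValueError) as exc:
            raise ParseError(f"{path}: malformed frame record at line {i + 1}") from exc
        box = None
        if "box" in parts:
            j = parts.index("box")
            box = np.array([float(x) for x in parts[j + 1 : j + 4]])
        if i + natoms >= len(lines) + 0 and i + 1 + natoms > len(lines):
            raise ParseError(f"{path}: truncated frame block starting at line {i + 1}")
        block = lines[i + 1 : i + 1 + natoms]
        if len(block) < natoms:
            raise ParseError(f"{path}: truncated frame block starting at line {i + 1}")
        try:
            coords = np.array([[float(x) for x in ln.split()[:3]] for ln in block])
        except (ValueError, IndexError) as exc:
            raise ParseError(f"{path}: malformed coordinate line near line {i + 2}") from exc
        if coords.shape != (natoms, 3):
            raise ParseError(f"{path}: truncated frame block starting at line {i + 1}")
        frames.append(Frame(time_ns, coords, box))
        i += 1 + natoms
    return Trajectory(system, frames, dt_ns)


def _write_text_trajectory(traj: Trajectory, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"natoms {traj.system.n_atoms} dt_ns {traj.dt_ns:.9g}\n")
        for k, f in enumerate(traj.frames):
            line = f"frame {k} time_ns {f.time_ns:.9g}"
            if f.box is not None:
                line += " box " + " ".join(f"{b:.6f}" for b in f.box)
            fh.write(line + "\n")
            for xyz in f.coords:
                fh.write(f"{xyz[0]:.6f} {xyz[1]:.6f} {xyz[2]:.6f}\n")


def _read_dcd_trajectory(system: MolecularSystem, path: str) -> Trajectory:
    from MDAnalysis.coordinates.DCD import DCDReader

    frames = []
    with DCDReader(path) as reader:
        if reader.n_atoms != system.n_atoms:
            raise ValueError(
                f"{path}: file has {reader.n_atoms} atoms, system has {system.n_atoms}"
            )
        for ts in reader:
            box = None
            if ts.dimensions is not None and np.all(ts.dimensions[:3] > 0):
                box = np.array(ts.dimensions[:3], dtype=float)
            frames.append(Frame(len(frames) * 1.0, ts.positions.astype(float).copy(), box))
    # DCD time metadata is engine-dependent; re-time at nominal spacing
    dt_ns = 1.0
    for k, f in enumerate(frames):
        f.time_ns = k * dt_ns
    return Trajectory(system, frames, dt_ns)


def _write_dcd_trajectory(traj: Trajectory, path: str) -> None:
    from MDAnalysis.coordinates.DCD import DCDWriter

    with DCDWriter(path, n_atoms=traj.system.n_atoms) as w:
        import MDAnalysis as mda

        u = mda.Universe.empty(traj.system.n_atoms, trajectory=True)
        for f in traj.frames:
            u.atoms.positions = f.coords
            if f.box is not None:
                u.dimensions = [*f.box, 90.0, 90.0, 90.0]
            w.write(u.atoms)


# ---------------------------------------------------------------------------
# MSA / IV / profiles

def read_msa(path: str, reference_id: str | None = None) -> Msa:
    """Aligned FASTA -> Msa. Reference defaults to the first record."""
    from Bio import AlignIO

    try:
        aln = AlignIO.read(path, "fasta")
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    records = [MsaRecord(r.id, str(r.seq).upper()) for r in aln]
    ref = reference_id if reference_id is not None else records[0].id
    return Msa(records, ref)


def write_msa(msa: Msa, path: str) -> None:
    with open(path, "w") as fh:
        for r in msa.records:
            fh.write(f">{r.id}\n{r.aligned_seq}\n")


def read_iv(path: str) -> IVSeries:
    import pandas as pd

    df = pd.read_csv(path)
    for col in ("voltage_mV", "current_pA"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            raise ParseError(f"{path}: non-numeric value in column {col!r}") from exc
    return IVSeries(df["voltage_mV"].to_numpy(), df["current_pA"].to_numpy())


def write_iv(iv: IVSeries, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("voltage_mV,current_pA\n")
        for v, i in zip(iv.voltage_mV, iv.current_pA):
            fh.write(f"{v:.10g},{i:.10g}\n")


def write_profile(profile, path: str) -> None:
    """TSV with columns z_center, value, se, n_samples; missing values as NA."""
    centers = profile.bin_centers
    se = profile.se if profile.se is not None else [None] * len(centers)
    with open(path, "w") as fh:
        fh.write("z_center\tvalue\tse\tn_samples\n")
        for c, v, s, n in zip(centers, profile.values, se, profile.n_samples):
            vs = "NA" if v is None else f"{v:.6g}"
            ss = "NA" if s is None else f"{s:.6g}"
            fh.write(f"{c:.6g}\t{vs}\t{ss}\t{int(n)}\n")


def read_profile(path: str, quantity: str = "occupancy_fraction"):
    from .profiles_energetics import ZProfile

    centers, values, ses, ns = [], [], [], []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("z_center"):
            raise ParseError(f"{path}: missing profile header")
        for line in fh:
            c, v, s, n = line.split("\t")
            centers.append(float(c))
            values.append(None if v == "NA" else float(v))
            ses.append(None if s == "NA" else float(s))
            ns.append(int(n))
    if len(centers) < 1:
        raise ParseError(f"{path}: empty profile")
    if len(centers) == 1:
        width = 1.0
    else:
        width = centers[1] - centers[0]
    edges = np.array([centers[0] - width / 2] + [c + width / 2 for c in centers])
    se = None if all(s is None for s in ses) else ses
    return ZProfile(edges, values, se, np.array(ns), quantity)
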