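"""Translocation-event detection across the pore slab.

A full event is a passage between the two boundary regions z > z_hi and
z < z_lo with hysteresis: after last being seen above +z_hi, the particle
must reach below z_lo without re-entering the upper region (direction
``cyt_to_ims``), or symmetrically (``ims_to_cyt``).  Excursions into the
interior that return to the same side are not events, and boundary jitter
cannot double-count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .model_io import Trajectory
from .pore_frame import PoreFrame, z_series

__all__ = ["TranslocationEvent", "detect_translocations", "count_events_by_species"]

DIRECTIONS = ("cyt_to_ims", "ims_to_cyt")


@dataclass(frozen=True)
class TranslocationEvent:
    particle_id: str
    direction: str
    entry_frame: int
    exit_frame: int
    duration_ns: float

    def __post_init__(self) -> None:
        if self.entry_frame >= self.exit_frame:
            raise ValueError("entry_frame must precede exit_frame")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"unknown direction {self.direction!r}")


def detect_translocations(z_values: Sequence[float], dt_ns: float,
                          z_hi: float = 15.0, z_lo: float = -15.0,
                          particle_id: str = "particle") -> list:
    """Scan one particle's z series for full slab crossings.

    entry_frame is the last frame in the departure boundary region before
    the crossing; exit_frame the first frame in the arrival region.
    """
    if z_hi <= z_lo:
        raise ValueError("z_hi must exceed z_lo")
    zs = np.asarray(z_values, dtype=float)
    if len(zs) < 2:
        raise ValueError("need at least 2 frames")
    events = []
    state = None          # boundary region last visited: "above" | "below"
    last_above = last_below = None
    for i, z in enumerate(zs):
        if z > z_hi:
            if state == "below":
                events.append(TranslocationEvent(
                    particle_id, "ims_to_cyt", last_below, i,
                    (i - last_below) * dt_ns))
            state = "above"
            last_above = i
        elif z < z_lo:
            if state == "above":
                events.append(TranslocationEvent(
                    particle_id, "cyt_to_ims", last_above, i,
                    (i - last_above) * dt_ns))
            state = "below"
            last_below = i
    return events


def count_events_by_species(traj: Trajectory, species_atoms: Mapping[str, Sequence[int]],
                            pore: PoreFrame,
                            z_hi: float | None = None,
                            z_lo: float | None = None) -> dict:
    """Per species: (n_cyt_to_ims, n_ims_to_cyt) summed over its particles."""
    if z_hi is None:
        z_hi = pore.pore_half_length_A
    if z_lo is None:
        z_lo = -pore.pore_half_length_A
    out = {}
    for species, atom_indices in species_atoms.items():
        n_down = n_up = 0
        for ai in atom_indices:
            zs = z_series(traj, pore, ai)
            for ev in detect_translocations(zs, traj.dt_ns, z_hi, z_lo,
                                            particle_id=f"{species}:{ai}"):
                if ev.direction == "cyt_to_ims":
                    n_down += 1
                else:
                    n_up += 1
        out[species] = (n_down, n_up)
    return out
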