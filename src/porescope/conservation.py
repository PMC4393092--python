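"""Per-position MSA conservation relative to a reference sequence.

For a reference residue number, the alignment column is located via the
reference's ungapped coordinate; conservation and %-substituted-to-K/R are
computed over the non-reference sequences with a non-gap character in that
column (gaps are excluded from the denominator). Percentages are reported to
one decimal.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .model_io import Msa

__all__ = ["ConservationRow", "map_ref_position", "conservation_at", "column_composition"]

GAP_CHARS = frozenset("-.")


@dataclass(frozen=True)
class ConservationRow:
    ref_residue_number: int
    ref_residue: str
    conserved_pct: float | None
    to_K_pct: float | None
    to_R_pct: float | None
    n_sequences_counted: int


def map_ref_position(msa: Msa, ref_residue_number: int) -> int:
    """0-based alignment column of the reference's n-th (1-based) non-gap
    character."""
    ref = msa.record(msa.reference_id).aligned_seq
    if ref_residue_number < 1:
        raise ValueError("residue numbers are 1-based")
    count = 0
    for col, ch in enumerate(ref):
        if ch not in GAP_CHARS:
            count += 1
            if count == ref_residue_number:
                return col
    raise ValueError(
        f"residue number {ref_residue_number} beyond ungapped reference length {count}"
    )


def column_composition(msa: Msa, column: int, include_reference: bool = False) -> Counter:
    """Non-gap character counts in a column over the counted sequences."""
    counts: Counter = Counter()
    for rec in msa.records:
        if not include_reference and rec.id == msa.reference_id:
            continue
        ch = rec.aligned_seq[column]
        if ch not in GAP_CHARS:
            counts[ch] += 1
    return counts


def conservation_at(msa: Msa, ref_residue_number: int,
                    include_reference: bool = False) -> ConservationRow:
    col = map_ref_position(msa, ref_residue_number)
    ref_char = msa.record(msa.reference_id).aligned_seq[col]
    counts = column_composition(msa, col, include_reference)
    n = sum(counts.values())
    if n == 0:
        return ConservationRow(ref_residue_number, ref_char, None, None, None, 0)
    conserved = round(100.0 * counts.get(ref_char, 0) / n, 1)
    to_k = None if ref_char == "K" else round(100.0 * counts.get("K", 0) / n, 1)
    to_r = None if ref_char == "R" else round(100.0 * counts.get("R", 0) / n, 1)
    return ConservationRow(ref_residue_number, ref_char, conserved, to_k, to_r, n)
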