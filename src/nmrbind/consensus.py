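"""Residue-number ↔ consensus-column mapping from a multiple sequence alignment.

Homologous proteins differ in length and numbering; plotting per-residue
quantities on a common axis requires mapping each protein's 1-based residue
index onto the 1-based column of the (gapped) alignment.  Alignments are
consumed, never computed, here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from Bio import AlignIO

from .errors import IntegrityError, PeakListFormatError

__all__ = ["AlignmentMap", "build_map", "to_consensus", "from_consensus"]

GAP_CHARS = {"-", "."}


@dataclass
class AlignmentMap:
    """Per-protein strictly increasing residue→column mappings."""

    maps: dict[str, dict[int, int]]
    consensus_length: int

    def proteins(self) -> list[str]:
        return sorted(self.maps)


def build_map(msa_path: str | Path) -> AlignmentMap:
    """Build residue→column maps from an aligned FASTA file.

    Column k (1-based) is assigned to the residue whose cumulative
    non-gap count at k equals its sequence index.  Gap characters are
    '-' and '.'.
    """
    try:
        alignment = AlignIO.read(str(msa_path), "fasta")
    except ValueError as exc:
        raise PeakListFormatError(f"{msa_path}: not a valid aligned FASTA ({exc})") from exc
    maps: dict[str, dict[int, int]] = {}
    length = alignment.get_alignment_length()
    for record in alignment:
        if record.id in maps:
            raise IntegrityError(f"duplicate sequence id {record.id!r} in alignment")
        seq = str(record.seq)
        if len(seq) != length:
            raise PeakListFormatError("ragged alignment: sequences differ in length")
        mapping: dict[int, int] = {}
        residue = 0
        for col, char in enumerate(seq, start=1):
            if char not in GAP_CHARS:
                residue += 1
                mapping[residue] = col
        maps[record.id] = mapping
    return AlignmentMap(maps=maps, consensus_length=length)


def to_consensus(amap: AlignmentMap, protein_id: str, residue_index: int) -> int:
    """Consensus column of a residue; raises on unknown protein or out-of-range index."""
    if protein_id not in amap.maps:
        raise KeyError(f"unknown protein {protein_id!r}")
    mapping = amap.maps[protein_id]
    if residue_index not in mapping:
        raise IndexError(
            f"residue {residue_index} out of range for {protein_id} "
            f"(1..{len(mapping)})"
        )
    return mapping[residue_index]


def from_consensus(amap: AlignmentMap, protein_id: str, column: int) -> int | None:
    """Residue at a consensus column, or None when the column is a gap."""
    if protein_id not in amap.maps:
        raise KeyError(f"unknown protein {protein_id!r}")
    if not (1 <= column <= amap.consensus_length):
        raise IndexError(f"column {column} outside 1..{amap.consensus_length}")
    inverse = {c: r for r, c in amap.maps[protein_id].items()}
    return inverse.get(column)
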