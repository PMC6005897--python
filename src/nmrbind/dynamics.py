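"""Coordinated vs uncoordinated dynamical changes across three protein states.

A residue's millisecond exchange is summarized by a boolean per state
(apo, ligand A-bound, ligand B-bound) from the ΔR2 dispersion screen.
A gain (or loss) of exchange in *both* bound states relative to apo is a
coordinated change; a gain or loss in *only one* bound state is
uncoordinated.  The result can be overlaid with the shift-projection
classes and annotated with distance from the catalytic residues.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import pandas as pd

from .chespa import ChespaClass, ChespaRecord
from .errors import PeakListFormatError

__all__ = [
    "ChangeClass",
    "DynamicsChangeRecord",
    "classify_change",
    "build_change_records",
    "overlay_chespa",
    "annotate_distal",
]


class ChangeClass(str, Enum):
    COORDINATED_GAIN = "coordinated_gain"
    COORDINATED_LOSS = "coordinated_loss"
    UNCOORDINATED = "uncoordinated"
    UNCHANGED = "unchanged"


@dataclass
class DynamicsChangeRecord:
    residue_index: int
    dispersive_apo: bool
    dispersive_A: bool
    dispersive_B: bool
    change_class: ChangeClass
    chespa_class: ChespaClass | None = None
    distal: bool | None = None
    min_distance_A: float | None = None


def classify_change(
    dispersive_apo: bool, dispersive_A: bool, dispersive_B: bool
) -> ChangeClass:
    """Truth table over the three per-state dispersion flags.

    (apo, A, B):
      (F, T, T) → coordinated gain; (T, F, F) → coordinated loss;
      exactly one bound state differing from apo → uncoordinated;
      (F, F, F) and (T, T, T) → unchanged.
    """
    a, b = dispersive_A != dispersive_apo, dispersive_B != dispersive_apo
    if a and b:
        return ChangeClass.COORDINATED_LOSS if dispersive_apo else ChangeClass.COORDINATED_GAIN
    if a or b:
        return ChangeClass.UNCOORDINATED
    return ChangeClass.UNCHANGED


def build_change_records(
    apo_flags: dict[int, bool],
    boundA_flags: dict[int, bool],
    boundB_flags: dict[int, bool],
) -> list[DynamicsChangeRecord]:
    """Classify every residue screened in all three states."""
    shared = set(apo_flags) & set(boundA_flags) & set(boundB_flags)
    records = []
    for idx in sorted(shared):
        fa, fA, fB = apo_flags[idx], boundA_flags[idx], boundB_flags[idx]
        records.append(
            DynamicsChangeRecord(idx, fa, fA, fB, classify_change(fa, fA, fB))
        )
    return records


def overlay_chespa(
    dynamics: list[DynamicsChangeRecord],
    chespa: list[ChespaRecord],
) -> tuple[pd.DataFrame, dict]:
    """Join dynamics classes with shift-projection classes per residue.

    Returns the joined table and a summary with class cross-counts and the
    concordance fraction: among residues classified by both analyses (and
    not CHESPA-excluded / dynamics-unchanged), the fraction whose
    coordinated/uncoordinated labels agree.
    """
    chespa_by_idx = {r.residue_index: r for r in chespa}
    rows = []
    for d in dynamics:
        c = chespa_by_idx.get(d.residue_index)
        d.chespa_class = c.classification if c is not None else None
        rows.append(
            {
                "residue_index": d.residue_index,
                "change_class": d.change_class.value,
                "chespa_class": c.classification.value if c is not None else "dynamics-only",
                "cos_theta": c.cos_theta if c is not None else float("nan"),
                "fractional_shift_X": c.fractional_shift_X if c is not None else float("nan"),
            }
        )
    table = pd.DataFrame(rows)
    if table.empty:
        warnings.warn("overlay: no shared residues between dynamics and projection analyses")
        return table, {"counts": {}, "concordance": float("nan"), "n_comparable": 0}

    counts = (
        table.groupby(["change_class", "chespa_class"]).size().to_dict()
        if len(table)
        else {}
    )
    coord_dyn = {ChangeClass.COORDINATED_GAIN.value, ChangeClass.COORDINATED_LOSS.value}
    comparable = table[
        (table["chespa_class"].isin(["coordinated", "uncoordinated"]))
        & (table["change_class"] != ChangeClass.UNCHANGED.value)
    ]
    if len(comparable):
        agree = (
            (comparable["change_class"].isin(coord_dyn) & (comparable["chespa_class"] == "coordinated"))
            | ((comparable["change_class"] == ChangeClass.UNCOORDINATED.value)
               & (comparable["chespa_class"] == "uncoordinated"))
        )
        concordance = float(agree.mean())
    else:
        concordance = float("nan")
    summary = {
        "counts": {f"{k[0]}|{k[1]}": int(v) for k, v in counts.items()},
        "concordance": concordance,
        "n_comparable": int(len(comparable)),
    }
    return table, summary


def annotate_distal(
    records: list[DynamicsChangeRecord],
    structure_path: str | Path,
    catalytic_residues: list[int],
    cutoff: float = 6.0,
    chain_id: str | None = None,
) -> list[DynamicsChangeRecord]:
    """Flag residues farther than ``cutoff`` Å from the catalytic residues.

    The distance is the minimum over all heavy-atom pairs between the
    residue and any catalytic residue; ``distal`` is strict
    (min_distance > cutoff).  Residues absent from the structure keep
    ``distal=None`` rather than raising.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionException

    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure("s", str(structure_path))
    except (PDBConstructionException, ValueError) as exc:
        raise PeakListFormatError(f"malformed coordinate file: {exc}") from exc
    models = list(structure)
    if not models:
        raise PeakListFormatError(f"{structure_path}: no models in coordinate file")
    chains = list(models[0])
    if chain_id is not None:
        chains = [c for c in chains if c.id == chain_id]
        if not chains:
            raise PeakListFormatError(f"chain {chain_id!r} not found in {structure_path}")

    def heavy_atoms(residue):
        return [a for a in residue if a.element != "H"]

    by_index: dict[int, list] = {}
    for chain in chains:
        for residue in chain:
            if residue.id[0] != " ":  # skip hetero/water
                continue
            by_index.setdefault(residue.id[1], []).extend(heavy_atoms(residue))

    cat_atoms = [a for idx in catalytic_residues for a in by_index.get(idx, [])]
    if not cat_atoms:
        raise PeakListFormatError(
            f"none of the catalytic residues {catalytic_residues} found in structure"
        )
    for rec in records:
        atoms = by_index.get(rec.residue_index)
        if not atoms:
            rec.distal = None
            rec.min_distance_A = None
            continue
        dmin = min(a - b for a in atoms for b in cat_atoms)
        rec.min_distance_A = float(dmin)
        rec.distal = bool(dmin > cutoff)
    return records
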