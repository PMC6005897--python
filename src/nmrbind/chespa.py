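"""Chemical shift projection analysis of two ligand-bound states versus apo.

Each residue's peak displacement from apo to bound state 1 (vector A) and
apo to bound state 2 (vector B) is formed in the weighted shift plane
(Δδ_H, w·Δδ_N).  Two scalars compare the displacements:

    cos θ = A·B / (|A||B|)      — direction agreement,
    X     = A·B / |B|²          — signed magnitude of A projected on B.

Residues whose displacements satisfy cos θ ≥ 0.9 with similar magnitudes
move along a common direction for both ligands ("coordinated"); residues
with cos θ < 0.9 respond differently to the two ligands ("uncoordinated").
Residues whose perturbation never exceeds the Δδ_obs filter are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .peaklist import PeakList
from .titration import DEFAULT_N_WEIGHT, compounded_shift

__all__ = [
    "ShiftVector",
    "ChespaClass",
    "ChespaRecord",
    "build_vectors",
    "projection_angle",
    "fractional_shift",
    "classify",
    "run_chespa",
]


class ChespaClass(str, Enum):
    COORDINATED = "coordinated"
    UNCOORDINATED = "uncoordinated"
    EXCLUDED = "excluded"


@dataclass
class ShiftVector:
    """Peak displacement in the (Δδ_H, n_weight·Δδ_N) ppm plane."""

    residue_index: int
    comp_H: float
    comp_N_scaled: float

    @property
    def norm(self) -> float:
        return float(np.hypot(self.comp_H, self.comp_N_scaled))

    def dot(self, other: "ShiftVector") -> float:
        return self.comp_H * other.comp_H + self.comp_N_scaled * other.comp_N_scaled


@dataclass
class ChespaRecord:
    residue_index: int
    cos_theta: float  # NaN when either vector has zero length
    fractional_shift_X: float
    delta_obs_A: float
    delta_obs_B: float
    classification: ChespaClass = ChespaClass.EXCLUDED
    note: str = ""


def build_vectors(
    apo: PeakList,
    boundA: PeakList,
    boundB: PeakList,
    n_weight: float = DEFAULT_N_WEIGHT,
) -> tuple[dict[int, tuple[ShiftVector, ShiftVector]], list[int]]:
    """Per-residue (A, B) displacement vectors from three matched states.

    Returns the vector pairs keyed by residue index and the list of residues
    skipped because they are unobserved in at least one state.
    """
    shared = (
        apo.residue_indices() & boundA.residue_indices() & boundB.residue_indices()
    )
    everything = (
        apo.residue_indices() | boundA.residue_indices() | boundB.residue_indices()
    )
    skipped = sorted(everything - shared)
    pairs: dict[int, tuple[ShiftVector, ShiftVector]] = {}
    for idx in sorted(shared):
        r0, ra, rb = apo[idx], boundA[idx], boundB[idx]
        if r0.missing_flag or ra.missing_flag or rb.missing_flag:
            skipped.append(idx)
            continue
        va = ShiftVector(idx, ra.shift_H - r0.shift_H, n_weight * (ra.shift_N - r0.shift_N))
        vb = ShiftVector(idx, rb.shift_H - r0.shift_H, n_weight * (rb.shift_N - r0.shift_N))
        pairs[idx] = (va, vb)
    return pairs, sorted(skipped)


def projection_angle(A: ShiftVector, B: ShiftVector) -> float:
    """cos θ between the two displacement vectors; raises on zero vectors."""
    na, nb = A.norm, B.norm
    if na == 0.0 or nb == 0.0:
        raise ZeroDivisionError("projection angle undefined for zero-length shift vector")
    return float(np.clip(A.dot(B) / (na * nb), -1.0, 1.0))


def fractional_shift(A: ShiftVector, B: ShiftVector) -> float:
    """Signed fractional shift X = A·B/|B|²; negative means anti-parallel."""
    nb = B.norm
    if nb == 0.0:
        raise ZeroDivisionError("fractional shift undefined for |B| = 0")
    return float(A.dot(B) / (nb * nb))


def classify(
    record: ChespaRecord,
    cos_threshold: float = 0.9,
    csp_threshold_ppm: float = 0.05,
    x_tol: float = 2.0,
) -> ChespaClass:
    """Assign coordinated / uncoordinated / excluded to one record.

    Excluded when neither ligand perturbs the residue beyond the Δδ_obs
    filter (strict >, applied to either bound state) or when the angle is
    undefined.  Otherwise coordinated requires cos θ ≥ ``cos_threshold``
    and a similar displacement magnitude, operationalized as
    X ∈ [1/x_tol, x_tol]; anything else is uncoordinated.
    """
    if max(record.delta_obs_A, record.delta_obs_B) <= csp_threshold_ppm:
        return ChespaClass.EXCLUDED
    if not np.isfinite(record.cos_theta):
        return ChespaClass.EXCLUDED
    if record.cos_theta >= cos_threshold and (
        1.0 / x_tol <= record.fractional_shift_X <= x_tol
    ):
        return ChespaClass.COORDINATED
    return ChespaClass.UNCOORDINATED


def run_chespa(
    apo: PeakList,
    boundA: PeakList,
    boundB: PeakList,
    n_weight: float = DEFAULT_N_WEIGHT,
    cos_threshold: float = 0.9,
    csp_threshold_ppm: float = 0.05,
    x_tol: float = 2.0,
) -> list[ChespaRecord]:
    """Full projection analysis across three states at saturation."""
    pairs, skipped = build_vectors(apo, boundA, boundB, n_weight)
    records: list[ChespaRecord] = []
    for idx, (va, vb) in pairs.items():
        # Compounded Δδ_obs for the filter re-uses the same shift components;
        # comp_N_scaled already carries n_weight, so unscale for the formula.
        da = float(compounded_shift(va.comp_H, va.comp_N_scaled / n_weight, n_weight))
        db = float(compounded_shift(vb.comp_H, vb.comp_N_scaled / n_weight, n_weight))
        try:
            cos_t = projection_angle(va, vb)
            x = fractional_shift(va, vb)
            note = ""
        except ZeroDivisionError:
            cos_t, x, note = float("nan"), float("nan"), "zero-length shift vector"
        rec = ChespaRecord(idx, cos_t, x, da, db, note=note)
        rec.classification = classify(rec, cos_threshold, csp_threshold_ppm, x_tol)
        records.append(rec)
    for idx in skipped:
        records.append(
            ChespaRecord(idx, float("nan"), float("nan"), 0.0, 0.0,
                         classification=ChespaClass.EXCLUDED,
                         note="missing in at least one state")
        )
    return records
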