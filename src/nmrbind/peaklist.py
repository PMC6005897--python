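"""Assigned 2-D ¹H-¹⁵N peak lists: data model, Sparky-style I/O, state matching.

A :class:`PeakList` holds the backbone-amide resonances of one protein state
(apo or a given enzyme:ligand ratio); a :class:`TitrationSeries` orders such
states along a ligand-concentration axis.  Shifts are stored in ppm only —
any Hz conversion happens downstream where the static field is known.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from .errors import AnalysisError, IntegrityError, PeakListFormatError

__all__ = [
    "Resonance",
    "PeakList",
    "TitrationSeries",
    "MatchResult",
    "read_peak_list",
    "write_peak_list",
    "match_states",
]

#: Sparky assignment token, e.g. "T45N-H" or "K41N-H".
_ASSIGNMENT_RE = re.compile(r"^([A-Za-z])(\d+)N-?H?$")


@dataclass
class Resonance:
    """One assigned amide cross-peak.

    Parameters
    ----------
    residue_index : int
        Author (sequence) numbering, 1-based.
    residue_label : str
        One-letter code + index, e.g. ``"T45"``.
    shift_N : float
        ¹⁵N chemical shift (ω1) in ppm.
    shift_H : float
        ¹H chemical shift (ω2) in ppm.
    intensity : float, optional
        Peak height/volume in arbitrary units.
    missing_flag : bool
        True when the peak is broadened beyond detection in this state; the
        resonance is retained so downstream stages can report the loss.
    """

    residue_index: int
    residue_label: str
    shift_N: float
    shift_H: float
    intensity: float | None = None
    missing_flag: bool = False

    def __post_init__(self) -> None:
        if self.residue_index < 1:
            raise IntegrityError(f"residue_index must be >= 1, got {self.residue_index}")
        if not self.missing_flag:
            if not (-2.0 <= self.shift_H <= 15.0):
                raise IntegrityError(
                    f"{self.residue_label}: shift_H {self.shift_H} ppm outside [-2, 15]"
                )
            if not (90.0 <= self.shift_N <= 140.0):
                raise IntegrityError(
                    f"{self.residue_label}: shift_N {self.shift_N} ppm outside [90, 140]"
                )


@dataclass
class PeakList:
    """All assigned resonances of one protein state."""

    state_label: str
    field_MHz: float
    resonances: dict[int, Resonance] = field(default_factory=dict)
    n_skipped_rows: int = 0

    def add(self, res: Resonance) -> None:
        if res.residue_index in self.resonances:
            raise IntegrityError(
                f"duplicate assignment for residue {res.residue_label}"
            )
        self.resonances[res.residue_index] = res

    def __len__(self) -> int:
        return len(self.resonances)

    def __iter__(self) -> Iterator[Resonance]:
        return iter(self.resonances.values())

    def __getitem__(self, residue_index: int) -> Resonance:
        return self.resonances[residue_index]

    def __contains__(self, residue_index: int) -> bool:
        return residue_index in self.resonances

    def residue_indices(self) -> set[int]:
        return set(self.resonances)


@dataclass
class TitrationSeries:
    """Ordered titration points (P_total μM, L_total μM, PeakList).

    The first point must be the apo state (L_total = 0) and ligand
    concentration must be non-decreasing across points.
    """

    protein_id: str
    ligand_id: str
    points: list[tuple[float, float, PeakList]]

    def __post_init__(self) -> None:
        if not self.points:
            raise IntegrityError("TitrationSeries needs at least one point")
        if self.points[0][1] != 0.0:
            raise IntegrityError("first titration point must be apo (L_total = 0)")
        last = -1.0
        for p_tot, l_tot, _ in self.points:
            if p_tot <= 0:
                raise IntegrityError("P_total must be positive at every point")
            if l_tot < last:
                raise IntegrityError("L_total must be non-decreasing across points")
            last = l_tot

    @property
    def apo(self) -> PeakList:
        return self.points[0][2]

    @property
    def saturated(self) -> PeakList:
        """Peak list at the highest ligand ratio."""
        return self.points[-1][2]

    def __len__(self) -> int:
        return len(self.points)


def _parse_assignment(token: str) -> tuple[int, str] | None:
    m = _ASSIGNMENT_RE.match(token)
    if m is None:
        return None
    letter, idx = m.group(1), int(m.group(2))
    return idx, f"{letter}{idx}"


def read_peak_list(
    path: str | Path,
    dialect: str = "sparky",
    state_label: str | None = None,
    field_MHz: float = 800.0,
) -> PeakList:
    """Read a Sparky-style ``.list`` file into a :class:`PeakList`.

    Data rows are whitespace-delimited: assignment token (``T45N-H``),
    ¹⁵N shift (ppm), ¹H shift (ppm), and an optional intensity column.
    Lines that are blank or start with ``Assignment`` are headers.  Rows
    whose assignment token does not parse are skipped and counted in
    ``PeakList.n_skipped_rows``.
    """
    if dialect != "sparky":
        raise ValueError(f"unknown peak-list dialect {dialect!r}")
    path = Path(path)
    text = path.read_text()
    pl = PeakList(state_label=state_label or path.stem, field_MHz=field_MHz)
    n_rows = 0
    for line in text.splitlines():
        stripped = line.strip()
        if not stripped or stripped.startswith("Assignment"):
            continue
        n_rows += 1
        parts = stripped.split()
        parsed = _parse_assignment(parts[0]) if parts else None
        if parsed is None or len(parts) < 3:
            pl.n_skipped_rows += 1
            continue
        idx, label = parsed
        try:
            shift_n, shift_h = float(parts[1]), float(parts[2])
        except ValueError:
            pl.n_skipped_rows += 1
            continue
        intensity = None
        if len(parts) >= 4:
            try:
                intensity = float(parts[3])
            except ValueError:
                intensity = None
        pl.add(Resonance(idx, label, shift_n, shift_h, intensity))
    if n_rows > 0 and len(pl) == 0:
        raise PeakListFormatError(f"{path}: no parseable peak rows")
    if n_rows == 0 and "w1" not in text and "Assignment" not in text:
        raise PeakListFormatError(f"{path}: empty peak-list file")
    return pl


def write_peak_list(pl: PeakList, path: str | Path) -> int:
    """Write a :class:`PeakList` as a Sparky-style list.

    Resonances carrying ``missing_flag`` are omitted from the table (they
    have no observable position); their count is recorded in a comment-free
    sidecar line of the header.  Returns the number of rows written.
    """
    path = Path(path)
    lines = [f"{'Assignment':>12} {'w1':>9} {'w2':>9} {'height':>12}"]
    n_missing = sum(1 for r in pl if r.missing_flag)
    n = 0
    for res in sorted(pl, key=lambda r: r.residue_index):
        if res.missing_flag:
            continue
        inten = f"{res.intensity:12.3f}" if res.intensity is not None else " " * 12
        lines.append(
            f"{res.residue_label + 'N-H':>12} {res.shift_N:9.4f} {res.shift_H:9.4f} {inten}".rstrip()
        )
        n += 1
    lines.append("")
    path.write_text("\n".join(lines))
    if n_missing:
        Path(str(path) + ".missing").write_text(f"{n_missing}\n")
    return n


@dataclass
class MatchResult:
    """Residues paired across two states, plus those seen in only one.

    Unmatched residues are candidates for exchange broadening and must be
    reported downstream, never silently dropped.
    """

    paired: set[int]
    only_a: set[int]
    only_b: set[int]


def match_states(a: PeakList, b: PeakList) -> MatchResult:
    """Intersect two peak lists on residue index."""
    if len(a) == 0 or len(b) == 0:
        raise AnalysisError("cannot match empty peak lists")
    ia, ib = a.residue_indices(), b.residue_indices()
    paired = ia & ib
    if not paired:
        raise AnalysisError(
            f"no residues shared between states {a.state_label!r} and {b.state_label!r}"
        )
    return MatchResult(paired=paired, only_a=ia - paired, only_b=ib - paired)
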