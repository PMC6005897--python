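"""Chemical-shift perturbations and global dissociation-constant fitting.

The compounded perturbation between two states combines the ¹H and scaled
¹⁵N shift changes,

    Δδ_obs = sqrt( (Δδ_H² + (w·Δδ_N)²) / 2 ),   w = 0.2 by default,

and, in the fast-exchange regime, tracks the bound fraction of a single-site
binding equilibrium.  The bound fraction follows the quadratic isotherm in
total concentrations

    f([P]t, [L]t; Kd) = ( b − sqrt(b² − 4 [L]t [P]t) ) / (2 [P]t),
    b = [P]t + [L]t + Kd,

so that per residue r and titration point i

    Δδ_obs(r, i) = Δδ_max(r) · f([P]t_i, [L]t_i; Kd)

with a single Kd shared by all residues.  ``global_kd_fit`` solves this
nonlinear least-squares problem over {Kd, Δδ_max(r)}.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import lmfit

from .errors import AnalysisError
from .peaklist import PeakList, TitrationSeries, match_states

__all__ = [
    "CSPRecord",
    "BindingCurve",
    "KdFitResult",
    "compute_csp",
    "fraction_bound",
    "global_kd_fit",
    "select_affected_residues",
]

DEFAULT_N_WEIGHT = 0.2

# Kd search bounds in μM: spans sub-μM tight binders to the >10 mM
# very-weak mononucleotide regime.
KD_BOUNDS_UM = (1e-2, 1e7)


@dataclass
class CSPRecord:
    """Per-residue shift change between a bound state and apo."""

    residue_index: int
    delta_H: float
    delta_N: float
    delta_obs: float
    state_label: str
    missing: bool = False


@dataclass
class BindingCurve:
    """Δδ_obs of one residue as a function of ligand concentration."""

    residue_index: int
    observations: list[tuple[float, float, float]]  # (P_total, L_total, delta_obs)


@dataclass
class KdFitResult:
    """Outcome of the global single-site fit.

    ``Kd_sd`` is the standard deviation of the fitted Kd (from the
    covariance of the converged fit); ``delta_max`` maps residue index to
    (value, sd) in ppm.
    """

    Kd: float
    Kd_sd: float
    delta_max: dict[int, tuple[float, float]]
    residuals: np.ndarray
    n_residues: int
    converged: bool
    redchi: float = float("nan")
    dropped_residues: list[int] = field(default_factory=list)


def compounded_shift(delta_H, delta_N, n_weight: float = DEFAULT_N_WEIGHT):
    """Weighted-average (compounded) shift change in ppm."""
    delta_H = np.asarray(delta_H, dtype=float)
    delta_N = np.asarray(delta_N, dtype=float)
    return np.sqrt((delta_H**2 + (n_weight * delta_N) ** 2) / 2.0)


def compute_csp(
    apo: PeakList,
    bound: PeakList,
    n_weight: float = DEFAULT_N_WEIGHT,
) -> list[CSPRecord]:
    """Compounded shift perturbations of ``bound`` relative to ``apo``.

    One record per residue paired across the two states; residues present
    in only one state are appended with ``missing=True`` (zero shifts) so
    that exchange-broadening losses remain visible downstream.
    """
    match = match_states(apo, bound)
    records: list[CSPRecord] = []
    for idx in sorted(match.paired):
        ra, rb = apo[idx], bound[idx]
        if ra.missing_flag or rb.missing_flag:
            records.append(CSPRecord(idx, 0.0, 0.0, 0.0, bound.state_label, missing=True))
            continue
        dh = rb.shift_H - ra.shift_H
        dn = rb.shift_N - ra.shift_N
        records.append(
            CSPRecord(idx, dh, dn, float(compounded_shift(dh, dn, n_weight)), bound.state_label)
        )
    for idx in sorted(match.only_a | match.only_b):
        records.append(CSPRecord(idx, 0.0, 0.0, 0.0, bound.state_label, missing=True))
    if all(r.missing for r in records):
        raise AnalysisError("no paired residues with observable shifts")
    return records


def fraction_bound(P_total, L_total, Kd):
    """Bound fraction of protein from the single-site quadratic isotherm.

    All concentrations share one unit (μM conventionally).  Valid for any
    [P]t > 0, including the tight-binding regime [P]t > Kd where the
    hyperbolic approximation fails.
    """
    P = np.asarray(P_total, dtype=float)
    L = np.asarray(L_total, dtype=float)
    if np.any(P <= 0):
        raise ValueError("P_total must be positive")
    if np.any(L < 0):
        raise ValueError("L_total must be non-negative")
    if np.any(np.asarray(Kd) <= 0):
        raise ValueError("Kd must be positive")
    b = P + L + Kd
    disc = b * b - 4.0 * L * P
    # disc >= (P - L + Kd)^2 - 4*Kd*... always non-negative analytically;
    # clip guards rounding when L ~ P and Kd -> 0.
    f = (b - np.sqrt(np.clip(disc, 0.0, None))) / (2.0 * P)
    return f if f.ndim else float(f)


def build_binding_curves(
    series: TitrationSeries, n_weight: float = DEFAULT_N_WEIGHT
) -> dict[int, BindingCurve]:
    """Per-residue Δδ_obs vs ligand concentration, relative to the apo point."""
    apo = series.apo
    curves: dict[int, BindingCurve] = {}
    for p_tot, l_tot, pl in series.points:
        if l_tot == 0.0:
            for idx in apo.residue_indices():
                curves.setdefault(idx, BindingCurve(idx, [])).observations.append(
                    (p_tot, 0.0, 0.0)
                )
            continue
        for rec in compute_csp(apo, pl, n_weight):
            if rec.missing:
                continue
            curves.setdefault(
                rec.residue_index, BindingCurve(rec.residue_index, [])
            ).observations.append((p_tot, l_tot, rec.delta_obs))
    return curves


def select_affected_residues(
    csp: list[CSPRecord], threshold: float = 0.05
) -> set[int]:
    """Residues with Δδ_obs strictly above ``threshold`` ppm.

    Applied at the highest ligand ratio; the comparison is strict, so a
    residue sitting exactly at the threshold is excluded.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return {r.residue_index for r in csp if not r.missing and r.delta_obs > threshold}


def global_kd_fit(
    series: TitrationSeries,
    residue_filter: set[int] | None = None,
    n_weight: float = DEFAULT_N_WEIGHT,
    max_nfev: int | None = None,
) -> KdFitResult:
    """Simultaneously fit one Kd and per-residue Δδ_max to all binding curves.

    Parameters
    ----------
    series : TitrationSeries
        Titration with an apo first point and ≥ 2 liganded points.
    residue_filter : set of int, optional
        Residues to include (e.g. from :func:`select_affected_residues`).
        ``None`` uses every residue with a nonzero curve.
    n_weight : float
        ¹⁵N scaling of the compounded shift.

    Notes
    -----
    Kd is fitted in log-space (bounds 1e-2..1e7 μM) with a trust-region
    reflective solver; it is initialized at the midpoint of the ligand
    concentrations and each Δδ_max at the residue's final-point Δδ_obs.
    Residues with an all-zero curve are dropped with a warning.  A fit that
    exhausts its iteration budget returns ``converged=False`` rather than
    raising.
    """
    liganded = [(p, l) for p, l, _ in series.points if l > 0]
    if len(liganded) < 2:
        raise AnalysisError("need at least 2 titration points with ligand")
    curves = build_binding_curves(series, n_weight)
    if residue_filter is not None:
        if not residue_filter:
            raise AnalysisError("residue_filter is empty")
        curves = {i: c for i, c in curves.items() if i in residue_filter}

    dropped: list[int] = []
    usable: dict[int, BindingCurve] = {}
    for idx, curve in sorted(curves.items()):
        obs = [o for o in curve.observations if o[1] > 0]
        if len(obs) < 3:
            dropped.append(idx)
            continue
        if all(o[2] == 0.0 for o in obs):
            warnings.warn(f"residue {idx}: all-zero shift curve, dropped from Kd fit")
            dropped.append(idx)
            continue
        usable[idx] = BindingCurve(idx, obs)
    if not usable:
        raise AnalysisError("no usable residues for the global Kd fit")

    l_values = sorted({l for _, l in liganded})
    kd_init = 0.5 * (l_values[0] + l_values[-1])
    kd_init = float(np.clip(kd_init, *KD_BOUNDS_UM))

    params = lmfit.Parameters()
    params.add("log10_Kd", value=np.log10(kd_init),
               min=np.log10(KD_BOUNDS_UM[0]), max=np.log10(KD_BOUNDS_UM[1]))
    res_ids = sorted(usable)
    for idx in res_ids:
        final = usable[idx].observations[-1][2]
        params.add(f"dmax_{idx}", value=max(final, 1e-4), min=0.0)

    P = {idx: np.array([o[0] for o in usable[idx].observations]) for idx in res_ids}
    L = {idx: np.array([o[1] for o in usable[idx].observations]) for idx in res_ids}
    Y = {idx: np.array([o[2] for o in usable[idx].observations]) for idx in res_ids}

    def residual(p: lmfit.Parameters) -> np.ndarray:
        kd = 10.0 ** p["log10_Kd"].value
        out = []
        for idx in res_ids:
            f = fraction_bound(P[idx], L[idx], kd)
            out.append(p[f"dmax_{idx}"].value * f - Y[idx])
        return np.concatenate(out)

    minimizer = lmfit.Minimizer(residual, params)
    fit = minimizer.least_squares(max_nfev=max_nfev)
    converged = bool(fit.success)

    kd = 10.0 ** fit.params["log10_Kd"].value
    log_sd = fit.params["log10_Kd"].stderr
    kd_sd = float(kd * np.log(10.0) * log_sd) if log_sd is not None else float("nan")
    dmax = {}
    for idx in res_ids:
        par = fit.params[f"dmax_{idx}"]
        dmax[idx] = (float(par.value), float(par.stderr) if par.stderr is not None else float("nan"))
    return KdFitResult(
        Kd=float(kd),
        Kd_sd=kd_sd,
        delta_max=dmax,
        residuals=np.asarray(fit.residual),
        n_residues=len(res_ids),
        converged=converged,
        redchi=float(fit.redchi),
        dropped_residues=dropped,
    )
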