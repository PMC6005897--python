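"""CSP arithmetic, the quadratic binding isotherm, and the global Kd fit."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import nmrbind as nb
from nmrbind.errors import AnalysisError
from nmrbind.synthetic import TitrationSpec, generate_titration, ratio_grid
from nmrbind.titration import compounded_shift

from conftest import make_peaklist


class TestCompoundedShift:
    @pytest.mark.parametrize(
        "dh, dn, expected",
        [
            (0.0, 0.0, 0.0),
            (0.1, 0.5, 0.1),                 # sqrt((0.01 + 0.01)/2)
            (0.0, 1.0, 0.2 / np.sqrt(2.0)),  # pure nitrogen displacement
        ],
    )
    def test_hand_values(self, dh, dn, expected):
        assert compounded_shift(dh, dn) == pytest.approx(expected, abs=1e-12)

    def test_compute_csp_on_matched_states(self):
        apo = make_peaklist({1: (8.0, 120.0), 2: (8.5, 115.0)})
        bound = make_peaklist({1: (8.1, 120.5), 2: (8.5, 115.0)})
        recs = nb.compute_csp(apo, bound)
        by_idx = {r.residue_index: r for r in recs}
        assert by_idx[1].delta_obs == pytest.approx(0.1, abs=1e-12)
        assert by_idx[2].delta_obs == 0.0

    def test_unmatched_residue_reported_not_dropped(self):
        apo = make_peaklist({1: (8.0, 120.0), 2: (8.5, 115.0)})
        bound = make_peaklist({1: (8.1, 120.5)})
        recs = nb.compute_csp(apo, bound)
        missing = [r for r in recs if r.missing]
        assert [r.residue_index for r in missing] == [2]


class TestFractionBound:
    def test_zero_ligand_gives_zero(self):
        assert nb.fraction_bound(300.0, 0.0, 100.0) == 0.0

    def test_stoichiometric_limit(self):
        # Kd -> 0 with excess ligand drives the protein fully bound
        assert nb.fraction_bound(100.0, 150.0, 1e-9) == pytest.approx(1.0, abs=1e-6)

    def test_dilute_protein_closed_form_value(self):
        assert nb.fraction_bound(1.0, 100.0, 100.0) == pytest.approx(0.49875, abs=1e-5)

    def test_agrees_with_hyperbola_when_protein_dilute(self):
        kd = 500.0
        p = kd / 200.0  # well below Kd/100
        for l_tot in [10.0, 100.0, 1000.0, 5000.0]:
            f = nb.fraction_bound(p, l_tot, kd)
            hyper = l_tot / (l_tot + kd)
            assert abs(f - hyper) / hyper < 0.01

    def test_rejects_nonpositive_inputs(self):
        with pytest.raises(ValueError):
            nb.fraction_bound(0.0, 10.0, 100.0)
        with pytest.raises(ValueError):
            nb.fraction_bound(300.0, 10.0, -1.0)

    @given(
        kd=st.floats(1.0, 1e5),
        p=st.floats(1.0, 1e3),
        l1=st.floats(0.0, 1e5),
        l2=st.floats(0.0, 1e5),
    )
    @settings(max_examples=200, derandomize=True)
    def test_monotone_in_ligand_and_bounded(self, kd, p, l1, l2):
        lo, hi = sorted([l1, l2])
        f_lo, f_hi = nb.fraction_bound(p, lo, kd), nb.fraction_bound(p, hi, kd)
        assert -1e-12 <= f_lo <= f_hi + 1e-12
        assert f_hi <= min(1.0, hi / p) + 1e-9


def _series(kd, seed=0, noise=(0.0, 0.0), ratios=None, n_residues=5):
    return generate_titration(
        TitrationSpec(
            Kd_true=kd,
            ratios=ratios or ratio_grid(12.0),
            n_residues=n_residues,
            noise_sd_H=noise[0],
            noise_sd_N=noise[1],
            seed=seed,
        )
    )


class TestGlobalKdFit:
    def test_noiseless_recovery_within_0p1_percent(self):
        series = _series(300.0, seed=4)
        fit = nb.global_kd_fit(series)
        assert fit.converged
        assert fit.Kd == pytest.approx(300.0, rel=1e-3)
        # all planted saturation shifts recovered too
        for idx, (val, _) in fit.delta_max.items():
            assert val > 0

    def test_matches_brute_force_grid_oracle_single_residue(self):
        """Grid search over Kd (shared-shape SSE) agrees with the optimizer."""
        series = _series(450.0, seed=9, n_residues=1)
        curves = [(p, l) for p, l, _ in series.points if l > 0]
        csp_by_point = []
        for p_tot, l_tot, pl in series.points:
            if l_tot == 0:
                continue
            rec = nb.compute_csp(series.apo, pl)[0]
            csp_by_point.append((p_tot, l_tot, rec.delta_obs))
        obs = np.array([d for _, _, d in csp_by_point])
        kd_grid = np.arange(1.0, 100001.0)
        sse = np.empty_like(kd_grid)
        for i, kd in enumerate(kd_grid):
            f = np.array([nb.fraction_bound(p, l, kd) for p, l, _ in csp_by_point])
            # optimal delta_max for fixed Kd is the least-squares slope
            dmax = (f @ obs) / (f @ f)
            sse[i] = ((dmax * f - obs) ** 2).sum()
        kd_oracle = kd_grid[np.argmin(sse)]
        fit = nb.global_kd_fit(series)
        assert abs(fit.Kd - kd_oracle) <= 1.0

    def test_recovery_with_noise_within_fit_sd(self):
        series = _series(455.9, seed=21, noise=(0.002, 0.01), n_residues=20)
        fit = nb.global_kd_fit(series)
        assert abs(fit.Kd - 455.9) < 3.0 * fit.Kd_sd + 1e-9

    def test_invariant_under_residue_permutation(self):
        series = _series(300.0, seed=4)
        full = nb.global_kd_fit(series, residue_filter=set(range(1, 6)))
        subset_order = nb.global_kd_fit(series, residue_filter={5, 3, 1, 2, 4})
        assert full.Kd == pytest.approx(subset_order.Kd, rel=1e-9)

    def test_invariant_under_common_concentration_rescale(self):
        # Rescaling all concentrations and Kd by 10x is a pure units change
        s1 = _series(200.0, seed=13)
        s2 = nb.TitrationSeries(
            s1.protein_id,
            s1.ligand_id,
            [(p * 10.0, l * 10.0, pl) for p, l, pl in s1.points],
        )
        f1, f2 = nb.global_kd_fit(s1), nb.global_kd_fit(s2)
        assert f2.Kd == pytest.approx(10.0 * f1.Kd, rel=1e-4)

    def test_all_zero_residue_dropped_with_warning(self):
        series = _series(300.0, seed=4)
        # forge an unshifted residue by copying apo positions everywhere
        for _, l, pl in series.points:
            res = pl[1]
            apo_res = series.apo[1]
            res.shift_H, res.shift_N = apo_res.shift_H, apo_res.shift_N
        with pytest.warns(UserWarning, match="all-zero"):
            fit = nb.global_kd_fit(series)
        assert 1 in fit.dropped_residues

    def test_too_few_liganded_points_raise(self):
        s = _series(300.0, seed=4)
        short = nb.TitrationSeries(s.protein_id, s.ligand_id, s.points[:2])
        with pytest.raises(AnalysisError):
            nb.global_kd_fit(short)


class TestSelectAffectedResidues:
    def test_strict_threshold(self):
        recs = [
            nb.titration.CSPRecord(1, 0.05, 0.0, 0.05, "b"),
            nb.titration.CSPRecord(2, 0.051, 0.0, 0.051, "b"),
        ]
        assert nb.select_affected_residues(recs, 0.05) == {2}

    def test_empty_input_gives_empty_selection(self):
        assert nb.select_affected_residues([], 0.05) == set()

    def test_rejects_nonpositive_threshold(self):
        with pytest.raises(ValueError):
            nb.select_affected_residues([], 0.0)
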