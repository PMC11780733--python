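"""Fourier dihedral model, frcmod I/O, composite energies and refitting."""

import math

import numpy as np
import pytest

from puckerfit import torsion as tr
from puckerfit.synthetic import synth_scan

T1 = ("CT", "CT", "CT", "OS")
T2 = ("OS", "CT", "CT", "OH")


def spec_two_types():
    return tr.FitSpec(
        fitted_types=[
            tr.FittedTypeSpec(atom_types=T1, instances=("tau1",), periodicities=(1, 2, 3)),
            tr.FittedTypeSpec(atom_types=T2, instances=("delta",), periodicities=(1, 2, 3)),
        ]
    )


PLANTED = {
    (T1, 1): 0.9,
    (T1, 2): -0.35,
    (T1, 3): 0.6,
    (T2, 1): -0.2,
    (T2, 2): 0.45,
    (T2, 3): 0.15,
}


class TestDihedralEnergy:
    def test_single_term_closed_form(self):
        tt = tr.TorsionType(T1, (tr.FourierTerm(2, 1.0, 180.0),))
        assert tr.dihedral_energy(tt, 90.0) == pytest.approx(2.0)

    def test_zero_amplitudes_flat(self):
        tt = tr.TorsionType(T1, (tr.FourierTerm(1, 0.0), tr.FourierTerm(3, 0.0)))
        phis = np.arange(0, 360, 5.0)
        assert np.allclose(tr.dihedral_energy(tt, phis), 0.0)

    def test_matches_term_by_term_oracle(self):
        terms = (
            tr.FourierTerm(1, 0.7, 0.0, 1),
            tr.FourierTerm(2, 1.3, 180.0, 2),
            tr.FourierTerm(3, 0.4, 0.0, 1),
        )
        tt = tr.TorsionType(T1, terms)
        phis = np.arange(0.0, 360.0, 1.0)
        expect = np.zeros_like(phis)
        for t in terms:  # independently coded summation
            expect += (t.half_barrier / t.divider) * (
                1.0 + np.cos(np.radians(t.periodicity * phis - t.phase))
            )
        assert np.allclose(tr.dihedral_energy(tt, phis), expect, atol=1e-12)

    def test_idivf_halves_energy(self):
        t1 = tr.TorsionType(T1, (tr.FourierTerm(2, 1.0, 0.0, 1),))
        t2 = tr.TorsionType(T1, (tr.FourierTerm(2, 1.0, 0.0, 2),))
        phis = np.arange(0, 360, 10.0)
        assert np.allclose(tr.dihedral_energy(t2, phis), tr.dihedral_energy(t1, phis) / 2)

    def test_periodicity_360(self):
        tt = tr.TorsionType(T1, (tr.FourierTerm(3, 0.8, 180.0),))
        phis = np.linspace(-180, 180, 73)
        assert np.allclose(
            tr.dihedral_energy(tt, phis), tr.dihedral_energy(tt, phis + 360.0), atol=1e-12
        )


FRCMOD = """test frcmod with one multi-term dihedral

MASS
CT 12.01

BOND
CT-OS  320.0   1.410

ANGLE
CT-CT-OS   50.0  109.50

DIHE
CT-CT-CT-OS    1     0.90000000    0.000   -1.0
CT-CT-CT-OS    1     0.35000000  180.000   -2.0
CT-CT-CT-OS    1     0.60000000    0.000    3.0
OS-CT-CT-OH    2     1.17500000    0.000    2.0

IMPROPER

NONBON
  CT  1.9080  0.1094
"""


class TestFrcmod:
    def test_multi_term_parse(self):
        pset = tr.read_frcmod(FRCMOD)
        assert len(pset.dihedrals) == 2
        tt = pset.find(("CT", "CT", "CT", "OS"))
        assert [t.periodicity for t in tt.terms] == [1, 2, 3]
        assert tt.terms[1].phase == 180.0
        tt2 = pset.find(("OH", "CT", "CT", "OS"))  # palindromic lookup
        assert tt2 is not None and tt2.terms[0].divider == 2

    def test_read_write_read_fixed_point(self):
        once = tr.write_frcmod(tr.read_frcmod(FRCMOD))
        twice = tr.write_frcmod(tr.read_frcmod(once))
        assert once == twice

    def test_dihe_block_byte_stable(self):
        text = tr.write_frcmod(tr.read_frcmod(FRCMOD))
        block = text.split("DIHE\n")[1].split("\n\n")[0]
        text2 = tr.write_frcmod(tr.read_frcmod(text))
        block2 = text2.split("DIHE\n")[1].split("\n\n")[0]
        assert block == block2

    def test_non_dihe_blocks_pass_through_verbatim(self):
        out = tr.write_frcmod(tr.read_frcmod(FRCMOD))
        assert "CT-OS  320.0   1.410" in out
        assert "  CT  1.9080  0.1094" in out

    def test_malformed_line_reports_lineno(self):
        bad = FRCMOD.replace("OS-CT-CT-OH    2     1.17500000    0.000    2.0",
                             "OS-CT-CT-OH    2     oops    0.000    2.0")
        with pytest.raises(tr.FrcmodParseError, match="line 16"):
            tr.read_frcmod(bad)

    def test_dangling_continuation_raises(self):
        bad = "t\n\nDIHE\nCT-CT-CT-OS 1 1.0 0.0 -3.0\n"
        with pytest.raises(tr.FrcmodParseError, match="continuation"):
            tr.read_frcmod(bad)


class TestCompositeEnergy:
    def test_extrapolation_fixed_point(self):
        # equal TZ/QZ correlation energies are their own CBS limit
        out = tr.composite_reference_energy(-10.0, -10.0, -1.0, -1.0, 0.0, 0.0, 0.0)
        assert out == pytest.approx(-11.0)

    def test_zero_higher_order_correction(self):
        base = tr.composite_reference_energy(-5.0, -5.2, -0.8, -0.9, -3.3, -3.3, 0.0)
        assert base == pytest.approx(tr.cbs_hf(-5.0, -5.2) + tr.cbs_correlation(-0.8, -0.9))

    def test_recovers_planted_cbs_limit(self):
        e_inf, a = -2.345, 1.7
        e_tz = e_inf + a * 3.0**-3
        e_qz = e_inf + a * 4.0**-3
        assert tr.cbs_correlation(e_tz, e_qz) == pytest.approx(e_inf, abs=1e-10)
        h_inf, b = -40.0, 5.0
        h_tz = h_inf + b * 3.0**-5
        h_qz = h_inf + b * 4.0**-5
        assert tr.cbs_hf(h_tz, h_qz) == pytest.approx(h_inf, abs=1e-10)

    def test_hartree_conversion(self):
        assert tr.hartree_to_kcal(1.0) == pytest.approx(627.509474)


class TestFitTarget:
    def test_identical_components_flat_zero(self):
        recs = [
            tr.ConformerRecord(P=p, dihedral_values={"tau1": 0.0}, e_qm_gas=3.0,
                               g_solv_qm=-1.0, e_mm_nontorsion=1.5, g_solv_mm=0.5)
            for p in (0.0, 10.0, 20.0)
        ]
        assert np.allclose(tr.fit_target(recs), 0.0)

    def test_planted_profile_reproduced(self):
        records, truth = synth_scan(spec_two_types().fitted_types, PLANTED, offset=2.0)
        res = tr.fit_target(records, shift_min_to_zero=False)
        assert np.allclose(res, truth["profile"], atol=1e-10)

    def test_constant_shift_gauge_invariance(self):
        spec = spec_two_types()
        records, _ = synth_scan(spec.fitted_types, PLANTED)
        shifted = [
            tr.ConformerRecord(r.P, r.dihedral_values, r.e_qm_gas + 7.3, r.g_solv_qm,
                               r.e_mm_nontorsion, r.g_solv_mm)
            for r in records
        ]
        f0 = tr.fit_fourier(records, spec)
        f1 = tr.fit_fourier(shifted, spec)
        for k in f0.amplitudes:
            assert f1.amplitudes[k] == pytest.approx(f0.amplitudes[k], abs=1e-9)
        assert f1.offset - f0.offset == pytest.approx(7.3, abs=1e-9)


class TestFitFourier:
    def test_zero_profile_gives_zero_fit(self):
        spec = spec_two_types()
        records, _ = synth_scan(spec.fitted_types, {k: 0.0 for k in PLANTED})
        fit = tr.fit_fourier(records, spec)
        assert all(abs(v) < 1e-10 for v in fit.amplitudes.values())
        assert fit.rmse == pytest.approx(0.0, abs=1e-10)

    def test_noiseless_exact_recovery(self):
        spec = spec_two_types()
        records, _ = synth_scan(spec.fitted_types, PLANTED, offset=1.2)
        fit = tr.fit_fourier(records, spec)
        for k, v in PLANTED.items():
            assert fit.amplitudes[k] == pytest.approx(v, abs=1e-8)
        assert fit.offset == pytest.approx(1.2, abs=1e-8)

    def test_negative_amplitudes_fold_into_phase_180(self):
        spec = spec_two_types()
        records, _ = synth_scan(spec.fitted_types, PLANTED)
        fit = tr.fit_fourier(records, spec)
        for tt in fit.torsion_types:
            for term in tt.terms:
                assert term.half_barrier >= 0.0
                assert term.phase in (0.0, 180.0)

    def test_noisy_recovery_unbiased_over_seeds(self):
        spec = spec_two_types()
        sigma = 0.1
        ests = {k: [] for k in PLANTED}
        for seed in range(200):
            records, _ = synth_scan(spec.fitted_types, PLANTED, noise_sd=sigma, seed=seed)
            fit = tr.fit_fourier(records, spec)
            for k in PLANTED:
                ests[k].append(fit.amplitudes[k])
        for k, v in PLANTED.items():
            arr = np.array(ests[k])
            se = arr.std(ddof=1) / math.sqrt(len(arr))
            assert abs(arr.mean() - v) < 3 * se + 1e-12, k

    def test_linearity_in_target(self):
        spec = spec_two_types()
        other = {k: -0.5 * v + 0.07 for k, v in PLANTED.items()}
        r1, _ = synth_scan(spec.fitted_types, PLANTED, offset=0.5)
        r2, _ = synth_scan(spec.fitted_types, other, offset=-0.2)
        summed = [
            tr.ConformerRecord(a.P, a.dihedral_values, a.e_qm_gas + b.e_qm_gas,
                               a.g_solv_qm + b.g_solv_qm,
                               a.e_mm_nontorsion + b.e_mm_nontorsion,
                               a.g_solv_mm + b.g_solv_mm)
            for a, b in zip(r1, r2)
        ]
        f1 = tr.fit_fourier(r1, spec)
        f2 = tr.fit_fourier(r2, spec)
        fs = tr.fit_fourier(summed, spec)
        for k in PLANTED:
            assert fs.amplitudes[k] == pytest.approx(
                f1.amplitudes[k] + f2.amplitudes[k], abs=1e-8
            )

    def test_rank_deficiency_names_columns(self):
        # two types sharing the same instance angle are perfectly collinear
        spec = tr.FitSpec(
            fitted_types=[
                tr.FittedTypeSpec(atom_types=T1, instances=("tau1",), periodicities=(1,)),
                tr.FittedTypeSpec(atom_types=T2, instances=("tau1",), periodicities=(1,)),
            ]
        )
        records, _ = synth_scan(spec.fitted_types, {(T1, 1): 0.5})
        with pytest.raises(tr.RankDeficientError, match="collinear"):
            tr.fit_fourier(records, spec)

    def test_too_few_conformers_raises(self):
        spec = spec_two_types()
        records, _ = synth_scan(spec.fitted_types, PLANTED)
        with pytest.raises(ValueError, match="free parameters"):
            tr.fit_fourier(records[:4], spec)


class TestEmpiricalAdjustment:
    BASE = tr.TorsionType(T1, (tr.FourierTerm(1, 0.8), tr.FourierTerm(2, 1.1, 180.0),
                               tr.FourierTerm(3, 0.3)))

    def test_zero_delta_is_identity(self):
        out = tr.empirical_adjustment(self.BASE, 18.0, 0.0)
        assert out.torsion_type == self.BASE
        assert out.delta_terms == ()

    def test_targeted_stabilization(self):
        out = tr.empirical_adjustment(self.BASE, 18.0, -0.3, hold_center=162.0)
        assert out.achieved_delta_target == pytest.approx(-0.3, abs=0.03)
        assert abs(out.achieved_delta_hold) < 0.03

    def test_infeasible_request_reports(self):
        # an n=1-only correction cannot move a narrow window without
        # dragging the rest of the profile along
        with pytest.raises(tr.AdjustmentInfeasibleError) as exc:
            tr.empirical_adjustment(
                self.BASE, 18.0, -1.0, hold_center=60.0, window_halfwidth=30.0,
                periodicities=(1,),
            )
        assert "achieved" in str(exc.value)
        assert exc.value.report["requested_delta"] == -1.0
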