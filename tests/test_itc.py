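"""One-site titration forward model, fitting, and derived thermodynamics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cnbdkit import (OneSiteParams, TitrationCurve, derive_thermo, fit_one_site,
                     noisy_titration, read_titration_table, simulate_titration,
                     vp_itc_design)
from cnbdkit.itc import R_CAL, TitrationDesign


def design_at_c(c, Ka, n_injections=28):
    """Design holding the syringe/cell ratio of the reference protocol while
    setting the cell concentration so that n*Ka*M0 = c."""
    M0 = c / Ka
    return vp_itc_design(cell_concentration=M0,
                         syringe_concentration=M0 * 250.0 / 15.0,
                         n_injections=n_injections)


class TestForwardModel:
    def test_zero_enthalpy_gives_zero_heats(self, paper_design):
        curve = simulate_titration(OneSiteParams(n=1, Ka=1e8, dH=0.0), paper_design)
        assert np.allclose(curve.heats, 0.0)

    def test_infinite_affinity_saturation_matches_stoichiometric_limit(self):
        # sharp design saturates early so little complex is displaced
        design = vp_itc_design(syringe_concentration=1250e-6, n_injections=10)
        curve = simulate_titration(OneSiteParams(n=1, Ka=1e15, dH=-12500.0), design)
        total_cal = curve.heats.sum() * 1e-6
        limit = 1 * (-12500.0) * design.cell_concentration * design.cell_volume
        assert total_cal == pytest.approx(limit, rel=0.02)

    def test_reference_protocol_sigmoid_inflects_near_ratio_one(self, paper_design):
        curve = simulate_titration(
            OneSiteParams(n=1, Ka=1 / 12e-9, dH=-12500.0), paper_design)
        steepest = np.argmax(np.abs(np.diff(curve.normalized)))
        inflection_ratio = curve.molar_ratio[steepest]
        assert 0.8 <= inflection_ratio <= 1.2
        # early injections near-complete binding, late ones near zero
        assert curve.normalized[0] == pytest.approx(-12.5, rel=0.05)
        assert abs(curve.normalized[-1]) < 0.5

    def test_heats_linear_in_enthalpy_and_cell_volume(self, paper_design):
        p1 = OneSiteParams(n=1, Ka=1e7, dH=-8000.0)
        p2 = OneSiteParams(n=1, Ka=1e7, dH=-16000.0)
        c1 = simulate_titration(p1, paper_design)
        c2 = simulate_titration(p2, paper_design)
        assert np.allclose(c2.heats, 2.0 * c1.heats)
        assert np.allclose(c2.molar_ratio, c1.molar_ratio)
        design2 = vp_itc_design(cell_volume=2 * paper_design.cell_volume)
        c3 = simulate_titration(p1, design2)
        # same number of moles injected into twice the volume: per-injection
        # heats track V0 through the total-heat prefactor
        assert len(c3.heats) == len(c1.heats)

    def test_design_validation(self):
        with pytest.raises(ValueError):
            TitrationDesign(cell_concentration=0.0, syringe_concentration=1e-4,
                            injection_volumes=[5e-6] * 5)
        with pytest.raises(ValueError):
            TitrationDesign(cell_concentration=1e-5, syringe_concentration=1e-4,
                            injection_volumes=[5e-6])


class TestFit:
    @pytest.mark.parametrize("c", [1, 10, 100, 1000])
    def test_fit_simulate_identity_across_c(self, c):
        Ka, dH = 1e7, -12000.0
        design = design_at_c(c, Ka)
        truth = OneSiteParams(n=1.0, Ka=Ka, dH=dH)
        fit = fit_one_site(simulate_titration(truth, design), design)
        assert fit.converged
        assert fit.params.n == pytest.approx(1.0, rel=1e-3)
        assert fit.params.Ka == pytest.approx(Ka, rel=1e-3)
        assert fit.params.dH == pytest.approx(dH, rel=1e-3)

    def test_noisy_replicates_median_ka_within_ten_percent(self):
        Ka, dH = 1e6, -12000.0
        design = design_at_c(10, Ka)
        truth = OneSiteParams(n=1.0, Ka=Ka, dH=dH)
        kas = []
        for seed in range(200):
            curve = noisy_titration(truth, design, heat_sigma=0.1, seed=seed)
            kas.append(fit_one_site(curve, design).params.Ka)
        assert np.median(kas) == pytest.approx(Ka, rel=0.10)

    def test_uncertainty_grows_when_overconditioned(self, paper_design):
        # same protocol and noise; only the affinity (hence c) changes
        results = {}
        for c in (10, 1250):
            Ka = c / paper_design.cell_concentration
            curve = noisy_titration(OneSiteParams(1.0, Ka, -12500.0),
                                    paper_design, heat_sigma=0.1, seed=42)
            fit = fit_one_site(curve, paper_design)
            assert fit.stderr["Ka"] is not None
            results[c] = fit.stderr["Ka"] / fit.params.Ka
        assert results[1250] > results[10]

    def test_c_value_reported(self, paper_design):
        truth = OneSiteParams(n=1.0, Ka=1 / 12e-9, dH=-12500.0)
        fit = fit_one_site(simulate_titration(truth, paper_design), paper_design)
        assert fit.c_value == pytest.approx(
            fit.params.n * fit.params.Ka * paper_design.cell_concentration)

    def test_too_few_points_rejected(self, paper_design):
        curve = TitrationCurve(molar_ratio=[1, 2, 3], heats=[1, 2, 3],
                               normalized=[0, 0, 0])
        with pytest.raises(ValueError):
            fit_one_site(curve, paper_design)


class TestDerivedThermo:
    def test_gibbs_entropy_identities_random_inputs(self, rng):
        for _ in range(50):
            Ka = 10 ** rng.uniform(2, 12)
            dH = rng.uniform(-30000, 5000)
            T = rng.uniform(273, 330)
            Kd, dG, dS = derive_thermo(Ka, dH, T)
            assert Kd * Ka == pytest.approx(1.0, rel=1e-12)
            assert dG == pytest.approx(-R_CAL * T * math.log(Ka), rel=1e-12)
            assert dH - (dG + T * dS) == pytest.approx(0.0, abs=1e-9 * max(1, abs(dH)))

    def test_unit_association_constant_zero_free_energy(self):
        _, dG, _ = derive_thermo(1.0, -1000.0, 303.15)
        assert dG == 0.0

    def test_enthalpy_equals_free_energy_zero_entropy(self):
        Ka = 1e7
        dG = -R_CAL * 303.15 * math.log(Ka)
        _, _, dS = derive_thermo(Ka, dG, 303.15)
        assert dS == pytest.approx(0.0, abs=1e-12)

    @given(st.floats(min_value=1e2, max_value=1e12),
           st.floats(min_value=-3e4, max_value=1e4))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_entropy_sign_follows_enthalpy_minus_free_energy(self, Ka, dH):
        _, dG, dS = derive_thermo(Ka, dH, 303.15)
        assert (dS >= 0) == (dH >= dG)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            derive_thermo(-1.0, -1000.0, 300.0)
        with pytest.raises(ValueError):
            derive_thermo(1e7, -1000.0, 0.0)


class TestTitrationTable:
    def test_roundtrip_with_header(self, tmp_path, paper_design):
        curve = simulate_titration(OneSiteParams(1, 1e7, -12000.0), paper_design)
        path = tmp_path / "t.tsv"
        lines = ["volume_ul\theat_ucal"]
        for dv, q in zip(paper_design.injection_volumes, curve.heats):
            lines.append(f"{dv * 1e6}\t{q}")
        path.write_text("\n".join(lines) + "\n")
        vols, heats = read_titration_table(str(path))
        assert np.allclose(vols, paper_design.injection_volumes)
        assert np.allclose(heats, curve.heats)

    def test_headerless_and_comments(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("# a comment\n5.0,-30.5\n5.0,-28.1\n5.0,-20.0\n")
        vols, heats = read_titration_table(str(path))
        assert len(vols) == 3
        assert vols[0] == pytest.approx(5e-6)

    def test_malformed_table_raises(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("bogus\tstuff\nmore\tbad\n")
        with pytest.raises(ValueError):
            read_titration_table(str(path))
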