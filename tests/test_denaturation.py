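"""Two-state / bimodal LEM melt fitting, chemical denaturation, phase diagram."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import dimerstab as ds
from dimerstab.denaturation import MeltCurve, _two_state_theta
from dimerstab.exceptions import FitFailureError, InvalidInputError
from dimerstab import synthetic as syn


class TestMeltCurveValidation:
    def test_celsius_autoconversion(self):
        t_c = np.linspace(25, 90, 40)
        c = MeltCurve(temperature=t_c, ellipticity=np.linspace(-20, -5, 40))
        assert c.temperature[0] == pytest.approx(298.15)

    @pytest.mark.parametrize("bad", [
        dict(temperature=np.linspace(25, 90, 10),
             ellipticity=np.zeros(10)),                       # too few points
        dict(temperature=np.linspace(25, 50, 30),
             ellipticity=np.zeros(30)),                       # span too small
        dict(temperature=np.r_[np.linspace(25, 60, 20),
                               np.linspace(60, 90, 20)],
             ellipticity=np.zeros(40)),                       # non-increasing
    ])
    def test_invalid_curves_rejected(self, bad):
        with pytest.raises(InvalidInputError):
            MeltCurve(**bad)


class TestTwoStateMelt:
    def test_zero_noise_recovery(self):
        curve = syn.melt_curve_monomer(seed=0, noise=0.0)
        est = ds.fit_two_state_melt(curve)
        assert est.tm_ == pytest.approx(341.45, rel=1e-4)
        assert est.dh_ == pytest.approx(75.0, rel=1e-4)

    def test_noisy_tm_within_experimental_uncertainty(self):
        """2% noise leaves Tm within the ±0.6 K experimental band."""
        errs = [abs(ds.fit_two_state_melt(
            syn.melt_curve_monomer(seed=int(s), noise=0.02)).tm_ - 341.45)
            for s in syn.replicate_seeds(3, 25)]
        assert np.median(errs) <= 0.6

    def test_flat_curve_rejected(self):
        t = np.linspace(25, 90, 50)
        with pytest.raises(FitFailureError):
            ds.TwoStateMeltEstimator().fit(t, np.full(50, -12.0))

    def test_celsius_kelvin_reparameterization(self):
        """Identical Tm (to 1e-9) whether input is °C or K."""
        curve = syn.melt_curve_monomer(seed=5, noise=0.02)
        t_k = curve.temperature
        est_k = ds.TwoStateMeltEstimator().fit(t_k, curve.ellipticity)
        est_c = ds.TwoStateMeltEstimator().fit(t_k - 273.15, curve.ellipticity)
        assert est_c.tm_ == pytest.approx(est_k.tm_, rel=1e-9)

    def test_dg_zero_at_tm(self):
        params = ds.fit_two_state_melt(
            syn.melt_curve_monomer(seed=1, noise=0.0)).params_()
        assert params.dg(params.tm) == 0.0
        assert params.dg(params.tm - 10) > 0 > params.dg(params.tm + 10)


class TestBimodalMelts:
    def test_chi_zero_reduces_to_two_state(self):
        """χ_A = 0 collapses the mixture onto the plain two-state fit."""
        curve = syn.melt_curve_monomer(seed=3, noise=0.02)
        two = ds.fit_two_state_melt(curve)
        bi = ds.fit_bimodal_melts([curve], fix_chi_a=0.0)
        assert bi.tm2_ == pytest.approx(two.tm_, rel=1e-6)
        assert bi.dh2_ == pytest.approx(two.dh_, rel=1e-6)

    def test_family_recovery_and_monotone_chi(self):
        """Dimer-regime family: Tm1 ≈ 48 °C recovered, χ_A rises with C_T."""
        curves, chi_truth = syn.melt_family_dimer(seed=4, noise=0.02)
        est = ds.fit_bimodal_melts(curves)
        assert abs(est.tm1_ - 273.15 - 48.0) <= 2.0
        assert abs(est.tm2_ - 273.15 - 70.0) <= 2.0
        assert np.all(np.diff(est.chi_a_) > 0)
        assert est.chi_a_ == pytest.approx(chi_truth, abs=0.05)

    def test_single_curve_warns(self):
        curves, _ = syn.melt_family_dimer(seed=6, noise=0.02,
                                          c_totals=(10.0,))
        with pytest.warns(UserWarning, match="single curve"):
            ds.fit_bimodal_melts(curves)

    def test_tm_ordering_invariant(self):
        curves, _ = syn.melt_family_dimer(seed=8, noise=0.02)
        est = ds.fit_bimodal_melts(curves)
        assert est.tm1_ < est.tm2_
        assert np.all((est.chi_a_ >= 0) & (est.chi_a_ <= 1))


class TestChemicalDenaturation:
    def test_zero_noise_recovery(self):
        c, theta = syn.chem_denat_curve(seed=0, noise=0.0)
        est = ds.fit_chemical_denaturation(c, theta, temperature=310.15)
        assert est.dg0_ == pytest.approx(9.5, rel=1e-4)
        assert est.m_ == pytest.approx(3.0, rel=1e-4)
        assert est.cm_ == pytest.approx(est.dg0_ / est.m_, rel=1e-6)

    def test_noisy_dg_within_experimental_uncertainty(self):
        """2% noise keeps ΔG0 within the ±0.4 kcal/mol band (median)."""
        errs = [abs(ds.fit_chemical_denaturation(
            *syn.chem_denat_curve(seed=int(s), noise=0.02),
            temperature=310.15).dg0_ - 9.5)
            for s in syn.replicate_seeds(5, 25)]
        assert np.median(errs) <= 0.4

    def test_sign_agnostic(self):
        """Ascending and descending signal conventions give the same fit."""
        c, theta = syn.chem_denat_curve(seed=2, noise=0.02)
        up = ds.fit_chemical_denaturation(c, theta, temperature=310.15)
        down = ds.fit_chemical_denaturation(c, -theta, temperature=310.15)
        assert down.dg0_ == pytest.approx(up.dg0_, rel=1e-6)

    def test_no_transition_rejected(self):
        c = np.linspace(0, 7, 30)
        with pytest.raises(FitFailureError):
            ds.fit_chemical_denaturation(c, np.full(30, -9.0))


class TestDdgFromTmShift:
    def test_identical_tm_gives_zero(self):
        assert ds.ddg_from_tm_shift(75.0, 341.45, 341.45) == 0.0

    def test_destabilizing_shift(self):
        # 75 · 4.553 / 341.45 computed independently
        expected = 75.0 * 4.553 / 341.45
        assert ds.ddg_from_tm_shift(75.0, 341.45, 341.45 - 4.553) == \
            pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(1.000, abs=1e-3)

    def test_stabilizing_shift_is_negative(self):
        val = ds.ddg_from_tm_shift(75.0, 341.45, 351.45)
        assert val == pytest.approx(75.0 * (-10.0) / 341.45, rel=1e-12)
        assert val == pytest.approx(-2.196, abs=1e-3)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(dtm=st.floats(-20, 20))
    def test_linear_in_shift_and_antisymmetric(self, dtm):
        tm_wt = 341.45
        one = ds.ddg_from_tm_shift(75.0, tm_wt, tm_wt - dtm)
        two = ds.ddg_from_tm_shift(75.0, tm_wt, tm_wt - 2 * dtm)
        assert two == pytest.approx(2 * one, abs=1e-9)
        swapped = ds.ddg_from_tm_shift(75.0, tm_wt - dtm, tm_wt)
        assert swapped == pytest.approx(-one * tm_wt / (tm_wt - dtm),
                                        rel=1e-9)


class TestPhaseDiagram:
    def test_all_monomeric_is_diagonal(self):
        ct = np.array([1.0, 5.0, 10.0])
        with pytest.warns(UserWarning, match="monomeric"):
            fit = ds.phase_diagram(ct, np.zeros(3))
        assert fit.diagonal and np.isinf(fit.c_star)
        assert fit.monomer == pytest.approx(ct)

    def test_noiseless_cstar_recovery(self):
        ct = np.array([1.0, 2.5, 5.0, 10.0, 25.0])
        chi = 1.0 - np.exp(-ct / 5.0)
        fit = ds.phase_diagram(ct, chi)
        assert fit.c_star == pytest.approx(5.0, rel=1e-4)

    def test_aggregating_species_below_diagonal(self):
        ct = np.array([2.5, 5.0, 10.0, 25.0])
        chi = 1.0 - np.exp(-ct / 5.0)
        fit = ds.phase_diagram(ct, chi)
        assert np.all(fit.monomer < ct)
        assert fit.deviation == pytest.approx(1 - fit.monomer / ct, rel=1e-12)

    def test_invalid_chi_rejected(self):
        with pytest.raises(InvalidInputError):
            ds.phase_diagram([1.0, 2.0, 3.0], [0.1, 1.2, 0.3])
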