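"""Monomer-dimer partitioning, two-state populations, and enzymology fits."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

import dimerstab as ds
from dimerstab.exceptions import FitFailureError, InvalidParameterError
from dimerstab import synthetic as syn

R = 1.987e-3


def bisection_monomer(c_total, k_d):
    """Independent root of the mass balance 2M²/K_D + M − C_T = 0."""
    if c_total == 0:
        return 0.0
    f = lambda m: 2 * m**2 / k_d + m - c_total  # noqa: E731
    return brentq(f, 0.0, c_total, xtol=1e-15, rtol=1e-15)


class TestPartition:
    def test_empty_system(self):
        st_ = ds.monomer_dimer_partition(ds.EquilibriumSpec(0.0, 0.5))
        assert st_.monomer == 0 and st_.dimer == 0
        assert st_.fraction_dimer == 0

    def test_reference_concentration(self):
        """C_T = 1 μM at K_D = 0.5 μM against the bisection oracle."""
        m_oracle = bisection_monomer(1.0, 0.5)
        st_ = ds.monomer_dimer_partition(ds.EquilibriumSpec(1.0, 0.5))
        assert st_.monomer == pytest.approx(m_oracle, rel=1e-9)
        assert st_.monomer == pytest.approx(0.3904, abs=5e-5)
        assert st_.dimer == pytest.approx(0.3048, abs=5e-5)
        assert st_.fraction_dimer == pytest.approx(0.6096, abs=5e-5)

    def test_strong_dimer_limit(self):
        spec = ds.EquilibriumSpec(1e4 * 0.5, 0.5)
        st_ = ds.monomer_dimer_partition(spec)
        assert st_.fraction_dimer > 0.98
        assert st_.monomer == pytest.approx(
            bisection_monomer(spec.c_total, spec.k_d), rel=1e-9)

    def test_invalid_kd(self):
        with pytest.raises(InvalidParameterError):
            ds.EquilibriumSpec(1.0, 0.0)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(kd=st.floats(1e-3, 1e3), ct=st.floats(1e-3, 1e3))
    def test_oracle_equivalence_and_mass_balance(self, kd, ct):
        st_ = ds.monomer_dimer_partition(ds.EquilibriumSpec(ct, kd))
        assert st_.monomer == pytest.approx(bisection_monomer(ct, kd),
                                            rel=1e-9)
        assert st_.monomer + 2 * st_.dimer == pytest.approx(ct, rel=1e-9)
        assert 0 <= st_.fraction_dimer <= 1

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(kd=st.floats(1e-3, 1e3), ct=st.floats(1e-3, 1e2))
    def test_fraction_dimer_monotonicity(self, kd, ct):
        f = lambda c, k: ds.monomer_dimer_partition(  # noqa: E731
            ds.EquilibriumSpec(c, k)).fraction_dimer
        assert f(ct * 2, kd) >= f(ct, kd)
        assert f(ct, kd * 2) <= f(ct, kd)


class TestFoldedFraction:
    def test_symmetric_two_state(self):
        assert ds.folded_fraction(0.0, 310.15) == 0.5

    def test_stable_wild_type_population(self):
        """ΔG = 9.5 kcal/mol leaves the folded state >99% populated."""
        assert ds.folded_fraction(9.5, 310.15) > 0.99

    def test_marginal_variant_unfolded_population(self):
        # 1/(1+exp(-1.2/(R·310.15))) evaluated directly
        expected = 1.0 / (1.0 + np.exp(-1.2 / (R * 310.15)))
        f = ds.folded_fraction(1.2, 310.15)
        assert f == pytest.approx(expected, rel=1e-12)
        assert 1 - f == pytest.approx(0.125, abs=2e-3)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(dg=st.floats(-20, 20), t=st.floats(270, 380))
    def test_symmetry_and_monotonicity(self, dg, t):
        assert (ds.folded_fraction(dg, t)
                + ds.folded_fraction(-dg, t)) == pytest.approx(1.0, abs=1e-12)
        assert ds.folded_fraction(dg + 1, t) >= ds.folded_fraction(dg, t)


class TestDimerActivityRate:
    KIN = ds.EnzymeKinetics(km=25.2, kcat=0.10)

    def test_vanishing_enzyme(self):
        spec = ds.EquilibriumSpec(0.0, 0.5)
        for s in (1.0, 100.0, 1e4):
            assert ds.dimer_activity_rate(spec, self.KIN, s) == 0.0

    def test_half_saturation_identity(self):
        spec = ds.EquilibriumSpec(5.0, 0.5)
        v_half = ds.dimer_activity_rate(spec, self.KIN, self.KIN.km)
        d = ds.monomer_dimer_partition(spec).dimer
        assert v_half == pytest.approx(self.KIN.kcat * 2 * d / 2, rel=1e-12)

    def test_composed_oracle_value(self):
        """v at C_T=10, K_D=0.5, S=250 from independently composed pieces."""
        m = bisection_monomer(10.0, 0.5)
        d = (10.0 - m) / 2
        expected = 0.10 * 2 * d * 250.0 / (25.2 + 250.0)
        v = ds.dimer_activity_rate(ds.EquilibriumSpec(10.0, 0.5),
                                   self.KIN, 250.0)
        assert v == pytest.approx(expected, rel=1e-9)
        assert v == pytest.approx(0.7757, abs=1e-4)

    def test_monotone_in_ct_and_saturating_in_s(self):
        cts = [0.1, 0.5, 2.0, 10.0]
        vs = [ds.dimer_activity_rate(ds.EquilibriumSpec(c, 0.5),
                                     self.KIN, 100.0) for c in cts]
        assert np.all(np.diff(vs) > 0)
        s = np.array([1, 10, 100, 1000, 1e5])
        v = ds.dimer_activity_rate(ds.EquilibriumSpec(5.0, 0.5), self.KIN, s)
        assert np.all(np.diff(v) > 0)
        vmax = 0.10 * 2 * ds.monomer_dimer_partition(
            ds.EquilibriumSpec(5.0, 0.5)).dimer
        assert v[-1] < vmax <= v[-1] * 1.01

    def test_negative_substrate_rejected(self):
        with pytest.raises(InvalidParameterError):
            ds.dimer_activity_rate(ds.EquilibriumSpec(5.0, 0.5),
                                   self.KIN, -1.0)


class TestMichaelisMentenFit:
    def test_zero_noise_exact_recovery(self):
        s, v = syn.mm_rates(seed=0, cv=0.0)
        est = ds.fit_michaelis_menten(s, v, enzyme_total_uM=5.0, k_d_uM=0.5)
        assert est.km_ == pytest.approx(25.2, rel=1e-6)
        assert est.kcat_ == pytest.approx(0.10, rel=1e-6)

    def test_noise_replicate_coverage(self):
        """5% proportional noise: Km within ±3 μM in >=90% of replicates."""
        kms = []
        for s in syn.replicate_seeds(1, 200):
            sub, v = syn.mm_rates(seed=int(s), cv=0.05)
            kms.append(ds.fit_michaelis_menten(sub, v).km_)
        assert np.mean(np.abs(np.array(kms) - 25.2) < 3.0) >= 0.90

    def test_constant_rates_rejected(self):
        s = np.array([5.0, 20.0, 80.0, 320.0])
        with pytest.raises(FitFailureError):
            ds.fit_michaelis_menten(s, np.full(4, 0.2))

    def test_too_few_points_rejected(self):
        with pytest.raises(FitFailureError):
            ds.fit_michaelis_menten([10.0, 20.0, 30.0], [0.1, 0.15, 0.18])


class TestActivityTitrationFit:
    def test_zero_noise_recovery(self):
        ct, v = syn.ctotal_rates(seed=0, cv=0.0)
        est = ds.fit_activity_vs_concentration(ct, v, 2000.0)
        assert est.kd_ == pytest.approx(0.5, rel=1e-4)
        assert not est.unidentifiable_

    def test_noise_replicates_within_factor_two(self):
        kds = []
        for s in syn.replicate_seeds(2, 200):
            ct, v = syn.ctotal_rates(seed=int(s), cv=0.10)
            kds.append(ds.fit_activity_vs_concentration(ct, v, 2000.0).kd_)
        kds = np.array(kds)
        assert np.mean((kds > 0.25) & (kds < 1.0)) >= 0.90

    def test_saturated_grid_flagged(self):
        ct = np.array([50.0, 100.0, 200.0, 400.0, 800.0])  # all >> K_D
        kin = ds.EnzymeKinetics(km=25.2, kcat=0.10)
        v = np.array([ds.dimer_activity_rate(ds.EquilibriumSpec(c, 0.5),
                                             kin, 2000.0) for c in ct])
        with pytest.warns(UserWarning, match="K_D"):
            est = ds.fit_activity_vs_concentration(ct, v, 2000.0)
        assert est.unidentifiable_


class TestScheme1Timecourse:
    def test_no_aggregation_is_static(self):
        spec = ds.EquilibriumSpec(5.0, 0.5)
        out = ds.simulate_scheme1_timecourse(spec, 0.0, np.linspace(0, 1e4, 20))
        assert np.all(out["aggregate"] == 0)
        assert np.ptp(out["monomer"]) == 0 and np.ptp(out["dimer"]) == 0

    def test_monomeric_limit_is_exponential(self):
        """C_T << K_D: soluble protein decays as C_T·exp(−k_Ag·t)."""
        spec = ds.EquilibriumSpec(1e-4, 0.5)
        k = 1e-3
        t = np.linspace(0, 5000, 50)
        out = ds.simulate_scheme1_timecourse(spec, k, t)
        assert out["monomer"] == pytest.approx(
            spec.c_total * np.exp(-k * t), rel=1e-3)

    def test_dimer_buffering_slows_decay(self):
        """At C_T >> K_D the dimer reservoir slows monomer loss."""
        spec = ds.EquilibriumSpec(10.0, 0.5)
        k = 1e-3
        t = np.linspace(0, 5000, 60)
        out = ds.simulate_scheme1_timecourse(spec, k, t)
        soluble = out["monomer"] + 2 * out["dimer"]
        assert np.all(soluble[1:] > spec.c_total * np.exp(-k * t[1:]))

    def test_mass_conservation_and_monotone_aggregate(self):
        spec = ds.EquilibriumSpec(10.0, 0.5)
        t = np.linspace(0, 2e4, 100)
        out = ds.simulate_scheme1_timecourse(spec, 5e-4, t)
        total = out["monomer"] + 2 * out["dimer"] + out["aggregate"]
        assert total == pytest.approx(spec.c_total, rel=1e-6)
        assert np.all(np.diff(out["aggregate"]) >= -1e-12)

    def test_agrees_with_stiff_integrator_oracle(self):
        """Cross-check against an independent Radau integration."""
        spec = ds.EquilibriumSpec(10.0, 0.5)
        k = 1e-3
        t = np.linspace(0, 8000, 40)

        def rhs(_t, y):
            soluble = max(spec.c_total - y[0], 0.0)
            m = brentq(lambda mm: 2 * mm**2 / spec.k_d + mm - soluble,
                       0.0, soluble + 1e-12) if soluble > 0 else 0.0
            return [k * m]

        oracle = solve_ivp(rhs, (0, t[-1]), [0.0], t_eval=t, method="Radau",
                           rtol=1e-10, atol=1e-12)
        out = ds.simulate_scheme1_timecourse(spec, k, t)
        assert out["aggregate"][1:] == pytest.approx(oracle.y[0][1:], rel=1e-5)

    def test_negative_rate_rejected(self):
        with pytest.raises(InvalidParameterError):
            ds.simulate_scheme1_timecourse(ds.EquilibriumSpec(1.0, 0.5),
                                           -1e-3, [0, 1, 2])
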