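"""Chemical potentials, rate laws and osmotic tension (dilute + crowded)."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from peeldyn import (ParameterSet, chemical_potentials, rate_functions,
                     reaction_rate, osmotic_tension, CrowdingError)

P_DILUTE = ParameterSet(koff_bar=10.0)
P_CROWD5 = ParameterSet(koff_bar=10.0, crowding=True, cmax=5 * 2.5e3)


class TestChemicalPotentials:
    def test_reference_state_is_zero(self):
        mu1, _ = chemical_potentials(P_DILUTE.c0_i, P_DILUTE.c0_i, 0.0,
                                     P_DILUTE)
        assert mu1 == pytest.approx(0.0, abs=1e-15)

    def test_stretching_by_one_x_gamma_adds_kBT(self):
        mu0, _ = chemical_potentials(P_DILUTE.c0_i, P_DILUTE.c0_i, 0.0,
                                     P_DILUTE)
        mu1, _ = chemical_potentials(P_DILUTE.c0_i, P_DILUTE.c0_i,
                                     P_DILUTE.x_gamma_i, P_DILUTE)
        assert mu1 - mu0 == pytest.approx(P_DILUTE.kBT_i, rel=1e-12)

    def test_free_binder_standard_potential(self):
        _, mu2 = chemical_potentials(P_DILUTE.c0_i, P_DILUTE.c0_i, 0.0,
                                     P_DILUTE)
        assert mu2 == pytest.approx(0.5 * P_DILUTE.kBT_i * math.log(2.0),
                                    rel=1e-12)

    def test_empty_state_sentinel(self):
        mu1, mu2 = chemical_potentials(0.0, 0.0, 0.0, P_DILUTE)
        assert mu1 == -math.inf and mu2 == -math.inf

    def test_crowded_approaches_dilute_at_large_cmax(self):
        # cmax/c0 = 500 nearly coincides with the dilute limit
        p500 = ParameterSet(crowding=True, cmax=500 * 2.5e3)
        c1 = c2 = 1.5 * p500.c0_i
        mu_c, _ = chemical_potentials(c1, c2, 0.0, p500)
        mu_d, _ = chemical_potentials(c1, c2, 0.0, P_DILUTE)
        # difference is O(c/cmax) · kBT
        assert abs(mu_c - mu_d) / p500.kBT_i < 3.0 * 3.0 / 500.0
        assert abs(mu_c - mu_d) > 0

    def test_crowding_overflow_is_hard_error(self):
        with pytest.raises(CrowdingError):
            chemical_potentials(3 * 2.5e3, 3 * 2.5e3, 0.0, P_CROWD5)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(c=st.floats(0.01, 4.9e3), h=st.floats(0.0, 0.02))
    def test_monotone_in_concentration_and_stretch(self, c, h):
        for p in (P_DILUTE, P_CROWD5):
            cmax_room = 0.999 * (p.cmax_i if p.crowding else math.inf)
            c1 = min(c, 0.5 * cmax_room)
            m0, _ = chemical_potentials(c1, 0.0 * c1, h, p)
            m1, _ = chemical_potentials(c1 * 1.01, 0.0 * c1, h, p)
            m2, _ = chemical_potentials(c1, 0.0 * c1, h + 1e-3, p)
            assert m1 > m0
            assert m2 > m0


class TestRateFunctions:
    def test_unstressed_values(self):
        kon, koff = rate_functions(0.0, P_DILUTE)
        assert kon == pytest.approx(P_DILUTE.kon_bar_i, rel=1e-12)
        assert koff == pytest.approx(P_DILUTE.koff_bar, rel=1e-12)

    def test_e_folding_scales(self):
        p = replace(P_DILUTE, f_beta=4.0 * math.sqrt(P_DILUTE.k
                                                     * P_DILUTE.kBT))
        kon, koff = rate_functions(p.x_beta_i, p)
        assert koff == pytest.approx(math.e * p.koff_bar, rel=1e-12)
        kon, _ = rate_functions(p.x_gamma_i, p)
        assert kon == pytest.approx(p.kon_bar_i / math.e, rel=1e-12)

    def test_ideal_bonds_force_insensitive(self):
        h = np.linspace(-0.01, 0.01, 7)
        _, koff = rate_functions(h, P_DILUTE)
        assert np.allclose(koff, P_DILUTE.koff_bar)

    def test_compression_slows_slip_unbinding(self):
        p = replace(P_DILUTE, f_beta=4e-12)
        _, koff = rate_functions(-1e-3, p)
        assert koff < p.koff_bar

    def test_separation_dependent_equilibrium_constant(self):
        # c0·kon(h)/koff = K̄·exp[−(h/xγ)²] for ideal bonds
        h = np.linspace(0.0, 3.0 * P_DILUTE.x_gamma_i, 9)
        kon, koff = rate_functions(h, P_DILUTE)
        K_h = P_DILUTE.c0_i * kon / koff
        expected = P_DILUTE.Kbar * np.exp(-(h / P_DILUTE.x_gamma_i) ** 2)
        assert np.allclose(K_h, expected, rtol=1e-12)

    def test_crowded_detailed_balance(self):
        """In crowding mode the v⁻² unbinding factor makes reaction
        equilibrium coincide with μ1 = 2μ2 for the crowded potentials."""
        from peeldyn.kinetics import crowding_unbinding_factor
        p = P_CROWD5
        c2 = 0.8 * p.c0_i
        for h in (0.0, p.x_gamma_i):
            kon, koff = rate_functions(h, p)
            # solve kon·c2² = koff·v⁻²·c1 for c1 by fixed point
            c1 = kon * c2 ** 2 / koff
            for _ in range(200):
                fac = crowding_unbinding_factor(c1, c2, p)
                c1 = kon * c2 ** 2 / (koff * fac)
            mu1, mu2 = chemical_potentials(c1, c2, h, p)
            assert abs(mu1 - 2 * mu2) < 1e-8 * p.kBT_i
            assert reaction_rate(c1, c2, h, p) == pytest.approx(
                0.0, abs=1e-8 * koff * c1)

    def test_detailed_balance_equivalence(self):
        """kon·c2² = koff·c1 iff μ1 = 2μ2 at every separation (dilute,
        ideal bonds)."""
        for h in (0.0, 0.5 * P_DILUTE.x_gamma_i, 2.0 * P_DILUTE.x_gamma_i):
            c2 = 0.7 * P_DILUTE.c0_i
            kon, koff = rate_functions(h, P_DILUTE)
            c1 = kon * c2 ** 2 / koff        # reaction equilibrium
            mu1, mu2 = chemical_potentials(c1, c2, h, P_DILUTE)
            assert abs(mu1 - 2 * mu2) < 1e-10 * P_DILUTE.kBT_i
            assert reaction_rate(c1, c2, h, P_DILUTE) == pytest.approx(
                0.0, abs=1e-10 * koff * c1)


class TestOsmoticTension:
    def test_dilute_vant_hoff(self, params_default, eq_default):
        Pi = osmotic_tension(eq_default.c1_eq * params_default.c0_i,
                             params_default)
        # kBT·c1 at the prepared state, in N/m × l_lat
        assert Pi * 1e-6 == pytest.approx(1.62e-5, rel=2e-3)

    def test_crowded_at_ten_percent_occupancy(self):
        p = P_CROWD5
        c1 = 0.1 * p.cmax_i
        Pi = osmotic_tension(c1, p)
        assert Pi / (p.kBT_i * p.cmax_i) == pytest.approx(0.11072, abs=1e-4)

    def test_crowded_reduces_to_vant_hoff(self):
        p = ParameterSet(crowding=True, cmax=500 * 2.5e3)
        c1 = 0.001 * p.cmax_i
        assert osmotic_tension(c1, p) == pytest.approx(p.kBT_i * c1,
                                                       rel=2e-3)

    def test_divergence_and_monotonicity(self):
        p = P_CROWD5
        cs = np.linspace(0.1, 0.999, 40) * p.cmax_i
        Pi = osmotic_tension(cs, p)
        assert np.all(np.diff(Pi) > 0)
        with pytest.raises(CrowdingError):
            osmotic_tension(p.cmax_i, p)

    def test_gibbs_duhem_consistency(self):
        """∫ c·(∂μ1/∂c) dc from 0 to c1 (crowded, c2 = 0, h = 0)
        reproduces the closed-form crowded osmotic tension to 1e-8.

        The derivative is evaluated by complex step, the integral by
        adaptive quadrature — an independent route that pins the
        logarithmic concentration term of the crowded potential.
        """
        from scipy.integrate import quad
        p = P_CROWD5
        kBT, cmax, c0 = p.kBT_i, p.cmax_i, p.c0_i

        def mu1(c):   # complex-analytic crowded potential at c2=0, h=0
            return kBT * (np.log(c / c0) - 2.0 * np.log((cmax - c) / cmax))

        def integrand(c):
            hstep = 1e-200
            return c * (mu1(c + 1j * hstep).imag / hstep)

        c1 = 0.6 * cmax
        val, err = quad(integrand, 1e-12 * cmax, c1, limit=200)
        assert val == pytest.approx(float(osmotic_tension(c1, p)), rel=1e-8)


class TestThermoState:
    def test_reference_state_values(self):
        from peeldyn import ThermoState
        st = ThermoState.evaluate(P_DILUTE.c0_i, P_DILUTE.c0_i, 0.0,
                                  P_DILUTE)
        assert st.mu1 == pytest.approx(0.0, abs=1e-15)
        assert st.mu2 == pytest.approx(st.mu2_0, rel=1e-12)
        assert st.mu2_over_mu20 == pytest.approx(1.0, rel=1e-12)

    def test_normalization_by_standard_potential(self):
        from peeldyn import ThermoState
        st = ThermoState.evaluate(2.0 * P_DILUTE.c0_i, P_DILUTE.c0_i,
                                  0.0, P_DILUTE)
        mu2_0 = 0.5 * P_DILUTE.kBT_i * math.log(2.0)
        assert st.mu1_over_mu20 == pytest.approx(st.mu1 / mu2_0, rel=1e-12)
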