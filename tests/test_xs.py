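"""Cross sections and stopping powers against closed forms and quadrature
oracles."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from itmc import xs
from itmc.constants import M_E_C2, R_E
from itmc.materials import get_element, get_material


class TestComptonKinematics:
    def test_forward_scatter(self):
        ap, T = xs.compton_kinematics(2.0, 1.0)
        assert ap == 2.0 and T == 0.0

    def test_backscatter_limit(self):
        ap, _ = xs.compton_kinematics(1e9, -1.0)
        assert ap == pytest.approx(0.5, rel=1e-6)

    def test_co60_backscatter(self):
        # alpha = 1.25 MeV / m_e c^2; alpha' = alpha/(1+2 alpha)
        a = 1.25 / M_E_C2
        ap, T = xs.compton_kinematics(a, -1.0)
        assert ap == pytest.approx(a / (1 + 2 * a), rel=1e-12)
        assert ap * M_E_C2 == pytest.approx(0.2122, abs=2e-4)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            xs.compton_kinematics(1.0, 1.5)


class TestKleinNishina:
    def test_forward_value(self):
        # mu=1: K = 2 pi r_e^2 independent of energy
        for a in (0.1, 1.0, 10.0):
            assert xs.klein_nishina_dcs(a, 1.0) == pytest.approx(
                2 * math.pi * R_E**2)
        assert 2 * math.pi * R_E**2 == pytest.approx(4.989e-25, rel=1e-3)

    def test_thomson_limit(self):
        mu = np.linspace(-1, 1, 7)
        got = xs.klein_nishina_dcs(1e-6, mu)
        assert np.allclose(got, math.pi * R_E**2 * (1 + mu**2), rtol=1e-4)

    def test_integral_matches_closed_form(self):
        for a in (0.5, 1.0, 3.0, 29.0):
            num, _ = quad(lambda m: xs.klein_nishina_dcs(a, m), -1, 1,
                          limit=200)
            assert num == pytest.approx(float(xs.klein_nishina_total(a)),
                                        rel=1e-9)


class TestAtomicFactors:
    def test_coherent_forward_limit(self):
        el = get_element("C")
        got = xs.coherent_dcs(el, 0.1, 1.0)
        assert got == pytest.approx(math.pi * R_E**2 * 2 * el.Z**2,
                                    rel=1e-9)

    def test_max_momentum_transfer(self):
        a = 2.0
        q = xs.momentum_transfer(a, -1.0)
        assert q == pytest.approx(xs.K_COH * a * math.sqrt(2), rel=1e-12)

    def test_coherent_integral_vs_quadrature(self):
        el = get_element("O")
        E = 0.1
        total = float(xs.element_photon_xs(el, np.array([E]),
                                           "coherent")[0])
        oracle, _ = quad(lambda m: float(xs.coherent_dcs(el, E, m)),
                         -1, 1, limit=400)
        assert total == pytest.approx(oracle, rel=2e-3)

    def test_clamping(self):
        el = get_element("C")
        f0, S = xs.atomic_factors(el, 1e9)
        assert f0 == pytest.approx(0.0, abs=1e-6)
        assert S == pytest.approx(el.Z, rel=1e-3)
        with pytest.raises(ValueError):
            xs.atomic_factors(el, -1.0)


class TestMacroXs:
    def test_branch_probabilities_sum_to_one(self, water):
        _, probs = xs.photon_macro_xs(water, np.array([0.02, 0.5, 10.0]))
        s = sum(probs.values())
        assert np.allclose(s, 1.0)

    def test_no_pair_below_threshold(self, water):
        _, probs = xs.photon_macro_xs(water, np.array([1.0]))
        assert probs["pair"][0] == 0.0

    def test_density_linearity(self, water):
        heavy = water.with_density(2.0)
        t1, _ = xs.photon_macro_xs(water, np.array([1.0]))
        t2, _ = xs.photon_macro_xs(heavy, np.array([1.0]))
        assert t2[0] == pytest.approx(2 * t1[0], rel=1e-12)

    def test_range_error(self, water):
        with pytest.raises(ValueError):
            xs.photon_macro_xs(water, np.array([2e-4]))


class TestMoller:
    def test_vanishes_at_half(self, water):
        assert xs.moller_xs(np.array([1.0]), 0.5, water)[0] == 0.0
        assert xs.moller_xs(np.array([0.3]), 0.2, water)[0] == 0.0

    @pytest.mark.parametrize("T,EM", [(1.0, 0.2), (0.6, 0.05),
                                      (10.0, 0.5), (2.0, 0.9)])
    def test_total_equals_quadrature(self, water, T, EM):
        total = float(xs.moller_xs(np.array([T]), EM, water)[0])
        per_e, _ = quad(lambda W: float(xs.moller_dcs(T, W)), EM, T / 2,
                        limit=400, epsrel=1e-10)
        oracle = per_e * water.electron_density
        assert total == pytest.approx(oracle, rel=1e-6)

    def test_density_linearity(self, water):
        d = water.with_density(2.0)
        assert xs.moller_xs(np.array([1.0]), 0.2, d)[0] == pytest.approx(
            2 * xs.moller_xs(np.array([1.0]), 0.2, water)[0], rel=1e-12)


class TestBrems:
    def test_vanishes_at_threshold(self, water):
        assert xs.brems_xs(np.array([0.01]), 0.01, water)[0] == 0.0

    @pytest.mark.parametrize("T,EB", [(1.0, 0.01), (10.0, 0.1),
                                      (0.5, 0.05)])
    def test_total_equals_quadrature(self, water, T, EB):
        total = float(xs.brems_xs(np.array([T]), EB, water)[0])
        oracle = 0.0
        for el, n in zip(water.elements, water.number_densities):
            # substitute y = ln k so the 1/k weight is integrated exactly
            val, _ = quad(
                lambda y: float(xs.brems_dcs(T, math.exp(y), el))
                * math.exp(y),
                math.log(EB / T), 0.0, limit=400, epsrel=1e-11)
            oracle += n * val
        assert total == pytest.approx(oracle, rel=1e-6)

    def test_z_squared_scaling(self):
        c, pb = get_element("C"), get_element("Pb")
        rc = float(xs.brems_dcs(1.0, 0.5, c)) / c.Z**2 / c.brems_a \
            / (1 - c.brems_b * 0.5)
        rp = float(xs.brems_dcs(1.0, 0.5, pb)) / pb.Z**2 / pb.brems_a \
            / (1 - pb.brems_b * 0.5)
        assert rc == pytest.approx(rp, rel=1e-12)


class TestStoppingPower:
    def test_water_example(self, water):
        # 0.5 MeV, E_M = 0.2: restricted collision SP ~ 2.0 MeV/cm
        L = float(xs.restricted_stopping_power(
            np.array([0.5]), water, 0.2, 1e-9)[0])
        assert L == pytest.approx(2.006, rel=0.01)

    def test_lb_reduction_b_zero(self, water):
        # with b = 0 the radiative part reduces to a n Z^2 E_B / beta^2
        T, EB = 1.0, 0.05
        beta2 = 1 - 1 / (1 + T / M_E_C2) ** 2
        expected = sum(
            el.brems_a * n * el.Z**2 * EB / beta2
            * (1 - el.brems_b * EB / (2 * T))
            for el, n in zip(water.elements, water.number_densities))
        full = float(xs.restricted_stopping_power(
            np.array([T]), water, 0.2, EB)[0])
        coll = float(xs.restricted_stopping_power(
            np.array([T]), water, 0.2, 1e-12)[0])
        assert full - coll == pytest.approx(expected, rel=1e-6)

    @pytest.mark.parametrize("T", [0.6, 2.0, 10.0])
    def test_total_collision_sp_invariance(self, water, T):
        """L_c(E_M) + int_EM^{T/2} W dSigma_M/dW is independent of E_M."""
        def total(EM):
            L = float(xs.restricted_stopping_power(
                np.array([T]), water, EM, 1e-12)[0])
            tail, _ = quad(lambda W: W * float(xs.moller_dcs(T, W)),
                           EM, T / 2, limit=400, epsrel=1e-11)
            return L + tail * water.electron_density
        a, b = total(0.05), total(0.25)
        assert a == pytest.approx(b, rel=1e-3)

    def test_unrestricted_matches_reference(self, water):
        """eps -> 1/2 limit vs ESTAR water collision stopping powers."""
        refs = {0.1: 4.115, 0.5: 2.034, 1.0: 1.849, 10.0: 1.968}
        for T, ref in refs.items():
            L = float(xs.restricted_stopping_power(
                np.array([T]), water, T / 2, 1e-12)[0])
            assert L == pytest.approx(ref, rel=0.03)

    def test_domain_error(self, water):
        with pytest.raises(ValueError):
            xs.restricted_stopping_power(np.array([-1.0]), water, 0.2,
                                         0.01)


class TestElastic:
    def test_pdf_normalized(self):
        # integrate in v = ln(1 + 2 eta - mu) to resolve the forward peak
        for eta in (1e-8, 1e-5, 1e-3):
            lo, hi = math.log(2 * eta), math.log(2 + 2 * eta)
            val, _ = quad(
                lambda v, eta=eta: float(xs.screened_rutherford_pdf(
                    1 + 2 * eta - math.exp(v), eta)) * math.exp(v),
                lo, hi, limit=400, epsrel=1e-11)
            assert val == pytest.approx(1.0, rel=1e-8)

    def test_eta_decreasing_in_energy(self, graphite):
        T = np.array([0.1, 0.5, 2.0, 10.0])
        eta, ssr = xs.elastic_parameters(T, graphite)
        assert np.all(np.diff(eta) < 0)
        assert np.all(ssr > 0)

    def test_isotropic_limit(self):
        mu = np.linspace(-1, 1, 5)
        assert np.allclose(xs.screened_rutherford_pdf(mu, 1e9), 0.5,
                           rtol=1e-8)

    def test_sigma_linear_in_density(self, graphite):
        d = graphite.with_density(3.4)
        _, s1 = xs.elastic_parameters(np.array([1.0]), graphite)
        _, s2 = xs.elastic_parameters(np.array([1.0]), d)
        assert s2[0] == pytest.approx(2 * s1[0], rel=1e-12)


class TestEnergyTransfer:
    def test_graphite_value(self, graphite):
        got = float(xs.kn_energy_transfer_coeff(
            graphite, np.array([1.25]))[0])
        assert got == pytest.approx(0.0267, rel=3e-3)

    def test_al_over_c_is_za_ratio(self, graphite, aluminum):
        r = float(xs.kn_energy_transfer_coeff(aluminum,
                                              np.array([1.25]))[0]
                  / xs.kn_energy_transfer_coeff(graphite,
                                                np.array([1.25]))[0])
        za = (13 / 26.9815385) / (6 / 12.011)
        assert r == pytest.approx(za, rel=1e-9)

    def test_thomson_limit_no_transfer(self, water):
        assert float(xs.kn_energy_transfer_coeff(
            water, np.array([1e-3]))[0]) < 1e-3


def test_nonnegativity_property(rng, water):
    """All cross sections / stopping powers nonnegative on random input."""
    E = 10 ** rng.uniform(-2.9, 1.9, 50)
    total, probs = xs.photon_macro_xs(water, E)
    assert np.all(total > 0)
    for v in probs.values():
        assert np.all(v >= 0)
    T = 10 ** rng.uniform(-2.0, 1.9, 50)
    assert np.all(xs.moller_xs(T, 0.2, water) >= 0)
    assert np.all(xs.brems_xs(T, 0.01, water) >= 0)
    assert np.all(xs.restricted_stopping_power(T, water, 0.2, 0.01) > 0)
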