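"""Separation-profile solver against independent analytic solutions."""

import math
from dataclasses import replace

import numpy as np
import pytest

from peeldyn import ParameterSet, solve_separation, per_bond_force_scale
from peeldyn.micromech import (micromech_grid, MicromechError, _N_REF, _GW,
                               _shape_ref)


def analytic_piecewise(params, c1_uniform, gamma, theta, P, s_hat):
    """Closed-form solution of the piecewise constant-coefficient ODE.

    Patch (0, ŝ): κh'''' − γh'' + q·h = −P with q = k·c1; even solutions
    built from cosh(r·x) with κr⁴ − γr² + q = 0.  Overhang (ŝ, αŝ):
    κh'''' − γh'' = 0 (affine + exponentials in ℓ1).  Matching h..h''' at
    ŝ and the free-end conditions close a 6×6 linear system — a fully
    independent oracle for the FEM.
    """
    kap, k = params.kappa_i, params.k_i
    q = k * c1_uniform
    roots = np.roots([kap, 0.0, -gamma, 0.0, q])
    r = next(z for z in roots if z.real > 0 and z.imag > 0)
    l1 = math.sqrt(kap / gamma)
    a_end = params.alpha * s_hat
    hp = -P / q

    def patch_basis(x):
        x = np.asarray(x, dtype=complex)
        f = np.cosh(r * x) / np.cosh(r * s_hat)
        d1 = r * np.sinh(r * x) / np.cosh(r * s_hat)
        d2 = r ** 2 * np.cosh(r * x) / np.cosh(r * s_hat)
        d3 = r ** 3 * np.sinh(r * x) / np.cosh(r * s_hat)
        return [np.array([v.real, v.imag]) for v in (f, d1, d2, d3)]

    def over_basis(x):
        e1 = math.exp(-(x - s_hat) / l1)
        e2 = math.exp((x - a_end) / l1)
        return [np.array([1.0, x, e1, e2]),
                np.array([0.0, 1.0, -e1 / l1, e2 / l1]),
                np.array([0.0, 0.0, e1 / l1 ** 2, e2 / l1 ** 2]),
                np.array([0.0, 0.0, -e1 / l1 ** 3, e2 / l1 ** 3])]

    M = np.zeros((6, 6))
    rhs = np.zeros(6)
    pb = patch_basis(s_hat)
    ob = over_basis(s_hat)
    for i in range(4):
        M[i, :2] = pb[i]
        M[i, 2:] = -ob[i]
    rhs[0] = -hp
    obe = over_basis(a_end)
    M[4, 2:] = obe[2]
    M[5, 2:] = kap * obe[3] - gamma * obe[1]
    rhs[5] = -gamma * math.sin(theta)
    coef = np.linalg.solve(M, rhs)

    def h(x):
        x = np.asarray(x, float)
        out = np.empty_like(x)
        mask = x <= s_hat
        fb = patch_basis(x[mask])[0]
        out[mask] = hp + coef[0] * fb[0] + coef[1] * fb[1]
        xo = x[~mask]
        out[~mask] = (coef[2] + coef[3] * xo
                      + coef[4] * np.exp(-(xo - s_hat) / l1)
                      + coef[5] * np.exp((xo - a_end) / l1))
        return out

    return h


@pytest.fixture(scope="module")
def compliant_params():
    return ParameterSet(compliant=True)


def uniform_c1(value):
    return lambda s: np.full_like(np.asarray(s, float), value)


class TestAnalyticOracle:
    def test_matches_piecewise_solution(self, compliant_params):
        p = compliant_params
        c1u, gamma, theta, s_hat = 4e3, 255.0, 0.45, 0.5
        prof = solve_separation(uniform_c1(c1u), gamma, theta, 0.0, p,
                                s_hat=s_hat)
        h_ex = analytic_piecewise(p, c1u, gamma, theta, 0.0, s_hat)(prof.x)
        num = np.sqrt(np.trapezoid((prof.h - h_ex) ** 2, prof.x))
        den = np.sqrt(np.trapezoid(h_ex ** 2, prof.x))
        assert num / den < 1e-3

    def test_matches_with_pressure(self, compliant_params):
        p = compliant_params
        c1u, gamma, theta, P, s_hat = 4e3, 255.0, 0.3, 30.0, 0.5
        prof = solve_separation(uniform_c1(c1u), gamma, theta, P, p,
                                s_hat=s_hat)
        h_ex = analytic_piecewise(p, c1u, gamma, theta, P, s_hat)(prof.x)
        num = np.sqrt(np.trapezoid((prof.h - h_ex) ** 2, prof.x))
        den = np.sqrt(np.trapezoid(h_ex ** 2, prof.x))
        assert num / den < 1e-3

    def test_decay_length_matches_l2(self, compliant_params):
        """At weak tension, the boundary-layer envelope decays on
        ℓ2 = [4κ/(k·c1)]^(1/4) (beam on elastic foundation)."""
        p = compliant_params
        c1u, gamma, theta, s_hat = 4e3, 5.0, 0.3, 0.6
        l2 = (4.0 * p.kappa_i / (p.k_i * c1u)) ** 0.25
        prof = solve_separation(uniform_c1(c1u), gamma, theta, 0.0, p,
                                s_hat=s_hat)
        xf = np.linspace(s_hat - 10 * l2, s_hat - 0.2 * l2, 4000)
        habs = np.abs(prof.interp(xf))
        peaks = [i for i in range(1, len(xf) - 1)
                 if habs[i] > habs[i - 1] and habs[i] > habs[i + 1]]
        assert len(peaks) >= 3
        slope = np.polyfit(xf[peaks], np.log(habs[peaks]), 1)[0]
        assert 1.0 / slope == pytest.approx(l2, rel=0.05)


class TestStaticsProperties:
    def test_unloaded_profile_is_flat(self, compliant_params):
        prof = solve_separation(uniform_c1(4e3), 255.0, 0.0, 0.0,
                                compliant_params, s_hat=0.5)
        assert np.max(np.abs(prof.h)) < 1e-14

    def test_discrete_force_balance(self, compliant_params):
        """∫ k·c1·h over the patch (consistent Gauss quadrature) balances
        γ·sinθ − P·ŝ to near round-off."""
        p = compliant_params
        c1u, gamma, theta, P, s_hat = 4e3, 255.0, 0.45, 25.0, 0.5
        prof = solve_separation(uniform_c1(c1u), gamma, theta, P, p,
                                s_hat=s_hat)
        x, h, dh = prof.x, prof.h, prof.dh
        total = 0.0
        for e in range(len(x) - 1):
            if x[e + 1] > s_hat + 1e-12:
                break
            L = x[e + 1] - x[e]
            t = 0.5 * (np.array([-0.861136311594053, -0.339981043584856,
                                 0.339981043584856, 0.861136311594053]) + 1)
            N = _shape_ref(t)[0]
            hg = (N[0] * h[e] + N[1] * L * dh[e]
                  + N[2] * h[e + 1] + N[3] * L * dh[e + 1])
            total += np.sum(_GW * hg) * L / 2 * p.k_i * c1u
        assert total == pytest.approx(gamma * math.sin(theta) - P * s_hat,
                                      rel=1e-6)

    def test_mesh_convergence(self, compliant_params):
        p = compliant_params
        c1u, s_hat = 4e3, 0.5
        l2 = (4.0 * p.kappa_i / (p.k_i * c1u)) ** 0.25
        res = []
        for npl2 in (10, 20):
            grid = micromech_grid(s_hat, p.alpha, l2, nodes_per_l2=npl2)
            prof = solve_separation(uniform_c1(c1u), 255.0, 0.45, 0.0, p,
                                    s_hat=s_hat, grid=grid)
            res.append(np.max(np.abs(prof.h)))
        assert abs(res[1] - res[0]) / res[0] < 1e-3

    def test_alpha_insensitivity(self, compliant_params):
        """Results drift < 0.5% when the domain factor α goes 1.3 → 1.5."""
        vals = []
        for alpha in (1.3, 1.5):
            p = replace(compliant_params, alpha=alpha)
            prof = solve_separation(uniform_c1(4e3), 255.0, 0.45, 0.0, p,
                                    s_hat=0.5)
            on = prof.x <= 0.5
            vals.append(np.max(np.abs(prof.h[on])))
        assert abs(vals[1] - vals[0]) / vals[0] < 0.005

    def test_nonlinear_mode_agrees_at_small_slope(self, compliant_params):
        p = compliant_params
        kw = dict(gamma=255.0, theta=0.05, P=0.0, s_hat=0.5)
        lin = solve_separation(uniform_c1(4e3), kw["gamma"], kw["theta"],
                               kw["P"], p, s_hat=kw["s_hat"])
        assert np.max(np.abs(lin.dh)) < 0.1
        nl = solve_separation(uniform_c1(4e3), kw["gamma"], kw["theta"],
                              kw["P"], p, s_hat=kw["s_hat"],
                              nonlinear=True)
        assert np.max(np.abs(nl.h - lin.h)) / np.max(np.abs(lin.h)) < 0.01


class TestPerBondForce:
    def test_zero_profile(self, compliant_params):
        prof = solve_separation(uniform_c1(4e3), 255.0, 0.0, 0.0,
                                compliant_params, s_hat=0.5)
        assert per_bond_force_scale(prof, compliant_params) == pytest.approx(
            0.0, abs=1e-10)

    def test_linear_in_stiffness_at_fixed_h(self, compliant_params):
        prof = solve_separation(uniform_c1(4e3), 255.0, 0.45, 0.0,
                                compliant_params, s_hat=0.5)
        doubled = replace(prof, per_bond_force=2 * prof.per_bond_force)
        assert per_bond_force_scale(doubled, compliant_params) \
            == pytest.approx(2 * per_bond_force_scale(
                prof, compliant_params), rel=1e-12)


class TestErrors:
    def test_singular_foundation(self, compliant_params):
        with pytest.raises(MicromechError):
            solve_separation(uniform_c1(0.0), 0.0, 0.3, 0.0,
                             compliant_params, s_hat=0.5)

    def test_grid_must_contain_patch_edge(self, compliant_params):
        grid = np.linspace(0.0, 0.63, 40)   # 0.5 not a node
        with pytest.raises(ValueError, match="s_hat"):
            solve_separation(uniform_c1(4e3), 255.0, 0.3, 0.0,
                             compliant_params, s_hat=0.5, grid=grid)

    def test_negative_concentration_rejected(self, compliant_params):
        with pytest.raises(ValueError):
            solve_separation(uniform_c1(-1.0), 255.0, 0.3, 0.0,
                             compliant_params, s_hat=0.5)
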