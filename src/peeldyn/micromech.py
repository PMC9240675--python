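"""Membrane separation profile over the adhesion patch.

The patch margin behaves as a beam on an elastic foundation: the
membrane (bending stiffness κ, tension γ) rests on the bond carpet of
areal stiffness k·c1(x) on [0, ŝ], continues bond-free on the overhang
(ŝ, αŝ], is pressed down by the Laplace pressure P on the patch and
pulled up by the transverse tension component γ·sinθ at the outer end.
The separation h (relative to the unstressed bond length, h > 0 =
stretched) minimizes

    F[h] = γ∫√(1+h'²) + κ/2 ∫ h''²/(1+h'²)^{5/2}
           + ∫₀^ŝ (k c1/2) h² + ∫₀^ŝ P h  −  γ sinθ h(αŝ).

The default solver is the small-slope linearization (stationarity ODE
κh⁗ − γh″ + k c1 h·𝟙[x≤ŝ] = −P·𝟙[x≤ŝ], symmetry h'(0) = 0, h'''(0) = 0,
free end h''(αŝ) = 0, κh''' − γh' = −γ sinθ), justified because the
boundary layer ℓ2 = [4κ/(k c1)]^¼ is nanometric while separations are a
few xγ, so |h'| ≪ 1.  A full-nonlinear mode (damped Newton on the exact
discretized energy) is retained for verification.

Discretization: cubic Hermite finite elements (nodal h and h'), banded
Cholesky solve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solveh_banded

from .parameters import ParameterSet

__all__ = ["SeparationProfile", "solve_separation", "per_bond_force_scale",
           "micromech_grid", "MicromechError"]


class MicromechError(RuntimeError):
    """Singular stiffness or Newton non-convergence."""


@dataclass
class SeparationProfile:
    """Separation h(x) on [0, αŝ] and derived per-bond forces.

    ``x`` grid [μm] (graded toward ŝ), ``h`` signed separation [μm],
    ``dh`` nodal slope, ``per_bond_force`` k·h [pN], ``traction``
    k·c1·h [pN/μm] (zero beyond ŝ), ``s_hat`` patch half-size [μm].
    """

    x: np.ndarray
    h: np.ndarray
    dh: np.ndarray
    per_bond_force: np.ndarray
    traction: np.ndarray
    s_hat: float

    def interp(self, s):
        """Cubic-Hermite evaluation of h at arbitrary points."""
        return _hermite_eval(self.x, self.h, self.dh, np.asarray(s))


# -- grids ------------------------------------------------------------

def graded_spacings(length: float, d_min: float, d_max: float,
                    ratio: float = 1.25) -> np.ndarray:
    """Geometric spacings from d_min up to d_max filling ``length``
    (first spacing is d_min; returned ordered from the fine end)."""
    spacings = []
    d, total = d_min, 0.0
    while total < length:
        spacings.append(min(d, length - total))
        total += spacings[-1]
        d = min(d * ratio, d_max)
    return np.asarray(spacings)


def micromech_grid(s_hat: float, alpha: float, l2: float,
                   nodes_per_l2: int = 10, ratio: float = 1.25) -> np.ndarray:
    """Grid on [0, αŝ] with node at ŝ, resolving ℓ2 near the patch edge."""
    d_min = l2 / nodes_per_l2
    d_max = max(s_hat / 40.0, 4.0 * d_min)
    left = graded_spacings(s_hat, d_min, d_max, ratio)
    x_left = s_hat - np.concatenate(([0.0], np.cumsum(left)))
    x_left = x_left[::-1]
    x_left[0] = 0.0
    right = graded_spacings((alpha - 1.0) * s_hat, d_min, d_max, ratio)
    x_right = s_hat + np.cumsum(right)
    x_right[-1] = alpha * s_hat
    return np.concatenate((x_left, x_right))


# -- Hermite element machinery ---------------------------------------

# 4-point Gauss-Legendre on [-1, 1] (exact to degree 7)
_GP = np.array([-0.8611363115940526, -0.3399810435848563,
                0.3399810435848563, 0.8611363115940526])
_GW = np.array([0.3478548451374538, 0.6521451548625461,
                0.6521451548625461, 0.3478548451374538])


def _shape_ref(t):
    """Hermite shapes and derivatives on [0,1] w.r.t. t (slope DOFs carry
    the element length separately)."""
    N = np.array([1 - 3 * t ** 2 + 2 * t ** 3,
                  t - 2 * t ** 2 + t ** 3,
                  3 * t ** 2 - 2 * t ** 3,
                  -t ** 2 + t ** 3])
    dN = np.array([-6 * t + 6 * t ** 2,
                   1 - 4 * t + 3 * t ** 2,
                   6 * t - 6 * t ** 2,
                   -2 * t + 3 * t ** 2])
    ddN = np.array([-6 + 12 * t,
                    -4 + 6 * t,
                    6 - 12 * t,
                    -2 + 6 * t])
    return N, dN, ddN


_T = 0.5 * (_GP + 1.0)
_N_REF, _DN_REF, _DDN_REF = _shape_ref(_T)          # (4 dof, 4 gauss)
# linear interpolation of a nodal coefficient to Gauss points
_LIN = np.vstack((1.0 - _T, _T))                    # (2, 4 gauss)


def _bending_ke(L):
    """κ=1 bending element matrices for an array of lengths (n,4,4)."""
    n = L.shape[0]
    ke = np.empty((n, 4, 4))
    base = np.array([[12., 6., -12., 6.],
                     [6., 4., -6., 2.],
                     [-12., -6., 12., -6.],
                     [6., 2., -6., 4.]])
    pw = np.array([[3, 2, 3, 2], [2, 1, 2, 1], [3, 2, 3, 2], [2, 1, 2, 1]])
    for a in range(4):
        for b in range(4):
            ke[:, a, b] = base[a, b] / L ** pw[a, b]
    return ke


def _tension_ke(L):
    """γ=1 ∫N'N' element matrices (n,4,4)."""
    n = L.shape[0]
    ke = np.empty((n, 4, 4))
    base = np.array([[36., 3., -36., 3.],
                     [3., 4., -3., -1.],
                     [-36., -3., 36., -3.],
                     [3., -1., -3., 4.]])
    pw = np.array([[1, 0, 1, 0], [0, -1, 0, -1], [1, 0, 1, 0], [0, -1, 0, -1]])
    for a in range(4):
        for b in range(4):
            ke[:, a, b] = base[a, b] / (30.0 * L ** pw[a, b])
    return ke


def _foundation_ke(L, q_nodes):
    """∫ q(x) N N with q linear per element; q_nodes shape (n, 2).

    Slope DOFs carry the element length (N_slope_phys = L·N_ref), so the
    assembled system uses physical slopes everywhere.
    """
    qg = q_nodes @ _LIN                                  # (n, 4 gauss)
    n = L.shape[0]
    Nphys = np.empty((n, 4, 4))
    for a in range(4):
        fac = L if a in (1, 3) else np.ones_like(L)
        Nphys[:, a, :] = fac[:, None] * _N_REF[a][None, :]
    w = (qg * _GW[None, :]) * (L[:, None] / 2.0)
    return np.einsum("nag,ng,nbg->nab", Nphys, w, Nphys)


def _load_fe(L, P):
    """−P ∫N per patch element; shape (n, 4)."""
    fe = np.empty((L.shape[0], 4))
    fe[:, 0] = -P * L / 2.0
    fe[:, 1] = -P * L ** 2 / 12.0
    fe[:, 2] = -P * L / 2.0
    fe[:, 3] = P * L ** 2 / 12.0
    return fe


def _assemble_banded(x, patch_mask, q_nodes, kappa, gamma, P, theta):
    """Upper-banded symmetric stiffness (bw 3) and load vector.

    DOF order (h0, h0', h1, h1', ...); slope DOFs in physical units.
    """
    L = np.diff(x)
    n_el = L.shape[0]
    ndof = 2 * (n_el + 1)
    ke = kappa * _bending_ke(L) + gamma * _tension_ke(L)
    qn = np.where(patch_mask[:, None], q_nodes, 0.0)
    ke += _foundation_ke(L, qn)
    fe = np.where(patch_mask[:, None], _load_fe(L, P), 0.0)

    ab = np.zeros((4, ndof))           # upper form: ab[3 + i - j, j], i<=j
    g0 = 2 * np.arange(n_el)
    for a in range(4):
        for b in range(a, 4):
            i, j = g0 + a, g0 + b
            np.add.at(ab[3 + a - b], j, ke[:, a, b])
    f = np.zeros(ndof)
    for a in range(4):
        np.add.at(f, g0 + a, fe[:, a])
    f[-2] += gamma * math.sin(theta)
    return ab, f


def _hermite_eval(x, h, dh, s):
    idx = np.clip(np.searchsorted(x, s) - 1, 0, len(x) - 2)
    L = x[idx + 1] - x[idx]
    t = (s - x[idx]) / L
    N, _, _ = _shape_ref(t)
    return (N[0] * h[idx] + N[1] * L * dh[idx]
            + N[2] * h[idx + 1] + N[3] * L * dh[idx + 1])


def _solve_constrained(ab, f):
    """Solve with DOF 1 (h'(0) = 0, symmetry) enforced by exact
    row/column elimination in the upper-banded storage; banded Cholesky."""
    ab = ab.copy()
    f = f.copy()
    diag = ab[3, 1]
    if not diag > 0:
        diag = max(np.max(ab[3]), 1.0)
    # zero the couplings of DOF 1 (upper storage: ab[3+i-j, j] for i<=j)
    ab[2, 1] = 0.0                     # (0,1)
    for j in (2, 3, 4):                # (1,j) entries
        if j < ab.shape[1]:
            ab[3 + 1 - j, j] = 0.0
    ab[3, 1] = diag
    f[1] = 0.0
    try:
        sol = solveh_banded(ab, f, lower=False)
    except np.linalg.LinAlgError as exc:
        raise MicromechError(f"singular micromechanical stiffness: {exc}") from exc
    return sol


def solve_separation(c1, gamma: float, theta: float, P: float,
                     params: ParameterSet, s_hat: float | None = None,
                     grid: np.ndarray | None = None,
                     nonlinear: bool = False) -> SeparationProfile:
    """Minimize the patch energy for a given bond field.

    Parameters
    ----------
    c1 : tuple ``(s, values)`` of the bond line density on [0, ŝ]
        [molecules/μm], or a callable s → c1.
    gamma, theta, P : tension [pN], contact angle [rad], pressure
        [pN/μm²] from the capillary shape.
    s_hat : patch half-size [μm]; defaults to ``s[-1]`` of the field.
    grid : optional precomputed node positions (must contain ŝ).
    nonlinear : solve the exact (finite-slope, exact-curvature) energy
        by damped Newton instead of the small-slope linearization.
    """
    if callable(c1):
        if s_hat is None:
            raise ValueError("s_hat required when c1 is callable")
        c1_fun = c1
    else:
        s_c1, v_c1 = np.asarray(c1[0], float), np.asarray(c1[1], float)
        if s_hat is None:
            s_hat = float(s_c1[-1])
        c1_fun = lambda s: np.interp(s, s_c1, v_c1)
    if np.any(np.asarray(c1_fun(np.linspace(0, s_hat, 7))) < 0):
        raise ValueError("c1 must be non-negative")

    if grid is None:
        l2ref = max(float(np.max(c1_fun(np.linspace(0, s_hat, 31)))), 1e-300)
        l2 = (4.0 * params.kappa_i / (params.k_i * l2ref)) ** 0.25
        grid = micromech_grid(s_hat, params.alpha, min(l2, s_hat / 4.0))
    x = np.asarray(grid, float)
    i_hat = int(np.argmin(np.abs(x - s_hat)))
    if abs(x[i_hat] - s_hat) > 1e-9 * s_hat:
        raise ValueError("grid must contain the patch edge s_hat as a node")
    patch_mask = np.arange(len(x) - 1) < i_hat

    q_nodes = params.k_i * np.column_stack((c1_fun(x[:-1]), c1_fun(x[1:])))
    q_nodes[~patch_mask] = 0.0
    if gamma <= 0 and not np.any(q_nodes > 0):
        raise MicromechError("singular stiffness: c1 == 0 with gamma == 0")

    ab, f = _assemble_banded(x, patch_mask, q_nodes, params.kappa_i,
                             gamma, P, theta)
    sol = _solve_constrained(ab, f)
    h, dh = sol[0::2], sol[1::2]

    if nonlinear:
        h, dh = _newton_nonlinear(x, patch_mask, q_nodes, params.kappa_i,
                                  gamma, P, theta, h, dh)

    kb = params.k_i
    c1n = np.where(x <= s_hat, c1_fun(np.minimum(x, s_hat)), 0.0)
    return SeparationProfile(x=x, h=h, dh=dh, per_bond_force=kb * h,
                             traction=kb * c1n * h, s_hat=s_hat)


def per_bond_force_scale(profile: SeparationProfile,
                         params: ParameterSet) -> float:
    """max over the patch of k·|h| [pN]; compare against fγ = √(k·kBT)."""
    on_patch = profile.x <= profile.s_hat
    if not np.any(on_patch):
        return 0.0
    return float(np.max(np.abs(profile.per_bond_force[on_patch])))


# -- full nonlinear verification mode ---------------------------------

def _newton_nonlinear(x, patch_mask, q_nodes, kappa, gamma, P, theta,
                      h0, dh0, tol=1e-11, max_iter=60):
    """Damped Newton on the exact discretized energy (verification mode)."""
    L = np.diff(x)
    n_el = L.shape[0]
    ndof = 2 * (n_el + 1)
    g0 = 2 * np.arange(n_el)
    qg = (q_nodes @ _LIN)                       # (n,4)
    wq = _GW[None, :] * (L[:, None] / 2.0)
    # physical shape values at Gauss points
    Np = np.empty((n_el, 4, 4)); Dp = np.empty_like(Np); Sp = np.empty_like(Np)
    for a in range(4):
        fac = L if a in (1, 3) else np.ones_like(L)
        Np[:, a] = fac[:, None] * _N_REF[a][None, :]
        Dp[:, a] = (fac / L)[:, None] * _DN_REF[a][None, :]
        Sp[:, a] = (fac / L ** 2)[:, None] * _DDN_REF[a][None, :]

    def split(vec):
        el = np.empty((n_el, 4))
        el[:, 0] = vec[g0]; el[:, 1] = vec[g0 + 1]
        el[:, 2] = vec[g0 + 2]; el[:, 3] = vec[g0 + 3]
        return el

    def energy_grad_hess(vec):
        el = split(vec)
        u = np.einsum("nag,na->ng", Np, el)
        p = np.einsum("nag,na->ng", Dp, el)
        q = np.einsum("nag,na->ng", Sp, el)
        s2 = 1.0 + p * p
        r = np.sqrt(s2)
        pm = patch_mask[:, None]
        W = gamma * r + 0.5 * kappa * q * q * s2 ** -2.5 \
            + pm * (0.5 * qg * u * u + P * u)
        Wu = pm * (qg * u + P)
        Wp = gamma * p / r - 2.5 * kappa * q * q * p * s2 ** -3.5
        Wq = kappa * q * s2 ** -2.5
        Wuu = pm * qg
        Wpp = gamma * s2 ** -1.5 - 2.5 * kappa * q * q * s2 ** -3.5 \
            + 17.5 * kappa * q * q * p * p * s2 ** -4.5
        Wpq = -5.0 * kappa * q * p * s2 ** -3.5
        Wqq = kappa * s2 ** -2.5
        E = float(np.sum(W * wq)) - gamma * math.sin(theta) * vec[-2]
        ge = np.einsum("nag,ng->na", Np, Wu * wq) \
            + np.einsum("nag,ng->na", Dp, Wp * wq) \
            + np.einsum("nag,ng->na", Sp, Wq * wq)
        He = (np.einsum("nag,ng,nbg->nab", Np, Wuu * wq, Np)
              + np.einsum("nag,ng,nbg->nab", Dp, Wpp * wq, Dp)
              + np.einsum("nag,ng,nbg->nab", Sp, Wqq * wq, Sp)
              + np.einsum("nag,ng,nbg->nab", Dp, Wpq * wq, Sp)
              + np.einsum("nag,ng,nbg->nab", Sp, Wpq * wq, Dp))
        g = np.zeros(ndof)
        for a in range(4):
            np.add.at(g, g0 + a, ge[:, a])
        g[-2] -= gamma * math.sin(theta)
        return E, g, He

    vec = np.empty(ndof)
    vec[0::2], vec[1::2] = h0, dh0
    for it in range(max_iter):
        E, g, He = energy_grad_hess(vec)
        g[1] = 0.0
        gnorm = np.linalg.norm(g)
        scale = max(gamma, kappa, float(np.max(q_nodes)) + 1.0)
        if gnorm < tol * scale:
            return vec[0::2], vec[1::2]
        ab = np.zeros((4, ndof))
        for a in range(4):
            for b in range(a, 4):
                np.add.at(ab[3 + a - b], g0 + b, He[:, a, b])
        # regularize until the constrained banded system factorizes
        shift = 0.0
        for _ in range(40):
            ab_try = ab.copy()
            ab_try[3] += shift
            try:
                step = _solve_constrained(ab_try, -g)
                break
            except MicromechError:
                shift = max(2.0 * shift, 1e-8 * np.max(np.abs(ab[3])))
        else:  # pragma: no cover
            raise MicromechError("nonlinear mode: Hessian not factorizable")
        t = 1.0
        for _ in range(30):
            E_new, _, _ = energy_grad_hess(vec + t * step)
            if E_new <= E + 1e-4 * t * float(g @ step):
                break
            t *= 0.5
        vec = vec + t * step
    raise MicromechError(
        f"nonlinear Newton did not converge: |grad| = {gnorm:.3e}")
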