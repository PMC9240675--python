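"""Reaction–diffusion of bonds and free binders on the moving patch.

The bond field c1 lives on the shrinking patch [0, ŝ(t)], the free
binder field c2 on the whole half-vesicle [0, L0]; the patch edge moves
with velocity v̂ set by a Stefan-type condition.  Both fields are
discretized by vertex-centred finite volumes on front-fixed reference
grids (ξ = s/ŝ on the patch, η = (s−ŝ)/(L0−ŝ) outside), graded toward
the patch edge to resolve the nanometric process zone (ℓ2, ℓ3).

Numerical choices
-----------------
* Edge fluxes use Scharfetter–Gummel exponential fitting with the total
  drift potential (bond-stretching bias (h/xγ)², Flory–Huggins vacancy
  drift in crowding mode, and the ALE mesh-motion term), which is
  positivity-preserving and reduces to central differencing for pure
  diffusion.
* The moving-interface conditions are imposed *conservatively*: the
  relative bond flux through the patch edge is exactly zero (the edge is
  a barrier for bonds), and the interface velocity v̂ is the scalar
  unknown iterated (secant + bisection fallback) until the bond
  concentration at the edge equals the Young–Dupré value
  c1(ŝ) = 2γ(1−cosθ)/kBT (or its crowded analogue).  Total binder
  number is then conserved to machine precision in every mode, and bond
  number is exactly conserved when reactions are off.
* Backward-Euler in time; reactions semi-implicit (unbinding implicit,
  binding explicit); the identical per-cell reaction integral is applied
  with opposite signs to c1 and c2 so reactions exchange molecules
  exactly.
* Adaptive time step: CFL on the interface motion, an accuracy cap on
  the reaction rate, and step-doubling error control; negative
  concentrations reject the step and halve dt.
* The vesicle shape and the separation profile are quasi-static: both
  are recomputed from the current (ŝ, c1) at the start of each step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import solve_banded
from scipy.optimize import brentq

from . import kinetics
from .equilibrium import (VesicleShape, prepare_equilibrium, reference_area,
                          solve_vesicle_shape, arc_radius)
from .micromech import SeparationProfile, graded_spacings, solve_separation
from .parameters import ParameterSet, derive_scales

__all__ = ["SolverOptions", "ConcentrationState", "Trajectory",
           "PeelingSimulator", "SolverError", "interface_concentration",
           "interface_velocity", "advance_step", "run"]


class SolverError(RuntimeError):
    pass


# --------------------------------------------------------------------
# options / containers
# --------------------------------------------------------------------

@dataclass
class SolverOptions:
    """Numerical controls for the moving-boundary integrator.

    ``d_min`` / ``d_max`` override the near-interface / interior grid
    spacing [μm] of the patch grid at t = 0 (defaults derive from the
    process-zone scales: min(ℓ2/10, ℓ3/4), capped by ŝ0/2000 for purely
    diffusive runs).  ``constant_theta`` (rad) bypasses the capillary
    shape solve and holds the contact angle fixed, reproducing the
    analytic peeling assumption.  ``s_min`` is the failure threshold
    (default max(5ℓ2, 0.01·ŝ0)).
    """

    d_min: float | None = None
    d_max: float | None = None
    d_min_outer: float | None = None
    grid_ratio: float = 1.2
    dt_init: float | None = None
    dt_max: float | None = None
    rtol: float = 1e-5
    cfl: float = 0.2
    reaction_dt_factor: float = 0.2
    constant_theta: float | None = None
    s_min: float | None = None
    snapshot_every: float | None = None
    check_every: int = 1
    max_rejections: int = 20
    store_profiles: bool = False
    relax_tol: float = 1e-6
    relax_max_time: float | None = None
    steady_v_tol: float | None = None


@dataclass
class ConcentrationState:
    """Fields and geometry at one instant.

    ``xi``/``eta`` are the fixed reference grids; nodal positions are
    ``xi*s_hat`` and ``s_hat + eta*(L0 − s_hat)``.  ``c2`` holds the
    free-binder field on the composite grid (patch nodes then outer
    nodes, sharing the interface node).  Concentrations are line
    densities [molecules/μm].
    """

    t: float
    s_hat: float
    xi: np.ndarray
    eta: np.ndarray
    c1: np.ndarray
    c2: np.ndarray
    gamma: float              # pN (internal)
    A0: float                 # μm²
    theta0: float             # rad, prepared contact angle
    F_over_gamma: float = 0.0
    v_hat: float = 0.0
    shape: VesicleShape | None = None
    profile: SeparationProfile | None = None

    @property
    def s1(self) -> np.ndarray:
        return self.xi * self.s_hat

    @property
    def s2(self) -> np.ndarray:
        # composite free-binder grid: patch nodes then [ŝ, L0] nodes
        return np.concatenate((self.s1, self.s_hat
                               + self.eta[1:] * (self._L0 - self.s_hat)))

    _L0: float = 0.0

    def bond_number(self) -> float:
        return _integrate(self.s1, self.c1)

    def binder_number(self) -> float:
        return self.bond_number() + _integrate(self.s2, self.c2)


def _integrate(s, c):
    return float(np.trapezoid(c, s))


@dataclass
class Trajectory:
    """Scalar time series, optional snapshots and the failure event."""

    t: np.ndarray
    s_hat: np.ndarray
    theta: np.ndarray
    v_hat: np.ndarray
    N1: np.ndarray
    Ntot: np.ndarray
    t_fail: float = math.inf
    arrested: bool = False
    snapshots: list = field(default_factory=list)
    n_steps: int = 0
    n_rejections: int = 0
    params: ParameterSet | None = None
    final_state: ConcentrationState | None = None
    r0: float = 0.0           # kymograph rate normalization k̄off·c0

    def kymograph(self, key: str):
        """Stack a snapshot field into (t, s, values) rasters."""
        ts = np.array([sn["t"] for sn in self.snapshots])
        ss = [sn["s1"] if key in ("c1", "mu1", "r") else sn["s2"]
              for sn in self.snapshots]
        vals = [sn[key] for sn in self.snapshots]
        return ts, ss, vals

    def scalars_frame(self):
        import pandas as pd
        return pd.DataFrame({"t": self.t, "s_hat": self.s_hat,
                             "theta": self.theta, "v_hat": self.v_hat,
                             "N1": self.N1, "Ntot": self.Ntot})

    def to_csv(self, path: str) -> None:
        self.scalars_frame().to_csv(path, index=False)

    def to_hdf5(self, path: str) -> None:
        import h5py
        with h5py.File(path, "w") as f:
            g = f.create_group("scalars")
            for k in ("t", "s_hat", "theta", "v_hat", "N1", "Ntot"):
                g.create_dataset(k, data=getattr(self, k))
            f.attrs["t_fail"] = self.t_fail
            f.attrs["arrested"] = self.arrested
            f.attrs["r0"] = self.r0
            sg = f.create_group("snapshots")
            for i, sn in enumerate(self.snapshots):
                grp = sg.create_group(f"{i:06d}")
                for k, v in sn.items():
                    if np.ndim(v):
                        grp.create_dataset(k, data=v)
                    else:
                        grp.attrs[k] = v
            if self.params is not None:
                pg = f.create_group("params")
                for fname, fval in vars(self.params).items():
                    pg.attrs[fname] = fval if fval is not None else math.nan


# --------------------------------------------------------------------
# interface conditions
# --------------------------------------------------------------------

def interface_concentration(shape: VesicleShape | float,
                            params: ParameterSet,
                            gamma: float | None = None) -> float:
    """Bond concentration at the patch edge from the edge force balance.

    Dilute: c1(ŝ) = 2γ(1−cosθ)/kBT.  Crowded: the unique root of
    Π(c1) = 2γ(1−cosθ) below cmax.  ``shape`` may be a VesicleShape or a
    bare contact angle (with ``gamma`` [pN] supplied).  Returns a line
    density [molecules/μm].
    """
    if isinstance(shape, VesicleShape):
        theta = shape.theta
        if gamma is None:
            raise ValueError("gamma [pN] required alongside a VesicleShape")
    else:
        theta = float(shape)
        if gamma is None:
            raise ValueError("gamma [pN] required")
    target = 2.0 * gamma * (1.0 - math.cos(theta))
    if not params.crowding:
        return target / params.kBT_i
    cmax = params.cmax_i
    f = lambda c: kinetics.osmotic_tension(c / params.l_lat, params) - target
    hi = cmax * (1.0 - 1e-14)
    c = brentq(f, 0.0, hi, xtol=1e-15 * cmax, rtol=8.9e-16)
    return float(c)


def _one_sided_derivative(x, y):
    """Second-order one-sided derivative at the last node (nonuniform)."""
    h1 = x[-1] - x[-2]
    h2 = x[-2] - x[-3]
    return float((y[-1] * (2 * h1 + h2) / (h1 * (h1 + h2))
                  - y[-2] * (h1 + h2) / (h1 * h2)
                  + y[-3] * h1 / (h2 * (h1 + h2))))


def interface_velocity(state: ConcentrationState,
                       params: ParameterSet) -> float:
    """Diagnostic Stefan velocity from one-sided fluxes at the edge:
    v̂ = −D1·{c1' + c1·[(h/xγ)²]'}|ŝ / c1(ŝ) [μm/s]."""
    s = state.s1
    c1 = state.c1
    if not c1[-1] > 0:
        raise SolverError("c1(s_hat) = 0: interface velocity undefined")
    dc = _one_sided_derivative(s, c1)
    if state.profile is not None:
        g = (state.profile.interp(s) / params.x_gamma_i) ** 2
        dg = _one_sided_derivative(s, g)
    else:
        dg = 0.0
    return -params.D1 * (dc + c1[-1] * dg) / c1[-1]


# --------------------------------------------------------------------
# the simulator
# --------------------------------------------------------------------

def _bernoulli(z):
    """B(z) = z/(e^z − 1), stable near 0 and for large |z|."""
    z = np.asarray(z, float)
    out = np.empty_like(z)
    small = np.abs(z) < 1e-5
    out[small] = 1.0 - 0.5 * z[small] + z[small] ** 2 / 12.0
    zb = np.clip(z[~small], -500.0, 500.0)
    out[~small] = zb / np.expm1(zb)
    return out


def _bernoulli_prime(z):
    """dB/dz, stable: → −1 as z → −∞, → 0 as z → +∞."""
    z = np.asarray(z, float)
    out = np.empty_like(z)
    small = np.abs(z) < 1e-5
    out[small] = -0.5 + z[small] / 6.0
    mid = ~small & (np.abs(z) < 30.0)
    zm = z[mid]
    em = np.expm1(zm)
    out[mid] = (em - zm * (em + 1.0)) / em ** 2
    hi = z >= 30.0
    out[hi] = (1.0 - z[hi]) * np.exp(-np.minimum(z[hi], 700.0))
    out[z <= -30.0] = -1.0
    return out


class PeelingSimulator:
    """Integrates the coupled geometry / micro-mechanics / transport loop."""

    def __init__(self, params: ParameterSet,
                 options: SolverOptions | None = None):
        self.params = params
        self.opts = options or SolverOptions()
        self.scales = derive_scales(params)
        self._build_reference_grids()
        self._stats = {"rejections": 0, "steps": 0}

    # -- grids --------------------------------------------------------

    def _build_reference_grids(self) -> None:
        p, o = self.params, self.opts
        s0 = p.s_hat0
        l2 = self.scales.l2 * 1e6
        l3 = self.scales.l3 * 1e6
        cands = []
        if p.compliant:
            cands.append(l2 / 10.0)
        if p.reactions_on and p.koff_bar > 0 and math.isfinite(l3):
            cands.append(l3 / 4.0)
        if not cands:           # purely diffusive: resolve the √t layer
            cands.append(s0 / 2000.0)
        d_min = o.d_min if o.d_min is not None else min(cands)
        d_max = o.d_max if o.d_max is not None else s0 / 50.0
        spac = graded_spacings(s0, d_min, d_max, o.grid_ratio)
        pos = s0 - np.concatenate(([0.0], np.cumsum(spac)))
        pos = np.maximum(pos[::-1], 0.0)
        pos[0] = 0.0
        self.xi = np.unique(pos) / s0
        self.xi[-1] = 1.0

        douter = o.d_min_outer if o.d_min_outer is not None else max(
            d_min, (p.L0 - s0) / 2000.0)
        spac_o = graded_spacings(p.L0 - s0, douter, (p.L0 - s0) / 30.0,
                                 max(o.grid_ratio, 1.25))
        eta = np.concatenate(([0.0], np.cumsum(spac_o))) / (p.L0 - s0)
        eta[-1] = 1.0
        self.eta = eta

        # overhang extension (reference units of ŝ) for the mechanics grid
        spac_e = graded_spacings((p.alpha - 1.0) * s0, d_min, d_max,
                                 o.grid_ratio)
        self.zeta = 1.0 + np.cumsum(spac_e) / s0
        self.zeta[-1] = p.alpha

        # reference edge (midpoint) coordinates
        self.xi_e = 0.5 * (self.xi[:-1] + self.xi[1:])
        n1 = len(self.xi)
        # control-volume widths in reference units
        edges1 = np.concatenate(([0.0], self.xi_e, [1.0]))
        self.w1 = np.diff(edges1)                         # (n1,)
        # composite c2 grid in reference description
        self.n1 = n1
        self.n2 = len(self.eta) - 1                       # extra outer nodes

    # -- initial state ------------------------------------------------

    def initial_state(self) -> ConcentrationState:
        p = self.params
        eq = prepare_equilibrium(p)
        gamma = p.gamma_i if p.gamma is not None else eq.gamma_eq_i
        A0 = reference_area(p.R0, p.s_hat0)
        c1 = np.full(self.n1, eq.c1_eq * p.c0_i)
        c2 = np.full(self.n1 + self.n2, eq.c2_eq * p.c0_i)
        st = ConcentrationState(
            t=0.0, s_hat=p.s_hat0, xi=self.xi, eta=self.eta, c1=c1, c2=c2,
            gamma=gamma, A0=A0, theta0=eq.theta0,
            F_over_gamma=p.F_over_gamma)
        st._L0 = p.L0
        return st

    # -- quasi-static mechanics ---------------------------------------

    def _shape(self, s_hat, gamma, F_over_gamma) -> VesicleShape:
        o = self.opts
        F = F_over_gamma * gamma
        if o.constant_theta is not None:
            theta = o.constant_theta
            beta = math.asin(min(F / (2.0 * gamma), 1.0 - 1e-12))
            if math.sin(theta) <= math.sin(beta):
                beta = 0.0
            R = arc_radius(theta, beta, s_hat)
            return VesicleShape(s_hat=s_hat, theta=theta, beta=beta, R=R,
                                P=gamma / R, A0=math.nan)
        A0 = self._A0
        return solve_vesicle_shape(gamma, F, s_hat, A0)

    def _mechanics(self, state: ConcentrationState, shape: VesicleShape):
        """Quasi-static step inputs: drift potential g, rates, profile."""
        p = self.params
        s1 = state.xi * state.s_hat
        if not p.compliant:
            zeros = np.zeros(self.n1)
            kon = np.full(self.n1, p.kon_bar_i)
            koff = np.full(self.n1, p.koff_bar)
            prof = None
            g = zeros
        else:
            grid = np.concatenate((s1, self.zeta * state.s_hat))
            prof = solve_separation((s1, state.c1), state.gamma,
                                    shape.theta, shape.P, p,
                                    s_hat=state.s_hat, grid=grid)
            h = prof.h[:self.n1]
            g = (h / p.x_gamma_i) ** 2
            kon, koff = kinetics.rate_functions(h, p)
            kon, koff = np.asarray(kon), np.asarray(koff)
        # koff here is the bare (Bell) rate; the crowding unbinding
        # factor v⁻² is applied implicitly inside the bond solve
        return g, kon, koff, prof

    # -- one backward-Euler substep ------------------------------------

    def _solve_c1(self, state, dt, v_hat, g, koff, kon, c2_lag,
                  c1_init=None):
        """Backward-Euler solve of c1 for a trial v̂ (tridiagonal).

        In crowding mode the Flory–Huggins vacancy drift −2kBT·ln v is
        implicit in c1 (damped Newton, tridiagonal Jacobian) with the
        free-binder field lagged; otherwise a single linear solve.
        """
        p = self.params
        s_new = state.s_hat + v_hat * dt
        if s_new <= 0:
            raise SolverError("patch size became non-positive")
        xi, xi_e, w1 = self.xi, self.xi_e, self.w1
        ds = np.diff(xi) * s_new
        V_new = w1 * s_new
        V_old = w1 * state.s_hat
        n = self.n1
        dphi0 = np.diff(g) + (xi_e * v_hat) * ds / p.D1
        C = p.D1 / ds
        rhs = V_old * state.c1 + dt * V_new * kon * c2_lag[:n] ** 2
        diag0 = V_new * (1.0 + dt * koff)

        if not p.crowding:
            Bp = _bernoulli(dphi0)
            Bm = _bernoulli(-dphi0)
            lower = np.zeros(n)
            diag = diag0.copy()
            upper = np.zeros(n)
            diag[:-1] += dt * C * Bp
            upper[1:] = -dt * C * Bm
            diag[1:] += dt * C * Bm
            lower[:-1] = -dt * C * Bp
            ab = np.vstack((upper, diag, lower))
            return solve_banded((1, 1), ab, rhs), s_new, V_new

        cmax = p.cmax_i
        other = c2_lag[:n]
        c = (state.c1 if c1_init is None else c1_init).copy()
        c = np.minimum(np.maximum(c, 0.0), np.maximum(cmax - other, 0.0) * (1 - 1e-9))
        # crowding-enhanced unbinding (v⁻² factor) is nonlinear in c1 and
        # must be implicit alongside the vacancy drift
        react = (dt * V_new * koff if not p.mu2_vacancy
                 else None)
        diag_lin = V_new.copy() if react is not None else diag0
        c_new = self._newton_vacancy(c, other, 2.0, dphi0, C, ds, diag_lin,
                                     rhs, dt, cmax, react_koff=react)
        return c_new, s_new, V_new

    def _solve_c2(self, state, dt, v_hat, s_new, c1_lag, r_cells,
                  c2_init=None):
        """Backward-Euler solve of c2 on the composite moving grid."""
        p = self.params
        n1, n2 = self.n1, self.n2
        L0 = p.L0
        # new node positions and reference-consistent edge velocities
        s_old_nodes = np.concatenate((self.xi * state.s_hat,
                                      state.s_hat + self.eta[1:] * (L0 - state.s_hat)))
        s_new_nodes = np.concatenate((self.xi * s_new,
                                      s_new + self.eta[1:] * (L0 - s_new)))
        edges_new = 0.5 * (s_new_nodes[:-1] + s_new_nodes[1:])
        edges_old = 0.5 * (s_old_nodes[:-1] + s_old_nodes[1:])
        v_edges = (edges_new - edges_old) / dt
        ds = np.diff(s_new_nodes)
        V_new = np.diff(np.concatenate(([0.0], edges_new, [L0])))
        V_old = np.diff(np.concatenate(([0.0], edges_old, [L0])))
        dphi0 = v_edges * ds / p.D2
        C = p.D2 / ds
        n = n1 + n2
        rhs = V_old * state.c2
        rhs[:n1] -= dt * r_cells          # reactions only on the patch
        diag0 = V_new.copy()

        # free binders always feel the single-site vacancy drift in
        # crowding mode: the Flory–Huggins mobility couples every
        # species to the volume constraint, so unbinding debris is
        # pushed out of saturated zones even when μ2's ideal part keeps
        # the reaction affinity crowding-sensitive
        if not p.crowding:
            Bp = _bernoulli(dphi0)
            Bm = _bernoulli(-dphi0)
            lower = np.zeros(n)
            diag = diag0.copy()
            upper = np.zeros(n)
            diag[:-1] += dt * C * Bp
            upper[1:] = -dt * C * Bm
            diag[1:] += dt * C * Bm
            lower[:-1] = -dt * C * Bp
            ab = np.vstack((upper, diag, lower))
            return solve_banded((1, 1), ab, rhs)

        cmax = p.cmax_i
        other = np.concatenate((c1_lag, np.zeros(n2)))
        c = (state.c2 if c2_init is None else c2_init).copy()
        c = np.minimum(np.maximum(c, 0.0), np.maximum(cmax - other, 0.0) * (1 - 1e-9))
        return self._newton_vacancy(c, other, 1.0, dphi0, C, ds, diag0,
                                    rhs, dt, cmax)

    def _newton_vacancy(self, c, other, stoich, dphi0, C, ds, diag0, rhs,
                        dt, cmax, max_iter=40, react_koff=None,
                        v_floor=0.01):
        """Damped Newton for a drift-diffusion solve whose vacancy drift
        −stoich·ln[(cmax − c − other)/cmax] is implicit in ``c``.

        Residual R_i = diag0_i·c_i − dt·(G_i − G_{i−1}) − rhs_i with the
        Scharfetter–Gummel edge fluxes G; the Jacobian stays
        tridiagonal.  Zero relative flux through both boundary edges.
        ``react_koff`` (dt·V·koff per node, bond equation only) adds the
        crowding-enhanced unbinding sink koff·v⁻²·c, also implicit; the
        v⁻² factor is clipped at ``v_floor`` to bound its stiffness.
        """
        n = c.shape[0]
        eps_v = 1e-10

        def vac(cv):
            return np.maximum((cmax - cv - other) / cmax, eps_v)

        def flux_and_resid(cv):
            v = vac(cv)
            phi = -stoich * np.log(v)
            dphi = dphi0 + np.diff(phi)
            Bp = _bernoulli(dphi)
            Bm = _bernoulli(-dphi)
            G = C * (Bm * cv[1:] - Bp * cv[:-1])
            R = diag0 * cv - rhs
            R[:-1] -= dt * G
            R[1:] += dt * G
            if react_koff is not None:
                R += react_koff * np.maximum(v, v_floor) ** -2 * cv
            return R, v, dphi, Bp, Bm

        scale = max(float(np.max(np.abs(rhs))), 1e-300)
        R, v, dphi, Bp, Bm = flux_and_resid(c)
        for it in range(max_iter):
            if float(np.max(np.abs(R))) < 1e-12 * scale:
                return c
            # q_i = dφ_i/dc_i (zero where the vacancy clip is active)
            q = np.where(v > eps_v, stoich / (cmax * v), 0.0)
            dBm = _bernoulli_prime(-dphi)
            dBp = _bernoulli_prime(dphi)
            S = dBm * c[1:] + dBp * c[:-1]
            dG_dL = C * (-Bp + q[:-1] * S)
            dG_dR = C * (Bm - q[1:] * S)
            diag = diag0.copy()
            if react_koff is not None:
                vr = np.maximum(v, v_floor)
                diag += react_koff * vr ** -2
                unclipped = v > v_floor
                diag += np.where(unclipped,
                                 react_koff * c * 2.0 * vr ** -3 / cmax,
                                 0.0)
            upper = np.zeros(n)
            lower = np.zeros(n)
            diag[:-1] -= dt * dG_dL
            upper[1:] = -dt * dG_dR
            diag[1:] += dt * dG_dR
            lower[:-1] = dt * dG_dL
            ab = np.vstack((upper, diag, lower))
            try:
                step = solve_banded((1, 1), ab, -R)
            except np.linalg.LinAlgError as exc:
                raise _StepRejected(f"vacancy Newton: singular Jacobian") from exc
            # damp to keep c ≥ 0 and c + other < cmax
            t = 1.0
            for _ in range(50):
                cand = c + t * step
                if np.all(cand >= 0.0) and np.all(cand + other
                                                  < cmax * (1 - 1e-12)):
                    Rc, vc, dphic, Bpc, Bmc = flux_and_resid(cand)
                    if (float(np.max(np.abs(Rc)))
                            < (1.0 - 0.1 * t) * float(np.max(np.abs(R)))
                            or t < 1e-3):
                        c, R, v, dphi, Bp, Bm = cand, Rc, vc, dphic, Bpc, Bmc
                        break
                t *= 0.5
            else:
                raise _StepRejected("vacancy Newton: no admissible step")
        if float(np.max(np.abs(R))) < 1e-9 * scale:
            return c
        raise _StepRejected("vacancy Newton did not converge")

    # -- interface velocity solve --------------------------------------

    def _step_once(self, state: ConcentrationState, dt: float,
                   mech) -> ConcentrationState:
        """One backward-Euler step with the scalar v̂ iteration."""
        p = self.params
        g, kon, koff, prof = mech["g"], mech["kon"], mech["koff"], mech["prof"]
        c1_target = mech["c1_target"]
        if not p.reactions_on:
            kon = np.zeros(self.n1)
            koff = np.zeros(self.n1)
        # cross-species (crowding) and mechanics couplings are lagged;
        # extra Picard sweeps refresh them from the new fields
        n_picard = 3 if p.crowding else 1

        # the Young–Dupré edge value is imposed implicitly: for a trial
        # v̂ the target is evaluated at the end-of-step patch size, so an
        # accepted step ends exactly on its own target and the next step
        # starts mismatch-free (otherwise a sharp dt reduction would
        # demand a diverging bridging velocity)
        target_cache: dict[float, float] = {}

        def target_of(s_new: float) -> float:
            if self.opts.constant_theta is not None:
                return c1_target
            hit = target_cache.get(s_new)
            if hit is None:
                from .equilibrium import GeometryError
                try:
                    shape_new = self._shape(s_new, state.gamma,
                                            state.F_over_gamma)
                except GeometryError as exc:
                    raise _StepRejected(f"shape infeasible at trial "
                                        f"patch size: {exc}") from exc
                hit = interface_concentration(shape_new, p,
                                              gamma=state.gamma)
                target_cache[s_new] = hit
            return hit

        v_guess = state.v_hat
        c2_lag = state.c2
        c1_ws = [None]
        for ip in range(n_picard):
            def resid(v):
                c1n, s_new, _ = self._solve_c1(state, dt, v, g, koff, kon,
                                               c2_lag, c1_init=c1_ws[0])
                c1_ws[0] = c1n
                return c1n[-1] - target_of(s_new)

            # the residual usually decreases with v̂ (faster shrinkage
            # compresses bonds, raising the edge concentration), but the
            # crowding-enhanced unbinding can locally invert this, so the
            # bracket search tries both directions
            v_cap = 0.45 * state.s_hat / dt
            v_ref = p.s_hat0 / self.scales.tau_diff1
            v0 = float(np.clip(v_guess, -v_cap, v_cap))
            v1 = v0 + 1e-2 * max(abs(v0), v_ref)
            f0, f1 = resid(v0), resid(v1)
            tol = 1e-10 * max(c1_target, p.c0_i)
            converged = False
            for _ in range(30):
                if abs(f1) < tol:
                    converged = True
                    break
                if f1 == f0:
                    break
                v2 = v1 - f1 * (v1 - v0) / (f1 - f0)
                v2 = float(np.clip(v2, -v_cap, v_cap))
                v0, f0, v1, f1 = v1, f1, v2, resid(v2)
            if not converged and abs(f1) >= tol:
                primary = float(np.sign(f1)) or 1.0
                bracket = None
                for direction in (primary, -primary):
                    a, fa = v1, f1
                    step = max(abs(v1), v_ref)
                    for _ in range(60):
                        cand = float(np.clip(a + direction * step,
                                             -v_cap, v_cap))
                        fc = resid(cand)
                        if fa * fc <= 0:
                            bracket = (a, fa, cand, fc)
                            break
                        a, fa = cand, fc
                        step *= 2.0
                        if abs(cand) >= v_cap:
                            break
                    if bracket is not None:
                        break
                if bracket is None:
                    raise _StepRejected(
                        "no interface-velocity bracket in CFL-safe range")
                a, fa, b, fb = bracket
                for _ in range(200):
                    m = 0.5 * (a + b)
                    fm = resid(m)
                    if abs(fm) < tol or abs(b - a) < 1e-14 * max(1.0, abs(m)):
                        v1, f1 = m, fm
                        break
                    if fa * fm <= 0:
                        b, fb = m, fm
                    else:
                        a, fa = m, fm
                else:  # pragma: no cover
                    raise SolverError("interface velocity bisection stalled")
            v_hat = v1
            c1_new, s_new, V1_new = self._solve_c1(state, dt, v_hat, g, koff,
                                                   kon, c2_lag,
                                                   c1_init=c1_ws[0])
            # per-cell reaction integral actually exchanged with c2 (the
            # crowding factor must match the implicit bond solve exactly)
            koff_eff = koff
            if p.crowding and not p.mu2_vacancy:
                v = (p.cmax_i - c1_new - c2_lag[:self.n1]) / p.cmax_i
                koff_eff = koff * np.maximum(v, 0.01) ** -2
            r_cells = V1_new * (kon * c2_lag[:self.n1] ** 2
                                - koff_eff * c1_new)
            c2_new = self._solve_c2(state, dt, v_hat, s_new, c1_new, r_cells)
            v_guess = v_hat
            if ip < n_picard - 1:
                # refresh the lagged couplings — the free-binder field
                # seen by c1 and, in compliant crowding mode, the
                # quasi-static mechanics (backward quasi-statics is
                # stabler near saturation)
                if np.any(c1_new < 0) or np.any(c2_new < 0):
                    raise _StepRejected("negative concentration (picard)")
                c2_lag = c2_new
                if p.compliant:
                    tmp = replace(state, s_hat=s_new, c1=c1_new, c2=c2_new)
                    tmp._L0 = p.L0
                    shape2 = self._shape(s_new, state.gamma,
                                         state.F_over_gamma)
                    g, kon, koff, prof = self._mechanics(tmp, shape2)
                    c1_target = interface_concentration(
                        shape2, p, gamma=state.gamma)
        if np.any(c1_new < 0) or np.any(c2_new < 0):
            raise _StepRejected("negative concentration")
        if p.crowding:
            cT = c1_new + c2_new[:self.n1]
            if np.any(cT >= p.cmax_i) or np.any(c2_new >= p.cmax_i):
                raise _StepRejected("crowding overflow")
        new = replace(state, t=state.t + dt, s_hat=s_new, c1=c1_new,
                      c2=c2_new, v_hat=v_hat,
                      shape=mech["shape"], profile=prof)
        new._L0 = p.L0
        return new

    # -- public stepping ----------------------------------------------

    def _mech_inputs(self, state: ConcentrationState) -> dict:
        shape = self._shape(state.s_hat, state.gamma, state.F_over_gamma)
        g, kon, koff, prof = self._mechanics(state, shape)
        c1_target = interface_concentration(shape, self.params,
                                            gamma=state.gamma)
        return {"shape": shape, "g": g, "kon": kon, "koff": koff,
                "prof": prof, "c1_target": c1_target}

    def step(self, state: ConcentrationState, dt: float,
             error_control: bool = True,
             mech: dict | None = None) -> tuple[ConcentrationState, float]:
        """Advance one adaptive step; returns (new_state, error_estimate)."""
        self._A0 = state.A0
        if mech is None:
            mech = self._mech_inputs(state)
        full = self._step_once(state, dt, mech)
        if not error_control:
            return full, 0.0
        half = self._step_once(state, 0.5 * dt, mech)
        mech_mid = self._mech_inputs(half)
        two = self._step_once(half, 0.5 * dt, mech_mid)
        # volume-weighted RMS step-doubling estimate: the graded cells in
        # the nanometric process zone carry their share of the norm, not
        # a max-norm veto over the whole step
        scale = max(float(np.max(np.abs(state.c1))),
                    float(np.max(np.abs(state.c2))), self.params.c0_i)
        w1 = self.w1
        e1 = math.sqrt(float(np.sum(w1 * (full.c1 - two.c1) ** 2)
                             / np.sum(w1)))
        s2 = two.s2
        w2 = np.diff(np.concatenate(([s2[0]], 0.5 * (s2[:-1] + s2[1:]),
                                     [s2[-1]])))
        e2 = math.sqrt(float(np.sum(w2 * (full.c2 - two.c2) ** 2)
                             / np.sum(w2)))
        err = max(e1 / scale, e2 / scale,
                  abs(full.s_hat - two.s_hat) / state.s_hat)
        return two, err

    # -- driver --------------------------------------------------------

    def _dt_caps(self, state: ConcentrationState, mech) -> float:
        o, p = self.opts, self.params
        caps = [o.dt_max if o.dt_max is not None
                else 0.05 * self.scales.tau_diff2]
        ds_min = float(np.min(np.diff(self.xi))) * state.s_hat
        if state.v_hat != 0.0:
            caps.append(o.cfl * ds_min / abs(state.v_hat))
        koff = np.asarray(mech["koff"]) * kinetics.crowding_unbinding_factor(
            state.c1, state.c2[:self.n1], p)
        if p.reactions_on and np.max(koff, initial=0.0) > 0:
            caps.append(o.reaction_dt_factor / float(np.max(koff)))
        return min(caps)

    def run(self, t_end: float,
            schedule: list[tuple[float, float]] | None = None,
            state: ConcentrationState | None = None,
            relax_first: bool | None = None) -> Trajectory:
        """Integrate to ``t_end`` or failure.

        ``schedule`` is a force-step protocol [(t, F/γ), ...]; the
        default applies ``params.F_over_gamma`` at t = 0.  In compliant
        mode the state is first relaxed at F = 0 (the non-compliant
        equilibrium is not an equilibrium for compliant bonds).
        """
        p, o = self.params, self.opts
        if state is None:
            state = self.initial_state()
        if relax_first is None:
            # constant-θ runs reproduce analytic travelling/similarity
            # assumptions whose long-time behaviour is independent of the
            # initial transient; skip the (slow) F = 0 relaxation there
            relax_first = p.compliant and o.constant_theta is None
        if relax_first:
            state = self.relax(state)
        if schedule is None:
            schedule = [(0.0, p.F_over_gamma)]
        schedule = sorted(schedule)
        s_min = o.s_min if o.s_min is not None else max(
            5.0 * self.scales.l2 * 1e6, 0.01 * p.s_hat0)

        rec = {k: [] for k in ("t", "s_hat", "theta", "v_hat", "N1", "Ntot")}
        snaps = []
        t_fail = math.inf
        arrested = False
        self._A0 = state.A0

        dt = o.dt_init if o.dt_init is not None else 1e-7 * self.scales.tau_diff1
        next_snap = state.t
        n_steps = n_rej = 0
        sched_i = 0
        while state.t < t_end:
            jumped = False
            while sched_i < len(schedule) and schedule[sched_i][0] <= state.t:
                state = replace(state, F_over_gamma=schedule[sched_i][1])
                sched_i += 1
                jumped = True
            mech = self._mech_inputs(state)
            if jumped:
                # a force jump makes the Young–Dupré edge value jump
                # discontinuously; the continuum solution starts with a
                # zero-width concentration jump at the edge, applied here
                # to the interface node before integrating further
                c1 = state.c1.copy()
                c1[-1] = mech["c1_target"]
                state = replace(state, c1=c1)
                dt = min(dt, o.dt_init if o.dt_init is not None
                         else 1e-7 * self.scales.tau_diff1)
            if not rec["t"] or rec["t"][-1] < state.t:
                self._record(rec, state, mech)
                if o.snapshot_every is not None and state.t >= next_snap - 1e-12:
                    snaps.append(self._snapshot(state, mech))
                    next_snap = state.t + o.snapshot_every
            cap = self._dt_caps(state, mech)
            if sched_i < len(schedule):
                cap = min(cap, max(schedule[sched_i][0] - state.t, 1e-12))
            dt = min(dt, cap, t_end - state.t)
            check = o.check_every <= 1 or (n_steps % o.check_every == 0)
            rejected = 0
            while True:
                try:
                    new, err = self.step(state, dt, error_control=check,
                                         mech=mech)
                except _StepRejected:
                    dt *= 0.5
                    rejected += 1
                    n_rej += 1
                    if rejected > o.max_rejections:
                        raise SolverError(
                            f"step rejected {rejected} times at t = {state.t:.6g}")
                    continue
                if check and err > o.rtol:
                    dt *= max(0.3, 0.9 * math.sqrt(o.rtol / max(err, 1e-300)))
                    rejected += 1
                    n_rej += 1
                    if rejected > o.max_rejections:
                        raise SolverError(
                            f"error control failed at t = {state.t:.6g}")
                    continue
                break
            state = new
            n_steps += 1
            if check:
                dt = dt * (2.0 if err == 0.0 else
                           min(2.0, max(0.3, 0.9 * math.sqrt(o.rtol / err))))
            if state.s_hat < s_min:
                t_fail = state.t
                break
            if (o.steady_v_tol is not None
                    and abs(state.v_hat) < o.steady_v_tol
                    and state.t > 10 * dt):
                arrested = True
                break

        mech = self._mech_inputs(state)
        self._record(rec, state, mech)
        if o.snapshot_every is not None:
            snaps.append(self._snapshot(state, mech))
        traj = Trajectory(
            t=np.array(rec["t"]), s_hat=np.array(rec["s_hat"]),
            theta=np.array(rec["theta"]), v_hat=np.array(rec["v_hat"]),
            N1=np.array(rec["N1"]), Ntot=np.array(rec["Ntot"]),
            t_fail=t_fail, arrested=arrested, snapshots=snaps,
            n_steps=n_steps, n_rejections=n_rej, params=p,
            final_state=state, r0=p.koff_bar * p.c0_i)
        return traj

    def relax(self, state: ConcentrationState,
              tol: float | None = None) -> ConcentrationState:
        """Relax at F = 0 until max|dc1/dt| < tol·c0/τdiff,1 (compliant
        preparation before force application)."""
        p, o = self.params, self.opts
        tol = tol if tol is not None else o.relax_tol
        rate_scale = p.c0_i / self.scales.tau_diff1
        t_max = (o.relax_max_time if o.relax_max_time is not None
                 else 50.0 * self.scales.tau_diff1)
        st = replace(state, F_over_gamma=0.0)
        st._L0 = p.L0
        self._A0 = st.A0
        dt = 1e-6 * self.scales.tau_diff1
        t0 = st.t
        # relaxation is the F = 0 preparation stage: always use the
        # capillary shape, even if the production run holds θ constant
        ct_saved, self.opts.constant_theta = self.opts.constant_theta, None
        while st.t - t0 < t_max:
            mech = self._mech_inputs(st)
            dt = min(dt, self._dt_caps(st, mech))
            rejected = 0
            while True:
                try:
                    new, err = self.step(st, dt, mech=mech)
                except _StepRejected:
                    dt *= 0.5
                    rejected += 1
                    if rejected > o.max_rejections:
                        raise SolverError("relaxation step kept failing")
                    continue
                # only the relaxed end point matters, not the path:
                # loosen the step-doubling tolerance during preparation
                rtol_r = 30.0 * o.rtol
                if err > rtol_r:
                    dt *= max(0.3, 0.9 * math.sqrt(rtol_r / max(err, 1e-300)))
                    rejected += 1
                    if rejected > o.max_rejections:
                        raise SolverError("relaxation error control failed")
                    continue
                break
            rate = float(np.max(np.abs(new.c1 - st.c1))) / dt
            st = new
            dt *= 1.7
            if rate < tol * rate_scale:
                break
        self.opts.constant_theta = ct_saved
        out = replace(st, t=0.0, v_hat=0.0,
                      F_over_gamma=self.params.F_over_gamma)
        out._L0 = p.L0
        return out

    # -- recording -----------------------------------------------------

    def _record(self, rec, state, mech):
        rec["t"].append(state.t)
        rec["s_hat"].append(state.s_hat)
        rec["theta"].append(mech["shape"].theta)
        rec["v_hat"].append(state.v_hat)
        rec["N1"].append(state.bond_number())
        rec["Ntot"].append(state.binder_number())

    def _snapshot(self, state, mech):
        p = self.params
        s1 = state.s1
        s2 = state.s2
        prof = mech["prof"]
        h1 = prof.h[:self.n1] if prof is not None else np.zeros(self.n1)
        mu1, _ = kinetics.chemical_potentials(state.c1, state.c2[:self.n1],
                                              h1, p)
        _, mu2 = kinetics.chemical_potentials(
            np.full_like(state.c2, p.c0_i), state.c2, 0.0, p)
        kon, koff = mech["kon"], mech["koff"]
        fac = kinetics.crowding_unbinding_factor(state.c1,
                                                 state.c2[:self.n1], p)
        r = kon * state.c2[:self.n1] ** 2 - koff * fac * state.c1
        sn = {"t": state.t, "s_hat": state.s_hat, "s1": s1.copy(),
              "s2": s2.copy(), "c1": state.c1.copy(), "c2": state.c2.copy(),
              "mu1": np.asarray(mu1), "mu2": np.asarray(mu2),
              "r": np.asarray(r), "theta": mech["shape"].theta}
        if self.opts.store_profiles and prof is not None:
            sn["x_profile"] = prof.x.copy()
            sn["h_profile"] = prof.h.copy()
        return sn


class _StepRejected(Exception):
    pass


# --------------------------------------------------------------------
# convenience API
# --------------------------------------------------------------------

def advance_step(state: ConcentrationState, dt: float, params: ParameterSet,
                 options: SolverOptions | None = None,
                 simulator: PeelingSimulator | None = None
                 ) -> ConcentrationState:
    """One adaptive-error-checked step of the full quasi-static loop."""
    sim = simulator or PeelingSimulator(params, options)
    if simulator is None:
        sim.xi, sim.eta = state.xi, state.eta
        sim.n1 = len(state.xi)
        sim.n2 = len(state.eta) - 1
        sim.xi_e = 0.5 * (sim.xi[:-1] + sim.xi[1:])
        edges1 = np.concatenate(([0.0], sim.xi_e, [1.0]))
        sim.w1 = np.diff(edges1)
    sim._A0 = state.A0
    new, _ = sim.step(state, dt)
    return new


def run(params: ParameterSet, t_end: float,
        schedule: list[tuple[float, float]] | None = None,
        options: SolverOptions | None = None) -> Trajectory:
    """Prepare the equilibrium state, apply the force schedule, integrate."""
    sim = PeelingSimulator(params, options)
    return sim.run(t_end, schedule=schedule)
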