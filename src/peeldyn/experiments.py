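"""Regime drivers and derived analyses.

Reproduces the three peeling regimes and their summary statistics:

* diffusion-dominated (reactions off): self-similar Stefan shrinkage and
  similarity collapse of bond profiles;
* reaction-dominated (fast unbinding, slow diffusion, compliant slip
  bonds): travelling decohesion fronts with speed ~ v0 = √(D1·k̄off);
* mixed reaction–diffusion: force-dependent failure with a power-law
  lifetime t_fail ∝ (F − Fc)^a defining the patch strength Fc, and its
  weakening by molecular crowding.
"""

from __future__ import annotations

import hashlib
import json
import math
import os
from dataclasses import dataclass, field, replace, asdict

import numpy as np
from scipy.optimize import least_squares

from .parameters import ParameterSet, derive_scales
from .solver import PeelingSimulator, SolverOptions, Trajectory
from . import stefan

__all__ = ["FrontSpeedEstimate", "StrengthFit", "SweepResult",
           "estimate_front_speed", "sweep_failure_times", "fit_power_law",
           "regime_driver", "REGIME_PRESETS", "collapse_deviation"]


# --------------------------------------------------------------------
# front-speed estimation
# --------------------------------------------------------------------

@dataclass
class FrontSpeedEstimate:
    """Fitted interface speed over the best trailing linear window."""

    v_hat: float            # nm/s, signed (negative = shrinking patch)
    window: tuple[float, float]
    r_squared: float
    v_over_v0: float | None = None


class NoTravellingRegime(RuntimeError):
    """No trailing window of ŝ(t) is linear at the required R²."""


def _linfit(t, s):
    A = np.vstack((t, np.ones_like(t))).T
    coef, res, *_ = np.linalg.lstsq(A, s, rcond=None)
    pred = A @ coef
    sstot = float(np.sum((s - np.mean(s)) ** 2))
    ssres = float(np.sum((s - pred) ** 2))
    r2 = 1.0 if sstot == 0 else 1.0 - ssres / sstot
    return coef[0], r2


def estimate_front_speed(trajectory, v0: float | None = None,
                         transient_fraction: float = 0.2,
                         r2_min: float = 0.999) -> FrontSpeedEstimate:
    """Least-squares slope of ŝ(t) on the longest trailing window with
    R² ≥ ``r2_min``; the first ``transient_fraction`` of the run is
    always excluded.  ``v0`` [μm/s] normalizes the reported speed."""
    if isinstance(trajectory, Trajectory):
        t, s = trajectory.t, trajectory.s_hat
    else:
        t, s = map(np.asarray, trajectory)
    if len(t) < 5:
        raise NoTravellingRegime("trajectory too short")
    t0 = t[0] + transient_fraction * (t[-1] - t[0])
    mask = t >= t0
    t, s = t[mask], s[mask]
    n = len(t)
    if n < 5:
        raise NoTravellingRegime("trajectory too short after transient cut")
    for frac in np.linspace(1.0, 0.15, 18):
        i0 = n - max(int(frac * n), 5)
        slope, r2 = _linfit(t[i0:], s[i0:])
        if r2 >= r2_min:
            return FrontSpeedEstimate(
                v_hat=slope * 1e3, window=(float(t[i0]), float(t[-1])),
                r_squared=r2,
                v_over_v0=None if v0 is None else abs(slope) / v0)
    raise NoTravellingRegime("no travelling regime detected (R2 below "
                             f"{r2_min} on every trailing window)")


# --------------------------------------------------------------------
# failure-time sweeps with config-hash caching
# --------------------------------------------------------------------

@dataclass
class SweepResult:
    forces: np.ndarray
    t_fail: np.ndarray
    n_simulated: int            # sims actually run (0 if fully cached)
    errors: dict = field(default_factory=dict)


def _config_hash(params: ParameterSet, options: SolverOptions | None,
                 force: float, t_end: float) -> str:
    payload = {"params": {k: (repr(v)) for k, v in asdict(params).items()},
               "options": {k: repr(v) for k, v in
                           (vars(options).items() if options else [])},
               "force": repr(force), "t_end": repr(t_end)}
    return hashlib.sha1(json.dumps(payload, sort_keys=True).encode()).hexdigest()


def sweep_failure_times(params: ParameterSet, force_list,
                        t_end: float,
                        options: SolverOptions | None = None,
                        cache_dir: str | None = None) -> SweepResult:
    """One simulation per F/γ; t_fail = inf for runs that do not fail by
    ``t_end``.  Results are cached on disk keyed by a config hash, so an
    identical re-sweep performs zero new simulations.  Per-run solver
    errors are recorded and do not abort the sweep."""
    forces = np.asarray(force_list, float)
    t_fail = np.full(forces.shape, math.inf)
    errors: dict = {}
    n_sim = 0
    relaxed = None            # F = 0 preparation is force independent
    for i, f in enumerate(forces):
        p = replace(params, F_over_gamma=float(f))
        key = _config_hash(p, options, float(f), t_end)
        cache_file = (os.path.join(cache_dir, key + ".json")
                      if cache_dir else None)
        if cache_file and os.path.exists(cache_file):
            t_fail[i] = json.load(open(cache_file))["t_fail"]
            continue
        try:
            sim = PeelingSimulator(p, options)
            if p.compliant and relaxed is None and (
                    options is None or options.constant_theta is None):
                relaxed = sim.relax(sim.initial_state())
            if relaxed is not None:
                state = replace(relaxed, F_over_gamma=float(f))
                state._L0 = p.L0
                traj = sim.run(t_end, state=state, relax_first=False)
            else:
                traj = sim.run(t_end)
            t_fail[i] = traj.t_fail
            n_sim += 1
        except Exception as exc:   # propagate per-run, keep sweeping
            errors[float(f)] = repr(exc)
            continue
        if cache_file:
            os.makedirs(cache_dir, exist_ok=True)
            json.dump({"t_fail": t_fail[i]}, open(cache_file, "w"))
    return SweepResult(forces=forces, t_fail=t_fail, n_simulated=n_sim,
                       errors=errors)


# --------------------------------------------------------------------
# power-law strength fit
# --------------------------------------------------------------------

@dataclass
class StrengthFit:
    """t_fail = A·(F − Fc)^a fitted in log–log space with Fc free."""

    a: float
    F_c: float
    A: float
    forces: np.ndarray
    t_fail: np.ndarray
    cov: np.ndarray | None = None


class FitFailure(RuntimeError):
    pass


def fit_power_law(forces, t_fail, seed: int = 0,
                  n_starts: int = 5) -> StrengthFit:
    """Nonlinear least squares of ln t_fail = ln A + a·ln(F − Fc).

    Multi-start (jittered initializations, seeded) with best-residual
    selection; points with F within 1% of the fitted Fc are dropped and
    the fit repeated once, to avoid leverage blow-up near the threshold.
    """
    F = np.asarray(forces, float)
    T = np.asarray(t_fail, float)
    finite = np.isfinite(T) & np.isfinite(F)
    F, T = F[finite], T[finite]
    if len(F) < 5:
        raise FitFailure("need at least 5 finite failure times")
    order = np.argsort(F)
    F, T = F[order], T[order]
    logT = np.log(T)
    Fmin = float(np.min(F))
    rng = np.random.default_rng(seed)

    def resid(p):
        lnA, a, fc = p
        d = F - fc
        return lnA + a * np.log(d) - logT

    a0 = (logT[-1] - logT[0]) / (np.log(F[-1] - 0.98 * Fmin)
                                 - np.log(F[0] - 0.98 * Fmin))
    best = None
    trace = []
    for j in range(n_starts):
        fc0 = Fmin * (0.98 - 0.15 * rng.random()) if j else 0.98 * Fmin
        ag = a0 if j == 0 else -2.0 + 0.5 * rng.standard_normal()
        lnA0 = logT[0] - ag * np.log(F[0] - fc0)
        try:
            sol = least_squares(
                resid, x0=[lnA0, ag, fc0],
                bounds=([-np.inf, -np.inf, -np.inf],
                        [np.inf, np.inf, Fmin * (1.0 - 1e-9)]),
                xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception as exc:
            trace.append(repr(exc))
            continue
        trace.append(f"start {j}: cost {sol.cost:.3e}")
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise FitFailure("no start converged: " + "; ".join(trace))
    lnA, a, fc = best.x
    keep = F > 1.01 * fc
    if np.sum(keep) >= 5 and not np.all(keep):
        return fit_power_law(F[keep], T[keep], seed=seed + 1,
                             n_starts=n_starts)
    cov = None
    m = len(F)
    if m > 3:
        J = best.jac
        try:
            cov = np.linalg.inv(J.T @ J) * 2.0 * best.cost / (m - 3)
        except np.linalg.LinAlgError:
            cov = None
    return StrengthFit(a=float(a), F_c=float(fc), A=float(math.exp(lnA)),
                       forces=F, t_fail=T, cov=cov)


def is_arrested(traj: Trajectory, params: ParameterSet,
                s_hat_tol: float = 1e-4, mu_tol: float = 1e-4) -> bool:
    """Arrest test: over the trailing window (up to 2·τdiff,2) the patch
    size changes by less than ``s_hat_tol`` relative, and the chemical
    potentials are equilibrated, |μ1 − 2μ2| < ``mu_tol``·|μ2⁰|,
    throughout the patch.  A failed run is never arrested."""
    import math as _math
    from . import kinetics
    if _math.isfinite(traj.t_fail):
        return False
    scales = derive_scales(params)
    window = min(2.0 * scales.tau_diff2, traj.t[-1] - traj.t[0])
    sel = traj.t >= traj.t[-1] - window
    s_win = traj.s_hat[sel]
    if (np.max(s_win) - np.min(s_win)) / s_win[-1] > s_hat_tol:
        return False
    state = traj.final_state
    if state is None:
        raise ValueError("trajectory has no final state to test")
    n1 = len(state.c1)
    h = (state.profile.h[:n1] if state.profile is not None
         else np.zeros(n1))
    mu1, mu2 = kinetics.chemical_potentials(state.c1, state.c2[:n1], h,
                                            params)
    mu2_0 = 0.5 * params.kBT_i * _math.log(params.Kbar)
    return bool(np.max(np.abs(np.asarray(mu1) - 2.0 * np.asarray(mu2)))
                < mu_tol * abs(mu2_0))


def s_min_sensitivity(params: ParameterSet, force: float, t_end: float,
                      options: SolverOptions,
                      t_fail_ref: float | None = None) -> dict:
    """Report how the failure time depends on the threshold ŝ_min.

    Runs the given force with the default threshold (unless
    ``t_fail_ref`` is supplied) and with ŝ_min halved, and returns the
    two failure times and their difference.  In this model the terminal
    phase of mixed-regime failure is a decelerating shrinkage tail, so
    t_fail carries a definitional uncertainty of the order of the time
    to cross the last threshold decade — report it alongside any
    strength fit.
    """
    from dataclasses import replace as _replace
    scales = derive_scales(params)
    s_min_default = (options.s_min if options.s_min is not None
                     else max(5.0 * scales.l2 * 1e6, 0.01 * params.s_hat0))
    p = _replace(params, F_over_gamma=float(force))
    if t_fail_ref is None:
        t_fail_ref = PeelingSimulator(p, options).run(t_end).t_fail
    opts_half = _replace(options, s_min=0.5 * s_min_default)
    t_half = PeelingSimulator(p, opts_half).run(t_end).t_fail
    return {"force": float(force), "s_min": s_min_default,
            "t_fail": float(t_fail_ref), "t_fail_half_threshold": float(t_half),
            "delta": float(t_half - t_fail_ref)}


# --------------------------------------------------------------------
# similarity-collapse diagnostic
# --------------------------------------------------------------------

def collapse_deviation(traj: Trajectory, U: float, s_hat0: float,
                       tau_diff1: float, C0: float,
                       tau_max: float = 0.05) -> float:
    """Max deviation (in units of |U−1|) of rescaled c1 snapshots from
    the similarity profile in the variable x/√τ, over snapshots with
    0 < τ ≤ tau_max."""
    sol = stefan.StefanSolution.from_driving(U, s_hat0, tau_diff1, C0)
    worst = 0.0
    used = 0
    for sn in traj.snapshots:
        tau = sn["t"] / tau_diff1
        if not (0.0 < tau <= tau_max):
            continue
        x = sn["s1"] / s_hat0 - 1.0
        u_num = sn["c1"] / C0 - U
        u_ref = sol.u(x, tau)
        worst = max(worst, float(np.max(np.abs(u_num - u_ref))) / abs(U - 1.0))
        used += 1
    if used == 0:
        raise ValueError("no snapshots in (0, tau_max]")
    return worst


# --------------------------------------------------------------------
# regime presets and driver
# --------------------------------------------------------------------

def _f_beta_from_ratio(params: ParameterSet, ratio: float) -> float:
    """fβ in N from the requested fβ/fγ with fγ = √(k·kBT)."""
    return ratio * math.sqrt(params.k * params.kBT)


REGIME_PRESETS = {
    # long-lived mobile bonds: reactions off, D typical of lipid membranes
    "diffusion": dict(D1=0.25, D2=0.5, reactions_on=False, koff_bar=0.0,
                      compliant=False),
    # short-lived bonds with ~1000x reduced mobility (cytoskeleton-bound)
    "reaction": dict(D1=0.25e-3, D2=0.5e-3, koff_bar=10.0,
                     reactions_on=True, compliant=True),
    # short-lived mobile bonds (cadherins on a lipid membrane)
    "mixed": dict(D1=0.25, D2=0.5, koff_bar=10.0, reactions_on=True,
                  compliant=True),
    # ideal bonds; non-compliant keeps the scaled-down crowding sweep
    # tractable (compliance is orthogonal to the saturation physics)
    "crowding": dict(D1=0.25, D2=0.5, koff_bar=10.0, reactions_on=True,
                     compliant=False, crowding=True),
}


def preset_params(regime: str, base: ParameterSet | None = None,
                  **overrides) -> ParameterSet:
    if regime not in REGIME_PRESETS:
        raise ValueError(f"unknown regime {regime!r}; choose from "
                         f"{sorted(REGIME_PRESETS)}")
    base = base or ParameterSet()
    kw = dict(REGIME_PRESETS[regime])
    if regime == "reaction" and "f_beta" not in overrides:
        kw["f_beta"] = _f_beta_from_ratio(base, 4.0)
    kw.update(overrides)
    return replace(base, **kw)


def regime_driver(regime: str, params: ParameterSet | None = None,
                  overrides: dict | None = None, *,
                  scaled: bool = True, cache_dir: str | None = None) -> dict:
    """Run a regime's scenario list and return a report bundle.

    ``scaled`` selects the coarse problem sizes meant for routine use
    (the full-resolution settings are obtained with ``scaled=False``).
    """
    overrides = dict(overrides or {})
    forces = overrides.pop("forces", None)
    t_end = overrides.pop("t_end", None)
    p = preset_params(regime, params, **overrides)
    scales = derive_scales(p)
    report: dict = {"regime": regime, "params": p}

    if regime == "diffusion":
        U_values = (1.5, 2.0, 3.0)
        theta0 = math.asin(p.s_hat0 / p.R0)
        t_run = t_end if t_end is not None else 0.05 * scales.tau_diff1
        opts_kw = dict(snapshot_every=t_run / 8.0)
        if scaled:
            opts_kw.update(d_min=p.s_hat0 * 1e-3, check_every=4)
        from .equilibrium import prepare_equilibrium
        eq = prepare_equilibrium(p)
        C0 = eq.c1_eq * p.c0_i
        out = {}
        for U in U_values:
            theta = math.acos(1.0 - U * (1.0 - math.cos(theta0)))
            sim = PeelingSimulator(p, SolverOptions(
                constant_theta=theta, **opts_kw))
            traj = sim.run(t_run)
            dev = collapse_deviation(traj, U, p.s_hat0, scales.tau_diff1, C0)
            lam_fit = _fit_lambda(traj, p.s_hat0, scales.tau_diff1)
            out[U] = {"trajectory": traj, "collapse_dev": dev,
                      "lambda_fit": lam_fit,
                      "lambda_exact": stefan.lambda_of_U(U)}
        report["stefan"] = out
        return report

    if regime == "reaction":
        thetas = overrides.pop("theta_deg_list", None) or (26.0, 32.0, 40.0)
        ratios = overrides.pop("f_beta_over_f_gamma_list", None) or (2.0, 4.0)
        F_over_gamma = 0.5
        t_run = t_end if t_end is not None else 4.0
        speeds = {}
        for th in thetas:
            pp = replace(p, F_over_gamma=F_over_gamma)
            opts = _reaction_opts(pp, scales, th, scaled)
            traj = PeelingSimulator(pp, opts).run(t_run)
            speeds[("theta", th)] = estimate_front_speed(
                traj, v0=scales.v0 * 1e6)
        for ratio in ratios:
            pp = replace(p, F_over_gamma=F_over_gamma,
                         f_beta=_f_beta_from_ratio(p, ratio))
            opts = _reaction_opts(pp, scales, 32.0, scaled)
            traj = PeelingSimulator(pp, opts).run(t_run)
            speeds[("f_beta_ratio", ratio)] = estimate_front_speed(
                traj, v0=scales.v0 * 1e6)
        report["front_speeds"] = speeds
        report["v0_nm_s"] = scales.v0 * 1e9
        return report

    if regime == "mixed":
        if forces is None:
            # geometric ladder (ratio 1.08) above the estimated patch
            # strength Fc ≈ 0.36 of this model variant
            forces = np.round(0.40 * 1.08 ** np.arange(6), 4)
        t_run = t_end if t_end is not None else 120.0 * scales.tau_diff1
        opts = _mixed_opts(p, scales, scaled)
        sweep = sweep_failure_times(p, forces, t_run, opts,
                                    cache_dir=cache_dir)
        report["sweep"] = sweep
        finite = np.isfinite(sweep.t_fail)
        if np.sum(finite) >= 5:
            report["strength_fit"] = fit_power_law(
                sweep.forces[finite], sweep.t_fail[finite])
        return report

    if regime == "crowding":
        cmax_list = overrides.pop("cmax_list", None) or (5.0, 20.0, 500.0)
        F_over_gamma = overrides.pop("F_over_gamma", 0.3)
        t_run = t_end if t_end is not None else 48.0 * scales.tau_diff1
        out = {}
        for cm in cmax_list:
            pp = replace(p, cmax=cm * p.c0, F_over_gamma=F_over_gamma)
            opts = _crowding_opts(scaled)
            traj = PeelingSimulator(pp, opts).run(t_run)
            out[cm] = traj.t_fail
        report["t_fail_by_cmax"] = out
        return report

    raise ValueError(f"unknown regime {regime!r}")


def _reaction_opts(p, scales, theta_deg, scaled):
    l2 = scales.l2 * 1e6
    kw = dict(constant_theta=math.radians(theta_deg))
    if scaled:
        kw.update(d_min=max(scales.l3 * 1e6 / 2.0, l2 / 6.0),
                  check_every=8, rtol=3e-5)
    return SolverOptions(**kw)


def _mixed_opts(p, scales, scaled):
    l2 = scales.l2 * 1e6
    if scaled:
        return SolverOptions(d_min=l2 / 6.0, check_every=8, rtol=3e-5,
                             reaction_dt_factor=1.0)
    return SolverOptions()


def _crowding_opts(scaled):
    # the crowded burn-in is stiff (v⁻² unbinding at the edge): larger
    # rejection budget, weighted-norm tolerance matched to t_fail needs
    if scaled:
        return SolverOptions(check_every=8, rtol=3e-4,
                             reaction_dt_factor=1.0, max_rejections=40)
    return SolverOptions(rtol=3e-5, reaction_dt_factor=1.0,
                         max_rejections=40)


def _fit_lambda(traj: Trajectory, s_hat0: float, tau_diff1: float) -> float:
    """λ from a least-squares fit of ŝ(t)/ŝ0 − 1 against 2√τ."""
    tau = traj.t / tau_diff1
    X = traj.s_hat / s_hat0 - 1.0
    z = 2.0 * np.sqrt(tau)
    denom = float(z @ z)
    if denom == 0:
        return 0.0
    return float(z @ X) / denom
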