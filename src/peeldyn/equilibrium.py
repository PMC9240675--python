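"""Equilibrium preparation and quasi-static vesicle capillary shape.

The initial state is the equilibrium of two identical vesicles adhering
through mobile, non-compliant ideal bonds: the law of mass action
K̄ = c0·c1/c2² together with conservation of the total binder number
Ntot = c1·ŝ0 + c2·L0 = c0·L0 fixes the concentrations, and the
Young–Dupré balance kBT·c1 = 2γ(1−cosθ0) with sinθ0 = ŝ0/R0 fixes the
membrane tension.

At the vesicle scale the membrane is treated in the capillary (high
tension) limit: the free contour of each half-vesicle is a circular arc
(uniform tension and pressure imply constant curvature), the loading
device attaches on the symmetry axis and pulls with force F, so the two
membrane leaves leave the apex at an angle β with sinβ = F/(2γ), and the
enclosed area is held fixed by the Laplace pressure P = γ/R.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq

from .parameters import ParameterSet


class GeometryError(ValueError):
    """The capillary shape problem has no admissible solution."""


@dataclass
class VesicleShape:
    """Macroscopic capillary state of one half-vesicle.

    ``s_hat`` patch half-size [μm], ``theta`` contact angle at the patch
    edge, ``beta`` tangent angle at the load apex, ``R`` free-arc radius
    [μm], ``P`` Laplace pressure γ/R [pN/μm²·l_lat], ``A0`` conserved
    enclosed area [μm²].
    """

    s_hat: float
    theta: float
    beta: float
    R: float
    P: float
    A0: float


@dataclass
class EquilibriumState:
    """Prepared equilibrium: concentrations (×c0), tension and potentials."""

    c1_eq: float        # ×c0
    c2_eq: float        # ×c0
    gamma_eq: float     # N/m × l_lat
    gamma_eq_i: float   # pN (internal)
    mu1_0: float        # J (0 by convention)
    mu2_0: float        # J, (kBT ln K̄)/2
    theta0: float       # rad
    C0: float           # interface bond concentration scale, ×c0


def equilibrium_concentrations(params: ParameterSet) -> tuple[float, float]:
    """Equilibrium (c1, c2) in units of c0, closed form.

    With x = c2/c0, mass action c1/c0 = K̄ x² turns binder conservation
    into the quadratic K̄·ŝ0·x² + L0·x − L0 = 0 whose unique
    non-negative root is returned.
    """
    K, s0, L0 = params.Kbar, params.s_hat0, params.L0
    if K == 0.0:
        return 0.0, 1.0
    a, b, c = K * s0, L0, -L0
    disc = b * b - 4.0 * a * c
    if disc < 0:  # impossible for valid inputs
        raise ArithmeticError("mass-action quadratic has no real root")
    # numerically stable positive root
    x = 2.0 * (-c) / (b + math.sqrt(disc))
    return K * x * x, x


def equilibrium_tension(params: ParameterSet,
                        c1_eq: float) -> tuple[float, float]:
    """Young–Dupré tension [N/m × l_lat] and contact angle θ0.

    ``c1_eq`` is the bond concentration in molecules/μm² × l_lat.  The
    balancing tension uses the osmotic tension of the bond gas — kBT·c1
    in the dilute model, its Flory–Huggins generalization in crowding
    mode — so the prepared state satisfies the edge force balance of the
    model that will be integrated.
    """
    if params.s_hat0 >= params.R0:
        raise GeometryError("s_hat0 must be < R0")
    theta0 = math.asin(params.s_hat0 / params.R0)
    from . import units
    from .kinetics import osmotic_tension
    Pi = osmotic_tension(c1_eq * params.l_lat, params)
    gamma_i = Pi / (2.0 * (1.0 - math.cos(theta0)))
    return gamma_i / (params.l_lat * units.NPM_TO_PNPUM), theta0


def prepare_equilibrium(params: ParameterSet) -> EquilibriumState:
    """Full equilibrium preparation (concentrations, tension, potentials)."""
    c1, c2 = equilibrium_concentrations(params)
    gamma, theta0 = equilibrium_tension(params, c1 * params.c0)
    from . import units
    return EquilibriumState(
        c1_eq=c1,
        c2_eq=c2,
        gamma_eq=gamma,
        gamma_eq_i=gamma * params.l_lat * units.NPM_TO_PNPUM,
        mu1_0=0.0,
        mu2_0=0.5 * params.kBT * math.log(params.Kbar) if params.Kbar > 0 else -math.inf,
        theta0=theta0,
        C0=c1,  # at preparation c1(ŝ) = c1_eq by construction
    )


def enclosed_area(theta: float, beta: float, R: float, s_hat: float) -> float:
    """Area enclosed by one half-vesicle (patch chord + circular arc).

    Closed form of the shoelace integral over the contour
    (0,0) → (ŝ,0) → arc → (0, y_apex) → (0,0); only the arc contributes.
    """
    del s_hat  # determined by (theta, beta, R); kept for a readable signature
    return 0.5 * R * R * (
        math.pi - theta - beta
        - math.sin(beta) * math.cos(beta)
        + math.sin(theta) * math.cos(theta)
        - 2.0 * math.sin(beta) * math.cos(theta)
    )


def reference_area(R0: float, s_hat0: float) -> float:
    """A0 convention: prepared shape = circle of radius R0 truncated by a
    chord of half-length ŝ0 (F = 0, β = 0)."""
    theta0 = math.asin(s_hat0 / R0)
    return enclosed_area(theta0, 0.0, R0, s_hat0)


def arc_radius(theta: float, beta: float, s_hat: float) -> float:
    """Free-arc radius from the edge/apex tangency conditions."""
    denom = math.sin(theta) - math.sin(beta)
    if denom <= 0:
        raise GeometryError("need sin(theta) > sin(beta) for a closed arc")
    return s_hat / denom


def solve_vesicle_shape(gamma: float, F: float, s_hat: float,
                        A0: float) -> VesicleShape:
    """Solve the capillary shape for given tension, force and patch size.

    All inputs in internal units (γ, F in pN; ŝ in μm; A0 in μm²).
    β = arcsin(F/(2γ)); θ is the unique root in (β, π/2) of the
    area-closure equation; P = γ/R.
    """
    if not F < 2.0 * gamma:
        raise GeometryError("tension cannot balance load: need F < 2*gamma")
    if F < 0:
        raise GeometryError("F must be >= 0")
    beta = math.asin(F / (2.0 * gamma))

    def darea(theta: float) -> float:
        return enclosed_area(theta, beta, arc_radius(theta, beta, s_hat),
                             s_hat) - A0

    lo = beta + 1e-12
    hi = math.pi / 2.0 - 1e-12
    flo, fhi = darea(lo), darea(hi)
    if flo * fhi > 0:
        raise GeometryError(
            "no contact angle in (beta, pi/2) closes the area: "
            f"dA({lo:.3g}) = {flo:.3g}, dA({hi:.3g}) = {fhi:.3g}")
    theta = brentq(darea, lo, hi, xtol=1e-13, rtol=8.9e-16)
    R = arc_radius(theta, beta, s_hat)
    return VesicleShape(s_hat=s_hat, theta=theta, beta=beta, R=R,
                       P=gamma / R, A0=A0)


def driving_parameter(theta: float, theta0: float) -> float:
    """U = (1−cosθ)/(1−cosθ0); U = 1 at the prepared state."""
    if not (0.0 < theta < math.pi and 0.0 < theta0 < math.pi):
        raise GeometryError("angles must lie in (0, pi)")
    return (1.0 - math.cos(theta)) / (1.0 - math.cos(theta0))
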