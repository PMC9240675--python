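"""Closed-form similarity machinery for the diffusion-dominated regime.

With reactions off, non-compliant bonds and a constant contact angle,
the bond field on the shrinking patch obeys a classical one-phase Stefan
problem.  In non-dimensional variables x = s/ŝ0 − 1, τ = t/τdiff,1,
u = c1/C0 − U, X(τ) = ŝ/ŝ0 − 1 with driving parameter
U = (1−cosθ)/(1−cosθ0), the short-time/large-domain solution is

    u(x, τ) = √π λ e^{λ²} U [erf(λ) − erf(x/(2√τ))],
    X(τ)    = 2 λ √τ,

where λ(U) solves the transcendental equation

    √π λ e^{λ²} U [erf(λ) + 1] = 1 − U,

so that u → 1−U far behind the front and u = 0 on the moving interface.
For U > 1 (force applied) λ < 0 and the patch shrinks like √t.  This is
the primary analytic oracle for the moving-boundary solver.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import erf, erfc

SQRT_PI = math.sqrt(math.pi)


def _residual(lam: float, U: float) -> float:
    # erf(λ)+1 written as erfc(−λ) to avoid cancellation for λ ≪ 0
    return (SQRT_PI * lam * math.exp(lam * lam) * U * erfc(-lam)
            - (1.0 - U))


def _residual_prime(lam: float, U: float) -> float:
    # d/dλ [√π λ e^{λ²} (erf λ + 1)] = √π e^{λ²}(1 + 2λ²)(erf λ + 1) + 2λ
    return U * (SQRT_PI * math.exp(lam * lam) * (1.0 + 2.0 * lam * lam)
                * erfc(-lam) + 2.0 * lam)


def lambda_of_U(U: float) -> float:
    """Similarity constant λ(U); λ = 0 at U = 1, λ < 0 for U > 1.

    Bracketed bisection followed by Newton polish; the residual of the
    transcendental at the returned value is below 1e-12.
    """
    if not (0.0 < U <= 50.0):
        raise ValueError(f"U must lie in (0, 50], got {U!r}")
    if U == 1.0:
        return 0.0
    a, b = (-5.0, 0.0) if U > 1.0 else (0.0, 5.0)
    fa = _residual(a, U)
    fb = _residual(b, U)
    if fa * fb > 0:  # pragma: no cover - cannot happen for U in range
        raise ArithmeticError("transcendental root not bracketed")
    for _ in range(60):
        m = 0.5 * (a + b)
        fm = _residual(m, U)
        if fa * fm <= 0.0:
            b, fb = m, fm
        else:
            a, fa = m, fm
    lam = 0.5 * (a + b)
    for _ in range(8):
        step = _residual(lam, U) / _residual_prime(lam, U)
        lam -= step
        if abs(step) < 1e-16:
            break
    return lam


def similarity_solution(x, tau, U: float):
    """Rescaled bond concentration u(x, τ) of the similarity solution."""
    if np.any(np.asarray(tau) <= 0):
        raise ValueError("tau must be strictly positive")
    lam = lambda_of_U(U)
    z = np.asarray(x) / (2.0 * np.sqrt(np.asarray(tau, dtype=float)))
    u = SQRT_PI * lam * math.exp(lam * lam) * U * (erf(lam) - erf(z))
    return float(u) if np.ndim(u) == 0 else u


def interface_position(tau, U: float):
    """X(τ) = 2λ√τ."""
    return 2.0 * lambda_of_U(U) * np.sqrt(tau)


def s_hat_of_t(t, U: float, s_hat0: float, tau_diff1: float):
    """Dimensional interface trajectory ŝ(t) = ŝ0·(1 + 2λ√(t/τdiff,1))."""
    return s_hat0 * (1.0 + interface_position(np.asarray(t) / tau_diff1, U))


@dataclass(frozen=True)
class StefanSolution:
    """Similarity solution bundled with its dimensional mapping constants."""

    U: float
    lam: float
    s_hat0: float
    tau_diff1: float
    C0: float  # interface concentration scale [molecules/μm]

    @classmethod
    def from_driving(cls, U: float, s_hat0: float, tau_diff1: float,
                     C0: float) -> "StefanSolution":
        return cls(U=U, lam=lambda_of_U(U), s_hat0=s_hat0,
                   tau_diff1=tau_diff1, C0=C0)

    def u(self, x, tau):
        return similarity_solution(x, tau, self.U)

    def X(self, tau):
        return 2.0 * self.lam * np.sqrt(tau)

    def s_hat(self, t):
        return self.s_hat0 * (1.0 + self.X(np.asarray(t) / self.tau_diff1))

    def c1(self, s, t):
        """Dimensional bond field c1(s, t) [molecules/μm]."""
        x, tau = self.to_similarity_coords(s, t)
        return (self.u(x, tau) + self.U) * self.C0

    # -- bijective nondimensional mapping -----------------------------

    def to_similarity_coords(self, s, t):
        return np.asarray(s) / self.s_hat0 - 1.0, np.asarray(t) / self.tau_diff1

    def from_similarity_coords(self, x, tau):
        return self.s_hat0 * (np.asarray(x) + 1.0), self.tau_diff1 * np.asarray(tau)

    def to_similarity_field(self, c1):
        return np.asarray(c1) / self.C0 - self.U

    def from_similarity_field(self, u):
        return (np.asarray(u) + self.U) * self.C0


def map_nondimensional(s, t, c1, s_hat, *, U: float, s_hat0: float,
                       tau_diff1: float, C0: float):
    """Map dimensional (s, t, c1, ŝ) to similarity (x, τ, u, X)."""
    sol = StefanSolution.from_driving(U, s_hat0, tau_diff1, C0)
    x, tau = sol.to_similarity_coords(s, t)
    return x, tau, sol.to_similarity_field(c1), np.asarray(s_hat) / s_hat0 - 1.0
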