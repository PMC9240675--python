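"""Chemical potentials, separation-dependent rate laws and osmotic tension.

Dilute variant: μi = μi⁰ + kBT·ln(ci/c0), with a bond-stretching term
kBT·(h/xγ)² added to μ1.  Crowded variant (Flory–Huggins lattice with
saturation concentration cmax): the vacancy fraction
v = (cmax − c1 − c2)/cmax enters the bond potential as −2kBT·ln v.
By default μ2 stays ideal, so the reaction affinity μ1 − 2μ2 grows by
−2kBT·ln v under crowding and the matching Boltzmann factor v⁻²
multiplies the off-rate (:func:`crowding_unbinding_factor`) — a crowded
patch unbinds faster, which is what weakens crowded adhesion.  The
``mu2_vacancy`` switch instead gives μ2 a single-site vacancy term,
cancelling the crowding contribution to the affinity (bonds then keep
plain mass-action kinetics and crowding acts through transport and the
edge force balance only).

Rates: kon(h) = k̄on·exp[−(h/xγ)²] (partner proximity under thermal
fluctuation) and the Bell slip-bond law koff(h) = k̄off·exp(h/xβ) with
the signed exponent — compression (h < 0) slows unbinding.  Ideal bonds
(fβ = ∞) have koff ≡ k̄off.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .parameters import ParameterSet

#: sentinel for the chemical potential of an absent species (c = 0)
MU_EMPTY = -math.inf


class CrowdingError(ValueError):
    """Concentrations at or above the crowding saturation cmax."""


def _log_vacancy(c1, c2, params: ParameterSet):
    v = (params.cmax_i - np.asarray(c1) - np.asarray(c2)) / params.cmax_i
    if np.any(v <= 0.0):
        raise CrowdingError("c1 + c2 must stay strictly below cmax")
    return np.log(v)


def chemical_potentials(c1, c2, h, params: ParameterSet):
    """(μ1, μ2) in internal energy units [pN·μm]; scalars or arrays.

    ``c1``/``c2`` are line densities [molecules/μm], ``h`` [μm].
    Zero concentration returns the −inf sentinel, never fed to
    arithmetic downstream.
    """
    kBT = params.kBT_i
    c0 = params.c0_i
    c1 = np.asarray(c1, dtype=float)
    c2 = np.asarray(c2, dtype=float)
    if np.any(c1 < 0) or np.any(c2 < 0):
        raise ValueError("concentrations must be non-negative")
    mu2_0 = 0.5 * kBT * math.log(params.Kbar) if params.Kbar > 0 else MU_EMPTY
    stretch = kBT * (np.asarray(h, dtype=float) / params.x_gamma_i) ** 2
    with np.errstate(divide="ignore"):
        mu1 = np.where(c1 > 0, kBT * np.log(np.where(c1 > 0, c1, 1.0) / c0), MU_EMPTY)
        mu2 = np.where(c2 > 0, kBT * np.log(np.where(c2 > 0, c2, 1.0) / c0), MU_EMPTY)
    mu1 = mu1 + stretch
    mu2 = mu2 + mu2_0
    if params.crowding:
        logv = _log_vacancy(c1, c2, params)
        mu1 = mu1 - 2.0 * kBT * logv
        if params.mu2_vacancy:
            mu2 = mu2 - kBT * logv
    if mu1.ndim == 0:
        return float(mu1), float(mu2)
    return mu1, mu2


@dataclass(frozen=True)
class ThermoState:
    """Local thermodynamic state: concentrations, separation and the
    chemical potentials evaluated from them.

    Potentials are stored in internal energy units [pN·μm];
    ``mu1_over_mu20``/``mu2_over_mu20`` give the μ2⁰-normalized values
    used for reporting.
    """

    c1: float
    c2: float
    h: float
    mu1: float
    mu2: float
    mu2_0: float

    @classmethod
    def evaluate(cls, c1, c2, h, params: ParameterSet) -> "ThermoState":
        mu1, mu2 = chemical_potentials(c1, c2, h, params)
        mu2_0 = (0.5 * params.kBT_i * math.log(params.Kbar)
                 if params.Kbar > 0 else MU_EMPTY)
        return cls(c1=float(c1), c2=float(c2), h=float(h),
                   mu1=float(mu1), mu2=float(mu2), mu2_0=mu2_0)

    @property
    def mu1_over_mu20(self) -> float:
        return self.mu1 / self.mu2_0

    @property
    def mu2_over_mu20(self) -> float:
        return self.mu2 / self.mu2_0


def rate_functions(h, params: ParameterSet):
    """(kon, koff) at separation h: kon in μm/(molecule·s), koff in 1/s."""
    h = np.asarray(h, dtype=float)
    kon = params.kon_bar_i * np.exp(-((h / params.x_gamma_i) ** 2))
    if math.isinf(params.f_beta):
        koff = np.broadcast_to(params.koff_bar, h.shape).copy() if h.ndim else params.koff_bar
    else:
        koff = params.koff_bar * np.exp(h / params.x_beta_i)
    if h.ndim == 0:
        return float(kon), float(koff)
    return kon, np.asarray(koff, dtype=float)


def crowding_unbinding_factor(c1, c2, params: ParameterSet,
                              v_min: float = 0.01):
    """Boltzmann factor multiplying koff in crowding mode.

    The crowded part of the reaction affinity, μ1 − 2μ2 =
    (dilute affinity) − (2 − 2·𝟙[μ2 vacancy])·kBT·ln v with
    v = (cmax − c1 − c2)/cmax, is assigned to the unbinding rate (Bell
    convention: the escape rate carries the excess free energy of the
    bound state).  Returns v⁻² by default, 1 when μ2 carries the
    single-site vacancy term (full cancellation) or in dilute mode.
    ``v_min`` clips the vacancy to keep the factor finite while a step
    iterates through near-saturated states.
    """
    if not params.crowding or params.mu2_vacancy:
        return np.ones_like(np.asarray(c1, dtype=float)) \
            if np.ndim(c1) else 1.0
    v = (params.cmax_i - np.asarray(c1, float)
         - np.asarray(c2, float)) / params.cmax_i
    out = np.maximum(v, v_min) ** -2
    return float(out) if out.ndim == 0 else out


def reaction_rate(c1, c2, h, params: ParameterSet):
    """Net bond formation rate kon(h)·c2² − koff(h)·fcrowd·c1
    [molec/(μm·s)]; fcrowd is the crowding unbinding factor (1 in the
    dilute model)."""
    kon, koff = rate_functions(h, params)
    fac = crowding_unbinding_factor(c1, c2, params)
    return kon * np.asarray(c2) ** 2 - koff * fac * np.asarray(c1)


def osmotic_tension(c1, params: ParameterSet):
    """In-plane osmotic tension Π of the bond gas [pN per unit depth].

    Dilute: Π = kBT·c1 (van't Hoff).  Crowded:
    Π = −kBT·(2·cmax·ln[(cmax−c1)/cmax] + c1), strictly increasing and
    divergent as c1 → cmax.
    """
    kBT = params.kBT_i
    c1 = np.asarray(c1, dtype=float)
    if np.any(c1 < 0):
        raise ValueError("c1 must be non-negative")
    if not params.crowding:
        out = kBT * c1
    else:
        cmax = params.cmax_i
        if np.any(c1 >= cmax):
            raise CrowdingError("c1 must stay strictly below cmax")
        out = -kBT * (2.0 * cmax * np.log((cmax - c1) / cmax) + c1)
    return float(out) if out.ndim == 0 else out
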