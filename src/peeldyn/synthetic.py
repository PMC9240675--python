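"""Synthetic fixtures: manufactured trajectories and failure-time data.

Used to calibrate and validate the estimators in
:mod:`peeldyn.experiments` independently of the PDE solver.
"""

from __future__ import annotations

import numpy as np


def linear_front_trajectory(s_hat0: float, speed: float, t_end: float,
                            n: int = 200):
    """ŝ(t) = ŝ0 − |speed|·t: an exact travelling front (speed in μm/s)."""
    t = np.linspace(0.0, t_end, n)
    return t, s_hat0 - abs(speed) * t


def transient_front_trajectory(s_hat0: float, speed: float, t_end: float,
                               tau_transient: float, amplitude: float,
                               n: int = 400):
    """Linear tail of slope −|speed| preceded by an exponential transient."""
    t = np.linspace(0.0, t_end, n)
    return t, (s_hat0 - abs(speed) * t
               - amplitude * np.expm1(-t / tau_transient) * (-1.0))


def power_law_failure_times(forces, A: float, a: float, F_c: float,
                            noise: float = 0.0, rng=None):
    """t_fail = A·(F − Fc)^a, optionally with multiplicative lognormal
    noise of the given relative σ."""
    forces = np.asarray(forces, float)
    if np.any(forces <= F_c):
        raise ValueError("all forces must exceed F_c")
    t = A * (forces - F_c) ** a
    if noise > 0.0:
        rng = np.random.default_rng(rng)
        t = t * rng.lognormal(mean=0.0, sigma=noise, size=t.shape)
    return t


def manufactured_linear_c1(C0: float, slope: float, s_hat: float, n: int = 101):
    """c1(s) = C0·(1 + slope·s/ŝ): linear bond profile for flux checks."""
    s = np.linspace(0.0, s_hat, n)
    return s, C0 * (1.0 + slope * s / s_hat)
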