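"""Shared fixtures.

Expensive simulations (the constant-θ Stefan runs, the relaxed compliant
state) are session-scoped so several tests can interrogate the same
trajectory.
"""

import math

import numpy as np
import pytest

from peeldyn import (ParameterSet, PeelingSimulator, SolverOptions,
                     prepare_equilibrium)
from peeldyn.parameters import derive_scales


@pytest.fixture(scope="session")
def params_default():
    return ParameterSet()


@pytest.fixture(scope="session")
def eq_default(params_default):
    return prepare_equilibrium(params_default)


@pytest.fixture(scope="session")
def scales_default(params_default):
    return derive_scales(params_default)


def diffusion_params(**kw):
    base = dict(D1=0.25, D2=0.5, reactions_on=False, koff_bar=0.0,
                compliant=False)
    base.update(kw)
    return ParameterSet(**base)


@pytest.fixture(scope="session")
def stefan_runs():
    """Constant-θ, reactions-off, non-compliant runs at three drivings.

    Returns {U: (trajectory, simulator)} integrated to τ = 0.05.
    """
    p = diffusion_params()
    eq = prepare_equilibrium(p)
    sc = derive_scales(p)
    t_end = 0.05 * sc.tau_diff1
    out = {}
    for U in (1.5, 2.0, 3.0):
        theta = math.acos(1.0 - U * (1.0 - math.cos(eq.theta0)))
        sim = PeelingSimulator(p, SolverOptions(
            constant_theta=theta, snapshot_every=t_end / 8.0,
            check_every=4))
        out[U] = (sim.run(t_end), sim)
    return out


@pytest.fixture(scope="session")
def relaxed_compliant():
    """Compliant diffusion-regime state relaxed at F = 0 (coarse grid).

    Returns (params, simulator, relaxed_state).
    """
    p = diffusion_params(compliant=True)
    sc = derive_scales(p)
    sim = PeelingSimulator(p, SolverOptions(
        d_min=sc.l2 * 1e6 / 6.0, check_every=8, rtol=3e-5,
        relax_tol=1e-4, relax_max_time=20.0 * sc.tau_diff1))
    state = sim.relax(sim.initial_state())
    return p, sim, state
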