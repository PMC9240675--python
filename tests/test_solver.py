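"""Moving-boundary reaction–diffusion solver: interface conditions,
conservation, oracle equivalence and the quasi-static coupling."""

import math
from dataclasses import replace

import numpy as np
import pytest

from peeldyn import (ParameterSet, PeelingSimulator, SolverOptions,
                     interface_concentration, interface_velocity,
                     advance_step, prepare_equilibrium, lambda_of_U)
from peeldyn.parameters import derive_scales
from peeldyn.solver import SolverError
from peeldyn.equilibrium import VesicleShape

from conftest import diffusion_params


def max_drift(series):
    series = np.asarray(series)
    return float(np.max(np.abs(series - series[0]))) / abs(series[0])


class TestInterfaceConcentration:
    def test_prepared_state_consistency(self, params_default, eq_default):
        p = params_default
        c_if = interface_concentration(eq_default.theta0, p,
                                       gamma=eq_default.gamma_eq_i)
        assert c_if / p.c0_i == pytest.approx(eq_default.c1_eq, rel=1e-12)

    def test_dilute_linearity_in_driving(self, params_default, eq_default):
        p, eq = params_default, eq_default
        theta2 = math.acos(1 - 2 * (1 - math.cos(eq.theta0)))  # U = 2
        c2x = interface_concentration(theta2, p, gamma=eq.gamma_eq_i)
        c1x = interface_concentration(eq.theta0, p, gamma=eq.gamma_eq_i)
        assert c2x == pytest.approx(2 * c1x, rel=1e-12)

    def test_crowded_root_against_bisection(self):
        """Crowded edge value for Π target = 3·kBT·c0, cmax = 5·c0."""
        p = ParameterSet(crowding=True, cmax=5 * 2.5e3)
        # pick γ, θ so that 2γ(1−cosθ) = 3·kBT·c0
        theta = 0.5
        gamma = 3.0 * p.kBT_i * p.c0_i / (2 * (1 - math.cos(theta)))
        c_if = interface_concentration(theta, p, gamma=gamma)
        # frozen from an independent bisection on the printed Π(c1)
        assert c_if / p.c0_i == pytest.approx(1.95309, abs=2e-4)


class TestInterfaceVelocity:
    def test_uniform_field_is_stationary(self):
        p = diffusion_params()
        sim = PeelingSimulator(p)
        st = sim.initial_state()
        assert interface_velocity(st, p) == pytest.approx(0.0, abs=1e-12)

    def test_manufactured_linear_profile(self):
        """c1 = C0·(1 + 0.1·s/ŝ), h ≡ 0 → v̂ = −0.1·D1/(1.1·ŝ)."""
        p = diffusion_params()
        sim = PeelingSimulator(p)
        st = sim.initial_state()
        C0 = st.c1[0]
        st.c1[:] = C0 * (1.0 + 0.1 * st.xi)
        v = interface_velocity(st, p)
        assert v == pytest.approx(-0.1 * p.D1 / (1.1 * st.s_hat), rel=1e-9)

    def test_empty_interface_is_an_error(self):
        p = diffusion_params()
        sim = PeelingSimulator(p)
        st = sim.initial_state()
        st.c1[:] = 0.0
        with pytest.raises(SolverError):
            interface_velocity(st, p)


class TestStationarity:
    def test_equilibrium_is_a_fixed_point_without_reactions(self):
        p = diffusion_params(F_over_gamma=0.0)
        sc = derive_scales(p)
        sim = PeelingSimulator(p)
        traj = sim.run(10.0 * sc.tau_diff1)
        assert max_drift(traj.s_hat) < 1e-6
        assert max_drift(traj.N1) < 1e-9

    def test_equilibrium_is_a_fixed_point_with_reactions(self):
        p = ParameterSet(koff_bar=10.0, F_over_gamma=0.0)
        sim = PeelingSimulator(p, SolverOptions(check_every=8))
        traj = sim.run(2.0)          # 20 reaction times
        assert max_drift(traj.s_hat) < 1e-6
        assert max_drift(traj.N1) < 1e-5


class TestStefanOracle:
    def test_interface_and_profiles_match_similarity(self, stefan_runs):
        from peeldyn.experiments import collapse_deviation
        p = diffusion_params()
        sc = derive_scales(p)
        eq = prepare_equilibrium(p)
        for U, (traj, sim) in stefan_runs.items():
            lam = lambda_of_U(U)
            tau = traj.t / sc.tau_diff1
            exact = p.s_hat0 * (1 + 2 * lam * np.sqrt(tau))
            rel = np.max(np.abs(traj.s_hat - exact) / exact)
            assert rel < 0.02, f"U={U}: interface error {rel:.3%}"
            dev = collapse_deviation(traj, U, p.s_hat0, sc.tau_diff1,
                                     eq.c1_eq * p.c0_i)
            assert dev < 0.03, f"U={U}: collapse deviation {dev:.3%}"

    def test_fitted_lambda_increases_with_driving(self, stefan_runs):
        from peeldyn.experiments import _fit_lambda
        p = diffusion_params()
        sc = derive_scales(p)
        lams = [abs(_fit_lambda(stefan_runs[U][0], p.s_hat0, sc.tau_diff1))
                for U in sorted(stefan_runs)]
        assert lams[0] < lams[1] < lams[2]

    def test_refinement_convergence(self):
        """Interface error decreases under mesh/step refinement."""
        p = diffusion_params()
        sc = derive_scales(p)
        eq = prepare_equilibrium(p)
        U = 2.0
        theta = math.acos(1 - U * (1 - math.cos(eq.theta0)))
        lam = lambda_of_U(U)
        errs = []
        for d_min, rtol in ((8e-3, 3e-4), (2e-3, 3e-5)):
            sim = PeelingSimulator(p, SolverOptions(
                constant_theta=theta, d_min=d_min, rtol=rtol,
                check_every=4))
            traj = sim.run(0.01 * sc.tau_diff1)
            tau = traj.t / sc.tau_diff1
            exact = p.s_hat0 * (1 + 2 * lam * np.sqrt(tau))
            errs.append(np.max(np.abs(traj.s_hat - exact) / exact))
        assert errs[1] < errs[0]


class TestConservation:
    def test_bond_number_exact_without_reactions(self, stefan_runs):
        for U, (traj, _) in stefan_runs.items():
            assert max_drift(traj.N1) < 1e-12
            assert max_drift(traj.Ntot) < 1e-12

    def test_total_binders_with_reactions(self):
        p = ParameterSet(koff_bar=10.0, F_over_gamma=0.3)
        sim = PeelingSimulator(p, SolverOptions(check_every=8))
        traj = sim.run(1.0)
        assert max_drift(traj.Ntot) < 1e-6
        # bonds ARE consumed by reactions here
        assert traj.N1[-1] != traj.N1[0]

    def test_total_binders_in_crowding_mode(self):
        p = ParameterSet(koff_bar=10.0, F_over_gamma=0.3, crowding=True,
                         cmax=5 * 2.5e3)
        sim = PeelingSimulator(p, SolverOptions(check_every=8,
                                                reaction_dt_factor=1.0))
        traj = sim.run(0.3)
        assert max_drift(traj.Ntot) < 1e-6


class TestQuasiStaticCoupling:
    def test_diffusion_regime_reaches_young_dupre_steady_state(self):
        """F/γ = 0.2 shrinks the patch to a new uniform equilibrium
        satisfying the edge force balance."""
        p = diffusion_params(F_over_gamma=0.2)
        sc = derive_scales(p)
        sim = PeelingSimulator(p, SolverOptions(check_every=4))
        traj = sim.run(8.0 * sc.tau_diff1)
        st = traj.final_state
        assert traj.s_hat[-1] < p.s_hat0
        assert np.max(st.c1) / np.min(st.c1) - 1 < 1e-6   # uniform
        resid = (p.kBT_i * st.c1[-1]
                 - 2 * st.gamma * (1 - math.cos(traj.theta[-1])))
        assert abs(resid) / (p.kBT_i * st.c1[-1]) < 1e-6
        assert max_drift(traj.Ntot) < 1e-9

    def test_force_step_schedule_is_applied(self):
        p = diffusion_params()
        sc = derive_scales(p)
        sim = PeelingSimulator(p, SolverOptions(check_every=4))
        t_half = 0.005 * sc.tau_diff1
        traj = sim.run(2 * t_half, schedule=[(0.0, 0.0), (t_half, 0.3)])
        early = traj.theta[traj.t < 0.9 * t_half]
        late = traj.theta[traj.t > 1.1 * t_half]
        assert np.allclose(early, early[0], atol=1e-9)
        assert late[-1] > early[0] + 0.05

    def test_failure_threshold_bookkeeping(self):
        p = diffusion_params(F_over_gamma=0.4)
        sc = derive_scales(p)
        sim = PeelingSimulator(p, SolverOptions(
            check_every=4, s_min=0.95 * p.s_hat0))
        traj = sim.run(5 * sc.tau_diff1)
        assert math.isfinite(traj.t_fail)
        assert traj.s_hat[-1] < 0.96 * p.s_hat0


class TestCompliantPreparation:
    def test_relaxed_state_shrinks_and_depletes_edge(self, relaxed_compliant):
        """For compliant bonds the prepared non-compliant state is not an
        equilibrium: relaxation shrinks the patch and leaves a bond-
        depleted boundary layer near the edge."""
        p, sim, state = relaxed_compliant
        assert state.s_hat < 0.97 * p.s_hat0
        interior = np.median(state.c1[: sim.n1 // 2])
        # concentrated interior relative to the prepared value
        assert interior > 1.05 * prepare_equilibrium(p).c1_eq * p.c0_i

    def test_per_bond_force_scale_is_order_f_gamma(self, relaxed_compliant):
        from peeldyn import per_bond_force_scale
        p, sim, state = relaxed_compliant
        mech = sim._mech_inputs(state)
        f_scale = per_bond_force_scale(mech["prof"], p)
        f_gamma = math.sqrt(p.k_i * p.kBT_i)
        assert 0.1 * f_gamma < f_scale < 10.0 * f_gamma


class TestAdvanceStepAPI:
    def test_single_step_advances_time_and_conserves(self):
        p = diffusion_params(F_over_gamma=0.2)
        sim = PeelingSimulator(p)
        st = sim.initial_state()
        new = advance_step(st, 1e-4, p, simulator=sim)
        assert new.t == pytest.approx(1e-4)
        assert new.binder_number() == pytest.approx(st.binder_number(),
                                                    rel=1e-12)


class TestTrajectoryIO:
    def test_csv_and_hdf5_round_trip(self, tmp_path, stefan_runs):
        import pandas as pd
        import h5py
        traj, _ = stefan_runs[2.0]
        csv = tmp_path / "scalars.csv"
        traj.to_csv(str(csv))
        df = pd.read_csv(csv)
        assert np.allclose(df["s_hat"].values, traj.s_hat)
        h5 = tmp_path / "traj.h5"
        traj.to_hdf5(str(h5))
        with h5py.File(h5) as f:
            assert np.allclose(f["scalars/s_hat"][...], traj.s_hat)
            assert len(f["snapshots"]) == len(traj.snapshots)

    def test_kymograph_raster(self, stefan_runs):
        traj, _ = stefan_runs[2.0]
        ts, ss, vals = traj.kymograph("c1")
        assert len(ts) == len(ss) == len(vals) == len(traj.snapshots)
        assert all(np.all(np.diff(s) > 0) for s in ss)
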