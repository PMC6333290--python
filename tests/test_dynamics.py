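"""Rigid-body time stepping: background flows, Heun convergence, halting."""

import math

import numpy as np
import pytest

from shearswim.bem import FlowModel, solve_mobility
from shearswim.dynamics import SwimmerState, background_velocity, simulate, step
from shearswim.geometry import SwimmerConfig, build_spheroid_mesh
from shearswim.phase import jeffery_orbit, jeffery_period


class TestBackgroundFlow:
    def test_bulk_shear_vanishes_at_origin(self):
        flow = FlowModel(gamma_d=2.0)
        assert np.allclose(background_velocity(flow, np.zeros(3)), 0.0)
        assert np.allclose(background_velocity(flow, [0.0, 3.0, 0.0]), [6.0, 0.0, 0.0])

    def test_wall_shear_no_slip_on_plane(self):
        flow = FlowModel(gamma_d=1.5, geometry="wall_shear", wall_present=True)
        assert np.allclose(background_velocity(flow, [0.0, 5.0, -2.0]), 0.0)
        assert np.allclose(background_velocity(flow, [2.0, 0.0, 0.0]), [0.0, -3.0, 0.0])

    def test_linearity_in_shear_rate(self):
        x = np.array([1.0, 2.0, 3.0])
        u1 = background_velocity(FlowModel(gamma_d=1.0), x)
        u2 = background_velocity(FlowModel(gamma_d=2.0), x)
        assert np.allclose(u2, 2 * u1)

    def test_wall_shear_requires_wall(self):
        with pytest.raises(ValueError):
            FlowModel(geometry="wall_shear", wall_present=False)


class TestStateAngles:
    @pytest.mark.parametrize("theta", [0.0, 0.8, math.pi, 4.9])
    def test_planar_round_trip(self, theta):
        st = SwimmerState.from_planar(theta)
        assert st.theta == pytest.approx(theta % (2 * math.pi), abs=1e-12)

    def test_wall_coordinates(self):
        st = SwimmerState.from_wall_coordinates(1.0, 7.5)
        assert st.wall_separation == 7.5
        assert st.theta == pytest.approx(1.0)


@pytest.fixture(scope="module")
def small_spheroid():
    return build_spheroid_mesh(2.0, 1.0, n_az=10, n_rings=12)


class TestStepping:
    def test_passive_body_in_quiescent_fluid_is_stationary(self, small_spheroid):
        sol = solve_mobility(small_spheroid, SwimmerState(), FlowModel(gamma_d=0.0))
        assert np.abs(sol.U).max() < 1e-10
        assert np.abs(sol.Omega).max() < 1e-10

    def test_galilean_consistency(self, small_spheroid):
        st = SwimmerState.from_planar(0.6)
        base = solve_mobility(small_spheroid, st, FlowModel(gamma_d=1.0))
        shifted = solve_mobility(small_spheroid, st, FlowModel(gamma_d=1.0, uniform=(0.7, -0.2, 0.1)))
        assert np.allclose(shifted.U - base.U, [0.7, -0.2, 0.1], atol=1e-8)
        assert np.allclose(shifted.Omega, base.Omega, atol=1e-8)

    def test_heun_second_order_on_jeffery_orbit(self, small_spheroid):
        """dt-halving on a passive spheroid rotating in shear against the
        closed-form Jeffery orbit (global Richardson estimate)."""
        gamma, r = 2.0, 2.0
        cfg = SwimmerConfig(beat_amplitude=0.0)  # beat phase irrelevant
        flow = FlowModel(gamma_d=gamma)
        duration = 0.8
        errs = []
        for dt in (0.2, 0.1, 0.05):
            state = SwimmerState.from_planar(0.3)
            n = int(round(duration / dt))
            for _ in range(n):
                sol1 = solve_mobility(small_spheroid, state, flow)
                from shearswim.dynamics import _advance

                pred = _advance(state, sol1.U, sol1.Omega, dt)
                sol2 = solve_mobility(small_spheroid, pred, flow)
                state = _advance(state, 0.5 * (sol1.U + sol2.U), 0.5 * (sol1.Omega + sol2.Omega), dt)
            exact = float(jeffery_orbit(np.array([duration]), gamma, r, 0.3)[0])
            # mesh discretization biases the rate slightly; compare against
            # the finest-step run for the time-integration error alone
            errs.append(state.theta)
        e1 = abs(errs[0] - errs[2])
        e2 = abs(errs[1] - errs[2])
        assert e1 / e2 == pytest.approx(5.0, rel=0.5)  # (4x - x)/(x) with halving ≈ 5 for order 2
        # and the converged angle is close to Jeffery's closed form
        assert errs[2] == pytest.approx(float(jeffery_orbit(np.array([duration]), gamma, r, 0.3)[0]), abs=0.05)

    def test_quaternion_norm_preserved(self, small_spheroid):
        cfg = SwimmerConfig(beat_amplitude=0.0)
        traj = simulate(SwimmerState.from_planar(0.1), 0.5, cfg, FlowModel(gamma_d=2.0), dt=0.05, refinement=0)
        norms = np.linalg.norm(traj.quaternions, axis=1)
        assert np.abs(norms - 1.0).max() < 1e-10


class TestSimulate:
    def test_passive_spheroid_tracks_jeffery_orbit(self, small_spheroid):
        """Simulated θ(t) vs the analytic Jeffery orbit over a good fraction
        of a period (RMS < 1% of the swept angle)."""
        gamma, r = 2.0, 2.0
        cfg = SwimmerConfig(beat_amplitude=0.0)
        T = jeffery_period(gamma, r)  # 7.85 s
        duration = 0.45 * T
        dt = 0.04
        state = SwimmerState.from_planar(0.0)
        # bypass mesh rebuild per step: use simulate on the real config at
        # coarse refinement is the promastigote; here step the spheroid manually
        from shearswim.dynamics import _advance

        flow = FlowModel(gamma_d=gamma)
        ts = [0.0]
        thetas = [state.theta]
        n = int(round(duration / dt))
        for _ in range(n):
            sol1 = solve_mobility(small_spheroid, state, flow)
            pred = _advance(state, sol1.U, sol1.Omega, dt)
            sol2 = solve_mobility(small_spheroid, pred, flow)
            state = _advance(state, 0.5 * (sol1.U + sol2.U), 0.5 * (sol1.Omega + sol2.Omega), dt)
            ts.append(ts[-1] + dt)
            thetas.append(thetas[-1] + ((state.theta - thetas[-1] + math.pi) % (2 * math.pi)) - math.pi)
        exact = jeffery_orbit(np.array(ts), gamma, r, 0.0)
        rms = np.sqrt(np.mean((np.array(thetas) - exact) ** 2))
        assert rms < 0.01 * (exact[-1] - exact[0])

    def test_planar_beat_stays_planar(self):
        """One beat of the promastigote: out-of-plane drift is a small
        fraction of in-plane motion (the structured triangulation is only
        approximately mirror-symmetric)."""
        cfg = SwimmerConfig()
        traj = simulate(SwimmerState(), cfg.beat_period, cfg, FlowModel(), dt=cfg.beat_period / 30, refinement=0)
        inplane = np.linalg.norm(traj.positions[-1][:2] - traj.positions[0][:2])
        outplane = abs(traj.positions[-1][2] - traj.positions[0][2])
        assert outplane < 0.02 * inplane

    def test_collision_bound_configuration_halts_on_passive_wall(self):
        """A configuration well below the separatrix collides with the wall
        and the simulation halts at the 2 nm clearance threshold."""
        cfg = SwimmerConfig()
        flow = FlowModel(gamma_d=1.0, geometry="wall_shear", wall_present=True)
        state = SwimmerState.from_wall_coordinates(4.5, 3.2)
        traj = simulate(state, 0.4, cfg, flow, dt=cfg.beat_period / 30, refinement=0)
        assert traj.halt_reason == "wall_collision"
        # contact either at the monitored threshold or within the final step
        assert traj.clearances.min() < 0.2
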