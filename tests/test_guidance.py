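"""Ensembles, shear-schedule guidance and wall behavior control."""

import math

import numpy as np
import pytest
from scipy.stats import kstest

import shearswim as ss
from shearswim import guidance as gd
from shearswim import phase as ph
from shearswim.dynamics import SwimmerState


@pytest.fixture(scope="module")
def fit549():
    return ph.JefferyFit(r=5.49, residual=0.0, gamma_grid=np.array([1.0]), periods=np.array([ph.jeffery_period(1.0, 5.49)]))


class TestSchedule:
    def test_validation(self):
        with pytest.raises(ValueError):
            gd.ShearSchedule((0.0, 0.0), (1.0, -1.0))
        with pytest.raises(ValueError):
            gd.ShearSchedule((), ())
        s = gd.ShearSchedule((0.0, 2.0), (1.0, -1.0))
        assert s.rate(1.9) == 1.0
        assert s.rate(2.0) == -1.0
        assert s.flipped().rate(0.5) == -1.0


class TestSampling:
    def test_uniform_sampler_distribution(self):
        th = gd.sample_orientations(10_000, "uniform", seed=1)
        stat = kstest(th / (2 * math.pi), "uniform").statistic
        assert stat < 0.02

    def test_jeffery_sphere_is_uniform(self):
        th = gd.sample_orientations(10_000, "jeffery_weighted", fit=1.0, seed=2)
        stat = kstest(th / (2 * math.pi), "uniform").statistic
        assert stat < 0.02

    def test_jeffery_weight_peaks_at_flow_alignment(self, fit549):
        """Residence-time density maxima at θ ∈ {0, π} where θ̇ is minimal."""
        th = gd.sample_orientations(20_000, "jeffery_weighted", fit=fit549, seed=3)
        hist, edges = np.histogram(th, bins=36, range=(0, 2 * math.pi))
        centers = 0.5 * (edges[1:] + edges[:-1])
        aligned = hist[(np.minimum(centers, 2 * math.pi - centers) < 0.35) | (np.abs(centers - math.pi) < 0.35)]
        broadside = hist[(np.abs(centers - math.pi / 2) < 0.35) | (np.abs(centers - 3 * math.pi / 2) < 0.35)]
        assert aligned.mean() > 5 * broadside.mean()

    def test_reproducible_under_seed(self):
        a = gd.sample_orientations(100, "uniform", seed=7)
        b = gd.sample_orientations(100, "uniform", seed=7)
        assert np.array_equal(a, b)


class TestEnsembles:
    def test_aligned_swimmer_goes_straight_without_flow(self, coarse_table):
        res = gd.ensemble_endpoints(1, duration=2.0, gamma_d=0.0, mode="uniform", seed=0, table=coarse_table)
        # overwrite the sampled angle with an aligned swimmer
        dyn = gd.ReducedBulkDynamics(coarse_table)
        states = dyn.integrate(np.array([[0.0, 0.0, 0.0]]), 2.0, gamma=0.0)
        speed = coarse_table.swim_speed()
        assert states[0, 0] == pytest.approx(2.0 * speed, rel=1e-4)
        assert abs(states[0, 1]) < 1e-6 * states[0, 0]
        assert abs(states[0, 2]) < 1e-8

    def test_bitwise_reproducible(self, coarse_table):
        a = gd.ensemble_endpoints(50, duration=1.0, gamma_d=1.0, seed=11, table=coarse_table)
        b = gd.ensemble_endpoints(50, duration=1.0, gamma_d=1.0, seed=11, table=coarse_table)
        assert np.array_equal(a.endpoints, b.endpoints)

    def test_jeffery_weighting_biases_travel_along_flow(self, coarse_table, fit549):
        res = gd.ensemble_endpoints(
            400, duration=2.0, gamma_d=1.0, mode="jeffery_weighted", seed=5, table=coarse_table, fit=fit549
        )
        var_along = res.endpoints[:, 0].var()
        var_across = res.endpoints[:, 1].var()
        assert var_along / var_across > 1.0


class TestPlanning:
    def test_first_reversal_at_half_period(self, fit549):
        T = fit549.period(1.0)
        sched = gd.plan_schedule(0.0, fit549, gamma_mag=1.0, duration=3 * T)
        assert sched.times[1] == pytest.approx(T / 2)
        assert sched.times[2] == pytest.approx(3 * T / 2)
        assert sched.rates[0] == 1.0
        assert sched.rates[1] == -1.0

    def test_reversed_target_flips_sign_pattern(self, fit549):
        fwd = gd.plan_schedule(0.0, fit549, gamma_mag=1.0)
        bwd = gd.plan_schedule(math.pi, fit549, gamma_mag=1.0)
        assert np.allclose(bwd.rates, -np.array(fwd.rates))

    def test_guided_reduced_path_is_periodic_per_lobe(self, coarse_table):
        """Under the alternating schedule the reduced orbit angle retraces:
        θ returns to its start after each full reversal period."""
        pts = [(g, ph.rotation_period(g, None, table=coarse_table)) for g in (1.0,)]
        fit = ph.fit_jeffery_ratio(pts)
        T = pts[0][1]
        sched = gd.plan_schedule(0.0, fit, gamma_mag=1.0, duration=4 * T)
        dyn = gd.ReducedBulkDynamics(coarse_table)
        ts, path = dyn.integrate(np.array([[0.0, 0.0, 0.0]]), 2 * T, gamma=sched, dt=0.005, record=True)
        th = path[:, 0, 2]
        i_T = int(np.argmin(np.abs(ts - T)))
        assert th[i_T] == pytest.approx(0.0, abs=0.05)
        assert abs(th.max() - math.pi) < 0.2  # sweeps one half-orbit per lobe


class TestGuidedSimulation:
    def test_zero_shear_paths_agree(self, promastigote, coarse_table):
        """With no flow both descriptions are straight; the gap reflects the
        frozen-configuration approximation of phase averaging."""
        sched = gd.ShearSchedule((0.0,), (0.0,))
        duration = 5 * promastigote.beat_period
        traj, reduced, metrics = gd.simulate_guided(
            SwimmerState.from_planar(0.0), sched, duration, promastigote,
            table=coarse_table, dt=promastigote.beat_period / 40, refinement=0,
        )
        # both straight
        assert abs(traj.positions[-1][1]) < 0.05 * traj.positions[-1][0]
        assert abs(reduced[-1, 2]) < 1e-6 * reduced[-1, 1]
        assert metrics["normalized_endpoint_gap"] < 0.15

    def test_schedule_sign_flip_mirrors_path(self, coarse_table):
        pts = [(1.0, ph.rotation_period(1.0, None, table=coarse_table))]
        fit = ph.fit_jeffery_ratio(pts)
        sched = gd.plan_schedule(0.0, fit, gamma_mag=1.0)
        dyn = gd.ReducedBulkDynamics(coarse_table)
        T = pts[0][1]
        _, p_fwd = dyn.integrate(np.array([[0.0, 0.0, 0.0]]), T, gamma=sched, dt=0.01, record=True)
        _, p_flip = dyn.integrate(np.array([[0.0, 0.0, 0.0]]), T, gamma=sched.flipped(), dt=0.01, record=True)
        # mirror about the flow axis: x1 even, x2 odd
        assert np.allclose(p_flip[:, 0, 0], p_fwd[:, 0, 0], atol=1e-6 + 0.02 * np.abs(p_fwd[:, 0, 0]).max())
        assert np.allclose(p_flip[:, 0, 1], -p_fwd[:, 0, 1], atol=1e-6 + 0.02 * np.abs(p_fwd[:, 0, 1]).max())


class TestWallBehaviorSwitch:
    @staticmethod
    def _band_probe(wall_field, theta):
        """A configuration between the +γ separatrix and its θ ↦ 2π−θ
        mirror (the band whose label a reversal flips)."""
        ana = ph.compute_separatrix(wall_field, ph.find_saddle(wall_field, 1.0), 1.0)
        h_plus = ana.separatrix_height(theta)
        h_minus = ana.separatrix_height(2 * math.pi - theta)
        assert h_minus < h_plus
        return math.sqrt(h_plus * h_minus)

    def test_configuration_between_separatrices_switches(self, wall_field):
        """A point below the +γ separatrix but above the −γ separatrix (the
        cross-hatched band) changes its long-time label under reversal."""
        th_probe = 1.6
        h0 = self._band_probe(wall_field, th_probe)
        res = gd.wall_behavior_switch(wall_field, th_probe, h0, 1.0, reversal_time=0.2)
        assert res["label_before"] == "collision"
        assert res["label_under_reversed_flow"] == "escape"
        assert res["outcome_with_reversal"] == "escape"
        assert res["switched"]

    def test_far_bulk_configuration_keeps_escape_label(self, wall_field):
        h0 = wall_field.h_grid.max() * 0.9
        res = gd.wall_behavior_switch(wall_field, 1.0, h0, 1.0, reversal_time=0.5)
        assert res["label_before"] == "escape"
        assert res["outcome_with_reversal"] == "escape"
        assert not res["switched"]

    def test_continuous_ramp_matches_instantaneous_reversal(self, wall_field):
        th_probe = 1.6
        h0 = self._band_probe(wall_field, th_probe)
        instant = gd.wall_behavior_switch(wall_field, th_probe, h0, 1.0, reversal_time=0.2)
        ramped = gd.wall_behavior_switch(wall_field, th_probe, h0, 1.0, reversal_time=0.2, ramp_duration=2.0)
        assert instant["outcome_with_reversal"] == "escape"
        assert ramped["outcome_with_reversal"] == instant["outcome_with_reversal"]


class TestRepulsiveWallCycles:
    def test_downstream_quasiperiodic_mode(self, promastigote, wall_field):
        """From a downstream-facing start near the wall: repeated
        approach–escape cycles with net downstream drift."""
        res = gd.repulsive_wall_cycle(
            wall_field, math.pi / 2, 3.0, 1.0, duration=4.0,
            config=promastigote, refinement=0, dt=promastigote.beat_period / 40,
        )
        assert res["cycles"] >= 2
        assert res["net_downstream_displacement"] > 0
        assert res["mode"] == "downstream-facing"

    def test_mode_stable_under_height_perturbation(self, promastigote, wall_field):
        res = gd.repulsive_wall_cycle(
            wall_field, math.pi / 2, 3.3, 1.0, duration=3.0,
            config=promastigote, refinement=0, dt=promastigote.beat_period / 40,
        )
        assert res["cycles"] >= 1
        assert res["mode"] == "downstream-facing"
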