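"""Ensemble trajectories, shear-schedule guidance and boundary-cycle runs.

The phase-averaged reduced dynamics make three kinds of study cheap:

* **Ensembles** — endpoint distributions of swimmers released at the origin
  with unknown initial orientation, sampled either uniformly or with the
  residence-time weight of the fitted Jeffery orbit, p(θ) ∝ 1/θ̇(θ) (the
  fraction of orbit time spent near each angle).
* **Guidance** — because the tumbling period is set by the shear rate and a
  shear reversal mirrors the dynamics, a piecewise-constant shear schedule
  alternating ±γ with its first switch at half the rotation period steers a
  swimmer along the flow axis; the reduced prediction is validated against
  the full beat-resolved boundary-element simulation.
* **Wall behavior** — near a wall, reversing the shear maps the reduced
  field through θ ↦ 2π − θ, so configurations between the two mirrored
  separatrices change their long-time label (collision-bound vs
  escape-bound) under a reversal.  With a repulsive boundary the swimmer
  settles into quasiperiodic approach–reorient–escape cycles, simulated
  here with a hybrid scheme: full boundary-element stepping while any
  surface element is within a few repulsion decay lengths of the wall,
  reduced dynamics otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as dc_replace
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.interpolate import CubicSpline

from .bem import FlowModel
from .dynamics import SwimmerState, Trajectory, simulate, step
from .geometry import SwimmerConfig, build_mesh
from .phase import (
    BulkPhaseTable,
    JefferyFit,
    PhaseField,
    classify_configuration,
    jeffery_theta_dot,
)
from .walls import WallRepulsion

__all__ = [
    "ShearSchedule",
    "EnsembleResult",
    "sample_orientations",
    "ensemble_endpoints",
    "plan_schedule",
    "simulate_guided",
    "wall_behavior_switch",
    "repulsive_wall_cycle",
    "ReducedBulkDynamics",
]


@dataclass(frozen=True)
class ShearSchedule:
    """Piecewise-constant shear rate γ_d(t).

    ``times`` are strictly increasing breakpoints starting at 0; ``rates[i]``
    applies on [times[i], times[i+1]).
    """

    times: tuple[float, ...]
    rates: tuple[float, ...]

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        r = np.asarray(self.rates, dtype=float)
        if len(t) != len(r) or len(t) == 0:
            raise ValueError("times and rates must be equal-length, non-empty")
        if np.any(np.diff(t) <= 0):
            raise ValueError("schedule times must be strictly increasing")
        if not np.all(np.isfinite(r)):
            raise ValueError("schedule rates must be finite")

    def rate(self, t: float) -> float:
        idx = int(np.searchsorted(self.times, t, side="right")) - 1
        return float(self.rates[max(idx, 0)])

    def flipped(self) -> "ShearSchedule":
        return ShearSchedule(self.times, tuple(-r for r in self.rates))

    @property
    def end_time(self) -> float:
        return float(self.times[-1])


@dataclass
class EnsembleResult:
    """Per-swimmer initial angles, planar endpoints and metadata."""

    initial_theta: np.ndarray
    endpoints: np.ndarray  # (n, 2) laboratory (x1, x2)
    elapsed: float
    mode: str
    seed: int


def sample_orientations(
    n: int,
    mode: str,
    fit: JefferyFit | float | None = None,
    seed: int = 0,
    gamma_d: float = 1.0,
) -> np.ndarray:
    """Initial angles on [0, 2π): ``"uniform"`` or ``"jeffery_weighted"``.

    The Jeffery weight is the orbit residence-time density p(θ) ∝ 1/θ̇(θ),
    sampled by inverse CDF on a fine grid; it peaks at the flow-aligned
    angles θ = 0, π where the orbit lingers.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed)
    if mode == "uniform":
        return rng.uniform(0.0, 2.0 * math.pi, size=n)
    if mode != "jeffery_weighted":
        raise ValueError(f"unknown sampling mode {mode!r}")
    r = fit.r if isinstance(fit, JefferyFit) else float(fit if fit is not None else 1.0)
    grid = np.linspace(0.0, 2.0 * math.pi, 4097)
    rate = jeffery_theta_dot(grid, gamma_d, r)
    if np.any(rate <= 0):
        raise ValueError("jeffery_weighted sampling requires theta_dot > 0 everywhere")
    dens = 1.0 / rate
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (dens[1:] + dens[:-1]) * np.diff(grid))])
    cdf /= cdf[-1]
    return np.interp(rng.uniform(size=n), cdf, grid)


class ReducedBulkDynamics:
    """Planar reduced system (x1, x2, θ) from a bulk phase table.

    ẋ = R(θ)·⟨U⟩(θ, γ) + γ x2 x̂1 (background advection),
    θ̇ = −⟨Ω3⟩(θ, γ); the γ-dependence is affine, so time-varying shear
    schedules evaluate at spline cost.  States integrate vectorized with
    fixed-step RK4.
    """

    def __init__(self, table: BulkPhaseTable, n_knots: int = 181):
        th = np.linspace(0.0, 2.0 * math.pi, n_knots)
        u0 = np.empty((n_knots, 2))
        u1 = np.empty((n_knots, 2))
        w0 = np.empty(n_knots)
        w1 = np.empty(n_knots)
        for i, t in enumerate(th):
            Ua, Wa = table.average(t, 0.0)
            Ub, Wb = table.average(t, 1.0)
            u0[i] = Ua[:2]
            u1[i] = Ub[:2] - Ua[:2]
            w0[i] = -Wa[2]
            w1[i] = -(Wb[2] - Wa[2])
        # enforce exact periodicity at the seam
        for arr in (u0, u1):
            arr[-1] = arr[0]
        w0[-1] = w0[0]
        w1[-1] = w1[0]
        self._u0 = CubicSpline(th, u0, bc_type="periodic")
        self._u1 = CubicSpline(th, u1, bc_type="periodic")
        self._w0 = CubicSpline(th, w0, bc_type="periodic")
        self._w1 = CubicSpline(th, w1, bc_type="periodic")

    def rhs(self, states: np.ndarray, gamma_d: float) -> np.ndarray:
        """Time derivative of states (n, 3) = (x1, x2, θ)."""
        th = np.mod(states[:, 2], 2.0 * math.pi)
        u = self._u0(th) + gamma_d * self._u1(th)
        d = np.empty_like(states)
        d[:, 0] = u[:, 0] + gamma_d * states[:, 1]
        d[:, 1] = u[:, 1]
        d[:, 2] = self._w0(th) + gamma_d * self._w1(th)
        return d

    def integrate(
        self,
        states0: np.ndarray,
        duration: float,
        gamma: float | ShearSchedule = 0.0,
        dt: float = 0.01,
        record: bool = False,
    ):
        """Fixed-step RK4; returns final states, or (times, path) if recording."""
        states = np.atleast_2d(np.asarray(states0, dtype=float)).copy()
        n_steps = max(1, int(round(duration / dt)))
        dt = duration / n_steps
        gfun = gamma.rate if isinstance(gamma, ShearSchedule) else (lambda t: gamma)
        path = [states.copy()] if record else None
        times = [0.0] if record else None
        t = 0.0
        for _ in range(n_steps):
            g1 = gfun(t)
            g2 = gfun(t + 0.5 * dt)
            g3 = gfun(t + dt)
            k1 = self.rhs(states, g1)
            k2 = self.rhs(states + 0.5 * dt * k1, g2)
            k3 = self.rhs(states + 0.5 * dt * k2, g2)
            k4 = self.rhs(states + dt * k3, g3)
            states += dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
            t += dt
            if record:
                path.append(states.copy())
                times.append(t)
        if record:
            return np.array(times), np.array(path)
        return states


def ensemble_endpoints(
    n: int,
    duration: float = 2.0,
    gamma_d: float = 1.0,
    mode: str = "uniform",
    seed: int = 0,
    table: Optional[BulkPhaseTable] = None,
    config: SwimmerConfig = SwimmerConfig(),
    fit: JefferyFit | float | None = None,
    n_phases: int = 20,
    refinement: int = 1,
    dt: float = 0.01,
) -> EnsembleResult:
    """Endpoint distribution of swimmers released at the origin.

    Integrates the reduced planar system for ``n`` initial orientations
    sampled by ``mode``; bitwise reproducible under a fixed seed.
    """
    if table is None:
        table = BulkPhaseTable(config, n_phases=n_phases, refinement=refinement)
    if mode == "jeffery_weighted" and fit is None:
        raise ValueError("jeffery_weighted sampling requires a JefferyFit (or aspect ratio)")
    thetas = sample_orientations(n, mode, fit=fit, seed=seed, gamma_d=abs(gamma_d) or 1.0)
    dyn = ReducedBulkDynamics(table)
    states0 = np.zeros((n, 3))
    states0[:, 2] = thetas
    states = dyn.integrate(states0, duration, gamma=gamma_d, dt=dt)
    return EnsembleResult(
        initial_theta=thetas,
        endpoints=states[:, :2].copy(),
        elapsed=duration,
        mode=mode,
        seed=seed,
    )


def plan_schedule(
    target_direction: float | Sequence[float],
    fit: JefferyFit,
    gamma_mag: float = 1.0,
    duration: float | None = None,
) -> ShearSchedule:
    """Shear schedule guiding a tumbling swimmer along the flow axis.

    Alternates ±γ with the first reversal at half the rotation period
    T(γ)/2 and subsequent reversals every T thereafter, which retraces each
    half-orbit and rectifies the phase-averaged displacement along ±x̂1.
    ``target_direction`` is an angle (rad) or 2-vector; its component along
    the flow axis picks the sign pattern.
    """
    if gamma_mag <= 0:
        raise ValueError("gamma_mag must be positive (tumbling regime)")
    if isinstance(target_direction, (int, float)):
        along = math.cos(float(target_direction))
    else:
        v = np.asarray(target_direction, dtype=float)
        along = v[0] / (np.linalg.norm(v) or 1.0)
    sign = 1.0 if along >= 0 else -1.0
    T = fit.period(gamma_mag)
    if duration is None:
        duration = 4.0 * T
    times = [0.0]
    rates = [sign * gamma_mag]
    t = T / 2.0
    s = -sign
    while t < duration:
        times.append(t)
        rates.append(s * gamma_mag)
        s = -s
        t += T
    return ShearSchedule(tuple(times), tuple(rates))


def simulate_guided(
    initial: SwimmerState,
    schedule: ShearSchedule,
    duration: float,
    config: SwimmerConfig = SwimmerConfig(),
    table: Optional[BulkPhaseTable] = None,
    dt: Optional[float] = None,
    refinement: int = 1,
    n_phases: int = 20,
    reduced_dt: float = 0.01,
) -> tuple[Trajectory, np.ndarray, dict]:
    """Full simulation and reduced prediction under a shear schedule.

    Returns the beat-resolved trajectory, the reduced path array
    (t, x1, x2, θ), and discrepancy metrics (endpoint gap normalized by
    reduced path length, and the raw endpoint gap).
    """
    if schedule.end_time > duration:
        pass  # schedule may extend beyond; only rates up to duration are used
    if dt is None:
        dt = config.beat_period / 100.0
    if table is None:
        table = BulkPhaseTable(config, n_phases=n_phases, refinement=refinement)

    # full simulation, stepping the piecewise-constant schedule
    n_steps = max(1, int(round(duration / dt)))
    state = initial
    times = [state.t]
    positions = [state.x0.copy()]
    quats = [state.quaternion.copy()]
    vels = [np.zeros(3)]
    omegas = [np.zeros(3)]
    base = FlowModel(gamma_d=0.0, geometry="bulk_shear")
    for _ in range(n_steps):
        flow = dc_replace(base, gamma_d=schedule.rate(state.t - initial.t))
        state, sol = step(state, dt, config, flow, refinement)
        times.append(state.t)
        positions.append(state.x0.copy())
        quats.append(state.quaternion.copy())
        vels.append(sol.U)
        omegas.append(sol.Omega)
    vels[0] = vels[1]
    omegas[0] = omegas[1]
    traj = Trajectory(
        times=np.array(times),
        positions=np.array(positions),
        quaternions=np.array(quats),
        velocities=np.array(vels),
        angular_velocities=np.array(omegas),
        clearances=np.full(len(times), np.inf),
    )

    # reduced prediction
    rdyn = ReducedBulkDynamics(table)
    s0 = np.array([[initial.x0[0], initial.x0[1], initial.theta]])
    rt, rpath = rdyn.integrate(s0, duration, gamma=schedule, dt=reduced_dt, record=True)
    reduced = np.column_stack([rt, rpath[:, 0, :]])

    seg = np.linalg.norm(np.diff(rpath[:, 0, :2], axis=0), axis=1)
    path_len = float(seg.sum())
    gap = float(np.linalg.norm(traj.positions[-1][:2] - rpath[-1, 0, :2]))
    metrics = {
        "endpoint_gap": gap,
        "reduced_path_length": path_len,
        "normalized_endpoint_gap": gap / path_len if path_len > 0 else math.inf,
    }
    return traj, reduced, metrics


def _wall_reduced_rhs(field: PhaseField, gamma: float | Callable):
    """Reduced wall rhs for (θ, h, x2) with possibly time-dependent γ."""
    ftd0, fhd0 = field.interpolants(0.0)
    ftd1, fhd1 = field.interpolants(1.0)
    u2_0 = field.downstream_rate(0.0)
    u2_1 = field.downstream_rate(1.0)
    gfun = gamma if callable(gamma) else (lambda t: gamma)

    def rhs(t, y):
        th, h = y[0], y[1]
        g = gfun(t)
        td0 = float(ftd0(th, h))
        td1 = float(ftd1(th, h))
        hd0 = float(fhd0(th, h))
        hd1 = float(fhd1(th, h))
        x0 = u2_0(th, h)
        x1 = u2_1(th, h)
        return [td0 + g * (td1 - td0), hd0 + g * (hd1 - hd0), x0 + g * (x1 - x0)]

    return rhs


def wall_behavior_switch(
    field: PhaseField,
    theta0: float,
    h0: float,
    gamma_d: float,
    reversal_time: float,
    ramp_duration: float = 0.0,
    t_max: float = 600.0,
) -> dict:
    """Classify long-time wall behavior before and after a shear reversal.

    The configuration is labelled against the dynamics at +γ and at −γ
    (``"collision"`` / ``"escape"``); the reduced system is then integrated
    with the reversal applied at ``reversal_time`` (instantaneous, or a
    linear ramp of the given duration) and the final label recorded.
    """
    label_before = classify_configuration(field, theta0, h0, gamma_d, t_max=t_max)
    label_mirror = classify_configuration(field, theta0, h0, -gamma_d, t_max=t_max)

    def gfun(t):
        if t < reversal_time:
            return gamma_d
        if ramp_duration > 0 and t < reversal_time + ramp_duration:
            frac = (t - reversal_time) / ramp_duration
            return gamma_d * (1.0 - 2.0 * frac)
        return -gamma_d

    rhs = _wall_reduced_rhs(field, gfun)
    h_lo = field.h_grid.min() * 1.05
    h_hi = field.h_grid.max() * 0.98

    def hit_low(t, y):
        return y[1] - h_lo

    def hit_high(t, y):
        return h_hi - y[1]

    hit_low.terminal = True
    hit_high.terminal = True
    t_switched = reversal_time + ramp_duration
    # stage 1: original flow (plus ramp); reaching the wall or the bulk
    # before the reversal completes decides the outcome outright
    sol = solve_ivp(
        rhs, (0.0, t_switched), [theta0, h0, 0.0], events=(hit_low, hit_high), max_step=1.0, rtol=1e-8, atol=1e-10
    )
    outcome = None
    if sol.t_events[0].size:
        outcome = "collision"
    elif sol.t_events[1].size:
        outcome = "escape"
    if outcome is None:
        # stage 2: fully reversed flow; surviving a complete tumble without
        # collision counts as bulk escape (bounded tumbling orbit)
        y1 = sol.y[:, -1]
        th_rev = float(y1[0])

        def full_tumble(t, y):
            return abs(y[0] - th_rev) - 2.35 * math.pi

        full_tumble.terminal = True
        sol2 = solve_ivp(
            rhs,
            (t_switched, t_max),
            y1,
            events=(hit_low, hit_high, full_tumble),
            max_step=2.0,
            rtol=1e-8,
            atol=1e-10,
        )
        if sol2.t_events[0].size:
            outcome = "collision"
        elif sol2.t_events[1].size or sol2.t_events[2].size:
            outcome = "escape"
        else:
            outcome = "undetermined"
        sol_y = np.concatenate([sol.y, sol2.y], axis=1)
        sol_t = np.concatenate([sol.t, sol2.t])
    else:
        sol_y, sol_t = sol.y, sol.t
    return {
        "label_before": label_before,
        "label_under_reversed_flow": label_mirror,
        "outcome_with_reversal": outcome,
        "switched": label_before != outcome and outcome != "undetermined",
        "path": sol_y.T,
        "times": sol_t,
    }


def _clearance_offset(config: SwimmerConfig, n_phases: int, refinement: int):
    """c(θ): lowest surface point relative to x0-height, over the beat.

    clearance(θ, h) = h + c(θ) with c ≤ 0; spline over θ.
    """
    meshes = [build_mesh(config, p, refinement=refinement) for p in np.arange(n_phases) / n_phases]
    th = np.linspace(0.0, 2.0 * math.pi, 73)
    c = np.empty_like(th)
    for i, t in enumerate(th):
        R = BulkPhaseTable._rotation(t)
        c[i] = min((m.nodes @ R.T)[:, 0].min() for m in meshes)
    c[-1] = c[0]
    return CubicSpline(th, c, bc_type="periodic")


def repulsive_wall_cycle(
    field: PhaseField,
    theta0: float,
    h0: float,
    gamma_d: float,
    duration: float,
    config: SwimmerConfig = SwimmerConfig(),
    repulsion: Optional[WallRepulsion] = None,
    refinement: int = 0,
    dt: Optional[float] = None,
    handoff_in: float = 0.6,
    handoff_out: float = 1.5,
    approach_clearance: Optional[float] = None,
    max_reduced_step: float = 0.5,
) -> dict:
    """Hybrid simulation of boundary swimming against a repulsive wall.

    Far from the wall (minimum surface clearance above ``handoff_in`` μm,
    a few repulsion decay lengths) the phase-averaged reduced dynamics
    advance (θ, h, x2); once the swimmer would come closer, the full
    beat-resolved boundary-element simulation with the Blake kernel and the
    repulsive load takes over until the clearance exceeds ``handoff_out``
    (the hysteresis suppresses handoff chatter from beat-phase clearance
    wiggle).

    A completed approach–escape **cycle** is a full-solver episode whose
    minimum clearance entered the strong-repulsion zone (default two decay
    lengths) before the swimmer retreated past ``handoff_out``.  The mode
    label is ``"tumbling"`` when the unwrapped θ sweeps a full circle during
    the run and ``"downstream-facing"`` otherwise.
    """
    if repulsion is None:
        repulsion = WallRepulsion(beat_period=config.beat_period)
    if approach_clearance is None:
        approach_clearance = 2.0 * repulsion.decay_length
    if dt is None:
        dt = config.beat_period / 50.0
    flow = FlowModel(gamma_d=gamma_d, geometry="wall_shear", wall_present=True, repulsion=repulsion)
    coff = _clearance_offset(config, 8, refinement)
    rhs = _wall_reduced_rhs(field, gamma_d)
    h_hi = field.h_grid.max() * 0.98

    t = 0.0
    theta, h, x2 = float(theta0), float(h0), 0.0
    path = [(t, theta, h, x2, "start")]
    cycles = 0
    th_min = th_max = theta

    def track(th_new):
        nonlocal th_min, th_max
        th_min = min(th_min, th_new)
        th_max = max(th_max, th_new)

    while t < duration:
        clearance = h + float(coff(theta % (2 * math.pi)))
        if clearance > handoff_in:
            # reduced flight until the handoff clearance is reached
            def approach(tt, y):
                return (y[1] + float(coff(y[0] % (2 * math.pi)))) - handoff_in

            approach.terminal = True
            approach.direction = -1.0

            def too_high(tt, y):
                return h_hi - y[1]

            too_high.terminal = True
            sol = solve_ivp(
                rhs,
                (t, duration),
                [theta, h, x2],
                events=(approach, too_high),
                max_step=max_reduced_step,
                rtol=1e-8,
                atol=1e-10,
            )
            track(float(sol.y[0].min()))
            track(float(sol.y[0].max()))
            theta, h, x2 = float(sol.y[0, -1]), float(sol.y[1, -1]), float(sol.y[2, -1])
            t = float(sol.t[-1])
            path.append((t, theta, h, x2, "reduced"))
            if not sol.t_events[0].size:
                break  # duration exhausted (or left the resolved grid upward)
        else:
            # full boundary-element episode with the repulsive load
            state = SwimmerState.from_planar(theta % (2 * math.pi), x0=(h, x2, 0.0), t=t)
            th_unwrapped = theta
            escaped = False
            min_clr = clearance
            n_max = int(round((duration - t) / dt))
            for _ in range(max(n_max, 1)):
                state, sol = step(state, dt, config, flow, refinement)
                t = state.t
                # continuous unwrap of the planar angle
                d = (state.theta - th_unwrapped) % (2 * math.pi)
                th_unwrapped += d if d <= math.pi else d - 2 * math.pi
                track(th_unwrapped)
                mesh = build_mesh(config, state.phase(config), refinement=refinement)
                clr = float((mesh.nodes @ state.rotation_matrix[0]).min() + state.x0[0])
                min_clr = min(min_clr, clr)
                if clr > handoff_out:
                    escaped = True
                    break
                if t >= duration:
                    break
            theta, h, x2 = th_unwrapped, float(state.x0[0]), float(state.x0[1])
            path.append((t, theta, h, x2, "full"))
            if escaped and min_clr < approach_clearance:
                cycles += 1

    downstream = -(x2 - 0.0) * math.copysign(1.0, gamma_d)  # flow is −x̂2 for γ > 0
    theta_excursion = th_max - th_min
    mode = "tumbling" if theta_excursion > 2.0 * math.pi * 0.98 else "downstream-facing"
    return {
        "path": path,
        "cycles": cycles,
        "net_downstream_displacement": downstream,
        "mode": mode,
        "final_state": (theta, h, x2),
        "theta_excursion": theta_excursion,
    }
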