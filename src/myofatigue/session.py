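"""Coupled load-sharing / fatigue simulation of training sessions.

Each time step closes the loop between the redundancy solver and the
fatigue model: (1) the fatigue-modified force ceilings are computed from
the current compartment states, (2) the load-sharing problem is solved for
the required net torque, (3) per-muscle activations are back-computed, and
(4) each muscle's target load ``TL_i = 100 a_i`` (activation from the
previous step, an explicit one-step lag) drives its three-compartment
state to the next instant.

Protocols are ordered segments — MVCs (agonists forced fully active),
static holds, curl sets (torque demand from a kinematics source), and
rests (TL = 0, rest-recovery multiplier active).  Failure during a static
task is the first instant the available maximal flexion moment drops below
the demanded torque.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import fatigue as fat
from .hill import DEFAULT_CURVES, FiberState, HillCurves, fiber_state_rigid_tendon, \
    force_bounds
from .load_sharing import LoadSharingSolution, solution_activations, \
    solve_fatigue_weighted
from .model import MusculoskeletalModel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class JointSample:
    """One time point of elbow kinematics/kinetics."""

    t: float  # s
    phi: float  # elbow angle (deg, 0 = full extension)
    phidot: float  # angular velocity (deg/s)
    q: float  # net flexion torque (N*m)

    def __post_init__(self) -> None:
        if not all(map(math.isfinite, (self.t, self.phi, self.phidot, self.q))):
            raise ValueError("joint sample fields must be finite")


@dataclass
class Segment:
    """One protocol segment."""

    kind: str  # "mvc" | "static_hold" | "curl_set" | "rest"
    duration_s: Optional[float] = None
    reps: Optional[int] = None
    cadence_s: Optional[float] = None  # seconds per curl repetition
    load_kg: Optional[float] = None
    load_pct_mvc: Optional[float] = None
    phi_deg: float = 50.0  # posture for mvc / static_hold
    q_nm: Optional[float] = None  # torque demand for static_hold
    cycle_end: bool = False  # marks the end of one protocol cycle

    def __post_init__(self) -> None:
        if self.kind not in ("mvc", "static_hold", "curl_set", "rest"):
            raise ValueError(f"unknown segment kind {self.kind!r}")
        if self.kind == "curl_set":
            if not (self.reps and self.reps >= 1 and self.cadence_s and self.cadence_s > 0):
                raise ValueError("curl_set needs reps >= 1 and cadence_s > 0")
        elif not (self.duration_s and self.duration_s > 0):
            raise ValueError(f"{self.kind} segment needs duration_s > 0")


@dataclass
class Protocol:
    """An ordered list of segments making up one recorded session."""

    segments: List[Segment]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("protocol has no segments")


@dataclass
class SessionResult:
    """Time series and events from a simulated session."""

    time: pd.DataFrame  # t_s, segment, phi_deg, Q_Nm, available_Nm, torque_residual_Nm
    muscle: pd.DataFrame  # long: t_s, muscle, force_N, activation, Ma, Mr, Mf
    failure_times: List[float] = field(default_factory=list)
    equilibrium_reached: Optional[bool] = None
    cycle_mf: List[np.ndarray] = field(default_factory=list)

    def summary(self) -> Dict:
        return {
            "duration_s": float(self.time["t_s"].iloc[-1]) if len(self.time) else 0.0,
            "failure_times_s": self.failure_times,
            "equilibrium_reached": self.equilibrium_reached,
            "max_torque_residual_Nm": float(self.time["torque_residual_Nm"].max())
            if len(self.time) else 0.0,
        }


def _fiber_states(
    model: MusculoskeletalModel, phi: float, phidot: float, curves: HillCurves
) -> List[FiberState]:
    geo = model.geometry
    return [
        fiber_state_rigid_tendon(
            m, float(geo.lmt(m.name, phi)), geo.vmt(m.name, phi, phidot), curves
        )
        for m in model.muscles
    ]


def _bounds(
    model: MusculoskeletalModel,
    fibers: Sequence[FiberState],
    states: fat.CompartmentState,
    curves: HillCurves,
) -> Tuple[np.ndarray, np.ndarray]:
    n = len(model.muscles)
    lb = np.empty(n)
    ub = np.empty(n)
    mf = np.atleast_1d(states.mf)
    for i, (m, fib) in enumerate(zip(model.muscles, fibers)):
        b = force_bounds(m, fib, curves)
        lb[i] = b.f_min
        ceiling_state = fat.CompartmentState.__new__(fat.CompartmentState)
        ceiling_state.mf = mf[i]
        ub[i] = max(
            fat.fatigued_force_ceiling(m, fib, ceiling_state, curves), b.f_min
        )
    return lb, ub


def run_timestep(
    model: MusculoskeletalModel,
    states: fat.CompartmentState,
    sample: JointSample,
    dt: float,
    criterion: str = "sumsq",
    curves: HillCurves = DEFAULT_CURVES,
    forced_tl: Optional[np.ndarray] = None,
) -> Tuple[LoadSharingSolution, fat.CompartmentState]:
    """One pass of the coupled loop; returns the solution and next states.

    ``forced_tl`` overrides the activation-derived target loads (used for
    MVC segments where agonists are driven at TL = 100).  Infeasible torque
    demands are clamped and carried as ``torque_residual``.
    """
    fibers = _fiber_states(model, sample.phi, sample.phidot, curves)
    lb, ub = _bounds(model, fibers, states, curves)
    arms = np.array(
        [float(model.geometry.moment_arm(m.name, sample.phi)) for m in model.muscles]
    )
    weights = (
        np.array([m.fatigue.F for m in model.muscles])
        if criterion == "fatigue-weighted"
        else None
    )
    solution = solve_fatigue_weighted(arms, sample.q, lb, ub, weights)
    mf = np.atleast_1d(states.mf)
    acts = solution_activations(solution, model, fibers, mf_pct=mf, curves=curves)
    tl = forced_tl if forced_tl is not None else 100.0 * acts
    params = (
        np.array([m.fatigue.F for m in model.muscles]),
        np.array([m.fatigue.R for m in model.muscles]),
        np.array([m.fatigue.r_rest for m in model.muscles]),
    )
    new_states = fat.step(states, tl, params, dt)
    return solution, new_states


def available_max_moment(
    model: MusculoskeletalModel,
    fibers: Sequence[FiberState],
    states: fat.CompartmentState,
    phi: float,
    curves: HillCurves = DEFAULT_CURVES,
) -> float:
    """Maximal flexion moment (N*m): flexors at their fatigued ceiling,
    extensors at their passive minimum."""
    mf = np.atleast_1d(states.mf)
    total = 0.0
    for i, (m, fib) in enumerate(zip(model.muscles, fibers)):
        arm = float(model.geometry.moment_arm(m.name, phi))
        if m.role == "flexor":
            s = fat.CompartmentState.__new__(fat.CompartmentState)
            s.mf = mf[i]
            total += arm * fat.fatigued_force_ceiling(m, fib, s, curves)
        else:
            total += arm * force_bounds(m, fib, curves).f_min
    return total


def available_max_moment_static(
    model: MusculoskeletalModel,
    phi: float,
    curves: HillCurves = DEFAULT_CURVES,
    states: Optional[fat.CompartmentState] = None,
) -> float:
    """Rested (or given-state) maximal flexion moment at a static posture."""
    fibers = _fiber_states(model, phi, 0.0, curves)
    if states is None:
        states = fat.CompartmentState.rested(len(model.muscles))
    return available_max_moment(model, fibers, states, phi, curves)


@dataclass
class FailurePrediction:
    """Outcome of a static endurance simulation."""

    time_s: Optional[float]  # None when censored
    censored: bool
    horizon_s: float


def predict_failure_time(
    model: MusculoskeletalModel,
    q_const: float,
    phi: float,
    dt: float = 0.01,
    horizon_s: float = 600.0,
    criterion: str = "sumsq",
    curves: HillCurves = DEFAULT_CURVES,
) -> FailurePrediction:
    """Endurance time of a static hold: first instant the available maximal
    flexion moment crosses the demanded torque, linearly interpolated
    between steps.  Demands above the rested capacity fail at t = 0."""
    fibers = _fiber_states(model, phi, 0.0, curves)
    states = fat.CompartmentState.rested(len(model.muscles))
    avail = available_max_moment(model, fibers, states, phi, curves)
    if avail < q_const:
        return FailurePrediction(time_s=0.0, censored=False, horizon_s=horizon_s)
    t = 0.0
    n = int(round(horizon_s / dt))
    prev_margin = avail - q_const
    for i in range(n):
        sample = JointSample(t=t, phi=phi, phidot=0.0, q=q_const)
        _, states = run_timestep(model, states, sample, dt, criterion, curves)
        t = (i + 1) * dt
        avail = available_max_moment(model, fibers, states, phi, curves)
        margin = avail - q_const
        if margin < 0:
            # linear interpolation of the zero crossing inside the step
            frac = prev_margin / (prev_margin - margin)
            return FailurePrediction(
                time_s=t - dt + frac * dt, censored=False, horizon_s=horizon_s
            )
        prev_margin = margin
    return FailurePrediction(time_s=None, censored=True, horizon_s=horizon_s)


MotionSource = Callable[[Segment], pd.DataFrame]


def simulate_protocol(
    model: MusculoskeletalModel,
    protocol: Protocol,
    motion_source: Optional[MotionSource] = None,
    dt: float = 0.01,
    criterion: str = "sumsq",
    curves: HillCurves = DEFAULT_CURVES,
    record_every: int = 1,
    equilibrium_tol: float = 0.01,
) -> SessionResult:
    """Execute a protocol segment by segment.

    * ``rest``: TL = 0 for every muscle (rest-recovery multiplier active).
    * ``mvc`` / ``static_hold``: static posture; MVC forces agonist
      (flexor) TL = 100 and records the available maximal moment;
      static_hold demands ``q_nm`` through the load-sharing loop and logs
      a failure event when capacity crosses the demand.
    * ``curl_set``: per-sample torque demand from ``motion_source``
      (columns t_s, phi_deg, phidot_deg_s, Q_Nm).

    Cycle-end markers enable equilibrium detection: the session is flagged
    as equilibrated when every muscle's Mf changes by less than
    ``equilibrium_tol`` %MU between consecutive cycle ends.
    """
    n = len(model.muscles)
    names = model.muscle_names
    states = fat.CompartmentState.rested(n)
    flexor_mask = np.array([m.role == "flexor" for m in model.muscles])
    params = (
        np.array([m.fatigue.F for m in model.muscles]),
        np.array([m.fatigue.R for m in model.muscles]),
        np.array([m.fatigue.r_rest for m in model.muscles]),
    )
    t_rows: List[tuple] = []
    m_rows: List[tuple] = []
    failure_times: List[float] = []
    cycle_mf: List[np.ndarray] = []
    t = 0.0
    step_i = 0

    def record(seg_kind, phi, q, avail, residual, forces, acts):
        if step_i % record_every:
            return
        t_rows.append((t, seg_kind, phi, q, avail, residual))
        for k, name in enumerate(names):
            m_rows.append(
                (t, name, forces[k], acts[k], states.ma[k], states.mr[k], states.mf[k])
            )

    for seg in protocol.segments:
        if seg.kind == "rest":
            n_steps = int(round(seg.duration_s / dt))
            for _ in range(n_steps):
                record("rest", float("nan"), 0.0, float("nan"), 0.0,
                       np.zeros(n), np.zeros(n))
                states = fat.step(states, np.zeros(n), params, dt)
                t += dt
                step_i += 1
        elif seg.kind in ("mvc", "static_hold"):
            phi = seg.phi_deg
            fibers = _fiber_states(model, phi, 0.0, curves)
            n_steps = int(round(seg.duration_s / dt))
            failed = False
            for _ in range(n_steps):
                avail = available_max_moment(model, fibers, states, phi, curves)
                if seg.kind == "mvc":
                    lb, ub = _bounds(model, fibers, states, curves)
                    forces = np.where(flexor_mask, ub, lb)
                    acts = flexor_mask.astype(float)
                    tl = 100.0 * flexor_mask
                    residual = 0.0
                    q_dem = avail
                    states = fat.step(states, tl, params, dt)
                else:
                    q_dem = float(seg.q_nm)
                    sample = JointSample(t=t, phi=phi, phidot=0.0, q=q_dem)
                    sol, states = run_timestep(
                        model, states, sample, dt, criterion, curves
                    )
                    forces, acts = sol.forces, sol.activations
                    residual = sol.torque_residual
                    if not failed and avail < q_dem:
                        failure_times.append(t)
                        failed = True
                record(seg.kind, phi, q_dem, avail, residual, forces, acts)
                t += dt
                step_i += 1
        elif seg.kind == "curl_set":
            if motion_source is None:
                raise ValueError("curl_set segment requires a motion source")
            motion = motion_source(seg)
            tm = np.asarray(motion["t_s"], float)
            for i in range(len(tm) - 1):
                h = float(tm[i + 1] - tm[i])
                sample = JointSample(
                    t=t,
                    phi=float(motion["phi_deg"].iloc[i]),
                    phidot=float(motion["phidot_deg_s"].iloc[i]),
                    q=float(motion["Q_Nm"].iloc[i]),
                )
                fibers = _fiber_states(model, sample.phi, sample.phidot, curves)
                avail = available_max_moment(model, fibers, states, sample.phi, curves)
                sol, states = run_timestep(model, states, sample, h, criterion, curves)
                record("curl_set", sample.phi, sample.q, avail,
                       sol.torque_residual, sol.forces, sol.activations)
                t += h
                step_i += 1
        if seg.cycle_end:
            cycle_mf.append(np.atleast_1d(states.mf).copy())

    equilibrium = None
    if len(cycle_mf) >= 2:
        deltas = [
            float(np.max(np.abs(b - a))) for a, b in zip(cycle_mf, cycle_mf[1:])
        ]
        equilibrium = deltas[-1] < equilibrium_tol
    time_df = pd.DataFrame(
        t_rows,
        columns=["t_s", "segment", "phi_deg", "Q_Nm", "available_Nm",
                 "torque_residual_Nm"],
    )
    muscle_df = pd.DataFrame(
        m_rows, columns=["t_s", "muscle", "force_N", "activation", "Ma", "Mr", "Mf"]
    )
    return SessionResult(
        time=time_df,
        muscle=muscle_df,
        failure_times=failure_times,
        equilibrium_reached=equilibrium,
        cycle_mf=cycle_mf,
    )


def compare_mvc(
    simulated: pd.DataFrame,
    measured: pd.DataFrame,
    windows: Sequence[Tuple[float, float]],
) -> Dict:
    """RMSE per window and first-peak error between moment traces.

    Both inputs need columns t_s and Q_Nm on a shared clock; the measured
    trace is interpolated onto the simulated time stamps.  The first-peak
    error is simulated peak minus measured peak inside the first window.
    """
    t = np.asarray(simulated["t_s"], float)
    sim = np.asarray(simulated["Q_Nm"], float)
    meas = np.interp(t, np.asarray(measured["t_s"], float),
                     np.asarray(measured["Q_Nm"], float))
    rmse = []
    for (t0, t1) in windows:
        mask = (t >= t0) & (t <= t1)
        if not np.any(mask):
            raise ValueError(f"empty comparison window [{t0}, {t1}]")
        rmse.append(float(np.sqrt(np.mean((sim[mask] - meas[mask]) ** 2))))
    t0, t1 = windows[0]
    mask = (t >= t0) & (t <= t1)
    peak_error = float(np.max(sim[mask]) - np.max(meas[mask]))
    return {"rmse_Nm": rmse, "first_peak_error_Nm": peak_error}
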