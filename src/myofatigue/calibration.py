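"""Subject-specific calibration of geometry, force, and fatigue parameters.

Four procedures, each driven by maximum-voluntary-contraction (MVC) data:

1. **Condensed-actuator F0 estimation** — during a flexion MVC the flexors
   are taken fully active and the extensors passive, so the measured peak
   flexion moment (corrected for the extensor passive moment, Q*_max)
   divided by the mean flexor moment arm and the mean dimensionless force
   factors yields the maximum isometric force of a single condensed flexor
   actuator.  If the geometry were accurate this estimate would not depend
   on the posture it is evaluated at.

2. **Moment-arm scale k1** — the spread of the F0 estimates across postures
   is attributed to moment-arm error; the arm profile is recalibrated as
   ``J*(phi) = k1 (J(phi) - J(0)) + J(0)`` (anchored at full extension) with
   k1 chosen to minimize the sample SD of the estimates.  The same k1 is
   applied to every muscle's moment arm.

3. **Maximal-force scale k2** — the pointwise ratio of the measured MVC
   moment to the model's maximal flexion moment; its maximum over the trace
   rescales every muscle's F0M so the model can just reproduce the
   measured maximum (no reserve actuators).

4. **Fatigue-parameter fitting** — least-squares fit of the simulated
   residual capacity (TL = 100 during effort, 0 during rest) to normalized
   MVC force traces, yielding subject-specific (F, R, r_rest); a group-B
   variant freezes R at 0.001 1/s and fits (F_B, r_B) on the fast-fatigable
   share of the force.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize_scalar

from . import fatigue as fat
from .hill import DEFAULT_CURVES, HillCurves, force_length_active, \
    force_length_passive, force_velocity
from .model import FatigueParameters, GeometryModel, MusculoskeletalModel

logger = logging.getLogger(__name__)

# bounded, deterministic optimizer settings
FIT_BOUNDS_F = (1e-5, 1.0)
FIT_BOUNDS_R = (1e-5, 1.0)
FIT_BOUNDS_R_REST = (1.0, 50.0)
FIT_TOL = 1e-8


@dataclass(frozen=True)
class PostureEstimate:
    """Condensed-actuator inputs and F0 estimate at one posture/trial."""

    phi: float  # elbow flexion angle (deg)
    q_max_star: float  # measured max flexion moment, extensor-passive corrected (N*m)
    j_flex: float  # mean flexor moment arm (m)
    f_l: float = 1.0
    f_v: float = 1.0
    f_pe: float = 0.0
    f0_est: float = 0.0


@dataclass
class CalibrationResult:
    """Outcome of a geometry or force calibration."""

    k1: float = 1.0
    k2: float = 1.0
    f0_scaled: Dict[str, float] = field(default_factory=dict)
    fitted_fatigue: Optional[FatigueParameters] = None
    diagnostics: Dict[str, float] = field(default_factory=dict)


def estimate_actuator_f0(
    samples: Sequence[PostureEstimate], static: bool = False
) -> List[PostureEstimate]:
    """Maximum isometric force of the condensed flexor actuator per posture.

    ``F0 = Q*_max / (J_flex (f_l f_v + f_PE))``; the ``static`` variant
    drops the physiological factor (``F0 = Q_max / J_flex``).
    """
    out = []
    for s in samples:
        if s.j_flex <= 0:
            raise ValueError(f"posture {s.phi} deg: mean flexor moment arm must be > 0")
        denom = s.j_flex if static else s.j_flex * (s.f_l * s.f_v + s.f_pe)
        if denom <= 0:
            raise ValueError(
                f"posture {s.phi} deg: zero physiological denominator "
                f"(f_l*f_v + f_PE = {s.f_l * s.f_v + s.f_pe:.4g})"
            )
        out.append(
            PostureEstimate(
                phi=s.phi, q_max_star=s.q_max_star, j_flex=s.j_flex,
                f_l=s.f_l, f_v=s.f_v, f_pe=s.f_pe,
                f0_est=s.q_max_star / denom,
            )
        )
    return out


def summarize_estimates(values: Sequence[float]) -> Tuple[float, float]:
    """Arithmetic mean and sample (n-1) standard deviation."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 estimates to summarize")
    return float(v.mean()), float(v.std(ddof=1))


def _actuator_factors(
    model: MusculoskeletalModel, phi: float, curves: HillCurves
) -> Tuple[float, float, float, float]:
    """Mean flexor moment arm and mean (f_l, f_v, f_PE) at a static posture."""
    from .hill import fiber_state_rigid_tendon

    arms, fls, fvs, fpes = [], [], [], []
    for m in model.flexors():
        fib = fiber_state_rigid_tendon(m, float(model.geometry.lmt(m.name, phi)), 0.0, curves)
        arms.append(float(model.geometry.moment_arm(m.name, phi)))
        fls.append(force_length_active(fib.l_norm, curves))
        fvs.append(force_velocity(fib.v_norm, curves))
        fpes.append(force_length_passive(fib.l_norm, curves))
    return (
        float(np.mean(arms)), float(np.mean(fls)),
        float(np.mean(fvs)), float(np.mean(fpes)),
    )


def extensor_passive_moment(
    model: MusculoskeletalModel, phi: float, curves: HillCurves = DEFAULT_CURVES
) -> float:
    """Passive (a=0) extensor flexion moment at a static posture (N*m, <= 0)."""
    from .hill import fiber_state_rigid_tendon, force_bounds

    total = 0.0
    for m in model.extensors():
        fib = fiber_state_rigid_tendon(m, float(model.geometry.lmt(m.name, phi)), 0.0, curves)
        total += float(model.geometry.moment_arm(m.name, phi)) * force_bounds(m, fib, curves).f_min
    return total


def posture_estimates_from_model(
    model: MusculoskeletalModel,
    trials: Sequence[Tuple[float, float]],
    curves: HillCurves = DEFAULT_CURVES,
    static: bool = False,
) -> List[PostureEstimate]:
    """Build Eq-style posture estimates from (phi_deg, measured Q_max) trials.

    The measured maximal flexion moment is corrected by the model's
    extensor passive moment before dividing by the condensed-actuator
    factors.
    """
    samples = []
    for phi, q_max in trials:
        j, fl, fv, fpe = _actuator_factors(model, phi, curves)
        q_star = q_max - extensor_passive_moment(model, phi, curves)
        samples.append(PostureEstimate(phi=phi, q_max_star=q_star, j_flex=j,
                                       f_l=fl, f_v=fv, f_pe=fpe))
    return estimate_actuator_f0(samples, static=static)


def calibrate_moment_arm_scale(
    model: MusculoskeletalModel,
    trials: Sequence[Tuple[float, float]],
    curves: HillCurves = DEFAULT_CURVES,
    k1_bounds: Tuple[float, float] = (0.05, 20.0),
) -> Tuple[float, MusculoskeletalModel, CalibrationResult]:
    """Find the moment-arm scale k1 minimizing the SD of F0 estimates.

    Every muscle's moment arm is recalibrated as
    ``J*(phi) = k1 (J(phi) - J(0 deg)) + J(0 deg)`` (anchored at full
    extension so the rescaling changes the arm's variation with angle, not
    its extension value).

    The spread is measured as the coefficient of variation (SD/mean) of the
    F0 estimates: a raw-SD objective is degenerate under this one-parameter
    family (large k1 shrinks every estimate, and with it the SD, toward
    zero without making the geometry any more consistent), while the
    relative spread is scale-invariant and has its zero exactly where the
    estimates agree.  k1 = 1 is always admissible and the result is
    guarded so the calibrated SD never exceeds the original.
    """
    if len(trials) < 2:
        raise ValueError("need at least 2 posture trials to calibrate k1")
    geo = model.geometry
    phi0 = float(geo.phi_deg[0])
    arm0 = {n: float(geo.moment_arm(n, phi0)) for n in geo.muscle_names}

    def scaled_model(k1: float) -> MusculoskeletalModel:
        arms = {
            n: k1 * (geo.arm_tables[n] - arm0[n]) + arm0[n]
            for n in geo.muscle_names
        }
        return MusculoskeletalModel(
            model.muscles, geo.with_tables(moment_arm_m=arms), model.variant_tag
        )

    def spread_at(k1: float) -> Tuple[float, float]:
        est = posture_estimates_from_model(scaled_model(k1), trials, curves)
        mean, sd = summarize_estimates([e.f0_est for e in est])
        return sd / abs(mean), sd

    pre_est = [e.f0_est for e in posture_estimates_from_model(model, trials, curves)]
    pre_mean, pre_sd = summarize_estimates(pre_est)

    # coarse log-spaced scan to bracket the global minimum, then refine
    grid = np.geomspace(k1_bounds[0], k1_bounds[1], 80)
    cvs = np.array([spread_at(k)[0] for k in grid])
    i = int(np.argmin(cvs))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(lambda k: spread_at(k)[0], bounds=(lo, hi),
                          method="bounded", options={"xatol": 1e-10})
    if not res.success:
        raise RuntimeError(f"k1 optimization failed: {res.message}")
    k1 = float(res.x)
    if spread_at(1.0)[0] <= res.fun or spread_at(k1)[1] > pre_sd:
        k1 = 1.0  # identity is always admissible and never worsens the SD
    recal = scaled_model(k1)
    post_est = [e.f0_est for e in posture_estimates_from_model(recal, trials, curves)]
    post_mean, post_sd = summarize_estimates(post_est)
    result = CalibrationResult(
        k1=k1,
        diagnostics={
            "pre_mean_N": pre_mean, "pre_sd_N": pre_sd,
            "post_mean_N": post_mean, "post_sd_N": post_sd,
        },
    )
    return k1, recal, result


def calibrate_f0_scale(
    q_trace: pd.DataFrame,
    model: MusculoskeletalModel,
    phi: float,
    curves: HillCurves = DEFAULT_CURVES,
) -> Tuple[float, MusculoskeletalModel, CalibrationResult]:
    """Scale every F0M so the model just reproduces a measured MVC trace.

    ``k2(t) = Q(t) / Q_max,flex(t)`` pointwise, with Q_max,flex the model's
    maximal flexion moment (flexors fully active, extensors passive) at the
    static MVC posture; ``F0M* = max_t(k2) F0M`` for all muscles, extensors
    included.
    """
    from dataclasses import replace
    from .session import available_max_moment_static

    q = np.asarray(q_trace["Q_Nm"], dtype=float)
    q_cap = available_max_moment_static(model, phi, curves)
    if q_cap <= 0:
        raise ValueError(f"model maximal flexion moment non-positive at {phi} deg")
    k2_trace = q / q_cap
    k2 = float(np.max(k2_trace))
    scaled = MusculoskeletalModel(
        [replace(m, F0M=m.F0M * k2) for m in model.muscles],
        model.geometry, model.variant_tag,
    )
    result = CalibrationResult(
        k2=k2,
        f0_scaled={m.name: m.F0M for m in scaled.muscles},
        diagnostics={"q_cap_pre_Nm": q_cap, "q_peak_Nm": float(np.max(q))},
    )
    return k2, scaled, result


# ---------------------------------------------------------------------------
# fatigue-parameter fitting


def _effort_rest_effort_capacity(
    params: FatigueParameters,
    t_decay: np.ndarray,
    rest_s: float,
    t_probe: Optional[np.ndarray],
    dt: float,
) -> Tuple[np.ndarray, Optional[np.ndarray]]:
    """Residual capacity (fraction of baseline) along effort/rest/effort."""
    state = fat.CompartmentState.rested()
    cap_decay = np.empty_like(t_decay)
    t = 0.0
    i = 0
    cap_decay[0] = 1.0
    # sustained maximal effort sampled at the trace's own times
    for i in range(1, t_decay.size):
        while t < t_decay[i] - 1e-12:
            h = min(dt, t_decay[i] - t)
            state = fat.step(state, 100.0, params, h)
            t += h
        cap_decay[i] = fat.residual_capacity(state) / 100.0
    if t_probe is None:
        return cap_decay, None
    # rest, then the recovery-probe effort
    t = 0.0
    while t < rest_s - 1e-12:
        h = min(dt, rest_s - t)
        state = fat.step(state, 0.0, params, h)
        t += h
    cap_probe = np.empty_like(t_probe)
    t = 0.0
    cap_probe[0] = fat.residual_capacity(state) / 100.0
    for i in range(1, t_probe.size):
        while t < t_probe[i] - 1e-12:
            h = min(dt, t_probe[i] - t)
            state = fat.step(state, 100.0, params, h)
            t += h
        cap_probe[i] = fat.residual_capacity(state) / 100.0
    return cap_decay, cap_probe


def fit_fatigue_parameters(
    decay_trace: pd.DataFrame,
    recovery_probe: Optional[pd.DataFrame] = None,
    rest_s: float = 15.0,
    initial: FatigueParameters = FatigueParameters(F=0.01, R=0.01, r_rest=5.0),
    dt: float = 0.05,
) -> Tuple[FatigueParameters, float]:
    """Fit (F, R, r_rest) to normalized MVC force traces.

    ``decay_trace`` holds a sustained maximal effort (columns t_s,
    force_norm, forces normalized to the baseline maximum); the optional
    ``recovery_probe`` holds a second maximal effort after ``rest_s``
    seconds of rest, which identifies the recovery parameters.  The forward
    model is the simulated residual capacity at TL = 100 during efforts and
    TL = 0 during the rest.  Returns the fitted parameters and the residual
    norm; deterministic for fixed initial guess and tolerances.
    """
    t_d = np.asarray(decay_trace["t_s"], dtype=float)
    y_d = np.asarray(decay_trace["force_norm"], dtype=float)
    t_p = y_p = None
    if recovery_probe is not None:
        t_p = np.asarray(recovery_probe["t_s"], dtype=float)
        y_p = np.asarray(recovery_probe["force_norm"], dtype=float)

    def residuals(x):
        params = FatigueParameters(F=x[0], R=x[1], r_rest=x[2])
        cap_d, cap_p = _effort_rest_effort_capacity(params, t_d, rest_s, t_p, dt)
        res = cap_d - y_d
        if cap_p is not None:
            res = np.concatenate([res, cap_p - y_p])
        if not np.all(np.isfinite(res)):
            raise FloatingPointError("non-finite residual in fatigue fit")
        return res

    lo = [FIT_BOUNDS_F[0], FIT_BOUNDS_R[0], FIT_BOUNDS_R_REST[0]]
    hi = [FIT_BOUNDS_F[1], FIT_BOUNDS_R[1], FIT_BOUNDS_R_REST[1]]
    x0 = np.clip([initial.F, initial.R, initial.r_rest], lo, hi)
    sol = least_squares(residuals, x0, bounds=(lo, hi),
                        xtol=FIT_TOL, ftol=FIT_TOL, gtol=FIT_TOL)
    fitted = FatigueParameters(F=float(sol.x[0]), R=float(sol.x[1]),
                               r_rest=float(sol.x[2]))
    return fitted, float(np.linalg.norm(sol.fun))


def fit_group_b_parameters(
    decay_trace: pd.DataFrame,
    recovery_probe: Optional[pd.DataFrame],
    share_b: float,
    rest_s: float = 15.0,
    r_b_fixed: float = 0.001,
    group_a: Optional[FatigueParameters] = None,
    initial: Tuple[float, float] = (0.05, 10.0),
    dt: float = 0.05,
) -> Tuple[FatigueParameters, float]:
    """Fit the group-B coefficients (F_B, r_B) with R_B frozen.

    The total normalized force is modeled as the fiber-share-weighted sum of
    the two groups' residual capacities; group A uses the fixed coefficients
    (F = 0.004, R = 0.01, r = 1) and ``share_b`` is the group-B fraction of
    F0M.  R_B stays at ``r_b_fixed`` (default 0.001 1/s, reflecting the
    anaerobic metabolism of type IIx fibers).
    """
    from .model import GROUP_A_FATIGUE

    if r_b_fixed <= 0:
        raise ValueError("R_B must be positive")
    if share_b <= 1e-6:
        raise ValueError(
            "group-B share is zero: its fatigue parameters are unidentifiable"
        )
    group_a = group_a or GROUP_A_FATIGUE
    share_a = 1.0 - share_b
    t_d = np.asarray(decay_trace["t_s"], dtype=float)
    y_d = np.asarray(decay_trace["force_norm"], dtype=float)
    t_p = y_p = None
    if recovery_probe is not None:
        t_p = np.asarray(recovery_probe["t_s"], dtype=float)
        y_p = np.asarray(recovery_probe["force_norm"], dtype=float)

    cap_a_d, cap_a_p = _effort_rest_effort_capacity(group_a, t_d, rest_s, t_p, dt)

    def residuals(x):
        params_b = FatigueParameters(F=x[0], R=r_b_fixed, r_rest=x[1])
        cap_b_d, cap_b_p = _effort_rest_effort_capacity(params_b, t_d, rest_s, t_p, dt)
        res = share_a * cap_a_d + share_b * cap_b_d - y_d
        if t_p is not None:
            res = np.concatenate([res, share_a * cap_a_p + share_b * cap_b_p - y_p])
        if not np.all(np.isfinite(res)):
            raise FloatingPointError("non-finite residual in group-B fit")
        return res

    lo = [FIT_BOUNDS_F[0], FIT_BOUNDS_R_REST[0]]
    hi = [FIT_BOUNDS_F[1], FIT_BOUNDS_R_REST[1]]
    x0 = np.clip(list(initial), lo, hi)
    sol = least_squares(residuals, x0, bounds=(lo, hi),
                        xtol=FIT_TOL, ftol=FIT_TOL, gtol=FIT_TOL)
    fitted = FatigueParameters(F=float(sol.x[0]), R=r_b_fixed,
                               r_rest=float(sol.x[1]))
    return fitted, float(np.linalg.norm(sol.fun))


def bin_average_trace(trace: pd.DataFrame, factor: int) -> pd.DataFrame:
    """Decimate a uniformly sampled trace by averaging consecutive bins.

    Standard preprocessing before least-squares fitting: retains the full
    record's information while reducing per-point noise by sqrt(factor)
    and the fit's sample count by the same factor.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    n = (len(trace) // factor) * factor
    out = {}
    for col in trace.columns:
        v = np.asarray(trace[col], dtype=float)[:n]
        out[col] = v.reshape(-1, factor).mean(axis=1)
    return pd.DataFrame(out)


def compute_pct_decay(mvc_trace: pd.DataFrame, window_s: float = 0.5) -> float:
    """Percentage force decay over a sustained maximal effort.

    ``100 (peak - final) / peak`` with the peak taken as the maximum of a
    ``window_s`` rolling mean (a short trimmed mean suppresses gauge noise)
    and the final value as the mean over the last ``window_s`` seconds.
    """
    t = np.asarray(mvc_trace["t_s"], dtype=float)
    y = np.asarray(mvc_trace["force_N"], dtype=float)
    if t[-1] - t[0] < 2.0:
        raise ValueError("MVC trace must span at least 2 s")
    dt = float(np.median(np.diff(t)))
    n = max(int(round(window_s / dt)), 1)
    smoothed = pd.Series(y).rolling(n, min_periods=n).mean().to_numpy()
    peak = float(np.nanmax(smoothed))
    final = float(np.mean(y[t >= t[-1] - window_s]))
    if peak <= 0:
        raise ValueError("non-positive peak force in MVC trace")
    return max(0.0, 100.0 * (peak - final) / peak)
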