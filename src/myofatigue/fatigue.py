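"""Three-compartment controller (3CCr) localized muscle fatigue model.

Motor units (100% of them, the conserved currency) flow between an active
pool Ma, a resting pool Mr, and a fatigued pool Mf:

    dMa/dt = C(t) - F * Ma
    dMf/dt = F * Ma - R * r * Mf
    dMr/dt = -C(t) + R * r * Mf

where the feedback controller C(t) recruits (or de-recruits) resting units
to match the target load TL (percent of maximum):

    C = TL - Ma   if Ma < TL and Mr >  TL - Ma    (enough reserve)
    C = Mr        if Ma < TL and Mr <= TL - Ma    (capacity-limited)
    C = TL - Ma   if Ma > TL                      (de-recruitment)

F and R are the fatigue and recovery coefficients (1/s); the rest
multiplier r equals 1 whenever TL > 0 and r_rest when TL = 0, boosting
recovery during rest periods.  The three flows conserve Ma + Mr + Mf = 100
exactly; integration is fixed-step classical RK4 with a renormalization
guard (clip at zero, rescale the sum) each step.

All state functions accept scalars or aligned numpy arrays, so a vector of
muscles can be advanced in one call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .hill import DEFAULT_CURVES, FiberState, HillCurves, force_length_active, \
    force_length_passive, force_velocity
from .model import FatigueParameters, MusculotendonParameters


@dataclass
class CompartmentState:
    """Motor-unit occupancy of the three compartments, in % MU.

    Fields may be scalars or aligned arrays (one entry per muscle).
    """

    ma: np.ndarray
    mr: np.ndarray
    mf: np.ndarray

    def __post_init__(self) -> None:
        self.ma = np.asarray(self.ma, dtype=float)
        self.mr = np.asarray(self.mr, dtype=float)
        self.mf = np.asarray(self.mf, dtype=float)
        if np.any(self.ma < -1e-9) or np.any(self.mr < -1e-9) or np.any(self.mf < -1e-9):
            raise ValueError("compartment values must be non-negative")
        if np.any(np.abs(self.ma + self.mr + self.mf - 100.0) > 1e-6):
            raise ValueError("compartments must sum to 100 %MU")

    @classmethod
    def rested(cls, n: Optional[int] = None) -> "CompartmentState":
        """Fully rested state: all motor units in the resting pool."""
        shape = () if n is None else (n,)
        return cls(np.zeros(shape), np.full(shape, 100.0), np.zeros(shape))

    def copy(self) -> "CompartmentState":
        return CompartmentState(self.ma.copy(), self.mr.copy(), self.mf.copy())


def controller(state: CompartmentState, tl) -> np.ndarray:
    """Feedback drive C (%MU/s) moving units between resting and active."""
    tl = np.asarray(tl, dtype=float)
    want = tl - state.ma
    # recruiting: limited by the resting reserve; de-recruiting: want < 0
    c = np.where(want > 0, np.minimum(want, state.mr), want)
    return c if c.ndim else float(c)


def _rates(params: FatigueParameters | np.ndarray):
    if isinstance(params, FatigueParameters):
        return params.F, params.R, params.r_rest
    return params  # tuple of arrays (F, R, r_rest)


def derivatives(state: CompartmentState, tl, params) -> tuple:
    """Compartment time-derivatives (d/dt of Ma, Mr, Mf), %MU/s.

    ``params`` is a FatigueParameters or a tuple of aligned arrays
    (F, R, r_rest).  The rest multiplier applies only where TL = 0.
    """
    F, R, r_rest = _rates(params)
    tl = np.asarray(tl, dtype=float)
    c = controller(state, tl)
    r = np.where(tl > 0, 1.0, r_rest)
    recovery = R * r * state.mf
    dma = c - F * state.ma
    dmf = F * state.ma - recovery
    dmr = -c + recovery
    return dma, dmr, dmf


def step(state: CompartmentState, tl, params, dt: float) -> CompartmentState:
    """One RK4 step of the compartment ODEs, renormalized to sum 100."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    ma, mr, mf = state.ma, state.mr, state.mf

    def f(ma_, mr_, mf_):
        s = CompartmentState.__new__(CompartmentState)
        s.ma, s.mr, s.mf = ma_, mr_, mf_
        return derivatives(s, tl, params)

    k1 = f(ma, mr, mf)
    k2 = f(ma + dt / 2 * k1[0], mr + dt / 2 * k1[1], mf + dt / 2 * k1[2])
    k3 = f(ma + dt / 2 * k2[0], mr + dt / 2 * k2[1], mf + dt / 2 * k2[2])
    k4 = f(ma + dt * k3[0], mr + dt * k3[1], mf + dt * k3[2])
    ma1 = ma + dt / 6 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
    mr1 = mr + dt / 6 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
    mf1 = mf + dt / 6 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
    ma1, mr1, mf1 = (np.maximum(v, 0.0) for v in (ma1, mr1, mf1))
    total = ma1 + mr1 + mf1
    scale = 100.0 / np.where(total > 0, total, 1.0)
    out = CompartmentState.__new__(CompartmentState)
    out.ma, out.mr, out.mf = ma1 * scale, mr1 * scale, mf1 * scale
    return out


def simulate_profile(
    tl_fn: Callable[[float], float],
    params: FatigueParameters,
    duration: float,
    dt: float = 0.01,
    initial: Optional[CompartmentState] = None,
) -> pd.DataFrame:
    """Integrate the 3CCr model under a target-load profile TL(t).

    Returns a DataFrame with columns t_s, Ma, Mr, Mf, TL sampled at every
    step, starting from the fully rested state unless ``initial`` is given.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    n = int(round(duration / dt))
    state = (initial or CompartmentState.rested()).copy()
    rows = np.empty((n + 1, 5))
    t = 0.0
    rows[0] = (t, float(state.ma), float(state.mr), float(state.mf), tl_fn(0.0))
    for i in range(n):
        tl = tl_fn(t)
        state = step(state, tl, params, dt)
        t = (i + 1) * dt
        rows[i + 1] = (t, float(state.ma), float(state.mr), float(state.mf), tl_fn(t))
    return pd.DataFrame(rows, columns=["t_s", "Ma", "Mr", "Mf", "TL"])


def residual_capacity(state: CompartmentState):
    """Remaining force capacity, % of the rested maximum: 100 - Mf."""
    out = 100.0 - state.mf
    return out if np.ndim(out) else float(out)


def endurance_asymptote(params: FatigueParameters) -> float:
    """Long-run residual capacity under sustained maximal demand.

    At the fatigue/recovery balance of a sustained static task the residual
    capacity approaches ``100 / (F/R + 1)`` percent of baseline.
    """
    return 100.0 / (params.F / params.R + 1.0)


def fatigued_force_ceiling(
    muscle: MusculotendonParameters,
    fiber: FiberState,
    state: CompartmentState,
    curves: HillCurves = DEFAULT_CURVES,
) -> float:
    """Maximum force (N) with only the non-fatigued units recruitable.

    Fatigue scales the contractile term by (100 - Mf)/100; the passive
    elastic contribution is unaffected.
    """
    cos_a = math.cos(fiber.alpha)
    f_lv = force_length_active(fiber.l_norm, curves) * force_velocity(
        fiber.v_norm, curves
    )
    f_pe = force_length_passive(fiber.l_norm, curves)
    mf = float(state.mf)
    return (f_lv * (100.0 - mf) / 100.0 + f_pe) * muscle.F0M * cos_a
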