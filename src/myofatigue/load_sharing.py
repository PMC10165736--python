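"""Muscle redundancy load-sharing at a single time instant.

The elbow has one actuated degree of freedom served by many muscles, so the
net joint torque constraint ``sum_i J_i F_i = Q`` (J_i the signed moment
arms) leaves infinitely many force distributions.  A recruitment criterion
selects one:

* classical: minimize ``sum_i F_i^2``;
* fiber-type weighted (Henneman size principle): minimize
  ``sum_i (F_i w_i)^2`` with ``w_i`` each muscle's fatigue coefficient, so
  fatigue-resistant (small-w) fibers are recruited preferentially.

Both are convex quadratic programs with box bounds (the physiological
minimum/maximum forces, fatigue-modified at the ceiling).  With one
equality constraint the KKT conditions give the exact solution

    F_i(lam) = clip(lam * J_i / (2 w_i^2), f_min_i, f_max_i)

with the multiplier ``lam`` chosen so the torque constraint holds; the
achieved torque is monotone in ``lam``, so a bracketed scalar root find
(scipy brentq) solves the problem to machine precision, deterministically.
If the demanded torque exceeds what the bounds allow, the bound-clamped
maximal-torque solution is returned with the unmet torque reported as
``torque_residual`` (no residual "hand of God" actuator is added).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .hill import DEFAULT_CURVES, FiberState, HillCurves, activation_from_force
from .model import MusculoskeletalModel

logger = logging.getLogger(__name__)

_TORQUE_TOL = 1e-9


@dataclass
class LoadSharingSolution:
    """Per-muscle forces solving the redundancy problem at one instant."""

    forces: np.ndarray  # N, ordered as the input moment arms
    activations: Optional[np.ndarray] = None
    at_upper_bound: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))
    torque_residual: float = 0.0  # unmet torque (N*m), 0 when feasible
    objective_value: float = 0.0
    achieved_torque: float = 0.0

    @property
    def feasible(self) -> bool:
        return self.torque_residual <= 1e-6


def _validate(moment_arms, q, lb, ub, weights):
    j = np.asarray(moment_arms, dtype=float)
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    if not (j.shape == lb.shape == ub.shape):
        raise ValueError("moment arms and bounds must have matching shapes")
    if np.any(lb > ub + 1e-12):
        raise ValueError("lower bounds exceed upper bounds")
    if np.all(j == 0):
        raise ValueError("all moment arms are zero: torque constraint unsatisfiable")
    if weights is None:
        w = np.ones_like(j)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != j.shape:
            raise ValueError("weights shape mismatch")
        if np.any(w <= 0):
            raise ValueError("recruitment weights must be strictly positive")
    if q != 0 and not np.any(np.sign(j) == np.sign(q)):
        raise ValueError("no muscle has a moment arm of the sign of the demanded torque")
    return j, float(q), lb, ub, w


def solve_fatigue_weighted(
    moment_arms: Sequence[float],
    q: float,
    lb: Sequence[float],
    ub: Sequence[float],
    weights: Optional[Sequence[float]] = None,
) -> LoadSharingSolution:
    """Minimize ``sum (F_i w_i)^2`` s.t. ``J.F = Q`` and box bounds.

    Unit (or omitted) weights give the classical minimum-sum-of-squares
    criterion.  Infeasible demands return the clamped maximal-torque
    solution with a positive ``torque_residual`` and a logged warning.
    """
    j, q, lb, ub, w = _validate(moment_arms, q, lb, ub, weights)
    coef = j / (2.0 * w**2)

    def force_at(lam: float) -> np.ndarray:
        return np.clip(lam * coef, lb, ub)

    def torque_at(lam: float) -> float:
        return float(j @ force_at(lam))

    # achieved torque is non-decreasing in lam; find the saturation range
    lam_lo, lam_hi = -1.0, 1.0
    rest = np.clip(0.0, lb, ub)  # optimum of unconstrained coordinates
    f_hi = np.where(coef > 0, ub, np.where(coef < 0, lb, rest))
    f_lo = np.where(coef > 0, lb, np.where(coef < 0, ub, rest))
    t_hi_cap = float(j @ f_hi)
    t_lo_cap = float(j @ f_lo)

    if q > t_hi_cap + _TORQUE_TOL or q < t_lo_cap - _TORQUE_TOL:
        # demand outside reachable torque: clamp to the nearer extreme
        forces = f_hi if q > t_hi_cap else f_lo
        achieved = float(j @ forces)
        residual = max(0.0, q - achieved)
        logger.warning(
            "load sharing infeasible: demanded %.3f N*m, reachable [%.3f, %.3f]; "
            "clamped with residual %.3f N*m", q, t_lo_cap, t_hi_cap, residual,
        )
        return _finish(forces, j, w, ub, achieved, residual)

    while torque_at(lam_hi) < q - _TORQUE_TOL:
        lam_hi *= 2.0
        if lam_hi > 1e18:
            break
    while torque_at(lam_lo) > q + _TORQUE_TOL:
        lam_lo *= 2.0
        if lam_lo < -1e18:
            break

    if abs(torque_at(lam_hi) - q) <= _TORQUE_TOL:
        lam = lam_hi
    elif abs(torque_at(lam_lo) - q) <= _TORQUE_TOL:
        lam = lam_lo
    else:
        lam = brentq(lambda l: torque_at(l) - q, lam_lo, lam_hi, xtol=1e-14, rtol=1e-15)
    forces = force_at(lam)
    achieved = float(j @ forces)
    return _finish(forces, j, w, ub, achieved, max(0.0, q - achieved) if abs(achieved - q) > 1e-6 else 0.0)


def _finish(forces, j, w, ub, achieved, residual) -> LoadSharingSolution:
    return LoadSharingSolution(
        forces=forces,
        at_upper_bound=forces >= ub - 1e-9,
        torque_residual=residual,
        objective_value=float(np.sum((forces * w) ** 2)),
        achieved_torque=achieved,
    )


def solve_min_sum_squares(
    moment_arms: Sequence[float],
    q: float,
    lb: Sequence[float],
    ub: Sequence[float],
) -> LoadSharingSolution:
    """Classical criterion: minimize the sum of squared muscle forces."""
    return solve_fatigue_weighted(moment_arms, q, lb, ub, weights=None)


def solution_activations(
    solution: LoadSharingSolution,
    model: MusculoskeletalModel,
    fibers: List[FiberState],
    mf_pct: Optional[Sequence[float]] = None,
    curves: HillCurves = DEFAULT_CURVES,
) -> np.ndarray:
    """Back-compute per-muscle activations for a load-sharing solution.

    ``mf_pct`` (fatigued percentage per muscle) makes a = 1 correspond to
    the fatigue-reduced ceiling, matching the session coupling loop.
    """
    mf = np.zeros(len(model.muscles)) if mf_pct is None else np.asarray(mf_pct, float)
    acts = np.empty(len(model.muscles))
    for i, (m, fib) in enumerate(zip(model.muscles, fibers)):
        acts[i] = activation_from_force(
            m, fib, float(solution.forces[i]), curves=curves, mf_pct=float(mf[i]),
            tol=1e-5,
        )
    solution.activations = acts
    return acts
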