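"""Rigid-tendon Hill-type musculotendon mechanics.

Force along the tendon is ``F_MT = (F_CE + F_PE) cos(alpha)`` with the
contractile element ``F_CE = F0M * a * f_l(l_norm) * f_v(v_norm)`` and the
passive element ``F_PE = F0M * f_PE(l_norm)``.  Under the rigid-tendon
assumption the fiber state follows directly from joint kinematics, and
excitation equals activation (no activation dynamics).

Dimensionless curve shapes (the literature offers many; these are standard
smooth choices satisfying the qualitative constraints — f_l a symmetric bell
peaking at the optimal length, f_v a Hill hyperbola vanishing at maximal
shortening with an eccentric plateau, f_PE zero at or below optimal length
and rising exponentially above it):

* ``f_l(l) = exp(-((l - 1)/gamma)^2)``, gamma = 0.45;
* shortening (v_norm in [-1, 0]): ``f_v = (1 + v)/(1 - v/a_f)``, a_f = 0.25;
  lengthening: ``f_v = f_ecc - (f_ecc - 1) exp(-v/b)`` with b chosen for a
  continuous slope at v = 0 and plateau f_ecc = 1.4;
* ``f_PE(l) = (exp(k_pe (l - 1)/e0) - 1)/(exp(k_pe) - 1)`` for l > 1,
  k_pe = 4, e0 = 0.6 (f_PE = 1 at 60% passive strain), else 0.

All shape constants are overridable through :class:`HillCurves`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import MusculotendonParameters


@dataclass(frozen=True)
class HillCurves:
    """Shape constants of the dimensionless Hill curves."""

    gamma: float = 0.45  # force-length bell width
    a_f: float = 0.25  # force-velocity curvature (shortening)
    f_ecc_max: float = 1.4  # eccentric force plateau
    k_pe: float = 4.0  # passive exponential shape
    e0: float = 0.6  # passive strain at which f_PE = 1
    v_max_factor: float = 10.0  # max shortening velocity, in l0M per second

    @property
    def _b_ecc(self) -> float:
        # slope-matching constant: concentric slope at v=0 is 1 + 1/a_f
        return (self.f_ecc_max - 1.0) / (1.0 + 1.0 / self.a_f)


DEFAULT_CURVES = HillCurves()


@dataclass(frozen=True)
class FiberState:
    """Instantaneous fiber kinematics of one muscle."""

    lM: float  # fiber length (m)
    vM: float  # fiber velocity (m/s, lengthening positive)
    alpha: float  # pennation angle (rad)
    l_norm: float  # lM / l0M
    v_norm: float  # vM / (v_max_factor * l0M)


@dataclass(frozen=True)
class ForceBounds:
    """Physiological force bounds along the tendon (N)."""

    f_min: float
    f_max: float

    def __post_init__(self) -> None:
        if not (0 <= self.f_min <= self.f_max + 1e-12):
            raise ValueError(f"invalid bounds: [{self.f_min}, {self.f_max}]")


def force_length_active(l_norm, curves: HillCurves = DEFAULT_CURVES):
    """Active force-length bell: 1 at optimal length, symmetric decay."""
    l_norm = np.asarray(l_norm, dtype=float)
    out = np.exp(-(((l_norm - 1.0) / curves.gamma) ** 2))
    return out if out.ndim else float(out)


def force_velocity(v_norm, curves: HillCurves = DEFAULT_CURVES):
    """Force-velocity factor: 1 isometric, 0 at maximal shortening."""
    v = np.asarray(v_norm, dtype=float)
    shortening = np.clip(v, -1.0, 0.0)
    con = (1.0 + shortening) / (1.0 - shortening / curves.a_f)
    ecc = curves.f_ecc_max - (curves.f_ecc_max - 1.0) * np.exp(
        -np.maximum(v, 0.0) / curves._b_ecc
    )
    out = np.where(v < 0, con, ecc)
    return out if out.ndim else float(out)


def force_length_passive(l_norm, curves: HillCurves = DEFAULT_CURVES):
    """Passive force-length: zero at or below optimal length, then rising."""
    l_norm = np.asarray(l_norm, dtype=float)
    strain = np.maximum(l_norm - 1.0, 0.0)
    out = np.expm1(curves.k_pe * strain / curves.e0) / math.expm1(curves.k_pe)
    return out if out.ndim else float(out)


def fiber_state_rigid_tendon(
    muscle: MusculotendonParameters,
    lmt: float,
    vmt: float = 0.0,
    curves: HillCurves = DEFAULT_CURVES,
) -> FiberState:
    """Fiber kinematics from musculotendon kinematics with a rigid tendon.

    The tendon length is held at its slack value, so the fiber spans
    ``lMT - lST`` along the tendon line; a constant-thickness pennation
    model (``lM sin(alpha) = l0M sin(alpha0)``) gives the instantaneous
    pennation, and the fiber velocity is the along-tendon velocity
    projected onto the fiber, ``vM = vMT cos(alpha)``.
    """
    proj = lmt - muscle.lST
    if proj <= 0:
        raise ValueError(
            f"{muscle.name}: musculotendon length {lmt:.4f} m does not exceed "
            f"tendon slack length {muscle.lST:.4f} m (geometry infeasible)"
        )
    h = muscle.l0M * math.sin(muscle.alpha0)
    lm = math.hypot(proj, h)
    alpha = math.atan2(h, proj)
    vm = vmt * math.cos(alpha)
    v_max = curves.v_max_factor * muscle.l0M
    return FiberState(
        lM=lm, vM=vm, alpha=alpha, l_norm=lm / muscle.l0M, v_norm=vm / v_max
    )


def force_bounds(
    muscle: MusculotendonParameters,
    fiber: FiberState,
    curves: HillCurves = DEFAULT_CURVES,
) -> ForceBounds:
    """Instantaneous minimum (a=0) and maximum (a=1) musculotendon forces."""
    cos_a = math.cos(fiber.alpha)
    f_pe = force_length_passive(fiber.l_norm, curves)
    f_lv = force_length_active(fiber.l_norm, curves) * force_velocity(
        fiber.v_norm, curves
    )
    return ForceBounds(
        f_min=f_pe * muscle.F0M * cos_a,
        f_max=(f_lv + f_pe) * muscle.F0M * cos_a,
    )


def activation_from_force(
    muscle: MusculotendonParameters,
    fiber: FiberState,
    f_mt: float,
    curves: HillCurves = DEFAULT_CURVES,
    mf_pct: float = 0.0,
    tol: float = 1e-6,
) -> float:
    """Back-compute the activation that yields a given musculotendon force.

    ``a = (F_MT / cos(alpha) - F_PE) / F_CE,max`` where ``F_CE,max`` is the
    a=1 contractile force at the current fiber state, reduced by the
    fatigued motor-unit fraction ``mf_pct`` (percent) when the muscle is
    fatigued — so a = 1 means "all currently recruitable units active".
    Forces outside the physiological bounds beyond a relative tolerance
    raise; small excursions are clamped.
    """
    cos_a = math.cos(fiber.alpha)
    f_pe = force_length_passive(fiber.l_norm, curves) * muscle.F0M
    f_ce_max = (
        force_length_active(fiber.l_norm, curves)
        * force_velocity(fiber.v_norm, curves)
        * muscle.F0M
        * (100.0 - mf_pct)
        / 100.0
    )
    if f_ce_max <= 0:
        # no contractile capacity: only the passive force is admissible
        if abs(f_mt - f_pe * cos_a) <= tol * max(1.0, abs(f_pe * cos_a)):
            return 0.0
        raise ValueError(
            f"{muscle.name}: force {f_mt:.3f} N infeasible with zero "
            "contractile capacity"
        )
    a = (f_mt / cos_a - f_pe) / f_ce_max
    slack = tol * max(1.0, f_ce_max)
    if a < -slack / f_ce_max - tol or a > 1.0 + slack / f_ce_max + tol:
        raise ValueError(
            f"{muscle.name}: force {f_mt:.3f} N outside physiological bounds "
            f"(activation {a:.4f})"
        )
    return float(min(max(a, 0.0), 1.0))
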