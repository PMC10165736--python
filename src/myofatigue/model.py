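"""Musculoskeletal model data structures and model-variant construction.

The elbow is treated as a single planar flexion/extension degree of freedom
actuated by a redundant set of musculotendon units.  Geometry (musculotendon
length and moment arm as functions of the elbow angle) is supplied as lookup
tables with cubic interpolation; the angle convention is degrees, 0 deg =
full extension, flexion positive.

Three model variants are supported:

* ``7M`` — individual muscles (the anatomical set),
* ``2M`` — one condensed flexor and one condensed extensor actuator,
* ``14M`` — each muscle split into a fatigue-resistant fiber group (A,
  type I + IIa) and a fast-fatigable group (B, type IIx).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
from scipy.interpolate import CubicSpline


@dataclass(frozen=True)
class FatigueParameters:
    """Three-compartment fatigue coefficients for one muscle (or fiber group).

    Parameters
    ----------
    F : float
        Fatigue rate (1/s): flow rate from the active to the fatigued pool.
    R : float
        Recovery rate (1/s): flow rate from the fatigued to the resting pool.
    r_rest : float
        Dimensionless rest multiplier (>= 1) applied to ``R`` whenever the
        target load is zero, accelerating recovery during rest periods.
    """

    F: float
    R: float
    r_rest: float = 1.0

    def __post_init__(self) -> None:
        if not (self.F > 0):
            raise ValueError(f"fatigue rate F must be > 0, got {self.F}")
        if not (self.R > 0):
            raise ValueError(f"recovery rate R must be > 0, got {self.R}")
        if not (self.r_rest >= 1):
            raise ValueError(f"rest multiplier r_rest must be >= 1, got {self.r_rest}")


#: Group-A (type I + IIa) coefficients: chosen to produce a reduced fatigue
#: (~25% force decay after 120 s at TL = 100%) and essentially full
#: regeneration after a few minutes of rest.
GROUP_A_FATIGUE = FatigueParameters(F=0.004, R=0.01, r_rest=1.0)

#: Group-B recovery coefficient is fixed at 0.001 1/s to represent the
#: anaerobic functioning of type IIx fibers; F and r_rest are subject-fitted.
GROUP_B_RECOVERY = 0.001


@dataclass(frozen=True)
class MusculotendonParameters:
    """Constant parameters of one musculotendon actuator."""

    name: str
    role: str  # "flexor" | "extensor"
    F0M: float  # maximum isometric force (N)
    l0M: float  # optimal fiber length (m)
    lST: float  # tendon slack length (m)
    alpha0: float = 0.0  # pennation angle at optimal fiber length (rad)
    fiber_group: str = "undivided"  # "A" | "B" | "undivided"
    fatigue: FatigueParameters = GROUP_A_FATIGUE

    def __post_init__(self) -> None:
        if self.role not in ("flexor", "extensor"):
            raise ValueError(f"{self.name}: role must be flexor|extensor, got {self.role}")
        if not (self.F0M >= 0):
            raise ValueError(f"{self.name}: F0M must be >= 0, got {self.F0M}")
        if not (self.l0M > 0):
            raise ValueError(f"{self.name}: l0M must be > 0, got {self.l0M}")
        if not (self.lST >= 0):
            raise ValueError(f"{self.name}: lST must be >= 0, got {self.lST}")
        if not (0 <= self.alpha0 < math.pi / 2):
            raise ValueError(f"{self.name}: alpha0 must lie in [0, pi/2), got {self.alpha0}")
        if self.fiber_group not in ("A", "B", "undivided"):
            raise ValueError(f"{self.name}: fiber_group must be A|B|undivided")


class GeometryModel:
    """Tabulated musculotendon lengths and moment arms over elbow angle.

    One shared angle grid (degrees) with per-muscle length (m) and moment
    arm (m) columns; cubic-spline interpolation in between.  Moment arms are
    signed: positive for flexors, negative for extensors, consistent with
    ``J = -d lMT / d phi`` (phi in radians).
    """

    def __init__(
        self,
        phi_deg: Sequence[float],
        lmt_m: Mapping[str, Sequence[float]],
        moment_arm_m: Mapping[str, Sequence[float]],
    ) -> None:
        phi = np.asarray(phi_deg, dtype=float)
        if phi.ndim != 1 or phi.size < 4:
            raise ValueError("geometry grid needs at least 4 angle samples")
        if not np.all(np.diff(phi) > 0):
            raise ValueError("geometry angle grid must be strictly increasing")
        if set(lmt_m) != set(moment_arm_m):
            raise ValueError("lMT and moment-arm tables must cover the same muscles")
        self.phi_deg = phi
        self.lmt_tables: Dict[str, np.ndarray] = {
            k: np.asarray(v, float) for k, v in lmt_m.items()
        }
        self.arm_tables: Dict[str, np.ndarray] = {
            k: np.asarray(v, float) for k, v in moment_arm_m.items()
        }
        for name, col in self.lmt_tables.items():
            if col.shape != phi.shape or self.arm_tables[name].shape != phi.shape:
                raise ValueError(f"{name}: geometry column length mismatch")
        self._lmt_splines = {k: CubicSpline(phi, v) for k, v in self.lmt_tables.items()}
        self._arm_splines = {k: CubicSpline(phi, v) for k, v in self.arm_tables.items()}

    @property
    def muscle_names(self) -> List[str]:
        return sorted(self.lmt_tables)

    def lmt(self, name: str, phi_deg: float | np.ndarray) -> float | np.ndarray:
        """Musculotendon length (m) at elbow angle phi (deg)."""
        return self._lmt_splines[name](phi_deg)

    def moment_arm(self, name: str, phi_deg: float | np.ndarray) -> float | np.ndarray:
        """Signed moment arm (m) at elbow angle phi (deg)."""
        return self._arm_splines[name](phi_deg)

    def vmt(self, name: str, phi_deg: float, phidot_deg_s: float) -> float:
        """Musculotendon velocity (m/s, lengthening positive).

        With J = -d lMT/d phi (phi in rad), vMT = -J(phi) * phidot(rad/s).
        """
        return float(
            -self._arm_splines[name](phi_deg) * math.radians(phidot_deg_s)
        )

    def with_tables(
        self,
        lmt_m: Optional[Mapping[str, Sequence[float]]] = None,
        moment_arm_m: Optional[Mapping[str, Sequence[float]]] = None,
    ) -> "GeometryModel":
        return GeometryModel(
            self.phi_deg,
            lmt_m if lmt_m is not None else self.lmt_tables,
            moment_arm_m if moment_arm_m is not None else self.arm_tables,
        )

    def consistency_error(self, name: str) -> float:
        """Max relative error of J(phi) vs -d lMT/d phi(rad) at interior points."""
        phi = self.phi_deg[2:-2]
        d_lmt = self._lmt_splines[name].derivative()(phi)  # m/deg
        implied = -d_lmt / math.radians(1.0)  # m/rad
        arm = self._arm_splines[name](phi)
        scale = np.maximum(np.abs(arm), 1e-6)
        return float(np.max(np.abs(implied - arm) / scale))


@dataclass
class MusculoskeletalModel:
    """A set of musculotendon actuators plus their shared geometry."""

    muscles: List[MusculotendonParameters]
    geometry: GeometryModel
    variant_tag: str = "7M"  # "2M" | "7M" | "14M"

    def __post_init__(self) -> None:
        names = [m.name for m in self.muscles]
        if len(set(names)) != len(names):
            raise ValueError("muscle names must be unique")
        roles = {m.role for m in self.muscles}
        if roles != {"flexor", "extensor"}:
            raise ValueError("model needs at least one flexor and one extensor")
        missing = [n for n in names if n not in self.geometry.lmt_tables]
        if missing:
            raise ValueError(f"geometry tables missing for: {missing}")

    @property
    def muscle_names(self) -> List[str]:
        return [m.name for m in self.muscles]

    def muscle(self, name: str) -> MusculotendonParameters:
        for m in self.muscles:
            if m.name == name:
                return m
        raise KeyError(name)

    def flexors(self) -> List[MusculotendonParameters]:
        return [m for m in self.muscles if m.role == "flexor"]

    def extensors(self) -> List[MusculotendonParameters]:
        return [m for m in self.muscles if m.role == "extensor"]


@dataclass(frozen=True)
class FiberSplitSpec:
    """How a muscle's maximal force is apportioned between fiber groups.

    ``pct_decay`` is the percentage force decay observed during a sustained
    maximal calibration effort; 90% of it (``group_b_share``) is attributed
    to the fast-fatigable group B, the remainder to group A.
    """

    pct_decay: float
    group_b_share: float = 0.9

    def __post_init__(self) -> None:
        if not (0 <= self.pct_decay <= 100):
            raise ValueError(f"pct_decay must lie in [0, 100], got {self.pct_decay}")
        if not (0 <= self.group_b_share <= 1):
            raise ValueError("group_b_share must lie in [0, 1]")

    @property
    def b_fraction(self) -> float:
        """Fraction of F0M assigned to group B."""
        return self.pct_decay * self.group_b_share / 100.0


def scale_length_parameters(
    model: MusculoskeletalModel,
    subject_lmt0: Mapping[str, float],
    reference_lmt0: Mapping[str, float],
) -> MusculoskeletalModel:
    """Scale l0M and lST per muscle by the outstretched-arm length ratio.

    The scale factor for each muscle is ``s = subject_lMT0 / reference_lMT0``,
    the ratio between the subject's musculotendon length with the arm
    outstretched and the reference model's in the same posture.  Only the
    two length parameters change.
    """
    scaled = []
    for m in model.muscles:
        try:
            subj = subject_lmt0[m.name]
            ref = reference_lmt0[m.name]
        except KeyError as exc:
            raise KeyError(f"missing outstretched-arm length for muscle {exc}") from exc
        if not (subj > 0 and ref > 0):
            raise ValueError(
                f"{m.name}: outstretched-arm lengths must be positive "
                f"(subject={subj}, reference={ref})"
            )
        s = subj / ref
        scaled.append(replace(m, l0M=m.l0M * s, lST=m.lST * s))
    return MusculoskeletalModel(scaled, model.geometry, model.variant_tag)


def aggregate_to_joint_actuators(model: MusculoskeletalModel) -> MusculoskeletalModel:
    """Condense a 7M model into one flexor and one extensor actuator (2M).

    Per side, l0M, lST, alpha0, the fatigue coefficients and the geometry
    tables are arithmetic means over that side's muscles; F0M is the sum.
    """
    if model.variant_tag != "7M":
        raise ValueError(
            f"aggregation expects a 7M model, got variant {model.variant_tag!r}"
        )
    lmt: Dict[str, np.ndarray] = {}
    arm: Dict[str, np.ndarray] = {}
    actuators = []
    for role, name in (("flexor", "flexor"), ("extensor", "extensor")):
        group = [m for m in model.muscles if m.role == role]
        if not group:
            raise ValueError(f"cannot aggregate: no {role} muscles")
        fat = FatigueParameters(
            F=float(np.mean([m.fatigue.F for m in group])),
            R=float(np.mean([m.fatigue.R for m in group])),
            r_rest=float(np.mean([m.fatigue.r_rest for m in group])),
        )
        actuators.append(
            MusculotendonParameters(
                name=name,
                role=role,
                F0M=float(sum(m.F0M for m in group)),
                l0M=float(np.mean([m.l0M for m in group])),
                lST=float(np.mean([m.lST for m in group])),
                alpha0=float(np.mean([m.alpha0 for m in group])),
                fiber_group="undivided",
                fatigue=fat,
            )
        )
        lmt[name] = np.mean([model.geometry.lmt_tables[m.name] for m in group], axis=0)
        arm[name] = np.mean([model.geometry.arm_tables[m.name] for m in group], axis=0)
    geometry = GeometryModel(model.geometry.phi_deg, lmt, arm)
    return MusculoskeletalModel(actuators, geometry, "2M")


def split_fiber_types(
    model: MusculoskeletalModel,
    spec: FiberSplitSpec,
    group_a_fatigue: FatigueParameters = GROUP_A_FATIGUE,
    group_b_fatigue: FatigueParameters = FatigueParameters(
        F=0.05, R=GROUP_B_RECOVERY, r_rest=10.0
    ),
) -> MusculoskeletalModel:
    """Split each muscle into fiber groups A and B (7M -> 14M).

    F0M is apportioned as fractions so the pair sums to the original
    exactly: F0M_B = F0M * (pct_decay * 0.9) / 100, F0M_A = F0M - F0M_B.
    Geometry and length parameters are shared by both halves.
    """
    if model.variant_tag != "7M":
        raise ValueError(
            f"fiber split expects a 7M model, got variant {model.variant_tag!r}"
        )
    frac_b = spec.b_fraction
    muscles = []
    lmt: Dict[str, np.ndarray] = {}
    arm: Dict[str, np.ndarray] = {}
    for m in model.muscles:
        f0_b = m.F0M * frac_b
        f0_a = m.F0M - f0_b
        for suffix, f0, group, fat in (
            ("_A", f0_a, "A", group_a_fatigue),
            ("_B", f0_b, "B", group_b_fatigue),
        ):
            name = m.name + suffix
            muscles.append(
                replace(m, name=name, F0M=f0, fiber_group=group, fatigue=fat)
            )
            lmt[name] = model.geometry.lmt_tables[m.name]
            arm[name] = model.geometry.arm_tables[m.name]
    geometry = GeometryModel(model.geometry.phi_deg, lmt, arm)
    return MusculoskeletalModel(muscles, geometry, "14M")
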