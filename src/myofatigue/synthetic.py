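"""Synthetic subjects, elbow models, curl kinematics and MVC gauge traces.

Everything needed to exercise the pipeline is generated from code: a toy
planar elbow with a redundant muscle set, hammer-curl kinematics with the
corresponding inverse-dynamics torque, and strain-gauge-like MVC force
traces whose fatigue decay comes from known three-compartment parameters
(so fitting routines can be validated by parameter recovery).  All
generators are pure functions of their parameters and a seed.

The toy geometry is built backwards from the moment arms: smooth flexor
arms peaking at mid-flexion (extensor arms negative, flatter), and the
musculotendon length integrated from ``lMT' = -J`` so the moment-arm /
length consistency constraint holds by construction.  Muscle constants are
drawn from ranges typical for adult elbow muscles (F0M 200-800 N, optimal
fiber lengths 8-16 cm).

The default protocol mirrors a high-intensity training session: a baseline
MVC triplet (8 s, to-failure, 6 s holds with 15 s rests), then 3 cycles of
3 sets of 10 hammer-curl repetitions with 90 s rests and an MVC triplet
(3 x 8 s, 6 s rests) after each cycle; the dumbbell is chosen to demand
65% of the subject's rested capacity at the 50 deg MVC posture.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import fatigue as fat
from .hill import DEFAULT_CURVES, HillCurves
from .model import FatigueParameters, GeometryModel, GROUP_A_FATIGUE, \
    MusculoskeletalModel, MusculotendonParameters
from .session import Protocol, Segment

G = 9.81  # m/s^2

#: Default "true" whole-muscle fatigue parameters of the synthetic subject,
#: in the mid-range of reported joint-level coefficients: noticeable decay
#: within a one-minute maximal effort and recovery over a few minutes of rest.
DEFAULT_SUBJECT_FATIGUE = FatigueParameters(F=0.01, R=0.005, r_rest=15.0)


@dataclass
class SyntheticSubject:
    """A reproducible synthetic subject: model, dynamics and true parameters."""

    model: MusculoskeletalModel
    fatigue_true: FatigueParameters = DEFAULT_SUBJECT_FATIGUE
    dumbbell_kg: float = 8.0
    forearm_mass_kg: float = 1.8  # forearm + hand
    forearm_com_m: float = 0.18  # elbow-to-COM distance
    hand_m: float = 0.33  # elbow-to-hand-COM distance (load application)
    forearm_inertia_kgm2: float = 0.065  # about the elbow
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("dumbbell_kg", "forearm_mass_kg", "forearm_com_m",
                     "hand_m", "forearm_inertia_kgm2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def make_toy_elbow_model(
    n_flexors: int = 4,
    n_extensors: int = 3,
    seed: int = 0,
    phi_max_deg: float = 150.0,
    n_grid: int = 61,
) -> MusculoskeletalModel:
    """Deterministic toy elbow model with a redundant muscle set.

    Flexor moment arms are raised-sine profiles peaking mid-flexion;
    extensor arms are negative with mild angle dependence.  Arm magnitudes
    scale with each muscle's optimal fiber length so normalized fiber
    lengths stay within the physiological bell over the full angle range.
    """
    if n_flexors < 1 or n_extensors < 1:
        raise ValueError("need at least one flexor and one extensor")
    rng = np.random.default_rng(seed)
    phi = np.linspace(0.0, phi_max_deg, n_grid)
    phi_rad = np.radians(phi)
    lmt: Dict[str, np.ndarray] = {}
    arm: Dict[str, np.ndarray] = {}
    muscles = []

    def build(name: str, role: str) -> None:
        f0 = rng.uniform(200.0, 800.0)
        l0 = rng.uniform(0.08, 0.16)
        lst = rng.uniform(1.4, 2.2) * l0
        alpha0 = math.radians(rng.uniform(0.0, 12.0))
        if role == "flexor":
            peak = rng.uniform(0.22, 0.32) * l0
            base = rng.uniform(0.04, 0.08) * l0
            j = base + (peak - base) * np.sin(np.pi * phi / phi_max_deg) ** 2
        else:
            peak = rng.uniform(0.12, 0.20) * l0
            base = rng.uniform(0.08, 0.12) * l0
            j = -(base + (peak - base) * 0.5 * (1 + np.cos(np.pi * phi / phi_max_deg)))
        # lMT' (per rad) = -J; anchor the optimal fiber length at 50 deg
        delta = np.concatenate(
            ([0.0], np.cumsum((j[1:] + j[:-1]) / 2 * np.diff(phi_rad)))
        )
        lmt_col = -delta
        anchor = np.interp(50.0, phi, lmt_col)
        offset = lst + (l0 if role == "flexor" else 0.95 * l0) * math.cos(alpha0) - anchor
        lmt_col = lmt_col + offset
        muscles.append(
            MusculotendonParameters(
                name=name, role=role, F0M=f0, l0M=l0, lST=lst, alpha0=alpha0,
                fatigue=GROUP_A_FATIGUE,
            )
        )
        lmt[name] = lmt_col
        arm[name] = j

    for i in range(n_flexors):
        build(f"flexor{i + 1}", "flexor")
    for i in range(n_extensors):
        build(f"extensor{i + 1}", "extensor")
    geometry = GeometryModel(phi, lmt, arm)
    return MusculoskeletalModel(muscles, geometry, "7M")


def make_subject(
    seed: int = 0,
    fatigue_true: FatigueParameters = DEFAULT_SUBJECT_FATIGUE,
    n_flexors: int = 4,
    n_extensors: int = 3,
) -> SyntheticSubject:
    """A full synthetic subject with the toy model and true fatigue values."""
    from dataclasses import replace as _replace

    model = make_toy_elbow_model(n_flexors, n_extensors, seed)
    model = MusculoskeletalModel(
        [_replace(m, fatigue=fatigue_true) for m in model.muscles],
        model.geometry, model.variant_tag,
    )
    return SyntheticSubject(model=model, fatigue_true=fatigue_true, seed=seed)


def gravity_torque(subject: SyntheticSubject, phi_deg) -> np.ndarray:
    """Static flexion torque (N*m) holding the dumbbell at angle phi.

    Upper arm vertical, forearm at ``phi`` from full (hanging) extension:
    the moment arm of gravity about the elbow peaks with the forearm
    horizontal (phi = 90 deg), so the gravitational term scales with
    sin(phi).
    """
    phi_rad = np.radians(np.asarray(phi_deg, dtype=float))
    coef = (
        subject.forearm_mass_kg * subject.forearm_com_m
        + subject.dumbbell_kg * subject.hand_m
    )
    out = coef * G * np.sin(phi_rad)
    return out if out.ndim else float(out)


def generate_curl_motion(
    subject: SyntheticSubject,
    reps: int = 10,
    period_s: float = 3.0,
    phi_range_deg: tuple = (20.0, 130.0),
    dt: float = 0.01,
) -> pd.DataFrame:
    """Hammer-curl kinematics and inverse-dynamics torque.

    The elbow angle follows a raised cosine between the range endpoints
    (one up-down cycle per repetition); the net flexion torque is the
    planar rigid-body result
    ``Q = (I_f + m_d L^2) phi_dd + (m_f d_f + m_d L) g sin(phi)``.
    """
    if period_s <= 0 or reps < 1:
        raise ValueError("reps >= 1 and period_s > 0 required")
    lo, hi = phi_range_deg
    t = np.arange(0.0, reps * period_s + dt / 2, dt)
    omega = 2 * np.pi / period_s
    phi = lo + (hi - lo) * 0.5 * (1 - np.cos(omega * t))
    phidot = (hi - lo) * 0.5 * omega * np.sin(omega * t) * 1.0  # deg/s
    phidd = (hi - lo) * 0.5 * omega**2 * np.cos(omega * t)  # deg/s^2
    inertia = (
        subject.forearm_inertia_kgm2 + subject.dumbbell_kg * subject.hand_m**2
    )
    q = inertia * np.radians(phidd) + gravity_torque(subject, phi)
    return pd.DataFrame(
        {"t_s": t, "phi_deg": phi, "phidot_deg_s": phidot, "Q_Nm": q}
    )


def mvc_posture_capacity(
    subject: SyntheticSubject, phi_deg: float = 50.0,
    curves: HillCurves = DEFAULT_CURVES,
) -> float:
    """Rested maximal flexion moment (N*m) at the MVC posture."""
    from .session import available_max_moment_static

    return available_max_moment_static(subject.model, phi_deg, curves)


def generate_mvc_trace(
    subject: SyntheticSubject,
    duration_s: float = 60.0,
    noise_sd_pct: float = 0.0,
    seed: int = 0,
    dt: float = 0.01,
    phi_deg: float = 50.0,
    params: Optional[FatigueParameters] = None,
) -> pd.DataFrame:
    """Strain-gauge-like force trace of a sustained maximal effort.

    The baseline force is the model capacity at the MVC posture divided by
    the mean flexor moment arm (gauge reads force, not moment); decay
    follows the subject's true compartment parameters at TL = 100, with
    additive i.i.d. Gaussian noise of ``noise_sd_pct`` percent of baseline.
    Columns: t_s, force_N, force_norm.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    params = params or subject.fatigue_true
    rng = np.random.default_rng(seed)
    traj = fat.simulate_profile(lambda t: 100.0, params, duration_s, dt)
    capacity = (100.0 - traj["Mf"].to_numpy()) / 100.0
    arms = [
        float(subject.model.geometry.moment_arm(m.name, phi_deg))
        for m in subject.model.flexors()
    ]
    base_force = mvc_posture_capacity(subject, phi_deg) / float(np.mean(arms))
    force = base_force * capacity
    if noise_sd_pct > 0:
        force = force + rng.normal(
            0.0, noise_sd_pct / 100.0 * base_force, size=force.shape
        )
    return pd.DataFrame(
        {"t_s": traj["t_s"], "force_N": force, "force_norm": force / base_force}
    )


def default_protocol(
    cycles: int = 3,
    sets_per_cycle: int = 3,
    reps: int = 10,
    cadence_s: float = 3.0,
    rest_s: float = 90.0,
    mvc0_failure_s: float = 60.0,
) -> Protocol:
    """The benchmark training-session protocol.

    A baseline MVC triplet (8 s / to-failure / 6 s with 15 s rests), then
    ``cycles`` cycles of ``sets_per_cycle`` curl sets with ``rest_s`` rests,
    each cycle closed by an MVC triplet (3 x 8 s with 6 s rests).
    """
    segs = [
        Segment(kind="mvc", duration_s=8.0), Segment(kind="rest", duration_s=15.0),
        Segment(kind="mvc", duration_s=mvc0_failure_s),
        Segment(kind="rest", duration_s=15.0),
        Segment(kind="mvc", duration_s=6.0),
        Segment(kind="rest", duration_s=420.0),  # full recovery before training
    ]
    for _ in range(cycles):
        for _ in range(sets_per_cycle):
            segs.append(Segment(kind="curl_set", reps=reps, cadence_s=cadence_s))
            segs.append(Segment(kind="rest", duration_s=rest_s))
        for k in range(3):
            segs.append(Segment(kind="mvc", duration_s=8.0))
            if k < 2:
                segs.append(Segment(kind="rest", duration_s=6.0))
        segs[-1] = Segment(kind="mvc", duration_s=8.0, cycle_end=True)
    return Protocol(segments=segs)


def pick_dumbbell_mass(
    subject: SyntheticSubject, fraction: float = 0.65, phi_deg: float = 50.0
) -> float:
    """Dumbbell mass demanding ``fraction`` of the rested capacity at the
    MVC posture (gravitational torque only)."""
    q_target = fraction * mvc_posture_capacity(subject, phi_deg)
    coef = q_target / (G * math.sin(math.radians(phi_deg)))
    mass = (coef - subject.forearm_mass_kg * subject.forearm_com_m) / subject.hand_m
    if mass <= 0:
        raise ValueError("subject too weak for the requested load fraction")
    return mass


def generate_session_fixture(
    subject: SyntheticSubject,
    out_dir: Optional[str] = None,
    load_fraction: float = 0.65,
) -> Dict:
    """A complete session: protocol, curl motion, and baseline MVC traces.

    The dumbbell mass is set to ``load_fraction`` of the subject's rested
    MVC-posture capacity.  When ``out_dir`` is given the artifacts are also
    written to disk (protocol YAML, motion CSV, MVC trace CSVs).
    """
    from dataclasses import replace as _replace

    mass = pick_dumbbell_mass(subject, load_fraction)
    loaded = _replace(subject, dumbbell_kg=mass)
    protocol = default_protocol()
    motion = generate_curl_motion(loaded)
    mvc0_2 = generate_mvc_trace(loaded, duration_s=60.0, noise_sd_pct=2.0,
                                seed=subject.seed + 1)
    mvc0_3 = generate_mvc_trace(loaded, duration_s=6.0, noise_sd_pct=2.0,
                                seed=subject.seed + 2)
    artifacts = {
        "protocol": protocol,
        "motion": motion,
        "mvc0_2": mvc0_2,
        "mvc0_3": mvc0_3,
        "dumbbell_kg": mass,
    }
    if out_dir is not None:
        import pathlib

        from . import io as mio

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        mio.save_protocol(protocol, out / "protocol.yaml")
        mio.write_motion_csv(motion, out / "curl_motion.csv")
        mio.write_trace_csv(mvc0_2, out / "mvc0_2.csv")
        mio.write_trace_csv(mvc0_3, out / "mvc0_3.csv")
        mio.save_model_yaml(loaded.model, out / "model.yaml")
    return artifacts
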