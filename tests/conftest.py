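import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import myofatigue as mf

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_model():
    """Deterministic 4-flexor / 3-extensor toy elbow model."""
    return mf.make_toy_elbow_model(4, 3, seed=0)


@pytest.fixture(scope="session")
def subject():
    """Synthetic subject with known fatigue parameters."""
    return mf.make_subject(seed=0)


@pytest.fixture()
def small_model():
    """Hand-built 2-flexor / 1-extensor model with simple smooth geometry."""
    phi = np.linspace(0.0, 150.0, 31)
    phi_rad = np.radians(phi)

    def tables(arm_fn):
        j = arm_fn(phi)
        delta = np.concatenate(
            ([0.0], np.cumsum((j[1:] + j[:-1]) / 2 * np.diff(phi_rad)))
        )
        return j, -delta

    lmt, arm = {}, {}
    muscles = []
    specs = [
        ("f1", "flexor", 400.0, 0.10, 0.18,
         lambda p: 0.020 + 0.015 * np.sin(np.pi * p / 150.0) ** 2),
        ("f2", "flexor", 600.0, 0.14, 0.22,
         lambda p: 0.025 + 0.012 * np.sin(np.pi * p / 150.0) ** 2),
        ("e1", "extensor", 500.0, 0.12, 0.20,
         lambda p: -(0.018 + 0.0 * p)),
    ]
    for name, role, f0, l0, lst, arm_fn in specs:
        j, dl = tables(arm_fn)
        anchor = np.interp(50.0, phi, dl)
        lmt[name] = dl - anchor + lst + (l0 if role == "flexor" else 0.9 * l0)
        arm[name] = j
        muscles.append(
            mf.MusculotendonParameters(name=name, role=role, F0M=f0, l0M=l0, lST=lst)
        )
    geometry = mf.GeometryModel(phi, lmt, arm)
    return mf.MusculoskeletalModel(muscles, geometry, "7M")
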