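"""Coupled session simulation: timestep loop, capacity, failure, protocols."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

import myofatigue as mf
from myofatigue import fatigue as fat
from myofatigue.model import FatigueParameters
from myofatigue.session import JointSample, Protocol, Segment


def one_muscle_model(F0=600.0, lst=0.20, l0=0.10, arm=0.03):
    """One flexor with a constant arm (plus a weak extensor for validity),
    posture chosen so neither muscle has passive force."""
    phi = np.linspace(0.0, 150.0, 16)
    phi_rad = np.radians(phi)
    lmt_f = lst + l0 - arm * (phi_rad - np.radians(50.0))
    lmt_e = 0.2 + 0.9 * 0.1 + 0.015 * (phi_rad - np.radians(50.0))
    geometry = mf.GeometryModel(
        phi,
        {"flex": lmt_f, "ext": lmt_e},
        {"flex": np.full_like(phi, arm), "ext": np.full_like(phi, -0.015)},
    )
    muscles = [
        mf.MusculotendonParameters(name="flex", role="flexor", F0M=F0, l0M=l0,
                                   lST=lst, fatigue=mf.GROUP_A_FATIGUE),
        mf.MusculotendonParameters(name="ext", role="extensor", F0M=300.0,
                                   l0M=0.1, lST=0.2, fatigue=mf.GROUP_A_FATIGUE),
    ]
    return mf.MusculoskeletalModel(muscles, geometry, "7M")


class TestRunTimestep:
    def test_zero_torque_rested_model_stays_rested(self, small_model):
        states = fat.CompartmentState.rested(len(small_model.muscles))
        sample = JointSample(t=0.0, phi=50.0, phidot=0.0, q=0.0)
        sol, new = mf.run_timestep(small_model, states, sample, 0.01)
        fibers = [
            mf.fiber_state_rigid_tendon(
                m, float(small_model.geometry.lmt(m.name, 50.0)), 0.0
            )
            for m in small_model.muscles
        ]
        f_min = [mf.force_bounds(m, f).f_min
                 for m, f in zip(small_model.muscles, fibers)]
        np.testing.assert_allclose(sol.forces, f_min, atol=1e-9)
        np.testing.assert_allclose(sol.activations, 0.0, atol=1e-9)
        np.testing.assert_allclose(new.mf, 0.0, atol=1e-12)

    def test_compensatory_recruitment_under_constant_load(self, small_model):
        """As Mf accumulates the same torque needs higher activation."""
        cap = mf.available_max_moment_static(small_model, 50.0)
        states = fat.CompartmentState.rested(len(small_model.muscles))
        sample = JointSample(t=0.0, phi=50.0, phidot=0.0, q=0.5 * cap)
        acts = []
        for k in range(1500):
            sol, states = mf.run_timestep(small_model, states, sample, 0.05)
            if k % 300 == 0:
                acts.append(float(np.max(sol.activations)))
        assert all(b > a for a, b in zip(acts, acts[1:]))

    def test_single_muscle_target_load_closed_form(self):
        """With one flexor, TL = 100 Q/(J f_max(t)) exactly."""
        model = one_muscle_model()
        q = 0.5 * mf.available_max_moment_static(model, 50.0)
        states = fat.CompartmentState.rested(2)
        sample = JointSample(t=0.0, phi=50.0, phidot=0.0, q=q)
        arm = float(model.geometry.moment_arm("flex", 50.0))
        for _ in range(200):
            fib = mf.fiber_state_rigid_tendon(
                model.muscles[0], float(model.geometry.lmt("flex", 50.0)), 0.0
            )
            s = fat.CompartmentState.__new__(fat.CompartmentState)
            s.mf = states.mf[0]
            ceiling = mf.fatigued_force_ceiling(model.muscles[0], fib, s)
            expected_tl = 100.0 * q / (arm * ceiling)
            sol, states = mf.run_timestep(model, states, sample, 0.05)
            assert 100.0 * sol.activations[0] == pytest.approx(expected_tl, rel=1e-6)


class TestAvailableMaxMoment:
    def test_rested_matches_direct_bound_sum(self, small_model):
        phi = 50.0
        got = mf.available_max_moment_static(small_model, phi)
        expected = 0.0
        for m in small_model.muscles:
            fib = mf.fiber_state_rigid_tendon(
                m, float(small_model.geometry.lmt(m.name, phi)), 0.0
            )
            b = mf.force_bounds(m, fib)
            arm = float(small_model.geometry.moment_arm(m.name, phi))
            expected += arm * (b.f_max if m.role == "flexor" else b.f_min)
        assert got == pytest.approx(expected)

    def test_half_fatigue_halves_capacity_without_passive(self):
        model = one_muscle_model()
        # extensor contributes no passive force at 50 deg (l_norm < 1)
        full = mf.available_max_moment_static(model, 50.0)
        states = fat.CompartmentState(
            np.zeros(2), np.full(2, 50.0), np.full(2, 50.0)
        )
        half = mf.available_max_moment_static(model, 50.0, states=states)
        assert half == pytest.approx(full / 2)

    def test_monotone_nonincreasing_in_fatigue(self, small_model):
        vals = []
        for mf_pct in (0.0, 20.0, 60.0, 95.0):
            n = len(small_model.muscles)
            states = fat.CompartmentState(
                np.zeros(n), np.full(n, 100.0 - mf_pct), np.full(n, mf_pct)
            )
            vals.append(
                mf.available_max_moment_static(small_model, 50.0, states=states)
            )
        assert all(b <= a + 1e-12 for a, b in zip(vals, vals[1:]))


class TestPredictFailure:
    def test_demand_above_rested_capacity_fails_immediately(self, small_model):
        cap = mf.available_max_moment_static(small_model, 50.0)
        pred = mf.predict_failure_time(small_model, 1.1 * cap, 50.0, dt=0.05)
        assert pred.time_s == 0.0 and not pred.censored

    def test_sub_asymptote_demand_is_censored(self):
        model = one_muscle_model()
        # group-A asymptote is 71.4% residual: 50% demand never fails
        cap = mf.available_max_moment_static(model, 50.0)
        pred = mf.predict_failure_time(model, 0.5 * cap, 50.0, dt=0.1,
                                       horizon_s=120.0)
        assert pred.censored

    def test_halving_fatigue_rate_extends_endurance(self):
        slow = one_muscle_model()
        fast_muscles = [
            replace(m, fatigue=FatigueParameters(0.008, 0.01, 1.0))
            for m in slow.muscles
        ]
        fast = mf.MusculoskeletalModel(fast_muscles, slow.geometry, "7M")
        cap = mf.available_max_moment_static(slow, 50.0)
        t_slow = mf.predict_failure_time(slow, 0.85 * cap, 50.0, dt=0.05,
                                         horizon_s=300.0)
        t_fast = mf.predict_failure_time(fast, 0.85 * cap, 50.0, dt=0.05,
                                         horizon_s=300.0)
        assert t_fast.time_s < t_slow.time_s

    def test_matches_single_muscle_compartment_oracle(self):
        """Full-loop failure equals a direct scalar 3CCr endurance
        computation at the equivalent target load, within one time step."""
        model = one_muscle_model()
        dt = 0.05
        cap = mf.available_max_moment_static(model, 50.0)
        q = 0.85 * cap
        pred = mf.predict_failure_time(model, q, 50.0, dt=dt, horizon_s=300.0)

        # oracle: the muscle sees TL = 100 q_frac / ((100 - Mf)/100); failure
        # when the fatigued ceiling falls below the demand
        p = model.muscles[0].fatigue
        q_frac = q / cap  # demand as a fraction of the rested ceiling
        state = fat.CompartmentState.rested()
        t, oracle_t = 0.0, None
        while t < 300.0:
            capacity = (100.0 - float(state.mf)) / 100.0
            if capacity < q_frac:
                oracle_t = t
                break
            tl = min(100.0 * q_frac / capacity, 100.0)
            state = fat.step(state, tl, p, dt)
            t += dt
        assert oracle_t is not None
        assert pred.time_s == pytest.approx(oracle_t, abs=dt)

    def test_fatigue_free_limit_reduces_to_static_optimization(self):
        """With a negligible fatigue rate the coupled loop reproduces the
        rested static-optimization solution at every step."""
        base = one_muscle_model()
        frozen = mf.MusculoskeletalModel(
            [replace(m, fatigue=FatigueParameters(1e-12, 0.01, 1.0))
             for m in base.muscles],
            base.geometry, "7M",
        )
        q = 0.5 * mf.available_max_moment_static(frozen, 50.0)
        states = fat.CompartmentState.rested(2)
        sample = JointSample(t=0.0, phi=50.0, phidot=0.0, q=q)
        first, states = mf.run_timestep(frozen, states, sample, 0.05)
        for _ in range(400):
            sol, states = mf.run_timestep(frozen, states, sample, 0.05)
        np.testing.assert_allclose(sol.forces, first.forces, rtol=1e-8)


class TestVariantConsistency:
    def test_2m_equals_summed_identical_7m_flexors(self):
        """Identical flexors sharing one geometry: the aggregated actuator
        carries exactly the sum of the individual forces at every step."""
        phi = np.linspace(0, 150, 16)
        phi_rad = np.radians(phi)
        arm = np.full_like(phi, 0.03)
        lmt = 0.30 - 0.03 * (phi_rad - np.radians(50.0))
        lmt_e = 0.29 + 0.015 * (phi_rad - np.radians(50.0))
        geometry = mf.GeometryModel(
            phi,
            {"fa": lmt, "fb": lmt, "ext": lmt_e},
            {"fa": arm, "fb": arm, "ext": np.full_like(phi, -0.015)},
        )
        muscles = [
            mf.MusculotendonParameters(name=n, role="flexor", F0M=300.0,
                                       l0M=0.10, lST=0.20,
                                       fatigue=mf.GROUP_A_FATIGUE)
            for n in ("fa", "fb")
        ] + [
            mf.MusculotendonParameters(name="ext", role="extensor", F0M=300.0,
                                       l0M=0.10, lST=0.20,
                                       fatigue=mf.GROUP_A_FATIGUE)
        ]
        m7 = mf.MusculoskeletalModel(muscles, geometry, "7M")
        m2 = mf.aggregate_to_joint_actuators(m7)
        q = 0.6 * mf.available_max_moment_static(m7, 50.0)
        s7 = fat.CompartmentState.rested(3)
        s2 = fat.CompartmentState.rested(2)
        sample = JointSample(t=0.0, phi=50.0, phidot=0.0, q=q)
        for _ in range(300):
            sol7, s7 = mf.run_timestep(m7, s7, sample, 0.05)
            sol2, s2 = mf.run_timestep(m2, s2, sample, 0.05)
            flex7 = sol7.forces[0] + sol7.forces[1]
            flex2 = sol2.forces[list(m2.muscle_names).index("flexor")]
            assert flex7 == pytest.approx(flex2, abs=1e-6)


class TestSimulateProtocol:
    def test_rest_only_protocol_relaxes_to_rested(self, small_model):
        n = len(small_model.muscles)
        protocol = Protocol([Segment(kind="rest", duration_s=30.0)])
        res = mf.simulate_protocol(small_model, protocol, dt=0.05)
        final = res.muscle[res.muscle["t_s"] == res.muscle["t_s"].max()]
        assert np.all(final["Mr"] > 99.9)

    def test_mvc_available_moment_nonincreasing(self, small_model):
        protocol = Protocol([Segment(kind="mvc", duration_s=10.0)])
        res = mf.simulate_protocol(small_model, protocol, dt=0.05)
        avail = res.time["available_Nm"].to_numpy()
        assert np.all(np.diff(avail) <= 1e-9)

    def test_static_hold_records_failure_event(self):
        model = one_muscle_model()
        cap = mf.available_max_moment_static(model, 50.0)
        protocol = Protocol([
            Segment(kind="static_hold", duration_s=120.0, phi_deg=50.0,
                    q_nm=0.85 * cap)
        ])
        res = mf.simulate_protocol(model, protocol, dt=0.05)
        assert len(res.failure_times) == 1
        pred = mf.predict_failure_time(model, 0.85 * cap, 50.0, dt=0.05,
                                       horizon_s=300.0)
        assert res.failure_times[0] == pytest.approx(pred.time_s, abs=0.1)

    def test_cyclic_protocol_equilibrium_or_monotone_growth(self, subject):
        """Across identical work/rest cycles, per-muscle fatigue either
        settles (equilibrium flag) or keeps growing."""
        model = subject.model
        motion = mf.generate_curl_motion(subject, reps=3, period_s=3.0, dt=0.05)
        segs = []
        for _ in range(4):
            segs.append(Segment(kind="curl_set", reps=3, cadence_s=3.0))
            segs.append(Segment(kind="rest", duration_s=20.0, cycle_end=True))
        res = mf.simulate_protocol(
            subject.model, Protocol(segs), lambda seg: motion, dt=0.05
        )
        assert res.equilibrium_reached is not None
        peak_mf = [float(np.max(m)) for m in res.cycle_mf]
        growing = all(b >= a - 1e-9 for a, b in zip(peak_mf, peak_mf[1:]))
        assert res.equilibrium_reached or growing


class TestCompareMvc:
    def trace(self, values):
        t = np.arange(0, len(values) * 0.1, 0.1)[: len(values)]
        return pd.DataFrame({"t_s": t, "Q_Nm": values})

    def test_identical_traces_zero_error(self):
        a = self.trace(np.sin(np.linspace(0, 3, 50)) + 40)
        out = mf.compare_mvc(a, a, [(0.0, 2.0), (2.0, 4.9)])
        assert out["rmse_Nm"] == [0.0, 0.0]
        assert out["first_peak_error_Nm"] == 0.0

    def test_constant_offset_gives_offset_metrics(self):
        base = np.sin(np.linspace(0, 3, 50)) + 40
        out = mf.compare_mvc(
            self.trace(base + 2.0), self.trace(base), [(0.0, 4.9)]
        )
        assert out["rmse_Nm"][0] == pytest.approx(2.0)
        assert out["first_peak_error_Nm"] == pytest.approx(2.0)

    def test_windowed_rmse_decomposes_whole_trace(self):
        rng = np.random.default_rng(5)
        sim = self.trace(40 + rng.normal(0, 3, 60))
        meas = self.trace(40 + rng.normal(0, 3, 60))
        t = sim["t_s"].to_numpy()
        halves = [(float(t[0]), float(t[29])), (float(t[30]), float(t[-1]))]
        out = mf.compare_mvc(sim, meas, halves)
        whole = mf.compare_mvc(sim, meas, [(float(t[0]), float(t[-1]))])
        n1, n2 = 30, 30
        recombined = np.sqrt(
            (n1 * out["rmse_Nm"][0] ** 2 + n2 * out["rmse_Nm"][1] ** 2)
            / (n1 + n2)
        )
        assert whole["rmse_Nm"][0] == pytest.approx(recombined)

    def test_empty_window_rejected(self):
        a = self.trace(np.ones(20) * 30)
        with pytest.raises(ValueError, match="window"):
            mf.compare_mvc(a, a, [(100.0, 101.0)])
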