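"""Quick-look plots for session results and compartment trajectories."""

from __future__ import annotations

import pandas as pd


def plot_compartments(traj: pd.DataFrame, ax=None):
    """Resting / active / fatigued pools over time for one muscle.

    ``traj`` needs columns t_s, Ma, Mr, Mf (e.g. from
    :func:`myofatigue.simulate_profile` or one muscle's rows of a session
    result).
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(traj["t_s"], traj["Mr"], color="tab:blue", label="resting $M_r$")
    ax.plot(traj["t_s"], traj["Ma"], color="tab:green", label="active $M_a$")
    ax.plot(traj["t_s"], traj["Mf"], color="tab:red", label="fatigued $M_f$")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("motor units (% MU)")
    ax.set_ylim(0, 100)
    ax.legend()
    return ax


def plot_available_moment(result, ax=None, measured: pd.DataFrame | None = None):
    """Available maximal flexion moment vs the demanded torque.

    ``result`` is a :class:`myofatigue.SessionResult`; an optional measured
    trace (t_s, Q_Nm) is overlaid for comparison.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    t = result.time
    ax.plot(t["t_s"], t["available_Nm"], color="k", label="available max moment")
    ax.plot(t["t_s"], t["Q_Nm"], color="tab:red", label="demanded $Q$")
    if measured is not None:
        ax.plot(measured["t_s"], measured["Q_Nm"], color="tab:orange",
                alpha=0.7, label="measured")
    for ft in result.failure_times:
        ax.axvline(ft, color="tab:red", linestyle=":")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("elbow flexion moment (N·m)")
    ax.legend()
    return ax
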