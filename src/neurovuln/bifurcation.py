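"""Steady-state and hysteresis analysis under clamped ROS.

The activity subsystem is integrated with the ROS level held fixed (age, tau
load and the damaged mitochondrial fraction frozen at reference values) until
it reaches a steady state.  Sweeping the clamp up and then down along a grid,
with each steady state seeding the next (numerical continuation), exposes the
fold bifurcation of the self-reinforcing UPR hubs: over a window of clamps
the up- and down-branches disagree, and a cell carried past the fold does not
recover its stress-response capacity when ROS is removed late in life.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import network as net
from .network import NODES, InvalidParameterError, NetworkParameters, NodeActivities

__all__ = [
    "BranchTable",
    "clamped_ros_steady_state",
    "dose_response_sweep",
    "late_life_ros_removal",
]

#: convergence tolerance on max |dA/dt| (1/day) and step budget
TOLERANCE = 1e-8
MAX_STEPS = 1_000_000


@dataclass
class BranchTable:
    """Steady activities along an ordered ROS-clamp sweep.

    ``frame`` is long-form with columns (ros_clamp, direction, node,
    activity, converged), ordered by sweep position.
    """

    frame: pd.DataFrame

    def pivot(self, node: str = "uprmt_hsp60") -> pd.Series:
        """One node's steady activity indexed by clamp, in sweep order."""
        d = self.frame[self.frame.node == node]
        return pd.Series(d.activity.values, index=d.ros_clamp.values, name=node)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False, float_format="%.9g")


def _steady_activities(
    params,
    ros_clamp,
    A0: np.ndarray,
    *,
    tau_ref: float = 0.0,
    age_ref: float = 0.0,
    fd_ref: float = 0.0,
    tol: float = TOLERANCE,
    max_steps: int = MAX_STEPS,
) -> tuple[np.ndarray, bool]:
    """Relax the 9-dimensional activity subsystem to steady state (Euler)."""
    A = np.clip(np.asarray(A0, dtype=float).copy(), 0.0, 1.0)
    relax = net.relaxation_times(params, like=A)
    dt = 0.1 * float(np.min(relax))
    for _ in range(max_steps):
        tgt = net.activity_targets(ros_clamp, tau_ref, A, age_ref, fd_ref, params)
        dA = (tgt - A) / relax
        A = np.clip(A + dt * dA, 0.0, 1.0)
        if np.max(np.abs(dA)) < tol:
            return A, True
    return A, False


def clamped_ros_steady_state(
    params: NetworkParameters,
    ros_clamp: float,
    init: NodeActivities | None = None,
    *,
    tau_ref: float = 0.0,
    age_ref: float = 0.0,
    fd_ref: float = 0.0,
    tol: float = TOLERANCE,
    max_steps: int = MAX_STEPS,
) -> tuple[NodeActivities, bool]:
    """Steady activities with ROS held at ``ros_clamp``.

    Integrates from ``init`` (default: the basal high-activity state) until
    the largest activity rate falls below ``tol``.  On non-convergence the
    partial result is returned with the flag False; no exception is raised.
    """
    if ros_clamp < 0:
        raise InvalidParameterError("ros_clamp must be >= 0")
    params.validate()
    if init is None:
        init = net.basal_state(params).activities
    A, ok = _steady_activities(
        params, float(ros_clamp), init.as_array(),
        tau_ref=tau_ref, age_ref=age_ref, fd_ref=fd_ref, tol=tol, max_steps=max_steps,
    )
    return NodeActivities.from_array(A), ok


def dose_response_sweep(
    params: NetworkParameters,
    ros_grid,
    direction: str = "up",
    *,
    init: NodeActivities | None = None,
    tau_ref: float = 0.0,
    age_ref: float = 0.0,
    fd_ref: float = 0.0,
    tol: float = TOLERANCE,
    max_steps: int = MAX_STEPS,
) -> BranchTable:
    """Continuation sweep of steady activities along a monotone clamp grid.

    Each grid point's steady state seeds the next.  ``direction="down"``
    traverses the reversed grid, starting from the steady state reached at
    the high-ROS end, which is how the hysteresis branch is exposed.
    """
    grid = np.asarray(list(ros_grid), dtype=float)
    if grid.size == 0:
        raise InvalidParameterError("ros_grid must be nonempty")
    d = np.diff(grid)
    if grid.size > 1 and not (np.all(d > 0) or np.all(d < 0)):
        raise InvalidParameterError("ros_grid must be strictly monotone")
    if direction not in ("up", "down"):
        raise InvalidParameterError(f"direction must be 'up' or 'down', got {direction!r}")
    params.validate()

    order = grid if direction == "up" else grid[::-1]
    if init is None:
        init = net.basal_state(params).activities
    A = init.as_array()
    rows = []
    for clamp in order:
        A, ok = _steady_activities(
            params, float(clamp), A,
            tau_ref=tau_ref, age_ref=age_ref, fd_ref=fd_ref, tol=tol, max_steps=max_steps,
        )
        for j, node in enumerate(NODES):
            rows.append((float(clamp), direction, node, float(A[j]), bool(ok)))
    return BranchTable(
        pd.DataFrame(rows, columns=["ros_clamp", "direction", "node", "activity", "converged"])
    )


def hysteresis_gap(
    params: NetworkParameters,
    ros_grid,
    node: str = "uprmt_hsp60",
    **kwargs,
) -> float:
    """Largest up- vs down-branch disagreement of ``node`` over the grid."""
    up = dose_response_sweep(params, ros_grid, "up", **kwargs).pivot(node)
    down = dose_response_sweep(params, ros_grid, "down", **kwargs).pivot(node)
    down = down.iloc[::-1]  # align with the ascending grid
    return float(np.max(np.abs(up.values - down.values)))


def late_life_ros_removal(
    params: NetworkParameters,
    removal_fraction: float = 0.5,
    *,
    removal_day: float = 18.0,
    duration: float = 20.0,
    dt: float = 0.005,
) -> pd.DataFrame:
    """Single-cell aging run with late-life ROS removal.

    Integrates one deterministic cell (no mitochondrial stochasticity beyond
    the mean-field damaged fraction of zero) to ``removal_day``, multiplies
    its ROS by ``1 - removal_fraction``, and continues to ``duration``.  The
    returned frame (time x state) shows whether the stress responses recover:
    past the fold they do not, and UPR activities continue toward the
    compromised branch.
    """
    if not (0.0 <= removal_fraction <= 1.0):
        raise InvalidParameterError("removal_fraction must be in [0, 1]")
    params.validate()
    bs = net.basal_state(params)
    R, T = bs.ros, bs.tau
    A = bs.activities.as_array()
    relax = net.relaxation_times(params, like=A)
    n_steps = round(duration / dt)
    removal_step = round(removal_day / dt)
    rows = [(0.0, R, T, *A)]
    for step in range(1, n_steps + 1):
        t0 = (step - 1) * dt
        if step == removal_step:
            R *= 1.0 - removal_fraction
        k1 = net.state_rates(R, T, A, t0, 0.0, params, relax=relax)
        k2 = net.state_rates(R + 0.5 * dt * k1[0], T + 0.5 * dt * k1[1],
                             A + 0.5 * dt * k1[2], t0 + 0.5 * dt, 0.0, params, relax=relax)
        k3 = net.state_rates(R + 0.5 * dt * k2[0], T + 0.5 * dt * k2[1],
                             A + 0.5 * dt * k2[2], t0 + 0.5 * dt, 0.0, params, relax=relax)
        k4 = net.state_rates(R + dt * k3[0], T + dt * k3[1],
                             A + dt * k3[2], t0 + dt, 0.0, params, relax=relax)
        R = max(R + dt / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0]), 0.0)
        T = max(T + dt / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1]), 0.0)
        A = np.clip(A + dt / 6.0 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2]), 0.0, 1.0)
        if step % max(1, round(0.1 / dt)) == 0:
            rows.append((round(step * dt, 9), R, T, *A))
    return pd.DataFrame(rows, columns=["time", "ros", "tau", *NODES]).set_index("time")
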