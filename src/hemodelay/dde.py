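"""Method-of-steps integrator for the delayed hematopoiesis model.

The system has a single constant delay ``tau``.  The integrator is a
classical fixed-step fourth-order Runge-Kutta scheme whose step is
forced to divide ``tau`` exactly, so every delayed lookup falls on an
already-completed grid interval and the method of steps never iterates
on an overlapping segment.  Dense output between grid nodes uses cubic
Hermite interpolation on the stored states and nodal derivatives; for
times before the initial point the caller-supplied history function is
used.  The dense-output accuracy (order 3 uniformly) governs the
delayed-argument evaluation and hence the integrator's nominal order.

Stochastic deprivation noise is drawn once per accepted step from a
seeded generator and held constant across the step's stages
(piecewise-constant noise), so runs with identical seeds are
bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Callable

import numpy as np

from .model import _derivs
from .parameters import ModelParameters, SystemState

__all__ = [
    "ConstantHistory",
    "HistoryFunction",
    "Trajectory",
    "NegativePopulationError",
    "integrate",
    "dense_eval",
]

# A history function maps any time in [t0 - tau, t0] to a SystemState.
HistoryFunction = Callable[[float], SystemState]


class NegativePopulationError(RuntimeError):
    """A population dropped materially below zero; the run is invalid.

    The integrator never clamps: a negative excursion beyond tolerance
    signals a parameter regime where the model (or the step size) is
    not trustworthy, and silently repairing it would mask that.
    """

    def __init__(self, t: float, P: float, N: float):
        self.t, self.P, self.N = t, P, N
        super().__init__(
            f"population went negative at t={t:.6g} (P={P:.6g}, N={N:.6g})")


@dataclass(frozen=True)
class ConstantHistory:
    """History identically equal to the initial condition on [t0-tau, t0]."""

    P: float
    N: float
    A: float = 0.0

    def __call__(self, t: float) -> SystemState:
        return SystemState(t=t, P=self.P, N=self.N, A=self.A)


@dataclass
class Trajectory:
    """Dense solution of one integration run.

    Stores the time grid, the states, and the nodal derivatives needed
    for cubic Hermite dense evaluation.  Evaluation at any time in
    ``[t0 - tau, t_end]`` is defined: times at or before ``t0`` delegate
    to the history function, grid times reproduce the stored states
    exactly, and interior times are interpolated at the integrator's
    local order.
    """

    t: np.ndarray                      # strictly increasing grid, days
    y: np.ndarray                      # shape (len(t), 3): P, N, A
    dy: np.ndarray                     # nodal derivatives, same shape
    history: HistoryFunction
    params: ModelParameters
    step: float
    interpolation_order: int = 3
    metadata: dict[str, Any] = field(default_factory=dict)

    @property
    def t0(self) -> float:
        return float(self.t[0])

    @property
    def t_end(self) -> float:
        return float(self.t[-1])

    @property
    def P(self) -> np.ndarray:
        return self.y[:, 0]

    @property
    def N(self) -> np.ndarray:
        return self.y[:, 1]

    @property
    def A(self) -> np.ndarray:
        return self.y[:, 2]

    def state(self, i: int) -> SystemState:
        return SystemState(t=float(self.t[i]), P=float(self.y[i, 0]),
                           N=float(self.y[i, 1]), A=float(self.y[i, 2]))

    def __call__(self, t: float) -> SystemState:
        return dense_eval(self, t)

    def to_dataframe(self, stride: int = 1):
        import pandas as pd

        idx = np.arange(0, len(self.t), stride)
        if idx[-1] != len(self.t) - 1:
            idx = np.append(idx, len(self.t) - 1)
        return pd.DataFrame(
            {"t": self.t[idx], "P": self.y[idx, 0],
             "N": self.y[idx, 1], "A": self.y[idx, 2]})


def _hermite(t: float, t0: float, h: float,
             y0: np.ndarray, y1: np.ndarray,
             f0: np.ndarray, f1: np.ndarray) -> np.ndarray:
    """Cubic Hermite interpolant on [t0, t0+h]."""
    s = (t - t0) / h
    s2 = s * s
    h00 = (1.0 + 2.0 * s) * (1.0 - s) ** 2
    h10 = s * (1.0 - s) ** 2
    h01 = s2 * (3.0 - 2.0 * s)
    h11 = s2 * (s - 1.0)
    return h00 * y0 + h * h10 * f0 + h01 * y1 + h * h11 * f1


def dense_eval(traj: Trajectory, t: float) -> SystemState:
    """Evaluate the trajectory (or its history) at an arbitrary time."""
    t0, t_end, h = traj.t0, traj.t_end, traj.step
    lo = t0 - traj.params.tau
    if t < lo - 1e-9 * max(1.0, abs(lo)) or t > t_end + 1e-9 * max(1.0, t_end):
        raise ValueError(
            f"t={t} outside the covered interval [{lo}, {t_end}]")
    if t <= t0:
        return traj.history(t)
    x = (t - t0) / h
    i = int(round(x))
    if 0 <= i < len(traj.t) and abs(x - i) <= 1e-9 * max(1.0, abs(x)):
        return traj.state(i)
    j = min(int(math.floor(x)), len(traj.t) - 2)
    y = _hermite(t, float(traj.t[j]), h, traj.y[j], traj.y[j + 1],
                 traj.dy[j], traj.dy[j + 1])
    return SystemState(t=t, P=float(y[0]), N=float(y[1]), A=float(y[2]))


def _delayed_lookup(t_hist: list[float] | np.ndarray, Y: np.ndarray,
                    F: np.ndarray, n_done: int, t0: float, h: float,
                    history: HistoryFunction, s: float) -> tuple[float, float]:
    """(P, N) at time s from history or the completed part of the grid."""
    if s <= t0:
        st = history(s)
        return st.P, st.N
    x = (s - t0) / h
    i = int(round(x))
    if abs(x - i) <= 1e-9 * max(1.0, x) and i <= n_done:
        return float(Y[i, 0]), float(Y[i, 1])
    j = int(math.floor(x))
    y = _hermite(s, t0 + j * h, h, Y[j], Y[j + 1], F[j], F[j + 1])
    return float(y[0]), float(y[1])


def integrate(
    params: ModelParameters,
    history: HistoryFunction,
    t_end: float,
    step: float = 0.01,
    t0: float = 0.0,
    seed: int | None = None,
    metadata: dict[str, Any] | None = None,
) -> Trajectory:
    """Integrate the delayed system from ``t0`` to at least ``t_end``.

    Parameters
    ----------
    params
        Validated model parameters.
    history
        Maps any time in ``[t0 - tau, t0]`` to a state; its value at
        ``t0`` is the initial condition.
    t_end
        Integration horizon, days.  The actual final grid time is the
        first multiple of the effective step at or beyond ``t_end``.
    step
        Requested step, days.  The effective step is the nearest exact
        divisor of ``tau`` (``tau / round(tau/step)``) so delayed
        lookups only ever touch completed intervals.
    seed
        Required in stochastic deprivation mode; one uniform draw per
        accepted step.

    Raises
    ------
    NegativePopulationError
        If P or N falls below ``-1e-6`` times the initial population
        scale (the model has left its valid regime).
    ValueError
        For non-positive step or horizon, or a missing seed in
        stochastic mode.
    """
    if step <= 0:
        raise ValueError(f"step must be positive, got {step}")
    if t_end <= t0:
        raise ValueError(f"t_end ({t_end}) must exceed t0 ({t0})")
    stochastic = (not params.deterministic_r) and params.rbar > 0
    if stochastic and seed is None:
        raise ValueError("stochastic deprivation mode requires a seed")

    k = max(1, round(params.tau / step))
    h = params.tau / k
    n_steps = int(math.ceil((t_end - t0) / h - 1e-12))
    rng = np.random.default_rng(seed) if stochastic else None

    init = history(t0)
    guard_P = -1e-6 * max(abs(init.P), 1.0)
    guard_N = -1e-6 * max(abs(init.N), 1.0)

    T = t0 + h * np.arange(n_steps + 1)
    Y = np.empty((n_steps + 1, 3))
    F = np.empty((n_steps + 1, 3))
    Y[0] = (init.P, init.N, init.A)

    def f(ti: float, yi: np.ndarray, n_done: int, mult: float) -> np.ndarray:
        Pd, Nd = _delayed_lookup(T, Y, F, n_done, t0, h, history,
                                 ti - params.tau)
        return np.array(_derivs(yi[0], yi[1], Pd, Nd, ti, params, mult))

    for i in range(n_steps):
        ti = float(T[i])
        mult = (params.r_frozen if params.deterministic_r
                else float(rng.uniform(0.0, params.r_noise_width)))
        k1 = f(ti, Y[i], i, mult)
        F[i] = k1
        k2 = f(ti + 0.5 * h, Y[i] + 0.5 * h * k1, i, mult)
        k3 = f(ti + 0.5 * h, Y[i] + 0.5 * h * k2, i, mult)
        k4 = f(ti + h, Y[i] + h * k3, i, mult)
        Y[i + 1] = Y[i] + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if Y[i + 1, 0] < guard_P or Y[i + 1, 1] < guard_N:
            raise NegativePopulationError(
                float(T[i + 1]), float(Y[i + 1, 0]), float(Y[i + 1, 1]))
        # tiny negative round-off within the guard band is lifted to 0
        # so Hill terms stay defined
        if Y[i + 1, 0] < 0.0:
            Y[i + 1, 0] = 0.0
        if Y[i + 1, 1] < 0.0:
            Y[i + 1, 1] = 0.0
    # nodal derivative at the final point, for dense output
    mult = (params.r_frozen if params.deterministic_r
            else float(rng.uniform(0.0, params.r_noise_width)))
    F[n_steps] = f(float(T[n_steps]), Y[n_steps], n_steps, mult)

    meta = dict(metadata or {})
    meta.update({
        "t0": t0, "t_end_requested": t_end, "t_end": float(T[-1]),
        "step_requested": step, "step": h, "seed": seed,
        "stochastic": stochastic, "params": params.to_dict(),
    })
    return Trajectory(t=T, y=Y, dy=F, history=history, params=params,
                      step=h, metadata=meta)
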