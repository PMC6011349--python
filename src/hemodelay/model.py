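"""Rate functions and right-hand sides of the delayed hematopoiesis model.

The governing system (t > tau, subscript ``d`` marks values at t - tau):

    dP/dt = -gamma*P + beta(N)*N - exp(-gamma*tau)*beta(N_d)*N_d
            + beta_c(P_d, t)*N_d - rbar*r*P
    dN/dt = -(beta(N)*N + delta*N) + 2*exp(-gamma*tau)*beta(N_d)*N_d
            - beta_c(P, t)*N
    dA/dt = rbar*r*P + gamma*P

``beta`` is the Hill-type re-entry rate of quiescent cells into the cell
cycle, ``beta_c`` the cytokine-induced transfer rate (its time decay
``g_c`` always evaluated at the current time, as the system is written),
and ``rbar*r*P`` the growth-factor-deprivation loss with ``r`` a noise
multiplier.  Note the asymmetry printed into the system: the cytokine
gain in dP/dt is delayed while the matching loss in dN/dt is not.
"""

from __future__ import annotations

import math

from .parameters import ModelParameters, SystemState

__all__ = [
    "reentry_rate",
    "cytokine_decay",
    "cytokine_rate",
    "deprivation_loss_rate",
    "rhs",
]


def reentry_rate(N: float, params: ModelParameters) -> float:
    """Hill-type rate beta(N) = beta0 * theta^n / (theta^n + N^n), 1/day.

    Strictly decreasing in N, equal to ``beta0`` at N=0 and to
    ``beta0/2`` at N=theta.
    """
    if N < 0:
        raise ValueError(f"N must be non-negative, got {N}")
    tn = params.theta ** params.n
    return params.beta0 * tn / (tn + N ** params.n)


def cytokine_decay(t: float, params: ModelParameters) -> float:
    """Cytokine wear-off factor g_c(t): 1 up to tau1, then exp decay.

    Continuous at t = tau1 and non-increasing.
    """
    if t <= params.tau1:
        return 1.0
    return math.exp(-params.s1 * (t - params.tau1))


def cytokine_rate(P: float, t: float, params: ModelParameters) -> float:
    """Cytokine transfer rate beta_c(P)*g_c(t), 1/day.

    beta_c(P) = beta0c * theta1^m / (theta1^m + P^m): the transfer from
    quiescence into proliferation is strongest when the proliferating
    pool is depleted.  Identically zero when beta0c = 0.
    """
    if P < 0:
        raise ValueError(f"P must be non-negative, got {P}")
    if params.beta0c == 0.0:
        return 0.0
    tm = params.theta1 ** params.m
    return params.beta0c * tm / (tm + P ** params.m) * cytokine_decay(t, params)


def deprivation_loss_rate(
    P: float, params: ModelParameters, noise_draw: float | None = None
) -> float:
    """Growth-factor-deprivation loss rbar * r * P, cells/day.

    In deterministic mode the multiplier ``r`` is the frozen constant
    ``params.r_frozen``; in stochastic mode it is ``noise_draw``, which
    must lie in [0, r_noise_width].
    """
    if P < 0:
        raise ValueError(f"P must be non-negative, got {P}")
    if params.deterministic_r:
        mult = params.r_frozen
    else:
        if noise_draw is None:
            raise ValueError("stochastic mode requires a noise_draw")
        if not (0.0 <= noise_draw <= params.r_noise_width):
            raise ValueError(
                f"noise_draw {noise_draw} outside [0, {params.r_noise_width}]")
        mult = noise_draw
    return params.rbar * mult * P


def _derivs(
    P: float,
    N: float,
    Pd: float,
    Nd: float,
    t: float,
    params: ModelParameters,
    depr_mult: float,
) -> tuple[float, float, float]:
    """Raw derivative kernel; no validation (integrator hot path)."""
    tn = params.theta ** params.n
    beta_N = params.beta0 * tn / (tn + N ** params.n)
    beta_Nd = params.beta0 * tn / (tn + Nd ** params.n)
    surv = math.exp(-params.gamma * params.tau)
    if params.beta0c != 0.0:
        tm = params.theta1 ** params.m
        gc = cytokine_decay(t, params)
        bc_P = params.beta0c * tm / (tm + P ** params.m) * gc
        bc_Pd = params.beta0c * tm / (tm + Pd ** params.m) * gc
    else:
        bc_P = bc_Pd = 0.0
    loss = params.rbar * depr_mult * P
    dP = (-params.gamma * P + beta_N * N - surv * beta_Nd * Nd
          + bc_Pd * Nd - loss)
    dN = (-(beta_N * N + params.delta * N) + 2.0 * surv * beta_Nd * Nd
          - bc_P * N)
    dA = loss + params.gamma * P
    return dP, dN, dA


def rhs(
    state: SystemState,
    delayed_state: SystemState,
    t: float,
    params: ModelParameters,
    noise_draw: float | None = None,
) -> tuple[float, float, float]:
    """Evaluate (dP/dt, dN/dt, dA/dt) of the delayed system.

    Parameters
    ----------
    state
        Current state; ``state.t`` should equal ``t``.
    delayed_state
        State at ``t - tau``; its time stamp is checked.
    noise_draw
        Deprivation noise multiplier for stochastic mode, in
        ``[0, r_noise_width]``; ignored in deterministic mode.
    """
    if not math.isclose(delayed_state.t, t - params.tau,
                        rel_tol=1e-9, abs_tol=1e-9):
        raise ValueError(
            f"delayed_state.t = {delayed_state.t} does not equal "
            f"t - tau = {t - params.tau}")
    if state.P < 0 or state.N < 0 or delayed_state.P < 0 or delayed_state.N < 0:
        raise ValueError("cell counts must be non-negative")
    if params.deterministic_r:
        mult = params.r_frozen
    else:
        if noise_draw is None:
            raise ValueError("stochastic mode requires a noise_draw")
        if not (0.0 <= noise_draw <= params.r_noise_width):
            raise ValueError(
                f"noise_draw {noise_draw} outside [0, {params.r_noise_width}]")
        mult = noise_draw
    return _derivs(state.P, state.N, delayed_state.P, delayed_state.N,
                   t, params, mult)
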