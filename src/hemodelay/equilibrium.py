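"""Steady states, existence condition and linear stability analysis.

Setting the delayed terms equal to the instantaneous ones (a constant
solution) gives two fixed points of the (P, N) subsystem.  The trivial
one is extinction, P* = N* = 0.  The nontrivial one is

    N* = theta * [ beta0*(2*exp(-gamma*tau) - 1)/(delta + beta0c) - 1 ]^(1/n)
    P* = N*/(gamma + r_eff)
         * [ beta0c + (delta + beta0c)*(1 - exp(-gamma*tau))
                                       /(2*exp(-gamma*tau) - 1) ]

where ``r_eff`` is the effective deprivation loss rate.  The denominator
is written with a plus sign because the deprivation term is a loss in
the P balance; see the methods note for the sign discussion.

The nontrivial state exists iff

    0 < gamma*tau < ln( 2*beta0 / (delta + beta0c + beta0) ) < ln 2,

which is also exactly the condition for the bracket in N* to be
positive.  Linear stability about N* reduces, through the linearized
delayed N equation, to a Hayes-type criterion: with

    F = theta^n * (theta^n + (1 - n)*N*^n) / (theta^n + N*^n)^2
    A = delta + beta0*F + beta0c
    B = -2*beta0*exp(-gamma*tau)*F

and |A/B| < 1, the crossing frequency is omega = sqrt(B^2 - A^2) and the
state is stable iff omega*tau < arccos(-A/B).  When |A/B| >= 1 the
boundary test does not apply and the verdict is reported indeterminate.
``F`` is the slope of beta(N)*N at N*, normalised by beta0 (the analytic
derivative of the Hill feedback times N).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

from .parameters import ModelParameters

__all__ = [
    "SteadyStateReport",
    "trivial_steady_state",
    "nontrivial_steady_state",
    "existence_condition",
    "stability_analysis",
    "analyze",
]


class DegenerateParametersError(ValueError):
    """The steady-state denominator gamma + r_eff vanishes."""


@dataclass
class SteadyStateReport:
    """Nontrivial steady state with existence and stability verdicts.

    ``stable`` is three-valued: "stable" / "unstable" when the Hayes
    boundary test applies (|A/B| < 1), "indeterminate" otherwise, and
    None before :func:`stability_analysis` has run.
    """

    N_star: float | None
    P_star: float | None
    exists: bool
    F: float | None = None
    A_coef: float | None = None
    B_coef: float | None = None
    omega: float | None = None
    ratio: float | None = None          # A/B
    stable: str | None = None
    diagnostics: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return {
            "N_star": self.N_star, "P_star": self.P_star,
            "exists": self.exists, "F": self.F,
            "A_coef": self.A_coef, "B_coef": self.B_coef,
            "omega": self.omega, "ratio": self.ratio,
            "stable": self.stable, "diagnostics": dict(self.diagnostics),
        }


def trivial_steady_state() -> tuple[float, float]:
    """The extinction fixed point (P*, N*) = (0, 0)."""
    return (0.0, 0.0)


def existence_condition(params: ModelParameters) -> tuple[bool, dict[str, float]]:
    """Check 0 < gamma*tau < ln(2*beta0/(delta+beta0c+beta0)) < ln 2.

    Returns the verdict plus the numeric value of each bound so callers
    can report which link of the chain fails.
    """
    gt = params.gamma * params.tau
    bound = math.log(2.0 * params.beta0
                     / (params.delta + params.beta0c + params.beta0))
    diag = {"gamma_tau": gt, "upper_bound": bound, "ln2": math.log(2.0)}
    return (0.0 < gt < bound < math.log(2.0)), diag


def nontrivial_steady_state(params: ModelParameters) -> SteadyStateReport:
    """Closed-form nontrivial steady state with existence flag.

    ``exists`` is true iff the bracket in N* is positive and the
    existence chain holds (at valid parameters these are equivalent).
    When it is false, N* and P* are left unset.
    """
    E = math.exp(-params.gamma * params.tau)
    r_eff = params.effective_deprivation_rate
    denom = params.gamma + r_eff
    if denom == 0.0:
        raise DegenerateParametersError(
            "gamma + effective deprivation rate must be nonzero")
    bracket = params.beta0 * (2.0 * E - 1.0) / (params.delta + params.beta0c) - 1.0
    holds, diag = existence_condition(params)
    diag["bracket"] = bracket
    diag["effective_deprivation_rate"] = r_eff
    if bracket <= 0.0 or not holds:
        return SteadyStateReport(N_star=None, P_star=None, exists=False,
                                 diagnostics=diag)
    N_star = params.theta * bracket ** (1.0 / params.n)
    P_star = (N_star / denom) * (
        params.beta0c
        + (params.delta + params.beta0c) * (1.0 - E) / (2.0 * E - 1.0))
    return SteadyStateReport(N_star=N_star, P_star=P_star, exists=True,
                             diagnostics=diag)


def stability_analysis(
    params: ModelParameters, report: SteadyStateReport
) -> SteadyStateReport:
    """Complete a report with the Hayes-type boundary stability test.

    Requires ``report.exists``; fills F, A, B, the ratio A/B, the
    crossing frequency omega and the three-valued verdict.
    """
    if not report.exists:
        raise ValueError("stability analysis requires an existing "
                         "nontrivial steady state")
    Ns = report.N_star
    tn = params.theta ** params.n
    Nn = Ns ** params.n
    F = tn * (tn + (1.0 - params.n) * Nn) / (tn + Nn) ** 2
    A = params.delta + params.beta0 * F + params.beta0c
    B = -2.0 * params.beta0 * math.exp(-params.gamma * params.tau) * F
    report.F, report.A_coef, report.B_coef = F, A, B
    if B == 0.0 or abs(A / B) >= 1.0:
        report.ratio = math.inf if B == 0.0 else A / B
        report.stable = "indeterminate"
        return report
    report.ratio = A / B
    omega = math.sqrt(B * B - A * A)
    report.omega = omega
    crit = math.acos(-A / B)
    report.diagnostics.update({"omega_tau": omega * params.tau,
                               "arccos_bound": crit})
    report.stable = "stable" if omega * params.tau < crit else "unstable"
    return report


def analyze(params: ModelParameters) -> SteadyStateReport:
    """Steady state plus stability in one call (the CLI's entry point)."""
    report = nontrivial_steady_state(params)
    if report.exists:
        stability_analysis(params, report)
    return report
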