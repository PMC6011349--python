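"""Model parameters and state containers for the delayed hematopoiesis model.

The model tracks three bone-marrow compartments: proliferating stem cells
``P``, quiescent (G0) cells ``N``, and a cumulative apoptotic-cell tally
``A``.  Quiescent cells re-enter the cell cycle at a Hill-type rate
``beta(N)``; a proliferation cycle takes a fixed time ``tau`` days, so the
governing equations are delay differential equations.  Growth-factor
deprivation adds an extra death channel on ``P`` and cytokine
administration adds a decaying Hill-type transfer from ``N`` to ``P``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Any


class ParameterError(ValueError):
    """A parameter value violates the model's domain constraints."""


@dataclass(frozen=True)
class ModelParameters:
    """All rate constants, Hill exponents, delays and deprivation switches.

    Defaults are the simulation values of the source model's parameter
    table (the "baseline" column: no deprivation, no cytokine).

    Attributes
    ----------
    gamma : float
        Apoptosis rate of proliferating cells, 1/day.
    delta : float
        Rate of random cell loss from the quiescent pool to the
        periphery, 1/day.
    tau : float
        Duration of one proliferation cycle, days; the system's delay.
    theta : float
        Quiescent population at which cell-cycle re-entry runs at half
        its maximal rate, cells.
    theta1 : float
        Proliferating population at which the cytokine-induced transfer
        runs at half its maximal rate, cells.
    beta0 : float
        Maximal re-entry rate from rest (G0) into S phase, 1/day.
    beta0c : float
        Maximal cytokine-induced transition rate, 1/day; 0 switches the
        cytokine off.
    n, m : int
        Hill exponents of the re-entry and cytokine functions.
    s1 : float
        Cytokine decay rate, 1/day.
    tau1 : float
        Time at which the cytokine effect starts to decay, days.
    rbar : float
        Maximal deprivation death rate, 1/day; 0 switches deprivation
        off.
    r_noise_width : float
        Upper bound of the uniform noise multiplier applied to ``rbar``
        in stochastic mode, dimensionless.
    deterministic_r : bool
        If true the noise multiplier is frozen at ``r_frozen`` instead
        of being drawn per step.
    r_frozen : float
        The frozen multiplier used in deterministic mode.
    """

    gamma: float = 0.1
    delta: float = 0.07
    tau: float = 2.22
    theta: float = 650.0
    theta1: float = 450.0
    beta0: float = 16.0
    beta0c: float = 0.0
    n: int = 3
    m: int = 3
    s1: float = 0.01
    tau1: float = 100.0
    rbar: float = 0.0
    r_noise_width: float = 1.0
    deterministic_r: bool = True
    r_frozen: float = 1.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        strict_positive = ("gamma", "tau", "theta", "theta1", "beta0")
        non_negative = ("delta", "beta0c", "s1", "tau1", "rbar",
                        "r_noise_width", "r_frozen")
        for name in strict_positive:
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and v > 0):
                raise ParameterError(f"{name} must be > 0, got {v!r}")
        for name in non_negative:
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and v >= 0):
                raise ParameterError(f"{name} must be >= 0, got {v!r}")
        for name in ("n", "m"):
            v = getattr(self, name)
            if not (isinstance(v, int) and not isinstance(v, bool) and v >= 1):
                raise ParameterError(
                    f"Hill exponent {name} must be an integer >= 1, got {v!r}")
        if not isinstance(self.deterministic_r, bool):
            raise ParameterError("deterministic_r must be a bool")

    def with_overrides(self, **kwargs: Any) -> "ModelParameters":
        """Return a copy with the given fields replaced (re-validated)."""
        unknown = set(kwargs) - {f.name for f in fields(self)}
        if unknown:
            raise ParameterError(f"unknown parameter(s): {sorted(unknown)}")
        return replace(self, **kwargs)

    def to_dict(self) -> dict[str, Any]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @property
    def effective_deprivation_rate(self) -> float:
        """Deprivation loss rate per cell used in closed-form analysis.

        In deterministic mode this is ``rbar * r_frozen``; in stochastic
        mode the expected rate ``rbar * r_noise_width / 2`` (the mean of
        the uniform multiplier).
        """
        if self.deterministic_r:
            return self.rbar * self.r_frozen
        return self.rbar * self.r_noise_width / 2.0


@dataclass(frozen=True)
class SystemState:
    """The model state (P, N, A) at a time point ``t`` (days)."""

    t: float
    P: float
    N: float
    A: float = 0.0

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.P, self.N, self.A)
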