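# Methods

## Model

The package simulates three coupled compartments of bone-marrow
hematopoiesis: proliferating stem cells P(t), quiescent (G0) cells
N(t), and a cumulative apoptotic-cell count A(t). Quiescent cells
re-enter the cell cycle at the Hill rate β(N) = β₀θⁿ/(θⁿ+Nⁿ) — a
negative feedback, since a full quiescent pool suppresses re-entry. A
cell entering the cycle at time t−τ leaves the proliferating pool at
time t as two daughters, attenuated by the survival factor e^{−γτ}
(γ is the apoptosis rate during proliferation, τ the cycle duration).
Growth-factor deprivation adds a death term r̄·r·P on proliferating
cells; cytokine administration adds a transfer β_c(P)·N from quiescence
into proliferation with Hill dependence on P (strongest when the
proliferating pool is depleted) and a wear-off factor g_c(t) equal to 1
until τ₁ and decaying as e^{−s₁(t−τ₁)} afterwards.

A is pure bookkeeping: dA/dt = r̄rP + γP ≥ 0, so A is non-decreasing
and does not feed back on P or N.

Two structural asymmetries of the governing equations are implemented
exactly as the system is written, not "fixed":

* the cytokine gain in dP/dt is delayed (β_c(P_τ)N_τ) while the
  matching loss in dN/dt is instantaneous (β_c(P)N), so the transferred
  flux is only conserved on time-constant trajectories (a property test
  checks exactly that); during transients the transfer is temporarily
  non-conservative.
* g_c is always evaluated at the current time t, in the delayed and
  the undelayed cytokine terms alike.

## Parameters

Defaults (the simulation values of the model's parameter table; units
are days and cells):

| name | default | meaning |
|---|---|---|
| γ (`gamma`) | 0.1/d | apoptosis rate of proliferating cells |
| δ (`delta`) | 0.07/d | random loss from quiescence to periphery |
| τ (`tau`) | 2.22 d | proliferation-cycle duration (the delay) |
| θ (`theta`) | 650 cells | half-maximum of the re-entry Hill function |
| θ₁ (`theta1`) | 450 cells | half-maximum of the cytokine Hill function |
| β₀ (`beta0`) | 16/d | maximal re-entry rate |
| β₀,c (`beta0c`) | 0 (0.022 with cytokine) | maximal cytokine transfer rate |
| n, m | 3 | Hill exponents |
| s₁ (`s1`) | 0.01/d | cytokine decay rate |
| τ₁ (`tau1`) | 100 d | cytokine decay onset |
| r̄ (`rbar`) | 0 (0.07 with deprivation) | maximal deprivation death rate |

Scenario presets start from (P, N, A) = (1000, 10000, 0) — a
proliferating:quiescent ratio consistent with young adult bone marrow —
with a constant history on [−τ, 0], and run 400 days so that both the
damped transient (over by ≈ day 60) and the post-τ₁ cytokine wear-off
are visible.

## The deprivation term

The deprivation loss is genuinely under-determined in its source: the
prose defines r as a uniform random variable on (0, 0.0005) multiplying
a "maximal rate" r̄ whose functional form is never given, while the
parameter table lists r = 0.07 for the deprivation case. No single
literal reading reproduces the reported deprivation equilibrium of
≈674 cells: a frozen 0.07/d rate gives a closed-form equilibrium of
≈456 cells, and the literal U(0, 0.0005) multiplier leaves the
equilibrium at the baseline ≈775. The package therefore exposes every
reading as a `deprivation_mode`:

* `frozen` (preset default) — deterministic multiplier 1, loss 0.07/d.
* `stochastic` — multiplier drawn per accepted step from U(0, 1).
* `literal` — multiplier drawn from U(0, 0.0005).
* `calibrated` — deterministic, with the effective rate obtained by
  inverting the closed-form P* for the deprivation-scenario equilibrium
  target of 674 cells (N* does not depend on the deprivation rate, so
  the inversion is exact: r_eff = γ(P*₀/674 − 1) ≈ 0.015/d, with P*₀
  the deprivation-free equilibrium).

Every deprivation run's metadata carries an interpretation block with
the mode, the effective rate, the frozen-reading closed form and the
calibration target, so the discrepancy is always surfaced rather than
absorbed.

## Steady states and stability

Setting the delayed terms equal to the instantaneous ones yields the
extinction state P* = N* = 0 and the nontrivial state

    N* = θ[β₀(2e^{−γτ}−1)/(δ+β₀,c) − 1]^{1/n}
    P* = N*/(γ+r_eff) · [β₀,c + (δ+β₀,c)(1−e^{−γτ})/(2e^{−γτ}−1)]

Existence requires 0 < γτ < ln(2β₀/(δ+β₀,c+β₀)) < ln 2 — biologically,
apoptosis during the cycle must not consume more than the doubling
gain — which is algebraically the same condition as positivity of the
bracket in N*.

Two deliberate corrections to the published algebra:

* The P* denominator is implemented as (γ + r_eff). The printed form
  has a minus sign, but the deprivation term is a loss in the P
  balance, so the direct steady-state derivation gives a plus; at
  r_eff = 0 both coincide and reproduce P* ≈ 775. The printed side
  condition "γ = −r̄r" is read as non-degeneracy of this denominator.
* The slope factor is implemented as the analytic derivative of
  β(N)N/β₀ at N*, F = θⁿ(θⁿ+(1−n)N*ⁿ)/(θⁿ+N*ⁿ)². The printed form
  carries a bare θ (dimensionally inconsistent with θⁿ); at the default
  parameters the two differ only in the fourth decimal (−0.01438 vs
  −0.01443), but not in general.

Stability uses the Hayes boundary test for the linearized delayed
equation: with A = δ + β₀F + β₀,c and B = −2β₀e^{−γτ}F, a root can
cross the imaginary axis at frequency ω = √(B²−A²), which is real
exactly when |A/B| < 1, and the state is stable iff
ωτ < arccos(−A/B). When |A/B| ≥ 1 (including B = 0) the boundary test
is inapplicable and the verdict is reported `indeterminate` rather than
guessed; the full characteristic-root problem is out of scope. At the
defaults: F ≈ −0.01438, A ≈ −0.1601, B ≈ 0.3686, |A/B| ≈ 0.434,
ωτ ≈ 0.737 < arccos(−A/B) ≈ 1.121 → stable, in agreement with the
simulated damped oscillations.

A limitation found while validating: with the cytokine on
(β₀,c > 0) the closed forms above are not an exact fixed point of the
full equations — they implicitly replace β_c(P*) by its maximum β₀,c,
ignoring the Hill saturation θ₁ᵐ/(θ₁ᵐ+P*ᵐ) (≈ 0.02 at P* ≈ 1601). A
simulation with a non-decaying cytokine settles near 880 cells instead.
The equilibrium module reports the closed forms as published; the
simulation/closed-form agreement tests are therefore restricted to the
β₀,c = 0 family, where the forms are exact.

## Numerics

Integration is by the method of steps: a classical fixed-step
fourth-order Runge–Kutta scheme whose step is snapped to the nearest
exact divisor of τ (h = τ/round(τ/step), default request 0.01 d =
τ/222), so every delayed lookup lands on an already-completed grid
interval and no iteration on overlapping intervals is needed. Delayed
values between nodes come from cubic Hermite interpolation on the
stored states and nodal derivatives; times at or before t₀ delegate to
the history function. Constant histories are reproduced exactly by the
interpolant, which is why fixed points are held to round-off.

Measured step-halving behavior on the baseline scenario (horizon 9τ,
terminal-state error against a τ/800 reference): empirical order ≈ 4
until the error reaches the round-off floor near 5·10⁻¹⁵. The
convergence test asserts order ≥ 3, the uniform order guaranteed by the
cubic dense output. The system is non-stiff at the default rates
(fastest scale β₀ = 16/d, h·β₀ ≈ 0.16), so no adaptive or stiff
machinery is provided.

Stochastic deprivation noise is one uniform draw per accepted step,
held constant across the step's stages (piecewise-constant noise), from
a seeded `numpy` generator; a seed is required in stochastic mode and
echoed in the output metadata, making runs bit-reproducible. With
per-step noise the effective loss rate entering closed-form analysis is
the mean r̄·width/2.

Populations are never clamped: if P or N falls below −10⁻⁶ times its
initial value the run aborts with the offending time, because a
materially negative population means the parameter regime (or step)
has left the model's domain of validity. Round-off-scale negatives
within that band are lifted to zero so the Hill terms stay defined.

The trailing-window equilibrium estimate reports the mean and
peak-to-peak amplitude of P over the final `window` days (default 100)
and flags non-convergence when the amplitude exceeds 1% of the mean —
the 400-day cytokine scenario is deliberately reported as
non-converged, since P is still relaxing toward the deprivation-only
equilibrium as g_c decays.

## What the tests do and do not show

All quantitative checks run on trajectories generated by this package
from the parameter defaults above; no external biological data enters.
Passing tests show internal consistency (simulation agrees with the
closed forms where those are exact, orderings between scenarios match
the model's structure) and reproduce the reported equilibria under the
documented readings of the deprivation term. They do not validate the
model against flow-cytometry measurements, nor calibrate τ, θ or the
Hill exponents to any particular organism or cell line; the noise
model (uniform, per-step, piecewise-constant) is a modeling choice, not
an inferred property of real marrow.
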