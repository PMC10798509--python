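# Methods

This note documents the models, the assumptions behind them, the synthetic
study conditions, and the numerical choices the package makes.

## The control problem

A planar (sagittal-plane) musculoskeletal walker — 80 kg, 1.80 m, eight
Hill-type muscle actuators per leg (SOL, TA, GAS, VAS, HAM, RF, GLU, HFL) —
is driven by a reflex controller: muscle stimulations are computed from
*delayed* sensory signals through force feedback (Golgi tendon organ
pathway), length feedback (muscle-spindle stretch reflex) and muscle-driven
PD control toward target joint angles, with the wiring switching between the
stance and swing phases of each leg. The controller exposes 56 named scalar
parameters Y (gains, target lengths, PD gains, target angles, stimulation
offsets, foot-placement coefficients, phase thresholds).

The scientific question the toolchain addresses: how should Y vary with
walking velocity so that the gait both tracks a commanded speed and stays
energy-efficient — and which reflex circuits carry that efficiency?

## Muscle actuator model

Force is `F = {a·Fl(l̃)·Fv(ṽ) + Fp(l̃)}·F0` on the length/velocity scaled by
the rest length (`l̃ = l/l0`, `ṽ = v/l0`); the tendon is inelastic, so there
is no series-elastic state. The curve shapes are the standard reflex-walking
forms:

* `Fl`: bell curve `exp(ln(0.05)·|((l̃−1)/0.56)|³)` — maximum 1 at the rest
  length, 0.05 residual at ±0.56 rest lengths;
* `Fv`: Hill hyperbola on the shortening side (`ṽ ≤ 0`),
  `(v_max+ṽ)/(v_max−K·ṽ)` with `v_max = 12 /s`, `K = 5`, clipped at 0; on
  the eccentric side a plateau approaching `N = 1.5`;
* `Fp`: 0 at or below rest length, `((l̃−1)/0.56)²` above it.

These closed forms and their constants are an **adopted-form assumption**:
the qualitative behaviour (bell peak at `l̃ = 1`, `Fv(0) = 1` decreasing with
shortening speed, monotone passive force) is the contract; the constants
live in one `MuscleCurves` config block and are exercised only through
contract-level tests.

Activation low-pass filters the stimulation `u ∈ [0,1]` with the asymmetric
time constant `τ = 0.01(0.5+1.5a)` s during excitation (`u > a`) and
`τ = 0.04/(0.5+1.5a)` s during deactivation. Integration is explicit Euler
at the simulation timestep `dt = 5 ms` with clamping to [0, 1]; at this
step size (well below τ/2 ≈ 2.5 ms only for the very fastest excitation
corner) no overshoot is observed in the convergence tests, and the clamp
guarantees boundedness regardless.

Maximum isometric forces (N): SOL 4000, TA 800, GAS 1500, VAS 6000,
HAM 3000, RF 1000, GLU 1500, HFL 2000.

## Reflex controller

The three stimulation primitives are

* force feedback `u = G·F̃(t−Δt)`,
* length feedback `u = max{0, G·(l(t−Δt) − l_tar)}`,
* PD control `u = max{0, K(θ_tar−θ) − Dθ̇}` (agonist) /
  `max{0, K(θ−θ_tar) + Dθ̇}` (antagonist),

each reading through a zero-order-hold delay buffer (hold-first-sample
before history exists; never extrapolates forward). Default pathway delays
are 20 ms for ankle muscles, 10 ms for the knee, 5 ms for the hip — the
exact values are configuration, chosen to respect the proximal-to-distal
ordering of conduction delays.

Stance wiring: positive force feedback on GLU/VAS/SOL/GAS, TA stretch
reflex suppressed by crossed SOL force feedback, a knee-overextension guard
on VAS, and PD torso balance at the hip muscles toward `theta_t_tar`. Swing
wiring: the two hip-flexor circuits — `G_HFL·(l_HFL − l_HFL_tar)` excitatory
and `G_HAM_HFL·(l_HAM − l_HAM_HFL_tar)` inhibitory — plus braking force
feedback on GLU/HAM and TA toe clearance. Late stance adds push-off gains
and a pre-swing HFL offset; late swing adds leg retraction; stance
preparation applies PD fixation of hip and knee, with the hip target set by
the linear foot-placement (SIMBICON) law
`θ_h_tar = theta_h0 + c_d·d + c_v·v_x`.

Every output is clamped to `[u_min, 1]` with `u_min = 0.01`.

**Registry reconstruction.** The full published 56-name parameter list is
not available to this package; the registry here (`registry.py`) is a
reconstruction covering all of the above circuits, with exactly 56 entries
and with `G_HFL`, `l_HFL_tar`, `G_HAM_HFL`, `l_HAM_HFL_tar` and
`theta_t_tar` as mandatory names. Each entry carries bounds and a default;
parameter vectors round-trip to ordered arrays by registry order. The
sub-phase trigger conditions are likewise behind configurable normalized
phase-progress thresholds rather than guessed constants.

## Trial objective

A trial of at most `T = 5000` steps (25 s at 5 ms) is scored by

```
f(Y) = Σ_{t=1..T'} [ r_alive + r_forward + r_torso ] + r_fall + α_E·(CoT − 0.3)
```

with `r_alive = −1`, `r_forward = min(1, α_v|v_x − v_x_tar|²)`,
`r_torso = α_t·θ_t²`, `r_fall = 5000` when a fall occurs within the first
700 steps, and weights `α_E = 5000`, `α_v = 5`, `α_t = 1`. The prose
convention "`r_forward` with a lower limit of −1" conflicts with the min-cap
formula; the formula is implemented as printed, with an opt-in
`forward_lower_limit` flag that subtracts 1.

`CoT = J/(M·g·Δd)`. For zero-distance trials (immediate falls) CoT is
undefined; the objective substitutes a configured cap (default 10) so `f`
stays finite. Metabolic energy `J` uses an adopted
activation/maintenance-heat + shortening-heat + positive-mechanical-work
model with a small basal rate; only contract properties (non-negativity,
monotonicity in activation, additivity) are relied upon, since the exact
published energy equations are not available here.

## Dataset collection

Two sweeps with identical initial parameters: target velocity 1.3 → 2.0 m/s
in +0.1 steps, and 1.2 → 0.4 m/s in −0.1 steps (velocity grids are
materialized with integer step counts so 1.3 + 7·0.1 is exactly 2.0). At
each target, CMA-ES runs `G = 300` generations of `λ = 20` candidates with
`μ = 7` parents and `σ⁰ = 0.1`; the default schedule totals exactly 102,000
evaluation trials. On a velocity change, σ is reset to σ⁰ and both
evolution paths are emptied while the mean and covariance carry over, so
the search warm-starts at each new speed.

CMA-ES itself is the standard rank-one + rank-μ update with cumulative
step-size adaptation and log-linear weights, implemented in `cma.py`; a
sphere-function convergence test and bit-reproducibility test vet it. The
search runs in **bound-normalized [0,1]⁵⁶ coordinates** so that σ⁰ = 0.1 is
meaningful across parameters whose raw scales differ by two orders of
magnitude; candidates are clipped into the box.

A candidate is admitted to the dataset as `(v_x, Y, CoT)` only if its trial
survives to the timestep cap; all generations' candidates are eligible, and
the merged dataset is stably sorted by achieved velocity.

## PWLS regression and the parameter modulator

For each parameter, PWLS minimizes `‖β ⊗ (y − Vω)‖²` over degree-m
polynomial coefficients, with per-record weights

```
β_j = A^((CoT̄_j − CoT_j)/CoT̄_j),     CoT̄_j = mean CoT over records j−M..j+M
```

(2M+1 = 251 records at the default M = 125; the window shrinks at dataset
edges, a choice this package makes since no edge policy is published).
`A ≥ 1` sets the bias strength: A = 1 is ordinary least squares; large A
drives the fit through the most energy-efficient records at each velocity.
Degree m = 6 is the default.

Numerics: the explicit normal-equations inverse is ill-conditioned for
m = 6 on raw velocities, so the solver QR-factorizes `diag(β)V` on a
centred/scaled velocity basis and converts coefficients back to raw powers
(serialized modulators follow the raw-basis convention). β is computed in
log space and renormalized by its maximum — legitimate because the
minimizer is invariant to uniform weight rescaling — so A = 10⁶ (or far
beyond) never overflows. Identity with the normal-equations solution, the
OLS limit, scale invariance, exact interpolation at n = m+1, and agreement
with two independent routes (statsmodels WLS with weights β², and direct
numerical minimization of the weighted error) are all asserted in tests.

The fitted modulator maps a target velocity to all 56 parameters. Targets
outside the fitted velocity range are clamped to it with a warning (the
polynomials are meaningless outside their data); modulated values escaping
registry bounds are clamped to the bounds. Hybrid modulators for
substitution experiments copy named parameter functions from a donor fit,
recording per-entry provenance; substitution is idempotent and disjoint
substitutions commute.

## Surrogate gait evaluator

Running the full musculoskeletal physics is out of scope; the surrogate
(`surrogate.py`) is **not a physics model** and is labelled synthetic
throughout. It encodes exactly the structural assumptions the method
exploits:

* a smooth velocity-dependent optimal parameter bank `y*(v)` (clipped
  sinusoids in normalized coordinates, fixed per registry index);
* achieved velocity `v_x = v_tar − 0.35·d + ε`, where `d` is the weighted
  rms deviation of the candidate from `y*(v_tar)` and ε is N(0, 0.01²);
* `CoT = 0.55v² − 1.4v + 1.2 + 6·d² + |ε'|` — a concave-up quadratic with
  its minimum ≈ 0.31 near 1.27 m/s (values spanning ≈ 0.3–0.75 across
  0.4–2.0 m/s, the plausible human band), plus an efficiency-graded
  deviation penalty;
* a fall whenever `d` exceeds the stability radius 0.18.

The deviation weights concentrate 80% of the penalty on the four parameters
of the two swing-phase hip-flexor circuits, giving the substitution
analysis a known ground truth to recover. Traces are deterministic given a
seed, populated per-step so the trial objective, CoT and per-muscle energy
breakdown are all computable.

What the surrogate does **not** emulate: ground-reaction forces, joint
kinematics, muscle activation waveforms, gait-cycle structure, or any
contact dynamics. Tests passing against the surrogate demonstrate that the
pipeline recovers structure that is present by construction; they say
nothing about real musculoskeletal dynamics.

Two fixtures: an 18 × 9 two-CoT-level toy dataset (one parameter swept over
nine grid levels at 18 velocities, the grid point nearest `y*(v)` marked
efficient at CoT 0.5, the rest 1.0), and a bulk generator scattering
records around `y*(v)` with configurable noise (zero noise puts records
exactly on the curves). A third generator produces datasets whose parameter
curves are *known degree-6 polynomials*, for exact coefficient-recovery
tests.

## Efficiency analysis

Steady gaits (more than 30 m without a fall) evaluated over a velocity grid
give (v_x, CoT) samples; an unweighted quadratic is fitted and integrated
exactly over a velocity range to give ∫CoT. Comparisons report
`100·(test − baseline)/|baseline|` percent. Grid velocities whose achieved
speed misses the target by more than 0.05 m/s are excluded before fitting;
comparisons integrate over a common range (the intersection of the compared
fits' ranges unless fixed in config). Replicate seeds are averaged
(default n = 3). Fewer than three surviving velocities flags the condition
non-computable rather than extrapolating.

Because a 25 s trial cannot cover 30 m below 1.2 m/s, analysis evaluations
use a 45 s trace horizon (T = 9000); optimization trials keep the 25 s cap
that the objective's reward accumulation is defined over.

## Problem sizes for the shipped checks

The test suite and the acceptance script run a reduced collection schedule
— 3 target velocities (1.2, 1.3, 1.4 m/s), λ = 10, μ = 4 — with G = 30
generations in the fixed-seed tests and G = 60 in the acceptance script,
where the longer settling lets the fitted modulators track every grid
velocity within the 0.05 m/s gate across arbitrary seeds. The ∫CoT
comparison between A = 1 and A = 10⁶ fits uses a 9-point velocity grid
inside the collected range and 3 replicate seeds. The bulk-recovery check
uses n = 5000 records; the PWLS oracle check uses 20 random instances with
n ≤ 60, m ≤ 6.

## Known limitations

* Muscle-curve constants, metabolic-energy constants, the 56-name registry
  and the sub-phase trigger laws are reconstructions/adopted forms, not the
  published supplementary values; absolute CoT magnitudes are therefore not
  comparable to published ones (the quadratic *shape* and the relative
  ∫CoT comparisons are the meaningful outputs).
* The surrogate's ∫CoT improvements under performance weighting are
  structural demonstrations, not predictions about physical gaits.
* No within-stride (time-varying) parameter modulation; no 3-D extension;
  no physics adapter is shipped (the evaluator contract
  `(Y, v_tar, seed) → TrialTrace` is the integration point for one).
* The toolchain's worked example of the integral `∫(0.6v² − 1.2v − 0.1)dv`
  over [0.7, 1.6] evaluates to −0.5814 by the antiderivative; a negative
  CoT curve is of course unphysical — the integral operator is exact and
  indifferent to the sign of its input.
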