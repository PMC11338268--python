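# Methods

## Models

**Processes.** The default process is two-stage gene expression
(ẋ₁ = u + Δ − γ₁x₁, ẋ₂ = k₁x₁ − γ₂x₂, output y = x₂) with the basal
transcription rate Δ acting as a constant or piecewise-constant
disturbance. General stable unimolecular networks are supported through
their stoichiometry S, affine propensity λ(x) = Wx + b and actuation by
production of species 1; their steady-state map ȳ = αū + β is computed by
matrix inversion, with α = −e_Lᵀ(SW)⁻¹e₁ and β = −e_Lᵀ(SW)⁻¹Sb. The map is
defined only when SW is Hurwitz; because SW is also Metzler, its inverse
is entrywise nonpositive and the gain and offset are nonnegative, which
the property tests exercise on randomly generated first-order networks
(conversion rates with column-dominant degradation, Hurwitz by
Gershgorin).

**Controllers.** The classical integral controller uses hard saturations
sat(·; a, b) on actuation and sensing. The AIF controller uses two
sequestering species; saturating actuation and sensing enter as monotone
functions hₐ, hₛ (identity or Michaelis–Menten/Hill, h(s) = (s/κ)/(1+s/κ)).
The reduced (strong-sequestration) controller is the signed integrator
ż = μ − θ·hₛ(y), u = k·hₐ(max(z, 0)); the block-diagram actuation
nonlinearity is taken as ψₐ(v) = k·hₐ(max(v, 0)/k) with v = kz, which is
algebraically identical to the reduced control law (a property test
checks the identity on random states). Controller dilution is accepted as
an optional rate and defaults to zero; slow dilution turns the integrator
leaky and is outside the tested surface.

**Fixed-point existence.** The closed-loop fixed point exists iff the
setpoint is admissible, the sensor is unsaturated at steady state
(r_in ∈ range(hₛ)) and the actuator is unsaturated at steady state
(ū ∈ range(ψₐ)). Failures are reported per condition rather than raised;
a verdict is cross-checked against simulation on a grid of
(μ, Δ) pairs straddling the admissibility boundaries. Exact boundary hits
(supporting input equal to a hard saturation limit) are reported as
existing with a boundary warning; this situation is only detectable in
the hard-saturation (classical) mode.

## Numerics

* **Integration.** `scipy.integrate.solve_ivp` with the implicit BDF
  method, rtol 1e-8 and atol 1e-10 by default — sequestration rates up to
  1e4 make the loops stiff. Piecewise-constant schedules are
  right-continuous and the integrator is restarted at every breakpoint so
  steps are never averaged across a discontinuity.
* **Nonnegativity.** Propensities are evaluated at states clipped to the
  nonnegative orthant (solvers probe marginally negative values); output
  states within 10·atol below zero are clipped to zero, larger excursions
  are left visible because they indicate a modeling error. Signed
  coordinates of reduced models are exempt from clipping.
* **Steady states.** Chunked integration until ‖ẋ‖ < tol_rel·‖x‖ + tol_abs
  (defaults 1e-9/1e-9). Divergence is declared when a state magnitude
  exceeds 1e9 or when, at the time limit, the state norm has grown
  monotonically over the last 20 % of the horizon with a sustained
  vector-field norm — the signature of a missing fixed point, where a
  controller species ramps (often linearly) without bound. Near-saturated
  operating points leave very little loop gain; tests on such points use
  longer horizons and residual-level tolerances.
* **Root finding.** Supporting inputs and setpoint maps of monotone
  nonlinear functions are bracketed on [0, u] with a doubling upper bound
  (cap 1e12, beyond which the setpoint is declared unreachable) and solved
  by Brent's method to 1e-12 relative tolerance. Non-monotone sensing
  functions are rejected rather than silently returning one of several
  roots. Full-model fixed points are refined by `scipy.optimize.root`
  started from the lifted reduced fixed point, which is their unique
  limit point when the reduced fixed point is unique.
* **Discrepancy metrics.** Full and reduced trajectories are interpolated
  onto a common grid (≥ 2001 points per horizon; stable under doubling).
  The sup metric is the maximal Euclidean distance between (x, z₁ − z₂)
  and (x, z); the L1 metric is the trapezoidal integral of the Euclidean
  distance between (x, z₁, z₂) and (x, z⁺, z⁻). All norms are ℓ².
* **Stochastics.** Exact Gillespie direct-method sampling with a seeded
  `numpy.random.Generator`; rates are treated as constant between events.
  The reduced jump process of a switch lives on the signed integer
  coordinate (birth rate u₀ + δ₂z⁻, death rate u + δ₁z⁺), which is the
  exact strong-sequestration limit of the pair dynamics.

## Study conditions

The built-in scenarios fix the package's canonical parameter sets: the
basic loop (μ=10, θ=k=k₁=γ₁=γ₂=1, η=100) whose admissible disturbances
are [0, 10], and the saturated loop (θ=15, k=8, κₐ=κₛ=5, Δ=5 or μ=10)
whose admissible outputs are [5, 13] and admissible disturbances [2, 10].
Schedules step each quantity across its admissibility boundary with
plateaus of 50–100 time units (long enough for the slowest loop to settle
to ~1e-3) and closed-loop initial conditions are all-zero, overridable in
configs. The anti-windup scenario uses switch thresholds v₀=10, w₀=20,
switch rates η_v = η_w = 100, unit switch degradations, identity switch
input/readout maps, and a 50-time-unit disturbance pulse that overshoots
the admissible upper boundary by 50 % (Δ = 15): long enough that the
unprotected integrator's linear ramp (≈1.25 per time unit) dwarfs the
protected loop's capped excursion.

Two degeneracies discovered during design are worth recording. First,
with equal switch degradation rates the signed coordinate v₁ − v₂ obeys
the same closed ODE at every sequestration rate, so full and reduced
signed coordinates agree *exactly* and only the L1 metric is informative;
the convergence study therefore uses δ₁=1, δ₂=0.5 for the standalone
switch, and the exact-agreement property is tested in its own right.
Second, with W₁ = W₂ = W > 0 the pair equilibrates at z₁ = z₂ = √(W/η),
so the L1 metric decays only like 1/√η while the sup metric is
identically zero.

## Finite-sequestration effects in the anti-windup circuits

With finite switch sequestration rates the dormant switches leak: the
blue switch of topology I holds w̄₂ = z̄₁/(η_w(w₀ − z̄₁) + δ) ≈ 7·10⁻³ at
the canonical operating point, which enters the Z₂ balance and offsets
the steady-state output by ≈ 2·10⁻² (scaling as 1/η_w; measured
2.1·10⁻² at η_w = 100 and 2.1·10⁻³ at η_w = 1000). Adaptation is
therefore *exactly* preserved only in the phenomenological
(threshold-function) form of the topologies, where the switch output is
identically zero below threshold; the unit suite asserts both facts. The
phenomenological form of topology II models the anti-windup removal as an
absolute rate h₁(z₁), which is what reduces to the linear
conditional-integration leak; the reaction-network realization uses a
catalytic propensity h₁(v₂)·z₁ whose strong-sequestration limit grows
quadratically beyond the threshold, and both forms are implemented and
tested as distinct objects.

## What the synthetic scenarios do and do not show

The scenarios emulate deterministic, well-mixed, single-pair
sequestration loops with step disturbances and no resource coupling.
Passing tests demonstrate the algebra (admissibility, fixed points,
reductions) and the qualitative windup/anti-windup phenomenology at desk
scale; they say nothing about burden or resource sharing between the
controller and the protection circuitry, multi-pair reductions with
differing rates (pairs are reduced independently), dilution of controller
species, spatial effects, or parameter regimes far from the canonical
sets. Stochastic checks are distributional at a single time point and
desk-scale path counts.

## Known limitations

Single-input single-output processes only; sensing/actuation
nonlinearities must be monotone; the SSA treats time-varying rates as
constant between events (exact only for piecewise-constant schedules with
breakpoints far apart relative to event spacing); divergence detection is
heuristic and can misclassify extremely slow ramps as `max_time`; the
admissible-disturbance computation assumes the steady-state map is
monotone in the disturbance, which holds for all affine families built
here.
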