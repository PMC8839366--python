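# Methods

## Delayed mass action

Classical mass action makes product formation instantaneous: for
A + B -> C the rate of C is k·nA(t)·nB(t).  When the conversion passes
through intermediate complexes with a finite lifetime, the product appears
only after a lag, and the rate law becomes delayed:

    dnC/dt = k · nA(t − τ) · nB(t − τ)                   (discrete delay)
    dnC/dt = k · ∫ f(s) nA(t + s) nB(t + s) ds           (distributed delay)

with f a probability density of the (negative) lag s.  The enzyme–substrate
mechanism used throughout is the irreversible one-complex Brown mechanism:
binding E + S consumes both instantaneously at rate kd·nE·nS, and the
complex releases free enzyme and product after the delay.  Its state is
(nS, nE, nP); the complex itself is never a state variable — it is encoded
entirely by the delay distribution.  The multi-substrate multi-inhibitor
generalizations add one delayed return channel per complex R_{i,j} (enzyme
bound to substrates S_1..S_j and inhibitors I_1..I_i); inhibitor channels
sequester enzyme and return it after their own lag while the inhibitor is
consumed.  The full complex-resolved lattice ODE model (`lattice_full`) is
compiled directly from the binding/unbinding/catalysis reaction scheme under
mass action, which guarantees conservation of total enzyme
Σ_{i,j} nR_{i,j}; it serves as the non-delayed reference network.

## Delay kernel

The delay density is a shifted gamma distribution

    f(s) = a^(m+1)/Γ(m+1) · (s − τ_min)^m · e^{−a(s−τ_min)},  s > τ_min,

zero at and below τ_min.  Mean τ_min + (m+1)/a, variance (m+1)/a².  The
density is evaluated in log space (gammaln), so large shapes (m ≈ 10³,
used by the degenerate-kernel limit tests) do not overflow.  m = 0 is a
shifted exponential; integer m is equivalent to a linear chain of m+1
first-order stages, which supplies an independent ODE oracle for the
integrator.

Distributed-delay integrals require an infinite history.  They are
truncated at the Chebyshev bound

    τ_M = E(τ) + sqrt(Var(τ) / (1 − c)),

which guarantees delay mass ≥ c below τ_M regardless of the shape; for the
gamma family the actual coverage is far above c (measured ≥ 0.999 at
c = 0.95 for the fitted kernel).  The confidence level c is a free choice;
the package default is c = 0.95, which keeps the history window short
(τ_M ≈ 20.7 s for the fitted kernel) while the truncation deficit
1 − F(τ_M) ≈ 5·10⁻⁴ stays below the other error terms.  Raising c to
0.9999 is what the chain-trick comparison test does when it needs the
truncation error out of the way.

The truncated integral is discretized by the composite trapezoid rule on a
uniform lag grid aligned with the integrator step; τ_M is rounded *up* to a
step multiple so quadrature nodes coincide with stored trajectory nodes and
no interpolation enters the right-hand side.  Weights are unnormalized by
default (the untruncated density over a truncated window, sum ≈ F(τ_M));
`renormalize=True` rescales them to sum to one when exact mass conservation
is preferred over fidelity to the truncated-integral formulation.

## Integrator

Fixed-step explicit Heun (order 2) by the method of steps.  Discrete lags
are snapped to integer step multiples (the step is reduced when needed), so
delayed lookups are exact array reads.  The initial history is the
substrate-addition convention: substrates and inhibitors are identically
zero before t = 0 and jump to their initial values at t = 0; enzyme is
constant at nE0; products and complexes start at zero.

The jump makes the solution two-valued at t = 0.  Delayed lookups landing
exactly on the jump node use the mean of the two one-sided limits: a
quadrature that crosses a jump is second-order accurate only with the
average value at the discontinuity, and with the one-sided value the whole
scheme degrades to first order.  Measured observed orders are 2.00
(discrete delay) and 1.99 (distributed).  Instantaneous terms at t = 0 use
the post-jump state, as an ODE right limit should.

Default step dt = 0.05 s for the 500 s protocol horizons — roughly four
decades below the fitted rate scale (kd·nE ≈ 2·10⁻³ 1/s), and a full
protocol simulation runs in tens of milliseconds.  The inner loop is
JIT-compiled (numba); a pure-Python right-hand side with identical
semantics is kept as the readable reference and cross-checked step-for-step
in the tests.  Divergence (non-finite state) raises an error naming the
first bad step.  No adaptive stepping, stiff solver, or event detection:
the kinetics at the fitted scales are smooth and non-stiff, and the only
"event" (substrate addition) is the time origin.

Conservation diagnostics integrate the in-flight enzyme/substrate mass
(history convolved against the delay survival function) and report the
residuals of nE + in-flight = nE0 and nS + nP + in-flight = nS0.  With
unnormalized distributed weights the enzyme identity leaks at the
truncation-deficit rate; the expected residual bound
(1 − F(τ_M))·(consumed substrate) is part of the report, so integrator
error and truncation deficit are not conflated.

## Observation model and identification

The measured quantity is the specific conductance κ of the solution.  For
a strong electrolyte, Kohlrausch's law Λm = Λm0 − K·sqrt(n) combined with
Λm = κ/n gives

    κ_pred(t) = Λm0 · nP(t) − K · nP(t)^{3/2},

applied to the predicted product concentration.  κ_pred is increasing in nP
up to nP = (2Λm0/3K)²; a warning is emitted if a trajectory crosses that
turning point, because beyond it the strong-electrolyte map is no longer
injective.  The recorded conductance additionally contains an instrument
baseline; since κ_pred(0) = 0, the baseline (mean conductance over the
pre-addition window) is subtracted from the data before residuals are
formed, and model time starts at the addition instant.  A
`--no-baseline-subtract` flag is kept for sensitivity checks.  The pipeline
is unit-agnostic: concentrations are carried in mg/mL and the fitted Λm0, K
absorb the unit choice.

Six parameters Π = (kd, a, m, τ_min, Λm0, K) are identified jointly from
all dose series by minimizing the root-sum-of-squares residual
J(Π) = sqrt(Σ_i Σ_j (κ_exp,i(t_j) − κ_pred,i(t_j))²) under box bounds,
using COBYLA.  Because the default bounds span up to ten orders of
magnitude, the search runs in log10-parameter space (an unscaled simplex
is degenerate); the initial trust region is 0.5 log-units and the final
10⁻⁶.  Bounds are passed to COBYLA as explicit linear inequality
constraints by default; an exact-penalty mode
Φ = J + ξ·[largest bound violation]₊ with ξ = 10³ is kept as an
alternative formulation of the same constraint contract (ξ is otherwise
unused).  The driver tracks the best bound-feasible point across
evaluations and returns it if the optimizer's last iterate is worse, so
the result never regresses below the initialization; reaching the
evaluation cap flags the result as non-converged instead of raising.
Alongside J the driver reports RMSE = J/sqrt(N) over the N =
Σ n_i samples; J itself is unnormalized, so the two are stated separately
and neither is privileged.

Per-dose initial concentrations come from the protocol mixing arithmetic
(below) unless a series carries explicit overrides.

## Synthetic experiments

The generator emulates the dose–response conductometry protocol: 4.0 mL of
2 mg/mL BSA premixed with 0.1 mL of 2 mg/mL enzyme; at t = 250 s of a
500 s recording sampled every 5 s (100 samples), a dose v ∈ {0.1, 0.3,
0.9, 1.5} mL of 2 mg/mL substrate stock is added.  Dilution gives
nS0 = 2v/(4.1+v) and nE0 = 0.2/(4.1+v) mg/mL.  The forward model is the
distributed-delay enzyme–substrate system plus the Kohlrausch map; the
default baseline is 550 instrument units, drift-free, and measurement noise
is i.i.d. additive Gaussian on κ (conductometer noise at this scale is
approximately signal-independent).  Defaults are those protocol values; the
noise sd defaults to zero and is set explicitly by the recovery harness as
a fraction (default 2%) of the noise-free signal range across doses.

What the generator does *not* emulate: baseline drift and temperature/pH
dependence of conductance, substrate mixing transients at the addition
instant, and any inhibitor wet-lab protocol.  Passing recovery tests
therefore show that the estimator is self-consistent under the stated noise
model, not that it is robust to instrument drift or model misspecification
on real recordings.

The recovery harness generates one noisy experiment per seed, refits from
the default initialization and bounds, and reports per-parameter relative
errors (plus log10 ratios, the natural scale when bounds span decades),
with the median kd error as the headline number.

### Identifiability of the recovery problem

The six-parameter model has a near-degenerate direction: lowering kd while
raising Λm0 and reshaping the delay kernel changes the noise-free
conductance by only ≈ 0.2% of the signal range.  At 2% measurement noise
the data barely distinguish points along this valley, and COBYLA started
from the distant default initialization (Λm0 off by a factor 8, kernel
mean off by a factor 2.4) can terminate on the wrong side of it even when
run to full convergence: converged fits reach residuals at or below the
level the true parameters attain on the same noisy data while their kd sits
tens of percent away (median ≈ 18% over five seeds in the acceptance run),
whereas the same driver started at the true parameters stays within ~1% of
them.  This is a property of the estimation problem under the stated study
conditions, not of the optimizer configuration; the recovery report records
it honestly rather than hiding it.  Identifiability analysis (profile
likelihood, bootstrap) and multi-start optimization are out of scope.

## Numerical choices and edge cases

- Density at s = τ_min exactly is 0 (the defining piecewise branch), also
  for m = 0 where the unshifted exponential has a jump there; the first
  quadrature node therefore always carries zero weight.
- Discrete delays that do not divide the step reduce the step (never
  enlarge it) and warn.
- kd = 0 (or all channel rates 0) produces exactly constant trajectories
  and exactly zero conservation residuals.
- Trajectories are reported on the uniform grid; off-grid queries (the
  5 s observation grid is on-grid for the default dt) use linear
  interpolation over the stored nodes, including the pre-history segment.
- The ESI (one substrate + one inhibitor) models track the two products
  P01 and P11 separately and sum them for observation.
- Catalysis in the full lattice releases free enzyme E = R_{0,0} plus
  product; inhibitor-only complexes (j = 0) never release product.

## Problem sizes used by the tests and the acceptance script

Simulations use the protocol horizons (250–500 s at dt = 0.05 s, or
dt ≤ 0.01 s where an oracle comparison needs the discretization error well
below the tolerance).  The recovery study runs 5 seeds at 2% noise with a
COBYLA evaluation budget of 3500, enough for the trust region to contract
to its final radius on every seed.
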