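# delaykin

Delayed mass-action enzyme kinetics: distributed-delay kinetic models, a
conductometric observation model, and constrained parameter identification.

## The problem

In conductometric enzyme biosensing, an enzyme layer (a cross-linked
enzyme aggregate of BSA + enzyme, e.g. acetylcholinesterase) converts an
added substrate into charged products, and the measured specific
conductance κ(t) of the solution tracks the reaction.  Classical
Michaelis–Menten ODEs resolve the enzyme–substrate complex explicitly; the
delayed-mass-action alternative replaces the complex by a *lifetime*: in
Brown's irreversible one-complex mechanism

    E(t) + S(t) →(kd) E(t+τ) + P(t+τ)

binding consumes enzyme and substrate at rate kd·nE·nS and returns enzyme
with product a lag τ later.  Because the lag is physically random, this
package models it as a shifted-gamma-distributed delay with density
f(a, m, τ_min; s), giving delay differential equations with distributed
delays, e.g. for one substrate:

    nS'(t) = −kd nE(t) nS(t)
    nE'(t) = −kd nE(t) nS(t) + kd ∫_{−τ_M}^{0} f(s) nE(t+s) nS(t+s) ds
    nP'(t) = kd ∫_{−τ_M}^{0} f(s) nE(t+s) nS(t+s) ds

with the history truncated at the Chebyshev bound
τ_M = E(τ) + sqrt(Var(τ)/(1−c)).  Discrete-delay variants, one-substrate +
one-inhibitor (ESI) models, general multi-substrate multi-inhibitor delayed
channel networks, and the full complex-resolved lattice ODE system are all
available from the same builder.  The observable is mapped through
Kohlrausch's strong-electrolyte law κ = Λm0·nP − K·nP^{3/2}, and the six
parameters Π = (kd, a, m, τ_min, Λm0, K) are identified from multi-dose
conductance series by COBYLA under box bounds.

Intended users: modellers of enzyme kinetics and biosensor signals who
want delay-kernel models with a tested integrator, and anyone needing a
reproducible parameter-identification pipeline for conductometric
dose–response experiments.

## Worked example

Summarize the fitted delay kernel (rate a = 1.255818, shape m = 6.703709,
shift τ_min = 4.673685 s) and its 95% Chebyshev truncation:

```sh
$ delaykin kernel --a 1.255818 --m 6.703709 --tau-min 4.673685 --confidence 0.95
mean_s 10.80810018
variance_s2 4.884796346
tau_M_s 20.69222517
coverage 0.9994760808
```

The mean complex lifetime is ≈ 10.8 s; truncating the delay integral at
τ_M ≈ 20.7 s provably retains ≥ 95% of the delay mass (actually 99.95% —
Chebyshev is conservative).

Generate a synthetic four-dose experiment (100 samples over 500 s,
substrate added at 250 s, doses 0.1/0.3/0.9/1.5 mL) at the reference
parameter estimate, then re-identify the parameters starting from them:

```sh
$ delaykin generate --noise-sd 0 --out series.csv --seed 1
$ cat > fit.yaml <<'YAML'
fit:
  init: {kd: 0.04042714, a: 1.255818, m: 6.703709,
         tau_min: 4.673685, lambda0: 729.2215, K: 246.2885}
  max_iter: 25
YAML
$ delaykin fit --data series.csv --config fit.yaml --out fit.json
INFO delaykin: fitting 4 series (400 points), max 25 evaluations
INFO delaykin: J=3.92793e-07 rmse=1.96397e-08 after 25 evaluations (converged=False)
```

On noise-free data generated at the initialization the residual J is at
round-off level (the written CSV keeps 10 significant digits): the
generator and the fitting forward model agree exactly.
`fit.json` records Π_init, bounds, Π_opt, J, RMSE = J/sqrt(400), iteration
count and per-series residuals.  With the default initialization
(kd = 0.04, a = 1, m = 20, τ_min = 5, Λm0 = 6000, K = 50) and bounds
spanning up to ten decades the same command performs the full constrained
identification; `delaykin recover --out report.json` wraps the whole
generate-and-refit study over several seeds and reports per-parameter
recovery errors.

Library use mirrors the CLI (`delaykin.build_model`, `integrate`,
`objective_J`, `fit_parameters`, `generate_series`,
`recovery_experiment`); see `docs/methods.md` for the model, integrator
and identification details.

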