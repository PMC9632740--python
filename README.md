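# ptneuro

Multimodal Bayesian inference for conductance-based neuron models with
adaptive parallel tempering MCMC.

The package implements a complete inverse-problem pipeline:

- **`ptneuro.neuron_models`** — two ODE neuron models integrated with the
  stiff scipy solvers (LSODA via `odeint`, BDF via `solve_ivp`), with
  numba-jitted right-hand sides: a three-channel (Na/K/leak)
  Hodgkin–Huxley point neuron (conductance densities in pS/µm²) and an
  eight-conductance bursting neuron (Na, CaT, CaS, A, KCa, Kd, H, leak
  plus first-order calcium dynamics; nine inferred parameters).
- **`ptneuro.ground_truth`** — deterministic, noiseless model-generated
  voltage traces that play the role of observational data: one spiking
  HH trace at the true densities (200, 50) pS/µm², and five bursting
  traces at the true nine-parameter vector for injected currents
  {0.0, 0.1, 0.2, 0.3, 0.4} nA. Bundles cache to disk under a content
  hash (plain-text traces + JSON manifest).
- **`ptneuro.burst_loss`** — burst segmentation by interpolated threshold
  crossing (−35 mV, 100 ms intra-burst merge gap), inter-burst frequency
  and duty-cycle features, the weighted feature loss
  E = α·E_f + β·E_dc (α = β = 1000; the mid/slow-wave/lag terms are
  zero-weighted hooks), the max-over-currents aggregate loss, and the MSE
  trace loss for the HH problem.
- **`ptneuro.ptmcmc`** — adaptive parallel tempering: per-chain adaptive
  Metropolis–Hastings (Haario 2.38²/d covariance scaling with decaying
  running moments), replica-exchange swaps between adjacent tempering
  exponents, stochastic-approximation ladder adaptation targeting ~23%
  swap acceptance, uniform box priors, Gibbs likelihood
  log P(y|θ) = −E(θ). Bitwise reproducible from a master seed.
- **`ptneuro.diagnostics`** — Geweke burn-in determination (10% vs 50%
  windows, spectral-density variance, |z| < 2) and static-chain filtering
  by coefficient of variation.
- **`ptneuro.posterior`** — pooled posteriors, corner-style solution maps
  (loss-colored 2D marginals + normalized 1D histograms), gridded 2D KDEs
  and their renormalized products ("intersections"), bounds-normalized 1D
  Wasserstein distances and a sliced 9D approximation, low-loss solution
  counts and top-k rankings.
- **`ptneuro.config` / `ptneuro.cli`** — YAML run configuration (unknown
  keys rejected) and a `ptneuro` command with subcommands
  `simulate`, `ground-truth`, `evaluate`, `infer`, `diagnose`, `analyze`,
  `distance`.

## Command-line usage

```bash
# generate the five-current ground-truth bundle
ptneuro ground-truth --model am8 --out runs/gt

# evaluate the loss of a parameter set against the ground truth
ptneuro evaluate --aggregate --params '{"g_na": 1076.392, "g_cat": 6.4056,
  "g_cas": 10.048, "g_a": 8.0384, "g_kca": 17.584, "g_kd": 124.0928,
  "g_h": 0.11304, "g_leak": 0.17584, "tau_ca": 653.5}'

# run a (scaled-down) inference and analyze it
ptneuro infer --model am8 --constraint individual:0.0 \
    --chains 8 --samples 500 --seed 1 --out runs/am0
ptneuro diagnose --store runs/am0/store
ptneuro analyze --store runs/am0/store --out runs/am0/analysis

# distances between two posteriors
ptneuro distance --store-a runs/am0/store --store-b runs/agg/store
```

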