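# ringwander

Stochastic ring-attractor networks: wandering bumps, their phase reduction,
and analytic circular statistics of stimulus-dependent neural variability.

A ring network is a population of rate neurons indexed by a preferred
direction on `[-pi, pi)` with cosine recurrent weights. In the marginal
regime it supports a stationary activity bump `U(theta) = A cos(theta)`
whose position is free; weak spatially structured noise makes the bump
wander diffusively, and a weakly biased stimulus pins it. `ringwander`
implements the three coupled layers of this picture and cross-validates
them against each other:

- **`ringwander.model_core`** — parameter types, the sigmoid rate, the bump
  self-consistency solve (`A = J * int cos(theta) f(A cos theta) dtheta`,
  worked stable amplitude `A ≈ 1.85` at gain 4 / threshold 0.5 / `J = 1`)
  and linear stability (marginal translation mode, even expansion mode,
  essential spectrum at -1), including the discretized linearized operator.
- **`ringwander.phase_reduction`** — coefficients of the reduced phase SDE
  `d beta = -eps Lambda sin(beta + bias) dt - eps K(beta - beta_other) dt
  + sqrt(2 eps D) dw`: drift amplitude `Lambda = contrast / A`, diffusion
  `D` from the noise correlation `a delta(theta) + b cos(theta)` (closed
  forms plus independent double-quadrature oracles), and the inter-network
  coupling `K` for the cosine kernel (closed form `c sin(beta)`) and the
  delta kernel (tabulated, with its even potential `phi`).
- **`ringwander.circular_stats`** — stationary statistics: von Mises phase
  density with concentration `kappa = Lambda / D`, circular moments, cosine
  mean tuning and M-shaped variance tuning; the bivariate cosine-model
  density for a coupled pair (Bessel-series normalization, marginal,
  modality classification, Gaussian limit, mean/variance/correlation tuning)
  and the generalized surround-modulation density for the delta-kernel pair.
- **`ringwander.simulate`** — Euler-Maruyama integration of the full field
  equations (trapezoidal ring convolutions, exact low-rank sampling of the
  structured noise) and of the reduced phase SDEs; phase extraction from the
  first circular harmonic; pooled circular ensemble statistics and
  total-variation comparisons against the analytic densities.
- **`ringwander.cli_experiments`** — named experiments and the
  `ringwander` CLI.

## CLI

```sh
ringwander bump                      # stationary bump solutions + stability
ringwander reduce                    # reduced-SDE coefficients as JSON
ringwander stats --kappa 2 --out tuning.csv
ringwander simulate --kind field --duration 100 --out phases.csv
ringwander experiment model_a_stats --out results/
ringwander validate --realizations 50 --duration 500
```

Experiments: `bump_diagnostics`, `single_ring_wander`,
`single_ring_variance`, `model_a_stats`, `model_a_field`,
`model_b_surround`. Defaults mirror the worked parameter set (gain 4,
threshold 0.5, `J = 1`, noise `a = 3`, `b = 0.5`, `eps = 0.05`); overrides
come from a JSON or YAML config (`--config`), and every run writes a
`config_echo.json` sufficient to reproduce it byte-for-byte.

## Conventions worth knowing

- Time is integrated in units of the network time constant (`tau = 10 ms`
  is display-only); the default step is `dt = 0.001` with 200 ring points
  (`dtheta = 0.01 pi`).
- The white part of the noise correlation supports two discretizations
  (`NoiseParams.white_convention`): per-grid-point increments (default; the
  regime in which a wandering bump survives realistic weights) or the
  literal continuum delta (`a dt / dtheta` per point). The diffusion
  coefficient uses the matching effective weight either way.
- `epsilon` rescales drift and noise-variance identically, so it sets the
  relaxation timescale but cancels from stationary densities:
  `kappa = contrast / (A D)` and `chi = coupling_strength / D`.
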