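# Methods

## The model

`vie` predicts rare binary outcomes (events with prevalence of a few percent
or less) by pushing the problem into a latent space whose *tail* is modeled
explicitly. The working hypothesis is that rare events are driven by extreme
values of a small number of latent factors, so the model spends its capacity
on characterizing the tail of the latent distribution rather than on the
bulk of the majority class.

Four components interact:

**Latent prior — Gaussian body, generalized Pareto tail.** Each latent
dimension has prior CDF

    F(z) = Phi(z),                                  z <= u
    F(z) = Phi(u) + (1 - Phi(u)) G_{xi,sigma}(z-u), z >  u

with `G` the generalized Pareto CDF. This is the peaks-over-threshold
construction from extreme value theory: whatever the true latent law, its
exceedances over a high threshold are asymptotically GPD, so two parameters
per dimension (shape `xi`, scale `sigma`) suffice to describe the tail and
can be estimated from the handful of extreme (minority-class) samples.
`xi > 0` gives a power-law tail, heavier than Gaussian. Above the threshold
the CDF is evaluated through the *translated* parameterization
(`sigma~ = sigma (1-Phi(u))^xi`, `u~ = u - sigma~((1-Phi(u))^{-xi}-1)/xi`),
which makes the mixture continuous at `u` by construction; the density and
the quantile function use the same translation, so CDF, pdf and sampler are
mutually consistent to machine precision. Only the right tail is modeled;
whether a large latent value raises or lowers risk is carried by the
decoder's signed direction weights.

**Posterior — inverse autoregressive flow.** The approximate posterior
q(z|x) is a diagonal Gaussian base (from a feed-forward encoder, conditioned
on x only, because labels are unavailable at prediction time) refined by T
affine IAF steps `z_t = mu_t + sigma_t * z_{t-1}` whose conditioners are
masked autoregressive networks over (z_{t-1}, context). The triangular
Jacobians give the exact log-density

    log q(z_T|x) = -sum_j ( e_j^2/2 + log(2 pi)/2 + sum_{t=0..T} log sigma_{t,j} ),

needed for a low-variance Monte-Carlo KL against the heavy-tailed prior.
`e` is the standardized base residual (z_0 - mu_0)/sigma_0 — i.e. the base
noise draw. A density-free "implicit" encoder (feed-forward sampler with
injected noise) is provided for the ablation variant that regularizes only
adversarially.

**Decoder — additive monotonic neural network with CLL link.** The risk
score is `H(z) = sum_j alpha_j int_l^{z_j} h_j(s) ds + gamma` with each
integrand `h_j = exp(net_j)` strictly positive, so each additive term is
monotone in its latent coordinate with the sign of `alpha_j`. Additivity
avoids fitting combinatorial interactions from few positive examples;
monotonicity restricts the hypothesis class, which is the point of isotonic
regression. The binary likelihood uses the complementary log-log link
`P(y=1) = 1 - exp(-exp(H))`, which is asymmetric and more responsive in the
tail than the logistic.

**Aggregated-posterior matching — Fenchel dual KL.** Besides the per-datum
KL, the objective penalizes `KL(q(z) || p(z))` for the aggregated posterior,
whose density is intractable; it is estimated through the Fenchel dual

    Gamma = E_q[nu(Z)] - E_p[exp(nu(Z'))] + 1,   KL = sup_nu Gamma,

with a neural critic `nu` trained adversarially. The `+1` makes the supremum
equal the KL itself (the bare dual form peaks at KL - 1); being a constant
it changes no gradient. Prior samples for the penalty are drawn by inverse-
CDF, so the tail parameters receive gradient through the penalty as well as
through the per-datum KL.

The full objective is the mini-max game

    max_{psi, phi, theta}  min_nu   Psi_beta(x, y) - lambda * Gamma,
    Psi_beta = E_q[log p(y|Z)] - beta * KL(q(z|x) || p(z)),

where the covariate-reconstruction term of a standard VAE is deliberately
dropped (the model is a predictor, not a generative model of x; this is the
variational information bottleneck form).

## Parameters that matter

| parameter | default | meaning / why |
|---|---|---|
| `u` | `Phi^-1(0.99)` (~2.326) | tail threshold in latent units; 1% of prior mass is tail |
| `xi_j, sigma_j` | init 0.1, 1.0 | per-dimension learnable GPD tail; `xi` unconstrained, `sigma` via softplus |
| `beta` | 1e-4 | per-datum KL weight. At ~1% prevalence the label log-likelihood is O(0.05) nats per datum while KL(q‖p) is O(1–10) nats, so beta near 1 collapses the posterior onto the prior and predictions to the base rate (measured: chance AUC). beta must be several orders below 1; 1e-4 keeps the KL a regularizer rather than the objective |
| `lam` | 0.1 | aggregated-posterior penalty weight |
| `latent_dim` | 10 | latent dimensionality `p` |
| `flow_depth` | 2 | IAF steps T |
| `encoder_extra_steps` | 5 | extra encoder-only ascent steps per joint step (posterior-lag compensation) |
| `lower_end` | -10 | AMNN integration lower limit, beyond the effective prior support |
| `n_grid` | 64 | trapezoid panels per integral; gradients flow through integrand and limit |
| CLL / exp clamps | 30 | overflow guards in the link and the critic exponent |
| learning rates | 3e-3 model, 1e-3 critic | Adam; one critic step per joint step |

The `xi = 0` exponential branch is taken when `|xi| < 1e-6`; the same
tolerance governs the tail-parameter translation, and branch continuity is
verified to 1e-6 in the tests. Out-of-support points give `-inf` log-density
in the public API; inside the training KL the per-dimension log-density is
floored at -50 so that a transiently negative `xi` (bounded support) cannot
produce an infinite objective — the floor only matters for samples outside a
bounded tail, where the exact value is -inf anyway.

## Training schedule

Per batch: (1) `critic_steps` ascent steps on Gamma with the model frozen;
(2) one joint Adam ascent step on `Psi - lambda*Gamma` for prior, encoder,
flows and decoder; (3) `encoder_extra_steps` encoder/flow-only ascent steps
on `Psi` with fresh noise. Features are standardized with training-split
statistics only. Early stopping tracks validation AUPRC (the
prevalence-sensitive metric) with the configured patience; the returned
checkpoint is the best-validation epoch. The decoder bias starts at
`CLL^-1(prevalence)` so initial predictions match the base rate — with a
shared 1%-risk start, the first epochs are spent learning ranking rather
than recalibrating.

Prediction averages the CLL-inverted decoder score over `s_eval = 20`
posterior draws per row, fixed by seed.

## The simulator

The generator reproduces survival-mechanics semi-synthetic designs:
covariates (half correlated Gaussian with exchangeable rho = 0.3, half
Bernoulli(0.3), mimicking a mix of continuous and binary clinical
covariates), a log-hazard `g(x)` that is either linear or a frozen random
network (standardized to mean 0 / sd 1 on a reference draw so event
difficulty is comparable across the two), and CoxPH-Weibull times

    T = ( -log U / (lambda e^{g(x)}) )^{1/nu},   lambda = 1, nu = 2.

The label is `y = 1(T < t0)` with `t0` the empirical r-quantile of the
simulated times, which tunes prevalence to the target r (default 1%). The
oracle risk `1 - exp(-lambda e^{g(x)} t0^nu)` is strictly increasing in
`g(x)`, so oracle ranking metrics can be computed from `g` directly; the
oracle AUC is the ceiling any trained model can approach. Under this design
the event indicator is `1(W - g(x) < c)` with `W = log(-log U)` of fixed
variance pi^2/6, so the oracle AUC (~0.76-0.82 at 1%) is a property of the
design, not a tunable.

What the simulator does *not* emulate: real covariate distributions (the
published benchmarks use clinical cohorts that are not redistributable),
censoring, measurement error, and temporal structure. Tests passing on this
generator demonstrate the machinery is correct and that the method's
comparative ordering holds under its own generative assumptions; they do not
certify performance on real EHR data.

## Problem sizes used in verification

The test-suite and the acceptance script use deliberately small instances
chosen to exercise every code path at desk scale: cohorts of n = 10,000
(20,000 for prevalence checks) with d = 10 covariates at 1% prevalence;
models with p = 4 latent dimensions, one flow step, width-16 networks and
16-panel quadrature; 5 simulation seeds for the variant-ordering comparison
and 3 for the oracle-proximity check; 1e5 draws for distributional checks;
critic training with 500 steps of batch 2048 for the KL duality checks.
Package defaults (p = 10, T = 2, width 32, n_grid 64) are for real use.

## Design choices where the design was open

- **Per-dimension tail parameters.** The tail formulas are scalar in the
  source formulation; each latent dimension gets its own learnable
  (xi_j, sigma_j) while the threshold u is one shared constant. A shared
  pair would couple unrelated factors; per-dimension costs 2p parameters.
- **Conditioner architecture.** The flow's (mu_t, sigma_t) are produced by
  MADE-style masked networks (two hidden layers) over (z_{t-1}, context),
  natural dimension ordering, no permutations between steps; context feeds
  every step. sigma_t = sigmoid(s + 1.5) keeps steps near-identity at init.
- **Quadrature.** Uniform trapezoid with the upper endpoint at z_j; the
  error halves (at least) per grid doubling on smooth integrands, verified.
- **AUPRC convention.** Step-wise average precision with tied scores as one
  threshold block, no interpolation; a constant ranker scores the
  prevalence. Bootstrap CIs are stratified percentile (positives and
  negatives resampled separately), n_boot = 1000, level 95%.
- **Implicit-encoder variant.** With no tractable log q, the per-datum KL is
  dropped and only the Fenchel penalty regularizes — this is the point of
  that ablation row.
- **Early-stopping metric.** Validation AUPRC, since ranking the rare class
  is the target; with few validation positives this is noisy, so validation
  risk is averaged over 20 posterior draws.

## Known limitations

- Gradients reach the tail parameters only through samples that actually
  exceed u; batches with no exceedances contribute none, so tail learning is
  slow at small n — inherent to threshold-exceedance estimation.
- The factorized prior cannot represent tail *dependence* between latent
  dimensions (no extreme-value copula).
- Training is CPU-bound numpy/autograd; it is sized for tabular clinical
  data (thousands to tens of thousands of rows), not image-scale corpora.
- The AUPRC of any method at 1% prevalence has high run-to-run variance;
  comparisons should always be made over repeated simulations (the
  `ablation_harness` exists for exactly this).
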