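# Methods

## The task and the simulation

`fedsilo` benchmarks cross-silo federated learning (FL) against central
training for binary phenotype classification on tabular multi-omics
features. The federation is simulated in-process: clients are disjoint
index sets over one training cohort, rounds are synchronous and
failure-free, and the "network" is a function call. No transport,
stragglers, dropout, secure aggregation or differential privacy are
modeled — the aggregation server is assumed honest.

## Federated optimization

Let *wᵗ* be the global parameters at round *t* and *F_k(w)* the mean
regularized log-loss on client *k*'s shard. One round:

1. every client loads *wᵗ*;
2. client *k* runs *E* local epochs of gradient descent on
   *F_k(w) + (μ/2)‖w − wᵗ‖²* (μ = 0 under FedAvg);
3. the server averages the returned parameters elementwise, **unweighted**
   by shard size. Unweighted averaging is a deliberate fidelity choice for
   the benchmark design this mirrors; a size-weighted mean is available via
   `FederationConfig(size_weighted=True)` but off by default.

After *R* rounds (default 5, local epochs default 1) the global model with
the highest validation AUC-PR is selected, earliest round on ties.

### Numerical treatment of the proximal term

The proximal gradient μ(w − wᵗ) is treated implicitly (backward Euler):

    w' = (w − η ∇F_k(w) + η μ wᵗ) / (1 + η μ)

An explicit step η·μ(w − wᵗ) diverges at fixed step size once η μ > 2;
the implicit update is stable for every μ ≥ 0, contracts monotonically to
the anchor as μ → ∞, and at μ = 0 reduces bit-for-bit to the plain update,
so FedProx(μ=0) ≡ FedAvg exactly.

### Aggregation details

- For parametric learners the client tensors are sorted elementwise along
  the client axis before summation, making the mean exactly invariant to
  client ordering (floating-point addition is not associative). Averaging
  identical parameter sets returns them unchanged, bit-for-bit.
- The forest learner is federated by bagging: each round every client
  boosts `trees_per_round` new regression trees (depth ≤ 3, shrinkage 0.3,
  `sqrt` feature subsampling, fitted to log-loss pseudo-residuals from the
  incoming global margin) and the server appends all new trees with leaf
  values scaled by 1/N. The round's margin increment is therefore the
  client average, and N = 1 reduces exactly to central boosting. The
  federation mechanism for tree ensembles is unspecified in the benchmark
  design this package mirrors; this scheme was chosen for those two
  reduction properties. Scores are the logistic of the summed leaf values.

## Local learners

| kind | update schedule | notes |
|---|---|---|
| `logistic_regression` | full-batch GD, one step per epoch | zero init |
| `sgd_linear` | per-sample, shuffled, η_t = η₀/√(1+t) | t = lifetime step count, persisted |
| `mlp` | mini-batch GD (batch 32), one ReLU hidden layer of 32, logistic output | Glorot init from the learner seed |
| `forest` | boosted trees as above | only non-parametric kind; no proximal support |

Config defaults: learning rate 0.1, batch size 32, L2 1e-4 (weights only,
never biases). Gradients use the **mean** log-loss over the shard so step
sizes are comparable across shard sizes — with a sum convention a client's
effective step would scale with its shard size, confounding the dispersion
experiments. All defaults live in `fedsilo.config` and are recorded in run
manifests.

Every epoch's shuffle derives from `(seed, epoch_counter)` with the counter
persisted in the learner state, so *E* epochs in one call equal *E* chained
single-epoch calls, and an N = 1 federation with *R* rounds × *E* epochs
reproduces central training with *R·E* epochs to machine precision under
the shared seed schedule.

The distinct SGD entry uses the inverse-scaling step-size schedule because
that is what the stochastic-gradient classifier it mirrors actually does;
a fixed per-sample rate of 0.1 on 673 standardized features makes single
updates move margins by ~30 and the final iterate is dominated by the last
samples seen.

## Split strategies

- `uniform_stratified`: each phenotype partition is shuffled and dealt
  ⌊n_class/N⌋ per client; per-class surpluses go to the last client.
- `uniform_random`: ⌊C/N⌋ per client from a global shuffle, surplus to the
  last client.
- `linear_random`: client *i* (1-based) receives *i·c* samples with
  *c = ⌊2C/(N(N+1))⌋*, surplus to the last client, preserving strictly
  increasing sizes; membership uniform at random.

Surplus always goes to the *last* client (the benchmark design states both
a random-client and a last-client rule; the deterministic variant was
chosen for reproducibility). Every shard must contain at least one case
and one control; the random strategies redraw with a derived seed up to
100 times before raising. Heterogeneity is summarized by label skew (max
pairwise difference in shard case fractions) and size skew (max/min shard
size).

## Evaluation protocol

Stratified K-fold (K = 6, so ~100 samples per fold on the 598-sample
default cohort; realized fold sizes are exactly 99 or 100 via
capacity-balanced stratified folds). Per fold: the holdout fold is the
internal test set; the remaining samples split 80:20 (stratified) into fit
and validation subsets; the standardizer is fitted on the fit subset only
and applied verbatim to validation, holdout and the external cohort;
central models train on the fit subset for `epochs` passes (default 5,
matching R·E of the federated arm); federated models train on shards of
the fit subset with the validation subset driving best-round selection.
The external cohort never enters any fitting or selection step — fitting
functions only ever receive the fit subset, and `kfold_protocol` exposes an
`on_fit` hook so instrumented runs can verify it.

Metrics: ROC-AUC (rank definition, ties ½), AUC-PR by step-wise
average-precision summation (not trapezoidal — the two differ in the third
decimal on small sets), balanced accuracy, precision, recall, F₀.₅/F₁/F₂,
log loss with probabilities clipped at 1e-15, and MCC (0 when a marginal
is empty). Thresholded metrics cut at score ≥ 0.5; the threshold is
config-exposed. All ten delegate to scikit-learn; the test suite checks
them against independent explicit-loop reference implementations.

## Synthetic cohort generator

The generator emulates the *post-preprocessing* state of a harmonized
multi-omics cohort: covariate-adjusted, Z-scaled features. Per class the
omics features are Gaussian with unit variance and equicorrelated modular
sub-blocks (ρ = 0.2 within 12-feature genetic blocks — an LD-block
analogue — and 20-feature transcriptomic blocks — a co-expression-module
analogue). A sparse subset (`informative_fraction`, default 0.1) of omics
features carries a standardized class-mean difference of ±`effect_scale`,
split symmetrically (±δ/2 per class) so the marginal stays near
mean 0 / sd 1 regardless of the case:control ratio. The clinical block has
age (δ = 0.5·s), binary family history / ancestry flag / sex with
class-dependent Bernoulli rates, and a smell-test analogue with the
dominant effect (δ = −3·s), all scaled by `effect_scale` s so that s = 0
yields identical class laws.

Defaults are the study composition: 171 cases / 427 controls,
72 + 596 + 5 = 673 features. `effect_scale = 0.4` was calibrated once so
the centrally trained logistic regression operates at internal
AUC-PR ≈ 0.92 (≥ 0.85), the regime the benchmark's real-data results
occupy. The external cohort (default 404 cases / 712 controls) reuses the
same feature space with effects multiplied by 0.7 and informative-feature
means offset by 0.15 — a treatment-effect/covariate-shift analogue.

What the generator does **not** emulate: raw genotypes or read counts,
LD/ co-expression structure beyond equicorrelated blocks, batch effects,
missingness, site effects, or label noise. Passing tests therefore show
that the federation, splitting and evaluation machinery behaves correctly
and that the qualitative FL-vs-central relationships hold under a clean
Gaussian field — not that the absolute scores transfer to real cohorts.

One master seed drives a documented hierarchy of derived streams (cohort
draw, shard membership, learner init, epoch shuffles), so any component is
independently reproducible and every experiment replays bit-for-bit from
its manifest.

## Preprocessing module

Z-scaling uses the population sd (divide by n) — documented because the
two conventions differ at third-decimal level on ~100-sample folds; sd is
floored at 1e-12 and constant columns standardize to exactly 0.
Residualization fits ordinary least squares per feature against
caller-supplied covariates plus an intercept and keeps residuals;
rank-deficient designs are rejected rather than pseudo-inverted. Feature
selection ranks features with an extremely-randomized-trees classifier,
drops those below `importance_quantile` (default 0.5), then greedily drops
the lower-importance member of any pair with r² above `correlation_cap`
(default 0.36, echoing the maximum observed redundancy in the data this
emulates); all dropped features are logged with a reason. The benchmark's
K-fold protocol applies standardization only; selection and
residualization are provided as standalone, training-set-fitted steps.

## Problem sizes used in tests and the acceptance script

Unit and property tests run on cohorts of 60–150 samples with 40 features;
behavioral claims (FL-tracks-central, dispersion, heterogeneity) run on
the full 598 × 673 synthetic cohort with K = 6 folds, 10 seed replicates
in the acceptance tests and 3 in `scripts/acceptance.py`. These sizes were
chosen so a complete run is a desk-scale computation on one CPU core.

## Known limitations

- Tree ensembles cannot use FedProx (no parameter vector to tether);
  requesting it raises.
- Runtime measurements are wall-clock and hardware-dependent; only
  orderings (federated > central) are meaningful.
- With few local epochs the per-sample SGD learner benefits from
  cross-client averaging, so its dispersion curve can *improve* with more
  clients at desk scale — unlike learners fitted to local convergence,
  where local sample size binds. The dispersion experiments report
  whatever the data shows.
- The 80:20 validation split is used only for federated best-round
  selection; central hyperparameters are fixed, not tuned.
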