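# fedsilo

Cross-silo federated learning benchmark for multi-omics case/control
classification.

Institutions holding omics cohorts often cannot pool patient-level data, so
a natural question is how much classification performance is lost when a
model is trained *federatedly* — each silo fits a local learner on its own
samples and a server aggregates only model parameters — compared with
classical central training on the pooled data. `fedsilo` implements that
comparison end to end for binary phenotype prediction on tabular
multi-omics features (genetic, transcriptomic, clinico-demographic), with
synthetic cohorts standing in for access-controlled patient data. It is
aimed at biostatisticians and ML researchers who want a reproducible,
dependency-light simulation of cross-silo federation on omics-shaped data.

## What it implements

**Federation.** Synchronous rounds of

1. broadcast the global parameters *wᵗ* to all *N* clients,
2. each client *k* minimizes its local objective
   *F_k(w) = mean log-loss + (λ/2)‖w‖²*, optionally with the proximal
   tether *(μ/2)‖w − wᵗ‖²* (FedProx; μ = 0 recovers FedAvg exactly),
3. the server forms *wᵗ⁺¹* as the **unweighted** elementwise mean of
   client parameters (shard sizes deliberately ignored; a size-weighted
   mean sits behind a flag).

The global model with the best validation AUC-PR over the *R* rounds is
kept. Local learners: full-batch logistic regression, per-sample SGD with
an inverse-scaling step size, a one-hidden-layer MLP, and a boosted
regression-tree ensemble federated by bagging each round's new trees with
1/N leaf scaling.

**Silos.** Three client-shard strategies of increasing heterogeneity:
`uniform_stratified` (label + size homogeneity), `uniform_random` (label
skew), and `linear_random` (label + size skew; client *i* gets
*i·c* samples with *c = ⌊2C / (N(N+1))⌋*). Every shard must contain both
classes; surpluses go to the last client.

**Evaluation.** Stratified K-fold (K = 6) cross-validation: each fold in
turn is the internal holdout, the rest splits 80:20 into fit and validation
subsets, preprocessing and training touch only the fit subset, and every
model is scored on the holdout and on a distribution-shifted external
cohort with ten metrics (ROC-AUC, AUC-PR, balanced accuracy, precision,
recall, F₀.₅/F₁/F₂, log loss, MCC), reported as mean ± sd over folds.

**Synthetic cohorts.** Class-conditional Gaussians with modular
correlation blocks per omics modality, a sparse standardized effect vector,
and a 5-column clinical block (age, family history, ancestry flag, sex, and
a smell-test score carrying the largest single-feature effect). The default
training cohort has 171 cases / 427 controls and 673 features
(72 genetic-like + 596 transcriptomic-like + 5 clinical); the default
external cohort has 404 cases / 712 controls with attenuated effects and a
mean shift, emulating a post-treatment validation cohort.

## Worked example

```python
import fedsilo as fs

spec = fs.CohortSpec(n_cases=171, n_controls=427, seed=1)
train = fs.generate_cohort(spec)
external = fs.generate_external_cohort(
    spec, fs.ShiftSpec(mean_shift=0.15, effect_attenuation=0.7,
                       label_ratio_override=(404, 712)))

roster = [
    fs.ModelSpec("central_lr", "logistic_regression"),
    fs.ModelSpec("fedavg_lr", "logistic_regression",
                 federation=fs.FederationConfig("logistic_regression", n_clients=2)),
]
summaries = fs.kfold_protocol(train, external, roster, K=6, seed=0)
for name, s in summaries.items():
    print(f"{name}: internal AUC-PR {s.mean('auc_pr'):.3f} ± {s.sd('auc_pr'):.3f}, "
          f"external AUC-PR {s.mean('auc_pr', 'external'):.3f} ± {s.sd('auc_pr', 'external'):.3f}")
```

prints

```
central_lr: internal AUC-PR 0.907 ± 0.018, external AUC-PR 0.847 ± 0.006
fedavg_lr: internal AUC-PR 0.906 ± 0.021, external AUC-PR 0.846 ± 0.006
```

i.e. on this cohort a two-silo FedAvg logistic regression tracks its
centrally trained counterpart to within a fraction of a percent of AUC-PR
on both the internal holdout folds and the shifted external cohort, the
qualitative headline of the benchmark. External scores sit below internal
ones because the external cohort's effects are attenuated.

## Command line

The same pipeline is exposed as a CLI:

```bash
fedsilo generate --seed 1 --out cohort.tsv
fedsilo split --cohort cohort.tsv --strategy linear_random --n-clients 4 --seed 0 --out shards.json
fedsilo train-federated --cohort cohort.tsv --n-clients 2 --seed 0 --out model.json
fedsilo evaluate --model model.json --cohort cohort.tsv --out metrics.json
fedsilo arm1 --seed 0 --out runs/arm1        # central vs federated
fedsilo sweep --seed 0 --out runs/sweep      # AUC-PR vs number of clients
fedsilo heterogeneity --seed 0 --out runs/het
fedsilo replay --manifest runs/arm1/manifest.json --out runs/arm1-replay
```

Every experiment directory contains a `manifest.json` from which `replay`
reproduces all CSV outputs bit-for-bit.

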