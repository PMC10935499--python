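"""End-to-end experiment arms on synthetic cohorts.

Three arms reproduce the benchmark design at whatever scale the plan asks
for, each from a single plan object with one master seed:

* ``central_vs_federated`` — the full central and federated rosters on
  identical folds at n = 2 stratified clients, with paired AUC-PR deltas
  per local-learner family.
* ``dispersion_sweep`` — federated AUC-PR as the same training data is
  spread over an increasing number of clients.
* ``heterogeneity`` — the three split strategies crossed with small client
  counts, with the shard heterogeneity indices that produced each score.

Every arm writes its outputs as data first (tidy CSV + summary CSV) plus a
manifest recording the plan and master seed; ``run_from_manifest`` replays
any arm bit-for-bit.  Plotting is a thin optional layer over the CSVs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from .cohort import CohortSpec, ShiftSpec, generate_cohort, generate_external_cohort
from .config import DEFAULT_K, DEFAULT_LOCAL_EPOCHS, DEFAULT_ROUNDS, logger
from .exceptions import ValidationError
from .federation import FederationConfig
from .learners import LearnerHyperparams
from .metrics import CVSummary, ModelSpec, kfold_protocol, _derive
from .silos import heterogeneity_indices, split as split_shards

ARMS = ("central_vs_federated", "dispersion_sweep", "heterogeneity")
KIND_LABELS = {
    "logistic_regression": "lr", "sgd_linear": "sgd", "mlp": "mlp", "forest": "forest",
}
_LABEL_KINDS = {v: k for k, v in KIND_LABELS.items()}


@dataclass(frozen=True)
class ExperimentPlan:
    arm: str
    cohort: CohortSpec = field(default_factory=lambda: CohortSpec(n_cases=171, n_controls=427))
    shift: ShiftSpec = field(default_factory=lambda: ShiftSpec(
        mean_shift=0.15, effect_attenuation=0.7, label_ratio_override=(404, 712)))
    seed: int = 0
    n_seed_reps: int = 10
    K: int = DEFAULT_K
    rounds: int = DEFAULT_ROUNDS
    local_epochs: int = DEFAULT_LOCAL_EPOCHS
    hyper: LearnerHyperparams = field(default_factory=LearnerHyperparams)
    central_kinds: tuple[str, ...] = ("logistic_regression", "sgd_linear", "mlp", "forest")
    fed_kinds: tuple[str, ...] = ("logistic_regression", "sgd_linear", "mlp", "forest")
    prox_kinds: tuple[str, ...] = ("logistic_regression", "mlp")
    mu_values: tuple[float, ...] = (0.5, 2.0)
    client_counts: tuple[int, ...] = (2, 4, 6, 8, 10, 12, 14, 16, 18)
    strategies: tuple[str, ...] = ("uniform_stratified", "uniform_random", "linear_random")
    het_counts: tuple[int, ...] = (2, 4)
    out_dir: str | None = None

    def validate(self) -> None:
        if self.arm not in ARMS:
            raise ValidationError(f"unknown arm {self.arm!r}; expected one of {ARMS}")
        self.cohort.validate()
        self.shift.validate()


def _fed_config(plan: ExperimentPlan, kind: str, n_clients: int,
                mu: float | None = None) -> FederationConfig:
    strategy = "fedavg" if mu is None else "fedprox"
    return FederationConfig(
        learner_kind=kind, n_clients=n_clients, strategy=strategy, mu=mu,
        rounds=plan.rounds, local_epochs=plan.local_epochs, hyper=plan.hyper)


def _central_spec(plan: ExperimentPlan, kind: str) -> ModelSpec:
    return ModelSpec(
        name=f"central_{KIND_LABELS[kind]}", learner_kind=kind, hyper=plan.hyper,
        epochs=plan.rounds * plan.local_epochs)


def _fed_spec(plan: ExperimentPlan, kind: str, n_clients: int,
              split_strategy: str = "uniform_stratified",
              mu: float | None = None, suffix: str = "") -> ModelSpec:
    base = (f"fedavg_{KIND_LABELS[kind]}" if mu is None
            else f"fedprox_mu{mu:g}_{KIND_LABELS[kind]}")
    return ModelSpec(
        name=base + suffix, learner_kind=kind, hyper=plan.hyper,
        federation=_fed_config(plan, kind, n_clients, mu),
        split_strategy=split_strategy)


def _tidy(summaries: dict[str, CVSummary], rep: int,
          annotations: dict[str, dict]) -> pd.DataFrame:
    frames = []
    for name, summary in summaries.items():
        frame = summary.tidy()
        frame["seed_rep"] = rep
        for key, value in annotations[name].items():
            frame[key] = value
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def _cohorts(plan: ExperimentPlan, rep: int):
    spec = replace(plan.cohort, seed=_derive(plan.seed, rep, 100))
    return generate_cohort(spec), generate_external_cohort(spec, plan.shift)


def _summary_table(tidy: pd.DataFrame, keys: list[str]) -> pd.DataFrame:
    """mean +/- sd over folds and seed reps, one row per model/metric."""
    grouped = tidy.groupby(keys + ["test_set", "metric"])["value"]
    out = grouped.agg(["mean", "std", "count"]).reset_index()
    return out.rename(columns={"std": "sd", "count": "n_values"})


def run_central_vs_federated(plan: ExperimentPlan) -> dict[str, pd.DataFrame]:
    """Arm 1: paired central-vs-federated comparison at n = 2 stratified."""
    plan.validate()
    n_clients = 2
    specs, annot = [], {}
    for kind in plan.central_kinds:
        s = _central_spec(plan, kind)
        specs.append(s)
        annot[s.name] = {"strategy": "central", "n_clients": 0,
                         "split_method": "", "learner": KIND_LABELS[kind]}
    for kind in plan.fed_kinds:
        s = _fed_spec(plan, kind, n_clients)
        specs.append(s)
        annot[s.name] = {"strategy": "fedavg", "n_clients": n_clients,
                         "split_method": "uniform_stratified",
                         "learner": KIND_LABELS[kind]}
    for mu in plan.mu_values:
        for kind in plan.prox_kinds:
            s = _fed_spec(plan, kind, n_clients, mu=mu)
            specs.append(s)
            annot[s.name] = {"strategy": "fedprox", "n_clients": n_clients,
                             "split_method": "uniform_stratified",
                             "learner": KIND_LABELS[kind], "mu": mu}
    tidy_frames = []
    for rep in range(plan.n_seed_reps):
        internal, external = _cohorts(plan, rep)
        summaries = kfold_protocol(internal, external, specs, K=plan.K,
                                   seed=_derive(plan.seed, rep, 200))
        tidy_frames.append(_tidy(summaries, rep, annot))
        logger.info("central_vs_federated: rep %d/%d done", rep + 1, plan.n_seed_reps)
    tidy = pd.concat(tidy_frames, ignore_index=True)

    aucpr = tidy[tidy.metric == "auc_pr"]
    mean_scores = (aucpr.groupby(["model", "strategy", "learner", "test_set"])
                   ["value"].mean().reset_index())
    deltas = []
    central = mean_scores[mean_scores.strategy == "central"]
    for _, row in mean_scores[mean_scores.strategy != "central"].iterrows():
        base = central[(central.learner == row.learner)
                       & (central.test_set == row.test_set)]
        if len(base):
            deltas.append({
                "model": row.model, "learner": row.learner,
                "test_set": row.test_set, "auc_pr": row.value,
                "central_auc_pr": float(base.value.iloc[0]),
                "delta_auc_pr": row.value - float(base.value.iloc[0]),
            })
    results = {"tidy": tidy,
               "summary": _summary_table(tidy, ["model", "strategy", "learner"]),
               "deltas": pd.DataFrame(deltas)}
    _emit(plan, results)
    return results


def _feasible(plan: ExperimentPlan, n_clients: int) -> bool:
    # each stratified shard of the fit split needs >= 1 case and control
    fit_cases = int(plan.cohort.n_cases * (plan.K - 1) / plan.K * 0.8)
    fit_controls = int(plan.cohort.n_controls * (plan.K - 1) / plan.K * 0.8)
    return min(fit_cases, fit_controls) >= n_clients


def run_dispersion_sweep(plan: ExperimentPlan) -> dict[str, pd.DataFrame]:
    """Arm 2: AUC-PR versus number of clients with total data constant."""
    plan.validate()
    specs, annot = [], {}
    for n in plan.client_counts:
        if not _feasible(plan, n):
            logger.warning("dispersion sweep: n=%d infeasible for cohort, skipped", n)
            continue
        for kind in plan.fed_kinds:
            s = _fed_spec(plan, kind, n, suffix=f"@n{n}")
            specs.append(s)
            annot[s.name] = {"strategy": "fedavg", "n_clients": n,
                             "split_method": "uniform_stratified",
                             "learner": KIND_LABELS[kind]}
    tidy_frames = []
    for rep in range(plan.n_seed_reps):
        internal, external = _cohorts(plan, rep)
        summaries = kfold_protocol(internal, external, specs, K=plan.K,
                                   seed=_derive(plan.seed, rep, 200))
        tidy_frames.append(_tidy(summaries, rep, annot))
        logger.info("dispersion_sweep: rep %d/%d done", rep + 1, plan.n_seed_reps)
    tidy = pd.concat(tidy_frames, ignore_index=True)
    aucpr = tidy[tidy.metric == "auc_pr"]
    curve = (aucpr.groupby(["learner", "n_clients", "test_set"])["value"]
             .agg(["mean", "std"]).reset_index().rename(columns={"std": "sd"}))
    results = {"tidy": tidy,
               "summary": _summary_table(tidy, ["model", "learner", "n_clients"]),
               "curve": curve}
    _emit(plan, results)
    return results


def run_heterogeneity(plan: ExperimentPlan) -> dict[str, pd.DataFrame]:
    """Arm 3: split strategies crossed with client counts, with the shard
    heterogeneity indices that produced every score."""
    plan.validate()
    specs, annot = [], {}
    for strategy in plan.strategies:
        for n in plan.het_counts:
            for kind in plan.fed_kinds:
                s = _fed_spec(plan, kind, n, split_strategy=strategy,
                              suffix=f"@{strategy}@n{n}")
                specs.append(s)
                annot[s.name] = {"strategy": "fedavg", "n_clients": n,
                                 "split_method": strategy,
                                 "learner": KIND_LABELS[kind]}
    tidy_frames, het_rows = [], []
    for rep in range(plan.n_seed_reps):
        internal, external = _cohorts(plan, rep)
        seed = _derive(plan.seed, rep, 200)
        summaries = kfold_protocol(internal, external, specs, K=plan.K, seed=seed)
        tidy_frames.append(_tidy(summaries, rep, annot))
        # recompute each model's shard sets exactly as the protocol drew them
        for mi, spec in enumerate(specs):
            summary = summaries[spec.name]
            for fold, assignment in enumerate(summary.fold_assignments):
                fit_cohort = internal.subset(assignment["fit"])
                shardset = split_shards(
                    fit_cohort, spec.split_strategy,
                    spec.federation.n_clients,
                    seed=_derive(_derive(seed, fold, mi), 7))
                indices = heterogeneity_indices(shardset, fit_cohort)
                het_rows.append({"model": spec.name, "seed_rep": rep,
                                 "fold": fold, **annot[spec.name], **indices})
        logger.info("heterogeneity: rep %d/%d done", rep + 1, plan.n_seed_reps)
    tidy = pd.concat(tidy_frames, ignore_index=True)
    het = pd.DataFrame(het_rows)

    aucpr = (tidy[tidy.metric == "auc_pr"]
             .groupby(["learner", "split_method", "n_clients", "test_set"])
             ["value"].mean().reset_index())
    stratified = aucpr[aucpr.split_method == "uniform_stratified"].rename(
        columns={"value": "stratified_value"}).drop(columns="split_method")
    deltas = aucpr.merge(stratified, on=["learner", "n_clients", "test_set"])
    deltas["delta_vs_stratified"] = deltas["value"] - deltas["stratified_value"]
    het_means = (het.groupby(["learner", "split_method", "n_clients"])
                 [["label_skew", "size_skew"]].mean().reset_index())
    deltas = deltas.merge(het_means, on=["learner", "split_method", "n_clients"])
    results = {"tidy": tidy,
               "summary": _summary_table(tidy, ["model", "learner", "split_method",
                                                "n_clients"]),
               "deltas": deltas, "heterogeneity": het}
    _emit(plan, results)
    return results


_ARM_RUNNERS = {
    "central_vs_federated": run_central_vs_federated,
    "dispersion_sweep": run_dispersion_sweep,
    "heterogeneity": run_heterogeneity,
}


def run_arm(plan: ExperimentPlan) -> dict[str, pd.DataFrame]:
    plan.validate()
    return _ARM_RUNNERS[plan.arm](plan)


# --- manifests and replay ------------------------------------------------

def plan_to_dict(plan: ExperimentPlan) -> dict:
    d = dataclasses.asdict(plan)
    if d["shift"]["label_ratio_override"] is not None:
        d["shift"]["label_ratio_override"] = list(d["shift"]["label_ratio_override"])
    return d


def plan_from_dict(d: dict) -> ExperimentPlan:
    d = dict(d)
    cohort = CohortSpec(**d.pop("cohort"))
    shift_d = d.pop("shift")
    if shift_d.get("label_ratio_override") is not None:
        shift_d["label_ratio_override"] = tuple(shift_d["label_ratio_override"])
    shift = ShiftSpec(**shift_d)
    hyper_d = d.pop("hyper")
    hyper_d["hidden"] = tuple(hyper_d["hidden"])
    hyper = LearnerHyperparams(**hyper_d)
    for key in ("central_kinds", "fed_kinds", "prox_kinds", "mu_values",
                "client_counts", "strategies", "het_counts"):
        d[key] = tuple(d[key])
    return ExperimentPlan(cohort=cohort, shift=shift, hyper=hyper, **d)


def _emit(plan: ExperimentPlan, results: dict[str, pd.DataFrame]) -> None:
    if plan.out_dir is None:
        return
    out = Path(plan.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "manifest.json").write_text(
        json.dumps({"arm": plan.arm, "plan": plan_to_dict(plan)},
                   indent=1, sort_keys=True))
    for name, frame in results.items():
        ordered = frame.sort_values(list(frame.columns), kind="stable")
        ordered.to_csv(out / f"{name}.csv", index=False, float_format="%.17g")


def run_from_manifest(manifest_path: str | Path,
                      out_dir: str | Path | None = None) -> dict[str, pd.DataFrame]:
    """Replay an emitted experiment exactly (same plan, same master seed)."""
    manifest = json.loads(Path(manifest_path).read_text())
    plan = plan_from_dict(manifest["plan"])
    if out_dir is not None:
        plan = replace(plan, out_dir=str(out_dir))
    return run_arm(plan)
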