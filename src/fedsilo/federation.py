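"""Synchronous cross-silo federation engine.

One communication round broadcasts the global parameters to every client,
runs E local epochs on each shard (with a proximal tether to the global
model under the fedprox strategy), and aggregates the returned parameters:
an unweighted elementwise mean for parametric learners — deliberately
ignoring shard sizes, a size-weighted mean is available behind a flag — or
a bagging-style tree merge for forest learners.  Rounds are synchronous and
failure-free; the best global model by validation AUC-PR (earliest round on
ties) is returned.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .config import DEFAULT_LOCAL_EPOCHS, DEFAULT_ROUNDS, logger
from .exceptions import ArchitectureError, FedsiloError, ValidationError
from .learners import (
    Learner,
    LearnerHyperparams,
    ModelParams,
    ProxSpec,
    TreeParams,
    get_parameters,
    init_learner,
    local_fit,
    predict_scores,
    set_parameters,
)
from sklearn.metrics import average_precision_score

STRATEGY_NAMES = ("fedavg", "fedprox")


@dataclass(frozen=True)
class FederationConfig:
    learner_kind: str
    n_clients: int
    strategy: str = "fedavg"
    mu: float | None = None
    rounds: int = DEFAULT_ROUNDS
    local_epochs: int = DEFAULT_LOCAL_EPOCHS
    hyper: LearnerHyperparams = field(default_factory=LearnerHyperparams)
    seed: int = 0
    size_weighted: bool = False

    def validate(self) -> None:
        if self.strategy not in STRATEGY_NAMES:
            raise ValidationError(f"unknown strategy {self.strategy!r}")
        if (self.mu is not None) != (self.strategy == "fedprox"):
            raise ValidationError("mu must be given exactly when strategy is fedprox")
        if self.mu is not None and self.mu < 0:
            raise ValidationError("mu must be nonnegative")
        if self.rounds < 1 or self.n_clients < 1 or self.local_epochs < 1:
            raise ValidationError("rounds, n_clients and local_epochs must be >= 1")


def client_seed(master_seed: int, client: int) -> int:
    """Derived per-client seed (also the global-init seed for client 0)."""
    return int(np.random.SeedSequence((master_seed, client)).generate_state(1)[0] % 2**31)


@dataclass
class RoundRecord:
    round_index: int
    client_params: list[ModelParams]
    global_params: ModelParams
    val_auc_pr: float | None = None


@dataclass
class FederatedResult:
    best_params: ModelParams
    history: list[RoundRecord]
    chosen_round: int            # 1-based; argmax of validation AUC-PR, earliest tie
    seconds: float


def aggregate_mean(params_list: list[ModelParams],
                   weights: np.ndarray | None = None) -> ModelParams:
    """Elementwise arithmetic mean of parametric client tensors.

    Unweighted by default (client sizes are ignored); identical inputs are
    returned exactly, so averaging k copies of one model is a no-op.
    """
    if not params_list:
        raise ValidationError("cannot aggregate an empty parameter list")
    if any(not p.is_parametric for p in params_list):
        raise ArchitectureError("forest parameters must go through aggregate_forest")
    arch = params_list[0].architecture()
    for p in params_list[1:]:
        if p.architecture() != arch or p.kind != params_list[0].kind:
            raise ArchitectureError("mixed architectures cannot be averaged")
    if weights is not None:
        weights = np.asarray(weights, dtype=float)
        weights = weights / weights.sum()
    out: dict[str, np.ndarray] = {}
    for name in params_list[0].tensors:
        stack = np.stack([p.tensors[name] for p in params_list])
        if (stack == stack[0]).all():
            out[name] = stack[0].copy()
        elif weights is None:
            # summing in sorted order makes the mean exactly invariant to
            # client ordering (floating addition is not commutative-assoc.)
            out[name] = np.sort(stack, axis=0).mean(axis=0)
        else:
            out[name] = np.tensordot(weights, stack, axes=1)
    return ModelParams(params_list[0].kind, out)


def aggregate_forest(ensembles: list[ModelParams],
                     incoming: ModelParams | None = None,
                     round_index: int = -1) -> ModelParams:
    """Merge the round's newly grown trees into the global ensemble.

    Every client ensemble must extend the incoming global ensemble; the new
    global is the incoming trees plus each client's new trees with leaf
    values scaled by 1/N, so the round's increment is the average of the
    clients' margin increments (bagging).  With N = 1 the client's trees
    pass through unscaled.
    """
    if not ensembles:
        raise ValidationError("cannot aggregate an empty ensemble list")
    if any(p.kind != "forest" for p in ensembles):
        raise ArchitectureError("aggregate_forest expects forest parameters only")
    if incoming is None:
        incoming = ModelParams("forest", trees=[])
    prefix = incoming.trees
    for ci, ens in enumerate(ensembles):
        if len(ens.trees) < len(prefix) or not all(
            a.equals(b) for a, b in zip(prefix, ens.trees)
        ):
            raise ArchitectureError(
                f"client {ci} ensemble does not extend the incoming global ensemble"
            )
    n = len(ensembles)
    merged = [t for t in incoming.copy().trees]
    for ci, ens in enumerate(ensembles):
        for tree in ens.trees[len(prefix):]:
            scaled = TreeParams(
                feature=tree.feature.copy(), threshold=tree.threshold.copy(),
                children_left=tree.children_left.copy(),
                children_right=tree.children_right.copy(),
                value=tree.value / n,
                round_index=round_index if round_index >= 0 else tree.round_index,
                client=ci,
            )
            merged.append(scaled)
    return ModelParams("forest", trees=merged)


ShardData = tuple[np.ndarray, np.ndarray]


def init_clients(config: FederationConfig, n_features: int) -> list[Learner]:
    return [
        init_learner(config.learner_kind, n_features, config.hyper,
                     seed=client_seed(config.seed, i))
        for i in range(config.n_clients)
    ]


def initial_global(config: FederationConfig, n_features: int) -> ModelParams:
    return get_parameters(
        init_learner(config.learner_kind, n_features, config.hyper,
                     seed=client_seed(config.seed, 0))
    )


def run_round(
    global_params: ModelParams,
    shard_datas: list[ShardData],
    config: FederationConfig,
    client_states: list[Learner] | None = None,
    round_index: int = 1,
) -> tuple[ModelParams, RoundRecord]:
    """One synchronous round: broadcast, local fit, aggregate."""
    config.validate()
    if len(shard_datas) != config.n_clients:
        raise ValidationError(
            f"{len(shard_datas)} shards for {config.n_clients} clients"
        )
    if client_states is None:
        client_states = init_clients(config, shard_datas[0][0].shape[1])
    client_params: list[ModelParams] = []
    for ci, (state, (X, y)) in enumerate(zip(client_states, shard_datas)):
        try:
            set_parameters(state, global_params)
            prox = (ProxSpec(config.mu, global_params)
                    if config.strategy == "fedprox" else None)
            local_fit(state, X, y, epochs=config.local_epochs, prox=prox,
                      round_index=round_index, client=ci)
            client_params.append(get_parameters(state))
        except FedsiloError as err:
            raise type(err)(f"client {ci}, round {round_index}: {err}") from err
    if config.learner_kind == "forest":
        new_global = aggregate_forest(client_params, incoming=global_params,
                                      round_index=round_index)
    else:
        weights = None
        if config.size_weighted:
            weights = np.array([len(y) for _, y in shard_datas], dtype=float)
        new_global = aggregate_mean(client_params, weights=weights)
    record = RoundRecord(round_index, client_params, new_global)
    return new_global, record


def train_federated(
    shard_datas: list[ShardData],
    validation: ShardData,
    config: FederationConfig,
) -> FederatedResult:
    """Run R rounds and return the global model with the best validation
    AUC-PR (earliest round on ties), with the full round history."""
    config.validate()
    Xv, yv = validation
    if len(yv) == 0:
        raise ValidationError("validation set is empty")
    start = time.perf_counter()
    n_features = shard_datas[0][0].shape[1]
    clients = init_clients(config, n_features)
    global_params = initial_global(config, n_features)
    history: list[RoundRecord] = []
    for r in range(1, config.rounds + 1):
        global_params, record = run_round(global_params, shard_datas, config,
                                          client_states=clients, round_index=r)
        record.val_auc_pr = float(
            average_precision_score(yv, predict_scores(global_params, Xv)))
        history.append(record)
        logger.debug("round %d: validation AUC-PR %.4f", r, record.val_auc_pr)
    scores = [rec.val_auc_pr for rec in history]
    chosen = int(np.argmax(scores)) + 1       # argmax takes the earliest tie
    return FederatedResult(
        best_params=history[chosen - 1].global_params.copy(),
        history=history,
        chosen_round=chosen,
        seconds=time.perf_counter() - start,
    )
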