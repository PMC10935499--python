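"""Local learners with an aggregation-friendly parameter contract.

Each federation client trains one of four learner families on its shard:

* ``logistic_regression`` — full-batch gradient descent on the mean
  regularized log-loss.
* ``sgd_linear`` — the same objective optimized per sample in shuffled
  order under the classic inverse-scaling step size
  eta_t = eta0 / sqrt(1 + t) (t = lifetime update count, persisted in the
  learner state).
* ``mlp`` — one ReLU hidden layer with a logistic output, mini-batch
  gradient descent.
* ``forest`` — a boosted ensemble of regression trees on log-loss
  pseudo-residuals; the only non-parametric kind.

All parametric kinds expose their raw tensors so a server can average them;
they optionally add the proximal gradient mu * (w - w_anchor), i.e. the
gradient of the penalty (mu/2) * ||w - w_anchor||^2 that tethers local
updates to the current global model under client heterogeneity.

The gradient convention is the MEAN log-loss over the shard (plus L2 on
weights, never on biases), so step sizes are comparable across shard sizes.
Every epoch's shuffle is drawn from (seed, epoch_counter), and the counter
persists in the learner state: E epochs in one call and E chained one-epoch
calls follow the identical schedule.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.tree import DecisionTreeRegressor

from .config import (
    DEFAULT_BATCH_SIZE,
    DEFAULT_HIDDEN,
    DEFAULT_L2,
    DEFAULT_LEARNING_RATE,
    DEFAULT_TREE_MAX_DEPTH,
    DEFAULT_TREE_SHRINKAGE,
    DEFAULT_TREES_PER_ROUND,
)
from .exceptions import (
    ArchitectureError,
    FeasibilityError,
    UnsupportedOperationError,
    ValidationError,
)

LEARNER_KINDS = ("logistic_regression", "sgd_linear", "mlp", "forest")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass(frozen=True)
class LearnerHyperparams:
    learning_rate: float = DEFAULT_LEARNING_RATE
    batch_size: int = DEFAULT_BATCH_SIZE
    l2: float = DEFAULT_L2
    hidden: tuple[int, ...] = DEFAULT_HIDDEN
    trees_per_round: int = DEFAULT_TREES_PER_ROUND
    tree_max_depth: int = DEFAULT_TREE_MAX_DEPTH
    tree_shrinkage: float = DEFAULT_TREE_SHRINKAGE

    def validate(self) -> None:
        if self.learning_rate <= 0 or self.batch_size < 1 or self.l2 < 0:
            raise ValidationError("invalid optimizer hyperparameters")
        if any(h < 1 for h in self.hidden):
            raise ValidationError("hidden sizes must be >= 1")
        if self.trees_per_round < 1 or self.tree_max_depth < 1 or self.tree_shrinkage <= 0:
            raise ValidationError("invalid forest hyperparameters")


@dataclass
class TreeParams:
    """One regression tree in flat-array form (sklearn node layout):
    ``children_left[i] == -1`` marks a leaf; samples with
    x[feature] <= threshold go left."""

    feature: np.ndarray
    threshold: np.ndarray
    children_left: np.ndarray
    children_right: np.ndarray
    value: np.ndarray            # additive margin contribution at each leaf
    round_index: int = -1        # provenance: federation round
    client: int = -1             # provenance: originating client

    def equals(self, other: "TreeParams") -> bool:
        return (
            np.array_equal(self.feature, other.feature)
            and np.array_equal(self.threshold, other.threshold)
            and np.array_equal(self.children_left, other.children_left)
            and np.array_equal(self.children_right, other.children_right)
            and np.array_equal(self.value, other.value)
        )

    def margins(self, X: np.ndarray) -> np.ndarray:
        node = np.zeros(len(X), dtype=np.intp)
        while True:
            internal = self.children_left[node] != -1
            if not internal.any():
                break
            idx = np.flatnonzero(internal)
            n = node[idx]
            go_left = X[idx, self.feature[n]] <= self.threshold[n]
            node[idx] = np.where(go_left, self.children_left[n], self.children_right[n])
        return self.value[node]


@dataclass
class ModelParams:
    """Aggregable learner parameters: named tensors for parametric kinds, an
    ordered tree list for the forest kind."""

    kind: str
    tensors: dict[str, np.ndarray] | None = None
    trees: list[TreeParams] | None = None

    @property
    def is_parametric(self) -> bool:
        return self.kind != "forest"

    def architecture(self) -> tuple:
        if self.is_parametric:
            return tuple((name, t.shape) for name, t in self.tensors.items())
        return ("forest",)

    def copy(self) -> "ModelParams":
        if self.is_parametric:
            return ModelParams(self.kind, {k: v.copy() for k, v in self.tensors.items()})
        return ModelParams(self.kind, trees=[copy.deepcopy(t) for t in self.trees])

    def n_features(self) -> int | None:
        if self.kind in ("logistic_regression", "sgd_linear"):
            return self.tensors["w"].shape[0]
        if self.kind == "mlp":
            return self.tensors["W0"].shape[0]
        return None

    def to_json(self, path: str | Path) -> None:
        if self.is_parametric:
            payload = {"kind": self.kind,
                       "tensors": {k: v.tolist() for k, v in self.tensors.items()}}
        else:
            payload = {"kind": self.kind, "trees": [{
                "feature": t.feature.tolist(), "threshold": t.threshold.tolist(),
                "children_left": t.children_left.tolist(),
                "children_right": t.children_right.tolist(),
                "value": t.value.tolist(),
                "round_index": t.round_index, "client": t.client,
            } for t in self.trees]}
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "ModelParams":
        d = json.loads(Path(path).read_text())
        if d["kind"] != "forest":
            return cls(d["kind"], {k: np.asarray(v, dtype=float)
                                   for k, v in d["tensors"].items()})
        trees = [TreeParams(
            feature=np.asarray(t["feature"], dtype=np.intp),
            threshold=np.asarray(t["threshold"], dtype=float),
            children_left=np.asarray(t["children_left"], dtype=np.intp),
            children_right=np.asarray(t["children_right"], dtype=np.intp),
            value=np.asarray(t["value"], dtype=float),
            round_index=t["round_index"], client=t["client"],
        ) for t in d["trees"]]
        return cls("forest", trees=trees)


@dataclass(frozen=True)
class ProxSpec:
    """Proximal penalty (mu/2)||w - anchor||^2 added to the local objective."""

    mu: float
    anchor: ModelParams

    def validate(self, kind: str, arch: tuple) -> None:
        if self.mu < 0:
            raise ValidationError("mu must be nonnegative")
        if self.anchor.kind != kind or self.anchor.architecture() != arch:
            raise ArchitectureError("proximal anchor architecture does not match the learner")


@dataclass
class Learner:
    """Mutable learner state: parameters plus the persistent epoch counter
    that drives the shuffle schedule."""

    kind: str
    n_features: int
    hyper: LearnerHyperparams
    seed: int
    params: ModelParams
    epoch_counter: int = 0
    step_counter: int = 0      # per-sample updates taken (sgd schedule)


def _initial_params(kind: str, d: int, hyper: LearnerHyperparams,
                    seed: int) -> ModelParams:
    if kind in ("logistic_regression", "sgd_linear"):
        return ModelParams(kind, {"w": np.zeros(d), "b": np.zeros(1)})
    if kind == "mlp":
        # tag 2**31 keeps the init stream clear of the epoch streams, whose
        # second entropy word is the (much smaller) epoch counter
        rng = np.random.default_rng(np.random.SeedSequence((seed, 2**31)))
        sizes = (d, *hyper.hidden, 1)
        tensors: dict[str, np.ndarray] = {}
        for i, (fan_in, fan_out) in enumerate(zip(sizes[:-1], sizes[1:])):
            bound = np.sqrt(6.0 / (fan_in + fan_out))
            tensors[f"W{i}"] = rng.uniform(-bound, bound, size=(fan_in, fan_out))
            tensors[f"b{i}"] = np.zeros(fan_out)
        return ModelParams(kind, tensors)
    return ModelParams("forest", trees=[])


def init_learner(kind: str, n_features: int,
                 hyper: LearnerHyperparams | None = None, seed: int = 0) -> Learner:
    """Deterministic initial state for a fixed seed; linear kinds start at
    zero, the MLP from a Glorot draw, the forest from an empty ensemble."""
    if kind not in LEARNER_KINDS:
        raise ValidationError(f"unknown learner kind {kind!r}; expected one of {LEARNER_KINDS}")
    if n_features < 1:
        raise ValidationError("n_features must be >= 1")
    hyper = hyper or LearnerHyperparams()
    hyper.validate()
    return Learner(kind, n_features, hyper, seed,
                   _initial_params(kind, n_features, hyper, seed))


def get_parameters(state: Learner) -> ModelParams:
    return state.params.copy()


def set_parameters(state: Learner, params: ModelParams) -> Learner:
    if params.kind != state.kind:
        raise ArchitectureError(f"cannot load {params.kind} params into a {state.kind} learner")
    if params.is_parametric:
        have, want = params.architecture(), state.params.architecture()
        if have != want:
            bad = [f"{n}: got {s}, want {ws}" for (n, s), (_, ws) in zip(have, want) if s != ws]
            if len(have) != len(want):
                bad.append(f"tensor count {len(have)} != {len(want)}")
            raise ArchitectureError("parameter shape mismatch: " + "; ".join(bad))
    state.params = params.copy()
    return state


def predict_scores(state_or_params: Learner | ModelParams, X: np.ndarray) -> np.ndarray:
    """Case probabilities in [0, 1]; purely a function of the parameters."""
    params = state_or_params.params if isinstance(state_or_params, Learner) else state_or_params
    X = np.asarray(X, dtype=float)
    d = params.n_features()
    if d is not None and X.shape[1] != d:
        raise ValidationError(f"feature count {X.shape[1]} does not match model dimension {d}")
    if params.kind in ("logistic_regression", "sgd_linear"):
        return _sigmoid(X @ params.tensors["w"] + params.tensors["b"][0])
    if params.kind == "mlp":
        return _mlp_forward(params.tensors, X)[-1].ravel()
    margin = np.zeros(len(X))
    for tree in params.trees:
        margin += tree.margins(X)
    return _sigmoid(margin)


def _mlp_forward(tensors: dict[str, np.ndarray], X: np.ndarray) -> list[np.ndarray]:
    """Activations per layer; ReLU hidden, logistic output."""
    n_layers = len(tensors) // 2
    acts = [X]
    h = X
    for i in range(n_layers):
        z = h @ tensors[f"W{i}"] + tensors[f"b{i}"]
        h = _sigmoid(z) if i == n_layers - 1 else np.maximum(z, 0.0)
        acts.append(h)
    return acts


def _epoch_rng(state: Learner) -> np.random.Generator:
    rng = np.random.default_rng(np.random.SeedSequence((state.seed, state.epoch_counter)))
    state.epoch_counter += 1
    return rng


def _prox_step(candidate: np.ndarray, anchor: np.ndarray, lr: float,
               mu: float) -> np.ndarray:
    """Backward-Euler treatment of the proximal penalty.

    Solves w' = candidate - lr * mu * (w' - anchor) for w', i.e. the
    penalty gradient is evaluated at the updated point.  Unconditionally
    stable: w' -> anchor as mu -> inf at any learning rate, and mu = 0
    returns the candidate bit-for-bit.
    """
    return (candidate + lr * mu * anchor) / (1.0 + lr * mu)


def _apply_update(t: dict[str, np.ndarray], name: str, grad: np.ndarray,
                  lr: float, prox: ProxSpec | None) -> None:
    candidate = t[name] - lr * grad
    if prox is not None:
        candidate = _prox_step(candidate, prox.anchor.tensors[name], lr, prox.mu)
    t[name] = candidate


def _fit_linear(state: Learner, X: np.ndarray, y: np.ndarray,
                epochs: int, prox: ProxSpec | None) -> None:
    hp = state.hyper
    t = state.params.tensors
    full_batch = state.kind == "logistic_regression"
    for _ in range(epochs):
        rng = _epoch_rng(state)
        if full_batch:
            p = _sigmoid(X @ t["w"] + t["b"][0])
            gw = X.T @ (p - y) / len(y) + hp.l2 * t["w"]
            gb = np.mean(p - y) * np.ones(1)
            _apply_update(t, "w", gw, hp.learning_rate, prox)
            _apply_update(t, "b", gb, hp.learning_rate, prox)
        else:
            for i in rng.permutation(len(y)):
                eta = hp.learning_rate / np.sqrt(1.0 + state.step_counter)
                p = _sigmoid(X[i] @ t["w"] + t["b"][0])
                gw = (p - y[i]) * X[i] + hp.l2 * t["w"]
                gb = (p - y[i]) * np.ones(1)
                _apply_update(t, "w", gw, eta, prox)
                _apply_update(t, "b", gb, eta, prox)
                state.step_counter += 1


def _fit_mlp(state: Learner, X: np.ndarray, y: np.ndarray,
             epochs: int, prox: ProxSpec | None) -> None:
    hp = state.hyper
    t = state.params.tensors
    n_layers = len(t) // 2
    for _ in range(epochs):
        rng = _epoch_rng(state)
        order = rng.permutation(len(y))
        for start in range(0, len(y), hp.batch_size):
            batch = order[start:start + hp.batch_size]
            Xb, yb = X[batch], y[batch]
            acts = _mlp_forward(t, Xb)
            # output delta for mean log-loss with logistic output
            delta = (acts[-1].ravel() - yb)[:, None] / len(yb)
            for i in range(n_layers - 1, -1, -1):
                gW = acts[i].T @ delta + hp.l2 * t[f"W{i}"]
                gb = delta.sum(axis=0)
                if i > 0:
                    delta = (delta @ t[f"W{i}"].T) * (acts[i] > 0)
                _apply_update(t, f"W{i}", gW, hp.learning_rate, prox)
                _apply_update(t, f"b{i}", gb, hp.learning_rate, prox)


def _extract_tree(reg: DecisionTreeRegressor, shrinkage: float,
                  round_index: int, client: int) -> TreeParams:
    tr = reg.tree_
    return TreeParams(
        feature=tr.feature.copy(),
        threshold=tr.threshold.copy(),
        children_left=tr.children_left.copy(),
        children_right=tr.children_right.copy(),
        value=shrinkage * tr.value[:, 0, 0].copy(),
        round_index=round_index, client=client,
    )


def _fit_forest(state: Learner, X: np.ndarray, y: np.ndarray, epochs: int,
                round_index: int = -1, client: int = -1) -> None:
    hp = state.hyper
    margin = np.zeros(len(y))
    for tree in state.params.trees:
        margin += tree.margins(X)
    for _ in range(epochs * hp.trees_per_round):
        rng = _epoch_rng(state)
        residual = y - _sigmoid(margin)
        reg = DecisionTreeRegressor(
            max_depth=hp.tree_max_depth, max_features="sqrt",
            random_state=int(rng.integers(2**31)),
        ).fit(X, residual)
        tree = _extract_tree(reg, hp.tree_shrinkage, round_index, client)
        state.params.trees.append(tree)
        margin += tree.margins(X)


def local_fit(state: Learner, X: np.ndarray, y: np.ndarray, epochs: int = 1,
              prox: ProxSpec | None = None, round_index: int = -1,
              client: int = -1) -> Learner:
    """Run ``epochs`` local passes, optionally under a proximal penalty.

    The shard must contain both classes; proximal fitting is undefined for
    the non-parametric forest kind.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if epochs < 1:
        raise ValidationError("epochs must be >= 1")
    if len(np.unique(y)) < 2:
        raise FeasibilityError("shard has a single class; local fitting is undefined")
    if X.shape[1] != state.n_features:
        raise ValidationError(
            f"shard has {X.shape[1]} features, learner expects {state.n_features}"
        )
    if prox is not None:
        if state.kind == "forest":
            raise UnsupportedOperationError("proximal fitting is unsupported for forest learners")
        prox.validate(state.kind, state.params.architecture())
    if state.kind in ("logistic_regression", "sgd_linear"):
        _fit_linear(state, X, y, epochs, prox)
    elif state.kind == "mlp":
        _fit_mlp(state, X, y, epochs, prox)
    else:
        _fit_forest(state, X, y, epochs, round_index, client)
    return state
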