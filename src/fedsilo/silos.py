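"""Client-shard construction for cross-silo federation experiments.

Three split strategies of increasing heterogeneity partition a training
cohort into n disjoint client datasets:

* ``uniform_stratified`` — phenotype-stratified, near-equal sizes: label and
  size homogeneity.
* ``uniform_random`` — near-equal sizes, random class composition: label
  heterogeneity.
* ``linear_random`` — client i receives i*c samples with
  c = floor(2C / (N(N+1))), random composition: label and size
  heterogeneity.

Any surplus after integer division goes to the LAST client.  Every shard
must contain at least one case and one control for its local learner to be
trainable; random strategies redraw (with a derived seed) up to
``MAX_SPLIT_RETRIES`` times before raising.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cohort import LabeledCohort
from .config import MAX_SPLIT_RETRIES
from .exceptions import FeasibilityError, ValidationError

STRATEGIES = ("uniform_stratified", "uniform_random", "linear_random")


def _check_strategy(name: str) -> str:
    if name not in STRATEGIES:
        raise ValidationError(f"unknown split strategy {name!r}; expected one of {STRATEGIES}")
    return name


@dataclass
class ShardSet:
    """A disjoint, exhaustive partition of a cohort's sample indices."""

    shards: list[np.ndarray]
    strategy: str
    n_clients: int
    seed: int
    source_size: int

    def sizes(self) -> list[int]:
        return [len(s) for s in self.shards]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "strategy": self.strategy,
            "n_clients": self.n_clients,
            "seed": self.seed,
            "source_size": self.source_size,
            "shards": [s.tolist() for s in self.shards],
        }))

    @classmethod
    def from_json(cls, path: str | Path) -> "ShardSet":
        d = json.loads(Path(path).read_text())
        return cls(
            shards=[np.asarray(s, dtype=np.intp) for s in d["shards"]],
            strategy=d["strategy"], n_clients=d["n_clients"],
            seed=d["seed"], source_size=d["source_size"],
        )


def _shard_rng(seed: int, attempt: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, attempt)))


def split_uniform_stratified(cohort: LabeledCohort, n_clients: int, seed: int) -> ShardSet:
    """Assign floor(n_class / N) samples of each phenotype to every client,
    surplus of each class to the last client."""
    if n_clients < 1:
        raise ValidationError("n_clients must be >= 1")
    cases = np.flatnonzero(cohort.labels == 1)
    controls = np.flatnonzero(cohort.labels == 0)
    if len(cases) < n_clients or len(controls) < n_clients:
        raise FeasibilityError(
            f"stratified split infeasible: {len(cases)} cases / {len(controls)} controls "
            f"cannot give every one of {n_clients} clients both classes"
        )
    rng = _shard_rng(seed)
    shards: list[list[int]] = [[] for _ in range(n_clients)]
    for pool in (cases, controls):
        perm = rng.permutation(pool)
        base = len(pool) // n_clients
        for i in range(n_clients):
            shards[i].extend(perm[i * base:(i + 1) * base])
        shards[-1].extend(perm[n_clients * base:])       # surplus to last
    out = ShardSet(
        shards=[np.sort(np.asarray(s, dtype=np.intp)) for s in shards],
        strategy="uniform_stratified", n_clients=n_clients,
        seed=seed, source_size=cohort.n_samples,
    )
    report = validate_shards(out, cohort)
    if not report.passed:
        raise FeasibilityError(report.summary())
    return out


def _random_partition(
    cohort: LabeledCohort, sizes: list[int], strategy: str,
    n_clients: int, seed: int,
) -> ShardSet:
    """Uniform random membership for given shard sizes, redrawn until every
    shard holds both classes."""
    for attempt in range(MAX_SPLIT_RETRIES):
        rng = _shard_rng(seed, attempt)
        perm = rng.permutation(cohort.n_samples)
        bounds = np.cumsum([0] + sizes)
        shards = [np.sort(perm[bounds[i]:bounds[i + 1]]) for i in range(n_clients)]
        out = ShardSet(shards=shards, strategy=strategy, n_clients=n_clients,
                       seed=seed, source_size=cohort.n_samples)
        if validate_shards(out, cohort).passed:
            return out
    raise FeasibilityError(
        f"{strategy}: no feasible draw with every shard holding both classes "
        f"after {MAX_SPLIT_RETRIES} attempts (sizes {sizes})"
    )


def split_uniform_random(cohort: LabeledCohort, n_clients: int, seed: int) -> ShardSet:
    """floor(C/N) samples per client, surplus to the last, membership by
    uniform random sampling without replacement."""
    if n_clients < 1:
        raise ValidationError("n_clients must be >= 1")
    c = cohort.n_samples // n_clients
    if c == 0:
        raise FeasibilityError(f"{cohort.n_samples} samples cannot fill {n_clients} clients")
    sizes = [c] * n_clients
    sizes[-1] += cohort.n_samples - c * n_clients
    return _random_partition(cohort, sizes, "uniform_random", n_clients, seed)


def split_linear_random(cohort: LabeledCohort, n_clients: int, seed: int) -> ShardSet:
    """Client i (1-based) receives i*c samples, c = floor(2C / (N(N+1)));
    the surplus goes to the last client, preserving strictly increasing
    sizes."""
    if n_clients < 1:
        raise ValidationError("n_clients must be >= 1")
    C = cohort.n_samples
    c = (2 * C) // (n_clients * (n_clients + 1))
    if c == 0:
        raise FeasibilityError(
            f"linear split infeasible: base allotment floor(2*{C}/({n_clients}*{n_clients + 1})) = 0"
        )
    sizes = [i * c for i in range(1, n_clients + 1)]
    sizes[-1] += C - c * n_clients * (n_clients + 1) // 2
    return _random_partition(cohort, sizes, "linear_random", n_clients, seed)


def split(cohort: LabeledCohort, strategy: str, n_clients: int, seed: int) -> ShardSet:
    """Dispatch on strategy name."""
    _check_strategy(strategy)
    fn = {
        "uniform_stratified": split_uniform_stratified,
        "uniform_random": split_uniform_random,
        "linear_random": split_linear_random,
    }[strategy]
    return fn(cohort, n_clients, seed)


@dataclass
class ShardReport:
    sizes: list[int]
    case_counts: list[int]
    control_counts: list[int]
    disjoint: bool
    exhaustive: bool
    per_shard_ok: list[bool]
    passed: bool = field(init=False)

    def __post_init__(self) -> None:
        self.passed = self.disjoint and self.exhaustive and all(self.per_shard_ok)

    def summary(self) -> str:
        lines = [f"partition disjoint={self.disjoint} exhaustive={self.exhaustive}"]
        for i, (s, ca, co, ok) in enumerate(
            zip(self.sizes, self.case_counts, self.control_counts, self.per_shard_ok)
        ):
            lines.append(f"shard {i}: size={s} cases={ca} controls={co} "
                         f"{'pass' if ok else 'FAIL'}")
        return "\n".join(lines)


def validate_shards(shardset: ShardSet, cohort: LabeledCohort) -> ShardReport:
    """Report partition invariants and per-shard class feasibility."""
    all_idx = np.concatenate(shardset.shards) if shardset.shards else np.array([], dtype=int)
    if all_idx.size and (all_idx.min() < 0 or all_idx.max() >= cohort.n_samples):
        raise ValidationError("shard indices out of cohort bounds")
    disjoint = len(np.unique(all_idx)) == all_idx.size
    exhaustive = all_idx.size == cohort.n_samples and disjoint
    sizes, cases, controls, ok = [], [], [], []
    for s in shardset.shards:
        y = cohort.labels[s]
        sizes.append(len(s))
        cases.append(int(y.sum()))
        controls.append(int((y == 0).sum()))
        ok.append(cases[-1] >= 1 and controls[-1] >= 1)
    return ShardReport(sizes, cases, controls, disjoint, exhaustive, ok)


def heterogeneity_indices(shardset: ShardSet, cohort: LabeledCohort) -> dict[str, float]:
    """Summary indices used to order strategies by heterogeneity:
    label skew = max pairwise difference in shard case fractions,
    size skew = max shard size / min shard size."""
    fracs = [cohort.labels[s].mean() for s in shardset.shards]
    sizes = shardset.sizes()
    return {
        "label_skew": float(max(fracs) - min(fracs)),
        "size_skew": float(max(sizes) / min(sizes)),
    }
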