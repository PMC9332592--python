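"""Elephant-herding / genetic-algorithm trained neural classifier (EHGA-DLNN).

A small fully connected network (input -> hidden layers -> output, sigmoid
units) classifies the reduced feature rows.  Its weights and biases are not
trained by backpropagation: a candidate solution is the flattened parameter
vector (a *genome*), and a population of genomes, partitioned into clans,
is evolved by elephant herding optimization (EHO) hybridized with genetic
crossover and mutation:

* **clan update** — every non-matriarch member moves toward its clan's
  best-fitness member (the matriarch):
  ``T_new = T + alpha * (T_best - T) * g`` with g ~ U[0,1] drawn per member;
  the matriarch itself moves to ``beta *`` the clan centre (standard EHO).
* **separation** — the clan's worst member is replaced gene-wise by
  ``T_min + (T_max - T_min) * fr``, fr ~ U[0,1] per gene.
* **crossover/mutation** — before each position update, clan members are
  paired for two-point crossover (points |T|/3 and |T|/3 + |T|/2, floored,
  capped at |T|-1) and the offspring mutated gene-wise: with probability
  ``mutation_rate`` a gene is resampled uniformly in bounds, redrawn until
  it differs from its predecessor.

Fitness is the mean squared error between the network's outputs and the
desired (one-hot or single-unit binary) targets over the whole training
set.  Moves produced by crossover/mutation and by the clan update are
accepted *greedily* — a candidate replaces its incumbent only if it lowers
the loss — while separation is unconditional (it is the exploration step);
a global best-ever genome is kept elitistically, so the best-fitness trace
is nonincreasing by construction.  All randomness flows from a single
seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, ValidationError

__all__ = [
    "NetworkParams",
    "ElephantPosition",
    "TrainConfig",
    "TrainedModel",
    "EHGAClassifier",
    "EHGAResults",
    "forward",
    "loss",
    "clan_update",
    "separation",
    "two_point_crossover",
    "mutate",
    "train",
    "predict",
]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


_ACTIVATIONS = {"sigmoid": _sigmoid}


@dataclass(frozen=True)
class NetworkParams:
    """Layer sizes plus per-layer weight matrices and bias vectors."""

    layer_sizes: tuple[int, ...]
    weights: tuple[np.ndarray, ...]
    biases: tuple[np.ndarray, ...]
    activation: str = "sigmoid"

    def __post_init__(self) -> None:
        if len(self.layer_sizes) < 2:
            raise ValidationError("need at least input and output layers")
        if self.activation not in _ACTIVATIONS:
            raise ValidationError(f"unknown activation {self.activation!r}")
        expected = list(zip(self.layer_sizes[:-1], self.layer_sizes[1:]))
        if len(self.weights) != len(expected) or len(self.biases) != len(expected):
            raise ValidationError("layer count mismatch")
        for (fan_in, fan_out), W, b in zip(expected, self.weights, self.biases):
            if W.shape != (fan_in, fan_out) or b.shape != (fan_out,):
                raise ValidationError("weight/bias shape mismatch")
            if not (np.isfinite(W).all() and np.isfinite(b).all()):
                raise ValidationError("non-finite parameters")

    @property
    def n_parameters(self) -> int:
        return genome_length(self.layer_sizes)


def genome_length(layer_sizes: Sequence[int]) -> int:
    return sum(
        a * b + b for a, b in zip(layer_sizes[:-1], layer_sizes[1:])
    )


def pack_genome(params: NetworkParams) -> np.ndarray:
    parts = []
    for W, b in zip(params.weights, params.biases):
        parts.append(W.ravel())
        parts.append(b)
    return np.concatenate(parts)


def unpack_genome(
    genome: np.ndarray, layer_sizes: Sequence[int], activation: str = "sigmoid"
) -> NetworkParams:
    genome = np.asarray(genome, dtype=float)
    if genome.shape != (genome_length(layer_sizes),):
        raise ValidationError("genome length does not match layer sizes")
    weights, biases = [], []
    pos = 0
    for fan_in, fan_out in zip(layer_sizes[:-1], layer_sizes[1:]):
        W = genome[pos : pos + fan_in * fan_out].reshape(fan_in, fan_out)
        pos += fan_in * fan_out
        b = genome[pos : pos + fan_out]
        pos += fan_out
        weights.append(W.copy())
        biases.append(b.copy())
    return NetworkParams(
        tuple(layer_sizes), tuple(weights), tuple(biases), activation
    )


def forward(params: NetworkParams, x: np.ndarray) -> np.ndarray:
    """Forward pass; accepts a single row or an (n, d) batch.

    Every layer computes bias + weighted sum of the previous layer's output
    and applies the activation; the output layer uses the same squashing so
    per-class outputs live in (0, 1).
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    a = x[None, :] if single else x
    if a.shape[1] != params.layer_sizes[0]:
        raise ValidationError(
            f"input width {a.shape[1]} != {params.layer_sizes[0]}"
        )
    act = _ACTIVATIONS[params.activation]
    for W, b in zip(params.weights, params.biases):
        a = act(b + a @ W)
    return a[0] if single else a


def loss(predicted: np.ndarray, desired: np.ndarray) -> float:
    """Mean squared error between produced and desired outputs."""
    predicted = np.asarray(predicted, dtype=float)
    desired = np.asarray(desired, dtype=float)
    if predicted.shape != desired.shape:
        raise ValidationError("predicted/desired shape mismatch")
    return float(np.mean((desired - predicted) ** 2))


# -- population operators ---------------------------------------------------


@dataclass
class ElephantPosition:
    """One candidate genome with its evaluated fitness and clan index."""

    genome: np.ndarray
    fitness: float
    clan_id: int


def clan_update(
    positions: np.ndarray,
    fitness: np.ndarray,
    alpha: float,
    bounds: tuple[float, float],
    rng: np.random.Generator,
    beta: float = 0.5,
) -> np.ndarray:
    """EHO clan-updating operator (candidate positions, not yet accepted).

    Non-matriarch members move toward the matriarch by ``alpha * g`` with a
    fresh scalar g ~ U[0,1] each; the matriarch moves to ``beta * centre``.
    All outputs are clipped to bounds.
    """
    k = len(positions)
    best = int(np.argmin(fitness))
    g = rng.uniform(0.0, 1.0, size=k)
    new = positions + alpha * g[:, None] * (positions[best] - positions)
    new[best] = beta * positions.mean(axis=0)
    return np.clip(new, bounds[0], bounds[1])


def separation(
    positions: np.ndarray,
    fitness: np.ndarray,
    bounds: tuple[float, float],
    rng: np.random.Generator,
) -> tuple[np.ndarray, int]:
    """Replace the worst member gene-wise by T_min + (T_max - T_min) * fr."""
    if len(positions) < 2:
        raise ValidationError("separation needs a clan of >= 2")
    worst = int(np.argmax(fitness))
    lo, hi = bounds
    fr = rng.uniform(0.0, 1.0, size=positions.shape[1])
    new = positions.copy()
    new[worst] = lo + (hi - lo) * fr
    return new, worst


def two_point_crossover(
    parent_a: np.ndarray, parent_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Swap the middle segment [|T|/3, |T|/3 + |T|/2) between two genomes."""
    n = len(parent_a)
    if len(parent_b) != n:
        raise ValidationError("parents must have equal length")
    if n < 3:
        raise ValidationError("genomes must have length >= 3")
    c1 = n // 3
    c2 = min(c1 + n // 2, n - 1)
    child_a = parent_a.copy()
    child_b = parent_b.copy()
    child_a[c1:c2] = parent_b[c1:c2]
    child_b[c1:c2] = parent_a[c1:c2]
    return child_a, child_b


def crossover_points(n: int) -> tuple[int, int]:
    """The (C1, C2) cut points used by :func:`two_point_crossover`."""
    if n < 3:
        raise ValidationError("genomes must have length >= 3")
    return n // 3, min(n // 3 + n // 2, n - 1)


def mutate(
    genome: np.ndarray,
    rate: float,
    bounds: tuple[float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Gene-wise uniform replacement, redrawn to differ from the old gene."""
    if not 0 <= rate <= 1:
        raise ValidationError("mutation rate must lie in [0, 1]")
    lo, hi = bounds
    out = genome.copy()
    mask = rng.uniform(size=len(genome)) < rate
    for i in np.flatnonzero(mask):
        new = rng.uniform(lo, hi)
        while new == out[i]:  # ~never loops for continuous genes
            new = rng.uniform(lo, hi)
        out[i] = new
    return out


# -- training ---------------------------------------------------------------


@dataclass(frozen=True)
class TrainConfig:
    """Population / stopping configuration for EHGA training."""

    n_clans: int = 10
    clan_size: int = 10
    max_iterations: int = 200
    loss_threshold: float = 0.0
    mutation_rate: float = 0.1
    alpha: float = 0.5
    beta: float = 0.5
    bounds: tuple[float, float] = (-5.0, 5.0)
    sample_count: int | None = None  # must equal the training row count
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clans < 1 or self.clan_size < 2:
            raise ConfigurationError("need >= 1 clan of size >= 2")
        if self.max_iterations < 1:
            raise ConfigurationError("max_iterations must be >= 1")
        if not 0 <= self.mutation_rate <= 1:
            raise ConfigurationError("mutation_rate must lie in [0, 1]")
        if not 0 < self.alpha <= 1:
            raise ConfigurationError("alpha must lie in (0, 1]")
        if self.bounds[0] >= self.bounds[1]:
            raise ConfigurationError("bounds must satisfy T_min < T_max")
        if self.sample_count is not None and (
            not isinstance(self.sample_count, int) or self.sample_count < 1
        ):
            raise ConfigurationError("sample_count must be a positive integer")


@dataclass
class TrainedModel:
    """Best network found by EHGA plus the optimization trace."""

    params: NetworkParams
    best_fitness: float
    trace: list[float] = field(default_factory=list)
    n_iterations: int = 0
    n_evaluations: int = 0
    config: TrainConfig | None = None
    classes: tuple[int, ...] = ()


def encode_targets(
    y: np.ndarray, classes: Sequence[int] | None = None
) -> tuple[np.ndarray, tuple[int, ...]]:
    """Binary labels -> one sigmoid unit; multi-class -> one-hot columns."""
    y = np.asarray(y)
    cls = tuple(int(c) for c in (np.unique(y) if classes is None else classes))
    if len(cls) < 2:
        raise ValidationError("need at least 2 classes to train")
    if len(cls) == 2:
        targets = (y == cls[1]).astype(float)[:, None]
    else:
        targets = np.zeros((len(y), len(cls)))
        for j, c in enumerate(cls):
            targets[y == c, j] = 1.0
    return targets, cls


def decode_outputs(outputs: np.ndarray, classes: Sequence[int]) -> np.ndarray:
    """Argmax over class units (binary: output >= 0.5 -> disease class)."""
    outputs = np.atleast_2d(outputs)
    cls = np.asarray(classes)
    if len(cls) == 2:
        return np.where(outputs[:, 0] >= 0.5, cls[1], cls[0])
    return cls[np.argmax(outputs, axis=1)]


def train(
    features: np.ndarray,
    labels: np.ndarray,
    config: TrainConfig | None = None,
    hidden_layers: Sequence[int] = (16,),
    activation: str = "sigmoid",
) -> TrainedModel:
    """Optimize the network's weights with the EHO + GA hybrid.

    Fitness of a genome is the MSE of the corresponding network over the
    whole training set; the returned model carries the global best genome
    and the per-iteration best-fitness trace.
    """
    config = config or TrainConfig()
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.size == 0:
        raise ValidationError("empty feature matrix")
    y = np.asarray(labels)
    if len(y) != len(X):
        raise ValidationError("label vector length != row count")
    if config.sample_count is not None and config.sample_count != len(X):
        raise ConfigurationError(
            f"sample_count {config.sample_count} != training rows {len(X)}"
        )

    targets, classes = encode_targets(y)
    layer_sizes = (X.shape[1], *hidden_layers, targets.shape[1])
    D = genome_length(layer_sizes)
    lo, hi = config.bounds
    rng = np.random.default_rng(config.seed)

    def fitness_of(genome: np.ndarray) -> float:
        params = unpack_genome(genome, layer_sizes, activation)
        return loss(forward(params, X), targets)

    n_evals = 0
    clans: list[np.ndarray] = []
    fits: list[np.ndarray] = []
    for _ in range(config.n_clans):
        pos = rng.uniform(lo, hi, size=(config.clan_size, D))
        clans.append(pos)
        fits.append(np.array([fitness_of(g) for g in pos]))
        n_evals += config.clan_size

    best_idx = min(
        ((ci, int(np.argmin(f))) for ci, f in enumerate(fits)),
        key=lambda t: fits[t[0]][t[1]],
    )
    best = ElephantPosition(
        clans[best_idx[0]][best_idx[1]].copy(),
        float(fits[best_idx[0]][best_idx[1]]),
        best_idx[0],
    )

    trace: list[float] = []
    iterations = 0
    for _ in range(config.max_iterations):
        iterations += 1
        for ci in range(config.n_clans):
            pos, fit = clans[ci], fits[ci]
            k = len(pos)

            # GA crossover + mutation, greedy acceptance against each parent
            order = rng.permutation(k)
            for a, b in zip(order[0::2], order[1::2]):
                ca, cb = two_point_crossover(pos[a], pos[b])
                ca = np.clip(mutate(ca, config.mutation_rate, config.bounds, rng), lo, hi)
                cb = np.clip(mutate(cb, config.mutation_rate, config.bounds, rng), lo, hi)
                for child, parent in ((ca, a), (cb, b)):
                    f = fitness_of(child)
                    n_evals += 1
                    if f < fit[parent]:
                        pos[parent] = child
                        fit[parent] = f

            # EHO clan update, greedy acceptance
            candidates = clan_update(
                pos, fit, config.alpha, config.bounds, rng, config.beta
            )
            for m in range(k):
                f = fitness_of(candidates[m])
                n_evals += 1
                if f < fit[m]:
                    pos[m] = candidates[m]
                    fit[m] = f

            # separation: worst member replaced unconditionally
            new_pos, worst = separation(pos, fit, config.bounds, rng)
            pos[worst] = new_pos[worst]
            fit[worst] = fitness_of(pos[worst])
            n_evals += 1

            ci_best = int(np.argmin(fit))
            if fit[ci_best] < best.fitness:
                best = ElephantPosition(pos[ci_best].copy(), float(fit[ci_best]), ci)

        trace.append(best.fitness)
        if best.fitness <= config.loss_threshold:
            break

    return TrainedModel(
        params=unpack_genome(best.genome, layer_sizes, activation),
        best_fitness=best.fitness,
        trace=trace,
        n_iterations=iterations,
        n_evaluations=n_evals,
        config=config,
        classes=classes,
    )


def predict(model: TrainedModel, features: np.ndarray) -> np.ndarray:
    """Class labels for new rows (argmax unit; binary threshold 0.5)."""
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    outputs = forward(model.params, X)
    return decode_outputs(outputs, model.classes)


# -- model / results objects ------------------------------------------------


class EHGAClassifier:
    """Neural classifier whose weights are found by the EHO + GA hybrid.

    Parameters
    ----------
    hidden_layers : widths of the hidden layers (default one layer of 16)
    config : :class:`TrainConfig` with population sizes, stopping rule,
        operator rates, search bounds and seed
    """

    def __init__(
        self,
        hidden_layers: Sequence[int] = (16,),
        config: TrainConfig | None = None,
    ) -> None:
        self.hidden_layers = tuple(hidden_layers)
        self.config = config or TrainConfig()

    def fit(self, X: np.ndarray, y: np.ndarray) -> "EHGAResults":
        model = train(X, y, self.config, self.hidden_layers)
        preds = predict(model, np.asarray(X, dtype=float))
        accuracy = float(np.mean(preds == np.asarray(y)))
        return EHGAResults(self, model, accuracy)


@dataclass
class EHGAResults:
    """Fitted classifier: best network, optimization trace, diagnostics."""

    classifier: EHGAClassifier
    model: TrainedModel
    train_accuracy: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        return predict(self.model, X)

    def summary(self) -> str:
        m = self.model
        cfg = m.config or TrainConfig()
        lines = [
            "EHGA-DLNN training results",
            "==========================",
            f"architecture:     {' -> '.join(map(str, m.params.layer_sizes))}",
            f"classes:          {list(m.classes)}",
            f"population:       {cfg.n_clans} clans x {cfg.clan_size}",
            f"iterations run:   {m.n_iterations} (max {cfg.max_iterations})",
            f"fitness evals:    {m.n_evaluations}",
            f"final MSE loss:   {m.best_fitness:.6f}",
            f"train accuracy:   {self.train_accuracy:.4f}",
        ]
        return "\n".join(lines)


# -- model persistence (text) -----------------------------------------------


def save_model(model: TrainedModel, path: str | Path) -> None:
    p = model.params
    cfg = model.config or TrainConfig()
    lines = [
        "layer_sizes\t" + " ".join(map(str, p.layer_sizes)),
        f"activation\t{p.activation}",
        "classes\t" + " ".join(map(str, model.classes)),
        f"best_fitness\t{model.best_fitness!r}",
        f"seed\t{cfg.seed}",
        "genome\t" + " ".join(repr(float(v)) for v in pack_genome(p)),
    ]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def load_model(path: str | Path) -> TrainedModel:
    fields = dict(
        line.split("\t", 1)
        for line in Path(path).read_text(encoding="utf-8").splitlines()
        if line.strip()
    )
    layer_sizes = tuple(int(v) for v in fields["layer_sizes"].split())
    genome = np.array([float(v) for v in fields["genome"].split()])
    params = unpack_genome(genome, layer_sizes, fields["activation"])
    return TrainedModel(
        params=params,
        best_fitness=float(fields["best_fitness"]),
        classes=tuple(int(v) for v in fields["classes"].split()),
    )
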