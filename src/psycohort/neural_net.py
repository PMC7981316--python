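"""Multi-layer sigmoid network with online backpropagation, from scratch.

Forward pass: the input layer copies the stimulus (s_k = x_k), every
subsequent layer applies sigmoid thresholding to the scalar product of
its weight vectors with the previous layer's activations.  Training uses
per-probe gradient-descent updates on the squared-error objective
SSE/2, i.e. for the output layer

    dw_ij = alpha * eps_i * s_j * s_i * (1 - s_i),   eps_i = y_i - s_i

and the chained analogue for hidden layers.  A k-fold cross-validation
harness (default k=10) provides approximately unbiased prediction-error
estimates.

Bias terms are modelled as weights from an always-on unit appended to
each layer (optional, on by default); their updates follow the same
gradient rule with the constant activation 1.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)


def sigmoid(x):
    """Logistic function R -> (0,1); saturates stably at the extremes."""
    out = np.empty_like(x, dtype=float) if isinstance(x, np.ndarray) else None
    if out is None:
        x = float(x)
        if x >= 0:
            return 1.0 / (1.0 + math.exp(-x))
        e = math.exp(x)
        return e / (1.0 + e)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


@dataclass
class NetModel:
    """Layer sizes, weight matrices and learning rate of a sigmoid net.

    ``weights[l]`` has shape (size[l+1], size[l]); ``biases[l]`` has shape
    (size[l+1],) and is all-zero when ``use_bias`` is False.
    """

    layer_sizes: tuple[int, ...]
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    alpha: float
    use_bias: bool = True
    iterations: int = 0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError(f"learning rate must be > 0, got {self.alpha}")
        if len(self.weights) != len(self.layer_sizes) - 1:
            raise ValueError("one weight matrix per layer transition required")
        for l, w in enumerate(self.weights):
            expect = (self.layer_sizes[l + 1], self.layer_sizes[l])
            if w.shape != expect:
                raise ValueError(
                    f"weight matrix {l} has shape {w.shape}, expected {expect}"
                )
            if self.biases[l].shape != (self.layer_sizes[l + 1],):
                raise ValueError(f"bias vector {l} has wrong shape")

    @property
    def n_inputs(self) -> int:
        return self.layer_sizes[0]

    @property
    def n_outputs(self) -> int:
        return self.layer_sizes[-1]

    def copy(self) -> "NetModel":
        return NetModel(
            layer_sizes=self.layer_sizes,
            weights=[w.copy() for w in self.weights],
            biases=[b.copy() for b in self.biases],
            alpha=self.alpha,
            use_bias=self.use_bias,
            iterations=self.iterations,
        )

    def to_dict(self) -> dict:
        return {
            "layer_sizes": list(self.layer_sizes),
            "alpha": self.alpha,
            "use_bias": self.use_bias,
            "iterations": self.iterations,
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetModel":
        return cls(
            layer_sizes=tuple(d["layer_sizes"]),
            weights=[np.asarray(w, dtype=float) for w in d["weights"]],
            biases=[np.asarray(b, dtype=float) for b in d["biases"]],
            alpha=float(d["alpha"]),
            use_bias=bool(d.get("use_bias", True)),
            iterations=int(d.get("iterations", 0)),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "NetModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def default_hidden(n_inputs: int, n_outputs: int) -> tuple[int]:
    """Smallest default hidden layer: ceil((N_k + N_i) / 2) units."""
    return (math.ceil((n_inputs + n_outputs) / 2),)


def init_net(
    n_inputs: int,
    n_outputs: int,
    hidden: Sequence[int] | None = None,
    alpha: float = 0.5,
    seed: int | np.random.Generator = 0,
    use_bias: bool = True,
    init_scale: float = 0.5,
) -> NetModel:
    """Fresh network with weights uniform in [-init_scale, init_scale]."""
    if hidden is None:
        hidden = default_hidden(n_inputs, n_outputs)
    if len(hidden) > 3:
        raise ValueError("at most 3 hidden layers are supported")
    sizes = (n_inputs, *hidden, n_outputs)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    weights = [
        rng.uniform(-init_scale, init_scale, size=(sizes[l + 1], sizes[l]))
        for l in range(len(sizes) - 1)
    ]
    biases = [
        rng.uniform(-init_scale, init_scale, size=sizes[l + 1])
        if use_bias
        else np.zeros(sizes[l + 1])
        for l in range(len(sizes) - 1)
    ]
    return NetModel(sizes, weights, biases, alpha, use_bias=use_bias)


def forward(net: NetModel, x: np.ndarray) -> list[np.ndarray]:
    """All layer activations for one probe: [s_k, s_j..., s_i]."""
    x = np.asarray(x, dtype=float)
    if x.shape != (net.n_inputs,):
        raise ValueError(
            f"input has shape {x.shape}, expected ({net.n_inputs},)"
        )
    acts = [x]
    for w, b in zip(net.weights, net.biases):
        acts.append(sigmoid(w @ acts[-1] + b))
    return acts


def predict(net: NetModel, X: np.ndarray) -> np.ndarray:
    """Vectorized output activations for a (p, N_k) probe matrix."""
    s = np.asarray(X, dtype=float)
    for w, b in zip(net.weights, net.biases):
        s = sigmoid(s @ w.T + b)
    return s


def probe_loss(net: NetModel, x: np.ndarray, y: np.ndarray) -> float:
    """Squared error / 2 of one probe."""
    s = forward(net, x)[-1]
    return 0.5 * float(np.sum((np.asarray(y, float) - s) ** 2))


def total_loss(net: NetModel, X: np.ndarray, Y: np.ndarray) -> float:
    """Squared error / 2 summed over all probes."""
    resid = np.asarray(Y, float) - predict(net, X)
    return 0.5 * float(np.sum(resid**2))


def backprop_step(
    net: NetModel,
    x: np.ndarray,
    y: np.ndarray,
    alpha: float | None = None,
) -> NetModel:
    """One online gradient-descent update from a single probe (in place).

    Output layer:  dw_ij = alpha * eps_i * s_j * s_i (1 - s_i).
    Hidden layers: the chained rule, e.g. for one hidden layer
    dw_jk = alpha * sum_i eps_i * s_k * s_i(1-s_i) * w_ij * s_j(1-s_j).
    """
    if alpha is None:
        alpha = net.alpha
    if alpha <= 0:
        raise ValueError(f"learning rate must be > 0, got {alpha}")
    acts = forward(net, x)
    eps = np.asarray(y, dtype=float) - acts[-1]
    # delta at the output layer; propagate through hidden layers
    delta = eps * acts[-1] * (1.0 - acts[-1])
    for l in range(len(net.weights) - 1, -1, -1):
        grad_w = np.outer(delta, acts[l])
        next_delta = (net.weights[l].T @ delta) * acts[l] * (1.0 - acts[l])
        net.weights[l] += alpha * grad_w
        if net.use_bias:
            net.biases[l] += alpha * delta
        delta = next_delta
    net.iterations += 1
    return net


@dataclass
class TrainResult:
    net: NetModel
    loss_trace: list[float]
    converged: bool


def train(
    net: NetModel,
    X: np.ndarray,
    Y: np.ndarray,
    alpha: float | None = None,
    max_iterations: int = 200_000,
    tolerance: float = 1e-6,
    seed: int | np.random.Generator = 0,
    log_every: int | None = None,
) -> TrainResult:
    """Online backpropagation over shuffled probes until the epoch loss
    change falls below ``tolerance`` or ``max_iterations`` probe
    presentations are spent.  Deterministic for a fixed seed; the input
    model is not modified.  With ``log_every`` the loss is logged every
    that many epochs.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    p = X.shape[0]
    if Y.shape[0] != p:
        raise ValueError("X and Y must have the same number of probes")
    if np.any((Y < 0) | (Y > 1)):
        raise ValueError("targets must lie in [0,1] (sigmoid output range)")
    net = net.copy()
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    if alpha is None:
        alpha = net.alpha
    if alpha <= 0:
        raise ValueError(f"learning rate must be > 0, got {alpha}")
    trace = [total_loss(net, X, Y)]
    converged = False
    # inlined per-probe update loop (same arithmetic as backprop_step,
    # kept local for speed: training dominates the pipeline runtime)
    weights, biases, use_bias = net.weights, net.biases, net.use_bias
    n_layers = len(weights)
    while net.iterations < max_iterations:
        for idx in rng.permutation(p):
            acts = [X[idx]]
            for w, b in zip(weights, biases):
                acts.append(sigmoid(w @ acts[-1] + b))
            delta = (Y[idx] - acts[-1]) * acts[-1] * (1.0 - acts[-1])
            for l in range(n_layers - 1, -1, -1):
                next_delta = (weights[l].T @ delta) * acts[l] * (1.0 - acts[l])
                weights[l] += alpha * np.outer(delta, acts[l])
                if use_bias:
                    biases[l] += alpha * delta
                delta = next_delta
            net.iterations += 1
            if net.iterations >= max_iterations:
                break
        loss = total_loss(net, X, Y)
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"non-finite training loss after {net.iterations} iterations"
            )
        trace.append(loss)
        if log_every and (len(trace) - 1) % log_every == 0:
            logger.info(
                "iteration %d: loss %.6g", net.iterations, loss
            )
        if abs(trace[-2] - loss) < tolerance:
            converged = True
            break
    return TrainResult(net=net, loss_trace=trace, converged=converged)


@dataclass(frozen=True)
class FoldPlan:
    """Assignment of each probe to exactly one of k folds."""

    k: int
    assignment: np.ndarray  # fold index per probe

    def __post_init__(self) -> None:
        present = np.unique(self.assignment)
        if not np.array_equal(present, np.arange(self.k)):
            raise ValueError("every fold must be non-empty")
        sizes = np.bincount(self.assignment, minlength=self.k)
        if sizes.max() - sizes.min() > 1:
            raise ValueError("fold sizes must differ by at most 1")

    @property
    def n(self) -> int:
        return len(self.assignment)

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignment != fold)


def kfold_split(
    n: int,
    k: int = 10,
    strata: Sequence | None = None,
    seed: int | np.random.Generator = 0,
) -> FoldPlan:
    """Disjoint, exhaustive folds of sizes differing by at most one.

    With ``strata``, labels are balanced across folds where possible by
    dealing each stratum round-robin through a shared fold rotation.
    """
    if not 2 <= k <= n:
        raise ValueError(f"need 2 <= k <= n, got k={k}, n={n}")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    assignment = np.empty(n, dtype=int)
    fold_order = rng.permutation(k)
    pointer = 0
    if strata is None:
        groups = [np.arange(n)]
    else:
        strata = np.asarray(strata)
        if len(strata) != n:
            raise ValueError("strata must have length n")
        groups = [np.flatnonzero(strata == s) for s in np.unique(strata)]
    for group in groups:
        for idx in rng.permutation(group):
            assignment[idx] = fold_order[pointer % k]
            pointer += 1
    return FoldPlan(k=k, assignment=assignment)


@dataclass
class CVResult:
    """Per-fold prediction errors and pooled out-of-fold predictions."""

    fold_errors: list[float]  # mean squared error on each held-out fold
    predictions: np.ndarray  # (p, N_i), each probe predicted exactly once
    models: list[NetModel]

    @property
    def mean_error(self) -> float:
        return float(np.mean(self.fold_errors))


def cross_validate(
    net_spec: dict,
    X: np.ndarray,
    Y: np.ndarray,
    fold_plan: FoldPlan,
) -> CVResult:
    """Train k models, each evaluated only on its held-out fold.

    ``net_spec`` mirrors :func:`init_net`/:func:`train` keywords:
    hidden, alpha, seed, use_bias, max_iterations, tolerance, init_scale.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if fold_plan.n != X.shape[0]:
        raise ValueError("fold plan does not match the number of probes")
    seed = net_spec.get("seed", 0)
    predictions = np.full(Y.shape, np.nan)
    fold_errors = []
    models = []
    for fold in range(fold_plan.k):
        tr = fold_plan.train_indices(fold)
        te = fold_plan.test_indices(fold)
        net = init_net(
            n_inputs=X.shape[1],
            n_outputs=Y.shape[1],
            hidden=net_spec.get("hidden"),
            alpha=net_spec.get("alpha", 0.5),
            seed=np.random.default_rng((seed, fold)),
            use_bias=net_spec.get("use_bias", True),
            init_scale=net_spec.get("init_scale", 0.5),
        )
        result = train(
            net,
            X[tr],
            Y[tr],
            max_iterations=net_spec.get("max_iterations", 200_000),
            tolerance=net_spec.get("tolerance", 1e-6),
            seed=np.random.default_rng((seed, fold, 1)),
        )
        pred = predict(result.net, X[te])
        predictions[te] = pred
        fold_errors.append(float(np.mean((Y[te] - pred) ** 2)))
        models.append(result.net)
    assert not np.any(np.isnan(predictions))
    return CVResult(
        fold_errors=fold_errors, predictions=predictions, models=models
    )
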