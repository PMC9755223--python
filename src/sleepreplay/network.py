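"""Bias-free dense networks and supervised (wake) training.

The networks used here are deliberately plain: fully connected layers with
rectifier hidden units, a softmax cross-entropy readout, and *no bias terms
anywhere*.  Bias-freeness is what makes the later conversion to
threshold/spiking semantics during the sleep phase exact — a rectifier
network without biases is positively homogeneous, so per-layer rescaling
commutes with the nonlinearity.

Training is minimal on purpose: mini-batch SGD with classical momentum and
inverted dropout on hidden activations.  The loss is always evaluated on the
samples presented (class-incremental training never sees old classes unless
an explicit rehearsal buffer supplies them).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "TrainingConfig",
    "RehearsalConfig",
    "DenseNet",
    "EvaluationResult",
    "init_network",
    "train_task",
    "train_task_with_rehearsal",
    "train_to_convergence",
    "evaluate",
]


@dataclass
class TrainingConfig:
    """Hyperparameters for supervised (wake) training.

    Defaults are the settings used for MNIST-scale experiments:
    learning rate 0.065, momentum 0.5, 10 epochs per task, mini-batches of
    100, dropout 0.2 on hidden layers and uniform init in [-0.02, 0.02].
    """

    learning_rate: float = 0.065
    momentum: float = 0.5
    epochs_per_task: int = 10
    batch_size: int = 100
    dropout_rate: float = 0.2
    init_range: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be non-negative")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must lie in [0, 1)")
        if self.epochs_per_task < 0:
            raise ValueError("epochs_per_task must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be positive")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.init_range < 0:
            raise ValueError("init_range must be non-negative")

    def replace(self, **kwargs) -> "TrainingConfig":
        return replace(self, **kwargs)


@dataclass
class RehearsalConfig:
    """Rehearsal scheme: store a fraction of old-task data with hard labels.

    The loss on mixed batches is weighted so that with ``n_tasks_seen`` tasks
    the current task contributes ``1 / n_tasks_seen`` and all old tasks
    together ``1 - 1 / n_tasks_seen``; the two weights always sum to one.
    """

    fraction_stored: float = 0.0075
    n_tasks_seen: int = 1

    def __post_init__(self) -> None:
        if not 0 <= self.fraction_stored <= 1:
            raise ValueError("fraction_stored must lie in [0, 1]")
        if self.n_tasks_seen < 1:
            raise ValueError("n_tasks_seen must be >= 1")

    @property
    def loss_weight_current(self) -> float:
        return 1.0 / self.n_tasks_seen

    @property
    def loss_weight_old(self) -> float:
        return 1.0 - 1.0 / self.n_tasks_seen


class DenseNet:
    """A bias-free multilayer perceptron.

    Parameters
    ----------
    layer_sizes
        Sizes of input, hidden..., output layers (at least two entries).
    weights
        Optional list of matrices; ``weights[l]`` has shape
        ``(layer_sizes[l + 1], layer_sizes[l])`` and maps activations of
        layer ``l`` to pre-activations of layer ``l + 1``.

    In wake mode hidden activations are ``max(0, .)`` and the output layer
    produces raw logits for a softmax cross-entropy readout.
    """

    def __init__(self, layer_sizes: Sequence[int], weights: list[np.ndarray] | None = None):
        layer_sizes = [int(s) for s in layer_sizes]
        if len(layer_sizes) < 2:
            raise ValueError("a network needs at least an input and an output layer")
        if any(s <= 0 for s in layer_sizes):
            raise ValueError(f"invalid architecture: non-positive layer size in {layer_sizes}")
        self.layer_sizes = layer_sizes
        if weights is None:
            weights = [
                np.zeros((layer_sizes[l + 1], layer_sizes[l]))
                for l in range(len(layer_sizes) - 1)
            ]
        for l, w in enumerate(weights):
            expect = (layer_sizes[l + 1], layer_sizes[l])
            if w.shape != expect:
                raise ValueError(f"weights[{l}] has shape {w.shape}, expected {expect}")
        self.weights = [np.asarray(w, dtype=np.float64) for w in weights]
        self.activation_mode = "wake"

    @property
    def n_layers(self) -> int:
        return len(self.layer_sizes)

    @property
    def n_outputs(self) -> int:
        return self.layer_sizes[-1]

    def copy(self) -> "DenseNet":
        new = DenseNet(self.layer_sizes, [w.copy() for w in self.weights])
        new.activation_mode = self.activation_mode
        return new

    def forward(self, x: np.ndarray, return_hidden: bool = False):
        """Wake-mode forward pass; returns logits (and hidden activations)."""
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        hidden: list[np.ndarray] = []
        a = x
        for l, w in enumerate(self.weights):
            z = a @ w.T
            if l < len(self.weights) - 1:
                a = np.maximum(z, 0.0)
                hidden.append(a)
            else:
                a = z
        if return_hidden:
            return a, hidden
        return a

    def hidden_activations(self, x: np.ndarray) -> list[np.ndarray]:
        _, hidden = self.forward(x, return_hidden=True)
        return hidden

    def pre_activations(self, x: np.ndarray) -> list[np.ndarray]:
        """Wake-mode pre-activations (input drive) of every non-input layer."""
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        out: list[np.ndarray] = []
        a = x
        for l, w in enumerate(self.weights):
            z = a @ w.T
            out.append(z)
            a = np.maximum(z, 0.0) if l < len(self.weights) - 1 else z
        return out


def init_network(layer_sizes: Sequence[int], config: TrainingConfig) -> DenseNet:
    """Create a bias-free network with uniform weights in ±init_range."""
    net = DenseNet(layer_sizes)
    rng = np.random.default_rng(config.seed)
    net.weights = [
        rng.uniform(-config.init_range, config.init_range, size=w.shape)
        for w in net.weights
    ]
    return net


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray) -> float:
    """Mean softmax cross-entropy (natural log)."""
    p = _softmax(logits)
    n = len(labels)
    return float(-np.log(np.clip(p[np.arange(n), labels], 1e-300, None)).mean())


def _check_labels(labels: np.ndarray, n_outputs: int) -> np.ndarray:
    labels = np.asarray(labels, dtype=np.int64)
    if labels.size and (labels.min() < 0 or labels.max() >= n_outputs):
        raise ValueError(
            f"label out of range: labels must lie in [0, {n_outputs}), "
            f"got range [{labels.min()}, {labels.max()}]"
        )
    return labels


def _sgd_step(net: DenseNet, xb, yb, lr, momentum, velocity, dropout_rate, rng,
              sample_weights=None) -> None:
    """One mini-batch SGD-with-momentum step on softmax cross-entropy.

    ``sample_weights`` replaces the uniform 1/n weighting of the mean loss;
    it is how the rehearsal-weighted loss enters the gradient.
    """
    n = len(xb)
    acts = [xb]
    masks = []
    a = xb
    for l, w in enumerate(net.weights):
        z = a @ w.T
        if l < len(net.weights) - 1:
            a = np.maximum(z, 0.0)
            if dropout_rate > 0:
                mask = (rng.random(a.shape) >= dropout_rate) / (1.0 - dropout_rate)
                a = a * mask
                masks.append(mask)
            else:
                masks.append(None)
            acts.append(a)
        else:
            logits = z
    p = _softmax(logits)
    delta = p.copy()
    delta[np.arange(n), yb] -= 1.0
    if sample_weights is None:
        delta /= n
    else:
        delta *= sample_weights[:, None]
    # backpropagate through the weight stack
    for l in range(len(net.weights) - 1, -1, -1):
        grad = delta.T @ acts[l]
        if l > 0:
            delta = delta @ net.weights[l]
            if masks[l - 1] is not None:
                delta = delta * masks[l - 1]
            delta = delta * (acts[l] > 0)
        velocity[l] = velocity[l] * momentum + grad
        net.weights[l] -= lr * velocity[l]


def _run_epochs(net, x, y, config, rng, epochs, sample_weight_fn=None) -> None:
    n = len(x)
    velocity = [np.zeros_like(w) for w in net.weights]
    for _ in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            sw = sample_weight_fn(idx) if sample_weight_fn is not None else None
            _sgd_step(net, x[idx], y[idx], config.learning_rate, config.momentum,
                      velocity, config.dropout_rate, rng, sample_weights=sw)


def train_task(net: DenseNet, x: np.ndarray, y: np.ndarray,
               config: TrainingConfig, rng: np.random.Generator | None = None) -> DenseNet:
    """Train on one task's data with mini-batch SGD + momentum.

    The cross-entropy is computed over the presented samples only; in the
    class-incremental protocols this is what produces catastrophic
    forgetting of earlier classes.
    """
    if net.activation_mode != "wake":
        raise ValueError("network must be in wake mode for supervised training")
    x = np.asarray(x, dtype=np.float64)
    y = _check_labels(y, net.n_outputs)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    _run_epochs(net, x, y, config, rng, config.epochs_per_task)
    return net


def train_task_with_rehearsal(net: DenseNet, new_x, new_y, old_x, old_y,
                              rehearsal: RehearsalConfig, config: TrainingConfig,
                              rng: np.random.Generator | None = None) -> DenseNet:
    """Train on a task while mixing in a buffer of old-task examples.

    Each step minimises ``w_cur * CE(current-in-batch) + w_old *
    CE(old-in-batch)`` where the weights come from :class:`RehearsalConfig`.
    Batches are drawn from the pooled data; a batch that happens to contain
    no old samples contributes only the current-task term.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    new_x = np.asarray(new_x, dtype=np.float64)
    new_y = _check_labels(new_y, net.n_outputs)
    old_x = np.asarray(old_x, dtype=np.float64)
    if old_x.size == 0:
        if rehearsal.n_tasks_seen > 1:
            warnings.warn("empty rehearsal buffer with n_tasks_seen > 1; "
                          "falling back to current-task loss", stacklevel=2)
        return train_task(net, new_x, new_y, config, rng=rng)
    old_y = _check_labels(old_y, net.n_outputs)

    x = np.concatenate([new_x, old_x])
    y = np.concatenate([new_y, old_y])
    is_old = np.zeros(len(x), dtype=bool)
    is_old[len(new_x):] = True
    w_cur = rehearsal.loss_weight_current
    w_old = rehearsal.loss_weight_old

    def sample_weight_fn(idx):
        old_mask = is_old[idx]
        n_old = int(old_mask.sum())
        n_cur = len(idx) - n_old
        sw = np.empty(len(idx))
        if n_cur:
            sw[~old_mask] = w_cur / n_cur
        if n_old:
            sw[old_mask] = w_old / n_old
        return sw

    _run_epochs(net, x, y, config, rng, config.epochs_per_task,
                sample_weight_fn=sample_weight_fn)
    return net


def train_to_convergence(net: DenseNet, x, y, learning_rate: float = 0.1,
                         tol: float = 1e-5, max_epochs: int = 500) -> DenseNet:
    """Full-batch gradient descent until the loss plateaus.

    Used for the toy binary-patch model: a softmax classifier with no
    momentum and no dropout, trained until the cross-entropy changes by less
    than ``tol`` between epochs (or ``max_epochs`` is reached).
    """
    x = np.asarray(x, dtype=np.float64)
    y = _check_labels(y, net.n_outputs)
    velocity = [np.zeros_like(w) for w in net.weights]
    rng = np.random.default_rng(0)  # unused: no dropout
    prev = cross_entropy(net.forward(x), y)
    for _ in range(max_epochs):
        _sgd_step(net, x, y, learning_rate, 0.0, velocity, 0.0, rng)
        loss = cross_entropy(net.forward(x), y)
        if abs(prev - loss) < tol:
            break
        prev = loss
    return net


@dataclass
class EvaluationResult:
    """Accuracy plus per-class (and optionally per-task) breakdowns."""

    accuracy: float
    per_class: dict = field(default_factory=dict)
    per_task: dict = field(default_factory=dict)

    def __float__(self) -> float:
        return self.accuracy


def evaluate(net: DenseNet, x, y, task_classes: dict | None = None) -> EvaluationResult:
    """Classification accuracy with argmax ties broken by lowest class index.

    ``task_classes`` optionally maps task id -> iterable of class labels to
    produce a per-task breakdown of the same predictions.
    """
    x = np.asarray(x, dtype=np.float64)
    y = _check_labels(y, net.n_outputs)
    if len(x) == 0:
        raise ValueError("cannot evaluate on an empty dataset")
    logits = net.forward(x)
    pred = logits.argmax(axis=1)  # argmax returns the first (lowest) maximiser
    correct = pred == y
    per_class = {int(c): float(correct[y == c].mean()) for c in np.unique(y)}
    per_task = {}
    if task_classes is not None:
        for tid, classes in task_classes.items():
            mask = np.isin(y, list(classes))
            per_task[tid] = float(correct[mask].mean()) if mask.any() else float("nan")
    return EvaluationResult(float(correct.mean()), per_class, per_task)
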