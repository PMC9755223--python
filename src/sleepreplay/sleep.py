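"""The sleep phase: noise-driven offline Hebbian consolidation.

A trained rectifier network is temporarily viewed as a threshold (spiking)
network: activations become Heaviside steps, every neuron carries a membrane
voltage that integrates scaled synaptic drive across time steps, and a
neuron "spikes" when its voltage strictly exceeds its layer threshold
(resetting the voltage to zero).  The input layer is driven by binary noise
whose per-pixel rate is the mean intensity of that pixel over everything the
network was ever trained on.  While this spontaneous activity propagates, a
local two-case Hebbian rule edits the stored weights:

* potentiation by ``inc`` when pre- and post-synaptic neurons spike at the
  same step;
* depression by ``dec`` when the post-synaptic neuron spikes but the
  pre-synaptic one is silent;
* no change when the post-synaptic neuron is silent.

Weights are never rescaled in place: per-layer scale factors derived from
the maximum activations observed during the last training (plus a
configurable multiplier) are applied at propagation time only, so converting
back to wake mode is a no-op on the weight matrices.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .datasets import InputStatistics
from .network import DenseNet, evaluate

__all__ = [
    "SleepConfig",
    "SleepNet",
    "SpikeLog",
    "layer_activation_maxima",
    "ann_to_sleep_ann",
    "sleep_ann_to_ann",
    "poisson_input",
    "forward_pass",
    "backward_pass",
    "sleep",
    "tune_sleep_hyperparameters",
]


@dataclass
class SleepConfig:
    """Hyperparameters of one sleep episode.

    ``thresholds`` and ``scale_multipliers`` may be a scalar (shared by all
    non-input layers) or one value per non-input layer.  The defaults are
    conservative placeholders: per-dataset values are meant to be found with
    :func:`tune_sleep_hyperparameters`, scored on training-set accuracy.
    """

    duration: int = 10_000
    inc: float = 0.001
    dec: float = 0.0001
    thresholds: float | Sequence[float] = 1.0
    scale_multipliers: float | Sequence[float] = 1.0
    input_mode: str = "bernoulli_mean"  # or "bernoulli_uniform"
    uniform_rate: float = 0.5
    use_max_weight: bool = True
    record_spikes: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration < 0:
            raise ValueError("duration must be >= 0")
        if self.inc < 0 or self.dec < 0:
            raise ValueError("inc and dec must be >= 0")
        if self.input_mode not in ("bernoulli_mean", "bernoulli_uniform"):
            raise ValueError(f"unknown input_mode {self.input_mode!r}")

    def replace(self, **kwargs) -> "SleepConfig":
        return replace(self, **kwargs)

    def per_layer(self, value, n_layers: int) -> np.ndarray:
        arr = np.atleast_1d(np.asarray(value, dtype=np.float64))
        if arr.size == 1:
            arr = np.full(n_layers, arr.item())
        if arr.size != n_layers:
            raise ValueError(f"expected {n_layers} per-layer values, got {arr.size}")
        return arr


class SleepNet:
    """A :class:`DenseNet` viewed through sleep (threshold/spiking) semantics.

    Shares the weight matrices with the source network — they stay unscaled;
    ``scales`` are applied at propagation time.  Voltages start at zero and
    persist across time steps except for reset-on-spike.
    """

    def __init__(self, net: DenseNet, scales: np.ndarray, thresholds: np.ndarray):
        self.net = net
        self.weights = net.weights  # shared, unscaled
        self.layer_sizes = net.layer_sizes
        self.scales = np.asarray(scales, dtype=np.float64)
        self.thresholds = np.asarray(thresholds, dtype=np.float64)
        self.reset_state()

    def reset_state(self) -> None:
        self.voltages = [np.zeros(s) for s in self.layer_sizes[1:]]


@dataclass
class SpikeLog:
    """Per-step binary spike records, one (steps x neurons) array per layer.

    ``layers[0]`` is the input layer; the last entry is the output layer.
    """

    layers: list[np.ndarray]

    @property
    def n_steps(self) -> int:
        return self.layers[0].shape[0]

    def rates(self, layer: int) -> np.ndarray:
        """Mean spikes per step for every neuron of ``layer``."""
        return self.layers[layer].mean(axis=0)

    def pair_counts(self, layer: int) -> tuple[np.ndarray, np.ndarray]:
        """(co-spike counts C, post-only counts D) for weight matrix ``layer``.

        ``C[j, i]`` counts steps where post-neuron j and pre-neuron i both
        spiked; ``D[j, i]`` counts steps where j spiked and i was silent.
        """
        pre = self.layers[layer].astype(np.float64)
        post = self.layers[layer + 1].astype(np.float64)
        c = post.T @ pre
        d = post.T @ (1.0 - pre)
        return c, d


def layer_activation_maxima(net: DenseNet, x: np.ndarray) -> np.ndarray:
    """Maximum wake activation of each non-input layer over a reference batch.

    For hidden layers this is the max rectified activation; for the output
    layer the max non-negative logit.
    """
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    maxima = []
    a = x
    for l, w in enumerate(net.weights):
        z = a @ w.T
        a = np.maximum(z, 0.0)
        maxima.append(float(a.max()) if a.size else 0.0)
        if l == len(net.weights) - 1:
            break
    return np.asarray(maxima)


def ann_to_sleep_ann(net: DenseNet, reference_activations: Sequence[float],
                     config: SleepConfig) -> tuple[SleepNet, np.ndarray, np.ndarray]:
    """Convert a wake network to sleep semantics; returns (net, scales, thresholds).

    The per-layer scale is the data-based normalization rule: with
    ``max_act`` the layer's maximum activation observed on the reference
    batch and ``max_w`` the maximum positive weight of the layer,

        scale = max_act / max(max_w, max_act)

    which bounds the scaled propagated activity of the reference batch by
    the layer's own maximum observed activation.  The configured
    ``scale_multipliers`` are applied on top.  Stored weights are not
    rewritten.
    """
    n_conn = len(net.weights)
    ref = np.asarray(reference_activations, dtype=np.float64)
    if ref.size != n_conn:
        raise ValueError(f"need {n_conn} reference activation maxima, got {ref.size}")
    multipliers = config.per_layer(config.scale_multipliers, n_conn)
    thresholds = config.per_layer(config.thresholds, n_conn)
    scales = np.empty(n_conn)
    for l in range(n_conn):
        max_act = ref[l]
        if max_act <= 0:
            warnings.warn(f"layer {l + 1} has all-zero reference activation; "
                          "scale defaults to 1", stacklevel=2)
            scales[l] = 1.0
        else:
            max_w = float(net.weights[l].max())
            denom = max(max_w, max_act) if config.use_max_weight else max_act
            scales[l] = max_act / denom
    scales *= multipliers
    net.activation_mode = "sleep"
    return SleepNet(net, scales, thresholds), scales, thresholds


def sleep_ann_to_ann(snet: SleepNet) -> DenseNet:
    """Restore wake semantics; weights carry over unchanged (stored unscaled)."""
    snet.net.activation_mode = "wake"
    return snet.net


def poisson_input(stats, rng: np.random.Generator) -> np.ndarray:
    """Draw one binary noise frame from the stored mean-intensity rates.

    Rates are per-step event probabilities, so a single-step Poisson event
    reduces to an independent Bernoulli draw per pixel; a fresh frame is
    drawn at every sleep step.  Accepts an :class:`InputStatistics` or a
    plain rate vector; rates outside [0, 1] are clipped with a warning.
    """
    rates = stats.mean_intensity if isinstance(stats, InputStatistics) else np.asarray(stats, dtype=np.float64)
    if rates.min() < 0 or rates.max() > 1:
        warnings.warn("mean intensities outside [0, 1]; clipping", stacklevel=2)
        rates = np.clip(rates, 0.0, 1.0)
    return (rng.random(rates.shape) < rates).astype(np.float64)


def forward_pass(snet: SleepNet, s_input: np.ndarray) -> list[np.ndarray]:
    """Propagate one frame of input spikes through the threshold network.

    Layer by layer: voltages integrate the scaled drive, neurons whose
    voltage strictly exceeds the layer threshold spike and reset to zero;
    sub-threshold voltages persist to the next time step.
    """
    spikes = [np.asarray(s_input, dtype=np.float64)]
    for l, w in enumerate(snet.weights):
        v = snet.voltages[l]
        v += snet.scales[l] * (w @ spikes[-1])
        s = (v > snet.thresholds[l])
        v[s] = 0.0
        spikes.append(s.astype(np.float64))
    return spikes


def backward_pass(snet: SleepNet, spikes: list[np.ndarray],
                  inc: float, dec: float) -> None:
    """Apply the two-case Hebbian rule to the unscaled stored weights.

    For every synapse with a spiking post-neuron: +``inc`` if the pre-neuron
    also spiked, -``dec`` if it was silent.  Synapses of silent post-neurons
    are untouched.
    """
    for l, w in enumerate(snet.weights):
        post = spikes[l + 1].astype(bool)
        if not post.any():
            continue
        pre = spikes[l]
        w[post] += inc * pre - dec * (1.0 - pre)


def sleep(net: DenseNet, stats: InputStatistics, config: SleepConfig,
          reference_activations: Sequence[float] | None = None,
          reference_data: np.ndarray | None = None,
          return_log: bool = False):
    """Run one full sleep episode and return the consolidated wake network.

    The input network is left untouched; plasticity acts on a copy.
    ``reference_activations`` (or a ``reference_data`` batch from the last
    training, from which they are computed) calibrate the conversion scales.
    With ``return_log=True`` (or ``config.record_spikes``) the per-step
    spike log is returned for the replay analyses.
    """
    if stats.n_samples_seen == 0:
        raise ValueError("sleep requires populated input statistics")
    if reference_activations is None:
        if reference_data is None:
            raise ValueError("provide reference_activations or reference_data")
        reference_activations = layer_activation_maxima(net, reference_data)

    net = net.copy()
    snet, _, _ = ann_to_sleep_ann(net, reference_activations, config)
    rng = np.random.default_rng(config.seed)
    if config.input_mode == "bernoulli_uniform":
        rates = np.full(net.layer_sizes[0], config.uniform_rate)
    else:
        rates = np.clip(stats.mean_intensity, 0.0, 1.0)

    keep_log = return_log or config.record_spikes
    log_layers = [[] for _ in net.layer_sizes] if keep_log else None
    for _ in range(config.duration):
        s_in = poisson_input(rates, rng)
        spikes = forward_pass(snet, s_in)
        backward_pass(snet, spikes, config.inc, config.dec)
        if keep_log:
            for buf, s in zip(log_layers, spikes):
                buf.append(s.astype(np.uint8))
    out = sleep_ann_to_ann(snet)
    if return_log:
        arrays = [np.asarray(buf, dtype=np.uint8).reshape(config.duration, size)
                  for buf, size in zip(log_layers, net.layer_sizes)]
        return out, SpikeLog(arrays)
    return out


def tune_sleep_hyperparameters(net: DenseNet, stats: InputStatistics,
                               x_score: np.ndarray, y_score: np.ndarray,
                               grid: dict[str, Sequence], base: SleepConfig,
                               reference_data: np.ndarray) -> tuple[SleepConfig, "object"]:
    """Grid search over sleep hyperparameters, scored on training accuracy.

    Stands in for the genetic search used to pick per-dataset thresholds and
    scale multipliers: every combination in ``grid`` (a dict of SleepConfig
    field -> candidate values; a tuple key such as ``("inc", "dec")`` couples
    fields, with tuple-valued candidates) is evaluated by running a sleep
    episode on a copy of ``net`` and measuring accuracy on
    ``(x_score, y_score)`` — which should be *training* data of the tasks
    seen so far, never test data.  Returns the best config (ties go to the
    earliest combination) and a list of (config, accuracy) pairs.
    """
    ref = layer_activation_maxima(net, reference_data)
    keys = list(grid)
    results = []
    best_cfg, best_acc = base, -1.0
    for combo in itertools.product(*(grid[k] for k in keys)):
        fields: dict = {}
        for key, value in zip(keys, combo):
            if isinstance(key, tuple):
                fields.update(dict(zip(key, value)))
            else:
                fields[key] = value
        cfg = base.replace(**fields)
        candidate = sleep(net, stats, cfg, reference_activations=ref)
        acc = evaluate(candidate, x_score, y_score).accuracy
        results.append((cfg, acc))
        if acc > best_acc:
            best_cfg, best_acc = cfg, acc
    return best_cfg, results
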