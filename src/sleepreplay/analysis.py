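"""Replay and representation diagnostics.

These routines quantify *why* a sleep phase helps: do hidden-layer
representations of different classes decorrelate, do task-responsive
neurons reactivate spontaneously under noise, and how does the synaptic
drive to task-specific neuron groups shift?  Nothing here modifies a
network; everything consumes wake networks, sleep-mode networks or spike
logs produced by :mod:`sleepreplay.sleep`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .datasets import PatchesData
from .network import DenseNet
from .sleep import SleepNet, SpikeLog, forward_pass, poisson_input

__all__ = [
    "class_correlation_matrix",
    "identify_task_neurons",
    "sleep_firing_comparison",
    "FiringComparison",
    "drive_change",
    "weight_category_histograms",
    "weight_cosine_similarity",
    "inactive_fraction",
    "treves_rolls_sparseness",
    "ReplayReport",
]


def class_correlation_matrix(net: DenseNet, x: np.ndarray, y: np.ndarray,
                             layer: int) -> np.ndarray:
    """Mean pairwise Pearson correlation of hidden activations, by class pair.

    Entry (a, b) averages the correlation between the activation vectors of
    every cross pair of samples from classes a and b (for a == b, distinct
    samples only).  Samples whose activation vector has zero variance are
    excluded; an entry with no valid pair is NaN.  ``layer`` indexes hidden
    layers from 0.
    """
    acts = net.hidden_activations(x)[layer]
    y = np.asarray(y)
    # standardize each sample's activation vector across neurons
    centered = acts - acts.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    valid = norms > 0
    z = np.zeros_like(centered)
    z[valid] = centered[valid] / norms[valid, None]
    corr = z @ z.T  # Pearson r for valid-valid pairs

    classes = np.unique(y)
    k = len(classes)
    out = np.full((k, k), np.nan)
    for i, a in enumerate(classes):
        ia = np.flatnonzero((y == a) & valid)
        for j, b in enumerate(classes[i:], start=i):
            ib = np.flatnonzero((y == b) & valid)
            block = corr[np.ix_(ia, ib)]
            if a == b:
                n = len(ia)
                if n < 2:
                    continue
                vals = block[np.triu_indices(n, k=1)]
            else:
                vals = block.ravel()
            if vals.size:
                out[i, j] = out[j, i] = float(vals.mean())
    return out


def identify_task_neurons(snet: SleepNet, class_inputs: Mapping[int, np.ndarray],
                          k: int = 100, passes: int = 25,
                          rng: np.random.Generator | None = None,
                          ) -> dict[int, dict[int, np.ndarray]]:
    """Find the hidden neurons most responsive to each input class.

    Each class's examples are presented to the sleep-mode network for
    ``passes`` forward passes (one fresh Bernoulli frame per pass with
    pixel-on probabilities equal to the example's intensities, cycling the
    examples; voltages reset per class).  Spikes per neuron per class are
    counted for the hidden layers only — the output layer is ignored so the
    selection reflects representation, not the classifier.  Each neuron is
    assigned to the class that maximally activates it (ties to the lower
    class index) and, per class, the ``k`` highest-count assigned neurons
    are returned (count ties to the lower neuron index).

    Returns ``{hidden_layer_index: {class: neuron indices}}``.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    classes = sorted(class_inputs)
    hidden = list(range(1, len(snet.layer_sizes) - 1))  # spike-list indices
    counts = {h: np.zeros((len(classes), snet.layer_sizes[h])) for h in hidden}
    for ci, c in enumerate(classes):
        examples = np.atleast_2d(np.asarray(class_inputs[c], dtype=np.float64))
        snet.reset_state()
        for p in range(passes):
            probs = np.clip(examples[p % len(examples)], 0.0, 1.0)
            frame = poisson_input(probs, rng)
            spikes = forward_pass(snet, frame)
            for h in hidden:
                counts[h][ci] += spikes[h]
    snet.reset_state()

    out: dict[int, dict[int, np.ndarray]] = {}
    for h in hidden:
        table = counts[h]
        assigned = table.argmax(axis=0)  # ties -> lower class index
        per_class: dict[int, np.ndarray] = {}
        for ci, c in enumerate(classes):
            pool = np.flatnonzero(assigned == ci)
            if len(pool) < k:
                warnings.warn(
                    f"layer {h}: only {len(pool)} neurons assigned to class {c} "
                    f"(< k={k}); returning the full pool", stacklevel=2)
                top = pool[np.argsort(-table[ci, pool], kind="stable")]
            else:
                top = pool[np.argsort(-table[ci, pool], kind="stable")[:k]]
            per_class[c] = top
        out[h - 1] = per_class  # report as hidden-layer index
    return out


@dataclass
class FiringComparison:
    """Result of comparing sleep firing of a neuron set vs. a random subset."""

    set_rates: np.ndarray
    random_rates: np.ndarray
    t_statistic: float
    df: float
    p_value: float          # Bonferroni-corrected, capped at 1
    p_value_raw: float
    alternative: str


def sleep_firing_comparison(spike_log: SpikeLog, neuron_sets: Mapping[object, np.ndarray],
                            layer: int, n_random: int = 100,
                            rng: np.random.Generator | None = None,
                            alternative: str = "greater",
                            n_comparisons: int = 1) -> dict[object, FiringComparison]:
    """Compare sleep firing rates of task-specific neurons to a random subset.

    For each named neuron set (e.g. the concatenated per-digit sets of one
    task), a pooled two-sample t-test compares its per-neuron mean spike
    rates against those of ``n_random`` randomly drawn neurons of the same
    hidden layer; p-values are Bonferroni-corrected by ``n_comparisons``.
    ``layer`` is the hidden-layer index (0-based); the spike log must come
    from a sleep run (typically driven by uniform random input to avoid
    bias from the task-averaged statistics).
    """
    if spike_log.n_steps == 0:
        raise ValueError("empty spike log")
    if rng is None:
        rng = np.random.default_rng(0)
    rates = spike_log.rates(layer + 1)  # skip the input layer
    out = {}
    for name, idx in neuron_sets.items():
        idx = np.asarray(idx, dtype=np.int64)
        rand = rng.choice(len(rates), size=min(n_random, len(rates)), replace=False)
        a, b = rates[idx], rates[rand]
        df = len(a) + len(b) - 2
        if a.std() == 0 and b.std() == 0 and a.mean() == b.mean():
            # degenerate case (e.g. all rates equal): no evidence either way
            t, p = 0.0, 0.5 if alternative != "two-sided" else 1.0
        else:
            res = sps.ttest_ind(a, b, equal_var=True, alternative=alternative)
            t, p = float(res.statistic), float(res.pvalue)
        out[name] = FiringComparison(
            set_rates=a, random_rates=b,
            t_statistic=t, df=float(df),
            p_value=min(1.0, p * n_comparisons),
            p_value_raw=p, alternative=alternative)
    return out


def drive_change(net_before: DenseNet, net_after: DenseNet, x: np.ndarray,
                 layer: int, neuron_sets: Mapping[object, np.ndarray]) -> dict:
    """Mean change in synaptic input drive to neuron groups after sleep.

    The drive is the wake-mode pre-activation of layer ``layer`` (0 = first
    non-input layer) averaged over the given inputs; the result maps each
    set name to the mean over its neurons of (after - before).
    """
    if net_before.layer_sizes != net_after.layer_sizes:
        raise ValueError("networks have mismatched architectures")
    before = net_before.pre_activations(x)[layer].mean(axis=0)
    after = net_after.pre_activations(x)[layer].mean(axis=0)
    delta = after - before
    return {name: float(delta[np.asarray(idx, dtype=np.int64)].mean())
            for name, idx in neuron_sets.items()}


def weight_category_histograms(net: DenseNet, patches: PatchesData) -> dict:
    """Partition toy-model input->output weights by pixel category.

    Returns ``{(pixel_category, output_task): flat weight array}`` with
    pixel categories ``unique_t1`` / ``unique_t2`` / ``overlapping`` and
    output tasks ``t1`` (outputs 0, 1) / ``t2`` (outputs 2, 3).
    """
    w = net.weights[0]
    if w.shape != (4, patches.spec.n_pixels):
        raise ValueError(
            f"toy network weights {w.shape} do not match the patches spec "
            f"(4, {patches.spec.n_pixels})")
    pixel_cats = {"unique_t1": patches.unique_t1_pixels,
                  "unique_t2": patches.unique_t2_pixels,
                  "overlapping": patches.overlapping_pixels}
    outputs = {"t1": [0, 1], "t2": [2, 3]}
    return {(pc, ot): w[np.ix_(rows, cols)].ravel()
            for pc, cols in pixel_cats.items()
            for ot, rows in outputs.items()}


def weight_cosine_similarity(weights_a: Sequence[np.ndarray],
                             weights_b: Sequence[np.ndarray]) -> float:
    """Cosine similarity of two weight collections, flattened and concatenated.

    NaN (missing) if either flattened vector is zero.
    """
    if len(weights_a) != len(weights_b):
        raise ValueError("weight lists differ in length")
    for wa, wb in zip(weights_a, weights_b):
        if np.shape(wa) != np.shape(wb):
            raise ValueError("weight shapes differ")
    a = np.concatenate([np.ravel(w) for w in weights_a])
    b = np.concatenate([np.ravel(w) for w in weights_b])
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return float("nan")
    return float(a @ b / (na * nb))


def inactive_fraction(net: DenseNet, x: np.ndarray, layer: int,
                      tol: float = 1e-6) -> float:
    """Fraction of hidden neurons essentially silent per stimulus (mean)."""
    acts = net.hidden_activations(x)[layer]
    return float((acts < tol).mean())


def treves_rolls_sparseness(net: DenseNet, x: np.ndarray, layer: int) -> float:
    """Treves–Rolls population sparseness, averaged over stimuli.

    ``a = (mean r)^2 / mean(r^2)`` per stimulus; small a = sparse code.
    Stimuli with no activity are skipped; NaN if none remain.
    """
    acts = net.hidden_activations(x)[layer]
    num = acts.mean(axis=1) ** 2
    den = (acts ** 2).mean(axis=1)
    ok = den > 0
    if not ok.any():
        return float("nan")
    return float((num[ok] / den[ok]).mean())


@dataclass
class ReplayReport:
    """Bundle of the diagnostics computed for one experiment."""

    correlation_matrices: dict = field(default_factory=dict)
    task_neuron_sets: dict = field(default_factory=dict)
    firing_comparisons: dict = field(default_factory=dict)
    drive_changes: dict = field(default_factory=dict)
    weight_histograms: dict = field(default_factory=dict)
    cosine_similarities: dict = field(default_factory=dict)
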