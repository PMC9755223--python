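"""Config-driven continual-learning protocols.

Each runner trains a task stream sequentially and records the full
per-phase accuracy picture: after every training phase (``T1``, ``T2``,
...) and every sleep phase (``S1``, ...) the network is evaluated on the
*complete* test set, broken down per task, single-head over all classes.
The runners differ only in what happens between tasks:

* :func:`run_sequential` — nothing (the catastrophic-forgetting baseline);
* :func:`run_src_protocol` — a sleep episode after each task;
* :func:`run_rehearsal_protocol` — a rehearsal buffer with the
  task-count-weighted loss, optionally followed by sleep;
* :func:`run_single_task_probe` — one task, variable amounts of training,
  sleep applied to probe under- vs. well-trained memories;
* :func:`run_patches_protocol` / :func:`run_patches_sweep` — the toy
  binary-patch model, trained to convergence per task.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datasets import (InputStatistics, PatchesSpec, RehearsalBuffer,
                       TaskStream, build_task_stream, generate_patches)
from .network import (DenseNet, RehearsalConfig, TrainingConfig, evaluate,
                      init_network, train_task, train_task_with_rehearsal,
                      train_to_convergence)
from .sleep import SleepConfig, SpikeLog, sleep, tune_sleep_hyperparameters

__all__ = [
    "RunResult",
    "run_protocol",
    "run_sequential",
    "run_src_protocol",
    "run_rehearsal_protocol",
    "run_single_task_probe",
    "run_patches_protocol",
    "run_patches_sweep",
    "run_two_task_fixture_experiment",
    "DEFAULT_TOY_SLEEP_GRID",
    "DEFAULT_FIXTURE_SLEEP_GRID",
    "toy_sleep_config",
    "fixture_sleep_config",
]


@dataclass
class RunResult:
    """Outcome of one protocol run.

    ``table`` has one row per (phase, task) plus an ``overall`` row per
    phase; ``phases`` maps phase label -> network snapshot when snapshots
    were requested.
    """

    table: pd.DataFrame
    net: DenseNet
    stats: InputStatistics
    phases: dict[str, DenseNet] = field(default_factory=dict)
    spike_logs: dict[str, SpikeLog] = field(default_factory=dict)
    sleep_configs: dict[str, SleepConfig] = field(default_factory=dict)


def _record(rows, phase, net, stream):
    res = evaluate(net, stream.x_test, stream.y_test,
                   task_classes=stream.task_classes)
    for tid in sorted(res.per_task):
        rows.append({"phase": phase, "task_id": str(tid),
                     "accuracy": res.per_task[tid]})
    rows.append({"phase": phase, "task_id": "overall", "accuracy": res.accuracy})
    return res.accuracy


def run_protocol(stream: TaskStream, layer_sizes: Sequence[int],
                 train_config: TrainingConfig,
                 sleep_config: SleepConfig | None = None,
                 rehearsal_config: RehearsalConfig | None = None,
                 seed: int = 0,
                 tune_grid: Mapping[str, Sequence] | None = None,
                 keep_networks: bool = False,
                 record_spikes: bool = False) -> RunResult:
    """Generic engine behind the named protocols.

    ``seed`` controls weight init, batch shuffling/dropout, rehearsal
    sampling and sleep noise through independent child seeds.  When
    ``tune_grid`` is given, the sleep hyperparameters are re-searched before
    each sleep phase, scored on the training data of all tasks seen so far
    (never on test data).
    """
    master = np.random.default_rng(seed)
    init_seed, train_seed, sleep_seed, buf_seed = master.integers(2 ** 31, size=4)
    net = init_network(layer_sizes, train_config.replace(seed=int(init_seed)))
    train_rng = np.random.default_rng(int(train_seed))
    buf_rng = np.random.default_rng(int(buf_seed))
    stats = InputStatistics(layer_sizes[0])
    buffer = RehearsalBuffer(rehearsal_config.fraction_stored) if rehearsal_config else None

    rows: list[dict] = []
    result = RunResult(pd.DataFrame(), net, stats)
    seen_x, seen_y = [], []
    for i, task in enumerate(stream.tasks, start=1):
        if buffer is not None and i > 1:
            old_x, old_y = buffer.data
            cfg = RehearsalConfig(rehearsal_config.fraction_stored, n_tasks_seen=i)
            train_task_with_rehearsal(net, task.x_train, task.y_train,
                                      old_x, old_y, cfg, train_config, rng=train_rng)
        else:
            train_task(net, task.x_train, task.y_train, train_config, rng=train_rng)
        stats.update(task.x_train)
        seen_x.append(task.x_train)
        seen_y.append(task.y_train)
        _record(rows, f"T{i}", net, stream)
        if keep_networks:
            result.phases[f"T{i}"] = net.copy()

        if sleep_config is not None:
            cfg = sleep_config.replace(seed=int(sleep_seed) + i)
            if tune_grid:
                cfg, _ = tune_sleep_hyperparameters(
                    net, stats, np.concatenate(seen_x), np.concatenate(seen_y),
                    tune_grid, cfg, reference_data=task.x_train)
            if record_spikes:
                new_net, log = sleep(net, stats, cfg,
                                     reference_data=task.x_train, return_log=True)
                result.spike_logs[f"S{i}"] = log
            else:
                new_net = sleep(net, stats, cfg, reference_data=task.x_train)
            net.weights = new_net.weights
            result.sleep_configs[f"S{i}"] = cfg
            _record(rows, f"S{i}", net, stream)
            if keep_networks:
                result.phases[f"S{i}"] = net.copy()

        if buffer is not None:
            buffer.add_task(task.x_train, task.y_train, buf_rng)

    result.table = pd.DataFrame(rows)
    result.net = net
    return result


def run_sequential(stream, layer_sizes, train_config, seed: int = 0,
                   **kwargs) -> RunResult:
    """Sequential training without sleep — the lower-bound baseline."""
    return run_protocol(stream, layer_sizes, train_config, sleep_config=None,
                        seed=seed, **kwargs)


def run_src_protocol(stream, layer_sizes, train_config, sleep_config,
                     seed: int = 0, **kwargs) -> RunResult:
    """Sequential training with a sleep episode after every task."""
    return run_protocol(stream, layer_sizes, train_config,
                        sleep_config=sleep_config, seed=seed, **kwargs)


def run_rehearsal_protocol(stream, layer_sizes, train_config, rehearsal_config,
                           sleep_config=None, with_src: bool = False,
                           seed: int = 0, **kwargs) -> RunResult:
    """Rehearsal buffer + weighted loss, optionally followed by sleep."""
    return run_protocol(stream, layer_sizes, train_config,
                        sleep_config=sleep_config if with_src else None,
                        rehearsal_config=rehearsal_config, seed=seed, **kwargs)


def run_single_task_probe(x_train, y_train, x_test, y_test,
                          layer_sizes: Sequence[int],
                          train_config: TrainingConfig,
                          sleep_config: SleepConfig,
                          epochs_grid: Sequence[int] = (0, 1, 2, 5, 10),
                          seed: int = 0,
                          tune_grid: Mapping[str, Sequence] | None = None) -> pd.DataFrame:
    """Accuracy before/after sleep as a function of training amount.

    Probes the under-training effect: sleep should lift an undertrained
    memory while leaving a well-trained one roughly unchanged (or slightly
    lower).
    """
    master = np.random.default_rng(seed)
    rows = []
    for epochs in epochs_grid:
        init_seed, train_seed, sleep_seed = master.integers(2 ** 31, size=3)
        cfg = train_config.replace(epochs_per_task=int(epochs), seed=int(init_seed))
        net = init_network(layer_sizes, cfg)
        train_task(net, x_train, y_train, cfg,
                   rng=np.random.default_rng(int(train_seed)))
        stats = InputStatistics(layer_sizes[0]).update(x_train)
        pre = evaluate(net, x_test, y_test).accuracy
        scfg = sleep_config.replace(seed=int(sleep_seed))
        if tune_grid:
            scfg, _ = tune_sleep_hyperparameters(net, stats, x_train, y_train,
                                                 tune_grid, scfg,
                                                 reference_data=x_train)
        post_net = sleep(net, stats, scfg, reference_data=x_train)
        post = evaluate(post_net, x_test, y_test).accuracy
        rows.append({"epochs": int(epochs), "pre_sleep": pre, "post_sleep": post})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Toy Patches protocols
# ---------------------------------------------------------------------------

#: Hyperparameter grid searched (on the training images) before the toy
#: sleep phase; stands in for the per-dataset genetic search.
DEFAULT_TOY_SLEEP_GRID: dict = {
    "thresholds": (0.25, 0.5, 1.0, 2.0),
    "duration": (500, 2000),
    ("inc", "dec"): ((0.002, 0.002), (0.002, 0.004), (0.004, 0.002)),
}

#: Grid used before sleep phases on the synthetic image fixtures.  The
#: per-layer threshold triples make the first hidden layer fire sparsely
#: (selectively) while keeping deeper layers and the output excitable.
DEFAULT_FIXTURE_SLEEP_GRID: dict = {
    "thresholds": ((2.0, 0.5, 0.5), (2.0, 1.0, 1.0), (1.0, 0.5, 0.5),
                   (3.0, 0.5, 0.5)),
    ("inc", "dec"): ((0.0002, 0.0001), (0.0005, 0.00025)),
}


def toy_sleep_config(seed: int = 0) -> SleepConfig:
    """Base sleep configuration for the toy model.

    Frequently spiking (recent-task) output neurons have their weights from
    rarely active pixels driven negative, which restores the old task; the
    exact threshold/duration/plasticity balance is found per run by the
    grid search, as recovery is sensitive to the interference level.
    """
    return SleepConfig(duration=2000, inc=0.002, dec=0.002, thresholds=0.5,
                       scale_multipliers=1.0, seed=seed)


def fixture_sleep_config(seed: int = 0) -> SleepConfig:
    """Base sleep configuration for the synthetic-image fixture networks."""
    return SleepConfig(duration=1500, inc=0.0002, dec=0.0001,
                       thresholds=[2.0, 0.5, 0.5], seed=seed)


def run_patches_protocol(overlap: int, with_sleep: bool = False, seed: int = 0,
                         n_on_pixels: int = 18,
                         sleep_config: SleepConfig | None = None,
                         tune_grid: Mapping[str, Sequence] | None = None,
                         keep_networks: bool = False) -> dict:
    """Train the toy two-task patch problem, optionally followed by sleep.

    The toy network has no hidden layer (a 100->4 softmax classifier) and is
    trained to convergence on each task with plain full-batch gradient
    descent (no momentum, no dropout).  Sleep — when enabled — runs once,
    after the second task, which is where forgetting has occurred.  With
    ``tune_grid`` (default :data:`DEFAULT_TOY_SLEEP_GRID` when ``None`` and
    sleep is on) the sleep hyperparameters are searched on the four training
    images.

    Returns a dict with accuracies after T1, after T2 and (if enabled)
    after sleep, plus the data and network snapshots.
    """
    patches = generate_patches(PatchesSpec(overlap=overlap, seed=seed,
                                           n_on_pixels=n_on_pixels))
    stream = build_task_stream(patches, protocol="patches")
    n_pix = patches.spec.n_pixels
    net = init_network([n_pix, 4], TrainingConfig(init_range=0.02, seed=seed))
    stats = InputStatistics(n_pix)
    out: dict = {"overlap": overlap, "seed": seed, "patches": patches}

    for i, task in enumerate(stream.tasks, start=1):
        train_to_convergence(net, task.x_train, task.y_train, learning_rate=0.1)
        stats.update(task.x_train)
        out[f"accuracy_after_t{i}"] = evaluate(net, stream.x_test,
                                               stream.y_test).accuracy
        if keep_networks:
            out[f"net_after_t{i}"] = net.copy()

    if with_sleep:
        cfg = sleep_config if sleep_config is not None else toy_sleep_config(seed)
        grid = DEFAULT_TOY_SLEEP_GRID if (tune_grid is None and sleep_config is None) else tune_grid
        ref = stream.tasks[-1].x_train
        if grid:
            cfg, _ = tune_sleep_hyperparameters(net, stats, patches.images,
                                                patches.labels, grid, cfg,
                                                reference_data=ref)
        net = sleep(net, stats, cfg, reference_data=ref)
        out["accuracy_after_sleep"] = evaluate(net, stream.x_test,
                                               stream.y_test).accuracy
        out["sleep_config"] = cfg
    out["net"] = net
    out["stats"] = stats
    return out


def run_two_task_fixture_experiment(seed: int = 0,
                                    layer_sizes: Sequence[int] = (100, 400, 400, 4),
                                    epochs_per_task: int = 30,
                                    samples_per_class: int = 250,
                                    tune_grid: Mapping | None = None,
                                    sleep_after_first_task: bool = False,
                                    record_uniform_sleep: bool = False) -> dict:
    """The reduced two-task class-incremental experiment on the synthetic fixture.

    Trains the four-class fixture as two tasks (classes 0/1 then 2/3) with a
    single shared head, which forgets task 1, then applies a sleep phase
    whose hyperparameters are grid-searched on the training data (default
    grid :data:`DEFAULT_FIXTURE_SLEEP_GRID`).  Optionally also sleeps after
    the first task (the full interleaved protocol) and records an extra
    uniform-noise sleep episode's spike log for the replay analyses.

    Returns a dict with the stream, input statistics, pre-/post-sleep
    networks and accuracies, the chosen sleep config, and (if requested)
    the uniform-input spike log.
    """
    from .datasets import generate_synthetic_images, two_task_synthetic_spec

    master = np.random.default_rng(seed)
    s_data, s_test, s_net, s_train, s_sleep = master.integers(2 ** 31, size=5)
    spec = two_task_synthetic_spec(seed=int(s_data),
                                   samples_per_class=samples_per_class)
    x_train, y_train = generate_synthetic_images(spec)
    test_spec = two_task_synthetic_spec(
        seed=int(s_test), samples_per_class=max(1, samples_per_class // 5))
    x_test, y_test = generate_synthetic_images(test_spec)
    stream = build_task_stream((x_train, y_train), (x_test, y_test),
                               classes_per_task=2)
    train_cfg = TrainingConfig(epochs_per_task=epochs_per_task, seed=int(s_net))
    net = init_network(list(layer_sizes), train_cfg)
    rng = np.random.default_rng(int(s_train))
    stats = InputStatistics(layer_sizes[0])
    grid = DEFAULT_FIXTURE_SLEEP_GRID if tune_grid is None else tune_grid
    from .sleep import tune_sleep_hyperparameters

    seen_x, seen_y = [], []
    out: dict = {"stream": stream, "stats": stats, "seed": seed}
    for i, task in enumerate(stream.tasks, start=1):
        train_task(net, task.x_train, task.y_train, train_cfg, rng=rng)
        stats.update(task.x_train)
        seen_x.append(task.x_train)
        seen_y.append(task.y_train)
        last = i == len(stream.tasks)
        if last or sleep_after_first_task:
            base = fixture_sleep_config(seed=int(s_sleep) + i)
            cfg, _ = tune_sleep_hyperparameters(
                net, stats, np.concatenate(seen_x), np.concatenate(seen_y),
                grid, base, reference_data=task.x_train)
            if last:
                out["net_pre_sleep"] = net.copy()
                out["accuracy_pre_sleep"] = evaluate(net, x_test, y_test).accuracy
                out["sleep_config"] = cfg
            net = sleep(net, stats, cfg, reference_data=task.x_train)
    out["net_post_sleep"] = net
    out["accuracy_post_sleep"] = evaluate(net, x_test, y_test).accuracy
    if record_uniform_sleep:
        ucfg = out["sleep_config"].replace(input_mode="bernoulli_uniform",
                                           seed=int(s_sleep) + 777)
        _, log = sleep(out["net_pre_sleep"], stats, ucfg,
                       reference_data=stream.tasks[-1].x_train, return_log=True)
        out["uniform_spike_log"] = log
        out["uniform_sleep_config"] = ucfg
    return out


def run_patches_sweep(overlaps: Sequence[int], seeds: Sequence[int],
                      with_sleep: bool = False, **kwargs) -> pd.DataFrame:
    """Interference sweep: final accuracies across overlaps and seeds."""
    rows = []
    for ov in overlaps:
        for s in seeds:
            r = run_patches_protocol(int(ov), with_sleep=with_sleep,
                                     seed=int(s), **kwargs)
            rows.append({"overlap": int(ov), "seed": int(s),
                         "after_t1": r["accuracy_after_t1"],
                         "after_t2": r["accuracy_after_t2"],
                         "after_sleep": r.get("accuracy_after_sleep", np.nan)})
    return pd.DataFrame(rows)
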