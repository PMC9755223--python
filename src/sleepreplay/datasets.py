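"""Datasets, task streams and input statistics.

Four data paths feed the continual-learning protocols:

* the toy "Patches" task — four binary 10x10 images split into two tasks,
  with a controlled number of pixels shared between cross-task image pairs
  (the single interference dial of the toy model);
* IDX-format readers for MNIST/Fashion-MNIST style archives and a CSV
  reader for precomputed feature-vector datasets;
* a synthetic image generator (class-conditional Bernoulli pixel maps)
  that emulates the per-class mean-intensity structure the sleep noise
  relies on, so every experiment can run without downloads;
* :class:`InputStatistics`, the running per-pixel mean over everything the
  network has been trained on — the only memory of old tasks the sleep
  phase is allowed.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PatchesSpec",
    "PatchesData",
    "generate_patches",
    "SyntheticImageSpec",
    "generate_synthetic_images",
    "two_task_synthetic_spec",
    "read_idx",
    "read_idx_dataset",
    "write_idx",
    "read_feature_csv",
    "Task",
    "TaskStream",
    "build_task_stream",
    "RehearsalBuffer",
    "InputStatistics",
]


# ---------------------------------------------------------------------------
# Toy Patches task
# ---------------------------------------------------------------------------

@dataclass
class PatchesSpec:
    """Geometry of the four-image binary toy task.

    Images 0,1 form task 1 and images 2,3 form task 2.  Each image has
    exactly ``n_on_pixels`` bright pixels.  The paired cross-task images
    (0<->2 and 1<->3) share exactly ``overlap`` bright pixels; every other
    pair of on-pixel sets is disjoint, so ``overlap`` is the only source of
    interference between the tasks.
    """

    image_side: int = 10
    n_on_pixels: int = 18
    overlap: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.overlap <= self.n_on_pixels:
            raise ValueError("overlap must lie in [0, n_on_pixels]")
        if 4 * self.n_on_pixels - 2 * self.overlap > self.image_side ** 2:
            raise ValueError(
                f"infeasible geometry: 4*{self.n_on_pixels} - 2*{self.overlap} "
                f"distinct pixels exceed the {self.image_side ** 2}-pixel image"
            )

    @property
    def n_pixels(self) -> int:
        return self.image_side ** 2


@dataclass
class PatchesData:
    """Generated toy images plus the pixel bookkeeping the analyses need."""

    spec: PatchesSpec
    images: np.ndarray          # (4, n_pixels) in {0.0, 1.0}, row-major
    labels: np.ndarray          # [0, 1, 2, 3]
    on_pixels: list[np.ndarray]  # per-image sorted on-pixel indices

    @property
    def overlapping_pixels(self) -> np.ndarray:
        """Pixels shared between the paired cross-task images."""
        a = np.intersect1d(self.on_pixels[0], self.on_pixels[2])
        b = np.intersect1d(self.on_pixels[1], self.on_pixels[3])
        return np.union1d(a, b)

    @property
    def unique_t1_pixels(self) -> np.ndarray:
        """On-pixels belonging to task-1 images only."""
        t1 = np.union1d(self.on_pixels[0], self.on_pixels[1])
        return np.setdiff1d(t1, self.overlapping_pixels)

    @property
    def unique_t2_pixels(self) -> np.ndarray:
        t2 = np.union1d(self.on_pixels[2], self.on_pixels[3])
        return np.setdiff1d(t2, self.overlapping_pixels)


def generate_patches(spec: PatchesSpec) -> PatchesData:
    """Draw the four binary images deterministically from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    n, ov = spec.n_on_pixels, spec.overlap
    pool = rng.permutation(spec.n_pixels)
    # consume disjoint blocks of the pixel permutation
    blocks, start = {}, 0
    for name, size in [("shared02", ov), ("unique0", n - ov), ("unique2", n - ov),
                       ("shared13", ov), ("unique1", n - ov), ("unique3", n - ov)]:
        blocks[name] = pool[start:start + size]
        start += size
    on = [
        np.sort(np.concatenate([blocks["shared02"], blocks["unique0"]])).astype(np.int64),
        np.sort(np.concatenate([blocks["shared13"], blocks["unique1"]])).astype(np.int64),
        np.sort(np.concatenate([blocks["shared02"], blocks["unique2"]])).astype(np.int64),
        np.sort(np.concatenate([blocks["shared13"], blocks["unique3"]])).astype(np.int64),
    ]
    images = np.zeros((4, spec.n_pixels))
    for i, idx in enumerate(on):
        images[i, idx] = 1.0
    return PatchesData(spec, images, np.arange(4, dtype=np.int64), on)


# ---------------------------------------------------------------------------
# Synthetic image fixture
# ---------------------------------------------------------------------------

@dataclass
class SyntheticImageSpec:
    """Class-conditional Bernoulli pixel model for download-free fixtures.

    ``prototypes`` holds one on-probability per pixel per class; a sample of
    class ``c`` turns pixel ``j`` on with probability
    ``p = proto[c, j] * (1 - noise_rate) + (1 - proto[c, j]) * noise_rate``
    (i.e. ``noise_rate`` is a pixel-flip rate).  Distinct prototypes give
    distinct class-conditional mean intensities, which is the structure the
    sleep-phase noise generator feeds on.
    """

    prototypes: np.ndarray       # (n_classes, n_pixels) in [0, 1]
    samples_per_class: int = 100
    noise_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.prototypes = np.asarray(self.prototypes, dtype=np.float64)
        if self.prototypes.ndim != 2:
            raise ValueError("prototypes must be a (n_classes, n_pixels) matrix")
        if self.prototypes.min() < 0 or self.prototypes.max() > 1:
            raise ValueError("prototype probabilities must lie in [0, 1]")
        if not 0 <= self.noise_rate <= 1:
            raise ValueError("noise_rate must lie in [0, 1]")

    @property
    def n_classes(self) -> int:
        return self.prototypes.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.prototypes.shape[1]


def generate_synthetic_images(spec: SyntheticImageSpec) -> tuple[np.ndarray, np.ndarray]:
    """Sample a labelled binary image dataset; deterministic given the seed."""
    rng = np.random.default_rng(spec.seed)
    xs, ys = [], []
    for c in range(spec.n_classes):
        p = spec.prototypes[c] * (1 - spec.noise_rate) + (1 - spec.prototypes[c]) * spec.noise_rate
        draws = (rng.random((spec.samples_per_class, spec.n_pixels)) < p).astype(np.float64)
        xs.append(draws)
        ys.append(np.full(spec.samples_per_class, c, dtype=np.int64))
    return np.concatenate(xs), np.concatenate(ys)


def two_task_synthetic_spec(n_classes: int = 4, image_side: int = 10,
                            samples_per_class: int = 250, seed: int = 0,
                            signature_pixels: int = 15, shared_pixels: int = 30,
                            signature_p: float = 0.9, shared_p: float = 0.375,
                            background_p: float = 0.05,
                            noise_rate: float = 0.02) -> SyntheticImageSpec:
    """The standard class-incremental fixture used throughout the tests.

    Every class lights a common block of ``shared_pixels`` pixels (the source
    of cross-task interference, analogous to overlapping strokes in digit
    images) plus a class-specific signature block; the rest is sparse
    background noise.  Defaults give a 4-class, two-task stream at desk
    scale.
    """
    d = image_side ** 2
    need = shared_pixels + n_classes * signature_pixels
    if need > d:
        raise ValueError(f"{need} structured pixels do not fit in {d}")
    proto = np.full((n_classes, d), background_p)
    proto[:, :shared_pixels] = shared_p
    for c in range(n_classes):
        lo = shared_pixels + c * signature_pixels
        proto[c, lo:lo + signature_pixels] = signature_p
    return SyntheticImageSpec(proto, samples_per_class=samples_per_class,
                              noise_rate=noise_rate, seed=seed)


# ---------------------------------------------------------------------------
# IDX and CSV readers
# ---------------------------------------------------------------------------

_IDX_DTYPES = {0x08: np.dtype("u1"), 0x09: np.dtype("i1"), 0x0B: np.dtype(">i2"),
               0x0C: np.dtype(">i4"), 0x0D: np.dtype(">f4"), 0x0E: np.dtype(">f8")}


def read_idx(path) -> np.ndarray:
    """Read one IDX file (the MNIST container format) into an ndarray."""
    raw = Path(path).read_bytes()
    if len(raw) < 4:
        raise ValueError(f"{path}: truncated IDX header (offset 0)")
    zero, zero2, code, ndim = raw[0], raw[1], raw[2], raw[3]
    if zero != 0 or zero2 != 0 or code not in _IDX_DTYPES:
        raise ValueError(f"{path}: bad IDX magic bytes {raw[:4]!r} (offset 0)")
    header_end = 4 + 4 * ndim
    if len(raw) < header_end:
        raise ValueError(f"{path}: truncated dimension header (offset 4)")
    dims = struct.unpack(f">{ndim}I", raw[4:header_end])
    dtype = _IDX_DTYPES[code]
    expected = int(np.prod(dims)) * dtype.itemsize if ndim else dtype.itemsize
    if len(raw) - header_end != expected:
        raise ValueError(
            f"{path}: payload is {len(raw) - header_end} bytes at offset "
            f"{header_end}, expected {expected} for dims {dims}"
        )
    return np.frombuffer(raw, dtype=dtype, offset=header_end).reshape(dims)


def read_idx_dataset(images_path, labels_path) -> tuple[np.ndarray, np.ndarray]:
    """Read paired IDX image/label files into ([0,1] features, int labels)."""
    imgs = read_idx(images_path)
    labels = read_idx(labels_path).astype(np.int64)
    if imgs.shape[0] != labels.shape[0]:
        raise ValueError(
            f"image/label count mismatch: {imgs.shape[0]} images vs "
            f"{labels.shape[0]} labels"
        )
    x = imgs.reshape(imgs.shape[0], -1).astype(np.float64)
    if imgs.dtype == np.uint8:
        x /= 255.0
    return x, labels


def write_idx(path, array: np.ndarray) -> None:
    """Write an ndarray as an IDX file (uint8 arrays only; fixture helper)."""
    array = np.ascontiguousarray(array, dtype=np.uint8)
    with open(path, "wb") as fh:
        fh.write(bytes([0, 0, 0x08, array.ndim]))
        fh.write(struct.pack(f">{array.ndim}I", *array.shape))
        fh.write(array.tobytes())


def read_feature_csv(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a generic feature-vector table (columns: label, f0..fd)."""
    df = pd.read_csv(path)
    if "label" not in df.columns:
        raise ValueError(f"{path}: feature CSV must have a 'label' column")
    y = df["label"].to_numpy(dtype=np.int64)
    x = df.drop(columns="label").to_numpy(dtype=np.float64)
    return x, y


# ---------------------------------------------------------------------------
# Task streams and rehearsal buffers
# ---------------------------------------------------------------------------

@dataclass
class Task:
    task_id: int
    classes: tuple[int, ...]
    x_train: np.ndarray
    y_train: np.ndarray


@dataclass
class TaskStream:
    """Ordered class-incremental tasks plus a single all-class test set.

    Evaluation is always single-head over all classes of the full protocol
    (class-incremental setting): the test split covers every class even
    before the corresponding task has been trained.
    """

    tasks: list[Task]
    x_test: np.ndarray
    y_test: np.ndarray

    @property
    def n_classes(self) -> int:
        return int(max(max(t.classes) for t in self.tasks)) + 1

    @property
    def task_classes(self) -> dict[int, tuple[int, ...]]:
        return {t.task_id: t.classes for t in self.tasks}


class RehearsalBuffer:
    """Stores a per-class random fraction of finished tasks' training data."""

    def __init__(self, fraction_stored: float):
        self.fraction_stored = float(fraction_stored)
        self._x: list[np.ndarray] = []
        self._y: list[np.ndarray] = []

    def add_task(self, x: np.ndarray, y: np.ndarray, rng: np.random.Generator) -> int:
        """Sample ``fraction_stored`` of each class without replacement."""
        stored = 0
        for c in np.unique(y):
            idx = np.flatnonzero(y == c)
            k = int(round(self.fraction_stored * len(idx)))
            if k == 0:
                continue
            pick = rng.choice(idx, size=k, replace=False)
            self._x.append(np.asarray(x)[pick])
            self._y.append(np.asarray(y)[pick])
            stored += k
        return stored

    def __len__(self) -> int:
        return sum(len(y) for y in self._y)

    @property
    def data(self) -> tuple[np.ndarray, np.ndarray]:
        if not self._x:
            return np.empty((0, 0)), np.empty(0, dtype=np.int64)
        return np.concatenate(self._x), np.concatenate(self._y)


def _split_pairs(n_classes: int, classes_per_task: int) -> list[tuple[int, ...]]:
    if n_classes % classes_per_task:
        raise ValueError(
            f"{n_classes} classes cannot be split into groups of {classes_per_task}"
        )
    return [tuple(range(i, i + classes_per_task))
            for i in range(0, n_classes, classes_per_task)]


def build_task_stream(train, test=None, protocol: str = "incremental",
                      classes_per_task: int = 2,
                      order_seed: int | None = None,
                      second_train=None, second_test=None) -> TaskStream:
    """Assemble a :class:`TaskStream` from labelled (x, y) splits.

    protocol
        ``incremental`` — consecutive groups of ``classes_per_task`` classes
        become tasks (class pairing fixed; the task *order* is permuted by
        ``order_seed``); ``multimodal`` — two whole datasets sharing the same
        output units become two tasks; ``patches`` — ``train`` is a
        :class:`PatchesData` and the four images form two 2-class tasks.
    """
    if protocol == "patches":
        pd_ = train
        tasks = [Task(0, (0, 1), pd_.images[:2], pd_.labels[:2]),
                 Task(1, (2, 3), pd_.images[2:], pd_.labels[2:])]
        return TaskStream(tasks, pd_.images, pd_.labels)

    if protocol == "multimodal":
        if second_train is None or second_test is None:
            raise ValueError("multimodal protocol needs a second dataset")
        (xa, ya), (xb, yb) = train, second_train
        classes = tuple(range(int(max(ya.max(), yb.max())) + 1))
        tasks = [Task(0, classes, xa, ya), Task(1, classes, xb, yb)]
        (xat, yat), (xbt, ybt) = test, second_test
        return TaskStream(tasks, np.concatenate([xat, xbt]),
                          np.concatenate([yat, ybt]))

    if protocol != "incremental":
        raise ValueError(f"unknown protocol {protocol!r}")
    x_train, y_train = train
    x_test, y_test = test
    y_train = np.asarray(y_train, dtype=np.int64)
    n_classes = int(y_train.max()) + 1
    groups = _split_pairs(n_classes, classes_per_task)
    order = np.arange(len(groups))
    if order_seed is not None:
        order = np.random.default_rng(order_seed).permutation(len(groups))
    tasks = []
    for tid, gi in enumerate(order):
        classes = groups[gi]
        mask = np.isin(y_train, classes)
        tasks.append(Task(tid, classes, np.asarray(x_train)[mask], y_train[mask]))
    return TaskStream(tasks, np.asarray(x_test),
                      np.asarray(y_test, dtype=np.int64))


# ---------------------------------------------------------------------------
# Input statistics
# ---------------------------------------------------------------------------

class InputStatistics:
    """Running per-pixel mean intensity over all training inputs seen so far.

    This is the only information about past tasks that the sleep phase may
    use; its size is fixed by the input dimension and does not grow with the
    number of tasks.
    """

    def __init__(self, n_inputs: int):
        self._total = np.zeros(int(n_inputs))
        self.n_samples_seen = 0

    @property
    def n_inputs(self) -> int:
        return self._total.shape[0]

    @property
    def mean_intensity(self) -> np.ndarray:
        if self.n_samples_seen == 0:
            return np.zeros_like(self._total)
        return self._total / self.n_samples_seen

    def update(self, batch: np.ndarray) -> "InputStatistics":
        batch = np.atleast_2d(np.asarray(batch, dtype=np.float64))
        if batch.shape[1] != self.n_inputs:
            raise ValueError(
                f"batch has {batch.shape[1]} features, statistics track {self.n_inputs}"
            )
        self._total += batch.sum(axis=0)
        self.n_samples_seen += len(batch)
        return self

    def copy(self) -> "InputStatistics":
        new = InputStatistics(self.n_inputs)
        new._total = self._total.copy()
        new.n_samples_seen = self.n_samples_seen
        return new
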