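"""Synthetic classification tasks and an IDX (MNIST-format) file reader.

The generators stand in for image benchmarks so the whole training pipeline
is exercisable without any download. Defaults mirror the MNIST fully
connected setting — 784 features, 10 classes — so sweep outputs have the
familiar shape.

`make_cluster_task` draws Gaussian clusters around mutually separated class
means (pairwise distance ≥ margin); the margin/noise ratio controls task
difficulty. `make_teacher_task` labels uniform random inputs with the argmax
of a frozen, randomly initialized teacher network, guaranteeing a realizable
decision boundary. `read_idx` loads user-supplied MNIST-style IDX files for
scaled-down replication on real data; it is never required.
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .network import LayerSpec, NetworkParams, ValidationError, forward, init_weights

__all__ = [
    "SyntheticTask",
    "make_cluster_task",
    "make_teacher_task",
    "read_idx",
    "IdxFormatError",
]


class IdxFormatError(ValidationError):
    """An IDX file failed structural validation."""


@dataclass
class SyntheticTask:
    """Features (n_samples × n_features) with one-hot labels and a train/test
    split. Metadata records how the task was generated."""

    features: np.ndarray
    labels: np.ndarray  # one-hot, (n_samples × n_classes)
    train_idx: np.ndarray
    test_idx: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def n_classes(self) -> int:
        return self.labels.shape[1]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def split(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(X_train, Y_train, X_test, Y_test), samples as rows."""
        return (
            self.features[self.train_idx],
            self.labels[self.train_idx],
            self.features[self.test_idx],
            self.labels[self.test_idx],
        )

    def class_ids(self) -> np.ndarray:
        return self.labels.argmax(axis=1)


def _one_hot(ids: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((ids.size, n_classes))
    out[np.arange(ids.size), ids] = 1.0
    return out


def _balanced_ids(n_samples: int, n_classes: int, rng: np.random.Generator) -> np.ndarray:
    """Class ids balanced within ±1, in random order."""
    ids = np.arange(n_samples) % n_classes
    rng.shuffle(ids)
    return ids


def _split_indices(
    n_samples: int, rng: np.random.Generator, test_fraction: float
) -> tuple[np.ndarray, np.ndarray]:
    perm = rng.permutation(n_samples)
    n_test = max(1, int(round(n_samples * test_fraction)))
    return np.sort(perm[n_test:]), np.sort(perm[:n_test])


def make_cluster_task(
    n_samples: int = 6000,
    n_features: int = 784,
    n_classes: int = 10,
    margin: float = 6.0,
    noise_scale: float = 1.0,
    seed: int = 0,
    test_fraction: float = 1.0 / 6.0,
) -> SyntheticTask:
    """Gaussian clusters at mutually separated class means.

    `margin` is the distance from each class mean to the nearest Bayes
    decision boundary: means sit at √2·margin times an orthonormal basis (one
    direction per class), so every pair of means is exactly 2·margin apart,
    and samples add isotropic Gaussian noise of scale `noise_scale`. With
    margin/noise_scale = 6 the task is comfortably linearly separable. Class
    counts are balanced within ±1 and the default train/test split is 5:1.
    """
    if n_classes < 2:
        raise ValidationError("need at least 2 classes")
    if margin <= 0:
        raise ValidationError("margin must be positive")
    if noise_scale < 0:
        raise ValidationError("noise_scale must be nonnegative")
    if n_classes > n_features:
        raise ValidationError(
            f"cannot place {n_classes} mutually separated means in "
            f"{n_features} dimensions with this construction"
        )
    rng = np.random.default_rng(seed)
    # random orthonormal directions via QR; pairwise mean distance == 2*margin
    q, _ = np.linalg.qr(rng.standard_normal((n_features, n_classes)))
    means = (margin * np.sqrt(2.0)) * q.T  # (n_classes × n_features)
    ids = _balanced_ids(n_samples, n_classes, rng)
    features = means[ids] + noise_scale * rng.standard_normal((n_samples, n_features))
    train_idx, test_idx = _split_indices(n_samples, rng, test_fraction)
    return SyntheticTask(
        features=features,
        labels=_one_hot(ids, n_classes),
        train_idx=train_idx,
        test_idx=test_idx,
        meta={
            "kind": "clusters",
            "class_count": n_classes,
            "feature_count": n_features,
            "noise_scale": noise_scale,
            "margin": margin,
            "seed": seed,
        },
    )


_TEACHER_RETRIES = 20


def make_teacher_task(
    teacher_specs: Sequence[LayerSpec],
    n_samples: int = 6000,
    seed: int = 0,
    test_fraction: float = 1.0 / 6.0,
    teacher: NetworkParams | None = None,
) -> SyntheticTask:
    """Label uniform random inputs by the argmax of a frozen random teacher.

    Inputs are uniform on [−1, 1]^d. If the teacher's argmax is constant on a
    draw (degenerate labeling), inputs are resampled up to a retry bound
    before erroring; draws missing some class are also retried but accepted
    (with a warning) if the bound is exhausted.
    """
    if teacher is None:
        teacher = init_weights(teacher_specs, seed=seed)
    n_features = teacher_specs[0].fan_in
    n_classes = teacher_specs[-1].fan_out
    rng = np.random.default_rng(seed + 1)
    best: tuple[np.ndarray, np.ndarray] | None = None
    for _ in range(_TEACHER_RETRIES):
        features = rng.uniform(-1.0, 1.0, size=(n_samples, n_features))
        ids = forward(teacher, features.T).output.argmax(axis=0)
        present = np.unique(ids)
        if present.size == n_classes:
            best = (features, ids)
            break
        if present.size >= 2 and (
            best is None or present.size > np.unique(best[1]).size
        ):
            best = (features, ids)
    if best is None:
        raise ValidationError("teacher network produced a constant argmax on every draw")
    features, ids = best
    covered = np.unique(ids).size
    if covered < n_classes:
        warnings.warn(
            f"teacher labels cover only {covered}/{n_classes} classes", stacklevel=2
        )
    train_idx, test_idx = _split_indices(n_samples, rng, test_fraction)
    return SyntheticTask(
        features=features,
        labels=_one_hot(ids, n_classes),
        train_idx=train_idx,
        test_idx=test_idx,
        meta={
            "kind": "teacher",
            "class_count": n_classes,
            "feature_count": n_features,
            "seed": seed,
        },
    )


# --- IDX reader --------------------------------------------------------------

_IDX_IMAGES_MAGIC = 0x00000803
_IDX_LABELS_MAGIC = 0x00000801


def _read_idx_array(path: Path, magic_expected: int, ndim: int) -> np.ndarray:
    data = path.read_bytes()
    header = 4 + 4 * ndim
    if len(data) < header:
        raise IdxFormatError(f"{path}: truncated IDX header")
    magic = struct.unpack(">I", data[:4])[0]
    if magic != magic_expected:
        raise IdxFormatError(
            f"{path}: bad magic 0x{magic:08x}, expected 0x{magic_expected:08x}"
        )
    dims = struct.unpack(f">{ndim}I", data[4:header])
    n_expected = int(np.prod(dims))
    payload = np.frombuffer(data, dtype=np.uint8, offset=header)
    if payload.size != n_expected:
        raise IdxFormatError(
            f"{path}: payload holds {payload.size} bytes, header promises {n_expected}"
        )
    return payload.reshape(dims)


def read_idx(
    images_path: str | Path, labels_path: str | Path, n_classes: int = 10
) -> SyntheticTask:
    """Load MNIST-style IDX image/label files as a SyntheticTask.

    Images (magic 0x00000803, dims count × rows × cols) are flattened and
    scaled to [0, 1] by /255; labels (magic 0x00000801) are one-hot encoded.
    The whole file becomes the training split; pass separate files for test
    data. Structural problems raise IdxFormatError naming the offending file.
    """
    images_path, labels_path = Path(images_path), Path(labels_path)
    images = _read_idx_array(images_path, _IDX_IMAGES_MAGIC, ndim=3)
    labels = _read_idx_array(labels_path, _IDX_LABELS_MAGIC, ndim=1)
    if images.shape[0] != labels.shape[0]:
        raise IdxFormatError(
            f"count mismatch: {images_path} has {images.shape[0]} images but "
            f"{labels_path} has {labels.shape[0]} labels"
        )
    if labels.size and labels.max() >= n_classes:
        raise IdxFormatError(f"{labels_path}: label {labels.max()} >= n_classes={n_classes}")
    n = images.shape[0]
    features = images.reshape(n, -1).astype(float) / 255.0
    all_idx = np.arange(n)
    return SyntheticTask(
        features=features,
        labels=_one_hot(labels.astype(int), n_classes),
        train_idx=all_idx,
        test_idx=all_idx[:0],
        meta={"kind": "idx", "images_path": str(images_path), "labels_path": str(labels_path)},
    )
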