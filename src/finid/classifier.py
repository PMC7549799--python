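"""Median-estimation (nearest-centroid) classification of dorsal-fin descriptors.

Six fin classes are recognized, the three shape families seen from either
flank.  Training aggregates every descriptor of every training image of a
class into one centroid vector (elementwise mean by default; elementwise
median optionally — the estimator the method is named after).  A sample
image is scored against class j by summing, over its descriptors d, the
squared Euclidean distance ||d - centroid_j||^2, and assigned to the class
with the smallest total.  Ties break toward the earlier class in the
declared order.  A K-NN over training images is provided as a baseline.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .features import Descriptor

#: The six dorsal-fin shape classes, in fixed declared order.
CLASS_LABELS: tuple[str, ...] = (
    "right_falcate",
    "left_falcate",
    "right_hooked",
    "left_hooked",
    "right_triangular",
    "left_triangular",
)

MODEL_FORMAT_VERSION = 1


def _descriptor_matrix(descriptors) -> np.ndarray:
    """Stack descriptors (Descriptor objects or raw vectors) into (n, d)."""
    rows = [
        d.values if isinstance(d, Descriptor) else np.asarray(d, dtype=np.float64)
        for d in descriptors
    ]
    if not rows:
        return np.empty((0, 128))
    return np.vstack(rows)


@dataclass
class TrainingSet:
    """Per-class descriptor sets, one entry per training image."""

    images: dict[str, list[np.ndarray]] = field(default_factory=dict)
    labels_of_images: dict[str, list[str]] = field(default_factory=dict)

    def add_image(self, label: str, descriptors) -> None:
        if label not in CLASS_LABELS:
            raise ValueError(f"unknown class label: {label!r}")
        self.images.setdefault(label, []).append(_descriptor_matrix(descriptors))

    def n_images(self, label: str) -> int:
        return len(self.images.get(label, []))

    def iter_images(self):
        """Yield (label, descriptor matrix) in declared class order."""
        for label in CLASS_LABELS:
            for mat in self.images.get(label, []):
                yield label, mat


@dataclass(frozen=True)
class ClassModel:
    """One aggregated descriptor centroid per fin class."""

    centroids: dict[str, np.ndarray]
    aggregator: str
    config_hash: str = ""

    def __post_init__(self) -> None:
        missing = [l for l in CLASS_LABELS if l not in self.centroids]
        if missing:
            raise ValueError(f"model missing centroids for classes: {missing}")

    def save(self, path: str | Path) -> None:
        payload = {
            "version": MODEL_FORMAT_VERSION,
            "aggregator": self.aggregator,
            "config_hash": self.config_hash,
            "centroids": {l: self.centroids[l].tolist() for l in CLASS_LABELS},
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "ClassModel":
        payload = json.loads(Path(path).read_text())
        if payload.get("version") != MODEL_FORMAT_VERSION:
            raise ValueError(f"unsupported model version: {payload.get('version')}")
        return cls(
            centroids={l: np.asarray(v) for l, v in payload["centroids"].items()},
            aggregator=payload["aggregator"],
            config_hash=payload.get("config_hash", ""),
        )


@dataclass(frozen=True)
class MatchResult:
    """Per-class distances and the arg-min prediction for one sample image."""

    distances: dict[str, float]
    predicted: str
    n_sample_descriptors: int


def train_median_classifier(
    ts: TrainingSet, aggregator: str = "mean", config_hash: str = ""
) -> ClassModel:
    """Aggregate all training descriptors of each class into its centroid.

    ``mean`` takes the elementwise average, ``median`` the elementwise
    median, over the pooled descriptors of all training images of the class.
    A class with no descriptors is a training error (named in the message).
    """
    if aggregator not in ("mean", "median"):
        raise ValueError(f"unknown aggregator: {aggregator!r}")
    centroids = {}
    for label in CLASS_LABELS:
        mats = [m for m in ts.images.get(label, []) if len(m)]
        if not mats:
            raise ValueError(f"class {label!r} has no training descriptors")
        pooled = np.vstack(mats)
        centroids[label] = (
            pooled.mean(axis=0) if aggregator == "mean" else np.median(pooled, axis=0)
        )
    return ClassModel(centroids=centroids, aggregator=aggregator, config_hash=config_hash)


def descriptor_distance(sample, model: ClassModel, class_j: str) -> float:
    """Sum over sample descriptors of squared L2 distance to the class centroid."""
    mat = _descriptor_matrix(sample)
    if len(mat) == 0:
        raise ValueError("cannot score an image with no descriptors")
    diff = mat - model.centroids[class_j][None, :]
    return float(np.sum(diff * diff))


def classify(sample, model: ClassModel) -> MatchResult:
    """Assign a sample to the class with the minimum summed squared distance.

    Ties break toward the earliest class in the declared order.
    """
    distances = {l: descriptor_distance(sample, model, l) for l in CLASS_LABELS}
    predicted = min(CLASS_LABELS, key=lambda l: (distances[l], CLASS_LABELS.index(l)))
    mat = _descriptor_matrix(sample)
    return MatchResult(
        distances=distances, predicted=predicted, n_sample_descriptors=len(mat)
    )


def knn_classify(sample, ts: TrainingSet, K: int = 3) -> str:
    """K-nearest-training-images baseline.

    The distance from the sample to a training image is the sum, over sample
    descriptors, of the minimum squared L2 distance to any of that image's
    descriptors.  Majority vote over the K nearest images; a vote tie goes to
    the tied class with the smallest summed distance.
    """
    total_images = sum(len(v) for v in ts.images.values())
    if K % 2 == 0 or not (1 <= K <= total_images):
        raise ValueError(f"K must be odd and in [1, {total_images}], got {K}")
    mat = _descriptor_matrix(sample)
    if len(mat) == 0:
        raise ValueError("cannot score an image with no descriptors")
    scored = []
    for label, train_mat in ts.iter_images():
        if len(train_mat) == 0:
            continue
        # pairwise squared distances (n_sample, n_train)
        d2 = (
            np.sum(mat * mat, axis=1)[:, None]
            + np.sum(train_mat * train_mat, axis=1)[None, :]
            - 2.0 * mat @ train_mat.T
        )
        scored.append((float(np.maximum(d2, 0.0).min(axis=1).sum()), label))
    scored.sort(key=lambda t: t[0])
    nearest = scored[:K]
    votes = Counter(label for _, label in nearest)
    top = votes.most_common()
    best_count = top[0][1]
    tied = [label for label, c in top if c == best_count]
    if len(tied) == 1:
        return tied[0]
    sums = {
        label: sum(d for d, l in nearest if l == label) for label in tied
    }
    return min(tied, key=lambda l: (sums[l], CLASS_LABELS.index(l)))
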