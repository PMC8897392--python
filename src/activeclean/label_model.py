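"""Core data model: samples, label-count vectors, majority votes, quality metrics.

A dataset under curation carries, for each sample, a vector of annotation
counts over the ``C`` categories (one entry per category, each entry the
number of annotators who assigned that category).  The *majority label* is
the category with the strictly largest count; the dataset-level objective of
label cleaning is the fraction of samples whose majority label equals the
true class, subject to a total annotation budget tracked by an
:class:`AnnotationLedger`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "UNDECIDED",
    "LabelCounts",
    "Sample",
    "NoisyDataset",
    "AnnotationLedger",
    "BudgetExhaustedError",
    "majority_label",
    "is_relabelling_complete",
    "add_annotation",
    "dataset_label_accuracy",
    "dataset_noise_rate",
]

#: Sentinel returned by :func:`majority_label` when the maximum count is tied.
UNDECIDED = "undecided"

_SIMPLEX_ATOL = 1e-9


class BudgetExhaustedError(RuntimeError):
    """Raised when an annotation is requested but the ledger budget is spent."""


def _as_counts(counts) -> np.ndarray:
    arr = np.asarray(counts)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("counts must be a non-empty 1-D vector")
    if np.any(arr < 0) or not np.allclose(arr, np.round(arr)):
        raise ValueError("counts must be non-negative integers")
    return arr.astype(np.int64)


@dataclass
class LabelCounts:
    """Per-sample annotation counts over ``C`` categories.

    Every initialised sample must carry at least one annotation in total.
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = _as_counts(self.counts)

    @property
    def n_categories(self) -> int:
        return int(self.counts.size)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def copy(self) -> "LabelCounts":
        return LabelCounts(self.counts.copy())


def _validate_simplex(dist: np.ndarray, atol: float = _SIMPLEX_ATOL) -> np.ndarray:
    dist = np.asarray(dist, dtype=float)
    if dist.ndim != 1:
        raise ValueError("distribution must be a 1-D vector")
    if np.any(dist < -atol):
        raise ValueError("distribution entries must be non-negative")
    if abs(float(dist.sum()) - 1.0) > max(atol, 1e-9):
        raise ValueError("distribution must sum to 1")
    return np.clip(dist, 0.0, None)


@dataclass
class Sample:
    """One sample: identifier, optional features/embedding, counts, optional truth.

    When ``true_dist`` is present, ``true_class`` is its argmax (lowest index
    on ties); supplying an inconsistent pair raises.
    """

    id: int | str
    counts: LabelCounts
    features: np.ndarray | None = None
    embedding_ref: int | None = None
    true_dist: np.ndarray | None = None
    true_class: int | None = None

    def __post_init__(self) -> None:
        if self.features is not None:
            self.features = np.asarray(self.features, dtype=float)
        if self.true_dist is not None:
            self.true_dist = _validate_simplex(self.true_dist)
            argmax = int(np.argmax(self.true_dist))
            if self.true_class is None:
                self.true_class = argmax
            elif self.true_class != argmax:
                raise ValueError(
                    f"true_class {self.true_class} does not match argmax of "
                    f"true_dist ({argmax})"
                )


class NoisyDataset:
    """Ordered collection of samples sharing a common category space.

    Internally columnar (one counts matrix, one truth matrix) so that
    dataset-level scoring and simulation are vectorised; :meth:`sample`
    materialises an individual :class:`Sample` view.
    """

    def __init__(
        self,
        ids: Sequence,
        counts: np.ndarray,
        true_dists: np.ndarray | None = None,
        true_classes: Sequence[int] | None = None,
        features: np.ndarray | None = None,
        category_names: Sequence[str] | None = None,
    ) -> None:
        self.ids = list(ids)
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("sample ids must be unique")
        counts = np.asarray(counts)
        if counts.ndim != 2 or counts.shape[0] != len(self.ids):
            raise ValueError("counts must be an N x C matrix aligned with ids")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        self.counts = counts.astype(np.int64)
        self.n_categories = int(counts.shape[1])

        self.true_dists = None
        if true_dists is not None:
            true_dists = np.asarray(true_dists, dtype=float)
            if true_dists.shape != self.counts.shape:
                raise ValueError("true_dists must be N x C")
            for row in true_dists:
                _validate_simplex(row)
            self.true_dists = true_dists

        if true_classes is not None:
            self.true_classes = np.asarray(true_classes, dtype=np.int64)
            if self.true_classes.shape != (len(self.ids),):
                raise ValueError("true_classes must have one entry per sample")
        elif self.true_dists is not None:
            self.true_classes = np.argmax(self.true_dists, axis=1)
        else:
            self.true_classes = None

        if self.true_dists is not None and self.true_classes is not None:
            if not np.array_equal(np.argmax(self.true_dists, axis=1), self.true_classes):
                raise ValueError("true_classes must equal argmax of true_dists")

        self.features = None
        if features is not None:
            features = np.asarray(features, dtype=float)
            if features.shape[0] != len(self.ids):
                raise ValueError("features must have one row per sample")
            self.features = features

        if category_names is not None and len(category_names) != self.n_categories:
            raise ValueError("category_names must have length C")
        self.category_names = list(category_names) if category_names else None

        self._index = {sid: i for i, sid in enumerate(self.ids)}

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_samples(cls, samples: Iterable[Sample], n_categories: int | None = None,
                     category_names: Sequence[str] | None = None) -> "NoisyDataset":
        samples = list(samples)
        if not samples:
            raise ValueError("dataset must contain at least one sample")
        C = n_categories or samples[0].counts.n_categories
        for s in samples:
            if s.counts.n_categories != C:
                raise ValueError("all counts vectors must have length C")
        ids = [s.id for s in samples]
        counts = np.stack([s.counts.counts for s in samples])
        has_dist = all(s.true_dist is not None for s in samples)
        true_dists = np.stack([s.true_dist for s in samples]) if has_dist else None
        has_class = all(s.true_class is not None for s in samples)
        true_classes = [s.true_class for s in samples] if has_class else None
        has_feat = all(s.features is not None for s in samples)
        features = np.stack([s.features for s in samples]) if has_feat else None
        return cls(ids, counts, true_dists, true_classes, features, category_names)

    # -- access ---------------------------------------------------------------

    def __len__(self) -> int:
        return len(self.ids)

    def index_of(self, sample_id) -> int:
        return self._index[sample_id]

    def sample(self, i: int) -> Sample:
        return Sample(
            id=self.ids[i],
            counts=LabelCounts(self.counts[i].copy()),
            features=None if self.features is None else self.features[i],
            true_dist=None if self.true_dists is None else self.true_dists[i],
            true_class=None if self.true_classes is None else int(self.true_classes[i]),
        )

    def copy(self) -> "NoisyDataset":
        return NoisyDataset(
            list(self.ids),
            self.counts.copy(),
            None if self.true_dists is None else self.true_dists.copy(),
            None if self.true_classes is None else self.true_classes.copy(),
            None if self.features is None else self.features.copy(),
            self.category_names,
        )

    # -- vectorised majority --------------------------------------------------

    def majority_labels(self) -> np.ndarray:
        """Majority label per sample; -1 marks an undecided (tied) vote."""
        maxval = self.counts.max(axis=1, keepdims=True)
        is_max = self.counts == maxval
        labels = np.argmax(self.counts, axis=1)
        labels[is_max.sum(axis=1) > 1] = -1
        labels[self.counts.sum(axis=1) == 0] = -1
        return labels


@dataclass
class AnnotationLedger:
    """Tracks annotation spending against a fixed budget ``B``.

    ``consumed`` always equals ``len(history)`` and never exceeds ``budget``.
    """

    budget: int
    consumed: int = 0
    history: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.budget < 0:
            raise ValueError("budget must be non-negative")
        if self.consumed != len(self.history):
            raise ValueError("consumed must equal history length")

    @property
    def remaining(self) -> int:
        return self.budget - self.consumed

    def record(self, sample_id, category: int) -> None:
        if self.consumed >= self.budget:
            raise BudgetExhaustedError("budget exhausted")
        self.history.append((sample_id, int(category)))
        self.consumed += 1


# -- operations ----------------------------------------------------------------


def majority_label(counts: LabelCounts | np.ndarray):
    """Category with the strictly largest count, or :data:`UNDECIDED` on a tie.

    Raises ``ValueError`` for an uninitialised (all-zero) sample.
    """
    arr = counts.counts if isinstance(counts, LabelCounts) else _as_counts(counts)
    if arr.sum() == 0:
        raise ValueError("uninitialised sample: counts are all zero")
    top = int(np.argmax(arr))
    if int(np.sum(arr == arr[top])) > 1:
        return UNDECIDED
    return top


def is_relabelling_complete(counts: LabelCounts | np.ndarray) -> bool:
    """True iff one category strictly dominates all others and total count > 1.

    A single initial annotation never completes a sample: the stopping rule is
    a strict majority among *collected* labels, which needs a total above 1.
    """
    arr = counts.counts if isinstance(counts, LabelCounts) else _as_counts(counts)
    if arr.sum() <= 1:
        return False
    return majority_label(arr) is not UNDECIDED


def add_annotation(counts: LabelCounts, category: int, ledger: AnnotationLedger,
                   sample_id) -> LabelCounts:
    """Add one annotation of ``category``, charging one unit to the ledger.

    Counts are only ever incremented; existing annotations are never removed.
    """
    if not 0 <= category < counts.n_categories:
        raise ValueError(f"category {category} out of range")
    ledger.record(sample_id, category)  # raises BudgetExhaustedError first
    counts.counts[category] += 1
    return counts


def dataset_label_accuracy(dataset: NoisyDataset) -> float:
    """Fraction of samples whose majority label equals the true class.

    Tied (undecided) majorities count as incorrect.
    """
    if dataset.true_classes is None:
        raise ValueError("ground truth unavailable")
    majorities = dataset.majority_labels()
    return float(np.mean(majorities == dataset.true_classes))


def dataset_noise_rate(dataset: NoisyDataset) -> float:
    """Fraction of samples whose majority label is wrong: 1 - accuracy."""
    return 1.0 - dataset_label_accuracy(dataset)
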