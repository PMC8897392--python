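"""Noisy-benchmark constructions and noise diagnostics.

Two synthetic noise models for datasets with known truth:

* **temperature-scaled instance-dependent noise (IDN)** — each sample's initial
  label is drawn from its true label distribution sharpened/flattened by a
  temperature ``tau`` (renormalised ``p**(1/tau)``).  Higher temperature pushes
  the distribution toward uniform over its support, raising the chance of a
  noisy draw while preserving the statistical dependence between the input and
  its label.
* **symmetric noise** — each label is independently replaced, with probability
  ``eta``, by a uniform draw over the other ``C - 1`` classes.

Also implements the chest-radiograph benchmark construction ("NoisyCXR"
style): NIH-derived source categories are mapped to binary pneumonia-like
opacity labels, with 10% of the consolidation/infiltration cases flipped
against the adjudicated (RSNA challenge) labels, and graded true label
distributions (1.0 / 0.66 / 0.33 / 0.0) assigned from bounding-box confidence.
Diagnostics cover per-sample difficulty (normalised Shannon entropy with a 0.3
threshold) and class-confusion diagonal dominance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .label_model import NoisyDataset

__all__ = [
    "NoiseConfig",
    "CXRCategoryRecord",
    "ConfusionMatrix",
    "temperature_scale",
    "sample_initial_labels_idn",
    "symmetric_noise_labels",
    "difficulty_class",
    "confusion_matrix",
    "diagonal_dominant",
    "build_noisycxr_labels",
    "noisycxr_true_distribution",
    "expected_crosstab",
    "NOISYCXR_CATEGORY_COUNTS",
]

CXR_CATEGORIES = (
    "pneumonia",
    "consolidation_infiltration",
    "other_disease_only",
    "no_finding",
)

#: Published category-by-adjudicated-label counts for the chest-radiograph
#: benchmark: {category: (adjudicated-positive count, adjudicated-negative count)}.
NOISYCXR_CATEGORY_COUNTS = {
    "pneumonia": (367, 441),
    "consolidation_infiltration": (3988, 8551),
    "other_disease_only": (1101, 5567),
    "no_finding": (556, 6113),
}


@dataclass
class NoiseConfig:
    """Configuration for a noise model.

    ``model='temperature_idn'`` requires ``tau >= 1``; ``model='symmetric'``
    requires ``0 <= eta < (C-1)/C`` (checked at application time against C).
    """

    model: str
    tau: float | None = None
    eta: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model == "temperature_idn":
            if self.tau is None:
                raise ValueError("temperature_idn requires tau")
            if self.tau < 1:
                raise ValueError("tau must be >= 1")
        elif self.model == "symmetric":
            if self.eta is None:
                raise ValueError("symmetric requires eta")
            if not 0 <= self.eta < 1:
                raise ValueError("eta must be in [0, 1)")
        else:
            raise ValueError(f"unknown noise model {self.model!r}")


@dataclass
class CXRCategoryRecord:
    """One chest-radiograph record for the benchmark construction.

    ``box_confidence`` grades the opacity bounding boxes of adjudicated
    positives; ``reader_delineated`` flags adjudicated negatives where some
    readers nonetheless delineated opacities.
    """

    id: int | str
    source_category: str
    adjudicated_positive: bool
    box_confidence: str = "none"
    reader_delineated: bool = False

    def __post_init__(self) -> None:
        if self.source_category not in CXR_CATEGORIES:
            raise ValueError(f"unknown category {self.source_category!r}")
        if self.box_confidence not in ("none", "low_only", "medium_or_high"):
            raise ValueError(f"unknown box confidence {self.box_confidence!r}")
        if self.box_confidence != "none" and not self.adjudicated_positive:
            raise ValueError("box confidence requires an adjudicated positive")
        if self.reader_delineated and self.adjudicated_positive:
            raise ValueError("reader_delineated applies to adjudicated negatives only")


@dataclass
class ConfusionMatrix:
    """C x C counts: entry (i, j) = samples with true class i, noisy label j."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1] or np.any(arr < 0):
            raise ValueError("confusion matrix must be square and non-negative")
        self.counts = arr.astype(np.int64)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def temperature_scale(dist, tau: float) -> np.ndarray:
    """Raise a distribution to the power ``1/tau`` and renormalise.

    ``tau = 1`` is the identity; ``tau -> inf`` tends to uniform over the
    support.  Zero entries stay zero, and the argmax is preserved for any
    finite temperature.
    """
    if tau < 1:
        raise ValueError("tau must be >= 1 (flattening only)")
    p = np.asarray(dist, dtype=float)
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("dist must be a probability vector")
    scaled = np.where(p > 0, p ** (1.0 / tau), 0.0)
    return scaled / scaled.sum()


def sample_initial_labels_idn(dataset: NoisyDataset, tau: float,
                              seed: int | np.random.Generator = 0) -> NoisyDataset:
    """Draw one initial label per sample from its temperature-scaled true dist.

    Returns a copy of the dataset whose counts are one-hot on the drawn label;
    reproducible for a fixed seed.
    """
    if dataset.true_dists is None:
        raise ValueError("instance-dependent noise requires true distributions")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    C = dataset.n_categories
    counts = np.zeros_like(dataset.counts)
    for i in range(len(dataset)):
        q = temperature_scale(dataset.true_dists[i], tau)
        counts[i, rng.choice(C, p=q)] = 1
    out = dataset.copy()
    out.counts = counts
    return out


def symmetric_noise_labels(true_classes, eta: float, C: int,
                           seed: int | np.random.Generator = 0) -> np.ndarray:
    """Flip each label with probability ``eta`` to a uniform other class.

    ``eta`` must stay below ``(C-1)/C`` so the expected class-confusion matrix
    remains diagonally dominant.
    """
    if not 0 <= eta < (C - 1) / C:
        raise ValueError(f"eta must be in [0, {(C - 1) / C:.4f}) for C={C}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    y = np.asarray(true_classes, dtype=np.int64)
    noisy = y.copy()
    flip = rng.random(y.size) < eta
    # uniform over the other C-1 classes: add a shift in [1, C-1] mod C
    shifts = rng.integers(1, C, size=y.size)
    noisy[flip] = (y[flip] + shifts[flip]) % C
    return noisy


def difficulty_class(dist, threshold: float = 0.3) -> tuple[str, float]:
    """Classify a label distribution as easy/difficult by normalised entropy.

    Normalised Shannon entropy ``-sum_c p_c log_C p_c`` lies in [0, 1]; a
    sample is *difficult* when it exceeds the threshold (default 0.3).
    Returns ``(label, value)``.
    """
    p = np.asarray(dist, dtype=float)
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("dist must be a probability vector")
    C = p.size
    if C < 2:
        raise ValueError("need at least two categories")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    value = float(-terms.sum() / math.log(C))
    return ("difficult" if value > threshold else "easy"), value


def confusion_matrix(dataset: NoisyDataset) -> ConfusionMatrix:
    """Cross-tabulate true classes against current majority labels.

    Tied majorities are resolved to the lowest-index argmax here so that the
    matrix total always equals N (elsewhere ties stay "undecided").
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    if dataset.true_classes is None:
        raise ValueError("ground truth unavailable")
    C = dataset.n_categories
    noisy = np.argmax(dataset.counts, axis=1)
    mat = np.zeros((C, C), dtype=np.int64)
    np.add.at(mat, (dataset.true_classes, noisy), 1)
    return ConfusionMatrix(mat)


def diagonal_dominant(matrix: ConfusionMatrix | np.ndarray) -> bool:
    """True iff, after row-normalising, mean(diagonal - max off-diagonal) > 0.

    Rows with no samples are skipped.  Dominance on average is the regime in
    which posterior-based cleaning outperforms random selection.
    """
    counts = matrix.counts if isinstance(matrix, ConfusionMatrix) else np.asarray(matrix)
    counts = counts.astype(float)
    totals = counts.sum(axis=1)
    keep = totals > 0
    if not np.any(keep):
        raise ValueError("confusion matrix has no samples")
    rows = counts[keep] / totals[keep, None]
    orig = np.flatnonzero(keep)  # original class index of each kept row
    diag = rows[np.arange(rows.shape[0]), orig]
    off = rows.copy()
    off[np.arange(rows.shape[0]), orig] = -np.inf
    margin = diag - off.max(axis=1)
    return bool(margin.mean() > 0)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def build_noisycxr_labels(records, flip_fraction: float = 0.1,
                          mode: str = "expected", seed: int = 0):
    """Map source categories to noisy binary labels and cross-tabulate.

    Pneumonia records become noisy positives; no-finding and other-disease
    records become noisy negatives; consolidation/infiltration records keep the
    adjudicated label for ``1 - flip_fraction`` of each adjudicated stratum and
    flip it for the rest.  In ``expected`` mode the flip count per stratum is
    ``round(flip_fraction * stratum size)`` applied to the first k ids in
    sorted order; in ``sampled`` mode a uniform random subset of that size is
    flipped.

    Returns ``(noisy, crosstab)`` where ``noisy`` maps record id -> bool and
    ``crosstab`` is the 2x2 array ``[[pos,pos], [pos,neg]; [neg,pos], [neg,neg]]``
    of (adjudicated, noisy) counts.
    """
    if mode not in ("expected", "sampled"):
        raise ValueError(f"unknown mode {mode!r}")
    records = list(records)
    noisy: dict = {}
    strata: dict[bool, list] = {True: [], False: []}
    for r in records:
        if not isinstance(r, CXRCategoryRecord):
            raise ValueError("records must be CXRCategoryRecord instances")
        if r.source_category == "pneumonia":
            noisy[r.id] = True
        elif r.source_category in ("no_finding", "other_disease_only"):
            noisy[r.id] = False
        else:  # consolidation_infiltration: flip a fraction per stratum
            strata[r.adjudicated_positive].append(r)

    rng = np.random.default_rng(seed)
    for adjudicated, group in strata.items():
        k = _round_half_away(flip_fraction * len(group))
        group = sorted(group, key=lambda r: str(r.id))
        if mode == "sampled":
            order = rng.permutation(len(group))
            flipped = {group[i].id for i in order[:k]}
        else:
            flipped = {r.id for r in group[:k]}
        for r in group:
            noisy[r.id] = (not adjudicated) if r.id in flipped else adjudicated

    crosstab = np.zeros((2, 2), dtype=np.int64)
    for r in records:
        i = 0 if r.adjudicated_positive else 1
        j = 0 if noisy[r.id] else 1
        crosstab[i, j] += 1
    return noisy, crosstab


def noisycxr_true_distribution(record: CXRCategoryRecord) -> float:
    """Probability of the positive class in the record's true label distribution.

    1.0 for confident positives (a medium/high-confidence box), 0.66 for
    positives with only low-confidence boxes (difficult), 0.33 for adjudicated
    negatives where some readers delineated opacities (ambiguous), 0.0 for
    clear negatives.
    """
    if record.adjudicated_positive:
        if record.box_confidence == "medium_or_high":
            return 1.0
        if record.box_confidence == "low_only":
            return 0.66
        raise ValueError("adjudicated positive requires a box confidence level")
    return 0.33 if record.reader_delineated else 0.0


def expected_crosstab(category_counts: dict, flip_fraction: float = 0.1):
    """Deterministic expected cross-tab of noisy vs adjudicated binary labels.

    ``category_counts`` maps each source category to
    ``(adjudicated_positive_count, adjudicated_negative_count)``; the flip
    count in each consolidation/infiltration stratum is rounded half away from
    zero.  Returns ``(crosstab, N, noise_rate)`` with noise_rate the
    off-diagonal fraction.
    """
    table = np.zeros((2, 2), dtype=np.int64)  # rows adjudicated +/-, cols noisy +/-
    for category, (pos, neg) in category_counts.items():
        if category not in CXR_CATEGORIES:
            raise ValueError(f"unknown category {category!r}")
        pos, neg = int(pos), int(neg)
        if pos < 0 or neg < 0:
            raise ValueError("counts must be non-negative")
        if category == "pneumonia":
            table[0, 0] += pos
            table[1, 0] += neg
        elif category in ("no_finding", "other_disease_only"):
            table[0, 1] += pos
            table[1, 1] += neg
        else:
            k_pos = _round_half_away(flip_fraction * pos)
            k_neg = _round_half_away(flip_fraction * neg)
            table[0, 0] += pos - k_pos
            table[0, 1] += k_pos
            table[1, 1] += neg - k_neg
            table[1, 0] += k_neg
    n = int(table.sum())
    if n == 0:
        return table, 0, 0.0
    noise_rate = float(table[0, 1] + table[1, 0]) / n
    return table, n, noise_rate
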