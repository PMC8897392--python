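"""Desk-scale synthetic datasets with analytic true label distributions.

Samples are drawn from an equal-prior mixture of isotropic unit-variance
Gaussians, one component per category, with means ``separation`` apart along
orthogonal axes.  Because the mixture is known, each sample's true label
distribution is the exact Bayes posterior at its feature vector — giving the
same per-sample ambiguity structure as crowd-sourced label histograms, but
with exact ground truth for testing scorers, oracles, and annotators.
``separation`` controls the difficult-sample fraction: large separations make
nearly all posteriors one-hot; separation 0 makes every sample maximally
ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import log_softmax

from .label_model import NoisyDataset
from .noise_benchmarks import (
    NoiseConfig,
    sample_initial_labels_idn,
    symmetric_noise_labels,
)

__all__ = [
    "MixtureSpec",
    "generate_mixture_dataset",
    "make_noisy_benchmark",
    "fixture_toy4",
]


@dataclass
class MixtureSpec:
    """Gaussian-mixture dataset parameters.

    ``separation`` is the distance between class means in units of the shared
    isotropic standard deviation; ``d`` must be at least ``C`` so the means
    can sit on orthogonal axes.
    """

    n: int
    C: int = 2
    d: int | None = None
    separation: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.C < 2:
            raise ValueError("need at least two categories")
        if self.n < self.C:
            raise ValueError("need at least C samples")
        if self.separation < 0:
            raise ValueError("separation must be non-negative")
        if self.d is None:
            self.d = self.C
        if self.d < self.C:
            raise ValueError("feature dimension must be >= C")


def generate_mixture_dataset(spec: MixtureSpec) -> NoisyDataset:
    """Sample the mixture and attach exact Bayes posteriors as true dists.

    Counts start at zero (no initial labels); pair with
    :func:`make_noisy_benchmark` to draw initial labels under a noise model.
    With equal priors and unit variance the posterior is
    ``softmax_k(mu_k . x - ||mu_k||^2 / 2)``.
    """
    rng = np.random.default_rng(spec.seed)
    means = np.zeros((spec.C, spec.d))
    means[np.arange(spec.C), np.arange(spec.C)] = spec.separation
    components = rng.integers(0, spec.C, size=spec.n)
    X = means[components] + rng.standard_normal((spec.n, spec.d))
    # exact mixture posterior at each x
    logits = X @ means.T - 0.5 * (means ** 2).sum(axis=1)
    true_dists = np.exp(log_softmax(logits, axis=1))
    true_dists /= true_dists.sum(axis=1, keepdims=True)
    return NoisyDataset(
        ids=list(range(spec.n)),
        counts=np.zeros((spec.n, spec.C), dtype=np.int64),
        true_dists=true_dists,
        features=X,
    )


def make_noisy_benchmark(dataset: NoisyDataset, noise: NoiseConfig) -> tuple[NoisyDataset, float]:
    """Give every sample one initial label under the configured noise model.

    Returns the noisy dataset and its achieved empirical noise rate (fraction
    of initial labels differing from the true class).
    """
    if dataset.true_dists is None:
        raise ValueError("benchmark construction requires true distributions")
    if noise.model == "temperature_idn":
        noisy = sample_initial_labels_idn(dataset, noise.tau, noise.seed)
    else:
        labels = symmetric_noise_labels(dataset.true_classes, noise.eta,
                                        dataset.n_categories, noise.seed)
        noisy = dataset.copy()
        noisy.counts = np.zeros_like(dataset.counts)
        noisy.counts[np.arange(len(dataset)), labels] = 1
    rate = float(np.mean(np.argmax(noisy.counts, axis=1) != noisy.true_classes))
    return noisy, rate


def fixture_toy4() -> NoisyDataset:
    """Deterministic 4-sample binary fixture used across the test suites.

    One-hot truths; samples 0 and 1 carry a correct single initial label,
    samples 2 and 3 a wrong one.  Initial accuracy is 0.5 and the minimal
    annotator needs exactly 2 annotations per mislabelled sample (tie, then
    majority), so the oracle budget to clean everything is 4.
    """
    true_classes = np.array([0, 1, 0, 1])
    initial = np.array([0, 1, 1, 0])
    counts = np.zeros((4, 2), dtype=np.int64)
    counts[np.arange(4), initial] = 1
    true_dists = np.eye(2)[true_classes]
    return NoisyDataset(ids=[0, 1, 2, 3], counts=counts,
                        true_dists=true_dists, true_classes=true_classes)
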