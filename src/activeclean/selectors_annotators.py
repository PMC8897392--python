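"""Sample-prioritisation strategies and simulated annotators.

Selectors rank the remaining pool for re-annotation:

* ``posterior`` — ranks by a score computed from model posteriors (the
  priority score phi, its cross-entropy term alone, or BALD).
* ``oracle`` — idealised upper bound: knows the truth, puts mislabelled
  samples first ordered from least to most ambiguous.
* ``random`` — uniform permutation, the naive baseline.

Annotators simulate the labelling workforce: the ``distribution`` annotator
draws each new label from the sample's true label distribution (realistic —
ambiguous samples attract conflicting labels); the ``minimal`` annotator
always returns the ground-truth class (an idealised lower bound on cost).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .label_model import NoisyDataset, is_relabelling_complete
from .noise_benchmarks import difficulty_class
from .scoring import rank_by_score, score_table

__all__ = [
    "SelectorSpec",
    "AnnotatorSpec",
    "posterior_rank",
    "oracle_rank",
    "random_rank",
    "distribution_annotate",
    "minimal_annotate",
    "expected_oracle_budget",
]


@dataclass
class SelectorSpec:
    """Which ranking strategy to use; ``scorer`` applies to kind='posterior'."""

    kind: str
    scorer: str | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("posterior", "oracle", "random"):
            raise ValueError(f"unknown selector kind {self.kind!r}")
        if self.kind == "posterior":
            if self.scorer not in ("phi", "ce_only", "bald"):
                raise ValueError("posterior selector needs scorer in {phi, ce_only, bald}")
        elif self.scorer is not None:
            raise ValueError("scorer only applies to the posterior selector")


@dataclass
class AnnotatorSpec:
    """Which simulated annotator to use."""

    kind: str
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("distribution", "minimal"):
            raise ValueError(f"unknown annotator kind {self.kind!r}")


def posterior_rank(pool, counts_by_id: dict, posterior_provider, scorer: str = "phi"):
    """Rank pool ids by a posterior-based score, highest priority first.

    ``posterior_provider(sample_id)`` must return either a simplex vector or,
    for ``scorer='bald'``, an M x C ensemble matrix.  Deterministic given the
    posteriors: ties break by ascending id.
    """
    pool = list(pool)
    if not pool:
        return []
    scores = []
    if scorer == "bald":
        from .scoring import bald_score

        for sid in pool:
            ens = np.atleast_2d(np.asarray(posterior_provider(sid), dtype=float))
            scores.append((sid, bald_score(ens)))
        return rank_by_score(scores)
    counts = np.stack([np.asarray(counts_by_id[sid]) for sid in pool])
    posts = []
    for sid in pool:
        p = np.asarray(posterior_provider(sid), dtype=float)
        posts.append(p.mean(axis=0) if p.ndim == 2 else p)  # marginalise ensembles
    table = score_table(counts, np.stack(posts))
    key = "phi" if scorer == "phi" else "ce"
    return rank_by_score(zip(pool, table[key]))


def oracle_rank(pool, dataset: NoisyDataset):
    """Ideal ranking: mislabelled samples first, least ambiguous first.

    Mislabelled means the current majority label (undecided counting as wrong)
    differs from the true class; among mislabelled samples, ascending
    normalised entropy of the true distribution, ties by id.  Correctly
    labelled samples follow in ascending id order.
    """
    if dataset.true_dists is None:
        raise ValueError("oracle requires true distributions")
    pool = list(pool)
    majorities = dataset.majority_labels()
    noisy, clean = [], []
    for sid in pool:
        i = dataset.index_of(sid)
        if majorities[i] != dataset.true_classes[i]:
            _, ent = difficulty_class(dataset.true_dists[i])
            noisy.append((ent, sid))
        else:
            clean.append(sid)
    noisy.sort(key=lambda t: (t[0], t[1]))
    clean.sort()
    return [sid for _, sid in noisy] + clean


def random_rank(pool, seed: int | np.random.Generator = 0):
    """Uniform random permutation of the pool, reproducible per seed."""
    pool = list(pool)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return [pool[i] for i in rng.permutation(len(pool))]


def distribution_annotate(sample, rng: np.random.Generator) -> int:
    """Draw one label from the sample's true label distribution."""
    dist = getattr(sample, "true_dist", None)
    if dist is None:
        raise ValueError("distribution annotator requires true_dist")
    dist = np.asarray(dist, dtype=float)
    return int(rng.choice(dist.size, p=dist / dist.sum()))


def minimal_annotate(sample) -> int:
    """Return the ground-truth class deterministically (idealised annotator)."""
    true_class = getattr(sample, "true_class", None)
    if true_class is None:
        raise ValueError("minimal annotator requires true_class")
    return int(true_class)


def expected_oracle_budget(dataset: NoisyDataset, annotator_kind: str = "minimal",
                           n_mc: int = 1000, seed: int = 0) -> float:
    """Expected annotations for the oracle to clean every mislabelled sample.

    With the minimal annotator each mislabelled single-label sample costs
    exactly 2 annotations (the first ties the vote, the second forms the
    majority), giving the closed form ``2 * n_mislabelled``.  With the
    distribution annotator the cost is random and is estimated by Monte Carlo:
    draws from the true distribution are added until a strict majority forms.
    """
    if dataset.true_classes is None:
        raise ValueError("ground truth unavailable")
    if n_mc < 1:
        raise ValueError("n_mc must be >= 1")
    majorities = dataset.majority_labels()
    mislabelled = np.flatnonzero(majorities != dataset.true_classes)
    if annotator_kind == "minimal":
        return float(2 * mislabelled.size)
    if annotator_kind != "distribution":
        raise ValueError(f"unknown annotator kind {annotator_kind!r}")
    if dataset.true_dists is None:
        raise ValueError("distribution annotator requires true distributions")
    rng = np.random.default_rng(seed)
    total = 0.0
    for i in mislabelled:
        dist = dataset.true_dists[i]
        base = dataset.counts[i]
        for _ in range(n_mc):
            counts = base.copy()
            draws = 0
            while not is_relabelling_complete(counts):
                counts[rng.choice(dist.size, p=dist)] += 1
                draws += 1
            total += draws
    return total / n_mc
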