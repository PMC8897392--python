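"""Relabelling priority scores.

The priority score ranks samples for re-annotation by combining two terms
computed from a classifier's predicted posterior p(y|x):

* **noisiness** — the cross-entropy from the sample's normalised label counts
  to the posterior.  Large when the collected labels disagree with what the
  model believes, i.e. the label looks wrong.
* **ambiguity** — the entropy of the posterior itself.  Large for samples the
  model finds intrinsically hard, which will need many annotations to reach a
  majority.

The priority is ``phi = noisiness - ambiguity``: clearly mislabelled samples
come first, ambiguous ones are deprioritised, and confidently correct samples
fall to the bottom.  All logarithms are natural; the ranking is invariant to
the base since both terms scale together.

The BALD acquisition baseline (mutual information between a sample's label and
the model parameters, estimated from an ensemble of posteriors) is provided
for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .label_model import LabelCounts

__all__ = [
    "DEFAULT_EPS",
    "PosteriorVector",
    "PosteriorEnsemble",
    "noisiness_ce",
    "ambiguity_entropy",
    "phi_score",
    "marginal_posterior",
    "bald_score",
    "rank_by_score",
    "score_table",
]

DEFAULT_EPS = 1e-12

_SCORER_MODES = ("phi", "ce_only", "bald")


def _as_simplex(probs, atol: float = 1e-9) -> np.ndarray:
    arr = np.asarray(probs, dtype=float)
    if arr.ndim != 1:
        raise ValueError("posterior must be a 1-D vector")
    if np.any(arr < -atol):
        raise ValueError("posterior entries must be non-negative")
    if abs(float(arr.sum()) - 1.0) > atol:
        raise ValueError("posterior must sum to 1")
    return np.clip(arr, 0.0, None)


@dataclass
class PosteriorVector:
    """Predicted class probabilities for one sample (a point on the simplex)."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = _as_simplex(self.probs)


@dataclass
class PosteriorEnsemble:
    """M x C row-stochastic matrix: one posterior per ensemble member."""

    members: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.members, dtype=float)
        if arr.ndim != 2 or arr.shape[0] < 1:
            raise ValueError("ensemble must be a non-empty M x C matrix")
        for row in arr:
            _as_simplex(row)
        self.members = np.clip(arr, 0.0, None)


def _probs(posterior) -> np.ndarray:
    if isinstance(posterior, PosteriorVector):
        return posterior.probs
    return _as_simplex(posterior)


def _counts_vec(counts) -> np.ndarray:
    arr = counts.counts if isinstance(counts, LabelCounts) else np.asarray(counts)
    if arr.sum() < 1:
        raise ValueError("counts total must be at least 1")
    return arr.astype(float)


def noisiness_ce(counts, posterior, eps: float = DEFAULT_EPS) -> float:
    """Cross-entropy from normalised label counts to the posterior (nats).

    ``-sum_c (l_c / ||l||_1) * log max(p_c, eps)``.  Zero when a one-hot
    posterior agrees with a one-hot label; grows as the collected labels land
    where the model puts little mass.
    """
    l = _counts_vec(counts)
    p = _probs(posterior)
    if l.size != p.size:
        raise ValueError("counts and posterior must have equal length")
    q = l / l.sum()
    return float(-(q * np.log(np.maximum(p, eps))).sum())


def ambiguity_entropy(posterior, eps: float = DEFAULT_EPS) -> float:
    """Shannon entropy of the posterior in nats, in ``[0, ln C]``.

    ``0 * log 0`` contributes zero, so one-hot posteriors score exactly 0.
    """
    p = _probs(posterior)
    logp = np.log(np.maximum(p, eps))
    return float(-(np.where(p > 0, p * logp, 0.0)).sum())


def phi_score(counts, posterior, eps: float = DEFAULT_EPS) -> float:
    """Relabelling priority: noisiness minus ambiguity.

    Vanishes identically when the posterior equals the normalised counts,
    since the cross-entropy of a distribution with itself is its entropy.
    """
    return noisiness_ce(counts, posterior, eps) - ambiguity_entropy(posterior, eps)


def marginal_posterior(ensemble: PosteriorEnsemble | np.ndarray) -> PosteriorVector:
    """Posterior marginalised over ensemble members (column-wise mean)."""
    members = ensemble.members if isinstance(ensemble, PosteriorEnsemble) \
        else PosteriorEnsemble(ensemble).members
    return PosteriorVector(members.mean(axis=0))


def bald_score(ensemble: PosteriorEnsemble | np.ndarray, eps: float = DEFAULT_EPS) -> float:
    """Mutual information between a sample's label and the model parameters.

    Entropy of the marginal posterior minus the mean member entropy; zero when
    all members agree, positive under disagreement.  Clipped at 0 from below
    against floating-point cancellation.
    """
    if not isinstance(ensemble, PosteriorEnsemble):
        ensemble = PosteriorEnsemble(ensemble)
    marginal_h = ambiguity_entropy(marginal_posterior(ensemble), eps)
    member_h = float(np.mean([ambiguity_entropy(row, eps) for row in ensemble.members]))
    return max(0.0, marginal_h - member_h)


def rank_by_score(scores) -> list:
    """Sort (id, score) pairs by score descending; ties broken by ascending id.

    Raises on NaN scores — a NaN has no place in a priority queue.
    """
    scores = list(scores)
    for sid, s in scores:
        if np.isnan(s):
            raise ValueError(f"NaN score for sample {sid!r}")
    return [sid for sid, _ in sorted(scores, key=lambda kv: (-kv[1], kv[0]))]


def score_table(counts_matrix: np.ndarray, posteriors: np.ndarray,
                ensembles: np.ndarray | None = None,
                eps: float = DEFAULT_EPS) -> dict:
    """Vectorised per-sample scores for an N x C counts matrix and posteriors.

    Returns a dict of arrays: ``ce``, ``entropy``, ``phi`` and, when an
    M x N x C ensemble stack is supplied, ``bald``.
    """
    counts = np.asarray(counts_matrix, dtype=float)
    p = np.asarray(posteriors, dtype=float)
    if counts.shape != p.shape:
        raise ValueError("counts and posteriors must be N x C with equal shapes")
    totals = counts.sum(axis=1, keepdims=True)
    if np.any(totals < 1):
        raise ValueError("every sample needs at least one label")
    q = counts / totals
    logp = np.log(np.maximum(p, eps))
    ce = -(q * logp).sum(axis=1)
    ent = -np.where(p > 0, p * logp, 0.0).sum(axis=1)
    out = {"ce": ce, "entropy": ent, "phi": ce - ent}
    if ensembles is not None:
        ens = np.asarray(ensembles, dtype=float)  # M x N x C
        marg = ens.mean(axis=0)
        logm = np.log(np.maximum(marg, eps))
        h_marg = -np.where(marg > 0, marg * logm, 0.0).sum(axis=1)
        loge = np.log(np.maximum(ens, eps))
        h_mem = -np.where(ens > 0, ens * loge, 0.0).sum(axis=2).mean(axis=0)
        out["bald"] = np.maximum(0.0, h_marg - h_mem)
    return out
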