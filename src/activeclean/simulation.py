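"""Sequential relabelling engine, trajectory recording, and AUC summaries.

The cleaning loop: rank the remaining pool, take the highest-priority
sample(s), collect annotations for each one at a time — every annotation
costs one unit of the budget — until a strict majority forms among all its
collected labels, then remove it from the pool and re-rank.  The selector
model can optionally be fine-tuned on the corrected labels at a configurable
cadence.  The loop ends when the budget is spent or the pool is empty.

Progress is recorded as a trajectory of (annotations consumed, dataset label
accuracy) points, one per annotation, summarised by the area under the
accuracy-vs-budget-fraction curve: a cost-efficient selector corrects many
labels early, pushing the curve (and its AUC) up.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .label_model import (
    AnnotationLedger,
    NoisyDataset,
    is_relabelling_complete,
)
from .selectors_annotators import (
    AnnotatorSpec,
    SelectorSpec,
    distribution_annotate,
    minimal_annotate,
    oracle_rank,
    posterior_rank,
    random_rank,
)

__all__ = [
    "SimulationConfig",
    "Trajectory",
    "CleaningResult",
    "run_cleaning",
    "cleaning_auc",
    "replicate_runs",
    "annotations_to_reach",
    "NOT_REACHED",
]

NOT_REACHED = "not reached"


@dataclass
class SimulationConfig:
    """Budget and loop cadence for one cleaning run.

    ``batch_size`` samples are fully relabelled per ranking iteration;
    ``update_every`` is the number of completed samples between selector
    fine-tunes (0 disables model updates).
    """

    budget: int
    batch_size: int = 1
    update_every: int = 0
    n_seeds: int = 5
    seed: int = 0
    finetune_epochs: int = 100

    def __post_init__(self) -> None:
        if self.budget < 0:
            raise ValueError("budget must be non-negative")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.n_seeds < 1:
            raise ValueError("n_seeds must be >= 1")


@dataclass
class Trajectory:
    """Per-annotation progress curve; the first point is the initial state."""

    annotations: np.ndarray
    accuracy: np.ndarray

    def __post_init__(self) -> None:
        self.annotations = np.asarray(self.annotations, dtype=np.int64)
        self.accuracy = np.asarray(self.accuracy, dtype=float)
        if self.annotations.size == 0 or self.annotations[0] != 0:
            raise ValueError("trajectory must start at 0 annotations")
        if np.any(np.diff(self.annotations) <= 0):
            raise ValueError("annotations_consumed must be strictly increasing")

    @property
    def noise_rate(self) -> np.ndarray:
        return 1.0 - self.accuracy


@dataclass
class CleaningResult:
    """Outcome of one cleaning run: final dataset, trajectory, AUC, ledger."""

    dataset: NoisyDataset
    trajectory: Trajectory
    auc: float
    ledger: AnnotationLedger
    config: SimulationConfig = None
    finetune_events: list = field(default_factory=list)

    @property
    def final_accuracy(self) -> float:
        return float(self.trajectory.accuracy[-1])

    @property
    def consumed(self) -> int:
        return self.ledger.consumed


def _make_selector(spec: SelectorSpec, dataset: NoisyDataset, posterior_provider,
                   rng: np.random.Generator):
    if spec.kind == "oracle":
        return lambda pool: oracle_rank(pool, dataset)
    if spec.kind == "random":
        perm_rng = np.random.default_rng(spec.seed) if spec.seed is not None else rng
        return lambda pool: random_rank(pool, perm_rng)
    if posterior_provider is None:
        raise ValueError("posterior selector requires a posterior provider")

    def select(pool):
        counts_by_id = {sid: dataset.counts[dataset.index_of(sid)] for sid in pool}
        return posterior_rank(pool, counts_by_id, posterior_provider, spec.scorer)

    return select


def _make_annotator(spec: AnnotatorSpec, dataset: NoisyDataset, rng: np.random.Generator):
    if spec.kind == "minimal":
        return lambda i: minimal_annotate(dataset.sample(i))
    ann_rng = np.random.default_rng(spec.seed) if spec.seed is not None else rng
    return lambda i: distribution_annotate(dataset.sample(i), ann_rng)


def run_cleaning(dataset: NoisyDataset, selector: SelectorSpec,
                 annotator: AnnotatorSpec, config: SimulationConfig,
                 posterior_provider=None, finetune_hook=None) -> CleaningResult:
    """Run the sequential relabelling loop on a copy of the dataset.

    ``posterior_provider(sample_id)`` supplies posteriors for the posterior
    selector; ``finetune_hook(dataset)`` is called every ``update_every``
    completed samples and may return a new posterior provider (model update).
    Counts are only ever incremented; if the budget runs out mid-sample the
    annotations already drawn remain (they were paid for) and the sample may
    end without a new majority.  Returns the result with a per-annotation
    trajectory and its AUC.
    """
    if dataset.true_classes is None:
        raise ValueError("simulation requires ground truth for evaluation")
    data = dataset.copy()
    rng = np.random.default_rng(config.seed)
    ledger = AnnotationLedger(budget=config.budget)
    annotate = _make_annotator(annotator, data, rng)

    majorities = data.majority_labels()
    n = len(data)
    correct = int(np.sum(majorities == data.true_classes))
    annotations = [0]
    accuracy = [correct / n]

    pool = {data.ids[i] for i in range(n) if not is_relabelling_complete(data.counts[i])}
    finetune_events: list[int] = []
    completed_since_update = 0

    # Re-ranking between model updates is a no-op: samples leave the pool the
    # moment their counts change (completion), so the relative order of the
    # untouched remainder is invariant.  Rank once, walk the order, and rebuild
    # it only after a fine-tune refreshes the posteriors.
    select = _make_selector(selector, data, posterior_provider, rng)
    order = [sid for sid in select(sorted(pool, key=str)) if sid in pool]
    cursor = 0

    while pool and ledger.remaining > 0 and cursor < len(order):
        batch, taken = [], 0
        while cursor < len(order) and taken < config.batch_size:
            sid = order[cursor]
            cursor += 1
            if sid in pool:
                batch.append(sid)
                taken += 1
        for sid in batch:
            i = data.index_of(sid)
            while not is_relabelling_complete(data.counts[i]) and ledger.remaining > 0:
                category = annotate(i)
                ledger.record(sid, category)
                data.counts[i, category] += 1
                # incremental accuracy update
                row = data.counts[i]
                top = int(np.argmax(row))
                new_maj = top if np.sum(row == row[top]) == 1 else -1
                was_correct = majorities[i] == data.true_classes[i]
                now_correct = new_maj == data.true_classes[i]
                majorities[i] = new_maj
                correct += int(now_correct) - int(was_correct)
                annotations.append(ledger.consumed)
                accuracy.append(correct / n)
            if is_relabelling_complete(data.counts[i]):
                pool.discard(sid)
                completed_since_update += 1
            if ledger.remaining == 0:
                break
        if (config.update_every > 0 and finetune_hook is not None
                and completed_since_update >= config.update_every):
            new_provider = finetune_hook(data)
            if new_provider is not None:
                posterior_provider = new_provider
            finetune_events.append(ledger.consumed)
            completed_since_update = 0
            select = _make_selector(selector, data, posterior_provider, rng)
            order = [sid for sid in select(sorted(pool, key=str)) if sid in pool]
            cursor = 0

    trajectory = Trajectory(np.array(annotations), np.array(accuracy))
    auc = cleaning_auc(trajectory, config.budget) if config.budget > 0 else float("nan")
    return CleaningResult(data, trajectory, auc, ledger, config, finetune_events)


def cleaning_auc(trajectory, budget: int) -> float:
    """Trapezoidal area of accuracy against the fraction of budget consumed.

    The curve is evaluated on ``[0, 1]`` with the last accuracy extended to
    the full budget; a constant-accuracy trajectory therefore has AUC equal to
    that accuracy.
    """
    if budget <= 0:
        raise ValueError("budget must be positive")
    if isinstance(trajectory, Trajectory):
        x, y = trajectory.annotations, trajectory.accuracy
    else:
        pts = np.asarray(trajectory, dtype=float)
        x, y = pts[:, 0], pts[:, 1]
    if x.size == 0:
        raise ValueError("trajectory is empty")
    x = np.asarray(x, dtype=float) / budget
    y = np.asarray(y, dtype=float)
    if x[-1] < 1.0:
        x = np.append(x, 1.0)
        y = np.append(y, y[-1])
    return float(np.trapezoid(y, x))


def annotations_to_reach(trajectory: Trajectory, target_accuracy: float):
    """Smallest annotation count at which accuracy reaches the target.

    Returns :data:`NOT_REACHED` when the trajectory never gets there.
    """
    hits = np.flatnonzero(trajectory.accuracy >= target_accuracy)
    if hits.size == 0:
        return NOT_REACHED
    return int(trajectory.annotations[hits[0]])


def replicate_runs(dataset: NoisyDataset, selector: SelectorSpec,
                   annotator: AnnotatorSpec, config: SimulationConfig,
                   posterior_provider=None):
    """Repeat the cleaning run over ``n_seeds`` independent seeds.

    Replicates differ only in the selection/annotation random streams.  The
    per-replicate trajectories are aggregated pointwise on the common grid
    ``0..budget`` (step interpolation, last value extended), returning
    ``(results, mean_curve, sd_curve)``.
    """
    seeds = np.random.SeedSequence(config.seed).generate_state(config.n_seeds) % (2 ** 31)
    results = []
    grid = np.arange(config.budget + 1)
    curves = np.empty((config.n_seeds, grid.size))
    for r, s in enumerate(seeds):
        sel = SelectorSpec(selector.kind, selector.scorer,
                           None if selector.seed is None else int(s))
        ann = AnnotatorSpec(annotator.kind, None if annotator.seed is None else int(s) + 1)
        cfg = SimulationConfig(config.budget, config.batch_size, config.update_every,
                               1, int(s), config.finetune_epochs)
        if selector.kind == "random":
            sel = SelectorSpec("random", None, int(s))
        if annotator.kind == "distribution":
            ann = AnnotatorSpec("distribution", int(s) + 1)
        res = run_cleaning(dataset, sel, ann, cfg, posterior_provider)
        results.append(res)
        idx = np.searchsorted(res.trajectory.annotations, grid, side="right") - 1
        curves[r] = res.trajectory.accuracy[np.clip(idx, 0, None)]
    return results, curves.mean(axis=0), curves.std(axis=0)
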