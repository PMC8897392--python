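# Methods

## Problem setting

A dataset of `N` samples over `C` mutually exclusive categories carries, per
sample, a vector of annotation counts `l̂ᵢ ∈ ℕᶜ` with at least one initial
label. The majority label is the category with the strictly largest count;
when the maximum is tied the vote is *undecided*. Cleaning aims to maximise
the fraction of samples whose majority label equals the true class `yᵢ` under
the budget constraint `Σᵢ ‖l̂ᵢ‖₁ ≤ B`, where every individual annotation costs
one unit.

Two conventions are fixed here because the strict-majority formulation leaves
them open:

* an undecided (tied) majority counts as **incorrect** in the accuracy metric
  and as **not complete** for the relabelling stopping rule;
* the true class of a sample with a non-degenerate true label distribution is
  the argmax of that distribution, lowest index on ties.

## Priority score

Samples are ranked by `Φ = CE(l̂, p_θ) − H(p_θ)`, cross-entropy of the
normalised counts under the model posterior minus the posterior's own entropy.
Natural logarithms are used throughout; rankings are invariant to the base
because both terms scale together. Posteriors are clipped at `eps = 1e-12`
before any logarithm so that one-hot posteriors cannot produce infinities.
When an ensemble of posteriors is available it is averaged (column-wise mean)
before scoring; the BALD baseline — entropy of the ensemble mean minus mean
member entropy — always requires the ensemble and is clipped at zero from
below against floating-point cancellation. A `ce_only` scorer mode drops the
entropy term, which is useful on binary tasks where ambiguity contributes
little to the ranking. Score ties are broken by ascending sample id so every
ranking is deterministic.

One analytic subtlety: for a one-hot labelled sample with posterior mass `q`
on the labelled class, `Φ(q) = −ln q − H(q)` is *not* globally monotone in
`q`. Its derivative `−1/q + ln(q/(1−q))` changes sign near `q ≈ 0.78` (binary
case), so Φ decreases from large positive values, dips below zero, and climbs
back to zero as `q → 1`. What matters for cleaning — and what the tests
assert — is that Φ is strictly decreasing over the disagreement regime and is
never positive once the model agrees with the label (`q ≥ 1/2`), so
disagreeing samples always outrank agreeing ones.

## Relabelling simulation

The engine loops: rank the remaining pool; take the top `batch_size` samples
(default 1); for each, draw annotations one at a time — each charged to the
ledger — until one category strictly exceeds every other with total count
above 1; remove completed samples; optionally fine-tune the selector model;
repeat until the budget is spent or the pool is empty. Counts are only ever
incremented. If the budget runs out mid-sample the drawn annotations remain
(they were paid for) and the sample may end without a new majority.

Because a sample's counts change only while it is being annotated, and it
leaves the pool the moment it completes, re-ranking between model updates
cannot reorder the untouched remainder. The implementation therefore ranks
once and walks the order, rebuilding it only after a fine-tune refreshes the
posteriors — an exact optimisation, not an approximation. The fine-tuning
hook defaults to off (`update_every = 0`), matching the main simulation
protocol; the loop structure itself is reconstructed from the prose
description of the procedure rather than a printed listing.

Annotators: the **distribution** annotator draws each new label from the
sample's true label distribution, so ambiguous samples genuinely consume more
annotations and can even settle on a wrong majority; the **minimal** annotator
returns the true class deterministically, giving a lower bound on cost (and
monotone non-decreasing accuracy, which the tests verify on every replicate).
The oracle selector orders mislabelled samples by ascending normalised entropy
of their true distribution (least ambiguous first), then correct samples by
ascending id — the interleaving of correct samples once noisy ones are
exhausted is a choice, as only the noisy-first/easiest-first rule is
prescribed.

Progress is recorded per annotation and summarised by the trapezoidal area
under accuracy versus fraction-of-budget on `[0, 1]`, with the final accuracy
extended to the right edge; a constant trajectory has AUC equal to its
accuracy. Replicate runs (default 5 seeds) differ only in the
selection/annotation random streams and are aggregated pointwise on the
`0..B` grid by step interpolation.

For the oracle's expected budget: with the minimal annotator a mislabelled
single-label sample costs exactly 2 annotations (one draw ties the vote, the
second forms the majority), giving the closed form `2 × n_mislabelled`; with
the distribution annotator the cost is random and is estimated by Monte Carlo
(default 1000 runs per sample), validated in tests against an exact
Markov-chain expectation over count states.

## Noise constructions

**Temperature-scaled instance-dependent noise.** Each sample's initial label
is drawn from `p^{1/τ} / Σ p^{1/τ}` applied to its true label distribution.
The scaling acts directly on the distribution (rather than on logits) because
that satisfies both required limits — identity at `τ = 1`, uniform over the
support as `τ → ∞` — while preserving the argmax and support for any finite
temperature, and keeping the statistical dependence between input and label.

**Symmetric noise.** Each label is independently flipped with probability `η`
to a uniform draw over the other `C − 1` classes; `η < (C−1)/C` is enforced so
the expected class-confusion matrix stays diagonally dominant (the regime in
which data-driven cleaning beats random selection). Dominance is diagnosed as
a positive mean, over row-normalised confusion rows, of the diagonal entry
minus the largest off-diagonal entry.

**Difficulty.** A sample is *difficult* when the normalised Shannon entropy
of its label distribution, `−Σ p_c log_C p_c ∈ [0, 1]`, exceeds 0.3. Note the
base-`C` logarithm here is a different quantity from the natural-log entropy
inside Φ; the two are deliberately kept separate.

**Chest-radiograph (NoisyCXR-style) construction.** Records fall into four
source categories. Pneumonia records always become noisy positives;
no-finding and other-disease records always become noisy negatives;
consolidation/infiltration records keep their adjudicated binary label for
90% of each adjudicated stratum and have it flipped for 10%. In *expected*
mode the flip count per stratum is `round(0.1 × stratum)` with half rounded
away from zero — applied to the first k ids in sorted order — which
reproduces the published cross-tab exactly (0.1 × 3,988 → 399; 0.1 × 8,551 →
855; cells 3956 / 1296 / 2056 / 19,376 of 26,684, noise rate 12.56% → 12.6%);
*sampled* mode flips a uniform random subset of the same size. Whether the
original construction flipped a rounded count per stratum or sampled
Bernoulli(0.1) per record is not documented; expected mode is the default
because it reproduces the printed table deterministically. (A 12.7% figure
also circulates for this benchmark's noise rate; the category-count arithmetic
gives 12.6%, which is what this package reports.) True label distributions for
relabel sampling are graded by bounding-box confidence: positive with a
medium/high-confidence box → 1.0; positive with only low-confidence boxes →
0.66; negative but reader-delineated → 0.33; otherwise 0.0.

## Selector models

The selector contract is only `fit` / `predict_posterior` with rows on the
simplex, so backends are softmax-regression models on feature vectors or
precomputed embeddings — deep image encoders are deliberately out of scope,
as the cleaning algorithm is agnostic to where the posteriors come from.
Three trainings are provided:

* **vanilla** — full-batch L-BFGS on the NLL of the (noisy) majority labels,
  with an L2 penalty (`l2 = 1`) for a unique optimum; an optional Gaussian
  feature jitter stands in for image augmentation.
* **co-teaching** — two peers with different seeds; each SGD step (default
  300 steps, batch 64, learning rate 0.5), each peer updates only on the
  `ceil((1−R)·batch)` smallest-loss samples selected by the *other* peer,
  with `R(t) = η̂ · min(t/T_k, 1)` ramping to the assumed noise rate over
  `T_k = 50` steps (the standard linear ramp; the original schedule is cited
  but not restated in the source description). Predictions are the ensemble
  mean of both peers.
* **SSL-linear** — a linear head on fixed embeddings with logits squashed by
  `γ(x) = α·tanh(x/α)` and cross-entropy against label-smoothed targets
  (`(1−ε)` on the label, `ε/(C−1)` elsewhere). Defaults `α = 10`, `ε = 0.1`:
  the squash constant is large enough not to distort well-calibrated logits
  while still bounding the maximum expressible confidence at
  `softmax(α, −α, …)`, and 0.1 is the conventional smoothing mass. With
  `ε = 0` and `α → ∞` the fit reduces to plain multinomial logistic
  regression, which the tests verify against an independent reference
  implementation to 1e-3 in posterior error.

All fits are deterministic given their seeds.

## Synthetic data

The generator draws `n` samples from an equal-prior mixture of isotropic
unit-variance Gaussians with means `separation · e_k` (requiring feature
dimension ≥ C), and sets each sample's true label distribution to the *exact*
Bayes posterior at its feature vector, `softmax_k(μ_k·x − ‖μ_k‖²/2)`. This
emulates the role of crowd-sourced per-sample label histograms — per-sample
ambiguity that annotator draws are sampled from — while providing exact
ground truth for scorer and oracle tests; what it does not emulate is image
content, annotator identity or correlated annotator error, so passing tests
demonstrate the correctness and relative efficiency of the cleaning machinery,
not absolute performance on real images. `separation ≈ 6` makes essentially
all posteriors one-hot (clean-label regime for symmetric-noise experiments);
`separation ≈ 1.5–2` puts a substantial fraction of samples above the
0.3-normalised-entropy difficulty threshold for ambiguity experiments.

The deterministic 4-sample binary fixture (two correct, two mislabelled,
one-hot truths) is small enough that every cleaning outcome can be enumerated
by hand, and is used as an exact oracle across the test suites.

## Evaluation protocol and problem sizes

The headline synthetic comparison runs `n = 2000`, `C = 5`, symmetric
`η = 0.15`, separation 6, a vanilla selector, the distribution annotator, and
5 relabelling seeds — large enough for stable AUC ordering (oracle ≥ Φ ≥
random within two pooled standard deviations) yet runs in seconds. The budget
is set to `2N` so that even the random baseline can reach the comparison
target of 90% of correctable noise; with the tighter oracle-expected budget
the random baseline never gets there and the efficiency ratio would be
undefined. On this benchmark the Φ-selector reaches the target with roughly a
quarter of the annotations random selection needs.

## Known limitations

* Backends are linear in the features; separating noisiness from ambiguity on
  data that is not linearly separable requires supplying better features or
  embeddings.
* The annotator model assumes i.i.d. draws from a stationary per-sample label
  distribution — no annotator identity, expertise, or drift.
* Multi-label (non-mutually-exclusive) targets are out of scope; the data
  model is strictly categorical.
* The real-data constructions are exercised on published summary counts and
  synthetic records; DICOM/image ingestion and bounding-box geometry are not
  modelled, only the confidence level and delineation flag.
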