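# Methods

## The prediction task

For one kinase, every curated phosphosite in the input becomes a sample:
sites annotated to that kinase are positives, all other sites are
negatives. Kinases with fewer than 25 positives are rejected
(`min_positives`, configurable) because per-kinase models trained on a
handful of examples are not reliable. The model is binary per kinase; a
multi-kinase screen is a loop over per-kinase models.

## Feature views

**Sequence view.** The window is the site ±`flank` residues
(default 7, window length 15). Positions beyond the protein termini and
non-standard residues map to a shared catch-all symbol `X`; the alphabet
is the 20 standard amino acids in alphabetical order followed by `X`
(21 symbols). One-hot encoding gives a 315-dimensional binary vector
with exactly 15 ones. The encoding is injective, and the squared
Euclidean distance between two encoded windows is twice their Hamming
distance — this is what the RBF kernel sees.

**Functional view.** A substrate's vector over the sorted PPI partner
universe: 1 where an interaction exists (default), or STRING
score/1000 in the opt-in `score` mode. Binary is the default because
the method uses interaction *presence*; score weighting is exposed for
sensitivity analyses. All sites of one substrate share one functional
row, so this view can at best separate substrates, not sites — an
intrinsic ceiling discussed under limitations.

## Kernels and their combination

Each view produces one RBF kernel per `β ∈ {1,…,5}`, with the exponent
scaled by the view's feature count `|F|` so that a 315-dimensional
binary view and a several-thousand-dimensional PPI view live on
comparable exponent scales. Kernel order is frozen (view-major,
β-minor) so weight vectors are comparable across runs. Squared
distances come from the Gram-expansion identity with tiny negatives
clamped to zero.

Trace normalization (`K / tr K`; for a raw RBF kernel this is `K / n`)
puts the kernels on a common scale. EasyMKL then solves a single convex
QP on the *average* normalized kernel `K^A` over the product of the two
class simplices; the per-kernel weights are the quadratic forms
`η_r = γ*ᵀ Y K̃_r Y γ*`, which are nonnegative whenever the kernels are
PSD. No iterative outer maximization over η is needed — the optimum of
the max–min problem is attained by this single pass, which is the point
of the algorithm.

Two conventions worth making explicit:

* The objective is `(1−λ)·γᵀYK^AYγ + λ‖γ‖²`. Some write-ups omit the
  `(1−λ)` factor; it only rescales the margin term and leaves the
  λ ∈ {0, 1} limits unchanged (λ=0: pure convex-hull separation,
  λ=1: uniform per-class distribution).
* The combined kernel uses the **raw** η on the trace-normalized base
  kernels. The unit-sum normalized η is reported alongside, since both
  conventions appear in practice and either reproduces the same
  ranking; the raw choice follows the weight formula as written.

A practical consequence of raw η on trace-normalized kernels is that
the combined kernel has small magnitude, so SVM decision values cluster
near the bias (±1 at most support vectors). Rankings — and therefore
ROC, AUC, top-k — are unaffected; operating thresholds should be taken
from the fixed-specificity analysis, not assumed to be 0.

## Solving the quadratic program

The QP is smooth and strongly convex for λ > 0, over a product of two
simplices. It is solved with accelerated projected gradient (FISTA) at
the fixed step 1/L, where L = 2((1−λ)·λ_max(YK^AY) + λ), using exact
Euclidean projection onto each class simplex. Iteration stops when the
largest coordinate change falls below 1e-8 (the step bound implies a
matching objective accuracy); entries below 1e-12 are snapped to zero
and the per-class sums renormalized to exactly 1. The solver is checked
in the test suite against an exhaustive 1e-3-resolution grid search on
4-sample problems and against the λ=1 closed form (uniform per-class
distribution).

## SVM

The soft-margin dual on the precomputed combined kernel is solved by
scikit-learn's `SVC(kernel="precomputed")`; the contract is the
KKT-verified dual solution (box constraint |α_i| ≤ C, zero signed sum,
free support vectors at decision value ±1·10⁻³-tight), which the tests
assert. Default `C = 1.0`: the evaluation protocol is threshold-based,
so ranking matters more than margin calibration, and no class weighting
is applied — class imbalance is handled downstream by the
fixed-specificity operating points and MCC. Prediction on new sites
encodes windows with the training alphabet/flank and projects
functional vectors onto the training partner universe (unseen partners
are ignored; substrates absent from the network get the zero vector).

## Evaluation protocol

* Stratified k-fold CV (default k = 10) with a caller-supplied seed;
  per fold, kernels are built from training rows only and test rows are
  scored through cross-kernels, so test labels cannot leak into their
  own scores (asserted by a label-flipping test).
* Out-of-fold scores are pooled before ROC/threshold analyses
  (per-fold records are retained for audit).
* Metrics from the confusion matrix at `score ≥ threshold`:
  Sn, Sp, Pre, F1, and MCC in its standard form — the phi coefficient
  of the binary label/prediction pair. Degenerate denominators return 0
  with a warning.
* Fixed-specificity operating points use the smallest threshold whose
  specificity meets the target (maximal sensitivity subject to the
  bound); exact equality is generally unattainable on finite data, so
  the achieved specificity is reported.
* Top-k% retrieval sorts by descending score with stable ties (input
  order) and takes the top ⌈fraction·n⌉.

AUC is computed by trapezoid over the threshold-swept ROC and equals
the normalized Mann–Whitney U statistic to 1e-12 (tested against the
scipy rank statistic on 1000 random instances).

## Synthetic benchmark generator

The generator emulates the statistical structure the method exploits,
at desk scale (defaults: 42 substrates × 3 sites = 126 samples, two
modeled kinases, ~38 positives each):

* **Sequence signal.** Each kinase has a consensus motif centered on
  the acceptor (defaults: basophilic `RR.S...`, acidophilic `...S.EE`),
  planted in positive windows position-by-position with probability
  `motif_fidelity` (default 0.9). Negative sites are *not* random
  windows: each carries the consensus of an unmodeled background kinase
  drawn from a pool that shares single determinants with the modeled
  kinases (one basic residue, one acidic residue, a threonine variant),
  because in real data every negative is itself a phosphosite written
  by some kinase, often from a related family. This keeps the sequence
  view informative but unsaturated — the regime in which combining it
  with functional information is the interesting question.
* **Functional signal.** Each kinase owns 14 hub partners; cohort
  substrates link to each hub with probability `p_in = 0.8`, and every
  substrate links to every partner at the background rate
  `p_out = 0.05` within a ~150-protein universe. On a cohort substrate,
  each site is annotated to the cohort kinase with probability
  `fraction_positive = 0.95`, so the functional fingerprint of a
  positive substrate is only mildly contaminated by negative sites.
* **No-signal control** (`null_config`): flat `...S...` motifs for
  everyone, `p_in = p_out`, and annotations scattered uniformly over
  sites of all substrates. The scattering matters: the functional view
  is substrate-level, so even with random wiring a site-level CV can
  memorize substrate fingerprints if labels concentrate on cohort
  substrates. With scattering, pooled AUC sits at chance.

What the generator does **not** emulate: sequence homology and
redundancy between substrates (real pipelines cluster at 70% identity
first; an exact-duplicate filter is the only guard here), degenerate
and overlapping real kinase motifs, proteome-scale PPI networks with
degree heterogeneity, and multiple kinases annotating one site. Passing
the synthetic benchmarks therefore demonstrates that the machinery
recovers planted signal of realistic shape — not a performance claim
about any curated dataset.

## Problem sizes and determinism

Tests and the acceptance script run 10-fold CV on 126-sample
benchmarks (tens of milliseconds per fold), 50 replicates for the
directional sequence-vs-sequence+functional comparison, 20 replicates
for the null band, and 1000 random instances for the metric oracles.
Every random quantity derives from an explicit seed; fixtures, folds
and reports are byte-identical across reruns with the same seed.

## Known limitations

* λ (default 0.1) and C (default 1.0) are exposed but not tuned per
  kinase; the defaults favor the margin term and ranking quality.
* The functional view cannot distinguish sites within one substrate by
  construction; site-level CV therefore shares substrate information
  across folds, which inflates absolute AUC relative to a
  substrate-held-out split (true of the standard protocol as well).
* Scores are not calibrated probabilities; thresholds must come from
  the operating-point analysis.
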