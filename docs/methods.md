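# Methods

## Problem setting

`mammofuse` operates at the decision level of a multi-classifier pipeline for
three-class mammogram classification (normal / benign / malignant).  Each of
`N` base classifiers emits a softmax score vector `S^(n) ∈ Δ^{L-1}` per
sample; the package's job is to combine those `N` probability vectors into a
single decision, and to evaluate and validate the result.  No classifier
training or inference happens here — the score tensor is the input.

## Fuzzy-rank fusion with a modified Gompertz function

A Gompertz curve `f(t) = m·exp(−exp(n − p·t))` rises sigmoidally to the
asymptote `m`.  The rank transform used here is its complement,

    R(S) = 1 − m·exp(−exp(n_shift − p·S)),

which for the default parameters `(m, n_shift, p) = (1, 0, 2)` becomes
`R(S) = 1 − exp(−exp(−2S))`.  `R` maps `[0, 1]` strictly decreasingly into
`(0, 1)`: a confident score earns a *low* rank, and because the curve
saturates exponentially, a score of exactly zero still gets the finite worst
rank `R(0) = 1 − 1/e ≈ 0.6321` rather than a degenerate value.  That
saturation is the reason for preferring this transform over, say, `1 − S`:
differences among highly confident scores are amplified, while the long tail
of near-zero scores is compressed.

Per classifier `i` and sample, the `k` classes with the smallest ranks form
the top-`k` set `K^(i)` (default `k = 2` of `L = 3`; rank ties break to the
lower class index).  Two per-class sums follow:

    FRS_l  = Σ_i  [ R_l^(i)      if l ∈ K^(i), else P^(R)  ]   (fuzzy rank sum)
    CCFS_l = ⟨ 1 − S_l^(i)       if l ∈ K^(i), else P^(CF) ⟩_i (complementary
                                                           confidence factoral sum)

and the fused class is `argmin_l FRS_l · CCFS_l`, ties to the lowest class
index.  Both factors are "costs" — small when classifiers rank the class
highly and score it confidently — so the product-argmin rewards agreement in
both rank and confidence.

Choices that the formulation leaves open, fixed here as package defaults:

* **Complement confidence** `CF = 1 − S`; it is the natural complement
  consistent with a min-based decision.
* **Penalties**: `P^(R) = R(0)` (the worst attainable rank under the current
  parameters) and `P^(CF) = 1` (complement of zero confidence).  Both are
  user-overridable; a configuration whose `penalty_rank` would beat the best
  attainable rank `R(1)` is rejected, since a penalty must never make an
  excluded class look better than an included one.
* **Tie-breaks** everywhere resolve to the lowest class index and are logged
  at debug level, making runs deterministic.

### Parameter adaptation (optional)

`tune_gompertz_params` adapts `(m, n_shift, p)` by plain gradient descent on
a mean-squared-error loss whose targets are frozen under the initial
parameters: the true class should reach the best rank `R_init(1)` and every
other class the worst rank `R_init(0)`.  Gradients are central finite
differences (step `1e-4`); each step is clipped to `m ∈ (0, 1]`,
`p ∈ [1e-3, 50]`, `n_shift ∈ [−5, 5]` and rejected when it does not decrease
the loss, so the returned loss never exceeds the initial one.  Freezing the
targets keeps the objective well-posed (otherwise the targets would chase the
parameters).  Tuning is opt-in; all fusion defaults use the fixed form.

## Baselines

**Weighted average** — scores are combined convexly with normalised
non-negative weights (default equal), decision by argmax.  The fused vector
is again a probability vector, and the rule is invariant to weight scaling.

**Sugeno integral** — per sample and class, classifier scores are sorted
descending, `h_(1) ≥ … ≥ h_(N)`, and fused as `max_j min(h_(j), g(A_j))`
where `A_j` is the set of the `j` top scorers and `g` a λ-fuzzy measure built
from per-classifier densities `g_i ∈ (0, 1)`:
`g(A ∪ B) = g(A) + g(B) + λ·g(A)·g(B)`, with λ the unique root > −1 of
`Π_i(1 + λ g_i) = 1 + λ`.  The root is located by bracketed bisection to a
residual below `1e-10` (λ = 0, the additive measure, when densities sum
to 1; the measure of the full set is pinned to exactly 1 to keep the
integral idempotent on constant inputs).  Default densities are `1/N`.

## Evaluation statistics

Per-class precision, recall and F1 come from the one-vs-rest decomposition of
the `L × L` confusion matrix and are reported in percent (rounded to 3
decimals in reports; full precision internally).  A zero denominator yields 0
with a warning.  Overall accuracy is `100·trace/total`; note that for any
multi-class confusion matrix the micro-averaged recall equals overall
accuracy, which the tests use as an identity check.  Cohen's kappa is
`(p_o − p_e)/(1 − p_e)` with the usual marginal-product chance agreement; it
is stored on its natural [−1, 1] scale, with a 0–100 presentation option.

The one-way ANOVA decomposes `SS_total = SS_between + SS_within` over groups
of overall-accuracy values, with `F = MS_between/MS_within`, the p-value from
the upper tail of `F(df_b, df_w)` and the critical value at α = 0.05.  Fed
the twelve published per-backbone overall accuracies (four ensemble variants
× three backbones, grouped by backbone), it reproduces the published table to
all six printed decimals — see `scripts/acceptance.py`.

A note on published per-class tables of this kind: several printed F1 values
exceed both their precision and recall, which is impossible for a harmonic
mean.  This package computes the mathematically correct F1 and makes no
attempt to emulate such cells.

## Preprocessing chain

Order: impulse filtering → border cropping → orientation → pectoral-muscle
removal → resize.  All steps are deterministic, so the chain is
bit-reproducible.

* **Adaptive median filter** (two-level, window growing 3 → `max_window`,
  default 7, borders by edge replication).  Level A grows the window until
  the window median is strictly between the window extrema; Level B keeps the
  pixel if it is itself strictly interior to that window's range and
  substitutes the median otherwise.  When no window produces an interior
  median, Level B is applied with the largest window's statistics — this
  reduces to the identity on constant images and removes isolated impulses.
* **Border cropping** automates a manual step: leading/trailing rows/columns
  with mean intensity below `frac` (default 0.02) of full scale are trimmed,
  capped at 25% of each dimension; an image that would drop below 8×8 is a
  degenerate-crop error.
* **Orientation** mirrors the image horizontally when the right half-image
  mean exceeds the left, so the breast and the pectoral-muscle corner of an
  MLO view sit on the upper left.  Strict inequality makes the operation
  idempotent and leaves symmetric images alone.
* **Pectoral-muscle removal** restricts itself to the upper-left quadrant
  (odd dimensions give the extra row/column to the lower/right quadrants).
  The quadrant is binarised at its own Otsu threshold — computed over the
  exact integer histogram with ties resolved to the lowest maximising
  threshold — and the 8-connected bright components touching the
  corner-adjacent half of the quadrant's top row or left column are zeroed.
  Requiring contact near the corner is what prevents interior dense tissue,
  or breast tissue entering the quadrant from below, from being removed.  If
  nothing touches the corner the image is returned unchanged with a warning.
* **Resize** is bilinear to `size × size` (default 224, the standard CNN
  input), rounded back to the input dtype.

## Synthetic generators

The score-tensor generator draws, per sample, a shared standard-normal latent
`z` and per-classifier noise, mixed as `u = √ρ·z + √(1−ρ)·ε` so each `u` is
marginally standard normal; classifier `n` is "correct" iff `Φ(u) < acc_n`.
The softmax row is Dirichlet with concentration `c` everywhere and `5c` on
the intended argmax class (the true label when correct, a uniformly drawn
wrong class otherwise); the intended class is then swapped with the row
maximum if the draw did not already place it on top.  The swap makes
correctness exact by construction — accuracy 1.0 really yields argmax = label
on every sample, and empirical accuracies concentrate binomially around the
targets — at the cost of slightly distorting the Dirichlet shape in the
swapped rows.  `ρ = 0` gives conditionally independent classifiers; `ρ → 1`
makes their errors redundant, which is the axis along which ensemble gain
disappears.

Defaults mirror the study conditions the package emulates: `L = 3` balanced
classes at 986 samples each (2,958 total), `N = 3` classifiers with
accuracies `(0.958, 0.962, 0.966)` — the standalone range of the published
backbones — concentration 2.0 and ρ = 0.

The phantom generator is geometric, not textural: dark background (10),
half-ellipse "breast" (100) flush with one side, bright right-triangle
"pectoral muscle" (200) anchored at that side's top corner and contained in
the top quadrant, with a thin background gap separating triangle and
ellipse, plus salt-and-pepper impulses at the requested rate.  It returns
the ground-truth muscle mask and the clean image, so restoration and
segmentation error are measured exactly.  Phantoms exercise geometry, noise
handling and thresholding; they make no claim of realistic mammographic
texture, so passing phantom tests demonstrates the chain's mechanics, not
clinical segmentation accuracy.

## Problem sizes and numerical choices

The bundled experiments run at desk scale: the ensemble-gain study uses
`N = 5` classifiers at accuracy 0.70 on 2,000 samples (the fused accuracy
typically lands near 87% against a best single classifier near 71%);
generator recovery uses 10,000 samples; phantoms are 256×256.  Score rows
must sum to 1 within `1e-6`; violations up to `1e-3` are renormalised with a
warning (CSV rounding), worse ones are errors.  All randomness flows through
`numpy.random.default_rng(seed)`, making every generator a pure function of
its arguments.

## Known limitations

* No DICOM input, no CC-view logic, and no learning-based muscle
  segmentation; the quadrant/threshold approach assumes an MLO-like geometry
  with the muscle in one upper corner.
* The Choquet integral is deliberately absent; the comparison set is
  weighted average and Sugeno only.
* Published per-class benchmark metrics require external mammogram databases
  and trained networks and are out of scope; the fusion rules are validated
  against brute-force oracles and synthetic ensembles instead.
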