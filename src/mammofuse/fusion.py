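"""Score-level ensemble fusion of softmax classifier outputs.

Three fusion rules operating on an ``(N, samples, L)`` tensor of per-classifier
softmax decision scores:

* **Fuzzy ranking with a modified Gompertz function** — each score ``S`` is
  mapped to a fuzzy rank ``R = 1 - m * exp(-exp(n_shift - p * S))`` (lower rank
  means higher confidence).  Per classifier, only the ``k`` top-ranked classes
  contribute their rank and complemented confidence ``CF = 1 - S``; classes
  outside the top-``k`` set incur fixed penalties.  The fused decision is the
  class minimising ``FRS * CCFS``, the product of the fuzzy-rank sum and the
  complementary-confidence factoral sum.
* **Weighted average** — convex combination of the score vectors, argmax
  decision.
* **Sugeno fuzzy integral** — sorted max–min aggregation against a
  lambda-fuzzy measure built from per-classifier densities.

An optional gradient-descent tuner adapts the Gompertz parameters
``(m, n_shift, p)`` to a frozen rank-target mean-squared-error loss.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ScoreTensor",
    "GompertzParams",
    "FusionConfig",
    "FusionResult",
    "gompertz_rank",
    "compute_ranks",
    "top_k_sets",
    "fuzzy_rank_fusion",
    "weighted_average_fusion",
    "solve_lambda",
    "sugeno_fusion",
    "tune_gompertz_params",
]

# Rows whose scores miss sum 1 by more than this are hard errors; smaller
# violations (beyond the 1e-6 softmax tolerance) are renormalised with a
# warning to absorb CSV rounding.
_ROW_SUM_STRICT = 1e-6
_ROW_SUM_REPAIR = 1e-3


@dataclass
class ScoreTensor:
    """Softmax decision scores of ``N`` classifiers on ``L`` classes.

    Parameters
    ----------
    scores
        Array of shape ``(N, n_samples, L)``; every ``(classifier, sample)``
        row is a probability vector.
    classifier_names, class_names
        Optional identifiers; defaulted to ``C1..CN`` / ``class1..classL``.
    """

    scores: np.ndarray
    classifier_names: list[str] = field(default_factory=list)
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 3:
            raise ValueError(
                f"scores must have shape (N, samples, L); got {self.scores.shape}"
            )
        n, s, l = self.scores.shape
        if n < 1 or s < 1 or l < 2:
            raise ValueError(
                f"need N >= 1, samples >= 1, L >= 2; got N={n}, samples={s}, L={l}"
            )
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores contain non-finite values")
        if np.any(self.scores < 0):
            raise ValueError("scores must be non-negative")
        sums = self.scores.sum(axis=2)
        err = np.abs(sums - 1.0)
        if np.any(err > _ROW_SUM_REPAIR):
            worst = np.unravel_index(np.argmax(err), err.shape)
            raise ValueError(
                "score rows must sum to 1: worst violation "
                f"{err[worst]:.3g} at (classifier={worst[0]}, sample={worst[1]})"
            )
        if np.any(err > _ROW_SUM_STRICT):
            warnings.warn(
                f"{int(np.sum(err > _ROW_SUM_STRICT))} score rows off sum 1 "
                "by <= 1e-3; renormalising",
                stacklevel=2,
            )
            self.scores = self.scores / sums[:, :, None]
        if not self.classifier_names:
            self.classifier_names = [f"C{i + 1}" for i in range(n)]
        if not self.class_names:
            self.class_names = [f"class{i + 1}" for i in range(l)]
        if len(self.classifier_names) != n:
            raise ValueError("classifier_names length mismatch")
        if len(self.class_names) != l:
            raise ValueError("class_names length mismatch")

    @property
    def n_classifiers(self) -> int:
        return self.scores.shape[0]

    @property
    def n_samples(self) -> int:
        return self.scores.shape[1]

    @property
    def n_classes(self) -> int:
        return self.scores.shape[2]


@dataclass(frozen=True)
class GompertzParams:
    """Parameters of the modified Gompertz rank transform.

    ``m`` scales the asymptote, ``n_shift`` displaces the curve horizontally
    and ``p`` sets the steepness.  The defaults ``(1, 0, 2)`` give the rank
    ``1 - exp(-exp(-2 * score))`` used throughout as the fixed form.
    """

    m: float = 1.0
    n_shift: float = 0.0
    p: float = 2.0

    def __post_init__(self) -> None:
        if not (0.0 < self.m <= 1.0):
            raise ValueError(f"m must lie in (0, 1]; got {self.m}")
        if self.p <= 0.0:
            raise ValueError(f"p must be positive; got {self.p}")
        if not np.isfinite(self.n_shift):
            raise ValueError("n_shift must be finite")


@dataclass(frozen=True)
class FusionConfig:
    """Configuration of the fuzzy-rank fusion rule.

    ``k`` is the per-classifier top-class count; classes outside a
    classifier's top-``k`` set contribute ``penalty_rank`` to the fuzzy-rank
    sum and ``penalty_cf`` to the complementary-confidence sum.  Defaults:
    ``penalty_rank`` is the worst attainable rank (rank at score 0 under the
    current parameters) and ``penalty_cf = 1`` (complement of zero
    confidence).
    """

    k: int = 2
    params: GompertzParams = field(default_factory=GompertzParams)
    penalty_rank: float | None = None
    penalty_cf: float = 1.0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be >= 1; got {self.k}")
        if not (0.0 <= self.penalty_cf <= 1.0):
            raise ValueError(f"penalty_cf must lie in [0, 1]; got {self.penalty_cf}")
        if self.penalty_rank is None:
            object.__setattr__(
                self, "penalty_rank", gompertz_rank(0.0, self.params)
            )
        best_rank = gompertz_rank(1.0, self.params)
        if self.penalty_rank < best_rank:
            raise ValueError(
                f"penalty_rank {self.penalty_rank:.6g} beats the best attainable "
                f"rank {best_rank:.6g}; a penalty must never outrank a top-k member"
            )


@dataclass
class FusionResult:
    """Outcome of a fusion rule.

    ``fused_class`` holds 1-based class indices.  For the fuzzy-rank method
    ``fused_score`` is ``FRS * CCFS`` (argmin decision) and the ``frs``,
    ``ccfs`` and ``ranks`` intermediates are populated; for the weighted
    average and Sugeno integral it is the aggregated score (argmax decision).
    """

    method: str
    fused_class: np.ndarray
    fused_score: np.ndarray
    frs: np.ndarray | None = None
    ccfs: np.ndarray | None = None
    ranks: np.ndarray | None = None


def _check_params(params: GompertzParams) -> GompertzParams:
    if not isinstance(params, GompertzParams):
        raise TypeError("params must be a GompertzParams instance")
    return params


def gompertz_rank(score, params: GompertzParams | None = None):
    """Fuzzy rank of a decision score via the modified Gompertz transform.

    Computes ``1 - m * exp(-exp(n_shift - p * score))``, a strictly decreasing
    map of ``[0, 1]`` into ``(0, 1)`` for ``p > 0``: confident scores receive
    low ranks.  Accepts scalars or arrays.

    Raises
    ------
    ValueError
        If any score is non-finite or outside ``[0, 1]``.
    """
    params = _check_params(params or GompertzParams())
    s = np.asarray(score, dtype=float)
    if not np.all(np.isfinite(s)):
        raise ValueError("score must be finite")
    if np.any(s < 0) or np.any(s > 1):
        raise ValueError(f"score must lie in [0, 1]; got {score!r}")
    r = 1.0 - params.m * np.exp(-np.exp(params.n_shift - params.p * s))
    return float(r) if np.isscalar(score) or s.ndim == 0 else r


def compute_ranks(tensor: ScoreTensor, params: GompertzParams | None = None) -> np.ndarray:
    """Elementwise Gompertz rank of a score tensor, shape preserved."""
    params = _check_params(params or GompertzParams())
    try:
        return gompertz_rank(tensor.scores, params)
    except ValueError as exc:  # locate the offending entry for the message
        bad = ~np.isfinite(tensor.scores) | (tensor.scores < 0) | (tensor.scores > 1)
        idx = np.argwhere(bad)
        where = tuple(idx[0]) if len(idx) else "?"
        raise ValueError(
            f"invalid score at (classifier, sample, class)={where}: {exc}"
        ) from exc


def top_k_sets(ranks: np.ndarray, k: int) -> np.ndarray:
    """Boolean membership of each class in a classifier's top-``k`` rank set.

    Per ``(classifier, sample)`` exactly ``k`` entries are True, marking the
    ``k`` smallest ranks; rank ties break towards the lower class index via
    stable sorting.
    """
    ranks = np.asarray(ranks, dtype=float)
    L = ranks.shape[-1]
    if not (1 <= k <= L):
        raise ValueError(f"k must lie in [1, L={L}]; got {k}")
    order = np.argsort(ranks, axis=-1, kind="stable")
    member = np.zeros(ranks.shape, dtype=bool)
    np.put_along_axis(member, order[..., :k], True, axis=-1)
    return member


def fuzzy_rank_fusion(tensor: ScoreTensor, config: FusionConfig | None = None) -> FusionResult:
    """Fuse classifier scores by modified-Gompertz fuzzy ranking.

    Per sample and class ``l``::

        FRS_l  = sum_i  [ R_l^(i)      if l in top-k of classifier i else P^(R)  ]
        CCFS_l = mean_i [ 1 - S_l^(i)  if l in top-k of classifier i else P^(CF) ]

    and the fused class is ``argmin_l FRS_l * CCFS_l`` (ties to the lowest
    class index).  Returns the per-class product, the ``FRS``/``CCFS``
    intermediates and the full rank tensor.
    """
    config = config or FusionConfig()
    L = tensor.n_classes
    if config.k > L:
        raise ValueError(f"k={config.k} exceeds the class count L={L}")
    ranks = compute_ranks(tensor, config.params)
    member = top_k_sets(ranks, config.k)
    cf = 1.0 - tensor.scores
    frs = np.where(member, ranks, config.penalty_rank).sum(axis=0)
    ccfs = np.where(member, cf, config.penalty_cf).mean(axis=0)
    fused_score = frs * ccfs
    fused_class = np.argmin(fused_score, axis=1) + 1
    _log_ties(fused_score, fused_class, minimise=True)
    return FusionResult(
        method="gompertz",
        fused_class=fused_class,
        fused_score=fused_score,
        frs=frs,
        ccfs=ccfs,
        ranks=ranks,
    )


def _log_ties(score: np.ndarray, chosen: np.ndarray, minimise: bool) -> None:
    extreme = score.min(axis=1) if minimise else score.max(axis=1)
    tied = (np.isclose(score, extreme[:, None], rtol=0, atol=0)).sum(axis=1) > 1
    n_ties = int(tied.sum())
    if n_ties:
        logger.debug(
            "%d sample(s) had tied fused scores; lowest class index chosen: %s",
            n_ties,
            np.nonzero(tied)[0][:20],
        )


def weighted_average_fusion(tensor: ScoreTensor, weights: Sequence[float] | None = None) -> FusionResult:
    """Fuse scores by a normalised weighted average (argmax decision).

    Weights default to equal; they must be non-negative with a positive sum
    and are invariant to overall scaling.  The fused per-sample score vector
    is itself a probability vector.
    """
    n = tensor.n_classifiers
    w = np.full(n, 1.0 / n) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (n,):
        raise ValueError(f"weights must have length N={n}; got shape {w.shape}")
    if np.any(w < 0) or not np.all(np.isfinite(w)):
        raise ValueError("weights must be finite and non-negative")
    total = w.sum()
    if total <= 0:
        raise ValueError("weights must not all be zero")
    w = w / total
    fused_score = np.tensordot(w, tensor.scores, axes=(0, 0))
    fused_class = np.argmax(fused_score, axis=1) + 1
    _log_ties(fused_score, fused_class, minimise=False)
    return FusionResult(method="wa", fused_class=fused_class, fused_score=fused_score)


def solve_lambda(densities: Sequence[float]) -> float:
    """Solve for the lambda of a lambda-fuzzy measure with the given densities.

    Finds the unique ``lambda > -1`` with ``prod_i(1 + lambda * g_i) = 1 +
    lambda`` by bracketed bisection (residual below 1e-10); returns 0 when the
    densities sum to 1 (additive measure).
    """
    g = np.asarray(densities, dtype=float)
    if g.ndim != 1 or g.size < 1:
        raise ValueError("densities must be a non-empty 1-D sequence")
    if np.any(g <= 0) or np.any(g >= 1):
        raise ValueError(f"each density must lie in (0, 1); got {list(g)}")
    total = g.sum()
    if g.size == 1 or abs(total - 1.0) <= 1e-9:
        return 0.0

    def resid(lam: float) -> float:
        return float(np.prod(1.0 + lam * g) - 1.0 - lam)

    # resid(0) = 0 is always a root; the measure's lambda is the other one:
    # positive when sum g < 1 (super-additive), in (-1, 0) when sum g > 1.
    if total < 1.0:
        lo, hi = 0.0, 1.0
        while resid(hi) < 0:
            hi *= 2.0
            if hi > 1e12:  # pragma: no cover - densities in (0,1) always bracket
                raise RuntimeError("failed to bracket lambda")
    else:
        lo, hi = -1.0, 0.0  # resid(-1) = prod(1 - g_i) > 0, resid(0-) < 0
        lo, hi = hi, lo  # orient so resid(lo) < 0 < resid(hi)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        r = resid(mid)
        if abs(r) < 1e-10:
            return mid
        if r < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def sugeno_fusion(tensor: ScoreTensor, densities: Sequence[float] | None = None) -> FusionResult:
    """Fuse scores with the Sugeno integral over a lambda-fuzzy measure.

    Per sample and class, classifier scores are sorted descending and
    aggregated as ``max_j min(h_(j), g(A_j))`` where ``A_j`` is the set of the
    ``j`` top-scoring classifiers and ``g`` the lambda-measure built from the
    per-classifier densities (default: equal densities ``1/N``, the additive
    measure).  Decision is argmax of the fused score.
    """
    n = tensor.n_classifiers
    g = np.full(n, 1.0 / n) if densities is None else np.asarray(densities, dtype=float)
    if g.shape != (n,):
        raise ValueError(f"densities must have length N={n}; got shape {g.shape}")
    lam = solve_lambda(g)
    # sort classifiers by score descending per (sample, class)
    scores = np.moveaxis(tensor.scores, 0, -1)  # (samples, L, N)
    order = np.argsort(-scores, axis=-1, kind="stable")
    h = np.take_along_axis(scores, order, axis=-1)
    g_sorted = g[order]
    g_cum = np.empty_like(g_sorted)
    g_cum[..., 0] = g_sorted[..., 0]
    for j in range(1, n):
        prev = g_cum[..., j - 1]
        g_cum[..., j] = g_sorted[..., j] + prev + lam * g_sorted[..., j] * prev
    g_cum[..., -1] = 1.0  # measure of the full set, exact by construction
    fused_score = np.max(np.minimum(h, g_cum), axis=-1)
    fused_class = np.argmax(fused_score, axis=1) + 1
    _log_ties(fused_score, fused_class, minimise=False)
    return FusionResult(method="sugeno", fused_class=fused_class, fused_score=fused_score)


def tune_gompertz_params(
    tensor: ScoreTensor,
    labels: Sequence[int],
    init: GompertzParams | None = None,
    learning_rate: float = 0.05,
    iterations: int = 100,
    seed: int = 0,
) -> GompertzParams:
    """Adapt the Gompertz parameters by gradient descent on a rank-target MSE.

    The targets are frozen under ``init``: the true class should attain the
    best rank (rank at score 1) and every other class the worst (rank at
    score 0).  Gradients come from central finite differences (step 1e-4);
    each step is clipped to the valid ranges ``m in (0, 1]``, ``p in [1e-3,
    50]``, ``n_shift in [-5, 5]`` and rejected if it does not decrease the
    loss, so the returned loss never exceeds the initial one.  ``seed`` is
    accepted for interface uniformity; the procedure is deterministic.
    """
    del seed
    init = _check_params(init or GompertzParams())
    labels = np.asarray(labels, dtype=int)
    if labels.shape != (tensor.n_samples,):
        raise ValueError("labels must align with the tensor's samples")
    if learning_rate < 0:
        raise ValueError("learning_rate must be >= 0")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")

    L = tensor.n_classes
    onehot = np.eye(L, dtype=bool)[labels - 1]  # (samples, L)
    t_true = gompertz_rank(1.0, init)
    t_false = gompertz_rank(0.0, init)
    targets = np.where(onehot, t_true, t_false)[None, :, :]

    def loss(p: GompertzParams) -> float:
        val = float(np.mean((gompertz_rank(tensor.scores, p) - targets) ** 2))
        if not np.isfinite(val):
            raise ArithmeticError("non-finite tuning loss")
        return val

    def clip(m: float, n_shift: float, p: float) -> GompertzParams:
        return GompertzParams(
            m=float(np.clip(m, 1e-6, 1.0)),
            n_shift=float(np.clip(n_shift, -5.0, 5.0)),
            p=float(np.clip(p, 1e-3, 50.0)),
        )

    current = init
    current_loss = loss(current)
    h = 1e-4
    for it in range(iterations):
        theta = np.array([current.m, current.n_shift, current.p])
        grad = np.empty(3)
        for j in range(3):
            plus, minus = theta.copy(), theta.copy()
            plus[j] += h
            minus[j] -= h
            try:
                grad[j] = (loss(clip(*plus)) - loss(clip(*minus))) / (2 * h)
            except ArithmeticError as exc:
                raise ArithmeticError(f"non-finite loss at iteration {it}") from exc
        candidate = clip(*(theta - learning_rate * grad))
        cand_loss = loss(candidate)
        if cand_loss < current_loss:
            current, current_loss = candidate, cand_loss
        else:
            logger.debug("iteration %d: uphill step rejected", it)
    return current
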