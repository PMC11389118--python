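import math

import numpy as np
import pytest

from mammofuse import ScoreTensor


@pytest.fixture
def worked_tensor():
    """Three classifiers, one sample, three classes — the hand-worked case."""
    return ScoreTensor(
        np.array([[[0.7, 0.2, 0.1]], [[0.5, 0.3, 0.2]], [[0.1, 0.6, 0.3]]])
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def random_tensor(rng, n=None, samples=None, l=None):
    """Dirichlet score tensor with random shape within the oracle limits."""
    n = n or int(rng.integers(1, 6))
    samples = samples or int(rng.integers(1, 21))
    l = l or int(rng.integers(2, 5))
    scores = rng.dirichlet(np.ones(l), size=(n, samples))
    return ScoreTensor(scores)


def scalar_gompertz(score, m=1.0, n_shift=0.0, p=2.0):
    """Independent scalar rank transform used by the brute-force oracles."""
    return 1.0 - m * math.exp(-math.exp(n_shift - p * score))


def brute_force_fuzzy_rank(scores, k=2, penalty_rank=None, penalty_cf=1.0):
    """Loop-based re-implementation of the fuzzy-rank fusion rule.

    Pure-Python, per-element: ranks via the scalar Gompertz transform, per
    classifier top-k by smallest rank (ties to lower class index), rank-sum
    and complement-confidence penalties, argmin of the product.
    """
    if penalty_rank is None:
        penalty_rank = scalar_gompertz(0.0)
    N = len(scores)
    S = len(scores[0])
    L = len(scores[0][0])
    fused_classes, fused_scores = [], []
    for s in range(S):
        frs = [0.0] * L
        ccfs = [0.0] * L
        for i in range(N):
            ranks = [scalar_gompertz(scores[i][s][l]) for l in range(L)]
            topk = sorted(range(L), key=lambda l: (ranks[l], l))[:k]
            for l in range(L):
                if l in topk:
                    frs[l] += ranks[l]
                    ccfs[l] += 1.0 - scores[i][s][l]
                else:
                    frs[l] += penalty_rank
                    ccfs[l] += penalty_cf
        fused = [frs[l] * (ccfs[l] / N) for l in range(L)]
        best = min(range(L), key=lambda l: (fused[l], l))
        fused_classes.append(best + 1)
        fused_scores.append(fused)
    return fused_classes, fused_scores
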