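"""Seeded generators for classifier score tensors and phantom mammograms.

The score-tensor generator emulates an ensemble of softmax classifiers with
configurable per-classifier accuracy, confidence concentration, and
inter-classifier correctness correlation (via a shared latent Gaussian).  The
phantom generator draws an MLO-like geometry — dark background, half-ellipse
breast, bright pectoral-muscle triangle anchored in the top corner — with
optional salt-and-pepper impulse noise, and returns the ground-truth muscle
mask and the clean image so restoration and segmentation quality can be
measured exactly.

Defaults mirror the study conditions of a three-class (normal / benign /
malignant) mammogram benchmark: 986 samples per class, three base
classifiers with standalone accuracies around 0.958-0.966.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .fusion import ScoreTensor

__all__ = ["SimConfig", "gen_labels", "gen_score_tensor", "gen_phantom_mammogram"]

#: Dirichlet concentration multiplier on the intended-argmax class.
_BOOST = 5.0


@dataclass
class SimConfig:
    """Conditions for one simulated multi-classifier experiment.

    ``accuracies`` are per-classifier probabilities that the classifier's
    argmax equals the true label; they must exceed chance ``1/L``.
    ``concentration`` sets Dirichlet sharpness (higher = more peaked softmax
    rows).  ``correlation`` in [0, 1) couples the classifiers' correctness
    events through a shared latent normal draw: 0 gives conditionally
    independent classifiers, values near 1 make their errors redundant.
    """

    n_classifiers: int = 3
    n_classes: int = 3
    n_samples: int = 2958  # 986 per class at L=3
    accuracies: tuple[float, ...] = (0.958, 0.962, 0.966)
    concentration: float = 2.0
    correlation: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classifiers < 1 or self.n_classes < 2 or self.n_samples < 1:
            raise ValueError("need n_classifiers >= 1, n_classes >= 2, n_samples >= 1")
        self.accuracies = tuple(float(a) for a in self.accuracies)
        if len(self.accuracies) != self.n_classifiers:
            raise ValueError(
                f"accuracies must have length {self.n_classifiers}; "
                f"got {len(self.accuracies)}"
            )
        chance = 1.0 / self.n_classes
        if any(not (chance < a < 1.0) and a != 1.0 for a in self.accuracies):
            raise ValueError(
                f"each accuracy must lie in ({chance:.3g}, 1]; got {self.accuracies}"
            )
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")
        if not (0.0 <= self.correlation < 1.0):
            raise ValueError("correlation must lie in [0, 1)")


def gen_labels(n_samples: int, n_classes: int, seed: int) -> np.ndarray:
    """Balanced 1-based label vector: stratified fill, then shuffle.

    Exact balance whenever ``n_samples`` is divisible by ``n_classes``; any
    remainder goes to the lowest class indices.
    """
    if n_samples < n_classes:
        raise ValueError("n_samples must be >= n_classes")
    rng = np.random.default_rng(seed)
    reps = -(-n_samples // n_classes)  # ceil
    labels = np.tile(np.arange(1, n_classes + 1), reps)[:n_samples]
    rng.shuffle(labels)
    return labels


def gen_score_tensor(config: SimConfig) -> tuple[ScoreTensor, np.ndarray]:
    """Draw a score tensor whose argmax behaviour matches ``config`` exactly.

    Per sample a shared standard-normal latent ``z`` is mixed with
    per-classifier noise, ``u = sqrt(rho) z + sqrt(1 - rho) eps`` (marginally
    standard normal), and classifier ``n`` is correct iff ``Phi(u) <
    accuracies[n]``.  The softmax row is Dirichlet with the concentration
    boosted x5 on the intended class — the true label when correct, a
    uniformly drawn wrong one otherwise — and the intended class is swapped
    with the row maximum if the draw did not already put it on top, so the
    correctness events are exact by construction.
    """
    rng = np.random.default_rng(config.seed)
    N, S, L = config.n_classifiers, config.n_samples, config.n_classes
    labels = gen_labels(S, L, int(rng.integers(2**31)))

    z = rng.standard_normal(S)
    eps = rng.standard_normal((N, S))
    rho = config.correlation
    u = np.sqrt(rho) * z[None, :] + np.sqrt(1.0 - rho) * eps
    correct = stats.norm.cdf(u) < np.asarray(config.accuracies)[:, None]

    # intended argmax class per (classifier, sample), 0-based
    wrong_offset = rng.integers(1, L, size=(N, S))
    intended = np.where(
        correct, labels[None, :] - 1, (labels[None, :] - 1 + wrong_offset) % L
    )

    alpha = np.full((N, S, L), config.concentration)
    np.put_along_axis(alpha, intended[:, :, None], _BOOST * config.concentration, axis=2)
    gamma = rng.standard_gamma(alpha)
    scores = gamma / gamma.sum(axis=2, keepdims=True)

    # enforce argmax == intended: swap the intended entry with the row max
    top = np.argmax(scores, axis=2)
    n_idx, s_idx = np.nonzero(top != intended)
    t_idx, i_idx = top[n_idx, s_idx], intended[n_idx, s_idx]
    tmp = scores[n_idx, s_idx, t_idx].copy()
    scores[n_idx, s_idx, t_idx] = scores[n_idx, s_idx, i_idx]
    scores[n_idx, s_idx, i_idx] = tmp
    scores /= scores.sum(axis=2, keepdims=True)

    return ScoreTensor(scores), labels


def gen_phantom_mammogram(
    height: int = 256,
    width: int = 256,
    pm_side: str = "left",
    pm_intensity: int = 200,
    breast_intensity: int = 100,
    background_intensity: int = 10,
    noise_rate: float = 0.05,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Phantom MLO mammogram: background, breast half-ellipse, muscle triangle.

    The pectoral-muscle right triangle is anchored at the top corner of
    ``pm_side`` and contained within that side's top quadrant; the breast
    half-ellipse sits below it on the same side, separated by a thin
    background gap so the two structures are not connected.  Salt-and-pepper
    impulses (half pepper at 0, half salt at full scale) corrupt a
    ``noise_rate`` fraction of pixels.

    Returns ``(noisy_image, pm_mask, clean_image)`` as uint8 arrays; with
    ``noise_rate=0`` the first and last are equal.
    """
    if height < 64 or width < 64:
        raise ValueError("phantom dimensions must be >= 64")
    if not (0.0 <= noise_rate < 0.5):
        raise ValueError("noise_rate must lie in [0, 0.5)")
    if not (pm_intensity > breast_intensity > background_intensity >= 0):
        raise ValueError("need pm_intensity > breast_intensity > background")
    if pm_side not in ("left", "right"):
        raise ValueError(f"pm_side must be 'left' or 'right'; got {pm_side!r}")

    rows = np.arange(height)[:, None]
    cols = np.arange(width)[None, :]

    # breast: half-ellipse flush with the left edge, lower-left of the image
    cy, ry = 0.675 * height, 0.275 * height
    rx = 0.55 * width
    breast = ((rows - cy) / ry) ** 2 + (cols / rx) ** 2 <= 1.0

    # pectoral muscle: right triangle with legs on the top and left edges,
    # inside the upper-left quadrant and clear of the breast ellipse
    leg_v, leg_h = 0.35 * height, 0.45 * width
    pm_mask = (rows / leg_v + cols / leg_h) <= 1.0

    clean = np.full((height, width), background_intensity, dtype=np.uint8)
    clean[breast] = breast_intensity
    clean[pm_mask] = pm_intensity

    if pm_side == "right":
        clean = clean[:, ::-1].copy()
        pm_mask = pm_mask[:, ::-1].copy()

    noisy = clean.copy()
    if noise_rate > 0:
        rng = np.random.default_rng(seed)
        impulse = rng.random((height, width)) < noise_rate
        salt = rng.random((height, width)) < 0.5
        noisy[impulse & salt] = 255
        noisy[impulse & ~salt] = 0
    return noisy, pm_mask, clean
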