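"""Mammogram preparation chain.

Steps, in pipeline order: adaptive median filtering of salt-and-pepper
impulse noise, trimming of dark scanner borders, horizontal-flip
standardisation so the breast (and the pectoral muscle corner) sits on the
left, quadrant-restricted pectoral-muscle removal by global (Otsu)
thresholding, and bilinear resizing to a square network-input raster.

Images are 2-D unsigned-integer rasters (8- or 16-bit), row-major with the
origin at the top-left — the convention of PNG/PGM grayscale files.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _skimage_resize

__all__ = [
    "adaptive_median_filter",
    "crop_dark_borders",
    "orient_muscle_upper_left",
    "otsu_threshold",
    "remove_pectoral_muscle",
    "resize_image",
    "preprocess_chain",
    "ChainReport",
]

_MIN_DIM = 8  # quadrant logic needs at least 8x8


def _check_image(img: np.ndarray, min_dim: int = 1) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image; got ndim={img.ndim}")
    if not np.issubdtype(img.dtype, np.integer):
        raise ValueError(f"expected an integer raster; got dtype {img.dtype}")
    if img.shape[0] < min_dim or img.shape[1] < min_dim:
        raise ValueError(
            f"image {img.shape} smaller than the required {min_dim}x{min_dim}"
        )
    return img


def _dtype_max(img: np.ndarray) -> int:
    return int(np.iinfo(img.dtype).max)


def adaptive_median_filter(img: np.ndarray, max_window: int = 7) -> np.ndarray:
    """Two-level adaptive median filter for impulse (salt-and-pepper) noise.

    Per pixel the window grows from 3x3 until the window median lies strictly
    between the window minimum and maximum, or ``max_window`` is reached
    (Level A).  The pixel is then kept if it is itself strictly between that
    window's min and max — i.e. not an impulse — and replaced by the window
    median otherwise (Level B).  Borders are handled by edge replication.
    Uncorrupted detail is preserved because interior pixels pass Level B
    untouched.
    """
    img = _check_image(img)
    if max_window % 2 == 0 or max_window < 3:
        raise ValueError(f"max_window must be odd and >= 3; got {max_window}")
    if max_window >= min(img.shape):
        raise ValueError(
            f"max_window {max_window} must be smaller than min(height, width) "
            f"= {min(img.shape)}"
        )
    sizes = range(3, max_window + 1, 2)
    med = {w: ndimage.median_filter(img, size=w, mode="nearest") for w in sizes}
    mn = {w: ndimage.minimum_filter(img, size=w, mode="nearest") for w in sizes}
    mx = {w: ndimage.maximum_filter(img, size=w, mode="nearest") for w in sizes}

    out_med = med[max_window].copy()
    out_min = mn[max_window].copy()
    out_max = mx[max_window].copy()
    settled = np.zeros(img.shape, dtype=bool)
    for w in sizes:
        interior = (mn[w] < med[w]) & (med[w] < mx[w]) & ~settled
        out_med[interior] = med[w][interior]
        out_min[interior] = mn[w][interior]
        out_max[interior] = mx[w][interior]
        settled |= interior
    keep = (out_min < img) & (img < out_max)
    return np.where(keep, img, out_med).astype(img.dtype)


def crop_dark_borders(img: np.ndarray, frac: float = 0.02) -> np.ndarray:
    """Trim leading/trailing rows and columns darker than ``frac`` of full scale.

    Automates the manual border-cropping step: a border row or column whose
    mean intensity falls below ``frac * dtype_max`` is removed.  At most 25%
    of either dimension is trimmed; an image that would vanish entirely (or
    drop below 8x8) raises a degenerate-crop error.
    """
    img = _check_image(img)
    if not (0 <= frac < 0.5):
        raise ValueError(f"frac must lie in [0, 0.5); got {frac}")
    thr = frac * _dtype_max(img)

    def _trims(means: np.ndarray) -> tuple[int, int]:
        dark = means < thr
        lead = int(np.argmin(dark)) if not dark.all() else means.size
        trail = int(np.argmin(dark[::-1])) if not dark.all() else 0
        return lead, trail

    row_means = img.mean(axis=1)
    col_means = img.mean(axis=0)
    top, bottom = _trims(row_means)
    left, right = _trims(col_means)
    h, w = img.shape
    if top >= h or left >= w or h - top - bottom < _MIN_DIM or w - left - right < _MIN_DIM:
        raise ValueError("degenerate crop: dark-border trim leaves less than 8x8")

    def _cap(lead: int, trail: int, dim: int) -> tuple[int, int]:
        budget = dim // 4
        if lead + trail <= budget:
            return lead, trail
        scale = budget / (lead + trail)
        return int(lead * scale), int(trail * scale)

    top, bottom = _cap(top, bottom, h)
    left, right = _cap(left, right, w)
    return img[top : h - bottom, left : w - right]


def orient_muscle_upper_left(img: np.ndarray) -> tuple[np.ndarray, bool]:
    """Mirror the image horizontally if its bright mass lies on the right.

    Standardises laterality so the breast, and hence the pectoral-muscle
    corner of an MLO view, sits on the left.  The side test compares the mean
    intensity of the two half-images; a flip happens only on strict
    inequality, which makes the operation idempotent.
    """
    img = _check_image(img)
    half = img.shape[1] // 2
    left_mean = img[:, :half].mean()
    right_mean = img[:, img.shape[1] - half :].mean()
    if right_mean > left_mean:
        return img[:, ::-1].copy(), True
    return img, False


def otsu_threshold(img: np.ndarray) -> int:
    """Global threshold maximising between-class variance of the histogram.

    Scans every observed intensity as a candidate threshold ``t`` (foreground
    ``> t``) and returns the lowest maximiser, making the result
    deterministic under ties.  A constant image has no threshold and raises.
    """
    img = _check_image(img)
    values, counts = np.unique(img, return_counts=True)
    if values.size < 2:
        raise ValueError("constant image: no threshold separates two classes")
    probs = counts / counts.sum()
    mu = values * probs
    omega0 = np.cumsum(probs)[:-1]  # background weight for t = values[:-1]
    mu0 = np.cumsum(mu)[:-1]
    mu_total = mu.sum()
    omega1 = 1.0 - omega0
    with np.errstate(invalid="ignore", divide="ignore"):
        sigma_b = (mu_total * omega0 - mu0) ** 2 / (omega0 * omega1)
    sigma_b[~np.isfinite(sigma_b)] = -np.inf
    return int(values[int(np.argmax(sigma_b))])


def remove_pectoral_muscle(img: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Blank the pectoral muscle in the upper-left quadrant of an MLO view.

    Pipeline: orient the image (no-op if already left-sided); split into four
    equal quadrants (odd dimensions put the extra row/column in the
    lower/right ones); Otsu-threshold the upper-left quadrant only; binarise
    it; keep the 8-connected bright components that reach the corner where
    the muscle inserts — contact with the corner-adjacent half of the
    quadrant's top row or left column, so interior dense tissue or breast
    tissue touching the far ends of those edges is never removed; and zero
    those pixels.  Returns the edited image and the boolean removal mask.
    If no bright component reaches the corner the image is returned
    unchanged with an empty mask and a warning.
    """
    import warnings

    img = _check_image(img, min_dim=_MIN_DIM)
    img, _ = orient_muscle_upper_left(img)
    h, w = img.shape
    qh, qw = h // 2, w // 2
    quad = img[:qh, :qw]
    thr = otsu_threshold(quad)
    bright = quad > thr
    labels, n_comp = ndimage.label(bright, structure=np.ones((3, 3), dtype=int))
    touching = set(np.unique(labels[0, : max(1, qw // 2)])) | set(
        np.unique(labels[: max(1, qh // 2), 0])
    )
    touching.discard(0)
    mask = np.zeros(img.shape, dtype=bool)
    if not touching:
        warnings.warn(
            "no bright component touches the upper-left corner; "
            "no pectoral muscle removed",
            stacklevel=2,
        )
        return img, mask
    mask[:qh, :qw] = np.isin(labels, sorted(touching))
    out = img.copy()
    out[mask] = 0
    return out, mask


def resize_image(img: np.ndarray, size: int = 224) -> np.ndarray:
    """Bilinear resize to ``size x size``, rounded back to the input dtype."""
    img = _check_image(img)
    if size < _MIN_DIM:
        raise ValueError(f"size must be >= {_MIN_DIM}; got {size}")
    if img.shape == (size, size):
        return img.copy()
    out = _skimage_resize(
        img.astype(float), (size, size), order=1, anti_aliasing=False,
        preserve_range=True, mode="edge",
    )
    return np.rint(np.clip(out, 0, _dtype_max(img))).astype(img.dtype)


@dataclass
class ChainReport:
    """Per-stage record of one preprocessing run."""

    flipped: bool
    threshold: int | None
    removed_pixel_count: int
    crop_shape: tuple[int, int]

    def as_dict(self) -> dict:
        return {
            "flipped": self.flipped,
            "threshold": self.threshold,
            "removed_pixel_count": self.removed_pixel_count,
            "crop_shape": list(self.crop_shape),
        }


def preprocess_chain(
    img: np.ndarray,
    max_window: int = 7,
    crop_frac: float = 0.02,
    size: int = 224,
    do_filter: bool = True,
    do_crop: bool = True,
    do_pm_removal: bool = True,
) -> tuple[np.ndarray, np.ndarray | None, ChainReport]:
    """Full chain: filter, crop, orient, remove pectoral muscle, resize.

    Returns the final ``size x size`` image, the pectoral-muscle mask in the
    pre-resize (oriented, cropped) frame or None when removal is disabled,
    and a :class:`ChainReport`.
    """
    out = _check_image(img, min_dim=_MIN_DIM)
    if do_filter:
        out = adaptive_median_filter(out, max_window=max_window)
    if do_crop:
        out = crop_dark_borders(out, frac=crop_frac)
    out, flipped = orient_muscle_upper_left(out)
    mask = None
    threshold = None
    removed = 0
    if do_pm_removal:
        qh, qw = out.shape[0] // 2, out.shape[1] // 2
        threshold = otsu_threshold(out[:qh, :qw])
        out, mask = remove_pectoral_muscle(out)
        removed = int(mask.sum())
    final = resize_image(out, size=size)
    return final, mask, ChainReport(
        flipped=flipped,
        threshold=threshold,
        removed_pixel_count=removed,
        crop_shape=out.shape,
    )
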