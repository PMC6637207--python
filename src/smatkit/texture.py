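"""Haralick texture statistics from gray-level co-occurrence matrices.

The 13 classic co-occurrence statistics are computed per cell on the masked
intensity patch, quantized to a fixed number of gray levels by min-max
scaling inside the mask, at pixel distance 1, averaged over the 4 standard
directions (0, 45, 90, 135 degrees).  Pixels outside the mask never
contribute a co-occurrence pair: the quantized image reserves level 0 for
background and the 0-row/column of the counts matrix is discarded before
normalization.

Conventions (recorded because the literature varies):

* natural logarithm for all entropies;
* sum variance is the variance of p_{x+y} about the sum average;
* correlation and the information measures are 0 when their denominators
  vanish (single-gray-level patch), except angular second moment which is
  then exactly 1.
"""

from __future__ import annotations

import numpy as np
from skimage.feature import graycomatrix

__all__ = ["HARALICK_NAMES", "quantize", "masked_glcm", "haralick_features"]

HARALICK_NAMES = (
    "asm",                 # angular second moment (energy)
    "contrast",
    "correlation",
    "variance",            # sum of squares
    "idm",                 # inverse difference moment (homogeneity)
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "difference_variance",
    "difference_entropy",
    "imc1",                # information measure of correlation 1
    "imc2",                # information measure of correlation 2
)

_ANGLES = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)


def quantize(patch: np.ndarray, mask: np.ndarray, levels: int = 8) -> np.ndarray:
    """Min-max quantize intensities inside ``mask`` to 1..levels (0 = background)."""
    patch = np.asarray(patch, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if patch.shape != mask.shape:
        raise ValueError("patch and mask shapes differ")
    out = np.zeros(patch.shape, dtype=np.uint8)
    vals = patch[mask]
    if vals.size == 0:
        return out
    lo, hi = vals.min(), vals.max()
    if hi > lo:
        q = np.floor((patch - lo) / (hi - lo) * levels).astype(int)
        q = np.clip(q, 0, levels - 1)
    else:
        q = np.zeros(patch.shape, dtype=int)
    out[mask] = q[mask] + 1
    return out


def masked_glcm(quantized: np.ndarray, levels: int = 8) -> np.ndarray:
    """Per-direction normalized GLCMs, background pairs excluded.

    Returns an array of shape (levels, levels, 4): one symmetric, normalized
    co-occurrence matrix per direction.  Directions whose count matrix is
    empty (e.g. a 1-pixel region) normalize to all zeros.
    """
    counts = graycomatrix(
        quantized, distances=[1], angles=list(_ANGLES),
        levels=levels + 1, symmetric=True, normed=False,
    )[1:, 1:, 0, :].astype(float)
    totals = counts.sum(axis=(0, 1), keepdims=True)
    with np.errstate(invalid="ignore"):
        return np.where(totals > 0, counts / np.where(totals > 0, totals, 1), 0.0)


def _entropy(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def _features_one(p: np.ndarray) -> np.ndarray:
    """The 13 statistics of one normalized co-occurrence matrix."""
    ng = p.shape[0]
    i, j = np.mgrid[0:ng, 0:ng]
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float((np.arange(ng) * px).sum())
    mu_y = float((np.arange(ng) * py).sum())
    sd_x = float(np.sqrt(((np.arange(ng) - mu_x) ** 2 * px).sum()))
    sd_y = float(np.sqrt(((np.arange(ng) - mu_y) ** 2 * py).sum()))

    # p_{x+y}(k), k = 0..2(ng-1) and p_{x-y}(k), k = 0..ng-1
    p_sum = np.zeros(2 * ng - 1)
    np.add.at(p_sum, (i + j).ravel(), p.ravel())
    p_diff = np.zeros(ng)
    np.add.at(p_diff, np.abs(i - j).ravel(), p.ravel())

    asm = float((p ** 2).sum())
    contrast = float((np.arange(ng) ** 2 * p_diff).sum())
    if sd_x > 0 and sd_y > 0:
        correlation = float(((i * j * p).sum() - mu_x * mu_y) / (sd_x * sd_y))
    else:
        correlation = 0.0
    variance = float((((i - mu_x) ** 2) * p).sum())
    idm = float((p / (1.0 + (i - j) ** 2)).sum())
    ks = np.arange(2 * ng - 1)
    sum_average = float((ks * p_sum).sum())
    sum_variance = float(((ks - sum_average) ** 2 * p_sum).sum())
    sum_entropy = _entropy(p_sum)
    entropy = _entropy(p)
    kd = np.arange(ng)
    mu_d = float((kd * p_diff).sum())
    difference_variance = float(((kd - mu_d) ** 2 * p_diff).sum())
    difference_entropy = _entropy(p_diff)

    # information measures of correlation
    pxy = np.outer(px, py)
    nz = (p > 0) & (pxy > 0)
    hxy1 = float(-(p[nz] * np.log(pxy[nz])).sum())
    nz2 = pxy > 0
    hxy2 = float(-(pxy[nz2] * np.log(pxy[nz2])).sum())
    hx, hy = _entropy(px), _entropy(py)
    denom = max(hx, hy)
    imc1 = (entropy - hxy1) / denom if denom > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy)))))

    return np.array([
        asm, contrast, correlation, variance, idm, sum_average, sum_variance,
        sum_entropy, entropy, difference_variance, difference_entropy, imc1, imc2,
    ])


def haralick_features(
    patch: np.ndarray, mask: np.ndarray, levels: int = 8
) -> np.ndarray:
    """13 Haralick statistics of a masked patch, averaged over 4 directions.

    Returns NaNs when no direction yields any co-occurrence pair (degenerate
    regions); callers are expected to drop such cells.
    """
    q = quantize(patch, mask, levels=levels)
    glcms = masked_glcm(q, levels=levels)
    feats = []
    for d in range(glcms.shape[2]):
        p = glcms[:, :, d]
        if p.sum() > 0:
            feats.append(_features_one(p))
    if not feats:
        return np.full(len(HARALICK_NAMES), np.nan)
    return np.mean(feats, axis=0)
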