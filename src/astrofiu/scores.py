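"""Per-pixel neighborhood-correlation z-score maps.

A pixel that belongs to an active unit shares its temporal signal with its
neighbors, so the Pearson correlation between its curve and a neighborhood
summary curve is positive; for background pixels with independent noise it is
zero in expectation. The Fisher z-transform

    z = sqrt(N - 3) * atanh(r)

maps the correlation on N timepoints to an approximately standard-normal
score under the null, giving a variance-stabilized map a region-level test
can consume directly.

Two variants are provided: ``neighbor8`` correlates each pixel with the mean
curve of its eight direct neighbors (robust to noise), and ``directional4``
takes the maximum correlation with the mean of the two opposite neighbors
along each of the four line orientations through the pixel (robust to slow
wave propagation, since pixels on the wavefront through [i, j] stay
synchronized) with a max-of-k null correction

    z = Phi^-1( Phi(F(r))^k ).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.special import log_ndtr, ndtri, ndtri_exp

from .io import VideoStack

logger = logging.getLogger("astrofiu")

#: (di, dj) offsets of the four line orientations (0, 45, 90, 135 degrees).
_DIRECTIONS = ((0, 1), (1, 1), (1, 0), (1, -1))


@dataclass
class ScoreMap:
    """A 2-D per-pixel statistic map with its declared null distribution."""

    values: np.ndarray
    kind: str  # "correlation" (r in [-1, 1]) or "zscore" (~N(0,1) null)
    variant: str  # "neighbor8" or "directional4"
    n_timepoints: int


def fisher_z(r, n_timepoints):
    """Normalized Fisher transform sqrt(N-3) * atanh(r).

    Correlations of exactly +-1 (noise-free duplicates) are nudged inside the
    open interval so the score stays finite.
    """
    r = np.clip(np.asarray(r, dtype=float), -1.0 + 1e-12, 1.0 - 1e-12)
    return np.sqrt(n_timepoints - 3.0) * np.arctanh(r)


def max_of_k_zscore(z, k):
    """Null correction for a max over k (approximately) standard-normal
    scores: Phi^-1(Phi(z)^k), evaluated in log space at both tails.

    For large z, 1 - Phi(z)^k ~ k * (1 - Phi(z)), so the upper tail is
    computed from log survival functions and the result stays finite for any
    finite input."""
    z_in = np.asarray(z, dtype=float)
    z = np.atleast_1d(z_in)
    k = np.broadcast_to(np.asarray(k, dtype=float), z.shape)
    logp = k * log_ndtr(z)  # log Phi(z)^k
    with np.errstate(invalid="ignore", divide="ignore"):
        one_m_p = -np.expm1(logp)  # 1 - Phi^k
        log_sf = np.where(one_m_p > 0, np.log(np.where(one_m_p > 0, one_m_p, 1.0)),
                          -np.inf)
    # expm1 loses precision once Phi^k rounds to 1: switch to the tail form
    tail = logp > -1e-12
    log_sf = np.where(tail, np.log(k) + log_ndtr(-z), log_sf)
    upper = -ndtri_exp(np.minimum(log_sf, 0.0))
    lower = ndtri_exp(np.minimum(logp, 0.0))
    out = np.where(logp > -0.6931471805599453, upper, lower)  # split at Phi^k = 1/2
    return out.reshape(z_in.shape) if z_in.shape else float(out[0])


def stabilize_variance(stack: VideoStack, enabled=True, gain=1.0, offset=0.0):
    """Generalized square-root (Anscombe-type) variance stabilization.

    For Poisson-Gaussian intensities y = gain * Poisson + read noise, the
    transform ``2 * sqrt(y / gain + 3/8 + offset)`` makes the noise
    approximately unit-variance Gaussian (offset absorbs the read-noise term
    (sigma_read / gain)^2). Disabled (the default for synthetic Gaussian
    data) it is the identity.
    """
    if not enabled:
        return stack
    data = stack.data
    if np.any(data < 0):
        raise ValueError("variance stabilization requires nonnegative intensities")
    if gain <= 0:
        raise ValueError("gain must be positive")
    out = 2.0 * np.sqrt(data / gain + 3.0 / 8.0 + offset)
    prov = dict(stack.provenance)
    prov["variance_stabilized"] = {"gain": gain, "offset": offset}
    return VideoStack(out, pixel_size_um=stack.pixel_size_um,
                      frame_interval_s=stack.frame_interval_s, provenance=prov)


def _pearson_maps(a, b):
    """Pixelwise Pearson correlation of two (T, H, W) stacks along axis 0.

    Zero-variance curves yield r = 0 (logged), never NaN.
    """
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    num = np.einsum("tij,tij->ij", a, b)
    va = np.einsum("tij,tij->ij", a, a)
    vb = np.einsum("tij,tij->ij", b, b)
    denom = np.sqrt(va * vb)
    bad = denom == 0
    if bad.any():
        logger.warning("%d zero-variance pixel curves; correlation set to 0", bad.sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(bad, 0.0, num / np.where(bad, 1.0, denom))
    return np.clip(r, -1.0, 1.0)


def _neighbor_mean(data):
    """Mean curve of the 8 in-bounds neighbors of every pixel."""
    kernel = np.ones((1, 3, 3))
    kernel[0, 1, 1] = 0.0
    nsum = ndimage.convolve(data, kernel, mode="constant", cval=0.0)
    count = ndimage.convolve(np.ones(data.shape[1:]), kernel[0],
                             mode="constant", cval=0.0)
    return nsum / count[None, :, :]


def correlation_map(stack: VideoStack, variant="neighbor8"):
    """Neighborhood correlation r_sc per pixel (before the Fisher step)."""
    data = np.asarray(stack.data, dtype=np.float64)
    t, h, w = data.shape
    if t < 10:
        raise ValueError("at least 10 frames required")
    if variant == "neighbor8":
        if h < 3 or w < 3:
            raise ValueError("neighbor8 requires at least a 3x3 field")
        r = _pearson_maps(data, _neighbor_mean(data))
        return ScoreMap(r, kind="correlation", variant=variant, n_timepoints=t), None
    if variant == "directional4":
        if h < 3 or w < 3:
            raise ValueError("directional4 requires at least a 3x3 field")
        r_best = np.full((h, w), -np.inf)
        n_dirs = np.zeros((h, w), dtype=np.int64)
        for di, dj in _DIRECTIONS:
            pair_sum = np.zeros_like(data)
            pair_cnt = np.zeros((h, w))
            for s in (+1, -1):
                src_i = np.clip(np.arange(h) + s * di, 0, h - 1)
                src_j = np.clip(np.arange(w) + s * dj, 0, w - 1)
                ok_i = (np.arange(h) + s * di >= 0) & (np.arange(h) + s * di < h)
                ok_j = (np.arange(w) + s * dj >= 0) & (np.arange(w) + s * dj < w)
                ok = ok_i[:, None] & ok_j[None, :]
                shifted = data[:, src_i][:, :, src_j]
                pair_sum += np.where(ok[None], shifted, 0.0)
                pair_cnt += ok
            avail = pair_cnt > 0
            mean_pair = pair_sum / np.where(avail, pair_cnt, 1.0)
            r_d = _pearson_maps(data, mean_pair)
            r_best = np.where(avail & (r_d > r_best), r_d, r_best)
            n_dirs += avail
        r_best[n_dirs == 0] = 0.0
        return (ScoreMap(r_best, kind="correlation", variant=variant, n_timepoints=t),
                n_dirs)
    raise ValueError(f"unknown variant {variant!r}")


def correlation_zscore_map(stack: VideoStack, variant="neighbor8") -> ScoreMap:
    """Per-pixel z-score map; ~N(0, 1) per pixel under pure noise.

    neighbor8: z = F(r). directional4: z = Phi^-1(Phi(F(r))^k) with k the
    number of in-bounds directions (4 away from the border).
    """
    rmap, n_dirs = correlation_map(stack, variant)
    z = fisher_z(rmap.values, rmap.n_timepoints)
    if variant == "directional4":
        k = np.maximum(n_dirs, 1)
        z = max_of_k_zscore(z, k)
    return ScoreMap(np.asarray(z, dtype=np.float64), kind="zscore",
                    variant=variant, n_timepoints=rmap.n_timepoints)
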