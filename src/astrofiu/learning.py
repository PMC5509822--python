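"""Sequential learning of functionally independent units (FIUs).

Within an active region the model for one unit m is

    Y[i, j, t] = beta0[i, j] + beta_m[i, j] X_m[t - tau_ij] + eps,

with ||X_m||_2 = 1, E[X_m] = 0. The parameters are learned by an alternating
(EM-like) scheme: given X_m, each pixel's integer lag tau is refined by a
correlation scan over a window of half-width ``u_tau`` around the lag of its
BFS predecessor (lags vary smoothly along a propagating wave, so the
predecessor anchors the search); beta is the projection of the lag-aligned,
mean-centered pixel curve onto X_m; sigma0^2 is the mean squared residual.
X_m is then re-estimated as the beta/sigma0^2-weighted sum of aligned curves,
renormalized to unit L2 norm. Iteration stops when
sd(X_new - X_old)/sd(X_new) drops below ``tol``.

Membership of pixels in unit m (vs. latent competing units) is scored by

    z_fit = 1/2 Phi^-1(Phi(F(r_fit))^K) - 1/2 F(r_res)

where r_fit is the best-lag correlation with X_m (max over the K = 2 u_tau + 1
candidate lags, hence the max-of-K null correction), and r_res is the
neighborhood correlation of the pixel's residual signal — residuals of pixels
in a *different* unit share that unit's curve and correlate, so r_res flags
confounders without knowing their curves. The two half-weighted ~N(0,1) terms
give a null variance of 1/2, so the score is rescaled by sqrt(2) to keep the
downstream unit-variance order-statistics test calibrated. The unit's mask is
then extracted by the same order-statistics region growing, and the final
curve is refined as the unnormalized weighted sum over mask pixels only.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator

from .io import VideoStack, RunConfig
from .scores import ScoreMap, correlation_zscore_map, fisher_z, max_of_k_zscore, \
    stabilize_variance
from .regions import grow_regions

logger = logging.getLogger("astrofiu")

_SIGMA2_FLOOR = 1e-12

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f
        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True)
def _scan_pass(curves, order, pred, tau, x, u_tau, self_anchor, lag_penalty):
    """One alternating-update pass over all pixels.

    For each pixel (in BFS ``order``), scans candidate lags around the
    anchor lag (the BFS predecessor's current lag, or the pixel's own lag if
    ``self_anchor``), picking the lag maximizing the correlation of the
    aligned curve with ``x`` (centered, unit-norm), minus ``lag_penalty``
    per frame of deviation from the anchor. The penalty keeps the scan from
    chasing noise at low SNR, where correlation differences between nearby
    lags are far below the noise level of r; a genuine propagation shift
    changes r by much more than the penalty. Updates ``tau`` in place and
    returns (beta, sigma2, r_best, means).
    """
    n, n_t = curves.shape
    beta = np.zeros(n)
    sigma2 = np.zeros(n)
    r_best_arr = np.zeros(n)
    means = np.zeros(n)
    for oi in range(n):
        p = order[oi]
        anchor = tau[p] if self_anchor else tau[pred[p]]
        # the init pixel (BFS root) defines the unit's time origin: its lag
        # stays pinned, which stops the whole lag field from drifting between
        # iterations
        win = 0 if (oi == 0 and not self_anchor) else u_tau
        best_score = -2.0
        best_r = 0.0
        best_s = anchor
        best_b = 0.0
        best_var = 0.0
        best_mean = 0.0
        for dt in range(-win, win + 1):
            s = anchor + dt
            sum_a = 0.0
            sum_a2 = 0.0
            sum_ax = 0.0
            for t in range(n_t):
                ts = t + s
                if ts < 0:
                    ts = 0
                elif ts >= n_t:
                    ts = n_t - 1
                a = curves[p, ts]
                sum_a += a
                sum_a2 += a * a
                sum_ax += a * x[t]
            var_a = sum_a2 - sum_a * sum_a / n_t
            # x is centered and unit-norm: cov = sum_ax, so r = beta/sd(a)
            if var_a > 0:
                r = sum_ax / np.sqrt(var_a)
            else:
                r = 0.0
            score = r - lag_penalty * abs(dt)
            if score > best_score:
                best_score = score
                best_r = r
                best_s = s
                best_b = sum_ax
                best_var = var_a
                best_mean = sum_a / n_t
        tau[p] = best_s
        beta[p] = best_b
        resid = (best_var - best_b * best_b) / n_t
        sigma2[p] = resid if resid > _SIGMA2_FLOOR else _SIGMA2_FLOOR
        r_best_arr[p] = best_r
        means[p] = best_mean
    return beta, sigma2, r_best_arr, means


@njit(cache=True)
def _scan_loo(curves, tau, weights, x_unnorm, u_tau, lag_penalty):
    """Best-lag correlation of each pixel with the *leave-one-out* unit
    curve: the pixel's own weighted contribution is removed from the
    unnormalized curve estimate before correlating. Without this, every
    pixel of a region — even a pure-noise region — correlates positively
    with a curve that contains its own noise, and the membership score's
    null is no longer standard normal."""
    n, n_t = curves.shape
    r_best = np.zeros(n)
    xloo = np.empty(n_t)
    for p in range(n):
        s0 = tau[p]
        m = 0.0
        for t in range(n_t):
            ts = t + s0
            if ts < 0:
                ts = 0
            elif ts >= n_t:
                ts = n_t - 1
            m += curves[p, ts]
        m /= n_t
        for t in range(n_t):
            ts = t + s0
            if ts < 0:
                ts = 0
            elif ts >= n_t:
                ts = n_t - 1
            xloo[t] = x_unnorm[t] - weights[p] * (curves[p, ts] - m)
        xm = 0.0
        for t in range(n_t):
            xm += xloo[t]
        xm /= n_t
        xss = 0.0
        for t in range(n_t):
            xloo[t] -= xm
            xss += xloo[t] * xloo[t]
        if xss <= 0.0:
            r_best[p] = 0.0
            continue
        xnrm = np.sqrt(xss)
        best_r = -1.0
        best_score = -2.0
        for dt in range(-u_tau, u_tau + 1):
            s = s0 + dt
            sum_a = 0.0
            sum_a2 = 0.0
            sum_ax = 0.0
            for t in range(n_t):
                ts = t + s
                if ts < 0:
                    ts = 0
                elif ts >= n_t:
                    ts = n_t - 1
                a = curves[p, ts]
                sum_a += a
                sum_a2 += a * a
                sum_ax += a * xloo[t]
            var_a = sum_a2 - sum_a * sum_a / n_t
            if var_a > 0:
                r = sum_ax / (np.sqrt(var_a) * xnrm)
            else:
                r = 0.0
            score = r - lag_penalty * abs(dt)
            if score > best_score:
                best_score = score
                best_r = r
        r_best[p] = best_r
    return r_best


@njit(cache=True)
def _weighted_sum(curves, tau, weights):
    """sum_k weights[k] * aligned (clamped-shift) raw curve of pixel k."""
    n, n_t = curves.shape
    out = np.zeros(n_t)
    for p in range(n):
        wgt = weights[p]
        if wgt <= 0:
            continue
        s = tau[p]
        for t in range(n_t):
            ts = t + s
            if ts < 0:
                ts = 0
            elif ts >= n_t:
                ts = n_t - 1
            out[t] += wgt * curves[p, ts]
    return out


@dataclass
class FIUModel:
    """One learned unit: curve, per-pixel parameters, mask and features."""

    curve: np.ndarray  # X_m, centered, unit L2 norm
    region_mask: np.ndarray  # pixels the model was fit on
    tau_map: np.ndarray  # int lags, valid on region_mask
    beta_map: np.ndarray
    sigma2_map: np.ndarray
    beta0_map: np.ndarray
    r_fit_map: np.ndarray
    init_pixel: tuple
    u_tau: int
    lag_penalty: float
    n_iter: int
    converged: bool
    weight_map: np.ndarray = None  # final beta/sigma0^2 weights on the region
    curve_unnorm: np.ndarray = None  # last weighted-sum curve before renormalizing
    mask: np.ndarray = None  # final K_m after extraction
    p_value: float = None
    refined_curve: np.ndarray = None  # C_m
    features: dict = field(default_factory=dict)

    @property
    def size(self):
        return int(self.mask.sum()) if self.mask is not None else int(self.region_mask.sum())


def _median_filter_lags(tau, pix, shape, radius=1):
    """In-region median filter of a per-pixel lag vector (rounded)."""
    local = np.full(shape, -1, dtype=np.int64)
    local[pix[:, 0], pix[:, 1]] = np.arange(len(pix))
    h, w = shape
    out = tau.copy()
    span = range(-radius, radius + 1)
    for k, (i, j) in enumerate(pix):
        vals = []
        for di in span:
            for dj in span:
                ni, nj = i + di, j + dj
                if 0 <= ni < h and 0 <= nj < w and local[ni, nj] >= 0:
                    vals.append(tau[local[ni, nj]])
        out[k] = int(round(np.median(vals)))
    return out


def rereference_to_source(model: "FIUModel", mask=None):
    """Shift the model into the unit's own time frame (in place).

    The fitted lags are relative to the init pixel, which itself sits at an
    arbitrary point of the propagating wave; fidelity against a ground-truth
    curve and the spec of tau (source-relative, nonnegative at the source)
    both want the frame of the *earliest* pixel. The reference lag is the
    minimum of the spatially median-filtered lag field over the unit's mask,
    so single-pixel lag jitter cannot drag the time origin.
    """
    mask = model.mask if mask is None else mask
    if mask is None or not mask.any():
        mask = model.region_mask
    pix = np.argwhere(mask)
    tau = model.tau_map[pix[:, 0], pix[:, 1]]
    shift = _robust_min_lag(tau, pix, mask.shape)
    if shift == 0:
        return model
    n_t = model.curve.shape[0]
    reg = model.region_mask
    model.tau_map[reg] = model.tau_map[reg] - shift
    idx = np.clip(np.arange(n_t) - shift, 0, n_t - 1)
    x = model.curve[idx]
    x = x - x.mean()
    nrm = np.linalg.norm(x)
    model.curve = x / nrm if nrm > 0 else x
    if model.curve_unnorm is not None:
        xu = model.curve_unnorm[idx]
        model.curve_unnorm = xu - xu.mean()
    return model


def _robust_min_lag(tau, pix, shape, radius=3):
    """Minimum over pixels of the median lag in each pixel's in-region
    (2*radius+1)^2 neighborhood. The window must be large enough that the
    minimum of the medians does not dig into the lag jitter (a 5x5 median
    keeps the bias of the time origin well under one frame)."""
    local = np.full(shape, -1, dtype=np.int64)
    local[pix[:, 0], pix[:, 1]] = np.arange(len(pix))
    h, w = shape
    best = None
    span = range(-radius, radius + 1)
    for k, (i, j) in enumerate(pix):
        vals = []
        for di in span:
            for dj in span:
                ni, nj = i + di, j + dj
                if 0 <= ni < h and 0 <= nj < w and local[ni, nj] >= 0:
                    vals.append(tau[local[ni, nj]])
        med = np.median(vals)
        if best is None or med < best:
            best = med
    return int(round(best))


def _bfs_order(mask, start):
    """Breadth-first order and predecessor over an 8-connected mask."""
    h, w = mask.shape
    idx_of = -np.ones(mask.sum(), dtype=np.int64)
    pix = np.argwhere(mask)
    flat2local = {(int(i), int(j)): k for k, (i, j) in enumerate(pix)}
    start_local = flat2local[tuple(start)]
    order = np.empty(len(pix), dtype=np.int64)
    pred = np.arange(len(pix), dtype=np.int64)
    seen = np.zeros(len(pix), dtype=bool)
    q = deque([start_local])
    seen[start_local] = True
    cnt = 0
    offs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    while q:
        cur = q.popleft()
        order[cnt] = cur
        cnt += 1
        ci, cj = pix[cur]
        for di, dj in offs:
            nb = flat2local.get((int(ci + di), int(cj + dj)))
            if nb is not None and not seen[nb]:
                seen[nb] = True
                pred[nb] = cur
                q.append(nb)
    if cnt != len(pix):
        raise ValueError("region mask is not connected")
    return pix, order, pred


def fit_characteristic(stack: VideoStack, region_mask, init_zmap, u_tau=5,
                       tol=0.01, max_iter=50, lag_penalty=0.01) -> FIUModel:
    """Learn one unit's characteristic curve and per-pixel parameters.

    ``init_zmap`` supplies the per-pixel z-scores used to pick the
    initialization pixel (the region's largest-z pixel, whose raw curve seeds
    X_m with lag 0). A single-pixel region is legal and returns that pixel's
    normalized curve. Non-convergence at ``max_iter`` is flagged, not raised.
    """
    region_mask = np.asarray(region_mask, dtype=bool)
    if not region_mask.any():
        raise ValueError("empty region")
    zvals = init_zmap.values if isinstance(init_zmap, ScoreMap) else np.asarray(init_zmap)
    data = stack.data
    n_t = data.shape[0]
    masked_z = np.where(region_mask, zvals, -np.inf)
    init = np.unravel_index(np.argmax(masked_z), masked_z.shape)
    pix, order, pred = _bfs_order(region_mask, init)
    curves = np.ascontiguousarray(
        data[:, pix[:, 0], pix[:, 1]].T.astype(np.float64))

    x = curves[order[0]].copy()
    x -= x.mean()
    nrm = np.linalg.norm(x)
    x = x / nrm if nrm > 0 else np.full(n_t, 1.0 / np.sqrt(n_t))
    tau = np.zeros(len(pix), dtype=np.int64)

    converged = False
    n_iter = 0
    beta = sigma2 = r_best = means = None
    weights = np.ones(len(pix))
    x_unnorm = x.copy()
    for n_iter in range(1, max_iter + 1):
        beta, sigma2, r_best, means = _scan_pass(
            curves, order, pred, tau, x, int(u_tau), False, float(lag_penalty))
        # On the first pass X *is* the init pixel's curve, so that pixel's
        # residual is exactly zero and 1/sigma0^2 weighting would freeze X
        # on its noisy curve; start from beta-only weights. Afterwards keep a
        # floor on sigma0^2 (within a unit the noise level varies little, so
        # a pixel claiming far-below-median variance reflects fit bias, not
        # low noise).
        if n_iter == 1:
            weights = np.maximum(beta, 0.0)
        else:
            sigma2 = np.maximum(sigma2, 0.25 * np.median(sigma2))
            weights = np.where(beta > 0, beta / sigma2, 0.0)
        x_new = _weighted_sum(curves, tau, weights)
        if not np.any(weights > 0) or np.linalg.norm(x_new) == 0:
            logger.warning("degenerate curve update; keeping previous estimate")
            break
        x_new -= x_new.mean()
        x_unnorm = x_new.copy()
        x_new = x_new / np.linalg.norm(x_new)
        sd_new = x_new.std()
        delta = (x_new - x).std() / sd_new if sd_new > 0 else 0.0
        x = x_new
        if delta < tol:
            converged = True
            break
    if not converged:
        logger.warning("curve learning did not converge in %d iterations", n_iter)

    # The per-pixel argmax lag carries independent noise-driven jitter of a
    # frame or two at low SNR, which smears the weighted-sum curve like a
    # smoothing kernel. Propagation is spatially smooth (the same continuity
    # assumption that justifies the predecessor-anchored search), so a 3x3
    # in-region median of the lag field removes the jitter; a final +-1
    # re-scan around the filtered value keeps noiseless recovery exact.
    if len(pix) > 1:
        tau = _median_filter_lags(tau, pix, region_mask.shape)
        beta, sigma2, r_best, means = _scan_pass(
            curves, order, pred, tau, x, 1, True, float(lag_penalty))
        sigma2 = np.maximum(sigma2, 0.25 * np.median(sigma2))
        weights = np.where(beta > 0, beta / sigma2, 0.0)
        if np.any(weights > 0):
            x_new = _weighted_sum(curves, tau, weights)
            if np.linalg.norm(x_new) > 0:
                x_new -= x_new.mean()
                x_unnorm = x_new.copy()
                x = x_new / np.linalg.norm(x_new)

    def scatter(vals, dtype=np.float64, fill=0.0):
        out = np.full(region_mask.shape, fill, dtype=dtype)
        out[pix[:, 0], pix[:, 1]] = vals
        return out

    return FIUModel(
        curve=x,
        region_mask=region_mask,
        tau_map=scatter(tau, dtype=np.int64, fill=0),
        beta_map=scatter(beta),
        sigma2_map=scatter(sigma2, fill=1.0),
        beta0_map=scatter(means),
        r_fit_map=scatter(r_best),
        init_pixel=(int(init[0]), int(init[1])),
        u_tau=int(u_tau),
        lag_penalty=float(lag_penalty),
        n_iter=n_iter,
        converged=converged,
        weight_map=scatter(weights),
        curve_unnorm=x_unnorm,
    )


@dataclass
class FitScoreMap:
    """Per-pixel membership score for one unit on the remaining region."""

    values: np.ndarray  # z_fit, NaN outside the region
    r_fit: np.ndarray
    r_res: np.ndarray
    variant: str  # "with_residual" or "without_residual"
    region_mask: np.ndarray


def fit_zscore_map(stack: VideoStack, region_mask, model: FIUModel,
                   variant="with_residual") -> FitScoreMap:
    """Score each region pixel's membership in the modeled unit.

    ``with_residual`` subtracts half the Fisher z of the residual
    neighborhood correlation (and rescales by sqrt(2) for a unit-variance
    null); ``without_residual`` uses the goodness-of-fit term alone.
    """
    region_mask = np.asarray(region_mask, dtype=bool)
    data = stack.data
    n_t = data.shape[0]
    pix = np.argwhere(region_mask)
    n = len(pix)
    curves = np.ascontiguousarray(data[:, pix[:, 0], pix[:, 1]].T.astype(np.float64))
    tau = model.tau_map[pix[:, 0], pix[:, 1]].astype(np.int64).copy()
    order = np.arange(n, dtype=np.int64)
    pred = order
    # beta/beta0 for the residual signals (scan against the fitted curve)
    beta, _sig, _r, means = _scan_pass(
        curves, order, pred, tau.copy(), model.curve, int(model.u_tau), True,
        model.lag_penalty)
    # membership correlation: leave-one-out, so a pixel is never scored
    # against a curve containing its own noise
    w = model.weight_map[pix[:, 0], pix[:, 1]]
    r_fit = _scan_loo(curves, tau, w, model.curve_unnorm, int(model.u_tau),
                      model.lag_penalty)

    # residual signals in the original (unshifted) time frame
    t_idx = np.arange(n_t)
    resid = np.empty_like(curves)
    for k in range(n):
        xs = model.curve[np.clip(t_idx - tau[k], 0, n_t - 1)]
        resid[k] = curves[k] - means[k] - beta[k] * xs
    local = -np.ones(region_mask.shape, dtype=np.int64)
    local[pix[:, 0], pix[:, 1]] = np.arange(n)
    h, w = region_mask.shape
    r_res = np.zeros(n)
    n_zero_var = 0
    offs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    for k, (i, j) in enumerate(pix):
        acc = None
        cnt = 0
        for di, dj in offs:
            ni, nj = i + di, j + dj
            if 0 <= ni < h and 0 <= nj < w and local[ni, nj] >= 0:
                nbres = resid[local[ni, nj]]
                acc = nbres if acc is None else acc + nbres
                cnt += 1
        if cnt == 0:
            continue
        a = resid[k] - resid[k].mean()
        b = acc / cnt
        b = b - b.mean()
        denom = np.sqrt((a @ a) * (b @ b))
        if denom == 0:
            n_zero_var += 1
            continue
        r_res[k] = np.clip(a @ b / denom, -1.0, 1.0)
    if n_zero_var:
        logger.warning("%d zero-variance residual curves; r_res set to 0", n_zero_var)

    k_lags = 2 * int(model.u_tau) + 1
    z_fit_term = max_of_k_zscore(fisher_z(r_fit, n_t), k_lags)
    if variant == "with_residual":
        z = (0.5 * z_fit_term - 0.5 * fisher_z(r_res, n_t)) * np.sqrt(2.0)
    elif variant == "without_residual":
        z = z_fit_term
    else:
        raise ValueError(f"unknown variant {variant!r}")
    values = np.full(region_mask.shape, np.nan)
    values[pix[:, 0], pix[:, 1]] = z
    return FitScoreMap(
        values=values,
        r_fit=_scatter_nan(r_fit, pix, region_mask.shape),
        r_res=_scatter_nan(r_res, pix, region_mask.shape),
        variant=variant,
        region_mask=region_mask,
    )


def _scatter_nan(vals, pix, shape):
    out = np.full(shape, np.nan)
    out[pix[:, 0], pix[:, 1]] = vals
    return out


def extract_fiu(zmap: FitScoreMap, alpha=0.05, min_size=4):
    """Grow the unit's mask on the membership z-map, seeded at its maximum.

    Returns (mask, p_value); the caller decides whether p is significant.
    """
    z = np.where(zmap.region_mask, np.nan_to_num(zmap.values, nan=-np.inf), -np.inf)
    z[~zmap.region_mask] = 0.0  # value irrelevant; excluded by mask
    # coverage-oriented state rule: within an active region every pixel is a
    # candidate member, the significance profile is a broad plateau, and
    # under-segmentation (not a noise rim) is the failure mode to avoid
    regions = grow_regions(z, alpha=alpha, min_size=min_size,
                           mask=zmap.region_mask, max_regions=1, force_seed=True,
                           patience=5, rel_tol=0.02)
    return regions[0]


def refine_curve(stack: VideoStack, model: FIUModel, mask=None):
    """Final characteristic curve C_m: the unnormalized beta/sigma0^2-weighted
    sum of lag-aligned raw pixel curves over the unit's mask only."""
    mask = model.mask if mask is None else np.asarray(mask, dtype=bool)
    if mask is None or not mask.any():
        raise ValueError("unit mask is empty")
    pix = np.argwhere(mask)
    curves = np.ascontiguousarray(
        stack.data[:, pix[:, 0], pix[:, 1]].T.astype(np.float64))
    beta = model.beta_map[pix[:, 0], pix[:, 1]]
    sigma2 = model.sigma2_map[pix[:, 0], pix[:, 1]]
    tau = model.tau_map[pix[:, 0], pix[:, 1]].astype(np.int64)
    sigma2 = np.maximum(sigma2, 0.25 * np.median(sigma2))
    weights = np.where(beta > 0, beta / np.maximum(sigma2, _SIGMA2_FLOOR), 0.0)
    if not np.any(weights > 0):
        weights = np.ones_like(weights)
    return _weighted_sum(curves, tau, weights)


def activity_pvalue(score_map: ScoreMap, mask):
    """One-sided p-value that the masked pixels carry any activity at all on
    the neighborhood-correlation z-map: mean z against N(0, 1/n).

    Used as a secondary acceptance veto for extracted units. The membership
    score's null is optimistically calibrated (the iterated lag search gives
    each pixel more freedom than its max-of-K correction models), so a unit
    carved out of a noise region that slipped past the active-region test
    can look spuriously significant there — but its pixels still have
    near-zero activity scores, while any genuine unit's are strongly
    positive. The unconditional test is the right form here: the question is
    whether the scores are compatible with pure noise, not whether they beat
    their own rank expectation.
    """
    from scipy.stats import norm
    z = score_map.values if isinstance(score_map, ScoreMap) else np.asarray(score_map)
    vals = z[np.asarray(mask, dtype=bool)]
    return float(norm.sf(vals.mean() * np.sqrt(vals.size)))


def _best_lag_correlation(a, b, max_lag):
    """Max Pearson correlation of two curves over integer shifts; returns
    (correlation, shift applied to ``b``)."""
    n = len(a)
    best = (-1.0, 0)
    for lag in range(-max_lag, max_lag + 1):
        idx = np.clip(np.arange(n) + lag, 0, n - 1)
        r = np.corrcoef(a, b[idx])[0, 1]
        if r > best[0]:
            best = (float(r), lag)
    return best


def merge_matching_units(stack, fius, min_corr=0.9, max_lag=10):
    """Merge spatially adjacent units whose refined curves match.

    A functionally independent unit is *defined* as a connected pixel group
    sharing one characteristic temporal pattern up to per-pixel lags; the
    sequential search can occasionally split one unit into adjacent pieces
    (each significant on its own). Pieces whose refined curves correlate
    above ``min_corr`` at the best relative lag are therefore one unit and
    are re-joined, keeping the larger piece's model and splicing the other
    piece's per-pixel parameters (lags shifted by the relative lag). Curves
    of genuinely distinct units correlate far below the threshold, so true
    neighbors are never merged.
    """
    fius = list(fius)
    merged = True
    while merged:
        merged = False
        for i in range(len(fius)):
            for j in range(i + 1, len(fius)):
                a, b = fius[i], fius[j]
                big, small = (a, b) if a.mask.sum() >= b.mask.sum() else (b, a)
                touch = ndimage.binary_dilation(
                    big.mask, structure=np.ones((3, 3))) & small.mask
                if not touch.any():
                    continue
                r, lag = _best_lag_correlation(
                    big.refined_curve, small.refined_curve, max_lag)
                if r < min_corr:
                    continue
                sm = small.mask
                big.mask = big.mask | sm
                # small's aligned curves satisfy Y[t + tau_small] ~ C_small(t)
                # and C_small(t + lag) ~ C_big(t), so splice with tau + lag
                big.tau_map[sm] = small.tau_map[sm] + lag
                big.beta_map[sm] = small.beta_map[sm]
                big.sigma2_map[sm] = small.sigma2_map[sm]
                big.beta0_map[sm] = small.beta0_map[sm]
                big.weight_map[sm] = small.weight_map[sm]
                big.region_mask = big.region_mask | small.region_mask
                big.p_value = min(big.p_value, small.p_value)
                big.refined_curve = refine_curve(stack, big)
                fius[i] = big
                fius.pop(j)
                merged = True
                break
            if merged:
                break
    return fius


def _components(mask, min_size=1):
    lab, n = ndimage.label(mask, structure=np.ones((3, 3)))
    out = []
    for k in range(1, n + 1):
        comp = lab == k
        if comp.sum() >= min_size:
            out.append(comp)
    return out


class FIUDetector(BaseEstimator):
    """End-to-end detector of functionally independent Ca2+ units.

    ``fit`` runs the full pipeline on a movie: (optional) variance
    stabilization, the neighborhood-correlation z-score map, order-statistics
    region growing into active regions, then per region a sequential loop —
    learn one unit's curve on the remaining pixels, score membership, extract
    the unit's mask, accept it if significant and repeat until no significant
    unit remains. The number of units is emergent from the significance
    threshold ``alpha``, never pre-specified.

    Parameters mirror :class:`~astrofiu.io.RunConfig`; see the package
    documentation for their meaning and defaults.

    Attributes
    ----------
    score_map_ : ScoreMap
        The pixel z-score map (module-1 statistic).
    active_regions_ : list of (mask, p_value)
    active_mask_ : ndarray of bool
    fius_ : list of FIUModel
        Accepted units with final masks, p-values and refined curves.
    labels_ : ndarray
        Unit label map, 0 = background.
    n_fius_ : int
    """

    def __init__(self, score_variant="neighbor8", stabilize=False,
                 stabilize_gain=1.0, stabilize_offset=0.0,
                 seed_threshold=2.0, alpha=0.05, u_tau=5, tol=0.01,
                 max_iter=50, min_size=4, use_residual=True,
                 lag_penalty=0.01, merge_min_corr=0.9, max_units=None):
        self.score_variant = score_variant
        self.stabilize = stabilize
        self.stabilize_gain = stabilize_gain
        self.stabilize_offset = stabilize_offset
        self.seed_threshold = seed_threshold
        self.alpha = alpha
        self.u_tau = u_tau
        self.tol = tol
        self.max_iter = max_iter
        self.min_size = min_size
        self.use_residual = use_residual
        self.lag_penalty = lag_penalty
        self.merge_min_corr = merge_min_corr
        self.max_units = max_units

    def fit(self, stack, y=None):
        if not isinstance(stack, VideoStack):
            stack = VideoStack(np.asarray(stack))
        stack.validate_for_analysis()
        if self.stabilize:
            stack = stabilize_variance(stack, enabled=True,
                                       gain=self.stabilize_gain,
                                       offset=self.stabilize_offset)
        self.score_map_ = correlation_zscore_map(stack, variant=self.score_variant)
        self.active_regions_ = grow_regions(
            self.score_map_, alpha=self.alpha,
            seed_threshold=self.seed_threshold, min_size=self.min_size)
        shape = self.score_map_.values.shape
        self.active_mask_ = np.zeros(shape, dtype=bool)
        for m, _ in self.active_regions_:
            self.active_mask_ |= m

        variant = "with_residual" if self.use_residual else "without_residual"
        fius = []
        # the active-region map is the union of all grown regions; the
        # sequential unit search runs per connected component of that union
        queue = _components(self.active_mask_, min_size=self.min_size)
        while queue:
            comp = queue.pop(0)
            if comp.sum() < self.min_size:
                continue
            if self.max_units is not None and len(fius) >= self.max_units:
                break
            model = fit_characteristic(
                stack, comp, self.score_map_, u_tau=self.u_tau,
                tol=self.tol, max_iter=self.max_iter,
                lag_penalty=self.lag_penalty)
            fmap = fit_zscore_map(stack, comp, model, variant=variant)
            mask, p = extract_fiu(fmap, alpha=self.alpha, min_size=self.min_size)
            if p <= self.alpha and mask.any():
                if (mask.sum() >= self.min_size
                        and activity_pvalue(self.score_map_, mask) <= self.alpha):
                    model.mask = mask
                    model.p_value = p
                    rereference_to_source(model)
                    model.refined_curve = refine_curve(stack, model)
                    fius.append(model)
                # significant but under-sized extractions are removed without
                # being reported, so the search can continue in the remainder
                queue = _components(comp & ~mask, min_size=self.min_size) + queue
            # else: no significant unit left in this component; stop searching it
        if self.merge_min_corr and self.merge_min_corr < 1.0:
            fius = merge_matching_units(stack, fius,
                                        min_corr=self.merge_min_corr,
                                        max_lag=2 * self.u_tau)
        self.fius_ = fius
        self.labels_ = np.zeros(shape, dtype=np.int64)
        for k, f in enumerate(fius, start=1):
            self.labels_[f.mask] = k
        self.n_fius_ = len(fius)
        return self

    def fit_predict(self, stack, y=None):
        return self.fit(stack).labels_


def detect_fius(stack: VideoStack, config: RunConfig = None, **overrides):
    """Functional wrapper over :class:`FIUDetector`; returns the fitted
    detector's list of accepted units."""
    config = config or RunConfig()
    det = FIUDetector(
        score_variant=config.score_variant, stabilize=config.stabilize,
        stabilize_gain=config.stabilize_gain,
        stabilize_offset=config.stabilize_offset,
        seed_threshold=config.seed_threshold, alpha=config.alpha,
        u_tau=config.u_tau, tol=config.tol, max_iter=config.max_iter,
        min_size=config.min_size, use_residual=config.use_residual,
        **overrides)
    det.fit(stack)
    return det.fius_
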