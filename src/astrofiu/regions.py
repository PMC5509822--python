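"""Order-statistics-guided region growing on z-score maps.

A candidate region C is scored by its mean pixel z-score s(C). Because the
procedure *selects* — the seed is the maximal unsearched pixel and growth
attaches the highest-scoring frontier pixels — the pixels in C are not an
i.i.d. sample under the null: they are order statistics of the pooled sample
A (current region) plus B (the surrounding unsearched pixels, i.e. the whole
remaining search sample; attachment candidates are still restricted to the
direct neighbors of A). The null mean and variance of s(C) are taken from
the asymptotic theory of linear combinations of normal order statistics.
With J[k] the 0-based ascending rank of C's k-th pixel within A u B,
n = |A| + |B| and v_k = (J[k] + 0.5)/n:

    E[S(C)]   = (1/n_C) sum_k Phi^-1(v_k)
    Var(S(C)) = (1/(n_C^2 n)) sum_{k1,k2} v_(k1)(1 - v_(k2))
                / ( phi(Phi^-1(v_(k1))) phi(Phi^-1(v_(k2))) ),   v_(k1) <= v_(k2)

i.e. the covariance Cov(X_(r), X_(s)) ~ v_r(1 - v_s)/(n phi_r phi_s) of
normal order statistics summed into the variance of the mean (validated
against a Monte-Carlo oracle in the test suite). The region significance is
z_region = (s(C) - E)/sqrt(Var), with a one-sided (right-tail) p-value.

Growth is greedy: the frontier is sorted by z descending and the prefix that
maximizes z_region is attached, terminating at the significance maximum.
A central-limit-theorem moments variant (E = 0, Var = 1/n_C), which ignores
the selection effect and is anti-conservative, is available behind a flag for
comparison.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.special import ndtri
from scipy.stats import norm
from sklearn.base import BaseEstimator

from .scores import ScoreMap

logger = logging.getLogger("astrofiu")

_SQRT2PI = np.sqrt(2.0 * np.pi)


def region_score(zmap, region):
    """Mean z-score over a pixel set (boolean mask or (n, 2) index array)."""
    z = zmap.values if isinstance(zmap, ScoreMap) else np.asarray(zmap)
    if isinstance(region, np.ndarray) and region.dtype == bool:
        vals = z[region]
    else:
        region = np.asarray(region)
        vals = z[region[:, 0], region[:, 1]]
    if vals.size == 0:
        raise ValueError("region must be nonempty")
    return float(vals.mean())


def plotting_positions(ranks, n_total, position="blom"):
    """Probability points v_k for 0-based ranks in a sample of ``n_total``.

    ``"blom"`` — (J + 0.625)/(n + 0.25), Blom's approximation to expected
    normal order statistics, accurate into the extreme ranks (the default:
    the null mean of a selected region then matches a brute-force
    order-statistics oracle closely). ``"hazen"`` — (J + 0.5)/n, the
    midpoint position; simpler but overestimates the extreme-rank
    expectations, which makes the region test noticeably conservative for
    weak regions.
    """
    ranks = np.asarray(ranks, dtype=float)
    if position == "blom":
        return (ranks + 0.625) / (n_total + 0.25)
    if position == "hazen":
        return (ranks + 0.5) / n_total
    raise ValueError(f"unknown plotting position {position!r}")


def null_moments(ranks, n_total, position="blom"):
    """Null mean and variance of the mean z over a rank-selected subset.

    Parameters
    ----------
    ranks : array of int
        Distinct 0-based ascending ranks of the subset's pixels within the
        pooled sample of size ``n_total``.
    n_total : int
        Size of the pooled sample the ranks refer to.
    position : str
        Plotting position for the probability points (see
        :func:`plotting_positions`).
    """
    ranks = np.asarray(ranks)
    if ranks.size == 0:
        raise ValueError("empty rank vector")
    if len(np.unique(ranks)) != ranks.size:
        raise ValueError("ranks must be distinct")
    if ranks.min() < 0 or ranks.max() >= n_total:
        raise ValueError("ranks out of range for n_total")
    v = plotting_positions(np.sort(ranks), n_total, position)
    q = ndtri(v)
    phi = np.exp(-0.5 * q * q) / _SQRT2PI
    u = v / phi
    w = (1.0 - v) / phi
    n_c = ranks.size
    mean = q.mean()
    # sum over ordered pairs v_i <= v_j of u_i * w_j; diagonal once, rest twice
    t_incl = np.sum(w * np.cumsum(u))
    diag = np.sum(u * w)
    var = (2.0 * t_incl - diag) / (n_c * n_c * n_total)
    return float(mean), float(var)


def _neighbor_table(shape, connectivity=8):
    """(n_pix, 8) flat-index neighbor table, -1 where out of bounds."""
    h, w = shape
    if connectivity == 8:
        offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        offsets = [(-1, 0), (0, -1), (0, 1), (1, 0)]
    ii, jj = np.indices(shape)
    table = np.full((h * w, len(offsets)), -1, dtype=np.int64)
    for k, (di, dj) in enumerate(offsets):
        ni, nj = ii + di, jj + dj
        ok = (ni >= 0) & (ni < h) & (nj >= 0) & (nj < w)
        table[:, k] = np.where(ok, ni * w + nj, -1).ravel()
    return table


def _rank_in_pool(z, idx):
    """0-based ascending ranks of z[idx], ties broken by flat index."""
    order = np.lexsort((idx, z[idx]))
    ranks = np.empty(idx.size, dtype=np.int64)
    ranks[order] = np.arange(idx.size)
    return ranks


class _Grower:
    """One map's growing machinery: shared neighbor table and z array."""

    def __init__(self, z2d, available=None, use_order_statistics=True,
                 patience=8, rel_tol=0.0, position="blom"):
        self.patience = patience
        self.rel_tol = rel_tol
        self.position = position
        self.shape = z2d.shape
        self.z = np.asarray(z2d, dtype=np.float64).ravel()
        if not np.all(np.isfinite(self.z[available.ravel() if available is not None
                                         else slice(None)])):
            raise ValueError("z-score map contains non-finite values")
        self.nbr = _neighbor_table(self.shape)
        self.available = (np.ones(self.z.size, dtype=bool) if available is None
                          else np.asarray(available, dtype=bool).ravel().copy())
        self.searched = ~self.available
        self.use_os = use_order_statistics

    def grow_from(self, seed):
        """Grow one region from a flat seed index; marks its pixels searched.

        The null sample for the rank bookkeeping is the entire pool of
        unsearched pixels at the start of the round (so seeding at the pool
        maximum and preferring high-z frontier pixels are both modeled as
        order-statistic selection). Attachment candidates are the direct
        8-neighbors of the region; at each step the frontier is sorted by
        rank descending and the prefix maximizing z_region is attached. The
        search stops at the significance maximum: because the significance
        profile of a real unit is typically a broad plateau (adding a
        genuine member barely moves an already-huge z), growth continues
        while z stays within ``rel_tol`` of the best value seen (with
        ``patience`` extra steps across dips) and the region is truncated
        back to the *largest* state within tolerance of the maximum. On a
        noise map the profile falls steeply, so this reduces to stopping at
        the first maximum.

        Returns (flat indices of the region, final region z-score).
        """
        z = self.z
        pool = np.where(self.available)[0]
        n_total = pool.size
        ranks = _rank_in_pool(z, pool)
        # per-pixel order-statistics ingredients, addressed by flat index
        rank_of = np.full(z.size, -1, dtype=np.int64)
        rank_of[pool] = ranks
        if self.use_os:
            v = plotting_positions(ranks, n_total, self.position)
            q_pix = np.zeros(z.size)
            u_pix = np.zeros(z.size)
            w_pix = np.zeros(z.size)
            qs = ndtri(v)
            phis = np.exp(-0.5 * qs * qs) / _SQRT2PI
            q_pix[pool] = qs
            u_pix[pool] = v / phis
            w_pix[pool] = (1.0 - v) / phis
        # in_a indexed by rank position for O(n) cumulative sums per step
        in_a_rank = np.zeros(n_total, dtype=bool)
        u_rank = np.zeros(n_total)
        w_rank = np.zeros(n_total)
        if self.use_os:
            u_rank[ranks] = v / phis
            w_rank[ranks] = (1.0 - v) / phis

        in_a = np.zeros(z.size, dtype=bool)
        in_b = np.zeros(z.size, dtype=bool)
        a_list = [seed]
        in_a[seed] = True
        in_a_rank[rank_of[seed]] = True
        frontier = []
        for nb in self.nbr[seed]:
            if nb >= 0 and self.available[nb] and not in_a[nb]:
                in_b[nb] = True
                frontier.append(int(nb))

        def moments_of_a():
            n_a = len(a_list)
            a_idx = np.fromiter(a_list, dtype=np.int64)
            s_z = z[a_idx].sum()
            if not self.use_os:
                return s_z / np.sqrt(n_a)
            s_q = q_pix[a_idx].sum()
            u_a = np.where(in_a_rank, u_rank, 0.0)
            cum_u = np.cumsum(u_a)
            t_a = np.sum(w_rank[in_a_rank] * cum_u[in_a_rank])
            d_a = np.sum(u_pix[a_idx] * w_pix[a_idx])
            var_a = (2.0 * t_a - d_a) / (n_a * n_a * n_total)
            return (s_z - s_q) / n_a / np.sqrt(var_a)

        z_cur = moments_of_a()
        best_z = z_cur
        states = [(1, z_cur)]  # (region size, z) along the growth path
        since_good = 0
        while frontier and since_good < self.patience:
            n_a = len(a_list)
            b_idx = np.fromiter(frontier, dtype=np.int64)
            rb = rank_of[b_idx]
            b_order = np.argsort(-rb)  # rank descending == z desc, ties row-major
            b_idx = b_idx[b_order]
            rb = rb[b_order]
            n_b = b_idx.size
            n_c = n_a + np.arange(1, n_b + 1)
            s_z_a = z[np.fromiter(a_list, dtype=np.int64)].sum()
            s_z = s_z_a + np.cumsum(z[b_idx])
            if self.use_os:
                u_a = np.where(in_a_rank, u_rank, 0.0)
                w_a = np.where(in_a_rank, w_rank, 0.0)
                cum_u_a = np.cumsum(u_a)
                cum_w_a = np.cumsum(w_a)
                tot_w_a = cum_w_a[-1]
                t_a = np.sum(w_rank[in_a_rank] * cum_u_a[in_a_rank])
                a_idx_arr = np.fromiter(a_list, dtype=np.int64)
                d_a = np.sum(u_pix[a_idx_arr] * w_pix[a_idx_arr])
                s_q_a = q_pix[a_idx_arr].sum()
                u_f, w_f, q_f = u_pix[b_idx], w_pix[b_idx], q_pix[b_idx]
                u_below = cum_u_a[rb]  # A-ranks below rb (rb itself not in A)
                w_above = tot_w_a - cum_w_a[rb]
                w_f_before = np.concatenate(([0.0], np.cumsum(w_f)[:-1]))
                t_add = u_f * w_f + w_f * u_below + u_f * (w_above + w_f_before)
                t_p = t_a + np.cumsum(t_add)
                d_p = d_a + np.cumsum(u_f * w_f)
                s_q = s_q_a + np.cumsum(q_f)
                var_p = (2.0 * t_p - d_p) / (n_c * n_c * n_total)
                z_p = (s_z - s_q) / n_c / np.sqrt(var_p)
            else:
                z_p = s_z / np.sqrt(n_c)
            best = int(np.argmax(z_p))
            z_cur = float(z_p[best])
            newly = b_idx[: best + 1]
            in_a[newly] = True
            in_b[newly] = False
            in_a_rank[rank_of[newly]] = True
            frontier = [p for p in frontier if in_b[p]]
            for p in newly:
                a_list.append(int(p))
                for nb in self.nbr[p]:
                    if nb >= 0 and self.available[nb] and not in_a[nb] and not in_b[nb]:
                        in_b[nb] = True
                        frontier.append(int(nb))
            states.append((len(a_list), z_cur))
            best_z = max(best_z, z_cur)
            if z_cur >= best_z - self.rel_tol * abs(best_z):
                since_good = 0
            else:
                since_good += 1
        tol = self.rel_tol * abs(best_z)
        best_size, z_final = max(
            (s for s in states if s[1] >= best_z - tol), key=lambda s: s[0])
        # truncate to that state (a_list records growth order)
        region = np.fromiter(a_list[:best_size], dtype=np.int64)
        self.available[region] = False
        self.searched[region] = True
        return region, float(z_final), len(states)


def grow_regions(zmap, alpha=0.05, seed_threshold=2.0, min_size=4,
                 mask=None, max_regions=None, use_order_statistics=True,
                 force_seed=False, patience=8, rel_tol=0.0):
    """Segment a z-score map into significant connected regions.

    Repeatedly seeds at the unsearched pixel of maximal z (required to exceed
    ``seed_threshold`` unless ``force_seed``), grows greedily to the
    significance maximum, and emits the region when its one-sided p-value is
    <= ``alpha`` and its size >= ``min_size``. Emitted regions are disjoint
    and 8-connected; ties are broken by row-major index, so the output is
    independent of memory layout. An all-noise map yields an empty list.

    Parameters
    ----------
    zmap : ScoreMap or 2-D array
    mask : 2-D bool array, optional
        Restrict seeding and growth to these pixels.
    max_regions : int, optional
        Stop after this many emitted regions (used for single-unit extraction).
    use_order_statistics : bool
        If False, use central-limit moments (anti-conservative; for
        comparison only).
    force_seed : bool
        Grow from the maximal pixel even if it is below ``seed_threshold``.

    Returns
    -------
    list of (mask, p_value)
        ``mask`` is a 2-D boolean array; ``p_value`` the region's one-sided
        p-value.
    """
    z2d = zmap.values if isinstance(zmap, ScoreMap) else np.asarray(zmap)
    grower = _Grower(z2d, available=mask, use_order_statistics=use_order_statistics,
                     patience=patience, rel_tol=rel_tol)
    out = []
    h, w = z2d.shape
    zflat = grower.z
    while True:
        remaining = np.where(grower.available)[0]
        if remaining.size == 0:
            break
        seed = remaining[np.argmax(zflat[remaining])]
        if not force_seed and not zflat[seed] > seed_threshold:
            break
        region, z_region, n_states = grower.grow_from(int(seed))
        # the reported state was selected as the best of the states visited
        # along the growth path: a union bound over them keeps the
        # region-level test honest (real regions sit orders of magnitude
        # below alpha, so this costs essentially no power)
        p = float(min(1.0, n_states * norm.sf(z_region)))
        if force_seed or (p <= alpha and region.size >= min_size):
            m = np.zeros(h * w, dtype=bool)
            m[region] = True
            out.append((m.reshape(h, w), p))
        if max_regions is not None and len(out) >= max_regions:
            break
        if force_seed:
            # single-extraction mode only ever grows one region
            break
    return out


def regions_to_labels(regions, shape):
    """Label map from a list of (mask, p) pairs; 0 = background."""
    labels = np.zeros(shape, dtype=np.int64)
    for k, (m, _) in enumerate(regions, start=1):
        labels[m] = k
    return labels


class RegionGrower(BaseEstimator):
    """Binarize a z-score map into statistically significant regions.

    scikit-learn-style estimator: ``fit`` consumes a 2-D z-score map (or
    :class:`~astrofiu.scores.ScoreMap`) and exposes the segmentation through
    fitted attributes.

    Parameters
    ----------
    alpha : float
        Region-level significance threshold (one-sided).
    seed_threshold : float
        Minimum pixel z to start a region ("qualified" seed).
    min_size : int
        Minimum emitted region size in pixels.
    use_order_statistics : bool
        Order-statistics null moments (default) vs. central-limit moments.

    Attributes
    ----------
    regions_ : list of (mask, p_value)
    labels_ : ndarray
        Integer label map, 0 = background.
    active_mask_ : ndarray of bool
        Union of emitted regions.
    p_values_ : list of float
    """

    def __init__(self, alpha=0.05, seed_threshold=2.0, min_size=4,
                 use_order_statistics=True, patience=8, rel_tol=0.0):
        self.alpha = alpha
        self.seed_threshold = seed_threshold
        self.min_size = min_size
        self.use_order_statistics = use_order_statistics
        self.patience = patience
        self.rel_tol = rel_tol

    def fit(self, zmap, mask=None):
        z2d = zmap.values if isinstance(zmap, ScoreMap) else np.asarray(zmap)
        self.regions_ = grow_regions(
            z2d, alpha=self.alpha, seed_threshold=self.seed_threshold,
            min_size=self.min_size, mask=mask,
            use_order_statistics=self.use_order_statistics,
            patience=self.patience, rel_tol=self.rel_tol,
        )
        self.labels_ = regions_to_labels(self.regions_, z2d.shape)
        self.active_mask_ = self.labels_ > 0
        self.p_values_ = [p for _, p in self.regions_]
        return self

    def fit_predict(self, zmap, mask=None):
        return self.fit(zmap, mask=mask).labels_
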