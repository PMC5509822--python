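"""Detection, curve and binarization metrics against ground truth.

Unit-level rules:

* recall — a ground-truth unit is *detected* when some reported unit covers
  more than 50% of its area;
* precision — a reported unit is *true* when it covers >50% of exactly the
  one ground-truth unit it matches and does not cover more than 10% of the
  area of any other ground-truth unit; when several reported units satisfy
  this for the same ground-truth unit, only the one with the largest overlap
  counts as the correct detection (the others are false);
* area accuracy — for each correct detection, the fraction of the matched
  ground-truth unit covered by the reported unit;
* fidelity — Pearson correlation between a learned curve and the matched
  ground-truth characteristic curve (offset/scale-free).

Pixel-level (binarization) metrics compare a predicted foreground mask with
the true active mask: misclassification rate (FP+FN)/total, recall, precision,
F-measure, and the missing-pixel rate FN/(TP+FN). A right-tailed per-pixel
test (z > Phi^-1(0.95)) is provided as the pixel-level baseline binarizer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.stats import norm

logger = logging.getLogger("astrofiu")


@dataclass
class MetricsReport:
    """Container for detection and/or binarization metrics of one run."""

    recall: float = None
    precision: float = None
    mean_fidelity: float = None
    fidelities: list = field(default_factory=list)
    area_accuracies: list = field(default_factory=list)
    matches: list = field(default_factory=list)  # (reported idx, truth idx)
    misclassification: float = None
    pixel_recall: float = None
    pixel_precision: float = None
    f_measure: float = None
    missing_pixel_rate: float = None
    n_truth: int = 0
    n_reported: int = 0
    n_detected: int = 0
    n_correct: int = 0
    metadata: dict = field(default_factory=dict)

    def to_dict(self):
        return asdict(self)


def _overlap_matrix(reported, truth):
    """overlap[r, g] = |reported_r & truth_g| in pixels."""
    n_r, n_g = len(reported), len(truth)
    out = np.zeros((n_r, n_g), dtype=np.int64)
    for r, rm in enumerate(reported):
        for g, gm in enumerate(truth):
            out[r, g] = np.count_nonzero(rm & gm)
    return out


def detection_metrics(reported_masks, truth_masks) -> MetricsReport:
    """Unit-level recall, precision, matches and area accuracy.

    Parameters are lists of boolean masks on a common grid. Metrics are
    invariant to the ordering (relabeling) of either list.
    """
    rep = MetricsReport()
    n_r, n_g = len(reported_masks), len(truth_masks)
    rep.n_truth, rep.n_reported = n_g, n_r
    if n_g == 0:
        rep.recall = np.nan
        rep.precision = 0.0 if n_r else np.nan
        return rep
    overlap = _overlap_matrix(reported_masks, truth_masks)
    g_area = np.array([m.sum() for m in truth_masks], dtype=float)

    covered = overlap > 0.5 * g_area[None, :]  # reported r covers >50% of g
    rep.n_detected = int(covered.any(axis=0).sum())
    rep.recall = float(np.mean(covered.any(axis=0)))

    if n_r == 0:
        rep.precision = np.nan
        rep.mean_fidelity = np.nan
        return rep

    # candidate true detections: >50% of one truth, <=10% of every other
    spills = overlap > 0.10 * g_area[None, :]
    correct = np.zeros(n_r, dtype=bool)
    claimed = {}
    for r in range(n_r):
        gs = np.where(covered[r])[0]
        if gs.size != 1:
            continue
        g = int(gs[0])
        if np.any(spills[r] & (np.arange(n_g) != g)):
            continue
        # one correct detection per truth unit: keep the largest overlap
        if g not in claimed or overlap[r, g] > overlap[claimed[g], g]:
            claimed[g] = r
    for g, r in claimed.items():
        correct[r] = True
        rep.matches.append((r, g))
        rep.area_accuracies.append(float(overlap[r, g] / g_area[g]))
    rep.n_correct = int(correct.sum())
    rep.precision = float(correct.mean())
    rep.matches.sort()
    return rep


def curve_fidelity(learned, truth, lag_compensate=False, max_lag=None):
    """Pearson correlation between a learned and a true curve.

    With ``lag_compensate`` the maximum correlation over integer shifts up to
    ``max_lag`` (default: a quarter of the curve) is returned instead.
    Zero-variance input yields NaN (excluded from fidelity means).
    """
    a = np.asarray(learned, dtype=float)
    b = np.asarray(truth, dtype=float)
    if a.shape != b.shape:
        raise ValueError("curves must have equal length")
    if a.std() == 0 or b.std() == 0:
        return np.nan
    if not lag_compensate:
        return float(np.corrcoef(a, b)[0, 1])
    max_lag = max_lag or len(a) // 4
    best = -1.0
    n = len(a)
    for lag in range(-max_lag, max_lag + 1):
        idx = np.clip(np.arange(n) + lag, 0, n - 1)
        r = np.corrcoef(a[idx], b)[0, 1]
        best = max(best, r)
    return float(best)


def attach_fidelities(report: MetricsReport, learned_curves, truth_curves,
                      lag_compensate=False):
    """Fill per-match fidelities and the NaN-excluding mean fidelity."""
    fids = []
    n_nan = 0
    for r, g in report.matches:
        f = curve_fidelity(learned_curves[r], truth_curves[g],
                           lag_compensate=lag_compensate)
        fids.append(f)
        if np.isnan(f):
            n_nan += 1
    if n_nan:
        logger.warning("%d NaN fidelities excluded from the mean", n_nan)
    report.fidelities = fids
    clean = [f for f in fids if not np.isnan(f)]
    report.mean_fidelity = float(np.mean(clean)) if clean else np.nan
    return report


def binarization_metrics(predicted_mask, truth_mask) -> MetricsReport:
    """Pixel-level confusion metrics of a foreground binarization."""
    pred = np.asarray(predicted_mask, dtype=bool)
    truth = np.asarray(truth_mask, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError("masks must share a grid")
    tp = np.count_nonzero(pred & truth)
    fp = np.count_nonzero(pred & ~truth)
    fn = np.count_nonzero(~pred & truth)
    total = pred.size
    rep = MetricsReport()
    rep.misclassification = (fp + fn) / total
    rep.pixel_recall = tp / (tp + fn) if (tp + fn) else np.nan
    rep.pixel_precision = tp / (tp + fp) if (tp + fp) else np.nan
    p, r = rep.pixel_precision, rep.pixel_recall
    rep.f_measure = 2 * p * r / (p + r) if (p or r) and not np.isnan(p + r) and (p + r) > 0 else 0.0
    rep.missing_pixel_rate = fn / (tp + fn) if (tp + fn) else np.nan
    return rep


def pixel_test_binarize(zmap, alpha=0.05):
    """Baseline binarizer: right-tailed per-pixel test z > Phi^-1(1-alpha)."""
    z = zmap.values if hasattr(zmap, "values") else np.asarray(zmap)
    return z > norm.isf(alpha)
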