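"""Per-unit functional features and automatic quality screening.

Six quantitative readouts are computed from each unit's refined fluorescence
curve C_m and spatial model:

* the dF/F0 time series, with baseline F0 = 10th percentile of C_m,
* per-event amplitude (maximum dF/F0 during the transient),
* event frequency = 1 / mean inter-peak interval (more stable than
  count/duration when only one or two events occur),
* the half time T0.5 — time from an event's peak down to half its amplitude,
  linearly interpolated,
* area in pixels and um^2,
* average propagation speed, from the spacing of the iso-delay wavefronts of
  the lag map tau: speed (px/frame) = 1 / mean(|grad tau|) over mask pixels
  with a nonzero gradient, converted to um/s with the stack metadata. A
  constant tau (synchronous unit) has no estimable speed and is reported as
  the sentinel ``inf``.

Events are peaks of the moving-average-smoothed dF/F0 curve (window 5
frames) with prominence at least ``0.2 * max dF/F0`` and at least 3x the
baseline noise SD — a scale-free rule that is robust at slow (~2 s) sampling.

The "roughness" screening statistic (SD of first differences over SD of the
curve) is a stand-in for curve smoothness; no canonical definition exists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

logger = logging.getLogger("astrofiu")

#: Sentinel for "no propagation detectable" (synchronous unit).
SYNCHRONOUS = np.inf


@dataclass
class FeatureSet:
    """Functional features of one unit; partial until both computations ran."""

    f0: float = None
    dff0: np.ndarray = None
    events: list = field(default_factory=list)  # (peak_frame, amplitude, t05_s)
    max_dff0: float = None
    frequency_hz: float = None
    area_px: int = None
    area_um2: float = None
    velocity_px_per_frame: float = None
    velocity_um_s: float = None
    screen_pass: bool = True
    screen_reason: str = ""

    @property
    def n_events(self):
        return len(self.events)

    @property
    def mean_t05_s(self):
        vals = [e[2] for e in self.events if np.isfinite(e[2])]
        return float(np.mean(vals)) if vals else np.nan


def _moving_average(x, window):
    if window <= 1:
        return np.asarray(x, dtype=float)
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.pad(x, pad, mode="edge")
    out = np.convolve(padded, kernel, mode="same")
    return out[pad:pad + len(x)] if pad else out


def _half_decay_time(dff0, peak, amplitude, frame_interval):
    """Time from the peak down to half the event amplitude, linearly
    interpolated between frames; NaN if the curve never gets there."""
    half = amplitude / 2.0
    for t in range(peak + 1, len(dff0)):
        if dff0[t] <= half:
            prev, cur = dff0[t - 1], dff0[t]
            frac = (prev - half) / (prev - cur) if prev != cur else 0.0
            return ((t - 1) + frac - peak) * frame_interval
    return np.nan


def compute_dff0_events(curve, frame_interval=2.0, smooth_window=5,
                        prominence_frac=0.2) -> FeatureSet:
    """Baseline, dF/F0, events, amplitudes, frequency and T0.5 from a curve.

    F0 is the 10th percentile of the curve (linear-interpolation percentile,
    so the baseline is bit-reproducible); dF/F0 = (C - F0)/F0. A nonpositive
    F0 signals an unusable baseline and raises.
    """
    curve = np.asarray(curve, dtype=float)
    if curve.size < 10:
        raise ValueError("curve too short for feature extraction")
    f0 = float(np.percentile(curve, 10, method="linear"))
    if f0 <= 0:
        raise ValueError(f"nonpositive baseline F0={f0:.3g}; features undefined")
    dff0 = (curve - f0) / f0
    smooth = _moving_average(dff0, smooth_window)
    peak_amp = float(dff0.max())
    noise_sd = float(np.diff(dff0).std() / np.sqrt(2)) if curve.size > 1 else 0.0
    fs = FeatureSet(f0=f0, dff0=dff0, max_dff0=peak_amp)
    if peak_amp <= 0:
        fs.frequency_hz = 0.0
        return fs
    prominence = max(prominence_frac * peak_amp, 3.0 * noise_sd)
    peaks, props = find_peaks(smooth, prominence=prominence)
    events = []
    if len(peaks):
        # event amplitude = max dF/F0 within the event's span around the peak
        bounds = np.concatenate(([0], (peaks[:-1] + peaks[1:]) // 2, [len(dff0)]))
        for k, pk in enumerate(peaks):
            lo, hi = bounds[k], bounds[k + 1]
            local_pk = lo + int(np.argmax(dff0[lo:hi]))
            amp = float(dff0[local_pk])
            t05 = _half_decay_time(dff0, local_pk, amp, frame_interval)
            events.append((int(local_pk), amp, float(t05)))
    fs.events = events
    if len(peaks) >= 2:
        intervals = np.diff([e[0] for e in events]) * frame_interval
        fs.frequency_hz = float(1.0 / intervals.mean())
    else:
        fs.frequency_hz = 0.0
    return fs


def _masked_boxcar(values, mask, radius=1):
    """Mean filter over the in-mask neighborhood of each mask pixel."""
    from scipy import ndimage
    vals = np.where(mask, values, 0.0)
    kernel = np.ones((2 * radius + 1, 2 * radius + 1))
    num = ndimage.convolve(vals, kernel, mode="constant", cval=0.0)
    den = ndimage.convolve(mask.astype(float), kernel, mode="constant", cval=0.0)
    out = np.where(mask, num / np.where(den > 0, den, 1.0), values)
    return out


def compute_geometry_velocity(mask, tau_map, pixel_size_um=1.0,
                              frame_interval=2.0, features: FeatureSet = None):
    """Area and average propagation speed from the mask and lag map."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty unit mask")
    fs = features or FeatureSet()
    fs.area_px = int(mask.sum())
    fs.area_um2 = fs.area_px * pixel_size_um ** 2
    tau = np.asarray(tau_map, dtype=float)
    # integer lags form a staircase whose raw gradient magnitude is biased
    # upward; a small in-mask box average restores the underlying ramp
    tau = _masked_boxcar(tau, mask)
    gi, gj = np.gradient(np.where(mask, tau, np.nan))
    grad = np.hypot(gi, gj)[mask]
    grad = grad[np.isfinite(grad) & (grad > 0)]
    if grad.size == 0:
        fs.velocity_px_per_frame = SYNCHRONOUS
        fs.velocity_um_s = SYNCHRONOUS
    else:
        v = 1.0 / grad.mean()
        fs.velocity_px_per_frame = float(v)
        fs.velocity_um_s = float(v * pixel_size_um / frame_interval)
    return fs


@dataclass
class ScreeningRules:
    """Configurable acceptance predicates; 0/None disables a rule."""

    min_area: int = 0
    max_area: int = 0
    min_events: int = 0
    max_roughness: float = 0.0


def roughness(curve):
    """SD of first differences over SD of the curve (stand-in smoothness
    statistic; large values mean a noise-dominated curve)."""
    curve = np.asarray(curve, dtype=float)
    sd = curve.std()
    return float(np.diff(curve).std() / sd) if sd > 0 else np.inf


def screen_fius(fius, rules: ScreeningRules = None):
    """Split units into accepted / rejected lists by the screening rules.

    Each unit must carry ``features`` (a FeatureSet) and a refined curve.
    Rejections record the first failed rule in ``screen_reason``.
    """
    rules = rules or ScreeningRules()
    accepted, rejected = [], []
    for f in fius:
        fs = f.features if isinstance(f.features, FeatureSet) else None
        reason = ""
        if rules.min_area and fs and fs.area_px < rules.min_area:
            reason = "min_area"
        elif rules.max_area and fs and fs.area_px > rules.max_area:
            reason = "max_area"
        elif rules.min_events and fs and fs.n_events < rules.min_events:
            reason = "min_events"
        elif rules.max_roughness and f.refined_curve is not None \
                and roughness(f.refined_curve) > rules.max_roughness:
            reason = "max_roughness"
        if reason:
            if fs is not None:
                fs.screen_pass = False
                fs.screen_reason = reason
            logger.info("unit rejected by screening rule %s", reason)
            rejected.append(f)
        else:
            accepted.append(f)
    return accepted, rejected


def compute_features(fius, pixel_size_um=1.0, frame_interval=2.0):
    """Attach a full FeatureSet to every unit (in place) and return them."""
    out = []
    for f in fius:
        fs = compute_dff0_events(f.refined_curve, frame_interval=frame_interval)
        compute_geometry_velocity(f.mask, f.tau_map, pixel_size_um=pixel_size_um,
                                  frame_interval=frame_interval, features=fs)
        f.features = fs
        out.append(fs)
    return out


def features_table(fius) -> pd.DataFrame:
    """One row per unit, mirroring the exported CSV layout."""
    rows = []
    for k, f in enumerate(fius, start=1):
        fs = f.features
        rows.append({
            "fiu_id": k,
            "area_px": fs.area_px,
            "area_um2": fs.area_um2,
            "f0": fs.f0,
            "max_dff0": fs.max_dff0,
            "n_events": fs.n_events,
            "frequency_hz": fs.frequency_hz,
            "mean_t05_s": fs.mean_t05_s,
            "velocity_um_s": fs.velocity_um_s,
            "p_value": f.p_value,
            "screen_pass": fs.screen_pass,
            "screen_reason": fs.screen_reason,
        })
    return pd.DataFrame(rows)
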