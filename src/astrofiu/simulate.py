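"""Ground-truthed synthetic astrocyte Ca2+ movies.

The generative model: each functionally independent unit (FIU) m occupies a
connected pixel mask and carries a characteristic curve X_m built as a sum of
calcium transients ``(t - t_on) * exp(-(t - t_on)/eta)``. A pixel [i, j] in the
unit observes

    Y[i, j, t] = beta0[i, j] + beta_m[i, j] * X_m[t - tau_ij] + eps,

where tau_ij is an integer frame delay from constant-velocity radial wave
propagation out of a source pixel, beta_m fades linearly toward the unit
boundary, and eps is i.i.d. Gaussian noise whose standard deviation is set per
unit from a target SNR in dB via the 20-log rule:

    sigma = signal_magnitude / 10**(snr_db / 20).

A configurable fraction of units is silent (visible baseline, no signal),
emulating calcium-inactive cells in the field of view.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from skimage.draw import polygon

from .io import VideoStack

logger = logging.getLogger("astrofiu")


class PlacementError(RuntimeError):
    """Raised when the requested number of units cannot be placed."""


@dataclass
class SimulationConfig:
    """Parameters of a synthetic movie.

    Defaults follow the standard simulation conditions used throughout the
    benchmarks: a 200 s movie sampled every 2 s (100 frames), transient
    amplitude max(dF/F0) uniform on [0.5, 4], radial propagation at a speed
    uniform on [1, 30] px/frame, and one silent unit for every three active
    units beyond the active ones (active_fraction = 1/4 of all units).
    """

    height: int = 128
    width: int = 128
    n_fius: int = 40
    active_fraction: float = 0.25
    snr_db: float = 5.0
    velocity_range: tuple = (1.0, 30.0)
    duration_s: float = 200.0
    frame_interval_s: float = 2.0
    pixel_size_um: float = 1.0
    max_dff0_range: tuple = (0.5, 4.0)
    eta_range: tuple = (2.0, 8.0)
    n_events_range: tuple = (2, 6)
    area_range: tuple = (30, 200)
    fade_width_px: float = 2.0
    beta_range: tuple = (0.5, 2.0)
    inactive_baseline_range: tuple = (0.5, 2.0)
    background_baseline: float = 0.2
    seed: int = 0
    max_place_tries: int = 200

    def __post_init__(self):
        for name in ("velocity_range", "max_dff0_range", "eta_range",
                     "n_events_range", "area_range", "beta_range",
                     "inactive_baseline_range"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ValueError(f"{name} is empty: {(lo, hi)}")
        if not np.isfinite(self.snr_db):
            raise ValueError("snr_db must be finite")
        if not 0 < self.active_fraction <= 1:
            raise ValueError("active_fraction must lie in (0, 1]")
        if self.n_fius < 0:
            raise ValueError("n_fius must be nonnegative")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s / self.frame_interval_s))


@dataclass
class GroundTruthScene:
    """Full ground truth of one synthetic movie."""

    config: SimulationConfig
    fiu_masks: list  # list of (H, W) bool arrays, pairwise disjoint, connected
    inactive_masks: list
    true_curves: np.ndarray  # (n_fius, T), arbitrary units > 0
    delay_maps: list  # per FIU, int frame delay on mask (0 elsewhere)
    beta_maps: list  # per FIU, nonnegative coefficients (0 outside mask)
    baseline_map: np.ndarray  # beta0 per pixel
    sigma_map: np.ndarray  # noise SD per pixel, > 0 everywhere
    sources: list = field(default_factory=list)  # (i, j) wave origin per FIU
    velocities: list = field(default_factory=list)  # px/frame per FIU

    @property
    def active_mask(self) -> np.ndarray:
        """Union of all FIU masks."""
        shape = (self.config.height, self.config.width)
        out = np.zeros(shape, dtype=bool)
        for m in self.fiu_masks:
            out |= m
        return out

    def label_map(self) -> np.ndarray:
        """uint16-compatible label image; 0 = background, m = FIU id (1-based)."""
        out = np.zeros((self.config.height, self.config.width), dtype=np.int64)
        for idx, m in enumerate(self.fiu_masks, start=1):
            out[m] = idx
        return out


def snr_to_sigma(signal_magnitude, snr_db):
    """Noise SD from signal magnitude and SNR in dB (20-log rule)."""
    return signal_magnitude / 10.0 ** (snr_db / 20.0)


def simulate_curve(onsets, eta, n_frames, max_dff0=None, rng=None,
                   max_dff0_range=(0.5, 4.0)):
    """Build a characteristic transient curve.

    The raw curve is ``sum_i (t - t_i) * exp(-(t - t_i)/eta)`` over onsets
    t_i (each transient peaks eta frames after its onset). With no events the
    raw curve is flat zero. The curve is then affinely rescaled onto
    [1, 1 + max_dff0] so that its relative amplitude (max - min)/min equals
    ``max_dff0`` and the minimum is strictly positive.

    Parameters
    ----------
    onsets : sequence of int
        Event onset frames in [0, n_frames).
    eta : float
        Transient duration scale in frames, > 0.
    n_frames : int
        Curve length.
    max_dff0 : float, optional
        Target relative amplitude; drawn uniformly from ``max_dff0_range``
        when omitted (requires ``rng``).
    """
    if eta <= 0:
        raise ValueError("eta must be positive")
    onsets = np.asarray(onsets, dtype=float)
    if onsets.size == 0:
        raise ValueError("at least one event onset is required")
    if np.any(onsets < 0) or np.any(onsets >= n_frames):
        raise ValueError("onsets must lie in [0, n_frames)")
    raw = raw_transient_curve(onsets, eta, n_frames)
    if max_dff0 is None:
        if rng is None:
            raise ValueError("rng required when max_dff0 is not given")
        max_dff0 = rng.uniform(*max_dff0_range)
    return rescale_curve(raw, max_dff0)


def raw_transient_curve(onsets, eta, n_frames):
    """The unscaled transient sum (zero baseline); flat zero with no onsets."""
    t = np.arange(n_frames, dtype=float)
    onsets = np.asarray(onsets, dtype=float)
    if onsets.size == 0:
        return np.zeros(n_frames)
    dt = t[None, :] - onsets[:, None]
    dt_pos = np.clip(dt, 0.0, None)
    return (dt_pos * np.exp(-dt_pos / eta)).sum(axis=0)


def rescale_curve(raw, max_dff0):
    """Affinely map a curve onto [1, 1 + max_dff0].

    After rescaling, (max - min)/min == max_dff0 and min == 1 > 0.
    """
    lo, hi = float(raw.min()), float(raw.max())
    if hi <= lo:
        raise ValueError("curve is constant; cannot rescale to a target amplitude")
    return 1.0 + max_dff0 * (raw - lo) / (hi - lo)


def _blob_mask(rng, center, target_area, shape, n_harmonics=4, irregularity=0.45):
    """Procedural irregular blob: star-shaped region with a random smooth
    radial profile, rasterised and rescaled to hit ``target_area`` pixels.

    Stands in for shape templates drawn from real astrocyte recordings, which
    are not shipped; preserves the irregular, heterogeneous morphology of
    astrocytic functional units.
    """
    n_vert = 48
    theta = np.linspace(0, 2 * np.pi, n_vert, endpoint=False)
    prof = np.ones(n_vert)
    for k in range(1, n_harmonics + 1):
        amp = irregularity / k * rng.standard_normal()
        phase = rng.uniform(0, 2 * np.pi)
        prof += amp * np.cos(k * theta + phase)
    prof = np.clip(prof, 0.25, None)
    # mean squared radius sets the enclosed area of the star polygon
    base = np.sqrt(target_area / (np.pi * np.mean(prof ** 2)))
    r = base * prof
    rr = center[0] + r * np.sin(theta)
    cc = center[1] + r * np.cos(theta)
    ri, ci = polygon(rr, cc, shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[ri, ci] = True
    if mask.sum() == 0:
        return mask
    # keep the component containing (or nearest to) the centroid
    lab, n = ndimage.label(mask, structure=np.ones((3, 3)))
    if n > 1:
        ci0 = min(max(int(round(center[0])), 0), shape[0] - 1)
        cj0 = min(max(int(round(center[1])), 0), shape[1] - 1)
        want = lab[ci0, cj0]
        if want == 0:
            sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
            want = int(np.argmax(sizes)) + 1
        mask = lab == want
    return mask


def _fade_beta(mask, beta_max, fade_width):
    """Linear boundary fade: beta = beta_max * min(1, d_boundary / w)."""
    dist = ndimage.distance_transform_edt(mask)
    beta = beta_max * np.minimum(1.0, dist / fade_width)
    beta[~mask] = 0.0
    return beta


def generate_scene(config: SimulationConfig, rng=None) -> GroundTruthScene:
    """Lay out units, curves, delays, coefficient and noise maps.

    Unit centroids are uniform in the field; each active unit gets a random
    wave source pixel, a propagation speed drawn from ``velocity_range``
    (``inf`` gives a synchronous unit with all-zero delays), and a noise SD
    from the configured SNR. Silent units contribute baseline only; silent
    units that cannot be placed without overlap are dropped with a log
    message, but failure to place a requested active unit raises
    :class:`PlacementError`.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    h, w = config.height, config.width
    shape = (h, w)
    n_frames = config.n_frames
    n_units = int(round(config.n_fius / config.active_fraction))
    n_inactive = max(0, n_units - config.n_fius)

    occupied = np.zeros(shape, dtype=bool)
    fiu_masks, inactive_masks = [], []

    def place_one(required):
        for _ in range(config.max_place_tries):
            area = np.exp(rng.uniform(np.log(config.area_range[0]),
                                      np.log(config.area_range[1] + 1)))
            center = (rng.uniform(0, h), rng.uniform(0, w))
            mask = _blob_mask(rng, center, area, shape)
            if mask.sum() < max(4, config.area_range[0] // 2) or (mask & occupied).any():
                continue
            occupied[mask] = True
            return mask
        if required:
            raise PlacementError(
                f"could not place all {config.n_fius} active units in a "
                f"{h}x{w} field after {config.max_place_tries} tries each"
            )
        return None

    for _ in range(config.n_fius):
        fiu_masks.append(place_one(required=True))
    for _ in range(n_inactive):
        m = place_one(required=False)
        if m is None:
            logger.info("dropped a silent unit that could not be placed")
            continue
        inactive_masks.append(m)

    # characteristic curves
    curves = np.empty((config.n_fius, n_frames))
    for m in range(config.n_fius):
        n_evt = int(rng.integers(config.n_events_range[0], config.n_events_range[1] + 1))
        onsets = np.sort(rng.integers(0, n_frames, size=n_evt))
        eta = rng.uniform(*config.eta_range)
        curves[m] = simulate_curve(onsets, eta, n_frames, rng=rng,
                                   max_dff0_range=config.max_dff0_range)

    # propagation delays, coefficients, noise
    delay_maps, beta_maps, sources, velocities = [], [], [], []
    sigma_map = np.zeros(shape)
    baseline_map = np.full(shape, config.background_baseline)
    ii, jj = np.indices(shape)
    for m, mask in enumerate(fiu_masks):
        pix = np.argwhere(mask)
        src = tuple(pix[rng.integers(len(pix))])
        vlo, vhi = config.velocity_range
        vel = np.inf if np.isinf(vlo) else float(rng.uniform(vlo, vhi))
        dist = np.hypot(ii - src[0], jj - src[1])
        if np.isinf(vel):
            delay = np.zeros(shape, dtype=np.int64)
        else:
            delay = np.round(dist / vel).astype(np.int64)
        delay[~mask] = 0
        beta_max = rng.uniform(*config.beta_range)
        beta = _fade_beta(mask, beta_max, config.fade_width_px)
        # noise SD tracks the local signal magnitude (shot-noise-like), so
        # every pixel of the unit sits at the configured SNR; the faded
        # boundary is dimmer but not noisier in relative terms
        magnitude = beta[mask] * (curves[m].max() - curves[m].min())
        sigma_map[mask] = snr_to_sigma(magnitude, config.snr_db)
        delay_maps.append(delay)
        beta_maps.append(beta)
        sources.append((int(src[0]), int(src[1])))
        velocities.append(float(vel))
        # the unit's own fluorescence carries its baseline (the curve minimum
        # is strictly positive), so the observed per-pixel dF/F0 equals the
        # configured curve amplitude; no background pedestal underneath
        baseline_map[mask] = 0.0

    for mask in inactive_masks:
        baseline_map[mask] = rng.uniform(*config.inactive_baseline_range)

    # background noise floor comparable to in-unit noise
    if config.n_fius:
        bg_sigma = float(np.median(sigma_map[sigma_map > 0]))
    else:
        bg_sigma = snr_to_sigma(np.mean(config.beta_range) * np.mean(config.max_dff0_range),
                                config.snr_db)
    sigma_map[sigma_map == 0] = bg_sigma

    return GroundTruthScene(
        config=config, fiu_masks=fiu_masks, inactive_masks=inactive_masks,
        true_curves=curves, delay_maps=delay_maps, beta_maps=beta_maps,
        baseline_map=baseline_map, sigma_map=sigma_map,
        sources=sources, velocities=velocities,
    )


def shifted_curve(curve, delay):
    """Evaluate curve[t - delay] with clamped (edge-hold) indexing."""
    n = len(curve)
    idx = np.clip(np.arange(n) - delay, 0, n - 1)
    return curve[idx]


def render_video(scene: GroundTruthScene, seed=None, noise=True) -> VideoStack:
    """Render the forward model into a movie.

    Y[t, i, j] = beta0[i, j] + beta_m[i, j] * X_m[t - tau_ij] + N(0, sigma^2),
    with temporal shifts handled by holding the first/last curve value at the
    movie edges. The same seed always yields an identical stack.
    """
    cfg = scene.config
    n_frames = cfg.n_frames
    clean = np.broadcast_to(scene.baseline_map, (n_frames, cfg.height, cfg.width)).copy()
    for m, mask in enumerate(scene.fiu_masks):
        pix = np.argwhere(mask)
        delays = scene.delay_maps[m][mask]
        betas = scene.beta_maps[m][mask]
        curve = scene.true_curves[m]
        # group pixels sharing a delay: one shifted-curve evaluation each
        for d in np.unique(delays):
            sel = delays == d
            sub = pix[sel]
            clean[:, sub[:, 0], sub[:, 1]] += betas[sel][None, :] * shifted_curve(curve, d)[:, None]
    if noise:
        rng = np.random.default_rng(cfg.seed if seed is None else seed)
        data = clean + rng.standard_normal(clean.shape) * scene.sigma_map[None, :, :]
    else:
        data = clean
    return VideoStack(
        data,
        pixel_size_um=cfg.pixel_size_um,
        frame_interval_s=cfg.frame_interval_s,
        provenance={"synthetic": True, "seed": int(cfg.seed if seed is None else seed)},
    )


def simulate_movie(config: SimulationConfig, noise=True):
    """Convenience: scene + rendered movie from one config/seed."""
    scene = generate_scene(config)
    return scene, render_video(scene, noise=noise)


def save_scene(directory, scene: GroundTruthScene):
    """Write a scene to plain files: scene JSON (config + layout), label-map
    TIFF, per-FIU curve CSV and delay-map TIFF stack."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cfg = asdict(scene.config)
    meta = {
        "config": cfg,
        "sources": scene.sources,
        "velocities": scene.velocities,
        "n_inactive_placed": len(scene.inactive_masks),
    }
    (directory / "scene.json").write_text(json.dumps(meta, indent=2, default=list) + "\n")
    tifffile.imwrite(directory / "labels.tif", scene.label_map().astype(np.uint16))
    if scene.inactive_masks:
        inact = np.zeros((scene.config.height, scene.config.width), dtype=np.uint16)
        for idx, m in enumerate(scene.inactive_masks, start=1):
            inact[m] = idx
        tifffile.imwrite(directory / "inactive_labels.tif", inact)
    rows = []
    for m, curve in enumerate(scene.true_curves, start=1):
        for t, v in enumerate(curve):
            rows.append((m, t, v))
    pd.DataFrame(rows, columns=["fiu_id", "frame", "value"]).to_csv(
        directory / "true_curves.csv", index=False
    )
    if scene.delay_maps:
        tifffile.imwrite(
            directory / "delay_maps.tif",
            np.stack(scene.delay_maps).astype(np.int32),
        )
    tifffile.imwrite(directory / "sigma_map.tif", scene.sigma_map.astype(np.float32))
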