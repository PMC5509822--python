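"""Reading and writing image stacks, label maps and run configuration.

Array convention: stacks are stored frame-major as ``(T, H, W)`` float arrays
(TIFF page index = frame). All coordinates in exported files are row-major and
0-based; label 0 is background.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import tifffile

logger = logging.getLogger("astrofiu")

#: Documented fallback metadata when neither TIFF tags nor overrides give them.
DEFAULT_PIXEL_SIZE_UM = 1.0
DEFAULT_FRAME_INTERVAL_S = 2.0

MIN_FRAMES = 10


@dataclass
class VideoStack:
    """A single-channel time-lapse fluorescence stack Y[t, i, j].

    Attributes
    ----------
    data : ndarray, shape (T, H, W)
        Fluorescence intensities, float.
    pixel_size_um : float
        Lateral pixel size in micrometres.
    frame_interval_s : float
        Time between consecutive frames in seconds.
    provenance : dict
        Free-form record of origin (source path, transforms applied).
    """

    data: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a (T, H, W) stack, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("stack contains non-finite intensities")
        if self.pixel_size_um <= 0 or self.frame_interval_s <= 0:
            raise ValueError("pixel size and frame interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def validate_for_analysis(self):
        if self.n_frames < MIN_FRAMES:
            raise ValueError(
                f"analysis requires at least {MIN_FRAMES} frames, got {self.n_frames}"
            )


def read_stack(path, pixel_size_um=None, frame_interval_s=None) -> VideoStack:
    """Read a multi-page grayscale TIFF into a :class:`VideoStack`.

    Integer data is promoted to float64 exactly. Metadata comes from TIFF
    tags where present, then from the override arguments, then from the
    documented defaults (1 um, 2 s).

    Raises
    ------
    ValueError
        If the file is RGB/multi-channel or has fewer than 10 frames.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        tag_px, tag_dt = _metadata_from_tags(tif)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(
            f"unsupported TIFF layout with shape {arr.shape}; "
            "only single-channel grayscale stacks are supported"
        )
    if arr.shape[-1] in (3, 4) and arr.shape[-1] < min(arr.shape[:-1]):
        raise ValueError("RGB/multi-channel TIFF input is not supported")
    if arr.shape[0] < MIN_FRAMES:
        raise ValueError(f"stack has {arr.shape[0]} frames; at least {MIN_FRAMES} required")
    data = np.asarray(arr, dtype=np.float64)
    px = pixel_size_um or tag_px or DEFAULT_PIXEL_SIZE_UM
    dt = frame_interval_s or tag_dt or DEFAULT_FRAME_INTERVAL_S
    return VideoStack(
        data, pixel_size_um=px, frame_interval_s=dt, provenance={"path": str(path)}
    )


def _metadata_from_tags(tif):
    """Best-effort pixel size / frame interval from ImageJ-style metadata."""
    px = dt = None
    try:
        meta = tif.imagej_metadata or {}
        if "finterval" in meta:
            dt = float(meta["finterval"])
        page = tif.pages[0]
        res = page.tags.get("XResolution")
        unit = (meta.get("unit") or "").lower()
        if res is not None and unit in ("um", "micron", "µm"):
            num, den = res.value
            if num:
                px = den / num
    except Exception:  # malformed tags: fall through to defaults
        pass
    return px, dt


def write_stack(path, stack: VideoStack, dtype="float32"):
    """Write a stack as a multi-page TIFF (float32 by default).

    ``dtype='uint16'`` rescales to the full uint16 range and records the
    scaling in the returned dict.
    """
    path = Path(path)
    data = stack.data
    scaling = {"dtype": dtype, "scale": 1.0, "offset": 0.0}
    if dtype == "uint16":
        lo, hi = float(data.min()), float(data.max())
        scale = (hi - lo) / 65535.0 if hi > lo else 1.0
        out = np.round((data - lo) / scale).astype(np.uint16)
        scaling.update(scale=scale, offset=lo)
    else:
        out = data.astype(np.float32)
    tifffile.imwrite(path, out, metadata={"axes": "TYX"})
    return scaling


def write_label_map(path, labels):
    """Write an integer label map (0 = background) as uint16 TIFF."""
    labels = np.asarray(labels)
    if labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 labels")
    tifffile.imwrite(Path(path), labels.astype(np.uint16))


def read_label_map(path):
    return tifffile.imread(Path(path)).astype(np.int64)


@dataclass
class RunConfig:
    """User-facing configuration of a full detection run."""

    score_variant: str = "neighbor8"
    stabilize: bool = False
    stabilize_gain: float = 1.0
    stabilize_offset: float = 0.0
    seed_threshold: float = 2.0
    alpha: float = 0.05
    u_tau: int = 5
    tol: float = 0.01
    max_iter: int = 50
    min_size: int = 4
    use_residual: bool = True
    min_area: int = 0
    max_area: int = 0  # 0 disables the rule
    min_events: int = 0
    max_roughness: float = 0.0  # 0 disables the rule
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.score_variant not in ("neighbor8", "directional4"):
            raise ValueError(f"unknown score variant {self.score_variant!r}")

    def to_json(self, path):
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path):
        return cls(**json.loads(Path(path).read_text()))
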