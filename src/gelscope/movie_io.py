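"""Calibrated image-stack I/O.

An :class:`ImageStack` is the common currency of every imaging stage: a
``(time, y, x)`` array of raw intensity counts together with its physical
calibration (pixel size in um/px, frame interval in s) and the elapsed-time
label of the movie inside the gelation run.  Calibration is mandatory —
reading a stack without it is an error, never a silent default — and every
transform propagates it.

On disk a stack is a plain multi-page grayscale TIFF (8- or 16-bit, no
compression) plus a sidecar JSON carrying the physical metadata.  The
sidecar schema is ``{pixel_size_um, frame_rate_hz, elapsed_time_min,
source, ...}``; extra keys round-trip untouched.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import tifffile

from .exceptions import BoundsError, CalibrationError, RangeError, ShapeError

__all__ = ["ImageStack", "read_stack", "write_stack", "crop_roi", "sidecar_path"]


@dataclass
class ImageStack:
    """A time-lapse movie with physical calibration.

    Attributes
    ----------
    frames : ndarray, shape (T, H, W)
        Raw intensity counts; never rescaled on I/O.
    pixel_size : float
        um per pixel.
    frame_interval : float
        Seconds between consecutive frames.
    elapsed_time : float or None
        Label of this movie within the gelation run, in minutes since the
        acidulant was added.
    source : str
        File path or ``"synthetic"``; provenance for the stage logs.
    meta : dict
        Free-form provenance (render reports, ROI history, ...).
    """

    frames: np.ndarray
    pixel_size: float
    frame_interval: float
    elapsed_time: Optional[float] = None
    source: str = "synthetic"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ShapeError(
                f"frames must be 3-D (time, y, x); got shape {self.frames.shape}"
            )
        if self.frames.shape[0] < 2:
            raise ShapeError("an image stack needs at least 2 frames")
        if not self.pixel_size > 0:
            raise CalibrationError("pixel_size must be positive")
        if not self.frame_interval > 0:
            raise CalibrationError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple:
        return self.frames.shape[1:]

    @property
    def frame_rate(self) -> float:
        """Frames per second."""
        return 1.0 / self.frame_interval

    @property
    def duration(self) -> float:
        """Movie duration in seconds (span between first and last frame)."""
        return (self.n_frames - 1) * self.frame_interval


def sidecar_path(path) -> Path:
    """The JSON sidecar accompanying a TIFF stack: ``movie.tif`` -> ``movie.json``."""
    return Path(path).with_suffix(".json")


def write_stack(stack: ImageStack, path) -> Path:
    """Write a stack losslessly as multi-page TIFF plus sidecar JSON.

    The bit depth is chosen from the data (8-bit if all values fit, else
    16-bit).  Values outside ``[0, 65535]`` raise :class:`RangeError`; there
    is no silent clipping on write.  Two writes of the same stack produce
    byte-identical files.
    """
    path = Path(path)
    frames = np.asarray(stack.frames)
    if not np.issubdtype(frames.dtype, np.integer):
        if not np.all(np.isfinite(frames)) or np.any(frames != np.round(frames)):
            raise RangeError("frames must hold integral counts to be written")
        frames = frames.astype(np.int64)
    lo = int(frames.min())
    hi = int(frames.max())
    if lo < 0 or hi > 65535:
        raise RangeError(
            f"intensity range [{lo}, {hi}] does not fit a 16-bit TIFF; "
            "no silent clipping on write"
        )
    if stack.frames.dtype == np.uint8:
        dtype = np.uint8
    elif stack.frames.dtype == np.uint16:
        dtype = np.uint16
    else:
        dtype = np.uint8 if hi <= 255 else np.uint16
    tifffile.imwrite(path, frames.astype(dtype), photometric="minisblack")

    sidecar = {
        "pixel_size_um": stack.pixel_size,
        "frame_rate_hz": stack.frame_rate,
        "elapsed_time_min": stack.elapsed_time,
        "source": stack.source,
    }
    for key, value in stack.meta.items():
        sidecar.setdefault(key, value)
    with open(sidecar_path(path), "w") as fh:
        json.dump(sidecar, fh, sort_keys=True, indent=1, default=str)
    return path


def read_stack(
    path,
    pixel_size: Optional[float] = None,
    frame_interval: Optional[float] = None,
    elapsed_time: Optional[float] = None,
) -> ImageStack:
    """Read a multi-page TIFF and its calibration.

    Calibration comes from the sidecar JSON next to the file; explicit
    arguments override it.  If neither supplies ``pixel_size`` or
    ``frame_interval`` a :class:`CalibrationError` names every missing
    field.  Frames are loaded unscaled.
    """
    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        raise ShapeError(f"{path} holds a single page; a movie needs >= 2 frames")

    meta: dict = {}
    sc = sidecar_path(path)
    if sc.exists():
        with open(sc) as fh:
            meta = json.load(fh)

    if pixel_size is None:
        pixel_size = meta.get("pixel_size_um")
    if frame_interval is None:
        rate = meta.get("frame_rate_hz")
        frame_interval = 1.0 / rate if rate else None
    if elapsed_time is None:
        elapsed_time = meta.get("elapsed_time_min")

    missing = []
    if pixel_size is None:
        missing.append("pixel_size")
    if frame_interval is None:
        missing.append("frame_interval")
    if missing:
        raise CalibrationError(
            f"missing calibration for {path.name}: {', '.join(missing)} "
            "(supply a sidecar JSON or explicit arguments)"
        )

    extra = {
        k: v
        for k, v in meta.items()
        if k not in {"pixel_size_um", "frame_rate_hz", "elapsed_time_min", "source"}
    }
    return ImageStack(
        frames=frames,
        pixel_size=float(pixel_size),
        frame_interval=float(frame_interval),
        elapsed_time=None if elapsed_time is None else float(elapsed_time),
        source=meta.get("source", str(path)),
        meta=extra,
    )


def crop_roi(stack: ImageStack, origin: tuple, size: tuple) -> ImageStack:
    """Crop a region of interest, preserving calibration.

    Parameters
    ----------
    origin : (x, y) in pixels, top-left corner of the ROI (x rightward,
        y downward, origin at the top-left pixel).
    size : (width, height) in pixels.

    The result owns its data (no aliasing of the parent stack).
    """
    x0, y0 = int(origin[0]), int(origin[1])
    w, h = int(size[0]), int(size[1])
    T, H, W = stack.frames.shape
    if x0 < 0 or y0 < 0 or w <= 0 or h <= 0 or x0 + w > W or y0 + h > H:
        raise BoundsError(
            f"ROI origin={origin} size={size} exceeds frame bounds {W}x{H}"
        )
    meta = dict(stack.meta)
    meta["roi"] = {"origin_px": [x0, y0], "size_px": [w, h]}
    return ImageStack(
        frames=stack.frames[:, y0 : y0 + h, x0 : x0 + w].copy(),
        pixel_size=stack.pixel_size,
        frame_interval=stack.frame_interval,
        elapsed_time=stack.elapsed_time,
        source=stack.source,
        meta=meta,
    )
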