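"""Particle image velocimetry by normalized cross-correlation block matching.

Each frame pair (t, t + lag) is divided into interrogation blocks; every
block of the first frame is matched against a search window of the second
by normalized cross-correlation (NCC), and the correlation peak — refined
to sub-pixel precision by three-point parabolic interpolation in each axis
— gives the block displacement.  Blocks whose correlation peak falls below
a threshold (empty or decorrelated regions) are marked invalid and
excluded from averages.

The per-movie average displacement magnitude, plotted against elapsed
time and normalized to the first movie, is the mobility curve: it decays
gradually while the matrix viscosity rises during incubation and drops
abruptly when the probe motion is frozen by the percolating gel network.
This is a qualitative monitor; the displacement-magnitude map (the "heat
map") is exactly this quantity before any colormapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from skimage.feature import match_template

from .exceptions import ConfigurationError, LagError, ParameterError
from .movie_io import ImageStack

__all__ = ["DisplacementField", "MobilityCurve", "displacement_field", "mobility_curve"]

#: Blocks with an NCC peak below this are excluded from averages.
PEAK_THRESHOLD = 0.3


@dataclass
class DisplacementField:
    """Block displacements (px) for one frame pair.

    ``u`` is the x (rightward) and ``v`` the y (downward) displacement at
    each block center; ``peak`` the NCC maximum; ``valid`` masks blocks
    that passed the peak threshold and stayed inside the search range.
    """

    u: np.ndarray
    v: np.ndarray
    peak: np.ndarray
    valid: np.ndarray
    block_centers_x: np.ndarray  # px
    block_centers_y: np.ndarray  # px
    block_size: int
    lag: float  # s
    pixel_size: float  # um/px
    t_start: int  # start frame index
    meta: dict = field(default_factory=dict)

    def magnitudes_um(self) -> np.ndarray:
        """Valid displacement magnitudes in um."""
        mag = np.hypot(self.u, self.v) * self.pixel_size
        return mag[self.valid]

    def to_frame(self) -> pd.DataFrame:
        cx, cy = np.meshgrid(self.block_centers_x, self.block_centers_y)
        return pd.DataFrame(
            {
                "t_start": self.t_start,
                "block_x": cx.ravel(),
                "block_y": cy.ravel(),
                "u_px": self.u.ravel(),
                "v_px": self.v.ravel(),
                "peak": self.peak.ravel(),
                "valid": self.valid.ravel(),
            }
        )


@dataclass
class MobilityCurve:
    """Normalized averaged displacement magnitude per elapsed time."""

    elapsed_times: np.ndarray  # min
    values: np.ndarray  # dimensionless, first entry 1 by construction
    lag: float  # s
    raw_um: np.ndarray  # unnormalized mean displacement magnitude, um
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "elapsed_min": self.elapsed_times,
                "normalized_mobility": self.values,
                "mean_displacement_um": self.raw_um,
                "lag_s": self.lag,
            }
        )


def _parabolic_offset(cm1: float, c0: float, cp1: float) -> float:
    denom = cm1 - 2.0 * c0 + cp1
    if denom >= 0 or abs(denom) < 1e-12:
        return 0.0
    return float(np.clip(0.5 * (cm1 - cp1) / denom, -1.0, 1.0))


def displacement_field(
    stack: ImageStack,
    lag: float,
    block_size: int = 32,
    search_radius: int = 8,
    overlap: float = 0.5,
    peak_threshold: float = PEAK_THRESHOLD,
    pair_step: Optional[int] = None,
) -> List[DisplacementField]:
    """Block-matching displacement fields for every analyzed frame pair.

    Parameters
    ----------
    lag : s; must be an integer multiple of the frame interval.
    block_size : px (>= 8); interrogation window side.
    search_radius : px; maximum displacement searched (must be smaller
        than the block size).
    overlap : fractional block overlap (0.5 = blocks every half block).
    pair_step : start-frame stride; defaults to the lag in frames
        (disjoint pairs).
    """
    ratio = lag / stack.frame_interval
    lag_frames = int(round(ratio))
    if abs(ratio - lag_frames) > 1e-6 * max(ratio, 1.0) or lag_frames < 1:
        raise LagError(
            f"lag {lag:g} s is not a positive integer multiple of the frame "
            f"interval {stack.frame_interval:g} s"
        )
    if lag_frames >= stack.n_frames:
        raise LagError("lag exceeds the movie duration")
    if block_size < 8:
        raise ParameterError("block_size must be >= 8 px")
    if search_radius >= block_size:
        raise ConfigurationError("search_radius must be smaller than block_size")

    frames = stack.frames.astype(np.float64, copy=False)
    T, H, W = frames.shape
    step = max(int(round(block_size * (1.0 - overlap))), 1)
    ys = np.arange(0, H - block_size + 1, step)
    xs = np.arange(0, W - block_size + 1, step)
    centers_y = ys + block_size / 2.0 - 0.5
    centers_x = xs + block_size / 2.0 - 0.5
    r = search_radius
    stride = pair_step or lag_frames

    fields = []
    for t0 in range(0, T - lag_frames, stride):
        a, b = frames[t0], frames[t0 + lag_frames]
        u = np.zeros((ys.size, xs.size))
        v = np.zeros((ys.size, xs.size))
        peak = np.zeros((ys.size, xs.size))
        valid = np.zeros((ys.size, xs.size), dtype=bool)
        for iy, y0 in enumerate(ys):
            for ix, x0 in enumerate(xs):
                template = a[y0 : y0 + block_size, x0 : x0 + block_size]
                wy0, wy1 = max(y0 - r, 0), min(y0 + block_size + r, H)
                wx0, wx1 = max(x0 - r, 0), min(x0 + block_size + r, W)
                window = b[wy0:wy1, wx0:wx1]
                if template.std() == 0 or window.std() == 0:
                    continue
                corr = match_template(window, template)
                iy_pk, ix_pk = np.unravel_index(np.argmax(corr), corr.shape)
                pk = float(corr[iy_pk, ix_pk])
                dy = iy_pk + wy0 - y0
                dx = ix_pk + wx0 - x0
                if 0 < iy_pk < corr.shape[0] - 1:
                    dy += _parabolic_offset(
                        corr[iy_pk - 1, ix_pk], pk, corr[iy_pk + 1, ix_pk]
                    )
                if 0 < ix_pk < corr.shape[1] - 1:
                    dx += _parabolic_offset(
                        corr[iy_pk, ix_pk - 1], pk, corr[iy_pk, ix_pk + 1]
                    )
                u[iy, ix], v[iy, ix], peak[iy, ix] = dx, dy, pk
                valid[iy, ix] = pk >= peak_threshold
        fields.append(
            DisplacementField(
                u=u,
                v=v,
                peak=peak,
                valid=valid,
                block_centers_x=centers_x,
                block_centers_y=centers_y,
                block_size=block_size,
                lag=lag_frames * stack.frame_interval,
                pixel_size=stack.pixel_size,
                t_start=t0,
                meta={"search_radius": r, "overlap": overlap},
            )
        )
    return fields


def mobility_curve(
    fields_per_movie: Sequence[Sequence[DisplacementField]],
    elapsed_times: Sequence[float],
) -> MobilityCurve:
    """Average displacement magnitude per movie, normalized to the first.

    All movies must have been analyzed at the same lag.  The arrest time of
    the resulting curve is estimated with
    :func:`gelscope.fitting.detect_changepoint`.
    """
    if len(fields_per_movie) == 0 or any(len(f) == 0 for f in fields_per_movie):
        raise ParameterError("every movie needs at least one displacement field")
    lags = {round(f[0].lag, 9) for f in fields_per_movie}
    if len(lags) != 1:
        raise ParameterError(f"movies analyzed at different lags: {sorted(lags)}")
    raw = np.empty(len(fields_per_movie))
    n_invalid = 0
    for i, fields in enumerate(fields_per_movie):
        mags = np.concatenate([f.magnitudes_um() for f in fields])
        n_invalid += sum(int(np.count_nonzero(~f.valid)) for f in fields)
        if mags.size == 0:
            raise ParameterError(
                f"movie {i} has no valid blocks; lower the peak threshold "
                "or enlarge the blocks"
            )
        raw[i] = float(np.mean(mags))
    if raw[0] <= 0:
        raise ParameterError("first movie has zero mobility; cannot normalize")
    return MobilityCurve(
        elapsed_times=np.asarray(elapsed_times, dtype=float),
        values=raw / raw[0],
        lag=fields_per_movie[0][0].lag,
        raw_um=raw,
        meta={"n_invalid_blocks": n_invalid},
    )
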