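"""Differential variance analysis (DVA).

DVA isolates the contribution of moving objects by differencing frames
separated by a variable lag dt: the spatial variance of the difference
image, averaged over all admissible start frames, grows with dt and
saturates at a plateau once the probes have moved farther than the image
correlation length.  Normalizing by that plateau gives the dynamic order
parameter

    Q(dt) = 1 - <I(dt)>_t / I_inf,

which decays from ~1 toward 0 as the structure relaxes and is fitted with
a stretched exponential to obtain the relaxation time tau.

Two plateau estimators are available.  The default (``plateau="lag"``)
averages the variance over the top half-decade of lags and accepts it only
if the local slope there is below a threshold; this makes insufficient
ensemble averaging at long lags an explicit error rather than a silent
bias.  The alternative (``plateau="frame"``) uses 2x the mean per-frame
spatial variance, which is the exact infinite-lag limit for fully
decorrelated frames and remains available when a movie is too slow for the
lag window.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import LagError, PlateauError
from .movie_io import ImageStack

__all__ = ["DVACurve", "default_lags", "differential_variance_curve", "order_parameter"]

#: Plateau acceptance: maximum relative slope (per decade of lag) of the
#: variance over the top half-decade of the lag range.
PLATEAU_SLOPE_TOL = 0.05


@dataclass
class DVACurve:
    """Lag-resolved differential variance of one movie.

    ``variance`` is the spatial variance of the difference image (counts^2)
    per lag, ensemble-averaged over all overlapping start frames;
    ``n_pairs`` records the ensemble size per lag.  ``plateau`` is the
    long-lag asymptote I_inf (None if it could not be established) and
    ``q_values`` the order parameter once populated.
    """

    lags: np.ndarray  # s
    variance: np.ndarray  # counts^2
    n_pairs: np.ndarray
    plateau: Optional[float] = None
    q_values: Optional[np.ndarray] = None
    elapsed_time: Optional[float] = None
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "elapsed_min": self.elapsed_time,
                "lag_s": self.lags,
                "variance": self.variance,
                "n_pairs": self.n_pairs,
                "plateau": self.plateau,
            }
        )
        if self.q_values is not None:
            df["Q"] = self.q_values
        return df


def _lags_to_frames(stack: ImageStack, lags: Sequence[float]) -> np.ndarray:
    lags = np.asarray(lags, dtype=float)
    if lags.size == 0:
        raise LagError("lag list is empty")
    frames = lags / stack.frame_interval
    rounded = np.rint(frames)
    if np.any(np.abs(frames - rounded) > 1e-6 * np.maximum(frames, 1.0)):
        bad = lags[np.abs(frames - rounded) > 1e-6 * np.maximum(frames, 1.0)][0]
        raise LagError(
            f"lag {bad:g} s is not an integer multiple of the frame interval "
            f"{stack.frame_interval:g} s"
        )
    out = rounded.astype(int)
    out = out[(out >= 1) & (out < stack.n_frames)]
    if out.size == 0:
        raise LagError("no lag is shorter than the movie duration")
    return np.unique(out)


def default_lags(stack: ImageStack, n: int = 20) -> np.ndarray:
    """20 log-spaced lags from one frame interval to duration/4 (seconds).

    The duration/4 cap keeps the ensemble of start frames large at the
    longest lag (>= ~375 pairs for a 10 s, 50 Hz movie).
    """
    max_frames = max(stack.n_frames // 4, 1)
    frames = np.unique(
        np.rint(np.geomspace(1, max_frames, n)).astype(int)
    )
    return frames * stack.frame_interval


def differential_variance_curve(
    stack: ImageStack,
    lags: Optional[Sequence[float]] = None,
    plateau: str = "lag",
    plateau_slope_tol: float = PLATEAU_SLOPE_TOL,
) -> DVACurve:
    """Compute the differential-variance curve I(dt) of a movie.

    For each lag, the per-pair statistic is the variance of
    ``frame(t+dt) - frame(t)`` over all pixels, and the curve value is its
    mean over every overlapping start frame t (maximal ensemble).  The
    plateau is then estimated per ``plateau`` ("lag" or "frame"; see module
    docstring).  A rejected lag-plateau leaves ``plateau=None`` with the
    diagnostic in ``meta['plateau_rejected']``; :func:`order_parameter`
    turns that into a :class:`PlateauError`.
    """
    if lags is None:
        lags = default_lags(stack)
    lag_frames = _lags_to_frames(stack, lags)
    frames = stack.frames.astype(np.float64, copy=False)
    T = stack.n_frames

    variance = np.empty(lag_frames.size)
    n_pairs = np.empty(lag_frames.size, dtype=int)
    for i, l in enumerate(lag_frames):
        diff = frames[l:] - frames[:-l]
        variance[i] = float(np.mean(np.var(diff, axis=(1, 2))))
        n_pairs[i] = T - l

    curve = DVACurve(
        lags=lag_frames * stack.frame_interval,
        variance=variance,
        n_pairs=n_pairs,
        elapsed_time=stack.elapsed_time,
        meta={"plateau_method": plateau},
    )

    if plateau == "frame":
        curve.plateau = 2.0 * float(np.mean(np.var(frames, axis=(1, 2))))
        return curve
    if plateau != "lag":
        raise ValueError(f"unknown plateau method {plateau!r}")

    value, diag = _lag_plateau(curve.lags, variance, plateau_slope_tol)
    if value is None:
        curve.meta["plateau_rejected"] = diag
    else:
        curve.plateau = value
        curve.meta["plateau_diagnostic"] = diag
    return curve


def _lag_plateau(lags, variance, slope_tol):
    """Mean variance over the top half-decade of lags, accepted only if the
    local relative slope there is below ``slope_tol`` per decade."""
    window = lags >= lags.max() / np.sqrt(10.0)
    if np.count_nonzero(window) < 2:
        return None, {"reason": "fewer than 2 lags in the top half-decade"}
    v = variance[window]
    mean = float(np.mean(v))
    if mean <= 0:
        # Static movie: the plateau is legitimately zero (and unusable).
        return 0.0, {"window_mean": mean}
    slope = float(np.polyfit(np.log10(lags[window]), v / mean, 1)[0])
    diag = {
        "window_lags_s": [float(lags[window][0]), float(lags[window][-1])],
        "relative_slope_per_decade": slope,
        "threshold": slope_tol,
    }
    if abs(slope) >= slope_tol:
        diag["reason"] = (
            "variance still drifting in the top half-decade of lags "
            "(insufficient relaxation or ensemble averaging)"
        )
        return None, diag
    return mean, diag


def order_parameter(curve: DVACurve) -> DVACurve:
    """Populate the dynamic order parameter Q = 1 - <I(dt)> / I_inf.

    Requires an accepted, positive plateau; otherwise a
    :class:`PlateauError` carries the stored diagnostic.
    """
    if curve.plateau is None:
        raise PlateauError(
            "plateau was not established for this movie",
            diagnostic=curve.meta.get("plateau_rejected", {}),
        )
    if curve.plateau <= 0:
        raise PlateauError(
            "plateau is nonpositive; Q is undefined",
            diagnostic={"plateau": curve.plateau},
        )
    q = 1.0 - curve.variance / curve.plateau
    return replace(curve, q_values=q)
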