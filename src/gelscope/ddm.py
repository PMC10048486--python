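"""Differential dynamic microscopy (DDM).

DDM performs a light-scattering experiment with a microscope: the image
structure function

    D(q, dt) = < |FFT2( I(x, y, t+dt) - I(x, y, t) )|^2 >_t,

azimuthally averaged over wavevector shells, decomposes as

    D(q, dt) = A(q) [1 - f(q, dt)] + B,

where A(q) carries the static scattering of the sample and optics, B is
the decorrelated (camera) noise floor, and f(q, dt) is the intermediate
scattering function.  For Brownian probes f = exp(-D_t q^2 dt), so fitted
relaxation times scale as 1/q^2 and the probe diffusivity follows without
tracking individual particles.  Inverting f at a single wavenumber gives
the mean-square displacement: for Gaussian displacement statistics
f = exp(-q^2 MSD / 4), hence MSD = (4/q^2)(-ln f).

Transform convention: the forward FFT is unscaled and the reported
spectrum is divided by the pixel count, so that summing the (unbinned)
spectrum over all modes reproduces the pixel-domain sum of the squared
difference image (Parseval), and spatially white noise of per-pixel
variance s^2 appears as a flat floor B = 2 s^2.  The convention is
recorded in the result's metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .dva import _lags_to_frames, default_lags
from .exceptions import (
    AmplitudeError,
    InsufficientDataError,
    LagError,
    ShapeError,
)
from .movie_io import ImageStack

__all__ = [
    "StructureFunction",
    "ISFCurve",
    "MSDCurve",
    "structure_function",
    "estimate_noise_and_amplitude",
    "extract_isf",
    "isf_to_msd",
]

FFT_NORM = "forward unscaled; spectrum divided by pixel count (|FFT|^2/Npix)"

#: Plateau acceptance per q bin, as in the DVA stage.
PLATEAU_SLOPE_TOL = 0.05


@dataclass
class StructureFunction:
    """Radially averaged image structure function of one movie.

    ``values[i, j]`` is D(q_bins[j], lags[i]) in counts^2 under the
    recorded normalization; ``amplitude_A``/``noise_floor_B`` are populated
    by :func:`estimate_noise_and_amplitude`, together with the per-q
    ``usable`` mask (bins whose long-lag plateau was accepted).
    """

    q_bins: np.ndarray  # um^-1, strictly increasing, spacing 2*pi/(L*pixel_size)
    lags: np.ndarray  # s
    values: np.ndarray  # (n_lags, n_q), counts^2
    n_pairs: np.ndarray  # per lag
    pixel_size: float
    noise_floor_B: Optional[float] = None
    amplitude_A: Optional[np.ndarray] = None
    usable: Optional[np.ndarray] = None
    elapsed_time: Optional[float] = None
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        qq, ll = np.meshgrid(self.q_bins, self.lags)
        return pd.DataFrame(
            {
                "elapsed_min": self.elapsed_time,
                "lag_s": ll.ravel(),
                "q_um_inv": qq.ravel(),
                "structure_function": self.values.ravel(),
            }
        )


@dataclass
class ISFCurve:
    """Intermediate scattering function at one wavenumber."""

    q: float  # um^-1 (bin center actually used)
    lags: np.ndarray  # s
    f_values: np.ndarray
    elapsed_time: Optional[float] = None
    meta: dict = field(default_factory=dict)


@dataclass
class MSDCurve:
    """Probe mean-square displacement extracted from the ISF."""

    lags: np.ndarray  # s (retained lags only)
    msd: np.ndarray  # um^2
    q_used: float  # um^-1
    beta_used: float
    exponent: float  # log-log slope over the central decade of retained lags
    elapsed_time: Optional[float] = None
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "elapsed_min": self.elapsed_time,
                "lag_s": self.lags,
                "msd_um2": self.msd,
                "q_um_inv": self.q_used,
                "beta_used": self.beta_used,
                "exponent": self.exponent,
            }
        )


def _square_frames(frames: np.ndarray, directive: Optional[str], meta: dict):
    T, H, W = frames.shape
    if H == W:
        return frames
    if directive == "crop":
        side = min(H, W)
        y0, x0 = (H - side) // 2, (W - side) // 2
        meta["squared"] = f"center-cropped {H}x{W} -> {side}x{side}"
        return frames[:, y0 : y0 + side, x0 : x0 + side]
    if directive == "pad":
        side = max(H, W)
        out = np.zeros((T, side, side), dtype=frames.dtype)
        out[:, :H, :W] = frames
        meta["squared"] = f"zero-padded {H}x{W} -> {side}x{side}"
        return out
    raise ShapeError(
        f"frames are {H}x{W}; pass square='crop' or square='pad' to analyze "
        "a non-square stack"
    )


def structure_function(
    stack: ImageStack,
    lags: Optional[Sequence[float]] = None,
    square: Optional[str] = None,
    batch: int = 64,
) -> StructureFunction:
    """Compute D(q, dt) by Fourier analysis of difference images.

    Per lag, the squared modulus of the 2-D FFT of
    ``frame(t+dt) - frame(t)`` is averaged over every overlapping start
    frame and then azimuthally averaged into annular bins one q-spacing
    wide (DC excluded, up to the Nyquist wavenumber).  Frame FFTs are
    computed once and differenced in Fourier space (the transform is
    linear), so the cost is one FFT per frame regardless of the lag count.

    Per-lag Parseval sums (spectral and pixel-domain) are accumulated in
    ``meta`` as a self-check of the recorded normalization.
    """
    if lags is None:
        lags = default_lags(stack)
    lag_frames = _lags_to_frames(stack, lags)
    meta: dict = {"fft_norm": FFT_NORM}
    frames = _square_frames(stack.frames, square, meta).astype(np.float64, copy=False)
    T, L, _ = frames.shape
    npix = L * L

    F = np.empty((T, L, L), dtype=np.complex128)
    for t0 in range(0, T, batch):
        F[t0 : t0 + batch] = np.fft.fft2(frames[t0 : t0 + batch])

    dq = 2.0 * np.pi / (L * stack.pixel_size)
    kx = np.fft.fftfreq(L, d=1.0 / L)  # integer mode numbers
    kmag = np.sqrt(kx[None, :] ** 2 + kx[:, None] ** 2)
    bin_index = np.rint(kmag).astype(int)
    n_bins = L // 2
    flat_bins = bin_index.ravel()
    in_range = (flat_bins >= 1) & (flat_bins <= n_bins)
    counts = np.bincount(flat_bins[in_range], minlength=n_bins + 1)[1:]

    values = np.empty((lag_frames.size, n_bins))
    n_pairs = np.empty(lag_frames.size, dtype=int)
    spectral_sum = np.empty(lag_frames.size)
    pixel_sum = np.empty(lag_frames.size)
    for i, l in enumerate(lag_frames):
        n = T - l
        power = np.zeros((L, L), dtype=np.float64)
        for t0 in range(0, n, batch):
            d = F[t0 + l : t0 + l + min(batch, n - t0)] - F[t0 : t0 + min(batch, n - t0)]
            power += np.einsum("tij->ij", d.real**2 + d.imag**2)
        power /= n * npix
        sums = np.bincount(flat_bins[in_range], weights=power.ravel()[in_range],
                           minlength=n_bins + 1)[1:]
        values[i] = sums / counts
        n_pairs[i] = n
        spectral_sum[i] = float(power.sum())
        diff = frames[l:] - frames[:-l]
        pixel_sum[i] = float(np.mean(np.sum(diff.astype(np.float64) ** 2, axis=(1, 2))))

    meta["parseval_spectral_sum"] = spectral_sum
    meta["parseval_pixel_sum"] = pixel_sum
    return StructureFunction(
        q_bins=dq * np.arange(1, n_bins + 1),
        lags=lag_frames * stack.frame_interval,
        values=values,
        n_pairs=n_pairs,
        pixel_size=stack.pixel_size,
        elapsed_time=stack.elapsed_time,
        meta=meta,
    )


def estimate_noise_and_amplitude(
    sf: StructureFunction,
    plateau_slope_tol: float = PLATEAU_SLOPE_TOL,
    noise_q_fraction: float = 0.1,
) -> StructureFunction:
    """Estimate the noise floor B and scattering amplitude A(q).

    B is the median of D over the top ``noise_q_fraction`` of wavenumbers
    at the smallest lag, where the static scattering amplitude has decayed
    to (nearly) nothing and only the decorrelated camera noise remains; it
    is treated as a single scalar constant.  A(q) is the long-lag plateau of
    D(q, dt) minus B, floored at zero; per-q plateau acceptance follows the
    DVA rule, and unaccepted bins are marked unusable.
    """
    if sf.lags.size < 3:
        raise InsufficientDataError(
            "need >= 3 lags (including long ones) to separate A(q) from B"
        )
    n_hi = max(int(np.ceil(noise_q_fraction * sf.q_bins.size)), 1)
    B = float(np.median(sf.values[0, -n_hi:]))

    window = sf.lags >= sf.lags.max() / np.sqrt(10.0)
    if np.count_nonzero(window) < 2:
        raise InsufficientDataError("need >= 2 lags in the top half-decade")
    logl = np.log10(sf.lags[window])
    v = sf.values[window, :]
    mean = v.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        slopes = np.polyfit(logl, v / np.where(mean > 0, mean, 1.0), 1)[0]
    usable = (mean > 0) & (np.abs(slopes) < plateau_slope_tol)
    if not np.any(usable):
        raise AmplitudeError(
            "no q bin reached an acceptable long-lag plateau "
            "(insufficient relaxation or ensemble averaging at long lags)",
            diagnostic={"max_lag_s": float(sf.lags.max()), "noise_floor_B": B},
        )
    A = np.clip(mean - B, 0.0, None)
    meta = dict(sf.meta)
    meta["plateau_slope_tol"] = plateau_slope_tol
    return replace(sf, noise_floor_B=B, amplitude_A=A, usable=usable, meta=meta)


def extract_isf(
    sf: StructureFunction,
    q: Optional[float] = None,
    probe_radius: Optional[float] = None,
) -> ISFCurve:
    """Extract f(q, dt) = 1 - (D - B)/A at one wavenumber.

    The target q defaults to ``2*pi/probe_radius`` — the wavenumber set by
    the probe size, so real-space (DVA) and Fourier-space estimates probe a
    comparable scale — and maps to the nearest q bin, whose actual center
    is reported.  Values are clipped to [-0.2, 1.2] with the clip count
    recorded; an A(q) below 5x the noise floor is flagged, not fatal.
    """
    if sf.amplitude_A is None or sf.noise_floor_B is None:
        sf = estimate_noise_and_amplitude(sf)
    if q is None:
        if probe_radius is None:
            raise ValueError("supply q or probe_radius")
        q = 2.0 * np.pi / probe_radius
    j = int(np.argmin(np.abs(sf.q_bins - q)))
    if not sf.usable[j]:
        raise AmplitudeError(
            f"q bin {sf.q_bins[j]:.3f} um^-1 has no accepted amplitude plateau",
            diagnostic={"requested_q": q, "bin_center": float(sf.q_bins[j])},
        )
    A, B = float(sf.amplitude_A[j]), sf.noise_floor_B
    raw = 1.0 - (sf.values[:, j] - B) / A
    clipped = int(np.count_nonzero((raw < -0.2) | (raw > 1.2)))
    f = np.clip(raw, -0.2, 1.2)
    return ISFCurve(
        q=float(sf.q_bins[j]),
        lags=sf.lags.copy(),
        f_values=f,
        elapsed_time=sf.elapsed_time,
        meta={
            "requested_q": float(q),
            "amplitude_A": A,
            "noise_floor_B": B,
            "amplitude_over_noise": A / B if B > 0 else np.inf,
            "low_amplitude": bool(B > 0 and A < 5.0 * B),
            "n_clipped": clipped,
        },
    )


def isf_to_msd(isf: ISFCurve, beta: float = 1.0) -> MSDCurve:
    """Invert the ISF into the probe mean-square displacement.

    ``msd = (4/q^2) * (-ln f)^(1/beta)``.  The default ``beta = 1`` is the
    Gaussian-displacement inversion ``f = exp(-q^2 MSD/4)``, exact for any
    Gaussian-increment process (Brownian, fractional Brownian, harmonic
    trap); a caller may supply a different beta to explore the stretched
    reading of the relaxation.  Lags where f lies outside (0, 1) are
    dropped (and counted); the reported exponent is the inverse-variance
    weighted least-squares log-log slope over the central decade of the
    well-measured retained lags.

    Weighting: for a measured ISF with (approximately lag-independent)
    additive noise s_f, error propagation gives
    ``var(ln msd) = (s_f / (beta * f * ln f))^2``, so each point enters
    with weight proportional to ``(f ln f)^2``.  Lags where the ISF has
    sunk to its noise floor thus contribute essentially nothing, instead
    of flattening the apparent slope.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    f = isf.f_values
    keep = (f > 0.0) & (f < 1.0)
    if np.count_nonzero(keep) < 5:
        raise InsufficientDataError(
            f"only {int(np.count_nonzero(keep))} lags have f in (0, 1); "
            "need >= 5 to extract an MSD"
        )
    lags = isf.lags[keep]
    fk = f[keep]
    msd = (4.0 / isf.q**2) * (-np.log(fk)) ** (1.0 / beta)
    weights = (fk * np.log(fk)) ** 2

    # Window: central decade of the lags that are actually measurable
    # (weight >= 1% of the best-measured point).
    measurable = weights >= 0.01 * weights.max()
    loglag = np.log10(lags)
    lm = loglag[measurable]
    if lm.max() - lm.min() > 1.0:
        center = 0.5 * (lm.max() + lm.min())
        window = np.abs(loglag - center) <= 0.5
        if np.count_nonzero(window) < 3:
            window = measurable
    else:
        window = measurable
    x = np.log(lags[window])
    y = np.log(msd[window])
    w = np.sqrt(weights[window])
    design = np.column_stack([x, np.ones_like(x)])
    slope = float(
        np.linalg.lstsq(design * w[:, None], y * w, rcond=None)[0][0]
    )

    return MSDCurve(
        lags=lags,
        msd=msd,
        q_used=isf.q,
        beta_used=beta,
        exponent=slope,
        elapsed_time=isf.elapsed_time,
        meta={"n_dropped": int(np.count_nonzero(~keep)),
              "fit_window_s": [float(lags[window][0]), float(lags[window][-1])]},
    )
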