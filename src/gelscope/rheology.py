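"""Bulk-rheology utilities: loss tangent, gel point, aging power laws.

Small-amplitude oscillatory shear during acid gelation yields the storage
modulus G'(t, w) and loss modulus G''(t, w) on a rectangular (time x
angular-frequency) grid.  The loss tangent tan(delta) = G''/G' tracks the
sol-gel transition: at the gel point it becomes independent of frequency,
taking a common value close to 1 (the Winter-Chambon criterion), and in the
post-peak aging regime both moduli decay as power laws of elapsed time so
tan(delta) itself follows a power law whose exponent is the difference of
the two moduli exponents.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .exceptions import DomainError, InsufficientDataError, MethodError, WindowError
from .fitting import PowerLawFit, fit_power_law

__all__ = [
    "RheoTrace",
    "GelPointResult",
    "loss_tangent",
    "detect_gel_point_winter",
    "aging_power_laws",
    "read_rheo_csv",
    "write_rheo_csv",
]


@dataclass
class RheoTrace:
    """Moduli table on a rectangular (time, frequency) grid.

    ``g_prime`` and ``g_double_prime`` have shape ``(n_times, n_omegas)``;
    missing cells are NaN.  ``tan_delta`` is populated by
    :func:`loss_tangent`.
    """

    times: np.ndarray  # elapsed time, min
    omegas: np.ndarray  # angular frequency, 1/s
    g_prime: np.ndarray  # Pa
    g_double_prime: np.ndarray  # Pa
    tan_delta: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.omegas = np.asarray(self.omegas, dtype=float)
        self.g_prime = np.asarray(self.g_prime, dtype=float)
        self.g_double_prime = np.asarray(self.g_double_prime, dtype=float)
        shape = (self.times.size, self.omegas.size)
        if self.g_prime.shape != shape or self.g_double_prime.shape != shape:
            raise DomainError(
                f"moduli must be rectangular with shape {shape}; got "
                f"{self.g_prime.shape} and {self.g_double_prime.shape}"
            )


@dataclass
class GelPointResult:
    """Critical gelation time and the loss tangent there."""

    tc: float  # min
    tan_delta_at_tc: float
    dispersion_at_tc: float  # coefficient of variation of tan(delta) across omega
    method: str  # "winter_chambon" or "ph_threshold_external"
    meta: dict = field(default_factory=dict)


def loss_tangent(trace: RheoTrace) -> RheoTrace:
    """Populate ``tan_delta = G''/G'`` elementwise.

    Cells where either modulus is missing (NaN) stay missing; a nonpositive
    modulus raises :class:`DomainError` naming the offending cell.
    """
    gp, gpp = trace.g_prime, trace.g_double_prime
    present = ~(np.isnan(gp) | np.isnan(gpp))
    bad = present & ((gp <= 0) | (gpp <= 0))
    if np.any(bad):
        i, j = map(int, np.argwhere(bad)[0])
        raise DomainError(
            f"nonpositive modulus at t={trace.times[i]:g} min, "
            f"omega={trace.omegas[j]:g} 1/s"
        )
    tan = np.full_like(gp, np.nan)
    tan[present] = gpp[present] / gp[present]
    return replace(trace, tan_delta=tan)


def detect_gel_point_winter(trace: RheoTrace) -> GelPointResult:
    """Locate the gel point as the time of frequency-independence of tan(delta).

    For every time the coefficient of variation (std/mean) of tan(delta)
    across the measured frequencies is computed; the gel point is the time
    minimizing it.  The minimum is refined by parabolic interpolation of the
    dispersion-vs-time curve — unless the grid minimum is already (numerically)
    zero, in which case the grid time is exact.  The result carries the
    omega-averaged tan(delta) at tc and the residual dispersion; a shallow
    minimum (curves that never intersect) is flagged in ``meta``.
    """
    if trace.omegas.size < 2:
        raise MethodError(
            "Winter-Chambon detection needs >= 2 frequencies; for a "
            "single-frequency trace use the changepoint fallback "
            "(gelscope.fitting.detect_changepoint)"
        )
    if trace.times.size < 4:
        raise InsufficientDataError("need >= 4 time points to locate a gel point")
    tr = trace if trace.tan_delta is not None else loss_tangent(trace)
    tan = tr.tan_delta
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(tan, axis=1)
        std = np.nanstd(tan, axis=1)
    cv = np.where(mean > 0, std / mean, np.inf)

    i = int(np.nanargmin(cv))
    t = trace.times
    tan_mean = mean

    if cv[i] <= 1e-10 or i == 0 or i == len(t) - 1:
        tc = float(t[i])
        tan_at_tc = float(tan_mean[i])
        disp = float(cv[i])
    else:
        # Parabolic vertex through the three samples bracketing the minimum;
        # the time grid may be non-uniform, so fit in t explicitly.
        ts = t[i - 1 : i + 2]
        cs = cv[i - 1 : i + 2]
        a, b, _c = np.polyfit(ts, cs, 2)
        if a > 0:
            tc = float(np.clip(-b / (2 * a), ts[0], ts[2]))
        else:
            tc = float(t[i])
        disp = float(max(np.polyval(np.polyfit(ts, cs, 2), tc), 0.0))
        tan_at_tc = float(np.interp(tc, t, tan_mean))

    shallow = bool(np.isfinite(cv[i]) and cv[i] > 0.5 * np.nanmedian(cv))
    return GelPointResult(
        tc=tc,
        tan_delta_at_tc=tan_at_tc,
        dispersion_at_tc=disp,
        method="winter_chambon",
        meta={"shallow_minimum": shallow, "grid_index": i},
    )


def aging_power_laws(
    trace: RheoTrace,
    window: Optional[Tuple[float, float]] = None,
    omega: Optional[float] = None,
) -> Tuple[PowerLawFit, PowerLawFit, PowerLawFit]:
    """Power-law fits of G'(t), G''(t) and tan(delta)(t) over the aging window.

    The aging window starts at the post-gel maximum of G' (auto-detected as
    the argmax when ``window`` is None).  A window reaching into the growth
    stage raises :class:`WindowError`.  Returns the (storage, loss,
    loss-tangent) fits at the chosen frequency (default: the lowest one).
    """
    tr = trace if trace.tan_delta is not None else loss_tangent(trace)
    j = 0 if omega is None else int(np.argmin(np.abs(trace.omegas - omega)))
    gp = tr.g_prime[:, j]
    gpp = tr.g_double_prime[:, j]
    tan = tr.tan_delta[:, j]
    t = tr.times

    i_peak = int(np.nanargmax(gp))
    t_peak = t[i_peak]
    if window is None:
        window = (float(t_peak), float(t[-1]))
    elif window[0] < t_peak:
        raise WindowError(
            f"aging window starts at {window[0]:g} min but G' peaks at "
            f"{t_peak:g} min; the window must exclude the growth stage"
        )
    fit_gp = fit_power_law(t, gp, window=window)
    fit_gpp = fit_power_law(t, gpp, window=window)
    fit_tan = fit_power_law(t, tan, window=window)
    return fit_gp, fit_gpp, fit_tan


def write_rheo_csv(trace: RheoTrace, path) -> None:
    """Long-format CSV: ``t_min, omega_per_s, g_prime_pa, g_double_prime_pa``."""
    tt, ww = np.meshgrid(trace.times, trace.omegas, indexing="ij")
    df = pd.DataFrame(
        {
            "t_min": tt.ravel(),
            "omega_per_s": ww.ravel(),
            "g_prime_pa": trace.g_prime.ravel(),
            "g_double_prime_pa": trace.g_double_prime.ravel(),
        }
    )
    df.to_csv(path, index=False)


def read_rheo_csv(path) -> RheoTrace:
    """Read the long-format moduli CSV back into a rectangular trace."""
    df = pd.read_csv(path)
    times = np.unique(df["t_min"].to_numpy())
    omegas = np.unique(df["omega_per_s"].to_numpy())
    shape = (times.size, omegas.size)
    gp = np.full(shape, np.nan)
    gpp = np.full(shape, np.nan)
    ti = np.searchsorted(times, df["t_min"].to_numpy())
    oi = np.searchsorted(omegas, df["omega_per_s"].to_numpy())
    gp[ti, oi] = df["g_prime_pa"].to_numpy()
    gpp[ti, oi] = df["g_double_prime_pa"].to_numpy()
    return RheoTrace(times=times, omegas=omegas, g_prime=gp, g_double_prime=gpp)
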