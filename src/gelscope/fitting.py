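"""Shared estimators for the imaging and rheology stages.

Four fitting primitives recur throughout the pipeline:

* stretched-exponential relaxation, ``exp[-(dt/tau)^beta]``, fitted to the
  dynamic order parameter Q(t, dt) and to the intermediate scattering
  function f(q, dt);
* power laws ``y = c x^a`` on log-log axes, for the aging of the shear
  moduli;
* a two-segment continuous piecewise-linear changepoint, locating the
  abrupt decay of a mobility curve at dynamical arrest;
* the probe-scale viscosity conversion (see :mod:`gelscope.constants`).

All fits are deterministic given their inputs: the stretched-exponential
fit multi-starts from a fixed grid of (tau, beta) and keeps the best
residual.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import linregress

from .constants import viscosity_from_tau
from .exceptions import (
    DomainError,
    FitError,
    InsufficientDataError,
    ParameterError,
)

__all__ = [
    "RelaxationFit",
    "PowerLawFit",
    "ViscosityEstimate",
    "ChangepointResult",
    "fit_stretched_exponential",
    "fit_power_law",
    "microscopic_viscosity",
    "detect_changepoint",
]

#: Bounds on the stretch exponent.  Below 0.2 the fit is degenerate on a
#: 10 s movie; above 2 is compressed-exponential territory not seen in
#: gelling milk.
BETA_BOUNDS = (0.2, 2.0)


@dataclass
class RelaxationFit:
    """Result of a stretched-exponential fit.

    ``diffusion_coefficient`` is populated when the fit was performed at a
    known wavenumber q (then ``D = 1/(tau q^2)``, the Brownian reading of
    the relaxation rate).
    """

    tau: float  # s
    beta: float
    residual_rms: float
    n_points: int
    converged: bool
    diffusion_coefficient: Optional[float] = None  # um^2/s
    at_boundary: bool = False
    meta: dict = field(default_factory=dict)

    def to_record(self) -> dict:
        return {
            "tau_s": self.tau,
            "beta": self.beta,
            "residual_rms": self.residual_rms,
            "n_points": self.n_points,
            "converged": self.converged,
            "diffusion_um2_s": self.diffusion_coefficient,
            "at_boundary": self.at_boundary,
        }


@dataclass
class PowerLawFit:
    exponent: float
    prefactor: float
    window: Tuple[float, float]
    r_squared: float

    def to_record(self) -> dict:
        return {
            "exponent": self.exponent,
            "prefactor": self.prefactor,
            "window": list(self.window),
            "r_squared": self.r_squared,
        }


@dataclass
class ViscosityEstimate:
    eta: float  # mPa*s
    tau: float  # s
    probe_radius: float  # um
    temperature: float  # K
    method: str  # "dva" | "ddm"

    def to_record(self) -> dict:
        return {
            "eta_mpas": self.eta,
            "tau_s": self.tau,
            "probe_radius_um": self.probe_radius,
            "temperature_k": self.temperature,
            "method": self.method,
        }


@dataclass
class ChangepointResult:
    changepoint: float  # abscissa units (elapsed minutes for mobility curves)
    slope_before: float
    slope_after: float
    degenerate: bool  # no abrupt decay: a single line fits (almost) as well
    sse: float


def _stretched(lags: np.ndarray, tau: float, beta: float) -> np.ndarray:
    return np.exp(-((lags / tau) ** beta))


def fit_stretched_exponential(
    lags: Sequence[float],
    values: Sequence[float],
    weights: Optional[Sequence[float]] = None,
    q: Optional[float] = None,
) -> RelaxationFit:
    """Least-squares fit of ``exp[-(dt/tau)^beta]``.

    Multi-starts over a decade grid of tau spanning the lag range crossed
    with beta in {0.5, 1.0, 1.5}; the best residual wins, making the result
    deterministic.  ``weights`` multiply the residuals (e.g. sqrt(n_pairs)
    to de-emphasize noisy long lags).  If ``q`` (um^-1) is given the
    Brownian diffusion coefficient ``1/(tau q^2)`` is reported alongside.
    """
    lags = np.asarray(lags, dtype=float)
    values = np.asarray(values, dtype=float)
    if lags.size != values.size:
        raise ParameterError("lags and values must have equal length")
    if lags.size < 5:
        raise InsufficientDataError("stretched-exponential fit needs >= 5 points")
    if np.any(lags <= 0):
        raise ParameterError("lags must be positive")
    if np.any(values < -0.2 - 1e-12) or np.any(values > 1.2 + 1e-12):
        raise ParameterError("values outside [-0.2, 1.2]; clip or mask first")
    w = np.ones_like(values) if weights is None else np.asarray(weights, dtype=float)

    lmin, lmax = lags.min(), lags.max()
    tau_lo, tau_hi = lmin * 1e-3, lmax * 1e3
    decades = np.arange(np.floor(np.log10(lmin)), np.ceil(np.log10(lmax)) + 1)
    tau_starts = 10.0**decades
    beta_starts = (0.5, 1.0, 1.5)

    def residuals(p):
        return w * (_stretched(lags, p[0], p[1]) - values)

    best = None
    for t0 in tau_starts:
        for b0 in beta_starts:
            try:
                sol = least_squares(
                    residuals,
                    x0=[t0, b0],
                    bounds=([tau_lo, BETA_BOUNDS[0]], [tau_hi, BETA_BOUNDS[1]]),
                    xtol=1e-14,
                    ftol=1e-14,
                    gtol=1e-14,
                )
            except Exception:
                continue
            if sol.success and (best is None or sol.cost < best.cost):
                best = sol
    if best is None:
        raise FitError(
            "stretched-exponential fit failed from every start "
            f"(n={lags.size}, lag range [{lmin:g}, {lmax:g}] s)"
        )
    tau, beta = float(best.x[0]), float(best.x[1])
    model = _stretched(lags, tau, beta)
    rms = float(np.sqrt(np.mean((model - values) ** 2)))
    at_boundary = bool(
        np.isclose(beta, BETA_BOUNDS[0])
        or np.isclose(beta, BETA_BOUNDS[1])
        or tau <= tau_lo * (1 + 1e-6)
        or tau >= tau_hi * (1 - 1e-6)
    )
    return RelaxationFit(
        tau=tau,
        beta=beta,
        residual_rms=rms,
        n_points=int(lags.size),
        converged=True,
        diffusion_coefficient=None if q is None else 1.0 / (tau * q**2),
        at_boundary=at_boundary,
    )


def fit_power_law(
    x: Sequence[float],
    y: Sequence[float],
    window: Optional[Tuple[float, float]] = None,
) -> PowerLawFit:
    """Least squares on (ln x, ln y) over ``window`` (inclusive).

    All points inside the window must be positive (:class:`DomainError`
    otherwise).  A constant ordinate yields exponent 0 with r^2 = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if window is None:
        window = (float(np.min(x)), float(np.max(x)))
    sel = (x >= window[0]) & (x <= window[1]) & ~np.isnan(y)
    if not np.any(sel):
        raise DomainError(f"empty fit window {window}")
    xs, ys = x[sel], y[sel]
    if np.any(xs <= 0) or np.any(ys <= 0):
        raise DomainError("power-law fit requires positive values in the window")
    if xs.size < 2:
        raise InsufficientDataError("power-law fit needs >= 2 points in the window")
    lx, ly = np.log(xs), np.log(ys)
    if np.allclose(ly, ly[0]):
        return PowerLawFit(0.0, float(np.exp(ly[0])), window, 1.0)
    res = linregress(lx, ly)
    return PowerLawFit(
        exponent=float(res.slope),
        prefactor=float(np.exp(res.intercept)),
        window=window,
        r_squared=float(res.rvalue**2),
    )


def microscopic_viscosity(
    fit: RelaxationFit,
    probe_radius: float,
    temperature: float,
    method: str = "dva",
) -> ViscosityEstimate:
    """Convert a fitted relaxation time into the microscopic viscosity.

    Exact inversion of ``tau = 6 pi eta R^3 / kB T`` (see
    :mod:`gelscope.constants`); tau in s and R in um yield eta in mPa*s.
    """
    if not fit.converged:
        raise FitError("cannot convert an unconverged relaxation fit to viscosity")
    if not (probe_radius > 0 and temperature > 0):
        raise ParameterError("probe_radius and temperature must be positive")
    eta = viscosity_from_tau(fit.tau, probe_radius, temperature)
    return ViscosityEstimate(
        eta=eta,
        tau=fit.tau,
        probe_radius=probe_radius,
        temperature=temperature,
        method=method,
    )


def detect_changepoint(curve_or_times, values=None) -> ChangepointResult:
    """Two-segment continuous piecewise-linear fit; the knee is the changepoint.

    Accepts either a mobility-curve object (with ``elapsed_times`` and
    ``values`` attributes) or two arrays.  The knee location is scanned over
    a fine grid between the second and second-to-last samples (including the
    sample positions themselves); for each candidate the continuous
    piecewise-linear model ``a + b t + d max(t - c, 0)`` is solved in closed
    form and the total squared residual minimized.  A series that a single
    line already explains is flagged ``degenerate`` (no abrupt decay).
    """
    if values is None:
        t = np.asarray(curve_or_times.elapsed_times, dtype=float)
        y = np.asarray(curve_or_times.values, dtype=float)
    else:
        t = np.asarray(curve_or_times, dtype=float)
        y = np.asarray(values, dtype=float)
    if t.size < 4:
        raise InsufficientDataError("changepoint detection needs >= 4 points")

    # Single-line baseline.
    A1 = np.column_stack([np.ones_like(t), t])
    coef1, *_ = np.linalg.lstsq(A1, y, rcond=None)
    sse_line = float(np.sum((A1 @ coef1 - y) ** 2))

    grid = np.unique(
        np.concatenate([t[1:-1], np.linspace(t[1], t[-2], 201)])
    )
    best = (np.inf, None, None)
    for c in grid:
        A = np.column_stack([np.ones_like(t), t, np.maximum(t - c, 0.0)])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        sse = float(np.sum((A @ coef - y) ** 2))
        if sse < best[0] - 1e-15:
            best = (sse, c, coef)
    sse, c, coef = best
    slope_before = float(coef[1])
    slope_after = float(coef[1] + coef[2])
    scale = float(np.sum((y - y.mean()) ** 2)) or 1.0
    degenerate = bool((sse_line - sse) / scale < 1e-3)
    return ChangepointResult(
        changepoint=float(c),
        slope_before=slope_before,
        slope_after=slope_after,
        degenerate=degenerate,
        sse=sse,
    )
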