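"""Synthetic ground truth: particle trajectories, rendered movies, rheology.

The generator emulates the experimental regime of GDL-acidified milk imaged
under bright-field microscopy: ~0.57 um-radius fat globules used as passive
probes, filmed at 50 Hz for 10 s at a handful of elapsed times during
gelation, plus small-amplitude oscillatory rheology of the same run.  Every
artifact carries its ground truth (trajectories in physical units, the
programmed gel time and aging exponents), so each analysis stage can be
verified without the original milk data.

Three motion models span the gelation sequence:

``brownian``
    Normal diffusion with coefficient D (um^2/s); the pre-gel state.
``fbm``
    Fractional Brownian motion with Hurst exponent H in (0, 1) and
    generalized coefficient D_alpha (um^2/s^{2H}), so that the ensemble
    mean-square displacement is ``4 D_alpha dt^{2H}``; the subdiffusive
    regime near the gel point.  H = 1/2 reduces exactly to ``brownian``.
``trapped``
    An overdamped harmonic well (position-reverting update with stiffness
    k in 1/s and noise scale D in um^2/s), whose MSD plateaus at ``4 D/k``;
    the arrested post-gel state, where probes are locally caged by the
    casein network.

fBm increments are synthesized from the exact fractional-Gaussian-noise
covariance (Cholesky factorization) for <= 2048 steps and by Davies-Harte
circulant embedding beyond that; exactness matters because the fBm MSD is
an oracle for the downstream analysis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .constants import stokes_einstein_diffusivity
from .exceptions import ConfigurationError, ParameterError
from .movie_io import ImageStack
from .rheology import RheoTrace

__all__ = [
    "MotionModel",
    "GelationSchedule",
    "Stage",
    "TrajectoryEnsemble",
    "OpticsModel",
    "simulate_trajectories",
    "render_movie",
    "synthesize_rheology",
    "simulate_schedule",
    "write_trajectories_csv",
]

#: Mean fat-globule radius (um) reported for pasteurized milk, with the
#: optional polydispersity sigma.
DEFAULT_PROBE_RADIUS_UM = 0.57
DEFAULT_PROBE_RADIUS_SIGMA_UM = 0.027
DEFAULT_TEMPERATURE_K = 298.15

#: Generalized coefficient of the gel-state fBm preset (um^2/s^{1/3}).
#: Chosen so the probe-scale relaxation (q ~ 11 um^-1) completes within a
#: 10 s movie while the MSD at 0.1 s stays below the pre-gel Brownian value.
GEL_STATE_FBM_COEFFICIENT = 0.03
GEL_STATE_HURST = 1.0 / 6.0


@dataclass
class MotionModel:
    """One of the three probe-motion models; exactly the fields of the
    selected kind are required (others must stay None)."""

    kind: str
    diffusion_coefficient: Optional[float] = None  # um^2/s (um^2/s^{2H} for fbm)
    hurst_exponent: Optional[float] = None
    trap_stiffness: Optional[float] = None  # 1/s
    noise_scale: Optional[float] = None  # um^2/s

    _REQUIRED = {
        "brownian": ("diffusion_coefficient",),
        "fbm": ("diffusion_coefficient", "hurst_exponent"),
        "trapped": ("trap_stiffness", "noise_scale"),
    }

    def __post_init__(self) -> None:
        if self.kind not in self._REQUIRED:
            raise ParameterError(f"unknown motion kind {self.kind!r}")
        required = self._REQUIRED[self.kind]
        for name in ("diffusion_coefficient", "hurst_exponent", "trap_stiffness", "noise_scale"):
            value = getattr(self, name)
            if name in required and value is None:
                raise ParameterError(f"{self.kind} model requires field {name!r}")
            if name not in required and value is not None:
                raise ParameterError(f"field {name!r} is not part of the {self.kind} model")
        if self.kind in ("brownian", "fbm") and self.diffusion_coefficient < 0:
            raise ParameterError("diffusion_coefficient must be >= 0")
        if self.kind == "fbm" and not (0.0 < self.hurst_exponent < 1.0):
            raise ParameterError("hurst_exponent must lie in (0, 1)")
        if self.kind == "trapped":
            if self.trap_stiffness <= 0:
                raise ParameterError("trap_stiffness must be > 0")
            if self.noise_scale < 0:
                raise ParameterError("noise_scale must be >= 0")

    @classmethod
    def brownian(cls, diffusion_coefficient: float) -> "MotionModel":
        return cls("brownian", diffusion_coefficient=diffusion_coefficient)

    @classmethod
    def fbm(cls, hurst_exponent: float, coefficient: float) -> "MotionModel":
        return cls("fbm", diffusion_coefficient=coefficient, hurst_exponent=hurst_exponent)

    @classmethod
    def trapped(cls, trap_stiffness: float, noise_scale: float) -> "MotionModel":
        return cls("trapped", trap_stiffness=trap_stiffness, noise_scale=noise_scale)

    def to_dict(self) -> dict:
        return {
            k: v
            for k, v in self.__dict__.items()
            if v is not None
        }


@dataclass
class Stage:
    """One elapsed time of the gelation run: its motion model and the
    nominal matrix viscosity (mPa*s) used as ground-truth label."""

    elapsed_time: float  # min
    motion: MotionModel
    viscosity: float  # mPa*s

    def __post_init__(self) -> None:
        if self.viscosity <= 0:
            raise ParameterError("stage viscosity must be > 0")


@dataclass
class GelationSchedule:
    """The programmed incubation -> network-formation progression.

    ``stages`` must be ordered by strictly increasing elapsed time.  The
    probe radius and temperature feed the Stokes-Einstein conversions on
    both the simulation and analysis sides.
    """

    stages: List[Stage]
    probe_radius: float = DEFAULT_PROBE_RADIUS_UM  # um
    temperature: float = DEFAULT_TEMPERATURE_K  # K
    polydispersity_sigma: float = 0.0  # um; 0 disables radius polydispersity

    def __post_init__(self) -> None:
        if not self.stages:
            raise ParameterError("a schedule needs at least one stage")
        times = [s.elapsed_time for s in self.stages]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ParameterError("elapsed_time labels must be strictly increasing")
        if self.probe_radius <= 0:
            raise ParameterError("probe_radius must be > 0")

    @classmethod
    def acid_milk_default(cls) -> "GelationSchedule":
        """Six elapsed times emulating acid gelation of milk at 25 C.

        Pre-gel stages are Newtonian with a mild viscosity rise (local
        aggregation of casein micelles before the gel point); the 40 min
        stage is the subdiffusive gel state (fBm, H = 1/6); the 50 min
        stage is arrested (trapped), where probe diffusion is frozen by
        the percolated casein network.  Viscosity labels of the non-
        Newtonian stages are nominal.
        """
        R, T = DEFAULT_PROBE_RADIUS_UM, DEFAULT_TEMPERATURE_K

        def d_of(eta):
            return stokes_einstein_diffusivity(eta, R, T)

        stages = [
            Stage(0.0, MotionModel.brownian(d_of(2.0)), 2.0),
            Stage(10.0, MotionModel.brownian(d_of(2.2)), 2.2),
            Stage(20.0, MotionModel.brownian(d_of(2.5)), 2.5),
            Stage(30.0, MotionModel.brownian(d_of(3.0)), 3.0),
            Stage(40.0, MotionModel.fbm(GEL_STATE_HURST, GEL_STATE_FBM_COEFFICIENT), 20.0),
            Stage(50.0, MotionModel.trapped(50.0, 0.01), 100.0),
        ]
        return cls(stages=stages, probe_radius=R, temperature=T)


@dataclass
class TrajectoryEnsemble:
    """Ground-truth 2-D particle paths at a uniform frame interval.

    ``positions`` are box-wrapped (what the camera sees); ``unwrapped``
    retains the continuous paths for MSD ground truth.  Both have shape
    ``(n_particles, n_frames, 2)`` with columns (x, y) in um; x points
    rightward and y downward, origin at the top-left pixel center.
    """

    positions: np.ndarray
    unwrapped: np.ndarray
    frame_interval: float  # s
    box: Tuple[float, float]  # um
    seed: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.unwrapped = np.asarray(self.unwrapped, dtype=float)
        if self.positions.shape != self.unwrapped.shape or self.positions.ndim != 3:
            raise ParameterError("positions and unwrapped must share shape (n, T, 2)")
        if self.frame_interval <= 0:
            raise ParameterError("frame_interval must be > 0")
        if not np.all(np.isfinite(self.unwrapped)):
            raise ParameterError("trajectory coordinates must be finite")

    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]

    @property
    def n_frames(self) -> int:
        return self.positions.shape[1]

    def ensemble_msd(self, lags_frames: Optional[Sequence[int]] = None):
        """Ensemble + time averaged MSD (um^2) from the unwrapped paths.

        Returns ``(lags_s, msd)``.  All overlapping start frames are used.
        """
        T = self.n_frames
        if lags_frames is None:
            lags_frames = range(1, T)
        lags = np.asarray([int(l) for l in lags_frames])
        if np.any(lags < 1) or np.any(lags >= T):
            raise ParameterError("MSD lags must lie in [1, n_frames)")
        msd = np.empty(lags.size)
        for i, l in enumerate(lags):
            d = self.unwrapped[:, l:, :] - self.unwrapped[:, :-l, :]
            msd[i] = np.mean(np.sum(d**2, axis=-1))
        return lags * self.frame_interval, msd


def _fgn_covariance(n_steps: int, hurst: float, step_var: float) -> np.ndarray:
    k = np.arange(n_steps, dtype=float)
    h2 = 2.0 * hurst
    return 0.5 * step_var * (
        np.abs(k + 1) ** h2 - 2.0 * np.abs(k) ** h2 + np.abs(k - 1) ** h2
    )


def _fgn_increments(rng, n_steps, n_series, hurst, step_var):
    """Fractional Gaussian noise, exact for <= 2048 steps (Cholesky),
    Davies-Harte circulant embedding otherwise."""
    gamma = _fgn_covariance(n_steps, hurst, step_var)
    if n_steps <= 2048:
        cov = gamma[np.abs(np.subtract.outer(np.arange(n_steps), np.arange(n_steps)))]
        L = np.linalg.cholesky(cov + 1e-14 * step_var * np.eye(n_steps))
        z = rng.standard_normal((n_steps, n_series))
        return L @ z
    # Davies-Harte: embed the covariance in a circulant of size 2M.
    M = n_steps
    row = np.concatenate([gamma, gamma[-2:0:-1]])
    eig = np.fft.rfft(row).real
    if np.any(eig < -1e-8 * step_var):
        raise ParameterError("Davies-Harte embedding failed (negative eigenvalue)")
    eig = np.clip(eig, 0.0, None)
    n_fft = row.size
    out = np.empty((M, n_series))
    for j in range(n_series):
        z = rng.standard_normal(n_fft)
        # Circular convolution with the filter whose DFT is sqrt(eig)
        # reproduces the circulant covariance exactly.
        spec = np.fft.rfft(z) * np.sqrt(eig)
        out[:, j] = np.fft.irfft(spec, n=n_fft)[:M]
    return out


def simulate_trajectories(
    model: MotionModel,
    n_particles: int,
    n_frames: int,
    frame_interval: float,
    box: Tuple[float, float],
    seed: int,
    diffusion_per_particle: Optional[np.ndarray] = None,
) -> TrajectoryEnsemble:
    """Simulate probe trajectories under the given motion model.

    Parameters
    ----------
    model : MotionModel
    n_particles, n_frames : ensemble and movie sizes (n_frames >= 2).
    frame_interval : s between frames.
    box : (width, height) of the periodic simulation box in um; wrapped
        coordinates are what the renderer sees, unwrapped ones are kept for
        MSD ground truth.
    seed : RNG seed; identical seeds give bit-identical ensembles.
    diffusion_per_particle : optional per-particle D (brownian only), used
        by the polydispersity option of :func:`simulate_schedule`.
    """
    if n_frames < 2:
        raise ParameterError("n_frames must be >= 2")
    if n_particles < 0:
        raise ParameterError("n_particles must be >= 0")
    rng = np.random.default_rng(seed)
    dt = float(frame_interval)
    w, h = float(box[0]), float(box[1])
    start = rng.uniform([0.0, 0.0], [w, h], size=(n_particles, 2))

    n_steps = n_frames - 1
    if model.kind == "brownian":
        d = model.diffusion_coefficient
        if diffusion_per_particle is not None:
            d = np.asarray(diffusion_per_particle, dtype=float)[:, None, None]
            if np.any(d < 0):
                raise ParameterError("diffusion_per_particle must be >= 0")
        steps = rng.standard_normal((n_particles, n_steps, 2)) * np.sqrt(2.0 * d * dt)
    elif model.kind == "fbm":
        step_var = 2.0 * model.diffusion_coefficient * dt ** (2.0 * model.hurst_exponent)
        if step_var == 0.0:
            steps = np.zeros((n_particles, n_steps, 2))
        else:
            flat = _fgn_increments(
                rng, n_steps, 2 * n_particles, model.hurst_exponent, step_var
            )
            steps = flat.T.reshape(n_particles, 2, n_steps).transpose(0, 2, 1)
    elif model.kind == "trapped":
        k, d = model.trap_stiffness, model.noise_scale
        var = d / k  # stationary per-axis variance, um^2
        decay = math.exp(-k * dt)
        kick = math.sqrt(var * (1.0 - decay**2))
        x = rng.standard_normal((n_particles, 2)) * math.sqrt(var)
        path = np.empty((n_particles, n_frames, 2))
        path[:, 0] = x
        for t in range(1, n_frames):
            x = x * decay + kick * rng.standard_normal((n_particles, 2))
            path[:, t] = x
        unwrapped = start[:, None, :] + path
        wrapped = np.mod(unwrapped, [w, h])
        return TrajectoryEnsemble(wrapped, unwrapped, dt, (w, h), seed,
                                  meta={"model": model.to_dict()})
    else:  # pragma: no cover - guarded by MotionModel validation
        raise ParameterError(f"unknown motion kind {model.kind!r}")

    unwrapped = np.concatenate(
        [start[:, None, :], start[:, None, :] + np.cumsum(steps, axis=1)], axis=1
    )
    wrapped = np.mod(unwrapped, [w, h])
    return TrajectoryEnsemble(wrapped, unwrapped, dt, (w, h), seed,
                              meta={"model": model.to_dict()})


@dataclass
class OpticsModel:
    """Idealized bright-field optics for rendering probe movies.

    Each probe is drawn as a 2-D Gaussian spot of width ``psf_sigma``
    (pixels) evaluated analytically at its sub-pixel position; spots sum
    linearly, then shot noise (Poisson) and Gaussian read noise are applied
    and the frame is quantized to the chosen bit depth.  The default
    ``psf_sigma`` of 1.0 px (0.10 um at 0.1 um/px) is the diffraction-
    limited Gaussian sigma of a high-NA oil-immersion objective at 550 nm.
    """

    pixel_size: float = 0.1  # um/px
    image_shape: Tuple[int, int] = (256, 256)  # (H, W) px
    psf_sigma: float = 1.0  # px
    peak_intensity: float = 400.0  # counts above background per spot
    background: float = 200.0  # counts
    read_noise_sigma: float = 3.0  # counts
    shot_noise: bool = True
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ParameterError("pixel_size must be > 0")
        if self.psf_sigma <= 0:
            raise ParameterError("psf_sigma must be > 0")
        if self.bit_depth not in (8, 16):
            raise ParameterError("bit_depth must be 8 or 16")
        if self.peak_intensity + self.background > 2**self.bit_depth - 1:
            raise ParameterError(
                "peak_intensity + background exceeds the bit-depth ceiling"
            )


def render_movie(
    traj: TrajectoryEnsemble, optics: OpticsModel, seed: int = 0
) -> ImageStack:
    """Render a trajectory ensemble into a calibrated movie.

    Spots are rendered analytically (separable Gaussian evaluated at the
    sub-pixel center), noise is applied after summing spots, and pixels
    exceeding the bit-depth ceiling are clipped with the count recorded in
    ``stack.meta['render_report']``.
    """
    H, W = optics.image_shape
    px = optics.pixel_size
    sigma = optics.psf_sigma
    radius = int(math.ceil(4.0 * sigma)) + 1
    n_frames = traj.n_frames
    ceiling = float(2**optics.bit_depth - 1)
    rng = np.random.default_rng(seed)

    frames = np.empty((n_frames, H, W), dtype=np.float64)
    clipped = 0
    for t in range(n_frames):
        canvas = np.full((H, W), optics.background, dtype=np.float64)
        for p in range(traj.n_particles):
            x_um, y_um = traj.positions[p, t]
            cx = x_um / px  # column coordinate, px
            cy = y_um / px  # row coordinate, px
            j0 = max(int(math.floor(cx)) - radius, 0)
            j1 = min(int(math.floor(cx)) + radius + 1, W)
            i0 = max(int(math.floor(cy)) - radius, 0)
            i1 = min(int(math.floor(cy)) + radius + 1, H)
            if j0 >= j1 or i0 >= i1:
                continue
            gx = np.exp(-((np.arange(j0, j1) - cx) ** 2) / (2.0 * sigma**2))
            gy = np.exp(-((np.arange(i0, i1) - cy) ** 2) / (2.0 * sigma**2))
            canvas[i0:i1, j0:j1] += optics.peak_intensity * np.outer(gy, gx)
        if optics.shot_noise:
            canvas = rng.poisson(canvas).astype(np.float64)
        if optics.read_noise_sigma > 0:
            canvas = canvas + rng.normal(0.0, optics.read_noise_sigma, size=(H, W))
        canvas = np.rint(canvas)
        over = canvas > ceiling
        under = canvas < 0
        clipped += int(np.count_nonzero(over) + np.count_nonzero(under))
        frames[t] = np.clip(canvas, 0.0, ceiling)

    if clipped:
        warnings.warn(
            f"{clipped} pixels clipped at the {optics.bit_depth}-bit ceiling/floor",
            stacklevel=2,
        )
    dtype = np.uint8 if optics.bit_depth == 8 else np.uint16
    return ImageStack(
        frames=frames.astype(dtype),
        pixel_size=px,
        frame_interval=traj.frame_interval,
        elapsed_time=traj.meta.get("elapsed_time"),
        source="synthetic",
        meta={
            "render_report": {"clipped_pixels": clipped},
            "render_seed": seed,
            "motion_model": traj.meta.get("model", {}),
            "psf_sigma_px": sigma,
        },
    )


def simulate_schedule(
    schedule: GelationSchedule,
    optics: Optional[OpticsModel] = None,
    n_particles: int = 500,
    n_frames: int = 500,
    frame_interval: float = 0.02,
    seed: int = 0,
) -> List[Tuple[ImageStack, TrajectoryEnsemble]]:
    """Simulate and render one movie per schedule stage.

    Defaults reproduce the imaging regime: 256x256 px at 0.1 um/px,
    500 frames at 50 Hz (10 s).  Per-stage seeds are spawned
    deterministically from ``seed``.  With ``polydispersity_sigma > 0``
    each Brownian particle gets its own Stokes-Einstein D drawn from the
    Gaussian radius distribution.
    """
    optics = optics or OpticsModel()
    H, W = optics.image_shape
    box = (W * optics.pixel_size, H * optics.pixel_size)
    out = []
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(2 * len(schedule.stages))
    for i, stage in enumerate(schedule.stages):
        traj_seed = int(children[2 * i].generate_state(1)[0] % 2**31)
        render_seed = int(children[2 * i + 1].generate_state(1)[0] % 2**31)
        d_per = None
        if schedule.polydispersity_sigma > 0 and stage.motion.kind == "brownian":
            rr = np.random.default_rng(traj_seed ^ 0x5EED).normal(
                schedule.probe_radius, schedule.polydispersity_sigma, n_particles
            )
            rr = np.clip(rr, 0.1 * schedule.probe_radius, None)
            d_per = stage.motion.diffusion_coefficient * schedule.probe_radius / rr
        traj = simulate_trajectories(
            stage.motion, n_particles, n_frames, frame_interval, box, traj_seed,
            diffusion_per_particle=d_per,
        )
        traj.meta["elapsed_time"] = stage.elapsed_time
        traj.meta["viscosity_mpas"] = stage.viscosity
        stack = render_movie(traj, optics, seed=render_seed)
        stack.elapsed_time = stage.elapsed_time
        out.append((stack, traj))
    return out


def write_trajectories_csv(traj: TrajectoryEnsemble, path) -> None:
    """Ground-truth CSV: ``particle_id, frame, x_um, y_um`` (wrapped coords)."""
    n, T, _ = traj.positions.shape
    pid = np.repeat(np.arange(n), T)
    frame = np.tile(np.arange(T), n)
    flat = traj.positions.reshape(n * T, 2)
    pd.DataFrame(
        {"particle_id": pid, "frame": frame, "x_um": flat[:, 0], "y_um": flat[:, 1]}
    ).to_csv(path, index=False)


def synthesize_rheology(
    tc: float = 32.0,
    aging_exponent_storage: float = -0.23,
    aging_exponent_loss: float = -0.38,
    omegas: Sequence[float] = (1.0, 5.0, 10.0, 50.0, 100.0),
    noise_cv: float = 0.0,
    seed: int = 0,
    times: Optional[np.ndarray] = None,
    t_peak: Optional[float] = None,
    g_incubation: float = 0.02,
    g_peak: float = 50.0,
) -> RheoTrace:
    """Three-stage synthetic rheology with an exact Winter-Chambon crossover.

    The trace runs through incubation (near-zero moduli, liquid-like
    tan(delta) > 1 that is frequency-dependent), rapid modulus growth
    constructed so that the tan(delta)(omega) curves all intersect at
    ``t = tc`` with common value exactly 1, and a post-peak aging stage in
    which ``G' = G_peak (t/t_peak)^a`` and ``G'' propto t^b`` are exact
    power laws (defaults a = -0.23, b = -0.38), making
    ``tan(delta) propto t^{b-a}``.

    ``noise_cv`` applies independent multiplicative log-normal noise of
    that coefficient of variation to both moduli.
    """
    if tc <= 0:
        raise ParameterError("tc must be > 0")
    if aging_exponent_storage >= 0 or aging_exponent_loss >= 0:
        raise ParameterError("aging exponents must be negative")
    if noise_cv < 0:
        raise ParameterError("noise_cv must be >= 0")
    omegas = np.asarray(omegas, dtype=float)
    if omegas.size < 2:
        raise ConfigurationError(
            "a Winter-Chambon crossover needs at least 2 frequencies"
        )
    if times is None:
        times = np.arange(1.0, 91.0)
    times = np.asarray(times, dtype=float)
    if t_peak is None:
        t_peak = tc + 8.0
    if not (tc < t_peak <= times.max()):
        raise ParameterError("need tc < t_peak <= max(times)")

    omega_ref = 10.0
    # tan(delta) just past the peak, mildly frequency dependent (< 1, gel).
    c_peak = 0.45 * (omegas / omega_ref) ** 0.06
    # Liquid-like incubation spread (> 1, frequency dependent).
    r_inc = 4.0 * (omegas / omega_ref) ** 0.15

    t = times[:, None]
    w_tan = np.empty((times.size, omegas.size))
    g_prime = np.empty_like(w_tan)

    incub = times < tc
    growth = (times >= tc) & (times <= t_peak)
    aging = times > t_peak

    # Loss tangent: linear approach to the common crossover value 1 at tc,
    # linear bridge to c_peak at t_peak, exact power law beyond.
    w_tan[incub] = 1.0 + r_inc[None, :] * ((tc - t[incub]) / tc)
    w_tan[growth] = 1.0 + (c_peak[None, :] - 1.0) * ((t[growth] - tc) / (t_peak - tc))
    diff = aging_exponent_loss - aging_exponent_storage
    w_tan[aging] = c_peak[None, :] * (t[aging] / t_peak) ** diff

    # Storage modulus: slow incubation creep, exponential growth spanning
    # g_incubation -> g_peak across the gelation window, power-law aging.
    g_prime[incub] = g_incubation * (0.5 + 0.5 * t[incub] / tc)
    ratio = g_peak / g_incubation
    g_prime[growth] = g_incubation * ratio ** ((t[growth] - tc) / (t_peak - tc))
    g_prime[aging] = g_peak * (t[aging] / t_peak) ** aging_exponent_storage

    g_double_prime = g_prime * w_tan

    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        s = math.sqrt(math.log(1.0 + noise_cv**2))
        g_prime = g_prime * np.exp(s * rng.standard_normal(g_prime.shape))
        g_double_prime = g_double_prime * np.exp(
            s * rng.standard_normal(g_double_prime.shape)
        )

    return RheoTrace(
        times=times,
        omegas=omegas,
        g_prime=g_prime,
        g_double_prime=g_double_prime,
        meta={
            "tc_min": tc,
            "t_peak_min": float(t_peak),
            "aging_exponent_storage": aging_exponent_storage,
            "aging_exponent_loss": aging_exponent_loss,
            "noise_cv": noise_cv,
            "seed": seed,
        },
    )
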