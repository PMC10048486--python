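# Methods

This note documents the models, estimators, defaults and numerical
choices behind `gelscope`, and what the synthetic-data suite does and
does not establish about real milk movies.

## Physical picture

Acid gelation of milk proceeds through incubation (the acidulant slowly
discharges the casein micelles), a percolation transition at a critical
time t_c at which the casein network first spans the sample, and aging of
the formed gel. Fat globules (mean radius R = 0.57 μm, spread
σ_R = 0.027 μm) are used as passive probes: their thermal motion reports
the viscoelasticity of the surrounding casein matrix at the probe's own
length scale. All analyses run at T = 298.15 K unless configured
otherwise.

## Synthetic ground truth

### Motion models

- **brownian** — independent Gaussian steps with per-axis variance
  2 D Δt; ensemble MSD = 4 D Δt. D in μm²/s.
- **fbm** — fractional Brownian motion with Hurst exponent H ∈ (0, 1)
  and generalized coefficient D_α (μm²/s^{2H}); MSD = 4 D_α Δt^{2H}.
  Increments are fractional Gaussian noise synthesized from the exact
  autocovariance by Cholesky factorization up to 2048 steps, and by
  Davies–Harte circulant embedding beyond (filtering white noise with
  the square root of the circulant eigenvalues reproduces the embedded
  covariance exactly; the implementation is validated against the
  closed-form MSD). Exactness matters because the fBm MSD is an oracle
  for the DDM inversion. H = 1/2 reduces to the Brownian case.
- **trapped** — an overdamped harmonic well (exact
  Ornstein–Uhlenbeck update with stiffness k in 1/s and noise scale D in
  μm²/s), started from its stationary distribution; MSD plateaus at
  4 D/k. This is the arrested state: the well stands in for the local
  cage of the casein network, whose confinement mechanism the imaging
  data do not resolve.

Trajectories live in a periodic box matching the field of view; wrapped
coordinates feed the renderer while unwrapped coordinates are retained as
MSD ground truth. Because the analysis wavenumbers are integer multiples
of 2π/L, wrapping does not alter the Fourier-side statistics.

### Default gelation schedule (`GelationSchedule.acid_milk_default`)

Six movies at elapsed times 0–50 min: four pre-gel Brownian stages whose
viscosity creeps from 2.0 to 3.0 mPa·s (local aggregation before the gel
point), a subdiffusive gel-state stage (fbm, H = 1/6), and an arrested
stage (trapped, k = 50 s⁻¹, D = 0.01 μm²/s). The gel-state amplitude
D_α = 0.03 μm²/s^{1/3} was fixed once so that the relaxation at the probe
wavenumber (q ≈ 11 μm⁻¹, τ_q = 1/(q² D_α)³ ≈ 0.02 s after the stretched
reading) completes comfortably inside a 10 s movie — otherwise the
structure-function plateau, and with it A(q), is not estimable — while
the MSD at Δt = 0.1 s stays below the pre-gel Brownian value. The
schedule's viscosity labels for the two non-Newtonian stages are nominal.

### Optics

Movies default to 256×256 px at 0.1 μm/px, 500 frames at 50 Hz (10 s).
Probes are rendered as analytic 2-D Gaussian spots of σ = 1.0 px
(0.10 μm — the diffraction-limited Gaussian width of a high-NA
oil-immersion objective at ~550 nm), summed linearly, then Poisson shot
noise and Gaussian read noise (σ = 3 counts) are applied and the frame is
quantized to 16 bits. Spot amplitude is 400 counts over a 200-count
background. Pixels past the bit-depth ceiling are clipped, warned about,
and counted in the render report. Radius polydispersity is off by
default (optionally Gaussian with σ = 0.027 μm, entering through
per-particle Stokes–Einstein diffusivities); the analyses all use the
mean radius.

### Synthetic rheology

Three stages on a 1-min grid to 90 min: incubation (G′ ≈ 0.02 Pa,
liquid-like tan δ > 1 with frequency spread), growth (G′ rises
exponentially from 0.02 to 50 Pa between t_c = 32 min and
t_peak = 40 min), and aging (G′ = G_peak (t/t_peak)^a exactly, with
G″ = G′ · tan δ and tan δ ∝ t^{b−a}; defaults a = −0.23, b = −0.38, so
tan δ ~ t^{−0.15}). The loss tangent is constructed to pass through
exactly 1 at t_c for every frequency — a noise-free Winter–Chambon
crossover — while being frequency dependent on both sides, so the
dispersion minimum is unique. Noise, when requested, is independent
multiplicative log-normal on both moduli with the given coefficient of
variation.

## Estimators

### DVA

The per-pair statistic is the pixel variance of frame(t+Δt) − frame(t),
averaged over **all** overlapping start frames (maximal ensemble; the
pair count is recorded per lag, since long lags are intrinsically
ensemble-starved). Default lag grid: 20 log-spaced lags from one frame
interval to a quarter of the movie duration, which keeps ≥ ~375 pairs at
the longest lag of a 10 s/50 Hz movie.

Two plateau estimators:

- `"lag"` (default): mean variance over the top half-decade of lags,
  accepted only if the local relative slope there is < 0.05/decade.
  For Gaussian-spot optics the variance approaches its plateau only
  algebraically — integrating exp(−D q² Δt) against the spot-power
  weight q·exp(−q²σ²) gives exactly
  Q(Δt) = 1/(1 + D Δt/σ²) — so slow movies (relaxation time within
  ~1/50 of the lag cap) legitimately fail this acceptance. The failure
  is an explicit, diagnosable error, mirroring the long-lag
  ensemble-averaging artifact seen in real DVA data.
- `"frame"`: I∞ = 2 × the mean per-frame spatial variance, the exact
  infinite-lag limit for decorrelated frames. The pipeline falls back to
  it (and counts the fallback) when the lag plateau is rejected.

The 1/(1+x) form also means the fitted stretch exponent of Q is
β ≈ 0.5–0.6 even for perfectly Brownian motion under these broadband
Gaussian optics: the real-space variance mixes all wavenumbers. A
near-single-exponential Q, as real milk movies can show, is a property
of band-limited microscope optics, not of the dynamics alone. The DVA τ
is therefore reported alongside the DDM τ with their ratio; analytically
τ_DVA/τ_DDM ≈ C·(σ_psf q)² with C ≈ 1.5–2 from the fit shape, ≈ 2–3 at
the default optics, and the suite asserts order-of-magnitude agreement
rather than equality.

### DDM

Frame FFTs are computed once (the transform is linear, so difference
spectra are differences of spectra); the convention is forward-unscaled
with the spectrum divided by the pixel count, making white noise of
per-pixel variance s² appear as a flat floor B = 2s² and the mode-summed
spectrum equal the pixel-domain energy (a per-lag Parseval self-check is
stored in the metadata). Radial bins are annuli one q-spacing
(2π/(L·pixel size)) wide, DC excluded, up to Nyquist. Non-square frames
require an explicit crop/pad directive. No window function is applied by
default: differencing already removes static structure, and windowing
would change the A(q) normalization.

B is the median of D(q, Δt_min) over the top 10 % of wavenumbers, where
the optical transfer of micron-scale probes has decayed to nothing;
it is treated as a single scalar. A(q) is the long-lag plateau of
D(q, Δt) minus B (floored at 0), per-q, with the same slope-acceptance
rule as DVA; unaccepted bins are unusable and requesting them is an
error. The ISF is f = 1 − (D − B)/A, clipped to [−0.2, 1.2] with clips
counted; the default analysis wavenumber is the bin nearest 2π/R
(≈ 11.0 μm⁻¹ for R = 0.57 μm; the bin center actually used is always
reported).

### ISF → MSD

For any Gaussian-increment process f(q, Δt) = exp(−q²⟨r²(Δt)⟩/4), so the
default inversion is ⟨r²⟩ = (4/q²)(−ln f). The generalized form
(4/q²)(−ln f)^{1/β} is available, but note that feeding it the β fitted
from f itself collapses any subdiffusive scaling back to slope 1 (for
fBm, f is exactly a stretched exponential with β = 2H); the Gaussian
β = 1 reading is what exposes the 1 → 1/3 slope change across gelation.
Lags with f outside (0, 1) are dropped and counted. The scaling exponent
is a weighted least-squares slope of ln MSD vs ln Δt over the central
decade of the measurably weighted lags, with weights ∝ (f ln f)² — the
exact inverse-variance weights for additive ISF noise of constant
amplitude, since var(ln MSD) = (s_f/(β f ln f))². Without the weighting,
lags where f has sunk to its statistical floor (|f| ~ a few 10⁻³ at this
ensemble size) masquerade as an MSD plateau and bias the slope low.

### PIV

Blocks of 32 px (50 % overlap) are matched by normalized
cross-correlation (`skimage.feature.match_template`) within a ±8 px
search window, with three-point parabolic sub-pixel refinement per axis.
Blocks with correlation peak < 0.3 are invalid and excluded from
averages. The default lag is 0.1 s (5 frames at 50 Hz); frame pairs
default to disjoint (stride = lag), which is ample ensemble for a
qualitative monitor. The "heat map" quantity is the mean displacement
magnitude in μm per block — the number a colormap would render. With
multiple independently moving probes per block the NCC peak is a
consensus displacement, so the quantitative RMS agreement with ground
truth holds in the sparse regime (of order one probe per block); at high
density the curve remains a faithful qualitative monitor of arrest.

### Fits and detections

- Stretched exponential: bounded least squares (β ∈ [0.2, 2.0]),
  multi-started over a decade grid of τ spanning the lag range × β ∈
  {0.5, 1.0, 1.5}; best residual wins, so the fit is deterministic.
  τ at a grid boundary raises a flag. With a known q the Brownian
  diffusivity 1/(τq²) is reported.
- Power laws: linear least squares in (ln x, ln y); exact for noise-free
  power-law inputs, so the aging exponents of the noise-free synthetic
  rheology are recovered to machine precision and the tan δ exponent
  equals the difference of the moduli exponents identically.
- Microscopic viscosity: η_τ = k_B T τ/(6π R³), the exact inversion of
  the probe-time relation, kept in a single named site
  (`gelscope.constants`). Units: τ in s and R in μm give mPa·s. The
  choice of the order-unity constant relating "time to diffuse R" to
  1/(Dq²) at q = 2π/R is a convention; both routes use the same site and
  the pipeline reports their ratio rather than hiding it.
- Changepoint: two-segment continuous piecewise-linear least squares
  with the knee scanned over a fine grid (including the sample times);
  appropriate for arrest curves with ≲ 12 elapsed-time points. A series
  a single line explains is flagged degenerate. For a
  gradual-then-frozen curve the knee marks the *onset* of the sudden
  decay, i.e. it lands between the last mobile and first arrested
  observation.
- Winter–Chambon: the gel point minimizes the coefficient of variation
  of tan δ across frequencies; the minimum is refined parabolically in
  time unless it is already numerically zero (the noise-free crossover),
  in which case the grid time is exact. A shallow minimum (curves that
  never intersect) is flagged rather than reported as a gel point. The
  detection is invariant under rescaling all moduli.

## Pipeline

One YAML/JSON config drives simulate → PIV/DVA/DDM → fits → rheology →
report. Per-stage seeds derive from the global seed as
SHA-256("stage:seed") mod 2³¹; reruns are bit-identical and the report
carries a configuration hash. Stage failures on individual movies are
caught, counted and left as missing values; counters (clipped ISF
values, invalid PIV blocks, plateau fallbacks) are the observability
surface for the long-lag artifacts discussed above.

## Problem sizes

The verification suite runs the imaging chain at the full default regime
(256² px × 500 frames) for the headline scaling checks and at 64–128 px
/ 60–500 frames elsewhere; these sizes put every statistical tolerance
used by the tests (5–10 % on recovered diffusivities and exponents) at
≥ 2–3 standard errors as estimated from the mode × pair counts.

## What the synthetic suite does not show

The renderer idealizes probes as identical Gaussian point emitters: no
defocus or 3-D motion, no hydrodynamic coupling between probes, no
imaging of the casein network itself, and spot overlap is linear. Real
milk movies add optical nonidealities (band-limited contrast transfer,
uneven illumination, drift) that chiefly reshape A(q) and the DVA β;
the q-space relaxation rates and the MSD inversion are insensitive to
these by construction, which is why the DDM route carries the
quantitative claims. Passing tests establish the correctness of the
estimators under the stated noise model, not the biology of any
particular milk sample.
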