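# Methods

## Problem and measurement model

`rootspeckle` models continuous, contact-free monitoring of the elongation
rate of a seedling root segment by two-beam laser speckle interferometry.
Two coherent beams (He-Ne, λ = 633 nm) illuminate a root at points
separated by the gauge length (3 mm). Each illuminated spot scatters a
fully developed speckle field; the camera records the interference of the
two fields. When the segment between the spots elongates by Δx, the
optical-path difference between the fields changes by Δx·sinθ (θ the angle
between illumination and observation), so the interference phase changes by

    Δφ = 2π · Δx · sinθ / λ.

θ is bench-dependent and configurable; the default sinθ = 1 makes one 2π
fringe correspond to exactly one wavelength of elongation, the cleanest
calibration for testing. All internal units are fixed — nm (elongation),
rad (phase), s (time), mm (gauge) — so the normalized rate

    RER_k = (x_{k+1} − x_k) / (dt · gauge)    [nm s⁻¹ mm⁻¹]

falls out directly with the default dt = 0.5 s and 3-mm gauge. Left-edge
forward differencing is used, timestamps at interval left edges, and no
smoothing is applied by default (a moving-average flag exists but is off).

## Synthetic growth traces

No public recordings exist for this kind of measurement, so the generator
is a first-class, tested component. A rate trace is

    r(t) = μ + A·sin(2π t / T + φ₀) + σ_n·ε(t),

with ε iid standard normal and φ₀ uniform per trace (traces are not
phase-locked across roots). The split between oscillation and noise is
parameterized by the variance fraction f: A = σ_tot·√(2f),
σ_n = σ_tot·√(1−f), so A²/2 + σ_n² = σ_tot² for every f. Defaults: T = 10 s
(the observed rhythm of root micro-growth and shrinkage), f = 0.5 — the
published group statistics constrain only the total moments and the
dominant period, not the variance decomposition, so half-and-half keeps
both the moments and a clearly detectable spectral peak reproducible.

The packaged calibration (`data/presets.yaml`) pins the two groups:
wet (well-watered) μ = −0.10, σ_tot = 3.41; dry (water-stressed)
μ = −23.44, σ_tot = 52.63, all nm s⁻¹ mm⁻¹. Negative rates are physical:
roots intermittently shrink. Standard runs are 150 s at 0.5 s (300
samples); group sizes in tests and the acceptance script are 100 traces
per group, which puts three standard errors of the pooled wet mean at
about ±0.04 and of the dry mean at ±0.9.

What the generator does **not** emulate: diurnal drift, trace-to-trace
heterogeneity in μ or σ (all traces of a group share one preset),
non-sinusoidal or drifting rhythms, and any correlation structure in the
noise. Passing tests therefore demonstrate that the pipeline recovers what
this model puts in — not that real roots follow the model.

## Speckle and frame synthesis

A fully developed speckle field is drawn as iid complex circular-Gaussian
amplitudes per pixel, optionally low-pass filtered (Gaussian, σ = half the
requested speckle size, periodic boundaries) and renormalized to unit mean
intensity. Filtering preserves Gaussianity, so the marginal phase stays
uniform on [−π, π] and the pointwise intensity contrast stays ≈ 1; both
properties are asserted by goodness-of-fit and contrast tests.

Frame k of a stack is rendered per pixel as

    I_k(p) = |A_a(p) + A_b(p)·e^{iΔφ_k}|² + n_k(p),

with Δφ_k the interference phase of the elongation at sample k, equal mean
intensity in both arms (maximal fringe contrast), and additive Gaussian
detector noise with sd equal to a configurable fraction (default 0.01) of
the mean clean intensity, clipped at zero. Polarization, coherence loss,
speckle decorrelation from surface micro-changes, and camera artifacts are
out of scope.

## Phase demodulation

Each pixel obeys I_k(p) = a(p) + b(p)·cos(ψ(p) + Δφ_k) with ψ(p) the
static, uniformly distributed speckle phase. The estimator exploits the
whole field jointly:

1. **Initialization.** Per-pixel temporal mean removal; pixels whose
   modulation amplitude falls in the bottom quantile (default 20%) are
   excluded — dark speckles carry mostly noise. The two leading temporal
   components of the remaining stack (eigenvectors of the frame-by-frame
   Gram matrix, cheap at a few hundred frames) span the
   (cos Δφ, sin Δφ) plane; their score ellipse is whitened to a circle and
   the two-argument arctangent gives a first phase estimate.
2. **Refinement.** Alternating least squares on the explicit model: given
   the phase, fit (a, b·cosψ, b·sinψ) per pixel by a 3-parameter linear
   solve; given the pixel coefficients, re-estimate each frame's phase
   from 2×2 normal equations over all kept pixels. Convergence is linear
   and slow when the phase excursion covers only part of a fringe, so the
   iteration ceiling is generous (200) with early stopping once the
   largest phase update drops below 1e-9 rad. On 128×128 stacks of 300
   frames with 1% detector noise this reaches ~1e-4 rad RMS in about a
   second, for full-fringe ramps and sub-fringe sinusoids alike.

The recovered trace is intrinsically defined only up to a global offset
and a global sign. Simulations resolve both against the known truth
(`align_to_reference`, least squares over both signs); production runs
resolve the sign against a configured expected drift direction. A stack
with no temporal modulation (relative temporal variance below 1e-12) is
flagged `degenerate` in the quality block and returns a zero trace rather
than raising — absence of growth is a valid measurement.

Temporal unwrapping is the classic 1-D rule: whenever a successive wrapped
difference exceeds π in magnitude, add the appropriate multiple of 2π.
This assumes true per-sample steps below π; with the default geometry the
dry-group mean rate implies ≈ 0.35 rad/frame, comfortably inside the
assumption, and violations are silently aliased by construction (they are
undetectable from wrapped data).

## Group statistics

- **Quartiles**: linear interpolation of order statistics; whisker fences
  at q1 − 1.5·IQR and q3 + 1.5·IQR; every sample outside the fences is an
  outlier. Verified against a brute-force sorting oracle.
- **Histograms**: bin edges computed on the pooled two-group sample
  (Freedman–Diaconis by default) and shared between groups.
- **Moments**: pooled over all samples of a group (sample sd, ddof = 1),
  plus per-trace moments.
- **Spectra**: mean removal, no taper (a Hann flag is available), one-sided
  amplitude scaling 2|X_k|/N so a pure sinusoid of amplitude A reads A at
  its bin; DC and the even-N Nyquist bin are unscaled. The dominant
  frequency is the argmax over non-DC bins, so a large mean rate cannot
  masquerade as periodicity. Parseval is enforced in tests.
- **Group comparison**: every spectrum's dominant frequency, a band-limit
  check (default 1.5 Hz) and the ratio of mean peak amplitudes. Note the
  1.5-Hz band limit quoted for this kind of data exceeds the 1-Hz Nyquist
  frequency of 0.5-s sampling; it is kept as a (trivially satisfiable)
  upper bound rather than silently tightened. Note also that with the
  packaged presets the dry group has the larger oscillation amplitude, so
  the wet/dry peak ratio is ≈ 0.065; the comparison reports the measured
  ratio against the configured one and takes no position on which group
  "should" be larger.
- **t-test**: Welch (unequal variances, Welch–Satterthwaite df) by
  default — the two groups' sds differ by ~15×, so the pooled-variance
  Student variant is physically inappropriate, though available behind a
  flag. With 30,000 samples per group the p-value underflows double
  precision and is reported as 0.

## Numerical and design choices

- Determinism: every random source takes an explicit seed;
  per-trace seeds are derived as (group_seed, index) sequences, recorded
  in the dataset manifest. Identical config + seed reproduces trace CSVs
  byte for byte (CSV floats are written at %.17g and parsed with
  round-trip precision).
- Degenerate inputs: zero-modulation stacks → flagged, not fatal;
  single-sample traces, empty groups, wrapped-phase input to the
  elongation converter, non-uniform sampling → `InputError`;
  invalid geometry → `GeometryError`; unknown config keys → `ConfigError`.
- Problem sizes in the test suite (100×300-sample groups, 128×128×300
  frame stacks) were chosen so three standard errors of each pooled
  estimate sit well inside the assertion tolerances while a full run
  completes in seconds on one core.

## Known limitations

- The demodulator assumes a static speckle pattern modulated only by the
  common object phase; real roots decorrelate the speckle over time,
  which this package neither simulates nor compensates.
- The oscillation-plus-white-noise growth model is the simplest process
  matching the published group moments and dominant period; real rate
  series are unlikely to be spectrally this clean.
- The sign of the recovered elongation is not observable from the frames
  alone; it must come from bench geometry (configuration) or ground truth
  (simulation).
- Unwrapping failure (true steps ≥ π per frame) is silent; with the
  default geometry this corresponds to rates beyond ≈ 0.42 µm s⁻¹ over a
  3-mm gauge, far outside the calibrated regime.
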