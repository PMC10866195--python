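# Methods

This note documents the models, numerical conventions, and validation
protocol implemented by `stprf`, including the choices made where the
design was genuinely open.

## Stimulus rendering

Both experimental designs are rendered as binarized movies `I(X, Y, t)` on
a 61×61 pixel grid covering the central 24° of the visual field, at 10 ms
temporal resolution. The square `[-12°, +12°]²` maps to pixel *centers*
(pixel size 24/61 ≈ 0.393°), x rightward and y upward; the field of view
is the inscribed 12°-radius disk and pixels outside it are always off.

**Spatiotemporal design.** A 3°-wide bar sweeps the field in 9 steps along
four orientations (0°, 45°, 90°, 135°), adjacent steps overlapping by
0.375° (so 9 steps exactly tile the 24° diameter). Each 5 s bar location
carries one of nine temporal conditions varying image duration, ISI and
image count (e.g., 30×133 ms images with 33 ms ISI; a single uninterrupted
5 s presentation). Image on/off boundaries are laid out in continuous
milliseconds and rounded per event to the 10 ms frame grid, so rounding
error never accumulates beyond half a frame. Condition 7's
duration/ISI, not printed anywhere we know of, are derived from its
constraints (15 images, 4 s total on-time, 5 s slot): 266.67 / 66.67 ms.
Across 9 runs, a seeded Latin-square-style assignment places every
condition exactly once at every bar location; the sweep order of
orientations is fixed (0°, 45°, 90°, 135°) and no blanks pad the runs
(run length 180 s).

**Toonotopy design.** The contrast design: 12 steps per sweep, 0.27°
overlap (bar width 2.2475° follows from the tiling constraint), 2 s per
step, 4 runs, images refreshing at 8 Hz. Because the refresh interval
(125 ms) is 12.5 frames, refresh boundaries are rounded per event and a
one-frame off gap is inserted at each refresh. This gap is the default:
the binarized movie of a stimulus whose content changes at 8 Hz is itself
time varying, and without it (solid-on bar, available as
`refresh_transients=False`) the compressive spatiotemporal model's σ and
n become structurally unidentifiable — the solver reaches R² = 1.0 at
grossly wrong parameters — which contradicts the recovery behavior this
design is known to produce.

Sequences are stored in factored form (bar apertures × per-slot temporal
profiles); `frames()` materializes any segment exactly, and every linear
model stage exploits the factorization (below).

## Forward models

All three models share the 2D isotropic Gaussian spatial receptive field

    spatialRF(X, Y) = exp(−((X−x)² + (Y−y)²) / 2σ²),

unnormalized (value 1 at the center), with x, y, σ in degrees. The
spatial drive is the frame-by-frame dot product of the stimulus with the
RF.

**Spatial model** — the neural response *is* the drive (purely linear).

**CST (compressive spatiotemporal)** — the drive is filtered by three
temporal impulse responses: a sustained gamma

    h(t) = (t/κτ)^(m−1) · exp(−t/κτ) / (κτ·(m−1)!),  κ = 1, m = 9,

an on-transient difference of gammas (the sustained gamma minus an
inhibitory gamma with κ = 1.33, m = 10, each lobe unit-area so the kernel
integrates to ~0), and its sign-flipped off-transient twin. Each channel
is rectified (ReLU) and compressed by a shared exponent n ∈ [0.1, 1].
(m−1)! is computed via log-gamma so non-integer m works if configured.
τ is expressed in 10 ms model samples ("centiseconds"), the unit of its
search bounds [4, 100]; the sustained kernel peaks at 8τ samples and
`cst_peak_time_ms` converts. The literature this model descends from is
inconsistent about whether τ itself or the 8τ peak time is the quantity
"in ms"; we expose both rather than resolve it.

**DN-ST (delayed divisive normalization)** —

    p(t) = |r(t)|^n / (σ_DN^n + (|r| ⊛ h₂)^n),  r = h₁ ⊛ drive,
    h₁(t) = t·e^(−t/τ₁),  h₂(t) = e^(−t/τ₂),  τ₁, τ₂ in seconds.

The bracketed denominator term is a causal convolution with the
exponential low-pass (a pointwise-product variant exists behind a flag).
For this model only, the drive is divided by the RF's grid sum so it lies
in [0, 1] (a contrast-like unit): with the raw peak-1 Gaussian the drive
is O(10–100) and the semisaturation range [0.01, 0.5] would be
numerically inert. The linear models keep the raw drive — their scale is
absorbed by the GLM gains.

**Kernel discretization.** All kernels are sampled at 10 ms by evaluating
the continuous form at sample midpoints and renormalizing to unit *sum*
over a finite support (the 1 − 1e−9 quantile of the gamma; 18τ for the
DN-ST kernels, ~3e−7 tail mass), so convolution preserves the drive's
scale and σ_DN's meaning is independent of dt. Convolutions are linear, causal, zero-padded on the
left, and applied independently per run (runs are separate acquisitions;
responses never bleed across boundaries).

## Hemodynamics

The HRF is a difference of two gamma densities, each parameterized by its
peak latency and FWHM in seconds; the map (peak, FWHM) → (shape, scale)
fixes the mode at the peak and solves the FWHM numerically (Brent). The
default parameters are peaks 5.4 / 10.9 s and FWHMs 5.2 / 7.35 s (the
Vistasoft convention). The undershoot's relative amplitude is not part of
that parameterization; we scale each gamma to unit peak and use weight
0.35, held fixed during optimization unless freed. The composite kernel
consequently peaks at ≈5.26 s, slightly before the 5.4 s first-gamma
parameter. Predicted neural activity at 10 ms is convolved with the HRF
and averaged within 1 s bins (a strided-sampling mode exists).

Per-voxel HRF fitting alternates (a) ordinary least squares for 36
location-by-orientation condition gains — the design codes only *where*
the bar is, ignoring within-slot temporal structure, so estimates are not
biased toward any presentation schedule — with (b) a bounded Nelder-Mead
update of the four latency/width parameters; a candidate is accepted only
if the jointly refit residual improves, so the residual is non-increasing.
No intercept column is added: with no blank periods the 36 boxcars sum to
a constant, and an intercept would make the design singular.

## Synthesizer

Ground-truth pRF centers are sampled as eccentricity |N(0, 5°)| truncated
to [0, 10°] (a half-normal "spanning" the stimulated range) at uniform
polar angle; sizes from N(1.6°, 0.7°) truncated to [0.2°, 3°]; temporal
parameters uniform within the solver's fine-search bounds. Channel gains
(β) are fixed at 1 — they are estimated by GLM during solving, excluded
from the recovery score, and the SNR calibration makes absolute scale
irrelevant. When several models are compared, they share identical
spatial parameters.

Noise is a per-voxel composite of three zero-mean components — white
Gaussian; "physiological" sinusoids at 1.17 Hz (cardiac, aliased by the
1 s sampling) and 0.3 Hz (respiratory) with random phases; and a per-run
cosine drift with period 1–3× the run length — mixed at 50/25/25 power
and scaled so that

    SNR(dB) = 10·log₁₀(var(signal) / var(noise))

hits the target exactly (default 0.1 dB, i.e., nearly equal signal and
noise power). A direct consequence: the ground-truth prediction scores
R² = 1 − Σnoise²/Σdata² ≈ 0.5–0.65 against its noisy series — with equal
powers this quantity cannot fall to ~0.3 under any power-ratio dB
reading, so the realized value is reported as measured rather than forced
to a lower figure by inflating the noise.

What the generator does *not* emulate: spatial correlations between
voxels, scanner spikes and motion, HRF variability across voxels (the
same default HRF generates and solves the synthetic data, deliberately,
to isolate solver error), and realistic pRF parameter covariances.
Passing recovery tests therefore demonstrate the *estimator's* internal
consistency at a realistic noise level, not performance on empirical
data.

## Solver

Stage 1 is an exhaustive grid search over spatial parameters with fixed
default temporal parameters (CST τ = 4.93 samples; DN-ST τ₁ = 0.05 s,
τ₂ = 0.1 s, n = 2, σ_DN = 0.1) and, for CST, exponents
{0.25, 0.5, 0.75, 1}; gains are solved linearly at every point and the
point with the highest variance explained wins (ties prefer smaller σ,
then smaller eccentricity). `GridSpec()` materializes the full published
grid — x/y over the 24° extent at 0.4° steps and 96 log-linear σ values
in [0.1°, 12°], ~1.4M CST combinations, sized for GPU enumeration.
Desk-scale solving uses `GridSpec.coarse()` (2° x/y steps, 10 σ values;
same ranges) — with the ±5° fine-search box around the grid estimate, the
coarse grid localizes well inside the basin the fine stage needs, which
the noiseless-recovery results confirm.

Stage 2 fits all parameters simultaneously by bounded Nelder-Mead on
parameters affinely rescaled to the unit box, with gains profiled out by
OLS inside the objective

    R² = 1 − Σ(model−data)² / Σdata²   (raw, not mean-centered, denominator).

Three restarts: the grid solution with default temporal parameters, plus
two with temporal parameters drawn from Latin-hypercube strata so the
restarts jointly cover their ranges (for CST this is what rescues voxels
whose true τ is far from the 4.93-sample grid default). The best restart
is then polished by a second Nelder-Mead started from a small simplex:
the hot path evaluates the nonlinearity in single precision for speed
(relative error ~1e−7, verified against the float64 reference in the
test suite), which is below the noise floor of noisy fits but masks the
shallow curvature of weakly identified DN-ST parameters on noiseless
data, so noiseless polishes are re-evaluated in double precision
(`polish_double`). Validation budgets: noiseless solves use 250–300
evaluations per restart and 350–450 for the polish (precision should be
limited by the method, not the optimizer; more for the 7-parameter
DN-ST model); noisy solves use 150/200 with the single-precision polish.

Degenerate inputs: an all-zero voxel is flagged, not solved; collinear
GLM predictors fall back to a tiny ridge with a warning; zero-variance
data make R² undefined (NaN) rather than raising. Exclusion policy is
flags, never deletion: `low_r2` below 10% variance explained,
`tau_at_bound` for CST fits pinned at τ = 100.

**The factored engine.** The stimulus is a schedule of
(aperture, temporal profile) slots, so `kernel ⊛ drive` decomposes into
one small convolution per temporal condition plus per-slot
scaled placements, and "convolve with the HRF at 10 ms then average 1 s
bins" is a single matrix product per run evaluated only at bin centers.
Both factorizations are exact reorderings of the naive pipeline (the test
suite checks equality at 1e−5 relative) and bring one model evaluation on
the full nine-run experiment to a few milliseconds on one CPU — the
difference between hours and minutes for the recovery studies. The
per-slot scatter loop is JIT-compiled when numba is available, with an
identical pure-numpy fallback.

## Validation protocol and problem sizes

`stprf.validation` packages the closed-loop studies used by
`scripts/acceptance.py` and the end-to-end tests: a noiseless arm
(30 voxels/model, nine-run design), a noisy arm (50 voxels/model,
0.1 dB), and a design-comparison arm (the same CST ground truth under the
four-run toonotopy design). These sizes are scaled down from the
300-voxel studies the framework is modeled on; medians over 30–50 voxels
are stable to a few percent, and the whole protocol runs in tens of
minutes on one CPU. All randomness derives from a single seed via
`numpy.random.SeedSequence` spawning.

## Known limitations

- Cross-validated model comparison on empirical data (the framework's
  downstream use) is implemented (`crossvalidate`,
  `compare_models_permutation`) but only exercised on synthetic data.
- The toonotopy arm recovers σ somewhat worse than the ~42.5% error the
  design is reported to produce (pilot medians 50–65% at 0.1 dB with four
  runs); the qualitative conclusion — the toonotopy design is far worse
  than the spatiotemporal design for spatiotemporal parameters — is
  robust. The residual gap plausibly reflects the unknown details of the
  original noise generator and toon simulation length.
- The biphasic-h₁ DN-ST variant and separate on/off transient gains are
  out of scope by design.
- NIfTI input is optional (guarded import); the canonical formats are
  TSV.
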