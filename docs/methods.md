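# Methods

## Model

The detector is a Chua–Yang cellular neural network: one first-order
analog cell per image pixel, coupled only to its 3×3 neighborhood.  Cell
`ij` evolves as

    dx_ij/dt = −x_ij + Σ_mn a_mn y_{i+m−2,j+n−2}
                      + Σ_mn b_mn u_{i+m−2,j+n−2} + I,

where `u` is the (static) input map and the output nonlinearity is the
saturating piecewise-linear function `y = ½(|x+1| − |x−1|)`, the identity
on [−1, 1] and clamped outside.  The ½ prefactor is required for the
output range to be [−1, 1]; without it the same expression spans [−2, 2].
The feedback template **A**, control template **B** and bias **I** are
shared by all cells — 19 trainable scalars in total.  A four-neighbor
variant pins the four corner entries of A and B to exactly zero.

**Boundary condition.**  Out-of-grid neighbors contribute zero to both
sums (virtual cells with `u = y = 0`).  This is the simplest contract
consistent with wavefronts terminating at the tissue boundary; replicated
borders would be the main alternative and differ only in a 1-px frame.

**Inference.**  The ODE is integrated by forward Euler from `x(0) = 0`
with `dt = 0.25` for at most 60 steps, stopping early when
`max|dx/dt| < 1e-4` (`steady_tol`).  The horizon `dt·max_steps = 15` time
constants brings pure decay to ~3e-7, far below the tolerance, and Euler
with `dt = 0.25` is comfortably inside the stability region of the
`−x` relaxation.  Templates with strong feedback can cycle indefinitely
in the linear region; the step cap makes inference total, and the
returned map is the saturated output of the final state.  States beyond
1e6 raise a divergence error naming the step and cell.  The Euler loop is
JIT-compiled (numba) with a pure-numpy fallback; `fastmath` is disabled
so trajectories are bit-reproducible across machines.

## Training

Per-cell loss is the half squared error `e = ½(d − y*)²` against labels
`d ∈ {−1 wavefront, +1 nonwavefront}`; the gradient signal is the
residual `d − y*`.  Template updates average `residual × shifted output`
(for A), `residual × shifted input` (for B) and the residual itself (for
I) over all `H·W` grid cells — the normalization is per grid cell, the
only dimensionally consistent reading — and batch training averages these
per-sample updates before applying `θ ← θ + η·Δ`.  The dataset is
reshuffled every epoch (seeded), the last partial batch is kept, and
training stops early once the epoch mean error varies by less than 1e-6
over 10 consecutive epochs.

Initializations: all-zero; i.i.d. uniform on [−1, 1]; or the classical
edge-detection cloning template (A = 0, B = Laplacian with center 8 and
ring −1, I = 1), which is already a serviceable wavefront detector since
the phase branch cut is a step edge.

**Binarization.**  Thresholds are quoted as a percentage of the output
range: p% ↦ −1 + 2p/100, so 50% is 0.  In *during* mode the thresholded
output replaces the grayscale output in both the error and the gradient
terms; in *after* mode training is grayscale throughout and thresholding
is purely an evaluation step.  History metrics are always recorded at the
50% threshold so convergence curves are comparable across modes.  On this
generator, during-mode training converges faster (its residuals are
full-scale ±2 from the first epoch) and is *not* less stable than
after-mode at the benchmark sizes; the oscillation sometimes associated
with thresholded feedback appears only marginally, in single-image
training.

**Learning rate.**  η = 0.1 with random initialization is the default
operating point; the suite checks that η = 1e-4 (no learning within the
epoch budget) and η = 1e4 (overshoot) are strictly worse in test
precision.

## Quantization and nonidealities

Memristive storage is modeled as a uniform grid of `2^bits` levels
spanning [−1, 1] inclusive (bits ∈ [1, 16]); values are clipped into
range before rounding, and the bias is quantized like any weight.
Round-to-nearest resolves exact ties to the level with even index.
Stochastic rounding maps `v` with bracketing levels `A1 ≤ v ≤ A2` up with
probability `(v − A1)/(A2 − A1)`, so the quantized value is unbiased.
Quantization-aware training applies the rounding after every batch
update (gradients themselves are not quantized) with templates clipped
to the grid range; post-training quantization is a single call on the
final templates.  At 6 bits the level spacing (2/63 ≈ 0.032) exceeds the
typical per-update step `η·Δ`, so round-to-nearest freezes training —
the mechanism behind the stochastic-vs-nearest precision gap the
acceptance suite checks.

Read noise adds i.i.d. N(0, σ²) to all 19 parameters, redrawn on every
inference call (read-time noise, not a programming error), with σ
independent of the conductance level.  Yield loss freezes
`ceil(fraction · 19)` parameter positions, drawn uniformly without
replacement over all 19 including the bias, at the grid maximum (ON),
minimum (OFF), or a fair mix.

## Preprocessing

Per pixel, the temporal mean is removed and the FFT-based discrete
Hilbert transform over the full recording forms the analytic signal; its
angle is the instantaneous phase.  Constant-in-time pixels (dead sensors,
electrode artifacts) have undefined phase: they are flagged NaN with a
warning, mapped to input 0, and excluded from losses and metrics via a
mask.  Phase frames map linearly [−π, π] → [−1, 1] so the saturating
output can represent the input identically.  Gaussian contact noise, when
requested, is added to the raw signal *before* the Hilbert step.  Crops
are 0-based half-open spatial windows.

## Synthetic generator

The generator emulates fibrillation optical-mapping data with kinematic
wave fields (no electrophysiological PDE is solved — the detector's
contract only concerns phase geometry):

* grid 70×35 px (the cropped field of view), 256 frames at 1 kHz;
* temporal frequency 4–8 Hz — the dominant-frequency band of human VF —
  drawn uniformly; the sign convention makes phase *advance* in time,
  matching the analytic signal's positive-frequency convention (the
  rendered cosine is identical either way; only labels care);
* wavelength 10–24 px so each frame carries a few well-resolved fronts;
* planar fields `φ = wrap(2π(x cosθ + y sinθ)/λ − ωt)` and Archimedean
  spirals `φ = wrap(±atan2(Δr, Δc) + 2πρ/λ − ωt)` in equal proportion;
* raw signal `0.05·cos(φ) + 1`: a 5% fractional-fluorescence amplitude
  typical of voltage-sensitive dyes, so raw-noise σ values are measured
  against a 0.05 signal;
* optional constant-valued artifact patch (pacing-electrode stand-in)
  that the Hilbert step flags NaN and the pipeline masks.

Labels are an algorithmic surrogate for the study's manual annotation: a
pixel is wavefront iff its phase is negative and a 4-adjacent neighbor
lies across the branch cut (|Δφ| > π).  Labels are one pixel thick by
construction, are derived from the *recovered* (Hilbert) phase frame the
network actually sees — the analytic phase serves as an independent
oracle, agreeing on ≥ 98% of pixels at zero noise — and the labeled frame
is the movie's center frame, away from transform edge effects.

What passing tests on this generator do **not** show: robustness to real
measurement artifacts (motion, uneven staining, wavebreak and rotor
meander, conduction block), to label ambiguity of thick or fragmented
fronts, or to phase noise structure beyond additive Gaussian sensor
noise.  Results transfer to real recordings only to the extent that
wavefronts remain clean phase branch cuts.

## Benchmark sizes and determinism

The acceptance suite trains on 200 images and tests on 50, with
η = 0.1, batch 20, up to 150 epochs, over three training seeds — sizes
chosen so the whole suite runs interactively while leaving wide margins
on every checked ordering.  The quantization comparison uses the
±1-clipped float regime as its baseline so the 6/16-bit contrasts
isolate rounding rather than range clipping.  Every random choice
(dataset, initialization, shuffling, rounding, noise) flows from an
explicit seed; identical configuration and seed reproduce templates
bit-exactly.

## Known limitations

* Fixed-point cycling under strong feedback templates means "steady
  state" is an integration-horizon snapshot for some parameter settings.
* Micro-averaged dataset metrics are the default (counts pooled before
  dividing); macro-averaging is available but undefined per-image metrics
  are simply dropped there.
* The stuck-device model perturbs the shared template parameters (19
  positions), not per-cell device instances; it models a single cell's
  programmed weights replicated network-wide.
* Neighborhoods beyond 3×3 are out of scope.
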