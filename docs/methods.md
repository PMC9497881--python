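# Methods

## Forward model

A slice is represented by four aligned 2D maps: proton density `pd` (a.u.,
non-negative), `T2` (ms, positive on the object), a slowly varying phase
`φ` (radians), and an integer tissue-label map. The single reference image
all metrics are computed against is the T2-weighted complex image at the
protocol's nominal echo time,

    I_gt = pd · exp(−TE/T2) · exp(iφ).

An SSFSE echo train acquires one phase-encode line per echo. Line `j`,
acquired at position `e(j)` of the train, contributes the corresponding row
of the unitary 2D FFT of

    S_c · pd · exp(−TE_eff(j)/T2) · exp(iφ),

where `S_c` is the coil-sensitivity map and
`TE_eff(j) = TE + (e(j) − e_center)·esp` with the center-most sampled line
pinned to the nominal TE (`esp` = echo spacing). The default echo ordering
is linear (ascending line index); center-out ordering is available. This
per-line decay is what produces T2 blurring of the phase-encode point-spread
function, and is the mechanism that makes shorter echo trains attractive.
Acquisition noise is i.i.d. complex Gaussian, standard deviation
`noise_sigma` per real/imaginary component, identical across coils; coil
noise correlation is not modelled.

Conventions: phase encode is image axis 0; k-space is DC-centered at index
`floor(n/2)`; the FFT is unitary, so Parseval holds exactly and masking is
an orthogonal projection.

## Sampling patterns

* **Variable density** (CS arm): a fully sampled contiguous center block of
  `round(center_fraction · budget)` lines plus peripheral lines drawn
  without replacement from a density decreasing linearly with distance from
  the center. The budget is the echo-train length
  `ETL = floor(matrix_pe / R)`; for the 253-line protocol at R = 3 this is
  84 lines, an effective acceleration of 3.0. `center_fraction` defaults to
  24/84 so the imaging scan itself covers the calibration region. The
  density slope parameter (`accel_increment`, default 1.0 with a 0.02
  floor) controls how fast the local acceleration grows toward the edge;
  its value is a package choice, as only the existence of such an increment
  is specified for this sequence family.
* **Uniform** (parallel-imaging geometry): every `r`-th line from an
  offset. Only the mask geometry is simulated; its matched reconstruction
  here is the coil-combined adjoint, not a GRAPPA kernel fit.
* **Partial Fourier**: one contiguous block of `ceil(fraction · n_pe)`
  lines — the upper half of k-space plus the symmetric margin below the
  center; 6/8 retains 75% of lines.
* **Reference scan**: a contiguous block of `n_acs` (default 24) center
  lines acquired as a second echo train with the same forward model.

## Reconstructions

**Zero-filled adjoint.** `Σ_c conj(S_c) · IFFT(masked data_c)` — the
baseline for every geometry.

**Homodyne partial Fourier.** The retained k-space is pre-weighted so a
line and its conjugate mirror carry total weight 2: weight 0 below the
sampled region, a linear 0→2 ramp across the doubly-sampled symmetric band,
2 on the singly-sampled side. The slowly varying object phase is estimated
from the Hamming-apodized symmetric center band, removed, and the real part
taken (negatives clipped). With full coverage nothing is missing and the
method reduces to the plain coil-combined magnitude, which is exact for
zero-phase objects. The weighting ramp is linear because its width is fully
determined by the mask; there is no free parameter.

**Compressed sensing.** Minimizes `½‖AI−D‖₂² + λ‖WI‖₁` by proximal
gradient. Since `W` (multilevel orthonormal Haar, periodization boundary,
default 3 levels) is orthonormal, `prox_{λ‖W·‖₁} = W⁻¹ ∘ soft-threshold ∘ W`
exactly — no inner iterations. Two solvers: plain ISTA (monotone for step ≤
1/L) and FISTA with function-value restart; the restart variant re-takes an
overshooting momentum step from the incumbent and keeps the best iterate,
so its accepted-objective trace is non-increasing by construction. Defaults:

* `step = "auto"`: 1/L with L = ‖A‖² from 30 power iterations (L ≤ 1 for
  RSS-normalized maps and unitary FFT, since masking is a projection);
* `λ = "auto"`: `1e-3 · max|Aᴴ D|`. Scaling λ with the data makes the
  default transferable across noise levels and image scales;
* stop when the relative iterate change falls below `tol = 1e-6` or at
  `n_iter` (80 in the bundled experiment — enough for the objective to
  flatten at the 128×128 problem size while keeping the four-arm demo in
  seconds);
* images whose sides are not divisible by `2^levels` get the largest
  feasible decomposition depth instead of padding (padding would change the
  data-consistency term); odd-sided images fall back to the identity
  transform.

Complex images are reconstructed throughout; magnitude is taken only for
metrics and export.

**Coil calibration.** Per-coil low-resolution images from the
Hamming-apodized, zero-filled ACS block, divided by their
root-sum-of-squares; RSS of the output is exactly 1 where the RSS magnitude
exceeds 5% of its maximum (support), 0 elsewhere. The apodization window is
centered on the DC line (using the largest DC-symmetric ACS sub-block), not
on the block itself: an off-center window would impose a spurious linear
phase ramp on the maps. Any true object phase — including the asymmetric
k-space weighting caused by per-echo T2 decay — is folded into the maps,
as is standard for RSS-referenced calibration; the reconstructed image then
carries the RSS phase reference, which is irrelevant after the magnitude is
taken.

## Phantom and coils

The phantom is an ellipse composition (body, liver, spleen) with focal
lesions placed inside the liver without overlap (bounded retries, explicit
failure): fluid lesions T2 ∈ [600, 1200] ms, solid lesions [60, 120] ms,
parenchyma [40, 60] ms, body wall [60, 90] ms. One T2 value is drawn per
region and modulated by a ±6% smooth field, then clipped back into the
configured class range so per-class contrasts are exact on the label masks.
The phase map is a low-order 2D polynomial with amplitude knob
(`phase_amplitude`, default 0.5 rad) — homodyne assumes slowly varying
phase, and the knob lets tests probe that assumption. Coils are Gaussian
envelopes centred on a ring around the body times smooth complex
perturbations, RSS-normalized; `n_coils = 1` is the exact identity
sensitivity.

What the generator does *not* emulate: real anatomy and its texture,
motion/pulsation (the artifacts reader studies penalize most), fat signal
and fat suppression, B0/B1 inhomogeneity, coil noise correlation, and
multi-shot segmentation. Passing tests therefore show the reconstruction
chain is correct and that CS beats zero-filling *under piecewise-smooth,
motion-free conditions*; they do not predict reader scores on patients.

Default experiment conditions: 128×128 matrix, 8 coils, TE 99 ms, echo
spacing 1.5 ms (not a published protocol field; chosen so the first echo
time stays positive under linear ordering and the per-slice readout is
consistent with a ≈500 ms repetition time), complex noise sigma 0.005
(≈1.5% of the k-space center magnitude — visibly noisy but diagnostic), CS
budget `floor(128/3) = 43` of 128 lines mirroring the 84-of-253 protocol
geometry at desk scale.

## Reader-study statistics

Scores are integers 1–5 per (case, sequence, criterion); a score ≤ 2 is
"insufficient" and rates are reported as count and percentage to one
decimal. Descriptive statistics use the sample SD (n−1) and
linear-interpolation quartiles.

The paired Wilcoxon signed-rank test is two-sided. Exact mode computes the
null distribution of `W+` (sum of positive-difference ranks) by
dynamic-programming convolution over doubled midranks — equivalent to full
`2^m` sign enumeration but polynomial, and exact in the presence of the
heavy ties ordinal data produce; the two-sided p is `2·min(P(W≤w), P(W≥w))`
capped at 1. Zero differences are handled by the Pratt rule by default
(zeros ranked, then dropped from the sums; the `wilcox` rule is available
for cross-checking). Above 25 nonzero differences the tie-corrected normal
approximation with continuity correction is used (via scipy). If all
differences are zero the result is degenerate with p = 1.

`compare_sequences` runs the three pairwise tests (conv–mtse, conv–cs,
mtse–cs) on cases present in both arms and declares significance at the
family threshold 0.025 per pair, following the convention of this study
design; Bonferroni-adjusted p-values (×3, capped at 1) are reported
alongside but do not drive the flag. The threshold is a parameter, since
the mapping of a 0.025 threshold onto three pairwise comparisons is a
convention rather than a derivation.

The ratings simulator draws `score = clip(round(latent + N(0, reader_sd)),
1, 5)` per case; `reader_sd = 0.7` is used in the power checks, putting
most mass on 2–3 adjacent categories as consensus reads typically show.

## Numerical choices and degenerate inputs

* Soft threshold at magnitude 0 uses a guarded denominator (no NaN).
* Power iteration failure (zero/non-finite iterate) raises rather than
  silently mis-stepping; non-finite k-space is rejected on model build.
* `nrmse` is reference-normalized and deliberately not symmetric; report
  level comparisons first rescale the test image to the reference l2 norm,
  because reconstructions differ from the ground truth by a global scale.
* SSIM uses an 11×11 Gaussian window (σ = 1.5), k1 = 0.01, k2 = 0.03,
  dynamic range = reference maximum, averaged over fully-valid window
  positions only (no border padding).
* Ties in the center-out echo ordering break toward the lower line index;
  the center-most sampled line is the TE anchor in all orderings.

## Problem sizes

The bundled experiment and the heavier tests run at 128×128 with 8 coils
and 60–80 solver iterations; solver-correctness checks run at 16×16 against
an independently coded 10⁵-iteration small-step reference solve; statistical
power checks use 200 replicates of n = 101 cases. These sizes are chosen so
the full chain demonstrates its properties at interactive speeds on one CPU.

## Known limitations

* The conventional parallel-imaging arm is reconstructed with the
  coil-combined adjoint; GRAPPA kernel calibration/interpolation and
  ESPIRiT-style eigen-calibration are out of scope.
* Multi-shot TSE is represented only by its protocol record and mask
  geometry (its segmented acquisition is not simulated), so echo-train
  arithmetic deliberately refuses multishot records.
* Scan-time prediction is not attempted; published scan times are not
  reproducible from a simple TR × slices model.
* Variable refocusing flip-angle trains, SAR, B1, non-Cartesian/wave
  trajectories and learned reconstructions are out of scope.
* Whether the published phase-encode matrix sizes already fold in the 6/8
  partial-Fourier factor is ambiguous in the source protocol tables; the
  package keeps partial Fourier as a separate, composable mask and makes
  no assumption either way.
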