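# csmri

Desk-scale simulator and reconstruction suite for **compressed-sensing (CS)
accelerated single-shot fast-spin-echo (SSFSE) MRI**, aimed at people who
want to study — without a scanner — why a variable-density CS acquisition
can outperform the conventional SSFSE protocol (uniform parallel-imaging
undersampling plus 6/8 partial Fourier with homodyne synthesis) at a higher
acceleration factor, and at the ordinal reader-study statistics such
sequence comparisons are judged by.

## What it computes

An SSFSE shot acquires all phase-encode lines of a slice in one echo train;
line `j`, acquired at echo index `e(j)`, sees the object decayed by
`exp(-TE_eff(j)/T2)`, which is the source of the characteristic T2 blurring
of long echo trains. Shortening the train by undersampling is therefore
attractive, and the CS variant samples a variable-density subset of lines
(denser at the k-space center) at total acceleration R = 3, plus a separate
24-line autocalibration reference scan for coil-sensitivity estimation.

The CS image **I** is the minimizer of

```
argmin_I  ½ ‖A I − D‖₂² + λ ‖W I‖₁
```

where **D** is the acquired multi-coil k-space, **A** = (sampling mask) ∘
(unitary 2D Fourier transform) ∘ (coil-sensitivity multiplication), **W** is
the orthonormal multilevel Haar transform and λ the regularization weight.
The solver is proximal-gradient (ISTA) or its accelerated variant with
function-value restart; because W is orthonormal, the proximal step is an
exact soft-threshold in the wavelet domain.

The package provides:

* `phantom` — procedural T2-weighted abdominal slice (proton-density / T2 /
  phase / tissue-label maps, fluid and solid focal lesions) and smooth
  RSS-normalized coil maps;
* `acquisition` — protocol records with echo-train arithmetic
  (`ETL = floor(matrix_pe / R)`), variable-density / uniform /
  partial-Fourier masks, the decaying echo-train forward model, the
  reference scan, interleaved slice ordering;
* `recon` — coil-map calibration, the `CSReconstruction` model object
  (`fit()` → `ReconResult` with image, objective trace and `summary()`),
  homodyne partial-Fourier reconstruction and the zero-filled adjoint
  baseline;
* `metrics` — NRMSE, PSNR, SSIM and label-boundary edge sharpness against
  the known ground truth;
* `ratings` — five-point ordinal rating tables, descriptive statistics,
  insufficiency rates (score ≤ 2), exact/approximate paired Wilcoxon
  signed-rank tests with a 0.025 significance threshold, and a
  latent-quality ratings simulator.

## Worked example

```sh
$ csmri demo --out-dir demo_out --seed 0
Experiment summary (NRMSE / PSNR dB / SSIM per arm)
----------------------------------------------------
full_adjoint       nrmse=0.0770 psnr=37.95 ssim=0.9414
homodyne           nrmse=0.0563 psnr=40.66 ssim=0.9630
uniform_adjoint    nrmse=0.3399 psnr=25.05 ssim=0.8139
cs                 nrmse=0.0625 psnr=39.76 ssim=0.9444
vd_zero_filled     nrmse=0.1614 psnr=31.52 ssim=0.8830
```

One 128×128 phantom slice is imaged under four sampling schemes and each is
reconstructed with its matched method. Reading the numbers: the fully
sampled adjoint (`full_adjoint`) is limited only by noise and T2 blurring;
`homodyne` reconstructs the 75% partial-Fourier acquisition nearly as well;
the plain adjoint of uniform R = 2 undersampling (`uniform_adjoint`)
aliases badly (NRMSE 0.34); and at the *higher* acceleration R ≈ 3 the CS
reconstruction (`cs`, NRMSE 0.063) recovers most of the quality lost by
zero-filling the same variable-density data (`vd_zero_filled`, NRMSE 0.16).
The output directory also holds the masks (CSV), reconstructions and ground
truth (NIfTI), the CS objective trace (CSV) and `metrics.csv`.

The same pipeline is available from Python:

```python
from csmri import RunConfig, run_experiment
result = run_experiment(RunConfig(seed=0))
print(result.summary())
```

and the reader-study side, e.g.

```python
from csmri import simulate_ratings, compare_sequences
table = simulate_ratings(101, {"ssfse_conv": 3.3, "mtse": 3.7, "ssfse_cs": 4.2},
                         reader_sd=0.7, seed=1)
print(compare_sequences(table, "overall").summary())
```

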