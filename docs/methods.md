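# Methods

This note documents the models, the synthetic data, the numerical choices,
and the limits of what the test suite demonstrates.

## Forward model and reconstruction

Multi-contrast, multi-coil Cartesian acquisition is modeled as
`y[p,c] = M_p F (C_c ⊙ x_p) + n`, with `x_p` the contrast-`p` image, `C_c`
the complex sensitivity of coil `c`, `F` the centered orthonormal 2D DFT,
and `M_p` a boolean sampling mask that zero-fills unmeasured points. The
DFT convention (fftshifted, `norm="ortho"`) is shared by every module, so
`E` is exactly unitary for a full mask and a single uniform coil, and
`EᴴE + λI` has spectrum in `[λ, 1+λ]` for RSS-normalized sensitivities —
the property that makes a fixed small CG iteration count adequate.

Reconstruction unrolls `n_unrolls` alternations of a learned denoiser and a
data-consistency (DC) solve of `(EᴴE + λI) x = Eᴴy + λz` by conjugate
gradients. Choices the formulation leaves open, and what this package does:

* **Initialization** `x₀ = Eᴴy` (zero-filled adjoint).
* **λ = 0.05, fixed** by default; a trainable-λ flag exists but is off.
* **Denoiser weights shared across unrolls** (the MoDL convention).
* **CG**: warm-started at `z`, a fixed 10 iterations by default (5 in the
  scaled-down suite), no tolerance-based early exit — the run is then a
  fixed deterministic computation graph. The recursion (inner products,
  step-size ratios) is built from differentiable primitives, so gradients
  flow through the iterations rather than through an implicit-function
  approximation.
* **Denoiser**: real/imaginary parts of all contrasts concatenated
  channel-wise (`[Re p1..pP, Im p1..pP]`), input conv → `n_blocks` residual
  blocks (conv 3×3, ReLU, conv 3×3, scale by α = 0.1) → output conv, plus a
  global skip. Defaults: 10 blocks, 64 filters. No normalization layers.
* **Weight initialization**: He-style random weights with the output
  convolution zeroed, so a fresh denoiser is exactly the identity and the
  unrolled network starts from the DC solution. Starting instead from a
  randomly perturbing denoiser wastes most of a short training budget
  undoing the perturbation; identity-start is standard for residual
  reconstruction networks.

## Autodiff and memory-efficient training

No tensor framework is used; `qmrecon.autodiff` is a minimal tape-based
reverse-mode engine over numpy arrays sized to this model family. Complex
gradients follow the steepest-ascent convention `g = ∂L/∂Re + i ∂L/∂Im`,
under which the VJP of any C-linear map is its Hermitian adjoint (so the
VJP of the unitary centered DFT is its inverse).

Gradient checkpointing wraps each denoise+DC segment: the forward pass runs
the identical numpy call sequence without recording (bit-identical
outputs), stores only the per-unroll inputs, and recomputes one segment at
a time during the backward sweep. Retained graph size is therefore bounded
by the number of unrolls, independent of denoiser depth, at the cost of one
extra denoiser evaluation per unroll (verified by instrumentation: exactly
`2 × n_unrolls` denoiser calls per training step). Reverse recomputation of
the CG layer itself is deliberately not implemented; the per-unroll
checkpoint already bounds memory.

## Training regimes

All regimes minimize the scale-invariant k-space loss
`L(u,v) = ‖u−v‖₁/‖u‖₁ + ‖u−v‖₂/‖u‖₂` with Adam (β = 0.9/0.999); learning
rates default to 1e-4 (SL, SSL) and 5e-4 (ZSSSL). The optimizer is the
package's choice — the formulation does not prescribe one. Batches support
gradient accumulation that is mathematically identical to the unsplit
batch (each chunk's loss is scaled by its share before backprop).

* **SL**: input `y_Ω`/`E_Ω`, loss on the full k-space reference.
* **SSL**: Ω split 60/40 into Θ (input) and Λ (loss), uniformly at random
  outside the autocalibration (ACS) block, which always stays in Θ; a
  Gaussian center-weighted selection is available behind a flag. The
  partition is drawn once per case and fixed across epochs. Access to fully
  sampled data is structurally forbidden: `fit` wraps every case in a proxy
  whose `y_full` attribute raises.
* **ZSSSL**: one case; Γ takes 20% of Ω for validation, the remaining Ξ is
  split 60/40 into Θ/Λ (so Θ holds 48% of Ω). Training optimizes Θ→Λ,
  validation monitors Ξ→Γ, and training halts once validation has failed to
  improve for more than `patience` (default 25) consecutive epochs — i.e. a
  frozen network evaluates `1 + patience + 1` epochs before stopping. Best
  -validation weights are restored for all regimes. Inference uses the full
  measured data `y_Ω` with `E_Ω`.

Every run is seeded end to end (case order shuffling, weight init) and
reproduces its loss history bitwise on one machine.

## Synthetic data

The generator replaces acquired data while preserving the statistical
structure the reconstruction problem cares about:

* **Phantom**: nested-ellipse brain-like label map (CSF rim, GM ribbon, WM
  interior, CSF ventricles, seeded WM lesions) with per-tissue PD/T1/T2.
  Default values (WM 0.70/800 ms/70 ms, GM 0.85/950 ms/100 ms, CSF
  1.0/4000 ms/1800 ms, lesion 0.90/1400 ms/250 ms) are artifact defaults
  chosen so the threshold evaluation regions T1 ≤ 1000 ms and T2 ≤ 120 ms
  select exactly WM+GM; a cartilage/fluid table serves knee-like qDESS
  cases.
* **Coils**: loop coils (radius 100 mm, default six, eight for knee-like
  cases) placed on a ring outside the field of view, normals pointing
  inward. Sensitivities are discretized Biot–Savart line integrals
  evaluated on the image plane; the complex phase is taken from the
  transverse field components (`B_x − iB_y`, main field along z), because a
  static field computation alone yields no phase model. The set is
  RSS-normalized to 1 inside the FOV.
* **Contrasts**: analytic signal models evaluated pixelwise —
  `I0·exp(−TE/T2)` for the multi-echo spin echo (ideal 90°/180° pulses, for
  which the analytic form and a Bloch simulation coincide), the
  spoiled-gradient-echo steady state for variable-flip-angle T1 mapping
  (with the standard `sin α` numerator; the printed form without it is
  selectable), and a two-contrast FID/echo pair for qDESS whose ratio
  follows the T1/diffusion-corrected steady-state expression. The TE
  entering the qDESS ratio is the FID echo time; diffusivity defaults to 0
  so the correction reduces to its non-diffusive form unless configured.
* **Noise**: complex Gaussian, σ = 0.01% of the peak k-space magnitude,
  added independently to real and imaginary parts (the noise model choice
  is recorded here because "Gaussian noise at 0.01%" does not by itself fix
  complex vs magnitude noise).
* **Undersampling**: uniformly random phase-encode lines or points plus a
  fully sampled ACS center, at a target acceleration factor AF; per-contrast
  masks are drawn independently by default (shared optionally). Effective
  AF after retaining a fraction f of samples is reported as
  `AF/f` truncated to one decimal (AF 4 → 6.6 at 60%, 8.3 at 48%).

What the generator does **not** emulate: B0/B1 inhomogeneity, motion,
slice-profile and partial-volume effects, realistic anatomical texture,
Rician magnitude bias, eddy-current effects of prospective acquisitions.
Passing tests therefore demonstrate correctness of the operators, training
mechanics, and the relative behavior of the regimes on controlled data —
not clinical image quality.

## Map fitting

* MSME T2: log-linear regression (signal-weighted) seeds a bounded
  Gauss-Newton refinement on (I0, 1/T2), vectorized over pixels; the
  scalar API uses a trust-region least-squares solver. Bounds (1, 5000] ms;
  a fit at a bound, a non-positive signal, or a non-decaying train is
  flagged invalid.
* VFA T1: DESPOT1 linearization (`S/sin α` on `S/tan α`; slope `E1`),
  closed form per pixel; slope outside (0, 1) is invalid. Bounds
  (1, 10000] ms.
* qDESS T2: closed-form inversion of the echo/FID ratio; invalid where the
  FID vanishes, the ratio does not decay, or T2 leaves (1, 500] ms.

## Evaluation

NRMSE over an evaluation region Φ: the requested region variant (whole,
T2 ≤ 120 ms, T1 ≤ 1000 ms — inclusive thresholds, strict variants
selectable — or an external mask) intersected with outlier exclusions
(predicted T1 > 5000 ms or T2 > 500 ms; ground-truth first-contrast
magnitude below 5% of its maximum; invalid fits). NRMSE is
`‖pred−gt‖₂/‖gt‖₂` over Φ (mean- and range-normalized variants
selectable). SSIM uses the standard single-scale form, 11×11 Gaussian
window (σ 1.5), K1 = 0.01, K2 = 0.03, data range = reference maximum.
Ground-truth maps for evaluation are fitted from the ground-truth contrast
images with the same fitter applied to reconstructions, so fit bias
cancels.

## Scaled-down study sizes

The full-scale study (256² matrices, 16 contrasts, 64-filter/10-block
network, 100+ epochs) is a GPU-class workload. The package's own study
suite runs desk-scale:

* operator/checkpointing checks on 4×4–16×16 instances;
* the zero-shot-vs-baseline experiment on a 32×32, 4-coil, 4-echo MSME
  case at AF 4 (2 residual blocks, 16 filters, 3 unrolls, 5 CG steps,
  ≤ 50 epochs in the test suite);
* the cross-regime ordering study at AF 8 (random-point masks — at AF 8 a
  32×32 line mask has no budget beyond the ACS block) with 6 training and
  2 validation cases, a scaled-down version of the 10/2/2 case split, 8
  filters and 40 epochs, repeated over 5 seeds. The regimes validate on
  structurally different k-space subsets, so for cross-regime comparison
  each trained model is scored on one shared test case by the supervised
  loss against its fully sampled reference. At AF 4 the three regimes are
  statistically indistinguishable on this suite (consistent with the
  full-scale finding); the supervised-over-self-supervised ordering
  emerges at AF 8, and it requires the multi-case training set — with only
  two training cases the zero-shot regime, which adapts to the test case
  itself, wins instead.

## Known limitations

* The autodiff engine materializes dense conv patch matrices; it is sized
  for ≤ 64² images, not production training.
* Sensitivities are the simulation's own (no self-calibrated estimation
  such as ESPIRiT); evaluation therefore isolates reconstruction error
  from calibration error.
* Single-component relaxometry only; no B1 correction, no Rician-bias
  correction on magnitudes.
* Non-Cartesian trajectories and off-resonance are out of scope.
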