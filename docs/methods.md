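# Methods

`bvlkit` estimates percentage brain volume loss (BVL) between a baseline
(BL) and a follow-up (FU) 3D T1-weighted MRI acquired on the same scanner
with the same sequence. This note describes the model, the numerical
choices, and what the synthetic phantom does and does not establish.

## Pipeline model

1. **Halfway-space preprocessing.** Both scans are resliced to isotropic
   voxels (1 mm default) in canonical transversal orientation, cropped to a
   fixed-size head box, and rigidly aligned in *halfway space*: the rigid
   motion `T` between the crops is estimated once (SimpleITK
   multi-resolution registration, correlation metric by default, Euler
   parameterization) and each image is resampled through the exact matrix
   square root of `T` (half rotation vector; translation solving
   `(I + R_half) t_half = t`). Each image is therefore interpolated exactly
   once, and neither scan is privileged — the construction that removes
   single-interpolation asymmetry bias from longitudinal change estimates.

2. **Deformable registration.** A small 3D U-Net maps the concatenated,
   foreground-normalized crops to a dense displacement field (voxels,
   pull/backward convention: output voxel `x` samples the source at
   `x + u(x)`). Training is unsupervised: the loss is

   `L = -localNCC(warp(src, u), tgt) + λ · mean‖∇u‖² + μ · mean‖u‖²`

   with local squared NCC over cubic windows (edge 9),
   `cc = (cross² + ε) / (var_src · var_tgt + ε)`, `ε = 1e-5`. The ε appears
   in numerator and denominator so a perfect match scores exactly 1 in every
   window, including flat background windows, and the loss is never NaN;
   Cauchy–Schwarz keeps `cc ≤ 1`. The gradient penalty (λ = 1.0) uses
   forward differences; constant fields are free. The weak magnitude prior
   (μ = 0.03) pins the field to zero wherever the similarity term is flat
   (uniform tissue, background) and the gradient penalty is blind (constant
   drift); it is negligible against genuine deformations at these weights.
   Both weights are configuration keys.

   The network and its training loop are implemented directly in NumPy with
   hand-derived forward/backward passes per layer (shifted-matmul 3×3×3
   convolutions, average-pool down, nearest-neighbour up, leaky ReLU, Adam
   with global gradient-norm clipping at 1.0). All gradients are verified
   against finite differences in the test suite's development history and
   the spatial-transformer gradient masks clamped (out-of-grid) samples.

   At prediction time the backend antisymmetrizes over input order,
   `u = (f(a,b) − f(b,a))/2`, an inverse-consistency construction that makes
   self-registration exactly zero and cancels order-independent drift, at
   the cost of a second forward pass.

   Desk-scale defaults: 64³ crops, encoder widths (8, 16, 16), flow head at
   quarter resolution (the fields of interest are smooth; the
   full-resolution decoder would dominate CPU cost), 40 epochs over 16
   pairs, Adam lr 5e-3, on-the-fly augmentation (left–right flip and
   optional rotation applied identically to both crops; Gaussian noise
   σ = 0.03 added *independently* to each crop — fresh noise per step is
   what prevents the network from aligning a fixed noise realization;
   random source/target interchange). Published-scale settings
   (176×208×208, 350 epochs, batch 2, lr 1e-4, full-resolution flow) remain
   reachable through the same configuration.

3. **Symmetric mask-warping volumetry.** Brain-parenchyma (BPV) and
   total-intracranial (TIV) masks — externally supplied, phantom ground
   truth, or the bundled multi-Otsu fallback (adequate for phantoms only) —
   are counted natively and pull-warped with trilinear interpolation in
   both registration directions. Warped masks stay *soft*: fractional
   boundary voxels contribute fractionally to the summed volume, never
   re-thresholded (trilinear interpolation of a 0/1 mask cannot leave
   [0, 1], so raw sums are safe). Changes:

   * forward: `dBPV_fw = 100 (BPV_FU←BL − BPV_BL) / BPV_BL`
   * backward: `dBPV_bw = 100 (BPV_FU − BPV_BL←FU) / BPV_BL←FU` — the
     denominator is deliberately the warped-to-BL volume, implemented as
     defined rather than simplified
   * symmetric means `dBPV`, `dTIV` of the two directions.

4. **Distortion correction and rescaling.** Scanner distortion inflates
   BPV and TIV by a nearly identical relative factor, so the apparent TIV
   change proxies distortion severity: `res_dBPV = dBPV − m_TIV·dTIV`. The
   regression intercept represents the calibration cohort's mean atrophy,
   not distortion, and is *not* subtracted. The residual is proportional to
   BVL but not on the percent scale; a second regression against a
   reference method's estimates provides the rescaling slope:
   `BVL = res_dBPV / m_rescale`. Negative BVL denotes loss. Shipped
   defaults are the published constants (`m_TIV = 0.95`, `c_TIV = −0.23`,
   `m_rescale = 0.30`, `c_rescale = −0.01`, reference = SIENA); `bvlkit
   calibrate` refits on any cohort with any reference (phantom ground truth
   in the self-contained studies), and every calibration carries a
   provenance string. By construction the final estimate satisfies
   `BVL = 0.5 (BVL_fw + BVL_bw) / m_rescale` with
   `BVL_fw/bw = dBPV_fw/bw − m_TIV·dTIV_fw/bw`, bit-exact.

   When the rescaling slope is refit for a trained backend on a small
   phantom cohort, only the rescaling regression is refit; the
   TIV slope stays at its published value. On a cohort where atrophy
   variance dominates the tiny distortion-induced TIV variance, refitting
   the TIV slope would conflate atrophy with distortion (the regression
   design assumes distortion is the dominant source of shared variance, as
   it is in a large multi-scanner cohort).

5. **Statistics.** Agreement is summarized Bland–Altman style with median
   and quartile IQR as headline numbers (linear-interpolation/type-7
   quantiles — stated because IQR endpoints are headline outputs), classic
   mean ± 1.96 SD limits alongside, and ICC (two-way random absolute
   agreement, single rater — ICC(A,1) in pingouin's labels; the consistency
   form is an option). Equality of paired variances uses the Pitman test:
   correlation between per-pair sums and differences, Spearman by default,
   Pearson (the classical Pitman–Morgan form) as a flag.

## The synthetic phantom

Four nested axis-aligned ellipsoids (skull shell, intracranial cavity,
parenchyma, central ventricle) rendered with a ~1.5 mm smoothstep edge so
registration has gradients. Default geometry: 64³ grid at 1 mm, skull
(24, 28, 24) mm semi-axes, TIV (20, 24, 20), ventricle ¼ of TIV; intensities
(0, 60, 25, 100) for background/skull/CSF/parenchyma (loosely T1-like —
absolute values are irrelevant after normalization). Cohorts jitter head
size ±6% and ventricle ratio in [0.2, 0.3] per subject.

*Radial atrophy* acts on the TIV-normalized radius `r` as
`g(r) = r + A·r(1−r²)²`: the TIV surface is fixed, the ventricle surface
moves, and the parenchyma shell volume change has the closed form
`(1 − g(κ)³)/(1 − κ³)` (κ = ventricle/TIV ratio, which is why the two must
be proportional in this mode). The amplitude hitting a requested BVL is a
cube root — no root finding — and monotonicity of `g` is verified so the
map never folds. *Scanner distortion* is a global affine scale `s` about
the grid center applied to the whole FU image; it changes BPV and TIV by
exactly `s³`, the assumption the TIV correction exploits. Because every
step maps ellipsoids to ellipsoids, the FU image is re-rendered
analytically (zero resampling error) and exact masks, exact pull/forward
fields (radial inversion by a few Newton steps) and exact continuum volumes
are all available. The *uniform-scale* mode scales the parenchyma
compartment only; the brain surface detaches from the TIV leaving a CSF rim
where no image-consistent deformation exists (CSF is created, not
advected) — volume truth is unaffected, but the radial mode is the default
for registration studies.

What the phantom does **not** emulate: anatomy, MRI physics (bias fields,
sequence contrast), lesions, inter-scanner contrast differences, nonlinear
distortion profiles (distortion here is a pure global scale — the minimal
model consistent with the TIV-correction rationale). Passing phantom
studies therefore establishes the correctness of the *pipeline mathematics*
(volumetry, correction, calibration, statistics) and the trainability of
the registration network on smooth geometry; they do not establish clinical
accuracy on real scans.

## Validation studies (what the suite computes)

* **Oracle recovery** — 20 noise-free pairs, BVL ∈ {0, −0.5, −1, −2}%,
  exact fields, unit rescaling: |estimate − truth| stays within 0.1
  percentage points (observed ≲ 0.04).
* **Distortion robustness** — 100 zero-atrophy pairs, distortion scale
  uniform in (0.997, 1.003): the corrected estimate's SD is ~5% of the
  uncorrected dBPV's, and the Pitman test flags the difference.
* **Mask-warp vs Jacobian integration** — on analytic radial and
  uniform-scale fields the two volume-change routes agree within 0.3
  percentage points at 64³ and within ~0.03 at 128³ (central-difference
  error at the mask boundary shrinks with resolution).
* **Algebraic identities** — the final-estimate identity holds bit-exact;
  swapping BL and FU flips the sign within 0.05 points on noise-free pairs.
* **Calibration fits** — 95% CIs cover generating slopes in ≥ 90/100
  simulated cohorts (n = 200; noise SD 0.05 and 0.02); noiseless lines at
  the shipped constants are recovered to machine precision.
* **Statistics** — Pitman type-I error within [0.03, 0.07] at α = 0.05
  (n = 200, 1000 reps, both methods); ICC within 0.02 of its closed form
  `1/(1+σ²)` under the truth-plus-noise model.
* **Trained backend** — 16-pair, 40-epoch desk-scale training (minutes on
  one CPU), rescaling slope refit on the training cohort (observed ≈
  0.85–0.90, the phantom analogue of the published 0.30 against SIENA):
  self-registration field exactly zero, correct signs on ±1% pairs,
  held-out error within 0.3 percentage points (observed ≲ 0.24).

Problem sizes above are the package's desk-scale defaults, chosen so the
whole validation runs on a single CPU in minutes while leaving every
quantity's mechanism intact; all are configuration parameters.

## Numerical choices and edge cases

* Field units are voxels, pull convention, recorded in NIfTI headers.
* Masks crossing rigid transforms are trilinearly resampled and
  re-thresholded at 0.5 only when a binary mask is required; warped-mask
  volumetry always keeps fractional values.
* Zero-variance NCC windows, empty masks, zero denominators, degenerate
  regression predictors and non-invertible affines raise typed errors;
  warped volumes deviating more than 20% from their native counterparts
  trip a sanity gate (registration/segmentation failure).
* Jacobian-determinant integration expects *forward* (Lagrangian)
  displacements and counts non-positive determinants (folding) as a
  runtime warning.
* Seeds: every stochastic component (phantom noise, cohort sampling,
  weight init, augmentation, shuffling) derives from explicit integer
  seeds; fixed seeds reproduce training trajectories bit-for-bit.

## Known limitations

* The registration engine is CPU-bound NumPy; at the published crop size
  training is possible but slow — the desk-scale configuration is the
  supported regime.
* The fallback Otsu segmenter is for phantoms; real scans need external
  parenchyma/TIV masks.
* Same-scanner BL/FU pairs are assumed throughout; no inter-scanner
  harmonization is attempted.
* The rescaling slope is definitionally tied to its reference (SIENA for
  the shipped constants, phantom truth for refits); estimates are on the
  reference's scale.
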