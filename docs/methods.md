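# Methods

## Kinetic model

The two-tissue-compartment model is linear, so the tissue impulse response
is a sum of two exponentials (a `t·e^{−αt}` term in the repeated-root
limit); amplitudes and rates follow from k1–k4 by the standard closed form
(see the README).  Two convolution back-ends implement `C_T = h ⊗ Cp`
exactly for the two plasma representations:

* **Parametric input** (the phantom's tri-exponential bolus): term-by-term
  analytic convolution.  Near the removable singularity α → λ the closed
  forms are replaced by fourth-order series (switch at |α−λ|·t < 1e-3),
  keeping full double precision.
* **Sampled input** (an IDIF): the input is piecewise linear between
  samples, and the convolution is advanced segment-by-segment with the
  exact update `y⁺ = y·e^{−x} + c₀Δ·φ1(x) + mΔ²·φ2(x)` (x = αΔ), using the
  stable φ-functions `φ1=(1−e^{−x})/x`, `φ2=(e^{−x}−1+x)/x²`,
  `φ3=(1−e^{−x}−x+x²/2)/x³` with series branches below x = 1e-3.  Frame
  integrals use the same functions, so frame averaging is exact for the
  piecewise-linear input — no quadrature error accumulates across the 25
  frames.  This recursion is numba-compiled; it is the inner loop of every
  voxel fit.

**Repeated roots.** When |α2−α1| < 1e-6 min⁻¹ the parametric path switches
to the degenerate analytic form.  The threshold is deliberately loose: just
outside it the generic two-exponential form loses ~`eps/|α2−α1|` of
precision to cancellation, while the degenerate form is wrong only by
O(|α2−α1|²) ≈ 1e-12 — so 1e-6 is where both branches are accurate to
better than 1e-8.  The sampled path handles the same corner by splitting
the double root symmetrically by 1e-6, equivalent to the same order.

**Units.** Rate constants are per minute (k1 in ml·cm⁻³·min⁻¹),
concentrations kBq·ml⁻¹; frame schedules are seconds on disk and converted
once at the boundary.  Activity is assumed decay-corrected.  The tissue
blood-volume fraction is fixed at zero (the model statement uses k1–k4
only); Ce/Cp uses the lumped-constant-type factor 0.26 as a configurable
scalar.

## Phantom generator

The phantom defines the study conditions for all downstream claims:

* **Geometry.** An ellipsoidal "brain" (semi-axes 0.4 of each dimension)
  partitioned into contiguous regions by farthest-point-seeded nearest-seed
  assignment; default 20×20×10 voxels of 0.4×0.4×0.8 mm with 8 regions named
  CP, BNST/LPO, MBH, PAG, ZI/aSNR, pSNR, MV, SPV.  A small blood-pool block
  sits outside the brain, as the aorta does.
* **Kinetics.** Per-region baselines drawn once per seed from physiological
  FDG ranges (k1 0.08–0.14 ml·cm⁻³·min⁻¹, k2 0.15–0.30, k3 0.04–0.09,
  k4 0.005–0.015 min⁻¹, giving Ce/Cp ≈ 0.15–0.35).  The insulin condition
  multiplies k1 in designated effect regions (default: ×0.7 in MBH, a 30%
  Ce/Cp reduction, since Ce/Cp is linear in k1); per-subject lognormal k1
  factors (σ = 0.1) add between-subject variability that pairing removes.
* **Input.** A tri-exponential bolus `a1·t·e^{−λ1t} + a2(e^{−λ2t}−e^{−λ1t})
  + a3(e^{−λ3t}−e^{−λ1t})` peaking near 20 s at ~25 kBq·ml⁻¹ with a
  slowly-decaying tail — a standard smooth, analytically integrable family.
  The real input is measured in vivo and has no published functional form;
  this is a stand-in.
* **Blood pool.** Voxels carry `0.6·Cp + 0.4·background`, exactly the
  mixture the downstream 0.6 correction inverts; a `vf_true` knob allows
  deliberate mismatch for sensitivity studies.
* **Noise.** Zero-mean Gaussian with per-frame variance `Sc·C/Δt` — the
  standard surrogate for count statistics in reconstructed frames (shorter
  frames noisier).  "x% noise" means `Sc` is calibrated so the *mean*
  frame-wise coefficient of variation over informative frames (>5% of TAC
  max) equals x%; 30-s frames then sit above, 240-s frames below that mean.

What the phantom does **not** emulate: reconstruction artefacts, spatially
correlated noise, attenuation/scatter, partial-volume blur between tissue
regions, motion, and anatomical realism.  Passing tests therefore validate
the estimator and statistics under the stated noise model, not robustness
to real scanner physics.

## Input function

The blood pool is found automatically as the connected component containing
the first-frame maximum above a quantile threshold (default 0.95 of positive
first-frame voxels) — the bolus makes blood the hottest structure in the
earliest frame.  The IDIF is the frame-wise mean over that mask, corrected
as `(measured − (1−vf)·background)/vf` with vf = 0.6; the default
background is zero (pure division), with the spill-in term available as an
option.  Negative corrected values are clamped to zero and counted in
provenance.  The continuous input for fitting interpolates linearly through
(0, 0) and the frame-mid samples, with a single-exponential tail fitted to
the last three samples beyond the final frame mid-time.

## Voxel fitting

Weighted bounded least squares (scipy trust-region reflective) minimizes
`Σ Δtᵢ·(TACᵢ − modelᵢ)²`; duration weights are standard for count-limited
frames (uniform weights selectable).  Bounds k1 ∈ [0,2] ml·cm⁻³·min⁻¹,
k2, k3 ∈ [0,2] min⁻¹, k4 ∈ [0,0.2] min⁻¹; fixed start (0.1, 0.1, 0.05, 0.01)
plus 4 seeded log-uniform multistarts; ties resolved by lowest weighted
residual then lowest k4.  k4 is free by default; `fix_k4=0` selects the
irreversible variant.  Convergence: ftol 1e-8, at most 500 residual
evaluations per start; non-converged voxels are flagged and NaN in maps,
never exceptions.  Identical TACs (noiseless phantoms) are fitted once and
broadcast.  The brain mask keeps voxels whose time-integrated activity
reaches the configured quantile of nonzero-voxel integrals (default 0:
every active voxel), minus the blood pool.

## Group statistics

Paired two-sided t-tests on subject-wise (saline − insulin) Ce/Cp
differences, df = n−1; voxels undefined in any subject are excluded.
Zero-variance voxels: t = 0, p = 1 when the mean difference is zero,
otherwise p is set to the smallest positive double and the voxel is
flagged.  VOIs are 6-connected components of p < α (default 0.05) with ≥ 4
voxels, split by effect direction and named by the dominant overlapping
atlas region; the VOI re-test runs the same paired t-test on per-subject
VOI-mean Ce/Cp.  No multiple-comparison correction is applied to the
voxel-wise map by default — the map is exploratory and the VOI re-test
confirmatory; an optional Benjamini–Hochberg adjustment exists.  The
p-map can be resampled trilinearly to a finer grid (e.g. 0.1 mm isotropic)
for presentation only; resampling never alters the stored statistics.
An open question in the emulated design is whether the voxel-wise test ran
on Ce/Cp or on cumulative uptake; Ce/Cp is the default compared quantity
here, and cumulative uptake can be derived from the same maps if needed.

## Photometry

The analysis is deliberately minimal: F = F465/F405 cancels shared
multiplicative artefacts exactly (the isosbestic channel is
calcium-independent); F0 is the median of F over the pre-event baseline
(10 min in the simulated protocol), robust to <50% contamination;
dF/F(%) = 100·(F−F0)/F0; the response magnitude is the trapezoidal AUC of
dF/F over a configurable post-event window, by default the full 20-min
post-event recording, in %·min.  No photobleaching correction is applied.
The simulator puts a shared sinusoid×bleach artefact on both channels and a
saturating response on the 465 channel only, at 20 Hz (analysis is
rate-agnostic), so artefact rejection and amplitude recovery are exact
identities in the noiseless case.

## Translatome overlap

Pure set logic on DE tables (no DE testing here): protein-coding + TPM ≥ 1
pre-filter; cell-type enrichment gate adjusted-p ≤ 0.05 AND log2FC > 0 on
the IP-vs-input table; "commonly regulated" genes are significant
(adjusted-p < 0.05) in both condition comparisons *with the same
fold-change sign* — the concordance requirement is an interpretation,
adopted because the up/down partition must sum to the common total; the
asymmetric boundary conventions (≤ vs <) are kept exactly as printed in the
emulated filter chain.  The generator plants configurable counts (default
74 up / 50 down, 60 / 28 inside the enriched set) and decoys (discordant,
single-comparison, non-coding, low-TPM) so the chain's outcome equals the
planted truth exactly.

## Problem sizes and defaults

The default end-to-end cohort runs 8 subjects × 2 conditions on a 16×16×8
phantom (~550 fitted voxels per scan) — large enough for stable paired
statistics and well-resolved regions, small enough for interactive use.
Recovery checks use the full 20×20×10 phantom (noiseless fits deduplicate
to one fit per region) and 100 noisy voxels; the null-calibration cohort
uses ~2000 voxels so the binomial error on a 5% false-positive rate is
~0.5%.  Reproducibility is checked by hashing map files from two identical
3-subject runs.

## Known limitations

* The IDIF path inherits interpolation bias from frame-mid sampling of the
  bolus peak (~1% on k1 at the default schedule); the paired design cancels
  it between conditions.
* k4 is weakly identified from a 43-min scan; its estimate absorbs noise
  (Ce/Cp does not involve k4 and is unaffected).
* Voxel-wise p-maps are uncorrected by design; interpret via the VOI
  re-test.
* The phantom's noise is independent across voxels; cluster-size behaviour
  on real, spatially smoothed reconstructions will differ.
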