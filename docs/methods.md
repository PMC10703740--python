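# Methods

This note documents the models inside `ctmar`, the parameters that matter,
the design decisions that were genuinely open, and what the synthetic
experiments do and do not demonstrate.

## Thorax phantom

A phantom is a composition of ellipses on a square canvas: body (soft
tissue, 40 HU), two lungs (−700 HU), heart (35 HU), a vertebra and eight
ribs (700 HU), on an air background (−1000 HU). Default geometry is 512 px
at 0.7 mm/px (a ~36 cm adult field of view); `PhantomSpec.default(n)`
rescales the spacing so physical extents survive resolution changes. Two
stochastic elements, both driven by `(jitter_seed, seed)`:

* **anatomical jitter** — ellipse centres, axes and rotations perturbed by
  ~3% per "patient"; jittered ellipses that touch the canvas are re-centred
  inside it (axes preserved) so every seed yields a valid phantom;
* **texture** — Gaussian HU noise (σ = 10 HU) inside the body, so SSIM and
  PSNR are not degenerate on piecewise-constant images.

The raster is then band-limited with a 0.8 px Gaussian (`edge_sigma_px`).
Clinical reference slices are themselves reconstructions and contain no
sub-pixel-sharp edges; without this step the Gibbs mismatch between a
hard-edged raster and any filtered-back-projection output dominates the
artifact-free simulation error and misrepresents what the simulator does.
The label map stays crisp; the exact construction invariants (region HU
equal to the configured value) hold with `edge_sigma_px = 0` and are tested
there.

The probe is a rectangular plastic housing (72 × 22 mm, −50 HU — the
housing has no quantitative description in the source material, so these
are free parameters) holding a 60 × 6 mm metal bar at 3000 HU. The bar
width matches a linear volume array probe; the HU guarantees recovery by
the 2000 HU extraction threshold (inclusive comparator). Insertion is a
rigid rotation–translation with linear resampling for HU and
nearest-neighbour for the masks (binarity and, to <2% at native
resolution, area are preserved).

## Artifact simulator

Pipeline per slice: threshold segmentation (lung < −300 ≤ water-equivalent
< 150 ≤ bone < 2000 ≤ metal, background = border-connected air below
−900 HU) → per-pixel density → per-energy attenuation → parallel-beam
projection → polychromatic Poisson counts → log conversion with a count
floor → FBP → HU recalibration.

**Attenuation model.** Mass attenuation coefficients are embedded as 8–10
energy knots per material (water, ICRU-44 lung tissue, cortical bone, Pb,
Zr, Ti, Al) transcribed from the public NIST tabulations, interpolated
log-log; lead carries extra knots bracketing its 88 keV K-edge, and the
PZT entry is the unweighted mean of Pb, Zr and Ti (reference density
7.5 g/cm³). Tissue density comes from the pixel HU. The default
(`density_model="consistent"`) chooses each pixel's density so that
ρ·(μ/ρ)_class at the reference energy reproduces the pixel HU exactly:
the artifact-free limit of the simulator then returns the reference slice,
which is the premise of paired supervision, while beam hardening still
arises from each class's energy dependence. The generic piecewise-linear
calibration (−1000→0.0, 0→1.0, 1000→1.6 g/cm³, clamped) remains available
as `density_model="ramp"`; it round-trips a 700 HU bone voxel to ~915 HU
and is kept for comparison, not as the default.

**Geometry.** Parallel beam, 720 views over [0°, 180°), detector pitch
equal to the pixel pitch, detector count the image diagonal. Parallel
geometry admits an analytic oracle (the projector is an exact Siddon-style
crossing-sort integrator, validated to 1e−6 against an independently coded
per-pixel clipping integrator) and is standard for simulation studies.

**Spectrum.** Filtered Kramers bremsstrahlung: N(E) ∝ (E_max−E)/E hardened
by 2.5 mm Al, 5 keV bins over 20–120 keV, i0 = 2×10⁵ photons per detector
element per view. This activates both artifact mechanisms: beam hardening,
and photon starvation behind the bar (the starvation path is ~12 mm of
PZT; rays beyond it are clipped by the one-count floor of the log
conversion, which is the dominant streak source). The energy loop is cheap
because μ_E = ρ·(μ/ρ)_class(E) factorizes: one density sinogram per tissue
class is projected once and recombined per bin.

**Reconstruction.** Ramp filter built as the discrete Ram-Lak kernel in
the spatial domain (FFT'd, Hann-apodized) — sampling |f| directly
underestimates the low-frequency response and biases large objects by tens
of HU — followed by linear-interpolation backprojection. HU recalibration
uses the water-calibrated effective energy of the configured spectrum
(transmission-matched through 20 cm of water, ~50.5 keV for the default
beam; the line energy for monochromatic spectra). A fixed recalibration
energy is config-exposed (`e_eff_keV`); leaving the scanner uncalibrated
for its own spectrum shows up as a global HU offset, which is a
calibration error rather than artifact physics.

**Artifact locality.** The geometric union of "rays through metal" over a
180° view set is the whole image (every pixel lies on some line through
the bar), so locality statements use the *starved-ray* region instead:
pixels on rays whose metal path exceeds the starvation length derived from
(spectrum, table, count floor). That region is where count clipping
actually corrupts projections; on the default phantom it covers ~40% of
the image and carries ~76–81% of the absolute HU error mass.

## Corrector network

Standard residual image-translation generators (7×7 ingress, two stride-2
downsamplers, residual blocks, two nearest-neighbour-upsample+conv stages,
7×7 tanh egress; instance normalization, reflection padding) and 70×70
receptive-field PatchGAN discriminators. Losses: least-squares adversarial
terms both directions, L1 cycle consistency (λ = 10), L1 identity
regularization (λ = 15), and an explicit paired pixel term
λ_paired·|G_corr(x) − y|₁ (λ = 10). The paired term is the one genuinely
open design point: paired data is stated to anchor restoration accuracy
but the coupling term is not written anywhere, so it is added as the
simplest pixel-space anchor, config-exposed, and λ_paired = 0 recovers the
unpaired objective. Optimization: Adam (lr 2×10⁻⁴, β₁ = 0.5 — the
customary values for this architecture family, since only the optimizer is
stated), batch size 1, a 50-image replay buffer for discriminator updates,
and joint augmentation of each pair (same sampled rotation ±10°, flip,
0.8–1.0 resized crop, mild perspective for both members; out-of-field
filled with −1).

The stack is pure numpy (float32) with hand-derived backpropagation and
explicit forward caches, so the generators can safely run several times
inside one objective (cycle, identity and paired passes). Every layer's
gradients are finite-difference checked in the test suite; training is
bit-reproducible for a fixed seed.

Two profiles: the reference configuration (512 px, ngf 64, 9 residual
blocks, 500 epochs, five-fold cross-validation) is recorded in
`TrainConfig.full_scale()` and is far beyond a CPU test run; all tests and
examples use `TrainConfig.desk()` (64 px, ngf 8, 3 residual blocks, 30
epochs, ~3 minutes), which suffices to demonstrate the direction of
effect: on held-out patients the corrected slices land at ~67 HU RMSE
versus ~1000 HU for the artifacted inputs.

## Splits and evaluation

All splits are by patient identifier, never by slice: an 85/15 holdout
plus a five-fold assignment of the training side, both seeded; no
identifier can appear on two sides, which the suite checks over repeated
random manifests. Metrics: RMSE in HU; PSNR = 20·log10(range/RMSE) with
range 2000 HU (the clipped span; identical pairs report an infinity
sentinel); SSIM with the canonical 11×11 Gaussian window (σ = 1.5,
k₁ = 0.01, k₂ = 0.03, population covariance — delegated to scikit-image).
Region statistics use population STD. The HU-improvement percentage is
computed both from overall mean deltas and as the mean of per-scan
percentages: the two differ in general (the improvement is a ratio, and
ratios do not commute with averaging), so both are always reported and
labelled; neither is privileged.

## Numerical choices

* Metal extraction comparator is ≥ (inclusive); boundary behaviour is
  pinned by test.
* Log conversion floors counts at 1 (configurable); photon starvation is
  thereby clipping, not infinities.
* Sinogram kinds (line-integral vs photon-count) are tagged and checked,
  never inferred.
* FBP requires ≥ 180° angular coverage (up to one view step) and errors
  otherwise; an all-zero sinogram reconstructs to exactly −1000 HU.
* All randomness flows from a single seed: pipeline stages derive
  independent generators as `default_rng([seed, ordinal])`; derived seeds
  stay below 2³¹.

## What the synthetic experiments show — and don't

The phantoms are class-correct in HU but anatomically trivial: elliptical
organs, no cardiac texture, no motion, 2-D slices only, and one probe
shape. The simulator omits scatter, detector cross-talk, fan/cone
geometry and tube-current modulation, and its spectrum and fluence are
assumptions rather than measured scanner properties. Passing tests
therefore demonstrate that the mechanisms work and interact correctly —
the simulator produces hardening- and starvation-driven streaks localized
on the predicted rays, the corrector learns to remove them from paired
supervision, splits never leak, and the whole chain is reproducible — not
that the trained desk-scale model would transfer to clinical scans. A
clinical claim would need the reference-scale profile trained on real
paired data and an evaluation against scans with genuine artifacts, plus
the dosimetric analysis that is out of scope here.
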