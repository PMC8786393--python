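# Methods

This note documents the models implemented in dotkit, the parameter
defaults and why they are what they are, the numerical choices that are not
forced by the mathematics, and what the synthetic phantom can and cannot
tell you about real data.

## Digitization cleaning

A digitization session yields an ordered list of 3D points in cm:
anatomical landmarks (nasion, inion, ears, vertex), then sources, then
detectors. Correspondence between caps is positional — cap layouts are
fixed per cap design, so no point-matching search is performed.

**Alignment** is rigid only (rotation + translation, no scaling): templates
are built per cap size, so scale is controlled experimentally. The optimal
proper rotation is the Kabsch solution via SVD of the cross-covariance,
with the smallest singular vector sign-flipped when the raw solution would
be a reflection. Fewer than three non-collinear correspondence points is an
error.

**Templates.** Every cap of one size is aligned to every other; a pair
matches when no aligned point is farther than the threshold (10 cm is a
practical default for infant caps) from its counterpart. The cap with the
most matches becomes the reference; ties break to the lowest mean distance
to its matches, then lexicographic cap id (the tie-break is our choice —
any deterministic rule works, this one favors the tightest cluster). The
template is the pointwise mean over the reference and its matches after
alignment to the reference.

**Correction.** Three methods share one skeleton — align on currently
retained points, drop points beyond a threshold (strict `>`; the inclusive
variant differs only on exact boundary hits), re-align, finally substitute
template coordinates for dropped points in the template frame, so corrected
caps come out co-registered to the template:

- *three-step*: user thresholds d1 ≥ d2 ≥ d3 (default 12, 10, 7 cm);
- *iterative*: threshold starts at 20 cm and decrements 1 cm per pass until
  the replaced proportion would exceed the user budget or all retained
  points sit within 0.5 cm of the template. The decrement is not given a
  floor by the method's description; we stop below 1 cm, since a 0 cm pass
  would replace every point.
- *head-wise*: whole caps are kept or replaced by the template according to
  their mean per-point distance.

Export is `digpts.txt` (`label: x y z`, landmarks/sources/detectors in
order), converted cm → mm as downstream anatomy tools expect.

## Sensitivity model

Per-measurement sensitivity volumes are flattened in **column-major
(Fortran) order over (x, y, z)** — the order is arbitrary but must be
consistent, and every embed/restrict path goes through the same two
functions. A voxel is retained iff any measurement's sensitivity strictly
exceeds `threshold × global max` (default 0.01), where the global max is a
single scalar over all measurements' volumes. `good_vox` is 0-based in
memory, 1-based on text export.

## Channel preprocessing

- Signal-level pruning converts the channel temporal mean intensity to
  dB as 20·log₁₀(mean/reference) with reference 1 intensity unit
  (configurable); channels outside [80, 130] dB are flagged bad, not
  deleted.
- OD uses the natural log against the channel temporal mean. Users wanting
  decadic OD can scale by 1/ln 10; all downstream math is linear.
- The band-pass is a zero-phase (forward–backward) Butterworth of order 3;
  the order/family is unconstrained by the processing chain's definition,
  and order 3 gives monotonic response with negligible passband ripple.
- Trigger rejection removes a stimulus whose (−1, +18) s window intersects
  any externally supplied artifact interval (closed endpoints). Motion
  detection/correction itself is a published third-party algorithm family
  and is deliberately a hook, not a re-implementation.
- Global signal regression is per wavelength: the regressor is the mean
  over good channels, fit with an intercept; residuals are exactly
  orthogonal to it. GSR is a surrogate for systemic physiology; when a
  large fraction of the array carries the same stimulus response, it
  removes signal too (see the phantom discussion below).
- Resampling is polyphase (anti-aliased); paradigm times are stored in
  seconds and are untouched.

The order of application is prune → OD → (motion hook) → trigger rejection
→ band-pass, with GSR and 25 Hz down-sampling applied on the branch that
feeds reconstruction.

## Reconstruction

For one wavelength, with measurement-space data y (time × measurements over
good channels), the inverse problem min ‖y − Ax‖² + λ₁‖Lx‖² is solved with
the spatially variant penalty

    diag(L) = sqrt(diag(AᵀA) + λ₂),   Ã = A L⁻¹,
    A# = L⁻¹ Ãᵀ (Ã Ãᵀ + λ₁ I)⁻¹ = L⁻¹ (ÃᵀÃ + λ₁ I)⁻¹ Ãᵀ.

The two forms are equal by the push-through identity; the implementation
picks the smaller matrix to factor and a test asserts their agreement. The
square-root reading of the penalty exponent follows the spatially variant
regularization literature; it is isolated in one function
(`spatially_variant_l`) should a different exponent ever be wanted. Voxels
the array barely senses get small L entries bounded below by √λ₂, which is
what keeps the inverse from exploding there and counteracts the superficial
bias of minimum-norm solutions (asserted on the phantom: λ₂ = 0.1 raises
the deep/shallow amplitude ratio versus λ₂ = 0). Defaults λ₁ = 0.01,
λ₂ = 0.1.

Gaussian smoothing (default 6 mm FWHM, recommended range 3–10 mm) is
applied to reconstructed images. Because smoothing and reconstruction are
both linear, the implementation smooths the operator's voxel maps once
instead of every frame — algebraically identical and much cheaper.

**Spectroscopy.** Absorption changes at the two wavelengths are converted
to ΔHbO₂/ΔHbR by inverting the 2×2 extinction system. The shipped table is
the standard tabulated compilation (decadic molar extinction, cm⁻¹/M, at
690/760/830/850 nm); the ln 10 factor and unit conversion to mm⁻¹·μM⁻¹ are
applied when the matrix is formed, and its condition number is exposed
(≈ 7 for 690/830 nm). ΔHbT = ΔHbO₂ + ΔHbR by definition.

## GLM

The default HRF is the double-gamma difference of gamma densities with
delay of response 4 s, delay of undershoot 15 s, unit dispersions, response
to undershoot ratio 6, onset 0, kernel length 16 s; the kernel is
peak-normalized to 1 (a pure scaling convention — betas are then in the
data's units; any other normalization rescales betas uniformly). A sampled
kernel file can replace the parametric form. Event trains (impulses or
boxcars, default boxcar 4.5 s) are convolved at frame resolution.

The design gets an intercept by default and no drift columns (the band-pass
already removes drift). **When the data have been temporally filtered, the
condition regressors are passed through the same zero-phase filter**
(`glm.filter_design`); fitting unfiltered regressors to filtered data
biases betas. Mapping many task conditions onto fewer regressors is
supported via an explicit condition → regressor map rather than any
implicit collapsing rule. Per-voxel OLS reports residual variance; runs are
combined per condition as the event-count-weighted mean of betas, with
zero-event conditions dropped and flagged.

## Verification

For each channel, the sphere (default 2 cm diameter) is centered at the
argmax of that channel's sensitivity restricted to the cortex mask (gray
matter by default, optionally gray + white; ties break to the first voxel
in linear order). The sphere-mean reconstructed chromophore series is
correlated (Pearson) with the channel-space series, which is the
preprocessed OD of that channel pair passed through the same extinction
matrix so both sides are in μM. The channel side does **not** include
global signal regression — it is the channel-space product of
preprocessing, whereas the image side is reconstructed from GSR'd data;
residual systemic physiology on the channel side is the main reason r < 1.
Pass criterion r > 0.25 (strict).

## Synthetic phantom: what it is and is not

The phantom is a concentric-layer sphere (default 40³ voxels at 2 mm:
36 mm outer radius; 6 mm scalp/skull, 2 mm CSF, 6 mm gray shell, white
core) with an interleaved ring of 8 sources and 8 detectors 35° off vertex,
giving 16 neighbor channels × 2 wavelengths (690/830 nm). Sensitivity
volumes are geometric surrogates: exp(−(dₛ + d_d − d_sd)/ℓ) masked to
tissue and peak-normalized, with falloff ℓ = 6 mm chosen so neighboring
channels' cortical projections are distinct at this probe spacing. They are
non-negative, channel-localized, and mutually overlapping — the properties
the downstream linear algebra actually uses — but they are **not** photon
transport: absolute sensitivity scales, partial-volume effects, and
wavelength-dependent path lengths are not emulated, so passing tests
validate the pipeline's mathematics and plumbing, not optical realism.

Channel recordings are forward simulations: a Gaussian blob (σ = 6 mm) of
hemoglobin change at a cortical voxel — by default the gray-matter
sensitivity maximum of the first channel, mirroring where verification
looks — driven by HRF-convolved event regressors (conditions A and B at
(1.0, −0.3) and (0.5, −0.15) μM HbO₂/HbR, a 2:1 ratio the GLM must
recover), mapped through the extinction matrix and the A-matrix to
measurement OD, plus a shared 0.33 Hz sinusoid per wavelength (systemic
physiology; removable by GSR because it is identical across channels) and
white noise, exponentiated to intensities around 10⁵ (100 dB). Noise
defaults (white SD 0.02 OD, physiology amplitude 0.15 OD) were calibrated
once so that channel-vs-image verification passes the 0.25 criterion with
margin but not trivially — the mean correlation over signal-bearing
channels comes out near 0.8. Note the OD scale is inflated relative to real
recordings because A is peak-normalized; only relative magnitudes matter
anywhere in the chain.

Two GSR caveats the phantom makes visible: with a single focal activation
and a small array, the stimulus response contributes to the global mean, so
GSR removes part of the signal (real arrays are larger and less
signal-dominated); and in a completely noise-free simulation the global
mean *is* the signal, so GSR annihilates it — the phantom's physiology
component is what keeps GSR honest.

## Problem sizes and determinism

Default fixture: 40³ voxels, ~5.6 k retained, 32 measurements, 120 s at
50 Hz down-sampled to 25 Hz; the full pipeline runs in well under a minute
on one CPU and every generator is a pure function of (spec, seed).
Re-running with the same config and seed reproduces outputs bit-identically
on one platform; across platforms, floating-point differences are possible
in the usual ways.

## Known limitations

- No photon-transport forward model (use external Monte Carlo tools and
  import their volumes); no MRI segmentation; no group-level statistics or
  registration to standard space.
- Motion-artifact detection/correction is a hook, not an implementation.
- The iterative correction's sub-centimeter behavior (floor at 1 cm) is a
  package choice where the method description is silent.
- The spherical phantom has no gyri/sulci; localization results on it are
  easier than on real anatomy.
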