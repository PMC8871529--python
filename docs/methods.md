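# Methods

`tomodose` simulates a digital breast tomosynthesis (DBT) dose-reduction
study on a BR3D-style structured phantom and quantifies how two
projection-domain denoisers — a pix2pix conditional GAN and multiscale
bilateral filtering (MSBF) — affect reconstructed image quality at reduced
radiation dose. This note records the models, the parameters that matter,
the numerical choices, and what the desk-scale results do and do not show.

## Phantom

The phantom is a voxelized attenuation map `mu(z, y, x)` in mm⁻¹ with
`z` the height above the detector and voxel centers at `(i + 0.5)·voxel`.
The background emulates a heterogeneous 50/50 glandular/adipose slab
stack: a white Gaussian field is smoothed to the texture correlation
length (default 3 mm), soft-thresholded to mixture weights `w ∈ [0, 1]`
over a blend band of one field standard deviation, and mapped to
`mu = mu_a + (mu_g − mu_a)·w`. The threshold is bisected so the
volumetric glandular fraction matches the requested value to ~1e-3. The
blend width is a deliberate choice: a much sharper blend creates
high-frequency tissue interfaces whose reconstructed grain buries the
microcalcifications even at reference dose, contradicting the premise of
the physical phantom (specks are conspicuous at reference dose).

Default attenuation coefficients (representative of ~20 keV breast
imaging, configurable): adipose 0.045 mm⁻¹, glandular 0.080 mm⁻¹,
microcalcification contrast +0.60 mm⁻¹, mass contrast +0.010 mm⁻¹.

Features live on one target plane (default mid-thickness): five-speck
crosses for each MC size (0.196, 0.23, 0.29 mm) and spheroidal masses
(3.9, 4.7 mm). Spheres are inserted with partial-volume weighting
(sub-cell supersampling, 8³ for small features), which conserves the
inserted attenuation mass to <5% even for sub-voxel specks. Feature
centers snap to voxel centers so layout phase does not arbitrarily split
a sub-voxel speck across eight voxels. Overlapping or out-of-bounds
features are rejected with the offending records named.

## Acquisition

Partial-isocentric geometry: the source rotates on an arc about a pivot
in the detector plane (source–detector distance 700 mm), the detector is
stationary, 15 views equally spaced over 15° symmetric about vertical.
Forward projection samples the Beer–Lambert line integral along each
source-to-pixel ray at half-voxel steps with trilinear interpolation;
intensity is `i0·exp(−integral)`. Verified against slab closed forms
(normal and oblique incidence, ≤0.2% with the default step) and a
brute-force ray/voxel intersection oracle for point objects.

Noise: `Poisson(dose_factor · I) + N(0, electronic_sigma²)`, clipped at
zero. Dose factors are the ratios of the published average glandular
doses for the 40 mm configuration: reduce50 = 0.66/1.36 ≈ 0.49,
reduce75 = 0.31/1.36 ≈ 0.23. Normalization to the network/metric domain:
`−ln(max(I, 1 photon) / (dose_factor·i0)) / max_att` clipped to [0, 1],
with one calibration constant `max_att = 4` shared by all arms and doses.
In a flat region the variance of this image scales as 1/dose_factor to
within a few tenths of a percent (quantum-mottle law).

The acquisition module default is `i0 = 1e5` photons/pixel/view. The
desk-scale **study** preset instead uses `i0 = 2e3` (~160 detected quanta
behind 40 mm at reference dose): at 1e5 the half-dose projections differ
from truth by an RMSE of ~0.004 of the dynamic range — visually
noiseless, so a dose-reduction comparison is vacuous and even an ideal
denoiser cannot produce a measurable PSNR gain. 2e3 puts the projections
in the visible-quantum-mottle regime the study design is about.

The study detector is trimmed along the sweep axis by
`thickness·tan(arc/2)` so every detector pixel is covered by the phantom
in every view; otherwise the extreme views contain unattenuated air
bands that dominate projection metrics and are meaningless for phantom
imaging.

## Reconstruction (FBP)

Projections are ramp-filtered along the tube-travel axis with the
band-limited Ramachandran–Lakshminarayanan kernel
(`h(0) = 1/4τ²`, `h(odd n) = −1/(π²n²τ²)`, even taps zero, `τ` = pixel
pitch), applied in the frequency domain. Rows are edge-replicated to an
FFT length of at least 4096 before the multiplication: the circular
convolution then acts linearly over the retained window, a constant row
maps to numerically zero (DC suppressed), and the centered impulse
response matches the kernel taps to ~1e-8. No apodization window is
applied.

Back projection is shift-and-add: each reconstruction pixel at height z
maps through the view's cone geometry to a detector coordinate, the
filtered projection is sampled with linear interpolation, and the views
that see the pixel are averaged (out-of-detector samples excluded, the
average renormalized by the hit count). The reconstruction grid is the
detector grid demagnified to the slice height, so the zero-degree view
maps identically at z = 0.

A noiseless point object reconstructs within one pixel of its true
lateral position on the in-focus slice, with the profile FWHM minimal in
focus. A note on depth blur: the Ram-Lak-filtered point response at 15
discrete views keeps a narrow central-view core superimposed on a
widening skirt, so the literal FWHM of the filtered response is
non-monotone beyond ~6 mm defocus. The monotone growth of limited-angle
depth blur is therefore demonstrated on the unfiltered shift-and-add
reconstruction, which isolates the geometric blur; the filtered
in-focus/out-of-focus contrast is asserted separately at ±5 mm.

## MSBF arm

The multiscale bilateral filter decomposes each projection with a
Laplacian pyramid (5-tap binomial kernel, factor 2, 4 levels), filters
each detail band with a bilateral filter, adds a high-frequency
enhancement to the finest band, collapses, and clips to [0, 1]. The
published parameter set is used: spatial sigma 1.0 px, range sigma 0.01,
enhancement weight α = 0.375 with a 5×5 Laplacian mask (normalized to
zero mean, center 24/25).

Two implementation details are this package's interpretation, since the
referenced processing chain is not fully specified in the available
literature:

- The pyramid upsampler extends symmetrically at the *coarse* level
  before zero-stuffing; reflecting the stuffed grid instead amplifies
  the border DC by ~25% and contaminates the bands. Band definition
  `band = level − upsample(downsample(level))` makes pyramid collapse an
  exact inverse by construction.
- The range kernel of the per-band bilateral is evaluated on the smooth
  coarse approximation of each band (joint/cross bilateral) rather than
  on the noisy band itself. With band noise ≈ 2× the range sigma, the
  classic self-guided kernel locks onto the noise and removes almost
  nothing (~2% band-std reduction measured); the coarse approximation
  carries the structure (edges, features) without the fine noise, so
  guiding on it preserves edges while averaging noise. On the flat+noise
  fixture (σ = 0.02) this yields an output/input std ratio of ~0.27
  while a step edge's 50% crossing moves by <0.01 px. The exported
  `bilateral` function retains the classic self-guided form (and is
  oracle-tested against an exhaustive double loop); the guide is an
  explicit argument used by `msbf_process`.

## pix2pix arm

The conditional GAN maps a low-dose projection to its reference-dose
counterpart. Objectives, per training pair (batch size 1):

    L_D = −E[log D(p_ld, p_ref)] − E[log(1 − D(p_ld, G(p_ld, z)))]
    L_G = −E[log D(p_ld, G(p_ld, z))] + α·E‖p_ref − G(p_ld, z)‖₁

with α = 50, Adam (lr 2e-4, β₁ = 0.5, β₂ = 0.999), and the
non-saturating generator form of the adversarial term. The noise source
z is dropout (p = 0.5) in the deepest decoder stage, active at training
and inference, the conventional pix2pix treatment.

The generator is a U-Net with a stride-1 full-resolution stem, three
stride-2 4×4 encoder stages (instance-normalized after the first),
a decoder of nearest-neighbor ×2 upsampling + 3×3 convolutions with skip
concatenation at every resolution, and a sigmoid head fed by the
concatenation of the decoder output with the stem features. The stem
skip gives the network an identity-capable pixel-scale path; without it
(the classic pix2pix layout, whose first skip sits at half resolution)
the network cannot track projection texture accurately enough for a
positive PSNR gain at these noise levels. The discriminator is a
PatchGAN: two stride-2 4×4 convolutions and a 1-channel head over the
channel-concatenated (input, candidate) pair, emitting a patch
probability map smaller than the image.

All layers, the backward passes, and Adam are implemented directly on
numpy (im2col convolutions); every analytic gradient is verified against
central finite differences in the test suite. Desk-scale defaults: 64×64
patches, base 16 channels, depth 3, 100 epochs over 64 patch pairs —
about five minutes on one CPU core. Base 8 also clears the PSNR-gain
margin but blurs the 0.29 mm specks by ~30%; 16 preserves their FWHM
within a few percent of the reference arm. The full-scale configuration
(larger patches, more channels, 300 epochs) is reachable through
`TrainConfig` but is not the tested default.

Training pairs are synthetic: independent noise realizations of the same
noiseless projections at `dose_factor` and 1.0, cut into random patches
across all views. Per checkpoint epoch the generator is evaluated on the
zero-degree validation view by MSE and mean SSIM; the operating epoch
minimizes MSE and maximizes MSSIM, with a rank-sum compromise (ties to
the later epoch) when they disagree. Inference on images larger than the
patch uses overlapping tiles blended with linear ramps.

## Metrics

- MSE, PSNR (`10·log10(PV²/MSE)`, PV = 1.0, +inf sentinel at MSE 0).
- SSIM: luminance·contrast·structure with unit exponents, 11×11 Gaussian
  window (σ 1.5), C1 = (0.01·PV)², C2 = (0.03·PV)², C3 = C2/2 (the
  original SSIM constants); MSSIM is the map mean. Implementation:
  `skimage.metrics.structural_similarity`, cross-checked against a
  direct windowed computation in the tests.
- CNR: `(μ_feature − μ_bg)/σ_bg` with a circular feature ROI of the mass
  diameter and four same-diameter background ROIs (up/down/left/right)
  offset by the mass diameter plus a 1.5 mm guard band; background
  pixels are pooled across the four ROIs (an interpretation — per-ROI
  std averaging is the alternative).
- FWHM: profiles through each speck, summing adjacent lines
  perpendicular to the profile direction over a 0.4 mm swath (four lines
  at 0.1 mm sampling; two lines at the desk-scale 0.2 mm sampling).
  Baseline is the mean of the outer 25% tails; half-maximum crossings
  are linearly interpolated. Profiles without a crossing on either side
  are recorded as missing observations, not errors — group sizes may
  therefore differ across arms, as in the original study design.

## Statistics

FWHM values are compared with a Tukey–Kramer all-pairs test across the
four groups (reference, without processing, MSBF, pix2pix; unequal n):
difference of group means, SE = √(MS_within/2·(1/nᵢ + 1/nⱼ)), p-values
from the studentized range distribution with the pooled within-group df,
and simultaneous 95% intervals. The factorial two-way ANOVA (processing
× dose, Type II sums of squares for unbalanced cells) excludes the
reference arm, which has no dose factor; with three processing arms and
two reduced dose levels the df structure is (2, 1, 2).

## Desk-scale study conditions

One fixed preset (`tomodose.study`) is used by the examples, the test
suite, and `scripts/acceptance.py`: 40 mm phantom, 0.2 mm voxels,
27.2 × 48.0 mm lateral extent, detector trimmed to the always-covered
126 × 178 pixels, 15 views / 15°, `i0 = 2e3`, electronic sigma 5
photons, all three MC sizes and both masses on the mid-thickness plane,
pix2pix trained at half dose for 100 epochs on 64 patch pairs. The
problem sizes are chosen so a complete study runs in minutes on one CPU
core.

## What the synthetic study shows — and what it does not

The desk-scale study reproduces the qualitative structure of the
physical experiment: denoising the projections raises projection-domain
PSNR by several dB at half dose; the pix2pix arm preserves
microcalcification FWHM close to the reference arm while MSBF broadens
it (and loses some profiles entirely); mass CNR orders
MSBF > pix2pix > without processing, with pix2pix close to the reference
dose. These are emergent outcomes of the simulation, not calibrated
reproductions: the phantom texture is a Gaussian random field rather
than the manufactured swirl pattern, the beam is monoenergetic with no
scatter or detector blur, the fluence is a scalar stand-in for AEC
exposure, and the networks are far smaller than GPU-scale pix2pix.
Numerical agreement with the published FWHM differences, p-values, or
dose values in mGy is therefore out of reach by design; the package's
claims are the physics contracts, oracle equivalences, and ordering
reproductions its tests assert.

## Known limitations

- No scatter, detector MTF, heel effect, or polyenergetic spectra.
- Iterative reconstruction is out of scope; only bare Ram-Lak FBP.
- The cGAN trains per dose level on one phantom realization; transfer
  across phantoms or to real scanner data is untested.
- Mass CNR at desk scale is texture-sensitive (the structural-noise
  term of the CNR definition): the 3.9 mm mass numerator is
  texture-dominated on the default phantom, and for unlucky texture
  realizations even the 4.7 mm mass's numerator can change sign, in
  which case the arm ordering measures texture rather than noise
  suppression. The study therefore treats the phantom like the single
  manufactured test object it emulates — one fixed realization, with
  randomness in the noise realizations and training — and only the
  4.7 mm mass is used for ordering claims.
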