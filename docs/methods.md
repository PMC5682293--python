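# Methods

## Geometry and conventions

Volumes are `(z, y, x)` arrays with voxel centers at integer multiples of
the pitch relative to a fractional-index origin; the origin defaults to the
grid center. The fixed frame has the camera looking down `z` and the mirror
in the plane `z = -x tan θ` through the origin, so both the real half-space
(on/above the mirror) and the virtual one are inside the grid. `θ` is the
angle between the detection axis and the mirror normal: 45° for a symmetric
dual-view system, 33° for the asymmetric high-NA arm (whose direct and
reflected views are then 180° − 2·33° = 114° apart; instrument papers
sometimes round both the tilt and the separation, which is why a printed
"~112°" can coexist with a printed "~33°" — we report the formula value).

At θ = 45° with equal x/z pitch, reflection across the mirror is an exact
on-grid index remap (an involution, used wherever tests demand bit-exact
symmetry). At general θ it is a cubic-spline affine resampling with zero
fill and clamping of interpolation undershoot; accuracy statements then
presume adequately band-limited content.

## Optics

The detection PSF is the scalar Born–Wolf integral
`|∫₀¹ J₀(k·NA·r·ρ) exp(-i k NA² z ρ²/(2n)) ρ dρ|²` (k = 2π/λ in vacuum,
n = 1.33 water). The integrand is analytic in ρ, so a 96-node
Gauss–Legendre rule evaluates it to below 1e-10 — a test cross-checks
against scipy's adaptive quadrature — on a dense radial grid per axial
slice (Δr = pitch/8), interpolated to voxel radii. PSFs are normalized to
unit *sum*, not unit peak, so forward projection conserves flux.

Defocused widefield light spreads laterally without bound (the
plane-integrated intensity of the paraxial PSF is constant in z), so any
finite kernel crops real energy. `make_detection_psf` flags kernels whose
one-voxel boundary shell holds more than 1e-3 of the energy; reconstruction
pathways deliberately accept cropped, renormalized kernels
(`strict=False`), as is standard deconvolution practice.

The emission wavelength is not an independent dial: the in-focus Born–Wolf
profile scales exactly with λ, so `calibrate_emission_wavelength` solves for
the λ whose lateral FWHM matches the instrument's raw-view lateral width
(0.305 µm for the 1.1 NA arm → λ ≈ 0.652 µm). Lateral width is
sheet-independent, which makes this calibration unambiguous; the raw-view
*axial* width is then emergent (detection axial profile × 1.6 µm sheet) and
comes out within ~10% of the instrument's nominal figure, absorbing the
scalar-model idealization.

Solid-angle collection efficiency is the spherical-cap formula
`Σ views · 2π(1 − cos arcsin(NA/n)) / 4π`; a mirrored lens counts twice.

## Illumination

Sheets are constant-thickness Gaussians (FWHM 1.6 µm, waist at the mirror);
beam divergence is not modeled — over fields a few tens of µm this
underestimates sheet growth but matches the single-FWHM description of the
instrument. The incident sheet lies in the detection focal plane; its
specular reflection is its mirror image, so with unit mirror reflectivity
the total pattern is simply the two crossed slabs and is exactly symmetric
under the mirror reflection. With reflectivity < 1 the pattern is assembled
per half-space (incident + r·reflected above; mirrored below), preserving
the symmetry. The four sheets are taken equally intense after reflection;
reflection losses fold into the single reflectivity parameter (default 1.0,
no reflectance figure being available for the coated coverslips).

## Forward and transpose operators

Stage offsets are chosen so the focal-plane coupling ξ = δ·tanθ equals the
z pitch: every focal plane lands on a grid plane and no focal interpolation
is needed. Per offset, the forward action multiplies the estimate by the
shifted illumination, convolves once in 3D with the PSF (zero-padded FFT, no
wrap-around) and reads out the focal plane; the plane extraction happens in
the Fourier domain (a phase-weighted contraction along k_z), so each stage
step costs a single 3D transform pair. The transpose embeds the measured
plane at the focal depth (rfft2 × phase ramp), convolves with the flipped
kernel and weights by the same illumination — the exact algebraic adjoint
for odd-shaped kernels, verified against a dense-matrix oracle to machine
precision. The sensitivity image `V = Mᵀ1` is cached per operator.

The virtual view's operator is the conjugation `M₂ = R·M₁·R` by the mirror
reflection, which automatically carries the complementary PSF orientation.
At 45° this is exact and exactly adjoint-consistent; at other angles `R`
interpolates and `Rᵀ` is approximated by `R` — a mildly mismatched
projector pair of the kind iterative reconstruction tolerates well (the
45°-exact path is what the oracle tests exercise). Second-camera views use
the analogous z↔x axis-swap conjugation, valid on cubic 45° grids.

An instrumented counter tallies every 3D FFT convolution executed, and
matches the scheme budgets exactly: 4·n_steps per alternating dual update
(reflective scheme), 4 per iteration for conventional shift-invariant joint
RL, versus 4·n_z 2D convolutions per step-update had the per-plane route
been taken.

## Deconvolution

The generalized Richardson–Lucy update divides data by prediction (guarded
at 1e-12 of the prediction maximum), back-projects with `Mᵀ` and normalizes
by `V`; voxels with vanishing sensitivity are frozen. Nonnegativity is
preserved by construction; the per-view Poisson deviance is logged each
update and is non-increasing (EM property). Initialization is a uniform
volume at the data mean, restricted to the support where every view's
sensitivity is positive. Joint schemes cycle views in order; **the
iteration index increments per view update** (U₁'s update takes n → n+1,
U₂'s n+1 → n+2), so "10 iterations" of the dual scheme means five full
cycles. Convergence in practice is judged from the logged data-fit history;
no numeric stopping tolerance is imposed.

`rl_conventional` is the deliberate baseline: plain shift-invariant RL with
detection PSFs only, which cannot represent the spatially varying
epifluorescence — on mirrored-bead phantoms it leaves strictly more energy
off the true support than the full model, reproducing the qualitative
raw-vs-modeled contrast the method exists for.

`post_smooth_y` equalizes the y′ width to a target by 1D Gaussian smoothing
with kernel FWHM `sqrt(target² − current²)`; it belongs to the
resolution-estimation pathway only (y′ converges faster than x′/z′ because
the two joint views share their y′ PSF, and quoting the unsmoothed y′ width
would overstate isotropic resolution).

## Bead-resolution protocol

`mirrorspim.resolution.bead_resolution` re-enacts the instrument's own
resolution estimate: a bead 1 µm above the mirror along its normal,
extended with its mirror image, pushed through the full 33°-tilt forward
model, and reconstructed with ten alternating RL updates of U₁ and the
reflected U₂; FWHMs are then read along x′/y′/z′ through the reconstructed
bead by cubic-spline interpolation.

Problem sizes are the package's choice: a 96³ grid at 65 nm pitch
(Nyquist-safe sampling, ≤ ¼ of the 305 nm lateral FWHM) with an
81×41×41 PSF kernel; float32 arithmetic for the large FFTs. The bead is
rendered at a fixed physical FWHM of 130 nm — one instrument sample pixel
(6.5 µm / 50×) — since the reconstructed width of a point-like object
includes the object's own rendered footprint; tying it to the instrument
pixel rather than to our (finer) simulation grid keeps the protocol
grid-independent. A 64³ instance of the same protocol (used in the test
suite) agrees with the 96³ default to ~3%.

## Phantoms

Features are mass-conserving Gaussian splats of σ = 0.5 voxel (or a fixed
physical width when given), so sub-voxel placement is exact in total
intensity and FWHM measurements are grid-stable. Pair resolvability uses a
Rayleigh-like dip-to-peak criterion of 0.735 (adjustable). The generator is
deterministic under a recorded seed. What phantoms do **not** emulate:
scattering, aberration, refractive-index structure, camera read noise, or
realistic tissue texture — passing tests demonstrate correctness of the
operators and the reconstruction machinery, not robustness to those
real-data effects.

## Image corrections and pipeline

Stripe correction divides each y′ line by its mean (rescaled to the global
mean), equalizing line means exactly; zero-mean lines are left untouched.
Registration is translation-only phase correlation with sub-voxel
refinement, validated by the Pearson correlation on the aligned overlap
region; the synthetic pipeline provides ground-truth transforms, so affine
residuals are out of scope. Background subtraction is a clamped constant
offset from a user-supplied dark level — a minimal stand-in, as the
upstream procedure is instrument-specific.

`run_pipeline` chains phantom → simulate → virtual view → joint RL →
(stripe correction), validates every component invariant before compute,
and serializes the verbatim configuration, seed, iteration count and
convolution tally into the run report; reruns with the same config and seed
are byte-identical apart from output paths.

## Known limitations

- The scalar Born–Wolf model omits high-NA vectorial effects and
  aberrations; at NA 1.1 true lateral profiles are slightly broader, which
  the wavelength calibration absorbs but does not model.
- General-θ reflections interpolate; quantitative claims of exactness are
  restricted to θ = 45°.
- Sheet divergence, scattering and sCMOS noise characteristics are not
  modeled.
- The quadruple-view scheme is implemented for the orthogonal (45°)
  geometry; the asymmetric instrument's non-orthogonal second camera would
  need its own projection axis.
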