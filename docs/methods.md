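# Methods

This note documents the models, numerical choices and limitations behind
`condrop`. Lengths are micrometres, angles degrees at public interfaces
(radians internally), temperatures kelvin.

## Drop geometry and the Young–Laplace integrator

The sessile-drop surface is parameterized by arc length from the apex
(`shapes`). The governing system

    dψ/ds = 2/R₀ + h/ℓc² − sin ψ/r,  dr/ds = cos ψ,  dh/ds = sin ψ

(h = depth below the apex) has a removable singularity at the apex,
where sin ψ/r → 1/R₀; integration starts from a circular-arc series
expansion on s < 10⁻³·R₀ and proceeds with classical fixed-step RK4 at
step ≤ s_max/2000 (numba-compiled; roughly half a millisecond per
objective evaluation, which is what makes the rescale-factor scans
below tractable on one core). Halving the step moves the endpoint by
far less than 10⁻⁶ µm, and the integrator agrees pointwise with an
independent implicit adaptive solve (Radau, rtol 10⁻¹¹) to better than
10⁻⁶ µm — both are asserted in the test suite. The internal sign
convention has ψ growing from 0 at the apex to θ at the contact line, so
a hemisphere reports exactly 90°; the orientation of the lab z axis is
absorbed into this convention and only |θ| is meaningful.

A note on gravity: at fixed apex curvature and *fixed arc length*,
moderate gravity can slightly increase the integrated descent while
ψ < 90°, so "smaller ℓc ⇒ lower drop" is not true pointwise along the
arc. The invariant tested here is the physically meaningful one: at
fixed R₀ and fixed contact angle, decreasing ℓc never increases the
drop height.

## Profile fitting

`adsa_fit.fit_profile` minimizes the mean squared nearest-trial-point
distance λ over (R₀, log ℓc, z₀) with Nelder–Mead (simplex tolerances
xatol 10⁻⁸, fatol 10⁻¹², at most 2000 iterations), with s_max held at
1.2× the smoothed contour length of the measured profile (7-point
centered moving average on the radii, windows clipped at the ends,
segments accumulated from the 4th point — the early points nearest the
substrate are the noisiest). ℓc is fitted in log-space: it stays
positive and the gravity-free regime (ℓc ≫ drop size), where λ is flat
in ℓc over decades, is handled gracefully. R₀ is initialized from an
axis-centered circle fit to the upper half of the profile, ℓc at
100 µm, z₀ (an offset of the theoretical apex from the measured apex
height) at 0. If the quality gate fails, the descent restarts from 0.5×
and 2× the initial R₀ and the best optimum is kept.

After convergence the profile is re-integrated to at most 3× s_max;
s_max is redefined where the theoretical surface crosses z = 0 (located
by linear interpolation between RK4 nodes, error ≪ 0.01°), and θ,
contact radius and λ are evaluated there. No re-optimization follows
the redefinition. Nearest-neighbour assignment uses a k-d tree and is
oracle-tested against exhaustive search.

Two filters mirror the measurement protocol: fits with λ·N/s_max >
0.5 µm are discarded as poor (this grouping of λ, N and s_max is the
only dimensionally consistent one, with units of length), and fits with
contact radius < 10 µm are discarded because the PSF dominates the
apparent shape there. Both thresholds are configurable; defaults are
the protocol values.

Recovery under the study conditions (asserted in the suite): noiseless
profiles over θ ∈ 70–130°, contact radii 12–35 µm, ℓc 200–1000 µm come
back within 0.5°; with 0.25 µm Gaussian radial noise within 2°; through
the full voxelize → segment → extract → fit pipeline within 2°.

## Synthetic confocal stacks

`synth_data.voxelize` renders a profile as a two-channel stack: uniform
interior intensity 100 over background 5 (a clean bimodal histogram, as
direct Otsu binarization of the real images presupposes), plus a bright
(1000) one-slice reflection plane marking the substrate. Axes are
(z, y, x); voxel centers sit at (i + 0.5)·spacing and the substrate is
the bottom face of the base slice. Default spacing 0.24 × 0.24 ×
0.42 µm, typical of a 63×/1.4 confocal stack. Membership is by voxel
center with no antialiasing; the 1-voxel tolerances used in round-trip
tests absorb the resulting quantization. Noise is Poisson (optional)
followed by additive Gaussian (default σ = 5), seeded and reproducible.
The refraction aberration is emulated by resampling the stack axially
by 1.2 above the base plane.

What the generator does *not* emulate: photobleaching, depth-dependent
intensity loss, dye partitioning (interior brightness is uniform),
refractive-index-dependent excitation. Tests passing on these stacks
therefore validate the geometry and protocol logic, not robustness to
every real-world artifact.

Cloud points are drawn from the model binodal: Tp(φ) = B/(χ*(φ) − A)
with Gaussian temperature noise (default σ_T = 0.5 K), where χ*(φ) is
the coexistence χ of composition φ.

## Segmentation protocol

The substrate plane is the z slice maximizing the xy-averaged reflected
intensity (ties to the lowest slice). Slices below it are discarded,
the fluorescence volume smoothed with a Gaussian of radius 2 voxels
(σ = radius/2, truncated at 4σ), thresholded once by Otsu over the
whole cropped volume, and labelled with 26-connectivity. Components
touching the base but no lateral or top boundary are kept — drops cut
by the field of view cannot be fitted. Per slice, interior holes are
filled and the radius taken as that of the equal-area disk √(A/π)
("best-fit disk" in the parameter-free reading; identical for convex
slices), augmented by the absolute distance between the slice centroid
and the whole-drop centroid axis; the apex point (0, z_max) is appended
at the top face of the highest occupied slice.

## Ray-traced apparent images and the 1/1.2 correction

The refraction simulator (`optics_sim.render_apparent_image`) works in
the meridional plane. For each nominal focal position — where the NA 1.4
cone (half-angle arcsin(NA/n_oil) ≈ 67° in oil, n_oil = 1.518) would
converge were the whole sample oil — rays on a fixed angular grid are
refracted at the coverslip–buffer plane (n_buffer = 1.334; the glass,
1.523, is treated as index-matched to the oil — a < 0.4 % mismatch —
unless toggled) and, where struck, at the spherical condensate surface
(n = 1.33 or 1.41). Rays beyond the critical angle (≈ 61.5° at the
plane) are lost to total internal reflection and excluded. The recorded
intensity is the fraction of crossings of angularly adjacent rays that
land inside the condensate: where the aberrated focal energy overlaps
the fluorophore. Ray placement is deterministic, so images are
bit-reproducible. With all indices matched the rendered boundary equals
the true boundary to one grid cell (identity control), and the
apparent lateral extent at the base always equals the true contact
radius, because near-substrate foci traverse negligible sample depth.

This model predicts aqueous caps appear axially stretched by ≈ 1.2:
each ray's actual crossing depth is tan β_oil/tan β_buffer ≈ 0.83–0.88
of nominal over the usable aperture, and the half-maximum of the
crossing fraction tracks the median. `apparent_axial_scale` quantifies
it end-to-end: apparent profiles of caps (θ 90–130°, r = 12 µm) are
fitted after dividing z by a candidate factor, scanned coarsely
(0.85–1.45, step 0.05) then finely (step 0.01), minimizing the summed
|θ_fit − θ_true|. Measured factors: 1.20 for condensate index 1.33 and
1.24 for 1.41 — the same within 0.05, which is why a single 1/1.2
correction is applied regardless of condensate composition. Candidate
factors whose fits degenerate (the trial profile never reaches the
substrate) contribute a worst-case 180° deviation so the scan steers
away rather than aborting.

## PSF measurement, convolution and the 10 µm size filter

The PSF proxy is the average of windowed, sub-voxel-recentered images
of sub-diffraction beads, background-subtracted at the modal intensity,
clipped and normalized to unit sum; overlapping beads are rejected and
counted. The model PSF is a separable anisotropic Gaussian, σ_lateral
0.15 µm and σ_axial 0.55 µm by default (axial FWHM ≈ 1.3 µm, typical of
a high-NA confocal), normalized to 1 within 10⁻⁶. Convolution is
linear (zero-padded, FFT-based via overlap-add) and oracle-tested
against a direct triple sum.

`theta_vs_radius_study` voxelizes caps of one contact angle over a
radius panel, blurs with the PSF, and runs the full pipeline with the
size filter off. Small caps are rendered at 0.15 µm isotropic voxels
(the lateral PSF is sub-voxel at coarser sampling and the trend becomes
noisy); caps above 10 µm use 0.3 µm voxels to keep stacks tractable —
the physical PSF is identical, only its sampling changes. For a 120°
cap the fitted angle rises monotonically as the radius shrinks (120.0°
at 28 µm through 125.5° at 1 µm with the default PSF), exceeding 2°
error below ≈ 2 µm, while staying within 2° for radii ≥ 20× the axial
FWHM. The monotonicity assertion allows 0.25° of voxelization jitter.
This reproduces the *trend* motivating the ≥ 10 µm contact-radius
filter; the measured-bead PSF in a real instrument is depth-dependent
(more diffuse away from the coverslip than at it), so the length scale
over which the distortion acts is instrument-specific, not a pointwise
prediction.

## Flory–Huggins binodals and Δφ

Free energy per site: f(φ) = (φ/n) ln φ + (1 − φ) ln(1 − φ) +
χ φ(1 − φ), with chain length n fixed from the construct (default 236
residues) and χ(T) = A + B/T — the minimal two-parameter form with UCST
behavior; the temperature mapping is a definition of this artifact, not
a reproduction of any particular prior fit. Coexistence solves
f′(φ₁) = f′(φ₂) and f − φf′ equal across branches by nested bracketing:
the dense partner by bisection beyond the dense spinodal, the dilute
composition in log φ (it is exponentially small for deep quenches),
confined to the interval where a partner exists (f′(φ₁) ≥ f′ at the
dense spinodal). Returned compositions satisfy both conditions to
10⁻⁸; χ ≤ χc = (1 + 1/√n)²/2 raises a one-phase flag. The solver is
oracle-tested against a convex-hull common-tangent construction on a
10⁵-point grid.

Cloud points are treated as binodal (not spinodal) crossings — the
onset of phase separation by nucleation tracks the coexistence curve.
Because χ*(φ) depends only on n, fitting (A, B) reduces to regressing
χ*(φᵢ) on 1/Tpᵢ; a nonlinear least-squares polish on temperature
residuals follows the linear initialization. Δφ = φ_dense − φ_dilute is
reported at 295.15 K (22 °C, the temperature of contact-angle
measurements) by default; 1 − Δφ approximates condensate water
content.

## Problem sizes and defaults

Simulation sizes are chosen so the whole suite and the acceptance
script each run in minutes on a single core: rescale-factor panels use
four cap angles at one radius (12 µm) per condensate index at 0.25 µm
rendering grid with 101 rays per focus; the PSF study uses eight radii
from 1 to 28 µm; recovery sweeps use 120-point profiles. All are
configurable upward.

## Known limitations

- The ray tracer is geometric: no diffraction, polarization, pinhole or
  apodization model. It reproduces the axial-stretch factor and its
  insensitivity to condensate index, not image textures.
- One condensate index per cap; graded-index interfaces and
  multi-condensate shadowing are out of scope.
- No contact-angle hysteresis, non-axisymmetric drops, pendant
  geometry, or time series.
- Fit uncertainties are not bootstrapped; quality is summarized by
  λ·N/s_max alone.
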