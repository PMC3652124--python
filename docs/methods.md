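# Methods

## Forward model

Photon pairs traversing tissue survive with probability
P = exp(−∫_L μ dl), where L is the full chord of the line of response
(LOR) through the object and μ the linear attenuation map at 511 keV
(cm⁻¹). The measured projections are therefore the attenuated Radon
transform: the ordinary line integral of the activity multiplied by the
chord's survival probability. Because P depends only on the chord and not
on the emission point, attenuation factorises out of the projection
elementwise — multiplying the measured sinogram by the attenuation
correction factors ACF = 1/P inverts it exactly in the noiseless limit.
This factorisation is what both correction routes rely on.

The simulation is per-slice 2D parallel-beam. A physical scanner acquires
in 3D and rebins (e.g. Fourier rebinning) before 2D reconstruction;
oblique-ray effects are therefore not modelled, which is one reason the
simulated recovery values need not match a physical scanner's to better
than a few points. No randoms, scatter, detector blur, decay or dead time
are modelled, matching an evaluation setting in which those corrections
are switched off.

Line integrals use Joseph's interpolating ray-driven method: the ray is
stepped along the image axis most parallel to it with linear interpolation
transversely, step length spacing/|cos θ|. The backprojector applies the
transposed weights, so forward/back are an exact adjoint pair (verified to
1e−6 relative in tests) — a requirement for EM-type reconstruction.
Units: μ is stored in cm⁻¹, path lengths are computed in mm, and the
single mm→cm conversion happens once, in the ACF exponent.

## Reconstruction

2D OSEM with interleaved angular subsets in fixed order, multiplicative
update x ← x · A_sᵀ(y_s/A_s x)/A_sᵀ1. Defaults: 8 subsets, 10 iterations,
uniform unit initialisation — chosen for stable convergence of the
phantom problems at desk scale and recorded in every report's provenance
(the reference reconstruction settings are not published, so absolute
ROI counts are not comparable; only ratios are). One subset reduces to
MLEM bitwise. Reconstruction is restricted to the circular field of view
inscribed by the outermost radial bin: voxels beyond it are seen by only
some angles, are not quantifiable, and would make reconstructions
non-reprojectable. Zero-sensitivity voxels are excluded from updates
rather than guarded by epsilons. No post-smoothing is applied; profiles
and flatness are computed on raw reconstructions.

Attenuation can enter either as sinogram precorrection (counts × ACF,
the default, mirroring the conventional pipeline) or inside the system
matrix (A′ = diag(1/ACF)·A); on noiseless data both converge to the same
image (tested), and the second route is retained as a cross-check.

## CT calibration

μ(HU) = a₁HU² + a₂HU + a₃, unweighted least squares on insert
measurements. The packaged reference coefficients (a₁ = −2.05e−8,
a₂ = 9.66e−5, a₃ = 0.12 cm⁻¹, r² = 0.993) were measured on a GE eXplore
Locus at 80 kV; note μ(0) = 0.12 ≠ μ_water, i.e. that scanner's CT numbers
are not anchored to water = 0. The calibration is therefore treated as
scanner-specific: synthetic CTs are always generated by inverting the
active curve on its monotone branch, never by assuming a standard HU
scale. Outside the fitted HU domain the curve is evaluated at the nearest
domain edge (flat extrapolation) — the quadratic turns over near
HU ≈ 2.36e3 and would otherwise map dense bone to falling μ — and results
are clamped to ≥ 0. Insert densities and μ₅₁₁ values (air, polyethylene,
polystyrene, water, acrylic, Teflon, aluminum) ship as packaged data from
the NIST tables of Hubbell & Seltzer; measured HU is scanner input, not
reference data.

## Coregistration

Fiducial beads (zeolite-like: radioactive and denser than water) around
the body give point landmarks in both frames. Detection thresholds at a
fraction of the image maximum, labels 26-connected components, drops a
dominant body component (only when it exceeds 3× the runner-up's size)
and returns intensity-weighted centroids sorted by integrated intensity.
On noisy emission reconstructions a 1 mm Gaussian pre-smoothing stabilises
the components; the kernel is symmetric, so centroids are unbiased.
Correspondence is by rank of integrated intensity, which is why the
default bead set has graded radii (2.0/1.9/1.8/1.7 mm) and activities
(10/8.5/7/5.5 MBq/cc): the ordering is then strict and identical in both
modalities. The rigid transform is the Kabsch/orthogonal-Procrustes
solution with the reflection branch excluded (handles coplanar bead sets);
resampling is trilinear (positivity-preserving), with `grid-constant`
boundary handling so fractional coordinates at the volume edge blend with
the air value instead of being discarded — important for thin axial
stacks where every slice is a boundary slice.

The default synthetic misalignment between the PET and CT frames is a
3.2 mm translation plus a 7° in-plane rotation, large enough to exercise
the registration path without losing grid overlap. The CT-frame phantom is
re-rasterized analytically in the offset frame (no interpolation round
trip), as an independently acquired CT would be.

## Segmented-emission μ-map

Global threshold on the uncorrected reconstruction; default policy is
10% of the 99th-percentile intensity. A high percentile rather than the
maximum makes the threshold robust to hot spots (tumour, bladder,
fiducial beads); the mask then keeps the largest connected component and
fills holes slice-wise, so cold interiors stay inside the body while
axially open structures are not sealed. Body voxels get μ_water =
0.0969 cm⁻¹. Otsu's method is available as an alternative policy. Bone is
deliberately mapped to soft tissue — the known failure mode for skeletal
tracers, and the reason the SE route's recovery deficit is largest on
¹⁸F-NaF studies.

## Phantoms and synthetic data

The phantom factory rasterizes mouse- (30 mm) and rat-sized (50 mm,
80 mm long) water cylinders, optionally with a hot sphere
(sphere:background = 4) and fiducial beads, at default activity
concentrations of 1 and 0.5 MBq/cc respectively. Rasterization is
anti-aliased: boundary voxels carry the analytic coverage fraction
estimated on an 8×8 (in-plane) or 4×4×4 subvoxel lattice, removing the
staircase bias a binary mask would imprint on line integrals. Default
grids are 90×90 (mouse) and 140×140 (rat) voxels at 0.5 mm with a few
2 mm slices standing in for the scanner's axial extent; the sinogram
default is 120 angles × 175 bins × 0.5 mm. Acquisitions draw independent
Poisson counts after scaling the attenuated sinogram to a total of 2×10⁶
expected counts (a deliberately modest statistic that stresses the
noise-robustness of both pipelines); synthetic CT noise is Gaussian with
σ = 20 HU. All randomness flows from a single integer seed.

What the generator does *not* emulate: anatomical heterogeneity (lungs,
bone), scatter and randoms, detector resolution and parallax, polyenergetic
CT physics (beam hardening), and the 3D acquisition geometry. Passing
phantom tests therefore demonstrates the correctness and internal
consistency of the correction machinery, not its accuracy on live-animal
data — in particular, the segmentation route's real-data failure modes
(blurred contours with low-uptake tracers, bone) are absent by
construction, so the two routes agree more closely here than on animals.

## Evaluation

Recovery values follow the shared-denominator definition
RV_CT = (ROI_AC-CT − ROI_NC)/ROI_AC-CT, RV_SE = (ROI_AC-SE −
ROI_NC)/ROI_AC-CT, in percent; the CT denominator in RV_SE makes the two
directly comparable (their difference is the SE count deficit in CT-AC
units). Flatness F = (C_max − C_min)/C_min is computed on the central
profile restricted to the interior 70% of the object diameter: at the rim,
partial-volume roll-off drives the profile toward zero and an
edge-inclusive minimum would measure resolution rather than attenuation.
The window fraction is configurable and logged. Pipeline profiles are
"thick" lines (3 mm band average); at the default count level a
single-voxel-row profile of a noisy reconstruction is noise-dominated and
its flatness is descriptive only — the quantitative flatness surfaces are
the noiseless simulations. ROI means are reported in arbitrary
counts-per-second-like units; default ROIs are centred disks of 35% of
the body radius (or 70% of the hot-sphere radius) in the central slice.

## Numerical choices and limitations

* Degenerate inputs fail loudly: truncated objects (mass outside the
  radial FOV beyond a 1-voxel margin), negative μ, even bin counts,
  collinear landmark sets, empty segmentation masks.
* CT-derived μ below 0.02 cm⁻¹ (≈10σ of the converted CT noise) is set to
  air; without this, noise makes air μ slightly positive everywhere and
  the truncation guard correctly refuses to project it.
* The ~20% uncorrected flatness of the simulated rat phantom sits a few
  points below physically measured values (22–23%): the 2D noiseless
  surrogate has no scatter, no oblique rays and no detector blur, and the
  interior window clips part of the cupping shoulder.
* On synthetic uniform phantoms the SE μ-map is near-exact, so
  |RV_CT − RV_SE| lands well inside the published 2–3 point envelope;
  the hot-sphere SE deficit seen on physical phantoms (contour errors) is
  not reproduced — the simulated difference is a fraction of a point, and
  its sign can go either way (the 10% threshold slightly dilates the mask
  on blurred reconstructions).
* One fixed subset ordering, no randomisation anywhere outside the seeded
  Poisson/CT-noise draws: identical manifests give identical outputs.
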