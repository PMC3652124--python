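# petac — attenuation correction for small-animal PET

Annihilation photons are absorbed inside the animal before they reach the
detectors, so uncorrected PET images underestimate activity — worst at the
object centre, where a uniform cylinder acquires the familiar *cupping*
artifact. For rodent-sized objects the effect is far from negligible: the
central lines of response through a 50 mm water cylinder lose a factor
exp(−μ·5 cm) ≈ 0.62 of their coincidences (μ_water = 0.0969 cm⁻¹ at
511 keV).

`petac` implements and compares the two practical correction routes used in
preclinical imaging, together with everything needed to evaluate them
without a scanner:

* **CT-AC** — convert a coregistered CT into a 511 keV μ-map via a
  quadratic calibration μ(HU) = a₁HU² + a₂HU + a₃ fitted to known-material
  inserts, then multiply the measured sinogram by the attenuation
  correction factors ACF(s, φ) = exp(+∫_LOR μ dl) before reconstruction.
* **SE-AC** — transmissionless: threshold-segment the emission image into
  air/soft tissue and assign the uniform water μ inside the body contour.
  No CT dose, no registration; bone and lung are deliberately mapped to
  soft tissue.

The forward model is the attenuated Radon transform,

    p(s, φ) = [∫_LOR f dl] · exp(−∫_LOR μ dl),

exact in PET because the attenuation factor depends on the whole chord, not
the emission point. The package provides an analytic phantom factory
(mouse/rat water cylinders, hot spheres, fiducial beads), a matched
Joseph projector/backprojector pair, 2D OSEM reconstruction, fiducial-based
rigid coregistration, and the two evaluation statistics used to compare the
methods: the **recovery value** RV_CT = (ROI_AC-CT − ROI_NC)/ROI_AC-CT and
RV_SE = (ROI_AC-SE − ROI_NC)/ROI_AC-CT (shared CT denominator), and the
profile **flatness** F = (C_max − C_min)/C_min.

Intended for physicists and methods developers who need a transparent,
fully synthetic testbed for preclinical attenuation-correction pipelines.

## Worked example

Both correction routes on one simulated, Poisson-noisy (2×10⁶ counts)
acquisition of the 50 mm rat-sized water phantom — CT-AC with a synthetic
CT on a deliberately offset grid (3.2 mm + 7°), realigned from the
fiducial beads:

```python
from petac import rat_phantom_spec, run_phantom_study, StudyConfig

report = run_phantom_study(rat_phantom_spec(),
                           cfg=StudyConfig(total_counts=2e6), seed=1)
print(f"RV_CT = {report.rv_ct:.1f}%  RV_SE = {report.rv_se:.1f}%")
print(f"registration residual = {report.provenance['registration_rms_mm']:.3f} mm")
```

prints

```
RV_CT = 47.7%  RV_SE = 47.6%
registration residual = 0.016 mm
```

Reading: attenuation correction raises the central-ROI counts by ~48% of
the corrected value for a rat-sized object, and the two μ-map routes agree
to a fraction of a percentage point — the CT-derived and the segmented
μ-maps are near-identical for a uniform water phantom. The noiseless
with/without-attenuation comparison quantifies the shape error that
correction removes:

```python
from petac import rat_phantom_spec, run_attenuation_comparison

res = run_attenuation_comparison(rat_phantom_spec(grid_shape=(140, 140, 1)))
# flatness_attenuated: 19.7      (cupping of the uncorrected image, %)
# flatness_unattenuated: 1.8     (attenuation-free reference, %)
# central_roi_deficit_percent: 45.8
```

A command-line interface mirrors the library (`petac simulate`,
`calibrate`, `mumap-ct`, `mumap-se`, `correct`, `recon`, `evaluate`,
`run-ct-ac`, `run-se-ac`, `run-study`, `compare-attenuation`); every run
writes a JSON manifest with the fully-defaulted configuration and seed.

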