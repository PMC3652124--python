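"""Transmissionless attenuation maps from the emission image itself.

A global threshold splits the (uncorrected) PET reconstruction into a
two-level image — air and soft tissue — and every body voxel is assigned
the attenuation coefficient of water at 511 keV.  This avoids the CT scan
(time, dose) and the PET-CT coregistration step entirely, at the cost of a
uniform attenuation assumption: lungs and, more importantly, bone are
mapped to soft-tissue mu, the known failure mode for skeletal tracers such
as 18F-NaF.

Threshold policies
------------------
``relative`` (default): T = fraction x the 99th-percentile intensity.
    Using a high percentile rather than the maximum makes the threshold
    robust to hot-spot outliers (tumour, bladder, fiducial beads).
``otsu``: Otsu's variance-based threshold on the positive voxels.

After thresholding, the largest connected component is kept (dropping
fiducial beads and noise specks) and internal holes are filled slice by
slice, so cold interiors — a ventricle, a low-uptake organ — stay inside
the body mask.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .calibration import MU_WATER_511
from .images import VoxelImage

__all__ = ["segment_emission", "mask_to_mumap"]


def compute_threshold(
    pet: VoxelImage,
    policy: str = "relative",
    fraction: float = 0.10,
    percentile: float = 99.0,
) -> float:
    vals = pet.values
    if policy == "relative":
        ref = float(np.percentile(vals, percentile))
        return fraction * ref
    if policy == "otsu":
        positive = vals[vals > 0]
        if positive.size < 2:
            raise ValueError("too few positive voxels for Otsu thresholding")
        return float(threshold_otsu(positive))
    raise ValueError(f"unknown threshold policy {policy!r}")


def segment_emission(
    pet: VoxelImage,
    policy: str = "relative",
    fraction: float = 0.10,
    percentile: float = 99.0,
) -> VoxelImage:
    """Global-threshold body segmentation of an emission image.

    Returns a 0/1 mask (role ``mask``): voxels >= T, reduced to the largest
    connected component, with internal holes filled independently per
    transaxial slice (the reconstruction pipeline is 2D, and slice-wise
    filling avoids sealing axially open structures).

    Raises if the image is identically zero, or if the threshold leaves an
    empty mask (the diagnostic reports the threshold used).
    """
    if np.any(pet.values < 0):
        raise ValueError("emission image must be nonnegative")
    if not np.any(pet.values > 0):
        raise ValueError("cannot segment an identically-zero emission image")
    thr = compute_threshold(pet, policy, fraction, percentile)
    binary = pet.values >= thr
    if not np.any(binary):
        raise ValueError(
            f"empty mask: no voxel reaches threshold {thr:.4g} "
            f"(policy={policy!r}, fraction={fraction}, percentile={percentile})"
        )
    labels, n = ndimage.label(binary, structure=np.ones((3, 3, 3)))
    sizes = ndimage.sum_labels(np.ones_like(pet.values), labels, np.arange(1, n + 1))
    body = labels == (int(np.argmax(sizes)) + 1)
    filled = np.zeros_like(body)
    for k in range(body.shape[2]):
        filled[:, :, k] = ndimage.binary_fill_holes(body[:, :, k])
    return pet.with_values(filled.astype(np.float64), role="mask")


def mask_to_mumap(mask: VoxelImage, mu_soft: float = MU_WATER_511) -> VoxelImage:
    """Uniform attenuation map: ``mu_soft`` inside the mask, 0 outside.

    Default is the 511 keV water value, 0.0969 cm^-1.
    """
    if mu_soft < 0:
        raise ValueError("mu_soft must be >= 0")
    if mask.role != "mask":
        uniq = np.unique(mask.values)
        if not np.all(np.isin(uniq, (0.0, 1.0))):
            raise ValueError("input must be a binary mask")
    return mask.with_values(mu_soft * mask.values, role="mu")
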