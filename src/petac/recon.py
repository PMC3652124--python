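"""2D OSEM reconstruction with two attenuation-correction routes.

Ordered-subsets expectation maximization applies the multiplicative EM
update restricted to interleaved angular subsets:

    x  <-  x * A_s^T(y_s / A_s x) / A_s^T 1

With one subset this is exactly MLEM, which monotonically increases the
Poisson log-likelihood.  Attenuation enters either by

* ``precorrected``: the count sinogram is multiplied by the ACF before
  reconstruction (the conventional sinogram-domain route), or
* ``system-matrix``: the projector is attenuated, A' = diag(1/ACF) A, and
  the raw counts are reconstructed directly (statistically preferable,
  kept as a cross-check of the precorrected route).

No convergence test is applied: the iteration count is fixed, as is usual
for emission tomography where early stopping acts as regularisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .images import VoxelImage, centered_grid
from .projector import Sinogram, SinogramGeometry, get_projector

__all__ = ["ReconConfig", "precorrect", "osem_reconstruct", "poisson_loglik"]


@dataclass(frozen=True)
class ReconConfig:
    """OSEM settings: subsets, iterations, initial value, AC route."""

    n_subsets: int = 8
    n_iterations: int = 10
    init_value: float = 1.0
    ac_mode: str = "precorrected"  # none | precorrected | system-matrix

    def __post_init__(self) -> None:
        if self.n_subsets < 1 or self.n_iterations < 1:
            raise ValueError("n_subsets and n_iterations must be >= 1")
        if self.init_value <= 0:
            raise ValueError("init_value must be positive (multiplicative updates)")
        if self.ac_mode not in ("none", "precorrected", "system-matrix"):
            raise ValueError(f"unknown ac_mode {self.ac_mode!r}")

    def subsets(self, n_angles: int) -> list[np.ndarray]:
        """Interleaved angle subsets in fixed order (deterministic)."""
        if n_angles % self.n_subsets != 0:
            raise ValueError(
                f"n_angles={n_angles} not divisible by n_subsets={self.n_subsets}"
            )
        return [np.arange(s, n_angles, self.n_subsets) for s in range(self.n_subsets)]


def precorrect(counts: Sinogram, acf: Sinogram) -> Sinogram:
    """Multiply measured counts by the ACF sinogram, elementwise.

    This undoes attenuation exactly in the noiseless limit; the result is
    no longer Poisson-distributed, so its kind becomes ``line-integral``.
    """
    if acf.kind != "acf":
        raise ValueError(f"second argument must be an ACF sinogram, got {acf.kind!r}")
    if counts.values.shape != acf.values.shape:
        raise ValueError("counts and ACF sinograms must have the same shape")
    if counts.geometry != acf.geometry:
        raise ValueError("counts and ACF sinograms must share geometry")
    return counts.with_values(counts.values * acf.values, kind="line-integral")


def osem_reconstruct(
    data: Sinogram,
    cfg: ReconConfig,
    image_shape: tuple[int, int] | None = None,
    spacing_mm: float | None = None,
    acf: Sinogram | None = None,
    slice_spacing_mm: float | None = None,
) -> VoxelImage:
    """Reconstruct a sinogram with 2D OSEM, slice by slice.

    Parameters
    ----------
    data : Sinogram
        Nonnegative projection data (counts or precorrected).
    cfg : ReconConfig
    image_shape, spacing_mm :
        Target in-plane grid.  Default: square grid of ``n_bins`` pixels at
        the bin width (Nyquist-matched to the sinogram sampling).
    acf : Sinogram, optional
        Required iff ``cfg.ac_mode == "system-matrix"``; the projector is
        then attenuated by 1/ACF.
    slice_spacing_mm : float, optional
        Axial spacing of the output volume (bookkeeping only).

    Returns
    -------
    VoxelImage (role ``activity``) centred on the isocenter.  Voxels with
    zero sensitivity (outside every measured LOR) are excluded from the
    multiplicative update and stay at zero.
    """
    if np.any(data.values < 0):
        raise ValueError("projection data must be nonnegative")
    geom = data.geometry
    if cfg.ac_mode == "system-matrix":
        if acf is None:
            raise ValueError("ac_mode='system-matrix' requires the ACF sinogram")
        if acf.kind != "acf":
            raise ValueError("acf argument must be an ACF sinogram")
    if image_shape is None:
        image_shape = (geom.n_bins, geom.n_bins)
    if spacing_mm is None:
        spacing_mm = geom.bin_width_mm
    proj = get_projector(geom, image_shape, spacing_mm)
    subsets = cfg.subsets(geom.n_angles)
    # circular FOV mask: voxels beyond the outermost radial bin are seen by
    # only a subset of angles and are not quantifiable; keeping them would
    # also make reconstructions non-reprojectable (radially truncated)
    nx, ny = image_shape
    xc = (np.arange(nx) + 0.5 - nx / 2) * spacing_mm
    yc = (np.arange(ny) + 0.5 - ny / 2) * spacing_mm
    r = np.hypot(xc[:, None], yc[None, :])
    fov_mask = r <= geom.s_mm[-1] + geom.bin_width_mm / 2 + spacing_mm

    out = np.zeros(image_shape + (data.n_slices,))
    atten = None
    for k in range(data.n_slices):
        y = data.values[:, :, k]
        if cfg.ac_mode == "system-matrix":
            atten = 1.0 / acf.values[:, :, k]
        out[:, :, k] = _osem_slice(proj, y, subsets, cfg, atten, fov_mask)

    vol = centered_grid(
        image_shape + (data.n_slices,),
        (spacing_mm, spacing_mm, slice_spacing_mm or spacing_mm),
        role="activity",
    )
    return vol.with_values(out)


def _osem_slice(
    proj,
    y: np.ndarray,
    subsets: list[np.ndarray],
    cfg: ReconConfig,
    atten: np.ndarray | None,
    fov_mask: np.ndarray,
) -> np.ndarray:
    """OSEM iterations for one transaxial slice."""
    eps = 1e-12
    x = np.where(fov_mask, float(cfg.init_value), 0.0)
    # per-subset sensitivity images A_s^T 1 (with attenuation if modelled)
    sens = []
    for sub in subsets:
        ones = np.ones((len(sub), proj.geom.n_bins))
        if atten is not None:
            ones = ones * atten[sub]
        sens.append(proj.back(ones, sub))
    support = [(s > eps) & fov_mask for s in sens]

    for _ in range(cfg.n_iterations):
        for sub, s_img, mask in zip(subsets, sens, support):
            fp = proj.forward(x, sub)
            if atten is not None:
                fp = fp * atten[sub]
            ratio = np.where(fp > eps, y[sub] / np.maximum(fp, eps), 0.0)
            if atten is not None:
                ratio = ratio * atten[sub]
            update = proj.back(ratio, sub)
            x = np.where(mask, x * update / np.where(mask, s_img, 1.0), 0.0)
    return x


def poisson_loglik(data: Sinogram, image: VoxelImage) -> float:
    """Poisson log-likelihood sum(y log(Ax) - Ax) of an image given data.

    Zero-mean bins with zero counts contribute 0 by convention.  Used to
    check the monotonicity of MLEM; not part of the reconstruction itself.
    """
    from .projector import radon_forward

    fp = radon_forward(image, data.geometry).values
    y = data.values
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(np.maximum(fp, 1e-300)), 0.0)
    return float((term - fp).sum())
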