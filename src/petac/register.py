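"""Rigid PET-CT alignment from fiducial marks, plus volume resampling.

The CT-based attenuation-correction route needs the CT-derived mu-map on
the PET grid.  Radioactive, attenuating beads (zeolites soaked with tracer)
fixed around the subject show up as isolated blobs in both modalities;
their intensity-weighted centroids provide point correspondences, a
least-squares rigid transform (orthogonal Procrustes with reflections
excluded) aligns the two frames, and trilinear resampling moves the mu-map
onto the PET grid.

Transforms map *moving-frame* world coordinates (mm) to *fixed-frame*
world coordinates: ``x_fixed = R @ x_moving + t``.  As a homogeneous
matrix the convention is column vectors on the right.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .images import VoxelImage

__all__ = [
    "RigidTransform",
    "detect_fiducials",
    "estimate_rigid",
    "resample",
]


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion: rotation (det = +1) plus translation (mm)."""

    rotation: np.ndarray  # (3, 3)
    translation_mm: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation_mm, dtype=float)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation_mm", t)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation length 3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-10):
            raise ValueError("rotation matrix is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-10):
            raise ValueError("rotation matrix must have det +1 (no reflections)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def inplane(
        cls, angle_deg: float, translation_mm: tuple[float, float, float]
    ) -> "RigidTransform":
        """Rotation about z by ``angle_deg`` plus a translation."""
        a = np.deg2rad(angle_deg)
        R = np.array(
            [
                [np.cos(a), -np.sin(a), 0.0],
                [np.sin(a), np.cos(a), 0.0],
                [0.0, 0.0, 1.0],
            ]
        )
        return cls(R, np.asarray(translation_mm, dtype=float))

    def apply(self, points_mm: np.ndarray) -> np.ndarray:
        """Transform an (n, 3) array of points."""
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        return pts @ self.rotation.T + self.translation_mm

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation_mm)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: (self o other)(x) = self(other(x))."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation_mm + self.translation_mm,
        )

    def as_matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix (column-vector convention)."""
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation_mm
        return m


def detect_fiducials(
    image: VoxelImage,
    intensity_threshold_fraction: float = 0.5,
    smooth_sigma_mm: float = 0.0,
) -> list[np.ndarray]:
    """Locate bead-like blobs: bright connected components off the body.

    With ``smooth_sigma_mm > 0`` the image is Gaussian-smoothed first
    (symmetric kernel, so centroids are unbiased) — needed on noisy
    reconstructions where single hot voxels would otherwise fragment or
    fake components.  Voxels above ``fraction * max`` are labelled
    (26-connectivity).  When
    one component dwarfs the others (>3x the voxel count of the runner-up)
    it is taken to be the body and discarded; bead-sized components are
    reduced to intensity-weighted centroids in world mm, sorted by
    descending integrated intensity (so rank order matches between
    modalities when beads have graded sizes/activities).

    Returns an empty list when nothing is found — the caller decides
    whether that is an error.
    """
    vals = image.values
    if smooth_sigma_mm > 0:
        sigma = [smooth_sigma_mm / s for s in image.spacing_mm]
        vals = ndimage.gaussian_filter(vals, sigma)
    vmax = vals.max()
    if vmax <= 0:
        return []
    thr = intensity_threshold_fraction * vmax
    labels, n = ndimage.label(vals > thr, structure=np.ones((3, 3, 3)))
    if n == 0:
        return []
    sizes = ndimage.sum_labels(np.ones_like(vals), labels, index=np.arange(1, n + 1))
    keep = np.arange(1, n + 1)
    if n > 1:
        order = np.argsort(sizes)
        if sizes[order[-1]] > 3.0 * sizes[order[-2]]:
            keep = keep[keep != (order[-1] + 1)]
    centroids = []
    for lab in keep:
        mask = labels == lab
        w = vals * mask
        total = w.sum()
        idx = np.array(ndimage.center_of_mass(vals, labels, lab))
        world = image.index_to_world(idx)
        centroids.append((total, world))
    centroids.sort(key=lambda c: -c[0])
    return [c[1] for c in centroids]


def estimate_rigid(
    moving_points: np.ndarray, fixed_points: np.ndarray
) -> tuple[RigidTransform, float]:
    """Least-squares rigid transform mapping moving points onto fixed points.

    Orthogonal Procrustes (Kabsch) with the reflection branch excluded:
    the sign of the smallest singular direction is flipped when needed so
    det(R) = +1, which also handles coplanar point sets.

    Returns
    -------
    (transform, rms_residual_mm)
    """
    P = np.atleast_2d(np.asarray(moving_points, dtype=float))
    Q = np.atleast_2d(np.asarray(fixed_points, dtype=float))
    if P.shape != Q.shape or P.shape[1] != 3:
        raise ValueError("point sets must be matching (n, 3) arrays")
    n = P.shape[0]
    if n < 3:
        raise ValueError(f"need >= 3 point pairs, got {n}")
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    if np.linalg.matrix_rank(Pc, tol=1e-9 * max(1.0, np.abs(Pc).max())) < 2:
        raise ValueError("degenerate configuration: points are collinear")
    H = Pc.T @ Qc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = Q.mean(axis=0) - R @ P.mean(axis=0)
    transform = RigidTransform(R, t)
    residual = transform.apply(P) - Q
    rms = float(np.sqrt((residual**2).sum(axis=1).mean()))
    return transform, rms


def resample(
    image: VoxelImage,
    transform: RigidTransform,
    target: VoxelImage,
    fill_value: float = 0.0,
) -> VoxelImage:
    """Resample ``image`` (moving frame) onto ``target``'s grid (fixed frame).

    Each target voxel centre is mapped back through the inverse transform
    and the moving image is sampled there by trilinear interpolation
    (positivity-preserving, appropriate for mu-maps).  Points outside the
    moving image get ``fill_value`` (0 = air attenuation by default).
    """
    inv = transform.inverse()
    sp_m = np.asarray(image.spacing_mm)
    or_m = np.asarray(image.origin_mm)
    sp_f = np.asarray(target.spacing_mm)
    or_f = np.asarray(target.origin_mm)
    # index_moving = (R_inv @ x_fixed + t_inv - origin_m) / sp_m - 0.5 with
    # x_fixed = origin_f + (index_fixed + 0.5) * sp_f; compose into one affine
    A = (inv.rotation * sp_f[None, :]) / sp_m[:, None]
    b = (
        inv.rotation @ (or_f + 0.5 * sp_f) + inv.translation_mm - or_m
    ) / sp_m - 0.5
    # snap numerical dust: a sample coordinate of -1e-15 would otherwise be
    # treated as out of bounds (filled with cval) for an entire hyperplane
    A[np.abs(A) < 1e-12] = 0.0
    b_round = np.round(b)
    near = np.abs(b - b_round) < 1e-9
    b[near] = b_round[near]
    out = ndimage.affine_transform(
        image.values,
        A,
        offset=b,
        output_shape=target.shape,
        order=1,
        mode="grid-constant",  # blend with the fill value at fractional
        cval=fill_value,       # boundary coordinates instead of hard-filling
    )
    role = image.role if image.role != "mask" else "activity"
    return VoxelImage(out, target.spacing_mm, target.origin_mm, role)
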