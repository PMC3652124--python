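"""Analytic phantom factory: activity maps, mu-maps and synthetic CT volumes.

The phantoms mirror the standard preclinical quantification set-up:

* a mouse-sized water cylinder, 30 mm diameter, uniformly filled;
* a rat-sized water cylinder, 50 mm diameter (80 mm long), uniformly filled;
* the rat cylinder with a hot sphere (sphere:background activity ratio 4);
* optional zeolite-like fiducial beads placed around the cylinder, used as
  registration marks between the PET and CT frames.

Rasterization is anti-aliased: boundary voxels receive the area (volume)
fraction of the voxel covered by the analytic shape, estimated on a regular
subvoxel lattice.  This removes the staircase bias that binary masks would
imprint on line integrals at 0.5 mm voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .calibration import MU_WATER_511, CalibrationCurve
from .images import VoxelImage, centered_grid

__all__ = [
    "Fiducial",
    "PhantomSpec",
    "mouse_phantom_spec",
    "rat_phantom_spec",
    "make_phantom",
    "add_hot_sphere",
    "make_synthetic_ct",
    "default_fiducials",
]

#: Subvoxel lattice used for anti-aliased rasterization.
_SUPERSAMPLE_2D = 8
_SUPERSAMPLE_3D = 4


@dataclass(frozen=True)
class Fiducial:
    """A small radioactive, attenuating bead fixed outside the body.

    Distinct sizes/concentrations give distinct integrated intensities,
    which is what makes rank-ordered point correspondence unambiguous in
    both the emission and the CT frame.
    """

    center_mm: tuple[float, float, float]
    radius_mm: float = 1.5
    concentration: float = 5.0  # MBq/cc
    mu: float = 0.15  # cm^-1 (hydrated zeolite, denser than water)


@dataclass
class PhantomSpec:
    """Parametric description of a cylindrical quantification phantom.

    The cylinder axis is z; ``center_mm`` defaults to the grid centre
    (the isocenter for grids built with :func:`petac.images.centered_grid`).
    """

    kind: str = "uniform-cylinder"  # or "cylinder-with-hot-sphere"
    diameter_mm: float = 50.0
    length_mm: float = 80.0
    activity_concentration: float = 0.5  # MBq/cc
    material_mu: float = MU_WATER_511  # cm^-1
    center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    sphere_center_mm: tuple[float, float, float] | None = None
    sphere_radius_mm: float = 0.0
    sphere_to_background_ratio: float = 1.0
    fiducials: tuple[Fiducial, ...] = ()
    grid_shape: tuple[int, int, int] = (140, 140, 4)
    voxel_mm: tuple[float, float, float] = (0.5, 0.5, 2.0)

    def __post_init__(self) -> None:
        if self.kind not in ("uniform-cylinder", "cylinder-with-hot-sphere"):
            raise ValueError(f"unknown phantom kind {self.kind!r}")
        if self.activity_concentration < 0:
            raise ValueError("activity_concentration must be >= 0")
        if self.material_mu < 0:
            raise ValueError("material_mu must be >= 0")
        if np.isscalar(self.voxel_mm):
            self.voxel_mm = (float(self.voxel_mm),) * 3
        self.voxel_mm = tuple(float(v) for v in self.voxel_mm)
        extent_x = self.grid_shape[0] * self.voxel_mm[0]
        extent_y = self.grid_shape[1] * self.voxel_mm[1]
        if self.diameter_mm > min(extent_x, extent_y):
            raise ValueError(
                f"cylinder diameter {self.diameter_mm} mm exceeds grid extent "
                f"({extent_x:.1f} x {extent_y:.1f} mm)"
            )
        if self.kind == "cylinder-with-hot-sphere":
            if self.sphere_center_mm is None or self.sphere_radius_mm <= 0:
                raise ValueError("hot-sphere phantom needs sphere_center_mm and radius")
            if self.sphere_to_background_ratio < 1:
                raise ValueError("sphere_to_background_ratio must be >= 1 (hot sphere)")
            dx = self.sphere_center_mm[0] - self.center_mm[0]
            dy = self.sphere_center_mm[1] - self.center_mm[1]
            if np.hypot(dx, dy) + self.sphere_radius_mm >= self.diameter_mm / 2:
                raise ValueError("hot sphere must lie strictly inside the cylinder")

    def grid(self, role: str = "activity") -> VoxelImage:
        return centered_grid(self.grid_shape, self.voxel_mm, role=role)


def default_fiducials(body_radius_mm: float, n_slices: int = 4) -> tuple[Fiducial, ...]:
    """Four beads of graded size/activity around the body, off the axes.

    Placed at distinct angles and (where the grid allows) distinct slices so
    the point set is never collinear; graded radii and concentrations give a
    strict integrated-intensity ordering for rank-based correspondence.
    """
    r = body_radius_mm + 4.0
    angles = np.deg2rad([20.0, 110.0, 200.0, 305.0])
    radii = (2.0, 1.9, 1.8, 1.7)
    concs = (10.0, 8.5, 7.0, 5.5)
    zs = [0.0] * 4
    return tuple(
        Fiducial(
            center_mm=(r * np.cos(a), r * np.sin(a), z),
            radius_mm=rad,
            concentration=c,
        )
        for a, rad, c, z in zip(angles, radii, concs, zs)
    )


def mouse_phantom_spec(**overrides) -> PhantomSpec:
    """30 mm diameter water cylinder, ~1 MBq/cc, on a 90x90 grid at 0.5 mm."""
    defaults = dict(
        kind="uniform-cylinder",
        diameter_mm=30.0,
        length_mm=40.0,
        activity_concentration=1.0,
        grid_shape=(90, 90, 4),
    )
    defaults.update(overrides)
    return PhantomSpec(**defaults)


def rat_phantom_spec(hot_sphere: bool = False, **overrides) -> PhantomSpec:
    """50 mm diameter, 80 mm long water cylinder, ~0.5 MBq/cc.

    With ``hot_sphere=True``, a 4 mm radius sphere at (10, 0) mm carries four
    times the background concentration.
    """
    defaults = dict(
        kind="uniform-cylinder",
        diameter_mm=50.0,
        length_mm=80.0,
        activity_concentration=0.5,
        grid_shape=(140, 140, 4),
    )
    if hot_sphere:
        defaults.update(
            kind="cylinder-with-hot-sphere",
            sphere_center_mm=(10.0, 0.0, 0.0),
            sphere_radius_mm=4.0,
            sphere_to_background_ratio=4.0,
        )
    defaults.update(overrides)
    return PhantomSpec(**defaults)


# -- rasterization ----------------------------------------------------------


def _subvoxel_offsets(n: int) -> np.ndarray:
    """Centres of an n-point regular subdivision of [-0.5, 0.5)."""
    return (np.arange(n) + 0.5) / n - 0.5


def disk_fraction(
    grid: VoxelImage, center_xy: tuple[float, float], radius_mm: float
) -> np.ndarray:
    """Per-voxel in-plane area fraction covered by a disk (2D array, x by y)."""
    x = grid.centers_mm(0)
    y = grid.centers_mm(1)
    dx, dy = grid.spacing_mm[0], grid.spacing_mm[1]
    ox = _subvoxel_offsets(_SUPERSAMPLE_2D) * dx
    oy = _subvoxel_offsets(_SUPERSAMPLE_2D) * dy
    # (nx, ny) distance of each subsample to the centre, averaged per voxel
    xs = x[:, None, None, None] + ox[None, None, :, None] - center_xy[0]
    ys = y[None, :, None, None] + oy[None, None, None, :] - center_xy[1]
    inside = (xs**2 + ys**2) <= radius_mm**2
    return inside.mean(axis=(2, 3))


def sphere_fraction(
    grid: VoxelImage, center_mm: tuple[float, float, float], radius_mm: float
) -> np.ndarray:
    """Per-voxel volume fraction covered by a sphere (3D array)."""
    frac = np.zeros(grid.shape)
    x = grid.centers_mm(0)
    y = grid.centers_mm(1)
    z = grid.centers_mm(2)
    dx, dy, dz = grid.spacing_mm
    # restrict the supersampled computation to a bounding box for speed
    pad = radius_mm
    ix = np.where(np.abs(x - center_mm[0]) <= pad + dx)[0]
    iy = np.where(np.abs(y - center_mm[1]) <= pad + dy)[0]
    iz = np.where(np.abs(z - center_mm[2]) <= pad + dz)[0]
    if ix.size == 0 or iy.size == 0 or iz.size == 0:
        return frac
    n = _SUPERSAMPLE_3D
    ox = _subvoxel_offsets(n) * dx
    oy = _subvoxel_offsets(n) * dy
    oz = _subvoxel_offsets(n) * dz
    xs = (x[ix][:, None] + ox[None, :] - center_mm[0]).reshape(-1)
    ys = (y[iy][:, None] + oy[None, :] - center_mm[1]).reshape(-1)
    zs = (z[iz][:, None] + oz[None, :] - center_mm[2]).reshape(-1)
    inside = (
        xs[:, None, None] ** 2 + ys[None, :, None] ** 2 + zs[None, None, :] ** 2
    ) <= radius_mm**2
    nx, ny, nz = ix.size, iy.size, iz.size
    inside = inside.reshape(nx, n, ny, n, nz, n)
    frac[np.ix_(ix, iy, iz)] = inside.mean(axis=(1, 3, 5))
    return frac


def _slice_coverage(grid: VoxelImage, center_z: float, length_mm: float) -> np.ndarray:
    """Axial coverage fraction of each slice by a cylinder of given length."""
    z = grid.centers_mm(2)
    dz = grid.spacing_mm[2]
    lo, hi = center_z - length_mm / 2, center_z + length_mm / 2
    overlap = np.minimum(z + dz / 2, hi) - np.maximum(z - dz / 2, lo)
    return np.clip(overlap / dz, 0.0, 1.0)


# -- phantom construction ---------------------------------------------------


def make_phantom(spec: PhantomSpec) -> tuple[VoxelImage, VoxelImage]:
    """Rasterize a phantom spec into an activity map and a mu-map.

    Returns
    -------
    (activity, mu) : VoxelImage pair on the spec's grid.  Activity is the
    background concentration inside the cylinder, scaled by the sphere ratio
    inside the hot sphere and by each fiducial's concentration inside its
    bead; mu is ``material_mu`` inside the cylinder and each fiducial's mu
    inside its bead.  Boundary voxels carry analytic coverage fractions.
    """
    grid = spec.grid()
    disk = disk_fraction(grid, spec.center_mm[:2], spec.diameter_mm / 2)
    axial = _slice_coverage(grid, spec.center_mm[2], spec.length_mm)
    body = disk[:, :, None] * axial[None, None, :]

    activity = spec.activity_concentration * body
    mu = spec.material_mu * body

    if spec.kind == "cylinder-with-hot-sphere":
        sph = sphere_fraction(grid, spec.sphere_center_mm, spec.sphere_radius_mm)
        activity += (
            spec.activity_concentration * (spec.sphere_to_background_ratio - 1.0) * sph
        )

    for fid in spec.fiducials:
        bead = sphere_fraction(grid, fid.center_mm, fid.radius_mm)
        activity += fid.concentration * bead
        mu += fid.mu * bead

    act_img = grid.with_values(activity, role="activity")
    mu_img = grid.with_values(mu, role="mu")
    return act_img, mu_img


def add_hot_sphere(
    activity: VoxelImage,
    center_mm: tuple[float, float, float],
    radius_mm: float,
    ratio: float,
) -> VoxelImage:
    """Scale activity inside a sphere so sphere:background mean equals ``ratio``.

    The input must carry a uniform positive background; the background level
    is taken as the median of the positive voxels (robust to fiducials and
    boundary anti-aliasing).
    """
    if ratio < 1:
        raise ValueError("only hot spheres (ratio >= 1) are supported")
    positive = activity.values[activity.values > 0]
    if positive.size == 0:
        raise ValueError("activity image has no positive background")
    background = float(np.median(positive))
    sph = sphere_fraction(activity, center_mm, radius_mm)
    return activity.with_values(activity.values + background * (ratio - 1.0) * sph)


def make_synthetic_ct(
    mu: VoxelImage,
    curve: CalibrationCurve,
    noise_sd_hu: float = 0.0,
    seed: int | None = None,
) -> VoxelImage:
    """Generate a CT volume whose calibrated conversion reproduces ``mu``.

    HU values are obtained by inverting the calibration quadratic on its
    monotone branch; optional Gaussian noise of the stated standard
    deviation (HU) is added with a seeded generator.  Raises if any mu value
    is not attainable by the curve over its HU domain.
    """
    hu = curve.invert(mu.values)
    if noise_sd_hu > 0:
        rng = np.random.default_rng(seed)
        hu = hu + rng.normal(0.0, noise_sd_hu, size=hu.shape)
    return mu.with_values(hu, role="hu")
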