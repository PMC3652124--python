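"""CT number to 511 keV attenuation coefficient calibration.

A small-animal CT scanner is calibrated by imaging cylindrical inserts of
known material.  The mean CT number (HU) measured in each insert is paired
with the material's published linear attenuation coefficient at 511 keV
(NIST values of Hubbell & Seltzer), and a quadratic

    mu(HU) = a1 * HU^2 + a2 * HU + a3        [cm^-1]

is fitted by ordinary least squares.  The fitted curve converts CT volumes
into mu-maps for attenuation correction of PET data.

The module ships the NIST reference coefficients used for insert materials
(``load_reference_materials``) and the quadratic measured on a GE eXplore
Locus scanner at 80 kV (``default_curve``), whose value at HU = 0 is
0.12 cm^-1 — note this scanner's CT numbers are not anchored to water = 0,
so the curve is treated as scanner-specific and synthetic CT images are
always generated by inverting the active curve.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .images import VoxelImage

__all__ = [
    "CalibrationPoint",
    "CalibrationCurve",
    "fit_calibration",
    "hu_to_mu",
    "measure_insert_hu",
    "load_reference_materials",
    "load_calibration_points",
    "save_calibration_points",
    "default_curve",
    "MU_WATER_511",
]

#: Linear attenuation coefficient of water at 511 keV (cm^-1), NIST.
MU_WATER_511 = 0.0969


@dataclass(frozen=True)
class CalibrationPoint:
    """One calibration insert: material, density, mu at 511 keV, measured HU."""

    material: str
    density: float  # g/cm^3
    mu_511: float  # cm^-1
    measured_hu: float

    def __post_init__(self) -> None:
        if self.mu_511 < 0:
            raise ValueError(f"mu_511 must be >= 0, got {self.mu_511}")


@dataclass(frozen=True)
class CalibrationCurve:
    """Quadratic HU -> mu(511 keV) conversion with its validity domain.

    ``mu = a1*HU^2 + a2*HU + a3``.  Outside ``hu_domain`` the curve is
    evaluated at the nearest domain edge (flat extrapolation); a quadratic
    with a1 < 0 turns over at high HU, which would map dense bone to a
    *falling* mu.  Results are clamped to >= 0.
    """

    a1: float  # cm^-1 HU^-2
    a2: float  # cm^-1 HU^-1
    a3: float  # cm^-1
    r_squared: float = float("nan")
    hu_domain: tuple[float, float] = (-1100.0, 2300.0)

    def __post_init__(self) -> None:
        lo, hi = self.hu_domain
        if not lo < hi:
            raise ValueError(f"empty HU domain {self.hu_domain}")
        d_lo = 2 * self.a1 * lo + self.a2
        d_hi = 2 * self.a1 * hi + self.a2
        if d_lo < 0 or d_hi < 0:
            raise ValueError(
                f"curve not monotone non-decreasing on {self.hu_domain}: "
                f"derivative spans [{min(d_lo, d_hi):.3g}, {max(d_lo, d_hi):.3g}]"
            )

    def __call__(self, hu: np.ndarray) -> np.ndarray:
        """Evaluate mu(HU) with flat extrapolation and clamping to >= 0."""
        hu = np.clip(np.asarray(hu, dtype=float), *self.hu_domain)
        mu = self.a1 * hu**2 + self.a2 * hu + self.a3
        return np.clip(mu, 0.0, None)

    @property
    def mu_range(self) -> tuple[float, float]:
        """Attainable mu values over the HU domain (monotone branch)."""
        lo, hi = self.hu_domain
        return float(self(lo)), float(self(hi))

    def invert(self, mu: np.ndarray) -> np.ndarray:
        """HU such that mu(HU) = mu, on the monotone (soft-tissue) branch.

        For a1 < 0 the parabola opens downward; the physically meaningful,
        increasing branch lies left of the vertex -a2 / (2*a1), and the
        root on that branch is selected.  Raises if a requested mu is not
        attainable on the curve over its HU domain.
        """
        mu = np.asarray(mu, dtype=float)
        lo, hi = self.mu_range
        if np.any(mu < lo - 1e-12) or np.any(mu > hi + 1e-12):
            raise ValueError(
                f"mu values outside attainable range [{lo:.4g}, {hi:.4g}] cm^-1"
            )
        if self.a1 == 0.0:
            hu = (mu - self.a3) / self.a2
        else:
            disc = self.a2**2 - 4.0 * self.a1 * (self.a3 - mu)
            disc = np.maximum(disc, 0.0)
            sqrt_disc = np.sqrt(disc)
            # Of the two roots, keep the one on the increasing branch
            # (derivative 2*a1*HU + a2 >= 0).
            r1 = (-self.a2 + sqrt_disc) / (2.0 * self.a1)
            r2 = (-self.a2 - sqrt_disc) / (2.0 * self.a1)
            vertex = -self.a2 / (2.0 * self.a1)
            hu = np.where((r1 <= vertex) == (self.a1 < 0), r1, r2)
        return np.clip(hu, *self.hu_domain)


def default_curve() -> CalibrationCurve:
    """Quadratic calibration measured on a GE eXplore Locus CT at 80 kV.

    a1 = -2.05e-8, a2 = 9.66e-5, a3 = 0.12 cm^-1 (r^2 = 0.993).  The
    derivative 2*a1*HU + a2 stays positive up to HU ~ 2.36e3, so the curve
    is monotone over the whole insert range.
    """
    return CalibrationCurve(a1=-2.05e-8, a2=9.66e-5, a3=0.12, r_squared=0.993)


def fit_calibration(
    points: list[CalibrationPoint], hu_margin: float = 100.0
) -> CalibrationCurve:
    """Ordinary least-squares quadratic fit of mu_511 on measured HU.

    Parameters
    ----------
    points : list of CalibrationPoint
        At least 3 inserts with distinct measured HU.
    hu_margin : float
        The returned curve's HU domain extends this far beyond the fitted
        insert range.

    Returns
    -------
    CalibrationCurve with the fitted (a1, a2, a3) and the coefficient of
    determination r^2.
    """
    if len(points) < 3:
        raise ValueError(f"need >= 3 calibration points, got {len(points)}")
    hu = np.array([p.measured_hu for p in points], dtype=float)
    mu = np.array([p.mu_511 for p in points], dtype=float)
    if len(np.unique(hu)) < 3:
        raise ValueError("need >= 3 distinct HU values for a quadratic fit")
    # np.polyfit raises on a rank-deficient design only with warnings; check
    # conditioning explicitly so degenerate inputs fail loudly.
    design = np.vander(hu, 3)
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError("degenerate calibration design (collinear HU values)")
    coeffs, residuals, *_ = np.linalg.lstsq(design, mu, rcond=None)
    a1, a2, a3 = (float(c) for c in coeffs)
    fitted = design @ coeffs
    ss_res = float(np.sum((mu - fitted) ** 2))
    ss_tot = float(np.sum((mu - mu.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    domain = (float(hu.min() - hu_margin), float(hu.max() + hu_margin))
    return CalibrationCurve(a1, a2, a3, r_squared=r2, hu_domain=domain)


def hu_to_mu(ct: VoxelImage, curve: CalibrationCurve) -> VoxelImage:
    """Convert a CT volume to a 511 keV mu-map, voxelwise.

    Values outside the curve's HU domain are evaluated at the nearest
    domain edge; results are clamped to >= 0, so the output is a valid
    mu image for any finite input.
    """
    if not np.all(np.isfinite(ct.values)):
        raise ValueError("CT volume contains non-finite values")
    return ct.with_values(curve(ct.values), role="mu")


def measure_insert_hu(
    ct: VoxelImage,
    roi_center_mm: tuple[float, float, float],
    roi_radius_mm: float,
) -> float:
    """Mean CT number inside a cylindrical ROI (circular in-plane, all slices).

    The ROI must lie fully inside the image in-plane; a ROI crossing the
    edge raises, matching how insert means are measured in practice.
    """
    cx, cy, _ = roi_center_mm
    x = ct.centers_mm(0)
    y = ct.centers_mm(1)
    if (
        cx - roi_radius_mm < x[0] - 0.5 * ct.spacing_mm[0]
        or cx + roi_radius_mm > x[-1] + 0.5 * ct.spacing_mm[0]
        or cy - roi_radius_mm < y[0] - 0.5 * ct.spacing_mm[1]
        or cy + roi_radius_mm > y[-1] + 0.5 * ct.spacing_mm[1]
    ):
        raise ValueError("ROI extends beyond the image in-plane extent")
    in_roi = (x[:, None] - cx) ** 2 + (y[None, :] - cy) ** 2 <= roi_radius_mm**2
    if not np.any(in_roi):
        raise ValueError("ROI contains no voxels")
    return float(ct.values[in_roi, :].mean())


# -- reference data and text I/O -------------------------------------------


def load_reference_materials() -> list[CalibrationPoint]:
    """NIST densities and 511 keV attenuation coefficients of the QC inserts.

    Measured HU is set to NaN: it is scanner-specific and must come from an
    actual (or synthetic) CT acquisition.
    """
    text = resources.files("petac.data").joinpath("nist_mu511.tsv").read_text()
    points = []
    for row in csv.DictReader(text.splitlines(), delimiter="\t"):
        points.append(
            CalibrationPoint(
                material=row["material"],
                density=float(row["density_g_cm3"]),
                mu_511=float(row["mu_511_cm1"]),
                measured_hu=float("nan"),
            )
        )
    return points


def load_calibration_points(path: str | Path) -> list[CalibrationPoint]:
    """Read (material, density, mu_511, measured_hu) from a TSV file."""
    points = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            points.append(
                CalibrationPoint(
                    material=row["material"],
                    density=float(row["density_g_cm3"]),
                    mu_511=float(row["mu_511_cm1"]),
                    measured_hu=float(row["measured_hu"]),
                )
            )
    names = [p.material for p in points]
    if len(set(names)) != len(names):
        raise ValueError("duplicate material names in calibration file")
    return points


def save_calibration_points(points: list[CalibrationPoint], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["material", "density_g_cm3", "mu_511_cm1", "measured_hu"])
        for p in points:
            writer.writerow([p.material, p.density, p.mu_511, p.measured_hu])
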