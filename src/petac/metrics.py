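"""Quantitative evaluation of attenuation correction.

Two summary statistics are used throughout:

*Recovery value* (RV) — the fractional count increase of an
attenuation-corrected image over the uncorrected one, both referred to the
CT-corrected ROI mean:

    RV_CT = (ROI_AC-CT - ROI_NC) / ROI_AC-CT
    RV_SE = (ROI_AC-SE - ROI_NC) / ROI_AC-CT

Note that *both* recovery values share the CT-AC denominator; this makes
RV_SE directly comparable to RV_CT (their difference is the SE method's
count deficit in units of the CT-corrected signal).

*Flatness* — the residual cupping artifact of a uniform object,

    F = (Cmax - Cmin) / Cmin

over a line profile through the object centre.  By default the profile is
restricted to the central 70% of the object diameter: at the physical
edge, partial-volume roll-off drives the profile to zero and an
edge-inclusive minimum would measure resolution, not attenuation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .images import VoxelImage

__all__ = [
    "recovery_values",
    "flatness",
    "line_profile",
    "roi_mean",
    "EvalReport",
]


def recovery_values(
    roi_nc: float, roi_ac_ct: float, roi_ac_se: float | None = None
) -> tuple[float, float | None]:
    """Recovery values in percent from ROI means.

    Parameters
    ----------
    roi_nc, roi_ac_ct, roi_ac_se :
        Mean ROI counts of the uncorrected, CT-corrected and (optionally)
        segmentation-corrected images.  ``roi_ac_ct`` must be positive: it
        is the common denominator of both recovery values.

    Returns
    -------
    (rv_ct, rv_se) in percent; ``rv_se`` is None when ``roi_ac_se`` is.
    """
    if roi_ac_ct <= 0:
        raise ValueError("ROI_AC-CT must be positive (it is the RV denominator)")
    rv_ct = 100.0 * (roi_ac_ct - roi_nc) / roi_ac_ct
    rv_se = None
    if roi_ac_se is not None:
        rv_se = 100.0 * (roi_ac_se - roi_nc) / roi_ac_ct
    return rv_ct, rv_se


def flatness(
    profile: np.ndarray,
    positions_mm: np.ndarray | None = None,
    center_mm: float = 0.0,
    diameter_mm: float | None = None,
    interior_fraction: float = 0.7,
) -> float:
    """(Cmax - Cmin)/Cmin over a profile's interior samples, in percent.

    With ``positions_mm`` and ``diameter_mm`` given, the profile is first
    restricted to ``|position - center| <= interior_fraction * diameter/2``;
    otherwise all samples are used.  Raises if the interior minimum is not
    positive (flatness is undefined there).
    """
    profile = np.asarray(profile, dtype=float)
    if diameter_mm is not None:
        if positions_mm is None:
            raise ValueError("positions_mm required when diameter_mm is given")
        positions_mm = np.asarray(positions_mm, dtype=float)
        keep = np.abs(positions_mm - center_mm) <= interior_fraction * diameter_mm / 2
        profile = profile[keep]
    if profile.size == 0:
        raise ValueError("no samples in the interior window")
    cmin, cmax = float(profile.min()), float(profile.max())
    if cmin <= 0:
        raise ValueError("flatness undefined: interior minimum is not positive")
    return 100.0 * (cmax - cmin) / cmin


def line_profile(
    image: VoxelImage,
    slice_index: int,
    axis: str = "x",
    offset_mm: float = 0.0,
    band_mm: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """1D count profile through the slice centre.

    ``axis="x"`` samples along x at the row nearest ``y = centre + offset``;
    ``axis="y"`` the transpose.  With ``band_mm > 0`` the profile is the
    mean over all rows within ``offset +- band/2`` — a thick profile line,
    which suppresses voxel noise on noisy reconstructions.  Returns
    (positions_mm, values); positions are world coordinates.
    """
    if not 0 <= slice_index < image.n_slices:
        raise IndexError(f"slice {slice_index} out of range [0, {image.n_slices})")
    sl = image.values[:, :, slice_index]
    cx, cy, _ = image.center_mm
    if axis == "x":
        perp, target, data, out_pos = (
            image.centers_mm(1),
            cy + offset_mm,
            sl,
            image.centers_mm(0),
        )
    elif axis == "y":
        perp, target, data, out_pos = (
            image.centers_mm(0),
            cx + offset_mm,
            sl.T,
            image.centers_mm(1),
        )
    else:
        raise ValueError(f"axis must be 'x' or 'y', got {axis!r}")
    dist = np.abs(perp - target)
    if dist.min() > image.spacing_mm[1 if axis == "x" else 0]:
        raise IndexError("offset places the profile outside the image")
    if band_mm > 0:
        cols = dist <= band_mm / 2
        if not np.any(cols):
            cols = dist == dist.min()
        return out_pos, data[:, cols].mean(axis=1)
    j = int(np.argmin(dist))
    return out_pos, data[:, j].copy()


def roi_mean(
    image: VoxelImage,
    center_mm: tuple[float, float, float],
    radius_mm: float,
    slice_index: int | None = None,
) -> float:
    """Mean value in a circular (one slice) or spherical ROI.

    With ``slice_index`` the ROI is a disk in that transaxial slice;
    without it, a sphere across the volume.  Voxels are included when
    their centre lies inside the ROI.
    """
    x = image.centers_mm(0)[:, None] - center_mm[0]
    y = image.centers_mm(1)[None, :] - center_mm[1]
    if slice_index is not None:
        if not 0 <= slice_index < image.n_slices:
            raise IndexError("slice index out of range")
        inside = x**2 + y**2 <= radius_mm**2
        if not np.any(inside):
            raise ValueError("ROI contains no voxels")
        return float(image.values[:, :, slice_index][inside].mean())
    z = image.centers_mm(2)[None, None, :] - center_mm[2]
    inside = x[:, :, None] ** 2 + y[:, :, None] ** 2 + z**2 <= radius_mm**2
    if not np.any(inside):
        raise ValueError("ROI contains no voxels")
    return float(image.values[inside].mean())


@dataclass
class EvalReport:
    """Evaluation summary for one phantom/acquisition experiment.

    ROI means are in arbitrary counts-per-second-like units (absolute
    scanner counts are not modelled); recovery values and flatness are in
    percent.  ``provenance`` echoes every parameter that produced the
    numbers.
    """

    roi_nc: float
    roi_ac_ct: float | None = None
    roi_ac_se: float | None = None
    rv_ct: float | None = None
    rv_se: float | None = None
    flatness_nc: float | None = None
    flatness_ac_ct: float | None = None
    flatness_ac_se: float | None = None
    profiles: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def to_json(self, path=None, indent: int = 2) -> str:
        def _default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            raise TypeError(f"not JSON serialisable: {type(o)}")

        text = json.dumps(asdict(self), default=_default, indent=indent)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def to_table(self) -> str:
        """Delimited-text summary with ROI counts, RV and flatness columns."""
        rows = [("image", "roi_counts", "rv_percent", "flatness_percent")]

        def fmt(v):
            return "" if v is None else f"{v:.2f}"

        rows.append(("original", fmt(self.roi_nc), "", fmt(self.flatness_nc)))
        if self.roi_ac_ct is not None:
            rows.append(
                ("ct_ac", fmt(self.roi_ac_ct), fmt(self.rv_ct), fmt(self.flatness_ac_ct))
            )
        if self.roi_ac_se is not None:
            rows.append(
                ("se_ac", fmt(self.roi_ac_se), fmt(self.rv_se), fmt(self.flatness_ac_se))
            )
        return "\n".join("\t".join(r) for r in rows)


def plot_profiles(report: "EvalReport", ax=None):
    """Plot the report's line profiles in the conventional style: thick line
    for the uncorrected image, full and dotted lines for the CT- and
    SE-corrected ones.  Requires matplotlib (``pip install petac[plot]``)."""
    try:
        import matplotlib.pyplot as plt
    except ImportError as exc:  # pragma: no cover
        raise ImportError("plot_profiles requires matplotlib") from exc
    if ax is None:
        _, ax = plt.subplots()
    styles = {
        "nc": dict(lw=2.5, color="k", label="uncorrected"),
        "ac_ct": dict(lw=1.2, color="tab:blue", label="CT-AC"),
        "ac_se": dict(lw=1.2, ls=":", color="tab:red", label="SE-AC"),
    }
    for name, prof in report.profiles.items():
        ax.plot(prof["position_mm"], prof["counts"], **styles.get(name, {}))
    ax.set_xlabel("position (mm)")
    ax.set_ylabel("counts (a.u.)")
    ax.legend()
    return ax
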