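"""File formats and run configuration.

Volumes travel as single-file NIfTI-1 (spacing in ``pixdim``, role in the
``descrip`` header field); sinograms as raw little-endian float32 arrays
with a JSON sidecar describing the geometry; calibration points as
delimited text (see :mod:`petac.calibration`); configuration as a single
YAML file with nested sections; every run can write a JSON manifest
echoing the fully-defaulted configuration and the seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .images import ROLES, VoxelImage
from .phantoms import Fiducial, PhantomSpec
from .pipelines import StudyConfig
from .projector import SINOGRAM_KINDS, Sinogram, SinogramGeometry
from .recon import ReconConfig

__all__ = [
    "read_nifti",
    "write_nifti",
    "read_sinogram",
    "write_sinogram",
    "RunConfig",
    "load_config",
    "write_manifest",
]


# -- NIfTI ------------------------------------------------------------------


def write_nifti(image: VoxelImage, path: str | Path) -> None:
    """Write a volume as NIfTI-1 (float32), preserving spacing and origin.

    The affine is diagonal RAS with the translation set so that voxel
    centre (i, j, k) maps to ``origin + (index + 0.5) * spacing`` — i.e.
    NIfTI's voxel-centre world coordinates match this package's convention.
    The image role is stored in the ``descrip`` header field.
    """
    sp = np.asarray(image.spacing_mm)
    origin = np.asarray(image.origin_mm)
    affine = np.diag(list(sp) + [1.0])
    affine[:3, 3] = origin + 0.5 * sp
    img = nib.Nifti1Image(image.values.astype(np.float32), affine)
    img.header["descrip"] = f"petac role={image.role}".encode()
    nib.save(img, str(path))


def read_nifti(path: str | Path, role: str | None = None) -> VoxelImage:
    """Read a NIfTI-1 volume back into a :class:`VoxelImage`.

    Only scalar 3D volumes are supported.  A missing/degenerate affine
    falls back to identity spacing at the origin, with a warning.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(
            f"unsupported NIfTI layout: expected a 3D scalar volume, "
            f"got shape {data.shape} (field: dim)"
        )
    if not np.issubdtype(data.dtype, np.number):
        raise ValueError(f"unsupported NIfTI datatype {data.dtype} (field: datatype)")
    affine = img.affine
    if (
        affine is None
        or not np.all(np.isfinite(affine))
        or np.any(np.diag(affine[:3, :3]) <= 0)  # degenerate or flipped axes
    ):
        warnings.warn(
            "NIfTI affine missing, degenerate or axis-flipped; assuming "
            "1 mm spacing at origin",
            stacklevel=2,
        )
        spacing = (1.0, 1.0, 1.0)
        origin = (-0.5, -0.5, -0.5)
    else:
        lin = affine[:3, :3]
        if not np.allclose(lin, np.diag(np.diag(lin)), atol=1e-6):
            raise ValueError("only axis-aligned (diagonal-affine) NIfTI is supported")
        spacing = tuple(float(abs(d)) for d in np.diag(lin))
        origin = tuple(affine[:3, 3] - 0.5 * np.asarray(spacing))
    if role is None:
        descrip = img.header["descrip"].tobytes().decode(errors="ignore")
        role = "activity"
        for r in ROLES:
            if f"role={r}" in descrip:
                role = r
                break
    return VoxelImage(np.asarray(data, dtype=np.float64), spacing, origin, role)


# -- sinograms --------------------------------------------------------------


def write_sinogram(sino: Sinogram, path: str | Path) -> None:
    """Raw float32 little-endian array plus a ``.json`` geometry sidecar."""
    path = Path(path)
    sino.values.astype("<f4").tofile(path)
    sidecar = {
        "n_angles": sino.geometry.n_angles,
        "n_bins": sino.geometry.n_bins,
        "bin_width_mm": sino.geometry.bin_width_mm,
        "n_slices": sino.n_slices,
        "angle_range": "[0,pi)",
        "kind": sino.kind,
        "dtype": "<f4",
        "order": "C (angle, bin, slice)",
    }
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2)


def read_sinogram(path: str | Path) -> Sinogram:
    path = Path(path)
    with open(path.with_suffix(path.suffix + ".json")) as fh:
        meta = json.load(fh)
    geom = SinogramGeometry(meta["n_angles"], meta["n_bins"], meta["bin_width_mm"])
    raw = np.fromfile(path, dtype="<f4")
    expected = meta["n_angles"] * meta["n_bins"] * meta["n_slices"]
    if raw.size != expected:
        raise ValueError(
            f"sinogram file holds {raw.size} values but sidecar promises {expected}"
        )
    values = raw.astype(np.float64).reshape(
        meta["n_angles"], meta["n_bins"], meta["n_slices"]
    )
    if meta["kind"] not in SINOGRAM_KINDS:
        raise ValueError(f"sidecar kind {meta['kind']!r} is not a sinogram kind")
    return Sinogram(values, geom, kind=meta["kind"])


# -- configuration ----------------------------------------------------------


@dataclass
class RunConfig:
    """Fully-defaulted configuration for the pipeline runners."""

    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    geometry: SinogramGeometry = field(default_factory=SinogramGeometry)
    recon: ReconConfig = field(default_factory=ReconConfig)
    study: StudyConfig = field(default_factory=StudyConfig)
    seed: int = 0


def _build_section(cls, data: dict, section: str):
    spec = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(spec)
    if unknown:
        raise ValueError(
            f"unknown key(s) {sorted(unknown)} in section {section!r}; "
            f"allowed: {sorted(spec)}"
        )
    coerced = {}
    for key, value in data.items():
        ftype = str(spec[key].type)
        # YAML 1.1 reads "2.0e5" (no signed exponent) as a string
        if ftype.startswith("float") and isinstance(value, (str, int)):
            value = float(value)
        elif ftype.startswith("int") and isinstance(value, str):
            value = int(value)
        elif ftype.startswith("tuple") and isinstance(value, list):
            value = tuple(value)
        coerced[key] = value
    return cls(**coerced)


def load_config(path: str | Path | None = None, text: str | None = None) -> RunConfig:
    """Load and validate a YAML run configuration.

    Sections ``phantom``, ``geometry``, ``recon``, ``study`` plus a
    top-level ``seed``; every key is optional (defaults are materialised),
    unknown keys are rejected by name.
    """
    if text is None:
        text = Path(path).read_text() if path is not None else ""
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError("configuration root must be a mapping")
    known = {"phantom", "geometry", "recon", "study", "seed"}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown top-level key(s) {sorted(unknown)}")
    phantom_data = dict(data.get("phantom") or {})
    fid_data = phantom_data.pop("fiducials", None)
    phantom = _build_section(PhantomSpec, phantom_data, "phantom")
    if fid_data:
        phantom.fiducials = tuple(
            _build_section(Fiducial, dict(f), "phantom.fiducials") for f in fid_data
        )
        for f in phantom.fiducials:
            object.__setattr__(f, "center_mm", tuple(f.center_mm))
    return RunConfig(
        phantom=phantom,
        geometry=_build_section(SinogramGeometry, dict(data.get("geometry") or {}), "geometry"),
        recon=_build_section(ReconConfig, dict(data.get("recon") or {}), "recon"),
        study=_build_section(StudyConfig, dict(data.get("study") or {}), "study"),
        seed=int(data.get("seed", 0)),
    )


def config_to_dict(cfg: RunConfig) -> dict:
    d = asdict(cfg)
    d["phantom"]["fiducials"] = [asdict(f) for f in cfg.phantom.fiducials]
    return d


def write_manifest(cfg: RunConfig, path: str | Path, **extra) -> None:
    """JSON manifest: the complete materialised configuration plus extras."""
    manifest = {"config": config_to_dict(cfg)}
    manifest.update(extra)

    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        return str(o)

    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=_default)
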