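"""Volume data model, file I/O and the preprocessing chain.

Volumes are 3D voxel grids with isotropic spacing. Throughout the package
axis 2 is the specimen's long (loading) axis and slice index 0 is the
proximal face. Grayscale data is density-calibrated in mg HA/cm^3.

Supported on-disk dialects:

* NIfTI (``.nii``/``.nii.gz``) — spacing taken from the header zooms,
  which are stored in millimetres.
* multi-page TIFF — pages are slices along axis 2; spacing comes from a
  JSON sidecar ``<stem>.json`` containing ``{"spacing_um": <float>}``.
* raw little-endian array + JSON metadata
  ``{"shape", "dtype", "spacing_um", "axis_order"}`` — the fixture
  dialect; round-trips bit-exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "DensityVolume",
    "BinaryVolume",
    "PreprocessParams",
    "SpecimenMask",
    "read_volume",
    "write_volume",
    "smooth",
    "binarize",
    "cylinder_mask",
    "bvtv",
]

#: loading axis (specimen long axis); index 0 along it = proximal face
LOADING_AXIS = 2


def _check_grid(data: np.ndarray, spacing: float) -> None:
    if data.ndim != 3 or data.size == 0:
        raise ValueError("volume grid must be a non-empty 3D array")
    if not (spacing > 0):
        raise ValueError("voxel spacing must be positive")


@dataclass
class DensityVolume:
    """Density-calibrated grayscale grid (mg HA/cm^3), isotropic spacing in um."""

    data: np.ndarray
    spacing: float  # um

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        _check_grid(self.data, self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class BinaryVolume:
    """Segmented bone/background grid, same axis convention as DensityVolume."""

    data: np.ndarray
    spacing: float  # um

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        _check_grid(self.data, self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def count(self) -> int:
        return int(self.data.sum())


@dataclass
class PreprocessParams:
    """Gaussian smoothing sigma (voxels) and segmentation threshold (mg HA/cm^3)."""

    gaussian_sigma: float = 1.2
    threshold: float = 800.0

    def __post_init__(self) -> None:
        if self.gaussian_sigma < 0:
            raise ValueError("gaussian_sigma must be >= 0")
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")


@dataclass
class SpecimenMask:
    """Total-volume (TV) mask, typically a cylinder matching the specimen."""

    data: np.ndarray
    spacing: float  # um
    diameter: float | None = None  # mm; None for non-cylindrical masks
    length: float | None = None  # mm

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        _check_grid(self.data, self.spacing)

    def count(self) -> int:
        return int(self.data.sum())

    def pair_check(self, b: BinaryVolume) -> None:
        """Assert the mask covers the foreground of ``b`` (pairing contract)."""
        if b.data.shape != self.data.shape:
            raise ValueError("mask and volume shapes differ")
        if np.any(b.data & ~self.data):
            raise ValueError("mask does not cover the volume's foreground")


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_FORMATS = ("nifti", "tiff", "raw+json")


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json") if path.suffix != ".json" else path


def read_volume(path: str | Path, format: str | None = None) -> DensityVolume:
    """Read a 3D volume with its spacing metadata.

    A missing spacing declaration is an explicit error; there is no silent
    default voxel size.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "nifti":
        import nibabel as nib

        img = nib.load(str(path))
        zooms = img.header.get_zooms()[:3]
        if not all(z > 0 for z in zooms):
            raise ValueError("spacing required: NIfTI header has no positive zooms")
        if max(zooms) - min(zooms) > 1e-6 * max(zooms):
            raise ValueError("anisotropic NIfTI spacing is not supported")
        data = np.asarray(img.dataobj, dtype=np.float64)
        return DensityVolume(data, spacing=float(zooms[0]) * 1000.0)
    if fmt == "tiff":
        import tifffile

        meta = _sidecar(path)
        if not meta.exists():
            raise ValueError(f"spacing required: no JSON sidecar {meta.name}")
        spacing = float(json.loads(meta.read_text())["spacing_um"])
        pages = tifffile.imread(str(path))  # (z, y, x)
        data = np.ascontiguousarray(np.transpose(pages, (2, 1, 0)).astype(np.float64))
        return DensityVolume(data, spacing=spacing)
    if fmt == "raw+json":
        meta_path = _sidecar(path)
        if not meta_path.exists():
            raise ValueError(f"spacing required: no JSON metadata {meta_path.name}")
        meta = json.loads(meta_path.read_text())
        if "spacing_um" not in meta:
            raise ValueError("spacing required: metadata lacks 'spacing_um'")
        raw = path.with_suffix(".raw")
        arr = np.fromfile(raw, dtype=np.dtype(meta["dtype"]).newbyteorder("<"))
        arr = arr.reshape(meta["shape"])
        if meta.get("axis_order", "xyz") != "xyz":
            raise ValueError("only 'xyz' axis_order is supported")
        return DensityVolume(arr.astype(np.float64), spacing=float(meta["spacing_um"]))
    raise ValueError(f"unsupported format {fmt!r}; supported: {_FORMATS}")


def _infer_format(path: Path) -> str:
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith((".tif", ".tiff")):
        return "tiff"
    if name.endswith((".raw", ".json")):
        return "raw+json"
    raise ValueError(f"cannot infer format of {path.name!r}; supported: {_FORMATS}")


def write_volume(
    v: DensityVolume | BinaryVolume, path: str | Path, format: str | None = None
) -> None:
    """Write a volume; binary volumes are stored as 0/1."""
    path = Path(path)
    fmt = format or _infer_format(path)
    is_binary = isinstance(v, BinaryVolume)
    data = v.data.astype(np.uint8) if is_binary else np.asarray(v.data, np.float64)
    if fmt == "nifti":
        import nibabel as nib

        zoom_mm = v.spacing / 1000.0
        img = nib.Nifti1Image(data, affine=np.diag([zoom_mm, zoom_mm, zoom_mm, 1.0]))
        img.header.set_zooms((zoom_mm, zoom_mm, zoom_mm))
        nib.save(img, str(path))
        return
    if fmt == "tiff":
        import tifffile

        tifffile.imwrite(str(path), np.transpose(data, (2, 1, 0)))
        _sidecar(path).write_text(json.dumps({"spacing_um": v.spacing}))
        return
    if fmt == "raw+json":
        raw = path.with_suffix(".raw")
        arr = np.ascontiguousarray(data.astype(data.dtype.newbyteorder("<")))
        arr.tofile(raw)
        meta = {
            "shape": list(v.data.shape),
            "dtype": arr.dtype.str,
            "spacing_um": v.spacing,
            "axis_order": "xyz",
            "binary": bool(is_binary),
        }
        _sidecar(path).write_text(json.dumps(meta))
        return
    raise ValueError(f"unsupported format {fmt!r}; supported: {_FORMATS}")


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def smooth(v: DensityVolume, p: PreprocessParams) -> DensityVolume:
    """Gaussian noise filtering; reflect padding at the grid boundary."""
    if p.gaussian_sigma < 0:
        raise ValueError("gaussian_sigma must be >= 0")
    if p.gaussian_sigma == 0:
        return DensityVolume(v.data.copy(), v.spacing)
    out = ndimage.gaussian_filter(v.data, sigma=p.gaussian_sigma, mode="reflect")
    return DensityVolume(out, v.spacing)


def binarize(v: DensityVolume, p: PreprocessParams) -> BinaryVolume:
    """Threshold segmentation; a voxel is bone iff density >= threshold."""
    return BinaryVolume(v.data >= p.threshold, v.spacing)


def preprocess(v: DensityVolume, p: PreprocessParams | None = None) -> BinaryVolume:
    """smooth + binarize with the standard parameters (sigma 1.2, 800 mg HA/cm^3)."""
    p = p or PreprocessParams()
    return binarize(smooth(v, p), p)


def cylinder_mask(
    shape: tuple[int, int, int],
    spacing: float,
    diameter: float,
    length: float,
    *,
    proximal_offset: int = 0,
) -> SpecimenMask:
    """Axis-aligned cylinder mask: axis along the loading axis, radially centered.

    The cylinder occupies slices ``[proximal_offset, proximal_offset + length)``.
    A voxel belongs to the mask iff its center lies inside the cylinder.
    """
    nx, ny, nz = shape
    d_vox = diameter * 1000.0 / spacing
    l_vox = length * 1000.0 / spacing
    if d_vox > nx + 1e-9 or d_vox > ny + 1e-9:
        raise ValueError("cylinder diameter exceeds grid extent")
    if proximal_offset + l_vox > nz + 1e-9:
        raise ValueError("cylinder length exceeds grid extent")
    cx, cy = nx / 2.0, ny / 2.0
    x = np.arange(nx) + 0.5
    y = np.arange(ny) + 0.5
    r2 = (x[:, None] - cx) ** 2 + (y[None, :] - cy) ** 2
    disc = r2 <= (d_vox / 2.0) ** 2
    z = np.arange(nz) + 0.5
    zin = (z >= proximal_offset) & (z <= proximal_offset + l_vox)
    data = disc[:, :, None] & zin[None, None, :]
    return SpecimenMask(data, spacing, diameter=diameter, length=length)


def full_mask(shape: tuple[int, int, int], spacing: float) -> SpecimenMask:
    """Rectangular mask covering the whole grid (TV = bounding box)."""
    return SpecimenMask(np.ones(shape, bool), spacing)


def bvtv(b: BinaryVolume, m: SpecimenMask) -> float:
    """Conventional (unweighted) bone volume fraction BV/TV."""
    if b.data.shape != m.data.shape:
        raise ValueError("volume and mask shapes differ")
    tv = m.count()
    if tv == 0:
        raise ValueError("empty mask: BV/TV undefined")
    return float(np.count_nonzero(b.data & m.data)) / tv
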