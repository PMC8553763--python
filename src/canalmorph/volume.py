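"""Voxel volume container and file I/O.

Axis convention
---------------
Axis 0 is the slice axis, increasing coronal -> apical.  Voxels are isotropic;
the world coordinate (mm) of voxel index ``i`` along any axis is
``origin + i * voxel_size_mm``.  Only isotropic volumes are supported, matching
the isometric voxel size of the micro-CT scans this package targets.

Supported formats: multi-page TIFF stacks (one page per slice, voxel size in
the resolution tags / ImageJ metadata) and NRRD or MetaImage single files
(voxel size in the header spacing).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import SimpleITK as sitk
import tifffile

__all__ = ["VoxelVolume", "VolumeFormatError", "read_volume", "write_volume"]

#: relative spacing mismatch tolerated before a volume counts as anisotropic
_ISO_RTOL = 1e-4


class VolumeFormatError(ValueError):
    """Raised for unreadable volumes or missing/unsupported metadata."""


@dataclass
class VoxelVolume:
    """A 3D scalar grid with isotropic voxel size and world origin (mm)."""

    data: np.ndarray
    voxel_size_mm: float
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_convention: str = "slice-coronal-to-apical"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.size == 0:
            raise ValueError("volume grid must be a non-empty 3D array")
        if not self.voxel_size_mm > 0:
            raise ValueError("voxel_size_mm must be > 0")
        self.origin_mm = tuple(float(o) for o in self.origin_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def world(self, index: tuple[float, float, float]) -> np.ndarray:
        """World coordinate (mm) of a (possibly fractional) voxel index."""
        return np.asarray(self.origin_mm) + np.asarray(index, dtype=float) * self.voxel_size_mm

    def index(self, world_mm: tuple[float, float, float]) -> np.ndarray:
        """Fractional voxel index of a world coordinate (mm)."""
        return (np.asarray(world_mm, dtype=float) - np.asarray(self.origin_mm)) / self.voxel_size_mm

    def with_data(self, data: np.ndarray, origin_shift_vox: tuple[int, int, int] = (0, 0, 0)) -> "VoxelVolume":
        origin = tuple(
            o + s * self.voxel_size_mm for o, s in zip(self.origin_mm, origin_shift_vox)
        )
        return replace(self, data=data, origin_mm=origin)


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.lower()
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        return "tiff"
    if suffix == ".nrrd":
        return "nrrd"
    if suffix in (".mha", ".mhd"):
        return "mha"
    raise VolumeFormatError(f"cannot infer volume format from suffix {suffix!r}")


def read_volume(path: str | Path, fmt: str | None = None) -> VoxelVolume:
    """Read a volume from a TIFF stack or an NRRD/MetaImage file.

    The voxel size is taken from the file metadata; a file without voxel-size
    metadata raises :class:`VolumeFormatError` (never a silent default), and
    anisotropic spacings are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise VolumeFormatError(f"no such volume file: {path}")
    fmt = _infer_format(path, fmt)
    if fmt == "tiff":
        return _read_tiff(path)
    if fmt in ("nrrd", "mha", "mhd", "metaimage"):
        return _read_itk(path)
    raise VolumeFormatError(f"unsupported volume format {fmt!r}")


def write_volume(volume: VoxelVolume, path: str | Path, fmt: str | None = None) -> Path:
    """Write a volume with its voxel size and origin embedded in the metadata.

    Lossless for integer grids; floats are written at native precision.
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "tiff":
        _write_tiff(volume, path)
    elif fmt in ("nrrd", "mha", "mhd", "metaimage"):
        _write_itk(volume, path)
    else:
        raise VolumeFormatError(f"unsupported volume format {fmt!r}")
    return path


# -- TIFF ------------------------------------------------------------------

def _write_tiff(volume: VoxelVolume, path: Path) -> None:
    vx = volume.voxel_size_mm
    # resolution tags are pixels per unit; store in-plane size there and the
    # slice spacing + origin in the ImageJ metadata block.
    tifffile.imwrite(
        path,
        volume.data,
        resolution=(1.0 / vx, 1.0 / vx),
        resolutionunit="MILLIMETER",
        imagej=True,
        metadata={
            "spacing": vx,
            "unit": "mm",
            "origin_mm": list(volume.origin_mm),
        },
    )


def _read_tiff(path: Path) -> VoxelVolume:
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        if data.ndim == 2:
            data = data[None]
        page = tf.pages[0]
        res_unit = page.tags.get("ResolutionUnit")
        x_res = page.tags.get("XResolution")
        y_res = page.tags.get("YResolution")
        ij = tf.imagej_metadata or {}
    if x_res is None or y_res is None:
        raise VolumeFormatError(
            f"{path}: TIFF stack lacks XResolution/YResolution tags; "
            "voxel size metadata is required"
        )

    def _ratio(tag) -> float:
        value = tag.value
        if isinstance(value, tuple):
            num, den = value
            return num / den
        return float(value)

    unit = getattr(res_unit, "value", res_unit)
    unit_mm = {2: 25.4, 3: 10.0, 4: 1.0, 5: 0.001}  # inch, cm, mm, um per unit
    unit_code = int(unit) if unit is not None else 1
    if unit_code not in unit_mm:
        raise VolumeFormatError(f"{path}: TIFF ResolutionUnit missing or unitless")
    vx_x = unit_mm[unit_code] / _ratio(x_res)
    vx_y = unit_mm[unit_code] / _ratio(y_res)
    spacing = ij.get("spacing")
    if spacing is None:
        raise VolumeFormatError(
            f"{path}: TIFF stack lacks slice spacing metadata (ImageJ 'spacing')"
        )
    vx_z = float(spacing)
    sizes = np.array([vx_z, vx_y, vx_x])
    if not np.allclose(sizes, sizes[0], rtol=_ISO_RTOL):
        raise VolumeFormatError(
            f"{path}: anisotropic voxels {sizes.tolist()} mm are unsupported"
        )
    origin = ij.get("origin_mm", [0.0, 0.0, 0.0])
    if isinstance(origin, str):
        origin = [float(x) for x in origin.strip("[] ").split(",")]
    return VoxelVolume(data, float(sizes[0]), tuple(float(o) for o in origin))


# -- NRRD / MetaImage ------------------------------------------------------

def _write_itk(volume: VoxelVolume, path: Path) -> None:
    img = sitk.GetImageFromArray(volume.data)
    vx = volume.voxel_size_mm
    img.SetSpacing((vx, vx, vx))
    # ITK orders spacing/origin x,y,z; our arrays are z,y,x
    img.SetOrigin(tuple(reversed(volume.origin_mm)))
    sitk.WriteImage(img, str(path), useCompression=False)


def _read_itk(path: Path) -> VoxelVolume:
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:  # pragma: no cover - ITK error text varies
        raise VolumeFormatError(f"unreadable volume {path}: {exc}") from exc
    spacing = np.asarray(img.GetSpacing(), dtype=float)
    if not np.allclose(spacing, spacing[0], rtol=_ISO_RTOL):
        raise VolumeFormatError(
            f"{path}: anisotropic voxels {spacing.tolist()} mm are unsupported"
        )
    data = sitk.GetArrayFromImage(img)
    origin = tuple(reversed(img.GetOrigin()))
    return VoxelVolume(data, float(spacing[0]), tuple(float(o) for o in origin))
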