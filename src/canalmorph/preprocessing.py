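"""Dataset conditioning: maximum intensity projections, minimal cropping,
and extraction of the apical analysis window.

The apical window defaults to the most apical 3.5 mm of the tooth, the region
in which foramen metrology is performed.  Measurements downstream are carried
out natively in 3D; re-slicing is exposed only as an export convenience.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .volume import VoxelVolume

__all__ = [
    "MIPSet",
    "compute_mips",
    "crop_to_content",
    "extract_apical_window",
    "equidistant_slices",
]

log = logging.getLogger(__name__)

APICAL_WINDOW_MM = 3.5


@dataclass
class MIPSet:
    """Per-axis maximum intensity projections of one volume."""

    axial: np.ndarray      # projection along axis 0 (slice axis)
    frontal: np.ndarray    # projection along axis 1
    sagittal: np.ndarray   # projection along axis 2
    source_id: str = ""

    def __iter__(self):
        return iter((self.axial, self.frontal, self.sagittal))

    def save(self, directory, prefix: str = "mip", fmt: str = "png") -> list:
        """Export the three projections as PNG or TIFF images."""
        import imageio.v3 as iio
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = []
        for name, img in zip(("axial", "frontal", "sagittal"), self):
            path = directory / f"{prefix}_{name}.{fmt}"
            iio.imwrite(path, np.asarray(img))
            paths.append(path)
        return paths


def compute_mips(volume: VoxelVolume, source_id: str = "") -> MIPSet:
    """Maximum intensity projection along each of the three axes."""
    data = volume.data
    return MIPSet(
        axial=data.max(axis=0),
        frontal=data.max(axis=1),
        sagittal=data.max(axis=2),
        source_id=source_id,
    )


def crop_to_content(
    volume: VoxelVolume, background_level: float | None = None
) -> tuple[VoxelVolume, tuple[int, int, int]]:
    """Tight bounding box of above-background voxels.

    ``background_level`` defaults to 10% of the dominant non-background
    intensity mode (a robust stand-in for the dentin mode); pass an absolute
    value to override.  Returns the cropped volume (with a consistently
    shifted world origin) and the offset of its corner in the input grid.
    Idempotent; an all-background volume raises ``ValueError``.
    """
    data = volume.data
    if background_level is None:
        sample = data[::4, ::4, ::4].astype(np.float32)
        fg = sample[sample > sample.max() * 0.25]
        if fg.size == 0:
            raise ValueError("all-background volume: nothing to crop to")
        hist, edges = np.histogram(fg, bins=64)
        mode = 0.5 * (edges[np.argmax(hist)] + edges[np.argmax(hist) + 1])
        background_level = 0.10 * mode
    mask = data > background_level
    if not mask.any():
        raise ValueError("all-background volume: nothing to crop to")
    offset = []
    slices = []
    for axis in range(3):
        axes = tuple(i for i in range(3) if i != axis)
        profile = mask.any(axis=axes)
        idx = np.flatnonzero(profile)
        offset.append(int(idx[0]))
        slices.append(slice(int(idx[0]), int(idx[-1]) + 1))
    cropped = volume.with_data(data[tuple(slices)], tuple(offset))
    return cropped, tuple(offset)


def extract_apical_window(
    volume: VoxelVolume,
    apex_index: int,
    window_mm: float = APICAL_WINDOW_MM,
) -> VoxelVolume:
    """Sub-volume spanning ``window_mm`` coronal of the apex along the slice axis.

    ``apex_index`` is the slice index of the apex.  The window is clamped
    (with a logged warning) when it exceeds the volume extent; world
    coordinates of retained voxels are unchanged.
    """
    if window_mm <= 0:
        raise ValueError("window_mm must be > 0")
    nz = volume.shape[0]
    if not 0 <= apex_index < nz:
        raise ValueError(f"apex slice {apex_index} outside volume of {nz} slices")
    n_slices = int(round(window_mm / volume.voxel_size_mm))
    start = apex_index + 1 - n_slices
    if start < 0:
        log.warning(
            "apical window of %.2f mm exceeds the volume extent; clamping to slice 0",
            window_mm,
        )
        start = 0
    return volume.with_data(volume.data[start: apex_index + 1], (start, 0, 0))


def equidistant_slices(
    volume: VoxelVolume, apex_index: int, cej_index: int, n: int = 4
) -> list[np.ndarray]:
    """Export convenience: ``n`` equidistant axial slices between the most
    apical region and the cemento-enamel junction (not used by classification)."""
    positions = np.linspace(cej_index, apex_index, n + 1)[1:]
    return [volume.data[int(round(p))] for p in positions]
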