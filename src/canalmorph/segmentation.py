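"""Tissue labelling and anatomical landmark detection.

Voxels are classified into background, canal lumen, dentin and enamel by
3-class multi-level Otsu thresholding (manual thresholds can be supplied when
the histogram lacks three modes).  The lumen is recovered geometrically as
the cavity enclosed by the mineralised tissues: per-axial-slice hole filling
of the tooth mask, which keeps the canal separate from exterior background
even where foramina open the cavity to the outside.

Landmarks: the CEJ is operationalised as the most apical slice containing
enamel, the apex as the most apical dentin voxel, and the DEJ as the most
apical enamel-dentin contact.  Root thirds divide the CEJ-to-apex span into
three equal parts; two-rooted teeth get per-root apices and third limits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_multiotsu

from .volume import VoxelVolume

__all__ = [
    "TissueLabels",
    "Landmarks",
    "ThirdBoundaries",
    "RootInfo",
    "SegmentationError",
    "segment_tissues",
    "detect_landmarks",
    "split_root_thirds",
    "detect_roots",
]

log = logging.getLogger(__name__)

LABEL_BACKGROUND, LABEL_LUMEN, LABEL_DENTIN, LABEL_ENAMEL = 0, 1, 2, 3

_MIN_LUMEN_VOXELS = 60      # 3D specks below this are noise, not canal
_MIN_ROOT_AREA_PX = 40      # 2D dentin islands below this do not count as a root


class SegmentationError(ValueError):
    """Raised when a volume cannot be segmented into the expected tissues."""


@dataclass
class TissueLabels:
    """Label volume (0 bg, 1 lumen, 2 dentin, 3 enamel) plus grid metadata."""

    labels: np.ndarray
    voxel_size_mm: float
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    thresholds: tuple[float, float] | None = None

    @property
    def lumen(self) -> np.ndarray:
        return self.labels == LABEL_LUMEN

    @property
    def dentin(self) -> np.ndarray:
        return self.labels == LABEL_DENTIN

    @property
    def enamel(self) -> np.ndarray:
        return self.labels == LABEL_ENAMEL

    def z_mm(self, k: int | np.ndarray) -> float | np.ndarray:
        return self.origin_mm[0] + np.asarray(k) * self.voxel_size_mm


@dataclass
class Landmarks:
    apex_index: int
    cej_index: int
    dej_index: int
    apex_mm: float
    cej_mm: float
    dej_mm: float


@dataclass
class ThirdBoundaries:
    """Coronal limits of the coronal/middle/apical thirds of one root (mm)."""

    cej_mm: float
    apex_mm: float

    @property
    def span_mm(self) -> float:
        return self.apex_mm - self.cej_mm

    @property
    def limits_mm(self) -> tuple[float, float, float]:
        L = self.span_mm
        return (self.cej_mm, self.cej_mm + L / 3.0, self.cej_mm + 2.0 * L / 3.0)

    def third_of(self, z_mm: float) -> str:
        L = self.span_mm
        rel = (z_mm - self.cej_mm) / L if L > 0 else 0.0
        if rel < 1.0 / 3.0:
            return "coronal"
        if rel < 2.0 / 3.0:
            return "middle"
        return "apical"


@dataclass
class RootInfo:
    """Root count, per-root apices and the two-rooted territory split."""

    count: int
    bifurcation_index: int | None
    bifurcation_third: str | None
    apex_indices: list[int]
    labels_order: list[str]                       # 'single' or ['buccal', 'lingual']
    split_point: np.ndarray | None = None         # (y, x) px on the bisector
    split_normal: np.ndarray | None = None        # (y, x) unit vector toward root 1

    def side(self, yx: np.ndarray) -> int:
        """0 for the first root (buccal), 1 for the second (lingual)."""
        if self.count == 1:
            return 0
        return int(np.dot(np.asarray(yx, dtype=float) - self.split_point,
                          self.split_normal) > 0)


# -- tissue segmentation ---------------------------------------------------

def segment_tissues(
    volume: VoxelVolume,
    thresholds: tuple[float, float] | None = None,
    presmooth_sigma: float = 0.5,
) -> TissueLabels:
    """Classify voxels into background / lumen / dentin / enamel.

    Thresholds default to 3-class multi-Otsu on the volume histogram; supply
    ``(low, high)`` manually when the histogram lacks three modes.  The lumen
    is the enclosed cavity of the largest mineralised component, recovered by
    per-slice hole filling, so it stays distinct from exterior background
    even where the canal opens at a foramen.
    """
    data = volume.data.astype(np.float32)
    if presmooth_sigma > 0:
        data = ndimage.gaussian_filter(data, presmooth_sigma)
    if thresholds is None:
        try:
            t1, t2 = threshold_multiotsu(data[::2, ::2, ::2], classes=3)
        except ValueError as exc:
            raise SegmentationError(
                "histogram does not separate into three intensity classes; "
                "supply manual thresholds"
            ) from exc
        if t2 - t1 < 1e-6:
            raise SegmentationError(
                "degenerate multi-Otsu thresholds; supply manual thresholds"
            )
    else:
        t1, t2 = thresholds

    mineral = data > t1
    if not mineral.any():
        raise SegmentationError("no tooth: no voxels above the low threshold")
    # largest 6-connected mineralised component is the tooth
    comp, n = ndimage.label(mineral, structure=ndimage.generate_binary_structure(3, 1))
    if n == 0:
        raise SegmentationError("no tooth: no mineralised component")
    sizes = np.bincount(comp.ravel())
    sizes[0] = 0
    tooth = comp == int(np.argmax(sizes))

    enamel = tooth & (data > t2)
    # enclosed cavity: per-axial-slice hole fill of the tooth cross-section
    cavity = np.zeros_like(tooth)
    for k in range(tooth.shape[0]):
        sl = tooth[k]
        if sl.any():
            cavity[k] = ndimage.binary_fill_holes(sl) & ~sl
    # retain 26-connected cavity components of meaningful size
    comp, n = ndimage.label(cavity, structure=ndimage.generate_binary_structure(3, 3))
    lumen = np.zeros_like(cavity)
    if n:
        sizes = np.bincount(comp.ravel())
        keep = np.flatnonzero(sizes >= _MIN_LUMEN_VOXELS)
        keep = keep[keep != 0]
        if keep.size:
            lumen = np.isin(comp, keep)

    labels = np.zeros(volume.shape, dtype=np.uint8)
    labels[tooth] = LABEL_DENTIN
    labels[enamel] = LABEL_ENAMEL
    labels[lumen] = LABEL_LUMEN
    if not lumen.any():
        log.warning("empty lumen: no canal will be reported for this volume")
    return TissueLabels(labels, volume.voxel_size_mm, volume.origin_mm, (float(t1), float(t2)))


# -- landmarks -------------------------------------------------------------

def detect_landmarks(tissue: TissueLabels, cej_index: int | None = None) -> Landmarks:
    """Apex (most apical dentin), CEJ (most apical enamel slice), DEJ extent.

    Decoronated inputs (no enamel) need ``cej_index`` from configuration,
    otherwise an error is raised.
    """
    dentin_per_slice = (tissue.labels >= LABEL_DENTIN).any(axis=(1, 2))
    if not dentin_per_slice.any():
        raise SegmentationError("no dentin found; cannot place the apex")
    apex_index = int(np.flatnonzero(dentin_per_slice)[-1])

    enamel_per_slice = tissue.enamel.any(axis=(1, 2))
    if enamel_per_slice.any():
        detected_cej = int(np.flatnonzero(enamel_per_slice)[-1])
    elif cej_index is None:
        raise SegmentationError(
            "no enamel voxels (decoronated tooth?); supply the CEJ slice via config"
        )
    else:
        detected_cej = None
    cej = int(cej_index) if cej_index is not None else detected_cej

    # DEJ: most apical slice with enamel-dentin contact
    dej = cej
    enamel_slices = np.flatnonzero(enamel_per_slice)[::-1] if enamel_per_slice.any() else []
    for k in enamel_slices:
        if (ndimage.binary_dilation(tissue.enamel[k]) & tissue.dentin[k]).any():
            dej = int(k)
            break
    return Landmarks(
        apex_index=apex_index, cej_index=cej, dej_index=dej,
        apex_mm=float(tissue.z_mm(apex_index)),
        cej_mm=float(tissue.z_mm(cej)),
        dej_mm=float(tissue.z_mm(dej)),
    )


def split_root_thirds(
    cej_mm: float, apex_mm: float, voxel_size_mm: float
) -> ThirdBoundaries:
    """Divide the CEJ->apex span into three equal thirds."""
    if apex_mm <= cej_mm:
        raise SegmentationError("apex must be apical of the CEJ")
    if (apex_mm - cej_mm) / voxel_size_mm < 9:
        raise SegmentationError("degenerate root span (< 9 voxels)")
    return ThirdBoundaries(cej_mm=cej_mm, apex_mm=apex_mm)


# -- roots -----------------------------------------------------------------

def detect_roots(tissue: TissueLabels, landmarks: Landmarks) -> RootInfo:
    """Root count and bifurcation third from per-slice dentin components.

    A tooth counts as two-rooted when the dentin cross-section splits into
    two sustained components below the CEJ; three or more components raise an
    unsupported-anatomy error.  For two roots the returned territory split is
    the perpendicular bisector of the root centroids; the buccal label goes
    to the root on the lower second-axis side (orientation metadata).
    """
    mineral = tissue.labels >= LABEL_DENTIN
    structure = np.ones((3, 3), dtype=bool)
    counts = np.zeros(tissue.labels.shape[0], dtype=int)
    first_two = None
    for k in range(landmarks.cej_index, landmarks.apex_index + 1):
        comp, n = ndimage.label(mineral[k], structure=structure)
        if n > 1:
            sizes = np.bincount(comp.ravel())[1:]
            n = int((sizes >= _MIN_ROOT_AREA_PX).sum())
        counts[k] = n
    sustained = 8
    for k in range(landmarks.cej_index, landmarks.apex_index - sustained + 1):
        window = counts[k: k + sustained]
        if (window >= 3).all():
            raise SegmentationError(
                f"{window.max()} dentin components near slice {k}: anatomies with "
                "more than two roots are unsupported"
            )
        if first_two is None and (window == 2).all():
            first_two = k
    if first_two is None:
        return RootInfo(1, None, None, [landmarks.apex_index], ["single"])

    # two-rooted: centroids a little below the bifurcation define the split
    probe = min(first_two + 15, landmarks.apex_index)
    comp, n = ndimage.label(mineral[probe], structure=structure)
    sizes = np.bincount(comp.ravel())
    order = np.argsort(sizes[1:])[::-1][:2] + 1
    c0 = np.array(ndimage.center_of_mass(comp == order[0]))
    c1 = np.array(ndimage.center_of_mass(comp == order[1]))
    if c0[0] > c1[0]:   # sort by second axis (y): buccal = lower y
        c0, c1 = c1, c0
    midpoint = (c0 + c1) / 2.0
    normal = (c1 - c0) / np.linalg.norm(c1 - c0)

    info = RootInfo(
        count=2,
        bifurcation_index=first_two,
        bifurcation_third=None,
        apex_indices=[landmarks.apex_index, landmarks.apex_index],
        labels_order=["buccal", "lingual"],
        split_point=midpoint,
        split_normal=normal,
    )
    # per-root apices: last slice with dentin on each side of the bisector
    for side in (0, 1):
        apex_k = first_two
        for k in range(first_two, landmarks.apex_index + 1):
            ys, xs = np.nonzero(mineral[k])
            if ys.size == 0:
                break
            sides = (np.stack([ys, xs], axis=1) - midpoint) @ normal > 0
            if (sides == bool(side)).sum() >= _MIN_ROOT_AREA_PX:
                apex_k = k
        info.apex_indices[side] = apex_k
    thirds = ThirdBoundaries(landmarks.cej_mm, float(tissue.z_mm(max(info.apex_indices))))
    info.bifurcation_third = thirds.third_of(float(tissue.z_mm(first_two)))
    return info
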