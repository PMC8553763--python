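"""Apical foramen metrology.

Locates the physiological foramen (the apical constriction, i.e. the
narrowest cross-section of a canal near its exit) and the anatomical foramen
(the external opening), measures the wide (W) and narrow (N) Feret diameters
of the constriction from a sub-voxel contour, the constriction-to-opening
distance D, and classifies each opening:

* physiological iff the wide diameter W >= 0.2 mm, accessory otherwise
  (the threshold is applied to W: reported narrow diameters of physiological
  foramina go well below 0.2 mm, so the criterion cannot be on N);
* shape irregular when the contour's relative ellipse-fit residual exceeds a
  tolerance, else oval when W - N >= 0.02 mm, else round.

Cross-sections are taken normal to the local canal direction so oblique exits
are not overestimated; contours are extracted at the half-way iso-level
between lumen and dentin intensity, giving sub-voxel localisation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure as skmeasure

__all__ = [
    "CrossSection",
    "ForamenRecord",
    "feret_diameters",
    "ellipse_fit_residual",
    "extract_cross_section",
    "cross_section_from_mask",
    "measure_foramen",
    "classify_opening",
    "classify_shape",
    "locate_foramen_pair",
]

log = logging.getLogger(__name__)

FORAMEN_DIAMETER_MM = 0.2     #: physiological/accessory split on the wide diameter
OVAL_DELTA_MM = 0.02          #: W - N at or above which a foramen is oval
IRREGULAR_RESIDUAL = 0.08     #: relative ellipse-fit residual above which shape is irregular


@dataclass
class CrossSection:
    """A planar canal cross-section: sub-voxel contour in plane coordinates."""

    contour_mm: np.ndarray                 # (n, 2) closed polygon, plane (u, v) mm
    center_idx: np.ndarray                 # (3,) fractional voxel index of plane center
    normal: np.ndarray                     # (3,) unit plane normal (voxel index space)
    basis: np.ndarray                      # (2, 3) plane axes u, v in index space
    voxel_size_mm: float
    touches_border: bool = False

    @property
    def area_mm2(self) -> float:
        return abs(_shoelace(self.contour_mm))

    @property
    def centroid_idx(self) -> np.ndarray:
        """Contour centroid as a fractional voxel index in the volume."""
        cu, cv = _polygon_centroid(self.contour_mm)
        offset = (cu * self.basis[0] + cv * self.basis[1]) / self.voxel_size_mm
        return self.center_idx + offset


@dataclass
class ForamenRecord:
    """One apical opening with its constriction metrology."""

    exit_id: int
    constriction_mm: tuple[float, float, float]
    opening_mm: tuple[float, float, float]
    wide_mm: float
    narrow_mm: float
    distance_mm: float
    klass: str                              # physiological | accessory
    shape: str | None = None                # oval | round | irregular (physiological only)
    residual: float = float("nan")
    root_label: str = "single"
    third: str | None = None
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "exit_id": self.exit_id,
            "constriction_mm": list(self.constriction_mm),
            "opening_mm": list(self.opening_mm),
            "W_mm": round(self.wide_mm, 3),
            "N_mm": round(self.narrow_mm, 3),
            "D_mm": round(self.distance_mm, 3),
            "class": self.klass,
            "shape": self.shape,
            "residual": None if np.isnan(self.residual) else round(float(self.residual), 4),
            "root": self.root_label,
            "third": self.third,
            "flags": list(self.flags),
        }


# -- geometry primitives ---------------------------------------------------

def _shoelace(poly: np.ndarray) -> float:
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _polygon_centroid(poly: np.ndarray) -> tuple[float, float]:
    x, y = poly[:, 0], poly[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    area = 0.5 * cross.sum()
    if abs(area) < 1e-12:
        return float(x.mean()), float(y.mean())
    cx = ((x + xn) * cross).sum() / (6.0 * area)
    cy = ((y + yn) * cross).sum() / (6.0 * area)
    return float(cx), float(cy)


def feret_diameters(points: np.ndarray) -> tuple[float, float]:
    """Exact maximum and minimum Feret diameters of a planar point set.

    The maximum Feret diameter is the largest pairwise distance between convex
    hull vertices; the minimum is the smallest width over hull edge normals
    (rotating-calipers width of the convex hull), which is exact for convex
    polygons and for Feret purposes in general, since Feret diameters of a set
    equal those of its convex hull.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        raise ValueError("need at least 2 points for Feret diameters")
    try:
        from scipy.spatial import ConvexHull

        hull = pts[ConvexHull(pts).vertices]
    except Exception:  # collinear/degenerate input
        hull = pts
    diff = hull[:, None, :] - hull[None, :, :]
    w_max = float(np.sqrt((diff ** 2).sum(-1)).max())
    # min width: for each hull edge, extent of projections on the edge normal
    edges = np.roll(hull, -1, axis=0) - hull
    lengths = np.linalg.norm(edges, axis=1)
    good = lengths > 1e-12
    if not good.any():
        return w_max, 0.0
    normals = np.stack([-edges[good, 1], edges[good, 0]], axis=1) / lengths[good, None]
    proj = hull @ normals.T
    widths = proj.max(axis=0) - proj.min(axis=0)
    return w_max, float(widths.min())


def ellipse_fit_residual(points: np.ndarray) -> float:
    """Relative RMS deviation of a contour from its best-fit ellipse.

    Normalised by the geometric mean of the fitted semi-axes so the value is
    scale-free.  Returns ``inf`` when no ellipse can be fitted.
    """
    pts = np.asarray(points, dtype=float)
    try:
        model = skmeasure.EllipseModel.from_estimate(pts)
    except Exception:
        return float("inf")
    if not model:
        return float("inf")
    a, b = model.axis_lengths
    if a <= 0 or b <= 0:
        return float("inf")
    res = model.residuals(pts)
    return float(np.sqrt(np.mean(res ** 2)) / np.sqrt(a * b))


# -- cross-section extraction ---------------------------------------------

def _plane_basis(normal: np.ndarray) -> np.ndarray:
    n = normal / np.linalg.norm(normal)
    helper = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(n, helper)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    return np.stack([u, v])


def _point_in_poly(poly: np.ndarray, point: tuple[float, float]) -> bool:
    x, y = point
    px, py = poly[:, 0], poly[:, 1]
    qx, qy = np.roll(px, -1), np.roll(py, -1)
    crossing = ((py > y) != (qy > y)) & (
        x < px + (y - py) * (qx - px) / np.where(qy == py, np.inf, qy - py)
    )
    return bool(np.count_nonzero(crossing) % 2)


def extract_cross_section(
    data: np.ndarray,
    voxel_size_mm: float,
    center_idx: np.ndarray,
    normal: np.ndarray,
    iso_level: float,
    half_extent_mm: float = 0.8,
    step_mm: float | None = None,
    smooth_sigma_px: float = 0.8,
    lumen_is_low: bool = True,
) -> CrossSection | None:
    """Resample a plane normal to ``normal`` and contour the canal at ``iso_level``.

    Returns the closed contour that encloses the plane center (the canal the
    plane was anchored on), or ``None`` when no such contour exists.
    """
    if step_mm is None:
        step_mm = voxel_size_mm / 2.0
    basis = _plane_basis(np.asarray(normal, dtype=float))
    n_half = int(np.ceil(half_extent_mm / step_mm))
    coords_1d = np.arange(-n_half, n_half + 1) * (step_mm / voxel_size_mm)
    uu, vv = np.meshgrid(coords_1d, coords_1d, indexing="ij")
    sample = (
        np.asarray(center_idx, dtype=float)[:, None, None]
        + basis[0][:, None, None] * uu
        + basis[1][:, None, None] * vv
    )
    if data.dtype != np.float32:
        data = data.astype(np.float32)
    cval = np.max(data) if lumen_is_low else np.min(data)
    plane = ndimage.map_coordinates(
        data, sample, order=1, mode="constant", cval=float(cval)
    )
    if smooth_sigma_px > 0:
        plane = ndimage.gaussian_filter(plane, smooth_sigma_px * voxel_size_mm / step_mm)
    contours = skmeasure.find_contours(plane, iso_level)
    center_px = float(n_half)
    best = None
    for contour in contours:
        closed = np.allclose(contour[0], contour[-1])
        if not closed:
            continue
        if _point_in_poly(contour, (center_px, center_px)):
            if best is None or abs(_shoelace(contour)) < abs(_shoelace(best)):
                best = contour
    touches = False
    if best is None:
        # open contour through the center region: plane window clipped
        for contour in contours:
            if np.linalg.norm(contour - [center_px, center_px], axis=1).min() < n_half:
                best = contour
                touches = True
                break
    if best is None:
        return None
    contour_mm = (best - center_px) * step_mm
    return CrossSection(
        contour_mm=contour_mm,
        center_idx=np.asarray(center_idx, dtype=float),
        normal=np.asarray(normal, dtype=float) / np.linalg.norm(normal),
        basis=basis,
        voxel_size_mm=voxel_size_mm,
        touches_border=touches,
    )


def cross_section_from_mask(mask: np.ndarray, voxel_size_mm: float) -> CrossSection | None:
    """Cross-section from a 2D boolean mask (iso-level 0.5 contour)."""
    data3 = mask.astype(np.float32)[None]
    center = np.array([0.0, *np.argwhere(mask).mean(axis=0)])
    return extract_cross_section(
        data3,
        voxel_size_mm,
        center,
        normal=np.array([1.0, 0.0, 0.0]),
        iso_level=0.5,
        half_extent_mm=voxel_size_mm * max(mask.shape),
        step_mm=voxel_size_mm / 2.0,
        smooth_sigma_px=0.0,
        lumen_is_low=False,
    )


# -- measurement and classification ---------------------------------------

def measure_foramen(section: CrossSection) -> tuple[float, float, float]:
    """Wide and narrow Feret diameters (mm) and relative ellipse residual."""
    wide, narrow = feret_diameters(section.contour_mm)
    residual = ellipse_fit_residual(section.contour_mm)
    return wide, narrow, residual


def classify_opening(wide_mm: float, threshold_mm: float = FORAMEN_DIAMETER_MM) -> str:
    """Physiological iff the wide diameter is >= the threshold (boundary inclusive)."""
    return "physiological" if wide_mm >= threshold_mm else "accessory"


def classify_shape(
    wide_mm: float,
    narrow_mm: float,
    residual: float,
    oval_delta_mm: float = OVAL_DELTA_MM,
    irregular_residual: float = IRREGULAR_RESIDUAL,
) -> str:
    """Irregular above the residual tolerance; else oval iff W - N >= 0.02 mm."""
    if residual > irregular_residual:
        return "irregular"
    if wide_mm - narrow_mm >= oval_delta_mm:
        return "oval"
    return "round"


def locate_foramen_pair(
    data: np.ndarray,
    voxel_size_mm: float,
    path_idx: np.ndarray,
    iso_level: float,
    window_mm: float = 3.5,
    smooth_sigma_px: float = 0.8,
) -> tuple[CrossSection | None, CrossSection | None, float, list[str]]:
    """Constriction and anatomical-opening cross-sections along a terminal path.

    ``path_idx`` is the canal centerline near one exit, ordered interior ->
    exit (last point on the lumen-exterior interface).  The constriction is
    the minimal-area cross-section along the path (restricted to the apical
    ``window_mm``); the anatomical opening is the cross-section at the exit;
    D is the Euclidean distance between the two centroids.  A monotonically
    flaring exit (minimum at the opening) yields D = 0 with a flag.
    """
    path = np.asarray(path_idx, dtype=float)
    if len(path) < 2:
        raise ValueError("terminal path needs at least two points")
    # restrict to the apical window measured back from the exit along the path
    steps = np.linalg.norm(np.diff(path, axis=0), axis=1) * voxel_size_mm
    arc_from_exit = np.concatenate([[0.0], np.cumsum(steps[::-1])])[::-1]
    keep = arc_from_exit <= window_mm
    path = path[keep]

    # smooth the centerline: skeleton voxels zigzag by half a voxel, which
    # would tilt the sampling planes and inflate cross-section areas.  The
    # opening position itself stays exact (the path end is the lumen-exterior
    # contact centroid), but tangents come from the smoothed curve only, so
    # the restored endpoint cannot tilt the terminal sampling planes.
    opening_pos = path[-1].copy()
    if len(path) >= 5:
        path = ndimage.uniform_filter1d(path, size=7, axis=0, mode="nearest")
    tangents = np.gradient(path, axis=0)
    norms = np.linalg.norm(tangents, axis=1)
    bad = norms < 1e-9
    for i in np.flatnonzero(bad):
        j = i - 1 if i > 0 else i + 1
        tangents[i] = tangents[j]
        norms[i] = np.linalg.norm(tangents[i]) or 1.0
    tangents = tangents / norms[:, None]

    data32 = data if data.dtype == np.float32 else data.astype(np.float32)
    sections: list[CrossSection | None] = [None] * len(path)
    areas = np.full(len(path), np.nan)

    def eval_at(i: int) -> None:
        if sections[i] is not None or not np.isnan(areas[i]):
            return
        section = extract_cross_section(
            data32, voxel_size_mm, path[i], tangents[i], iso_level,
            smooth_sigma_px=smooth_sigma_px,
        )
        sections[i] = section
        if section is not None and not section.touches_border:
            areas[i] = section.area_mm2
        else:
            areas[i] = np.inf

    # coarse pass every other point, then refine around the coarse minimum
    stride = 2 if len(path) > 40 else 1
    for i in range(0, len(path), stride):
        eval_at(i)
    eval_at(len(path) - 1)
    finite = np.where(np.isfinite(areas) & ~np.isnan(areas))[0]
    if stride > 1 and finite.size:
        best = int(finite[np.argmin(areas[finite])])
        for i in range(max(0, best - 3), min(len(path), best + 4)):
            eval_at(i)
    areas[np.isinf(areas)] = np.nan

    flags: list[str] = []
    valid = np.isfinite(areas)
    if not valid.any():
        return None, None, float("nan"), ["no-measurable-cross-section"]
    # 3-tap smoothing of the area profile suppresses noise-driven argmin jitter
    smoothed = areas.copy()
    idx = np.flatnonzero(valid)
    if idx.size >= 3:
        vals = areas[idx]
        sm = vals.copy()
        sm[1:-1] = 0.25 * vals[:-2] + 0.5 * vals[1:-1] + 0.25 * vals[2:]
        smoothed[idx] = sm
    i_open = int(idx[-1])
    opening = sections[i_open]
    # constriction candidates stay clear of the surface: contours within
    # ~2.5 voxels of the opening are distorted by the exit flare meeting the
    # root surface.  D is measured to the path end (the lumen-exterior
    # contact centroid), since the opening contour may clip at the surface.
    dist_to_end = np.linalg.norm(path - opening_pos, axis=1)
    candidates = idx[dist_to_end[idx] > 2.6]
    if candidates.size == 0:
        candidates = idx
    i_min = int(candidates[np.argmin(smoothed[candidates])])
    constriction = sections[i_min]
    if i_min == candidates.max() and dist_to_end[i_min] < 4.5:
        flags.append("flaring-exit-no-interior-constriction")
        distance = 0.0
    else:
        distance = float(
            np.linalg.norm(constriction.centroid_idx - opening_pos) * voxel_size_mm
        )
    return constriction, opening, distance, flags
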