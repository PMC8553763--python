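"""Synthetic voxel tooth phantoms with fully known canal topology.

A phantom is a grayscale micro-CT-like volume of a single- or two-rooted
tooth whose canal system realises a prescribed four-digit RCC code per root:
the canal count equals the code digits at the coronal limits of the coronal,
middle and apical root thirds, splits/merges happen strictly inside the third
in which the digit transition occurs, and each physiological foramen exits
through an elliptic constriction with prescribed wide/narrow axes placed a
prescribed distance above the anatomical opening.  Accessory canals (thin
branches to the root surface) and connecting canals (loop-type L within one
canal, communicating C between two canals) can be added per third.

Intensities follow the radiographic ordering enamel > dentin > lumen, with
the pulp space as radiolucent as background; edges are rendered with
partial-volume (coverage) shading, and Gaussian noise of configurable
standard deviation is added.  Every phantom ships with a ``GroundTruth``
record of the constructed geometry, serialisable to a JSON sidecar.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .rcc import parse_rcc
from .volume import VoxelVolume

__all__ = [
    "ForamenSpec",
    "AccessorySpec",
    "ConnectingSpec",
    "RootSpec",
    "PhantomSpec",
    "GroundTruth",
    "PhantomSpecError",
    "make_tooth_phantom",
    "render_label_volume",
    "make_cohort",
    "iter_cohort",
    "spec_hash",
]

log = logging.getLogger(__name__)

THIRDS = ("coronal", "middle", "apical")

#: default tissue intensities (8-bit scale); lumen is as radiolucent as background
INTENSITIES = {"background": 0.0, "lumen": 0.0, "dentin": 120.0, "enamel": 220.0}

_FLARE_SLOPE = 0.30          # mm of extra semi-axis per mm below the constriction
_CHANNEL_RADIUS_MM = 0.06    # connecting-canal radius (diameter 0.12 < 0.2 mm)
_WALL_MM = 0.20              # minimal dentin wall kept around any lumen feature


class PhantomSpecError(ValueError):
    """Inconsistent or unresolvable phantom specification."""


# -- specification types ---------------------------------------------------

@dataclass(frozen=True)
class ForamenSpec:
    """One physiological foramen: constriction axes, offset to the opening, shape."""

    wide_mm: float = 0.40
    narrow_mm: float = 0.28
    offset_mm: float = 0.45      # constriction -> anatomical opening distance D
    shape: str = "oval"          # oval | round | irregular
    angle_deg: float = 0.0       # constriction ellipse orientation

    def __post_init__(self):
        if not (self.wide_mm >= self.narrow_mm > 0):
            raise PhantomSpecError(
                f"foramen axes must satisfy wide >= narrow > 0, got {self.wide_mm}/{self.narrow_mm}"
            )
        if self.offset_mm < 0:
            raise PhantomSpecError("constriction offset must be >= 0")
        if self.shape not in ("oval", "round", "irregular"):
            raise PhantomSpecError(f"unknown foramen shape {self.shape!r}")


@dataclass(frozen=True)
class AccessorySpec:
    """A thin branch from a main canal to the root surface (< 0.2 mm opening)."""

    third: str = "middle"
    opening_diameter_mm: float = 0.10
    direction_deg: float = 0.0   # azimuth of the outward course

    def __post_init__(self):
        if self.third not in THIRDS:
            raise PhantomSpecError(f"accessory third must be one of {THIRDS}")
        if not self.opening_diameter_mm < 0.2:
            raise PhantomSpecError(
                f"accessory opening {self.opening_diameter_mm} mm must be < 0.2 mm"
            )


@dataclass(frozen=True)
class ConnectingSpec:
    """Loop-type (L, same canal) or communicating (C, two canals) connection."""

    third: str = "middle"
    ctype: str = "L"

    def __post_init__(self):
        if self.third not in THIRDS:
            raise PhantomSpecError(f"connecting third must be one of {THIRDS}")
        if self.ctype not in ("L", "C"):
            raise PhantomSpecError("connecting type must be 'L' or 'C'")


@dataclass(frozen=True)
class RootSpec:
    """One root: its RCC target and the apical/accessory features it carries."""

    rcc: str = "1-1-1/1"
    length_mm: float = 16.0
    foramina: tuple[ForamenSpec, ...] | None = None
    accessories: tuple[AccessorySpec, ...] = ()
    connectors: tuple[ConnectingSpec, ...] = ()
    label: str = "single"

    def resolved_foramina(self) -> tuple[ForamenSpec, ...]:
        code = parse_rcc(self.rcc)
        if self.foramina is None:
            base = ForamenSpec() if code.foramina == 1 else ForamenSpec(0.38, 0.22, 0.16)
            return tuple(base for _ in range(code.foramina))
        return tuple(self.foramina)


@dataclass(frozen=True)
class PhantomSpec:
    """Full phantom specification; validated before construction."""

    roots: tuple[RootSpec, ...] = (RootSpec(),)
    crown_height_mm: float = 11.0
    voxel_size_mm: float = 0.02
    noise_sd: float = 8.0
    seed: int = 0
    bifurcation_third: str = "middle"     # two-rooted only
    root_radius_mm: float = 1.2
    crown_radius_mm: float = 1.6
    enamel_thickness_mm: float = 0.30
    curvature_mm: float = 0.0             # lateral bow amplitude of the canal system
    exit_rotation_deg: float = 0.0        # rotation of multi-foramen exit layouts

    @classmethod
    def single(cls, rcc: str = "1-1-1/1", **kwargs) -> "PhantomSpec":
        root_kwargs = {
            k: kwargs.pop(k) for k in ("length_mm", "foramina", "accessories", "connectors")
            if k in kwargs
        }
        return cls(roots=(RootSpec(rcc=rcc, **root_kwargs),), **kwargs)

    @classmethod
    def two_rooted(
        cls, rcc_buccal: str, rcc_lingual: str,
        bifurcation_third: str = "middle", **kwargs,
    ) -> "PhantomSpec":
        lengths = kwargs.pop("lengths_mm", (16.0, 15.4))
        fb = kwargs.pop("foramina_buccal", None)
        fl = kwargs.pop("foramina_lingual", None)
        acc_b = kwargs.pop("accessories_buccal", ())
        acc_l = kwargs.pop("accessories_lingual", ())
        return cls(
            roots=(
                RootSpec(rcc_buccal, lengths[0], fb, acc_b, label="buccal"),
                RootSpec(rcc_lingual, lengths[1], fl, acc_l, label="lingual"),
            ),
            bifurcation_third=bifurcation_third,
            **kwargs,
        )

    def validate(self) -> None:
        v = self.voxel_size_mm
        if not 1 <= len(self.roots) <= 2:
            raise PhantomSpecError("n_roots must be 1 or 2")
        if len(self.roots) == 2 and self.bifurcation_third not in ("middle", "apical"):
            raise PhantomSpecError("two-rooted phantoms bifurcate in the middle or apical third")
        if self.enamel_thickness_mm < 3 * v:
            raise PhantomSpecError("enamel thickness: spans < 3 voxels (unresolvable)")
        for root in self.roots:
            code = parse_rcc(root.rcc)
            foramina = root.resolved_foramina()
            if len(foramina) != code.foramina:
                raise PhantomSpecError(
                    f"root {root.label!r}: {len(foramina)} foramen specs but the "
                    f"RCC fourth digit of {root.rcc!r} is {code.foramina}"
                )
            if max(code.digits) > 4:
                raise PhantomSpecError(f"canal counts above 4 unsupported ({root.rcc})")
            third_len = root.length_mm / 3.0
            if third_len < 1.8:
                raise PhantomSpecError(
                    f"root {root.label!r}: thirds of {third_len:.2f} mm are too short "
                    "to host digit transitions"
                )
            for i, f in enumerate(foramina):
                if f.narrow_mm < 3 * v:
                    raise PhantomSpecError(
                        f"root {root.label!r} foramen {i}: narrow axis "
                        f"{f.narrow_mm} mm spans < 3 voxels (unresolvable)"
                    )
                if f.offset_mm > root.length_mm / 3.0 - 1.0:
                    raise PhantomSpecError(
                        f"root {root.label!r} foramen {i}: constriction offset "
                        f"{f.offset_mm} mm does not fit the apical third"
                    )
            for i, a in enumerate(root.accessories):
                if a.opening_diameter_mm < 3 * v:
                    raise PhantomSpecError(
                        f"root {root.label!r} accessory {i}: opening "
                        f"{a.opening_diameter_mm} mm spans < 3 voxels (unresolvable)"
                    )
                if a.third == "coronal":
                    log.warning("coronal accessory canals were not observed; generating anyway")
        if _CHANNEL_RADIUS_MM * 2 < 3 * v and any(r.connectors for r in self.roots):
            raise PhantomSpecError("connecting-canal diameter spans < 3 voxels at this voxel size")


# -- ground truth ----------------------------------------------------------

@dataclass
class GroundTruth:
    """Exact constructed geometry of one phantom (JSON-serialisable)."""

    roots: list[dict]
    cej_z_mm: float
    dej_z_mm: float
    apex_z_mm: float
    bifurcation_third: str | None
    voxel_size_mm: float
    seed: int
    n_exterior_openings: int

    def to_json_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_json_dict(cls, d: dict) -> "GroundTruth":
        return cls(**d)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_json_dict(), indent=1, sort_keys=True))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "GroundTruth":
        return cls.from_json_dict(json.loads(Path(path).read_text()))

    def root(self, label: str) -> dict:
        for r in self.roots:
            if r["label"] == label:
                return r
        raise KeyError(label)


def spec_hash(spec: PhantomSpec) -> str:
    """Stable short hash of a phantom specification."""
    blob = json.dumps(dataclasses.asdict(spec), sort_keys=True, default=str)
    return hashlib.sha1(blob.encode()).hexdigest()[:12]


# -- geometry helpers ------------------------------------------------------

def _smoothstep(t: np.ndarray | float) -> np.ndarray | float:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def _positions(n: int, sep: float) -> list[tuple[float, float]]:
    return [((i - (n - 1) / 2.0) * sep, 0.0) for i in range(n)]


def _exit_layout(f: int, rot_deg: float) -> list[tuple[float, float]]:
    if f == 0:
        return []
    if f == 1:
        return [(0.0, 0.0)]
    if f == 2:
        pts = [(-0.40, 0.0), (0.40, 0.0)]
    elif f == 3:
        pts = [(0.45 * np.cos(np.deg2rad(a)), 0.45 * np.sin(np.deg2rad(a)))
               for a in (90.0, 210.0, 330.0)]
    else:
        pts = [(0.62 * np.cos(np.deg2rad(a)), 0.62 * np.sin(np.deg2rad(a)))
               for a in (45.0, 135.0, 225.0, 315.0)]
    if rot_deg:
        c, s = np.cos(np.deg2rad(rot_deg)), np.sin(np.deg2rad(rot_deg))
        pts = [(x * c - y * s, x * s + y * c) for x, y in pts]
    return pts


@dataclass
class _Ellipse:
    x: float
    y: float
    a: float
    b: float
    theta: float = 0.0
    lobe: float = 0.0


def _ellipse_cov(X: np.ndarray, Y: np.ndarray, e: _Ellipse, v: float) -> np.ndarray:
    dx = X - e.x
    dy = Y - e.y
    if e.theta:
        c, s = np.cos(e.theta), np.sin(e.theta)
        dx, dy = dx * c + dy * s, -dx * s + dy * c
    rho = np.sqrt((dx / e.a) ** 2 + (dy / e.b) ** 2)
    target = 1.0
    if e.lobe:
        target = 1.0 + e.lobe * np.cos(3.0 * np.arctan2(dy, dx))
    d = (rho - target) * e.b
    return np.clip(0.5 - d / v, 0.0, 1.0)


def _circle_cov(X: np.ndarray, Y: np.ndarray, x0: float, y0: float, r: float, v: float) -> np.ndarray:
    d = np.sqrt((X - x0) ** 2 + (Y - y0) ** 2) - r
    return np.clip(0.5 - d / v, 0.0, 1.0)


# -- per-root canal plan ---------------------------------------------------

class _RootPlan:
    """Canal descriptors for one root as a function of height."""

    def __init__(self, spec: PhantomSpec, root: RootSpec, y_center, bow, v: float):
        self.root = root
        self.code = parse_rcc(root.rcc)
        self.L = root.length_mm
        self.v = v
        self.y_center = y_center          # callable z_rel -> root center y (mm)
        self.bow = bow                    # callable z_rel -> lateral bow x (mm)
        self.foramina = root.resolved_foramina()
        self.two_rooted = len(spec.roots) == 2

        c, m, a = self.code.digits
        f = self.code.foramina
        L = self.L
        self.r_avail = (0.74 if self.two_rooted else spec.root_radius_mm * 0.92)

        # exit layout and bottom sizing
        self.exits = _exit_layout(f, spec.exit_rotation_deg)
        if self.two_rooted:
            self.exits = [(x * 0.9, y * 0.9) for x, y in self.exits]
        self.d_real = [round(fo.offset_mm / v) * v for fo in self.foramina]
        open_semi = [
            fo.wide_mm / 2.0 * (1 + (0.18 if fo.shape == "irregular" else 0.0))
            + _FLARE_SLOPE * d
            for fo, d in zip(self.foramina, self.d_real)
        ]
        self._autoscale_exits(open_semi)
        self.r_end = (max(np.hypot(x, y) + s for (x, y), s in zip(self.exits, open_semi))
                      + _WALL_MM + 0.06) if f else 0.55

        # transition heights (z relative to CEJ)
        d_max = max(self.d_real, default=0.0)
        t3 = min(5.0 * L / 6.0, L - d_max - 0.55)
        if t3 < 2.0 * L / 3.0 + 0.45:
            raise PhantomSpecError(
                f"root {root.label!r}: constriction offsets too deep for the apical third"
            )
        self.t3 = t3
        self.w = 0.30                     # transition half-zone (mm)
        self.chamber_single = (not self.two_rooted) and c == 1
        start = -0.75 if not self.chamber_single else -0.35
        self.z_start = start
        stages: list[tuple[float, int, list[tuple[float, float]]]] = []
        n0 = 1
        stages.append((start, n0, _positions(n0, 0.0)))
        if c != 1:
            stages.append((-0.35, c, _positions(c, self._sep(c))))
        if m != c:
            stages.append((L / 6.0, m, _positions(m, self._sep(m))))
        if a != m:
            stages.append((L / 2.0, a, _positions(a, self._sep(a))))
        stages.append((t3, f, list(self.exits)))
        self.stages = stages
        # per-foramen constriction heights; the opening lies on the last drawn
        # slice at z_rel = L - v, so the constriction sits d above that
        self.z_c = [L - v - d for d in self.d_real]
        self.z_app = [max(self.t3 + self.w + 0.05, zc - 0.9) for zc in self.z_c]

    def _limb_factor(self, n: int) -> float:
        if n <= 1:
            return 1.0
        factor = 0.85 if n == 2 else 0.68
        return factor * (0.82 if self.two_rooted else 1.0)

    def _sep(self, n: int) -> float:
        if n <= 1:
            return 0.0
        base = {2: 0.70, 3: 0.58}.get(n, 0.55)
        # limb radius at the depth where separated limbs are measured
        r_limb = (0.35 - 0.028) * self._limb_factor(n)
        floor = 2 * r_limb + 0.06    # limb diameter + dentin septum
        max_off = self.r_avail - 0.24 - _WALL_MM
        sep = min(base, 2.0 * max_off / (n - 1))
        if sep < floor:
            if self.two_rooted:
                raise PhantomSpecError(
                    f"root {self.root.label!r}: cannot separate {n} canals at "
                    f"radius {self.r_avail:.2f}"
                )
            # grow the root envelope instead of failing (builder honours r_avail)
            sep = floor
            self.r_avail = floor * (n - 1) / 2.0 + 0.24 + _WALL_MM
        return sep

    def _autoscale_exits(self, open_semi: list[float]) -> None:
        pts = self.exits
        if len(pts) < 2:
            return
        for _ in range(20):
            ok = True
            for i in range(len(pts)):
                for j in range(i + 1, len(pts)):
                    need = open_semi[i] + open_semi[j] + 0.12
                    if np.hypot(pts[i][0] - pts[j][0], pts[i][1] - pts[j][1]) < need:
                        ok = False
            if ok:
                break
            pts = [(x * 1.12, y * 1.12) for x, y in pts]
        self.exits = pts

    # radius of a main canal at height z_rel
    def _r_main(self, zr: float, n: int) -> float:
        r = 0.35 - 0.07 * np.clip(zr, 0.0, self.L) / self.L
        r *= self._limb_factor(n)
        if n == 1:
            # the feeding canal must stay wider than the largest constriction,
            # or the minimal cross-section would not be the constriction
            need = max(
                (np.sqrt(fo.wide_mm * fo.narrow_mm) / 2.0 + 0.10 for fo in self.foramina),
                default=0.0,
            )
            r = max(r, need)
        return r

    def _branch_axes(self, j: int, zr: float) -> tuple[float, float, float, float]:
        """Semi-axes (a, b), angle and lobe of exit branch j at height zr."""
        fo = self.foramina[j]
        a_c, b_c = fo.wide_mm / 2.0, fo.narrow_mm / 2.0
        zc, za = self.z_c[j], self.z_app[j]
        r_branch = max(a_c + 0.06, 0.17)
        lobe = 0.18 if fo.shape == "irregular" else 0.0
        theta = np.deg2rad(fo.angle_deg)
        if zr < za:
            return r_branch, r_branch, theta, 0.0
        if zr < zc:
            s = (zr - za) / (zc - za)
            return (r_branch + (a_c - r_branch) * s,
                    r_branch + (b_c - r_branch) * s, theta, lobe * s)
        return (a_c + _FLARE_SLOPE * (zr - zc),
                b_c + _FLARE_SLOPE * (zr - zc), theta, lobe)

    def descriptors(self, zr: float) -> list[_Ellipse]:
        """Canal cross-section descriptors at height zr (mm below the CEJ)."""
        if zr < self.z_start or zr >= self.L:
            return []
        yc = self.y_center(zr)
        bow = self.bow(zr)
        stages = self.stages

        def stage_desc(idx: int, z: float) -> list[_Ellipse]:
            _, n, pos = stages[idx]
            if idx == len(stages) - 1:        # exit stage
                out = []
                for j, (ex, ey) in enumerate(self.exits):
                    a, b, th, lobe = self._branch_axes(j, z)
                    out.append(_Ellipse(ex + bow, ey + yc, a, b, th, lobe))
                return out
            r = self._r_main(z, n)
            return [_Ellipse(px + bow, py + yc, r, r, 0.0, 0.0) for px, py in pos]

        # find active stage / transition
        idx = 0
        for i, (t, _, _) in enumerate(stages):
            if zr >= t:
                idx = i
        nxt = idx + 1
        if nxt < len(stages):
            t_next = stages[nxt][0]
            if zr >= t_next - self.w:
                s = float(_smoothstep((zr - (t_next - self.w)) / (2 * self.w)))
                return self._blend(stage_desc(idx, zr), stage_desc(nxt, zr), s)
        if idx > 0 and zr <= stages[idx][0] + self.w:
            s = float(_smoothstep((zr - (stages[idx][0] - self.w)) / (2 * self.w)))
            return self._blend(stage_desc(idx - 1, zr), stage_desc(idx, zr), s)
        return stage_desc(idx, zr)

    @staticmethod
    def _blend(old: list[_Ellipse], new: list[_Ellipse], s: float) -> list[_Ellipse]:
        def lerp(e0: _Ellipse, e1: _Ellipse) -> _Ellipse:
            return _Ellipse(
                e0.x + (e1.x - e0.x) * s, e0.y + (e1.y - e0.y) * s,
                e0.a + (e1.a - e0.a) * s, e0.b + (e1.b - e0.b) * s,
                e1.theta if s > 0.5 else e0.theta,
                e0.lobe + (e1.lobe - e0.lobe) * s,
            )

        if not new:                   # canal ends blind: shrink away
            return [_Ellipse(e.x, e.y, max(e.a * (1 - s), 1e-6),
                             max(e.b * (1 - s), 1e-6), e.theta, e.lobe) for e in old]
        if len(new) >= len(old):      # split: each child grows out of nearest parent
            out = []
            for child in new:
                parent = min(old, key=lambda p: (p.x - child.x) ** 2 + (p.y - child.y) ** 2)
                out.append(lerp(parent, child))
            return out
        out = []                      # merge: each parent converges to nearest survivor
        for parent in old:
            child = min(new, key=lambda p: (p.x - parent.x) ** 2 + (p.y - parent.y) ** 2)
            out.append(lerp(parent, child))
        return out

    def third_span(self, third: str) -> tuple[float, float]:
        i = THIRDS.index(third)
        return i * self.L / 3.0, (i + 1) * self.L / 3.0


# -- the builder -----------------------------------------------------------

class _PhantomBuilder:
    def __init__(self, spec: PhantomSpec):
        spec.validate()
        self.spec = spec
        v = spec.voxel_size_mm
        self.v = v
        self.two_rooted = len(spec.roots) == 2
        self.crown_h = round(spec.crown_height_mm / v) * v
        self.lengths = [round(r.length_mm / v) * v for r in spec.roots]
        self.L_max = max(self.lengths)

        # bifurcation height (two-rooted): inside the stated third, clear of
        # the canal-transition zones at the third midpoints
        if self.two_rooted:
            frac = 0.45 if spec.bifurcation_third == "middle" else 0.78
            self.zb = frac * self.L_max
        else:
            self.zb = None

        self.plans: list[_RootPlan] = []
        for i, (root, L) in enumerate(zip(spec.roots, self.lengths)):
            sign = 0.0 if not self.two_rooted else (-1.0 if i == 0 else 1.0)
            y_center = self._make_y_center(sign)
            bow = self._make_bow(L)
            self.plans.append(_RootPlan(spec, replace(root, length_mm=L), y_center, bow, v))

        # root envelope radii
        self.R_root = [max(spec.root_radius_mm if not self.two_rooted else 0.92,
                           p.r_end + 0.05, p.r_avail / 0.92 if not self.two_rooted else 0.0)
                       for p in self.plans]
        crown_ax = max(spec.crown_radius_mm, max(self.R_root) + 0.1)
        crown_ay = crown_ax + (0.45 if self.two_rooted else 0.0)
        self.crown_ax, self.crown_ay = crown_ax, crown_ay

        x_half = max(crown_ax, max(self.R_root)) + 0.14
        y_half = crown_ay + 0.14
        if self.two_rooted:
            y_half = max(y_half, 1.0 + max(self.R_root) + 0.14)
        self.nx = 2 * int(np.ceil(x_half / v)) + 1
        self.ny = 2 * int(np.ceil(y_half / v)) + 1
        self.nz = int(round((self.crown_h + self.L_max) / v))
        self.cx = (self.nx - 1) / 2.0
        self.cy = (self.ny - 1) / 2.0
        x = (np.arange(self.nx) - self.cx) * v
        y = (np.arange(self.ny) - self.cy) * v
        self.X, self.Y = np.meshgrid(x, y, indexing="xy")   # shape (ny, nx)

    # root center y as a function of z_rel
    def _make_y_center(self, sign: float):
        if sign == 0.0:
            return lambda zr: 0.0
        zb = self.zb

        def y_center(zr: float) -> float:
            s = _smoothstep((zr - (zb - 0.35)) / 0.7)
            return sign * (0.45 + 0.55 * float(s))

        return y_center

    def _make_bow(self, L: float):
        amp = self.spec.curvature_mm

        def bow(zr: float) -> float:
            if amp == 0.0:
                return 0.0
            t = np.clip(zr / (5.0 * L / 6.0), 0.0, 1.0)
            return amp * float(np.sin(np.pi * t))

        return bow

    def _envelope_radius(self, plan: _RootPlan, R0: float, zr: float) -> float:
        L = plan.L
        if self.two_rooted:
            s = _smoothstep((zr - (self.zb - 0.35)) / 0.7)
            R0 = R0 - 0.14 * float(s)
        z_taper = 0.55 * L
        if zr <= z_taper:
            return R0
        return R0 + (plan.r_end - R0) * (zr - z_taper) / (L - z_taper)

    # ---- rasterisation ---------------------------------------------------

    def build(self, want_labels: bool = False):
        spec, v = self.spec, self.v
        nz, ny, nx = self.nz, self.ny, self.nx
        out = np.zeros((nz, ny, nx), dtype=np.float32)
        enamel = np.zeros_like(out)
        lumen = np.zeros_like(out)
        X, Y = self.X, self.Y
        e_th = spec.enamel_thickness_mm

        chamber_bottom = 0.35 if all(p.chamber_single for p in self.plans) else -0.5
        ch_top = min(0.5, 0.25 * self.crown_h)
        ch_ay = 0.75 if self.two_rooted else 0.45

        for k in range(nz):
            z = k * v
            zr = z - self.crown_h           # height relative to the CEJ plane
            if z < self.crown_h:
                cov_out = _ellipse_cov(X, Y, _Ellipse(0, 0, self.crown_ax, self.crown_ay), v)
                if z < e_th:
                    cov_en = cov_out.copy()
                else:
                    inner = _ellipse_cov(
                        X, Y, _Ellipse(0, 0, self.crown_ax - e_th, self.crown_ay - e_th), v)
                    cov_en = np.clip(cov_out - inner, 0.0, 1.0)
            else:
                cov_out = np.zeros((ny, nx), dtype=np.float32)
                cov_en = None
                for plan, R0 in zip(self.plans, self.R_root):
                    if zr >= plan.L:
                        continue
                    R = self._envelope_radius(plan, R0, zr)
                    yc = plan.y_center(zr)
                    np.maximum(cov_out, _circle_cov(X, Y, 0.0, yc, R, v), out=cov_out)

            cov_lum = np.zeros((ny, nx), dtype=np.float32)
            has_canal = any(max(p.code.digits) > 0 or p.code.foramina > 0 for p in self.plans)
            if has_canal and z >= ch_top and zr < chamber_bottom:
                depth = min(1.0, (z - ch_top) / max(0.3, 0.3 * self.crown_h))
                r_ch = 0.15 + 0.30 * depth
                ay = 0.15 + (ch_ay - 0.15) * depth
                np.maximum(cov_lum, _ellipse_cov(X, Y, _Ellipse(0, 0, r_ch, ay), v), out=cov_lum)
            for plan in self.plans:
                if zr >= plan.L:
                    continue
                for e in plan.descriptors(zr):
                    np.maximum(cov_lum, _ellipse_cov(X, Y, e, v), out=cov_lum)

            out[k] = cov_out
            lumen[k] = cov_lum
            if cov_en is not None:
                enamel[k] = cov_en

        self._draw_channels(lumen)

        gt = self._ground_truth()
        if want_labels:
            base = out >= 0.5
            lab = np.zeros(out.shape, dtype=np.uint8)
            lab[base] = 2
            lab[(enamel >= 0.5) & base] = 3
            lab[(lumen >= 0.5) & base] = 1
            return lab, gt

        e = np.minimum(enamel, out)
        l = np.minimum(lumen, out)
        d = np.clip(out - e - l, 0.0, 1.0)
        intens = (INTENSITIES["enamel"] * e + INTENSITIES["dentin"] * d
                  + INTENSITIES["lumen"] * l)
        if spec.noise_sd > 0:
            rng = np.random.default_rng(spec.seed)
            intens = intens + rng.normal(0.0, spec.noise_sd, size=intens.shape)
        vol = np.clip(np.rint(intens), 0, 255).astype(np.uint8)
        return VoxelVolume(vol, v), gt

    # thin channels: accessory canals and connecting canals, drawn as capsules
    def _draw_channels(self, lumen: np.ndarray) -> None:
        v = self.v
        for plan, R0 in zip(self.plans, self.R_root):
            for i, acc in enumerate(plan.root.accessories):
                ts, te = plan.third_span(acc.third)
                z_o = ts + 0.45 * (te - ts)
                anchor = plan.descriptors(z_o)[0]
                phi = np.deg2rad(acc.direction_deg + 180.0 * i)
                ux, uy = np.cos(phi), np.sin(phi)
                # march outward at 45 degrees until past the envelope
                p0 = np.array([anchor.x, anchor.y, z_o])
                t = 0.1
                for _ in range(400):
                    px = anchor.x + ux * t
                    py = anchor.y + uy * t
                    zq = z_o + t
                    yc = plan.y_center(zq)
                    R = self._envelope_radius(plan, R0, zq)
                    if np.hypot(px - 0.0, py - yc) > R + 0.10 or zq >= plan.L - 0.1:
                        break
                    t += v
                p1 = np.array([anchor.x + ux * t, anchor.y + uy * t, z_o + t])
                self._capsule(lumen, p0, p1, acc.opening_diameter_mm / 2.0)
            for con in plan.root.connectors:
                ts, te = plan.third_span(con.third)
                z1 = ts + 0.15 * (te - ts)
                desc = plan.descriptors(z1)
                if con.ctype == "L":
                    z2 = z1 + 0.45
                    a0 = desc[0]
                    a1 = plan.descriptors(z2)[0]
                    # loop bulges in y (no other canal of this root there),
                    # away from the tooth midline for two-rooted phantoms
                    dir_y = -1.0 if a0.y < -1e-6 else 1.0
                    mid = np.array([a0.x, a0.y + dir_y * (a0.b + 0.32), (z1 + z2) / 2.0])
                    self._capsule(lumen, np.array([a0.x, a0.y, z1]), mid, _CHANNEL_RADIUS_MM)
                    self._capsule(lumen, mid, np.array([a1.x, a1.y, z2]), _CHANNEL_RADIUS_MM)
                else:
                    if len(desc) < 2:
                        raise PhantomSpecError(
                            f"type C connecting canal needs >= 2 canals in the {con.third} third"
                        )
                    a0, a1 = desc[0], desc[1]
                    self._capsule(lumen, np.array([a0.x, a0.y, z1]),
                                  np.array([a1.x, a1.y, z1 + 0.1]), _CHANNEL_RADIUS_MM)

    def _capsule(self, lumen: np.ndarray, p0: np.ndarray, p1: np.ndarray, r: float) -> None:
        """Union a capsule (cylinder with round caps) into the lumen coverage.

        p = (x, y, z_rel) in mm; z_rel relative to the CEJ.
        """
        v = self.v
        z0 = min(p0[2], p1[2]) - r - 2 * v
        z1 = max(p0[2], p1[2]) + r + 2 * v
        k0 = max(0, int(np.floor((z0 + self.crown_h) / v)))
        k1 = min(self.nz - 1, int(np.ceil((z1 + self.crown_h) / v)))
        d = p1 - p0
        dd = float(d @ d)
        X, Y = self.X, self.Y
        for k in range(k0, k1 + 1):
            zr = k * v - self.crown_h
            # closest point on segment for every pixel of this slice
            wx = X - p0[0]
            wy = Y - p0[1]
            wz = zr - p0[2]
            if dd > 0:
                tt = np.clip((wx * d[0] + wy * d[1] + wz * d[2]) / dd, 0.0, 1.0)
            else:
                tt = 0.0
            ex = wx - tt * d[0]
            ey = wy - tt * d[1]
            ez = wz - tt * d[2]
            dist = np.sqrt(ex * ex + ey * ey + ez * ez) - r
            np.maximum(lumen[k], np.clip(0.5 - dist / v, 0.0, 1.0), out=lumen[k])

    # ---- ground truth ----------------------------------------------------

    def _ground_truth(self) -> GroundTruth:
        v = self.v
        roots = []
        n_open = 0
        for plan, L in zip(self.plans, self.lengths):
            k_a = int(round((self.crown_h + L) / v)) - 1
            foramina = []
            for j, fo in enumerate(plan.foramina):
                d_real = plan.d_real[j]
                k_c = k_a - int(round(d_real / v))
                ex, ey = plan.exits[j]
                foramina.append({
                    "wide_mm": fo.wide_mm,
                    "narrow_mm": fo.narrow_mm,
                    "offset_nominal_mm": fo.offset_mm,
                    "offset_mm": round((k_a - k_c) * v, 6),
                    "shape": fo.shape,
                    "opening_world_mm": [round(k_a * v, 6),
                                         round(self.cy * v + ey + plan.y_center(L - 0.01), 6),
                                         round(self.cx * v + ex, 6)],
                    "constriction_z_mm": round(k_c * v, 6),
                })
            n_open += len(plan.foramina) + len(plan.root.accessories)
            roots.append({
                "label": plan.root.label,
                "rcc": plan.root.rcc,
                "digits": list(plan.code.digits),
                "n_physiological": plan.code.foramina,
                "length_mm": round(L, 6),
                "apex_z_mm": round((int(round((self.crown_h + L) / v)) - 1) * v, 6),
                "foramina": foramina,
                "accessories": [
                    {"third": a.third, "opening_diameter_mm": a.opening_diameter_mm}
                    for a in plan.root.accessories
                ],
                "connecting": [
                    {"third": c.third, "type": c.ctype} for c in plan.root.connectors
                ],
            })
        return GroundTruth(
            roots=roots,
            cej_z_mm=round(self.crown_h, 6),
            dej_z_mm=round(self.crown_h, 6),
            apex_z_mm=round((self.nz - 1) * v, 6),
            bifurcation_third=self.spec.bifurcation_third if self.two_rooted else None,
            voxel_size_mm=v,
            seed=self.spec.seed,
            n_exterior_openings=n_open,
        )


# -- public API ------------------------------------------------------------

def make_tooth_phantom(spec: PhantomSpec) -> tuple[VoxelVolume, GroundTruth]:
    """Construct one phantom volume and its exact ground truth."""
    return _PhantomBuilder(spec).build(want_labels=False)


def render_label_volume(spec: PhantomSpec) -> tuple[np.ndarray, GroundTruth]:
    """Noise-free tissue label volume (0 bg, 1 lumen, 2 dentin, 3 enamel)."""
    return _PhantomBuilder(spec).build(want_labels=True)


def _jittered(spec: PhantomSpec, rng: np.random.Generator, child_seed: int) -> PhantomSpec:
    """Per-phantom nuisance jitter: continuous geometry only, never the
    discrete structure (RCC, foramen count, thirds)."""
    roots = []
    for root in spec.roots:
        foramina = root.resolved_foramina()
        foramina = tuple(
            replace(f, angle_deg=float(rng.uniform(0.0, 180.0))) for f in foramina
        )
        length = root.length_mm + float(rng.uniform(-0.25, 0.25))
        roots.append(replace(root, length_mm=length, foramina=foramina))
    return replace(
        spec,
        roots=tuple(roots),
        curvature_mm=float(rng.uniform(0.0, 0.10)),
        exit_rotation_deg=float(rng.uniform(0.0, 180.0)),
        seed=child_seed,
    )


def iter_cohort(composition: list[tuple[PhantomSpec, int]], seed: int):
    """Yield ``(index, spec_used, volume, ground_truth)`` for a cohort.

    Per-phantom seeds derive deterministically from the global seed; continuous
    nuisance parameters are jittered per phantom, discrete structure never.
    """
    if not composition:
        raise PhantomSpecError("empty cohort composition")
    for spec, count in composition:
        if count < 1:
            raise PhantomSpecError("composition counts must be >= 1")
    total = sum(c for _, c in composition)
    seeds = np.random.SeedSequence(seed).spawn(total)
    idx = 0
    for spec, count in composition:
        for _ in range(count):
            rng = np.random.default_rng(seeds[idx])
            child_seed = int(rng.integers(0, 2**31 - 1))
            jspec = _jittered(spec, rng, child_seed)
            vol, gt = make_tooth_phantom(jspec)
            yield idx, jspec, vol, gt
            idx += 1


def make_cohort(
    composition: list[tuple[PhantomSpec, int]], seed: int
) -> list[tuple[VoxelVolume, GroundTruth]]:
    """Materialise a whole cohort (see :func:`iter_cohort`)."""
    return [(vol, gt) for _, _, vol, gt in iter_cohort(composition, seed)]
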