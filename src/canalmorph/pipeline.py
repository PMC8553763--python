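"""End-to-end analysis of one tooth volume.

Chains preprocessing (crop), tissue segmentation, landmark and root
detection, canal-graph extraction, foramen metrology and RCC coding into a
single per-tooth report.  All stage parameters live in
:class:`PipelineConfig`, which serialises to/from a TOML file and is echoed
into every report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import foramen as fm
from . import graph as gr
from . import preprocessing as pre
from . import segmentation as seg
from .rcc import classify_rcc, format_rcc
from .volume import VoxelVolume

__all__ = ["PipelineConfig", "ToothReport", "analyze_volume"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Effective analysis parameters (all thresholds in mm)."""

    voxel_size_mm: float | None = None         # override; None = from metadata
    foramen_threshold_mm: float = 0.2          # physiological vs accessory, on W
    oval_delta_mm: float = 0.02                # W - N at/above which shape is oval
    irregular_residual: float = 0.08           # ellipse-fit residual tolerance
    apical_window_mm: float = 3.5
    prune_length_mm: float = 0.1
    caliber_mm: float = 0.2                    # main-canal caliber for digit counting
    axis_convention: str = "slice-coronal-to-apical"
    maf_policy: str = "table-lookup"
    seed: int = 0
    output_dir: str = "out"
    manual_thresholds: tuple[float, float] | None = None
    cej_index: int | None = None               # manual CEJ for decoronated teeth

    def __post_init__(self):
        for name in ("foramen_threshold_mm", "oval_delta_mm", "irregular_residual",
                     "apical_window_mm", "prune_length_mm", "caliber_mm"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")

    def to_toml(self, path: str | Path) -> Path:
        path = Path(path)
        lines = []
        for f_ in dataclasses.fields(self):
            value = getattr(self, f_.name)
            if value is None:
                continue
            if isinstance(value, str):
                lines.append(f'{f_.name} = "{value}"')
            elif isinstance(value, tuple):
                lines.append(f"{f_.name} = [{', '.join(str(v) for v in value)}]")
            else:
                lines.append(f"{f_.name} = {value}")
        path.write_text("\n".join(lines) + "\n")
        return path

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        import tomllib

        data = tomllib.loads(Path(path).read_text())
        if "manual_thresholds" in data:
            data["manual_thresholds"] = tuple(data["manual_thresholds"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d.get("manual_thresholds") is not None:
            d["manual_thresholds"] = list(d["manual_thresholds"])
        return d


@dataclass
class ToothReport:
    """Per-tooth analysis result."""

    tooth_id: str
    root_count: int
    bifurcation_third: str | None
    codes: dict[str, str]                       # root label -> "c-m-a/f"
    digits: dict[str, list[int]]
    foramina: list[dict]
    accessory_canals: list[dict]
    connecting_canals: list[dict]
    landmarks: dict
    flags: list[str]
    config: dict

    @property
    def n_physiological(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for rec in self.foramina:
            if rec["class"] == "physiological":
                out[rec["root"]] = out.get(rec["root"], 0) + 1
        for label in self.codes:
            out.setdefault(label, 0)
        return out

    def to_json_dict(self) -> dict:
        return dataclasses.asdict(self)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(self.to_json_dict(), indent=1))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "ToothReport":
        return cls(**json.loads(Path(path).read_text()))


def analyze_volume(
    volume: VoxelVolume,
    config: PipelineConfig | None = None,
    tooth_id: str = "",
) -> ToothReport:
    """Run the full morphometry pipeline on one grayscale volume."""
    config = config or PipelineConfig()
    flags: list[str] = []

    cropped, offset = pre.crop_to_content(volume)
    tissue = seg.segment_tissues(cropped, thresholds=config.manual_thresholds)
    landmarks = seg.detect_landmarks(tissue, cej_index=config.cej_index)
    roots = seg.detect_roots(tissue, landmarks)

    lumen = tissue.lumen
    data = cropped.data

    if not lumen.any():
        flags.append("no canal")
        codes = {
            label: format_rcc(classify_rcc((0, 0, 0), 0, label))
            for label in roots.labels_order
        }
        return ToothReport(
            tooth_id=tooth_id, root_count=roots.count,
            bifurcation_third=roots.bifurcation_third,
            codes=codes, digits={l: [0, 0, 0] for l in roots.labels_order},
            foramina=[], accessory_canals=[], connecting_canals=[],
            landmarks=_landmark_dict(landmarks, offset), flags=flags,
            config=config.to_dict(),
        )

    background = tissue.labels == seg.LABEL_BACKGROUND
    canal_graph = gr.skeletonize_canals(
        lumen, tissue.voxel_size_mm, background=background,
        prune_length_mm=config.prune_length_mm,
    )

    # iso-level: midpoint between lumen and dentin intensity
    lumen_mean = float(data[lumen].mean())
    dentin_mean = float(data[tissue.dentin].mean())
    iso = 0.5 * (lumen_mean + dentin_mean)

    # per-root third boundaries (each root spans CEJ -> its own apex)
    thirds: dict[str, seg.ThirdBoundaries] = {}
    for label, apex_k in zip(roots.labels_order, roots.apex_indices):
        thirds[label] = seg.split_root_thirds(
            landmarks.cej_mm, float(tissue.z_mm(apex_k)), tissue.voxel_size_mm
        )

    def root_of_point(yx) -> str:
        return roots.labels_order[roots.side(yx)]

    # ---- foramen metrology on every exterior exit ------------------------
    foramina: list[dict] = []
    physiological: set[int] = set()
    for rec in canal_graph.exits:
        path = canal_graph.terminal_path(rec.exit_id)
        label = root_of_point(rec.centroid_idx[1:])
        try:
            constriction, opening, distance, f_flags = fm.locate_foramen_pair(
                data, tissue.voxel_size_mm, path, iso,
                window_mm=config.apical_window_mm,
            )
        except Exception as exc:    # isolated per exit
            log.warning("%s: exit %d metrology failed: %s", tooth_id, rec.exit_id, exc)
            flags.append(f"exit-{rec.exit_id}-metrology-failed")
            continue
        if constriction is None:
            wide = narrow = rec.opening_diameter_mm
            residual = float("nan")
            const_pos = open_pos = rec.centroid_idx
            distance = 0.0
            f_flags = list(f_flags) + ["opening-size-only"]
        else:
            wide, narrow, residual = fm.measure_foramen(constriction)
            const_pos = constriction.centroid_idx
            open_pos = opening.centroid_idx if opening is not None else rec.centroid_idx
        klass = fm.classify_opening(wide, config.foramen_threshold_mm)
        shape = None
        if klass == "physiological":
            physiological.add(rec.exit_id)
            shape = fm.classify_shape(
                wide, narrow, residual,
                config.oval_delta_mm, config.irregular_residual,
            )
        record = fm.ForamenRecord(
            exit_id=rec.exit_id,
            constriction_mm=tuple(
                np.asarray(const_pos) * tissue.voxel_size_mm + np.asarray(tissue.origin_mm)
            ),
            opening_mm=tuple(
                np.asarray(open_pos) * tissue.voxel_size_mm + np.asarray(tissue.origin_mm)
            ),
            wide_mm=wide, narrow_mm=narrow, distance_mm=distance,
            klass=klass, shape=shape, residual=residual,
            root_label=label,
            third=thirds[label].third_of(float(tissue.z_mm(const_pos[0]))),
            flags=list(f_flags),
        )
        foramina.append(record.to_dict())

    canal_graph.assign_roles(physiological, caliber_mm=config.caliber_mm)

    # ---- canal inventory -------------------------------------------------
    side_label = (lambda yx: root_of_point(yx)) if roots.count == 2 else None
    origin_z = tissue.origin_mm[0]
    third_of_local = lambda z_local: thirds[roots.labels_order[0]].third_of(z_local + origin_z)
    accessory_exits = {r.exit_id for r in canal_graph.exits} - physiological
    accessory = gr.find_accessory_canals(
        canal_graph, accessory_exits, third_of=third_of_local, side=side_label,
    )
    connecting = gr.classify_connecting_canals(
        canal_graph, third_of=third_of_local, side=side_label,
    )

    # ---- RCC digits ------------------------------------------------------
    codes: dict[str, str] = {}
    digits: dict[str, list[int]] = {}
    n_phys_by_root = {label: 0 for label in roots.labels_order}
    for rec in foramina:
        if rec["class"] == "physiological":
            n_phys_by_root[rec["root"]] += 1
    for i, label in enumerate(roots.labels_order):
        limit_planes = [
            int(round((z - origin_z) / tissue.voxel_size_mm))
            for z in thirds[label].limits_mm
        ]
        side = None
        if roots.count == 2:
            want = i

            def side(yx, want=want):
                return roots.side(yx) == want

        counts = tuple(
            gr.count_canals_at_plane(lumen, k, graph=canal_graph, side=side)
            for k in limit_planes
        )
        code = classify_rcc(counts, n_phys_by_root[label], label)
        codes[label] = format_rcc(code)
        digits[label] = list(counts)
        flags.extend(f"{label}:{fl}" for fl in code.flags)

    return ToothReport(
        tooth_id=tooth_id,
        root_count=roots.count,
        bifurcation_third=roots.bifurcation_third,
        codes=codes,
        digits=digits,
        foramina=foramina,
        accessory_canals=accessory,
        connecting_canals=connecting,
        landmarks=_landmark_dict(landmarks, offset),
        flags=flags,
        config=config.to_dict(),
    )


def _landmark_dict(landmarks: seg.Landmarks, crop_offset) -> dict:
    return {
        "apex_mm": landmarks.apex_mm,
        "cej_mm": landmarks.cej_mm,
        "dej_mm": landmarks.dej_mm,
        "crop_offset_vox": list(crop_offset),
    }
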