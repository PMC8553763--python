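"""Skeleton graph extraction, canal counting and the canal inventory."""

import numpy as np
import pytest
from scipy import ndimage

from canalmorph.graph import (
    CanalGraphError,
    count_canals_at_plane,
    skeletonize_canals,
)
from canalmorph.phantom import AccessorySpec, make_tooth_phantom
from canalmorph.pipeline import PipelineConfig, analyze_volume
from canalmorph.segmentation import segment_tissues
from conftest import single_spec

VOX = 0.02


def cylinder_mask(length=120, radius_px=6, n=24):
    z, y, x = np.mgrid[:length, :n, :n]
    c = (n - 1) / 2
    return (y - c) ** 2 + (x - c) ** 2 <= radius_px ** 2


# -- skeleton graph ---------------------------------------------------------

def test_straight_cylinder_gives_a_path_graph():
    graph = skeletonize_canals(cylinder_mask(), VOX)
    degrees = [d for _, d in graph.g.degree()]
    assert sorted(degrees) == [1, 1] or degrees.count(1) == 2
    assert graph.chamber_node is not None


def test_cylinder_node_radius_matches_analytic_radius():
    radius_px = 6
    graph = skeletonize_canals(cylinder_mask(radius_px=radius_px), VOX)
    # interior chain radius: distance to the nearest non-lumen voxel
    radii = [attrs["mean_radius_mm"] for _, _, attrs in graph.g.edges(data=True)]
    assert max(radii) == pytest.approx(radius_px * VOX, abs=VOX)


def test_empty_mask_rejected():
    with pytest.raises(CanalGraphError):
        skeletonize_canals(np.zeros((10, 10, 10), dtype=bool), VOX)


def test_split_merge_phantom_has_branch_and_merge_between_third_limits(phantom_121):
    vol, gt = phantom_121
    tissue = segment_tissues(vol)
    graph = skeletonize_canals(tissue.lumen, VOX, background=tissue.labels == 0)
    root = gt.roots[0]
    lo = (gt.cej_z_mm + 0.0) / VOX
    hi = (gt.cej_z_mm + 2 * root["length_mm"] / 3.0) / VOX
    junctions = [
        n for n, a in graph.g.nodes(data=True)
        if graph.g.degree(n) >= 3 and lo < a["pos"][0] < hi
    ]
    assert len(junctions) == 2        # one split, one merge


def test_exit_nodes_lie_on_the_lumen_exterior_interface(phantom_111):
    vol, gt = phantom_111
    tissue = segment_tissues(vol)
    background = tissue.labels == 0
    graph = skeletonize_canals(tissue.lumen, VOX, background=background)
    assert len(graph.exits) == 1
    z, y, x = np.round(graph.exits[0].centroid_idx).astype(int)
    # the centroid sits on lumen voxels whose 6-neighborhood reaches exterior
    neighborhood = tissue.lumen[max(0, z - 1): z + 2, y - 2: y + 2, x - 2: x + 2]
    assert neighborhood.any()


# -- canal counting vs flood-fill oracle ------------------------------------

def test_plain_count_equals_flood_fill_oracle_everywhere(phantom_121):
    vol, _ = phantom_121
    tissue = segment_tissues(vol)
    lumen = tissue.lumen
    rng = np.random.default_rng(0)
    planes = rng.integers(0, lumen.shape[0], size=40)
    for k in planes:
        _, expected = ndimage.label(lumen[k], structure=np.ones((3, 3), bool))
        assert count_canals_at_plane(lumen, int(k)) == expected


def test_count_through_empty_plane_is_zero():
    lumen = np.zeros((10, 8, 8), dtype=bool)
    lumen[5:, 2:5, 2:5] = True
    assert count_canals_at_plane(lumen, 0) == 0


def test_plane_outside_volume_rejected():
    with pytest.raises(CanalGraphError):
        count_canals_at_plane(np.ones((5, 5, 5), dtype=bool), 9)


# -- inventory through the pipeline ----------------------------------------

def test_accessory_branch_reported_with_third_and_diameter():
    spec = single_spec(accessories=(AccessorySpec("middle", 0.10),), seed=61)
    vol, _ = make_tooth_phantom(spec)
    report = analyze_volume(vol, PipelineConfig())
    assert len(report.accessory_canals) == 1
    acc = report.accessory_canals[0]
    assert acc["third"] == "middle"
    assert acc["opening_diameters_mm"][0] == pytest.approx(0.10, abs=0.06)
    assert acc["opening_diameters_mm"][0] < 0.2


def test_wide_branch_is_a_physiological_foramen_not_accessory():
    # a second exit with a 0.25 mm constriction exceeds the 0.2 mm rule:
    # it must contribute a physiological foramen, not an accessory canal
    from canalmorph.phantom import ForamenSpec

    spec = single_spec(
        "1-1-1/2", seed=62,
        foramina=(ForamenSpec(0.40, 0.28, 0.30), ForamenSpec(0.25, 0.21, 0.16)),
    )
    vol, _ = make_tooth_phantom(spec)
    report = analyze_volume(vol, PipelineConfig())
    phys = [f for f in report.foramina if f["class"] == "physiological"]
    assert len(phys) == 2
    assert not report.accessory_canals
    assert report.codes["single"] == "1-1-1/2"


def test_connecting_canal_types_from_battery(battery_results):
    by_code = {spec.roots[0].rcc: rep for spec, _, rep in battery_results
               if len(spec.roots) == 1}
    loop = by_code["1-2-1/1"].connecting_canals
    assert [c["type"] for c in loop] == ["L"]
    assert loop[0]["third"] == "middle"
    comm = by_code["2-3-1/1"].connecting_canals
    assert [c["type"] for c in comm] == ["C"]
    assert comm[0]["third"] == "middle"
    assert by_code["1-1-1/1"].connecting_canals == []


def test_graph_exports_json_and_edge_csv(tmp_path):
    graph = skeletonize_canals(cylinder_mask(), VOX)
    payload = graph.to_json_dict()
    assert payload["voxel_size_mm"] == VOX
    assert payload["nodes"] and payload["edges"]
    jpath = graph.save_json(tmp_path / "g.json")
    cpath = graph.save_edge_csv(tmp_path / "g.csv")
    assert jpath.exists()
    header, *rows = cpath.read_text().strip().splitlines()
    assert header == "u,v,length_mm,mean_radius_mm,kind"
    assert len(rows) == len(payload["edges"])


def test_exit_count_euler_consistency(battery_results):
    # tree-like systems: physiological + accessory exits are classified once each
    for spec, gt, rep in battery_results:
        want = sum(r["n_physiological"] + len(r["accessories"]) for r in gt.roots)
        n_phys = sum(f["class"] == "physiological" for f in rep.foramina)
        n_acc = sum(a["n_foramina"] for a in rep.accessory_canals)
        assert n_phys + n_acc == want
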