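"""Tissue segmentation, landmarks, thirds and root detection."""

import numpy as np
import pytest
from scipy import ndimage

from canalmorph.segmentation import (
    LABEL_DENTIN,
    LABEL_ENAMEL,
    LABEL_LUMEN,
    SegmentationError,
    TissueLabels,
    detect_landmarks,
    detect_roots,
    segment_tissues,
    split_root_thirds,
)
from canalmorph.volume import VoxelVolume
from canalmorph.phantom import PhantomSpec, make_tooth_phantom, render_label_volume
from conftest import GEOM, ROOT_LEN, single_spec


@pytest.fixture(scope="module")
def seg_pair():
    spec = single_spec(noise_sd=0.0, seed=13)
    vol, gt = make_tooth_phantom(spec)
    truth_labels, _ = render_label_volume(spec)
    tissue = segment_tissues(vol)
    return tissue, truth_labels, gt


def test_labels_partition_the_grid(seg_pair):
    tissue, _, _ = seg_pair
    assert tissue.labels.max() <= 3          # every voxel exactly one class


def test_noise_free_segmentation_matches_generator_labels(seg_pair):
    tissue, truth, _ = seg_pair
    # exclude a 1-voxel shell around any class boundary of the truth
    boundary = np.zeros(truth.shape, dtype=bool)
    for axis in range(3):
        diff = np.diff(truth, axis=axis) != 0
        pad_lo = [(0, 0)] * 3
        pad_lo[axis] = (1, 0)
        pad_hi = [(0, 0)] * 3
        pad_hi[axis] = (0, 1)
        boundary |= np.pad(diff, pad_lo) | np.pad(diff, pad_hi)
    interior = ~boundary
    agree = (tissue.labels == truth)[interior].mean()
    assert agree >= 0.99


def test_noisy_segmentation_preserves_rcc_topology():
    # noise at 20% of the dentin-lumen contrast must not change the per-plane
    # lumen component counts at the third limits
    spec = single_spec("1-2-1/1", noise_sd=24.0, seed=31)
    vol, gt = make_tooth_phantom(spec)
    tissue = segment_tissues(vol)
    root = gt.roots[0]
    v = gt.voxel_size_mm
    for i, want in enumerate(root["digits"]):
        k = int(round((gt.cej_z_mm + i * root["length_mm"] / 3.0) / v))
        _, n = ndimage.label(tissue.labels[k] == LABEL_LUMEN,
                             structure=np.ones((3, 3), dtype=bool))
        assert n == want


def test_pure_background_raises_no_tooth():
    vol = VoxelVolume(np.zeros((30, 20, 20), dtype=np.uint8), 0.02)
    with pytest.raises(SegmentationError):
        segment_tissues(vol)


def test_landmarks_within_two_voxels_of_ground_truth(seg_pair):
    tissue, _, gt = seg_pair
    lm = detect_landmarks(tissue)
    v = gt.voxel_size_mm
    assert abs(lm.cej_mm - gt.cej_z_mm) <= 2 * v
    assert abs(lm.apex_mm - gt.apex_z_mm) <= 2 * v


def test_cej_moves_with_the_enamel_cap(seg_pair):
    tissue, _, _ = seg_pair
    lm = detect_landmarks(tissue)
    shifted = tissue.labels.copy()
    k = lm.cej_index
    # extend the enamel cap apically by 3 slices (construction)
    for dk in range(1, 4):
        ring = shifted[k] == LABEL_ENAMEL
        shifted[k + dk][ring] = LABEL_ENAMEL
    lm2 = detect_landmarks(TissueLabels(shifted, tissue.voxel_size_mm))
    assert lm2.cej_index == lm.cej_index + 3


def test_missing_enamel_needs_manual_cej(seg_pair):
    tissue, _, _ = seg_pair
    bare = tissue.labels.copy()
    bare[bare == LABEL_ENAMEL] = LABEL_DENTIN
    with pytest.raises(SegmentationError, match="CEJ"):
        detect_landmarks(TissueLabels(bare, tissue.voxel_size_mm))
    lm = detect_landmarks(TissueLabels(bare, tissue.voxel_size_mm), cej_index=90)
    assert lm.cej_index == 90


def test_thirds_partition_the_root_span_exactly():
    thirds = split_root_thirds(cej_mm=1.0, apex_mm=16.0, voxel_size_mm=0.02)
    limits = thirds.limits_mm
    assert limits[0] == 1.0
    assert limits[1] == pytest.approx(6.0)
    assert limits[2] == pytest.approx(11.0)
    assert thirds.third_of(5.99) == "coronal"
    assert thirds.third_of(6.0) == "middle"
    assert thirds.third_of(15.9) == "apical"


def test_degenerate_span_rejected():
    with pytest.raises(SegmentationError):
        split_root_thirds(1.0, 1.1, 0.02)
    with pytest.raises(SegmentationError):
        split_root_thirds(2.0, 1.0, 0.02)


def test_single_rooted_detection(seg_pair):
    tissue, _, _ = seg_pair
    lm = detect_landmarks(tissue)
    roots = detect_roots(tissue, lm)
    assert roots.count == 1
    assert roots.bifurcation_third is None


def test_two_rooted_detection_and_per_root_apices():
    spec = PhantomSpec.two_rooted("1-1-1/1", "1-1-1/1",
                                  lengths_mm=(ROOT_LEN, ROOT_LEN - 0.4),
                                  seed=19, **GEOM)
    vol, gt = make_tooth_phantom(spec)
    tissue = segment_tissues(vol)
    lm = detect_landmarks(tissue)
    roots = detect_roots(tissue, lm)
    assert roots.count == 2
    assert roots.bifurcation_third == "middle"
    # unequal root lengths give distinct per-root apices
    apex_mm = sorted(tissue.z_mm(k) for k in roots.apex_indices)
    want = sorted(r["apex_z_mm"] for r in gt.roots)
    assert np.allclose(apex_mm, want, atol=3 * gt.voxel_size_mm)


def test_three_dentin_components_unsupported(seg_pair):
    tissue, _, _ = seg_pair
    lm = detect_landmarks(tissue)
    labels = np.zeros_like(tissue.labels)
    k0 = lm.cej_index
    for k in range(k0, tissue.labels.shape[0]):
        for cx in (30, 70, 110):
            labels[k, 28:40, cx - 6:cx + 6] = LABEL_DENTIN
    labels[: k0 + 1] = tissue.labels[: k0 + 1]
    with pytest.raises(SegmentationError, match="two roots|unsupported"):
        detect_roots(TissueLabels(labels, tissue.voxel_size_mm), lm)
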