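import math

import numpy as np
import pytest

from nucoloc import (ImageStack, SegmentationConfig, compute_volumes,
                     crop_nucleus, measure_nuclei, segment_nuclei)
from helpers import single_ellipsoid_stack


class TestSegmentNuclei:
    def test_all_zero_stack_gives_no_labels(self):
        stack = ImageStack(voxels=np.zeros((4, 20, 20, 1), dtype=np.uint8),
                           channel_roles={0: "DAPI"})
        labels = segment_nuclei(stack)
        assert labels.max() == 0

    def test_single_uniform_ellipsoid_is_one_component(self):
        stack = single_ellipsoid_stack(intensity=200)
        labels = segment_nuclei(stack)
        assert labels.max() == 1

    def test_scene_recovers_true_nucleus_count(self, wt_scene):
        stack, truth = wt_scene
        labels = segment_nuclei(stack)
        assert labels.max() == len(truth.nuclei)

    def test_missing_dapi_role_rejected(self):
        stack = ImageStack(voxels=np.zeros((1, 8, 8, 1), dtype=np.uint8),
                           channel_roles={0: "PMP22"})
        with pytest.raises(KeyError):
            segment_nuclei(stack)

    def test_label_count_invariant_to_channel_order(self, wt_scene):
        stack, _ = wt_scene
        flipped = ImageStack(voxels=stack.voxels[..., ::-1].copy(),
                             voxel_size=stack.voxel_size,
                             channel_roles={3 - k: v for k, v in stack.channel_roles.items()})
        assert segment_nuclei(flipped).max() == segment_nuclei(stack).max()

    def test_invalid_threshold_window(self):
        with pytest.raises(ValueError):
            SegmentationConfig(low_threshold=200, high_threshold=100)


class TestVolumes:
    def test_volume_is_count_times_voxel_volume(self):
        labels = np.zeros((10, 10, 10), dtype=np.int32)
        labels.ravel()[:1000] = 1
        vols = compute_volumes(labels, (1.0, 0.379, 0.379))
        assert vols[1] == pytest.approx(1000 * 1.0 * 0.379 * 0.379)  # 143.641
        assert vols[1] == pytest.approx(143.641, abs=1e-3)

    def test_single_voxel_unit_volume(self):
        labels = np.zeros((2, 2, 2), dtype=np.int32)
        labels[0, 0, 0] = 1
        assert compute_volumes(labels, (1, 1, 1))[1] == 1.0

    def test_ellipsoid_volume_within_ten_percent_of_closed_form(self):
        semiaxes = (5.0, 10.0, 10.0)  # µm, (z, y, x)
        stack = single_ellipsoid_stack(semiaxes_um=semiaxes, intensity=60,
                                       voxel_size=(0.21, 0.1, 0.1), pad=30)
        labels = segment_nuclei(stack)
        assert labels.max() == 1
        vol = compute_volumes(labels, stack.voxel_size)[1]
        expected = 4.0 / 3.0 * math.pi * semiaxes[0] * semiaxes[1] * semiaxes[2]
        assert vol == pytest.approx(expected, rel=0.10)

    def test_total_volume_bounded_by_stack(self, wt_scene):
        stack, _ = wt_scene
        labels = segment_nuclei(stack)
        total = sum(compute_volumes(labels, stack.voxel_size).values())
        physical = np.prod(labels.shape) * stack.voxel_volume
        assert total <= physical

    def test_noise_free_volumes_within_ten_percent_of_truth(self, clean_scene):
        stack, truth = clean_scene
        labels = segment_nuclei(stack)
        vols = compute_volumes(labels, stack.voxel_size)
        assert labels.max() == len(truth.nuclei)
        for nuc in truth.nuclei:
            m = truth.label_map == nuc.label
            ids, counts = np.unique(labels[m], return_counts=True)
            seg_label = int(ids[np.argmax(np.where(ids > 0, counts, 0))])
            assert vols[seg_label] == pytest.approx(nuc.volume_analytic, rel=0.10)


class TestMeasureAndCrop:
    def test_mean_intensities_on_raw_channels(self):
        vox = np.zeros((2, 12, 12, 2), dtype=np.uint8)
        vox[:, 2:10, 2:10, 0] = 100  # DAPI block, segmented without blur
        vox[:, 2:10, 2:10, 1] = 50
        stack = ImageStack(voxels=vox, voxel_size=(1, 1, 1),
                           channel_roles={0: "DAPI", 1: "PMP22"})
        labels = segment_nuclei(stack, SegmentationConfig(blur_sigma=0, min_voxels=10))
        recs = measure_nuclei(stack, labels)
        assert len(recs) == 1
        assert recs[0].mean_intensity["DAPI"] == pytest.approx(100)
        assert recs[0].mean_intensity["PMP22"] == pytest.approx(50)
        assert recs[0].volume == recs[0].voxel_count * 1.0

    def test_crop_zero_margin_equals_bounding_box(self, clean_scene):
        stack, truth = clean_scene
        labels = segment_nuclei(stack)
        crop, mask = crop_nucleus(stack, labels, 1, margin=0)
        where = np.argwhere(labels == 1)
        expected = tuple(int(hi - lo + 1) for lo, hi in
                         zip(where.min(axis=0), where.max(axis=0)))
        assert crop.shape[:3] == expected
        assert mask.shape == expected

    def test_crop_clears_extranuclear_signal(self):
        vox = np.zeros((1, 20, 20, 2), dtype=np.uint8)
        vox[0, 5:12, 5:12, 0] = 120   # nucleus
        vox[0, 0:3, 0:3, 1] = 200     # PMP22 wholly outside
        stack = ImageStack(voxels=vox, voxel_size=(1, 1, 1),
                           channel_roles={0: "DAPI", 1: "PMP22"})
        labels = segment_nuclei(stack, SegmentationConfig(blur_sigma=0, min_voxels=5))
        crop, _ = crop_nucleus(stack, labels, 1, margin=3)
        assert crop.channel("PMP22").sum() == 0

    def test_crop_preserves_interior_signal_sum(self):
        vox = np.zeros((1, 20, 20, 2), dtype=np.uint8)
        vox[0, 5:12, 5:12, 0] = 120
        vox[0, 7:9, 7:9, 1] = 33      # PMP22 wholly inside
        stack = ImageStack(voxels=vox, voxel_size=(1, 1, 1),
                           channel_roles={0: "DAPI", 1: "PMP22"})
        labels = segment_nuclei(stack, SegmentationConfig(blur_sigma=0, min_voxels=5))
        crop, _ = crop_nucleus(stack, labels, 1, margin=2)
        assert int(crop.channel("PMP22").sum()) == int(stack.channel("PMP22").sum())

    def test_unknown_label(self, clean_scene):
        stack, _ = clean_scene
        labels = segment_nuclei(stack)
        with pytest.raises(KeyError):
            crop_nucleus(stack, labels, 999)
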