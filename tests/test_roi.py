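import numpy as np
import pytest

from lynsu.evaluation import iou3d
from lynsu.io_formats import BoundingBox2D, LabelVolume, VolumeStack
from lynsu.roi import (
    CUBE_SHAPE,
    STD_SHAPE,
    Cube,
    Region3D,
    ROIGeometry,
    StandardizedROI,
    box_to_roi3d,
    build_training_cubes,
    restore,
    sliding_windows,
    standardize,
    stitch,
)


def _dummy_roi(fill: int = 0) -> StandardizedROI:
    geometry = ROIGeometry(
        box=(0, 168, 0, 168), full_shape=(124, 168, 168),
        roi_shape=(124, 168, 168), pad_before=0, pad_after=0,
    )
    data = np.full(STD_SHAPE, fill, dtype=np.uint8)
    return StandardizedROI(data=data, geometry=geometry, source_id="dummy")


class TestBoxToRoi3d:
    def test_margin_zero(self):
        vol = VolumeStack(np.zeros((6, 60, 60), dtype=np.uint8))
        region = box_to_roi3d(BoundingBox2D("AL", 10, 10, 50, 50), vol, margin_frac=0.0)
        assert region.data.shape == (6, 40, 40)
        assert region.box == (10, 50, 10, 50)

    def test_margin_dilation_arithmetic(self):
        # 5% of a 40-px box = 2 px per side
        vol = VolumeStack(np.zeros((4, 100, 100), dtype=np.uint8))
        region = box_to_roi3d(BoundingBox2D("AL", 30, 30, 70, 70), vol, margin_frac=0.05)
        assert region.box == (28, 72, 28, 72)

    def test_corner_box_clipped_at_zero(self):
        vol = VolumeStack(np.zeros((4, 50, 50), dtype=np.uint8))
        region = box_to_roi3d(BoundingBox2D("CX", 0, 0, 20, 20), vol, margin_frac=0.1)
        assert region.box == (0, 22, 0, 22)

    def test_z_extent_is_full_depth(self):
        vol = VolumeStack(np.zeros((17, 40, 40), dtype=np.uint8))
        region = box_to_roi3d(BoundingBox2D("AL", 5, 5, 20, 20), vol)
        assert region.data.shape[0] == 17


class TestStandardize:
    def test_identity_shape(self):
        region = Region3D(
            data=np.random.default_rng(0).integers(0, 256, STD_SHAPE).astype(np.uint8),
            mask=None, box=(0, 168, 0, 168), full_shape=STD_SHAPE,
        )
        roi = standardize(region)
        np.testing.assert_array_equal(roi.data, region.data)
        assert roi.geometry.pad_before == roi.geometry.pad_after == 0

    def test_padding_arithmetic_even(self):
        region = Region3D(
            data=np.full((100, 50, 50), 9, dtype=np.uint8), mask=None,
            box=(0, 50, 0, 50), full_shape=(100, 60, 60),
        )
        roi = standardize(region)
        assert roi.geometry.pad_before == 12 and roi.geometry.pad_after == 12
        assert (roi.data[:12] == 0).all() and (roi.data[-12:] == 0).all()

    def test_padding_extra_layer_at_far_end(self):
        region = Region3D(
            data=np.full((101, 50, 50), 9, dtype=np.uint8), mask=None,
            box=(0, 50, 0, 50), full_shape=(101, 60, 60),
        )
        roi = standardize(region)
        assert roi.geometry.pad_before == 11 and roi.geometry.pad_after == 12

    def test_constant_region_stays_constant(self):
        region = Region3D(
            data=np.full((64, 30, 45), 77, dtype=np.uint8), mask=None,
            box=(0, 30, 0, 45), full_shape=(64, 40, 50),
        )
        roi = standardize(region)
        core = roi.data[roi.geometry.pad_before : roi.geometry.pad_before + 64]
        assert (core == 77).all()

    def test_too_deep_rejected(self):
        region = Region3D(
            data=np.zeros((125, 10, 10), dtype=np.uint8), mask=None,
            box=(0, 10, 0, 10), full_shape=(125, 10, 10),
        )
        with pytest.raises(ValueError, match="depth"):
            standardize(region)


class TestSlidingWindows:
    def test_36_windows_without_mirror(self):
        # ((124-64)/20+1) * ((168-128)/20+1)^2 = 4*3*3
        cubes = sliding_windows(_dummy_roi(), stride=20, mirror=False)
        assert len(cubes) == 36
        assert len({c.offset for c in cubes}) == 36

    def test_72_windows_with_mirror(self):
        cubes = sliding_windows(_dummy_roi(), stride=20, mirror=True)
        assert len(cubes) == 72
        assert sum(c.mirrored for c in cubes) == 36

    def test_stride_divisibility_asserted(self):
        with pytest.raises(ValueError, match="divisible"):
            sliding_windows(_dummy_roi(), stride=19)

    def test_windows_lie_inside(self):
        for cube in sliding_windows(_dummy_roi(), stride=(60, 40, 40)):
            for o, c, s in zip(cube.offset, CUBE_SHAPE, STD_SHAPE):
                assert 0 <= o and o + c <= s

    def test_mirrored_data_is_z_flip(self, small_phantom):
        box = [b for b in small_phantom.boxes if b.roi_class == "CX"][0]
        roi = standardize(box_to_roi3d(box, small_phantom.volume))
        cubes = sliding_windows(roi, stride=(60, 40, 40), mirror=True)
        plain = [c for c in cubes if not c.mirrored]
        flipped = [c for c in cubes if c.mirrored]
        np.testing.assert_array_equal(plain[0].data[::-1], flipped[0].data)


class TestBuildTrainingCubes:
    def test_one_brain_bilateral_is_144(self, small_phantom):
        brains = [(small_phantom.volume, small_phantom.masks, small_phantom.boxes)]
        cubes = build_training_cubes(brains, "MB_CAL")
        assert len(cubes) == 144

    def test_one_brain_midline_is_72(self, small_phantom):
        brains = [(small_phantom.volume, small_phantom.masks, small_phantom.boxes)]
        assert len(build_training_cubes(brains, "CX")) == 72

    def test_missing_box_raises(self, small_phantom):
        boxes = [b for b in small_phantom.boxes if b.roi_class != "AL"]
        brains = [(small_phantom.volume, small_phantom.masks, boxes)]
        with pytest.raises(ValueError, match="no box"):
            build_training_cubes(brains, "AL")

    def test_cubes_carry_masks_and_source(self, small_phantom):
        brains = [(small_phantom.volume, small_phantom.masks, small_phantom.boxes)]
        cubes = build_training_cubes(brains, "CX", stride=(60, 40, 40))
        assert all(c.mask is not None for c in cubes)
        assert all(c.source_id == small_phantom.volume.source_id for c in cubes)


class TestStitch:
    def test_single_full_cover_identity(self):
        # a minimal 8-cube cover with identical constant probabilities
        roi = _dummy_roi()
        cubes = sliding_windows(roi, stride=(60, 40, 40))
        probs = np.full(CUBE_SHAPE + (2,), 0.5)
        out = stitch([(c, probs) for c in cubes])
        np.testing.assert_allclose(out, 0.5)

    def test_rows_sum_to_one(self, rng):
        roi = _dummy_roi()
        cubes = sliding_windows(roi, stride=(60, 40, 40))
        pairs = []
        for c in cubes:
            p1 = rng.random(CUBE_SHAPE)
            pairs.append((c, np.stack([p1, 1 - p1], axis=-1)))
        out = stitch(pairs)
        np.testing.assert_allclose(out.sum(axis=-1), 1.0, atol=1e-9)

    def test_matches_bruteforce_accumulation(self, rng):
        # independent oracle: explicit per-cube, per-z-layer accumulation
        roi = _dummy_roi()
        cubes = sliding_windows(roi, stride=(60, 40, 40), mirror=True)[:6]
        pairs = [(c, rng.random(CUBE_SHAPE + (2,))) for c in cubes]

        accum = np.zeros(STD_SHAPE + (2,))
        count = np.zeros(STD_SHAPE)
        for cube, probs in pairs:
            p = probs[::-1] if cube.mirrored else probs
            z0, y0, x0 = cube.offset
            for dz in range(CUBE_SHAPE[0]):
                accum[z0 + dz, y0 : y0 + 128, x0 : x0 + 128] += p[dz]
                count[z0 + dz, y0 : y0 + 128, x0 : x0 + 128] += 1

        covered = count > 0
        with pytest.raises(ValueError, match="zero cubes"):
            stitch(pairs)  # 6 cubes do not cover the whole ROI
        # compare on a fully covering set instead
        pairs_full = [(c, rng.random(CUBE_SHAPE + (2,))) for c in sliding_windows(roi, stride=(60, 40, 40))]
        out = stitch(pairs_full)
        accum2 = np.zeros(STD_SHAPE + (2,))
        count2 = np.zeros(STD_SHAPE)
        for cube, probs in pairs_full:
            z0, y0, x0 = cube.offset
            for dz in range(CUBE_SHAPE[0]):
                accum2[z0 + dz, y0 : y0 + 128, x0 : x0 + 128] += probs[dz]
                count2[z0 + dz, y0 : y0 + 128, x0 : x0 + 128] += 1
        np.testing.assert_allclose(out, accum2 / count2[..., None], atol=1e-6)
        assert covered.sum() > 0  # sanity on the partial-cover bookkeeping


class TestRestore:
    def test_identity_geometry(self, rng):
        roi = _dummy_roi()
        probs = rng.random(STD_SHAPE + (2,))
        labels = restore(probs, roi.geometry, (124, 168, 168))
        expected = (probs[..., 1] > probs[..., 0]).astype(np.int64)
        np.testing.assert_array_equal(labels.data, expected)

    def test_all_background(self):
        roi = _dummy_roi()
        probs = np.zeros(STD_SHAPE + (2,))
        probs[..., 0] = 1.0
        labels = restore(probs, roi.geometry, (124, 168, 168))
        assert not labels.data.any()

    def test_tie_goes_to_background(self):
        roi = _dummy_roi()
        probs = np.full(STD_SHAPE + (2,), 0.5)
        labels = restore(probs, roi.geometry, (124, 168, 168))
        assert not labels.data.any()

    def test_shape_mismatch_rejected(self):
        roi = _dummy_roi()
        with pytest.raises(ValueError, match="shape"):
            restore(np.zeros(STD_SHAPE + (2,)), roi.geometry, (10, 10, 10))

    def test_mask_round_trip_iou(self, small_phantom):
        # standardize -> restore of the true mask keeps 3D IoU >= 0.9
        for name in ("MB_CAL", "CX"):
            mask = small_phantom.masks[name]
            box = [b for b in small_phantom.boxes if b.roi_class == name][0]
            region = box_to_roi3d(box, small_phantom.volume, mask=mask)
            roi = standardize(region)
            fg = (roi.mask > 0).astype(np.float64)
            probs = np.stack([1 - fg, fg], axis=-1)
            back = restore(probs, roi.geometry, small_phantom.volume.shape)
            gt = np.zeros(small_phantom.volume.shape, dtype=np.int64)
            y0, y1, x0, x1 = roi.geometry.box
            gt[:, y0:y1, x0:x1] = mask.data[:, y0:y1, x0:x1]
            assert iou3d(gt, back.data) >= 0.9
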