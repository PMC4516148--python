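import numpy as np
import pytest

from fibroid3d.contour_segmentation import (
    Contour,
    ContourValidationError,
    InterpolationError,
    KeySliceSet,
    cross_plane_correct,
    interpolate_between,
    load_contours,
    propagate_segmentation,
    rasterize_contour,
    save_contours,
)
from fibroid3d.phantom import simulate_key_slice_tracing
from fibroid3d.reader_study import segmentation_metrics
from fibroid3d.volume_io import BODY, ENDOMETRIUM, FIBROID, LabelMap


def square(x0, y0, side, structure=BODY, k=0):
    return Contour(
        structure, k, [(x0, y0), (x0 + side, y0), (x0 + side, y0 + side), (x0, y0 + side)]
    )


def disk_mask(shape, center, radius):
    x, y = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    return (x - center[0]) ** 2 + (y - center[1]) ** 2 <= radius**2


class TestContourValidation:
    def test_two_vertex_contour_rejected(self):
        with pytest.raises(ContourValidationError):
            Contour(BODY, 0, [(0, 0), (1, 1)])

    def test_self_intersecting_bowtie_rejected(self):
        with pytest.raises(ContourValidationError):
            Contour(BODY, 0, [(0, 0), (2, 2), (2, 0), (0, 2)])

    def test_clockwise_input_normalized_to_counterclockwise(self):
        c = Contour(BODY, 0, [(0, 0), (0, 2), (2, 2), (2, 0)])
        assert c.polygon.exterior.is_ccw

    def test_explicitly_closed_ring_accepted(self):
        c = Contour(BODY, 0, [(0, 0), (2, 0), (2, 2), (0, 2), (0, 0)])
        assert len(c.vertices_mm) == 4


class TestRasterize:
    def test_square_aligned_with_voxel_centers_counts_boundary_as_interior(self):
        # corners on voxel centers 2..12: 11x11 centers inside-or-on-boundary
        mask = rasterize_contour(square(2.0, 2.0, 10.0), (20, 20), (1.0, 1.0))
        assert mask.sum() == 121

    def test_half_offset_square_gives_exact_interior_count(self):
        # boundary at x=1.5..11.5 never touches a center: exactly 10x10 inside
        mask = rasterize_contour(square(1.5, 1.5, 10.0), (20, 20), (1.0, 1.0))
        assert mask.sum() == 100

    def test_circle_area_matches_analytic_within_3_percent(self):
        theta = np.linspace(0, 2 * np.pi, 256, endpoint=False)
        verts = np.column_stack([15 + 10 * np.cos(theta), 15 + 10 * np.sin(theta)])
        mask = rasterize_contour(Contour(BODY, 0, verts), (31, 31), (1.0, 1.0))
        assert mask.sum() == pytest.approx(np.pi * 100, rel=0.03)

    def test_anisotropic_spacing_scales_the_footprint(self):
        mask = rasterize_contour(square(0.5, 0.5, 9.0), (30, 30), (0.5, 1.0))
        # x: centers at 0.5mm steps -> 19 columns; y: 1mm steps -> 9-10 rows
        assert mask.any()
        cols = np.flatnonzero(mask.any(axis=1))
        rows = np.flatnonzero(mask.any(axis=0))
        assert len(cols) == pytest.approx(19, abs=1)
        assert len(rows) == pytest.approx(10, abs=1)


class TestInterpolateBetween:
    def test_identical_masks_reproduce_themselves(self):
        m = disk_mask((40, 40), (20, 20), 10)
        for out in interpolate_between(m, m, 3):
            assert np.array_equal(out, m)

    def test_concentric_disks_interpolate_to_mean_radius(self):
        a = disk_mask((64, 64), (32, 32), 10)
        b = disk_mask((64, 64), (32, 32), 20)
        mid = interpolate_between(a, b, 1)[0]
        r_eq = np.sqrt(mid.sum() / np.pi)
        assert r_eq == pytest.approx(15.0, abs=1.0)
        # the midpoint disk lies between the endpoint disks
        assert np.all(mid[a])
        assert np.all(b[mid])

    def test_taper_to_empty_is_strictly_decreasing(self):
        a = disk_mask((40, 40), (20, 20), 12)
        empty = np.zeros_like(a)
        areas = [m.sum() for m in interpolate_between(a, empty, 3)]
        assert areas[0] < a.sum()
        assert all(x > y for x, y in zip(areas, areas[1:]))
        assert all(a > 0 for a in areas)

    def test_both_empty_raises(self):
        empty = np.zeros((10, 10), dtype=bool)
        with pytest.raises(InterpolationError):
            interpolate_between(empty, empty, 2)

    def test_matches_per_column_interval_oracle_within_one_voxel(self):
        # masks whose rows are all identical reduce to 1D intervals; for
        # overlapping intervals SDF blending must match direct linear
        # interpolation of the interval endpoints to within one voxel
        # (disjoint cross-sections taper instead of translating, which is
        # inherent to distance-field interpolation)
        def interval_mask(lo, hi, n=50, rows=12):
            m = np.zeros((rows, n), dtype=bool)
            m[:, lo : hi + 1] = True
            return m

        cases = [((10, 30), (18, 38)), ((5, 40), (18, 25)), ((0, 10), (0, 30))]
        for (alo, ahi), (blo, bhi) in cases:
            a, b = interval_mask(alo, ahi), interval_mask(blo, bhi)
            n_between = 4
            for m_idx, mask in enumerate(interpolate_between(a, b, n_between), start=1):
                w = m_idx / (n_between + 1)
                lo = (1 - w) * alo + w * blo
                hi = (1 - w) * ahi + w * bhi
                cols = np.flatnonzero(mask[0])
                assert cols[0] == pytest.approx(lo, abs=1.0)
                assert cols[-1] == pytest.approx(hi, abs=1.0)


class TestPropagate:
    def test_single_key_slice_fills_only_that_slice(self):
        keyset = KeySliceSet.from_contours([square(2, 2, 10, BODY, k=4)])
        lm = propagate_segmentation(keyset, (20, 20, 10), (1, 1, 1))
        occupied = np.flatnonzero(lm.labels.any(axis=(0, 1)))
        assert list(occupied) == [4]

    def test_key_slices_reproduce_their_contours_exactly(self):
        keyset = KeySliceSet.from_contours(
            [square(2, 2, 10, BODY, k=0), square(4, 4, 6, BODY, k=6)]
        )
        lm = propagate_segmentation(keyset, (20, 20, 8), (1, 1, 1))
        assert np.array_equal(
            lm.labels[:, :, 0] == BODY, rasterize_contour(square(2, 2, 10), (20, 20), (1, 1))
        )
        assert np.array_equal(
            lm.labels[:, :, 6] == BODY, rasterize_contour(square(4, 4, 6), (20, 20), (1, 1))
        )
        # intermediate slices interpolate monotonically between the squares
        areas = [(lm.labels[:, :, k] == BODY).sum() for k in range(7)]
        assert all(x >= y for x, y in zip(areas, areas[1:]))

    def test_multi_part_slices_union_before_interpolation(self):
        parts = [square(2, 2, 4, FIBROID, k=0), square(10, 10, 4, FIBROID, k=0)]
        keyset = KeySliceSet.from_contours(parts)
        lm = propagate_segmentation(keyset, (20, 20, 2), (1, 1, 1))
        assert (lm.labels[:, :, 0] == FIBROID).sum() == 50  # 2 squares of 25

    def test_slices_beyond_first_last_key_slice_stay_empty(self):
        keyset = KeySliceSet.from_contours(
            [square(2, 2, 10, BODY, k=3), square(2, 2, 10, BODY, k=6)]
        )
        lm = propagate_segmentation(keyset, (20, 20, 10), (1, 1, 1))
        assert not lm.labels[:, :, :3].any()
        assert not lm.labels[:, :, 7:].any()
        assert all(lm.labels[:, :, k].any() for k in (3, 4, 5, 6))

    def test_key_slice_outside_grid_raises(self):
        keyset = KeySliceSet.from_contours([square(2, 2, 10, BODY, k=12)])
        with pytest.raises(IndexError):
            propagate_segmentation(keyset, (20, 20, 10), (1, 1, 1))

    def test_label_priority_resolves_overlaps(self):
        keyset = KeySliceSet.from_contours(
            [square(2, 2, 12, BODY, k=0), square(5, 5, 4, FIBROID, k=0)]
        )
        lm = propagate_segmentation(keyset, (20, 20, 1), (1, 1, 1))
        assert np.all(lm.labels[6:9, 6:9, 0] == FIBROID)
        assert (lm.labels[:, :, 0] == BODY).sum() == 13 * 13 - 25

    def test_contour_json_round_trip(self, tmp_path):
        keyset = KeySliceSet.from_contours(
            [square(2, 2, 10, BODY, k=0), square(5, 5, 3, FIBROID, k=2)]
        )
        path = tmp_path / "contours.json"
        save_contours(keyset, path)
        back = load_contours(path)
        assert back.structures() == keyset.structures()
        for c0, c1 in zip(keyset.all_contours(), back.all_contours()):
            np.testing.assert_allclose(c0.vertices_mm, c1.vertices_mm)


class TestCrossPlaneCorrect:
    def _labelmap(self, labels):
        return LabelMap(labels.astype(np.int16), (1.0, 1.0, 1.0))

    def test_satellite_speck_removed_main_component_kept(self):
        labels = np.zeros((20, 20, 8), dtype=np.int16)
        labels[4:14, 4:14, 2:6] = BODY
        labels[17, 17, 7] = BODY  # 1-voxel satellite
        labels[18, 17, 7] = BODY  # 2-voxel speck
        out = cross_plane_correct(self._labelmap(labels))
        assert not out.labels[15:, 15:, :].any()
        assert np.array_equal(out.labels[4:14, 4:14, 2:6], labels[4:14, 4:14, 2:6])

    def test_idempotent_on_consistent_truth(self, default_phantom):
        _, truth = default_phantom
        out = cross_plane_correct(truth.labelmap)
        assert np.array_equal(out.labels, truth.labelmap.labels)

    def test_endometrium_outside_body_is_emptied(self):
        labels = np.zeros((20, 20, 8), dtype=np.int16)
        labels[2:8, 2:8, 2:6] = BODY
        labels[12:16, 12:16, 2:6] = ENDOMETRIUM  # displaced fully outside
        out = cross_plane_correct(self._labelmap(labels))
        assert not (out.labels == ENDOMETRIUM).any()

    def test_small_fibroids_below_threshold_removed(self):
        labels = np.zeros((20, 20, 8), dtype=np.int16)
        labels[5:10, 5:10, 2:5] = FIBROID  # 75 voxels
        labels[15, 15, 6] = FIBROID  # 1 voxel
        out = cross_plane_correct(self._labelmap(labels), min_fibroid_voxels=5)
        assert (out.labels == FIBROID).sum() == 75

    def test_correction_never_adds_voxels(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            labels = rng.integers(0, 4, size=(15, 15, 6)).astype(np.int16)
            out = cross_plane_correct(LabelMap(labels, (1, 1, 1)))
            for s in (BODY, ENDOMETRIUM, FIBROID):
                assert np.all((out.labels == s) <= (labels == s))


class TestPhantomSegmentationQuality:
    def test_body_dice_at_step5_beats_095(self, iso_phantom, iso_segmentation_step5):
        _, truth = iso_phantom
        _, lm = iso_segmentation_step5
        dice, _ = segmentation_metrics(
            lm.labels == BODY, truth.labelmap.labels == BODY, lm.spacing
        )
        assert dice >= 0.95

    def test_key_slice_fidelity_after_correction(self, iso_phantom, iso_segmentation_step5):
        from fibroid3d.contour_segmentation import rasterize_slice

        _, truth = iso_phantom
        keyset, lm = iso_segmentation_step5
        for k in keyset.key_slices(BODY):
            manual = rasterize_slice(
                keyset.slice_contours(BODY, k), lm.shape[:2], lm.spacing[:2], lm.origin[:2]
            )
            # higher-priority structures overwrite the body label where they
            # overlap it; outside those, the tracing is reproduced exactly
            higher = (lm.labels[:, :, k] == ENDOMETRIUM) | (lm.labels[:, :, k] == FIBROID)
            assert np.array_equal(lm.labels[:, :, k] == BODY, manual & ~higher)

    def test_dice_non_decreasing_with_tracing_density(self):
        from fibroid3d.phantom import PhantomConfig, generate_phantom, sample_fibroid_specs

        for seed in (1, 2, 3):
            base = PhantomConfig(shape=(110, 80, 90), spacing=(1.0, 1.0, 1.0), seed=seed)
            fibs = sample_fibroid_specs(np.random.default_rng(seed), base)
            cfg = PhantomConfig(
                shape=base.shape, spacing=base.spacing, fibroids=fibs, seed=seed
            )
            _, truth = generate_phantom(cfg)
            dices = []
            for step in (10, 5, 2, 1):
                keyset = simulate_key_slice_tracing(truth, step, jitter=0.0, seed=seed)
                lm = cross_plane_correct(
                    propagate_segmentation(keyset, truth.labelmap.shape, truth.labelmap.spacing)
                )
                dice, _ = segmentation_metrics(
                    lm.labels == BODY, truth.labelmap.labels == BODY, lm.spacing
                )
                dices.append(dice)
            assert all(a <= b + 1e-12 for a, b in zip(dices, dices[1:]))
            assert dices[-1] == 1.0
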