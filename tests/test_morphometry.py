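"""Segmentation, object splitting, overlap rejection and length metrics."""

import numpy as np
import pytest

from crystalscope.io import IntensityImage
from crystalscope.morphometry import (
    MorphometryConfig,
    ObjectStatus,
    measure_length,
    otsu_threshold,
    reject_overlaps,
    run_morphometry,
    watershed_split,
)
from crystalscope.synth import NeedleFieldParams, generate_needle_field, _needle_coverage_patch


def brute_force_otsu(arr: np.ndarray, nbins: int = 256) -> float:
    """Independent oracle: exhaustive between-class-variance maximization."""
    counts, edges = np.histogram(arr, bins=nbins, range=(arr.min(), arr.max()))
    centers = (edges[:-1] + edges[1:]) / 2.0
    best_var, best_thr = -1.0, centers[0]
    total = counts.sum()
    for k in range(1, nbins):
        w0, w1 = counts[:k].sum(), counts[k:].sum()
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (counts[:k] * centers[:k]).sum() / w0
        mu1 = (counts[k:] * centers[k:]).sum() / w1
        var = (w0 / total) * (w1 / total) * (mu0 - mu1) ** 2
        if var > best_var:
            best_var, best_thr = var, centers[k - 1]
    return best_thr


def render_needle_mask(shape, center, theta_deg, length_px, width_px):
    rs, cs, cov = _needle_coverage_patch(shape, center, theta_deg, length_px, width_px)
    m = np.zeros(shape, dtype=bool)
    m[rs, cs] = cov > 0.5
    return m


class TestOtsu:
    def test_bimodal_image_split_between_modes(self, rng):
        arr = np.full((100, 100), 10.0)
        idx = rng.choice(10000, size=1000, replace=False)
        arr.ravel()[idx] = 100.0
        thr, mask = otsu_threshold(arr)
        assert 10.0 < thr < 100.0
        assert mask.sum() == 1000

    def test_matches_exhaustive_variance_search(self, rng):
        for _ in range(20):
            arr = np.concatenate(
                [rng.normal(30, 8, 600), rng.normal(120, 25, 400)]
            ).reshape(10, 100)
            arr = np.clip(arr, 0, None)
            thr, _ = otsu_threshold(arr)
            # same histogram bin as the brute-force scan
            assert abs(thr - brute_force_otsu(arr)) <= (arr.max() - arr.min()) / 256

    def test_intensity_inversion_selects_complement_class(self, rng):
        arr = np.full((64, 64), 10.0)
        idx = rng.choice(4096, size=400, replace=False)
        arr.ravel()[idx] = 100.0
        _, mask = otsu_threshold(arr)
        _, mask_inv = otsu_threshold(arr.max() - arr)
        np.testing.assert_array_equal(mask_inv, arr < 100.0)
        np.testing.assert_array_equal(mask, ~mask_inv)

    def test_constant_image_raises_degenerate_histogram(self):
        with pytest.raises(ValueError, match="degenerate histogram"):
            otsu_threshold(np.full((32, 32), 7.0))


class TestWatershedSplit:
    def test_disjoint_needles_keep_their_components(self):
        m1 = render_needle_mask((128, 128), (30, 60), 20.0, 40, 3)
        m2 = render_needle_mask((128, 128), (90, 60), 120.0, 40, 3)
        labels = watershed_split(m1 | m2)
        assert labels.max() == 2
        # label pixel sets equal the connected components
        assert len({labels[m1].min(), labels[m2].min()}) == 2
        assert np.all(labels[m1] == labels[m1][0])
        assert np.all(labels[m2] == labels[m2][0])

    def test_dumbbell_splits_into_two_blobs(self):
        mask = np.zeros((40, 60), dtype=bool)
        mask[15:24, 5:20] = True
        mask[15:24, 30:45] = True
        mask[19:21, 20:30] = True  # 2-px bridge
        labels = watershed_split(mask)
        assert labels.max() == 2
        assert labels[19, 12] != labels[19, 37]  # blob centers in different labels

    @pytest.mark.parametrize("theta", [0, 27, 45, 77, 120, 160])
    def test_single_rotated_needle_is_never_oversplit(self, theta):
        mask = render_needle_mask((110, 110), (55, 55), theta, 40, 3)
        assert watershed_split(mask).max() == 1

    def test_convex_blob_stays_one_label(self):
        rr, cc = np.mgrid[0:64, 0:64]
        blob = (rr - 32) ** 2 + (cc - 32) ** 2 <= 15**2
        assert watershed_split(blob).max() == 1

    def test_empty_mask_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="empty"):
            labels = watershed_split(np.zeros((16, 16), dtype=bool))
        assert labels.max() == 0

    def test_foreground_partition_is_conserved(self, rng):
        params = NeedleFieldParams(seed=21, n_needles=30)
        image, _ = generate_needle_field(params)
        thr, mask = otsu_threshold(image)
        labels = watershed_split(mask)
        np.testing.assert_array_equal(labels > 0, mask)


class TestRejectOverlaps:
    def test_parallel_needles_far_apart_both_pass(self):
        m1 = np.argwhere(render_needle_mask((128, 128), (40, 64), 0.0, 40, 3))
        m2 = np.argwhere(render_needle_mask((128, 128), (80, 64), 0.0, 40, 3))
        objs = reject_overlaps([m1, m2])
        assert all(o.status is ObjectStatus.PASSED for o in objs)

    def test_perpendicular_crossing_of_stubby_needles_both_fail(self):
        # rasterized-rectangle oracle: axis-aligned bounding boxes of the two
        # needles, intersection pixel count over own-box pixel count
        a = np.argwhere(render_needle_mask((64, 64), (32, 32), 0.0, 15, 5))
        b = np.argwhere(render_needle_mask((64, 64), (32, 32), 90.0, 15, 5))
        def box(p):
            g = np.zeros((64, 64), dtype=bool)
            g[p[:, 0].min(): p[:, 0].max() + 1, p[:, 1].min(): p[:, 1].max() + 1] = True
            return g
        boxes = [box(a), box(b)]
        oracle = [(boxes[0] & boxes[1]).sum() / boxes[k].sum() for k in (0, 1)]
        assert min(oracle) > 0.2  # the stubby-crossing regime
        objs = reject_overlaps([a, b])
        assert all(o.status is ObjectStatus.FAILED_OVERLAP for o in objs)
        for o, frac in zip(objs, oracle):
            assert o.overlap_fraction == pytest.approx(frac, abs=0.1)

    def test_single_needle_passes(self):
        a = np.argwhere(render_needle_mask((64, 64), (32, 32), 30.0, 30, 3))
        (obj,) = reject_overlaps([a])
        assert obj.status is ObjectStatus.PASSED
        assert obj.overlap_fraction == 0.0

    def test_small_objects_fail_on_size(self):
        speck = np.array([[5, 5], [5, 6], [6, 5]])
        (obj,) = reject_overlaps([speck], min_object_px=8)
        assert obj.status is ObjectStatus.FAILED_SIZE

    def test_raising_threshold_never_decreases_passes(self):
        rng = np.random.default_rng(0)
        sets = []
        for _ in range(12):
            c = rng.uniform(30, 220, 2)
            sets.append(
                np.argwhere(
                    render_needle_mask((256, 256), c, rng.uniform(0, 180), 30, 3)
                )
            )
        sets = [s for s in sets if len(s)]
        passes = []
        for thr in (0.05, 0.1, 0.2, 0.4, 0.8):
            objs = reject_overlaps(sets, overlap_fraction_max=thr)
            passes.append(sum(o.status is ObjectStatus.PASSED for o in objs))
        assert passes == sorted(passes)


class TestMeasureLength:
    def test_horizontal_segment_boundary_convention(self):
        pixels = np.array([[10, c] for c in range(5, 46)])  # 1 x 41 px
        length_um, orient = measure_length(pixels, pixel_size_um=0.5)
        assert length_um == pytest.approx(20.5, abs=0.5)
        assert orient == pytest.approx(0.0, abs=2.0)

    def test_single_pixel_has_one_pixel_extent(self):
        length_um, orient = measure_length(np.array([[3, 4]]), pixel_size_um=0.7)
        assert length_um == pytest.approx(0.7)
        assert orient == 0.0

    def test_rotation_by_90_preserves_length_and_shifts_orientation(self):
        pixels = np.array([[10, c] for c in range(5, 46)])
        rotated = pixels[:, ::-1].copy()  # (row, col) swap = 90 deg rotation
        l1, o1 = measure_length(pixels, 1.0)
        l2, o2 = measure_length(rotated, 1.0)
        assert l2 == pytest.approx(l1, rel=1e-9)
        # thin-object chord ambiguity is atan2(1, 41) ~ 1.4 deg per object
        assert (o2 - o1) % 180 == pytest.approx(90.0, abs=3.0)

    def test_brute_force_feret_oracle_on_random_blobs(self, rng):
        for _ in range(5):
            pix = np.unique(rng.integers(0, 12, size=(30, 2)), axis=0)
            length_um, _ = measure_length(pix, 1.0)
            corners = np.concatenate(
                [pix + d for d in ([-0.5, -0.5], [-0.5, 0.5], [0.5, -0.5], [0.5, 0.5])]
            )
            d = corners[:, None, :] - corners[None, :, :]
            expected = np.sqrt((d**2).sum(axis=2)).max()
            assert length_um == pytest.approx(expected, rel=1e-9)

    def test_skeleton_metric_close_to_feret_for_straight_needles(self):
        pix = np.argwhere(render_needle_mask((64, 64), (32, 32), 0.0, 30, 3))
        feret, _ = measure_length(pix, 1.0, metric="feret")
        skel, _ = measure_length(pix, 1.0, metric="skeleton")
        assert skel == pytest.approx(feret, abs=6.0)


class TestRunMorphometry:
    def test_noiseless_disjoint_field_counts_exactly(self):
        image, _ = generate_needle_field(NeedleFieldParams(seed=1))
        res = run_morphometry(image)
        assert res.n_passed == 40
        assert res.n_total == 40

    def test_crossing_pairs_rejected_not_counted(self):
        image, _ = generate_needle_field(
            NeedleFieldParams(seed=1, n_forced_crossing_pairs=3)
        )
        res = run_morphometry(image)
        n_failed = sum(1 for o in res.objects if o.status is ObjectStatus.FAILED_OVERLAP)
        assert res.n_passed == 40
        assert n_failed >= 6

    def test_density_identity(self):
        image, _ = generate_needle_field(NeedleFieldParams(seed=9))
        res = run_morphometry(image)
        assert res.density_per_mm2 * res.analysis_area_mm2 == pytest.approx(res.n_passed)

    def test_background_only_field_has_no_objects(self):
        image = IntensityImage(np.full((128, 128), 10.0), pixel_size_um=0.5)
        res = run_morphometry(image)
        assert res.n_passed == 0
        assert res.n_total == 0
        assert res.density_per_mm2 == 0.0

    def test_plaque_mask_restricts_analysis_area(self):
        image, _ = generate_needle_field(NeedleFieldParams(seed=1))
        mask = np.zeros(image.shape, dtype=bool)
        mask[:, :256] = True
        res = run_morphometry(image, plaque_mask=mask)
        assert res.analysis_area_mm2 == pytest.approx(image.area_mm2() / 2)
        assert res.n_passed <= 40
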