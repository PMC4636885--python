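"""Segmentation and n-sigma positivity scoring of fluorescence FOVs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skimage.filters import threshold_otsu as skimage_otsu

from sonopore import (
    DegenerateDataError,
    FieldOfViewImages,
    FovQuantification,
    ObjectSet,
    classify_positive,
    generate_fov,
    otsu_threshold,
    quantify_fov,
    replicate_average,
    segment_cell_boundaries,
    segment_nuclei,
)


def brute_force_otsu_partition(raster):
    """Oracle: minimize intra-class weighted variance over every candidate split."""
    flat = np.asarray(raster, dtype=float).ravel()
    values = np.unique(flat)
    best, best_t = np.inf, None
    for i in range(values.size - 1):
        t = 0.5 * (values[i] + values[i + 1])
        lo, hi = flat[flat <= t], flat[flat > t]
        w = (len(lo) * lo.var() + len(hi) * hi.var()) / flat.size
        if w < best - 1e-12:
            best, best_t = w, t
    return best_t


def _disk(img, center, radius, value):
    rr, cc = np.ogrid[: img.shape[0], : img.shape[1]]
    img[(rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2] += value


class TestOtsuThreshold:
    def test_perfectly_bimodal_image_split_between_modes(self):
        img = np.array([[10, 10, 200, 200]] * 4)
        t = otsu_threshold(img)
        assert 10 < t < 200

    def test_four_pixel_image_matches_exhaustive_partition(self):
        img = np.array([0, 0, 100, 100])
        assert otsu_threshold(img) == brute_force_otsu_partition(img)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_enumeration_oracle_on_random_images(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 40, size=(12, 12))
        assert otsu_threshold(img) == pytest.approx(brute_force_otsu_partition(img))

    @given(
        data=st.lists(st.integers(min_value=0, max_value=255), min_size=4, max_size=60)
    )
    @settings(max_examples=60, deadline=None)
    def test_property_agrees_with_oracle(self, data):
        img = np.asarray(data)
        if np.unique(img).size < 2:
            with pytest.raises(DegenerateDataError):
                otsu_threshold(img)
        else:
            assert otsu_threshold(img) == pytest.approx(
                brute_force_otsu_partition(img)
            )

    @pytest.mark.parametrize("seed", range(3))
    def test_partition_agrees_with_library_otsu(self, seed):
        # independent cross-check: same foreground mask as scikit-image
        rng = np.random.default_rng(seed)
        img = np.concatenate(
            [rng.normal(80, 10, 600), rng.normal(200, 15, 300)]
        ).reshape(30, 30)
        img = np.clip(np.rint(img), 0, 4095).astype(np.uint16)
        ours = img > otsu_threshold(img)
        theirs = img > skimage_otsu(img)
        np.testing.assert_array_equal(ours, theirs)

    def test_constant_image_rejected(self):
        with pytest.raises(DegenerateDataError):
            otsu_threshold(np.full((8, 8), 7))


@pytest.fixture
def disk_fov():
    """Noiseless FOV with 12 disjoint bright nuclei on a flat background."""
    blue = np.full((200, 200), 100.0)
    centers = [(r, c) for r in (30, 80, 130, 180) for c in (40, 100, 160)]
    for ctr in centers:
        _disk(blue, ctr, 7, 1200)
    blue = blue.astype(np.uint16)
    flat = np.full((200, 200), 100, dtype=np.uint16)
    return FieldOfViewImages(blue=blue, green=flat.copy(), red=flat.copy()), centers


class TestSegmentNuclei:
    def test_disjoint_disks_found_exactly(self, disk_fov):
        fov, centers = disk_fov
        objs = segment_nuclei(fov)
        assert objs.n_objects == len(centers)

    def test_centroids_within_one_pixel_of_ground_truth(self):
        fov, truth = generate_fov(n_cells=40, seed=7, background_sd=6.0)
        objs = segment_nuclei(fov)
        assert objs.n_objects == truth.n_cells
        found = objs.centroids()
        for ctr in truth.centers_px:
            d = np.linalg.norm(found - ctr, axis=1).min()
            assert d <= 1.0

    def test_speck_noise_only_image_yields_empty_set(self):
        # no nuclei, just isolated hot pixels: everything Otsu lifts out is
        # below the minimum object area, so the result is empty, not an error
        rng = np.random.default_rng(3)
        blue = np.full((128, 128), 100, dtype=np.uint16)
        hot = rng.choice(blue.size, size=60, replace=False)
        blue.ravel()[hot] = 900
        fov = FieldOfViewImages(blue=blue, green=blue.copy(), red=blue.copy())
        objs = segment_nuclei(fov)
        assert objs.n_objects == 0


class TestSegmentCellBoundaries:
    def test_one_cell_object_per_nucleus_and_superset(self):
        fov, truth = generate_fov(n_cells=25, transfected_fraction=0.2, seed=11)
        nuclei = segment_nuclei(fov)
        cells = segment_cell_boundaries(fov, nuclei)
        assert cells.n_objects == nuclei.n_objects == truth.n_cells
        nuc, cel = nuclei.label_raster, cells.label_raster
        assert np.all(cel[nuc > 0] == nuc[nuc > 0])

    def test_zero_green_degenerates_to_nuclei(self, disk_fov):
        fov, _ = disk_fov
        fov = FieldOfViewImages(
            blue=fov.blue, green=np.zeros_like(fov.green), red=fov.red
        )
        nuclei = segment_nuclei(fov)
        cells = segment_cell_boundaries(fov, nuclei)
        np.testing.assert_array_equal(cells.label_raster > 0, nuclei.label_raster > 0)
        assert cells.n_objects == nuclei.n_objects

    def test_touching_cells_split_by_watershed(self):
        blue = np.full((120, 120), 100.0)
        green = np.full((120, 120), 100.0)
        for ctr in ((60, 45), (60, 75)):
            _disk(blue, ctr, 8, 1200)
            _disk(green, ctr, 16, 500)  # cytoplasms overlap between the nuclei
        fov = FieldOfViewImages(
            blue=blue.astype(np.uint16),
            green=green.astype(np.uint16),
            red=np.full((120, 120), 100, dtype=np.uint16),
        )
        cells = segment_cell_boundaries(fov)
        assert cells.n_objects == 2

    def test_no_nuclei_returns_empty_set(self):
        rng = np.random.default_rng(5)
        noise = np.full((96, 96), 100, dtype=np.uint16)
        hot = rng.choice(noise.size, size=40, replace=False)
        noise.ravel()[hot] = 900
        fov = FieldOfViewImages(blue=noise, green=noise.copy(), red=noise.copy())
        cells = segment_cell_boundaries(fov)
        assert cells.n_objects == 0


def _object_set(obj_means, bg_mean, bg_std, channel="green"):
    """Minimal ObjectSet with prescribed statistics."""
    side = int(np.ceil(np.sqrt(len(obj_means)))) + 2
    labels = np.zeros((side, side), dtype=int)
    labels.ravel()[: len(obj_means)] = np.arange(1, len(obj_means) + 1)
    o = ObjectSet(label_raster=labels, kind="cell_boundary", background_n=12)
    o.object_means[channel] = np.asarray(obj_means, dtype=float)
    o.background_mean[channel] = bg_mean
    o.background_std[channel] = bg_std
    return o


class TestClassifyPositive:
    def test_three_sigma_boundary_cases(self):
        objs = _object_set([10.0, 7.9, 8.0], bg_mean=5.0, bg_std=1.0)
        np.testing.assert_array_equal(
            classify_positive(objs, "green", n=3), [True, False, True]
        )

    def test_inclusive_at_n_zero(self):
        objs = _object_set([5.0], bg_mean=5.0, bg_std=1.0)
        assert classify_positive(objs, "green", n=0)[0]

    def test_monotone_in_n(self):
        rng = np.random.default_rng(0)
        objs = _object_set(rng.uniform(0, 20, 3), bg_mean=8.0, bg_std=2.0)
        pos3 = classify_positive(objs, "green", n=3)
        pos2 = classify_positive(objs, "green", n=2)
        assert np.all(pos2 | ~pos3)  # positives at n=3 are a subset of n=2

    @given(
        a=st.floats(min_value=0.01, max_value=50.0),
        b=st.floats(min_value=-100.0, max_value=100.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_affine_invariance(self, a, b):
        # objects off the exact decision boundary (a tie is not preserved by
        # floating-point rescaling, though it is mathematically)
        means = np.array([3.0, 7.9, 8.1, 12.5])
        base = _object_set(means, bg_mean=5.0, bg_std=1.0)
        scaled = _object_set(a * means + b, bg_mean=a * 5.0 + b, bg_std=a * 1.0)
        np.testing.assert_array_equal(
            classify_positive(base, "green", n=3),
            classify_positive(scaled, "green", n=3),
        )

    def test_empty_background_rejected(self):
        objs = _object_set([5.0], bg_mean=5.0, bg_std=1.0)
        objs.background_n = 0
        with pytest.raises(DegenerateDataError):
            classify_positive(objs, "green", n=3)


class TestQuantifyFov:
    def test_noiseless_round_trip_recovers_fractions_exactly(self):
        fov, truth = generate_fov(
            n_cells=40,
            transfected_fraction=0.1,
            apoptotic_fraction=0.05,
            background_sd=0.0,
            seed=21,
        )
        q = quantify_fov(fov)
        assert q.n_cells == truth.n_cells
        assert q.transfected_fraction == pytest.approx(truth.transfected_fraction)
        assert q.apoptotic_fraction == pytest.approx(truth.apoptotic_fraction)

    def test_all_negative_fov_scores_zero_fractions(self):
        fov, _ = generate_fov(
            n_cells=30, transfected_fraction=0.0, apoptotic_fraction=0.0, seed=3
        )
        q = quantify_fov(fov)
        assert q.n_cells == 30
        assert q.transfected_fraction == 0.0
        assert q.apoptotic_fraction == 0.0

    def test_empty_fov_reports_missing_fractions(self):
        rng = np.random.default_rng(9)
        noise = np.full((96, 96), 100, dtype=np.uint16)
        hot = rng.choice(noise.size, size=40, replace=False)
        noise.ravel()[hot] = 900
        fov = FieldOfViewImages(blue=noise, green=noise.copy(), red=noise.copy())
        q = quantify_fov(fov)
        assert q.n_cells == 0
        assert q.transfected_fraction is None
        assert q.apoptotic_fraction is None

    def test_channel_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            FieldOfViewImages(
                blue=np.zeros((4, 4), dtype=np.uint16),
                green=np.zeros((4, 5), dtype=np.uint16),
                red=np.zeros((4, 4), dtype=np.uint16),
            )

    def test_bit_range_enforced(self):
        over = np.full((4, 4), 5000, dtype=np.uint16)
        with pytest.raises(ValueError):
            FieldOfViewImages(blue=over, green=over.copy(), red=over.copy())


class TestReplicateAverage:
    def test_unweighted_mean_of_fractions(self):
        results = [
            FovQuantification(n_cells=50, n_transfected=2, n_apoptotic=0),
            FovQuantification(n_cells=100, n_transfected=6, n_apoptotic=0),
        ]
        # unweighted: (0.04 + 0.06)/2 = 0.05, not pooled 8/150
        assert replicate_average(results).transfected_fraction == pytest.approx(0.05)

    def test_single_fov_passthrough_and_empty_excluded(self):
        results = [
            FovQuantification(n_cells=0, n_transfected=0, n_apoptotic=0),
            FovQuantification(n_cells=20, n_transfected=3, n_apoptotic=1),
        ]
        summary = replicate_average(results)
        assert summary.n_fov == 1
        assert summary.transfected_fraction == pytest.approx(0.15)

    def test_matches_brute_force_mean_over_25_fovs(self):
        rng = np.random.default_rng(4)
        results = [
            FovQuantification(100, int(rng.integers(0, 10)), int(rng.integers(0, 3)))
            for _ in range(25)
        ]
        summary = replicate_average(results)
        assert summary.transfected_fraction == pytest.approx(
            sum(r.n_transfected / 100 for r in results) / 25
        )

    def test_all_empty_rejected(self):
        with pytest.raises(DegenerateDataError):
            replicate_average([FovQuantification(0, 0, 0)])
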