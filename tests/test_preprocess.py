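"""Preprocessing chain: hot pixels, probe normalization, Otsu,
Moore-Neighbor tracing, skeleton extraction, crop/resize, augmentation."""

import numpy as np
import pytest
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.filters import threshold_otsu as skimage_otsu

from l2l.errors import CalibrationError, DegenerateInputError, ParameterError
from l2l.fixtures import LeafSpec, make_leaf
from l2l.images import LeafImage, SkeletonImage
from l2l.preprocess import (
    PreprocessedSample,
    ProbeCalibration,
    augment,
    blade_mask_from_nir,
    crop_and_resize,
    extract_skeleton,
    normalize_channel,
    otsu_threshold,
    remove_hot_pixels,
    trace_boundary,
)


class TestRemoveHotPixels:
    def test_constant_image_unchanged(self):
        img = np.full((8, 8), 0.4)
        assert np.array_equal(remove_hot_pixels(img), img)

    def test_single_hot_center_replaced_by_neighbour_mean(self):
        img = np.zeros((5, 5))
        img[2, 2] = 1.0
        out = remove_hot_pixels(img)          # midrange criterion = 0.05
        assert out[2, 2] == 0.0
        assert np.array_equal(out, np.zeros((5, 5)))

    def test_pixel_equal_to_one_neighbour_survives(self):
        img = np.zeros((5, 5))
        img[2, 2] = 1.0
        img[1, 1] = 1.0                       # ties one neighbour: not "all" greater
        out = remove_hot_pixels(img)
        assert out[2, 2] == 1.0 and out[1, 1] == 1.0

    def test_decisions_use_input_not_partial_updates(self):
        # (2,2)=1.0 is hot; (2,3)=0.9 is shielded by its bright neighbour.
        # A sequential filter that first clears (2,2) would then see (2,3)
        # towering over an already-updated neighbourhood and clear it too.
        img = np.zeros((5, 7))
        img[2, 2] = 1.0
        img[2, 3] = 0.9
        out = remove_hot_pixels(img)
        assert out[2, 2] == pytest.approx(0.9 / 8)   # neighbour mean of the input
        assert out[2, 3] == 0.9                      # not hot w.r.t. the input

    def test_too_small_rejected(self):
        with pytest.raises(ParameterError):
            remove_hot_pixels(np.zeros((2, 5)))


class TestNormalizeChannel:
    def test_probe_endpoints_and_midpoint(self):
        cal = ProbeCalibration(m=0.1, M=0.9)
        ch = np.array([[0.1, 0.9], [0.5, 2.0]])
        out = normalize_channel(ch, cal)
        assert out[0, 0] == 0.0
        assert out[0, 1] == 1.0
        assert out[1, 0] == pytest.approx(0.5)
        assert out[1, 1] == 1.0               # clipped

    def test_invalid_calibration_rejected(self):
        with pytest.raises(CalibrationError):
            ProbeCalibration(m=0.5, M=0.5)


def brute_force_otsu(x, n_bins=256):
    """Independent oracle: per-threshold intraclass variance, direct loop."""
    x = np.asarray(x, dtype=np.float64).ravel()
    lo, hi = x.min(), x.max()
    edges = np.histogram_bin_edges(x, bins=n_bins, range=(lo, hi))
    best_t, best_v = None, np.inf
    for t in edges[1:-1]:
        c0, c1 = x[x < t], x[x >= t]
        if len(c0) == 0 or len(c1) == 0:
            continue
        within = len(c0) * np.var(c0) + len(c1) * np.var(c1)
        if within < best_v - 1e-12:           # strict: first minimum = lowest t
            best_v, best_t = within, t
    return best_t


class TestOtsu:
    def test_bimodal_separation(self):
        x = np.array([0.2] * 50 + [0.8] * 50).reshape(10, 10)
        t = otsu_threshold(x)
        assert 0.2 < t < 0.8
        assert np.array_equal(x > t, x == 0.8)

    def test_two_pixel_image(self):
        t = otsu_threshold(np.array([[0.0, 1.0]]))
        assert 0.0 < t < 1.0

    def test_matches_brute_force_on_random_images(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            x = rng.random((12, 12)) ** rng.uniform(0.5, 2.0)
            assert otsu_threshold(x) == pytest.approx(brute_force_otsu(x), abs=1e-12)

    def test_shift_invariance_of_split(self):
        rng = np.random.default_rng(1)
        x = rng.random((16, 16))
        t0 = otsu_threshold(x)
        t1 = otsu_threshold(x + 0.25)
        assert t1 - t0 == pytest.approx(0.25, abs=1e-9)

    def test_agrees_with_library_otsu(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([rng.normal(0.25, 0.05, 400), rng.normal(0.75, 0.05, 400)])
        x = np.clip(x, 0, 1).reshape(20, 40)
        assert otsu_threshold(x) == pytest.approx(skimage_otsu(x, nbins=256), abs=0.02)

    def test_constant_image_rejected(self):
        with pytest.raises(DegenerateInputError):
            otsu_threshold(np.full((4, 4), 0.3))


def random_blob(seed, side=48):
    """Smooth filled blob: single 4-connected component, no narrow necks."""
    from skimage.morphology import disk

    rng = np.random.default_rng(seed)
    field = ndimage.gaussian_filter(rng.standard_normal((side, side)), sigma=5)
    blob = field > np.quantile(field, 0.75)
    blob = ndimage.binary_opening(blob, structure=disk(2))
    blob = ndimage.binary_closing(blob, structure=disk(2))
    lab, n = ndimage.label(blob, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    return ndimage.binary_fill_holes(lab == 1 + int(np.argmax(sizes)))


class TestTraceBoundary:
    def test_single_pixel(self):
        b = np.zeros((5, 5), dtype=bool)
        b[2, 2] = True
        assert trace_boundary(b) == [(2, 2)]

    def test_filled_3x3_square_has_8_boundary_pixels(self):
        b = np.zeros((5, 5), dtype=bool)
        b[1:4, 1:4] = True
        path = trace_boundary(b)
        expected = {(r, c) for r in range(1, 4) for c in range(1, 4)} - {(2, 2)}
        assert set(path) == expected
        assert len(path) == 8

    @pytest.mark.parametrize("seed", range(8))
    def test_path_matches_background_adjacent_set_on_random_blobs(self, seed):
        # Sandwich characterization of the outer contour: every traced pixel
        # touches background within its 8-neighbourhood, and every pixel with
        # an edge (4-) contact to the background is traced.  Pixels touching
        # background only diagonally sit on 45° staircases that the Moore
        # walk legitimately crosses corner-to-corner.
        blob = random_blob(seed)
        path = set(trace_boundary(blob))
        adj8 = blob & ~ndimage.binary_erosion(blob, structure=np.ones((3, 3)))
        adj4 = blob & ~ndimage.binary_erosion(
            blob, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
        assert path <= set(map(tuple, np.argwhere(adj8)))
        assert set(map(tuple, np.argwhere(adj4))) <= path

    @pytest.mark.parametrize("seed", range(4))
    def test_path_is_closed_and_8_connected(self, seed):
        path = trace_boundary(random_blob(seed + 100))
        n = len(path)
        for i in range(n):
            r0, c0 = path[i]
            r1, c1 = path[(i + 1) % n]      # includes the closing step
            assert max(abs(r0 - r1), abs(c0 - c1)) == 1

    def test_empty_rejected(self):
        with pytest.raises(DegenerateInputError):
            trace_boundary(np.zeros((4, 4), dtype=bool))


class TestExtractSkeleton:
    @pytest.mark.parametrize("seed", range(5))
    def test_within_2px_hausdorff_of_ground_truth(self, seed):
        s = make_leaf(LeafSpec(side=128, seed=seed))
        nir = s.image.channel("NIR")
        nirn = normalize_channel(remove_hot_pixels(nir),
                                 ProbeCalibration.from_probes(nir, s.probes))
        det = extract_skeleton(nirn).mask
        gt = s.skeleton.mask
        d_gt = cKDTree(np.argwhere(det)).query(np.argwhere(gt))[0].max()
        d_det = cKDTree(np.argwhere(gt)).query(np.argwhere(det))[0].max()
        assert max(d_gt, d_det) <= 2.0

    def test_contains_full_traced_boundary(self):
        s = make_leaf(LeafSpec(side=128, seed=9))
        nir = s.image.channel("NIR")
        nirn = normalize_channel(nir, ProbeCalibration.from_probes(nir, s.probes))
        sk = extract_skeleton(nirn).mask
        blade = blade_mask_from_nir(nirn)
        for px in trace_boundary(blade):
            assert sk[px]

    def test_blank_image_rejected(self):
        with pytest.raises(DegenerateInputError):
            extract_skeleton(np.zeros((64, 64)))


class TestCropAndResize:
    def test_output_shapes(self):
        s = make_leaf(LeafSpec(side=128, seed=0))
        out = crop_and_resize(s.image, s.skeleton, side=64, blade_mask=s.blade_mask)
        assert out.image.channels.shape == (4, 64, 64)
        assert out.skeleton.shape == (64, 64)
        assert out.image.channels.min() >= 0 and out.image.channels.max() <= 1

    def test_offset_leaf_recentred(self):
        s = make_leaf(LeafSpec(side=128, seed=1))
        # embed the leaf off-centre in a larger frame
        big = np.zeros((4, 512, 512))
        big[:, 30:158, 210:338] = s.image.channels
        mask = np.zeros((512, 512), dtype=bool)
        mask[30:158, 210:338] = s.blade_mask
        sk = np.zeros((512, 512), dtype=bool)
        sk[30:158, 210:338] = s.skeleton.mask
        out = crop_and_resize(LeafImage(big, s.image.bands), SkeletonImage(sk),
                              side=256, blade_mask=mask)
        rows, cols = np.nonzero(out.skeleton.mask)
        blade = ndimage.binary_fill_holes(out.skeleton.mask)
        r, c = np.nonzero(blade)
        assert abs(r.mean() - 127.5) <= 2 and abs(c.mean() - 127.5) <= 2

    def test_empty_mask_rejected(self):
        s = make_leaf(LeafSpec(side=128, seed=2))
        with pytest.raises(DegenerateInputError):
            crop_and_resize(s.image, s.skeleton, side=64,
                            blade_mask=np.zeros((128, 128), dtype=bool))


class TestAugment:
    def _samples(self, n):
        out = []
        for i in range(n):
            s = make_leaf(LeafSpec(side=64, seed=i))
            out.append(PreprocessedSample(s.image, s.skeleton))
        return out

    def test_expansion_factor_three(self):
        assert len(augment(self._samples(1), seed=0)) == 3
        assert len(augment(self._samples(5), seed=0)) == 15

    def test_variants_binary_and_same_shape(self):
        out = augment(self._samples(2), seed=0)
        for s in out:
            assert s.skeleton.mask.dtype == bool
            assert s.image.channels.shape[1:] == s.skeleton.shape

    def test_deterministic_under_seed(self):
        a = augment(self._samples(2), seed=42)
        b = augment(self._samples(2), seed=42)
        for x, y in zip(a, b):
            assert np.array_equal(x.image.channels, y.image.channels)
            assert np.array_equal(x.skeleton.mask, y.skeleton.mask)

    def test_variants_differ_from_originals(self):
        out = augment(self._samples(1), seed=0)
        assert not np.array_equal(out[0].skeleton.mask, out[1].skeleton.mask) or \
            not np.array_equal(out[0].skeleton.mask, out[2].skeleton.mask)

    def test_empty_list_rejected(self):
        with pytest.raises(ParameterError):
            augment([], seed=0)
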