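"""Centerline extraction, VOI construction, and the reference segmenter."""

import numpy as np
import pytest
from scipy import ndimage

from spinelabel.canal import (Centerline, build_voi, centerline_from_truth,
                              centroid_error, extract_centerline,
                              train_canal_segmenter)
from spinelabel.phantom import PhantomConfig, generate_phantom


def make_line_mask(n_slices=10, ap=12, lr=7, shape=(10, 24, 16)):
    mask = np.zeros(shape, dtype=bool)
    mask[:, ap, lr] = True
    return mask


class TestExtractCenterline:
    def test_single_voxel_line_exact(self):
        spacing = (2.5, 1.17, 1.17)
        cl = extract_centerline(make_line_mask(), spacing)
        assert cl.slice_start == 0 and cl.n_slices == 10
        np.testing.assert_allclose(cl.pos_mm,
                                   np.tile([12 * 1.17, 7 * 1.17], (10, 1)))

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            extract_centerline(np.zeros((4, 4, 4), bool), (1, 1, 1))

    def test_interior_empty_slices_interpolated(self):
        mask = make_line_mask()
        mask[4:6] = False  # drop two interior slices
        cl = extract_centerline(mask, (1.0, 1.0, 1.0))
        np.testing.assert_allclose(cl.pos_mm, np.tile([12.0, 7.0], (10, 1)))

    def test_sinusoidal_canal_within_one_voxel(self):
        shape = (60, 64, 32)
        spacing = np.array([2.5, 1.17, 1.17])
        mask = np.zeros(shape, bool)
        s = np.arange(shape[0])
        ap_mm = 35.0 + 8.0 * np.sin(2 * np.pi * s / shape[0])
        jj, kk = np.meshgrid(np.arange(shape[1]) * spacing[1],
                             np.arange(shape[2]) * spacing[2], indexing="ij")
        for i in s:
            mask[i] = (jj - ap_mm[i]) ** 2 + (kk - 18.0) ** 2 <= 4.0**2
        cl = extract_centerline(mask, spacing)
        dev = np.abs(cl.pos_mm[:, 0] - ap_mm)
        assert dev.max() < spacing[1]

    def test_phantom_centerline_close_to_truth(self, thoracic_phantom):
        _, vol, truth = thoracic_phantom
        cl = extract_centerline(truth.canal_mask, vol.spacing)
        ref = centerline_from_truth(truth.canal_centerline, vol.spacing)
        err = centroid_error(cl, ref)
        assert err["distance_mm"].max() < 0.5 * vol.spacing[1:].max()


class TestVOI:
    def test_default_window_is_55px(self, truth_centerline):
        voi = build_voi(truth_centerline, 55)
        wins = voi.windows((10_000, 10_000, 10_000))  # no clipping
        width = wins[:, 1] - wins[:, 0]
        assert np.all(width == 55) and np.all(wins[:, 3] - wins[:, 2] == 55)

    def test_anterior_constraint_excludes_posterior(self, thoracic_phantom,
                                                    truth_centerline):
        _, vol, _ = thoracic_phantom
        voi = build_voi(truth_centerline, 55, anterior_constrained=True)
        mask = voi.mask(vol.shape)
        centers = voi.center_indices()
        for s, (ap_c, _) in zip(truth_centerline.slices, centers):
            hit = np.nonzero(mask[s].any(axis=1))[0]
            if hit.size:
                assert hit.max() <= ap_c  # boundary inclusive on anterior side

    def test_cross_section_one_is_centerline(self, thoracic_phantom,
                                             truth_centerline):
        _, vol, _ = thoracic_phantom
        voi = build_voi(truth_centerline, 1)
        mask = voi.mask(vol.shape)
        assert mask.sum() == truth_centerline.n_slices

    def test_invalid_cross_section(self, truth_centerline):
        with pytest.raises(ValueError):
            build_voi(truth_centerline, 0)

    def test_voi_translation_invariance(self):
        """Windows follow the centerline under rigid in-plane translation."""
        spacing = np.array([2.5, 1.17, 1.17])
        pos = np.column_stack([(np.arange(20) % 5 + 30.3) * 1.17,
                               np.full(20, 40.2 * 1.17)])
        base = Centerline(0, pos, spacing)
        voi = build_voi(base, 15)
        shifted = Centerline(0, pos + [10 * 1.17, 5 * 1.17], spacing)
        voi2 = build_voi(shifted, 15)
        big = (10_000, 10_000, 10_000)
        w1, w2 = voi.windows(big), voi2.windows(big)
        np.testing.assert_array_equal(w2[:, :2] - w1[:, :2], 10)  # 11.7/1.17
        np.testing.assert_array_equal(w2[:, 2:] - w1[:, 2:], 5)


class TestCentroidError:
    def test_identity_zero(self, truth_centerline):
        err = centroid_error(truth_centerline, truth_centerline)
        assert err["mean"] == 0.0 and np.all(err["distance_mm"] == 0)

    def test_3_4_5_triangle(self, truth_centerline):
        shifted = Centerline(truth_centerline.slice_start,
                             truth_centerline.pos_mm + [3.0, 4.0],
                             truth_centerline.spacing)
        err = centroid_error(shifted, truth_centerline)
        np.testing.assert_allclose(err["distance_mm"], 5.0)

    def test_symmetry(self, truth_centerline):
        shifted = Centerline(truth_centerline.slice_start,
                             truth_centerline.pos_mm + [1.0, -2.0],
                             truth_centerline.spacing)
        a = centroid_error(shifted, truth_centerline)
        b = centroid_error(truth_centerline, shifted)
        assert a["mean"] == b["mean"]

    def test_no_overlap_rejected(self, truth_centerline):
        other = Centerline(truth_centerline.slice_start + 10_000,
                           truth_centerline.pos_mm, truth_centerline.spacing)
        with pytest.raises(ValueError, match="overlap"):
            centroid_error(other, truth_centerline)

    def test_rayleigh_mean_of_gaussian_jitter(self):
        # isotropic jitter sd=0.2 mm -> mean 2D distance = 0.2*sqrt(pi/2)
        rng = np.random.default_rng(0)
        n = 500
        base = Centerline(0, np.full((n, 2), 30.0), np.array([2.5, 1.0, 1.0]))
        jit = Centerline(0, base.pos_mm + rng.normal(0, 0.2, (n, 2)),
                         base.spacing)
        err = centroid_error(jit, base)
        expected = 0.2 * np.sqrt(np.pi / 2)
        assert abs(err["mean"] - expected) / expected < 0.2


@pytest.fixture(scope="module")
def slice_data():
    slices, masks = [], []
    for seed in range(3):
        cfg = PhantomConfig(seed=seed,
                            level_plan=tuple(f"T{i}" for i in range(1, 13)))
        vol, truth = generate_phantom(cfg)
        for s, ap, lr in truth.canal_centerline[::2]:
            s = int(s)
            ap_i = int(ap / vol.spacing[1])
            lr_i = int(lr / vol.spacing[2])
            sl = vol.data[s, ap_i - 24:ap_i + 24, lr_i - 24:lr_i + 24]
            mk = truth.canal_mask[s, ap_i - 24:ap_i + 24, lr_i - 24:lr_i + 24]
            if sl.shape == (48, 48):
                slices.append(sl)
                masks.append(mk)
    return slices, masks


class TestSegmenter:
    def test_trained_segmenter_centroid_error_under_2_voxels(self, slice_data):
        slices, masks = slice_data
        model = train_canal_segmenter(slices[:120], masks[:120], epochs=12,
                                      seed=0)
        errs = []
        for sl, mk in zip(slices[120:160], masks[120:160]):
            pred = model(sl)
            if pred.sum() == 0:
                continue  # empty prediction is permitted; interpolation covers
            pc = ndimage.center_of_mass(pred)
            tc = ndimage.center_of_mass(mk)
            errs.append(np.hypot(pc[0] - tc[0], pc[1] - tc[1]))
        assert len(errs) >= 20
        assert np.mean(errs) < 2.0

    def test_all_air_slice_gives_valid_empty_mask(self, slice_data):
        slices, masks = slice_data
        model = train_canal_segmenter(slices[:24], masks[:24], epochs=2, seed=0)
        pred = model(np.full((48, 48), -1000.0, np.float32))
        assert pred.dtype == bool and pred.shape == (48, 48)

    def test_training_is_deterministic(self, slice_data):
        slices, masks = slice_data
        m1 = train_canal_segmenter(slices[:24], masks[:24], epochs=3, seed=5)
        m2 = train_canal_segmenter(slices[:24], masks[:24], epochs=3, seed=5)
        assert m1.history == m2.history

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            train_canal_segmenter([], [])
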