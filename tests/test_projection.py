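"""CIP formation (vs brute-force oracle), padding, labels, cropping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spinelabel.canal import Centerline, VOISpec, build_voi, centerline_from_truth
from spinelabel.levels import LEVEL_NAMES, CentroidSet
from spinelabel.projection import (crop_augment, form_cip, form_cip_pair,
                                   gaussian_blob_radius, gaussian_label_image,
                                   make_gaussian_labels, make_label_stack,
                                   pad_and_register, pad_pair, resample_volume,
                                   select_cip_set, unpad, ImageGeometry)
from spinelabel.volume import CTVolume


def full_cover_voi(shape, spacing=(1.0, 1.0, 1.0)):
    """A VOI whose windows cover the whole in-plane extent of the volume."""
    n = shape[0]
    pos = np.column_stack([np.full(n, (shape[1] // 2) * spacing[1]),
                           np.full(n, (shape[2] // 2) * spacing[2])])
    cl = Centerline(0, pos, np.asarray(spacing, float))
    return build_voi(cl, 4 * max(shape))


def cip_oracle(volume, voi, view, window, w, rescale=False):
    """Independent per-column loop implementation of the CIP formula."""
    lo, hi = window
    norm = (np.clip(volume.data, lo, hi) - lo) / (hi - lo)
    mask = voi.mask(volume.shape)
    rows = [s for s in voi.centerline.slices if 0 <= s < volume.shape[0]]
    t_ax, proj_ax = (1, 2) if view == "sagittal" else (2, 1)
    cols = range(volume.shape[t_ax])
    img = np.zeros((len(rows), volume.shape[t_ax]))
    for ri, s in enumerate(rows):
        for c in cols:
            line = norm[s, c, :] if t_ax == 1 else norm[s, :, c]
            mline = mask[s, c, :] if t_ax == 1 else mask[s, :, c]
            inside = line[mline]
            outside = line[~mline]
            if inside.size == 0:
                continue
            val = w * inside.mean() + inside.max()
            if w != 2.0 and outside.size:
                val += (w - 2.0) * outside.max()
            img[ri, c] = val
    if rescale:
        ptp = img.max() - img.min()
        img = (img - img.min()) / ptp if ptp > 0 else np.zeros_like(img)
    return img


class TestResample:
    def test_identity_at_target(self, thoracic_phantom):
        _, vol, _ = thoracic_phantom
        assert resample_volume(vol, 2.5) is vol

    def test_linear_ramp_exact(self):
        # 5.0 mm -> 2.5 mm on an SI-linear HU ramp: order-1 interp is exact
        data = np.arange(10, dtype=np.float32)[:, None, None] * np.ones((1, 4, 4))
        vol = CTVolume(data * 10.0, (5.0, 1.0, 1.0))
        out = resample_volume(vol, 2.5)
        expected = np.arange(out.shape[0]) * 0.5 * 10.0
        np.testing.assert_allclose(out.data[:, 2, 2], expected, rtol=1e-6)
        assert out.spacing[0] == 2.5

    def test_world_coordinates_preserved(self, thoracic_phantom):
        _, vol, truth = thoracic_phantom
        out = resample_volume(vol, 1.0)
        # bone block centers keep their world position: HU at the original
        # centroid world coordinate stays bone-bright
        for _, xyz in truth.centroids.items():
            i, j, k = np.rint((xyz - out.origin) / out.spacing).astype(int)
            assert out.data[i, j, k] > 300.0

    def test_bad_spacing_rejected(self, thoracic_phantom):
        _, vol, _ = thoracic_phantom
        with pytest.raises(ValueError):
            resample_volume(vol, -1.0)


class TestFormCIP:
    @pytest.mark.parametrize("view", ["sagittal", "coronal"])
    def test_matches_oracle_on_small_volumes(self, view):
        rng = np.random.default_rng(1)
        for trial in range(40):
            shape = tuple(rng.integers(1, 9, size=3))
            vol = CTVolume(rng.uniform(-1000, 2000, shape).astype(np.float32),
                           (1.0, 1.0, 1.0))
            voi = full_cover_voi(shape)
            w = float(rng.choice([2.0, 1.0, 3.0]))
            win = (-1000.0, 1600.0)
            img, _ = form_cip(vol, voi, view, win, w, rescale=False)
            ref = cip_oracle(vol, voi, view, win, w, rescale=False)
            np.testing.assert_allclose(img, ref, atol=1e-5)

    def test_w2_independent_of_outside_voi(self):
        rng = np.random.default_rng(2)
        shape = (6, 8, 8)
        vol = CTVolume(rng.uniform(-500, 1500, shape).astype(np.float32),
                       (1.0, 1.0, 1.0))
        pos = np.column_stack([np.full(6, 4.0), np.full(6, 4.0)])
        voi = build_voi(Centerline(0, pos, np.ones(3)), 3)
        img1, _ = form_cip(vol, voi, "sagittal", (-1000, 1600), 2.0)
        vol2 = CTVolume(vol.data.copy(), vol.spacing)
        vol2.data[~voi.mask(shape)] = 3000.0  # trash everything outside
        img2, _ = form_cip(vol2, voi, "sagittal", (-1000, 1600), 2.0)
        np.testing.assert_allclose(img1, img2)

    def test_single_voxel_column_is_2mean_plus_max(self):
        vol = CTVolume(np.full((3, 3, 3), 800.0, np.float32), (1, 1, 1))
        pos = np.tile([1.0, 1.0], (3, 1))
        voi = build_voi(Centerline(0, pos, np.ones(3)), 1)
        img, _ = form_cip(vol, voi, "sagittal", (-1000, 1600), 2.0,
                          rescale=False)
        norm = (800.0 + 1000) / 2600
        assert img.shape == (3, 1)  # 1 px window -> 1 column
        np.testing.assert_allclose(img[:, 0], 2 * norm + norm, rtol=1e-6)

    def test_constant_volume_constant_image(self):
        vol = CTVolume(np.full((4, 6, 6), 100.0, np.float32), (1, 1, 1))
        voi = full_cover_voi(vol.shape)
        img, _ = form_cip(vol, voi, "coronal", (-1000, 1600), 2.0,
                          rescale=False)
        assert np.allclose(img, img.flat[0])

    def test_bad_window_rejected(self, thoracic_phantom):
        _, vol, _ = thoracic_phantom
        voi = full_cover_voi(vol.shape, vol.spacing)
        with pytest.raises(ValueError, match="lower < upper"):
            form_cip(vol, voi, "sagittal", (100, 100), 2.0)


class TestSelectCipSet:
    def test_three_pairs_one_anterior(self, thoracic_phantom, truth_centerline):
        _, vol, _ = thoracic_phantom
        voi = build_voi(truth_centerline, 55)
        pairs = select_cip_set(vol, voi)
        assert len(pairs) == 3
        assert sum(p.anterior_constrained for p in pairs) == 1
        assert len({p.window for p in pairs[:2]}) == 2

    def test_shared_geometry(self, thoracic_phantom, truth_centerline):
        _, vol, _ = thoracic_phantom
        voi = build_voi(truth_centerline, 55)
        pairs = select_cip_set(vol, voi)
        g0 = pairs[0].geometry_sagittal
        assert all(p.geometry_sagittal == g0 for p in pairs)

    def test_duplicate_windows_rejected(self, thoracic_phantom,
                                        truth_centerline):
        _, vol, _ = thoracic_phantom
        voi = build_voi(truth_centerline, 55)
        with pytest.raises(ValueError, match="duplicate"):
            select_cip_set(vol, voi, windows=((-200, 800), (-200, 800)))

    def test_anterior_pair_drops_posterior_processes(self, thoracic_phantom,
                                                     truth_centerline):
        """Pixels posterior to the canal centroid vanish in the constrained
        sagittal image."""
        _, vol, _ = thoracic_phantom
        voi = build_voi(truth_centerline, 55)
        pairs = select_cip_set(vol, voi)
        ant = pairs[2]
        geom = ant.geometry_sagittal
        for i, s in enumerate(truth_centerline.slices):
            ap_c = truth_centerline.pos_mm[i, 0]
            _, col = geom.mm_to_pixel(0.0, ap_c)
            row = s - truth_centerline.slice_start
            post = ant.sagittal[row, int(np.ceil(col)) + 1:]
            assert np.all(post == 0.0)


class TestPadding:
    def test_roundtrip_bit_exact(self):
        rng = np.random.default_rng(0)
        img = rng.random((100, 50)).astype(np.float32)
        geom = ImageGeometry(10.0, 2.5, 5.0, 1.17, "sagittal")
        padded, g2 = pad_and_register(img, geom, (608, 192))
        assert padded.shape == (608, 192)
        np.testing.assert_array_equal(unpad(padded, g2), img)
        # pixel -> mm round-trips exactly through the padded geometry
        r0, _, c0, _ = g2.content_box
        assert g2.pixel_to_mm(r0, c0) == (10.0, 5.0)

    def test_full_size_is_identity(self):
        img = np.ones((608, 192), np.float32)
        geom = ImageGeometry(0.0, 2.5, 0.0, 1.17, "coronal")
        padded, g2 = pad_and_register(img, geom, (608, 192))
        np.testing.assert_array_equal(padded, img)
        assert g2.content_box == (0, 608, 0, 192)

    def test_oversize_error_names_axis(self):
        img = np.zeros((700, 50), np.float32)
        geom = ImageGeometry(0.0, 2.5, 0.0, 1.17, "sagittal")
        with pytest.raises(ValueError, match="SI"):
            pad_and_register(img, geom, (608, 192))
        with pytest.raises(ValueError, match="in-plane"):
            pad_and_register(np.zeros((10, 300), np.float32), geom, (608, 192))

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.integers(1, 60), st.integers(1, 30),
           st.integers(0, 2**31 - 1))
    def test_roundtrip_any_content_size(self, h, w, seed):
        """pad_and_register followed by inverse geometry is the identity on
        both pixels and coordinates, whatever the content size."""
        img = np.random.default_rng(seed).random((h, w)).astype(np.float32)
        geom = ImageGeometry(7.5, 2.5, -3.0, 1.17, "sagittal")
        padded, g2 = pad_and_register(img, geom, (64, 32))
        np.testing.assert_array_equal(unpad(padded, g2), img)
        r0, _, c0, _ = g2.content_box
        assert g2.pixel_to_mm(r0, c0) == geom.pixel_to_mm(0, 0)

    def test_canvas_si_capacity(self):
        # 608 px at 2.5 mm/px: the canvas holds 152 cm of scan; computed
        # from geometry, never asserted against any other figure
        assert 608 * 2.5 == 1520.0


class TestGaussianLabels:
    def test_blob_radius_closed_form(self):
        r = gaussian_blob_radius(2.0, 225.0, 75.0)
        assert np.isclose(r, np.sqrt(8 * np.log(3)))
        blob = gaussian_label_image((41, 41), (20.0, 20.0))
        assert not blob[20, 23]  # distance 3.0 px > 2.9636 -> False
        assert blob[20, 22]  # distance 2.0 px -> True
        # fractional center: distance 2.9 -> True, 3.0 -> False
        blob = gaussian_label_image((41, 41), (20.0, 20.9))
        assert blob[20, 18]  # distance 2.9
        assert not blob[20, 24]  # distance 3.1

    def test_absent_level_channel_all_false(self):
        geom = ImageGeometry(0.0, 2.5, 0.0, 1.17, "sagittal")
        cents = CentroidSet.from_items([("T5", [50.0, 30.0, 20.0])])
        stack = make_gaussian_labels(cents, geom, (64, 64))
        assert stack[:, :, LEVEL_NAMES.index("T5")].any()
        assert not stack[:, :, LEVEL_NAMES.index("T6")].any()
        # null channel is the exact complement of the union
        union = stack[:, :, :26].any(axis=2)
        np.testing.assert_array_equal(stack[:, :, 26], ~union)

    def test_adjacent_blobs_do_not_overlap_at_18mm(self):
        geom = ImageGeometry(0.0, 2.5, 0.0, 2.5, "sagittal")
        cents = CentroidSet.from_items([
            ("C3", [50.0, 30.0, 0.0]), ("C4", [68.0, 30.0, 0.0])])
        stack = make_gaussian_labels(cents, geom, (64, 64))
        a = stack[:, :, LEVEL_NAMES.index("C3")]
        b = stack[:, :, LEVEL_NAMES.index("C4")]
        assert a.any() and b.any() and not np.any(a & b)

    def test_centroid_outside_canvas_rejected(self):
        geom = ImageGeometry(0.0, 2.5, 0.0, 1.17, "sagittal")
        cents = CentroidSet.from_items([("T5", [500.0, 30.0, 20.0])])
        with pytest.raises(ValueError, match="outside"):
            make_gaussian_labels(cents, geom, (64, 64))

    def test_label_blob_com_recovers_projection(self, thoracic_phantom,
                                                truth_centerline):
        from scipy import ndimage

        _, vol, truth = thoracic_phantom
        voi = build_voi(truth_centerline, 55)
        pair = pad_pair(form_cip_pair(vol, voi, (-200, 800)), (608, 192))
        stack = make_label_stack(pair, truth.centroids)
        for name, xyz in truth.centroids.items():
            r, c = pair.geometry_sagittal.project_centroid(xyz)
            blob = stack.sagittal[:, :, LEVEL_NAMES.index(name)]
            com = ndimage.center_of_mass(blob)
            assert np.hypot(com[0] - r, com[1] - c) < 0.5


class TestCropAugment:
    @pytest.fixture()
    def padded(self, thoracic_phantom, truth_centerline):
        _, vol, truth = thoracic_phantom
        voi = build_voi(truth_centerline, 55)
        pair = pad_pair(form_cip_pair(vol, voi, (-200, 800)), (608, 192))
        return pair, make_label_stack(pair, truth.centroids), truth.centroids

    def test_increment_larger_than_scan_empty(self, padded):
        pair, labels, truth = padded
        assert crop_augment(pair, labels, truth, increment_mm=10_000) == []

    def test_bad_increment(self, padded):
        pair, labels, truth = padded
        with pytest.raises(ValueError):
            crop_augment(pair, labels, truth, increment_mm=0)

    def test_span_without_centroid_skipped(self, thoracic_phantom,
                                           truth_centerline):
        _, vol, truth = thoracic_phantom
        voi = build_voi(truth_centerline, 55)
        pair = pad_pair(form_cip_pair(vol, voi, (-200, 800)), (608, 192))
        labels = make_label_stack(pair, truth.centroids)
        out_small = crop_augment(pair, labels, truth.centroids,
                                 increment_mm=5.0, mode="sup_to_inf")
        si = truth.centroids.array()[:, 0]
        geom = pair.geometry_sagittal
        first_si = geom.si_origin
        # oracle: count spans that contain a centroid (the emission rule)
        n_rows = geom.content_box[1]
        step = geom.si_step
        inc_px = max(int(round(5.0 / step)), 1)
        expected = 0
        for k in range(1, n_rows // inc_px + 1):
            a = first_si + (k - 1) * inc_px * step
            b = first_si + k * inc_px * step
            if n_rows - k * inc_px < 1:
                break
            if np.any((si >= a) & (si < b)):
                expected += 1
        assert len(out_small) == expected
        # the canal leader span holds no centroid: first cropping skipped,
        # so the first emitted cropping already lost a centroid
        assert not np.any((si >= first_si) & (si < first_si + inc_px * step))
        n0 = out_small[0][1].sagittal[:, :, :26].any(axis=(0, 1)).sum()
        assert n0 < len(truth.centroids)

    def test_medial_mode_shrinks_monotonically(self, padded):
        pair, labels, truth = padded
        out = crop_augment(pair, labels, truth, increment_mm=25.0,
                           mode="medial")
        assert out
        extents = [p.geometry_sagittal.content_box[1] for p, _ in out]
        assert all(b < a for a, b in zip(extents, extents[1:]))
        # croppings stay centered on the scan midpoint
        mids = [
            p.geometry_sagittal.si_origin
            + p.geometry_sagittal.content_box[1] / 2
            * p.geometry_sagittal.si_step
            for p, _ in out
        ]
        assert np.ptp(mids) <= 2 * 2.5  # within one slice each side
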