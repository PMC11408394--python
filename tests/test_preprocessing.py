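import numpy as np
import pytest

from pelviseg.preprocessing import (
    ClassLabelVector,
    PreprocessConfig,
    assign_class_labels,
    bias_correct,
    class_vector_to_volume,
    keep_largest_component,
    max_inscribed_radius,
    merge_cgu,
    normalize_intensity,
    resample_to_grid,
)
from pelviseg.volumes import ImageVolume, LabelVolume, labels_from_indexmap


def _ball_mask(shape, center, radius_mm, spacing):
    grids = np.meshgrid(*[np.arange(n) * s for n, s in zip(shape, spacing)],
                        indexing="ij")
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return d2 <= radius_mm**2


class TestBiasCorrect:
    def test_disabled_is_identity(self, rng):
        img = ImageVolume(rng.normal(size=(8, 8, 8)))
        out = bias_correct(img, enabled=False)
        np.testing.assert_array_equal(out.data, img.data)

    def test_constant_image_stays_nearly_constant(self):
        img = ImageVolume(np.full((24, 24, 12), 5.0), spacing=(2, 2, 4))
        out = bias_correct(img, enabled=True)
        assert out.data.shape == img.data.shape
        # a constant is fit exactly by any smooth bias model, up to scale
        assert out.data.std() / out.data.mean() < 0.01

    def test_polynomial_bias_reduces_cv(self):
        """The external N4 corrector shrinks the intensity spread inside a
        homogeneous organ under a smooth multiplicative bias."""
        shape, spacing = (32, 32, 16), (2.0, 2.0, 4.0)
        mask = _ball_mask(shape, (32, 32, 32), 20, spacing)
        base = np.where(mask, 1.0, 0.4)
        gx = np.linspace(-1, 1, shape[0])[:, None, None]
        gz = np.linspace(-1, 1, shape[2])[None, None, :]
        bias = 1.0 + 0.4 * gx + 0.3 * gz + 0.2 * gx * gz
        img = ImageVolume(base * bias, spacing=spacing)
        out = bias_correct(img, enabled=True)
        cv_before = img.data[mask].std() / img.data[mask].mean()
        cv_after = out.data[mask].std() / out.data[mask].mean()
        assert cv_after < cv_before


class TestResample:
    def test_identity_when_already_on_grid(self, rng):
        cfg = PreprocessConfig(target_shape=(8, 8, 4), target_spacing=(1, 1, 2))
        img = ImageVolume(rng.normal(size=(8, 8, 4)), spacing=(1, 1, 2))
        lab = labels_from_indexmap(rng.integers(0, 4, size=(8, 8, 4)), 4,
                                   spacing=(1, 1, 2))
        out_img, out_lab = resample_to_grid(img, lab, cfg)
        np.testing.assert_array_equal(out_img.data, img.data)
        np.testing.assert_array_equal(out_lab.data, lab.data)

    def test_labels_stay_one_hot(self, rng):
        cfg = PreprocessConfig(target_shape=(12, 10, 6), target_spacing=(2.0, 2.0, 3.0))
        img = ImageVolume(rng.normal(size=(16, 16, 8)), spacing=(1.5, 1.5, 2.5))
        lab = labels_from_indexmap(rng.integers(0, 4, size=(16, 16, 8)), 4,
                                   spacing=(1.5, 1.5, 2.5))
        _, out_lab = resample_to_grid(img, lab, cfg)
        assert (out_lab.data.sum(axis=-1) == 1).all()

    def test_sphere_volume_preserved(self):
        """A centred sphere's physical volume changes by <5% when resampling
        1.2 mm -> 1.64 mm in plane."""
        shape, spacing = (48, 48, 24), (1.2, 1.2, 3.0)
        mask = _ball_mask(shape, (28.8, 28.8, 36.0), 15.0, spacing)
        idx = mask.astype(int)
        img = ImageVolume(idx.astype(float), spacing=spacing)
        lab = labels_from_indexmap(idx, 2, spacing=spacing)
        cfg = PreprocessConfig(target_shape=(36, 36, 24), target_spacing=(1.64, 1.64, 3.0))
        _, out_lab = resample_to_grid(img, lab, cfg)
        vol_in = mask.sum() * np.prod(spacing)
        vol_out = out_lab.data[..., 1].sum() * np.prod(cfg.target_spacing)
        assert abs(vol_out - vol_in) / vol_in < 0.05


class TestMergeCgu:
    def _labels(self, cervix, gtv, uterus, shape=(6, 6, 6)):
        names = ("background", "bladder", "cervix", "gtv", "uterus", "rectum")
        data = np.zeros(shape + (6,), dtype=np.uint8)
        for vox in cervix:
            data[vox + (2,)] = 1
        for vox in gtv:
            data[vox + (3,)] = 1
        for vox in uterus:
            data[vox + (4,)] = 1
        data[..., 0] = 1 - data[..., 1:].sum(axis=-1)
        return LabelVolume(data, channel_names=names)

    def test_disjoint_union_counts(self):
        cervix = [(0, 0, z) for z in range(2)]
        gtv = [(1, 0, z) for z in range(3)]
        uterus = [(2, 0, z) for z in range(4)]
        lab = merge_cgu(self._labels(cervix, gtv, uterus))
        assert lab.channel("cgu").sum() == 9
        assert "cervix" not in lab.channel_names

    def test_subset_union(self):
        # GTV entirely inside the uterus: contested voxels carry the GTV label
        idx = np.zeros((6, 6, 6), dtype=int)
        idx[:3, :3, :3] = 4  # uterus, 27 voxels
        idx[1, 1, 1] = 3     # gtv inside it
        names = ("background", "bladder", "cervix", "gtv", "uterus", "rectum")
        lab = merge_cgu(labels_from_indexmap(idx, 6, channel_names=names))
        assert lab.channel("cgu").sum() == 27

    def test_random_overlap_matches_or_oracle(self, rng):
        shape = (6, 6, 6)
        masks = [rng.random(shape) < 0.25 for _ in range(3)]
        idx = np.zeros(shape, dtype=int)  # overlaps resolved: later mask wins
        for i, m in enumerate(masks):
            idx[m] = 2 + i
        names = ("background", "bladder", "cervix", "gtv", "uterus", "rectum")
        lab = merge_cgu(labels_from_indexmap(idx, 6, channel_names=names))
        expected = masks[0] | masks[1] | masks[2]
        np.testing.assert_array_equal(lab.channel("cgu").astype(bool), expected)

    def test_missing_channel_is_error(self):
        lab = labels_from_indexmap(np.zeros((2, 2, 2), dtype=int), 4)
        with pytest.raises(KeyError, match="cervix"):
            merge_cgu(lab)


class TestMaxInscribedRadius:
    def test_single_voxel(self):
        m = np.zeros((5, 5, 5), dtype=bool)
        m[2, 2, 2] = True
        assert max_inscribed_radius(m, (1, 1, 1)) == pytest.approx(1.0)

    def test_digitized_ball(self):
        m = _ball_mask((48, 48, 48), (24, 24, 24), 20.0, (1, 1, 1))
        r = max_inscribed_radius(m, (1, 1, 1))
        assert abs(r - 20.0) <= 1.0

    def test_thin_slab_uses_out_of_plane_spacing(self):
        m = np.zeros((9, 9, 5), dtype=bool)
        m[:, :, 2] = True
        assert max_inscribed_radius(m, (1.0, 1.0, 3.0)) == pytest.approx(3.0)

    def test_empty_mask_is_error(self):
        with pytest.raises(ValueError):
            max_inscribed_radius(np.zeros((3, 3, 3), dtype=bool), (1, 1, 1))


class TestAssignClassLabels:
    spacing = (1.0, 1.0, 1.0)

    def _case(self, bladder_r, gtv_n, uterus_n, shape=(64, 64, 64)):
        bladder = _ball_mask(shape, (32, 32, 32), bladder_r, self.spacing)
        gtv = np.zeros(shape, dtype=bool)
        gtv.flat[:gtv_n] = True
        uterus = np.zeros(shape, dtype=bool)
        uterus.flat[-uterus_n:] = uterus_n > 0
        return bladder, gtv, uterus

    def test_inflated_bladder_large_tumour(self):
        bladder, gtv, uterus = self._case(20.0, 500, 100)
        vec = assign_class_labels(bladder, gtv, uterus, self.spacing)
        assert vec == (0, 1, 1, 0)

    def test_threshold_radius_is_strict(self):
        # a slab exactly 17 mm in half-thickness: radius == threshold -> 0
        m = np.zeros((40, 40, 40), dtype=bool)
        m[1:36, 1:36, 3:37] = True  # inscribed radius 17 along z
        r = max_inscribed_radius(m, self.spacing)
        assert r == pytest.approx(17.0)
        vec = assign_class_labels(m, np.zeros_like(m), np.ones_like(m), self.spacing)
        assert vec.values[1] == 0

    def test_ratio_exactly_four_is_zero(self):
        bladder, gtv, uterus = self._case(20.0, 400, 100)
        vec = assign_class_labels(bladder, gtv, uterus, self.spacing)
        assert vec.values[2] == 0

    def test_empty_uterus_with_gtv_warns_and_flags(self):
        bladder, gtv, uterus = self._case(5.0, 10, 0)
        with pytest.warns(UserWarning, match="degenerate"):
            vec = assign_class_labels(bladder, gtv, uterus, self.spacing)
        assert vec.values[2] == 1

    def test_translation_invariance(self, rng):
        bladder, gtv, uterus = self._case(18.0, 450, 100)
        v1 = assign_class_labels(bladder, gtv, uterus, self.spacing)
        shiftvec = (3, -2, 1)
        v2 = assign_class_labels(
            np.roll(bladder, shiftvec, axis=(0, 1, 2)),
            np.roll(gtv, shiftvec, axis=(0, 1, 2)),
            np.roll(uterus, shiftvec, axis=(0, 1, 2)),
            self.spacing,
        )
        assert v1 == v2


class TestClassVectorVolume:
    def test_worked_example(self):
        out = class_vector_to_volume(ClassLabelVector((0, 1, 1, 0)), (16, 16, 8))
        assert out.shape == (16, 16, 8, 4)
        assert out[..., 1].all() and out[..., 2].all()
        assert not out[..., 0].any() and not out[..., 3].any()

    def test_channel_sums(self):
        vec = (1, 0, 1, 0)
        out = class_vector_to_volume(ClassLabelVector(vec), (4, 5, 6))
        for c, v in enumerate(vec):
            assert out[..., c].sum() == v * 4 * 5 * 6


class TestKeepLargestComponent:
    def _with_blobs(self, blobs, shape=(12, 12, 12)):
        idx = np.zeros(shape, dtype=int)
        for sl in blobs:
            idx[sl] = 1
        return labels_from_indexmap(idx, 4)

    def test_small_satellite_removed(self):
        lab = self._with_blobs([
            (slice(0, 5), slice(0, 5), slice(0, 4)),    # 100 voxels
            (slice(9, 10), slice(9, 10), slice(7, 12)),  # 5 voxels
        ])
        out = keep_largest_component(lab)
        assert out.data[..., 1].sum() == 100
        assert (out.data.sum(axis=-1) == 1).all()

    def test_single_component_unchanged(self):
        lab = self._with_blobs([(slice(2, 6), slice(2, 6), slice(2, 6))])
        out = keep_largest_component(lab)
        np.testing.assert_array_equal(out.data, lab.data)

    def test_empty_channel_unchanged(self):
        lab = labels_from_indexmap(np.zeros((4, 4, 4), dtype=int), 4)
        out = keep_largest_component(lab)
        np.testing.assert_array_equal(out.data, lab.data)

    def test_never_increases_foreground(self, rng):
        idx = (rng.random((10, 10, 10)) < 0.3).astype(int)
        lab = labels_from_indexmap(idx, 2)
        out = keep_largest_component(lab)
        assert out.data[..., 1].sum() <= lab.data[..., 1].sum()


def test_normalize_intensity_zero_mean_unit_sd(rng):
    img = ImageVolume(rng.normal(3.0, 2.0, size=(8, 8, 8)))
    out = normalize_intensity(img)
    assert out.data.mean() == pytest.approx(0.0, abs=1e-5)
    assert out.data.std() == pytest.approx(1.0, abs=1e-4)
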