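"""Feature extraction: standardization, windowed statistics, label augmentation."""

import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from cascadeseg import (FeatureConfig, ImageVolume, LabelMap, LabelScheme, Modality,
                        PhantomConfig, augment_with_labels, generate_case,
                        normalize_intensity, pixel_features)


class TestNormalizeIntensity:
    def test_two_point_standardization(self):
        vol = ImageVolume(data=np.array([[1.0, 3.0], [0.0, 0.0]]))
        out = normalize_intensity(vol)
        np.testing.assert_allclose(out.data[0], [-1.0, 1.0])
        assert np.all(out.data[1] == 0)

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        vol = ImageVolume(data=rng.normal(5, 2, size=(16, 16)))
        once = normalize_intensity(vol)
        twice = normalize_intensity(once)
        np.testing.assert_allclose(twice.data, once.data, atol=1e-9)

    def test_moments_on_phantom(self):
        case = generate_case(PhantomConfig(seed=6))
        out = normalize_intensity(case.volumes[Modality.T2])
        nz = out.data[out.data != 0]
        assert abs(nz.mean()) < 1e-9
        assert abs(nz.std() - 1.0) < 1e-9
        # zero background stays zero
        assert np.all(out.data[case.volumes[Modality.T2].data == 0] == 0)

    def test_constant_nonzero_centered_with_warning(self, caplog):
        vol = ImageVolume(data=np.full((4, 4), 7.0))
        with caplog.at_level(logging.WARNING, logger="cascadeseg.features"):
            out = normalize_intensity(vol)
        assert np.all(out.data == 0)
        assert any("unit scaling skipped" in r.message for r in caplog.records)


class TestPixelFeatures:
    def test_constant_image(self):
        table = pixel_features(ImageVolume(data=np.full((6, 6), 3.0)))
        np.testing.assert_array_equal(table.features, np.full((36, 3), 3.0))

    def test_center_of_1_to_25(self):
        img = ImageVolume(data=np.arange(1.0, 26.0).reshape(5, 5))
        table = pixel_features(img, FeatureConfig(window=5))
        center = table.features[12]  # row-major index of (2, 2)
        assert center[0] == 13
        assert center[1] == 13  # mean of 1..25
        assert center[2] == 13  # median of 1..25

    def test_window_one_degenerate(self):
        rng = np.random.default_rng(1)
        img = ImageVolume(data=rng.normal(size=(7, 7)))
        table = pixel_features(img, FeatureConfig(window=1))
        np.testing.assert_array_equal(table.features[:, 1], table.features[:, 0])
        np.testing.assert_array_equal(table.features[:, 2], table.features[:, 0])

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            FeatureConfig(window=4)

    def test_window_larger_than_image_rejected(self):
        with pytest.raises(ValueError, match="window"):
            pixel_features(ImageVolume(data=np.zeros((3, 3))), FeatureConfig(window=5))

    def test_row_major_scan_order(self):
        img = ImageVolume(data=np.arange(12.0).reshape(3, 4))
        table = pixel_features(img, FeatureConfig(window=1))
        np.testing.assert_array_equal(table.features[:, 0], np.arange(12.0))
        np.testing.assert_array_equal(table.coords[:3], [[0, 0], [0, 1], [0, 2]])

    def test_translation_equivariance_away_from_borders(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=(12, 12))
        shifted = np.roll(base, (1, 1), axis=(0, 1))
        ta = pixel_features(ImageVolume(data=base), FeatureConfig(window=3))
        tb = pixel_features(ImageVolume(data=shifted), FeatureConfig(window=3))
        fa = ta.features.reshape(12, 12, 3)[2:-2, 2:-2]
        fb = tb.features.reshape(12, 12, 3)[3:-1, 3:-1]
        np.testing.assert_array_equal(fa, fb)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(hnp.arrays(np.float64, (8, 8), elements=st.floats(-10, 10)))
    def test_median_bounded_by_window_extremes(self, data):
        table = pixel_features(ImageVolume(data=data), FeatureConfig(window=3))
        padded = np.pad(data, 1, mode="reflect")
        for idx, (r, c) in enumerate(table.coords):
            window = padded[r:r + 3, c:c + 3]
            assert window.min() <= table.features[idx, 2] <= window.max()


class TestAugmentWithLabels:
    def test_zero_labels_append_zero_column(self):
        table = pixel_features(ImageVolume(data=np.ones((6, 6))))
        labels = LabelMap(data=np.zeros((6, 6), dtype=int))
        out = augment_with_labels(table, labels)
        assert out.features.shape == (36, 4)
        assert np.all(out.features[:, 3] == 0)

    def test_column_matches_per_coordinate_lookup(self):
        rng = np.random.default_rng(4)
        data = rng.normal(size=(6, 6))
        labels = LabelMap(data=rng.integers(0, 2, size=(6, 6)))
        out = augment_with_labels(pixel_features(ImageVolume(data=data)), labels)
        for idx, (r, c) in enumerate(out.coords):
            assert out.features[idx, -1] == labels.data[r, c]

    def test_applying_twice_appends_two_columns(self):
        table = pixel_features(ImageVolume(data=np.ones((6, 6))))
        labels = LabelMap(data=np.ones((6, 6), dtype=int))
        out = augment_with_labels(augment_with_labels(table, labels), labels)
        assert out.features.shape[1] == 5
        assert out.columns[-2:] == ["label", "label2"]

    def test_shape_mismatch_rejected(self):
        table = pixel_features(ImageVolume(data=np.ones((6, 6))))
        with pytest.raises(ValueError, match="shape"):
            augment_with_labels(table, LabelMap(data=np.zeros((5, 5), dtype=int)))
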