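"""Gabor pyramid, Butterworth spatial-frequency bank, and model RDMs."""

import numpy as np
import pytest

from catdecode import (BandDefinition, GaborConfig, ImageSet, ModelFeatureSet,
                       bandpass_image, butterworth_bandpass_gain, feature_rdm,
                       gabor_features, group_layers, load_layer_activations,
                       make_band_filters, pixel_band_rdms,
                       save_layer_activations, to_luminance)


def grating(n, cycles_per_image, theta=0.0, deg=5.0):
    """Zero-mean sinusoidal grating at an exact FFT frequency."""
    y, x = np.mgrid[0:n, 0:n] / n
    u = x * np.cos(theta) + y * np.sin(theta)
    return np.sin(2 * np.pi * cycles_per_image * u)


class TestBandFilters:
    def test_default_bank_layout(self):
        bands = make_band_filters(n=100, lo=0.1, hi=30.0, order=5)
        assert len(bands) == 100
        centers = np.array([b.center for b in bands])
        assert centers[0] == pytest.approx(0.1)
        assert centers[-1] == pytest.approx(30.0)
        ratios = centers[1:] / centers[:-1]
        np.testing.assert_allclose(ratios, (30.0 / 0.1) ** (1 / 99))
        # adjacent bands share edges at geometric midpoints
        assert bands[0].hi_edge == pytest.approx(
            np.sqrt(centers[0] * centers[1]))

    def test_single_band_centered_at_geometric_mean(self):
        (band,) = make_band_filters(n=1, lo=0.1, hi=30.0)
        assert band.center == pytest.approx(np.sqrt(0.1 * 30.0))

    def test_invalid_layout_rejected(self):
        with pytest.raises(ValueError):
            make_band_filters(n=0)
        with pytest.raises(ValueError):
            make_band_filters(lo=5.0, hi=1.0)
        with pytest.raises(ValueError):
            BandDefinition(center=1.0, lo_edge=2.0, hi_edge=3.0)


class TestBandpassImage:
    def test_edge_amplitude_ratio_analytic(self):
        """At the low edge the gain is (1/sqrt2)*[1+(lo/hi)^(2n)]^(-1/2)."""
        n, deg = 128, 5.0
        lo_cpi = 8                       # cycles per image
        lo = lo_cpi / deg                # cpd
        band = BandDefinition(center=lo * 2, lo_edge=lo, hi_edge=lo * 4,
                              order=5)
        img = grating(n, lo_cpi)
        out = bandpass_image(img, band, deg)
        ratio = out.std() / img.std()
        expected = (1 / np.sqrt(2)) / np.sqrt(
            1 + (band.lo_edge / band.hi_edge) ** 10)
        assert ratio == pytest.approx(expected, rel=0.01)

    def test_center_of_wide_band_passes_unchanged(self):
        n, deg = 128, 5.0
        band = BandDefinition(center=2.0, lo_edge=0.2, hi_edge=20.0, order=5)
        img = grating(n, int(2.0 * deg))
        out = bandpass_image(img, band, deg)
        assert out.std() / img.std() == pytest.approx(1.0, abs=0.01)

    def test_all_pass_band_is_identity_on_zero_mean_image(self, rng):
        img = rng.standard_normal((64, 64))
        img -= img.mean()
        band = BandDefinition(center=1.0, lo_edge=1e-9, hi_edge=1e9, order=5)
        out = bandpass_image(img, band, 5.0)
        np.testing.assert_allclose(out, img, atol=1e-9)

    def test_linearity(self, rng):
        band = BandDefinition(center=2.0, lo_edge=1.0, hi_edge=4.0)
        x = rng.standard_normal((32, 32))
        y = rng.standard_normal((32, 32))
        lhs = bandpass_image(2.5 * x - 0.5 * y, band, 5.0)
        rhs = 2.5 * bandpass_image(x, band, 5.0) - 0.5 * bandpass_image(
            y, band, 5.0)
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    def test_energy_never_amplified(self, rng):
        band = BandDefinition(center=2.0, lo_edge=1.0, hi_edge=4.0)
        img = rng.standard_normal((64, 64))
        out = bandpass_image(img, band, 5.0)
        assert np.sum(out ** 2) <= np.sum(img ** 2) * (1 + 1e-9)

    def test_gain_profile_closed_form(self):
        band = BandDefinition(center=2.0, lo_edge=1.0, hi_edge=4.0, order=5)
        f = np.array([0.0, 1.0, 2.0, 4.0])
        g = butterworth_bandpass_gain(f, band)
        assert g[0] == 0.0
        assert g[1] == pytest.approx(
            (1 + 1.0) ** -0.5 * (1 + 0.25 ** 10) ** -0.5)

    def test_non_square_rejected(self):
        band = BandDefinition(center=2.0, lo_edge=1.0, hi_edge=4.0)
        with pytest.raises(ValueError, match="square"):
            bandpass_image(np.zeros((10, 12)), band, 5.0)

    def test_band_above_nyquist_rejected(self):
        band = BandDefinition(center=60.0, lo_edge=50.0, hi_edge=70.0)
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_image(np.zeros((32, 32)), band, 1.0)


class TestGabor:
    def test_uniform_image_silent(self):
        imgs = ImageSet(images=np.full((4, 32, 32), 0.5),
                        labels=np.array([0, 0, 1, 1]),
                        category_names=("a", "b"))
        feats = gabor_features(imgs, GaborConfig(n_frequencies=2,
                                                 n_orientations=4))
        np.testing.assert_allclose(feats.activations, 0.0, atol=1e-8)

    def test_orientation_tuning_and_rotation(self):
        n = 64
        cfg = GaborConfig(n_frequencies=1, n_orientations=4,
                          min_cycles_per_image=8, max_cycles_per_image=8)
        img_v = grating(n, 8, theta=0.0)
        img_h = np.rot90(img_v).copy()
        sets = ImageSet(images=np.stack([img_v, img_h, img_v, img_h]) * 0.5 + 0.5,
                        labels=np.array([0, 0, 1, 1]),
                        category_names=("a", "b"))
        feats = gabor_features(sets, cfg).activations
        n_pos = feats.shape[1] // 4
        energy = feats.reshape(4, 4, n_pos).sum(axis=2)   # img x orientation
        # grating along x varies with x -> tuned orientation theta=0
        assert np.argmax(energy[0]) == 0
        assert np.argmax(energy[1]) == 2                  # rotated by 90 deg
        # 90 deg rotation permutes the orientation channels
        assert energy[1, 2] == pytest.approx(energy[0, 0], rel=0.05)
        assert energy[0, 2] < 0.1 * energy[0, 0]          # orthogonal silent

    def test_empty_bank_rejected(self):
        imgs = ImageSet(images=np.zeros((4, 16, 16)),
                        labels=np.array([0, 0, 1, 1]), category_names=("a", "b"))
        with pytest.raises(ValueError):
            gabor_features(imgs, GaborConfig(n_orientations=0))


class TestFeatureRDM:
    def test_anticorrelated_categories_dissimilarity_two(self):
        acts = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0], [0.0, 1.0]])
        rdm = feature_rdm(ModelFeatureSet(acts, np.array([0, 0, 1, 1])))
        assert rdm[1, 0] == pytest.approx(2.0)
        assert np.isnan(rdm[0, 0])

    def test_identical_category_means_zero(self, rng):
        base = rng.standard_normal((2, 6))
        acts = np.concatenate([base + 0.1, base - 0.1, base + 0.1, base - 0.1])
        labels = np.repeat([0, 1], 4)
        rdm = feature_rdm(ModelFeatureSet(acts, labels))
        np.testing.assert_allclose(rdm[1, 0], 0.0, atol=1e-12)

    def test_identical_stimuli_zero_rdm(self):
        acts = np.tile([1.0, 2.0, 3.0], (8, 1))
        rdm = feature_rdm(ModelFeatureSet(acts, np.repeat([0, 1], 4)))
        assert rdm[1, 0] == 0.0

    def test_affine_feature_rescaling_invariance(self, rng):
        acts = rng.standard_normal((12, 5))
        labels = np.repeat(np.arange(4), 3)
        a = feature_rdm(ModelFeatureSet(acts, labels))
        b = feature_rdm(ModelFeatureSet(acts * [2, 5, 0.1, 7, 3] + 4, labels))
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_stimulus_order_within_category_invariance(self, rng):
        acts = rng.standard_normal((8, 5))
        labels = np.repeat([0, 1], 4)
        perm = np.array([3, 1, 0, 2, 7, 4, 6, 5])
        a = feature_rdm(ModelFeatureSet(acts, labels))
        b = feature_rdm(ModelFeatureSet(acts[perm], labels[perm]))
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_zero_variance_category_identified(self):
        acts = np.array([[1.0, 1.0], [1.0, 1.0], [0.0, 1.0], [1.0, 0.0]])
        with pytest.raises(ValueError, match="category"):
            feature_rdm(ModelFeatureSet(acts, np.array([0, 0, 1, 1])))


class TestPixelBandRDMs:
    def test_disjoint_bands_discriminate_in_their_band(self, rng):
        from catdecode import SynthImageConfig, simulate_stimuli
        cfg = SynthImageConfig(n_per_category=4, image_size=64,
                               category_bands=((0.5, 1.0), (0.5, 1.0),
                                               (4.0, 6.0), (4.0, 6.0)),
                               seed=5)
        imgs = simulate_stimuli(cfg)
        bands = [BandDefinition(center=0.7, lo_edge=0.5, hi_edge=1.0),
                 BandDefinition(center=5.0, lo_edge=4.0, hi_edge=6.0)]
        rdms = pixel_band_rdms(imgs, bands)
        assert len(rdms) == 2
        # cross-band category pairs always dissimilar; within-band pairs
        # are dissimilar only where their content lives
        for rdm in rdms:
            assert rdm[2, 0] > 0.5

    def test_band_count_matches_output(self, rng):
        imgs = ImageSet(images=rng.random((4, 32, 32)),
                        labels=np.array([0, 0, 1, 1]), category_names=("a", "b"))
        rdms = pixel_band_rdms(imgs, make_band_filters(n=5, lo=0.5, hi=3.0))
        assert len(rdms) == 5


class TestLayerAdapter:
    def test_roundtrip_and_rdm(self, rng, tmp_path):
        path = tmp_path / "layers.h5"
        labels = np.repeat(np.arange(4), 32)
        layers = {"relu1": rng.standard_normal((128, 40)),
                  "relu2": rng.standard_normal((128, 100))}
        save_layer_activations(path, layers, labels)
        sets = load_layer_activations(path, n_stimuli=128)
        assert {s.source for s in sets} == {"layer:relu1", "layer:relu2"}
        np.testing.assert_array_equal(sets[0].activations, layers["relu1"])
        rdm = feature_rdm(sets[1])
        tri = rdm[np.tril_indices(4, -1)]
        assert np.all(np.isfinite(tri))

    def test_stimulus_count_mismatch_rejected(self, rng, tmp_path):
        path = tmp_path / "layers.h5"
        save_layer_activations(path, {"x": rng.random((10, 4))}, np.arange(10) % 2)
        with pytest.raises(ValueError, match="stimulus"):
            load_layer_activations(path, n_stimuli=128)

    def test_layer_grouping_for_reporting(self):
        groups = group_layers(list(range(16)), n_groups=5)
        assert len(groups) == 5
        assert sum(len(g) for g in groups) == 16


def test_luminance_conversion():
    rgb = np.ones((4, 4, 3)) * [0.2, 0.5, 0.9]
    lum = to_luminance(rgb)
    assert lum.shape == (4, 4)
    assert lum[0, 0] == pytest.approx(0.2 * 0.299 + 0.5 * 0.587 + 0.9 * 0.114)
    with pytest.raises(ValueError):
        to_luminance(np.zeros((4, 4, 2)))
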