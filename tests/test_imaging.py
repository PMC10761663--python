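import numpy as np
import pytest

from petkin.aif import FENG_POPULATION_MEAN, multi_injection_aif
from petkin.imaging import (
    DEFAULT_REGION_PARAMS,
    DynamicImage,
    LabelMap,
    combined_fwhm,
    default_phantom_labels,
    gaussian_smooth,
    label_roi_tacs,
    spherical_roi_mean,
    synth_phantom,
    voxelwise_maps,
)
from petkin.kinetics import TwoTCMParams, net_influx_rate, tac_2tcm
from petkin.noise import NoiseConfig


@pytest.fixture(scope="module")
def small_phantom():
    """Noiseless phantom on a reduced grid for fast voxel-wise tests."""
    labels = default_phantom_labels(shape=(16, 16, 8))
    return synth_phantom(labels=labels, noise=NoiseConfig(0.0, seed=0))


class TestCombinedFwhm:
    def test_single_component(self):
        assert combined_fwhm([4.2]) == pytest.approx(4.2)
        assert combined_fwhm([4.2, 0.0, 0.0]) == pytest.approx(4.2)

    def test_pythagorean_triple(self):
        assert combined_fwhm([3.0, 4.0]) == pytest.approx(5.0)

    def test_protocol_resolution_chain(self):
        # native 4.37 mm, reconstruction 2 mm, smoothing 4.11 mm
        assert combined_fwhm([4.37, 2.0, 4.11]) == pytest.approx(6.3237, abs=1e-3)

    def test_negative_component_rejected(self):
        with pytest.raises(ValueError):
            combined_fwhm([-1.0])


class TestGaussianSmooth:
    def test_zero_fwhm_is_identity(self, small_phantom):
        out = gaussian_smooth(small_phantom.image, 0.0)
        assert np.array_equal(out.data, small_phantom.image.data)

    def test_uniform_image_unchanged(self, small_phantom):
        image = DynamicImage(
            np.full((8, 8, 4, 3), 5.0),
            small_phantom.image.voxel_size,
            small_phantom.image.schedule.subset(np.arange(3)),
        )
        out = gaussian_smooth(image, 4.11)
        assert np.allclose(out.data, 5.0)

    def test_in_plane_mass_preserved(self, small_phantom):
        out = gaussian_smooth(small_phantom.image, 4.11)
        before = small_phantom.image.data[..., 30].sum(axis=(0, 1))
        after = out.data[..., 30].sum(axis=(0, 1))
        assert np.allclose(after, before, rtol=1e-3)

    def test_no_mixing_across_slices(self, small_phantom):
        data = np.zeros((9, 9, 5, 1))
        data[4, 4, 2, 0] = 1.0
        image = DynamicImage(
            data,
            small_phantom.image.voxel_size,
            small_phantom.image.schedule.subset([0]),
        )
        out = gaussian_smooth(image, 4.11)
        assert out.data[..., 0][:, :, [0, 1, 3, 4]].sum() == 0.0


class TestRoiExtraction:
    def test_uniform_image_spherical_mean(self, small_phantom):
        image = DynamicImage(
            np.full((10, 10, 6, 2), 3.5),
            (1.0, 1.0, 1.0),
            small_phantom.image.schedule.subset([0, 1]),
        )
        tac = spherical_roi_mean(image, (5.0, 5.0, 3.0), 4.0)
        assert np.allclose(tac.activity, 3.5)

    def test_tiny_sphere_selects_single_voxel(self, small_phantom):
        data = np.arange(10 * 10 * 6 * 1, dtype=float).reshape(10, 10, 6, 1)
        image = DynamicImage(
            data, (1.0, 1.0, 1.0), small_phantom.image.schedule.subset([0])
        )
        tac = spherical_roi_mean(image, (5.0, 5.0, 3.0), 0.5)
        assert tac.activity[0] == data[5, 5, 3, 0]

    def test_sphere_outside_grid_rejected(self, small_phantom):
        image = DynamicImage(
            np.zeros((4, 4, 2, 1)),
            (1.0, 1.0, 1.0),
            small_phantom.image.schedule.subset([0]),
        )
        with pytest.raises(ValueError):
            spherical_roi_mean(image, (100.0, 100.0, 100.0), 1.0)

    def test_label_means_match_region_curves(self, small_phantom):
        tacs = label_roi_tacs(small_phantom.image, small_phantom.labels)
        for name, expected in small_phantom.region_tacs.items():
            assert np.allclose(tacs[name].activity, expected.activity)

    def test_unknown_label_rejected(self, small_phantom):
        labels = LabelMap(
            small_phantom.labels.labels,
            {1: "white_matter"},  # table missing most present labels
            small_phantom.labels.voxel_size,
        )
        with pytest.raises(ValueError):
            label_roi_tacs(small_phantom.image, labels)


class TestPhantom:
    def test_gray_matter_voxel_carries_model_curve(self, small_phantom, protocol):
        schedule, injections, _ = protocol

        def aif(t):
            return multi_injection_aif(FENG_POPULATION_MEAN, injections, t)

        gm = DEFAULT_REGION_PARAMS[2]
        expected = tac_2tcm(gm, aif, schedule)
        voxel = np.argwhere(small_phantom.labels.labels == 2)[0]
        assert np.array_equal(
            small_phantom.image.data[tuple(voxel)], expected.activity
        )

    def test_gray_matter_truth_net_influx_rate(self, small_phantom):
        gm_mask = small_phantom.labels.labels == 2
        ki = small_phantom.truth_maps.ki[gm_mask]
        assert np.allclose(ki, 0.08 * 0.04 / 0.15)
        assert net_influx_rate(DEFAULT_REGION_PARAMS[2]) == pytest.approx(0.0213333, abs=1e-6)

    def test_same_seed_bit_identical(self):
        labels = default_phantom_labels(shape=(12, 12, 6))
        a = synth_phantom(labels=labels, noise=NoiseConfig(0.1, seed=21))
        b = synth_phantom(labels=labels, noise=NoiseConfig(0.1, seed=21))
        assert np.array_equal(a.image.data, b.image.data)

    def test_missing_region_parameters_rejected(self):
        labels = default_phantom_labels(shape=(12, 12, 6))
        params = {k: v for k, v in DEFAULT_REGION_PARAMS.items() if k != 2}
        with pytest.raises(ValueError):
            synth_phantom(labels=labels, params_per_region=params)


class TestVoxelwiseMaps:
    def test_noiseless_roundtrip_on_small_grid(self, small_phantom, protocol):
        _, injections, windows = protocol

        def aif(t):
            return multi_injection_aif(FENG_POPULATION_MEAN, injections, t)

        mask = small_phantom.truth_maps.mask
        maps = voxelwise_maps(
            small_phantom.image,
            aif,
            [windows["brain_late"], windows["brain_early"]],
            mask,
        )
        for name in ("k1", "k2", "k3", "ki"):
            est = getattr(maps, name)[mask]
            truth = getattr(small_phantom.truth_maps, name)[mask]
            assert np.nanmax(np.abs(est / truth - 1)) < 0.01

    def test_single_voxel_mask(self, small_phantom, protocol):
        _, injections, windows = protocol

        def aif(t):
            return multi_injection_aif(FENG_POPULATION_MEAN, injections, t)

        mask = np.zeros(small_phantom.image.shape, dtype=bool)
        voxel = tuple(np.argwhere(small_phantom.labels.labels == 1)[0])
        mask[voxel] = True
        maps = voxelwise_maps(
            small_phantom.image,
            aif,
            [windows["brain_late"], windows["brain_early"]],
            mask,
        )
        assert np.isfinite(maps.k1[voxel])
        assert np.isnan(maps.k1[~mask]).all()

    def test_empty_mask_rejected(self, small_phantom, protocol):
        _, injections, windows = protocol
        with pytest.raises(ValueError):
            voxelwise_maps(
                small_phantom.image,
                lambda t: np.asarray(t, dtype=float),
                [windows["brain_early"]],
                np.zeros(small_phantom.image.shape, dtype=bool),
            )

    def test_smoothing_reduces_map_variance(self, protocol):
        """SD of the K1 map over a uniform noisy region drops after
        4.11-mm smoothing."""
        _, injections, windows = protocol

        def aif(t):
            return multi_injection_aif(FENG_POPULATION_MEAN, injections, t)

        labels = np.ones((10, 10, 4), dtype=np.int16)
        labelmap = LabelMap(labels, {1: "gray"}, (1.028, 1.028, 2.02))
        phantom = synth_phantom(
            labels=labelmap,
            params_per_region={1: DEFAULT_REGION_PARAMS[2]},
            noise=NoiseConfig(0.1, seed=8),
        )
        mask = np.zeros(labels.shape, dtype=bool)
        mask[2:8, 2:8, 1:3] = True  # interior voxels, away from edges
        wins = [windows["brain_late"], windows["brain_early"]]
        raw = voxelwise_maps(phantom.image, aif, wins, mask)
        smoothed_img = gaussian_smooth(phantom.image, 4.11)
        smoothed = voxelwise_maps(smoothed_img, aif, wins, mask)
        assert np.nanstd(smoothed.k1[mask]) < np.nanstd(raw.k1[mask])
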