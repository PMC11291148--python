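import numpy as np
import pytest
from scipy import stats

from morphrep.punctate import (
    JitterConfig,
    PointSamplingConfig,
    _exponential_density,
    intensity_to_density,
    jitter_augment,
    sample_intensity_pointcloud,
)
from morphrep.types import InvalidInputError, LabeledPointCloud, VolumeImage


@pytest.fixture(scope="module")
def skewed_pair():
    rng = np.random.default_rng(0)
    vol = VolumeImage(rng.exponential(1.0, (8, 8, 8)), role="intensity")
    mask = VolumeImage(np.ones((8, 8, 8)), role="mask")
    return vol, mask


class TestDensity:
    def test_two_voxel_hand_case(self):
        # intensities 0 and 1, combined coefficient ln 3:
        # weights (1, 3) -> density (1/4, 3/4)
        intensity = np.zeros((1, 1, 2))
        intensity[0, 0, 1] = 1.0
        d = _exponential_density(intensity, np.ones((1, 1, 2)), np.log(3.0))
        assert np.allclose(d.ravel(), [0.25, 0.75])

    def test_constant_intensity_uniform(self):
        vol = VolumeImage(np.full((4, 4, 4), 7.0), role="intensity")
        mask = VolumeImage(np.ones((4, 4, 4)), role="mask")
        d = intensity_to_density(vol, mask)
        assert np.allclose(d.data, 1.0 / 64)
        assert d.meta["skewness"] == 0.0

    def test_symmetric_intensity_uniform(self):
        # a perfectly symmetric distribution has zero skewness, so the
        # exponent vanishes and the density is uniform over the mask
        vals = np.concatenate([np.linspace(0, 1, 32), 1 - np.linspace(0, 1, 32)])
        vol = VolumeImage(vals.reshape(4, 4, 4), role="intensity")
        mask = VolumeImage(np.ones((4, 4, 4)), role="mask")
        d = intensity_to_density(vol, mask)
        assert np.allclose(d.data, 1.0 / 64)

    def test_skewness_matches_scipy(self, skewed_pair):
        vol, mask = skewed_pair
        d = intensity_to_density(vol, mask, lam=100.0)
        vals = vol.data.ravel()
        scaled = (vals - vals.min()) / np.ptp(vals)
        assert np.isclose(d.meta["skewness"], stats.skew(scaled, bias=True))

    def test_sums_to_one_and_zero_outside_mask(self, skewed_pair):
        vol, _ = skewed_pair
        mask = np.zeros((8, 8, 8))
        mask[2:6, 2:6, 2:6] = 1
        d = intensity_to_density(vol, VolumeImage(mask, role="mask"))
        assert np.isclose(d.data.sum(), 1.0)
        assert np.all(d.data[mask == 0] == 0)

    def test_empty_mask_errors(self, skewed_pair):
        vol, _ = skewed_pair
        with pytest.raises(InvalidInputError):
            intensity_to_density(vol, VolumeImage(np.zeros((8, 8, 8)), role="mask"))

    def test_grid_mismatch_errors(self, skewed_pair):
        vol, _ = skewed_pair
        with pytest.raises(InvalidInputError):
            intensity_to_density(vol, VolumeImage(np.ones((4, 4, 4)), role="mask"))


class TestSampling:
    def test_counts_and_channels(self, skewed_pair):
        vol, mask = skewed_pair
        d = intensity_to_density(vol, mask, lam=100.0)
        cfg = PointSamplingConfig(lam=100.0, n_dense=4096, n_sparse=512, seed=1)
        pc = sample_intensity_pointcloud(d, vol, mask, cfg)
        assert pc.points.shape == (4096, 3)
        assert pc.scalars.shape == (4096,)

    def test_centering_on_mask_centroid(self):
        # uniform density over a full mask: sample mean ~ mask centroid,
        # so centered coordinates average to ~0
        vol = VolumeImage(np.ones((6, 6, 6)), role="intensity")
        mask = VolumeImage(np.ones((6, 6, 6)), role="mask")
        d = intensity_to_density(vol, mask)
        cfg = PointSamplingConfig(n_dense=4096, n_sparse=512, seed=1)
        pc = sample_intensity_pointcloud(d, vol, mask, cfg)
        assert np.abs(pc.points.mean(axis=0)).max() < 0.2

    def test_sparse_subsamples(self, skewed_pair):
        vol, mask = skewed_pair
        d = intensity_to_density(vol, mask, lam=100.0)
        cfg = PointSamplingConfig(lam=100.0, n_dense=2048, n_sparse=256, seed=2)
        pc = sample_intensity_pointcloud(d, vol, mask, cfg, sparse=True)
        assert len(pc) == 256

    def test_intensity_channel_scaled(self, skewed_pair):
        vol, mask = skewed_pair
        d = intensity_to_density(vol, mask, lam=100.0)
        cfg = PointSamplingConfig(lam=100.0, n_dense=512, n_sparse=64,
                                  intensity_scale=0.1, seed=3)
        pc = sample_intensity_pointcloud(d, vol, mask, cfg)
        assert pc.scalars.max() <= 0.1 * vol.data.max() + 1e-12

    def test_deterministic(self, skewed_pair):
        vol, mask = skewed_pair
        d = intensity_to_density(vol, mask, lam=100.0)
        cfg = PointSamplingConfig(lam=100.0, n_dense=512, n_sparse=64, seed=4)
        a = sample_intensity_pointcloud(d, vol, mask, cfg)
        b = sample_intensity_pointcloud(d, vol, mask, cfg)
        assert np.array_equal(a.points, b.points)

    def test_high_density_voxels_sampled_more(self):
        # one voxel holds 3/4 of the density -> about 3/4 of the samples
        intensity = np.zeros((1, 1, 2))
        intensity[0, 0, 1] = 1.0
        vol = VolumeImage(intensity, role="intensity")
        mask = VolumeImage(np.ones((1, 1, 2)), role="mask")
        dens = VolumeImage(
            np.array([0.25, 0.75]).reshape(1, 1, 2), role="density"
        )
        cfg = PointSamplingConfig(n_dense=8000, n_sparse=100, seed=5)
        pc = sample_intensity_pointcloud(dens, vol, mask, cfg)
        frac_hot = np.mean(pc.scalars > 0)
        assert abs(frac_hot - 0.75) < 0.02


class TestJitter:
    def test_noise_clipped_and_scalars_kept(self):
        rng = np.random.default_rng(6)
        pc = LabeledPointCloud(points=rng.normal(size=(128, 3)),
                               scalars=rng.uniform(size=128))
        copies = jitter_augment(pc, JitterConfig(sd=0.1, clip=0.2, repeats=10, seed=0))
        assert len(copies) == 10
        for c in copies:
            assert np.abs(c.points - pc.points).max() <= 0.2 + 1e-12
            assert np.array_equal(c.scalars, pc.scalars)

    def test_expand_concatenates(self):
        rng = np.random.default_rng(7)
        pc = LabeledPointCloud(points=rng.normal(size=(256, 3)))
        out = jitter_augment(pc, JitterConfig(repeats=8, seed=1), expand=True)
        assert len(out) == 2048

    def test_zero_sd_identity(self):
        pc = LabeledPointCloud(points=np.ones((4, 3)))
        copies = jitter_augment(pc, JitterConfig(sd=0.0, repeats=2, seed=0))
        assert np.array_equal(copies[0].points, pc.points)

    def test_empty_cloud_errors(self):
        with pytest.raises(InvalidInputError):
            jitter_augment(LabeledPointCloud(points=np.empty((0, 3))), JitterConfig())

    def test_config_validation(self):
        with pytest.raises(InvalidInputError):
            JitterConfig(sd=-0.1)
        with pytest.raises(InvalidInputError):
            JitterConfig(repeats=0)
        with pytest.raises(InvalidInputError):
            PointSamplingConfig(lam=0.0)
        with pytest.raises(InvalidInputError):
            PointSamplingConfig(n_dense=10, n_sparse=20)
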