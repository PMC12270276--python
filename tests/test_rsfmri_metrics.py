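import numpy as np
import pytest
from scipy import stats

from gutbrainlink import rsfmri_metrics as rm
from gutbrainlink.rsfmri_metrics import MetricMap, Volume4D
from gutbrainlink.synth_cohort import simulate_volume4d

TR = 2.0


def make_vol(data, tr=TR, mask=None):
    data = np.asarray(data, dtype=float)
    if mask is None:
        mask = np.ones(data.shape[:3], dtype=bool)
    return Volume4D(data=data, tr=tr, mask=mask)


# --------------------------------------------------------------------------
# independent oracles

def dft_amplitude_oracle(x, tr):
    """Single-sided amplitude spectrum by literal summation DFT."""
    T = len(x)
    n_bins = T // 2 + 1
    amps = np.zeros(n_bins)
    t = np.arange(T)
    for k in range(1, n_bins):
        fk = np.sum(x * np.exp(-2j * np.pi * k * t / T))
        amps[k] = 2 * abs(fk) / T
        if T % 2 == 0 and k == T // 2:
            amps[k] = abs(fk) / T
    freqs = np.arange(n_bins) / (T * tr)
    return freqs, amps


def kendall_w_oracle(series_block):
    """Literal Kendall's W on an (m, T) block: rank each series, sum ranks
    per timepoint, S-summation, W = 12 S / (m^2 (T^3 - T))."""
    m, T = series_block.shape
    ranks = np.vstack([stats.rankdata(s) for s in series_block])
    R = ranks.sum(axis=0)
    S = np.sum((R - R.mean()) ** 2)
    return 12.0 * S / (m**2 * (T**3 - T))


# --------------------------------------------------------------------------
# ALFF / fALFF

class TestAlff:
    def test_constant_series_is_zero(self):
        vol = make_vol(np.full((2, 2, 1, 64), 5.0))
        assert np.all(rm.alff(vol).values == 0)

    def test_amplitude_linearity(self):
        t = np.arange(128) * TR
        s = np.sin(2 * np.pi * 0.05 * t)
        data = np.zeros((2, 1, 1, 128))
        data[0, 0, 0] = 2 * s
        data[1, 0, 0] = s
        vals = rm.alff(make_vol(data)).values
        assert vals[0, 0, 0] / vals[1, 0, 0] == pytest.approx(2.0, abs=1e-6)

    def test_matches_dft_summation_oracle(self, rng):
        data = rng.normal(size=(3, 2, 1, 50))
        vol = make_vol(data)
        amap = rm.alff(vol, band=(0.01, 0.1)).values
        for idx in np.ndindex(3, 2, 1):
            freqs, amps = dft_amplitude_oracle(data[idx], TR)
            sel = (freqs >= 0.01) & (freqs <= 0.1)
            assert amap[idx] == pytest.approx(amps[sel].mean(), abs=1e-10)

    def test_empty_band_reports_bin_grid(self):
        vol = make_vol(np.random.default_rng(0).normal(size=(1, 1, 1, 20)))
        with pytest.raises(ValueError, match="bin grid"):
            rm.alff(vol, band=(0.011, 0.012))

    def test_time_reversal_invariance(self, rng):
        data = rng.normal(size=(2, 2, 1, 40))
        a1 = rm.alff(make_vol(data)).values
        a2 = rm.alff(make_vol(data[..., ::-1])).values
        np.testing.assert_allclose(a1, a2, atol=1e-10)


class TestFalff:
    def test_in_band_sinusoid_is_one(self):
        T = 100
        t = np.arange(T) * TR
        f = 5 / (T * TR)  # exactly on a bin, 0.025 Hz, inside the band
        data = np.sin(2 * np.pi * f * t)[None, None, None, :]
        vals = rm.falff(make_vol(data)).values
        assert vals[0, 0, 0] == pytest.approx(1.0, abs=1e-9)

    def test_out_of_band_sinusoid_is_zero(self):
        T = 100
        t = np.arange(T) * TR
        f = 40 / (T * TR)  # 0.2 Hz, outside 0.01-0.1
        data = np.sin(2 * np.pi * f * t)[None, None, None, :]
        vals = rm.falff(make_vol(data)).values
        assert vals[0, 0, 0] == pytest.approx(0.0, abs=1e-9)

    def test_two_tone_matches_oracle(self, rng):
        T = 80
        t = np.arange(T) * TR
        x = (1.3 * np.sin(2 * np.pi * 0.05 * t)
             + 0.7 * np.sin(2 * np.pi * 0.15 * t) + rng.normal(size=T))
        vol = make_vol(x[None, None, None, :])
        freqs, amps = dft_amplitude_oracle(x, TR)
        sel = (freqs >= 0.01) & (freqs <= 0.1)
        expected = amps[sel].sum() / amps[1:].sum()
        assert rm.falff(vol).values[0, 0, 0] == pytest.approx(expected, abs=1e-10)

    def test_all_zero_series_flagged_zero(self):
        data = np.zeros((1, 1, 1, 32))
        with pytest.warns(UserWarning, match="all-zero"):
            vals = rm.falff(make_vol(data)).values
        assert vals[0, 0, 0] == 0.0

    def test_range(self, rng):
        vol = make_vol(rng.normal(size=(4, 4, 2, 60)))
        vals = rm.falff(vol).values[vol.mask]
        assert np.all((vals >= 0) & (vals <= 1))


# --------------------------------------------------------------------------
# ReHo

class TestReho:
    def test_identical_series_w_is_one(self, rng):
        series = rng.normal(size=40)
        data = np.tile(series, (3, 3, 3, 1))
        vals = rm.reho(make_vol(data)).values
        assert vals[1, 1, 1] == pytest.approx(1.0, abs=1e-12)

    def test_monotone_series_w_is_one(self, rng):
        # strictly increasing series have identical rank matrices
        data = np.empty((3, 3, 3, 30))
        for idx in np.ndindex(3, 3, 3):
            data[idx] = np.cumsum(rng.uniform(0.1, 1.0, 30))
        vals = rm.reho(make_vol(data)).values
        assert vals[1, 1, 1] == pytest.approx(1.0, abs=1e-12)

    def test_matches_literal_oracle_on_random_neighborhoods(self, rng):
        for _ in range(100):
            data = rng.normal(size=(3, 3, 3, 40))
            vol = make_vol(data)
            got = rm.reho(vol).values[1, 1, 1]
            expected = kendall_w_oracle(data.reshape(27, 40))
            assert got == pytest.approx(expected, abs=1e-12)

    def test_edge_voxels_use_in_mask_neighbors(self, rng):
        data = rng.normal(size=(3, 3, 3, 25))
        vol = make_vol(data)
        corner = rm.reho(vol).values[0, 0, 0]
        block = data[:2, :2, :2].reshape(8, 25)  # corner sees 7 neighbors
        assert corner == pytest.approx(kendall_w_oracle(block), abs=1e-12)

    def test_isolated_voxel_zero_flagged(self, rng):
        data = rng.normal(size=(3, 3, 3, 20))
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[0, 0, 0] = True
        with pytest.warns(UserWarning, match="isolated"):
            vals = rm.reho(Volume4D(data=data, tr=TR, mask=mask)).values
        assert vals[0, 0, 0] == 0.0

    def test_range(self, rng):
        vol = make_vol(rng.normal(size=(4, 4, 3, 30)))
        vals = rm.reho(vol).values[vol.mask]
        assert np.all((vals >= 0) & (vals <= 1))


# --------------------------------------------------------------------------
# FCD

class TestFcd:
    def test_identical_series_all_connected(self, rng):
        series = rng.normal(size=30)
        data = np.tile(series, (5, 1, 1, 1))
        vals = rm.fcd(make_vol(data)).values
        assert np.all(vals[:, 0, 0] == 4)

    def test_threshold_is_strict(self):
        # two +-1 series of length 16, zero mean, 10 agreements:
        # r = 4 / (sqrt(16) * sqrt(16)) = 0.25 exactly in floats -> not counted
        x = np.array([1.0] * 8 + [-1.0] * 8)
        y = np.array([1.0] * 5 + [-1.0] * 3 + [1.0] * 3 + [-1.0] * 5)
        assert np.corrcoef(x, y)[0, 1] == pytest.approx(0.25, abs=1e-15)
        data = np.stack([x, y])[:, None, None, :]
        vals = rm.fcd(make_vol(data), r_threshold=0.25).values
        assert np.all(vals == 0)

    def test_matches_brute_force_all_pairs(self, rng):
        V, T = 200, 60
        data = rng.normal(size=(V, 1, 1, T))
        vol = make_vol(data)
        got = rm.fcd(vol).values[:, 0, 0]
        X = data[:, 0, 0, :]
        expected = np.zeros(V, dtype=int)
        for i in range(V):
            for j in range(V):
                if i != j and stats.pearsonr(X[i], X[j])[0] > 0.25:
                    expected[i] += 1
        np.testing.assert_array_equal(got, expected)

    def test_constant_series_zero_flagged(self, rng):
        data = rng.normal(size=(4, 1, 1, 30))
        data[0] = 3.0
        with pytest.warns(UserWarning, match="constant"):
            vals = rm.fcd(make_vol(data)).values
        assert vals[0, 0, 0] == 0

    def test_single_voxel_mask_errors(self, rng):
        data = rng.normal(size=(2, 1, 1, 20))
        mask = np.zeros((2, 1, 1), dtype=bool)
        mask[0] = True
        with pytest.raises(ValueError):
            rm.fcd(Volume4D(data=data, tr=TR, mask=mask))

    def test_timepoint_permutation_invariance(self, rng):
        data = rng.normal(size=(10, 2, 1, 40))
        perm = rng.permutation(40)
        v1 = rm.fcd(make_vol(data)).values
        v2 = rm.fcd(make_vol(data[..., perm])).values
        np.testing.assert_array_equal(v1, v2)


# --------------------------------------------------------------------------
# VMHC

class TestVmhc:
    def test_mirror_symmetric_volume_is_one(self):
        vol = simulate_volume4d(shape=(6, 4, 3), n_timepoints=40, tr=TR,
                                components=[(0.05, 1.0, None)], noise_sd=0.3,
                                mirror_symmetric=True, seed=3)
        vals = rm.vmhc(vol).values[vol.mask]
        np.testing.assert_allclose(vals, 1.0, atol=1e-10)

    def test_negated_counterpart_is_minus_one(self, rng):
        half = rng.normal(size=(2, 3, 2, 30))
        data = np.concatenate([half, -half[::-1]], axis=0)
        vals = rm.vmhc(make_vol(data)).values
        np.testing.assert_allclose(vals[vals != 0], -1.0, atol=1e-10)

    def test_matches_per_pair_correlation_oracle(self, rng):
        data = rng.normal(size=(6, 3, 2, 40))
        vol = make_vol(data)
        got = rm.vmhc(vol).values
        for i, j, k in np.ndindex(6, 3, 2):
            expected = stats.pearsonr(data[i, j, k], data[5 - i, j, k])[0]
            assert got[i, j, k] == pytest.approx(expected, abs=1e-12)

    def test_asymmetric_mask_symmetrized(self, rng):
        data = rng.normal(size=(4, 2, 1, 30))
        mask = np.ones((4, 2, 1), dtype=bool)
        mask[0, 0, 0] = False  # mirror partner (3,0,0) must drop out too
        vol = Volume4D(data=data, tr=TR, mask=mask)
        vals = rm.vmhc(vol).values
        assert vals[0, 0, 0] == 0.0 and vals[3, 0, 0] == 0.0

    def test_mirror_equivariance(self, rng):
        data = rng.normal(size=(6, 2, 2, 30))
        v1 = rm.vmhc(make_vol(data)).values
        v2 = rm.vmhc(make_vol(data[::-1].copy())).values
        np.testing.assert_allclose(v1, v2[::-1], atol=1e-12)

    def test_empty_effective_mask_errors(self, rng):
        data = rng.normal(size=(4, 1, 1, 20))
        mask = np.zeros((4, 1, 1), dtype=bool)
        mask[0] = True  # mirror (3,) not in mask
        with pytest.raises(ValueError, match="effective"):
            rm.vmhc(Volume4D(data=data, tr=TR, mask=mask))


# --------------------------------------------------------------------------
# standardization and cluster means

class TestStandardize:
    def test_mask_mean_is_one(self, rng):
        vol = make_vol(rng.normal(size=(4, 4, 2, 40)))
        m = rm.standardize_map(rm.alff(vol), vol.mask)
        assert m.values[vol.mask].mean() == pytest.approx(1.0, abs=1e-9)
        assert m.standardized

    def test_idempotent_on_mean_one_map(self, rng):
        vol = make_vol(rng.normal(size=(3, 3, 2, 40)))
        m1 = rm.standardize_map(rm.alff(vol), vol.mask)
        m2 = rm.standardize_map(m1, vol.mask)
        np.testing.assert_allclose(m1.values, m2.values, atol=1e-12)

    def test_input_scale_homogeneity(self, rng):
        data = rng.normal(size=(3, 3, 2, 40))
        v1 = make_vol(data)
        v2 = make_vol(4.2 * data)
        m1 = rm.standardize_map(rm.alff(v1), v1.mask)
        m2 = rm.standardize_map(rm.alff(v2), v2.mask)
        np.testing.assert_allclose(m1.values, m2.values, atol=1e-10)

    def test_degenerate_map_errors(self):
        m = MetricMap(values=np.zeros((2, 2, 2)), metric="ALFF")
        with pytest.raises(ValueError, match="degenerate"):
            rm.standardize_map(m, np.ones((2, 2, 2), dtype=bool))


class TestClusterMeans:
    def test_single_voxel_cluster(self, rng):
        vals = rng.normal(size=(3, 3, 2))
        labels = np.zeros((3, 3, 2), dtype=int)
        labels[1, 2, 0] = 5
        m = MetricMap(values=vals, metric="ALFF")
        out = rm.extract_cluster_means(m, labels)
        assert out.loc[0, "mean"] == pytest.approx(vals[1, 2, 0])

    def test_partition_weighted_average_identity(self, rng):
        vals = rng.normal(size=(4, 3, 2))
        labels = np.ones((4, 3, 2), dtype=int)
        labels[2:] = 2
        m = MetricMap(values=vals, metric="ALFF")
        out = rm.extract_cluster_means(m, labels).set_index("label")
        weighted = (out["mean"] * out["n_voxels"]).sum() / out["n_voxels"].sum()
        assert weighted == pytest.approx(vals.mean(), abs=1e-12)

    def test_matches_per_label_loop_oracle(self, rng):
        vals = rng.normal(size=(5, 4, 3))
        labels = rng.integers(0, 4, size=(5, 4, 3))
        m = MetricMap(values=vals, metric="ReHo")
        out = rm.extract_cluster_means(m, labels).set_index("label")
        for lab in (1, 2, 3):
            if (labels == lab).any():
                assert out.loc[lab, "mean"] == pytest.approx(
                    vals[labels == lab].mean(), abs=1e-12)

    def test_out_of_mask_label_omitted_with_warning(self, rng):
        vals = rng.normal(size=(2, 2, 2))
        labels = np.zeros((2, 2, 2), dtype=int)
        labels[0, 0, 0] = 1
        labels[1, 1, 1] = 2
        mask = np.ones((2, 2, 2), dtype=bool)
        mask[1, 1, 1] = False
        m = MetricMap(values=vals, metric="FCD")
        with pytest.warns(UserWarning, match="label 2"):
            out = rm.extract_cluster_means(m, labels, mask)
        assert list(out["label"]) == [1]


class TestVolumeContracts:
    def test_metric_maps_zero_outside_mask(self, rng):
        data = rng.normal(size=(4, 4, 2, 40))
        mask = rng.random((4, 4, 2)) > 0.3
        mask[0, 0, 0] = True
        mask[3, 0, 0] = True  # keep the mirror pair nonempty
        vol = Volume4D(data=data, tr=TR, mask=mask)
        for fn in (rm.alff, rm.falff, rm.reho, rm.fcd, rm.vmhc):
            assert np.all(fn(vol).values[~mask] == 0)

    def test_too_few_timepoints_rejected(self, rng):
        with pytest.raises(ValueError, match="16"):
            make_vol(rng.normal(size=(2, 2, 1, 10)))

    def test_nonfinite_inside_mask_rejected(self, rng):
        data = rng.normal(size=(2, 2, 1, 20))
        data[0, 0, 0, 3] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            make_vol(data)

    def test_bandpass_keeps_in_band_tone_only(self):
        T = 200
        t = np.arange(T) * TR
        tone_in = np.sin(2 * np.pi * 0.05 * t)
        tone_out = np.sin(2 * np.pi * 0.2 * t)
        vol = make_vol((tone_in + tone_out)[None, None, None, :])
        filt = rm.bandpass_filter(vol)
        np.testing.assert_allclose(filt.data[0, 0, 0], tone_in, atol=1e-10)


class TestSimulatedVolume:
    def test_determinism(self):
        kw = dict(shape=(5, 4, 3), n_timepoints=40, tr=TR, noise_sd=0.5, seed=9)
        v1 = simulate_volume4d(**kw)
        v2 = simulate_volume4d(**kw)
        np.testing.assert_array_equal(v1.data, v2.data)

    def test_mirror_symmetry_exact(self):
        vol = simulate_volume4d(shape=(6, 3, 2), n_timepoints=32, tr=TR,
                                noise_sd=1.0, mirror_symmetric=True, seed=2)
        np.testing.assert_array_equal(vol.data, vol.data[::-1])

    def test_noise_free_tone_has_single_in_band_peak(self):
        T, tr = 80, 2.0
        f = 8 / (T * tr)  # exactly on bin 8
        vol = simulate_volume4d(shape=(2, 2, 1), n_timepoints=T, tr=tr,
                                components=[(f, 1.0, None)], noise_sd=0.0,
                                seed=4)
        spec = np.abs(np.fft.rfft(vol.data[0, 0, 0]))
        peaks = np.nonzero(spec > 1e-8)[0]
        assert list(peaks) == [8]

    def test_nyquist_frequency_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            simulate_volume4d(components=[(0.25, 1.0, None)], tr=2.0)
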