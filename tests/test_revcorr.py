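import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lnkit.revcorr import (
    Nonlinearity,
    TemporalFilter,
    compute_nonlinearity,
    compute_spatial_sta,
    compute_sta,
    gain_ratio,
    passes_sta_criterion,
    sta_from_counts,
    sta_pvalues,
)
from lnkit.session import SpikeTrain
from lnkit.synth import (
    GroundTruthNeuron,
    SpatialRF,
    biphasic_filter,
    gen_checkerboard,
    gen_fullfield_noise,
    gen_ln_spikes,
    gen_poisson_spikes,
)

from conftest import naive_sta


class TestSTA:
    def test_constructed_determinism(self):
        # spikes placed exactly 5 frames after every white frame
        stim = gen_fullfield_noise(60, seed=0)
        white = np.where(stim.values == 1)[0]
        spike_frames = white[white >= 29] + 5
        spike_frames = spike_frames[spike_frames < stim.n_frames]
        times = stim.frame_times[spike_frames] + 1e-4
        train = SpikeTrain("u", times, 0.0, 61.0)
        tf = compute_sta(train, stim)
        assert tf.values[5] == pytest.approx(1.0)
        others = np.delete(tf.values, 5)
        assert np.all(np.abs(others) < 0.2)

    def test_null_unit_sta_is_small(self):
        stim = gen_fullfield_noise(600, seed=1)
        train = gen_poisson_spikes(17.0, 600, seed=2)  # ~1e4 spikes
        tf = compute_sta(train, stim)
        assert tf.spike_count > 5000
        assert np.all(np.abs(tf.values) < 5 / np.sqrt(tf.spike_count))

    def test_matches_bruteforce_oracle_bit_exact(self, std_neuron):
        stim = gen_fullfield_noise(10_000 / 60, seed=3)
        spikes = gen_ln_spikes(stim, std_neuron, seed=3)
        tf = compute_sta(spikes, stim)
        from lnkit.session import bin_spikes

        counts = bin_spikes(spikes, stim.frame_times)
        spike_frames = np.repeat(np.arange(stim.n_frames), counts)
        oracle, count = naive_sta(spike_frames, stim.values, 30)
        assert count == tf.spike_count
        np.testing.assert_array_equal(tf.values, oracle)

    def test_mask_requires_full_history(self):
        stim = gen_fullfield_noise(60, seed=4)
        train = gen_poisson_spikes(20.0, 60, seed=5)
        mask = np.ones(stim.n_frames, dtype=bool)
        mask[100:130] = False  # break the history of frames 100..159
        tf_full = compute_sta(train, stim)
        tf_masked = compute_sta(train, stim, state_mask=mask)
        assert tf_masked.spike_count < tf_full.spike_count
        from lnkit.session import bin_spikes

        counts = bin_spikes(train, stim.frame_times)
        # frames 100..129 are masked out; 130..158 have histories crossing
        # the gap; frame 159 is the first with a clean 30-frame history
        excluded = counts[100:159].sum()
        assert tf_masked.spike_count == tf_full.spike_count - excluded

    def test_no_spikes_under_mask_raises(self):
        stim = gen_fullfield_noise(10, seed=0)
        train = gen_poisson_spikes(5.0, 10, seed=1)
        with pytest.raises(ValueError, match="no spikes"):
            compute_sta(train, stim, state_mask=np.zeros(stim.n_frames, bool))


class TestPValues:
    def test_zero_sta_bin_gives_p_one(self):
        tf = TemporalFilter(values=np.zeros(30), spike_count=100)
        assert np.all(sta_pvalues(tf) == 1.0)

    def test_quantile_anchors(self):
        C = 400
        vals = np.zeros(30)
        vals[3] = 1.96 / np.sqrt(C)
        vals[7] = 6.5 / np.sqrt(C)
        p = sta_pvalues(TemporalFilter(values=vals, spike_count=C))
        assert p[3] == pytest.approx(0.05, abs=1e-3)
        assert p[7] < 1e-10

    def test_criterion_window_and_threshold(self):
        C = 400
        vals = np.zeros(30)
        tf = TemporalFilter(values=vals.copy(), spike_count=C)
        tf.p_values = sta_pvalues(tf)
        assert not passes_sta_criterion(tf)  # all p = 1
        vals[20] = 7.0 / np.sqrt(C)  # 333 ms: outside the 200 ms window
        tf = TemporalFilter(values=vals, spike_count=C)
        tf.p_values = sta_pvalues(tf)
        assert not passes_sta_criterion(tf)
        vals[5] = 7.0 / np.sqrt(C)  # 83 ms: inside
        tf = TemporalFilter(values=vals, spike_count=C)
        tf.p_values = sta_pvalues(tf)
        assert passes_sta_criterion(tf)

    def test_planted_filter_passes(self, ln_recording):
        stim, spikes = ln_recording
        assert passes_sta_criterion(compute_sta(spikes, stim))


class TestNonlinearity:
    def test_flat_for_homogeneous_poisson(self):
        stim = gen_fullfield_noise(600, seed=6)
        train = gen_poisson_spikes(10.0, 600, seed=7)
        tf = TemporalFilter(values=biphasic_filter(), spike_count=train.n_spikes)
        nl = compute_nonlinearity(train, stim, tf)
        occ_ok = nl.occupancy >= 200
        se = 10.0 / np.sqrt(nl.occupancy[occ_ok] * (1 / 60.0) * 10.0)
        assert np.all(np.abs(nl.rate_hz[occ_ok] - 10.0) < 3 * se)

    def test_conservation_exact(self, ln_recording):
        stim, spikes = ln_recording
        tf = compute_sta(spikes, stim)
        nl = compute_nonlinearity(spikes, stim, tf)
        total = np.sum(nl.rate_hz * nl.occupancy * nl.dt)
        assert total == pytest.approx(nl.spike_counts.sum(), abs=1e-6)

    def test_recovers_rectified_linear_curve(self, ln_recording, std_neuron):
        stim, spikes = ln_recording
        tf = compute_sta(spikes, stim)
        nl = compute_nonlinearity(spikes, stim, tf)
        m, x0, b = (std_neuron.nl_slope, std_neuron.nl_threshold,
                    std_neuron.baseline_rate)
        truth = b + np.maximum(0.0, m * (nl.bin_centers - x0))
        sel = (nl.occupancy >= 200) & (truth > 5)
        assert sel.sum() >= 5
        # within 10% of truth up to the Poisson counting error of each bin
        se = np.sqrt(truth[sel] / (nl.occupancy[sel] * nl.dt))
        err = np.abs(nl.rate_hz[sel] - truth[sel])
        assert np.all(err < 0.1 * truth[sel] + 3 * se)

    def test_zero_spike_rates(self):
        stim = gen_fullfield_noise(30, seed=8)
        train = SpikeTrain("u", np.array([]), 0.0, 30.0)
        tf = TemporalFilter(values=biphasic_filter(), spike_count=0)
        nl = compute_nonlinearity(train, stim, tf)
        assert np.all(nl.rate_hz == 0)

    def test_zero_norm_filter_rejected(self):
        stim = gen_fullfield_noise(10, seed=0)
        train = gen_poisson_spikes(5.0, 10, seed=0)
        tf = TemporalFilter(values=np.zeros(30), spike_count=10)
        with pytest.raises(ValueError):
            compute_nonlinearity(train, stim, tf)


def _nl(rates, occ, lo=0.0, width=0.1):
    rates = np.asarray(rates, float)
    occ = np.asarray(occ, float)
    edges = lo + np.arange(rates.size + 1) * width
    return Nonlinearity(bin_edges=edges, rate_hz=rates, occupancy=occ,
                        spike_counts=rates * occ / 60.0)


class TestGainRatio:
    def test_identity_curve_gives_zero(self):
        nl = _nl([1, 2, 3, 4, 5], [200] * 5)
        assert gain_ratio(nl, nl) == pytest.approx(0.0)

    def test_exact_halving(self):
        before = _nl([2, 4, 6, 8], [500] * 4)
        after = _nl([1, 2, 3, 4], [500] * 4)
        assert gain_ratio(after, before) == pytest.approx(-50.0)

    def test_undefined_with_few_bins(self):
        before = _nl([2, 4], [500, 500])
        after = _nl([1, 2], [500, 500])
        assert np.isnan(gain_ratio(after, before))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.floats(0.1, 5.0), st.integers(0, 10_000))
    def test_scale_equivariance(self, k, seed):
        rng = np.random.default_rng(seed)
        rates = rng.uniform(1, 20, 8)
        before = _nl(rates, [300] * 8)
        after = _nl(rates * rng.uniform(0.5, 2.0, 8), [300] * 8)
        base = gain_ratio(after, before)
        scaled = gain_ratio(_nl(after.rate_hz * k, [300] * 8), before)
        assert 1 + scaled / 100 == pytest.approx(k * (1 + base / 100))


@pytest.fixture(scope="module")
def spatial_recording():
    rf = SpatialRF(center_y=9, center_x=16, sigma_long=2.0, sigma_short=1.0)
    neuron = GroundTruthNeuron(
        true_filter=biphasic_filter(), nl_slope=30.0, nl_threshold=0.2,
        baseline_rate=2.0, spatial_rf=rf,
    )
    stim = gen_checkerboard(900, seed=5)
    spikes = gen_ln_spikes(stim, neuron, seed=5)
    return stim, spikes


class TestSpatialSTA:
    def test_peak_pixel_near_true_center(self, spatial_recording):
        stim, spikes = spatial_recording
        sf = compute_spatial_sta(spikes, stim)
        iy, ix = np.unravel_index(np.argmax(np.abs(sf.map)), sf.map.shape)
        assert abs(iy - 9) <= 1 and abs(ix - 16) <= 1

    def test_null_unit_no_significant_pixel(self):
        stim = gen_checkerboard(300, seed=6)
        train = gen_poisson_spikes(15.0, 300, seed=7)
        sf = compute_spatial_sta(train, stim)
        assert not np.any(sf.p_values < 1e-10)

    def test_all_excluded_mask_raises(self, spatial_recording):
        stim, spikes = spatial_recording
        with pytest.raises(ValueError):
            compute_spatial_sta(
                spikes, stim, stable_mask=np.zeros(stim.n_frames, bool)
            )


class TestArrayCore:
    def test_sta_from_counts_weighted_spikes(self):
        stim = np.array([1.0, -1, 1, 1, -1, 1, -1, -1, 1, -1])
        counts = np.zeros(10, int)
        counts[4] = 2
        counts[7] = 1
        sta, C = sta_from_counts(counts, stim, n_lags=3)
        assert C == 3
        expected = np.array(
            [(2 * stim[4] + stim[7]), (2 * stim[3] + stim[6]),
             (2 * stim[2] + stim[5])]
        ) / 3
        np.testing.assert_allclose(sta, expected)
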