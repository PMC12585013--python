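import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lnkit.features import (
    classify_types,
    ds_os_index,
    fit_dog_latency,
    fit_rf,
    flash_analysis,
    polarity_index,
    snr,
    spectral_peak_frequency,
)
from lnkit.lif import canonical_filter
from lnkit.revcorr import SpatialFilter, TemporalFilter
from lnkit.synth import (
    SpatialRF,
    biphasic_filter,
    gen_flash_protocol,
    gen_flash_spikes,
)

DT = 1.0 / 60.0


def tf(values, dt=DT):
    return TemporalFilter(values=np.asarray(values, float), dt=dt,
                          spike_count=1000)


class TestDogLatency:
    def test_noiseless_gaussian_bump(self):
        t = np.arange(30) * DT
        v = np.exp(-((t - 0.05) ** 2) / (2 * 0.015**2))
        assert fit_dog_latency(tf(v)) == pytest.approx(0.05, abs=DT)

    def test_sign_flip_invariance(self):
        t = np.arange(30) * DT
        v = np.exp(-((t - 0.08) ** 2) / (2 * 0.02**2)) - 0.4 * np.exp(
            -((t - 0.15) ** 2) / (2 * 0.03**2)
        )
        assert fit_dog_latency(tf(v)) == pytest.approx(
            fit_dog_latency(tf(-v)), abs=1e-6
        )

    def test_canonical_filter_latency_matches_argmax(self):
        L = canonical_filter()
        filt = tf(L)
        raw = np.argmax(np.abs(L)) * DT
        assert abs(fit_dog_latency(filt) - raw) <= DT


class TestSpectralPeak:
    def test_pure_sinusoid(self):
        t = np.arange(60) * DT
        v = np.sin(2 * np.pi * 6.0 * t)
        assert spectral_peak_frequency(tf(v)) == pytest.approx(6.0, abs=0.06)

    def test_time_stretch_halves_frequency(self):
        t = np.arange(30) * DT
        v = np.sin(2 * np.pi * 6.0 * t)
        stretched = np.repeat(v, 2)  # same shape over twice the duration
        f1 = spectral_peak_frequency(tf(v))
        f2 = spectral_peak_frequency(tf(stretched))
        assert f2 == pytest.approx(f1 / 2, abs=0.12)

    def test_canonical_filter_frozen_value(self):
        # regression value from a direct FFT of the closed-form filter
        assert spectral_peak_frequency(tf(canonical_filter())) == pytest.approx(
            2.8125, abs=1e-9
        )

    def test_flat_filter_undefined(self):
        assert np.isnan(spectral_peak_frequency(tf(np.ones(30))))


class TestPolarity:
    def test_purely_positive(self):
        assert polarity_index(tf(np.abs(biphasic_filter()))) == pytest.approx(1.0)

    def test_odd_symmetric_is_zero(self):
        v = np.sin(2 * np.pi * np.arange(30) / 30)
        assert polarity_index(tf(v)) == pytest.approx(0.0, abs=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_antisymmetric_under_sign_flip(self, seed):
        v = np.random.default_rng(seed).standard_normal(30)
        assert polarity_index(tf(-v)) == pytest.approx(
            -polarity_index(tf(v)), abs=1e-12
        )


class TestSNR:
    def test_identical_trials_inf(self):
        m = np.tile(np.sin(np.arange(120)), (5, 1))
        assert snr(m) == np.inf

    def test_signal_plus_noise_matches_analytic(self):
        rng = np.random.default_rng(0)
        s = 10 * np.sin(2 * np.pi * np.arange(120) / 60)
        sigma = 4.0
        m = s + sigma * rng.standard_normal((30, 120))
        expected = np.var(s) / sigma**2
        assert snr(m) == pytest.approx(expected, rel=0.2)

    def test_pure_noise_below_threshold(self):
        rng = np.random.default_rng(1)
        below = sum(
            snr(rng.standard_normal((10, 120))) < 0.15 for _ in range(100)
        )
        assert below >= 95

    def test_constant_offset_invariance(self):
        rng = np.random.default_rng(2)
        m = rng.standard_normal((10, 50)) + np.sin(np.arange(50))
        assert snr(m + 7.5) == pytest.approx(snr(m))


class TestFlashAnalysis:
    def test_on_cell_polarity_and_peak(self):
        flash = gen_flash_protocol(30)
        spikes = gen_flash_spikes(flash, on_off_pref=1.0, peak_rate_hz=100.0,
                                  latency_s=0.05, tau_s=0.02, seed=0)
        fr = flash_analysis(spikes, flash)
        assert fr.on_off_index > 0
        assert fr.aligned_to == "onset"
        # alpha-function rate peaks one tau after the latency
        assert fr.peak_latency_ms == pytest.approx(70.0, abs=15.0)
        assert fr.peak_rate_hz > 20

    def test_off_cell_aligned_to_offset(self):
        flash = gen_flash_protocol(30)
        spikes = gen_flash_spikes(flash, on_off_pref=-1.0, seed=1)
        fr = flash_analysis(spikes, flash)
        assert fr.on_off_index < 0
        assert fr.aligned_to == "offset"

    def test_balanced_cell_zero_index(self):
        from lnkit.session import SpikeTrain
        from lnkit.synth import flash_epoch_starts

        flash = gen_flash_protocol(10)
        starts = flash_epoch_starts(flash)
        times = np.sort(np.concatenate([
            starts["ON"] + 0.5, starts["OFF2"] + 0.5
        ]))
        spikes = SpikeTrain("u", times, 0.0, 71.0)
        fr = flash_analysis(spikes, flash)
        assert fr.on_off_index == pytest.approx(0.0)


class TestFitRF:
    def _spatial(self, sy, sx, theta=0.0, amp=1.0, noise=0.0, seed=0):
        rf = SpatialRF(center_y=9.0, center_x=16.0, sigma_long=sy,
                       sigma_short=sx, orientation=theta)
        m = amp * rf.map() * np.linalg.norm(rf.map())  # un-normalized shape
        if noise:
            m = m + noise * np.random.default_rng(seed).standard_normal(m.shape)
        return SpatialFilter(map=m, peak_lag=3, dt=DT, spike_count=1000)

    def test_noiseless_recovery(self):
        sf = self._spatial(2.0, 1.0)
        assert fit_rf(sf) == pytest.approx(3.0, abs=1e-3)
        assert sf.fit["sigma_long"] == pytest.approx(2.0, abs=1e-3)

    def test_isotropic_size_stable(self):
        sf = self._spatial(1.5, 1.5)
        assert fit_rf(sf) == pytest.approx(3.0, abs=1e-3)

    def test_negative_amplitude_off_map(self):
        sf = self._spatial(2.0, 1.0, amp=-1.0)
        assert fit_rf(sf) == pytest.approx(3.0, abs=1e-3)
        assert sf.fit["amplitude"] < 0


class TestDSOSIndex:
    def test_single_direction_is_one(self):
        r = np.zeros(8)
        r[2] = 5.0
        assert ds_os_index(r, 1) == pytest.approx(1.0, abs=1e-12)
        assert ds_os_index(r, 2) == pytest.approx(1.0, abs=1e-12)

    def test_uniform_is_zero(self):
        r = np.full(8, 3.0)
        assert ds_os_index(r, 1) == pytest.approx(0.0, abs=1e-12)
        assert ds_os_index(r, 2) == pytest.approx(0.0, abs=1e-12)

    def test_cosine_tuning_gives_half(self):
        angles = np.arange(8) * 45.0
        r = 1 + np.cos(np.deg2rad(angles - 90.0))
        assert ds_os_index(r, 1) == pytest.approx(0.5, abs=1e-12)

    def test_all_zero_undefined(self):
        assert np.isnan(ds_os_index(np.zeros(8)))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.floats(0.1, 100.0))
    def test_scale_invariant_and_bounded(self, seed, k):
        r = np.random.default_rng(seed).uniform(0.1, 10, 8)
        for alpha in (1, 2):
            v = ds_os_index(r, alpha)
            assert 0.0 <= v <= 1.0
            assert ds_os_index(k * r, alpha) == pytest.approx(v, abs=1e-9)


@pytest.fixture(scope="module")
def archetype_filters():
    rng = np.random.default_rng(0)
    filters, truth = [], []
    lags = {"fast": 0.04, "mid": 0.07, "slow": 0.11}
    for pol in (1, -1):
        for name, lag in lags.items():
            base = biphasic_filter(peak_lag_s=lag, polarity=pol)
            for _ in range(20):
                noisy = base + 0.05 * rng.standard_normal(base.size)
                filters.append(tf(noisy))
                truth.append(f"{name}_{pol}")
    return filters, truth


class TestClassifyTypes:
    def test_archetype_purity(self, archetype_filters):
        filters, truth = archetype_filters
        out = classify_types(filters, seed=0)
        assert not out.attrs["degenerate"]
        # each true archetype should map almost entirely to one cluster
        import pandas as pd

        df = pd.DataFrame({"truth": truth, "cluster": out["cluster"]})
        purity = (
            df.groupby("truth")["cluster"]
            .agg(lambda c: c.value_counts().iloc[0] / len(c))
            .min()
        )
        assert purity >= 0.95

    def test_deterministic_under_seed(self, archetype_filters):
        filters, _ = archetype_filters
        a = classify_types(filters, seed=3)
        b = classify_types(filters, seed=3)
        np.testing.assert_array_equal(a["cluster"].values, b["cluster"].values)

    def test_degenerate_input_flagged(self):
        filters = [tf(biphasic_filter())] * 12
        out = classify_types(filters, seed=0)
        assert out.attrs["degenerate"]

    def test_too_few_filters(self):
        with pytest.raises(ValueError):
            classify_types([tf(biphasic_filter())] * 3)
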