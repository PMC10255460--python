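"""Band-pass filtering, periodogram band powers and sliding ratio series."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eyesync import (EEG_SCHEME, EYE_SCHEME, BandRatioSeries, BandScheme,
                     align_ratio_series, band_powers, band_ratios, bandpass,
                     sliding_band_ratios)


def sine(freq, rate, duration, amp=1.0):
    t = np.arange(int(rate * duration)) / rate
    return amp * np.sin(2 * np.pi * freq * t)


class TestBandpass:
    def test_passband_retains_amplitude(self):
        x = sine(10.0, 500.0, 20.0)
        y = bandpass(x, 500.0, 8.0, 13.0)
        core = slice(2000, -2000)  # ignore filter edges
        assert y[core].std() >= 0.95 * x[core].std()

    def test_stopband_attenuates(self):
        x = sine(10.0, 500.0, 20.0)
        y = bandpass(x, 500.0, 1.0, 4.0)
        assert y.std() <= 0.05 * x.std()

    def test_zero_in_zero_out(self):
        assert np.allclose(bandpass(np.zeros(5000), 500.0, 1.0, 4.0), 0.0)

    def test_band_edges_validated(self):
        with pytest.raises(ValueError):
            bandpass(np.zeros(100), 60.0, 10.0, 40.0)  # hi > Nyquist


class TestBandPowers:
    def test_pure_alpha_concentrates(self):
        x = sine(10.0, 500.0, 20.0)
        p = band_powers(x, 500.0, EEG_SCHEME)
        assert p["alpha"] / sum(p.values()) >= 0.95

    def test_white_noise_powers_track_bandwidths(self, rng):
        x = rng.standard_normal(int(500 * 600))
        p = band_powers(x, 500.0, EEG_SCHEME)
        total = sum(p.values())
        widths = {name: hi - lo for name, lo, hi in EEG_SCHEME.bands}
        wsum = sum(widths.values())
        for name in p:
            assert p[name] / total == pytest.approx(widths[name] / wsum,
                                                    rel=0.10)

    def test_zero_signal_zero_powers(self):
        p = band_powers(np.zeros(5000), 500.0, EEG_SCHEME)
        assert all(v == 0.0 for v in p.values())

    def test_window_too_short_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            band_powers(np.zeros(100), 60.0, EYE_SCHEME)  # < 2/0.12 s

    def test_matches_bruteforce_dft(self, rng):
        """Periodogram band powers equal an explicit DFT summation."""
        n = 1000
        rate = 500.0
        x = rng.standard_normal(n)
        p = band_powers(x, rate, EEG_SCHEME)

        w = 0.5 - 0.5 * np.cos(2 * np.pi * np.arange(n) / n)  # periodic Hann
        xd = (x - x.mean()) * w
        k = np.arange(n // 2 + 1)
        dft = np.array([np.sum(xd * np.exp(-2j * np.pi * kk *
                                           np.arange(n) / n))
                        for kk in k])
        scale = 1.0 / (rate * np.sum(w ** 2))
        psd = scale * np.abs(dft) ** 2
        psd[1:-1] *= 2  # one-sided
        freqs = k * rate / n
        for name, lo, hi in EEG_SCHEME.bands:
            brute = psd[(freqs >= lo) & (freqs < hi)].sum()
            assert p[name] == pytest.approx(brute, rel=1e-8)


class TestFilteredVarianceRoute:
    def test_agrees_with_periodogram_on_narrowband(self):
        from eyesync.spectral import band_powers_filtered

        x = sine(10.0, 500.0, 30.0) + 0.01 * np.random.default_rng(
            2).standard_normal(30 * 500)
        psd_route = band_ratios(band_powers(x, 500.0, EEG_SCHEME))
        var_route = band_ratios(band_powers_filtered(x, 500.0, EEG_SCHEME))
        assert var_route["alpha"] == pytest.approx(psd_route["alpha"],
                                                   abs=0.02)


class TestBandRatios:
    def test_equal_powers(self):
        r = band_ratios({"delta": 1.0, "theta": 1.0, "alpha": 1.0,
                         "beta": 1.0})
        assert all(v == 0.25 for v in r.values())

    def test_arithmetic(self):
        r = band_ratios({"delta": 3.0, "theta": 1.0, "alpha": 0.0,
                         "beta": 0.0})
        assert r == {"delta": 0.75, "theta": 0.25, "alpha": 0.0, "beta": 0.0}

    def test_all_zero_flagged(self):
        assert band_ratios({"delta": 0.0, "theta": 0.0}) is None

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=1e-9, max_value=1e9), min_size=2,
                    max_size=6))
    def test_normalization(self, powers):
        r = band_ratios({f"b{i}": p for i, p in enumerate(powers)})
        assert sum(r.values()) == pytest.approx(1.0, abs=1e-12)


class TestSlidingBandRatios:
    def test_window_count_and_sizes(self):
        # 300 s at both rates: 121 windows; 10800 / 90000 samples per window
        eye = sliding_band_ratios(np.random.default_rng(0).standard_normal(
            300 * 60), 60.0, EYE_SCHEME, 180.0, 1.0)
        assert eye.n_windows == 121
        assert int(180.0 * 60) == 10800
        assert int(180.0 * 500) == 90000
        assert np.allclose(np.diff(eye.window_starts), 1.0)

    def test_rows_match_band_powers_per_window(self, rng):
        x = rng.standard_normal(60 * 60)
        series = sliding_band_ratios(x, 60.0, EYE_SCHEME, 20.0, 1.0)
        for k in [0, 17, 40]:
            window = x[k * 60:(k + 20) * 60]
            expected = band_ratios(band_powers(window, 60.0, EYE_SCHEME))
            np.testing.assert_allclose(
                series.ratios[k],
                [expected[b] for b in EYE_SCHEME.names], atol=1e-9)

    def test_ratios_sum_to_one(self, rng):
        series = sliding_band_ratios(rng.standard_normal(90 * 60), 60.0,
                                     EYE_SCHEME, 20.0, 1.0)
        sums = series.ratios[~series.excluded].sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_stationary_narrowband_is_stable(self):
        x = sine(10.0, 500.0, 120.0) + 0.01 * np.random.default_rng(
            0).standard_normal(120 * 500)
        series = sliding_band_ratios(x, 500.0, EEG_SCHEME, 20.0, 1.0)
        alpha = series.band("alpha")
        assert alpha.std() / alpha.mean() < 0.1

    def test_bad_windows_excluded(self, rng):
        x = rng.standard_normal(60 * 60)
        bad = np.zeros_like(x, dtype=bool)
        bad[:15 * 60] = True  # first 15 s interpolated
        series = sliding_band_ratios(x, 60.0, EYE_SCHEME, 20.0, 1.0,
                                     bad_mask=bad)
        assert series.excluded[0]          # 75% bad
        assert not series.excluded[-1]     # clean tail
        assert np.isnan(series.ratios[0]).all()

    def test_full_spectrum_denominator_option(self, rng):
        x = rng.standard_normal(60 * 60)
        bands = sliding_band_ratios(x, 60.0, EYE_SCHEME, 20.0, 1.0)
        full = sliding_band_ratios(x, 60.0, EYE_SCHEME, 20.0, 1.0,
                                   full_spectrum_denominator=True)
        # full-spectrum denominator is larger, so ratios shrink and no
        # longer sum to one
        assert (full.ratios <= bands.ratios + 1e-12).all()
        assert full.ratios[0].sum() < 1.0

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            sliding_band_ratios(np.zeros(10 * 60), 60.0, EYE_SCHEME, 20.0)


class TestAlign:
    def make(self, starts, excluded=None):
        n = len(starts)
        return BandRatioSeries(
            source="s", scheme=EYE_SCHEME,
            window_starts=np.asarray(starts, float),
            ratios=np.tile(np.array([0.25, 0.25, 0.25, 0.25]), (n, 1)),
            window_s=20.0, slide_s=1.0,
            excluded=None if excluded is None else np.asarray(excluded))

    def test_identical_grids(self):
        a = self.make(range(10))
        starts, xa, xb = align_ratio_series(a, self.make(range(10)))
        assert len(starts) == 10

    def test_offset_grid_drops_tail(self):
        a = self.make(range(10))
        b = self.make(range(5, 15))
        starts, xa, xb = align_ratio_series(a, b)
        assert len(starts) == 5
        assert starts[0] == 5.0

    def test_excluded_windows_dropped(self):
        a = self.make(range(10), excluded=[True] + [False] * 9)
        starts, _, _ = align_ratio_series(a, self.make(range(10)))
        assert len(starts) == 9

    def test_disjoint_grids_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            align_ratio_series(self.make(range(5)), self.make(range(50, 55)))

    def test_mismatched_window_length_rejected(self):
        b = self.make(range(10))
        b.window_s = 30.0
        with pytest.raises(ValueError):
            align_ratio_series(self.make(range(10)), b)


def test_scheme_validation():
    with pytest.raises(ValueError):
        BandScheme("eeg", (("a", 4.0, 2.0),))
    with pytest.raises(ValueError):
        BandScheme("eeg", (("a", 1.0, 4.0), ("b", 3.0, 8.0)))
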