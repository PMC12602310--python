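"""Spectral estimation, 1/f baseline interpolation and HFO unmasking."""

import numpy as np
import pandas as pd
import pytest

from pfcdyn.io_core import AnalysisConfig, Block, LfpRecording, ValidationError
from pfcdyn.lfp_spectral import (PowerSpectrum, band_power_timecourse,
                                 coherence_spectrum, hfo_power_difference,
                                 interpolate_1f_baseline, select_region_channels,
                                 spectrogram, welch_psd)

FS = 2500.0


def _lfp(data):
    data = np.atleast_2d(data.T).T if data.ndim == 1 else data
    n_ch = data.shape[1]
    ch = pd.DataFrame({"index": range(n_ch),
                       "depth_um": np.linspace(100, 1100, n_ch),
                       "region": ["IL"] * n_ch})
    return LfpRecording(data=data, fs=FS, channels=ch)


def _grid_spectrum(power_fn, n_channels=1, fmax=1250.0):
    """Analytic PowerSpectrum on the 0.25 Hz grid (noise-free construction)."""
    freqs = np.arange(0.25, fmax + 1e-9, 0.25)
    p = np.tile(power_fn(freqs)[:, None], (1, n_channels))
    ch = pd.DataFrame({"index": range(n_channels),
                       "depth_um": np.linspace(100, 1100, n_channels),
                       "region": ["IL"] * n_channels})
    return PowerSpectrum(freqs=freqs, power=p, channels=ch)


class TestWelch:
    def test_grid_spacing_is_quarter_hz(self, cfg):
        t = np.arange(int(8 * FS)) / FS
        lfp = _lfp(np.sin(2 * np.pi * 10 * t)[:, None])
        ps = welch_psd(lfp, Block("rest", "pre", 0.0, 8.0), cfg)
        assert np.allclose(np.diff(ps.freqs), 0.25)

    def test_sinusoid_peaks_at_its_own_bin(self, cfg):
        t = np.arange(int(60 * FS)) / FS
        lfp = _lfp(np.sin(2 * np.pi * 100.0 * t)[:, None])
        ps = welch_psd(lfp, Block("rest", "pre", 0.0, 60.0), cfg)
        assert ps.freqs[np.argmax(ps.power[:, 0])] == pytest.approx(100.0)

    def test_white_noise_total_power_conserved(self, cfg):
        rng = np.random.default_rng(0)
        sigma = 3.0
        lfp = _lfp(rng.normal(0, sigma, (int(120 * FS), 1)))
        ps = welch_psd(lfp, Block("rest", "pre", 0.0, 120.0), cfg)
        total = np.trapezoid(ps.power[:, 0], ps.freqs)
        assert total == pytest.approx(sigma ** 2, rel=0.05)

    def test_off_grid_sinusoid_matches_direct_dft_oracle(self, cfg):
        f0 = 100.1
        t = np.arange(int(60 * FS)) / FS
        x = np.sin(2 * np.pi * f0 * t)
        lfp = _lfp(x[:, None])
        ps = welch_psd(lfp, Block("rest", "pre", 0.0, 60.0), cfg)
        peak = ps.freqs[np.argmax(ps.power[:, 0])]
        # oracle: periodogram of one Hann-windowed 4-s segment via direct DFT
        seg = x[:10000] * np.hanning(10000)
        mag = np.abs(np.fft.rfft(seg))
        oracle_peak = np.fft.rfftfreq(10000, 1 / FS)[np.argmax(mag)]
        assert peak == oracle_peak
        assert peak in (100.0, 100.25)

    def test_block_shorter_than_window_rejected(self, cfg):
        lfp = _lfp(np.zeros((int(2 * FS), 1)))
        with pytest.raises(ValidationError, match="window"):
            welch_psd(lfp, Block("rest", "pre", 0.0, 2.0), cfg)


class TestSpectrogram:
    def test_stationary_sinusoid_constant_row(self, cfg):
        t = np.arange(int(180 * FS)) / FS
        lfp = _lfp(np.sin(2 * np.pi * 40.0 * t)[:, None])
        times, freqs, p = spectrogram(lfp, 0, cfg, window_s=60.0)
        assert p.shape[0] == 3
        row = p[:, np.argmin(np.abs(freqs - 40.0))]
        assert np.ptp(row) / row.mean() < 1e-6

    def test_zero_signal_gives_zero_map(self, cfg):
        lfp = _lfp(np.zeros((int(120 * FS), 1)))
        _, _, p = spectrogram(lfp, 0, cfg, window_s=60.0)
        assert np.all(p == 0)


class TestBaselineInterpolation:
    def test_exact_on_pure_power_law(self):
        ps = _grid_spectrum(lambda f: 50.0 * f ** -2.0)
        base = interpolate_1f_baseline(ps, (80.0, 110.0))
        raw = ps.power[ps.band_mask(80.0, 110.0)]
        assert np.max(np.abs(base - raw) / raw) < 1e-6

    @pytest.mark.parametrize("exponent", [0.5, 1.0, 3.0])
    def test_exact_on_any_exponent(self, exponent):
        ps = _grid_spectrum(lambda f: 10.0 * f ** -exponent)
        base = interpolate_1f_baseline(ps, (80.0, 110.0))
        raw = ps.power[ps.band_mask(80.0, 110.0)]
        assert np.max(np.abs(base - raw) / raw) < 1e-6

    def test_bump_confined_to_band_is_excluded_from_fit(self):
        law = lambda f: 20.0 * f ** -2.0
        bump = lambda f: 4.0 * law(100.0) * np.exp(-0.5 * ((f - 100) / 2.0) ** 2)
        ps = _grid_spectrum(lambda f: law(f) + bump(f))
        base = interpolate_1f_baseline(ps, (80.0, 110.0))[:, 0]
        pure = law(ps.freqs[ps.band_mask(80.0, 110.0)])
        assert np.max(np.abs(base - pure) / pure) < 0.01

    def test_flat_spectrum_gives_flat_baseline(self):
        ps = _grid_spectrum(lambda f: np.full_like(f, 7.0))
        base = interpolate_1f_baseline(ps, (80.0, 110.0))
        assert np.allclose(base, 7.0, rtol=1e-9)

    def test_nonpositive_flank_power_rejected(self):
        ps = _grid_spectrum(lambda f: np.maximum(100.0 - f, 0.0))
        with pytest.raises(ValidationError, match="non-positive"):
            interpolate_1f_baseline(ps, (80.0, 110.0))


class TestHfoPowerDifference:
    def test_pure_power_law_gives_near_zero_db(self, cfg):
        ps = _grid_spectrum(lambda f: 50.0 * f ** -2.0)
        prof = hfo_power_difference(ps, cfg)
        assert abs(prof.hfo_diff_db[0]) < 0.1

    @pytest.mark.parametrize("center", [100.0, 93.0])
    def test_bump_recovery_at_both_dose_profiles(self, cfg, center):
        law = lambda f: 50.0 * f ** -2.0
        ps = _grid_spectrum(
            lambda f: law(f) * (1 + 3.0 * np.exp(-0.5 * ((f - center) / 1.5) ** 2)))
        prof = hfo_power_difference(ps, cfg)
        assert prof.peak_freq_hz[0] == pytest.approx(center, abs=0.25)
        assert prof.hfo_diff_db[0] > 0

    def test_gain_invariance(self, cfg):
        rng = np.random.default_rng(0)
        noise = rng.uniform(0.8, 1.2, 5000)
        ps1 = _grid_spectrum(lambda f: 50.0 * f ** -2.0 * noise[:len(f)])
        ps2 = PowerSpectrum(freqs=ps1.freqs, power=ps1.power * 17.3,
                            channels=ps1.channels)
        p1 = hfo_power_difference(ps1, cfg)
        p2 = hfo_power_difference(ps2, cfg)
        np.testing.assert_allclose(p1.hfo_diff_db, p2.hfo_diff_db, atol=1e-9)
        np.testing.assert_array_equal(p1.peak_freq_hz, p2.peak_freq_hz)

    def test_peak_frequency_stays_in_band(self, cfg):
        rng = np.random.default_rng(1)
        ps = _grid_spectrum(lambda f: 50.0 * f ** -2.0
                            * rng.uniform(0.5, 1.5, len(f)))
        prof = hfo_power_difference(ps, cfg)
        assert 80.0 <= prof.peak_freq_hz[0] <= 110.0


class TestChannelSelection:
    def _multi_region_spectrum(self, il_bump_channel=1):
        freqs = np.arange(0.25, 1250.0 + 1e-9, 0.25)
        law = 50.0 * freqs ** -2.0
        n_ch = 9
        power = np.tile(law[:, None], (1, n_ch))
        bump = 3.0 * law * np.exp(-0.5 * ((freqs - 100) / 1.5) ** 2)
        power[:, il_bump_channel] += bump
        ch = pd.DataFrame({
            "index": range(n_ch),
            "depth_um": list(np.linspace(100, 1500, 3)) * 3,
            "region": ["IL"] * 3 + ["PL"] * 3 + ["CG"] * 3,
        })
        return PowerSpectrum(freqs=freqs, power=power, channels=ch)

    def test_il_channel_with_maximal_bump_selected(self, cfg):
        sel = select_region_channels(self._multi_region_spectrum(il_bump_channel=1), cfg)
        assert sel["IL"] == 1

    def test_pl_channel_nearest_mid_depth(self, cfg):
        # PL depths 100, 800, 1500 -> mid-depth 750 -> channel at 800
        sel = select_region_channels(self._multi_region_spectrum(), cfg)
        assert sel["PL"] == 4

    def test_cg_channel_nearest_fixed_offset(self, cfg):
        # CG depths 100, 800, 1500; default offset 284 µm -> channel at 100
        sel = select_region_channels(self._multi_region_spectrum(), cfg)
        assert sel["CG"] == 6

    def test_missing_region_raises_named_error(self, cfg):
        ps = self._multi_region_spectrum()
        keep = ps.channels["region"] != "IL"
        ps2 = PowerSpectrum(freqs=ps.freqs, power=ps.power[:, keep.to_numpy()],
                            channels=ps.channels[keep].reset_index(drop=True))
        with pytest.raises(ValidationError, match="IL"):
            select_region_channels(ps2, cfg)


class TestCoherence:
    def test_identical_channels_give_unit_coherence(self, cfg):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(int(60 * FS))
        lfp = _lfp(np.column_stack([x, x]))
        coh = coherence_spectrum(lfp, 0, 1, Block("rest", "pre", 0.0, 60.0), cfg)
        assert np.allclose(coh.coherence[1:], 1.0, atol=1e-9)

    def test_independent_noise_bias_shrinks_with_windows(self, cfg):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((int(240 * FS), 2))
        lfp = _lfp(x)
        short = coherence_spectrum(lfp, 0, 1, Block("rest", "pre", 0.0, 60.0), cfg)
        longer = coherence_spectrum(lfp, 0, 1, Block("rest", "pre", 0.0, 240.0), cfg)
        # expected Welch bias ~ 1/n_windows: 1/15 vs 1/60
        assert short.coherence.mean() < 0.2
        assert longer.coherence.mean() < short.coherence.mean()
        assert short.coherence.mean() == pytest.approx(1 / 15, rel=0.4)

    def test_common_component_peaks_at_its_frequency(self, cfg):
        rng = np.random.default_rng(2)
        t = np.arange(int(60 * FS)) / FS
        common = np.sin(2 * np.pi * 40.0 * t)
        x = common + 0.8 * rng.standard_normal(len(t))
        y = common + 0.8 * rng.standard_normal(len(t))
        lfp = _lfp(np.column_stack([x, y]))
        coh = coherence_spectrum(lfp, 0, 1, Block("rest", "pre", 0.0, 60.0), cfg)
        assert coh.freqs[np.argmax(coh.coherence)] == pytest.approx(40.0, abs=0.25)

    def test_zero_variance_channel_rejected(self, cfg):
        lfp = _lfp(np.column_stack([np.zeros(int(60 * FS)),
                                    np.random.default_rng(0).standard_normal(int(60 * FS))]))
        with pytest.raises(ValidationError, match="variance"):
            coherence_spectrum(lfp, 0, 1, Block("rest", "pre", 0.0, 60.0), cfg)


class TestTimecourseOnSyntheticSession:
    def test_hfo_appears_only_after_injection(self, drug_session, cfg):
        lfp, _, sched = drug_session
        tc = band_power_timecourse(lfp, 0, cfg, injection_time=sched.injection_time)
        pre = tc[tc["t"] < 0]["hfo_diff_db"]
        post = tc[tc["t"] > 60]["hfo_diff_db"]
        assert abs(pre.mean()) < 0.5
        assert post.mean() > 0.5

    def test_saline_timecourse_flat(self, saline_session, cfg):
        lfp, _, sched = saline_session
        tc = band_power_timecourse(lfp, 0, cfg, injection_time=sched.injection_time)
        assert np.abs(tc["hfo_diff_db"]).max() < 0.75

    def test_condition_difference_series_computable(self, drug_session,
                                                    saline_session, cfg):
        lfp_d, _, sched_d = drug_session
        lfp_s, _, sched_s = saline_session
        tc_d = band_power_timecourse(lfp_d, 0, cfg, injection_time=sched_d.injection_time)
        tc_s = band_power_timecourse(lfp_s, 0, cfg, injection_time=sched_s.injection_time)
        diff = tc_d["hfo_diff_db"] - tc_s["hfo_diff_db"]
        assert len(diff) == len(tc_d)
        assert diff[tc_d["t"] > 60].mean() > 0.5
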