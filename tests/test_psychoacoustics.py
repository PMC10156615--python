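"""Filterbank geometry, modulation decomposition, ROI, Spearman inference."""

from __future__ import annotations

import numpy as np
import pytest

import soundmap as sm
from soundmap.psychoacoustics import (
    FRAME_S,
    _bin_assignment,
    auditory_spectrogram,
    channel_centres,
    channel_edges,
    correlate_roi_ratings,
    cortical_representation,
    modulation_energy,
    roi_energy,
    spearman_critical_value,
)


class TestFilterbankGeometry:
    def test_lowest_centre_is_182_hz(self):
        assert round(channel_centres()[0]) == 182

    def test_reference_440_on_edge_grid(self):
        assert channel_edges()[31] == pytest.approx(440.0)

    def test_geometric_spacing(self):
        fc = channel_centres()
        assert fc.shape == (128,)
        np.testing.assert_allclose(fc[1:] / fc[:-1], 2 ** (1 / 24))
        assert np.all(np.diff(fc) > 0)


class TestAuditorySpectrogram:
    def test_tone_peaks_at_nearest_channel(self):
        w = sm.generate_stimulus("tone", 1.0, 16000, carrier_hz=1000.0)
        spec = auditory_spectrogram(w)
        nearest = int(np.abs(channel_centres() - 1000.0).argmin())
        assert int(spec.mean(axis=1).argmax()) == nearest
        # per-frame stability
        assert np.all(spec.argmax(axis=0) == nearest)

    def test_440_tone_within_one_channel_of_the_edge(self):
        # 440 Hz sits exactly on a filter edge: either neighbour may win
        w = sm.generate_stimulus("tone", 0.5, 16000, carrier_hz=440.0)
        spec = auditory_spectrogram(w)
        assert int(spec.mean(axis=1).argmax()) in (30, 31)

    def test_silence_is_all_zero(self):
        spec = auditory_spectrogram(sm.Waveform(np.zeros(8000), 16000))
        assert np.allclose(spec, 0.0)

    def test_white_noise_flat_after_q_compensation(self):
        w = sm.generate_stimulus("noise", 3.0, 16000, seed=5)
        spec = auditory_spectrogram(w)
        energy = (spec**2).mean(axis=1) / channel_centres()
        mid = energy[20:108]
        db = 10 * np.log10(mid / np.median(mid))
        assert np.abs(db).max() <= 3.0

    def test_low_sample_rate_rejected(self):
        with pytest.raises(ValueError, match="sample rate"):
            auditory_spectrogram(sm.Waveform(np.zeros(4000), 8000))

    def test_nonnegative(self):
        w = sm.generate_stimulus("noise", 0.5, 16000, seed=6)
        assert auditory_spectrogram(w).min() >= 0.0


class TestModulationEnergy:
    def test_am_noise_peaks_in_matching_rate_bins(self):
        w = sm.generate_stimulus("band-am", 2.5, 16000, band=(3000, 5000), mod_hz=8, seed=1)
        rep = cortical_representation(w)
        marg = rep.rate_marginal()
        bins = np.abs(rep.temporal_mod_bins)
        assert bins[int(np.argmax(marg))] == 8.0

    def test_static_noise_concentrates_in_lowest_bins(self):
        w = sm.generate_stimulus("noise", 2.5, 16000, seed=3)
        marg = cortical_representation(w).rate_marginal()
        bins = np.abs(sm.psychoacoustics.TEMPORAL_MOD_BINS)
        assert marg[bins == 1.0].sum() > marg[bins == 32.0].sum()

    def test_upward_ripple_maps_to_negative_rates(self):
        sr, dur = 16000, 2.5
        t = np.arange(int(dur * sr)) / sr
        up = sm.Waveform(np.sin(2 * np.pi * np.cumsum(500 * 2 ** (2 * t / dur)) / sr), sr)
        down = sm.Waveform(np.sin(2 * np.pi * np.cumsum(2000 * 2 ** (-2 * t / dur)) / sr), sr)
        m_up = cortical_representation(up).rate_marginal()
        m_down = cortical_representation(down).rate_marginal()
        assert m_up[:6].sum() > m_up[6:].sum()  # negative rates dominate
        assert m_down[6:].sum() > m_down[:6].sum()

    def test_parseval_partition(self):
        rng = np.random.default_rng(0)
        spec = rng.random((128, 500))
        rep = modulation_energy(spec, window_s=2.5)
        y = np.log1p(spec / 1e-4)
        yw = y - y.mean()
        Y = np.fft.fft2(yw)
        assign = _bin_assignment(128, 500, FRAME_S)
        # sum over channels and bins of (per-frame-mean energy * cell count)
        # equals the non-static power of the window
        total = (rep.intensity[:, :, :, 0] * rep.cell_counts[None]).sum()
        power = (np.abs(Y)[assign >= 0] ** 2).sum() / (128 * 500 * 500)
        assert total == pytest.approx(power, rel=1e-9)

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError, match="2 s"):
            modulation_energy(np.ones((128, 100)))

    def test_truncation_to_30_seconds(self):
        w = sm.generate_stimulus("noise", 2.0, 16000, seed=9)
        rep_full = cortical_representation(w)
        rep_cut = cortical_representation(w, max_duration_s=2.0)
        np.testing.assert_allclose(rep_full.intensity, rep_cut.intensity)


class TestRoi:
    def _roi(self, w):
        return roi_energy(cortical_representation(w))

    def test_modulated_exceeds_unmodulated_in_band(self):
        am = sm.generate_stimulus("band-am", 2.5, 16000, band=(3000, 5000), mod_hz=8, seed=1)
        flat = sm.generate_stimulus("band-am", 2.5, 16000, band=(3000, 5000), mod_hz=0, seed=1)
        assert self._roi(am) > self._roi(flat)

    def test_64_hz_modulation_falls_outside_roi(self):
        am8 = sm.generate_stimulus("band-am", 2.5, 16000, band=(3000, 5000), mod_hz=8, seed=1)
        am64 = sm.generate_stimulus("band-am", 2.5, 16000, band=(3000, 5000), mod_hz=64, seed=1)
        assert self._roi(am8) > 5 * self._roi(am64)

    def test_out_of_band_stimulus_scores_lower(self):
        low = sm.generate_stimulus("band-am", 2.5, 16000, band=(800, 1200), mod_hz=8, seed=2)
        high = sm.generate_stimulus("band-am", 2.5, 16000, band=(3800, 4200), mod_hz=8, seed=2)
        assert self._roi(low) < self._roi(high)

    def test_amplitude_monotonicity(self):
        w = sm.generate_stimulus("band-am", 2.5, 16000, band=(3000, 5000), mod_hz=8, seed=1)
        half = sm.Waveform(0.5 * w.samples, w.sample_rate)
        assert self._roi(half) < self._roi(w)

    def test_circular_shift_tolerance(self):
        w = sm.generate_stimulus("band-am", 4.0, 16000, band=(3000, 5000), mod_hz=8, seed=4)
        rolled = sm.Waveform(np.roll(w.samples, 4000), w.sample_rate)
        a, b = self._roi(w), self._roi(rolled)
        assert abs(a - b) / a < 0.15

    def test_invalid_roi_bounds_and_empty_channels(self):
        with pytest.raises(ValueError, match="lo < hi"):
            sm.RoiSpec(freq_lo=5000, freq_hi=2500)
        w = sm.generate_stimulus("noise", 2.5, 16000, seed=7)
        rep = cortical_representation(w)
        with pytest.raises(ValueError, match="no filterbank channels"):
            roi_energy(rep, sm.RoiSpec(freq_lo=7200, freq_hi=7600))


class TestSpearmanInference:
    def test_exact_critical_value_n8(self):
        assert spearman_critical_value(8, 0.05, method="exact") == pytest.approx(
            0.642857142857, abs=1e-9
        )

    def test_t_approx_printed_values(self):
        assert round(spearman_critical_value(24, 0.05), 3) == 0.344
        assert round(spearman_critical_value(32, 0.05), 3) == 0.296

    @pytest.mark.parametrize("n", [8, 9, 10])
    def test_exact_and_approx_agree_within_005(self, n):
        exact = spearman_critical_value(n, 0.05, method="exact")
        approx = spearman_critical_value(n, 0.05, method="t_approx")
        assert abs(exact - approx) < 0.05

    def test_exact_beyond_n10_refused(self):
        with pytest.raises(ValueError, match="t_approx"):
            spearman_critical_value(11, method="exact")

    def test_small_n_rejected(self):
        with pytest.raises(ValueError, match="n >= 4"):
            spearman_critical_value(3)

    def test_exact_tail_probability_is_valid(self):
        c = spearman_critical_value(8, 0.05, method="exact")
        from soundmap.psychoacoustics import _exact_rho_tail

        values, tail = _exact_rho_tail(8)
        i = int(np.flatnonzero(np.isclose(values, c))[0])
        assert tail[i] <= 0.05
        if i + 1 < len(values):  # next attainable value breaches alpha
            assert tail[i + 1] > 0.05


class TestRoiCorrelation:
    def test_monotone_relation_detected(self):
        roi = np.linspace(1, 5, 12)
        ratings = roi**2 + 3  # monotone
        res = correlate_roi_ratings(roi, ratings)
        assert res.rho == pytest.approx(1.0)
        assert res.significant

    def test_constant_vector_flagged_undefined(self):
        with pytest.warns(UserWarning, match="constant"):
            res = correlate_roi_ratings(np.ones(8), np.arange(8.0))
        assert np.isnan(res.rho) and not res.significant

    def test_null_calibration_at_n24(self):
        # independent rankings: rho should exceed the one-tailed critical
        # value in about 5% of draws
        rng = np.random.default_rng(0)
        crit = spearman_critical_value(24, 0.05)
        from scipy import stats

        hits = 0
        n_sim = 4000
        base = np.arange(24.0)
        for _ in range(n_sim):
            rho = stats.spearmanr(base, rng.permutation(base)).statistic
            hits += rho >= crit
        rate = hits / n_sim
        assert 0.03 <= rate <= 0.07

    def test_subsets_computed_separately(self):
        rng = np.random.default_rng(1)
        roi = rng.random(32)
        ratings = roi + rng.normal(0, 0.1, 32)
        scrambled = correlate_roi_ratings(roi[:8], ratings[:8])
        natural = correlate_roi_ratings(roi[8:], ratings[8:])
        assert scrambled.n == 8 and scrambled.method == "exact"
        assert natural.n == 24 and natural.method == "t_approx"
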