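import numpy as np
import pytest

import tapkin as tk
from tapkin.metrics import (
    BandOfInterest,
    band_mean_coherence,
    envelope_amplitude,
    estimate_band,
    inter_finger_coherence,
    inter_trial_coherence,
    mean_coherence_spectrum,
    modulation_index,
)
from tapkin.wavelet import WaveletParams, WTCMap, cone_of_influence


def _const_map(value, n=400, p=None):
    p = p or WaveletParams()
    coi = cone_of_influence(n, p)
    return WTCMap(
        coherence=np.full((n, p.n_freqs), value),
        phase=np.zeros((n, p.n_freqs)),
        coi_mask=coi,
        freqs=p.freqs,
        dt=p.dt,
    )


class TestMeanCoherenceSpectrum:
    def test_constant_map_flat_spectrum(self):
        spec = mean_coherence_spectrum([_const_map(0.7)])
        assert np.allclose(spec[np.isfinite(spec)], 0.7)

    def test_two_maps_average(self):
        spec = mean_coherence_spectrum([_const_map(0.2), _const_map(0.8)])
        assert np.allclose(spec[np.isfinite(spec)], 0.5)

    def test_frequency_without_valid_points_is_nan(self):
        p = WaveletParams()
        m = _const_map(0.5, n=150, p=p)  # short: lowest freqs fully outside COI
        spec = mean_coherence_spectrum([m])
        assert np.isnan(spec[0])
        assert np.isfinite(spec[-1])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mean_coherence_spectrum([])

    def test_spectrum_peaks_at_generator_rate(self, preprocessed_session, wavelet_params):
        """Pooled inter-trial spectrum peaks near (within the estimator's
        resolution of) the implanted tapping rate."""
        records, _, truth = preprocessed_session
        band, spec, _ = tk.participant_coherence(records, wavelet_params)
        f0 = truth.tapping_rate[0]
        assert abs(np.log2(band.tapping_rate / f0)) < 0.45  # within ~3 grid steps


class TestEstimateBand:
    def test_triangle_geometry(self):
        freqs = np.array([3.0, 4, 5, 6, 7])
        spec = np.array([0.1, 0.4, 0.8, 0.4, 0.1])
        band = estimate_band(freqs, spec)
        assert band.tapping_rate == 5.0
        assert band.f_low == pytest.approx(4.0)
        assert band.f_high == pytest.approx(6.0)

    def test_interpolated_crossings(self):
        freqs = np.array([1.0, 2, 3, 4, 5])
        spec = np.array([0.0, 0.2, 1.0, 0.2, 0.0])
        band = estimate_band(freqs, spec)
        # half max 0.5 crossed between grid points
        assert 2 < band.f_low < 3 < band.f_high < 4

    def test_flat_spectrum_rejected(self):
        with pytest.raises(ValueError, match="flat|interior"):
            estimate_band(np.arange(1, 6.0), np.full(5, 0.5))

    def test_boundary_peak_rejected(self):
        with pytest.raises(ValueError, match="boundary"):
            estimate_band(np.arange(1, 6.0), np.array([0.9, 0.5, 0.4, 0.3, 0.2]))

    def test_plateau_resolves_left_with_warning(self):
        freqs = np.arange(1, 8.0)
        spec = np.array([0.1, 0.2, 0.8, 0.8, 0.3, 0.2, 0.1])
        with pytest.warns(UserWarning, match="plateau"):
            band = estimate_band(freqs, spec)
        assert band.tapping_rate == 3.0

    def test_band_ordering_enforced(self):
        with pytest.raises(ValueError):
            BandOfInterest(tapping_rate=5.0, f_low=6.0, f_high=7.0)


class TestCoherenceSummaries:
    def test_duplicated_trial_coherence_near_one(self, wavelet_params):
        rng = np.random.default_rng(0)
        t = np.arange(344) / 60.0
        y = np.sin(2 * np.pi * 5 * t) + rng.normal(0, 0.3, len(t))
        band = BandOfInterest(5.0, 4.0, 6.2)
        coh, n = inter_trial_coherence([y, y.copy()], band, wavelet_params)
        assert n == 1
        assert coh >= 0.999

    def test_pair_counts(self, wavelet_params):
        rng = np.random.default_rng(1)
        t = np.arange(344) / 60.0
        trials = [
            np.sin(2 * np.pi * 5 * t) + rng.normal(0, 0.3, len(t)) for _ in range(5)
        ]
        band = BandOfInterest(5.0, 4.0, 6.2)
        _, n = inter_trial_coherence(trials, band, wavelet_params)
        assert n == 5 * 4 // 2

    def test_fewer_than_two_trials_rejected(self, wavelet_params):
        with pytest.raises(ValueError):
            inter_trial_coherence([np.zeros(344)], BandOfInterest(5, 4, 6))

    def test_inter_finger_six_pairs_and_lag_invariance(self, wavelet_params):
        """Fingertips with pure phase lags and common rate cohere ~1:
        coherence magnitude ignores constant phase offsets."""
        rng = np.random.default_rng(2)
        t = np.arange(344) / 60.0
        fingers = {
            f: np.sin(2 * np.pi * 5 * t - k * np.pi / 2) + rng.normal(0, 0.05, len(t))
            for k, f in enumerate(tk.FINGERS)
        }
        band = BandOfInterest(5.0, 4.0, 6.2)
        coh, n = inter_finger_coherence(fingers, band, wavelet_params)
        assert n == 6
        assert coh >= 0.97

    def test_one_jittered_finger_lowers_mean(self, wavelet_params):
        cfg = tk.SimConfig(
            noise_sd=1.0, tapping_rate=5.0,
            phase_jitter_sd={c: 0.0 for c in tk.CONDITIONS},
        )
        trial, _ = tk.generate_trial(cfg, "reference", "short", seed=0)
        roi = slice(90, 90 + 344)
        band = BandOfInterest(5.0, 4.0, 6.2)
        clean = {f: trial.y(f"{f}_tip")[roi] for f in tk.FINGERS}
        base, _ = inter_finger_coherence(clean, band, wavelet_params)
        rng = np.random.default_rng(1)
        # replace one finger with an independently jittered oscillation
        tt = np.arange(344) / 60.0
        jitter = np.cumsum(rng.normal(0, 0.12, 344))
        perturbed = dict(clean)
        perturbed["little"] = 10 * np.sin(2 * np.pi * 5 * tt + jitter) + rng.normal(
            0, 1.0, 344
        )
        worse, _ = inter_finger_coherence(perturbed, band, wavelet_params)
        assert worse < base

    def test_missing_fingertip_named(self, wavelet_params):
        with pytest.raises(ValueError, match="ring"):
            inter_finger_coherence(
                {"index": np.zeros(344), "middle": np.zeros(344), "little": np.zeros(344)},
                BandOfInterest(5, 4, 6),
            )


class TestEnvelopeAmplitude:
    def test_pure_tone_amplitude(self):
        t = np.arange(344) / 60.0
        y = 20.0 * np.sin(2 * np.pi * 5.0 * t)
        a = envelope_amplitude(y, BandOfInterest(5.0, 4.0, 6.2))
        assert a == pytest.approx(20.0, rel=0.02)

    def test_homogeneity(self):
        rng = np.random.default_rng(0)
        t = np.arange(344) / 60.0
        y = 10 * np.sin(2 * np.pi * 5 * t) + rng.normal(0, 1, len(t))
        band = BandOfInterest(5.0, 4.0, 6.2)
        assert envelope_amplitude(2 * y, band) == pytest.approx(
            2 * envelope_amplitude(y, band), rel=1e-9
        )

    def test_raised_cosine_gain_ratio(self):
        """The tap-train envelope ratio between two gains recovers the gain
        ratio within 2%."""
        cfg = tk.SimConfig(
            noise_sd=0.0, outlier_rate=0.0, rate_drift_sd=0.0,
            amplitude_jitter_cv=0.0, tapping_rate=5.0,
            phase_jitter_sd={c: 0.0 for c in tk.CONDITIONS},
        )
        band = BandOfInterest(5.0, 4.0, 6.2)
        roi = slice(90, 90 + 344)
        ref, _ = tk.generate_trial(cfg, "reference", "short", seed=0)
        att, _ = tk.generate_trial(cfg, "index_focused", "short", seed=0)
        g = cfg.condition_gain["index_focused"]["index"]
        ratio = envelope_amplitude(att.y("index_tip")[roi], band) / envelope_amplitude(
            ref.y("index_tip")[roi], band
        )
        assert ratio == pytest.approx(g, rel=0.02)

    def test_band_beyond_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            envelope_amplitude(np.zeros(344), BandOfInterest(20.0, 15.0, 31.0))

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="settling"):
            envelope_amplitude(np.zeros(30), BandOfInterest(5.0, 4.0, 6.2))


class TestModulationIndex:
    @pytest.mark.parametrize(
        "att,ref,expected", [(10, 10, 0.0), (15, 10, 0.5), (8, 10, -0.2)]
    )
    def test_arithmetic(self, att, ref, expected):
        assert modulation_index(att, ref) == pytest.approx(expected)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            modulation_index(5.0, 0.0)


class TestBandMeanCoherence:
    def test_band_restriction(self):
        m = _const_map(0.6)
        band = BandOfInterest(5.0, 4.0, 6.2)
        assert band_mean_coherence(m, band) == pytest.approx(0.6)

    def test_empty_band_rejected(self):
        m = _const_map(0.6)
        with pytest.raises(ValueError):
            band_mean_coherence(m, BandOfInterest(5.001, 5.0, 5.002))
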