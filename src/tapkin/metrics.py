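"""Automaticity metrics: tapping rate, FWHM band, coherence summaries,
Hilbert-envelope amplitude and the attentional modulation index I_A.

The participant's tapping rate is the frequency at which the inter-trial
coherence spectrum (averaged over COI-valid ROI points, trial pairs,
fingertips, durations and conditions) peaks; the frequency range of
interest is the full-width-at-half-maximum (FWHM) band around that peak.
Tapping amplitude A is the mean Hilbert-envelope magnitude of the
band-passed fingertip trajectory over the ROI, and the modulation index is

    I_A = A_attention / A_reference - 1,

so the reference condition maps to exactly 0, positive values mean
attentional facilitation and negative values inhibition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.signal import butter, filtfilt, hilbert, lfilter

from .keypoints import FINGERS
from .wavelet import WaveletParams, WTCMap, wtc

__all__ = [
    "BandOfInterest",
    "mean_coherence_spectrum",
    "estimate_band",
    "inter_trial_coherence",
    "inter_finger_coherence",
    "band_mean_coherence",
    "envelope_amplitude",
    "modulation_index",
]


@dataclass(frozen=True)
class BandOfInterest:
    """Tapping rate and its FWHM frequency band, in Hz."""

    tapping_rate: float
    f_low: float
    f_high: float

    def __post_init__(self) -> None:
        if not (self.f_low < self.tapping_rate < self.f_high):
            raise ValueError("band must satisfy f_low < tapping_rate < f_high")


def mean_coherence_spectrum(
    maps: list[WTCMap], roi: slice | None = None
) -> np.ndarray:
    """Per-frequency mean coherence over COI-valid (ROI) points, then maps.

    Frequencies with no valid point in any map are returned as NaN and are
    excluded from downstream peak search.
    """
    if not maps:
        raise ValueError("need at least one coherence map")
    freqs = maps[0].freqs
    acc = np.zeros((len(maps), len(freqs)))
    acc[:] = np.nan
    for i, m in enumerate(maps):
        if m.coherence.shape[1] != len(freqs) or not np.allclose(m.freqs, freqs):
            raise ValueError("maps must share one frequency grid")
        coh = m.coherence[roi] if roi is not None else m.coherence
        valid = m.coi_mask[roi] if roi is not None else m.coi_mask
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            acc[i] = np.nanmean(np.where(valid, coh, np.nan), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(acc, axis=0)


def estimate_band(freqs: np.ndarray, spectrum: np.ndarray) -> BandOfInterest:
    """Peak frequency and FWHM band of a coherence-vs-frequency spectrum.

    The tapping rate is the global peak; the band is the maximal contiguous
    interval around the peak on which the spectrum stays at or above half
    the peak value, with the endpoints linearly interpolated between grid
    points. A peak on the grid boundary raises (extend the grid); a plateau
    peak resolves to its leftmost point with a warning.
    """
    freqs = np.asarray(freqs, float)
    spec = np.asarray(spectrum, float)
    valid = np.isfinite(spec)
    if valid.sum() < 3:
        raise ValueError("spectrum has fewer than 3 finite points")
    peak_val = np.nanmax(spec)
    if np.nanmin(spec) == peak_val:
        raise ValueError("spectrum is flat; no interior peak")
    peak_candidates = np.flatnonzero(spec == peak_val)
    if len(peak_candidates) > 1:
        warnings.warn("plateau peak; using its leftmost frequency", stacklevel=2)
    ip = int(peak_candidates[0])
    if ip == 0 or ip == len(freqs) - 1:
        raise ValueError(
            "coherence peak lies on the frequency-grid boundary; extend the grid"
        )
    half = peak_val / 2.0

    def _cross(direction: int) -> float:
        i = ip
        while 0 <= i + direction < len(spec):
            j = i + direction
            if not np.isfinite(spec[j]) or spec[j] < half:
                if not np.isfinite(spec[j]):
                    return freqs[i]
                # linear interpolation of the half-maximum crossing
                t = (spec[i] - half) / (spec[i] - spec[j])
                return freqs[i] + t * (freqs[j] - freqs[i])
            i = j
        return freqs[i]  # never fell below half within the grid

    return BandOfInterest(
        tapping_rate=float(freqs[ip]),
        f_low=float(_cross(-1)),
        f_high=float(_cross(+1)),
    )


def band_mean_coherence(m: WTCMap, band: BandOfInterest, roi: slice | None = None) -> float:
    """Mean coherence over COI-valid (ROI) points inside the frequency band."""
    in_band = (m.freqs >= band.f_low) & (m.freqs <= band.f_high)
    if not in_band.any():
        raise ValueError("band contains no grid frequency")
    coh = m.coherence[roi][:, in_band] if roi is not None else m.coherence[:, in_band]
    valid = m.coi_mask[roi][:, in_band] if roi is not None else m.coi_mask[:, in_band]
    if not valid.any():
        raise ValueError("no COI-valid points inside the band")
    return float(coh[valid].mean())


def inter_trial_coherence(
    trials: list[np.ndarray],
    band: BandOfInterest,
    p: WaveletParams | None = None,
    roi: slice | None = None,
) -> tuple[float, int]:
    """Mean pairwise WTC of one fingertip across same-condition trials.

    ``trials`` are equal-length ROI series of a single fingertip. Returns
    ``(mean coherence, n_pairs)`` with coherence averaged over COI-valid
    points inside ``band`` and over all n(n-1)/2 unordered trial pairs.
    """
    if len(trials) < 2:
        raise ValueError("need at least 2 trials")
    if p is None:
        p = WaveletParams()
    vals = [
        band_mean_coherence(wtc(a, b, p), band, roi)
        for a, b in combinations(trials, 2)
    ]
    return float(np.mean(vals)), len(vals)


def inter_finger_coherence(
    fingertips: dict[str, np.ndarray],
    band: BandOfInterest,
    p: WaveletParams | None = None,
    roi: slice | None = None,
) -> tuple[float, int]:
    """Mean pairwise WTC across the four fingertips within one trial.

    ``fingertips`` maps finger name -> ROI series; all four tapping fingers
    must be present (6 unordered pairs).
    """
    for f in FINGERS:
        if f not in fingertips:
            raise ValueError(f"missing fingertip series for {f!r}")
    if p is None:
        p = WaveletParams()
    vals = [
        band_mean_coherence(wtc(fingertips[a], fingertips[b], p), band, roi)
        for a, b in combinations(FINGERS, 2)
    ]
    return float(np.mean(vals)), len(vals)


def envelope_amplitude(
    y: np.ndarray,
    band: BandOfInterest,
    fs: float = 60.0,
    causal: bool = False,
) -> float:
    """Mean Hilbert-envelope amplitude of a band-passed ROI series, in pixels.

    The series is band-pass filtered to [f_low, f_high] with a 4th-order
    Butterworth applied forward-backward (zero phase) by default; ``causal``
    switches to a single forward pass for comparison with causal-filter
    conventions. One filter settling length (``fs / f_low`` samples) is
    excluded at each end before averaging the analytic-signal magnitude.
    """
    y = np.asarray(y, float)
    if band.f_high >= fs / 2:
        raise ValueError("band extends beyond the Nyquist frequency")
    settle = int(round(fs / band.f_low))
    if len(y) <= 3 * settle:
        raise ValueError("ROI series shorter than 3 filter settling lengths")
    sos_b, sos_a = butter(4, [band.f_low, band.f_high], btype="bandpass", fs=fs)
    if causal:
        filt = lfilter(sos_b, sos_a, y - y.mean())
    else:
        filt = filtfilt(sos_b, sos_a, y - y.mean())
    env = np.abs(hilbert(filt))
    return float(env[settle:-settle].mean())


def modulation_index(a_attention: float, a_reference: float) -> float:
    """I_A = A_attention / A_reference - 1 (reference maps to exactly 0)."""
    if a_reference <= 0:
        raise ValueError("reference amplitude must be positive")
    return a_attention / a_reference - 1.0
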