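"""Morlet continuous wavelet transform and wavelet-transform coherence (WTC).

Coherence between two time series is computed from smoothed wavelet auto- and
cross-spectra,

    R^2(t, s) = |S(W_xy / s)|^2 / ( S(|W_x|^2 / s) * S(|W_y|^2 / s) ),

where ``S`` smooths first in time (Gaussian of standard deviation equal to
the scale ``s``) and then across scales (boxcar of fixed decorrelation
length, 0.6 octaves for the Morlet). ``R^2`` lies in [0, 1]; 1 means locally
phase-locked, 0 means unrelated. Edge artifacts are flagged through the cone
of influence (COI): a time-frequency point is valid only if its distance to
the nearer record edge exceeds the Morlet e-folding time ``sqrt(2) * s``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sfft
from scipy.ndimage import convolve1d

__all__ = ["WaveletParams", "WTCMap", "cwt_morlet", "wtc", "cone_of_influence"]


@dataclass(frozen=True)
class WaveletParams:
    """Morlet CWT / WTC configuration.

    Parameters
    ----------
    omega0
        Nondimensional Morlet frequency; 6 gives a good time/frequency
        trade-off and makes scale ~ 1/frequency.
    f_min, f_max, n_freqs
        Analysis grid: ``n_freqs`` log-spaced frequencies spanning
        [f_min, f_max] Hz. The default 40-point [0.5, 15] Hz grid brackets
        human tapping rates (~3-8.5 Hz) with margin for harmonics.
    dt
        Sampling interval in seconds (1/60 for 60 Hz video).
    scale_smoothing_octaves
        Width of the boxcar smoothing across scales, in octaves.
    """

    omega0: float = 6.0
    f_min: float = 0.5
    f_max: float = 15.0
    n_freqs: int = 40
    dt: float = 1.0 / 60.0
    scale_smoothing_octaves: float = 0.6

    def __post_init__(self) -> None:
        if self.omega0 < 5:
            raise ValueError("omega0 must be >= 5 for practical admissibility")
        if not (0 < self.f_min < self.f_max):
            raise ValueError("need 0 < f_min < f_max")
        if self.n_freqs < 2:
            raise ValueError("need at least 2 frequencies")
        if self.f_max >= 0.5 / self.dt:
            raise ValueError("f_max must lie below the Nyquist frequency")

    @property
    def freqs(self) -> np.ndarray:
        """Strictly increasing analysis frequencies in Hz."""
        return np.geomspace(self.f_min, self.f_max, self.n_freqs)

    @property
    def fourier_period_factor(self) -> float:
        """Fourier period / scale ratio for the Morlet wavelet."""
        return 4.0 * np.pi / (self.omega0 + np.sqrt(2.0 + self.omega0**2))

    @property
    def scales(self) -> np.ndarray:
        """Wavelet scales (seconds) matching ``freqs``, decreasing with f."""
        return 1.0 / (self.freqs * self.fourier_period_factor)

    @property
    def dj(self) -> float:
        """Grid spacing in octaves (log2 frequency step)."""
        return float(np.log2(self.f_max / self.f_min) / (self.n_freqs - 1))


@dataclass
class WTCMap:
    """Time x frequency wavelet coherence map.

    Attributes
    ----------
    coherence
        ``(n_times, n_freqs)`` squared coherence in [0, 1].
    phase
        ``(n_times, n_freqs)`` cross-spectrum phase in (-pi, pi]; positive
        means the first series leads.
    coi_mask
        ``(n_times, n_freqs)`` boolean; ``True`` where the point lies inside
        the cone of influence (i.e. is valid).
    freqs
        Analysis frequencies in Hz.
    dt
        Sampling interval in seconds.
    """

    coherence: np.ndarray
    phase: np.ndarray
    coi_mask: np.ndarray
    freqs: np.ndarray
    dt: float = 1.0 / 60.0
    times: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.times is None:
            self.times = np.arange(self.coherence.shape[0]) * self.dt


def _check_series(y: np.ndarray, p: WaveletParams) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if y.ndim != 1:
        raise ValueError("expected a 1-D series")
    if not np.all(np.isfinite(y)):
        raise ValueError("series contains non-finite values; preprocess first")
    longest_period = 1.0 / p.f_min
    if len(y) * p.dt < 2.0 * longest_period:
        raise ValueError(
            f"series of {len(y)} samples is shorter than twice the longest "
            f"analyzed period ({2 * longest_period:.2f} s at f_min={p.f_min} Hz)"
        )
    return y


def _pad_length(n: int, margin: int = 0) -> int:
    return int(2 ** np.ceil(np.log2(max(2, n + margin))))


def cwt_morlet(y: np.ndarray, p: WaveletParams) -> np.ndarray:
    """Morlet CWT of ``y`` at the scales of ``p.freqs``.

    Returns the complex coefficient array of shape ``(n_freqs, n_times)``.
    The transform is linear in the input and computed in the Fourier domain
    with zero padding to the next power of two (edge effects are handled
    downstream through the cone of influence).
    """
    y = _check_series(y, p)
    n = len(y)
    npad = _pad_length(2 * n)
    omega = 2.0 * np.pi * np.fft.fftfreq(npad, p.dt)  # angular frequency
    yhat = np.fft.fft(y - y.mean(), n=npad)

    s = p.scales[:, None]
    # analytic Morlet daughter in the Fourier domain (Heaviside cut at 0)
    norm = np.pi**-0.25 * np.sqrt(2.0 * np.pi * s / p.dt)
    psi_hat = norm * np.exp(-0.5 * (s * omega[None, :] - p.omega0) ** 2)
    psi_hat[:, omega <= 0] = 0.0

    W = np.fft.ifft(yhat[None, :] * psi_hat, axis=1)[:, :n]
    return W


def _smooth_spectrum(A: np.ndarray, p: WaveletParams) -> np.ndarray:
    """Time-then-scale smoothing of a (..., scale, time) spectral density.

    Time smoothing convolves each scale row with a Gaussian whose standard
    deviation equals the scale (in samples); scale smoothing is a boxcar of
    ``scale_smoothing_octaves`` octaves with fractional end weights.
    Identical positive weights are applied to auto- and cross-spectra, which
    keeps coherence within [0, 1].
    """
    n = A.shape[-1]
    snorm = p.scales / p.dt  # scale expressed in samples
    npad = _pad_length(n, margin=int(3 * snorm.max()))
    omega = 2.0 * np.pi * np.fft.fftfreq(npad)

    gauss = np.exp(-0.5 * (snorm[:, None] ** 2) * omega[None, :] ** 2)
    if A.dtype in (np.complex64, np.float32):
        gauss = gauss.astype(np.float32)
    sm = sfft.ifft(gauss * sfft.fft(A, n=npad, axis=-1), axis=-1)[..., :n]
    if not np.iscomplexobj(A):
        sm = sm.real

    # boxcar over scales of total width scale_smoothing_octaves, with
    # fractional end weights; zero-padded edges cancel in the coherence
    # ratio since the same kernel is applied to auto- and cross-spectra
    half_steps = p.scale_smoothing_octaves / (2.0 * p.dj)
    n_ones = max(1, 2 * int(round(half_steps)) - 1)
    frac = half_steps % 1.0
    kernel = np.concatenate(([frac], np.ones(n_ones), [frac]))
    kernel /= kernel.sum()
    if len(kernel) > 1:
        if np.iscomplexobj(sm):
            sm = convolve1d(sm.real, kernel, axis=-2, mode="constant") + 1j * (
                convolve1d(sm.imag, kernel, axis=-2, mode="constant")
            )
        else:
            sm = convolve1d(sm, kernel, axis=-2, mode="constant")
    return sm


def smoothed_auto_spectrum(W: np.ndarray, p: WaveletParams) -> np.ndarray:
    """S(|W|^2 / s): the smoothed scale-normalized auto power (scale x time)."""
    return _smooth_spectrum((W.real**2 + W.imag**2) / p.scales[:, None], p)


def smoothed_cross_spectrum(
    Wx: np.ndarray, Wy: np.ndarray, p: WaveletParams
) -> np.ndarray:
    """S(Wx * conj(Wy) / s): the smoothed scale-normalized cross spectrum."""
    return _smooth_spectrum(Wx * np.conj(Wy) / p.scales[:, None], p)


def coherence_from_spectra(
    Sxx: np.ndarray, Syy: np.ndarray, Sxy: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Squared coherence and phase from smoothed spectra (scale x time)."""
    denom = Sxx * Syy
    with np.errstate(invalid="ignore", divide="ignore"):
        rsq = (Sxy.real**2 + Sxy.imag**2) / denom
    rsq = np.clip(rsq, 0.0, 1.0)
    phase = np.arctan2(Sxy.imag, Sxy.real)
    return rsq, phase


def cone_of_influence(n_frames: int, p: WaveletParams) -> np.ndarray:
    """Boolean validity mask of shape ``(n_frames, n_freqs)``.

    A point is valid (True) iff its distance to the nearer record edge
    exceeds the Morlet e-folding time sqrt(2)*s of its scale.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    t = np.arange(n_frames) * p.dt
    edge_dist = np.minimum(t, t[::-1])
    efold = np.sqrt(2.0) * p.scales  # seconds, per frequency
    return edge_dist[:, None] > efold[None, :]


def wtc(x: np.ndarray, y: np.ndarray, p: WaveletParams | None = None) -> WTCMap:
    """Wavelet-transform coherence between two equally sampled series.

    Parameters
    ----------
    x, y
        Finite 1-D series of equal length sharing one sampling rate.
    p
        Wavelet parameters; defaults to the standard 40-frequency grid.

    Returns
    -------
    WTCMap
        Squared coherence, phase (positive = ``x`` leads) and COI mask,
        all of shape ``(n_times, n_freqs)``.
    """
    if p is None:
        p = WaveletParams()
    x = _check_series(x, p)
    y = _check_series(y, p)
    if len(x) != len(y):
        raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
    for name, s in (("x", x), ("y", y)):
        if np.ptp(s) == 0:
            raise ValueError(f"coherence undefined for constant series {name!r}")

    Wx = cwt_morlet(x, p)
    Wy = cwt_morlet(y, p)
    Sxx = smoothed_auto_spectrum(Wx, p)
    Syy = smoothed_auto_spectrum(Wy, p)
    Sxy = smoothed_cross_spectrum(Wx, Wy, p)
    rsq, phase = coherence_from_spectra(Sxx, Syy, Sxy)
    coi = cone_of_influence(len(x), p)
    return WTCMap(
        coherence=rsq.T.copy(),
        phase=phase.T.copy(),
        coi_mask=coi,
        freqs=p.freqs,
        dt=p.dt,
    )
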