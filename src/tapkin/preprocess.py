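"""Raw keypoint trajectories -> analysis-ready vertical series.

The pipeline order is: segment around the beep events, normalize trial
duration by Fourier resampling, smooth with a short moving average,
replace outlier jumps by linear interpolation, and finally restrict to the
temporal range of interest (ROI) in which tapping is assumed automatic:
from 1 s after the initiation beep up to (and including) the rounded
termination-beep frame. At 60 Hz this yields 344 ROI frames for a 6.71 s
trial and 609 for an 11.14 s trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import resample

__all__ = [
    "PreprocParams",
    "segment",
    "normalize_duration",
    "smooth",
    "interpolate_outliers",
    "roi_slice",
    "range_of_interest",
    "preprocess_trial",
]


@dataclass(frozen=True)
class PreprocParams:
    """Preprocessing constants.

    pre_pad / post_pad: frames kept before the initiation beep and after the
    termination beep (30 / 90). smooth_window: moving-average width in frames
    (6 frames = 100 ms at 60 Hz). outlier_threshold: minimum frame-to-frame
    jump, in pixels, that marks a sample as an outlier (100 px).
    target_durations: normalized duration per class, seconds.
    """

    pre_pad: int = 30
    post_pad: int = 90
    smooth_window: int = 6
    outlier_threshold: float = 100.0
    target_durations: dict = field(
        default_factory=lambda: {"short": 6.71, "long": 11.14}
    )

    def __post_init__(self) -> None:
        if self.pre_pad < 0 or self.post_pad < 0:
            raise ValueError("pads must be non-negative")
        if self.smooth_window < 1:
            raise ValueError("smooth_window must be a positive integer")
        if self.outlier_threshold <= 0:
            raise ValueError("outlier_threshold must be > 0")


def segment(traj, p: PreprocParams | None = None):
    """Cut a raw trajectory to [init - pre_pad, term + post_pad] (inclusive).

    Events are re-indexed so that the initiation-beep onset lands on frame
    ``pre_pad``. Raises if the recording does not contain enough padding.
    """
    if p is None:
        p = PreprocParams()
    ev = traj.events
    start = ev.initiation_frame - p.pre_pad
    stop = ev.termination_frame + p.post_pad  # inclusive
    n = traj.n_frames
    if start < 0 or stop > n - 1:
        raise ValueError(
            f"insufficient padding: need frames [{start}, {stop}] but the "
            f"recording has frames [0, {n - 1}]"
        )
    new_events = replace(
        ev,
        initiation_frame=p.pre_pad,
        termination_frame=p.pre_pad + (ev.termination_frame - ev.initiation_frame),
    )
    return replace(traj, coords=traj.coords[start : stop + 1], events=new_events)


def normalize_duration(y: np.ndarray, target_len: int) -> np.ndarray:
    """Fourier resampling (interpft-style) of a series to ``target_len``."""
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or len(y) < 2:
        raise ValueError("need a 1-D series of length >= 2")
    if target_len < 2:
        raise ValueError("target_len must be >= 2")
    if target_len == len(y):
        return y.copy()
    return resample(y, target_len)


def smooth(y: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; the window shrinks at the edges.

    With an even window the extra sample is taken on the causal side.
    Constant series are preserved exactly and output length equals input
    length.
    """
    y = np.asarray(y, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    n = len(y)
    if window > n:
        raise ValueError(f"window {window} exceeds series length {n}")
    if window == 1:
        return y.copy()
    left = (window - 1) // 2
    right = window - 1 - left
    csum = np.concatenate(([0.0], np.cumsum(y)))
    idx = np.arange(n)
    lo = np.maximum(idx - left, 0)
    hi = np.minimum(idx + right, n - 1)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def interpolate_outliers(
    y: np.ndarray, threshold: float = 100.0
) -> tuple[np.ndarray, np.ndarray]:
    """Flag jump outliers and fill all missing samples by linear interpolation.

    A sample is an outlier when its absolute difference from the previous
    *retained* (non-outlier, non-missing) sample is at least ``threshold``;
    comparing against the last retained sample makes runs of consecutive
    spikes fully flagged. Flagged and originally missing (NaN) samples are
    filled by piecewise-linear interpolation against the frame index
    (end-point extrapolation holds the nearest retained value).

    Returns ``(filled, outlier_mask)`` where the mask marks only the newly
    flagged jump outliers.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    mask = np.zeros(n, dtype=bool)
    last = np.nan
    for i in range(n):
        if np.isnan(y[i]):
            continue
        if not np.isnan(last) and abs(y[i] - last) >= threshold:
            mask[i] = True
        else:
            last = y[i]
    missing = mask | np.isnan(y)
    if missing.all():
        raise ValueError("all samples flagged or missing; nothing to interpolate from")
    filled = y.copy()
    idx = np.arange(n)
    filled[missing] = np.interp(idx[missing], idx[~missing], y[~missing])
    return filled, mask


def roi_slice(duration: float, fs: float = 60.0) -> slice:
    """Frame slice of the range of interest, 0-based from initiation onset.

    Frames ``i`` with ``fs <= i <= round(duration * fs)`` — i.e. from 1 s
    after the initiation beep through the rounded termination-onset frame.
    """
    first = int(round(fs))
    last = int(round(duration * fs))
    if last < first:
        raise ValueError(f"trial of {duration} s is too short for a 1 s lead-in")
    return slice(first, last + 1)


def range_of_interest(y: np.ndarray, duration: float, fs: float = 60.0) -> np.ndarray:
    """Restrict a series (0-based from initiation onset) to the ROI."""
    s = roi_slice(duration, fs)
    if s.stop > len(y):
        raise ValueError(
            f"series of {len(y)} frames does not cover the ROI ending at frame {s.stop - 1}"
        )
    return y[s]


def preprocess_trial(traj, p: PreprocParams | None = None):
    """Full preprocessing of one trial.

    Order: segment -> duration-normalize -> smooth -> de-outlier -> ROI,
    applied to the vertical (y) coordinate of every keypoint. Returns
    ``(roi_matrix, qc)`` where ``roi_matrix`` is ``(n_roi_frames, n_keypoints)``
    (columns in ``traj.keypoint_names`` order) and ``qc`` is a dict with
    per-keypoint outlier counts and the lengths at each stage.
    """
    if p is None:
        p = PreprocParams()
    seg = segment(traj, p)
    fs = seg.sampling_rate
    target_d = p.target_durations[seg.duration_class]
    target_len = int(round(target_d * fs)) + p.pre_pad + p.post_pad + 1

    n_kp = len(seg.keypoint_names)
    cols = []
    outlier_counts = {}
    for k in range(n_kp):
        yk = seg.coords[:, k, 1]
        # Fourier resampling requires finite input: bridge missing samples
        # first (they are re-filled after resampling only via the outlier
        # stage, so pre-bridging keeps the spectrum sane).
        if np.isnan(yk).any():
            yk, _ = interpolate_outliers(yk, threshold=np.inf)
        yk = normalize_duration(yk, target_len)
        yk = smooth(yk, p.smooth_window)
        yk, m = interpolate_outliers(yk, p.outlier_threshold)
        outlier_counts[seg.keypoint_names[k]] = int(m.sum())
        cols.append(yk)
    mat = np.column_stack(cols)

    # ROI measured from the (normalized) initiation frame at index pre_pad
    rs = roi_slice(target_d, fs)
    roi = mat[p.pre_pad + rs.start : p.pre_pad + rs.stop]
    qc = {
        "outlier_counts": outlier_counts,
        "segment_len": seg.n_frames,
        "normalized_len": target_len,
        "roi_len": roi.shape[0],
        "duration_class": seg.duration_class,
        "condition": seg.condition,
        "trial_id": seg.trial_id,
    }
    return roi, qc
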