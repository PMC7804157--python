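"""Synthetic finger-tapping trajectory generator with known ground truth.

Emulates 60 Hz video-derived keypoint trajectories of repetitive four-finger
sequential tapping: each tapping finger oscillates vertically at a
participant-specific rate (drawn from the empirically observed 3.07-8.43 Hz
range) with a fixed inter-finger phase lag, a condition-dependent
multiplicative amplitude gain (the ground truth behind the modulation index
I_A), a condition-dependent slowly varying phase jitter (the ground truth
behind coherence degradation), additive white pixel noise, and occasional
single-frame outlier spikes. The thumb anchor points are static up to noise.

Every stochastic element derives from one root seed through a documented
per-trial scheme (``SeedSequence([seed, trial_index])``) so any single trial
is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .io import KeypointTrajectory, TrialEvents
from .keypoints import (
    CONDITIONS,
    DURATION_CLASSES,
    FINGERS,
    FINGER_JOINTS,
    KEYPOINT_NAMES,
    THUMB_KEYPOINTS,
)

__all__ = ["SimConfig", "generate_trial", "generate_session"]

RATE_RANGE = (3.07, 8.43)  # Hz, span of observed participant tapping rates

#: vertical oscillation scale of each joint relative to the fingertip
JOINT_AMPLITUDE_SCALE = {"tip": 1.0, "dip": 0.75, "pip": 0.5, "mcp": 0.28}

#: resting pixel positions (x, y) on a 1920 x 1080 frame, y down
_BASELINES: dict[str, tuple[float, float]] = {}
for _i, _f in enumerate(FINGERS):
    for _j, _joint in enumerate(FINGER_JOINTS[_f]):
        _BASELINES[f"{_f}_{_joint}"] = (
            820.0 + 90.0 * _i + 10.0 * _j,
            620.0 + 55.0 * _j,
        )
for _j, _kp in enumerate(THUMB_KEYPOINTS):
    _BASELINES[_kp] = (700.0 - 30.0 * _j, 760.0 + 30.0 * _j)


def _default_gains() -> dict[str, dict[str, float]]:
    # Attention facilitates attended fingers (largest for the little finger
    # under whole-sequence focus) and mildly inhibits the unattended little
    # finger, mirroring the direction of the reported effects.
    return {
        "reference": {f: 1.0 for f in FINGERS},
        "sequence_focused": {"index": 1.10, "middle": 1.10, "ring": 1.12, "little": 1.15},
        "index_focused": {"index": 1.20, "middle": 1.0, "ring": 1.0, "little": 0.95},
        "middle_focused": {"index": 1.0, "middle": 1.20, "ring": 1.0, "little": 0.95},
    }


def _default_jitter() -> dict[str, float]:
    # Coherence is highest under reference (movement unattended) and lowest
    # when a single finger is scrutinized.
    return {
        "reference": 0.05,
        "sequence_focused": 0.20,
        "index_focused": 0.20,
        "middle_focused": 0.35,
    }


def _default_trial_counts() -> dict[tuple[str, str], int]:
    # 7 trials per condition x duration class (56-trial session design)
    return {(c, d): 7 for c in CONDITIONS for d in DURATION_CLASSES}


@dataclass
class SimConfig:
    """Generator configuration; defaults emulate the standard session.

    ``tapping_rate=None`` draws a participant rate uniformly from
    ``RATE_RANGE`` using the root seed. ``condition_gain`` maps
    condition -> finger -> amplitude gain (reference must be identically 1).
    ``phase_jitter_sd`` maps condition -> stationary SD (radians) of the
    slowly varying per-finger phase jitter. ``condition_lag_offsets``
    optionally perturbs the inter-finger phase lags per condition (off by
    default) so decodable pattern structure can be switched on independently
    of amplitude. ``coupling`` is an optional mechanical-enslaving
    coefficient mixing each finger's oscillation into its neighbours (0 by
    default).
    """

    tapping_rate: float | None = None
    finger_phase_lags: tuple[float, ...] = tuple(
        -2.0 * np.pi * k / 4.0 for k in range(4)
    )
    base_amplitude: float = 25.0  # px, fingertip oscillation amplitude
    condition_gain: dict = field(default_factory=_default_gains)
    phase_jitter_sd: dict = field(default_factory=_default_jitter)
    jitter_tau: float = 0.4  # s, jitter autocorrelation time
    amplitude_jitter_cv: float = 0.2  # cycle-to-cycle tap-depth variability
    rate_drift_sd: float = 0.05  # Hz per sqrt(s) random-walk scale
    noise_sd: float = 2.0  # px additive white noise
    outlier_rate: float = 0.002  # per frame x keypoint spike probability
    outlier_span: tuple[float, float] = (120.0, 250.0)  # px, spike magnitude
    trial_counts: dict = field(default_factory=_default_trial_counts)
    durations: dict = field(default_factory=lambda: {"short": 6.71, "long": 11.14})
    sampling_rate: float = 60.0
    pre_roll: int = 60  # frames recorded before the initiation beep
    post_roll: int = 120  # frames recorded after the termination beep
    waveform: str = "raised_cosine"  # or "sinusoid"
    tap_sharpness: float = 3.0  # raised-cosine pulse exponent
    condition_tap_sharpness: Mapping[str, float] | None = None  # per-condition style
    condition_lag_offsets: Mapping[str, tuple[float, ...]] | None = None
    coupling: float = 0.0
    participant_id: str = "sim01"
    seed: int = 0

    def __post_init__(self) -> None:
        for c, gains in self.condition_gain.items():
            if c == "reference" and any(g != 1.0 for g in gains.values()):
                raise ValueError("reference condition gains must all be 1")
        for sd in self.phase_jitter_sd.values():
            if sd < 0:
                raise ValueError("phase_jitter_sd must be non-negative")
        for v in (
            self.rate_drift_sd,
            self.noise_sd,
            self.outlier_rate,
            self.amplitude_jitter_cv,
        ):
            if v < 0:
                raise ValueError("SDs and rates must be non-negative")
        if self.waveform not in ("raised_cosine", "sinusoid"):
            raise ValueError(f"unknown waveform {self.waveform!r}")
        if self.pre_roll < 0 or self.post_roll < 0:
            raise ValueError("rolls must be non-negative")

    def resolve_rate(self, rng: np.random.Generator) -> float:
        if self.tapping_rate is not None:
            return float(self.tapping_rate)
        return float(rng.uniform(*RATE_RANGE))


def _ou_process(rng, n: int, dt: float, sd: float, tau: float) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck path with SD ``sd`` and time constant ``tau``.

    The same random draws are consumed whatever ``sd`` is (the path scales
    linearly with it), so trials generated from one seed differ only in
    magnitude when a jitter level is varied — paired comparisons across
    levels then see the same underlying noise paths.
    """
    a = np.exp(-dt / tau)
    z = rng.standard_normal(n)
    x = np.empty(n)
    x[0] = z[0]
    b = np.sqrt(1.0 - a * a)
    for i in range(1, n):
        x[i] = a * x[i - 1] + b * z[i]
    return sd * x


def _fundamental_coefficient(sharpness: float) -> float:
    """Fundamental-cosine amplitude of the ((1+cos)/2)**m tap pulse."""
    phi = np.linspace(0.0, 2.0 * np.pi, 4096, endpoint=False)
    pulse = ((1.0 + np.cos(phi)) / 2.0) ** sharpness
    return float(2.0 * np.mean(pulse * np.cos(phi)))


def _tap_waveform(phase: np.ndarray, kind: str, sharpness: float = 3.0) -> np.ndarray:
    """Unit-fundamental oscillation; positive = finger moving down (image y).

    The raised-cosine pulse keeps the finger mostly up with a brief
    down-stroke each cycle; ``sharpness`` is the pulse exponent (larger =
    crisper, briefer taps with stronger harmonics). Normalizing by the
    fundamental's cosine coefficient makes band-passed amplitudes recover
    gains exactly for any sharpness.
    """
    if kind == "sinusoid":
        return np.sin(phase)
    pulse = ((1.0 + np.cos(phase)) / 2.0) ** sharpness
    return (pulse - np.mean(pulse)) / _fundamental_coefficient(sharpness)


def generate_trial(
    cfg: SimConfig,
    condition: str,
    duration_class: str,
    seed: int | np.random.SeedSequence,
    tapping_rate: float | None = None,
    trial_id: str = "t000",
) -> tuple[KeypointTrajectory, dict]:
    """Generate one trial; returns ``(trajectory, ground_truth)``.

    The ground-truth dict records the realized rate, per-finger gains,
    jitter SD and the injected outlier (frame, keypoint) spikes.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    if duration_class not in cfg.durations:
        raise ValueError(f"unknown duration_class {duration_class!r}")
    rng = np.random.default_rng(seed)
    fs, dt = cfg.sampling_rate, 1.0 / cfg.sampling_rate
    duration = cfg.durations[duration_class]
    n_move = int(round(duration * fs))
    init, term = cfg.pre_roll, cfg.pre_roll + n_move
    n = term + cfg.post_roll + 1

    f0 = tapping_rate if tapping_rate is not None else cfg.resolve_rate(rng)
    drift = np.cumsum(rng.normal(0.0, cfg.rate_drift_sd * np.sqrt(dt), n))
    f_inst = np.clip(f0 + drift, 0.6, 14.0)
    base_phase = 2.0 * np.pi * np.cumsum(f_inst) * dt

    # smooth on/off envelope confining movement to the beep-delimited window
    env = np.zeros(n)
    ramp = max(2, int(round(0.2 * fs)))
    env[init:term + 1] = 1.0
    a = min(ramp, init)
    env[init - a : init] = np.linspace(0.0, 1.0, ramp)[-a:] if a else []
    stop = min(n, term + 1 + ramp)
    env[term + 1 : stop] = np.linspace(1.0, 0.0, ramp)[: stop - term - 1]

    gains = cfg.condition_gain[condition]
    jitter_sd = cfg.phase_jitter_sd.get(condition, 0.0)
    lag_off = (
        cfg.condition_lag_offsets.get(condition, (0.0,) * 4)
        if cfg.condition_lag_offsets
        else (0.0,) * 4
    )

    osc = {}
    for fi, finger in enumerate(FINGERS):
        jitter = _ou_process(rng, n, dt, jitter_sd, cfg.jitter_tau)
        phase = base_phase + cfg.finger_phase_lags[fi] + lag_off[fi] + jitter
        # every tap has its own vigor: amplitude modulation with roughly
        # one-tap-period memory, the dominant source of cycle-to-cycle
        # kinematic variability in real tapping
        mod = 1.0 + _ou_process(
            rng, n, dt, cfg.amplitude_jitter_cv, 0.5 / max(f0, 0.5)
        )
        mod = np.clip(mod, 0.1, None)
        sharp = (
            cfg.condition_tap_sharpness.get(condition, cfg.tap_sharpness)
            if cfg.condition_tap_sharpness
            else cfg.tap_sharpness
        )
        osc[finger] = gains[finger] * mod * _tap_waveform(phase, cfg.waveform, sharp)
    if cfg.coupling > 0:
        raw = {f: o.copy() for f, o in osc.items()}
        for fi, finger in enumerate(FINGERS):
            for fj, other in enumerate(FINGERS):
                if abs(fi - fj) == 1:
                    osc[finger] = osc[finger] + cfg.coupling * raw[other]

    coords = np.empty((n, len(KEYPOINT_NAMES), 2))
    for k, kp in enumerate(KEYPOINT_NAMES):
        bx, by = _BASELINES[kp]
        coords[:, k, 0] = bx
        if kp in THUMB_KEYPOINTS:
            coords[:, k, 1] = by
        else:
            finger, joint = kp.split("_", 1)
            amp = cfg.base_amplitude * JOINT_AMPLITUDE_SCALE[joint]
            coords[:, k, 1] = by + amp * env * osc[finger]
    coords += rng.normal(0.0, cfg.noise_sd, coords.shape)

    outliers: list[tuple[int, str]] = []
    if cfg.outlier_rate > 0:
        spike_mask = rng.random((n, len(KEYPOINT_NAMES))) < cfg.outlier_rate
        rows, cols = np.nonzero(spike_mask)
        lo, hi = cfg.outlier_span
        mags = rng.uniform(lo, hi, rows.size) * rng.choice([-1.0, 1.0], rows.size)
        coords[rows, cols, 1] += mags
        outliers = [(int(r), KEYPOINT_NAMES[c]) for r, c in zip(rows, cols)]

    traj = KeypointTrajectory(
        participant_id=cfg.participant_id,
        trial_id=trial_id,
        condition=condition,
        duration_class=duration_class,
        coords=coords,
        keypoint_names=KEYPOINT_NAMES,
        sampling_rate=fs,
        events=TrialEvents(
            initiation_frame=init,
            termination_frame=term,
            nominal_duration=duration,
        ),
    )
    truth = {
        "trial_id": trial_id,
        "condition": condition,
        "duration_class": duration_class,
        "tapping_rate": f0,
        "phase_jitter_sd": jitter_sd,
        **{f"gain_{f}": gains[f] for f in FINGERS},
        "n_outliers": len(outliers),
        "outliers": outliers,
    }
    return traj, truth


def generate_session(
    cfg: SimConfig,
) -> tuple[list[KeypointTrajectory], pd.DataFrame]:
    """Generate a balanced session for one simulated participant.

    Trials are generated per condition x duration class according to
    ``cfg.trial_counts`` with one shared participant tapping rate. Returns
    the trial list and the ground-truth table (one row per trial, listing
    the implanted rate, gains and jitter SD).
    """
    root = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xA11CE]))
    rate = cfg.resolve_rate(root)

    trials: list[KeypointTrajectory] = []
    rows: list[dict] = []
    idx = 0
    for condition in CONDITIONS:
        for dclass in DURATION_CLASSES:
            count = cfg.trial_counts.get((condition, dclass), 0)
            for _ in range(count):
                tid = f"{cfg.participant_id}_t{idx:03d}"
                traj, truth = generate_trial(
                    cfg,
                    condition,
                    dclass,
                    seed=np.random.SeedSequence([cfg.seed, idx]),
                    tapping_rate=rate,
                    trial_id=tid,
                )
                trials.append(traj)
                truth.pop("outliers")
                rows.append(truth)
                idx += 1
    if not trials:
        raise ValueError("trial_counts produced an empty session")
    truth_df = pd.DataFrame(rows)
    return trials, truth_df
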