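import numpy as np
import pytest

import tapkin as tk
from tapkin.keypoints import TAPPING_KEYPOINTS


def tapping_roi_matrix(record: dict) -> np.ndarray:
    """ROI matrix restricted to the 14 tapping-finger keypoints."""
    names = record["keypoint_names"]
    return np.column_stack([record["roi"][:, names.index(k)] for k in TAPPING_KEYPOINTS])


@pytest.fixture(scope="session")
def wavelet_params() -> tk.WaveletParams:
    return tk.WaveletParams()


@pytest.fixture(scope="session")
def small_session():
    """One participant, 4 short trials per condition, default effects."""
    cfg = tk.SimConfig(
        seed=42, trial_counts={(c, "short"): 4 for c in tk.CONDITIONS}
    )
    trials, truth = tk.generate_session(cfg)
    return cfg, trials, truth


@pytest.fixture(scope="session")
def preprocessed_session(small_session):
    _, trials, truth = small_session
    records, qc = tk.preprocess_session(trials)
    return records, qc, truth


def null_sim_config(seed: int) -> tk.SimConfig:
    """All four conditions generated with identical parameters."""
    return tk.SimConfig(
        seed=seed,
        condition_gain={c: {f: 1.0 for f in tk.FINGERS} for c in tk.CONDITIONS},
        phase_jitter_sd={c: 0.2 for c in tk.CONDITIONS},
        trial_counts={
            (c, d): 4 for c in tk.CONDITIONS for d in tk.DURATION_CLASSES
        },
    )


def contrast_sim_config(seed: int, strength: float = 1.0) -> tk.SimConfig:
    """Conditions separated by fast temporal-precision (jitter) differences.

    ``strength`` scales the between-condition jitter contrast toward zero
    (at 0 all conditions share jitter 0.3 rad and are indistinguishable).
    """
    base = 0.3
    levels = [base + strength * d for d in (-0.28, 0.0, 0.4, 0.9)]
    return tk.SimConfig(
        seed=seed,
        noise_sd=1.0,
        jitter_tau=0.15,
        condition_gain={c: {f: 1.0 for f in tk.FINGERS} for c in tk.CONDITIONS},
        phase_jitter_sd=dict(zip(tk.CONDITIONS, levels)),
        trial_counts={
            (c, d): 4 for c in tk.CONDITIONS for d in tk.DURATION_CLASSES
        },
    )
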