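"""Decode the attentional condition from movement-pattern features.

For every trial, wavelet coherence is computed between all 91 pairs of the
14 tapping-finger keypoints at 40 frequencies; pooled features are reduced
to 80 principal components; each condition's time points are cut into six
trial-disjoint datasets; sliding windows (60 points, step 4) become
samples; and an RBF-kernel SVM (gamma = 0.014) is evaluated under six-fold
cross-validation. Conditions here differ in temporal precision (fast
phase jitter), which coherence patterns can detect.

Runs in roughly half a minute.
"""

import warnings

import numpy as np
import pandas as pd

import tapkin as tk
from tapkin.decoding import DecoderParams, decode
from tapkin.keypoints import TAPPING_KEYPOINTS

cfg = tk.SimConfig(
    seed=5,
    noise_sd=1.0,
    jitter_tau=0.15,
    condition_gain={c: {f: 1.0 for f in tk.FINGERS} for c in tk.CONDITIONS},
    phase_jitter_sd=dict(zip(tk.CONDITIONS, [0.02, 0.3, 0.7, 1.2])),
    trial_counts={(c, d): 4 for c in tk.CONDITIONS for d in tk.DURATION_CLASSES},
)
trials, _ = tk.generate_session(cfg)
records, _ = tk.preprocess_session(trials)
rois = [
    (
        np.column_stack(
            [r["roi"][:, r["keypoint_names"].index(k)] for k in TAPPING_KEYPOINTS]
        ),
        r["condition"],
        r["trial_id"],
    )
    for r in records
]
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    res = decode(rois, params=DecoderParams(seed=5))

print(f"samples per dataset: {res.n_samples_per_dataset}")
print(f"explained variance of the 80 retained components: "
      f"{res.explained_variance:.1%}")
print("\nconfusion matrix (rows = true condition, row-normalized):")
print(pd.DataFrame(res.confusion, index=res.conditions,
                   columns=res.conditions).round(2).to_string())
print(f"\nmean decoding accuracy: {res.mean_accuracy:.3f} "
      f"(chance {res.chance_level})")
print(
    "\nAbove-chance accuracy means the four attentional states leave "
    "distinguishable\nsignatures in the movement's time-frequency "
    "coupling structure."
)
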