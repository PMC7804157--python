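"""Tapping rate, FWHM band, and coherence summaries for one participant.

Simulates a session, preprocesses every trial (segmentation, duration
normalization, smoothing, outlier interpolation, temporal range of
interest), then estimates the participant's tapping rate as the peak of
the pooled inter-trial wavelet-coherence spectrum, the FWHM frequency band
around it, and the per-condition inter-trial / inter-finger coherence.
"""

import tapkin as tk

cfg = tk.SimConfig(seed=3, trial_counts={(c, "short"): 6 for c in tk.CONDITIONS})
trials, truth = tk.generate_session(cfg)
records, qc = tk.preprocess_session(trials)

print(f"preprocessed {len(records)} trials; ROI length {qc.roi_len.unique()} frames")
print(f"outlier samples replaced per trial (median): {qc.n_outliers.median():.0f}")

band, spectrum, summary = tk.participant_coherence(records)
print(f"\nimplanted tapping rate : {truth.tapping_rate[0]:.2f} Hz")
print(f"estimated tapping rate : {band.tapping_rate:.2f} Hz  "
      "(the coherence-spectrum peak sits slightly above the true rate; "
      "see docs/methods.md)")
print(f"FWHM band of interest  : [{band.f_low:.2f}, {band.f_high:.2f}] Hz")

print("\nper-condition coherence (mean over COI-valid points in the band):")
print(summary.round(3).to_string())
print(
    "\nInter-trial coherence indexes cycle-to-cycle reproducibility "
    "(automaticity);\nthe generator's reference condition has the least "
    "phase jitter (highest\ncoherence) and middle_focused the most "
    "(lowest); single sessions carry a few\nhundredths of sampling noise "
    "on these values."
)
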