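"""Group-level inference on recovered metrics across simulated participants.

Simulates a small cohort, recovers each participant's per-condition
inter-trial coherence and modulation indices, then applies the study's
statistical battery: one-way repeated-measures ANOVA for the attention
effect on coherence, one-sample t-tests of I_A against zero, and a
two-way (condition x finger) repeated-measures ANOVA on I_A.
"""

import numpy as np

import tapkin as tk
from tapkin.stats import rm_anova_oneway, rm_anova_twoway, t_tests

N = 8
coh = np.empty((N, 4))
ia = np.empty((N, 3, 4))  # attention conditions x fingers

for s in range(N):
    cfg = tk.SimConfig(seed=100 + s,
                       trial_counts={(c, "short"): 4 for c in tk.CONDITIONS})
    trials, _ = tk.generate_session(cfg)
    records, _ = tk.preprocess_session(trials)
    band, _, summary = tk.participant_coherence(records)
    amp = tk.participant_amplitude(records, band)["I_A"].unstack()
    coh[s] = [summary.loc[c, "inter_trial_coherence"] for c in tk.CONDITIONS]
    for i, c in enumerate(tk.CONDITIONS[1:]):
        ia[s, i] = [amp.loc[f, c] for f in tk.FINGERS]

res = rm_anova_oneway(coh)
print("attention effect on inter-trial coherence:")
print(f"  F{res.df} = {res.statistic:.2f}, p = {res.p_value:.4f}, "
      f"partial eta^2 = {res.effect_size:.3f}")

print("\nI_A vs 0 for the attended finger of each movement-focused condition:")
for i, (c, f) in enumerate(
    [("sequence_focused", "little"), ("index_focused", "index"),
     ("middle_focused", "middle")]
):
    fi = tk.FINGERS.index(f)
    t = t_tests(ia[:, i, fi], 0.0)
    print(f"  {c:17s} {f:6s}: t({t.df[0]}) = {t.statistic:5.2f}, "
          f"p = {t.p_value:.4f}, d = {t.effect_size:.2f}")

two = rm_anova_twoway(ia)
print("\ntwo-way RM ANOVA on I_A (condition x finger):")
for name, r in two.items():
    label = {"A": "condition", "B": "finger", "AxB": "interaction"}[name]
    print(f"  {label:11s}: F{r.df} = {r.statistic:.2f}, p = {r.p_value:.4f}, "
          f"partial eta^2 = {r.effect_size:.3f}")
print(
    "\nA significant interaction mirrors the finding that which finger "
    "gains amplitude\ndepends on where attention is directed."
)
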