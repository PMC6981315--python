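"""Score a performance against expert/novice reference thresholds.

Derives per-index expert and novice medians from a synthetic labelled
reference cohort (6 experts, 23 novices), then scores one fresh
performance with the default (1/2, 1/3, 1/6) weighting.
"""

import lapmotion as lm

reference, _ = lm.simulate_cohort(lm.SyntheticCohortSpec(seed=11))
thresholds = lm.derive_thresholds(reference)
for name in ("L", "A", "J"):
    e, n = thresholds.anchors(name)
    print(f"{name}: expert median {e:.2f}, novice median {n:.2f}")

performance = lm.simulate_trajectory(lm.EXPERT_PROFILE, seed=99)
scored = lm.score_performance(lm.compute_indices(performance), thresholds)

s_L, s_A, s_J = scored.sub_scores
print(f"sub-scores: s_L={s_L:.2f}, s_A={s_A:.2f}, s_J={s_J:.2f}")
print(f"rho = {scored.rho:.2f} -> {scored.category}")
# rho is a convex combination of the sub-scores, so it lies in [0, 1]:
# 1 means expert-median-like on every index, 0 novice-median-like.
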