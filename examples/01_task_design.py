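"""The bubble task: schedule, probability trajectory, and a pseudorandom design.

Builds one trial's bubble schedule, evaluates the on-screen reward
probability at a 12-s response, and generates a 90-trial design whose
present factors are mutually near-orthogonal.
"""

import numpy as np

from acttime.task import (TaskSpec, TrialContext, bubble_schedule,
                          design_correlations, generate_design,
                          probability_at_time)

spec = TaskSpec()
trial = TrialContext(reward_magnitude=2, last_bubble_prob=0.8, noise_level=3)

sched = bubble_schedule(spec, trial)
print("bubble onsets (s):", sched.onsets)
print("nominal probabilities:", np.round(sched.nominal_probs, 4))
# 9 bubbles, 2 s apart; probability climbs linearly from 0.5 to 0.8.

p = probability_at_time(spec, trial, t=12.0)
print(f"probability at a 12-s response: {p:.4f} (~{round(100 * p)}%)")
# the bubble on screen at 12 s carries a 69% reward chance.

design = generate_design(spec, n_trials=90, max_abs_corr=0.1, seed=0)
corr = design_correlations(design)
worst = np.abs(corr.to_numpy()[np.triu_indices(3, k=1)]).max()
print(design.head())
print(f"worst |r| among present factors: {worst:.3f}")
# factor levels are balanced and pairwise correlations stay below 0.1,
# so trialwise regressors of the three present factors are separable.
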