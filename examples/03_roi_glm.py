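"""Time-resolved ROI GLM: where and when does BOLD track action timing?

Simulates coupled 7-ROI BOLD for several participants, regresses epoched
BOLD on the observed actTime at every epoch time point, and runs the
leave-one-out group-peak test with Holm correction across ROIs.
"""

import numpy as np

from acttime.task import TaskSpec, generate_design
from acttime.synth import (BehaviorGroundTruth, default_coupling,
                           default_neural_model, simulate_behavior,
                           simulate_bold, ROI_LABELS)
from acttime.tsglm import (epoch, fit_timecourse_glm, glm_observed,
                           loo_peak_tests, preprocess, responded)

spec = TaskSpec()
truth = BehaviorGroundTruth()
events = default_neural_model()
coupling = default_coupling()

store = {roi: [] for roi in ROI_LABELS}
epoch_times = None
for p in range(6):
    design = generate_design(spec, 60, seed=10 + p)
    session = simulate_behavior(design, truth, spec, seed=50 + p)
    bold = simulate_bold(session, events, coupling, seed=90 + p)
    resp = responded(session)
    rts = (resp.trial_onset_in_run + resp.acttime).to_numpy()
    for roi in ROI_LABELS:
        series = preprocess(bold[roi].to_numpy(), 1.0, 0.5)
        ep = epoch(series, rts)
        betas = fit_timecourse_glm(ep, glm_observed(resp.iloc[ep.trial_index]))
        epoch_times = betas.index.to_numpy()
        store[roi].append(betas["observed_actTime"].to_numpy())

stacks = {roi: np.vstack(v) for roi, v in store.items()}
table = loo_peak_tests(stacks, epoch_times, phase="full")
print(table[["roi", "mean_peak_time", "mean_peak_beta", "t", "p_holm",
             "significant"]].round(3).to_string(index=False))
# each row: where the group beta time course peaks relative to the response
# and whether the held-out peak betas differ from zero after Holm
# correction.  With the default generative model, striatal nodes carry a
# negative late actTime effect and onset-locked nodes an earlier one.
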