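"""Confirmatory circuit comparison: hypothesised vs reversed vs permuted.

Generates 7-ROI series from the hypothesised topology (ACC->BF; BF, PPN,
HB -> SN; SN -> CN, NAc), fits the path model by maximum likelihood, and
compares it against the direction-reversed circuit and the full ensemble of
5,040 ROI-to-position permutations.
"""

import numpy as np
import pandas as pd

from acttime.sem import fit_path_model, hypothesized_model, permute_rois, \
    reverse_model
from acttime.synth import ROI_LABELS

rng = np.random.default_rng(0)
weights = {("ACC", "BF"): 0.4, ("BF", "SN"): 0.5, ("PPN", "SN"): 0.3,
           ("HB", "SN"): 0.3, ("SN", "CN"): 0.5, ("SN", "NAc"): 0.5}
data = {}
for node in ("ACC", "PPN", "HB", "BF", "SN", "CN", "NAc"):
    x = rng.normal(0, 1.0, 2000)
    for (a, b), w in weights.items():
        if b == node:
            x = x + w * data[a]
    data[node] = x
df = pd.DataFrame(data)[list(ROI_LABELS)]

model = hypothesized_model()
fit = fit_path_model(model, df)
print(fit.summary().round(3).to_string(index=False))
print(f"fit indices: SRMR={fit.srmr:.3f} GFI={fit.gfi:.3f} "
      f"RMSEA={fit.rmsea:.3f} AIC={fit.aic:.1f}")
# path coefficients recover the generative weights; low SRMR/RMSEA and
# GFI near 1 say the implied covariance reproduces the sample covariance.

fit_rev = fit_path_model(reverse_model(model), df)
print(f"reversed-direction AIC: {fit_rev.aic:.1f} "
      f"(delta = {fit_rev.aic - fit.aic:+.1f}; equal free parameters)")
# the true directionality wins decisively on AIC at equal complexity.

ens = permute_rois(model, df)
print(f"ensemble of {len(ens.aics)} ROI permutations: "
      f"reference AIC sits at the {ens.percentile:.2f}th percentile")
# the hypothesised assignment of regions to circuit positions outranks
# essentially every relabelling of the same topology.
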