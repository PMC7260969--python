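# Methods

## Task model

A trial lasts 20 s (`trial_duration`); bubble k = 1…9 surfaces at 2k s and
stays on screen for one 2-s bubble period, so the ninth bubble disappears
exactly at tank drain. The on-screen reward probability is a
right-continuous step function of time: bubble k's nominal probability is
linear in bubble *index* from 0.5 at the first bubble to the trial's
last-bubble value, p(k) = 0.5 + (p_last − 0.5)(k−1)/8. Anchoring the first
bubble at 2 s (not 0 s) is the only convention under which nine 2-s bubbles
fit the 20-s trial and a response at 12 s meets the 0.6875 (~69%) bubble of
a 0.5→0.8 trial.

Factor levels: three reward magnitudes (5, 10, 20 p), six last-bubble
probabilities and five display-noise SDs. Only five last-bubble values are
unambiguous from the task description (0, 0.2, 0.4, 0.8, 1 plus the fixed
0.5 start); the slope factor is nevertheless six-leveled, so the default
set is {0, 0.2, 0.4, 0.6, 0.8, 1.0} with 0.6 interpolated; it is
configurable. Noise SDs are never given numerically; the default is five
equally spaced values in display units (0.02…0.10), also configurable, and
display noise is i.i.d. per bubble.

Designs are pseudorandomised by constrained reshuffling: each factor column
is balanced across its levels (counts within 1) and independently permuted
until all pairwise Pearson correlations among the present factors satisfy
|r| ≤ 0.1 (configurable), with a fixed iteration budget and a diagnostic of
the worst pair on failure.

## Behavioural generator and timing model

Response times are simulated from a proportional-hazards process:
λ(t|x) = λ₀(t)·exp(xᵀβ) with a piecewise-constant baseline over 1-s bins
and inverse-transform sampling; sampled times beyond 20 s become
non-responses (right-censored). Past covariates are the *realised* previous
outcome and actTime (censored trials carry 20 s forward and an unrewarded
outcome); first-trial past factors are drawn from their marginals. Reward
outcome is Bernoulli with the on-screen probability at the response (the
first bubble's value applies before 2 s).

Default ground truth (raw-covariate scale): β = −0.105 (magnitude level),
−1.75 (last-bubble probability), +0.175 (noise level), −0.28 (previous
rewarded), −0.084 s⁻¹ (previous actTime); baseline rates ramp from
0.09 to 0.675 over the first 14 s and then rise steeply (1.5…16) in the
final bins. These values were chosen once so that the simulated sessions
reproduce the study-scale conditions: mean actTime ≈ 10 s, non-response
rare (~1–2%), and a ground-truth PEV of ≈ 25–30% splitting roughly 2:1
between present and past context. The steep terminal hazard encodes the
behavioural fact that participants almost always respond before the tank
empties, which a gentle ramp cannot produce without inflating censoring.

The Cox fit (lifelines) standardises the five covariates per participant,
handles ties by Efron's method and estimates the baseline cumulative hazard
by the Breslow estimator. Because z-scoring is a linear map, the fitted
coefficients estimate β·sd(x) exactly and recovery tests compare on that
scale. Deterministic actTime is operationalised as the restricted mean
survival time ∫₀²⁰ S(t|x) dt — the canonical expectation under censoring at
trial end; with a step-function baseline the integral is computed exactly
as a sum over steps (unit tests verify against 0.01-s trapezoid
integration). Present-only and past-only predictions reuse the full model's
baseline and zero the excluded coefficients rather than refitting reduced
models. PEV is 100 × the squared Pearson correlation between observed and
predicted actTime over uncensored trials; the present/past decomposition is
approximately, not exactly, additive and additivity is never asserted.
Duplicating every trial changes the estimates by O(1/n) (duplication
creates exact ties, which Efron's correction weights differently); exact
replication-invariance would hold only under Breslow tie handling.

## BOLD generator

Each region's neural signal is a train of impulses at trial onsets or
responses with amplitude a + w·z(modulator), convolved with the canonical
double-gamma HRF (6-s peak, 16-s undershoot, unit dispersions, ratio 1/6,
unit peak height). Regions are then coupled instantaneously and linearly
along an acyclic graph (child = Σ w·parent + white innovations), and AR(1)
(φ = 0.3) plus white measurement noise is added. Default sampling interval
is 1.0 s (the acquisition TR is not constrained by the analysis; it is
configurable). The default event model gives BF an onset-locked signal
modulated by the ground-truth deterministic actTime, PPN/HB onset-locked
observed-actTime signals, SN a response-locked unmodulated (initiation)
signal, CN/NAc late negative observed-actTime signals, and couples the
regions along the hypothesised topology with weights 0.3–0.5.

What the generator does *not* emulate: voxel-level structure, physiological
noise and motion, hemodynamic variability across regions, and any
nonlinearity of neurovascular coupling. Passing recovery tests therefore
demonstrates the estimators' correctness under the stated model, not
robustness to real-data artefacts.

## Time-resolved GLMs

Preprocessing z-scores each run and up-samples by linear interpolation
(default 0.5 s — a defensible choice for a slow signal; the factor is
configurable). Epochs span −9…+6 s around each response (31 samples at
0.5 s); trials whose window leaves the run are dropped and counted.
At every epoch time an independent OLS across trials is solved by
least squares, with rank checks that name the collinear pair. All
parametric regressors are z-scored across trials; observed actTime enters
as the z-scored natural log; `totaltime` is the z-scored trial onset time
in the session. The PPI design adds, per epoch time, the seed's BOLD and
the elementwise product of mean-centred seed BOLD with the z-scored
psychological variable; no deconvolution to the neural level is performed —
the interaction is formed on the BOLD scale exactly as the regression is
written.

Group peak inference: for each participant the peak (largest |mean β| of
the other N−1 participants) is located within the phase window (full
epoch, early [−2, 0] s, or late [+4, +6] s); the held-out participant's β
at that time enters a one-sample t test, Holm–Bonferroni corrected across
the ROI family (family size = number of ROIs entering the test).

**Known limitation — null calibration.** Leave-one-out selection removes
*individual-level* peak-selection bias (no participant's value is read at
a time chosen from their own data), but all folds typically select the
same group peak, so the mean of the held-out values is still the maximised
column mean. Under a global null of exchangeable zero-mean β time courses
the procedure is anti-conservative: simulations in this package measure a
family-wise Holm rejection rate near 50–60% at nominal 5% (median null
|t| ≈ 1.6). Significant results from this test are therefore best read
jointly with effect sizes and the consistency of per-participant peaks,
and the package's own calibration test documents the miscalibration
rather than hiding it.

## Circuit path analysis

All observed variables x (seven ROI series, optionally plus exogenous
inputs) are modelled as x = Ax + e with A the acyclic path-coefficient
matrix and e mean-zero residuals with diagonal covariance for nodes (free
variances/covariances for exogenous inputs), giving
Σ(θ) = (I−A)⁻¹S(I−A)⁻ᵀ. Parameters minimise
F_ML = log|Σ| + tr(SₛΣ⁻¹) − log|Sₛ| − p by L-BFGS-B with an analytic
gradient, warm-started from per-equation OLS on the sample covariance;
standard errors come from the numerical Hessian of F_ML scaled by
2/(N−1). Fit indices use their standard formulas (χ² = (N−1)F_ML; SRMR on
standardised residual covariances; GFI; RMSEA), and AIC = (N−1)F_ML + 2k
(a consistent convention — only AIC *differences* are interpreted, and
they are invariant to common rescaling of the series). Exogenous-node
covariances are fixed at zero by default, matching the generator's
independent innovations and keeping the model overidentified
(df = 15 for the 7-node circuit); the reversed model flips every edge and
has the identical free-parameter count.

Series are demeaned per participant and concatenated before the pooled
covariance is formed (the pooling scheme is an implementation choice;
per-participant fitting is available by passing single-participant data).
Temporal autocorrelation is ignored in the likelihood, as is standard for
covariance-based SEM on fMRI series; N in the index formulas is the number
of pooled samples, recorded in the outputs. The model is lag-0 throughout —
no lagged edges.

The actTime control convolves two response-locked event series (unmodulated,
and scaled by z-scored observed actTime) with the HRF at the series'
sampling rate and feeds them as exogenous predictors of all seven nodes; a
parametric column that is constant after centring is dropped with a
warning. The permutation control enumerates all 7! = 5,040 assignments of
ROI labels to circuit positions exhaustively (the template's edge set is
fixed; the identity assignment is included and reproduces the reference
AIC); the reference model's percentile uses midranks for ties. Note that
some permuted topologies can be Markov-equivalent to the reference (e.g.
full reversal of a pure chain), in which case the minimum AIC is shared to
numerical precision.

## Pipeline

A single YAML-backed configuration drives five stages (simulate,
fit-timing, glm, ppi, sem); each stage reads and writes plain-text tables
in the run directory and the manifest records the effective configuration,
all seeds and a SHA-256 per output, so re-running with the same seed is
byte-identical. Per-participant seeds are spawned from the master seed via
`numpy.random.SeedSequence`. Default problem sizes (8 participants × 90
trials; 2,000-sample SEM fixtures; 50-replicate direction-recovery and
10-seed permutation-calibration ensembles in the tests) were chosen as the
smallest sizes at which the recovery properties are statistically
comfortable.

## Degenerate inputs and numerical conventions

Constant covariates, constant regressors, rank-deficient designs, singular
sample covariances, NaNs in raw series and cyclic graphs all raise
immediately with named offenders rather than propagating. Variance
parameters are bounded below at 1e-8 in the SEM optimiser; SEM
non-convergence raises with the final gradient norm unless the gradient is
already numerically flat. PEV is reported as missing when fewer than three
uncensored trials remain or either vector is constant.
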