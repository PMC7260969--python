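"""Deterministic model of the bubble task.

Participants watch a water tank drain over 20 s while bubbles surface one at
a time, every 2 s.  Bubble colour codes reward magnitude (5/10/20 p), bubble
size codes reward probability, which changes linearly across bubbles within a
trial, and Gaussian display noise of a per-trial level is added to the size.
A single button press at a self-chosen time attempts to collect the bubble
currently on screen.  This module holds the task parameterisation, the
within-trial bubble schedule and probability trajectory, and a
pseudorandomised design generator with near-zero pairwise factor correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "TaskSpec",
    "TrialContext",
    "BubbleSchedule",
    "bubble_schedule",
    "probability_at_time",
    "generate_design",
    "DesignError",
]


class DesignError(RuntimeError):
    """Raised when a pseudorandomised design cannot satisfy its constraints."""


@dataclass(frozen=True)
class TaskSpec:
    """Task parameters for one session.

    Defaults reflect the standard configuration: a 20-s trial with nine 2-s
    bubbles, reward probability rising or falling linearly from 0.5 at the
    first bubble to a per-trial last-bubble value, three reward magnitudes in
    pence, six probability-slope levels and five display-noise levels.
    """

    trial_duration: float = 20.0
    bubble_period: float = 2.0
    n_bubbles: int = 9
    first_bubble_prob: float = 0.5
    magnitude_levels: tuple[int, ...] = (5, 10, 20)
    slope_levels: tuple[float, ...] = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)
    noise_levels: tuple[float, ...] = (0.02, 0.04, 0.06, 0.08, 0.10)
    ao_delay_range: tuple[float, float] = (4.0, 10.0)

    def __post_init__(self) -> None:
        if self.n_bubbles * self.bubble_period > self.trial_duration:
            raise ValueError("bubbles do not fit in the trial: "
                             f"{self.n_bubbles} x {self.bubble_period}s > {self.trial_duration}s")
        if not 0.0 <= self.first_bubble_prob <= 1.0:
            raise ValueError("first_bubble_prob must be a probability")
        if any(not 0.0 <= p <= 1.0 for p in self.slope_levels):
            raise ValueError("slope_levels must be probabilities")
        if list(self.magnitude_levels) != sorted(set(self.magnitude_levels)):
            raise ValueError("magnitude_levels must be strictly increasing")
        if len(self.noise_levels) != len(set(self.noise_levels)):
            raise ValueError("noise_levels must be distinct")


@dataclass(frozen=True)
class TrialContext:
    """Contextual factors of a single trial.

    Present factors: reward magnitude (level index 1..3), the last-bubble
    reward probability defining the within-trial slope, and the display-noise
    level index 1..5.  Past factors: whether the previous trial was rewarded
    and its action time in seconds (both None on the first trial).
    """

    reward_magnitude: int
    last_bubble_prob: float
    noise_level: int
    prev_outcome: int | None = None
    prev_acttime: float | None = None
    trial_onset_in_run: float = 0.0

    def validate(self, spec: TaskSpec) -> None:
        if not 1 <= self.reward_magnitude <= len(spec.magnitude_levels):
            raise ValueError(f"reward_magnitude index {self.reward_magnitude} out of range")
        if not any(np.isclose(self.last_bubble_prob, s) for s in spec.slope_levels):
            raise ValueError(f"last_bubble_prob {self.last_bubble_prob} not a slope level")
        if not 1 <= self.noise_level <= len(spec.noise_levels):
            raise ValueError(f"noise_level index {self.noise_level} out of range")
        if self.prev_acttime is not None and not 0.0 < self.prev_acttime <= spec.trial_duration:
            raise ValueError(f"prev_acttime {self.prev_acttime} outside (0, {spec.trial_duration}]")


@dataclass(frozen=True)
class BubbleSchedule:
    """Onsets, nominal probabilities and noisy displayed sizes of one trial."""

    onsets: np.ndarray
    nominal_probs: np.ndarray
    displayed_sizes: np.ndarray


def bubble_schedule(spec: TaskSpec, trial: TrialContext,
                    rng: np.random.Generator | None = None) -> BubbleSchedule:
    """Bubble onsets and probabilities for one trial.

    Bubble k (k = 1..n) surfaces at k * bubble_period seconds and stays on
    screen for one bubble period.  Its nominal reward probability is linear
    in bubble index from the first-bubble probability to the trial's
    last-bubble probability.  Displayed size adds i.i.d. Gaussian noise with
    the trial's noise SD to the nominal probability.
    """
    trial.validate(spec)
    k = np.arange(1, spec.n_bubbles + 1)
    onsets = k * spec.bubble_period
    frac = (k - 1) / (spec.n_bubbles - 1)
    probs = spec.first_bubble_prob + (trial.last_bubble_prob - spec.first_bubble_prob) * frac
    if rng is None:
        sizes = probs.copy()
    else:
        sd = spec.noise_levels[trial.noise_level - 1]
        sizes = probs + rng.normal(0.0, sd, size=probs.shape)
    return BubbleSchedule(onsets=onsets, nominal_probs=probs, displayed_sizes=sizes)


def probability_at_time(spec: TaskSpec, trial: TrialContext, t: float) -> float:
    """Nominal reward probability of the bubble on screen at time ``t``.

    The on-screen probability is a right-continuous step function: bubble k's
    value holds on [onset_k, onset_k + bubble_period).  ``t`` must lie within
    the display of some bubble, i.e. in [first onset, trial end).
    """
    sched = bubble_schedule(spec, trial)
    first = sched.onsets[0]
    if t < first or t >= spec.trial_duration:
        raise ValueError(f"t={t} outside the bubble display window "
                         f"[{first}, {spec.trial_duration})")
    idx = int((t - first) // spec.bubble_period)
    idx = min(idx, spec.n_bubbles - 1)
    return float(sched.nominal_probs[idx])


def _balanced_column(levels: int, n: int) -> np.ndarray:
    """Level indices 1..levels repeated to length n, counts within 1."""
    reps = -(-n // levels)
    col = np.tile(np.arange(1, levels + 1), reps)[:n]
    return col


def design_correlations(design: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlations of the present factor columns."""
    cols = ["reward_magnitude", "last_bubble_prob", "noise_level"]
    return design[cols].corr()


def generate_design(spec: TaskSpec, n_trials: int, max_abs_corr: float = 0.1,
                    seed: int | np.random.Generator = 0,
                    max_iter: int = 5000) -> pd.DataFrame:
    """Pseudorandomised trial sequence with near-orthogonal factors.

    Each present factor (magnitude, probability slope, noise) is balanced
    across its levels up to rounding, then the columns are independently
    reshuffled until every pairwise Pearson correlation satisfies
    ``|r| <= max_abs_corr`` (reject-and-retry with a fixed iteration budget).

    Returns a DataFrame with one row per trial and columns
    trial, reward_magnitude (1..3), last_bubble_prob, noise_level (1..5).
    """
    if not 0.0 < max_abs_corr < 1.0:
        raise ValueError("max_abs_corr must be in (0, 1)")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    mag = _balanced_column(len(spec.magnitude_levels), n_trials)
    slope_idx = _balanced_column(len(spec.slope_levels), n_trials)
    noise = _balanced_column(len(spec.noise_levels), n_trials)
    slopes = np.asarray(spec.slope_levels)

    worst = (None, np.inf)
    for _ in range(max_iter):
        cand = pd.DataFrame({
            "reward_magnitude": rng.permutation(mag),
            "last_bubble_prob": slopes[rng.permutation(slope_idx) - 1],
            "noise_level": rng.permutation(noise),
        })
        corr = design_correlations(cand).to_numpy()
        off = np.abs(corr[np.triu_indices(3, k=1)])
        if off.max() <= max_abs_corr:
            cand.insert(0, "trial", np.arange(1, n_trials + 1))
            return cand
        if off.max() < worst[1]:
            worst = (corr, off.max())
    raise DesignError(
        f"no design with all |r| <= {max_abs_corr} in {max_iter} iterations; "
        f"best attempt's worst |r| = {worst[1]:.3f}")


def trial_contexts(spec: TaskSpec, design: pd.DataFrame) -> list[TrialContext]:
    """Materialise TrialContext objects from a design table (no past factors)."""
    out = []
    for row in design.itertuples(index=False):
        out.append(TrialContext(
            reward_magnitude=int(row.reward_magnitude),
            last_bubble_prob=float(row.last_bubble_prob),
            noise_level=int(row.noise_level),
        ))
    return out
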