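"""Synthetic behavioural sessions and multi-ROI BOLD series with known truth.

The generator is the testbed for every downstream stage: response times are
drawn from a proportional-hazards process with known coefficients and
right-censoring at tank drain, and region-of-interest BOLD series are built
from event-locked neural signals convolved with the canonical HRF, passed
through an instantaneous linear coupling graph, and corrupted with AR(1) plus
white measurement noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hrf import HrfSpec, hrf_kernel
from .task import TaskSpec, TrialContext, probability_at_time

__all__ = [
    "BehaviorGroundTruth",
    "NeuralEventModel",
    "CouplingModel",
    "simulate_behavior",
    "simulate_bold",
    "default_neural_model",
    "default_coupling",
    "CIRCUIT_EDGES",
    "ROI_LABELS",
]

COVARIATES = ("reward_t", "prob_change_t", "noise_t", "prev_outcome", "prev_acttime")

#: The seven circuit nodes and the hypothesised directed influences among
#: them: striatal nodes (CN, NAc) are driven by SN; SN collects inputs from
#: BF, PPN and HB; ACC drives BF.
ROI_LABELS = ("ACC", "BF", "PPN", "HB", "SN", "CN", "NAc")
CIRCUIT_EDGES = (
    ("ACC", "BF"),
    ("BF", "SN"),
    ("PPN", "SN"),
    ("HB", "SN"),
    ("SN", "CN"),
    ("SN", "NAc"),
)


def _default_rates() -> np.ndarray:
    # hazard ramps gently for most of the trial, then steeply as the tank
    # nears empty, so that non-response (censoring) is rare (~1%) and the
    # mean response time lands near 10 s at the default effect sizes
    return np.concatenate([0.09 + 0.045 * np.arange(14.0),
                           [1.5, 2.5, 4.0, 6.0, 10.0, 16.0]])


@dataclass(frozen=True)
class BehaviorGroundTruth:
    """Generative proportional-hazards model for response times.

    ``beta`` holds raw-scale log-hazard coefficients per contextual covariate
    (reward magnitude level, last-bubble probability, noise level, previous
    outcome, previous action time in seconds).  The baseline hazard is
    piecewise-constant over 1-s bins on [0, censor_time]; trials whose
    sampled time exceeds ``censor_time`` are non-responses.
    """

    # defaults give the contextual factors ~25-30% of actTime variance:
    # waiting pays when probability rises (negative hazard effect of slope),
    # large rewards and low noise lengthen waiting, and a rewarded or slow
    # previous trial slows the next response
    beta: dict[str, float] = field(default_factory=lambda: {
        "reward_t": -0.105,
        "prob_change_t": -1.75,
        "noise_t": 0.175,
        "prev_outcome": -0.28,
        "prev_acttime": -0.084,
    })
    baseline_rates: np.ndarray = field(default_factory=_default_rates)
    bin_width: float = 1.0
    censor_time: float = 20.0

    def __post_init__(self) -> None:
        rates = np.asarray(self.baseline_rates, dtype=float)
        if np.any(rates < 0):
            raise ValueError("baseline rates must be nonnegative")
        if len(rates) * self.bin_width < self.censor_time:
            raise ValueError("baseline rates do not cover [0, censor_time]")
        if set(self.beta) != set(COVARIATES):
            raise ValueError(f"beta must have exactly the keys {COVARIATES}")

    def beta_vector(self) -> np.ndarray:
        return np.array([self.beta[c] for c in COVARIATES])

    def expected_acttime(self, linpred: float | np.ndarray) -> np.ndarray:
        """Ground-truth expected actTime: RMST over [0, censor_time].

        With piecewise-constant baseline rates the integral of
        S(t|x) = exp(-L0(t) e^linpred) has a closed form per bin.
        """
        linpred = np.atleast_1d(np.asarray(linpred, dtype=float))
        hz = np.exp(linpred)[:, None]  # hazard multiplier per trial
        n_bins = int(np.ceil(self.censor_time / self.bin_width))
        rates = np.asarray(self.baseline_rates[:n_bins], dtype=float)
        cum0 = np.concatenate([[0.0], np.cumsum(rates * self.bin_width)])[:-1]
        s_start = np.exp(-hz * cum0)  # survival at each bin start
        lam = hz * rates
        with np.errstate(divide="ignore", invalid="ignore"):
            seg = np.where(lam > 0,
                           s_start * (1.0 - np.exp(-lam * self.bin_width)) / lam,
                           s_start * self.bin_width)
        return seg.sum(axis=1)

    def sample_time(self, linpred: float, u: float) -> float:
        """Invert S(t|x) = exp(-L0(t) e^linpred) at survival level ``u``.

        Returns the sampled event time; values above ``censor_time`` signal
        censoring.
        """
        if not np.isfinite(linpred):
            raise ValueError("non-finite linear predictor")
        target = -np.log(u) * np.exp(-linpred)  # required baseline cum. hazard
        acc = 0.0
        for k, rate in enumerate(self.baseline_rates):
            step = rate * self.bin_width
            if acc + step >= target and rate > 0:
                return k * self.bin_width + (target - acc) / rate
            acc += step
        return np.inf


def covariate_matrix(session: pd.DataFrame) -> pd.DataFrame:
    """Raw contextual covariates in fitting order from a session table."""
    return pd.DataFrame({
        "reward_t": session["reward_magnitude"].astype(float),
        "prob_change_t": session["last_bubble_prob"].astype(float),
        "noise_t": session["noise_level"].astype(float),
        "prev_outcome": session["prev_outcome"].astype(float),
        "prev_acttime": session["prev_acttime"].astype(float),
    })


def simulate_behavior(design: pd.DataFrame, truth: BehaviorGroundTruth,
                      spec: TaskSpec | None = None,
                      seed: int | np.random.Generator = 0,
                      participant: str = "sub-01") -> pd.DataFrame:
    """Simulate one behavioural session from a trial design.

    Each trial's action time is drawn by inverse transform from the
    proportional-hazards survival function given its present covariates and
    the realised past-trial covariates; times beyond the tank drain are
    censored (no response, no reward).  The reward outcome of a responded
    trial is Bernoulli with the on-screen bubble probability at the moment of
    response.  First-trial past factors are drawn from their marginals.

    Returns a session table with one row per trial: onset in run, the three
    present factors, realised past factors, actTime (NaN when censored),
    outcome and action-outcome delay.
    """
    spec = spec or TaskSpec()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    beta = truth.beta

    # first-trial past factors from their marginals: outcome fair coin,
    # previous action time from the baseline (covariate-free) process
    prev_outcome = int(rng.integers(0, 2))
    while True:
        t0 = truth.sample_time(0.0, rng.uniform())
        if t0 <= truth.censor_time:
            prev_acttime = t0
            break

    rows = []
    onset = 0.0
    for row in design.itertuples(index=False):
        trial = TrialContext(
            reward_magnitude=int(row.reward_magnitude),
            last_bubble_prob=float(row.last_bubble_prob),
            noise_level=int(row.noise_level),
            prev_outcome=prev_outcome,
            prev_acttime=prev_acttime,
        )
        linpred = (beta["reward_t"] * trial.reward_magnitude
                   + beta["prob_change_t"] * trial.last_bubble_prob
                   + beta["noise_t"] * trial.noise_level
                   + beta["prev_outcome"] * prev_outcome
                   + beta["prev_acttime"] * prev_acttime)
        t = truth.sample_time(linpred, rng.uniform())
        censored = t > truth.censor_time
        if censored:
            acttime, outcome = np.nan, 0
        else:
            acttime = float(t)
            # no bubble is on screen before the first onset; the first
            # bubble's probability applies from trial start for the outcome
            t_prob = min(max(acttime, spec.bubble_period), spec.trial_duration - 1e-9)
            p = probability_at_time(spec, trial, t_prob)
            outcome = int(rng.uniform() < p)
        ao_delay = float(rng.uniform(*spec.ao_delay_range))
        rows.append({
            "participant": participant,
            "trial": int(row.trial),
            "trial_onset_in_run": onset,
            "reward_magnitude": trial.reward_magnitude,
            "last_bubble_prob": trial.last_bubble_prob,
            "noise_level": trial.noise_level,
            "prev_outcome": prev_outcome,
            "prev_acttime": prev_acttime,
            "acttime": acttime,
            "outcome": outcome,
            "ao_delay": ao_delay,
        })
        # censored trials: the stimulus ran to the drain and paid nothing
        rows[-1]["linpred_true"] = linpred
        prev_outcome = outcome
        prev_acttime = truth.censor_time if censored else acttime
        onset += spec.trial_duration + ao_delay + 4.0  # outcome phase + ITI
    out = pd.DataFrame(rows)
    # ground-truth deterministic actTime (expected response time given context)
    out["det_acttime_true"] = truth.expected_acttime(out["linpred_true"].to_numpy())
    return out


@dataclass(frozen=True)
class NeuralEventModel:
    """Event-locked neural signal of one ROI.

    Impulses are placed at trial onsets or at responses; each impulse's
    amplitude is ``amplitude + weight * z(modulator)`` where the modulator is
    a per-trial column of the session table (e.g. observed or deterministic
    action time).
    """

    lock: str = "response"           # "response" | "onset"
    amplitude: float = 1.0
    modulator: str | None = None     # session column name
    weight: float = 0.0

    def __post_init__(self) -> None:
        if self.lock not in ("response", "onset"):
            raise ValueError(f"unknown event lock {self.lock!r}")


@dataclass(frozen=True)
class CouplingModel:
    """Instantaneous linear coupling among named ROI series.

    ``edges`` maps (parent, child) to a weight; the graph must be acyclic.
    Each node receives white innovation noise of ``innovation_sd`` and the
    returned series add AR(1) (coefficient ``ar1_phi``) plus white
    measurement noise.
    """

    nodes: tuple[str, ...] = ROI_LABELS
    edges: dict[tuple[str, str], float] = field(default_factory=dict)
    innovation_sd: float = 0.2
    ar1_phi: float = 0.3
    ar1_sd: float = 0.3
    white_sd: float = 0.3

    def __post_init__(self) -> None:
        for (a, b) in self.edges:
            if a not in self.nodes or b not in self.nodes:
                raise ValueError(f"edge ({a}, {b}) references unknown node")
        self.topological_order()

    def topological_order(self) -> list[str]:
        children = {n: [] for n in self.nodes}
        indeg = {n: 0 for n in self.nodes}
        for (a, b) in self.edges:
            children[a].append(b)
            indeg[b] += 1
        order = [n for n in self.nodes if indeg[n] == 0]
        head = 0
        while head < len(order):
            for c in children[order[head]]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    order.append(c)
            head += 1
        if len(order) != len(self.nodes):
            raise ValueError("coupling graph has a cycle")
        return order


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = np.nanstd(x)
    if sd == 0:
        return np.zeros_like(x)
    return (x - np.nanmean(x)) / sd


def event_regressor(session: pd.DataFrame, events: NeuralEventModel,
                    n_samples: int, dt: float, kernel: np.ndarray) -> np.ndarray:
    """HRF-convolved event signal for one ROI on the run grid (noise-free)."""
    x = np.zeros(n_samples)
    if events.modulator is not None:
        mod = _zscore(session[events.modulator].to_numpy(dtype=float))
    for i, row in enumerate(session.itertuples(index=False)):
        if events.lock == "response":
            if not np.isfinite(row.acttime):
                continue
            t_ev = row.trial_onset_in_run + row.acttime
        else:
            t_ev = row.trial_onset_in_run
        amp = events.amplitude
        if events.modulator is not None and np.isfinite(mod[i]):
            amp = amp + events.weight * mod[i]
        idx = int(round(t_ev / dt))
        if 0 <= idx < n_samples:
            x[idx] += amp
    return np.convolve(x, kernel)[:n_samples]


def simulate_bold(session: pd.DataFrame,
                  events: dict[str, NeuralEventModel],
                  coupling: CouplingModel,
                  hrf: HrfSpec | None = None,
                  sampling_interval: float = 1.0,
                  seed: int | np.random.Generator = 0,
                  pad: float = 30.0) -> pd.DataFrame:
    """Simulate coupled ROI BOLD series for one session.

    Every node's series is its own HRF-convolved event signal (if it has an
    entry in ``events``) plus the weighted sum of its parents' series plus
    white innovations, computed in topological order; AR(1) and white
    measurement noise are then added.  Returns a wide table with a ``time``
    column and one column per ROI, sampled at ``sampling_interval``.
    """
    hrf = hrf or HrfSpec()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    dt = float(sampling_interval)
    last = session.iloc[-1]
    run_len = float(last.trial_onset_in_run) + 20.0 + pad
    n = int(np.ceil(run_len / dt))
    kernel = hrf_kernel(hrf, dt)

    series: dict[str, np.ndarray] = {}
    for node in coupling.topological_order():
        y = np.zeros(n)
        if node in events:
            y += event_regressor(session, events[node], n, dt, kernel)
        for (a, b), w in coupling.edges.items():
            if b == node:
                y += w * series[a]
        if coupling.innovation_sd > 0:
            y += rng.normal(0.0, coupling.innovation_sd, n)
        series[node] = y

    out: dict[str, np.ndarray] = {"time": np.arange(n) * dt}
    for node in coupling.nodes:
        noise = np.zeros(n)
        if coupling.ar1_sd > 0:
            e = rng.normal(0.0, coupling.ar1_sd, n)
            noise = np.empty(n)
            noise[0] = e[0]
            for i in range(1, n):
                noise[i] = coupling.ar1_phi * noise[i - 1] + e[i]
        if coupling.white_sd > 0:
            noise = noise + rng.normal(0.0, coupling.white_sd, n)
        out[node] = series[node] + noise
    return pd.DataFrame(out)


def default_neural_model() -> dict[str, NeuralEventModel]:
    """Event models emulating the qualitative regional findings.

    BF carries an early (trial-onset-locked) signal modulated by the
    ground-truth deterministic actTime; PPN and HB carry early signals
    modulated by the observed actTime; SN encodes action initiation per se
    (response-locked, unmodulated); the striatal nodes CN and NAc carry late
    response-locked signals with negative observed-actTime modulation; ACC
    provides a weak onset-locked drive.
    """
    return {
        "ACC": NeuralEventModel(lock="onset", amplitude=0.3),
        "BF": NeuralEventModel(lock="onset", amplitude=0.5,
                               modulator="det_acttime_true", weight=0.5),
        "PPN": NeuralEventModel(lock="onset", amplitude=0.6,
                                modulator="acttime", weight=0.4),
        "HB": NeuralEventModel(lock="onset", amplitude=0.6,
                               modulator="acttime", weight=0.4),
        "SN": NeuralEventModel(lock="response", amplitude=1.0),
        "CN": NeuralEventModel(lock="response", amplitude=0.5,
                               modulator="acttime", weight=-0.4),
        "NAc": NeuralEventModel(lock="response", amplitude=0.5,
                                modulator="acttime", weight=-0.4),
    }


def default_coupling(weight_scale: float = 1.0) -> CouplingModel:
    """The hypothesised circuit topology with moderate positive weights."""
    w = {
        ("ACC", "BF"): 0.4, ("BF", "SN"): 0.5, ("PPN", "SN"): 0.3,
        ("HB", "SN"): 0.3, ("SN", "CN"): 0.5, ("SN", "NAc"): 0.5,
    }
    return CouplingModel(edges={e: weight_scale * v for e, v in w.items()})
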