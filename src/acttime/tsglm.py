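"""Time-resolved ROI GLMs: preprocessing, epoching, per-timestep OLS, PPI,
and leave-one-out group-peak inference.

The ROI-averaged BOLD series of a run is z-scored, linearly up-sampled, and
epoched in 15-s windows from 9 s before to 6 s after each response.  At each
epoch time point an ordinary-least-squares regression across trials relates
the BOLD sample to trialwise regressors (observed actTime, deterministic
actTime, contextual factors, a session-time confound, a constant), yielding
a beta time course per regressor.  Group inference avoids temporal selection
bias with a leave-one-out procedure: each participant's beta is read out at
the peak of the other participants' mean time course, and the held-out
values are tested with a one-sample t test, Holm-Bonferroni corrected across
the ROI family.  The psychophysiological-interaction (PPI) model adds, at
each epoch time, the seed region's BOLD and its interaction with
deterministic actTime (both factors mean-centered before multiplying).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "RoiTimeSeries", "EpochedMatrix", "GlmSpec",
    "preprocess", "epoch", "fit_timecourse_glm",
    "glm_observed", "glm_context", "glm_deterministic", "glm_present_past",
    "build_ppi_spec", "loo_peak_test", "loo_peak_tests",
    "PHASE_WINDOWS", "responded",
]

#: Epoch windows (seconds relative to response) used for peak selection.
PHASE_WINDOWS = {"full": (-9.0, 6.0), "early": (-2.0, 0.0), "late": (4.0, 6.0)}


@dataclass
class RoiTimeSeries:
    """One ROI's normalised BOLD series for one run."""

    values: np.ndarray
    sampling_interval: float
    roi: str = ""
    participant: str = ""
    run: str = ""

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) * self.sampling_interval


@dataclass
class EpochedMatrix:
    """Trials x time-samples BOLD locked to response onset."""

    data: np.ndarray
    epoch_times: np.ndarray
    trial_index: np.ndarray     # positions into the session the rows came from
    n_dropped: int = 0


def _z(x: np.ndarray, name: str = "") -> np.ndarray:
    sd = np.std(x)
    if sd == 0:
        raise ValueError(f"regressor {name or 'series'} has zero variance")
    return (x - np.mean(x)) / sd


def preprocess(values: np.ndarray, sampling_interval: float,
               upsample_interval: float = 0.5, **meta) -> RoiTimeSeries:
    """Z-score a raw ROI series over the run and up-sample it linearly."""
    values = np.asarray(values, dtype=float)
    if np.isnan(values).any():
        idx = np.flatnonzero(np.isnan(values))
        raise ValueError(f"NaNs in input series at samples {idx[:10].tolist()}")
    z = _z(values, "ROI series")
    t_old = np.arange(len(z)) * sampling_interval
    t_new = np.arange(0.0, t_old[-1] + upsample_interval / 2, upsample_interval)
    out = np.interp(t_new, t_old, z)
    return RoiTimeSeries(values=out, sampling_interval=upsample_interval, **meta)


def epoch(series: RoiTimeSeries, response_times: np.ndarray,
          window: tuple[float, float] = (-9.0, 6.0)) -> EpochedMatrix:
    """Cut trialwise epochs around response times (seconds into the run).

    Trials whose window extends beyond the run are dropped (counted in
    ``n_dropped``); an error is raised if nothing survives.
    """
    dt = series.sampling_interval
    rel = np.arange(window[0], window[1] + dt / 2, dt)
    n = len(series.values)
    rows, kept = [], []
    for i, rt in enumerate(np.asarray(response_times, dtype=float)):
        idx = np.round((rt + rel) / dt).astype(int)
        if idx[0] < 0 or idx[-1] >= n:
            continue
        rows.append(series.values[idx])
        kept.append(i)
    if not rows:
        raise ValueError("all trials dropped: epochs never fit inside the run")
    return EpochedMatrix(data=np.vstack(rows), epoch_times=rel,
                         trial_index=np.asarray(kept),
                         n_dropped=len(response_times) - len(rows))


@dataclass
class GlmSpec:
    """A named trialwise design for the per-timestep OLS.

    ``columns`` maps regressor name to either a length-n_trials vector or an
    (n_trials, n_times) array for regressors that vary over epoch time (the
    PPI seed and interaction).  A constant column is always present.
    """

    columns: dict[str, np.ndarray]
    of_interest: tuple[str, ...] = ()
    name: str = ""

    @property
    def names(self) -> list[str]:
        return list(self.columns)

    def design_at(self, j: int, n_trials: int) -> np.ndarray:
        cols = []
        for v in self.columns.values():
            v = np.asarray(v, dtype=float)
            cols.append(v[:, j] if v.ndim == 2 else v)
        x = np.column_stack(cols)
        if x.shape[0] != n_trials:
            raise ValueError("regressor length does not match trial count")
        return x


def _check_rank(x: np.ndarray, names: list[str]) -> None:
    if np.linalg.matrix_rank(x) < x.shape[1]:
        xc = x - x.mean(axis=0)
        sd = xc.std(axis=0)
        sd[sd == 0] = 1.0
        c = np.abs((xc / sd).T @ (xc / sd) / len(x))
        np.fill_diagonal(c, 0.0)
        i, j = np.unravel_index(np.argmax(c), c.shape)
        raise ValueError(f"rank-deficient design: {names[i]!r} vs {names[j]!r} "
                         f"(|r| = {c[i, j]:.4f})")


def fit_timecourse_glm(epoched: EpochedMatrix, spec: GlmSpec) -> pd.DataFrame:
    """Independent OLS at every epoch time; rows epoch times, columns betas."""
    y = epoched.data
    n_trials, n_times = y.shape
    k = len(spec.columns)
    if n_trials <= k + 5:
        raise ValueError(f"too few trials ({n_trials}) for {k} regressors")
    betas = np.empty((n_times, k))
    for j in range(n_times):
        x = spec.design_at(j, n_trials)
        _check_rank(x, spec.names)
        betas[j], *_ = np.linalg.lstsq(x, y[:, j], rcond=None)
    return pd.DataFrame(betas, index=pd.Index(epoched.epoch_times, name="epoch_time"),
                        columns=spec.names)


def responded(session: pd.DataFrame) -> pd.DataFrame:
    """Trials with a response and complete past covariates (GLM-eligible)."""
    ok = np.isfinite(session["acttime"].to_numpy(dtype=float))
    ok &= session["prev_acttime"].notna().to_numpy()
    return session.loc[ok]


def _log_z_acttime(session: pd.DataFrame) -> np.ndarray:
    return _z(np.log(session["acttime"].to_numpy(dtype=float)), "observed_actTime")


def _totaltime(session: pd.DataFrame) -> np.ndarray:
    return _z(session["trial_onset_in_run"].to_numpy(dtype=float), "totaltime")


def glm_observed(session: pd.DataFrame) -> GlmSpec:
    """Observed actTime (log, z-scored) + session-time confound + constant."""
    return GlmSpec(columns={
        "observed_actTime": _log_z_acttime(session),
        "totaltime": _totaltime(session),
        "constant": np.ones(len(session)),
    }, of_interest=("observed_actTime",), name="observed")


def glm_context(session: pd.DataFrame) -> GlmSpec:
    """Present and past contextual factors plus current outcome."""
    z = lambda c: _z(session[c].to_numpy(dtype=float), c)
    return GlmSpec(columns={
        "reward_t": z("reward_magnitude"),
        "probChange_t": z("last_bubble_prob"),
        "noise_t": z("noise_level"),
        "rewardOutcome_prev": z("prev_outcome"),
        "actTime_prev": z("prev_acttime"),
        "rewardOutcome_t": z("outcome"),
        "totaltime": _totaltime(session),
        "constant": np.ones(len(session)),
    }, of_interest=("reward_t", "probChange_t", "noise_t",
                    "rewardOutcome_prev", "actTime_prev"), name="context")


def glm_deterministic(session: pd.DataFrame, det: pd.DataFrame) -> GlmSpec:
    """Deterministic actTime (present+past) with observed actTime as covariate."""
    return GlmSpec(columns={
        "deterministic_actTime": _z(det["det_present_past"].to_numpy(dtype=float),
                                    "deterministic_actTime"),
        "observed_actTime": _log_z_acttime(session),
        "totaltime": _totaltime(session),
        "constant": np.ones(len(session)),
    }, of_interest=("deterministic_actTime",), name="deterministic")


def glm_present_past(session: pd.DataFrame, det: pd.DataFrame) -> GlmSpec:
    """Present-context and past-context deterministic actTime side by side."""
    return GlmSpec(columns={
        "deterministic_actTime_present": _z(det["det_present"].to_numpy(dtype=float),
                                            "det_present"),
        "deterministic_actTime_past": _z(det["det_past"].to_numpy(dtype=float),
                                         "det_past"),
        "observed_actTime": _log_z_acttime(session),
        "totaltime": _totaltime(session),
        "constant": np.ones(len(session)),
    }, of_interest=("deterministic_actTime_present",
                    "deterministic_actTime_past"), name="present_past")


def build_ppi_spec(seed_epoched: EpochedMatrix, session: pd.DataFrame,
                   det: pd.DataFrame) -> GlmSpec:
    """PPI design: seed BOLD, deterministic actTime, and their interaction.

    The psychological factor is the z-scored deterministic actTime
    (present+past); the interaction column is the elementwise product of the
    mean-centered seed BOLD (per epoch time) and the mean-centered
    psychological factor, so the PPI beta captures coupling that scales with
    deterministic actTime over and above the main effects.
    """
    seed = seed_epoched.data
    n_trials = len(session)
    if seed.shape[0] != n_trials:
        raise ValueError("seed epochs and session rows are misaligned")
    psych = det["det_present_past"].to_numpy(dtype=float)
    if np.std(psych) == 0:
        raise ValueError("psychological factor is constant; PPI undefined")
    psych_z = _z(psych, "deterministic_actTime")
    seed_c = seed - seed.mean(axis=0, keepdims=True)
    ppi = seed_c * psych_z[:, None]
    return GlmSpec(columns={
        "BOLDseed": seed,
        "deterministic_actTime": psych_z,
        "PPI": ppi,
        "observed_actTime": _log_z_acttime(session),
        "totaltime": _totaltime(session),
        "constant": np.ones(n_trials),
    }, of_interest=("PPI",), name="ppi")


def _phase_mask(epoch_times: np.ndarray, phase: str) -> np.ndarray:
    lo, hi = PHASE_WINDOWS[phase]
    return (epoch_times >= lo - 1e-9) & (epoch_times <= hi + 1e-9)


def loo_peak_test(betas: np.ndarray, epoch_times: np.ndarray,
                  phase: str = "full") -> dict:
    """Leave-one-out group-peak test for one ROI.

    ``betas`` is participants x epoch-times for the regressor of interest.
    For each participant, the peak time is the argmax of the absolute mean
    beta over the remaining participants within the phase window; the
    held-out participant's beta at that time enters a one-sample t test.
    """
    betas = np.asarray(betas, dtype=float)
    n_par, n_t = betas.shape
    if n_par < 5:
        raise ValueError(f"need at least 5 participants, got {n_par}")
    mask = _phase_mask(np.asarray(epoch_times), phase)
    win_times = np.asarray(epoch_times)[mask]
    held = np.empty(n_par)
    peak_times = np.empty(n_par)
    for i in range(n_par):
        others = np.delete(betas, i, axis=0).mean(axis=0)[mask]
        j = int(np.argmax(np.abs(others)))
        peak_times[i] = win_times[j]
        held[i] = betas[i, mask][j]
    t, p = stats.ttest_1samp(held, 0.0)
    d = held.mean() / held.std(ddof=1)
    return {"held_out": held, "peak_times": peak_times, "phase": phase,
            "t": float(t), "p_raw": float(p), "d": float(d),
            "mean_peak_time": float(peak_times.mean()), "n": n_par}


def loo_peak_tests(roi_betas: dict[str, np.ndarray], epoch_times: np.ndarray,
                   phase: str = "full", alpha: float = 0.05) -> pd.DataFrame:
    """Family-wise leave-one-out peak tests, Holm-corrected across ROIs."""
    rows = []
    for roi, b in roi_betas.items():
        r = loo_peak_test(b, epoch_times, phase)
        rows.append({"roi": roi, "phase": phase, "t": r["t"], "p_raw": r["p_raw"],
                     "d": r["d"], "mean_peak_time": r["mean_peak_time"],
                     "mean_peak_beta": r["held_out"].mean(), "n": r["n"]})
    out = pd.DataFrame(rows)
    reject, p_adj, *_ = multipletests(out["p_raw"], alpha=alpha, method="holm")
    out["p_holm"] = p_adj
    out["significant"] = reject
    return out
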