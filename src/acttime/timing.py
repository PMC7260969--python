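"""Proportional-hazards model of trialwise action timing.

The time from trial start to the button press (actTime) is modelled with a
Cox proportional-hazards regression on five contextual covariates: reward
magnitude, probability slope and display noise of the current trial, and the
outcome and actTime of the previous trial.  Non-response trials are
right-censored at tank drain (20 s).  The model's prediction for a trial —
the "deterministic actTime" — is the restricted mean survival time
``int_0^20 S(t|x) dt`` under the fitted covariate-conditional survival
curve; using only the present-trial or only the past-trial coefficients
yields the present-context and past-context variants.  Model quality is
summarised by the proportion of explained variance (PEV), the squared
Pearson correlation between observed and deterministic actTime across
uncensored trials, in percent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter

from .synth import COVARIATES, covariate_matrix

__all__ = ["CoxFit", "fit_cox", "deterministic_times", "pev",
           "PRESENT", "PAST", "SUBSETS"]

PRESENT = ("reward_t", "prob_change_t", "noise_t")
PAST = ("prev_outcome", "prev_acttime")
SUBSETS = {
    "present_past": PRESENT + PAST,
    "present": PRESENT,
    "past": PAST,
}


@dataclass
class CoxFit:
    """A fitted Cox model plus the machinery to predict deterministic actTime.

    ``coefficients`` are on the z-scored covariate scale (covariates are
    standardised per participant before fitting); ``baseline_times`` /
    ``baseline_cumhaz`` give the Breslow baseline cumulative hazard at the
    covariate mean, as a right-continuous step function starting at
    (0, 0); ``means`` / ``sds`` record the standardisation applied.
    """

    coefficients: pd.Series
    covariance: pd.DataFrame
    baseline_times: np.ndarray
    baseline_cumhaz: np.ndarray
    means: pd.Series
    sds: pd.Series
    n_events: int
    n_censored: int
    horizon: float = 20.0

    @property
    def standard_errors(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.covariance)),
                         index=self.coefficients.index)

    def standardize(self, covariates: pd.DataFrame) -> pd.DataFrame:
        return (covariates[list(self.coefficients.index)] - self.means) / self.sds

    def subset_coefficients(self, subset: str) -> pd.Series:
        """Coefficient vector with entries outside ``subset`` zeroed."""
        if subset not in SUBSETS:
            raise ValueError(f"unknown subset {subset!r}; choose from {sorted(SUBSETS)}")
        keep = SUBSETS[subset]
        beta = self.coefficients.copy()
        beta[~beta.index.isin(keep)] = 0.0
        return beta

    def survival_curve(self, linpred: float) -> tuple[np.ndarray, np.ndarray]:
        """Step-function S(t|x) on the baseline time grid, truncated at horizon."""
        return self.baseline_times, np.exp(-self.baseline_cumhaz * np.exp(linpred))

    def rmst(self, linpred: float | np.ndarray) -> np.ndarray:
        """Restricted mean survival time over [0, horizon] for linear predictors.

        The Breslow baseline is a step function, so the integral of
        S(t|x) = exp(-L0(t) e^xb) is an exact sum over the steps.
        """
        linpred = np.atleast_1d(np.asarray(linpred, dtype=float))
        t = np.minimum(self.baseline_times, self.horizon)
        widths = np.diff(np.append(t, self.horizon))
        # S is constant on [t_i, t_{i+1}); include the leading [0, t_0) span
        s = np.exp(-np.outer(np.exp(linpred), self.baseline_cumhaz))
        lead = t[0] if t.size else self.horizon
        return lead + s @ widths

    def deterministic_acttime(self, covariates: pd.DataFrame,
                              subset: str = "present_past") -> np.ndarray:
        """Deterministic actTime (RMST, seconds) per trial for a covariate subset."""
        z = self.standardize(covariates)
        beta = self.subset_coefficients(subset)
        return self.rmst(z.to_numpy() @ beta.to_numpy())


def fit_cox(session: pd.DataFrame, horizon: float = 20.0) -> CoxFit:
    """Fit the five-covariate Cox model to one participant's session.

    Covariates are z-scored before fitting; ties are handled by Efron's
    method and the baseline cumulative hazard is the Breslow estimator.
    Trials with missing past covariates (a first trial of a run) are
    dropped; non-response trials enter as right-censored at the horizon.
    """
    x = covariate_matrix(session)
    obs = session["acttime"].to_numpy(dtype=float)
    keep = x.notna().all(axis=1).to_numpy()
    x, obs = x.loc[keep], obs[keep]
    event = np.isfinite(obs)
    if event.sum() < 30:
        raise ValueError(f"need at least 30 uncensored trials, got {int(event.sum())}")
    means, sds = x.mean(), x.std(ddof=1)
    if (sds == 0).any():
        bad = sds.index[sds == 0].tolist()
        raise ValueError(f"constant covariate(s): {bad}")
    z = (x - means) / sds
    df = z.copy()
    df["duration"] = np.where(event, obs, horizon)
    df["event"] = event.astype(int)

    cph = CoxPHFitter()
    cph.fit(df, duration_col="duration", event_col="event")
    base = cph.baseline_cumulative_hazard_
    times = base.index.to_numpy(dtype=float)
    cumhaz = base.iloc[:, 0].to_numpy(dtype=float)
    pos = times > 0
    times, cumhaz = times[pos], cumhaz[pos]
    return CoxFit(
        coefficients=cph.params_.reindex(list(COVARIATES)),
        covariance=cph.variance_matrix_.reindex(
            index=list(COVARIATES), columns=list(COVARIATES)),
        baseline_times=times,
        baseline_cumhaz=cumhaz,
        means=means.reindex(list(COVARIATES)),
        sds=sds.reindex(list(COVARIATES)),
        n_events=int(event.sum()),
        n_censored=int((~event).sum()),
        horizon=horizon,
    )


def deterministic_times(fit: CoxFit, session: pd.DataFrame) -> pd.DataFrame:
    """Per-trial observed and deterministic actTimes.

    Returns a table aligned with ``session``: observed actTime, the
    deterministic actTime under the full model and under the present-only
    and past-only coefficient subsets, and the censoring flag.  Trials with
    missing past covariates get NaN predictions.
    """
    x = covariate_matrix(session)
    ok = x.notna().all(axis=1).to_numpy()
    out = pd.DataFrame(index=session.index)
    out["observed"] = session["acttime"].to_numpy(dtype=float)
    for subset, col in [("present_past", "det_present_past"),
                        ("present", "det_present"),
                        ("past", "det_past")]:
        vals = np.full(len(session), np.nan)
        vals[ok] = fit.deterministic_acttime(x.loc[ok], subset)
        out[col] = vals
    out["censored"] = ~np.isfinite(out["observed"])
    return out


def pev(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Proportion of explained variance, percent.

    100 x squared Pearson correlation between observed and predicted actTime
    across trials where both are defined (censored trials are excluded).
    NaN when fewer than 3 trials remain or either vector is constant.
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    keep = np.isfinite(observed) & np.isfinite(predicted)
    if keep.sum() < 3:
        return np.nan
    o, p = observed[keep], predicted[keep]
    if np.std(o) == 0 or np.std(p) == 0:
        return np.nan
    r = np.corrcoef(o, p)[0, 1]
    return float(100.0 * r ** 2)


def pev_summary(fit: CoxFit, session: pd.DataFrame) -> pd.DataFrame:
    """One-row PEV summary (present+past, present, past) for a session."""
    det = deterministic_times(fit, session)
    return pd.DataFrame([{
        "participant": session["participant"].iloc[0] if "participant" in session else "",
        "pev_present_past": pev(det["observed"], det["det_present_past"]),
        "pev_present": pev(det["observed"], det["det_present"]),
        "pev_past": pev(det["observed"], det["det_past"]),
        "n_events": fit.n_events,
        "n_censored": fit.n_censored,
    }])
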