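"""Observed-variable path analysis over ROI BOLD time series.

A directed, acyclic circuit over the seven regions (ACC, BF, PPN, HB, SN,
CN, NAc) is fit as a covariance-structure model: with all observed variables
stacked in x, coefficient matrix A (A[i, j] = path j -> i) and residual /
exogenous covariance S, the implied covariance is

    Sigma(theta) = (I - A)^-1 S (I - A)^-T,

and parameters minimise the maximum-likelihood discrepancy

    F_ML = log|Sigma| + tr(S_sample Sigma^-1) - log|S_sample| - p.

Fit quality is summarised by chi-square = (N-1) F_ML, SRMR, GFI, RMSEA and
AIC = (N-1) F_ML + 2 k.  The module also builds the confirmatory controls:
the direction-reversed circuit, the variant with response-locked
HRF-convolved actTime inputs fed to every node, and the exhaustive 7! = 5040
ensemble of ROI-to-position permutations with the reference model's AIC
percentile.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize

from .hrf import HrfSpec, hrf_kernel
from .synth import CIRCUIT_EDGES, ROI_LABELS

__all__ = [
    "PathModel", "SemFit", "PermutationEnsemble", "hypothesized_model",
    "fit_path_model", "reverse_model", "regress_out_acttime_model",
    "permute_rois", "acttime_inputs", "prepare_series",
]


@dataclass(frozen=True)
class PathModel:
    """A directed-edge circuit over named nodes, optionally with exogenous inputs.

    Free parameters: one path coefficient per edge, one residual (or
    exogenous) variance per variable, plus the covariances among exogenous
    inputs.  Inputs, when present, predict every node.
    """

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]
    inputs: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        seen = set()
        for (a, b) in self.edges:
            if a not in self.nodes or b not in self.nodes:
                raise ValueError(f"edge ({a}, {b}) references unknown node")
            if (a, b) in seen:
                raise ValueError(f"duplicate edge ({a}, {b})")
            seen.add((a, b))
        self._toposort()

    def _toposort(self) -> list[str]:
        indeg = {n: 0 for n in self.nodes}
        for (_, b) in self.edges:
            indeg[b] += 1
        order, frontier = [], [n for n in self.nodes if indeg[n] == 0]
        while frontier:
            n = frontier.pop()
            order.append(n)
            for (a, b) in self.edges:
                if a == n:
                    indeg[b] -= 1
                    if indeg[b] == 0:
                        frontier.append(b)
        if len(order) != len(self.nodes):
            raise ValueError("circuit has a cycle")
        return order

    @property
    def variables(self) -> tuple[str, ...]:
        return self.inputs + self.nodes

    @property
    def all_edges(self) -> tuple[tuple[str, str], ...]:
        """Node-node edges plus every input -> node edge."""
        return tuple((u, n) for u in self.inputs for n in self.nodes) + self.edges

    @property
    def n_free(self) -> int:
        k = len(self.inputs)
        return len(self.all_edges) + len(self.variables) + k * (k - 1) // 2


def hypothesized_model() -> PathModel:
    """The seven-node circuit: ACC->BF; BF, PPN, HB -> SN; SN -> CN, NAc."""
    return PathModel(nodes=ROI_LABELS, edges=CIRCUIT_EDGES)


def reverse_model(model: PathModel) -> PathModel:
    """Flip the direction of every node-node edge (inputs unchanged)."""
    return replace(model, edges=tuple((b, a) for (a, b) in model.edges))


@dataclass
class SemFit:
    """ML estimates and fit indices of one path model."""

    model: PathModel
    path_coefficients: pd.Series
    path_se: pd.Series
    residual_variances: pd.Series
    input_covariances: dict[tuple[str, str], float]
    fml: float
    chi2: float
    df: int
    srmr: float
    gfi: float
    rmsea: float
    aic: float
    n_samples: int
    n_free: int
    converged: bool

    def summary(self) -> pd.DataFrame:
        rows = [{"parameter": f"{a} -> {b}", "estimate": self.path_coefficients[(a, b)],
                 "se": self.path_se[(a, b)]} for (a, b) in self.path_coefficients.index]
        return pd.DataFrame(rows)


def _indices(model: PathModel):
    var = list(model.variables)
    pos = {v: i for i, v in enumerate(var)}
    a_idx = [(pos[b], pos[a]) for (a, b) in model.all_edges]  # A[child, parent]
    k = len(model.inputs)
    cov_idx = [(pos[u], pos[v]) for u, v in itertools.combinations(model.inputs, 2)]
    return var, a_idx, cov_idx


def _unpack(theta: np.ndarray, p: int, a_idx, cov_idx):
    n_a = len(a_idx)
    A = np.zeros((p, p))
    for t, (i, j) in enumerate(a_idx):
        A[i, j] = theta[t]
    S = np.zeros((p, p))
    np.fill_diagonal(S, theta[n_a:n_a + p])
    for t, (i, j) in enumerate(cov_idx):
        S[i, j] = S[j, i] = theta[n_a + p + t]
    return A, S


def _fml_and_grad(theta: np.ndarray, s_samp: np.ndarray, a_idx, cov_idx):
    p = s_samp.shape[0]
    A, S = _unpack(theta, p, a_idx, cov_idx)
    m = np.linalg.inv(np.eye(p) - A)
    sigma = m @ S @ m.T
    try:
        c = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        return 1e12, np.zeros_like(theta)
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    sigma_inv = np.linalg.inv(sigma)
    sign_s, logdet_s = np.linalg.slogdet(s_samp)
    f = logdet + np.trace(s_samp @ sigma_inv) - logdet_s - p
    # dF/dSigma = Sigma^-1 - Sigma^-1 S_samp Sigma^-1
    g = sigma_inv - sigma_inv @ s_samp @ sigma_inv
    grad = np.empty_like(theta)
    sgm = sigma @ g @ m          # for A entries: dF/dA_ij = 2 (Sigma G M)_{j,i}
    mtgm = m.T @ g @ m           # for S entries
    n_a = len(a_idx)
    for t, (i, j) in enumerate(a_idx):
        grad[t] = 2.0 * sgm[j, i]
    grad[n_a:n_a + p] = np.diag(mtgm)
    for t, (i, j) in enumerate(cov_idx):
        grad[n_a + p + t] = 2.0 * mtgm[i, j]
    return f, grad


def _start_values(model: PathModel, s_samp: np.ndarray, var: list[str]) -> np.ndarray:
    """Per-equation OLS from the sample covariance as a warm start."""
    pos = {v: i for i, v in enumerate(var)}
    parents = {v: [] for v in var}
    for (a, b) in model.all_edges:
        parents[b].append(a)
    coefs = {}
    resid = np.empty(len(var))
    for v in var:
        i = pos[v]
        pa = parents[v]
        if pa:
            ip = [pos[a] for a in pa]
            spp = s_samp[np.ix_(ip, ip)]
            spv = s_samp[ip, i]
            b = np.linalg.solve(spp + 1e-10 * np.eye(len(ip)), spv)
            for a, bb in zip(pa, b):
                coefs[(a, v)] = bb
            resid[i] = max(s_samp[i, i] - spv @ b, 1e-6)
        else:
            resid[i] = s_samp[i, i]
    theta_a = [coefs.get(e, 0.0) for e in model.all_edges]
    theta_cov = [s_samp[pos[u], pos[v]]
                 for u, v in itertools.combinations(model.inputs, 2)]
    return np.concatenate([theta_a, resid, theta_cov])


def prepare_series(series_by_participant: dict[str, pd.DataFrame],
                   columns: list[str] | None = None) -> pd.DataFrame:
    """Demean each participant's series per column and concatenate."""
    frames = []
    for _, df in series_by_participant.items():
        use = df[columns] if columns is not None else df
        frames.append(use - use.mean())
    return pd.concat(frames, ignore_index=True)


def fit_path_model(model: PathModel, data: pd.DataFrame,
                   gtol: float = 1e-7, maxiter: int = 500,
                   compute_se: bool = True) -> SemFit:
    """Fit the path model by ML to the sample covariance of ``data``.

    ``data`` needs one column per model variable (nodes and inputs),
    demeaned per participant and concatenated across participants.
    """
    var, a_idx, cov_idx = _indices(model)
    x = data[var].to_numpy(dtype=float)
    n = x.shape[0]
    s_samp = np.cov(x, rowvar=False, ddof=1)
    if np.linalg.matrix_rank(s_samp) < len(var):
        raise ValueError("sample covariance is singular")
    p = len(var)
    n_a = len(model.all_edges)
    theta0 = _start_values(model, s_samp, var)
    bounds = ([(None, None)] * n_a + [(1e-8, None)] * p
              + [(None, None)] * len(cov_idx))
    res = optimize.minimize(_fml_and_grad, theta0, args=(s_samp, a_idx, cov_idx),
                            jac=True, method="L-BFGS-B", bounds=bounds,
                            options={"gtol": gtol, "maxiter": maxiter})
    if not res.success and np.linalg.norm(res.jac) > 1e-3:
        raise RuntimeError(f"SEM optimisation did not converge: {res.message} "
                           f"(|grad| = {np.linalg.norm(res.jac):.2e})")
    theta = res.x
    fml = float(res.fun)
    A, S = _unpack(theta, p, a_idx, cov_idx)
    m = np.linalg.inv(np.eye(p) - A)
    sigma = m @ S @ m.T

    n_free = model.n_free
    df = p * (p + 1) // 2 - n_free
    chi2 = (n - 1) * fml
    d = np.sqrt(np.diag(s_samp))
    resid_std = (s_samp - sigma) / np.outer(d, d)
    iu = np.triu_indices(p)
    srmr = float(np.sqrt(np.mean(resid_std[iu] ** 2)))
    si_s = np.linalg.solve(sigma, s_samp)
    gfi = float(1.0 - np.trace((si_s - np.eye(p)) @ (si_s - np.eye(p)))
                / np.trace(si_s @ si_s))
    rmsea = float(np.sqrt(max(chi2 - df, 0.0) / (df * (n - 1)))) if df > 0 else 0.0
    aic = chi2 + 2.0 * n_free

    # SEs from the numerical Hessian of the ML discrepancy
    se = np.full(len(theta), np.nan)
    if compute_se:
        try:
            h = _numeric_hessian(theta, s_samp, a_idx, cov_idx)
            cov_theta = 2.0 / (n - 1) * np.linalg.inv(h)
            dvar = np.diag(cov_theta)
            se = np.sqrt(np.where(dvar > 0, dvar, np.nan))
        except np.linalg.LinAlgError:
            pass

    edge_index = pd.MultiIndex.from_tuples(model.all_edges)
    return SemFit(
        model=model,
        path_coefficients=pd.Series(theta[:n_a], index=edge_index),
        path_se=pd.Series(se[:n_a], index=edge_index),
        residual_variances=pd.Series(theta[n_a:n_a + p], index=var),
        input_covariances={(u, v): theta[n_a + p + t] for t, (u, v) in
                           enumerate(itertools.combinations(model.inputs, 2))},
        fml=fml, chi2=float(chi2), df=int(df), srmr=srmr, gfi=gfi,
        rmsea=rmsea, aic=float(aic), n_samples=int(n), n_free=n_free,
        converged=bool(res.success),
    )


def _numeric_hessian(theta, s_samp, a_idx, cov_idx, eps: float = 1e-5):
    k = len(theta)
    h = np.empty((k, k))
    for i in range(k):
        tp, tm = theta.copy(), theta.copy()
        tp[i] += eps
        tm[i] -= eps
        _, gp = _fml_and_grad(tp, s_samp, a_idx, cov_idx)
        _, gm = _fml_and_grad(tm, s_samp, a_idx, cov_idx)
        h[i] = (gp - gm) / (2 * eps)
    return (h + h.T) / 2


def acttime_inputs(session: pd.DataFrame, n_samples: int,
                   sampling_interval: float,
                   hrf: HrfSpec | None = None) -> pd.DataFrame:
    """Response-locked exogenous regressors for the actTime control model.

    Builds two HRF-convolved series on the run grid: the unmodulated main
    effect of responding (unit impulse at every response) and the parametric
    effect (impulses scaled by z-scored observed actTime).  A parametric
    column that is numerically zero after centering is dropped.
    """
    hrf = hrf or HrfSpec()
    dt = float(sampling_interval)
    kernel = hrf_kernel(hrf, dt)
    ok = np.isfinite(session["acttime"].to_numpy(dtype=float))
    resp = (session["trial_onset_in_run"].to_numpy(dtype=float)
            + session["acttime"].to_numpy(dtype=float))[ok]
    att = session["acttime"].to_numpy(dtype=float)[ok]
    if att.std() == 0:
        att_z = np.zeros_like(att)
    else:
        att_z = (att - att.mean()) / att.std()
    main = np.zeros(n_samples)
    param = np.zeros(n_samples)
    for t_ev, a in zip(resp, att_z):
        idx = int(round(t_ev / dt))
        if 0 <= idx < n_samples:
            main[idx] += 1.0
            param[idx] += a
    out = pd.DataFrame({
        "resp_main": np.convolve(main, kernel)[:n_samples],
        "resp_acttime": np.convolve(param, kernel)[:n_samples],
    })
    if np.allclose(out["resp_acttime"] - out["resp_acttime"].mean(), 0.0):
        import warnings
        warnings.warn("parametric actTime input is constant after centering; dropped")
        out = out.drop(columns="resp_acttime")
    return out


def regress_out_acttime_model(model: PathModel,
                              input_columns: tuple[str, ...] = ("resp_main", "resp_acttime"),
                              ) -> PathModel:
    """The actTime control: feed the response-locked inputs to every node."""
    return replace(model, inputs=tuple(input_columns))


@dataclass
class PermutationEnsemble:
    """All ROI-to-position assignments of the circuit and their AICs."""

    assignments: list[tuple[str, ...]]
    aics: np.ndarray
    reference_aic: float
    n_failed: int

    @property
    def percentile(self) -> float:
        """Percentile rank of the reference AIC (midrank for ties)."""
        less = np.sum(self.aics < self.reference_aic)
        ties = np.sum(self.aics == self.reference_aic)
        return float(100.0 * (less + 0.5 * ties) / len(self.aics))


def permute_rois(model: PathModel, data: pd.DataFrame,
                 max_fail_frac: float = 0.05) -> PermutationEnsemble:
    """Fit every assignment of ROI labels to circuit positions.

    The edge template is fixed; the n! label permutations (including the
    identity, whose AIC is the reference) are enumerated exhaustively.
    Assignments whose fit fails are excluded and counted; more than
    ``max_fail_frac`` failures invalidates the ensemble.
    """
    nodes = model.nodes
    ref = fit_path_model(model, data, compute_se=False)
    aics, assignments = [], []
    n_failed = 0
    for perm in itertools.permutations(nodes):
        if perm == tuple(nodes):
            aics.append(ref.aic)
            assignments.append(perm)
            continue
        relabel = dict(zip(nodes, perm))
        pm = replace(model, edges=tuple((relabel[a], relabel[b]) for a, b in model.edges))
        try:
            aics.append(fit_path_model(pm, data, compute_se=False).aic)
            assignments.append(perm)
        except (RuntimeError, ValueError, np.linalg.LinAlgError):
            n_failed += 1
    total = len(aics) + n_failed
    if n_failed > max_fail_frac * total:
        raise RuntimeError(f"{n_failed}/{total} permutation fits failed; ensemble invalid")
    return PermutationEnsemble(assignments=assignments, aics=np.asarray(aics),
                               reference_aic=ref.aic, n_failed=n_failed)
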