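"""End-to-end orchestration: simulate -> timing model -> GLMs -> PPI -> SEM.

Every stage reads its inputs from, and writes its outputs to, a run
directory; a JSON manifest records the effective configuration, all seeds,
and a content hash per output so any number is traceable to config + seed.
Stages are idempotent: re-running one from cached upstream outputs yields
byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io, sem, synth, task, timing, tsglm

__all__ = ["RunConfig", "run_pipeline", "STAGES"]

STAGES = ("simulate", "fit-timing", "glm", "ppi", "sem")


@dataclass
class RunConfig:
    """Configuration for a full synthetic-study run."""

    out_dir: str = "acttime_run"
    n_participants: int = 8
    n_trials: int = 90
    seed: int = 0
    max_abs_corr: float = 0.1
    sampling_interval: float = 1.0     # BOLD sampling (s)
    upsample_interval: float = 0.5     # epoching grid (s)
    epoch_window: tuple[float, float] = (-9.0, 6.0)
    seed_roi: str = "BF"               # PPI seed region
    run_ensemble: bool = False         # all 5040 ROI permutations (slow)
    coupling_scale: float = 1.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        if "epoch_window" in raw:
            raw["epoch_window"] = tuple(raw["epoch_window"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["epoch_window"] = list(self.epoch_window)
        return d


def _participants(cfg: RunConfig) -> list[str]:
    return [f"sub-{i + 1:02d}" for i in range(cfg.n_participants)]


def _paths(cfg: RunConfig) -> dict[str, Path]:
    root = Path(cfg.out_dir)
    return {
        "root": root,
        "sessions": root / "sessions",
        "bold": root / "bold",
        "timing": root / "timing",
        "glm": root / "glm",
        "ppi": root / "ppi",
        "sem": root / "sem",
    }


def stage_simulate(cfg: RunConfig) -> list[Path]:
    """Generate designs, behavioural sessions, and coupled ROI BOLD series."""
    p = _paths(cfg)
    p["sessions"].mkdir(parents=True, exist_ok=True)
    p["bold"].mkdir(parents=True, exist_ok=True)
    spec = task.TaskSpec()
    truth = synth.BehaviorGroundTruth()
    events = synth.default_neural_model()
    coupling = synth.default_coupling(cfg.coupling_scale)
    ss = np.random.SeedSequence(cfg.seed)
    outputs = []
    for part, child in zip(_participants(cfg), ss.spawn(cfg.n_participants)):
        rng = np.random.default_rng(child)
        design = task.generate_design(spec, cfg.n_trials, cfg.max_abs_corr, seed=rng)
        session = synth.simulate_behavior(design, truth, spec, seed=rng,
                                          participant=part)
        bold = synth.simulate_bold(session, events, coupling,
                                   sampling_interval=cfg.sampling_interval,
                                   seed=rng)
        sp = p["sessions"] / f"{part}.csv"
        session.to_csv(sp, index=False)          # keeps ground-truth columns
        outputs += [sp, io.write_roi_series(bold, p["bold"] / f"{part}.tsv")]
    truth_sidecar = p["sessions"] / "ground_truth.json"
    truth_sidecar.write_text(json.dumps({
        "beta": truth.beta,
        "baseline_rates": list(truth.baseline_rates),
        "coupling": {f"{a}->{b}": w for (a, b), w in coupling.edges.items()},
        "events": {k: dataclasses.asdict(v) for k, v in events.items()},
    }, indent=2))
    return outputs + [truth_sidecar]


def stage_fit_timing(cfg: RunConfig) -> list[Path]:
    """Per-participant Cox fits, deterministic actTimes, and PEV summary."""
    p = _paths(cfg)
    p["timing"].mkdir(parents=True, exist_ok=True)
    det_tables, summaries, coef_rows = [], [], []
    for part in _participants(cfg):
        session = pd.read_csv(p["sessions"] / f"{part}.csv")
        fit = timing.fit_cox(session)
        det = timing.deterministic_times(fit, session)
        det.insert(0, "participant", part)
        det.insert(1, "trial", session["trial"].to_numpy())
        det_tables.append(det)
        summaries.append(timing.pev_summary(fit, session))
        for cov in fit.coefficients.index:
            coef_rows.append({"participant": part, "covariate": cov,
                              "coef": fit.coefficients[cov],
                              "se": fit.standard_errors[cov]})
    out1 = p["timing"] / "deterministic_times.tsv"
    pd.concat(det_tables).to_csv(out1, sep="\t", index=False)
    out2 = p["timing"] / "pev_summary.tsv"
    pd.concat(summaries).to_csv(out2, sep="\t", index=False)
    out3 = p["timing"] / "coefficients.tsv"
    pd.DataFrame(coef_rows).to_csv(out3, sep="\t", index=False)
    return [out1, out2, out3]


def _epoched_for(cfg: RunConfig, part: str, roi: str,
                 session: pd.DataFrame) -> tuple[tsglm.EpochedMatrix, pd.DataFrame]:
    p = _paths(cfg)
    bold = io.read_roi_series(p["bold"] / f"{part}.tsv")
    series = tsglm.preprocess(bold[roi].to_numpy(), cfg.sampling_interval,
                              cfg.upsample_interval, roi=roi, participant=part)
    resp = tsglm.responded(session)
    rts = (resp["trial_onset_in_run"] + resp["acttime"]).to_numpy(dtype=float)
    ep = tsglm.epoch(series, rts, cfg.epoch_window)
    return ep, resp.iloc[ep.trial_index]


def stage_glm(cfg: RunConfig) -> list[Path]:
    """Beta time courses (observed and deterministic actTime) + peak tests."""
    p = _paths(cfg)
    p["glm"].mkdir(parents=True, exist_ok=True)
    det_all = pd.read_csv(p["timing"] / "deterministic_times.tsv", sep="\t")
    rois = list(synth.ROI_LABELS)
    long_rows = []
    beta_store: dict[tuple[str, str], dict[str, np.ndarray]] = {}
    epoch_times = None
    for part in _participants(cfg):
        session = pd.read_csv(p["sessions"] / f"{part}.csv")
        det_part = det_all[det_all["participant"] == part].set_index("trial")
        for roi in rois:
            ep, resp = _epoched_for(cfg, part, roi, session)
            det = det_part.loc[resp["trial"].to_numpy()]
            specs = [tsglm.glm_observed(resp),
                     tsglm.glm_deterministic(resp, det)]
            for gspec in specs:
                betas = tsglm.fit_timecourse_glm(ep, gspec)
                epoch_times = betas.index.to_numpy()
                for reg in gspec.of_interest:
                    beta_store.setdefault((gspec.name, reg), {}).setdefault(
                        roi, []).append(betas[reg].to_numpy())
                for reg in betas.columns:
                    for t, b in betas[reg].items():
                        long_rows.append({"participant": part, "roi": roi,
                                          "glm": gspec.name, "regressor": reg,
                                          "epoch_time": t, "beta": b})
    out1 = p["glm"] / "beta_timecourses.tsv"
    pd.DataFrame(long_rows).to_csv(out1, sep="\t", index=False)
    peak_frames = []
    for (glm_name, reg), rois_d in beta_store.items():
        stacks = {roi: np.vstack(v) for roi, v in rois_d.items()}
        for phase in ("full", "early", "late"):
            t = tsglm.loo_peak_tests(stacks, epoch_times, phase)
            t.insert(0, "glm", glm_name)
            t.insert(1, "regressor", reg)
            peak_frames.append(t)
    out2 = p["glm"] / "peak_tests.tsv"
    pd.concat(peak_frames).to_csv(out2, sep="\t", index=False)
    return [out1, out2]


def stage_ppi(cfg: RunConfig) -> list[Path]:
    """PPI with the seed region's BOLD and deterministic actTime."""
    p = _paths(cfg)
    p["ppi"].mkdir(parents=True, exist_ok=True)
    det_all = pd.read_csv(p["timing"] / "deterministic_times.tsv", sep="\t")
    targets = [r for r in synth.ROI_LABELS if r != cfg.seed_roi]
    beta_store: dict[str, list[np.ndarray]] = {r: [] for r in targets}
    epoch_times = None
    for part in _participants(cfg):
        session = pd.read_csv(p["sessions"] / f"{part}.csv")
        det_part = det_all[det_all["participant"] == part].set_index("trial")
        seed_ep, resp = _epoched_for(cfg, part, cfg.seed_roi, session)
        det = det_part.loc[resp["trial"].to_numpy()]
        spec = tsglm.build_ppi_spec(seed_ep, resp, det)
        for roi in targets:
            ep, _ = _epoched_for(cfg, part, roi, session)
            betas = tsglm.fit_timecourse_glm(ep, spec)
            epoch_times = betas.index.to_numpy()
            beta_store[roi].append(betas["PPI"].to_numpy())
    stacks = {roi: np.vstack(v) for roi, v in beta_store.items()}
    out = p["ppi"] / "ppi_peak_tests.tsv"
    tsglm.loo_peak_tests(stacks, epoch_times, "full").to_csv(out, sep="\t", index=False)
    return [out]


def stage_sem(cfg: RunConfig) -> list[Path]:
    """Hypothesised vs reversed vs actTime-regressed-out circuit; optional ensemble."""
    p = _paths(cfg)
    p["sem"].mkdir(parents=True, exist_ok=True)
    frames = {}
    inputs_frames = {}
    for part in _participants(cfg):
        bold = io.read_roi_series(p["bold"] / f"{part}.tsv")
        session = pd.read_csv(p["sessions"] / f"{part}.csv")
        node_df = bold[list(synth.ROI_LABELS)]
        ins = sem.acttime_inputs(session, len(bold), cfg.sampling_interval)
        frames[part] = node_df
        inputs_frames[part] = pd.concat([node_df, ins], axis=1)
    data = sem.prepare_series(frames)
    data_aug = sem.prepare_series(inputs_frames)

    hyp = sem.hypothesized_model()
    fit_h = sem.fit_path_model(hyp, data)
    fit_r = sem.fit_path_model(sem.reverse_model(hyp), data)
    fit_a = sem.fit_path_model(
        sem.regress_out_acttime_model(hyp, tuple(c for c in data_aug if c not in hyp.nodes)),
        data_aug)

    coef = fit_h.summary()
    out1 = p["sem"] / "path_coefficients.tsv"
    coef.to_csv(out1, sep="\t", index=False)
    comparison = {
        "hypothesized": {"aic": fit_h.aic, "fml": fit_h.fml, "srmr": fit_h.srmr,
                         "gfi": fit_h.gfi, "rmsea": fit_h.rmsea, "df": fit_h.df},
        "reversed": {"aic": fit_r.aic, "df": fit_r.df},
        "acttime_regressed_out": {"aic": fit_a.aic, "df": fit_a.df},
        "n_samples": fit_h.n_samples,
    }
    outputs = [out1]
    if cfg.run_ensemble:
        ens = sem.permute_rois(hyp, data)
        out_e = p["sem"] / "ensemble_aics.tsv"
        pd.DataFrame({"assignment": ["-".join(a) for a in ens.assignments],
                      "aic": ens.aics}).to_csv(out_e, sep="\t", index=False)
        comparison["ensemble"] = {"size": len(ens.aics),
                                  "percentile": ens.percentile,
                                  "n_failed": ens.n_failed}
        outputs.append(out_e)
    out2 = p["sem"] / "model_comparison.json"
    out2.write_text(json.dumps(comparison, indent=2))
    return outputs + [out2]


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "fit-timing": stage_fit_timing,
    "glm": stage_glm,
    "ppi": stage_ppi,
    "sem": stage_sem,
}


def run_pipeline(cfg: RunConfig, stages: tuple[str, ...] = STAGES) -> Path:
    """Run the requested stages in order and write the manifest."""
    outputs = []
    for name in stages:
        if name not in _STAGE_FUNCS:
            raise ValueError(f"unknown stage {name!r}; choose from {STAGES}")
        try:
            outputs += _STAGE_FUNCS[name](cfg)
        except Exception as e:
            raise RuntimeError(f"stage {name!r} failed: {e}") from e
    return io.write_manifest(Path(cfg.out_dir), cfg.to_dict(), outputs,
                             extra={"stages": list(stages)})
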