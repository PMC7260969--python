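"""Plain-text table dialects and run metadata.

Behavioural sessions travel as CSV (one row per trial), ROI series as
wide TSV (a ``time`` column plus one column per ROI), beta time courses as
long TSV, and every run directory carries a JSON manifest recording the
effective configuration, seeds, and a hash per output file.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

SESSION_COLUMNS = [
    "participant", "trial", "trial_onset_in_run", "reward_magnitude",
    "last_bubble_prob", "noise_level", "prev_outcome", "prev_acttime",
    "acttime", "outcome", "ao_delay",
]


def write_session(session: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    session[SESSION_COLUMNS].to_csv(path, index=False)
    return path


def read_session(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in SESSION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"session table {path} lacks columns {missing}")
    return df


def write_roi_series(series: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    series.to_csv(path, sep="\t", index=False, float_format="%.6f")
    return path


def read_roi_series(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "time" not in df.columns:
        raise ValueError(f"ROI series {path} lacks a 'time' column")
    return df


def validate_inputs(session_path: str | Path | None = None,
                    roi_path: str | Path | None = None,
                    trial_duration: float = 20.0) -> list[str]:
    """Schema and unit sanity checks; returns a list of problems (empty = ok)."""
    problems: list[str] = []
    if session_path is not None:
        p = Path(session_path)
        if not p.exists():
            return [f"missing session file: {p}"]
        try:
            s = read_session(p)
        except ValueError as e:
            return [str(e)]
        att = s["acttime"].to_numpy(dtype=float)
        bad = np.flatnonzero(np.isfinite(att) & ((att <= 0) | (att > trial_duration)))
        if bad.size:
            problems.append(
                f"actTime outside (0, {trial_duration}] at rows {bad[:5].tolist()}")
        for part, grp in s.groupby("participant"):
            tr = grp["trial"].to_numpy()
            if not np.array_equal(tr, np.arange(tr[0], tr[0] + len(tr))):
                problems.append(f"non-consecutive trial indices for {part}")
    if roi_path is not None:
        p = Path(roi_path)
        if not p.exists():
            return problems + [f"missing ROI series file: {p}"]
        r = read_roi_series(p)
        t = r["time"].to_numpy(dtype=float)
        d = np.diff(t)
        if len(d) and not np.allclose(d, d[0]):
            first = int(np.flatnonzero(~np.isclose(d, d[0]))[0])
            problems.append(f"irregular sampling: first offending interval at index {first}")
    return problems


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(out_dir: str | Path, config: dict, outputs: list[Path],
                   extra: dict | None = None) -> Path:
    out_dir = Path(out_dir)
    manifest = {
        "config": config,
        "outputs": {str(p.relative_to(out_dir)): file_sha256(p) for p in outputs},
    }
    if extra:
        manifest.update(extra)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return path
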