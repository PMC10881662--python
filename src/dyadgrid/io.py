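"""CSV/JSON readers and writers for all pipeline artifacts.

Everything is plain text: the long-format trials table (one row per dyad
trial), a cohort sidecar (type, gender, ages), square dissimilarity
matrices, linkage merge tables, cluster label tables, and a nested JSON
statistics report. Every writer has a matching reader and round-trips
exactly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .task_core import (
    MISSING,
    TaskConfig,
    DyadTrajectory,
    TrialRecord,
    ValidationError,
)
from .gsa import ClusterSolution, DissimilarityMatrix

__all__ = [
    "TRIAL_COLUMNS",
    "write_trials",
    "read_trials",
    "write_cohort_meta",
    "read_cohort_meta",
    "write_dissimilarity",
    "read_dissimilarity",
    "write_linkage",
    "write_clusters",
    "read_clusters",
    "write_json_report",
]

TRIAL_COLUMNS = (
    "dyad_id", "trial_index", "block_id", "is_fake",
    "sel_a", "sel_b", "disp_a", "disp_b",
    "outcome_a", "outcome_b", "payoff_a", "payoff_b",
)


def _cell(v):
    if v is MISSING:
        return ""
    return str(int(v)) if isinstance(v, (int, np.integer, float)) else str(v)


def write_trials(trajs, path, cfg: Optional[TaskConfig] = None) -> Path:
    """Write trajectories as the long-format trials CSV (MISSING = empty)."""
    path = Path(path)
    lines = [",".join(TRIAL_COLUMNS)]
    for traj in trajs:
        for r in traj.records:
            lines.append(
                ",".join(
                    [
                        r.dyad_id, str(r.trial_index), r.block_id,
                        "1" if r.is_fake else "0",
                        _cell(r.sel_a), _cell(r.sel_b), _cell(r.disp_a), _cell(r.disp_b),
                        r.outcome_a, r.outcome_b, str(r.payoff_a), str(r.payoff_b),
                    ]
                )
            )
    path.write_text("\n".join(lines) + "\n")
    return path


def _parse_opt_int(v):
    if pd.isna(v) or v == "":
        return MISSING
    return int(v)


def read_trials(
    path,
    cfg: Optional[TaskConfig] = None,
    meta: Optional[pd.DataFrame] = None,
    column_map: Optional[dict] = None,
) -> list:
    """Read and validate a long-format trials CSV into trajectories.

    ``column_map`` maps user column names to the canonical schema (for
    externally deposited tables with different headers). ``meta`` is an
    optional frame indexed by dyad_id with gender/age_a/age_b columns. Any
    invariant violation raises with row-level diagnostics.
    """
    cfg = cfg or TaskConfig()
    df = pd.read_csv(path, dtype={"dyad_id": str}, keep_default_na=True)
    if column_map:
        df = df.rename(columns=column_map)
    missing_cols = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"trials file missing columns {missing_cols}")
    dup = df.duplicated(subset=["dyad_id", "trial_index"])
    if dup.any():
        pairs = df.loc[dup, ["dyad_id", "trial_index"]].to_records(index=False)
        raise ValidationError(f"duplicate (dyad, trial) rows: {list(pairs)[:5]}")
    trajs = []
    for dyad_id, g in df.groupby("dyad_id", sort=True):
        g = g.sort_values("trial_index")
        records = [
            TrialRecord(
                dyad_id=str(row.dyad_id),
                trial_index=int(row.trial_index),
                block_id=str(row.block_id),
                is_fake=bool(int(row.is_fake)),
                sel_a=_parse_opt_int(row.sel_a),
                sel_b=_parse_opt_int(row.sel_b),
                disp_a=_parse_opt_int(row.disp_a),
                disp_b=_parse_opt_int(row.disp_b),
                outcome_a=str(row.outcome_a),
                outcome_b=str(row.outcome_b),
                payoff_a=int(row.payoff_a),
                payoff_b=int(row.payoff_b),
            )
            for row in g.itertuples()
        ]
        traj = DyadTrajectory(dyad_id=str(dyad_id), records=records)
        if meta is not None and str(dyad_id) in meta.index:
            m = meta.loc[str(dyad_id)]
            traj.gender = m.get("gender")
            if "age_a" in m and "age_b" in m:
                traj.ages = (float(m["age_a"]), float(m["age_b"]))
        traj.validate(cfg)
        trajs.append(traj)
    return trajs


def write_cohort_meta(trajs, labels, path) -> Path:
    """Sidecar CSV: dyad_id, true_type, gender, age_a, age_b."""
    path = Path(path)
    rows = ["dyad_id,true_type,gender,age_a,age_b"]
    for traj, lab in zip(trajs, labels):
        a, b = traj.ages if traj.ages else ("", "")
        rows.append(f"{traj.dyad_id},{lab},{traj.gender or ''},{a},{b}")
    path.write_text("\n".join(rows) + "\n")
    return path


def read_cohort_meta(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"dyad_id": str}).set_index("dyad_id")


def write_dissimilarity(d: DissimilarityMatrix, path) -> Path:
    """Square dissimilarity CSV with ids as header and index."""
    path = Path(path)
    pd.DataFrame(d.matrix, index=list(d.ids), columns=list(d.ids)).to_csv(
        path, index_label="id"
    )
    return path


def read_dissimilarity(path) -> DissimilarityMatrix:
    df = pd.read_csv(path, index_col="id")
    return DissimilarityMatrix(ids=tuple(df.columns), matrix=df.to_numpy(dtype=float))


def write_linkage(solution: ClusterSolution, path) -> Path:
    """Merge table CSV: step, left, right, height."""
    path = Path(path)
    rows = ["step,left,right,height"]
    for step, (a, b, h) in enumerate(solution.merges):
        rows.append(f"{step},{a},{b},{h!r}")
    path.write_text("\n".join(rows) + "\n")
    return path


def write_clusters(labels: dict, path) -> Path:
    """Cluster membership CSV: id, label."""
    path = Path(path)
    rows = ["id,label"] + [f"{i},{labels[i]}" for i in labels]
    path.write_text("\n".join(rows) + "\n")
    return path


def read_clusters(path) -> dict:
    df = pd.read_csv(path, dtype={"id": str})
    return dict(zip(df["id"], df["label"].astype(int)))


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_json_report(report: dict, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(report, indent=2, default=_jsonable, allow_nan=True) + "\n")
    return path
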