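"""End-to-end pipeline driver: simulate/ingest -> scores -> GSA -> stats.

One configured call (or ``dyadgrid run`` from the shell) produces every
artifact of the analysis in an output directory, plus a manifest capturing
the seed, configuration hash and package version so any run can be
reproduced bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .task_core import BLOCKS, MISSING, TaskConfig
from .synthetic_cohort import CohortSpec, generate_cohort
from .scoring import (
    individual_scores_frame,
    dyad_scores_frame,
    itap_dyad_panel,
)
from .gsa import (
    build_cost_matrix,
    encode_fake_member,
    encode_indistinguishable,
    hierarchical_cluster,
    pairwise_dissimilarity,
    select_k,
)
from .inference import (
    compare_clusters,
    dunn_posthoc,
    gee_block_gender,
    kruskal_wallis,
    posthoc_block_contrasts,
)
from . import io as dio

__all__ = ["PipelineConfig", "run_pipeline", "dyad_block_long"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything a full run needs; defaults reproduce the synthetic study."""

    out_dir: str = "dyadgrid_out"
    trials_path: Optional[str] = None  # ingest instead of simulate when set
    meta_path: Optional[str] = None
    seed: int = 0
    n_per_type: Optional[dict] = None  # simulate only; None = default cohort
    indel: float = 1.0
    method: str = "ward_d"
    k: int = 3
    k_fake: int = 3
    alpha: float = 0.05
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return asdict(self)


def dyad_block_long(dyad_scores: pd.DataFrame, dv: str = "mean") -> pd.DataFrame:
    """Melt the wide dyad-scores frame into the 5-rows-per-dyad GEE table."""
    cols = [f"{dv}_{b}" for b in BLOCKS]
    long = dyad_scores.melt(
        id_vars=["dyad_id", "gender"], value_vars=cols,
        var_name="block", value_name="value",
    )
    long["block"] = long["block"].str.removeprefix(f"{dv}_")
    return long


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


def run_pipeline(cfg: PipelineConfig, task_cfg: Optional[TaskConfig] = None) -> dict:
    """Run the whole analysis; returns artifact paths and key results.

    Stages: simulate (or ingest) trials -> individual/dyad scoring -> GSA in
    both grid modes -> Ward clustering -> manipulation-check GEEs, outcome
    Kruskal-Wallis, and cluster comparisons. Idempotent under a fixed seed.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    task_cfg = task_cfg or TaskConfig()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts = {}

    # --- trials -----------------------------------------------------------
    true_labels = None
    if cfg.trials_path:
        meta = dio.read_cohort_meta(cfg.meta_path) if cfg.meta_path else None
        trajs = _stage("ingest")(dio.read_trials)(cfg.trials_path, task_cfg, meta)
    else:
        spec = CohortSpec(seed=cfg.seed) if cfg.n_per_type is None else CohortSpec(
            n_per_type=cfg.n_per_type, seed=cfg.seed
        )
        trajs, true_labels = _stage("simulate")(generate_cohort)(spec, task_cfg)
        artifacts["trials"] = dio.write_trials(trajs, out / "trials.csv", task_cfg)
        artifacts["cohort_meta"] = dio.write_cohort_meta(
            trajs, true_labels, out / "cohort_meta.csv"
        )

    # --- scoring ----------------------------------------------------------
    ind = _stage("scoring")(individual_scores_frame)(trajs, task_cfg)
    dyad = _stage("scoring")(dyad_scores_frame)(trajs, task_cfg)
    ind.to_csv(out / "individual_scores.csv", index=False)
    dyad.to_csv(out / "dyad_scores.csv", index=False)
    artifacts["individual_scores"] = out / "individual_scores.csv"
    artifacts["dyad_scores"] = out / "dyad_scores.csv"

    # --- GSA, interactive (indistinguishable, dyad level) -----------------
    seqs = [encode_indistinguishable(t, task_cfg) for t in trajs]
    cost = build_cost_matrix("indistinguishable", cfg.indel)
    dmat = _stage("gsa")(pairwise_dissimilarity)(seqs, cost)
    solution = _stage("cluster")(hierarchical_cluster)(dmat, cfg.method, cfg.k)
    artifacts["dissimilarity"] = dio.write_dissimilarity(dmat, out / "dissimilarity.csv")
    artifacts["linkage"] = dio.write_linkage(solution, out / "linkage.csv")
    artifacts["clusters"] = dio.write_clusters(solution.labels, out / "clusters.csv")

    # --- GSA, fake block (distinguishable, member level) -------------------
    fake_seqs = [
        encode_fake_member(t, m, task_cfg) for t in trajs for m in ("a", "b")
    ]
    fake_cost = build_cost_matrix("distinguishable", cfg.indel)
    fake_dmat = _stage("gsa_fake")(pairwise_dissimilarity)(fake_seqs, fake_cost)
    fake_solution = _stage("cluster_fake")(hierarchical_cluster)(
        fake_dmat, cfg.method, cfg.k_fake
    )
    artifacts["fake_dissimilarity"] = dio.write_dissimilarity(
        fake_dmat, out / "fake_dissimilarity.csv"
    )
    artifacts["fake_linkage"] = dio.write_linkage(fake_solution, out / "fake_linkage.csv")
    artifacts["fake_clusters"] = dio.write_clusters(
        fake_solution.labels, out / "fake_clusters.csv"
    )
    fake_summary = summarize_fake_clusters(trajs, fake_solution.labels, task_cfg)

    # --- inference --------------------------------------------------------
    report = {"config": cfg.to_dict(), "k_recommended": select_k(solution)}
    gees = {}
    if dyad["gender"].notna().all() and dyad["gender"].nunique() == 2:
        for dv in ("mean", "diff"):
            long = dyad_block_long(dyad, dv)
            gee = _stage("gee")(gee_block_gender)(long)
            gees[dv] = gee
            report[f"gee_dyad_{dv}"] = gee.to_dict()
        report["posthoc_blocks_mean"] = [
            t.to_dict() for t in posthoc_block_contrasts(gees["mean"])
        ]
    else:
        logger.warning("gender missing or single-level; GEE manipulation check skipped")

    groups = [
        ind[c].dropna().to_numpy()
        for c in ("mean_after_win", "mean_after_loss", "mean_after_tie")
    ]
    kw = kruskal_wallis(groups, name="kw_outcome_conditioned")
    report["kw_outcome_conditioned"] = kw.to_dict()
    if np.isfinite(kw.p):
        report["dunn_outcome"] = [
            t.to_dict()
            for t in dunn_posthoc(groups, labels=("win", "loss", "tie"))
        ]

    panel = itap_dyad_panel(trajs, task_cfg)
    gender_map = {t.dyad_id: t.gender for t in trajs}
    comparison = _stage("compare")(compare_clusters)(
        solution.labels, panel,
        gender=gender_map if all(gender_map.values()) else None,
        alpha=cfg.alpha,
    )
    report["cluster_comparison"] = comparison.to_dict()
    report["fake_cluster_summary"] = fake_summary
    comparison.panel.to_csv(out / "radar_panels.csv", index_label="cluster")
    artifacts["radar_panels"] = out / "radar_panels.csv"
    artifacts["stats_report"] = dio.write_json_report(report, out / "stats_report.json")

    # --- manifest ---------------------------------------------------------
    cfg_json = json.dumps(cfg.to_dict(), sort_keys=True)
    manifest = {
        "package": "dyadgrid",
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "artifacts": {k: str(v) for k, v in artifacts.items()},
    }
    artifacts["manifest"] = dio.write_json_report(manifest, out / "manifest.json")

    return {
        "artifacts": artifacts,
        "trajectories": trajs,
        "true_labels": true_labels,
        "solution": solution,
        "fake_solution": fake_solution,
        "report": report,
    }


def summarize_fake_clusters(trajs, fake_labels: dict, task_cfg: TaskConfig) -> dict:
    """Per-cluster mean/SD of members' fake-trial selections plus the count
    of dyads whose two members fall into different fake clusters."""
    rows = []
    for t in trajs:
        for m in ("a", "b"):
            sels = [
                t.selections(m)[i - 1]
                for i in task_cfg.trials_in_block("FAKE")
                if t.selections(m)[i - 1] is not MISSING
            ]
            rows.append(
                {
                    "dyad_id": t.dyad_id,
                    "member": m,
                    "cluster": fake_labels[f"{t.dyad_id}:{m}"],
                    "fake_mean": float(np.mean(sels)) if sels else float("nan"),
                }
            )
    df = pd.DataFrame(rows)
    by = df.groupby("cluster")["fake_mean"]
    split = int(
        (df.pivot(index="dyad_id", columns="member", values="cluster")
           .apply(lambda r: r["a"] != r["b"], axis=1)).sum()
    )
    return {
        "cluster_means": {int(c): float(v) for c, v in by.mean().items()},
        "cluster_sds": {int(c): float(v) for c, v in by.std(ddof=1).items()},
        "cluster_sizes": {int(c): int(v) for c, v in by.count().items()},
        "split_pair_count": split,
        "n_dyads": df["dyad_id"].nunique(),
    }
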