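"""Derived aggression scores and questionnaire scoring.

Individual scores: per-block mean selections (the five blocks B1, B2, FAKE,
B3, B4), the mean over the 60 interactive trials, zero-selection counts,
the pre-post difference around the fake block, and selection means
conditioned on the previous trial's outcome. Dyad scores: per-block mean and
absolute difference of the two members' block means. Questionnaires: polarity-
aware sum scores with mean imputation, and Cronbach's alpha.

Undefined quantities (e.g. an all-missing block) are returned as NaN and
recorded in the ``flags`` field rather than silently zeroed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .task_core import (
    BLOCKS,
    LOSS,
    MISSING,
    TIE,
    WIN,
    TaskConfig,
    DyadTrajectory,
    ValidationError,
)

__all__ = [
    "IndividualScores",
    "DyadScores",
    "SubscaleScore",
    "block_mean_scores",
    "dyad_block_scores",
    "derived_scores",
    "outcome_conditioned_means",
    "individual_scores",
    "score_subscale",
    "cronbach_alpha",
    "individual_scores_frame",
    "dyad_scores_frame",
    "itap_dyad_panel",
    "ITAP_PANEL_VARS",
]


@dataclass
class IndividualScores:
    """All derived per-member scores for one dyad member."""

    dyad_id: str
    member: str
    block_means: dict
    interactive_mean: float
    zero_interactive: int
    zero_fake: int
    pre_post_diff: float
    outcome_means: dict
    flags: tuple = ()


@dataclass
class DyadScores:
    """Per-block dyad mean and absolute difference of the members' means."""

    dyad_id: str
    dyad_mean: dict
    dyad_diff: dict
    total_mean: float
    total_diff: float
    flags: tuple = ()


@dataclass
class SubscaleScore:
    """Polarity-aware sum score for one respondent on one subscale."""

    respondent: object
    instrument: str
    subscale: str
    score: float
    n_imputed: int
    flags: tuple = ()


def _mean_or_nan(values, flags, label):
    vals = [v for v in values if v is not MISSING]
    if not vals:
        flags.append(f"undefined:{label}")
        return float("nan")
    return float(np.mean(vals))


def block_mean_scores(traj: DyadTrajectory, member: str, cfg: Optional[TaskConfig] = None):
    """Mean selection per block (5 entries) plus the interactive-trials mean.

    Missing selections are excluded; an all-missing block yields NaN and a
    flag. Returns ``(block_means, interactive_mean, flags)``.
    """
    cfg = cfg or TaskConfig()
    sels = traj.selections(member)
    flags: list = []
    block_means = {
        b: _mean_or_nan(
            [sels[t - 1] for t in cfg.trials_in_block(b)], flags, f"{member}:block:{b}"
        )
        for b in BLOCKS
    }
    interactive = [s for r, s in zip(traj.records, sels) if not r.is_fake]
    interactive_mean = _mean_or_nan(interactive, flags, f"{member}:interactive")
    return block_means, interactive_mean, tuple(flags)


def dyad_block_scores(traj: DyadTrajectory, cfg: Optional[TaskConfig] = None) -> DyadScores:
    """Per block: mean of the two members' block means, and their absolute
    difference; plus averages of both across the five blocks."""
    cfg = cfg or TaskConfig()
    bm_a, _, fl_a = block_mean_scores(traj, "a", cfg)
    bm_b, _, fl_b = block_mean_scores(traj, "b", cfg)
    dyad_mean = {b: (bm_a[b] + bm_b[b]) / 2.0 for b in BLOCKS}
    dyad_diff = {b: abs(bm_a[b] - bm_b[b]) for b in BLOCKS}
    return DyadScores(
        dyad_id=traj.dyad_id,
        dyad_mean=dyad_mean,
        dyad_diff=dyad_diff,
        total_mean=float(np.mean(list(dyad_mean.values()))),
        total_diff=float(np.mean(list(dyad_diff.values()))),
        flags=fl_a + fl_b,
    )


def derived_scores(traj: DyadTrajectory, member: str, cfg: Optional[TaskConfig] = None):
    """Zero-selection counts and the pre-post difference around the fake block.

    ``pre_post_diff`` = mean over the 30 trials before the fake block minus
    the mean over the 30 trials after it. Returns
    ``(zero_interactive, zero_fake, pre_post_diff, flags)``.
    """
    cfg = cfg or TaskConfig()
    sels = traj.selections(member)
    flags: list = []
    pre = [sels[t - 1] for b in ("B1", "B2") for t in cfg.trials_in_block(b)]
    post = [sels[t - 1] for b in ("B3", "B4") for t in cfg.trials_in_block(b)]
    pre_post = _mean_or_nan(pre, flags, f"{member}:pre") - _mean_or_nan(
        post, flags, f"{member}:post"
    )
    zero_inter = sum(
        1 for r, s in zip(traj.records, sels) if not r.is_fake and s == 0
    )
    zero_fake = sum(1 for r, s in zip(traj.records, sels) if r.is_fake and s == 0)
    return zero_inter, zero_fake, float(pre_post), tuple(flags)


def outcome_conditioned_means(traj: DyadTrajectory, member: str):
    """Mean selection grouped by the member's own previous-trial outcome.

    The first trial has no preceding outcome and is excluded, so the three
    groups partition trials 2..65. Empty groups yield NaN with a flag.
    Returns ``(outcome_means, group_sizes, flags)``.
    """
    sels = traj.selections(member)
    attr = "outcome_a" if member == "a" else "outcome_b"
    groups = {WIN: [], LOSS: [], TIE: []}
    for prev, rec in zip(traj.records[:-1], traj.records[1:]):
        s = sels[rec.trial_index - 1]
        if s is not MISSING:
            groups[getattr(prev, attr)].append(s)
    flags: list = []
    means = {o: _mean_or_nan(v, flags, f"{member}:after:{o}") for o, v in groups.items()}
    sizes = {o: len(v) for o, v in groups.items()}
    return means, sizes, tuple(flags)


def individual_scores(
    traj: DyadTrajectory, member: str, cfg: Optional[TaskConfig] = None
) -> IndividualScores:
    """Assemble the full per-member score panel."""
    cfg = cfg or TaskConfig()
    block_means, inter_mean, f1 = block_mean_scores(traj, member, cfg)
    zero_inter, zero_fake, pre_post, f2 = derived_scores(traj, member, cfg)
    outcome_means, _, f3 = outcome_conditioned_means(traj, member)
    return IndividualScores(
        dyad_id=traj.dyad_id,
        member=member,
        block_means=block_means,
        interactive_mean=inter_mean,
        zero_interactive=zero_inter,
        zero_fake=zero_fake,
        pre_post_diff=pre_post,
        outcome_means=outcome_means,
        flags=f1 + f2 + f3,
    )


def score_subscale(
    items: pd.DataFrame,
    polarity: Sequence[bool],
    scale_min: float,
    scale_max: float,
    instrument: str = "",
    subscale: str = "",
) -> list:
    """Polarity-aware sum scores with within-respondent mean imputation.

    ``items`` is respondents x items; ``polarity[j]`` is True for a reversed
    item, mapped x -> (scale_min + scale_max - x) before scoring. Missing
    items are imputed with the respondent's mean over the subscale's
    non-missing (post-reversal) items. An all-missing respondent is flagged
    undefined (NaN score).
    """
    items = pd.DataFrame(items)
    if len(polarity) != items.shape[1]:
        raise ValidationError("polarity flags must match the number of items")
    vals = items.to_numpy(dtype=float)
    rev = np.asarray(polarity, dtype=bool)
    vals[:, rev] = scale_min + scale_max - vals[:, rev]
    out = []
    for resp, row in zip(items.index, vals):
        miss = np.isnan(row)
        if miss.all():
            out.append(
                SubscaleScore(resp, instrument, subscale, float("nan"),
                              int(miss.sum()), ("undefined:all_items_missing",))
            )
            continue
        filled = np.where(miss, np.nanmean(row), row)
        out.append(
            SubscaleScore(resp, instrument, subscale, float(filled.sum()), int(miss.sum()))
        )
    return out


def cronbach_alpha(items: pd.DataFrame) -> float:
    """Cronbach's alpha for internal consistency, with listwise deletion.

    alpha = k/(k-1) * (1 - sum of item variances / variance of sum scores),
    sample variances (ddof=1). Requires >=2 items and >=3 complete rows;
    zero total variance is undefined (NaN).
    """
    items = pd.DataFrame(items).dropna(axis=0, how="any")
    n, k = items.shape
    if k < 2:
        raise ValidationError("Cronbach's alpha needs at least 2 items")
    if n < 3:
        raise ValidationError("Cronbach's alpha needs at least 3 complete respondents")
    item_vars = items.var(axis=0, ddof=1).to_numpy()
    total_var = items.sum(axis=1).var(ddof=1)
    if total_var == 0:
        return float("nan")
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))


# ---------------------------------------------------------------------------
# Batch frames for cohorts

def individual_scores_frame(trajs, cfg: Optional[TaskConfig] = None) -> pd.DataFrame:
    """One row per member of each dyad with every individual score."""
    cfg = cfg or TaskConfig()
    rows = []
    for traj in trajs:
        for m in ("a", "b"):
            s = individual_scores(traj, m, cfg)
            row = {"dyad_id": s.dyad_id, "member": m}
            row.update({f"mean_{b}": s.block_means[b] for b in BLOCKS})
            row.update(
                interactive_mean=s.interactive_mean,
                zero_interactive=s.zero_interactive,
                zero_fake=s.zero_fake,
                pre_post_diff=s.pre_post_diff,
                mean_after_win=s.outcome_means[WIN],
                mean_after_loss=s.outcome_means[LOSS],
                mean_after_tie=s.outcome_means[TIE],
            )
            rows.append(row)
    return pd.DataFrame(rows)


def dyad_scores_frame(trajs, cfg: Optional[TaskConfig] = None) -> pd.DataFrame:
    """One row per dyad with per-block dyad means/differences (long on block
    via suffixed columns)."""
    cfg = cfg or TaskConfig()
    rows = []
    for traj in trajs:
        d = dyad_block_scores(traj, cfg)
        row = {"dyad_id": d.dyad_id, "gender": traj.gender}
        row.update({f"mean_{b}": d.dyad_mean[b] for b in BLOCKS})
        row.update({f"diff_{b}": d.dyad_diff[b] for b in BLOCKS})
        row.update(total_mean=d.total_mean, total_diff=d.total_diff)
        rows.append(row)
    return pd.DataFrame(rows)


#: The seven dyad-level task scores used for cluster characterization:
#: dyad mean/difference over interactive trials, over fake trials, of the
#: zero-selection count, and the dyad mean pre-post difference.
ITAP_PANEL_VARS = (
    "m_inter", "d_inter", "m_fake", "d_fake", "m_zero", "d_zero", "m_prepost",
)


def itap_dyad_panel(trajs, cfg: Optional[TaskConfig] = None) -> pd.DataFrame:
    """Dyad-level panel of the seven task scores, indexed by dyad_id."""
    cfg = cfg or TaskConfig()
    rows = []
    for traj in trajs:
        vals = {}
        per_member = {}
        for m in ("a", "b"):
            _, inter_mean, _ = block_mean_scores(traj, m, cfg)
            zi, zf, pp, _ = derived_scores(traj, m, cfg)
            fake = [
                traj.selections(m)[t - 1]
                for t in cfg.trials_in_block("FAKE")
                if traj.selections(m)[t - 1] is not MISSING
            ]
            per_member[m] = dict(
                inter=inter_mean,
                fake=float(np.mean(fake)) if fake else float("nan"),
                zero=zi + zf,
                prepost=pp,
            )
        a, b = per_member["a"], per_member["b"]
        vals = dict(
            dyad_id=traj.dyad_id,
            m_inter=(a["inter"] + b["inter"]) / 2.0,
            d_inter=abs(a["inter"] - b["inter"]),
            m_fake=(a["fake"] + b["fake"]) / 2.0,
            d_fake=abs(a["fake"] - b["fake"]),
            m_zero=(a["zero"] + b["zero"]) / 2.0,
            d_zero=abs(a["zero"] - b["zero"]),
            m_prepost=(a["prepost"] + b["prepost"]) / 2.0,
        )
        rows.append(vals)
    return pd.DataFrame(rows).set_index("dyad_id")
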