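"""Synthetic dyad cohorts with tit-for-tat reciprocity dynamics.

Each simulated member follows a linear reciprocity rule: the next selection
mixes a personal baseline (decaying after the provocation block when
de-escalation is active) with the punishment just displayed by the opponent,
plus a loss-reactivity bump and Gaussian noise, quantized to the 10-level
scale. The rule is the simplest mechanism that reproduces the phenomena the
task is built to elicit — tit-for-tat convergence, escalation under the
scripted provocation, and a reciprocal decline in the final block.

Cohorts plant three dyad types (both-low, both-high, mixed) so that the
downstream grid-sequence clustering has a known ground truth to recover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .task_core import (
    LOSS,
    MISSING,
    TaskConfig,
    DyadTrajectory,
    TrialRecord,
    ValidationError,
    build_outcome_schedule,
    settle_trial,
)

__all__ = [
    "AgentParams",
    "CohortSpec",
    "default_templates",
    "quantize",
    "simulate_dyad",
    "generate_cohort",
]


@dataclass(frozen=True)
class AgentParams:
    """Behavioral parameters of one simulated member.

    b      baseline punishment selection (cents, 0..90)
    rho    reciprocity weight in [0,1]; 1 = pure tit-for-tat
    gamma  loss reactivity (cents added after losing a trial)
    delta  de-escalation rate (cents/trial, applied after the fake block ends)
    sigma  pre-quantization Gaussian noise SD (cents)
    """

    b: float = 40.0
    rho: float = 0.3
    gamma: float = 0.0
    delta: float = 0.0
    sigma: float = 5.0

    def __post_init__(self):
        if not 0.0 <= self.b <= 90.0:
            raise ValidationError(f"baseline b={self.b} outside [0, 90]")
        if not 0.0 <= self.rho <= 1.0:
            raise ValidationError(f"reciprocity rho={self.rho} outside [0, 1]")
        for name in ("gamma", "delta", "sigma"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")


def default_templates() -> dict:
    """Planted dyad-type parameter templates (pairs of AgentParams).

    both_low pairs hover near 10 cents, both_high near 75 cents; mixed pairs
    couple a high-baseline member (70) with a low-baseline one (20), kept
    apart by a weak reciprocity weight. All carry a small loss-reactivity
    bump and post-provocation de-escalation.
    """
    low = AgentParams(b=10.0, rho=0.3, gamma=5.0, delta=0.2, sigma=5.0)
    high = AgentParams(b=75.0, rho=0.4, gamma=5.0, delta=0.5, sigma=5.0)
    mixed_hi = AgentParams(b=70.0, rho=0.2, gamma=5.0, delta=0.4, sigma=5.0)
    mixed_lo = AgentParams(b=20.0, rho=0.2, gamma=5.0, delta=0.1, sigma=5.0)
    return {
        "both_low": (low, low),
        "both_high": (high, high),
        "mixed": (mixed_hi, mixed_lo),
    }


@dataclass(frozen=True)
class CohortSpec:
    """Cohort composition: dyads per planted type, templates, seed."""

    n_per_type: dict = field(default_factory=lambda: {"both_low": 10, "both_high": 10, "mixed": 8})
    templates: dict = field(default_factory=default_templates)
    seed: int = 0
    p_nonresponse: float = 0.0
    male_pair_fraction: float = 13.0 / 28.0  # observed cohort composition

    def __post_init__(self):
        for t, n in self.n_per_type.items():
            if t not in self.templates:
                raise ValidationError(f"no parameter template for dyad type {t!r}")
            if n < 2:
                raise ValidationError(f"need at least 2 dyads per type, got {n} for {t!r}")
        if not 0.0 <= self.p_nonresponse < 1.0:
            raise ValidationError("p_nonresponse must lie in [0, 1)")


def quantize(x: float) -> int:
    """Clip to [0, 90] then round half-up to the nearest multiple of 10."""
    x = min(90.0, max(0.0, x))
    return int(math.floor(x / 10.0 + 0.5)) * 10


def simulate_dyad(
    params_a: AgentParams,
    params_b: AgentParams,
    cfg: Optional[TaskConfig] = None,
    seed: int = 0,
    dyad_id: str = "dyad",
    gender: Optional[str] = None,
    ages: Optional[tuple] = None,
    p_nonresponse: float = 0.0,
) -> DyadTrajectory:
    """Simulate one dyad's 65-trial session.

    Selection dynamics for member i with displayed punishment d_i(t) and
    outcome o_i(t) at trial t (epsilon ~ N(0, sigma); q = clip + round to
    scale)::

        s_i(1)   = q(b_i + eps)
        s_i(t+1) = q((1-rho_i) * (b_i - delta_i * max(0, t - fake_end))
                    + rho_i * d_i(t) + gamma_i * [o_i(t) = LOSS] + eps)

    Fake trials display the scripted provocation levels to both members.
    Fully reproducible given the seed.
    """
    cfg = cfg or TaskConfig()
    rng = np.random.default_rng(seed)
    schedule = build_outcome_schedule(cfg)
    records = []
    prev_disp = {"a": None, "b": None}
    prev_outcome = {"a": None, "b": None}
    params = {"a": params_a, "b": params_b}

    for t in range(1, cfg.n_trials + 1):
        sels = {}
        for m in ("a", "b"):
            p = params[m]
            eps = rng.normal(0.0, p.sigma) if p.sigma > 0 else 0.0
            if t == 1:
                x = p.b + eps
            else:
                drift_b = p.b - p.delta * max(0, (t - 1) - cfg.fake_end)
                d = prev_disp[m]
                recip = p.rho * d if d is not None else 0.0
                base_w = (1.0 - p.rho) if d is not None else 1.0
                x = (
                    base_w * drift_b
                    + recip
                    + (p.gamma if prev_outcome[m] == LOSS else 0.0)
                    + eps
                )
            sels[m] = quantize(x)
        if p_nonresponse > 0.0:
            for m in ("a", "b"):
                if rng.random() < p_nonresponse:
                    sels[m] = MISSING
        oa, ob, pa, pb = settle_trial(sels["a"], sels["b"], schedule[t - 1], cfg)
        if cfg.is_fake(t):
            script = cfg.fake_levels[t - cfg.fake_start]
            da = db = script
        else:
            da, db = sels["b"], sels["a"]
        records.append(
            TrialRecord(
                dyad_id, t, cfg.block_of(t), cfg.is_fake(t),
                sels["a"], sels["b"], da, db, oa, ob, pa, pb,
            )
        )
        prev_disp = {"a": da, "b": db}
        prev_outcome = {"a": oa, "b": ob}

    traj = DyadTrajectory(dyad_id=dyad_id, records=records, gender=gender, ages=ages)
    traj.validate(cfg)
    return traj


def generate_cohort(spec: Optional[CohortSpec] = None, cfg: Optional[TaskConfig] = None):
    """Generate a cohort of dyad trajectories with ground-truth type labels.

    Returns ``(trajectories, labels)`` with labels aligned to trajectories.
    Pair gender and member ages are drawn to match the study cohort's
    composition (13/28 male pairs; ages ~N(23.4, 3.4) clipped to 18-35 with
    within-pair gaps below 5 years) and are independent of planted type.
    Deterministic under ``spec.seed``.
    """
    spec = spec or CohortSpec()
    cfg = cfg or TaskConfig()
    n_total = sum(spec.n_per_type.values())
    root = np.random.SeedSequence(spec.seed)
    meta_rng = np.random.default_rng(root.spawn(1)[0])
    dyad_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(n_total + 1)[1:]]

    n_male = int(round(spec.male_pair_fraction * n_total))
    genders = np.array(["male_pair"] * n_male + ["female_pair"] * (n_total - n_male))
    meta_rng.shuffle(genders)

    trajectories, labels = [], []
    i = 0
    for dtype, n in spec.n_per_type.items():
        pa, pb = spec.templates[dtype]
        for _ in range(n):
            age_a = float(np.clip(meta_rng.normal(23.39, 3.42), 18.0, 33.0))
            gap = float(np.clip(abs(meta_rng.normal(2.3, 1.41)), 0.0, 5.0))
            sign = 1.0 if meta_rng.random() < 0.5 else -1.0
            age_b = float(np.clip(age_a + sign * gap, 18.0, 35.0))
            ages = (round(age_a, 1), round(age_b, 1))
            traj = simulate_dyad(
                pa, pb, cfg,
                seed=dyad_seeds[i],
                dyad_id=f"D{i + 1:02d}",
                gender=str(genders[i]),
                ages=ages,
                p_nonresponse=spec.p_nonresponse,
            )
            trajectories.append(traj)
            labels.append(dtype)
            i += 1
    return trajectories, labels
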