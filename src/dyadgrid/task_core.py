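"""Rules and data model of the interactive Taylor Aggression Paradigm (iTAP).

Two siblings play 65 trials of a rigged rock-paper-scissors competition. At
each trial both members pre-select the monetary punishment (0-90 cents in
steps of 10) the opponent forfeits on losing; the winner of a trial gains a
fixed amount, the loser loses the winner's selection. Trial outcomes are
scheduled (equal proportions of win/loss/tie per interactive block, fixed
order across dyads). A scripted "fake block" of five trials in the middle
shows escalating punishments (30-50-50-60-70 cents) as the opponent's
ostensible choices, injecting a provocation manipulation.

This module encodes those rules — scale, payoffs, outcome schedule, fake
script, block structure — as the shared data model for both simulated and
ingested sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

__all__ = [
    "MISSING",
    "WIN",
    "LOSS",
    "TIE",
    "WIN_A",
    "WIN_B",
    "BLOCKS",
    "TaskError",
    "ValidationError",
    "TaskConfig",
    "TrialRecord",
    "DyadTrajectory",
    "settle_trial",
    "build_outcome_schedule",
    "trajectory_from_selections",
]

#: Sentinel for a non-response (no punishment selected within the window).
MISSING = None

# Per-member trial outcomes.
WIN, LOSS, TIE = "WIN", "LOSS", "TIE"
# Scheduled (dyad-level) outcome labels.
WIN_A, WIN_B = "WIN_A", "WIN_B"

#: Block labels in task order; FAKE is the scripted provocation block.
BLOCKS = ("B1", "B2", "FAKE", "B3", "B4")

# Fixed balanced within-block outcome order (5 of each label per 15-trial
# interactive block). The published order is not public; any user-supplied
# order of the correct composition is accepted via TaskConfig.
_DEFAULT_BLOCK_PATTERN = (
    WIN_A, TIE, WIN_B, WIN_A, WIN_B, TIE, TIE, WIN_A,
    WIN_B, WIN_B, WIN_A, TIE, WIN_A, WIN_B, TIE,
)
# Five fake trials cannot split evenly three ways; default keeps the global
# balance as close as possible and is config-overridable.
_DEFAULT_FAKE_PATTERN = (WIN_A, WIN_B, TIE, WIN_A, WIN_B)


class TaskError(Exception):
    """Base error for task-rule violations."""


class ValidationError(TaskError):
    """Input violates a task invariant; message names the offending item."""


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of the iTAP session structure.

    Defaults reproduce the published task: a 10-level punishment scale
    (0..90 cents), four interactive blocks of 15 trials, a five-trial fake
    block before the third interactive block, a 50-cent win gain and a
    100-cent non-response penalty.
    """

    levels: tuple = tuple(range(0, 91, 10))
    n_interactive_blocks: int = 4
    trials_per_block: int = 15
    fake_levels: tuple = (30, 50, 50, 60, 70)
    win_gain: int = 50
    nonresponse_penalty: int = 100
    block_outcome_pattern: tuple = _DEFAULT_BLOCK_PATTERN
    fake_outcome_pattern: tuple = _DEFAULT_FAKE_PATTERN

    def __post_init__(self):
        lv = tuple(self.levels)
        if len(lv) != 10 or lv != tuple(range(0, 91, 10)):
            raise ValidationError("levels must be the 10 values 0,10,...,90")
        if len(self.fake_levels) != 5:
            raise ValidationError("fake block must contain exactly 5 scripted levels")
        if any(f not in lv for f in self.fake_levels):
            raise ValidationError("fake levels must lie on the punishment scale")
        if len(self.block_outcome_pattern) != self.trials_per_block:
            raise ValidationError("block_outcome_pattern length must equal trials_per_block")
        counts = {o: self.block_outcome_pattern.count(o) for o in (WIN_A, WIN_B, TIE)}
        if len(set(counts.values())) != 1:
            raise ValidationError(
                f"block outcome pattern must be balanced, got counts {counts}"
            )
        if len(self.fake_outcome_pattern) != 5:
            raise ValidationError("fake_outcome_pattern must have length 5")

    @property
    def n_trials(self) -> int:
        return self.n_interactive_blocks * self.trials_per_block + len(self.fake_levels)

    @property
    def fake_start(self) -> int:
        """1-based trial index of the first fake trial (31 by default)."""
        return 2 * self.trials_per_block + 1

    @property
    def fake_end(self) -> int:
        """1-based trial index of the last fake trial (35 by default)."""
        return self.fake_start + len(self.fake_levels) - 1

    def block_of(self, trial_index: int) -> str:
        """Block label for a 1-based trial index."""
        if not 1 <= trial_index <= self.n_trials:
            raise ValidationError(f"trial_index {trial_index} out of range 1..{self.n_trials}")
        t, tpb = trial_index, self.trials_per_block
        if t <= tpb:
            return "B1"
        if t <= 2 * tpb:
            return "B2"
        if t <= self.fake_end:
            return "FAKE"
        if t <= self.fake_end + tpb:
            return "B3"
        return "B4"

    def is_fake(self, trial_index: int) -> bool:
        return self.block_of(trial_index) == "FAKE"

    def trials_in_block(self, block: str) -> range:
        """1-based trial indices belonging to a block label."""
        tpb, fs, fe = self.trials_per_block, self.fake_start, self.fake_end
        spans = {
            "B1": range(1, tpb + 1),
            "B2": range(tpb + 1, 2 * tpb + 1),
            "FAKE": range(fs, fe + 1),
            "B3": range(fe + 1, fe + tpb + 1),
            "B4": range(fe + tpb + 1, self.n_trials + 1),
        }
        try:
            return spans[block]
        except KeyError:
            raise ValidationError(f"unknown block label {block!r}") from None


@dataclass
class TrialRecord:
    """One dyad-trial: both members' selections, displays, outcomes, payoffs."""

    dyad_id: str
    trial_index: int
    block_id: str
    is_fake: bool
    sel_a: Optional[int]
    sel_b: Optional[int]
    disp_a: Optional[int]
    disp_b: Optional[int]
    outcome_a: str
    outcome_b: str
    payoff_a: int
    payoff_b: int


@dataclass
class DyadTrajectory:
    """A dyad's full session: 65 ordered trials plus pair-level metadata."""

    dyad_id: str
    records: list = field(default_factory=list)
    gender: Optional[str] = None  # {"male_pair", "female_pair"} when known
    ages: Optional[tuple] = None  # (age_a, age_b) in years

    def validate(self, cfg: TaskConfig) -> None:
        """Check completeness and trial-level invariants; raise on violation."""
        idx = [r.trial_index for r in self.records]
        if sorted(idx) != list(range(1, cfg.n_trials + 1)):
            missing = sorted(set(range(1, cfg.n_trials + 1)) - set(idx))
            dups = sorted({i for i in idx if idx.count(i) > 1})
            raise ValidationError(
                f"dyad {self.dyad_id}: incomplete trajectory"
                + (f", missing trial_index {missing}" if missing else "")
                + (f", duplicate trial_index {dups}" if dups else "")
            )
        if idx != sorted(idx):
            raise ValidationError(f"dyad {self.dyad_id}: records not sorted by trial_index")
        for r in self.records:
            _check_on_scale(r.sel_a, cfg, r.dyad_id, r.trial_index, "a")
            _check_on_scale(r.sel_b, cfg, r.dyad_id, r.trial_index, "b")
            if r.block_id != cfg.block_of(r.trial_index) or r.is_fake != cfg.is_fake(r.trial_index):
                raise ValidationError(
                    f"dyad {self.dyad_id} trial {r.trial_index}: block label/fake flag "
                    f"inconsistent with task structure"
                )
            if r.is_fake:
                script = cfg.fake_levels[r.trial_index - cfg.fake_start]
                if r.disp_a != script or r.disp_b != script:
                    raise ValidationError(
                        f"dyad {self.dyad_id} trial {r.trial_index}: fake trial must "
                        f"display the scripted level {script}"
                    )
            else:
                if r.disp_a != r.sel_b or r.disp_b != r.sel_a:
                    raise ValidationError(
                        f"dyad {self.dyad_id} trial {r.trial_index}: displayed punishment "
                        f"must equal the opponent's selection on interactive trials"
                    )
            if r.outcome_a != TIE or r.outcome_b != TIE:
                if {r.outcome_a, r.outcome_b} != {WIN, LOSS}:
                    raise ValidationError(
                        f"dyad {self.dyad_id} trial {r.trial_index}: non-tie outcomes "
                        f"must be complementary"
                    )

    def selections(self, member: str) -> list:
        """Ordered selections (cents or MISSING) for member 'a' or 'b'."""
        if member not in ("a", "b"):
            raise ValidationError(f"member must be 'a' or 'b', got {member!r}")
        attr = "sel_a" if member == "a" else "sel_b"
        return [getattr(r, attr) for r in self.records]


def _check_on_scale(sel, cfg: TaskConfig, dyad_id, trial_index, member) -> None:
    if sel is not MISSING and sel not in cfg.levels:
        raise ValidationError(
            f"dyad {dyad_id} trial {trial_index} member {member}: selection {sel} "
            f"not on the punishment scale"
        )


def settle_trial(sel_a, sel_b, scheduled: str, cfg: TaskConfig):
    """Resolve one trial into per-member outcomes and payoffs (cents).

    The scheduled outcome applies when both members respond: the winner gains
    ``cfg.win_gain`` and the loser loses the winner's selection; ties transfer
    nothing. A non-responder forfeits ``cfg.nonresponse_penalty`` and loses
    the trial regardless of the schedule, the opponent winning the fixed gain.
    If both fail to respond, both are penalized and the trial is a tie.

    Returns ``(outcome_a, outcome_b, payoff_a, payoff_b)``.
    """
    if scheduled not in (WIN_A, WIN_B, TIE):
        raise ValidationError(f"scheduled outcome must be WIN_A/WIN_B/TIE, got {scheduled!r}")
    _check_on_scale(sel_a, cfg, "?", "?", "a")
    _check_on_scale(sel_b, cfg, "?", "?", "b")
    pen, gain = cfg.nonresponse_penalty, cfg.win_gain
    if sel_a is MISSING and sel_b is MISSING:
        return TIE, TIE, -pen, -pen
    if sel_a is MISSING:
        return LOSS, WIN, -pen, gain
    if sel_b is MISSING:
        return WIN, LOSS, gain, -pen
    if scheduled == TIE:
        return TIE, TIE, 0, 0
    if scheduled == WIN_A:
        return WIN, LOSS, gain, -sel_a
    return LOSS, WIN, -sel_b, gain


def build_outcome_schedule(cfg: TaskConfig) -> list:
    """Deterministic scheduled-outcome sequence over all trials.

    Identical for every dyad; each 15-trial interactive block carries exactly
    five WIN_A, five WIN_B and five TIE labels, the fake block the configured
    five-label pattern.
    """
    schedule = []
    for block in BLOCKS:
        if block == "FAKE":
            schedule.extend(cfg.fake_outcome_pattern)
        else:
            schedule.extend(cfg.block_outcome_pattern)
    return schedule


def trajectory_from_selections(
    dyad_id: str,
    sels_a: Sequence,
    sels_b: Sequence,
    cfg: Optional[TaskConfig] = None,
    gender: Optional[str] = None,
    ages: Optional[tuple] = None,
) -> DyadTrajectory:
    """Build a full trajectory from two ordered selection lists.

    Applies the shared outcome schedule, settles payoffs, and fills displayed
    punishments (opponent's selection on interactive trials, the script on
    fake trials). Useful for constructing ingestion fixtures and for tests.
    """
    cfg = cfg or TaskConfig()
    if len(sels_a) != cfg.n_trials or len(sels_b) != cfg.n_trials:
        raise ValidationError(
            f"dyad {dyad_id}: expected {cfg.n_trials} selections per member, "
            f"got {len(sels_a)}/{len(sels_b)}"
        )
    schedule = build_outcome_schedule(cfg)
    records = []
    for t in range(1, cfg.n_trials + 1):
        sa, sb = sels_a[t - 1], sels_b[t - 1]
        oa, ob, pa, pb = settle_trial(sa, sb, schedule[t - 1], cfg)
        if cfg.is_fake(t):
            disp = cfg.fake_levels[t - cfg.fake_start]
            da = db = disp
        else:
            da, db = sb, sa
        records.append(
            TrialRecord(dyad_id, t, cfg.block_of(t), cfg.is_fake(t), sa, sb, da, db, oa, ob, pa, pb)
        )
    traj = DyadTrajectory(dyad_id=dyad_id, records=records, gender=gender, ages=ages)
    traj.validate(cfg)
    return traj
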