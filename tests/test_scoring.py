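"""Derived aggression scores, subscale scoring, Cronbach's alpha."""

import numpy as np
import pandas as pd
import pytest

from dyadgrid.task_core import BLOCKS, build_outcome_schedule, trajectory_from_selections
from dyadgrid.scoring import (
    block_mean_scores,
    cronbach_alpha,
    derived_scores,
    dyad_block_scores,
    outcome_conditioned_means,
    score_subscale,
)


def constant_traj(cfg, a=30, b=30):
    return trajectory_from_selections("d1", [a] * 65, [b] * 65, cfg)


def test_block_means_constant(cfg):
    bm, inter, flags = block_mean_scores(constant_traj(cfg), "a", cfg)
    assert set(bm) == set(BLOCKS) and len(bm) == 5
    assert all(v == 30 for v in bm.values())
    assert inter == 30 and flags == ()


def test_block_means_step_profile(cfg):
    """0 cents on B1-B2, 90 from the fake block on: block means
    (0,0,90,90,90), interactive mean 45."""
    sels = [0 if t <= 30 else 90 for t in range(1, 66)]
    traj = trajectory_from_selections("d1", sels, [50] * 65, cfg)
    bm, inter, _ = block_mean_scores(traj, "a", cfg)
    assert [bm[b] for b in BLOCKS] == [0, 0, 90, 90, 90]
    assert inter == 45


def test_interactive_mean_is_weighted_block_mean(default_cohort, cfg):
    trajs, _ = default_cohort
    bm, inter, _ = block_mean_scores(trajs[0], "a", cfg)
    expected = np.mean([bm[b] for b in ("B1", "B2", "B3", "B4")])
    assert inter == pytest.approx(expected)


def test_dyad_scores_definition_and_symmetry(cfg):
    traj = trajectory_from_selections("d1", [20] * 65, [40] * 65, cfg)
    d = dyad_block_scores(traj, cfg)
    assert all(d.dyad_mean[b] == 30 for b in BLOCKS)
    assert all(d.dyad_diff[b] == 20 for b in BLOCKS)
    swapped = trajectory_from_selections("d1", [40] * 65, [20] * 65, cfg)
    ds = dyad_block_scores(swapped, cfg)
    assert ds.dyad_mean == d.dyad_mean and ds.dyad_diff == d.dyad_diff


def test_identical_members_zero_diff(cfg):
    d = dyad_block_scores(constant_traj(cfg, 60, 60), cfg)
    assert all(v == 0 for v in d.dyad_diff.values())


def test_derived_scores(cfg):
    sels = [20 if t <= 30 else (20 if 31 <= t <= 35 else 50) for t in range(1, 66)]
    traj = trajectory_from_selections("d1", sels, [50] * 65, cfg)
    _, _, pre_post, _ = derived_scores(traj, "a", cfg)
    assert pre_post == -30

    all_zero = trajectory_from_selections("d1", [0] * 65, [50] * 65, cfg)
    zi, zf, _, _ = derived_scores(all_zero, "a", cfg)
    assert (zi, zf) == (60, 5)

    b1_zero = [0 if t <= 15 else 50 for t in range(1, 66)]
    traj = trajectory_from_selections("d1", b1_zero, [50] * 65, cfg)
    zi, zf, _, _ = derived_scores(traj, "a", cfg)
    assert (zi, zf) == (15, 0)


def test_outcome_conditioned_means(cfg):
    means, sizes, _ = outcome_conditioned_means(constant_traj(cfg, 50, 50), "a")
    assert all(v == 50 for v in means.values())
    assert sum(sizes.values()) == 64  # all trials except the first

    # selections exactly 10 higher after an own loss
    sched = build_outcome_schedule(cfg)
    sels = [50]
    for t in range(2, 66):
        sels.append(60 if sched[t - 2] == "WIN_B" else 50)
    traj = trajectory_from_selections("d1", sels, [50] * 65, cfg)
    means, _, _ = outcome_conditioned_means(traj, "a")
    assert means["LOSS"] == means["WIN"] + 10
    assert means["TIE"] == means["WIN"]


@pytest.mark.parametrize(
    "responses,polarity,expected,imputed",
    [
        ([2, 3, 3], [True, False, False], 4 + 3 + 3, 0),  # reversed 2 -> 4 on 1-5
        ([4, 4, np.nan], [False, False, False], 12.0, 1),  # mean imputation
        ([1, 2, 3], [False, False, False], 6.0, 0),  # plain sum
    ],
)
def test_score_subscale(responses, polarity, expected, imputed):
    items = pd.DataFrame([responses])
    (s,) = score_subscale(items, polarity, 1, 5)
    assert s.score == pytest.approx(expected)
    assert s.n_imputed == imputed


def test_score_subscale_all_missing_flagged():
    (s,) = score_subscale(pd.DataFrame([[np.nan, np.nan]]), [False, False], 1, 5)
    assert np.isnan(s.score) and "undefined:all_items_missing" in s.flags


def test_cronbach_alpha_worked_cases():
    # duplicated identical items -> alpha = 1
    x = pd.DataFrame({"i1": [1, 2, 3, 4], "i2": [1, 2, 3, 4]})
    assert cronbach_alpha(x) == pytest.approx(1.0)
    # sample variances 1, covariance 0.5 -> alpha = 2 (1 - 2/3) = 2/3
    y = pd.DataFrame({"i1": [0, 1, 2], "i2": [1, 0, 2]})
    assert cronbach_alpha(y) == pytest.approx(2.0 / 3.0)


def test_cronbach_alpha_matches_pingouin():
    pingouin = pytest.importorskip("pingouin")
    rng = np.random.default_rng(5)
    base = rng.normal(size=(40, 1))
    items = pd.DataFrame(base + rng.normal(scale=0.8, size=(40, 4)))
    ours = cronbach_alpha(items)
    theirs = pingouin.cronbach_alpha(data=items)[0]
    assert ours == pytest.approx(theirs, abs=1e-10)


def test_alpha_invariant_under_reversal_with_polarity_flag():
    """Reversing an item's storage and flipping its polarity flag leaves the
    polarity-corrected matrix, hence alpha, unchanged."""
    rng = np.random.default_rng(9)
    raw = pd.DataFrame(rng.integers(1, 6, size=(30, 4)).astype(float))
    lo, hi = 1, 5

    def corrected(df, flags):
        out = df.copy()
        for j, f in enumerate(flags):
            if f:
                out.iloc[:, j] = lo + hi - out.iloc[:, j]
        return out

    flags = [False, True, False, False]
    stored = corrected(raw, [False, False, True, False])  # item 2 stored reversed
    flags2 = [False, True, True, False]
    a1 = cronbach_alpha(corrected(raw, flags))
    a2 = cronbach_alpha(corrected(stored, flags2))
    assert a1 == pytest.approx(a2)
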