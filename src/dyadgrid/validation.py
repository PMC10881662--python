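"""Validation studies: oracles and Monte-Carlo calibration harnesses.

Self-contained routines that check the pipeline against independent
references: an exhaustive edit-script enumerator for the optimal-matching
distance, planted-type recovery (adjusted Rand index) for the clustering
stage, and type-I error / power simulations for the GEE manipulation check.
Both the test suite and the results-reproduction script drive these.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .task_core import BLOCKS, TaskConfig
from .synthetic_cohort import AgentParams, CohortSpec, generate_cohort
from .scoring import dyad_scores_frame
from .gsa import (
    CostModel,
    build_cost_matrix,
    encode_indistinguishable,
    hierarchical_cluster,
    pairwise_dissimilarity,
)
from .inference import gee_block_gender

__all__ = [
    "bruteforce_edit_distance",
    "random_sequences",
    "ari_for_seed",
    "null_agent",
    "null_cohort_long",
    "gee_type1_rate",
    "gee_power",
]


def bruteforce_edit_distance(c1: Sequence, c2: Sequence, cost: CostModel) -> float:
    """Minimal edit cost by exhaustive recursion over all edit scripts.

    Independent oracle for the dynamic-programming OM distance: no
    memoization, plain three-way branching (substitute / delete / insert).
    Exponential — only for sequences of a handful of cells.
    """
    if not c1:
        return len(c2) * cost.indel
    if not c2:
        return len(c1) * cost.indel
    return min(
        bruteforce_edit_distance(c1[1:], c2[1:], cost) + cost.substitution(c1[0], c2[0]),
        bruteforce_edit_distance(c1[1:], c2, cost) + cost.indel,
        bruteforce_edit_distance(c1, c2[1:], cost) + cost.indel,
    )


def random_sequences(
    rng: np.random.Generator,
    n: int,
    max_len: int = 4,
    grid: int = 3,
    mode: str = "distinguishable",
):
    """Random cell sequences over a small sub-grid (for oracle comparisons)."""
    from .gsa import CellSequence, canonical_cell

    out = []
    for i in range(n):
        length = int(rng.integers(0, max_len + 1))
        cells = []
        for _ in range(length):
            u, v = int(rng.integers(0, grid)), int(rng.integers(0, grid))
            cells.append(canonical_cell(u, v) if mode == "indistinguishable" else (u, v))
        out.append(CellSequence(id=f"s{i}", mode=mode, cells=tuple(cells)))
    return out


def ari_for_seed(
    seed: int,
    method: str = "ward_d",
    k: int = 3,
    spec: Optional[CohortSpec] = None,
    cfg: Optional[TaskConfig] = None,
) -> float:
    """Planted-type recovery on the default synthetic cohort for one seed."""
    cfg = cfg or TaskConfig()
    spec = spec or CohortSpec(seed=seed)
    if spec.seed != seed:
        spec = CohortSpec(
            n_per_type=spec.n_per_type, templates=spec.templates, seed=seed,
            p_nonresponse=spec.p_nonresponse,
        )
    trajs, truth = generate_cohort(spec, cfg)
    seqs = [encode_indistinguishable(t, cfg) for t in trajs]
    d = pairwise_dissimilarity(seqs, build_cost_matrix("indistinguishable"))
    sol = hierarchical_cluster(d, method, k)
    return float(adjusted_rand_score(truth, [sol.labels[t.dyad_id] for t in trajs]))


def null_agent() -> AgentParams:
    """A behaviorally flat agent: no reciprocity, reactivity or drift, so
    every block shares the same mean selection (the GEE null)."""
    return AgentParams(b=40.0, rho=0.0, gamma=0.0, delta=0.0, sigma=10.0)


def null_cohort_long(seed: int, n_dyads: int = 28) -> pd.DataFrame:
    """Dyad-mean block scores (long format) from one null-cohort replicate."""
    from .pipeline import dyad_block_long

    a = null_agent()
    spec = CohortSpec(
        n_per_type={"null_type": n_dyads}, templates={"null_type": (a, a)}, seed=seed
    )
    trajs, _ = generate_cohort(spec)
    return dyad_block_long(dyad_scores_frame(trajs))


def gee_type1_rate(
    n_reps: int = 500, seed: int = 0, n_dyads: int = 28, alpha: float = 0.05
) -> float:
    """Block-term rejection rate of the GEE manipulation check under the
    null generator (no block or gender effect)."""
    ss = np.random.SeedSequence(seed)
    rep_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_reps)]
    rej = [
        gee_block_gender(null_cohort_long(s, n_dyads)).terms["block"].p < alpha
        for s in rep_seeds
    ]
    return float(np.mean(rej))


def _elevated_long(
    rng: np.random.Generator,
    n_dyads: int = 28,
    elevation: float = 20.0,
    sigma: float = 5.0,
    baseline: float = 30.0,
) -> pd.DataFrame:
    """Constructed dyad block scores with a FAKE-block elevation."""
    rows = []
    n_male = n_dyads // 2
    for d in range(n_dyads):
        g = "male_pair" if d < n_male else "female_pair"
        for b in BLOCKS:
            mu = baseline + (elevation if b == "FAKE" else 0.0)
            rows.append((f"d{d:02d}", b, g, mu + rng.normal(0.0, sigma)))
    return pd.DataFrame(rows, columns=["dyad_id", "block", "gender", "value"])


def gee_power(
    n_reps: int = 200,
    seed: int = 0,
    n_dyads: int = 28,
    elevation: float = 20.0,
    sigma: float = 5.0,
    alpha: float = 0.001,
) -> float:
    """Block-term rejection rate under a 20-cent fake-block elevation."""
    rng = np.random.default_rng(seed)
    rej = [
        gee_block_gender(_elevated_long(rng, n_dyads, elevation, sigma))
        .terms["block"].p < alpha
        for _ in range(n_reps)
    ]
    return float(np.mean(rej))
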