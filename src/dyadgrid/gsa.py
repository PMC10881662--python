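"""Grid Sequence Analysis: state-space-grid encoding, optimal matching,
Ward clustering.

A dyad's session is a path through a 10 x 10 grid whose cells are joint
punishment-level combinations (level index = cents / 10). Two encodings are
supported:

* indistinguishable — members are interchangeable, so cells mirrored at the
  diagonal are identified by sorting each pair to canonical (min, max) form;
  used for the 60 interactive trials at the dyad level.
* distinguishable — the participant is on the x-axis and the scripted fake
  opponent on the y-axis; used for the 5 fake trials at the member level.

Pairwise sequence dissimilarity is the optimal-matching (OM) edit distance:
the minimal total cost of substitutions (Manhattan distance between cells)
and insertions/deletions (unit cost by default) transforming one sequence
into another. Dyads are then grouped by agglomerative Ward clustering run
directly on the OM dissimilarity matrix via Lance-Williams updates.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from .task_core import MISSING, TaskConfig, DyadTrajectory, ValidationError

__all__ = [
    "CellSequence",
    "CostModel",
    "DissimilarityMatrix",
    "ClusterSolution",
    "canonical_cell",
    "encode_indistinguishable",
    "encode_distinguishable",
    "encode_fake_member",
    "build_cost_matrix",
    "om_distance",
    "pairwise_dissimilarity",
    "hierarchical_cluster",
    "cut_tree",
    "select_k",
    "cell_labels",
]

logger = logging.getLogger(__name__)

Cell = Tuple[int, int]


def canonical_cell(u: int, v: int) -> Cell:
    """Canonical (sorted) form of a grid cell: (u, v) and (v, u) identified."""
    return (u, v) if u <= v else (v, u)


def _check_level_index(i: int) -> None:
    if not 0 <= i <= 9:
        raise ValidationError(f"grid level index {i} outside 0..9")


@dataclass(frozen=True)
class CellSequence:
    """An ordered trajectory through the state-space grid."""

    id: str
    mode: str  # {"distinguishable", "indistinguishable"}
    cells: tuple

    def __post_init__(self):
        if self.mode not in ("distinguishable", "indistinguishable"):
            raise ValidationError(f"unknown grid mode {self.mode!r}")
        for u, v in self.cells:
            _check_level_index(u)
            _check_level_index(v)
            if self.mode == "indistinguishable" and u > v:
                raise ValidationError(
                    f"sequence {self.id}: cell ({u},{v}) not canonical (u <= v required)"
                )

    def __len__(self):
        return len(self.cells)

    def coords(self):
        """(u, v) coordinate arrays; empty sequences give shape-(0,) arrays."""
        arr = np.asarray(self.cells, dtype=int)
        if arr.size == 0:
            return np.zeros(0, dtype=int), np.zeros(0, dtype=int)
        return arr[:, 0], arr[:, 1]


@dataclass(frozen=True)
class CostModel:
    """Indel cost plus Manhattan substitution costs over the grid alphabet.

    Substitution between cells (u1,v1), (u2,v2) is |u1-u2| + |v1-v2| on the
    level indices; in indistinguishable mode it is evaluated on canonical
    forms, which equals the minimum over the two diagonal reflections. The
    maximal substitution on the 10 x 10 grid is 18.
    """

    mode: str = "indistinguishable"
    indel: float = 1.0

    def __post_init__(self):
        if self.mode not in ("distinguishable", "indistinguishable"):
            raise ValidationError(f"unknown grid mode {self.mode!r}")
        if self.indel < 0:
            raise ValidationError("indel cost must be non-negative")

    @property
    def alphabet(self) -> tuple:
        """Active cell alphabet: 55 canonical cells or the full 100."""
        if self.mode == "indistinguishable":
            return tuple((u, v) for u in range(10) for v in range(u, 10))
        return tuple(itertools.product(range(10), range(10)))

    def substitution(self, c1: Cell, c2: Cell) -> float:
        if self.mode == "indistinguishable":
            c1, c2 = canonical_cell(*c1), canonical_cell(*c2)
        return float(abs(c1[0] - c2[0]) + abs(c1[1] - c2[1]))

    def matrix(self) -> np.ndarray:
        """Cached-style full substitution matrix over the active alphabet."""
        cells = np.asarray(self.alphabet, dtype=int)
        return np.abs(cells[:, None, :] - cells[None, :, :]).sum(axis=2).astype(float)

    def pair_costs(self, s1: CellSequence, s2: CellSequence) -> np.ndarray:
        """len(s1) x len(s2) substitution-cost matrix."""
        u1, v1 = s1.coords()
        u2, v2 = s2.coords()
        return (
            np.abs(u1[:, None] - u2[None, :]) + np.abs(v1[:, None] - v2[None, :])
        ).astype(float)


def encode_indistinguishable(
    traj: DyadTrajectory, cfg: Optional[TaskConfig] = None
) -> CellSequence:
    """Encode the 60 interactive trials as canonical (min, max) level cells.

    Fake trials are excluded; trials with a missing selection are dropped
    from the sequence (OM tolerates unequal lengths) and logged.
    """
    cfg = cfg or TaskConfig()
    cells = []
    for r in traj.records:
        if r.is_fake:
            continue
        if r.sel_a is MISSING or r.sel_b is MISSING:
            logger.info(
                "dyad %s trial %d: missing selection, dropped from grid sequence",
                traj.dyad_id, r.trial_index,
            )
            continue
        if r.sel_a not in cfg.levels or r.sel_b not in cfg.levels:
            raise ValidationError(
                f"dyad {traj.dyad_id} trial {r.trial_index}: off-scale selection"
            )
        cells.append(canonical_cell(r.sel_a // 10, r.sel_b // 10))
    return CellSequence(id=traj.dyad_id, mode="indistinguishable", cells=tuple(cells))


def encode_distinguishable(
    selections: Sequence, cfg: Optional[TaskConfig] = None, id: str = "participant"
) -> CellSequence:
    """Encode one member's five fake-trial selections against the script.

    Cells are (participant level, scripted level) in scripted order, so the
    y-coordinates are always the scripted levels (3, 5, 5, 6, 7). Missing
    selections are dropped and logged.
    """
    cfg = cfg or TaskConfig()
    if len(selections) != len(cfg.fake_levels):
        raise ValidationError(
            f"{id}: expected {len(cfg.fake_levels)} fake-trial selections, "
            f"got {len(selections)}"
        )
    cells = []
    for sel, script in zip(selections, cfg.fake_levels):
        if sel is MISSING:
            logger.info("%s: missing fake-trial selection dropped", id)
            continue
        if sel not in cfg.levels:
            raise ValidationError(f"{id}: off-scale fake-trial selection {sel}")
        cells.append((sel // 10, script // 10))
    return CellSequence(id=id, mode="distinguishable", cells=tuple(cells))


def encode_fake_member(
    traj: DyadTrajectory, member: str, cfg: Optional[TaskConfig] = None
) -> CellSequence:
    """Distinguishable encoding of one dyad member's fake-trial responses."""
    cfg = cfg or TaskConfig()
    sels = [traj.selections(member)[t - 1] for t in cfg.trials_in_block("FAKE")]
    return encode_distinguishable(sels, cfg, id=f"{traj.dyad_id}:{member}")


def build_cost_matrix(mode: str = "indistinguishable", indel: float = 1.0) -> CostModel:
    """Construct the OM cost model for the given grid mode."""
    return CostModel(mode=mode, indel=indel)


def om_distance(s1: CellSequence, s2: CellSequence, cost: Optional[CostModel] = None) -> float:
    """Optimal-matching edit distance between two cell sequences.

    Dynamic programming over the standard recurrence
    ``D[i][j] = min(D[i-1][j-1] + sub, D[i-1][j] + indel, D[i][j-1] + indel)``
    with ``D[i][0] = i * indel`` and ``D[0][j] = j * indel``.
    """
    cost = cost or build_cost_matrix()
    if s1.mode != s2.mode:
        raise ValidationError(f"grid mode mismatch: {s1.mode} vs {s2.mode}")
    if cost.mode != s1.mode:
        raise ValidationError(f"cost model mode {cost.mode} does not match sequences")
    n, m = len(s1), len(s2)
    ind = cost.indel
    if n == 0 or m == 0:
        return float((n + m) * ind)
    sub = cost.pair_costs(s1, s2)
    j_ind = np.arange(m + 1) * ind
    prev = j_ind.copy()
    for i in range(1, n + 1):
        # candidates ignoring the within-row (left) dependency
        cand = np.minimum(prev[:-1] + sub[i - 1], prev[1:] + ind)
        # fold in the left dependency: row[j] = min_{k<=j} cand[k] + (j-k)*indel
        t = np.empty(m + 1)
        t[0] = i * ind
        t[1:] = cand - j_ind[1:]
        prev = np.minimum.accumulate(t) + j_ind
    return float(prev[m])


@dataclass
class DissimilarityMatrix:
    """Symmetric pairwise OM distances with aligned ids."""

    ids: tuple
    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValidationError("dissimilarity matrix shape does not match ids")
        self.matrix = m


def pairwise_dissimilarity(
    sequences: Sequence[CellSequence], cost: Optional[CostModel] = None
) -> DissimilarityMatrix:
    """All-pairs OM distances; symmetric with zero diagonal."""
    if len(sequences) < 2:
        raise ValidationError("need at least 2 sequences")
    cost = cost or build_cost_matrix(sequences[0].mode)
    n = len(sequences)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = om_distance(sequences[i], sequences[j], cost)
    return DissimilarityMatrix(ids=tuple(s.id for s in sequences), matrix=d)


@dataclass
class ClusterSolution:
    """Agglomerative linkage over a dissimilarity matrix plus a k-cut.

    ``merges`` is a list of (left_node, right_node, height) triples with
    original observations numbered 0..n-1 and merged nodes n, n+1, ...
    (scipy numbering). ``labels`` maps id -> cluster 1..k, clusters numbered
    by first appearance.
    """

    ids: tuple
    method: str
    merges: list
    k: int
    labels: dict = field(default_factory=dict)

    def heights(self) -> np.ndarray:
        return np.asarray([h for _, _, h in self.merges], dtype=float)

    def labels_for(self, k: int) -> dict:
        return cut_tree(self.merges, self.ids, k)


def hierarchical_cluster(
    d: DissimilarityMatrix, method: str = "ward_d", k: int = 3
) -> ClusterSolution:
    """Ward agglomeration on a precomputed dissimilarity matrix.

    Lance-Williams updates with Ward coefficients, applied to the raw
    dissimilarities (``ward_d``) or to their squares with square-root merge
    heights (``ward_d2``). Ties in the minimal pair are broken by the lowest
    pair index, making the tree fully deterministic.
    """
    if method not in ("ward_d", "ward_d2"):
        raise ValidationError(f"unknown linkage method {method!r}")
    n = len(d.ids)
    if not 1 <= k <= n:
        raise ValidationError(f"k={k} out of range 1..{n}")
    work = d.matrix.astype(float).copy()
    if method == "ward_d2":
        work = work**2
    np.fill_diagonal(work, np.inf)
    active = np.ones(n, dtype=bool)
    sizes = np.ones(n, dtype=float)
    node = np.arange(n)  # current scipy-style node id per slot
    big = np.full_like(work, np.inf)
    work = np.where(np.isfinite(work), work, big)
    merges = []
    for step in range(n - 1):
        masked = work.copy()
        masked[~active, :] = np.inf
        masked[:, ~active] = np.inf
        iu = np.triu_indices(n, 1)
        flat = masked[iu]
        best = int(np.argmin(flat))  # first minimum => lowest (i, j) pair
        i, j = int(iu[0][best]), int(iu[1][best])
        crit = float(masked[i, j])
        height = np.sqrt(crit) if method == "ward_d2" else crit
        merges.append((int(node[i]), int(node[j]), float(height)))
        ni, nj = sizes[i], sizes[j]
        for l in range(n):
            if not active[l] or l in (i, j):
                continue
            nl = sizes[l]
            tot = ni + nj + nl
            new = ((ni + nl) * work[i, l] + (nj + nl) * work[j, l] - nl * crit) / tot
            work[i, l] = work[l, i] = new
        active[j] = False
        sizes[i] = ni + nj
        node[i] = n + step
    labels = cut_tree(merges, d.ids, k)
    return ClusterSolution(ids=d.ids, method=method, merges=merges, k=k, labels=labels)


def cut_tree(merges: list, ids: tuple, k: int) -> dict:
    """Cut a linkage into k clusters; labels 1..k by first id appearance."""
    n = len(ids)
    if not 1 <= k <= n:
        raise ValidationError(f"k={k} out of range 1..{n}")
    members = {i: [i] for i in range(n)}
    for step, (a, b, _) in enumerate(merges[: n - k]):
        members[n + step] = members.pop(a) + members.pop(b)
    groups = sorted(members.values(), key=min)
    labels = {}
    for lab, group in enumerate(groups, start=1):
        for i in group:
            labels[ids[i]] = lab
    return labels


def select_k(
    solution: ClusterSolution, min_size: int = 3, gap_threshold: float = 2.5
) -> int:
    """Advisory cluster count from the dendrogram.

    The relative merge-height gap for a cut into k clusters is the ratio of
    the merge height bridged when going below k clusters to the last height
    inside the cut. Homogeneous data produce smoothly growing heights
    (ratios near 1-2) while real group structure shows an order-of-magnitude
    jump, so the recommendation is the feasible k (every cluster at least
    ``min_size`` ids) with the largest ratio above ``gap_threshold``, or 1
    when no gap clears it. Advisory only — k stays user-settable.
    """
    h = solution.heights()
    n = len(solution.ids)
    if n < 2 or h[-1] <= 0:
        return 1
    best_k, best_gap = 1, gap_threshold
    for k in range(2, n // min_size + 1):
        counts = np.bincount(list(solution.labels_for(k).values()))
        if counts[1:].min() < min_size:
            continue
        gap = h[n - k] / max(h[n - k - 1], 1e-12)
        if gap > best_gap:
            best_k, best_gap = k, gap
    return best_k


def cell_labels(mode: str = "indistinguishable") -> dict:
    """Presentation labels a, b, c, ... aa, ab, ... over the active alphabet."""

    def name(i: int) -> str:
        s = ""
        while True:
            s = chr(ord("a") + i % 26) + s
            i = i // 26 - 1
            if i < 0:
                return s

    cells = CostModel(mode=mode).alphabet
    return {cell: name(i) for i, cell in enumerate(cells)}
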