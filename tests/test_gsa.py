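"""Grid encoding, optimal matching, Ward clustering."""

import numpy as np
import pytest
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score

from dyadgrid.task_core import TaskConfig, ValidationError, trajectory_from_selections
from dyadgrid.gsa import (
    CellSequence,
    DissimilarityMatrix,
    build_cost_matrix,
    canonical_cell,
    encode_distinguishable,
    encode_indistinguishable,
    hierarchical_cluster,
    om_distance,
    pairwise_dissimilarity,
    select_k,
)


def seq(cells, mode="indistinguishable", id="s"):
    return CellSequence(id=id, mode=mode, cells=tuple(cells))


# --- encoding -------------------------------------------------------------

def test_indistinguishable_mirrors_and_length(cfg):
    sels_a = [30] + [50] * 64
    sels_b = [70] + [50] * 64
    t1 = trajectory_from_selections("d1", sels_a, sels_b, cfg)
    t2 = trajectory_from_selections("d2", sels_b, sels_a, cfg)
    s1, s2 = encode_indistinguishable(t1, cfg), encode_indistinguishable(t2, cfg)
    assert len(s1) == len(s2) == 60
    assert s1.cells == s2.cells
    assert s1.cells[0] == (3, 7)
    zero = trajectory_from_selections("d3", [0] * 65, [0] * 65, cfg)
    assert encode_indistinguishable(zero, cfg).cells[0] == (0, 0)


def test_distinguishable_encoding(cfg):
    script = encode_distinguishable([30, 50, 50, 60, 70], cfg)
    assert script.cells == ((3, 3), (5, 5), (5, 5), (6, 6), (7, 7))
    zeros = encode_distinguishable([0, 0, 0, 0, 0], cfg)
    assert zeros.cells == ((0, 3), (0, 5), (0, 5), (0, 6), (0, 7))
    # feasible alphabet: 10 participant levels x 4 distinct scripted rows
    rows = {v for v in (f // 10 for f in cfg.fake_levels)}
    assert len(rows) * 10 == 40
    with pytest.raises(ValidationError, match="expected 5"):
        encode_distinguishable([0, 0, 0], cfg)


# --- cost model -----------------------------------------------------------

def test_cost_examples():
    cost = build_cost_matrix("distinguishable")
    assert cost.substitution((3, 5), (4, 5)) == 1
    assert cost.substitution((0, 0), (9, 9)) == 18
    canon = build_cost_matrix("indistinguishable")
    assert canon.substitution((0, 9), (9, 0)) == 0
    assert len(canon.alphabet) == 55
    assert len(cost.alphabet) == 100


def test_cost_matrix_is_metric():
    for mode in ("distinguishable", "indistinguishable"):
        m = build_cost_matrix(mode).matrix()
        assert np.allclose(m, m.T)
        assert np.all(np.diag(m) == 0)
        assert m.max() <= 18


# --- optimal matching -----------------------------------------------------

def test_om_basic_cases():
    cost = build_cost_matrix("indistinguishable")
    a = seq([(1, 2), (3, 4), (5, 6)])
    assert om_distance(a, a, cost) == 0
    b = seq([(1, 2), (3, 5), (5, 6)])  # one adjacent-cell substitution
    assert om_distance(a, b, cost) == 1
    empty = seq([])
    assert om_distance(a, empty, cost) == 3 * cost.indel
    with pytest.raises(ValidationError, match="mode mismatch"):
        om_distance(a, seq([(1, 2)], mode="distinguishable"), cost)


def test_om_effective_substitution_capped_by_double_indel():
    """With indel=1 a substitution never costs more than delete+insert, so
    equal-length distances are bounded by 2 per position."""
    rng = np.random.default_rng(0)
    cost = build_cost_matrix("distinguishable")
    for _ in range(50):
        c1 = [(int(rng.integers(10)), int(rng.integers(10))) for _ in range(12)]
        c2 = [(int(rng.integers(10)), int(rng.integers(10))) for _ in range(12)]
        s1, s2 = seq(c1, "distinguishable"), seq(c2, "distinguishable")
        d = om_distance(s1, s2, cost)
        positionwise = sum(
            min(cost.substitution(x, y), 2 * cost.indel) for x, y in zip(c1, c2)
        )
        assert d <= positionwise + 1e-12
        assert d <= (len(c1) + len(c2)) * cost.indel + 1e-12


@pytest.mark.parametrize("indel", [1.0, 2.0])
def test_om_is_symmetric_and_identifies_equal_sequences(indel):
    from hypothesis import given, settings, strategies as st

    cells_strategy = st.lists(
        st.tuples(st.integers(0, 9), st.integers(0, 9)), max_size=8
    )
    cost = build_cost_matrix("distinguishable", indel)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(c1=cells_strategy, c2=cells_strategy)
    def check(c1, c2):
        s1, s2 = seq(c1, "distinguishable"), seq(c2, "distinguishable")
        d12 = om_distance(s1, s2, cost)
        assert d12 == om_distance(s2, s1, cost)
        assert d12 >= 0
        assert (d12 == 0) == (tuple(c1) == tuple(c2)) or indel == 0

    check()


def test_pairwise_matrix_properties(small_cohort, cfg):
    trajs, _ = small_cohort
    seqs = [encode_indistinguishable(t, cfg) for t in trajs]
    d = pairwise_dissimilarity(seqs)
    assert d.matrix.shape == (9, 9)
    assert np.allclose(d.matrix, d.matrix.T)
    assert np.all(np.diag(d.matrix) == 0)
    # permutation equivariance
    perm = [3, 1, 4, 0, 2, 8, 6, 5, 7]
    d2 = pairwise_dissimilarity([seqs[i] for i in perm])
    assert np.allclose(d2.matrix, d.matrix[np.ix_(perm, perm)])


def test_sibling_role_swap_is_invisible(cfg):
    """Swapping member roles anywhere changes nothing end-to-end in the
    indistinguishable pipeline."""
    from dyadgrid.synthetic_cohort import AgentParams, simulate_dyad

    pa = AgentParams(b=70, rho=0.2, sigma=5.0)
    pb = AgentParams(b=20, rho=0.2, sigma=5.0)
    t1 = simulate_dyad(pa, pb, cfg, seed=5, dyad_id="d")
    swapped = trajectory_from_selections(
        "d", t1.selections("b"), t1.selections("a"), cfg
    )
    assert (
        encode_indistinguishable(t1, cfg).cells
        == encode_indistinguishable(swapped, cfg).cells
    )


# --- clustering -----------------------------------------------------------

def test_ward_separated_blocks_perfect_split():
    n1, n2 = 4, 5
    m = np.full((n1 + n2, n1 + n2), 10.0)
    m[:n1, :n1] = 0.0
    m[n1:, n1:] = 0.0
    np.fill_diagonal(m, 0.0)
    d = DissimilarityMatrix(ids=tuple(f"i{i}" for i in range(n1 + n2)), matrix=m)
    sol = hierarchical_cluster(d, "ward_d", 2)
    labs = [sol.labels[f"i{i}"] for i in range(n1 + n2)]
    assert labs == [1] * n1 + [2] * n2


def test_ward_k_equals_n_singletons():
    rng = np.random.default_rng(1)
    m = squareform(pdist(rng.normal(size=(6, 2))))
    d = DissimilarityMatrix(ids=tuple("abcdef"), matrix=m)
    sol = hierarchical_cluster(d, "ward_d", 6)
    assert sorted(sol.labels.values()) == [1, 2, 3, 4, 5, 6]
    with pytest.raises(ValidationError, match="out of range"):
        hierarchical_cluster(d, "ward_d", 7)


def test_ward_d2_matches_scipy_on_euclidean_data():
    """On Euclidean distances, ward_d2 must agree with scipy's ward linkage
    (heights and cut labels)."""
    rng = np.random.default_rng(3)
    pts = np.vstack(
        [rng.normal(c, 0.3, size=(7, 2)) for c in ((0, 0), (4, 0), (0, 4))]
    )
    dm = squareform(pdist(pts))
    d = DissimilarityMatrix(ids=tuple(f"p{i}" for i in range(21)), matrix=dm)
    sol = hierarchical_cluster(d, "ward_d2", 3)
    Z = linkage(pdist(pts), method="ward")
    assert np.allclose(sorted(sol.heights()), sorted(Z[:, 2]), atol=1e-8)
    scipy_labels = fcluster(Z, t=3, criterion="maxclust")
    ours = [sol.labels[f"p{i}"] for i in range(21)]
    assert adjusted_rand_score(scipy_labels, ours) == 1.0


def test_cluster_recovery_on_small_cohort(small_cohort, cfg):
    trajs, truth = small_cohort
    seqs = [encode_indistinguishable(t, cfg) for t in trajs]
    d = pairwise_dissimilarity(seqs)
    sol = hierarchical_cluster(d, "ward_d", 3)
    ours = [sol.labels[t.dyad_id] for t in trajs]
    assert adjusted_rand_score(truth, ours) == 1.0
    assert select_k(sol, min_size=2) == 3


def test_select_k_degenerate_cases():
    rng = np.random.default_rng(4)
    m = squareform(pdist(rng.normal(size=(12, 3))))  # homogeneous cloud
    d = DissimilarityMatrix(ids=tuple(f"h{i}" for i in range(12)), matrix=m)
    sol = hierarchical_cluster(d, "ward_d", 1)
    assert select_k(sol) == 1
    # min_size beyond n/2 leaves no feasible multi-cluster cut
    assert select_k(sol, min_size=7) in (1, 2)
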