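"""Rank tests, correlations, chi-square, GEE manipulation check."""

import numpy as np
import pandas as pd
import pytest

from dyadgrid.task_core import BLOCKS, ValidationError
from dyadgrid.inference import (
    chi_square_independence,
    compare_clusters,
    dunn_adjusted_p,
    dunn_posthoc,
    gee_block_gender,
    kruskal_wallis,
    posthoc_block_contrasts,
    spearman_corr,
    spearman_p,
)


# --- Kruskal-Wallis -------------------------------------------------------

def test_kruskal_wallis_worked_example():
    res = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
    assert res.statistic == pytest.approx(7.2)
    assert res.df == 2


def test_kruskal_wallis_identical_groups_and_degenerate():
    res = kruskal_wallis([[1, 2, 3], [1, 2, 3]])
    assert res.statistic == pytest.approx(0.0)
    degenerate = kruskal_wallis([[5, 5], [5, 5]])
    assert np.isnan(degenerate.statistic) and "undefined" in degenerate.note


def test_kruskal_wallis_monotone_invariance():
    rng = np.random.default_rng(2)
    groups = [rng.normal(loc, 1, size=8) for loc in (0, 1, 2)]
    h1 = kruskal_wallis(groups).statistic
    h2 = kruskal_wallis([np.exp(g) for g in groups]).statistic
    assert h1 == pytest.approx(h2)


# --- Dunn -----------------------------------------------------------------

def test_dunn_bonferroni_reconstruction():
    """The published pairwise p values reconstruct from the z statistics
    with a Bonferroni factor of 3."""
    assert dunn_adjusted_p(2.36, 3) == pytest.approx(0.055, abs=5e-4)
    assert dunn_adjusted_p(-0.243, 3) > 0.999
    assert dunn_adjusted_p(2.07, 3) == pytest.approx(0.115, abs=5e-4)


def test_dunn_identical_groups():
    res = dunn_posthoc([[1, 2, 3], [1, 2, 3]])
    assert res[0].statistic == pytest.approx(0.0)
    assert res[0].p_adjusted == pytest.approx(1.0)


def test_dunn_orders_with_group_location():
    rng = np.random.default_rng(6)
    low, mid, high = (rng.normal(loc, 1, 30) for loc in (0, 2, 4))
    res = dunn_posthoc([low, mid, high], labels=("low", "mid", "high"))
    byname = {r.name: r for r in res}
    assert byname["dunn_low_vs_high"].statistic < byname["dunn_low_vs_mid"].statistic < 0


# --- Spearman -------------------------------------------------------------

def test_spearman_examples():
    x = np.arange(10.0)
    res = spearman_corr(x, np.exp(x))
    assert res.statistic == pytest.approx(1.0)
    assert spearman_p(0.36, 56) == pytest.approx(0.006, abs=1e-3)
    res = spearman_corr([1, 2, 3, 4, 5], [2, 1, 4, 3, 5], n_tests=3)
    assert res.alpha_adjusted == pytest.approx(0.05 / 3)


def test_spearman_zero_variance_flagged():
    res = spearman_corr([1, 1, 1, 1], [1, 2, 3, 4])
    assert np.isnan(res.statistic) and "zero variance" in res.note


# --- chi-square -----------------------------------------------------------

def test_chi_square_cases():
    prop = chi_square_independence([[10, 20], [5, 10]])
    assert prop.statistic == pytest.approx(0.0)
    diag = chi_square_independence([[10, 0], [0, 10]])
    assert diag.statistic == pytest.approx(20.0) and diag.df == 1
    res = chi_square_independence([[5, 6, 7], [7, 6, 5]])
    assert res.df == 2
    with pytest.raises(ValidationError, match="zero marginal"):
        chi_square_independence([[0, 0], [3, 4]])


# --- GEE ------------------------------------------------------------------

def elevated_frame(rng, n=28, elevation=20.0, sigma=5.0):
    rows = []
    for d in range(n):
        g = "male_pair" if d < n // 2 else "female_pair"
        for b in BLOCKS:
            mu = 30 + (elevation if b == "FAKE" else 0)
            rows.append((f"d{d:02d}", b, g, mu + rng.normal(0, sigma)))
    return pd.DataFrame(rows, columns=["dyad_id", "block", "gender", "value"])


def test_gee_terms_and_dfs():
    rng = np.random.default_rng(8)
    gee = gee_block_gender(elevated_frame(rng))
    assert gee.terms["block"].df == 4
    assert gee.terms["gender"].df == 1
    assert gee.terms["block_x_gender"].df == 4
    assert gee.terms["block"].p < 0.001
    assert gee.n_clusters == 28


def test_gee_unbalanced_panel_rejected():
    rng = np.random.default_rng(8)
    df = elevated_frame(rng).iloc[:-2]  # drop two rows of the last dyad
    with pytest.raises(ValidationError, match="unbalanced"):
        gee_block_gender(df)


def test_posthoc_block_contrasts():
    rng = np.random.default_rng(10)
    gee = gee_block_gender(elevated_frame(rng))
    contrasts = posthoc_block_contrasts(gee)
    assert len(contrasts) == 10  # C(5,2)
    names = {c.name for c in contrasts}
    assert len(names) == 10
    fake_pairs = [c for c in contrasts if "FAKE" in c.name]
    assert all(c.p_adjusted < 0.01 for c in fake_pairs)
    assert all(0 <= c.p_adjusted <= 1 for c in contrasts)


# --- cluster comparison ---------------------------------------------------

def test_compare_clusters_panel_and_alpha(default_cohort, cfg):
    from dyadgrid.gsa import (
        build_cost_matrix,
        encode_indistinguishable,
        hierarchical_cluster,
        pairwise_dissimilarity,
    )
    from dyadgrid.scoring import itap_dyad_panel

    trajs, truth = default_cohort
    seqs = [encode_indistinguishable(t, cfg) for t in trajs]
    sol = hierarchical_cluster(pairwise_dissimilarity(seqs), "ward_d", 3)
    panel = itap_dyad_panel(trajs, cfg)
    gender = {t.dyad_id: t.gender for t in trajs}
    report = compare_clusters(sol.labels, panel, gender=gender)
    assert report.alpha_itap == pytest.approx(0.05 / 7)
    # z-normalized panel: cohort mean 0, SD 1 per variable
    z = (panel - panel.mean()) / panel.std(ddof=1)
    assert np.allclose(z.mean(), 0, atol=1e-12)
    assert np.allclose(z.std(ddof=1), 1, atol=1e-12)
    # the planted both-high cluster tops the interactive dyad-mean panel
    high_cluster = sol.labels[
        next(t.dyad_id for t, lab in zip(trajs, truth) if lab == "both_high")
    ]
    assert report.panel["m_inter"].idxmax() == f"cluster_{high_cluster}"
    assert report.gender_test.df == 2  # 2 genders x 3 clusters
    # Dunn post hocs only where the KW test cleared its alpha
    for var, dunns in report.dunn_tests.items():
        assert report.kw_tests[var].p < report.kw_tests[var].alpha_adjusted
        assert len(dunns) == 3
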