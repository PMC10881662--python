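"""Manipulation-check and cluster-comparison statistics.

The manipulation check fits two marginal (GEE) models — dyad mean and dyad
difference aggression across the five task blocks and pair gender — with an
exchangeable working correlation and dyads as clusters, followed by
Bonferroni-corrected pairwise block contrasts. Outcome effects and cluster
characterizations use rank-based tests: Kruskal-Wallis across groups, Dunn's
z post hoc with tie correction and Bonferroni adjustment, Spearman
correlations with a Bonferroni-adjusted alpha, and Pearson chi-square for
the gender-by-cluster table.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm
import statsmodels.formula.api as smf

from .task_core import BLOCKS, ValidationError
from .scoring import ITAP_PANEL_VARS

__all__ = [
    "TestResult",
    "GEEResult",
    "ComparisonReport",
    "gee_block_gender",
    "posthoc_block_contrasts",
    "kruskal_wallis",
    "dunn_posthoc",
    "dunn_adjusted_p",
    "spearman_corr",
    "spearman_p",
    "chi_square_independence",
    "compare_clusters",
]


@dataclass
class TestResult:
    """One hypothesis test: statistic, df, p, and any multiplicity handling."""

    name: str
    statistic: float
    df: Optional[float]
    p: float
    p_adjusted: Optional[float] = None
    alpha_adjusted: Optional[float] = None
    group_sizes: Optional[tuple] = None
    note: Optional[str] = None

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "statistic": self.statistic,
            "df": self.df,
            "p": self.p,
            "p_adjusted": self.p_adjusted,
            "alpha_adjusted": self.alpha_adjusted,
            "group_sizes": list(self.group_sizes) if self.group_sizes else None,
            "note": self.note,
        }


@dataclass
class GEEResult:
    """Fitted marginal model: coefficients, robust covariance, Wald terms."""

    dv: str
    params: dict
    cov: np.ndarray
    terms: dict  # term -> TestResult (Wald chi-square)
    n_clusters: int
    cov_struct: str
    _results: object = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "dv": self.dv,
            "params": self.params,
            "n_clusters": self.n_clusters,
            "cov_struct": self.cov_struct,
            "terms": {k: v.to_dict() for k, v in self.terms.items()},
        }


def _cov_struct(name: str):
    structs = {
        "exchangeable": sm.cov_struct.Exchangeable,
        "independence": sm.cov_struct.Independence,
        "ar1": sm.cov_struct.Autoregressive,
    }
    try:
        return structs[name]()
    except KeyError:
        raise ValidationError(f"unknown working correlation {name!r}") from None


def _emm_rows(res) -> dict:
    """Design rows for every (block, gender) cell of the fitted model."""
    from patsy import build_design_matrices

    di = res.model.data.design_info
    infos = {f.name(): info for f, info in di.factor_infos.items()}
    block_name = next(n for n in infos if set(infos[n].categories) >= set(BLOCKS))
    gender_name = next(n for n in infos if n != block_name)
    genders = list(infos[gender_name].categories)
    rows = {}
    for b in BLOCKS:
        for g in genders:
            rows[(b, g)] = np.asarray(
                build_design_matrices([di], {block_name: [b], gender_name: [g]})[0]
            )[0]
    return rows


def _wald_term(name, L, beta, cov, n_clusters, small_sample="hotelling"):
    """Wald chi-square for contrast matrix L with a small-sample reference.

    The statistic is W = (Lb)' (L V L')^-1 (Lb) with the robust covariance.
    With K clusters and a q-df contrast, W behaves like a Hotelling T^2 in
    balanced repeated-measures designs, so the default p value refers
    W (K - q) / (q (K - 1)) to F(q, K - q); ``small_sample="chi2"`` gives
    the asymptotic chi-square(q) reference instead. Both agree as K grows.
    """
    L = np.atleast_2d(L)
    q = L.shape[0]
    est = L @ beta
    V = L @ cov @ L.T
    w = float(est @ np.linalg.solve(V, est))
    if small_sample == "hotelling":
        k = n_clusters
        p = float(stats.f.sf(w * (k - q) / (q * (k - 1)), q, k - q))
        note = f"p from Hotelling F({q}, {k - q}) small-sample reference"
    elif small_sample == "chi2":
        p = float(stats.chi2.sf(w, q))
        note = "p from asymptotic chi-square"
    else:
        raise ValidationError(f"unknown small_sample option {small_sample!r}")
    return TestResult(name=name, statistic=w, df=float(q), p=p, note=note)


def gee_block_gender(
    data: pd.DataFrame,
    dv: str = "value",
    block_col: str = "block",
    gender_col: str = "gender",
    dyad_col: str = "dyad_id",
    cov_struct: str = "exchangeable",
    small_sample: str = "hotelling",
) -> GEEResult:
    """GEE manipulation check: dv ~ block * gender, dyads as clusters.

    Gaussian family with identity link and (by default) an exchangeable
    working correlation; inference uses the robust sandwich covariance. The
    Wald chi-square terms carry df 4 (block), 1 (gender), 4 (interaction)
    and are built from marginal contrasts — block effects averaged over the
    gender factor and vice versa — with a Hotelling-type F reference by
    default to keep the tests calibrated at small cluster counts. Each dyad
    must contribute exactly one row per block.
    """
    df = data.copy()
    counts = df.groupby(dyad_col)[block_col].count()
    bad = counts[counts != len(BLOCKS)]
    if len(bad):
        raise ValidationError(
            f"unbalanced panels (need {len(BLOCKS)} rows per dyad): "
            + ", ".join(f"{d}={c}" for d, c in bad.items())
        )
    df[block_col] = pd.Categorical(df[block_col], categories=list(BLOCKS))
    formula = f"{dv} ~ {block_col} * {gender_col}"
    model = smf.gee(
        formula,
        groups=dyad_col,
        data=df,
        family=sm.families.Gaussian(),
        cov_struct=_cov_struct(cov_struct),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit()
    rows = _emm_rows(res)
    genders = sorted({g for _, g in rows})
    emm_block = {b: np.mean([rows[(b, g)] for g in genders], axis=0) for b in BLOCKS}
    emm_gender = {g: np.mean([rows[(b, g)] for b in BLOCKS], axis=0) for g in genders}
    ref = BLOCKS[0]
    l_block = [emm_block[b] - emm_block[ref] for b in BLOCKS[1:]]
    l_gender = [emm_gender[genders[1]] - emm_gender[genders[0]]]
    l_inter = [
        (rows[(b, genders[1])] - rows[(ref, genders[1])])
        - (rows[(b, genders[0])] - rows[(ref, genders[0])])
        for b in BLOCKS[1:]
    ]
    beta = res.params.to_numpy()
    cov = np.asarray(res.cov_params())
    n_clusters = df[dyad_col].nunique()
    terms = {
        key: _wald_term(f"gee_{dv}_{key}", L, beta, cov, n_clusters, small_sample)
        for key, L in (
            ("block", l_block),
            ("gender", l_gender),
            ("block_x_gender", l_inter),
        )
    }
    return GEEResult(
        dv=dv,
        params={k: float(v) for k, v in res.params.items()},
        cov=cov,
        terms=terms,
        n_clusters=n_clusters,
        cov_struct=cov_struct,
        _results=res,
    )


def posthoc_block_contrasts(gee: GEEResult) -> list:
    """All 10 pairwise block contrasts from the fitted GEE.

    Model-based marginal block means (averaged over the gender factor with
    equal weights), Wald z on each contrast with the robust SE, two-sided p,
    Bonferroni-adjusted with m = 10.
    """
    res = gee._results
    if res is None:
        raise ValidationError("GEEResult lacks a fitted model; refit before post hoc")
    cell_rows = _emm_rows(res)
    genders = sorted({g for _, g in cell_rows})
    rows = {
        b: np.mean([cell_rows[(b, g)] for g in genders], axis=0) for b in BLOCKS
    }
    beta = np.asarray(list(gee.params.values()))
    cov = gee.cov
    pairs = list(itertools.combinations(BLOCKS, 2))
    m = len(pairs)
    out = []
    for b1, b2 in pairs:
        L = rows[b1] - rows[b2]
        est = float(L @ beta)
        se = float(np.sqrt(L @ cov @ L))
        z = est / se if se > 0 else 0.0
        p = 1.0 if se == 0 and est == 0 else 2.0 * stats.norm.sf(abs(z))
        out.append(
            TestResult(
                name=f"contrast_{b1}_vs_{b2}",
                statistic=float(z),
                df=None,
                p=float(p),
                p_adjusted=float(min(1.0, m * p)),
                note=f"bonferroni m={m}",
            )
        )
    return out


def kruskal_wallis(groups: Sequence[Sequence[float]], name: str = "kruskal") -> TestResult:
    """Kruskal-Wallis H across groups (midranks, tie-corrected), p from
    chi-square with g-1 df. All-identical values are undefined (flagged)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) == 0 for g in groups) or len(groups) < 2:
        raise ValidationError("Kruskal-Wallis needs >=2 non-empty groups")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return TestResult(
            name=name, statistic=float("nan"), df=len(groups) - 1, p=float("nan"),
            group_sizes=tuple(len(g) for g in groups),
            note="undefined: all values identical (tie correction degenerates)",
        )
    h, p = stats.kruskal(*groups)
    return TestResult(
        name=name, statistic=float(h), df=len(groups) - 1, p=float(p),
        group_sizes=tuple(len(g) for g in groups),
    )


def dunn_adjusted_p(z: float, m: int) -> float:
    """Two-sided Bonferroni-adjusted p for a Dunn z statistic."""
    return float(min(1.0, m * 2.0 * stats.norm.sf(abs(z))))


def dunn_posthoc(
    groups: Sequence[Sequence[float]],
    labels: Optional[Sequence[str]] = None,
    m_comparisons: Optional[int] = None,
) -> list:
    """Dunn's pairwise z tests after a Kruskal-Wallis test.

    Pooled midranks with tie-corrected variance
    ``N(N+1)/12 - sum(t^3 - t) / (12 (N-1))``; two-sided p values are
    Bonferroni-multiplied by ``m_comparisons`` (default: the number of
    pairs) and capped at 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    g = len(groups)
    if g < 2:
        raise ValidationError("Dunn's test needs >=2 groups")
    labels = list(labels) if labels is not None else [f"g{i + 1}" for i in range(g)]
    pooled = np.concatenate(groups)
    n_tot = len(pooled)
    ranks = stats.rankdata(pooled)
    sizes = [len(x) for x in groups]
    mean_ranks = []
    pos = 0
    for s in sizes:
        mean_ranks.append(ranks[pos: pos + s].mean())
        pos += s
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_base = n_tot * (n_tot + 1) / 12.0 - tie_term / (12.0 * (n_tot - 1))
    pairs = list(itertools.combinations(range(g), 2))
    m = m_comparisons if m_comparisons is not None else len(pairs)
    out = []
    for i, j in pairs:
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z)) if se > 0 else 1.0
        out.append(
            TestResult(
                name=f"dunn_{labels[i]}_vs_{labels[j]}",
                statistic=float(z),
                df=None,
                p=float(p),
                p_adjusted=dunn_adjusted_p(z, m) if se > 0 else 1.0,
                group_sizes=(sizes[i], sizes[j]),
                note=f"bonferroni m={m}",
            )
        )
    return out


def spearman_p(rho: float, n: int) -> float:
    """Two-sided p for a Spearman rho via the t approximation
    ``t = rho * sqrt((n - 2) / (1 - rho^2))`` with n-2 df."""
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def spearman_corr(
    x: Sequence[float], y: Sequence[float], n_tests: int = 1, name: str = "spearman"
) -> TestResult:
    """Spearman rank correlation (midranks) with t-approximation p value and
    the Bonferroni-adjusted alpha reported alongside."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValidationError("Spearman needs paired samples with n >= 4")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return TestResult(
            name=name, statistic=float("nan"), df=len(x) - 2, p=float("nan"),
            alpha_adjusted=0.05 / n_tests, note="undefined: zero variance",
        )
    rho = float(stats.spearmanr(x, y).statistic)
    return TestResult(
        name=name,
        statistic=rho,
        df=len(x) - 2,
        p=spearman_p(rho, len(x)),
        alpha_adjusted=0.05 / n_tests,
        group_sizes=(len(x),),
    )


def chi_square_independence(table, name: str = "chi_square") -> TestResult:
    """Pearson chi-square of independence on a two-way count table."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2:
        raise ValidationError("need a 2-way count table")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValidationError("zero marginal in contingency table")
    chi2, p, dof, expected = stats.chi2_contingency(table, correction=False)
    note = None
    if (expected < 5).any():
        note = "expected counts below 5; chi-square approximation is rough"
    return TestResult(
        name=name, statistic=float(chi2), df=float(dof), p=float(p), note=note
    )


@dataclass
class ComparisonReport:
    """Cluster characterization: per-variable tests and the radar panel."""

    kw_tests: dict  # variable -> TestResult
    dunn_tests: dict  # variable -> list[TestResult] (significant KW only)
    panel: pd.DataFrame  # clusters x variables, z-normalized cluster means
    gender_test: Optional[TestResult]
    alpha_itap: float

    def to_dict(self) -> dict:
        return {
            "alpha_itap": self.alpha_itap,
            "kw_tests": {k: v.to_dict() for k, v in self.kw_tests.items()},
            "dunn_tests": {
                k: [t.to_dict() for t in v] for k, v in self.dunn_tests.items()
            },
            "panel": self.panel.to_dict(),
            "gender_test": self.gender_test.to_dict() if self.gender_test else None,
        }


def compare_clusters(
    labels: dict,
    variables: pd.DataFrame,
    itap_vars: Sequence[str] = ITAP_PANEL_VARS,
    gender: Optional[dict] = None,
    alpha: float = 0.05,
) -> ComparisonReport:
    """Compare clusters on dyad-level variables.

    Per variable: Kruskal-Wallis across clusters, Dunn post hoc when the KW
    test clears the variable's alpha (``alpha / len(itap_vars)`` for the task
    scores — 0.007 for the canonical seven — plain ``alpha`` otherwise). The
    radar panel z-normalizes each variable over the cohort and averages
    within cluster. Gender balance is tested by Pearson chi-square.
    """
    ids = list(variables.index)
    missing = [i for i in ids if i not in labels]
    if missing:
        raise ValidationError(f"no cluster label for ids {missing}")
    lab = np.asarray([labels[i] for i in ids])
    clusters = sorted(set(lab))
    if len(clusters) < 2:
        raise ValidationError("need at least 2 clusters to compare")
    sizes = {c: int((lab == c).sum()) for c in clusters}
    for c, s in sizes.items():
        if s < 2:
            warnings.warn(f"cluster {c} has fewer than 2 dyads; tests may be fragile")
    alpha_itap = alpha / max(1, len(itap_vars))
    kw_tests, dunn_tests = {}, {}
    for var in variables.columns:
        vals = variables[var].to_numpy(dtype=float)
        groups = [vals[lab == c] for c in clusters]
        res = kruskal_wallis(groups, name=f"kw_{var}")
        a = alpha_itap if var in itap_vars else alpha
        res.alpha_adjusted = a
        kw_tests[var] = res
        if np.isfinite(res.p) and res.p < a and len(clusters) >= 3:
            dunn_tests[var] = dunn_posthoc(
                groups, labels=[f"c{c}" for c in clusters]
            )
    z = (variables - variables.mean()) / variables.std(ddof=1)
    panel = z.groupby(lab).mean()
    panel.index = [f"cluster_{c}" for c in panel.index]
    gender_test = None
    if gender is not None:
        tab = pd.crosstab(
            pd.Series({i: gender[i] for i in ids}),
            pd.Series({i: labels[i] for i in ids}),
        )
        gender_test = chi_square_independence(tab.to_numpy(), name="gender_by_cluster")
    return ComparisonReport(
        kw_tests=kw_tests,
        dunn_tests=dunn_tests,
        panel=panel,
        gender_test=gender_test,
        alpha_itap=alpha_itap,
    )
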