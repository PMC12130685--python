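"""Statistical battery for the biomarker table.

Group comparisons are gated by Shapiro-Wilk normality (t-test when both
groups look normal, Wilcoxon rank-sum otherwise; chi-square with Yates
continuity correction for 2x2 counts).  Associations use Spearman rank
correlation matrices and ordinary-least-squares models with treatment coding
(female and MCI/AD as reference levels, so reported terms are ``sexM`` and
``dxNL``).  Partial-regression outputs follow the Frisch-Waugh identity: the
slope of response-residuals on focus-residuals equals the full-model
coefficient.  Multiplicity correction offers Holm step-down and
Benjamini-Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "RegressionResult",
    "CorrelationMatrix",
    "GroupComparison",
    "choose_test",
    "group_compare",
    "spearman_matrix",
    "fit_linear_model",
    "partial_regression",
    "adjust_pvalues",
    "percent_increase",
]

_DEFAULT_REFERENCES = {"sex": "F", "dx": "MCIAD"}


@dataclass
class RegressionResult:
    terms: pd.DataFrame  # index: term; columns: estimate, se, t, p
    r2: float
    r2_adj: float
    n: int
    residuals: np.ndarray
    design_columns: tuple[str, ...]


@dataclass
class CorrelationMatrix:
    variables: tuple[str, ...]
    rho: np.ndarray
    p: np.ndarray
    n: int
    degenerate: tuple[str, ...] = ()  # constant variables with undefined rho


@dataclass
class GroupComparison:
    test: str
    statistic: float
    pvalue: float


def choose_test(values_by_group, alpha: float = 0.05) -> str:
    """'t_test' when Shapiro-Wilk retains normality (p >= alpha) in both
    groups, otherwise 'wilcoxon'."""
    groups = list(values_by_group.values()) if isinstance(values_by_group, dict) else list(values_by_group)
    if len(groups) != 2:
        raise ValueError("expected exactly two groups")
    for g in groups:
        if len(np.asarray(g)) < 3:
            raise ValueError("each group needs n >= 3 for the normality gate")
    ps = [sps.shapiro(np.asarray(g, float)).pvalue for g in groups]
    return "t_test" if all(p >= alpha for p in ps) else "wilcoxon"


def _wilcoxon_ranksum(a: np.ndarray, b: np.ndarray) -> GroupComparison:
    # exact null for small tie-free samples, tie-corrected normal otherwise
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (len(a) <= 20 and len(b) <= 20 and not has_ties) else "asymptotic"
    r = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return GroupComparison("wilcoxon", float(r.statistic), float(r.pvalue))


def group_compare(table: pd.DataFrame, variable: str, by: str = "dx",
                  kind: str = "auto", yates: bool = True) -> GroupComparison:
    """Two-sided two-group comparison of ``variable`` across ``by`` levels.

    ``kind``: 'auto' (Shapiro-Wilk gate), 't', 'wilcoxon', or 'chi2' (2x2
    counts with Yates continuity correction by default).
    """
    if variable not in table.columns:
        raise ValueError(f"variable {variable!r} not in table")
    levels = sorted(table[by].unique())
    if len(levels) != 2:
        raise ValueError("group_compare requires exactly two groups")
    a = np.asarray(table.loc[table[by] == levels[0], variable], float)
    b = np.asarray(table.loc[table[by] == levels[1], variable], float)

    if kind == "chi2":
        counts = pd.crosstab(table[variable], table[by]).to_numpy()
        if counts.shape != (2, 2):
            raise ValueError("chi2 comparison needs a 2x2 count table")
        chi2, p, _, _ = sps.chi2_contingency(counts, correction=yates)
        return GroupComparison("chi2", float(chi2), float(p))

    if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
        raise ValueError(f"variable {variable!r} is constant; test degenerate")
    if kind == "auto":
        kind = {"t_test": "t", "wilcoxon": "wilcoxon"}[choose_test([a, b])]
    if kind == "t":
        r = sps.ttest_ind(a, b)
        return GroupComparison("t_test", float(r.statistic), float(r.pvalue))
    if kind == "wilcoxon":
        return _wilcoxon_ranksum(a, b)
    raise ValueError(f"unknown test kind {kind!r}")


def spearman_matrix(table: pd.DataFrame, variables, group_filter=None) -> CorrelationMatrix:
    """Pairwise Spearman rho (average ranks for ties) over complete rows,
    optionally restricted to one diagnostic group."""
    df = table
    if group_filter is not None:
        df = df[df["dx"] == group_filter] if isinstance(group_filter, str) else df[group_filter]
    df = df.loc[:, list(variables)].dropna()
    if len(df) < 3:
        raise ValueError("need >= 3 complete rows for a correlation matrix")
    k = len(variables)
    rho = np.eye(k)
    pmat = np.zeros((k, k))
    degenerate = [v for v in variables if df[v].nunique() == 1]
    for i in range(k):
        for j in range(i + 1, k):
            vi, vj = variables[i], variables[j]
            if vi in degenerate or vj in degenerate:
                rho[i, j] = rho[j, i] = np.nan
                pmat[i, j] = pmat[j, i] = np.nan
                continue
            r = sps.spearmanr(df[vi], df[vj])
            rho[i, j] = rho[j, i] = r.statistic
            pmat[i, j] = pmat[j, i] = r.pvalue
    return CorrelationMatrix(tuple(variables), rho, pmat, len(df), tuple(degenerate))


def _design_matrix(table: pd.DataFrame, covariates, references) -> pd.DataFrame:
    cols = {}
    collinear_check = []
    for var in covariates:
        s = table[var]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == bool:
            levels = sorted(map(str, s.astype(str).unique()))
            ref = references.get(var, levels[0])
            for lev in levels:
                if lev == ref:
                    continue
                cols[f"{var}{lev}"] = (s.astype(str) == lev).astype(float)
        else:
            cols[var] = s.astype(float)
        collinear_check.append(var)
    X = pd.DataFrame(cols, index=table.index)
    return X


def fit_linear_model(table: pd.DataFrame, response: str, covariates,
                     references: dict | None = None) -> RegressionResult:
    """OLS of ``response`` on ``covariates`` with an intercept; categorical
    covariates use treatment coding with the given reference levels (default:
    sex reference F, dx reference MCIAD)."""
    refs = dict(_DEFAULT_REFERENCES)
    if references:
        refs.update(references)
    X = _design_matrix(table, covariates, refs)
    y = table[response].astype(float)
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"n = {n} too small for {p} covariates")
    Xc = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        corr = X.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        worst = corr.stack().idxmax() if p > 1 else (X.columns[0],)
        raise ValueError(f"rank-deficient design; near-collinear terms: {worst}")
    fit = sm.OLS(y, Xc).fit()
    terms = pd.DataFrame({
        "estimate": fit.params, "se": fit.bse, "t": fit.tvalues, "p": fit.pvalues,
    })
    return RegressionResult(
        terms=terms, r2=float(fit.rsquared), r2_adj=float(fit.rsquared_adj),
        n=int(n), residuals=np.asarray(fit.resid), design_columns=tuple(Xc.columns),
    )


def partial_regression(table: pd.DataFrame, response: str, covariates, focus: str,
                       references: dict | None = None):
    """Residual-on-residual view of one coefficient.

    Regress response and focus variable each on the remaining covariates;
    return (x_residuals, y_residuals, partial slope).  By the Frisch-Waugh
    identity the slope equals the focus coefficient of the full model.
    """
    if focus not in covariates:
        raise ValueError(f"focus {focus!r} must be among the covariates")
    others = [c for c in covariates if c != focus]
    refs = dict(_DEFAULT_REFERENCES)
    if references:
        refs.update(references)
    Z = sm.add_constant(_design_matrix(table, others, refs), has_constant="add") if others \
        else pd.DataFrame({"const": np.ones(len(table))}, index=table.index)
    xf = _design_matrix(table, [focus], refs).iloc[:, 0].astype(float)
    y = table[response].astype(float)
    y_res = np.asarray(sm.OLS(y, Z).fit().resid)
    x_res = np.asarray(sm.OLS(xf, Z).fit().resid)
    slope = float(np.dot(x_res, y_res) / np.dot(x_res, x_res))
    return x_res, y_res, slope


def adjust_pvalues(p_values, method: str = "holm") -> np.ndarray:
    """Holm step-down or Benjamini-Hochberg step-up adjustment, preserving
    input order."""
    p = np.asarray(p_values, float)
    if p.ndim != 1 or np.any(p < 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must be a 1D vector in [0, 1]")
    key = {"holm": "holm", "bh": "fdr_bh"}.get(method)
    if key is None:
        raise ValueError("method must be 'holm' or 'bh'")
    return multipletests(p, method=key)[1]


def percent_increase(mean_reference: float, mean_comparison: float) -> float:
    """100 * (comparison - reference) / reference, rounded to one decimal (the
    report convention for group-sensitivity figures)."""
    if mean_reference <= 0:
        raise ValueError("reference mean must be positive")
    return round(100.0 * (mean_comparison - mean_reference) / mean_reference, 1)
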