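"""Cohort-level comparisons and per-taxon differential abundance.

Continuous demographics are compared with the two-sided Wilcoxon
rank-sum test, categoricals with Pearson's chi-square (Yates-corrected
for 2×2). Confounder-adjusted p-values come from an analysis-of-deviance
F-test between a quasi-binomial logistic model with and without the
target variable. Per-taxon differential abundance is summarised as
volcano statistics: log2 fold change of group mean relative abundance
and a Wilcoxon p-value per taxon.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .containers import FeatureTable, FormatError

__all__ = [
    "wilcoxon_test",
    "chisq_test",
    "AdjustedTestResult",
    "adjusted_group_test",
    "taxon_volcano",
    "comparison_table",
]


def wilcoxon_test(x, y) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact enumeration when both samples are small (min n ≤ 8) and
    untied; otherwise the normal approximation with tie correction.
    Missing values are dropped first.
    """
    x = np.asarray(pd.Series(x).dropna(), dtype=float)
    y = np.asarray(pd.Series(y).dropna(), dtype=float)
    if x.size == 0 or y.size == 0:
        raise FormatError("wilcoxon_test: a group is empty after dropping missing values")
    pooled = np.concatenate([x, y])
    ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (min(x.size, y.size) <= 8 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.pvalue)


def chisq_test(table) -> float:
    """Pearson chi-square p-value for an r×c count table.

    Yates continuity correction is applied iff the table is 2×2,
    matching standard epidemiological practice.
    """
    table = np.asarray(table, dtype=float)
    if (table < 0).any():
        raise FormatError("chisq_test: negative counts")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise FormatError("chisq_test: zero row or column margin")
    correction = table.shape == (2, 2)
    res = stats.chi2_contingency(table, correction=correction)
    return float(res.pvalue)


@dataclass
class AdjustedTestResult:
    """Full-vs-reduced model F-test for one predictor, confounder-adjusted."""

    p_value: float | None
    f_statistic: float | None
    df_num: int
    df_den: int
    dispersion: float | None
    converged: bool
    note: str = ""


def _design(meta: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Build a numeric design block, dummy-coding categorical columns."""
    parts = []
    for c in columns:
        col = meta[c]
        if pd.api.types.is_numeric_dtype(col):
            parts.append(col.astype(float).to_frame(c))
        else:
            parts.append(pd.get_dummies(col, prefix=c, drop_first=True, dtype=float))
    return pd.concat(parts, axis=1) if parts else pd.DataFrame(index=meta.index)


def adjusted_group_test(outcome, predictor, confounders) -> AdjustedTestResult:
    """Confounder-adjusted association test via quasi-binomial logistic models.

    Fits ``outcome ~ predictor + confounders`` (full) and
    ``outcome ~ confounders`` (reduced) as binomial GLMs and tests the
    predictor with an analysis-of-deviance F-statistic: the deviance
    difference scaled by the full model's Pearson dispersion, on
    (df_predictor, n − p_full) degrees of freedom. Complete cases only.
    """
    df = pd.concat(
        [pd.Series(outcome, name="__y__"), _design(pd.DataFrame(predictor), list(pd.DataFrame(predictor).columns)),
         _design(pd.DataFrame(confounders), list(pd.DataFrame(confounders).columns))],
        axis=1).dropna()
    y = df["__y__"].astype(float)
    X_full = sm.add_constant(df.drop(columns="__y__"), has_constant="add")
    pred_cols = [c for c in X_full.columns
                 if c != "const" and c not in pd.DataFrame(confounders).columns
                 and not any(c.startswith(f"{k}_") for k in pd.DataFrame(confounders).columns)]
    X_red = X_full.drop(columns=pred_cols)
    # rank-deficient full design (e.g. predictor duplicated in confounders)
    if np.linalg.matrix_rank(X_full.to_numpy(dtype=float)) <= np.linalg.matrix_rank(X_red.to_numpy(dtype=float)):
        raise FormatError("adjusted_group_test: predictor adds no degrees of freedom "
                          "(collinear with confounders)")
    try:
        full = sm.GLM(y, X_full, family=sm.families.Binomial()).fit(scale="X2")
        red = sm.GLM(y, X_red, family=sm.families.Binomial()).fit(scale="X2")
    except Exception as exc:
        return AdjustedTestResult(None, None, len(pred_cols), 0, None, False, f"fit failed: {exc}")
    if not np.isfinite(full.params).all() or np.abs(full.params).max() > 25:
        return AdjustedTestResult(None, None, len(pred_cols), 0, None, False,
                                  "separation suspected: non-finite or extreme coefficients")
    df_num = len(pred_cols)
    df_den = int(full.df_resid)
    dispersion = float(full.scale)
    f_stat = float((red.deviance - full.deviance) / df_num / dispersion)
    p = float(stats.f.sf(f_stat, df_num, df_den))
    return AdjustedTestResult(p, f_stat, df_num, df_den, dispersion, True)


def taxon_volcano(table: FeatureTable, groups, alpha: float = 0.05) -> pd.DataFrame:
    """Per-taxon volcano statistics between two groups.

    Returns one row per taxon with ``log2fc`` (group1 mean relative
    abundance over group0, pseudocount-protected), ``p`` (two-sided
    Wilcoxon), ``neg_log10_p`` and a ``significant`` flag at
    ``p < alpha``; a BH-FDR column ``q`` is included for reference but
    the flags use the raw p-value. Group labels must be binary.
    """
    if table.unit != "relative_abundance":
        raise FormatError("taxon_volcano expects relative abundances")
    groups = pd.Series(groups)
    if groups.index.inferred_type == "integer" and len(groups) == table.n_samples:
        groups.index = table.sample_ids
    groups = groups.reindex(table.sample_ids)
    levels = sorted(pd.unique(groups.dropna()))
    if len(levels) != 2:
        raise FormatError(f"taxon_volcano needs exactly 2 groups, got {levels}")
    m0 = groups == levels[0]
    m1 = groups == levels[1]
    if m0.sum() == 0 or m1.sum() == 0:
        raise FormatError("taxon_volcano: a group is empty")
    vals = table.values
    mean0 = vals.loc[:, m0.to_numpy()].mean(axis=1)
    mean1 = vals.loc[:, m1.to_numpy()].mean(axis=1)
    nz = pd.concat([mean0[mean0 > 0], mean1[mean1 > 0]])
    pc = float(nz.min()) / 2.0 if len(nz) else 1e-12
    # pseudocount substitutes only zero group means, so nonzero fold
    # changes are exact ratios of group means
    log2fc = np.log2(mean1.where(mean1 > 0, pc) / mean0.where(mean0 > 0, pc))
    # identical value multisets give p = 1 and fold change 0 by construction
    pvals = np.array([wilcoxon_test(vals.loc[t, m1.to_numpy()], vals.loc[t, m0.to_numpy()])
                      for t in vals.index])
    out = pd.DataFrame({
        "log2fc": log2fc, "p": pvals, "neg_log10_p": -np.log10(pvals),
        "q": stats.false_discovery_control(pvals, method="bh"),
        "significant": pvals < alpha,
        "mean_group0": mean0, "mean_group1": mean1,
    }, index=vals.index)
    out.index.name = "taxon_id"
    return out


def comparison_table(meta: pd.DataFrame, group: str, variables: list[str],
                     confounders: tuple[str, ...] = ("age", "sex")) -> pd.DataFrame:
    """Demographic comparison table between the two levels of ``group``.

    Continuous variables get mean (SD) per group and a Wilcoxon p;
    categoricals get counts and percentages per level (including an
    explicit Missing category) and a chi-square p. Variables other than
    the confounders also get a confounder-adjusted p from
    :func:`adjusted_group_test` (the group as outcome). Percentages are
    of the full group size, so categories including Missing sum to 100.
    """
    levels = sorted(pd.unique(meta[group].dropna()))
    if len(levels) != 2:
        raise FormatError(f"comparison_table needs a binary group, got {levels}")
    g0 = meta[meta[group] == levels[0]]
    g1 = meta[meta[group] == levels[1]]
    rows = []
    for var in variables:
        if var == group:
            continue
        col = meta[var]
        is_cont = pd.api.types.is_numeric_dtype(col) and col.dropna().nunique() > 2
        adj_p = None
        if var not in confounders and all(c in meta.columns for c in confounders):
            try:
                adj_p = adjusted_group_test(meta[group], meta[[var]], meta[list(confounders)]).p_value
            except FormatError:
                adj_p = None
        if is_cont:
            p = wilcoxon_test(g0[var], g1[var])
            rows.append({"variable": var, "category": "mean (SD)",
                         "group0": f"{g0[var].mean():.1f} ({g0[var].std():.2f})",
                         "group1": f"{g1[var].mean():.1f} ({g1[var].std():.2f})",
                         "p": p, "adjusted_p": adj_p})
            n_miss = (int(g0[var].isna().sum()), int(g1[var].isna().sum()))
            if sum(n_miss):
                rows.append({"variable": var, "category": "Missing",
                             "group0": f"{n_miss[0]} ({100*n_miss[0]/len(g0):.1f}%)",
                             "group1": f"{n_miss[1]} ({100*n_miss[1]/len(g1):.1f}%)",
                             "p": None, "adjusted_p": None})
        else:
            cats = sorted(col.dropna().unique().tolist())
            counts = np.array([[int((g[var] == c).sum()) for g in (g0, g1)] for c in cats])
            p = chisq_test(counts.T[:, counts.sum(axis=1) > 0].T) if counts.size else None
            for c, (n0, n1) in zip(cats, counts):
                rows.append({"variable": var, "category": str(c),
                             "group0": f"{n0} ({100*n0/len(g0):.1f}%)",
                             "group1": f"{n1} ({100*n1/len(g1):.1f}%)",
                             "p": p if c == cats[0] else None,
                             "adjusted_p": adj_p if c == cats[0] else None})
            n_miss = (int(g0[var].isna().sum()), int(g1[var].isna().sum()))
            if sum(n_miss):
                rows.append({"variable": var, "category": "Missing",
                             "group0": f"{n_miss[0]} ({100*n_miss[0]/len(g0):.1f}%)",
                             "group1": f"{n_miss[1]} ({100*n_miss[1]/len(g1):.1f}%)",
                             "p": None, "adjusted_p": None})
    return pd.DataFrame(rows)
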