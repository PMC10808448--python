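"""Alpha and beta diversity with group tests.

Alpha metrics (Observed richness, Chao1, Shannon, Simpson) are computed
per sample from raw counts and compared across groups by one-way ANOVA.
Beta diversity supports Canberra, unweighted UniFrac and (normalised)
weighted UniFrac, with group differences tested by PERMANOVA on the
distance matrix (the ADONIS pseudo-F with label permutations).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.diversity import beta_diversity
from skbio.diversity import alpha as _alpha

from .containers import FeatureTable, FormatError, PhyloTree

__all__ = [
    "ALPHA_METRICS",
    "AlphaResult",
    "PermanovaResult",
    "alpha_diversity",
    "canberra",
    "unifrac",
    "permanova",
]

ALPHA_METRICS = ("observed", "chao1", "shannon", "simpson")

_ALPHA_FUNCS = {
    "observed": lambda c: float(_alpha.sobs(c)),
    # bias-corrected Chao1: S_obs + F1(F1-1) / (2(F2+1))
    "chao1": lambda c: float(_alpha.chao1(c, bias_corrected=True)),
    "shannon": lambda c: float(_alpha.shannon(c, base=np.e)),
    "simpson": lambda c: float(_alpha.simpson(c)),
}


@dataclass
class AlphaResult:
    """Per-sample alpha diversity values plus per-metric ANOVA p-values."""

    values: pd.DataFrame          # samples × metrics
    anova_p: dict | None = None   # metric -> p across groups (if groups given)


def alpha_diversity(table: FeatureTable, metrics=ALPHA_METRICS,
                    groups: pd.Series | None = None) -> AlphaResult:
    """Alpha diversity per sample from a counts table.

    Chao1 relies on singleton/doubleton counts, so it (and Observed)
    requires integer counts; Shannon (natural log) and Simpson
    (1 − Σp²) are computed on within-sample proportions.
    """
    if table.unit != "counts":
        raise FormatError("alpha diversity is computed on raw counts")
    metrics = [m.lower() for m in metrics]
    unknown = set(metrics) - set(ALPHA_METRICS)
    if unknown:
        raise ValueError(f"unknown alpha metric(s): {sorted(unknown)}")
    vals = table.values.to_numpy(dtype=float)
    if ("chao1" in metrics or "observed" in metrics) and not np.allclose(vals, np.round(vals)):
        raise FormatError("Chao1/Observed require integer counts")
    rows = {}
    for j, sid in enumerate(table.sample_ids):
        counts = vals[:, j]
        icounts = counts.astype(np.int64)
        rows[sid] = {m: _ALPHA_FUNCS[m](icounts if m in ("observed", "chao1") else counts)
                     for m in metrics}
    values = pd.DataFrame.from_dict(rows, orient="index")[metrics]
    anova_p = None
    if groups is not None:
        groups = groups.reindex(values.index)
        anova_p = {}
        for m in metrics:
            samples = [values.loc[groups == g, m].dropna() for g in pd.unique(groups.dropna())]
            anova_p[m] = float(stats.f_oneway(*samples).pvalue)
    return AlphaResult(values, anova_p)


def canberra(table: FeatureTable) -> DistanceMatrix:
    """Canberra distance between samples: Σ |x−y| / (x+y), 0/0 terms skipped."""
    if table.n_samples < 2:
        raise FormatError("need at least 2 samples for a distance matrix")
    x = table.values.to_numpy(dtype=float).T  # samples × taxa
    return DistanceMatrix(squareform(pdist(x, metric="canberra")), ids=table.sample_ids)


def unifrac(table: FeatureTable, tree: PhyloTree, weighted: bool = False) -> DistanceMatrix:
    """UniFrac distance between samples on a rooted tree.

    Unweighted: fraction of branch length unique to one sample's taxon
    set (presence/absence only). Weighted: branch lengths weighted by
    abundance-fraction differences, normalised to [0, 1].
    """
    missing = sorted(set(table.taxon_ids) - set(tree.tip_names))
    if missing:
        raise FormatError(f"taxa absent from tree tips: {missing}")
    counts = table.values.to_numpy(dtype=float).T  # samples × taxa
    metric = "weighted_unifrac" if weighted else "unweighted_unifrac"
    kwargs = {"normalized": True} if weighted else {}
    return beta_diversity(metric, counts, ids=table.sample_ids,
                          taxa=table.taxon_ids, tree=tree.tree, validate=True, **kwargs)


@dataclass
class PermanovaResult:
    """PERMANOVA (ADONIS) pseudo-F test of group separation in a distance matrix."""

    statistic: float
    p_value: float
    n_permutations: int
    seed: int
    n_samples: int
    n_groups: int


def _pseudo_f(d2: np.ndarray, labels: np.ndarray, group_codes: np.ndarray) -> float:
    """ADONIS pseudo-F from squared distances and an integer label vector."""
    n = d2.shape[0]
    ss_total = d2.sum() / (2 * n)
    ss_within = 0.0
    for g in group_codes:
        idx = np.flatnonzero(labels == g)
        ss_within += d2[np.ix_(idx, idx)].sum() / (2 * idx.size)
    a = group_codes.size
    ss_between = ss_total - ss_within
    return (ss_between / (a - 1)) / (ss_within / (n - a))


def permanova(dist: DistanceMatrix, groups, n_perm: int = 999, seed: int = 0) -> PermanovaResult:
    """Permutation test of group differences in a distance matrix.

    The observed pseudo-F is compared with its distribution under
    ``n_perm`` random relabellings; p = (1 + #{F_perm ≥ F_obs}) /
    (n_perm + 1), so p is bounded below by 1/(n_perm+1).
    """
    groups = pd.Series(groups)
    if groups.index.inferred_type == "integer" and len(groups) == len(dist.ids):
        groups.index = list(dist.ids)
    labels, codes = pd.factorize(groups.reindex(list(dist.ids)).to_numpy())
    if (labels < 0).any():
        raise FormatError("group label missing for some samples in the distance matrix")
    group_codes = np.arange(len(codes))
    if len(codes) < 2:
        raise FormatError("PERMANOVA needs at least two groups")
    if min(np.bincount(labels)) < 2:
        raise FormatError("each group needs at least 2 samples")
    d2 = np.asarray(dist.data, dtype=float) ** 2
    rng = np.random.default_rng(seed)
    f_obs = _pseudo_f(d2, labels, group_codes)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        if _pseudo_f(d2, perm, group_codes) >= f_obs:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return PermanovaResult(float(f_obs), float(p), n_perm, seed,
                           n_samples=d2.shape[0], n_groups=len(codes))
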