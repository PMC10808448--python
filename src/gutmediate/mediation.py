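"""Difference-of-coefficients mediation of a disease effect on a binary
outcome through high-dimensional microbial mediators.

Three models quantify the pathways (exposure = disease status,
outcome = underweight, mediators = per-taxon log relative abundance,
confounders = age and sex by default):

* **Model 1** — quasi-binomial logistic regression of the outcome on
  exposure + confounders. The exposure coefficient is the *total
  effect* (TE).
* **Model 2** — the same model with mediator(s) added. The exposure
  coefficient is the *direct effect* (DE); each mediator coefficient is
  that mediator's *β-path*. With all mediators at once the mediator
  block is ridge-penalised (exposure and confounders stay unpenalised)
  because the mediator dimension can approach the sample size.
* **Model 3** — ordinary least squares of each mediator on exposure +
  confounders. The exposure coefficient is the *α-path*.

The indirect (mediation) effect is IE = TE − DE, the proportion
mediated PM = IE/TE, and the mediation p-value is the joint-significance
(max-p) test: max of the α-path and β-path Wald p-values.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .containers import FormatError, SampleMetadata, FeatureTable
from .preprocess import MediatorMatrix, build_mediators

log = logging.getLogger(__name__)

__all__ = [
    "ModelFit",
    "MediationConfig",
    "MediationRow",
    "MediationTable",
    "fit_model1",
    "fit_model2_single",
    "fit_model2_all",
    "fit_model3",
    "proportion_mediated",
    "joint_significance",
    "run_mediation",
]

Z95 = 1.96  # normal multiplier for 95% Wald intervals


@dataclass
class ModelFit:
    """Coefficients and Wald inference for one of the mediation models."""

    model: str                      # "1", "2-single", "2-all", "3"
    params: pd.Series
    se: pd.Series
    dispersion: float
    n: int
    converged: bool = True
    flags: list[str] = field(default_factory=list)
    penalty: float | None = None
    penalized: list[str] = field(default_factory=list)

    @property
    def ci_lower(self) -> pd.Series:
        return self.params - Z95 * self.se

    @property
    def ci_upper(self) -> pd.Series:
        return self.params + Z95 * self.se

    @property
    def pvalues(self) -> pd.Series:
        z = self.params / self.se
        return pd.Series(2 * stats.norm.sf(np.abs(z)), index=self.params.index)

    def coef(self, name: str):
        """(estimate, se, ci_low, ci_high, p) for one coefficient."""
        return (float(self.params[name]), float(self.se[name]),
                float(self.ci_lower[name]), float(self.ci_upper[name]),
                float(self.pvalues[name]))


def _complete_design(meta: SampleMetadata, confounders) -> pd.DataFrame:
    df = meta.data
    cols = ["underweight", "exposure", *confounders]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"metadata lacks column(s) {missing}")
    return df[cols].astype(float)


def _quasibinomial_fit(y: pd.Series, X: pd.DataFrame, model_id: str) -> ModelFit:
    """IRLS fit of a binomial GLM with Pearson-dispersion-scaled SEs."""
    try:
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit(scale="X2")
    except Exception as exc:
        raise FormatError(f"model {model_id} failed to fit: {exc}") from exc
    flags = []
    if not res.converged:
        flags.append("IRLS did not converge")
    if (not np.isfinite(res.params).all() or np.abs(res.params).max() > 15
            or np.nanmax(res.bse.to_numpy()) > 1e3):
        flags.append("separation suspected: extreme coefficients or standard errors")
    return ModelFit(model_id, res.params, res.bse, float(res.scale),
                    int(res.nobs), converged=not flags, flags=flags)


def fit_model1(meta: SampleMetadata, confounders=("age", "sex")) -> ModelFit:
    """Model 1: outcome ~ exposure + confounders (quasi-binomial logistic).

    Complete cases only; the exposure coefficient is the total effect.
    Dispersion is Pearson χ²/(n−p); CIs are estimate ± 1.96·SE.
    """
    df = _complete_design(meta, confounders).dropna()
    X = sm.add_constant(df[["exposure", *confounders]], has_constant="add")
    return _quasibinomial_fit(df["underweight"], X, "1")


def fit_model3(mediators: MediatorMatrix, meta: SampleMetadata,
               confounders=("age", "sex")) -> dict[str, ModelFit]:
    """Model 3 per mediator: mediator ~ exposure + confounders (OLS).

    The exposure coefficient is the α-path; its Wald p uses the
    residual-variance standard error and a normal reference.
    """
    df = meta.data.loc[mediators.sample_ids, ["exposure", *confounders]].astype(float)
    keep = df.dropna().index
    X = sm.add_constant(df.loc[keep], has_constant="add")
    fits: dict[str, ModelFit] = {}
    for taxon in mediators.mediator_ids:
        m = mediators.data.loc[keep, taxon].astype(float)
        if m.nunique() <= 1:
            raise FormatError(f"mediator {taxon!r} is constant; Model 3 is undefined")
        res = sm.OLS(m, X).fit()
        fits[taxon] = ModelFit("3", res.params, res.bse,
                               float(res.mse_resid), int(res.nobs))
    return fits


def fit_model2_single(mediator: pd.Series, meta: SampleMetadata,
                      confounders=("age", "sex")) -> ModelFit:
    """Model 2 with one mediator: outcome ~ exposure + mediator + confounders.

    Exposure coefficient = direct effect; mediator coefficient = β-path.
    """
    name = mediator.name or "mediator"
    df = _complete_design(meta, confounders)
    df = pd.concat([df, mediator.rename(name)], axis=1).dropna()
    X = sm.add_constant(df[["exposure", name, *confounders]], has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        fit = ModelFit("2-single", pd.Series(np.nan, index=X.columns),
                       pd.Series(np.nan, index=X.columns), np.nan, len(df),
                       converged=False, flags=[f"mediator {name!r} collinear with design"])
        return fit
    return _quasibinomial_fit(df["underweight"], X, "2-single")


# ---------------------------------------------------------------------------
# Ridge-penalised quasi-binomial logistic regression (mediator block only)

def _ridge_irls(y: np.ndarray, X: np.ndarray, pen_mask: np.ndarray, lam: float,
                max_iter: int = 100, tol: float = 1e-10):
    """IRLS for logistic loss + (lam/2)·Σ_{j penalised} b_j².

    Returns (beta, converged). Unpenalised columns (intercept, exposure,
    confounders) have pen_mask 0.
    """
    n, p = X.shape
    beta = np.zeros(p)
    P = np.diag(pen_mask.astype(float)) * lam
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1 / (1 + np.exp(-eta))
        w = np.clip(mu * (1 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        XtW = X.T * w
        try:
            new = np.linalg.solve(XtW @ X + P, XtW @ z)
        except np.linalg.LinAlgError:
            return beta, False
        if not np.isfinite(new).all():
            return beta, False
        step = np.max(np.abs(new - beta))
        beta = new
        if step < tol:
            return beta, True
    return beta, False


def _deviance(y: np.ndarray, X: np.ndarray, beta: np.ndarray) -> float:
    eta = np.clip(X @ beta, -30, 30)
    mu = np.clip(1 / (1 + np.exp(-eta)), 1e-12, 1 - 1e-12)
    return float(-2 * np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))


def _stratified_folds(y: np.ndarray, k: int, rng: np.random.Generator):
    """Fold assignment keeping both outcome classes in every training set."""
    folds = np.empty(y.size, dtype=int)
    for cls in (0, 1):
        idx = rng.permutation(np.flatnonzero(y == cls))
        folds[idx] = np.arange(idx.size) % k
    return folds


def fit_model2_all(mediators: MediatorMatrix, meta: SampleMetadata,
                   confounders=("age", "sex"), penalty: float | str = "cv",
                   folds: int = 10, seed: int = 0,
                   lambda_grid=None) -> ModelFit:
    """Model 2 with every mediator at once, ridge-penalising only mediators.

    The exposure and confounder coefficients stay unpenalised so that
    the exposure coefficient remains an unshrunken direct effect; the
    mediator block carries an L2 penalty chosen by ``folds``-fold
    stratified cross-validated deviance over ``lambda_grid`` (or set
    ``penalty`` to a number). As penalty → ∞ the mediator coefficients
    vanish and the direct effect approaches the total effect; at
    penalty 0 (with few mediators) the fit matches the unpenalised GLM.
    """
    df = _complete_design(meta, confounders)
    df = pd.concat([df, mediators.data], axis=1).dropna()
    med_ids = mediators.mediator_ids
    cols = ["const", "exposure", *confounders, *med_ids]
    X = sm.add_constant(df[["exposure", *confounders, *med_ids]], has_constant="add")
    Xn = X.to_numpy(dtype=float)
    y = df["underweight"].to_numpy(dtype=float)
    pen_mask = np.array([c in med_ids for c in X.columns])
    flags: list[str] = []

    if penalty == "cv":
        if lambda_grid is None:
            lambda_grid = np.logspace(-3, 3, 21)
        rng = np.random.default_rng(seed)
        if min((y == 0).sum(), (y == 1).sum()) < folds:
            folds = max(2, int(min((y == 0).sum(), (y == 1).sum())))
            flags.append(f"folds reduced to {folds} to keep both classes per fold")
        fold_of = _stratified_folds(y, folds, rng)
        cv_dev = np.zeros(len(lambda_grid))
        for f in range(folds):
            tr, va = fold_of != f, fold_of == f
            for i, lam in enumerate(lambda_grid):
                beta, _ = _ridge_irls(y[tr], Xn[tr], pen_mask, lam)
                cv_dev[i] += _deviance(y[va], Xn[va], beta)
        lam = float(lambda_grid[int(np.argmin(cv_dev))])
    else:
        lam = float(penalty)
        if lam < 0:
            raise ValueError("ridge penalty must be >= 0")

    beta, converged = _ridge_irls(y, Xn, pen_mask, lam)
    if not converged:
        flags.append("ridge IRLS did not converge")
    # Wald-style SEs from the penalised information matrix, scaled by the
    # Pearson dispersion with effective degrees of freedom tr(H).
    eta = np.clip(Xn @ beta, -30, 30)
    mu = 1 / (1 + np.exp(-eta))
    w = np.clip(mu * (1 - mu), 1e-10, None)
    XtWX = (Xn.T * w) @ Xn
    A = XtWX + np.diag(pen_mask.astype(float)) * lam
    Ainv = np.linalg.inv(A)
    edf = float(np.trace(Ainv @ XtWX))
    pearson = float(np.sum((y - mu) ** 2 / w))
    dispersion = pearson / max(y.size - edf, 1.0)
    cov = dispersion * (Ainv @ XtWX @ Ainv)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    return ModelFit("2-all", pd.Series(beta, index=cols), pd.Series(se, index=cols),
                    dispersion, int(y.size), converged=converged, flags=flags,
                    penalty=lam, penalized=list(med_ids))


def proportion_mediated(te: float, de: float, eps: float = 1e-8) -> float:
    """Proportion mediated: (TE − DE) / TE.

    The indirect effect is the coefficient difference TE − DE; PM is
    that difference divided by the total effect. Undefined when the
    total effect is (numerically) zero.
    """
    if abs(te) <= eps:
        raise FormatError(f"proportion mediated undefined: |total effect| <= {eps}")
    return (te - de) / te


def joint_significance(p_alpha: float, p_beta: float) -> float:
    """Joint-significance (max-p) mediation p-value: max of the path p's.

    Mediation requires both the exposure→mediator and mediator→outcome
    paths to be nonzero, so the mediation p-value is the larger of the
    two Wald p-values.
    """
    for p in (p_alpha, p_beta):
        if not (0 <= p <= 1):
            raise ValueError(f"p-value out of [0,1]: {p}")
    return max(p_alpha, p_beta)


@dataclass
class MediationConfig:
    """Settings for an end-to-end mediation run."""

    rank: str | None = None
    prevalence: float = 0.10
    pseudocount: float | str = "auto"
    confounders: tuple[str, ...] = ("age", "sex")
    penalty: float | str = "cv"
    folds: int = 10
    seed: int = 0
    alpha_level: float = 0.05


@dataclass
class MediationRow:
    """One mediator's pathway estimates (or the ALL / total-effect row)."""

    mediator: str
    te: float
    te_ci: tuple[float, float]
    de: float | None = None
    de_ci: tuple[float, float] | None = None
    alpha: float | None = None
    alpha_ci: tuple[float, float] | None = None
    beta: float | None = None
    beta_ci: tuple[float, float] | None = None
    ie: float | None = None
    pm: float | None = None
    p: float | None = None
    significant: bool | None = None


@dataclass
class MediationTable:
    """Full mediation analysis output mirroring a per-taxon pathway table."""

    te_unadjusted: float
    te_unadjusted_ci: tuple[float, float]
    te: float
    te_ci: tuple[float, float]
    all_row: MediationRow
    rows: list[MediationRow]
    skipped: dict[str, str]
    config: MediationConfig
    provenance: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for r in [self.all_row, *self.rows]:
            recs.append({
                "mediator": r.mediator, "TE": r.te,
                "TE_ci_low": r.te_ci[0], "TE_ci_high": r.te_ci[1],
                "DE": r.de,
                "DE_ci_low": None if r.de_ci is None else r.de_ci[0],
                "DE_ci_high": None if r.de_ci is None else r.de_ci[1],
                "alpha": r.alpha,
                "alpha_ci_low": None if r.alpha_ci is None else r.alpha_ci[0],
                "alpha_ci_high": None if r.alpha_ci is None else r.alpha_ci[1],
                "beta": r.beta,
                "beta_ci_low": None if r.beta_ci is None else r.beta_ci[0],
                "beta_ci_high": None if r.beta_ci is None else r.beta_ci[1],
                "IE": r.ie, "PM_percent": None if r.pm is None else 100 * r.pm,
                "p": r.p, "significant": r.significant,
            })
        return pd.DataFrame(recs)


def run_mediation(table: FeatureTable, meta: SampleMetadata,
                  config: MediationConfig | None = None,
                  mediators: MediatorMatrix | None = None) -> MediationTable:
    """End-to-end mediation analysis.

    Preprocesses the feature table into the mediator matrix (unless one
    is supplied), restricts every model to the common complete-case
    sample set (so the TE is identical in every row), fits Model 1, the
    all-mediator Model 2, and per-mediator Models 2/3, and assembles
    the pathway table sorted by mediation p-value.
    """
    config = config or MediationConfig()
    if mediators is None:
        mediators = build_mediators(table, rank=config.rank,
                                    prevalence=config.prevalence,
                                    pseudocount=config.pseudocount)
    # common complete-case set across all three models
    need = ["underweight", "exposure", *config.confounders]
    meta_cc = meta.data.loc[[s for s in mediators.sample_ids if s in meta.data.index]]
    keep = meta_cc[need].dropna().index
    if len(keep) == 0:
        raise FormatError("no complete-case samples for the mediation models")
    dropped = sorted(set(mediators.sample_ids) - set(keep))
    if dropped:
        log.info("run_mediation: %d samples dropped for missing outcome/covariates: %s",
                 len(dropped), dropped[:10])
    meta_cc = SampleMetadata(meta.data.loc[keep].copy())
    med_cc = MediatorMatrix(mediators.data.loc[keep], mediators.pseudocount,
                            dict(mediators.provenance))

    m1 = fit_model1(meta_cc, config.confounders)
    te, _, te_lo, te_hi, _ = m1.coef("exposure")
    m1_unadj = fit_model1(meta_cc, confounders=())
    te_u, _, te_u_lo, te_u_hi, _ = m1_unadj.coef("exposure")

    m2_all = fit_model2_all(med_cc, meta_cc, config.confounders,
                            penalty=config.penalty, folds=config.folds,
                            seed=config.seed)
    de_all = float(m2_all.params["exposure"])
    all_row = MediationRow("ALL", te, (te_lo, te_hi), de=de_all,
                           ie=te - de_all, pm=proportion_mediated(te, de_all))

    m3 = fit_model3(med_cc, meta_cc, config.confounders)
    rows: list[MediationRow] = []
    skipped: dict[str, str] = {}
    for taxon in med_cc.mediator_ids:
        m2 = fit_model2_single(med_cc.data[taxon], meta_cc, config.confounders)
        if not m2.converged and not np.isfinite(m2.params).all():
            skipped[taxon] = "; ".join(m2.flags) or "fit failed"
            continue
        de, _, de_lo, de_hi, _ = m2.coef("exposure")
        beta, _, b_lo, b_hi, p_beta = m2.coef(taxon)
        alpha, _, a_lo, a_hi, p_alpha = m3[taxon].coef("exposure")
        rows.append(MediationRow(
            taxon, te, (te_lo, te_hi), de=de, de_ci=(de_lo, de_hi),
            alpha=alpha, alpha_ci=(a_lo, a_hi), beta=beta, beta_ci=(b_lo, b_hi),
            ie=te - de, pm=proportion_mediated(te, de),
            p=joint_significance(p_alpha, p_beta)))
    for r in rows:
        r.significant = r.p < config.alpha_level
    rows.sort(key=lambda r: (r.p if r.p is not None else np.inf, r.mediator))
    return MediationTable(
        te_unadjusted=te_u, te_unadjusted_ci=(te_u_lo, te_u_hi),
        te=te, te_ci=(te_lo, te_hi), all_row=all_row, rows=rows, skipped=skipped,
        config=config,
        provenance={**med_cc.provenance, "n_samples": len(keep),
                    "n_mediators": len(med_cc.mediator_ids),
                    "ridge_penalty": m2_all.penalty,
                    "model1_flags": m1.flags,
                    "model2_all_flags": m2_all.flags,
                    "dropped_samples": dropped})
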