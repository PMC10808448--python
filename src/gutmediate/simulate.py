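"""Synthetic case-control microbiome cohorts with planted mediation.

The generator emulates the causal structure under study: disease status
(exposure) shifts the latent log-abundance of a designated mediator
subset of taxa (the α-paths); each sample's composition is a softmax of
latent logs (logistic-normal), sequenced to counts by a multinomial
draw; the binary outcome (underweight) depends on the exposure directly
(c′) and on the mediators' log relative abundance (the β-paths), with
age and sex confounding all three arrows. Group sizes, outcome
prevalence and effect scales default to the cohort this package is
designed around: 199 exposed vs 131 control samples and a rare outcome
(11 of 319 with observed BMI).

Every draw comes from one seeded generator, so cohorts are reproducible
byte-for-byte.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit, logsumexp

from .containers import FeatureTable, SampleMetadata

__all__ = ["SimulationConfig", "SyntheticTruth", "generate_cohort", "generate_truth"]


@dataclass
class SimulationConfig:
    """Ground-truth parameters for one synthetic cohort.

    Effect sizes sit on the scales the estimators use: ``alpha`` is the
    exposure-induced shift in a mediator's latent log abundance,
    ``beta`` the per-unit log-relative-abundance effect on the
    outcome's log-odds, ``direct_effect`` the exposure log-odds not
    running through taxa. ``noise_sd`` is the latent log-abundance
    standard deviation; its default is calibrated so that recovered
    path Wald statistics at the default effects match those typical of
    real sparse gut taxa (|z| ≈ 3–5 at n = 330).
    """

    n_exposed: int = 199
    n_control: int = 131
    n_taxa: int = 50
    n_mediators: int = 2
    alpha: float | tuple = -2.0
    beta: float | tuple = -0.35
    direct_effect: float = 1.0
    target_prevalence: float = 11 / 319
    age_mean_exposed: float = 68.4
    age_mean_control: float = 70.4
    age_sd: float = 9.0
    p_female_exposed: float = 0.332
    p_female_control: float = 0.603
    conf_age_taxa: float = 0.1      # per-SD-age shift of mediator latents
    conf_sex_taxa: float = 0.3      # female shift of mediator latents
    conf_age_outcome: float = 0.3   # per-SD-age outcome log-odds
    conf_sex_outcome: float = 1.5   # female outcome log-odds
    noise_sd: float = 2.5
    mediator_base: float = 1.5      # mediator latent log-abundance baseline
    base_range: tuple = (2.5, -2.5)  # non-mediator baselines (linspace)
    depth_meanlog: float = float(np.log(5e4))
    depth_sdlog: float = 0.3
    min_depth: int = 1000
    outcome_scale: str = "log_relative_abundance"  # or "latent" for misspecification studies
    seed: int = 0

    def alphas(self) -> np.ndarray:
        a = np.broadcast_to(np.asarray(self.alpha, dtype=float), (self.n_mediators,))
        return np.array(a)

    def betas(self) -> np.ndarray:
        b = np.broadcast_to(np.asarray(self.beta, dtype=float), (self.n_mediators,))
        return np.array(b)

    def validate(self) -> None:
        assert 0 < self.target_prevalence < 1, "target prevalence must be in (0,1)"
        assert self.min_depth >= 1, "sequencing depth must be >= 1"
        assert 1 <= self.n_mediators <= self.n_taxa, "mediators must be a taxon subset"
        for p in (self.p_female_exposed, self.p_female_control):
            assert 0 < p < 1, "sex probabilities must be in (0,1)"


@dataclass
class SyntheticTruth:
    """The generator's planted parameters, for recovery tests."""

    taxon_ids: list
    mediator_ids: list
    alpha: dict            # taxon -> planted α (0 for non-mediators)
    beta: dict             # taxon -> planted β
    direct_effect: float
    intercept: float
    seed: int
    true_te: float | None = None
    true_de: float | None = None
    true_pm: float | None = None
    #: population exposure coefficient of each mediator's log relative
    #: abundance (the analysis-scale α-path estimand; differs from the
    #: planted latent α by the compositional closure of the softmax)
    true_alpha: dict = field(default_factory=dict)
    product_ie: dict = field(default_factory=dict)  # taxon -> α·β (first-order IE)
    n_mc: int | None = None


def _confounders(cfg: SimulationConfig, rng: np.random.Generator, n_exp: int, n_ctl: int):
    exposure = np.concatenate([np.ones(n_exp), np.zeros(n_ctl)])
    age = np.where(exposure == 1,
                   rng.normal(cfg.age_mean_exposed, cfg.age_sd, exposure.size),
                   rng.normal(cfg.age_mean_control, cfg.age_sd, exposure.size))
    p_fem = np.where(exposure == 1, cfg.p_female_exposed, cfg.p_female_control)
    sex = (rng.random(exposure.size) < p_fem).astype(float)  # 1 = female
    return exposure, age, sex


def _latent_logs(cfg: SimulationConfig, rng, exposure, age, sex):
    """Latent log abundances and log relative abundances (n × taxa)."""
    n = exposure.size
    base = np.empty(cfg.n_taxa)
    base[:cfg.n_mediators] = cfg.mediator_base
    base[cfg.n_mediators:] = np.linspace(*cfg.base_range, cfg.n_taxa - cfg.n_mediators)
    z_age = (age - 69.2) / cfg.age_sd
    latent = np.tile(base, (n, 1))
    med = slice(0, cfg.n_mediators)
    latent[:, med] += (exposure[:, None] * cfg.alphas()
                       + z_age[:, None] * cfg.conf_age_taxa
                       + sex[:, None] * cfg.conf_sex_taxa)
    latent += rng.normal(0.0, cfg.noise_sd, latent.shape)
    logp = latent - logsumexp(latent, axis=1, keepdims=True)
    return latent, logp


def _outcome_eta(cfg: SimulationConfig, exposure, age, sex, latent, logp):
    med = slice(0, cfg.n_mediators)
    med_vals = latent[:, med] if cfg.outcome_scale == "latent" else logp[:, med]
    z_age = (age - 69.2) / cfg.age_sd
    return (cfg.direct_effect * exposure + med_vals @ cfg.betas()
            + cfg.conf_age_outcome * z_age + cfg.conf_sex_outcome * sex)


def _calibrate_intercept(eta: np.ndarray, target: float) -> float:
    """Bisection for the intercept that hits the target mean outcome probability."""
    lo, hi = -40.0, 40.0
    for _ in range(200):
        mid = (lo + hi) / 2
        if expit(mid + eta).mean() < target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def generate_cohort(config: SimulationConfig | None = None):
    """Draw one synthetic cohort.

    Returns ``(FeatureTable[counts], SampleMetadata, SyntheticTruth)``.
    BMI is back-filled to be consistent with the drawn outcome (below
    or above the 18.5 cutoff); it exercises the outcome-derivation path
    and is not a realistic BMI model. Raises if 100 outcome redraws
    cannot produce both outcome classes.
    """
    cfg = config or SimulationConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_exposed + cfg.n_control
    exposure, age, sex = _confounders(cfg, rng, cfg.n_exposed, cfg.n_control)
    latent, logp = _latent_logs(cfg, rng, exposure, age, sex)

    depth = np.maximum(np.round(rng.lognormal(cfg.depth_meanlog, cfg.depth_sdlog, n)),
                       cfg.min_depth).astype(np.int64)
    probs = np.exp(logp)
    counts = np.vstack([rng.multinomial(depth[i], probs[i] / probs[i].sum())
                        for i in range(n)])

    eta = _outcome_eta(cfg, exposure, age, sex, latent, logp)
    intercept = _calibrate_intercept(eta, cfg.target_prevalence)
    p_out = expit(intercept + eta)
    for attempt in range(100):
        outcome = (rng.random(n) < p_out).astype(float)
        if 0 < outcome.sum() < n:
            break
    else:
        raise RuntimeError(
            "could not realise both outcome classes in 100 redraws; "
            "adjust target_prevalence (the calibrated intercept is too extreme)")

    bmi = np.where(outcome == 1, rng.uniform(16.0, 18.4, n),
                   np.clip(rng.normal(27.0, 4.5, n), 19.0, None))
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    taxon_ids = [f"taxon{t + 1:03d}" for t in range(cfg.n_taxa)]

    lineages = pd.DataFrame({
        "kingdom": "Bacteria",
        "genus": taxon_ids,
        # sparse species annotation, as in real 16S taxonomy tables
        "species": [tid if (t % 5) else np.nan for t, tid in enumerate(taxon_ids)],
    }, index=pd.Index(taxon_ids))
    table = FeatureTable(pd.DataFrame(counts.T, index=taxon_ids, columns=sample_ids),
                         unit="counts", lineages=lineages)
    meta = SampleMetadata(pd.DataFrame({
        "exposure": exposure, "bmi": np.round(bmi, 1), "age": np.round(age, 1),
        "sex": sex,
    }, index=pd.Index(sample_ids, name="sample_id")))

    alphas, betas = cfg.alphas(), cfg.betas()
    med_ids = taxon_ids[:cfg.n_mediators]
    truth = SyntheticTruth(
        taxon_ids=taxon_ids, mediator_ids=med_ids,
        alpha={t: (float(alphas[i]) if i < cfg.n_mediators else 0.0)
               for i, t in enumerate(taxon_ids)},
        beta={t: (float(betas[i]) if i < cfg.n_mediators else 0.0)
              for i, t in enumerate(taxon_ids)},
        direct_effect=cfg.direct_effect, intercept=float(intercept), seed=cfg.seed,
        product_ie={t: float(alphas[i] * betas[i]) for i, t in enumerate(med_ids)})
    return table, meta, truth


def generate_truth(config: SimulationConfig | None = None, n_mc: int = 100_000,
                   seed: int | None = None) -> SyntheticTruth:
    """Monte-Carlo ground truth for the difference-of-coefficients estimand.

    Simulates a large population from the same mechanism (skipping the
    count draw — the latent log relative abundances are used directly),
    then fits the population-level logistic contrasts: the total effect
    from outcome ~ exposure + confounders and the direct effect from
    the model that additionally conditions on the mediators. The "true"
    proportion mediated is (TE − DE)/TE on those population fits.
    """
    cfg = config or SimulationConfig()
    cfg.validate()
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed + 1_000_003)
    frac_exp = cfg.n_exposed / (cfg.n_exposed + cfg.n_control)
    n_exp = int(round(n_mc * frac_exp))
    exposure, age, sex = _confounders(cfg, rng, n_exp, n_mc - n_exp)
    latent, logp = _latent_logs(cfg, rng, exposure, age, sex)
    eta = _outcome_eta(cfg, exposure, age, sex, latent, logp)
    intercept = _calibrate_intercept(eta, cfg.target_prevalence)
    y = (rng.random(n_mc) < expit(intercept + eta)).astype(float)

    z_age = (age - 69.2) / cfg.age_sd
    X1 = sm.add_constant(np.column_stack([exposure, z_age, sex]))
    te = float(sm.GLM(y, X1, family=sm.families.Binomial()).fit().params[1])
    med = logp[:, :cfg.n_mediators] if cfg.outcome_scale != "latent" else latent[:, :cfg.n_mediators]
    X2 = sm.add_constant(np.column_stack([exposure, z_age, sex, med]))
    de = float(sm.GLM(y, X2, family=sm.families.Binomial()).fit().params[1])

    alphas, betas = cfg.alphas(), cfg.betas()
    taxon_ids = [f"taxon{t + 1:03d}" for t in range(cfg.n_taxa)]
    med_ids = taxon_ids[:cfg.n_mediators]
    # analysis-scale α-path estimand: population OLS of log relative
    # abundance on exposure + confounders, per mediator
    X3 = sm.add_constant(np.column_stack([exposure, z_age, sex]))
    true_alpha = {med_ids[j]: float(sm.OLS(logp[:, j], X3).fit().params[1])
                  for j in range(cfg.n_mediators)}
    return SyntheticTruth(
        taxon_ids=taxon_ids, mediator_ids=med_ids,
        alpha={t: (float(alphas[i]) if i < cfg.n_mediators else 0.0)
               for i, t in enumerate(taxon_ids)},
        beta={t: (float(betas[i]) if i < cfg.n_mediators else 0.0)
              for i, t in enumerate(taxon_ids)},
        direct_effect=cfg.direct_effect, intercept=float(intercept), seed=seed,
        true_te=te, true_de=de, true_pm=(te - de) / te, true_alpha=true_alpha,
        product_ie={t: float(alphas[i] * betas[i]) for i, t in enumerate(med_ids)},
        n_mc=n_mc)


def truth_to_dict(truth: SyntheticTruth) -> dict:
    return asdict(truth)
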