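# Methods

## Scope and data model

`gutmediate` operates on a taxa × samples abundance table (counts or
relative abundances, optionally with rank-labelled lineages), a
per-sample metadata table (binary exposure, BMI, age, sex, arbitrary
extra covariates), and optionally a rooted Newick tree for UniFrac. The
binary outcome *underweight* is always derived as BMI < 18.5 (strict)
and is missing exactly when BMI is; it is never read from the input
file. Upstream read processing (primer trimming, denoising, taxonomy
assignment) is out of scope: the pipeline consumes an already-built
taxon table.

## Preprocessing

The mediator matrix is built as: aggregate to the working rank (taxa
unannotated at that rank are dropped and counted) → divide each sample
by its total count → keep taxa detected in **strictly more than** 10%
of samples (the strict inequality matters at cohort scale: presence in
34 of 330 samples passes, 33 does not) → take the natural log of
relative abundance plus a pseudocount.

The log scale is a documented assumption: per-taxon exposure effects of
magnitude ≈ 2 are implausible on the raw relative-abundance scale
(which is bounded by 1) and natural on the log scale, so the mediation
models operate on `ln(RA + pc)`. The default pseudocount is half the
smallest nonzero relative abundance in the table, keeping zeros below
every observed value; raw relative abundance remains available through
the `pseudocount`/config options for sensitivity analyses. No
rarefaction and no CLR/ILR transforms are applied.

## Diversity

Alpha diversity is computed per sample on raw (unrarefied) counts —
Observed richness, bias-corrected Chao1
($S_{obs} + F_1(F_1-1)/(2(F_2+1))$), Shannon ($-\sum p \ln p$), Simpson
($1-\sum p^2$) — via scikit-bio, with a one-way ANOVA per metric across
groups. Beta diversity supports Canberra (scipy), unweighted UniFrac
and normalised weighted UniFrac (scikit-bio, on the supplied rooted
tree). PERMANOVA is implemented directly from the squared-distance
decomposition (the ADONIS pseudo-F); its statistic is checked against
scikit-bio's in the test suite, and the permutation p-value
$(1 + \#\{F_{perm} \ge F_{obs}\})/(n_{perm}+1)$ uses a mandatory seed
(default 999 permutations).

## Cohort statistics

Continuous variables: two-sided Wilcoxon rank-sum, exact enumeration
when both groups are small (min n ≤ 8) and untied, otherwise the
normal approximation with tie correction. Categorical variables:
Pearson chi-square with Yates continuity correction iff 2×2 (the
correction is what reproduces the reference cohort's
underweight-by-disease p = 0.239). Confounder-adjusted p-values come
from an analysis-of-deviance F-test between full and reduced
quasi-binomial logistic models: $F = (D_{red}-D_{full})/(q\,\hat\phi)$
with $\hat\phi$ the full model's Pearson dispersion, on
$(q,\,n-p_{full})$ degrees of freedom — the quasi-likelihood F
convention rather than a likelihood-ratio chi-square. Volcano rows
carry the log2 ratio of group mean relative abundances (pseudocount
substituted only for zero group means, so nonzero fold changes are
exact ratios), the Wilcoxon p, and a significance flag at raw p < 0.05;
a BH-FDR column is emitted for reference but does not drive the flags,
matching the raw-p convention of the headline analysis.

## Mediation analysis

Models, estimands and the max-p test are described in the README. Key
numerical choices:

* **Common complete-case set.** Samples missing the outcome (BMI),
  exposure or a confounder are dropped once, before any model, so the
  TE is identical in every row of the output table. The unadjusted TE
  is reported alongside the adjusted one (the adjusted value is the
  default reference).
* **Quasi-binomial inference.** Dispersion is Pearson χ²/(n−p); CIs
  are estimate ± 1.96·SE; p-values use the normal reference. This
  reproduces, to rounding, published mediation p-values when applied
  to printed path estimates and CIs.
* **Ridge on mediators only.** In the all-mediator Model 2 the penalty
  $\tfrac{\lambda}{2}\sum_{j \in \text{mediators}} \beta_j^2$ is added
  to the negative log-likelihood and solved by IRLS; exposure,
  confounders and intercept are unpenalised so the DE stays an
  unshrunken exposure coefficient. λ is chosen by 10-fold stratified
  (by outcome) cross-validated deviance over a log grid 10⁻³–10³, with
  a mandatory seed; folds are reduced automatically if an outcome
  class is rarer than the fold count. Mediators are penalised on their
  native log-RA scale (no internal standardisation), which is
  homogeneous across taxa by construction.
* **Separation.** With ~11 events, quasi-complete separation of the
  exposure is a real possibility (a replicate with zero control-group
  events). Fits with extreme coefficients (>15) or standard errors
  (>10³) are flagged, not silently reported; flagged per-taxon fits go
  to a skipped list, and downstream consumers are expected to treat
  flagged TE/DE values as unusable.
* **PM guard.** PM is undefined when |TE| ≤ 1e-8 (configurable) and is
  reported as a percentage with two decimals in tables.

### Known limitations

* **CV-ridge PM is conservative.** With a rare outcome the
  cross-validated penalty is large, the mediator block shrinks hard,
  and the ALL-row DE moves toward the TE: the joint PM estimate
  understates the true proportion mediated (in the default synthetic
  conditions, a point estimate around 10–40% against a Monte-Carlo
  truth of ~53%). The per-taxon rows, which need no penalty, do not
  share this bias. The test suite asserts the direction (attenuation,
  conservativeness), not truth recovery, for the ALL row.
* **Non-collapsibility.** TE − DE on the logit scale is not exactly a
  product-of-paths indirect effect; for a rare outcome (~3%) the two
  agree to within ~20% relative error, which the suite checks at the
  default conditions. For common outcomes the difference-of-
  coefficients PM should not be interpreted causally.
* **Weakly penalised all-mediator fits at ~11 events are unstable**
  (rare-event bias inflates coefficients); the penalty-0 path is
  validated against the unpenalised GLM on configurations with a
  common outcome where the MLE is regular.

## Synthetic cohorts

The generator emulates the causal graph exposure → taxa → outcome with
age and sex into all three nodes:

1. Group sizes fixed at 199 exposed / 131 control. Age ~
   N(68.4, 9²) for exposed, N(70.4, 9²) for controls; P(female) 0.332
   vs 0.603 — the groups differ in both confounders by construction.
2. Latent log abundances: fixed baselines (mediators at 1.5;
   the other taxa spanning 2.5 … −2.5), plus α·exposure and small
   age/sex effects on mediator taxa, plus N(0, 2.5²) noise. Sample
   compositions are the softmax of the latent logs (logistic-normal),
   so taxa are compositionally coupled as in real relative-abundance
   data. Counts are multinomial at a lognormal depth (~5·10⁴).
3. Outcome: Bernoulli with logit = intercept + c′·exposure +
   Σβ_j·(log relative abundance)_j + confounder terms; the intercept
   is calibrated by bisection to a target prevalence of 11/319. BMI is
   back-filled consistently with the outcome (it exercises the
   BMI-threshold path, not a realistic BMI model).

Defaults (2 mediators, α = −2.0, β = −0.35, c′ = 1.0, noise SD 2.5)
were calibrated so that the recovered path Wald statistics at n = 330
match those of significant pathways in real cohorts of this design
(|z_α| ≈ 5–6, |z_β| ≈ 3) while keeping the total effect near 1.8–2.2
log-odds with realistically rare control-group events (~1–2 of 131).
β is somewhat larger in magnitude than typical published per-taxon
coefficients because the synthetic mediators' log-RA spread (SD ≈ 2.6)
is narrower than that of real sparse taxa; the standardised pathway
strength β·sd(M) is the matched quantity. With these defaults the
Monte-Carlo true proportion mediated is ≈ 0.53.

`generate_truth` computes the ground truth on the analysis scale by
Monte-Carlo marginalisation: a large population (default 10⁵–2·10⁵) is
simulated from the same mechanism without the count step, and TE/DE
come from population-level logistic fits with and without the
mediators; the per-mediator α estimand is the population OLS
coefficient of exposure on log relative abundance (which differs from
the planted latent α by the compositional closure, ≈ +0.1 at the
defaults — CI coverage is assessed against this estimand, as coverage
is a statement about the estimand, not about another scale's
parameter).

What the generator does **not** emulate: zero-inflation beyond what the
multinomial induces, batch effects, phylogenetic correlation between
taxa, longitudinal structure, and realistic BMI distributions. Passing
recovery tests therefore demonstrate correctness of the estimation
machinery under the stated generative model, not robustness to every
feature of real 16S data.

## Problem sizes in the test suite

Simulation-based tests use 15–200 replicates per property at the full
cohort size (n = 330, 50 taxa): 200 replicates for CI coverage,
detection power, type-I control and sign recovery; 40 for ALL-row
attenuation; 15 for the CV-heavy end-to-end PM checks (each involves a
full cross-validated ridge path). PERMANOVA null calibration uses 200
replicates of 16 samples at 199 permutations; exact-oracle tests
enumerate all label arrangements at n ≤ 8. These sizes put every Monte-
Carlo assertion's tolerance at ≥ 3 of its standard errors.
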