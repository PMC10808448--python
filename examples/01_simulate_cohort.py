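"""Draw a synthetic case-control microbiome cohort with planted mediation.

The generator emulates a two-group cohort (199 exposed, 131 controls)
with a rare binary outcome (~3.4%), age/sex confounding, and two taxa
whose latent log abundance is shifted by the exposure and which in turn
shift the outcome's log-odds.
"""
from gutmediate import SimulationConfig, generate_cohort, generate_truth

cfg = SimulationConfig(seed=42)
table, meta, truth = generate_cohort(cfg)

print(f"counts table: {table.n_taxa} taxa x {table.n_samples} samples")
print(f"exposed: {int(meta.data.exposure.sum())}, "
      f"underweight: {int(meta.data.underweight.sum())} "
      f"(missing BMI: {int(meta.data.bmi.isna().sum())})")
print(f"planted mediators: {truth.mediator_ids}")
print(f"planted paths: alpha={cfg.alpha}, beta={cfg.beta}, direct={cfg.direct_effect}")

mc = generate_truth(cfg, n_mc=100_000)
print(f"Monte-Carlo truth: TE={mc.true_te:.3f}  DE={mc.true_de:.3f}  "
      f"PM={100 * mc.true_pm:.1f}%")
# TE is the exposure's total log-odds effect on the outcome; PM is the
# fraction of it that flows through the planted taxa.
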