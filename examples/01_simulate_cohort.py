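"""Generate a synthetic methylation cohort and inspect its structure.

The generator emulates a multicentre child cohort assayed on a 450K-style
array: exposure groups with realistic covariate marginals, 6-cell-type
blood mixtures, slide/array batch structure, and five planted exposure
effects on the beta scale.
"""

from methewas import SimulationConfig, default_effects, simulate_cohort

config = SimulationConfig(n_probes=2000, seed=1)
cohort = simulate_cohort(config)

sheet = cohort.sheet.frame
print(f"samples: {len(sheet)}  "
      f"(unexposed {(sheet.exposure == 0).sum()}, "
      f"exposed {(sheet.exposure == 1).sum()}, "
      f"early-only/missing {sheet.exposure.isna().sum()})")
print(f"probes: {cohort.raw.meth.shape[0]}, "
      f"negative controls: {cohort.raw.controls_red.shape[0]}")
print("planted effects (probe, delta-beta):")
for name, delta in default_effects():
    print(f"  {name}  {delta:+.2f}")

# The exposed group differs in covariates too (confounding the pipeline
# must adjust away): e.g. maternal postnatal smoking by exposure group.
rate = sheet.groupby("exposure", observed=True)["mother_smokes_age4"] \
    .mean().astype(float)
print("P(mother smokes at age 4) by exposure:", dict(rate.round(2)))
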