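# Demo-scale pipeline configuration: a 2,000-subject synthetic cohort with
# three planted canonical correlations, reduced table widths and bootstrap
# counts so the full run completes in well under a minute on one CPU.
seed: 0
stages: [synth, deconfound, cca, divergence, phewas, clustering, interactions, latent, projection]

synth:
  n_subjects: 2000
  k_planted: 3
  planted_rhos: [0.51, 0.42, 0.39]
  n_phenotypes: 60
  n_risk_factors: 63

cca:
  k: 3

divergence:
  B: 50
  lower_pct: 10.0
  upper_pct: 90.0

phewas:
  modes: [1]
  lower_pct: 5.0
  upper_pct: 95.0

clustering:
  levels: 3

interactions:
  B: 200
  n_risk_outcomes: 2
  modes: [1]
  sides: [DN]

latent:
  B: 25
  n_components: 3

projection:
  n_external: 400
  n_phenotypes: 157
  B: 200
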