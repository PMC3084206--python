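# Minimal-medium diauxie: 1.0 mg/ml glucose + 1.5 mg/ml arabinose.
# Glucose is consumed first; its exhaustion produces one growth pause and
# one burst from the polymerase-limited spo0A-like promoter.
name: diauxie_mid_glucose
medium:
  substrates:
    - {name: glucose, conc: 1.0, mu_max: 0.9, K_s: 0.05, yield_od: 0.4}
    - {name: arabinose, conc: 1.5, mu_max: 0.65, K_s: 0.08, yield_od: 0.35}
  repression_order: [glucose, arabinose]
  induction_rate: 5.0
  decay_rate: 0.0
rnap: {f_max: 0.95, K_mu: 0.6, R_total: 1.0}
promoters:
  - {name: spo0A, kind: constitutive, strength: 1.0, K_R: 2.0,
     initiating_nucleotide: A}
reporter: {half_life: 0.1, light_coeff: 100000.0}
sampling_interval: 0.025
duration: 8.0
initial_biomass: 0.05
noise_cv: 0.02
od_background: 0.04
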