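# Minimal-medium diauxie: 2.5 mg/ml glucose in excess, no arabinose.
# With glucose in excess there is no diauxic shift: the growth-rate
# pause and the corresponding transcription burst are eliminated.
name: diauxie_glucose_only
medium:
  substrates:
    - {name: glucose, conc: 2.5, mu_max: 0.9, K_s: 0.05, yield_od: 0.4}
    - {name: arabinose, conc: 0.0, mu_max: 0.65, K_s: 0.08, yield_od: 0.35}
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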