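# Translation-arrest (puromycin-like) reference scenario: steady single-
# substrate growth with one constitutive reporter fusion.  Arresting at
# 1.0 h freezes biomass and silences transcription, so the luminescence
# decays as a pure exponential with the reporter's degradation rate --
# the run used to calibrate the reporter half-life by log-linear fitting.
name: arrest
medium:
  substrates:
    - {name: glucose, conc: 2.5, mu_max: 0.8, K_s: 0.05, yield_od: 0.4}
  repression_order: [glucose]
rnap: {f_max: 0.95, K_mu: 0.6, R_total: 1.0}
promoters:
  - {name: spo0A_core, kind: constitutive, strength: 1.0, K_R: 0.5,
     initiating_nucleotide: A}
reporter: {half_life: 0.1, light_coeff: 100000.0}
sampling_interval: 0.025
duration: 2.0
initial_biomass: 0.05
noise_cv: 0.02
od_background: 0.04
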