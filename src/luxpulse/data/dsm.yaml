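# Sporulation-medium (DSM-like) reference scenario.
#
# Growth consumes four ranked nutrient pools; exhaustion of pools a and b
# produces the two growth-phase pauses, exhaustion of pool c the pause at
# entry to stationary phase, and exhaustion of the slow pool d ends growth
# (T0).  The spo0A-like vegetative promoter is a polymerase-limited
# constitutive promoter, so each pause releases polymerase from rRNA genes
# and bursts its activity; scripted stationary-phase activation waves stand
# in for the sigH-dependent promoter takeover, calibrated so the
# growth-phase peaks reach about half to three-quarters of the final
# maximum.  The GTP pool dips only during the first pause, which blunts
# G-initiating promoters but leaves the A-initiating spo0A promoter alone.
name: dsm
medium:
  substrates:
    - {name: nutrient_a, conc: 0.6, mu_max: 1.4, K_s: 0.1, yield_od: 0.5}
    - {name: nutrient_b, conc: 0.8, mu_max: 1.15, K_s: 0.1, yield_od: 0.5}
    - {name: nutrient_c, conc: 1.6, mu_max: 0.95, K_s: 0.1, yield_od: 0.5}
    - {name: nutrient_d, conc: 1.2, mu_max: 0.7, K_s: 0.1, yield_od: 0.5}
  repression_order: [nutrient_a, nutrient_b, nutrient_c, nutrient_d]
  induction_rate: 5.0
  decay_rate: 0.0
rnap: {f_max: 0.95, K_mu: 0.6, R_total: 1.0}
promoters:
  - {name: spo0A, kind: constitutive, strength: 1.0, K_R: 2.0,
     initiating_nucleotide: A}
  - {name: rrnB, kind: rrn_like, strength: 1.0,
     initiating_nucleotide: G, intp_K: 0.5}
  - {name: abrB, kind: repressed, strength: 0.8, K_R: 2.0,
     regulator_K: 0.06, hill_n: 2.0, initiating_nucleotide: A}
  - {name: spoIIG, kind: activated, strength: 5.0,
     regulator_K: 0.28, hill_n: 4.0, initiating_nucleotide: A}
  - {name: comK, kind: activated, strength: 1.0,
     regulator_K: 0.12, hill_n: 3.0, initiating_nucleotide: A}
reporter: {half_life: 0.1, light_coeff: 100000.0}
spo0a: {gamma_P: 3.0, k_phos: 6.0, k_deph: 4.0}
spo0a_promoter: spo0A
gtp_dip_schedule:
  - {start: 1.4, end: 1.9, depth: 0.4}
stationary_program:
  - {promoter: spo0A, time: 4.65, step: 0.14}
  - {promoter: spo0A, time: 4.85, step: -0.10}
  - {promoter: spo0A, time: 5.30, step: 0.18}
  - {promoter: spo0A, time: 5.55, step: -0.11}
  - {promoter: spo0A, time: 6.30, step: 0.08}
  - {promoter: spo0A, time: 6.90, step: 0.08}
sampling_interval: 0.025
duration: 8.0
initial_biomass: 0.1
noise_cv: 0.02
od_background: 0.04
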