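# luxpulse

Tools for measuring the **rate** of transcription from plate-reader time
courses of bacteria carrying promoter fusions to destabilized firefly
luciferase, together with a generative simulator of the biology that makes
those measurements interesting: diauxic growth pauses, passive
reallocation of RNA polymerase away from rRNA genes, and the Spo0A~P
master-regulator responses of *Bacillus subtilis*.

## The problem

A conventional reporter (lacZ, stable GFP) accumulates, so its signal
integrates transcription and hides fast dynamics.  Firefly luciferase is
unstable in *B. subtilis* (half-life t½ ≈ 6 min), so the emitted light
tracks the *instantaneous* transcription rate.  With OD600 and
luminescence (RLU) sampled every ~1.5 min in a 96-well reader, one can
resolve events such as transient bursts of *spo0A* transcription that
coincide with diauxie-like pauses in growth.

The quantities this package computes from a dual-channel run:

- **Growth rate** — μ̂(t) = d ln OD/dt, from local least-squares
  (Savitzky–Golay) polynomial fits of ln OD.
- **Promoter activity** — either the classical OD-corrected readout
  A_naive = RLU/OD, or the deconvolved rate estimate

      A_dec(t) = (dRLU/dt + δ·RLU) / OD,      δ = ln 2 / t½,

  which inverts the reporter kinetics dl/dt = A(t) − δl per cell.
- **Reporter half-life** — log-linear fit of the luminescence decay after a
  translation arrest (puromycin-style experiment).
- **Events** — growth-rate pauses (scale-free local minima of μ̂), activity
  bursts (prominence-based local maxima), their greedy nearest-time
  pairing, and the phase displacement between μ̂ and activity from the
  cross-correlation extremum in units of the dominant oscillation period.
- **Downstream statistics** — Hill responses of Spo0A~P target promoters,
  an inhomogeneous-Poisson hazard model for rare transitions to
  competence, and exact (Clopper–Pearson) binomial intervals for rare-event
  frequencies such as spores per viable count.

The simulator (`luxpulse.simulate`) produces the matching ground truth:
multi-substrate Monod growth with catabolite repression and induction
lags, polymerase allocation f_rrn(μ) = f_max·μ/(μ+K_μ), promoter classes
(constitutive / rRNA-like / Spo0A~P-repressed / -activated, with optional
initiating-nucleotide GTP sensitivity), reporter kinetics, and a
measurement layer with multiplicative log-normal noise — so every analysis
stage can be validated against known inputs.

## Worked example

Run the bundled sporulation-medium (DSM-like) scenario end to end —
simulate, render noisy plate data, blank-correct, estimate μ̂ and
deconvolved activity, and detect events:

```python
from luxpulse.pipeline import run_pipeline
out = run_pipeline({"scenario": "dsm", "seed": 1}, "dsm_run")
```

`dsm_run/events.json` then contains (seed 1):

```
T0 = 4.98 h                           # entry into stationary phase
pauses at 1.53, 2.68, 3.75 h          # growth-rate minima, depths ~0.9
bursts at 1.50, 2.65, 3.73, 4.75, 5.43 h   # five bursts on the spo0A channel
pairs: each of the three pauses matches a burst within 0.03 h
phase(mu, spo0A activity) = 196 degrees     # antiphase, ~180
r(mu, rrnB) = +0.96,  r(mu, spo0A) = -0.89  # rRNA parallels growth,
                                            # spo0A opposes it
```

and `dsm_run/response.json` reports rare competence transitions sampled
from the comK-channel hazard: 0 of 20,000 cells before the first burst
(0.65 h) and 30 of 20,000 (0.15%) after the second (3.4 h).

Count statistics work directly from printed numbers:

```python
>>> from luxpulse.response import event_frequency, sporulation_frequency, fold_change
>>> event_frequency(30, 23000).frequency_pct       # comK-gfp positive cells
0.1304...                                          # -> 0.13%
>>> sporulation_frequency(0.16e8, 0.78e8)          # wild type, 48 h
20.51...
>>> fold_change(20.5, 2.15)
9.53...                                            # ~ten-fold
```

The same stages are available from a shell:

```bash
luxpulse simulate --scenario dsm --seed 1 --wells 2 --out run.csv
luxpulse analyze run.csv --estimator deconvolved --out report.json
luxpulse events report.json --channel spo0A --out events.json
luxpulse simulate-arrest --at 1.0 --seed 1 --out arrest.csv
luxpulse halflife arrest.csv --at 1.0
luxpulse freq --positives 30 --total 23000
```

## Layout

- `luxpulse.scenarios` — scenario schema (medium, polymerase allocation,
  promoters, reporter) with strict YAML/JSON loading; bundled scenarios
  `dsm`, `diauxie_{low,mid}_glucose`, `diauxie_glucose_only`, `arrest`.
- `luxpulse.simulate` — ODE simulator, Spo0A~P cascade, reporter kinetics,
  plate-run rendering, translation arrest.
- `luxpulse.plate` — long/wide CSV IO, blank correction, replicate
  alignment, gap filling.
- `luxpulse.kinetics` — smoothing/differentiation, growth rate, naive and
  deconvolved activity estimators, half-life fitting.
- `luxpulse.events` — T0 definition, pause/burst detection, event pairing,
  phase and correlation analysis.
- `luxpulse.response` — Spo0A~P target responses, stochastic transitions,
  frequency statistics, count tables.
- `luxpulse.pipeline` / `luxpulse.cli` — the end-to-end pipeline and the
  `luxpulse` command.

See `docs/methods.md` for the model equations, parameter choices, and
known limitations.
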