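# pipgate

Quantitative analysis of ligand-activated ion-channel gating from
single-channel patch-clamp records, built around the case of the epithelial
sodium channel (ENaC) activated by the anionic membrane lipid PIP₂
(phosphatidylinositol 4,5-bisphosphate).

The package is aimed at channel biophysicists who want to go from a raw
current trace (or a fully synthetic one with known ground truth) to gating
statistics and fitted models:

- **Markov gating schemes.** Ligand-dependent continuous-time Markov chains
  with open/closed conductance classes: a pseudo-first-order two-state scheme
  C ⇌ O (opening rate k₁·[L], closing rate k₋₁) and a sequential
  two-binding-site chain C ⇌ O₁ ⇌ O₂ in which a second bound ligand
  stabilises the open channel.  Exact stationary open probability
  Po, mean open/closed class dwell times, dose-response curves, and the local
  Hill slope d ln(Po/(1−Po))/d ln[L] are computed from the generator matrix.
  For the sequential chain the local Hill slope is analytically
  1 + b[L]/(1 + b[L]) with b = k₂/k₋₂ — strictly below 2, a useful diagnostic
  when a fitted Hill coefficient exceeds the two-site sequential bound.
- **Simulation.** Exact (Gillespie) state paths, rendered into sampled traces
  with unit current, Gaussian low-pass filtering (−3 dB cutoff f_c, implying
  the half-amplitude dead time 0.179/f_c) and additive noise; multi-channel
  patches carry their ground-truth event list.
- **Idealization and activity.** All-points-histogram baseline, half-amplitude
  multi-level idealization, NPo = Σₙ n·tₙ/T, channel counting from
  amplitude-histogram peaks, censored dwell-time summaries,
  exponential-mixture dwell fits by EM, and rate-constant recovery from a
  ligand titration of dwell means.
- **Curve fitting** (scikit-learn style estimators): `HillCurve` for
  Po = Pmax/(1 + (K₀.₅/[L])ⁿ), `GHKCurve` for the
  Goldman–Hodgkin–Katz current equation (reversal potential and slope
  conductance with standard errors), and an OLS rate-vs-concentration fit.
- **Colocalization.** Pearson, intensity-ratio coefficients
  m₁ = Σs1·s2/Σs1², m₂ = Σs1·s2/Σs2², thresholded overlap statistics
  (R, k₁, k₂), automatic (Costes-style) threshold determination from the
  channel-channel regression, and the colocalized-pixel mask
  (both channels above threshold and intensity ratio > 0.1).
- **Electrostatics.** Binding-well depth ΔG = RT·ln(C°/Kd), the Boltzmann
  local-concentration enhancement C°/Kd, and a two-dimensional diffusive
  encounter-time estimate for a lipid reaching sparse membrane channels.

## Worked example

Simulate a single channel following the sequential two-open-state scheme with
rates k₁ = 0.001 /ms/µM, k₋₁ = 0.01 /ms, k₂ = 0.0005 /ms/µM, k₋₂ = 0.005 /ms
at 20 µM ligand, idealize it, and compare with the exact theory:

```python
from pipgate import synth
from pipgate.kinetics import (sequential_open_scheme,
                              stationary_open_probability, mean_sojourn_times)
from pipgate.idealize import idealize, dwell_summary, npo_result

scheme = sequential_open_scheme(0.001, 0.01, 0.0005, 0.005)
print(stationary_open_probability(scheme, 20.0))   # 0.8571428571428577
print(mean_sojourn_times(scheme, 20.0))            # mean_open=300.0, mean_closed=50.0 (ms)

trace, truth = synth.simulate_patch(1, scheme, L=20.0, duration_ms=60_000.0,
                                    unit_current=0.5, noise_sd=0.05,
                                    filter_cutoff=1000.0, sampling_rate=4000.0,
                                    seed=1)
events = idealize(trace, unit_current=0.5, max_levels=1, baseline=0.0)
print(dwell_summary(events).mean_open)             # 328.2 ms (319 events, 60 s record)
print(npo_result(trace, unit_current=0.5, baseline=0.0).Po)  # 0.8699 vs truth 0.8699
```

The measured NPo agrees with the ground-truth time average to four decimal
places because NPo is exactly the time average of the idealized level
function; the dwell means scatter around the exact 300 ms / 50 ms values with
the sampling error of a one-minute record.

The same objects drive the command line:

```sh
pipgate simulate-trace --seed 1 --out trace.csv
pipgate dwell --in trace.csv --unit-current 0.5
pipgate electrostatics --kd-uM 15 --temp-C 20
```

The last command prints the energy well for a 15 µM dissociation constant,
`delta_G_kcal_mol: 6.4706` (inside the expected 6–6.5 kcal/mol band at 20 °C)
and the implied local concentration enhancement `66667`, i.e. far beyond
hundred-fold.

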