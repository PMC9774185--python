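# Methods

This note documents the models, numerical choices and known limitations of
`pipgate`.  Units throughout: time in ms, current in pA, ligand concentration
in µM, bulk ion concentrations in mM, voltage in mV (membrane convention,
intracellular minus extracellular; inward current negative), temperature in K.

## Gating model

A channel is a continuous-time Markov chain over a few conductance states,
each labelled open or closed.  Rates are either constant (units 1/ms) or
first order in ligand concentration (units 1/ms/µM); the effective rate at
concentration L is `coefficient * L**ligand_order`.  Two schemes are built
in:

* **Two-state** C ⇌ O: opening k₁·L, closing k₋₁.  Stationary
  Po = k₁L/(k₁L + k₋₁); mean open time 1/k₋₁ independent of L; mean closed
  time 1/(k₁L).
* **Sequential two-site chain** C ⇌ O₁ ⇌ O₂: both forward rates scale with L
  (k₁·L, k₂·L), backward rates k₋₁, k₋₂ fixed.  With a = k₁L/k₋₁ and
  b = k₂/k₋₂ the stationary weights are (1, a, abL) so
  Po = (a + abL)/(1 + a + abL); mean closed time 1/(k₁L); mean open class
  time (1 + bL)/k₋₁.  The local logistic slope d ln(Po/(1−Po))/d ln L equals
  1 + bL/(1 + bL), which lies strictly in (1, 2) for every finite L.  A
  fitted Hill coefficient above 2 therefore cannot arise from this scheme;
  the package reports the diagnostic but does not attempt to resolve such a
  discrepancy (observed fits on real ENaC data report n ≈ 2.5 ± 0.55, above
  the bound).

Stationary vectors are computed from the least-squares solution of the
balance equations with the normalisation row appended.  Mean class sojourn
times use the absorption form — entry distribution proportional to the
stationary entry flux, then a linear solve of −Q_AA t = 1 on the class
sub-generator — which is algebraically identical to the renewal identity
(occupancy / exit flux) but numerically stable when occupancies are lopsided
by several orders of magnitude.  L = 0 is a defined degenerate case for
stationary quantities (the closed state is absorbing, Po = 0) and an error
for sojourn means (the closed sojourn diverges).

The local Hill slope is evaluated by a central difference on a relative
log-step of 1e-3; it is only meaningful where 1 − Po is resolvable in double
precision (the implementation raises where Po ∈ {0, 1}).

## Simulation

State paths are sampled exactly (exponential holding time at the total exit
rate, destination proportional to rates).  The initial state is drawn from
the stationary distribution at the given L, matching recordings that begin in
steady state; `start="closed"` is available for excision-style protocols.
At L = 0 the path is a single everlasting closed sojourn.

Traces are rendered by sampling the piecewise-constant level function at the
midpoints of sampling intervals, multiplying by the unit current, convolving
with a Gaussian filter whose −3 dB point is f_c (time-domain sigma
0.1325/f_c), and adding white Gaussian noise **after** filtering.  The
Gaussian response implies the standard half-amplitude dead time
T_d ≈ 0.179/f_c: a rectangular pulse of width w reaches a filtered peak of
erf(w/(2√2 σ)), which crosses 0.5 exactly at w = T_d.  The default sampling
rate is 4000 Hz and the renderer requires f_s ≥ 4 f_c.  Simplifications:
noise is white (no 1/f component), no Bessel-filter emulation, no capacitance
transients, leak, drift, or sub-conductance levels — so passing tests
demonstrate estimator correctness under ideal recording conditions, not
robustness to every artefact of real patches.

Default fixture settings for simulated recordings are 0.5 pA unit current
with 0.15 pA r.m.s. noise and f_c = 100 Hz.  The recovery experiments use
0.05 pA noise with f_c = 1 kHz ("low noise, wide bandwidth"): with a
half-amplitude threshold at 0.25 pA this leaves a 5 σ margin, making false
threshold crossings negligible (expected ≪ 1 per record) while keeping the
dead-time bias on 40-ms dwells below a tenth of a percent.

## Idealization and activity statistics

The baseline (closed-channel current) is the mode of the all-points
histogram, with bin width noise_sd/4 when the noise amplitude is known and
Freedman–Diaconis otherwise.  This assumes the closed level is the most
occupied — false for records with Po > 0.5, in which case the caller should
pass the known baseline explicitly (simulated traces have baseline 0).

Idealization assigns each sample the level ⌊(I − baseline)/i_unit + 0.5⌋
clipped to [0, max_levels] (half-amplitude threshold, no hysteresis), then
collapses runs into events.  `unit_current` is signed, so inward-opening
traces use a negative unit current.  No missed-event correction is applied
to dwell means: short events suppressed by the filter are simply absent,
which reproduces the flickery, amplitude-attenuated appearance of
low-open-time phenotypes, and measured uncorrected means are the quantities
the recovery experiments target.

NPo is the exact time average of the level function, Σₙ n tₙ/T.  The channel
count N is the highest integer level among amplitude-histogram peaks
(prominence ≥ 1 % of the histogram maximum at 0.05-level bin resolution).  A
warning flags likely undercounts: if a hypothetical extra channel at the
implied per-channel Po would have gone unseen with probability > 0.05 over
the observed number of events, N is suspect.  Dwell summaries exclude the
first and last (censored) sojourns and are restricted to single-channel
records; multi-channel dwell analysis would require burst analysis, which is
out of scope.

Exponential mixtures (1–3 components) are fitted by EM with responsibilities
computed in log-space; convergence at log-likelihood gain < 1e-8 or 500
iterations, five random restarts keeping the best likelihood.  The dwell-time
density of an aggregated class has as many exponential components as states
in the class, so a likelihood-ratio test of 2 vs 1 components discriminates
the two-open-state chain from the two-state scheme.

Rate recovery from a titration uses the closed forms above: k₁ from a
through-origin regression of 1/mean_closed on L, k₋₁ from the reciprocal
intercept of mean_open vs L, and the ratio k₂/k₋₂ from that line's slope
times k₋₁.  Only the ratio is identifiable from dwell means; k₂ and k₋₂
individually are not.

## Curve fits

`HillCurve` fits Po = Pmax/(1 + (K₀.₅/L)ⁿ) by bounded nonlinear least
squares; replicates enter individually (not as per-concentration means),
L = 0 contributes Po = 0 via the limit, and a 3×3 multi-start grid over
K₀.₅ ∈ {5, 20, 50} µM and n ∈ {1, 2, 3} guards against local minima.
Standard errors come from the Jacobian.

`GHKCurve` fits the constant-field current
I = p·(c_in·g(u) − r·c_out·g(−u)), g(u) = u/(1 − e^(−u)), u = FV/RT, for one
permeant cation on each side.  The absolute permeability scale p (pA/mM,
the GHK prefactor P z²F²/RT folded into one constant) and the reversal
potential Erev are the fit parameters; the permeability ratio follows as
r = exp(Erev·F/RT)·c_in/c_out.  Fitting Erev directly makes its standard
error a plain covariance entry rather than a delta-method transform that
degenerates when the likelihood is flat in the p–r ridge direction.  V = 0
is evaluated by the analytic limit g(0) = 1.  Slope conductance is the OLS
slope of the fitted curve on a 1 mV grid over a stated window (default
−120…−40 mV), converted at 1 pA/mV = 1000 pS, with the covariance propagated
numerically.  When the measured voltages do not bracket the zero crossing the
fit warns and Erev is an extrapolation; in the ten-voltage protocol used by
the recovery experiment (−120…+60 mV with the zero crossing near +83 mV) the
two parameters are correlated at |ρ| > 0.999 and the reported Erev standard
error is accordingly large — tens of millivolts — which is a property of
that experimental design, not of the optimizer.  Temperature defaults to
295.15 K (22 °C).

## Colocalization

All statistics operate on registered, single-plane, background-unsubtracted
two-channel images.  The intensity-ratio coefficients are implemented exactly
as m₁ = Σs1·s2/Σs1² and m₂ = Σs1·s2/Σs2²; these overlap-style forms are not
bounded by 1 and obey exact scaling laws (m₁(a·s1, s2) = m₁/a).  The
classical bounded split fractions are provided separately
(`manders_split_fractions`).  Thresholded statistics (overlap R, k₁, k₂) are
computed over pixels above both thresholds; k₁/k₂ over that region mirror
what threshold-aware colocalization plugins report, while unrestricted m₁/m₂
are reported alongside.

Automatic thresholds follow the regression procedure: OLS of ch2 on ch1 over
all pixels, candidate pairs (t, slope·t + intercept) scanned downward from
the channel-1 maximum in steps of one intensity unit, stopping at the first
candidate where the Pearson correlation of pixels with both channels below
their thresholds is ≤ 0.  Two provisos make the scan well defined on
arbitrary images: (i) the crossing only counts after the scan has entered the
positively correlated zone, because with a shallow regression slope the
topmost candidate regions exclude bright ch2 pixels while retaining bright
ch1-only pixels — a spuriously anti-correlated subset; (ii) if the channels
show no positive correlation at all, or r never returns to ≤ 0, the
thresholds collapse to the minimum intensity with a warning.  The scan is
implemented with incrementally updated sums (each pixel leaves the
below-both region at a single critical t), so the exact step-1 scan costs
O(n log n).  A pixel is *colocalized* when both channels are above threshold
and min(s1,s2)/max(s1,s2) > 0.1 (scale-free, so the mask is invariant under
joint intensity rescaling); the mask corresponds to the conventional white
recoloring.  An empty above-both region reports zero overlap rather than an
error as long as at least one channel has pixels above its threshold.

The synthetic image generator places Gaussian puncta (default sigma 1.5 px,
amplitude 8000 on a background of 200 with 30 counts of Gaussian noise —
approximating Poisson statistics at these intensities) of which a specified
fraction share coordinates across channels.  Channel-exclusive puncta keep a
minimum separation of 4·psf_sigma from all others so the nominal colocalized
fraction is meaningful at pixel level; without it, PSF tails of
chance-adjacent exclusive spots register as colocalized pixels.  Real
micrographs differ in many ways (non-uniform background, bleed-through,
correlated noise, extended structures), so results on synthetic pairs
validate the arithmetic and the threshold procedure, not biological imaging
performance.

## Electrostatics

The binding-well depth is ΔG = R·T·ln(C°/Kd) against the 1 mol/L standard
state with R = 1.987×10⁻³ kcal/(mol·K); the local-concentration enhancement
is its Boltzmann factor exp(ΔG/RT) = C°/Kd.  The default temperature for the
well is 293.15 K; at 15 µM this gives 6.47 kcal/mol, inside the 6–6.5 band
at 20 °C but marginally above it at 23 °C — the calculation is that
sensitive to temperature.

The encounter-time model tiles the membrane into discs of radius
b = (π·ρ_ch)^(−1/2) around each channel (default ρ_ch = 7 µm⁻²), with an
absorbing trap of radius a (default 1 nm, a molecular scale — a package
default, not a measured value) at the centre and a reflecting outer
boundary.  One diffuser started uniformly is captured in mean time
τ₁ = (b²/2D)(ln(b/a) − 3/4); with N = x·ρ_lipid/ρ_ch independent diffusers
(default mole fraction 10⁻³ of a 2×10⁶ µm⁻² leaflet) the mean first arrival
is approximately τ₁/N.  All intermediate terms are reported.  With the
reference inputs (D = 4 µm²/s) this yields τ ≈ 9×10⁻⁵ s, orders of magnitude
below the ~6×10² s interval quoted in the motivating argument for the same
inputs; no standard 2-D capture formula reproduces that figure, so the
package reports its own documented model and the discrepancy stands.  The
Monte-Carlo validation uses a/b = 0.1 rather than the reference a/b ≈ 5×10⁻³
to keep the walk affordable; the logarithmic law is insensitive to this
choice and the formula is validated to 25 %.

## Problem sizes and determinism

Recovery experiments use: 5 concentrations × 11 replicates (noise sd 0.02)
for the Hill fit; 10 voltages with 0.05 pA noise for the GHK fit; a 230 s
two-state record (≈ 2200 open events) for the dwell-time recovery; a 600 s
record for the Po recovery; 10⁶ ms paths for occupancy checks.  These sizes
put Monte-Carlo error comfortably below the 2-standard-error acceptance
bands while keeping a full run in seconds.  Every stochastic routine takes an
explicit seed (numpy `default_rng`/`SeedSequence`), generators embed the seed
in their metadata, and fixed seeds reproduce bit-identical outputs.
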