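# Methods

## The model

`microdcm` implements a canonical-microcircuit (CMC) neural mass model of a
cortical column and uses it as the generative core of three EEG analyses:
resting power spectra, the mismatch negativity (MMN), and the 40-Hz
auditory steady-state response (ASSR).

A column contains four populations — spiny stellate (ss), superficial
pyramidal (sp), inhibitory interneuron (ii) and deep pyramidal (dp) cells.
Each population has second-order synaptic dynamics

    dv/dt = u
    du/dt = κ² (I − v) − 2κ u,        κ = 1/T,

where `T` is the population's lumped synaptic time constant and `I` the
summed presynaptic drive.  Presynaptic influence is the centred logistic
rate `σ(ρv) − 1/2` of the source population, weighted by the connection
gain; the DC gain of each synaptic kernel is normalized to one, so gains
are in millivolts per unit rate deviation.  The centred sigmoid makes the
zero state the exact fixed point of an undriven column.

The intrinsic wiring has ten connections: one inhibitory self-loop per
population (its *synaptic gain* — larger self-inhibition means a less
responsive population) and six between-population connections: ss→sp,
ss→ii, sp→ii, ii→sp, dp→ii, ii→dp.  This set was chosen so that every
connection the analyses estimate or report (sp↔ii, dp↔ii, and the sp/ii
self-loops) is present.  Multi-area networks add forward connections
(sp origin; ss and dp targets) and backward connections (dp origin; sp and
ii targets), with distinct intrinsic and extrinsic transmission delays.
Exogenous input enters spiny stellate cells.  The observed signal of an
area is a fixed population mixture dominated by superficial pyramidal
potentials (`J` weights).

All parameters are log-scalings of prior means (effective value =
prior mean × exp(λ)), so a log-scaling of zero is the baseline model and
effect sizes read as fractional changes (±0.2 ≈ ±20%).

## Baseline constants

The numeric prior means in `constants.py` are package choices, calibrated
once so that the baseline column expresses the canonical laminar resonance
structure within the analysis band (1–48 Hz):

- time constants (ms): ss 3, sp 10, ii 14, dp 40;
- self-inhibition gains: ss 8, sp 8, ii 4, dp 1.5;
- between-population gains: ss→sp 3, ss→ii 7, sp→ii 4, ii→sp 5, dp→ii 2,
  ii→dp 6;
- intrinsic delay 1 ms, extrinsic delay 12 ms; sigmoid slope ρ = 2/mV;
- lead field J = (0.2, 0.8, 0, 0.2) for (ss, sp, ii, dp).

Three features of this operating point carry the science:

1. the sp–ii loop resonates near 22 Hz (beta);
2. the observed (sp) population's gain-dependent corner frequency
   κ√(1 + g σ′) sits near the low gamma band, so *increasing sp
   self-inhibition genuinely extends its bandwidth* — trading gain for
   bandwidth — which raises relative gamma power at rest while damping
   the beta resonance;
3. the strong disynaptic feedforward inhibition ss→ii→sp dominates the
   low-frequency balance, so connectivity loss disinhibits the column at
   low frequencies (theta rise).

Prior variances are 1/16 for connection gains and condition effects and
1/32 for time constants, slope, lead field and delays.

## Spectral and evoked forward models

The spectral route linearizes the flow at the fixed point (damped Newton
with an integration fallback; residual tolerance well below 1e-8) and
propagates the drive spectrum through the transfer function

    H(ω) = L (iωI − J(ω))⁻¹ B,

with delays entering the coupling blocks as exact phase factors
exp(−iωτ).  Cross-spectra are H S_u Hᴴ plus white + 1/f observation-noise
floors; the drive cross-spectrum S_u is diagonal for independent drives or
rank-one for a common drive.  The ASSR model uses a *common* 40-Hz
Gaussian-bump drive to both auditory sources (a binaural click train is one
signal), which makes the between-source cross-spectrum informative.

The time-domain route integrates the delayed nonlinear flow with a
fixed-step classical 4th-order scheme (default dt = 0.1 ms; delays via a
fixed-lag ring buffer with linear interpolation, floored at one step).  It
is the package's own oracle for the spectral route: driving it with
band-limited spectrally shaped noise at small amplitude (so the system
stays in the regime the prediction linearizes around) reproduces the
predicted cross-spectra to within Welch estimator error (≈5–10% mean
relative error at 150 s of simulated data; the residual is estimator
noise, not model disagreement).

Evoked responses apply each condition's parameter deltas (`B`), re-derive
the fixed point, and integrate the response to a Gaussian-smoothed tone
envelope; the equilibrium observation is subtracted so baselines are
exactly zero.  The mismatch response is generated by a deviant-condition
*disinhibition* of superficial pyramidal cells (B = −0.3 on sp self-
inhibition in the reference regime); pathological increases of
self-inhibition erode this condition effect, shrinking the mismatch
amplitude with little latency change.

## Conventional features

Band powers are computed on the residual of a log–log line fit ("1/f
gradient") of the power spectrum.  The fit range defaults to the full
1–48 Hz analysis band: model spectra contain neither drift nor line noise,
the two artifacts that motivate trimming measured EEG; pass an explicit
range for measured data.  Bands are θ 3–7, α 8–14, β 15–30 and γ 31 Hz to
the grid maximum, all closed intervals on the grid.  Peak gamma is the
argmax of adjusted power in 35–45 Hz with ties broken toward the lower
frequency.  Time-frequency power uses 7-cycle Morlet wavelets normalized
to the pre-stimulus baseline mean per frequency.

## The five-model perturbation study

Five microcircuit pathologies are each applied in ten compounding 3% steps
to the single-column resting model: (1) loss of all six between-population
connections, (2) loss of pyramidal↔interneuron connections, (3) reduced
and (4) increased interneuron self-inhibition, (5) increased superficial
pyramidal self-inhibition.  Band changes are classified with a scale-free
rule fixed in advance of any cohort analysis: a band *reproduces* the
patient pattern (θ↑, β↓, γ↑) if its trajectory is monotone in the expected
direction and its final change is at least half the model's largest band
change (α is reported but excluded — the model has no α peak).  The rule
is deliberately relative: the 1/f refit redistributes any overall tilt, so
absolute thresholds would measure the refit, not the physiology.  Under
this rule only model 5 reproduces all three changes; models 1–2 reproduce
θ and β only (their γ change is a minor residue); model 4 loses its β
decrease because interneuron damping migrates the resonance upward; and
model 3 lowers the β peak frequency.  The classification is unchanged at
half step size.

## Inversion

Subjects are fitted by variational Laplace: Gauss–Newton ascent on the
Laplace free energy with trust-region damping (rejected steps re-damp and
never decrease F), central-finite-difference Jacobians (step 1e-3),
and log noise precisions (one per data block) updated in alternation under
a broad Gaussian hyperprior whose mean is matched to the data variance.
Convergence is ΔF < 0.01 nat on three consecutive accepted steps (max 128
iterations; studies use smaller budgets listed below).  For models linear
in the parameters and fixed hyperparameters the scheme is exact: the
posterior equals the conjugate closed form and F equals the log evidence.
Cross-spectral data are vectorized as the real diagonal (optionally
log-transformed — the default for fitting, since sample spectra have
variance proportional to squared power) plus real/imaginary upper-triangle
parts; ERP data as concatenated condition traces decimated to ≈6 ms
sampling, beyond the noise correlation length.

## Group inference

Bayesian model reduction computes reduced-prior posteriors and evidence
changes in closed form from the Gaussian algebra; it is exact on linear
instances and matches direct refitting within a fraction of a nat on small
nonlinear ones.

PEB first recovers each subject's *likelihood* in natural form by removing
the first-level prior from its posterior (precision subtraction, projected
to positive semidefinite), then fits a random-effects linear model across
subjects: θ_i ~ N(X_i β, exp(−γ) V), with V diagonal (first-level prior
variances × 1/16) and a single precision scale γ estimated by empirical
Bayes (bounded scalar optimization of the closed-form evidence, Gaussian
prior on γ with variance 1).  Removing the prior before pooling undoes
first-level shrinkage — without it group effects are systematically
attenuated.  Per-effect posterior probabilities come from BMR switch-off
of each (regressor × parameter) effect; greedy BMR pruning with Bayesian
model averaging over the visited models is available.  Design matrices
support the case–control scheme (PScz>Con, Rel>Con) and the genetic-risk/
diagnosis scheme (PScz+Rel>Con, PScz>Rel); covariates are mean-centred.

Random-effects model selection uses variational Dirichlet–multinomial
estimation of population model frequencies; exceedance probabilities by
seeded Monte Carlo over the Dirichlet posterior (1e5 draws); the protected
version blends with chance via the Bayesian omnibus risk.

## Synthetic cohorts

Cohorts default to the study's sizes (Con 107, PScz 108, Rel 57).
Subjects differ in their intrinsic gains and condition effects
(between-subject SD 0.1 log units by default); the biophysical constants
(time constants, slope, lead field, drive) are common to the cohort,
mirroring the analyses' assumption that connectivity, not kinetics,
varies across people.  Group effects are additive log-scale deltas: a
*diagnosis* effect (PScz only; default +0.25 on sp self-inhibition in both
auditory sources for the ASSR paradigm) and a genetic-*risk* effect (PScz
and Rel; default −0.2 on sp→ii).  Positive-symptom scores couple
negatively to auditory self-inhibition (disinhibition predicts abnormal
percepts), clipped to the 0–49 scale; negative symptoms to 0–28.
Covariates: age N(39.4, 14²), sex and smoking Bernoulli with group rates,
chlorpromazine-equivalent dose for patients only.

Observation noise: resting spectra get multiplicative log-normal noise
(SD 0.1); evoked traces additive colored noise (2 ms correlation,
amplitude ≈10% of the evoked peak, i.e. trial-averaged data); ASSR
cross-spectra a complex Wishart resampling with 150 degrees of freedom
(one per averaged epoch of a typical usable session), which preserves
Hermitian positive semidefiniteness by construction.

What the generator does *not* emulate: sensor-level volume conduction and
realistic lead fields, artifacts, non-Gaussian between-subject structure,
or kinetic (time-constant) heterogeneity.  Passing recovery tests
therefore show that the estimation machinery is correct and well
calibrated under the model's own assumptions — not that those assumptions
hold for measured EEG.

## Study configurations (desk scale)

The replicated studies are scaled to run on one CPU in minutes; sizes are
the package's own choices:

- *Group-effect recovery*: Con/PScz/Rel × 20 subjects, 20 replications.
  First-level fits free the per-source gains the ASSR analysis reports
  (sp→ii, ii→sp, sp self-inhibition) over a 10–50 Hz grid at 1 Hz (the
  band below the drive exposes the background resonances that
  disambiguate the gains), 16 iterations.  Detection = diagnosis effect
  flagged at p > .95 with positive sign in both sources.  Null cohorts
  (no group effects) calibrate the false-flag rate.
- *Model-selection self-consistency*: single-column oddball cohorts of 12
  subjects generated under the full connectivity model (6G) with
  between-subject SD 0.25 (equal to the prior SD, so the full connection
  set is expressed), fitted under all six mismatch models (ERPs at
  dt = 0.4 ms, 6 ms observation sampling, 12 iterations).
- *Oracle agreement*: 150 s of simulated data per parameter set at
  dt = 0.1 ms, Welch segments of 2 s.

## Numerical choices and degenerate inputs

- Fixed points: damped Newton, tolerance 1e-10, long-horizon relaxation
  fallback; unstable linearizations raise with the offending eigenvalue.
- Integrator delays are floored at one time step; a divergent trajectory
  raises with the time of divergence.
- BMR guards against numerically non-positive reduced precisions and
  advises a prior-variance floor; pinned parameters use variance 1e-8.
- Likelihood-precision recovery in PEB clips small negative eigenvalues
  to zero.
- Monte Carlo exceedance probabilities use a seeded generator; all
  pipelines are bit-reproducible under fixed seeds.

## Known limitations

- The spectral route is a fixed-point linearization: it is accurate for
  small fluctuations and will deviate for strongly driven or near-unstable
  regimes.
- The 40-Hz response is modeled in the spectral domain (steady state); the
  transient build-up visible in time-frequency analyses of measured ASSR
  is only captured by the time-domain route.
- Within-subject degeneracy among intrinsic gains is real: single-band
  cross-spectra cannot separate four gains per source, which is why the
  desk-scale studies fit the reported three-gain set over a wide band.
  With all four gains free, group effects disperse across gain
  combinations and hierarchical detection weakens.
- The single-column model produces no α peak; α band changes are reported
  but never classified.
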