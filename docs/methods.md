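# Methods

This note documents the models, parameter choices and numerical decisions
behind `satglia`, in the order the pipeline uses them.

## Density bookkeeping

All distance predictions start from three numbers for adult mouse
striatum: 16 spiny projection neurons (SPNs, approximated by
NeuN-positive neurons) per 100,000 µm³, one astrocyte per 6 SPNs, and one
cholinergic interneuron (ChI) per 50 SPNs. These imply an astrocyte
density of 2.67 per 100,000 µm³ (2.67 × 10⁻⁵ µm⁻³), one ChI per
312,500 µm³, and ~8.3 astrocytes within one ChI's share of tissue.
`DensitySpec` carries the inputs and exposes the derived quantities as
properties, so they can never drift out of consistency.

## Distance models

Four placement models predict the mean minimum distance from a neuron to
its nearest astrocyte centre at astrocyte density λ:

- **Cubic lattice** (`lattice3d`). Astrocytes on a lattice of spacing
  `s = λ^(-1/3)`; the prediction is `c·s`, where
  `c = E‖U‖, U ~ Uniform([-1/2, 1/2]³) ≈ 0.480296` is evaluated by
  96-point tensor Gauss–Legendre quadrature (deterministic to ~1e-12).
  At λ = 2.67 × 10⁻⁵ µm⁻³ this gives 16.1 µm — the lower end of the
  envelope, since a lattice is the most efficient covering of space.
- **3D Poisson** (`random3d`). Uniformly random centres; closed-form
  limit `Γ(4/3)·(4πλ/3)^(-1/3)` (18.5 µm at striatal density), checked by
  Monte Carlo.
- **Hard-core** (`random_excl`). As Poisson but with a minimum
  centre-to-centre distance (dart throwing with rejection; default
  exclusion is the astrocyte radius plus the smallest neuron radius,
  12 µm). Note that a hard core *regularizes* the pattern and therefore
  slightly *shortens* the mean distance from a random query point
  relative to Poisson (toward the lattice value) — the familiar
  "thinning lengthens nearest-neighbour distances" intuition applies to
  point-to-point distances, not to distances from independent query
  locations.
- **Thin section** (`random_slab`). Models confocal quantification of a
  30 µm z-stack: an astrocyte is only countable when its soma (nucleus)
  sits inside the stack, so centres are restricted to the effective
  thickness `t_eff = 30 − 2·r_astro = 18 µm`, and distances are measured
  in the 2D maximum-projection plane. The 2D Poisson limit is
  `1/(2√(λ·t_eff))` = 22.8 µm — the upper end of the envelope, because
  the section censors astrocytes just outside the stack whose 3D
  distances would have been short.

**Monte-Carlo design.** All MC models use periodic boxes (no edge bias)
sized for an expected astrocyte count of ≥ 2000, and split the query
budget across 16 independent point-pattern realizations. Both choices
target the same error source: with a single realization of a few hundred
points, the pattern-level fluctuation of the conditional mean
(~±0.5 µm) is comparable to the 1 µm granularity at which distances are
reported. The standard error attached to each result is the standard
deviation of per-realization means over √16, which captures query noise
and pattern noise together. With 10,000 query points the SE is ~0.1 µm
for every stochastic model. Reported distances are rounded to the
nearest µm (half away from zero) only at the reporting layer.

**Soma apposition.** The criterion "membranes apposed over more than
3 µm" is operationalised geometrically: somata are circles in the
projection plane (radius from area by circle equivalence `r = √(A/π)`),
and a pair is apposed when the chord of their intersection — the
radical-axis chord `L = 2√(r₁² − a²)`, `a = (d² + r₁² − r₂²)/(2d)` —
exceeds the threshold. Tangent or disjoint circles give 0; containment
gives the small circle's diameter. This is a proxy for a visual
judgement; no ground truth exists for the correspondence, which is a
known limitation.

## Anatomy quantification

Nearest-astrocyte search is an exhaustive 2D Euclidean argmin (ties go to
the lowest astrocyte identifier, making output deterministic). Gaussian
fits to distance histograms are maximum-likelihood normal fits; the mean
is the headline statistic. Location-probability maps bin
astrocyte-relative-to-neuron offsets on a 1 µm/pixel grid over a ±60 µm
window and smooth with an isotropic Gaussian of σ = 24 pixels (σ is quoted in
pixels; at 1 µm/pixel the two readings agree),
then normalise to unit mass. No shrinkage correction is applied. The
size-proximity association uses Pearson's r with a two-sided p-value.

## Firing-response classification

Spike rates are computed per trial in 100 ms bins aligned so a bin edge
falls at light onset, then averaged across trials. The light-epoch
z-score standardises the mean rate over bins inside the light epoch by
the mean and SD *across the ten 1 s-baseline bins* (SD across bins of
the trial-averaged trace, matching how peristimulus
z-score traces are conventionally constructed; an across-trial SD is a
defensible alternative, and the choice is recorded here).
Thresholds are strict: z > +0.5 → excited, z < −0.5 → inhibited,
otherwise non-responder; the post-light window (500 ms after light end)
uses z < −0.5 for offset inhibition. A silent or perfectly regular
baseline has zero SD; such cells are flagged and routed to voltage-based
analysis rather than force-classified.

Under the null (no programmed effect) this z-statistic is *not* a
standard normal — it is self-normalised across a handful of bins — and
its false-call rate at |z| > 0.5 depends on the firing regularity. For
the regular pacemaker generator (CV 0.2, 6 Hz, 20 trials) the measured
false-response rate is ~9%; for a Poisson-like cell it would be several
times higher. The ±0.5 thresholds correspond empirically to the extremes
observed in pre-light baselines, and they behave consistently with that
here.

Onset latencies of light-evoked membrane responses are milliseconds —
far below the rate-bin width — so they are estimated from the voltage
trace: the first post-light time at which |V − baseline mean| exceeds
k = 2 baseline SDs continuously for 5 ms (baseline = 100 ms pre-light).
The hold requirement rejects noise excursions; k and the hold are
package choices.

## Intrinsic membrane properties

From a square-step protocol (750 ms steps; −200 pA to suprathreshold):

- **Input resistance**: slope of the regression of steady-state voltage
  deflection (mean of the last 100 ms of the step) on injected current,
  over steps that elicit no spikes. mV/pA is GΩ; reported in MΩ.
- **Sag ratio**: steady-state deflection ÷ peak deflection at −200 pA
  (1 = no sag; smaller = more sag).
- **Spontaneous rate**: upward 0 mV crossings per second at 0 pA.
- **AP threshold**: the voltage where dV/dt first exceeds 10 mV/ms. The
  instantaneous derivative at 20 kHz is noise-dominated, so detection
  requires the slope criterion to hold for 0.5 ms (an AP upstroke
  sustains it throughout its rise; white noise cannot), and the
  threshold voltage is read as the intersection of lines fitted to the
  8 samples on either side of the detection point — exact when the trace
  is piecewise linear, noise-averaging otherwise.
- **AP amplitude** peak − threshold; **half-width** at half amplitude
  with linear interpolation of the crossings.
- **AHP amplitude**: threshold minus the trough after the spike. A raw
  minimum is biased by noise extremes, so the trough sample is located
  on a Savitzky–Golay-smoothed copy (window 21, order 2 — passes smooth
  troughs unchanged) and refined by a local parabola fit to the raw
  samples.
- **Adaptation index**: last ISI ÷ first ISI during the +100 pA step
  (> 1 = adapting).

Missing protocol pieces produce `None` fields listed in
`IntrinsicProperties.missing` rather than an error.

On noiseless synthetic traces every estimator recovers its programmed
parameter to numerical precision; at 0.5 mV white noise, worst-case
errors over 20 seeds are below 5% for all properties.

## Sensors

Ca²⁺-selective electrodes are fitted with
`V = slope·log₁₀[Ca²⁺] + intercept` by least squares over the
positive-concentration calibration points; the 0 mM solution is retained
in the raw data but excluded from the fit (log undefined — physically,
the electrode saturates at its detection limit). Sensitivity is the
fitted potential jump across the 0.2 → 2 mM decade, i.e. the slope
itself; acceptance requires strictly more than 20 mV. Using the fitted
line rather than the two raw readings makes the gate robust to
single-point noise; a raw two-point
difference is the obvious alternative. An ideal divalent Nernst electrode at 306 K (33 °C) has
slope 2.303·RT/2F ≈ 30.4 mV/decade and passes. Inversion
`[Ca²⁺] = 10^((V − b)/slope)` is only permitted for accepted curves.
Activity coefficients are not modelled.

ΔF/F₀ uses per-frame background subtraction (`F_t = signal − background`,
background from an equal-sized sensor-free ROI), with F₀ the mean F_t
over the 1 s (10-frame at 10 Hz) window before stimulation; a
non-positive F₀ is an error, not a silent NaN.

## Synthetic data: what it does and does not emulate

Generators are seeded (`numpy.random.default_rng`) and bit-reproducible.

- **Cell fields**: Poisson, hard-core (greedy dart throwing, somata may
  not overlap; largest cells placed first) or per-type jittered lattice
  placement at the striatal densities, with fixed soma radii per type
  (ChI 12.5 µm, SPN and astrocyte 6 µm). Real tissue has neither
  perfectly spherical somata nor type-independent placement.
- **Sections**: cells with z-centres in the effective slab, projected to
  x/y; soma area is the equatorial circle — real ROI areas vary with the
  cutting plane.
- **Spike trains**: the regular pacemaker is a gamma-renewal process
  (CV 0.2 by default; the source describes the rhythm only
  qualitatively), rate-modulated through time rescaling so the light
  multiplier applies after the programmed latency; bursting alternates
  exponential burst/silence epochs (20 Hz in-burst, 0.5 s/1 s means —
  free choices, no quantitative burst statistics being available).
  Baseline 6 Hz, 20 trials, 500 ms light in a 4 s trial window.
- **Step traces**: passive RC charging (τ_m = 10 ms), hyperpolarizing
  steps jump to `steady/sag_fraction` and relax with τ_sag = 30 ms, and
  APs are a stereotyped piecewise template (linear rise/fall sized so the
  half-width is exact, parabolic AHP trough with on-grid vertex, all
  sub-criterion slopes) rather than biophysics — the point is exact
  ground truth for the extractors, not channel realism.
- **Sensors**: exact Nernstian lines with optional Gaussian noise, and
  step-and-decay fluorescence with the programmed peak ΔF/F at the onset
  frame.

Closed-loop tests (generate → analyse → compare to programmed truth)
therefore validate the *estimators*, not the biology: passing them shows
the analysis recovers known parameters under the stated noise, not that
real recordings satisfy the generators' assumptions.

## Problem sizes

Default analyses run at desk scale: 10,000 Monte-Carlo query points per
distance model (SE ~0.1 µm), 16 pattern realizations, 100-seed batteries
for classification power, and 600 × 600 × 60 µm fields (~4000 cells) for
the end-to-end consistency check. All were chosen so that Monte-Carlo
error sits well below each quantity's reporting precision.
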