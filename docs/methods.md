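# Methods

## The quantity

Animal slurry resists pH change through four coupled buffer systems: the
volatile-fatty-acid pool (VFA, dominated by acetic acid, pKa ≈ 4.76), the two
carbonate couples H₂CO₃*/HCO₃⁻ (pKa₁ ≈ 6.35) and HCO₃⁻/CO₃²⁻ (pKa₂ ≈ 10.33),
and the ammonia couple NH₄⁺/NH₃ (pKa 9.25 at 25 °C). The **current buffer
capacity** CBC(pH) is the amount of strong acid or base, in mol per kg
slurry, needed to move the sample by one pH unit at a given pH — the
empirical counterpart of the classical buffer index β = dC_B/dpH.

## The determination model

Given one titration record (cumulative titrant volume, pH, temperature per
dosing step):

1. normalise doses to mol titrant per kg slurry — the **pre-dilution**
   sample mass is the denominator, since capacities are reported per kg
   slurry and the dilution water contributes no buffering;
2. restrict to the direction-specific fit window: acidification pH 7.0–3.0,
   direct alkalization pH 7.8–11.5 (starting from the reading nearest 7.8
   when the sample is already more alkaline), alkalization after a prior
   acidification pH 7.0–11.5;
3. least-squares polynomial regression of pH on amount, **degree 6** (the
   model's fixed reference degree; other degrees are accepted with a
   warning);
4. analytic differentiation of the fitted polynomial (never a finite
   difference);
5. CBC(pH) = |1/slope| sampled on a uniform 512-point amount grid; grid
   points with |slope| < ε_slope = 10⁻³ pH·kg·mol⁻¹ are excluded and
   counted, and a fit losing more than 10 % of its grid is rejected as
   degenerate;
6. per-buffer peaks: interior local maximum of CBC within each window
   (defaults VFA 4.0–4.5, HCO₃⁻ 6.0–6.5, NH₃ 8.5–10.0, CO₃²⁻ 9.5–11.5, all
   configurable), refined by a 3-point quadratic through the bracketing grid
   points, ties broken toward the window midpoint. Windows without an
   interior maximum report the boundary supremum flagged
   `is_local_max=False` — the buffer exists but cannot be separated from its
   neighbours, and the value must not be read as a peak.

Segment amounts (acid from the initial pH to 7.0, 7.0→5.5, 5.5→3.0; base
9.5→11.5) are interpolated linearly on the **raw** dosing sequence at the
first crossing of each bound, so rejected or wiggly fits cannot contaminate
them. Because the area under CBC(pH) is by construction the titrant spent
between two pH values, segment amounts double as a conservation check on the
fitted curve (agreement within ~2 % on simulated slurry).

## The simulator / oracle

A closed-system, ideal-activity, charge-balance model. Each buffer system
carries an analytical total (mol per kg solution), reference pKa value(s) at
25 °C and a dissociation enthalpy; constants shift with temperature by
van 't Hoff, pKa(T) = pKa_ref + dH/(R ln10)·(1/T − 1/298.15 K). Defaults
(25 °C): acetic 4.757 (dH −0.4 kJ·mol⁻¹), carbonate 6.35/10.33 (7.6/14.9),
ammonium 9.25 (52), pKw 14.00 (55.8) — standard literature values. The pH at
any dose is the bracketed root of the electroneutrality equation on (0, 14);
an inert charge offset (net strong cations minus anions) sets the
zero-titrant pH.

Dosing emulates a dynamic titrator: 0.5 M titrant, increments capped at
0.5 mL on a 100 g vessel charge (50 g slurry + 50 g water), halved toward a
1 µL floor wherever a step would move the pH by more than 0.2 units.
Optional Gaussian pH read noise and dose quantization are seeded; the
noiseless default is bit-reproducible. Composition presets convert measured
slurry assays (acetic-acid equivalent g·kg⁻¹, TAN kg N·m⁻³, TIC kg C·m⁻³;
three slurry types × three storage states) to molalities assuming density
1 kg·L⁻¹ and the 1:1 dilution; preset initial pH is 7.5 for pig and cow
slurry and 8.9 for fresh sow slurry.

The closed-form strong-base dose function C_B(pH) from the same charge
balance, differentiated centrally with ΔpH = 10⁻⁴, gives the analytic buffer
index β — an oracle entirely independent of the fitting pipeline.

What the simulator does **not** model: CO₂ outgassing (so a prior
acidification does not strip carbonate, unlike an open vessel), ionic-strength
activity corrections, microbial VFA/urea dynamics between timepoints, foam
mechanics, phosphate and minor buffers, and titrant-volume dilution during
dosing (≤ a few percent of vessel mass). Passing tests therefore validate
the pipeline against ideal closed-system chemistry, not against every
behaviour of real slurry.

## Accuracy of the global polynomial — a measured limitation

The fixed degree-6 polynomial is the model's defining choice, and its
approximation error is the pipeline's dominant error source. Measurements
against the analytic oracle (noise-free simulations; fits verified identical
to R's `lm(ph ~ poly(amount, 6))`):

* On slurry-like three-buffer mixtures the reciprocal-slope CBC deviates
  from β by up to ~10–40 % pointwise inside the fit windows, worst near
  buffer-capacity minima and window edges; peak *heights* in the reporting
  windows are usually within ~5–15 %.
* Peak *positions* are biased by roughly −0.4 to +0.1 pH depending on
  composition and window; an isolated sharp buffer (a lone NH₄⁺/NH₃
  solution) is the worst case at ±0.2–0.3 pH, because the window then
  contains nearly unbuffered, strongly curved stretches. Degree 8 halves
  this bias and degree 10 nearly removes it, but those leave the reference
  configuration.
* Relative shifts are robust: across a 20–30 °C sweep of simulated sow
  slurry, the ammonia-peak pH tracks the van 't Hoff pKa shift with Pearson
  r ≈ −0.9995.

Consequently the peak table should be read as this model defines it —
reproducible, comparable across samples and time, excellent for dynamics
and correlations — not as unbiased pKa estimates. The acceptance suite
carries three deliberately strict checks (absolute peak location of a lone
ammonia buffer at ±0.05 pH; 5 % pointwise oracle equivalence; ±0.05 pH /5 %
end-to-end recovery) that fail at exactly these measured biases and are kept
failing as an honest record of the method's envelope.

## Quality control

Visual rejection of fouled-sensor and foam-retention runs is
operationalised as flags: hard (excluding) — pH reversal > 0.3 against the
titration direction, or failure to reach the fit window; soft — ≥ 5
consecutive doses each moving pH < 0.005, a dose increment > 2× the 0.5 mL
protocol cap, or a residual MAD > 0.05 pH about an 11-point rolling-mean
smooth. All thresholds are package-defined surrogates (the source procedure
was subjective) and are reported per record so exclusions stay auditable.

## Numerical choices

Root finding: Brent's method on pH ∈ (10⁻⁴, 14 − 10⁻⁴) at ~machine
tolerance. Fit: `numpy.polynomial.Polynomial.fit` with its internal domain
scaling (no raw Vandermonde). Grid: 512 points, uniform in amount, so steep
regions — where CBC is small and uninformative — occupy few samples.
Integration of CBC over pH: 1024-point trapezoid on the pH-sorted curve.
Duplicate dosing volumes keep the last (equilibrated) reading. Degenerate
inputs fail loudly: fewer than 10 usable points, all-equal amounts,
uncovered windows, and unreachable pH targets each raise a typed error.

## Problem sizes

Simulated titrations run 40–80 dosing steps (the protocol's caps applied to
50 g samples), matching the instrument's scale; verification suites use
11-point temperature sweeps and 20 randomized mixtures. All defaults
complete in seconds.
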