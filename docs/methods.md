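# Methods

## Scope and data flow

`ilrkit` converts pH-stat lipolysis titration records of acylglycerol
nanoemulsions into surface-area-independent intrinsic lipolysis rates and
cross-validates them against a mechanistic digestion model. The stage order
is fixed:

```
titrant volume → ionized FA (µmol) → ionization scaling → blank subtraction
→ max-slope segmentation (k, lag, plateau) → droplet surface area A
→ ILR = k/A → shrinking-droplet fit (Φ_max, k_mech)
```

Units are held constant inside the package (mM, mL, µmol, minutes, nm, cm²,
µmol·min⁻¹·cm⁻²; the mechanistic rate constant alone in SI mol·s⁻¹·m⁻²)
and converted only at I/O boundaries, to keep silent factor-of-10³ errors
out of the stoichiometry.

## Titration processing

**Conversion.** Each mole of NaOH titrant neutralises one mole of ionized
fatty acid, so cumulative release is volume × molarity, re-anchored to zero
at the first sample. Records must have strictly increasing times and
non-decreasing volumes; downward volume excursions up to 0.005 mL (about
burette resolution) are monotonized away, larger ones are data errors.

**Ionization correction.** At the assay pH a fraction of released fatty
acids is unionized and invisible to the titrator. The end-of-run
back-titration to pH 9 measures that pool once; assuming the
ionized/unionized ratio is constant over the run, the whole curve is scaled
by s = (ionized_end + pH9_addition)/ionized_end. No pKa/pH speciation model
is applied — the constant-ratio assumption is taken as given.

**Blank correction.** Medium phospholipids are themselves digested; a blank
run without acylglycerols is converted to µmol (its own titrant molarity
and pH-9 volume cancel there), interpolated onto the sample grid and
subtracted. The blank is used as-is, with no rescaling, because the 1:1
medium dilution matches the sample vessel. Negative excursions within 1% of
the sample endpoint are floored at zero; larger ones are preserved and
flagged, since they indicate a real inconsistency rather than noise.

Corrections are applied ionization-first, both in µmol; the pipeline
enforces this order, under which the two commute with titrant-molarity
choices (property-tested).

**Segmentation.** k is the maximum over sliding windows (default 11 points)
of the ordinary least-squares slope. The lag time is the intersection of
the maximum-slope tangent (through the window centroid) with the zero
baseline, clipped to the record — the standard pH-stat convention; a
threshold alternative (first crossing of 1% of theoretical release) is
available via `lag_method`. The plateau is the mean of the final 10% of
points, and the extent of digestion its ratio to the theoretical release.
Optional moving-average pre-smoothing is off by default. A flat curve
yields k = 0 with an undefined lag.

The lag definition is an operational choice: published lag lengths are
reported without an algorithmic definition, and the tangent-intercept is
the convention adopted here. k is likewise estimated on the fully corrected
curve; since the ionization correction is a uniform scaling, this differs
from an ionized-only estimate exactly by that scale factor.

## Droplet geometry

The DLS z-average hydrodynamic diameter is read as the diameter of
monodisperse spheres; the PDI is carried for QC only (warning above 0.3).
The total interfacial area follows the per-droplet chain
n·SA = (m/ρ)/(4πr³/3)·4πr², algebraically 6m/(ρd), property-tested for
equality over 10⁶ random inputs. A is fixed at its pre-digestion value;
shrinkage during the run is the mechanistic model's business.

"Ideal mixing" for binary lipid phases is implemented as molar-volume
additivity, ρ = ΣxᵢMᵢ / Σ(xᵢMᵢ/ρᵢ) — the physically standard reading —
with a linear mass-fraction rule available as an option. For
triacylglycerol mixtures containing at most 10% of their fatty acids from a
1-monoacylglycerol, the triacylglycerol density is used unchanged; above
the threshold the code falls back to ideal mixing with a warning.

## ILR and the mixing rule

ILR = k/A, stored in base units and displayed ×10⁻³ µmol·min⁻¹·cm⁻².
Replicates are analysed per curve and then aggregated as mean ± sd, not
pooled. The mixture prediction is the convex combination over fatty-acid
molar fractions (from per-molecule release counts: 2 for tri- and
1,3-diacylglycerols, 1 for 1-monoacylglycerols), and its inversion
estimates a non-emulsifiable component's ILR from a binary measurement; a
negative inverted ILR is returned with a warning as a sign of model
extrapolation.

Relative deviations between predicted and experimental mixed ILRs use the
**predicted** value as denominator (option: experimental). With the
published rounded panel values this convention reproduces the reported 3%
(tricaprylin/tricaprin) and 15% (tricaprylin/triolein) deviations, whereas
the experimental denominator gives 17% for the latter. The published
predicted 1-monoacylglycerol ILRs (9.8 and 9.3×10⁻³) evidently come from
unrounded data: from the rounded panel values the inversion gives 10.9 and
~9.1×10⁻³, and the package reports the rounded-input results.

## Shrinking-droplet model

The first-order model (Li & McClements, corrected by Gaucel et al.) for a
monodisperse population of uniformly shrinking spheres:

Φ(t) = Φ_max·(1 − max{0, 1 − (kM)/(d₀ρ₀)·t}³),

implemented exactly in this clamped-cubic form; literature variants
absorbing extra factors into k are out of scope. Time is converted to
seconds internally (k is per second), and the fit is parameterised by the
rate group g = kM/(d₀ρ₀) for conditioning, with k recovered afterwards.
(Φ_max, g) are estimated by unweighted bounded nonlinear least squares
(scipy trust-region-reflective; Φ_max ∈ (0, 1.05] to tolerate titration
overshoot, k ≥ 0) from a 15-point multistart grid — Φ_max ∈ {0.3, 0.6,
0.9} × four decades of g around the early-slope estimate g ≈ max(dΦ/dt)/3.
Noise-free synthetic curves are recovered to ≤10⁻⁶ relative error; at
Gaussian noise sd 0.01 on Φ, Φ_max is recovered within 2% and k within 5%
(seeded tests). A flat curve drives Φ_max to its lower bound and is flagged
non-identifiable. The rate-constant comparison uses the derived factor
1 mol·s⁻¹·m⁻² = 10⁶ µmol × 60 min⁻¹ / 10⁴ cm² = 6×10³ µmol·min⁻¹·cm⁻².

The model has no lag term. Fitted to a lagged curve it under-estimates the
rate constant — visible in the worked example — which mirrors its behaviour
on real pH-stat data and is why the ILR's slope-based k and the mechanistic
k are compared as order-of-magnitude cross-checks, not expected to agree
exactly.

## Synthetic experiment generator

The generator emulates the triphasic pH-stat record (lag, maximum-rate
phase, plateau) from the shrinking-droplet forward model, time-shifted by a
lag input: the lag is a pure delay, not a surfactant-displacement model —
an input, never an output. Ground truth can be specified either as an ILR
(Φ_max = 1; the rate group follows from g = ILR·A/(3·n_total)) or as
mechanistic parameters (Φ_max, k). The generated bundle contains the sample
record, a blank record, the droplet population and a ground-truth file.

Defaults are the study conditions: 20 mL formulations composed for 5 mmol
theoretical release, 0.6 M sample titrant, 0.2 M blank titrant, 90 min
runs, ionized fraction 0.8 (constant by construction, so the back-titration
correction is exact on synthetic data), blank rate 1% of the sample's
maximum rate, ~1 min lag, and Gaussian titrant noise of 1 µmol per sample
(burette scale), applied as a seeded random walk and monotonized by
cumulative maximum so generated records always validate. The sampling
interval default is 0.01 min, a logging rate within modern autotitrator
capability; at this spacing the 11-point slope window spans 0.1 min and the
discretization bias of the max-slope estimate stays near 1% for the
fastest-digesting study compositions (the window average of a derivative
that decays like (1 − gt)² loses ≈ g·w relative; g ≤ ~0.14 min⁻¹ across
the panel).

What the generator does **not** emulate: droplet polydispersity and
size-distribution evolution, coalescence or phase separation, surfactant
dose–response of lag and rate (panel surfactant levels are carried as
metadata only), electrode/stirring transients, or pH-dependent speciation.
Passing tests therefore demonstrate the correctness of the numerics and
bookkeeping under the model's own assumptions — not that those assumptions
hold for any particular real emulsion.

The study-shaped panel generator reuses the published composition/diameter
table, taking each row's printed ILR as ground truth; those magnitudes are
wet-lab measurements and enter the package only as fixture inputs. One
printed inconsistency (118.5 vs 118.75 mM triolein in a mixture row) is
reproduced as printed and left unresolved.

## Numerical choices and degenerate inputs

* Sliding-window OLS slopes are computed vectorised; exact on
  piecewise-linear curves for any window within the ramp.
* Fractions and ratios are validated to 10⁻⁹ (sum-to-one) or exact
  (stoichiometry round-trips hold to 10⁻¹²).
* Zero formulations, zero areas, zero-endpoint back-titrations, flat
  curves and short blanks all raise typed errors or produce flagged
  degenerate results rather than NaNs.
* JSON reports serialise every float both at full precision and rounded to
  6 significant digits; reruns are byte-identical.

## Problem sizes

Test and acceptance runs use 90 min synthetic records at 0.01 min sampling
(9 001 points), 90-point fit curves, 100-replicate Monte-Carlo recovery
checks, and a 10⁶-sample property sweep for the area closed form — sizes
chosen so the whole suite completes in well under a minute while leaving
the discretization floor far below the asserted tolerances.

## Known limitations

* The ILR inherits the monodisperse-sphere area estimate; systematic DLS
  bias propagates 1:1 into the ILR.
* The mixing rule is linear by construction; interfacial enrichment of one
  component (amphiphilic monoacylglycerols in particular) can make real
  mixtures deviate, which is precisely what the deviation report is for.
* ILRs are comparable only at matched surfactant level; the package flags
  this in documentation but does not model surfactant inhibition.
* The registry's densities and melting points are placeholder
  literature-typical values (`provenance = "placeholder"`); quantitative
  area work should override them with measured data.
* 2-monoacylglycerols are representable but the stoichiometry and rate
  interpretation target sn-1(3) isomers.
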