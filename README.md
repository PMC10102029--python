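# ilrkit

Intrinsic lipolysis rate (ILR) analysis for pH-stat digestion of
acylglycerol nanoemulsions.

## The problem

The digestion rate of a lipid-based formulation (LBF) measured in a pH-stat
lipolysis assay depends on the emulsion droplet size: lipolysis is an
interfacial reaction, so the apparent rate scales with the total lipid–water
surface area. That makes raw pH-stat rates of different lipids and
formulations incomparable. The ILR removes this confounder the same way an
intrinsic dissolution rate does for solids — by normalising the maximum
release-phase slope *k* (µmol·min⁻¹) of the corrected lipolysis curve by the
total droplet surface area *A* (cm²):

```
ILR = k / A          [µmol·min⁻¹·cm⁻²]
```

with *A* computed from the DLS hydrodynamic diameter *d* and the dispersed
lipid mass *m* and density *ρ*, treating droplets as monodisperse spheres
(A = 6m/(ρd)). The corrected curve is the cumulative fatty-acid release,
obtained from titrant volume × molarity, scaled by the end-of-run pH-9
back-titration (ionized → total fatty acid) and blank-corrected for medium
phospholipid digestion.

Two consequences make the ILR useful to formulation scientists:

* **mixing rule** — the ILR of an acylglycerol mixture is the fatty-acid
  molar-fraction weighted sum of pure-component ILRs,
  `ILR_mix = Σ xᵢ·ILRᵢ`, which predicts the digestibility of binary
  nanoemulsions and, inverted, estimates the ILR of lipids (e.g.
  1-monoacylglycerols) that cannot be emulsified alone;
* **mechanistic cross-check** — the first-order shrinking-droplet model of
  Li & McClements (with the Gaucel correction),
  `Φ(t) = Φ_max·(1 − max{0, 1 − kM/(d₀ρ₀)·t}³)`, fitted to the same curve,
  yields a rate constant comparable to the ILR
  (1 mol·s⁻¹·m⁻² = 6×10³ µmol·min⁻¹·cm⁻²).

The package implements the full pipeline (titration processing → droplet
geometry → ILR → mixing predictions → mechanistic fit), a lipid property
registry, and a synthetic pH-stat experiment generator with known ground
truth, so every stage is testable without laboratory data.

## Worked example

Generate a synthetic tricaprylin experiment (125 mM in 20 mL, 250 nm
droplets, ground-truth ILR 5.0×10⁻³ µmol·min⁻¹·cm⁻², 1 min lag, mild
titration noise) and analyse it:

```
$ ilrkit simulate --out demo --noise-sd-umol 0.5 --lag-min 1.0 \
      --ilr-e3 5.0 --seed 11
$ ilrkit compute-ilr --config demo/experiment.toml --out demo/results
$ cat demo/results/summary.txt
experiment: synthetic_tricaprylin
  k (max-rate slope)    : 1459.96 umol/min
  droplet surface area  : 295412.0 cm2
  ILR                   : 4.94212 x1e-3 umol/min/cm2
  lag time              : 1.00514 min
  extent of digestion   : 1.02185
  mechanistic phi_max   : 1.01193
  mechanistic k         : 3.58316 x1e-3 umol/min/cm2
  fit rmse (fraction)   : 0.0247426
```

The recovered ILR (4.94×10⁻³) sits within ~1% of the generating ground
truth (5.0×10⁻³): the slope of the maximum-rate phase divided by the
2.95×10⁵ cm² of droplet interface returns the rate the curve was built
from. The lag estimate reproduces the 1 min input. The mechanistic rate
constant is biased low here because that model has no lag term — the same
qualitative offset seen when both constants are fitted to real pH-stat
curves.

Mixing-rule prediction from pure-component ILRs (values in
µmol·min⁻¹·cm⁻²):

```python
>>> import ilrkit as ik
>>> pred = ik.predict_mixed_ilr([("tricaprylin", 0.5, 6.3e-3),
...                              ("tricaprin", 0.5, 2.8e-3)])
>>> pred.predicted_ilr * 1e3
4.55
>>> ik.deviation_report(pred, 4.4e-3).relative_deviation_display
3
```

An equimolar tricaprylin/tricaprin nanoemulsion is predicted at
4.55×10⁻³, 3% away from the measured 4.4×10⁻³.

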