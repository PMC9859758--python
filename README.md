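# tipbody

Quantitative analysis of +TIP-body behaviour in budding yeast: microtubule
plus-end tracking proteins (Kar9, Bim1, Bik1) form a liquid-like condensate
— the +TIP body — at the tip of astral microtubules. This package implements
the quantitative pipeline such a study needs, both for the in vivo imaging
side (punctum trajectories) and the in vitro condensate side (droplet
coalescence, FRAP, phase diagrams), together with a synthetic-data module
that generates statistically realistic inputs for every stage.

It is aimed at cell biologists and image analysts who have per-frame
measurements (punctum-to-spindle-pole distances, punctum intensities,
droplet ellipse axes, phase-separation calls) and want reproducible,
tested estimates rather than ad hoc spreadsheet analysis.

## What it computes

**Phase annotation.** Microtubules alternate between growth and shrinkage
(dynamic instability). Given a punctum–SPB distance trajectory x(t), the
annotator (1) smooths with an order-1 Savitzky–Golay filter (window 5 — the
centred moving average), (2) finds piecewise-linear changepoints by exact
dynamic programming (minimum segment length 5 frames, at most 5 changes,
BIC model selection), (3) snaps changepoints to local extrema of the raw
series with topographic prominence ≥ 25% of the trajectory range, and (4)
labels each interval by an OLS slope t-test at α = 0.05: significantly
positive → growth, negative → shrinkage, else indeterminate.

**Joint rate models.** Per-phase rates are estimated per segment by OLS
and jointly across strains by a maximum-likelihood linear mixed-effects
model

&nbsp;&nbsp;&nbsp;&nbsp;y<sub>ij</sub> = β0<sub>s(j)</sub> + β1<sub>s(j)</sub>·t<sub>ij</sub> + b0<sub>j</sub> + b1<sub>j</sub>·t<sub>ij</sub> + ε<sub>ij</sub>,&nbsp;&nbsp;(b0, b1)<sub>j</sub> ~ N(0, Ψ),&nbsp;&nbsp;ε ~ N(0, σ²)

with per-strain fixed intercepts ("initial length") and slopes (rates), a
random intercept and slope per partial trajectory, and Wald t-tests for
strain contrasts.

**Intensity statistics.** Asymmetry index |I_bud − I_mother| / (I_bud +
I_mother), cumulative intensity, punctum-loss frequency with Wilson 95%
binomial CIs, fluorescence stoichiometry (brilliance of one fluorophore
from a reference complex of known copy number, e.g. 16 kinetochores × 17
Dam1 per kinetochore), exposure-time scaling, Welch's t-test and the
two-proportion z-test.

**Droplet hydrodynamics.** For a coalescing droplet the aspect parameter
A = (L − W)/(L + W) decays as A0·e^(−t/τ); τ grows linearly with the final
radius R and the slope τ/R (inverse capillary velocity) equals
(19/20)·η_int/γ when the condensed phase is far more viscous than the
dilute phase — the high-viscosity-ratio limit of the full two-fluid
relaxation time τ = [(2λ+3)(19λ+16)/(40(λ+1))]·η_ext·R/γ, λ = η_int/η_ext.
Plus FRAP reference-droplet bleaching correction, partition coefficients,
and moment-equivalent ellipse axes from binary masks.

**Phase diagrams.** Approximate binodal boundaries through the salt
midpoints between separated and soluble wells at each protein
concentration, critical-concentration brackets, and binodal comparison.

## Worked example

```python
from tipbody import (MtSimParams, IntensitySimParams, simulate_trajectory,
                     annotate, brilliance_per_molecule, molecule_count,
                     inverse_capillary_velocity)
from tipbody.rates import extract_partials, fit_lme

trajs = [simulate_trajectory(MtSimParams(seed=s, len_noise_sd=0.05, init_length=1.0),
                             IntensitySimParams(seed=s), cell_id=f"cell{s}",
                             strain="wt" if s < 20 else "mut")
         for s in range(40)]
partials = []
for tr in trajs:
    ann = annotate(tr)
    partials += [p for p in extract_partials(tr, ann, "length")
                 if p.phase_kind == "growth"]
fit = fit_lme(partials, "length", "growth")
for s in fit.strains:
    e = fit.slopes[s]
    print(f"{s}: growth rate {e.estimate*1000:.1f} nm/s "
          f"(95% CI {e.ci_lo*1000:.1f}..{e.ci_hi*1000:.1f})")

b = brilliance_per_molecule(912, 16, 17)
print(f"brilliance {b:.2f} a.u.; molecules {molecule_count(244, b):.1f}")
print(f"inverse capillary velocity {inverse_capillary_velocity(18.2, 7e-6):.2f} s/um")
```

prints

```
mut: growth rate 19.3 nm/s (95% CI 18.6..20.0)
wt: growth rate 19.9 nm/s (95% CI 19.3..20.5)
brilliance 3.35 a.u.; molecules 72.8
inverse capillary velocity 2.47 s/um
```

Both simulated strains grow at the generator's true 20 nm/s and the joint
model recovers it with per-strain CIs. The stoichiometry lines convert a
reference punctum of 912 a.u. spread over 272 molecules into a single-
molecule brilliance of 3.35 a.u., so a 244 a.u. punctum holds ≈ 73
molecules. The last line converts a condensed-phase viscosity of 18.2 Pa·s
and surface tension of 7 μN/m into the τ/R slope expected for droplet
fusion, 2.47 s/μm.

The same stages are available from the shell:

```
tipbody simulate-mt --seed 1 --n-trajectories 20 --out tracks.tsv
tipbody annotate tracks.tsv --out segments.tsv
tipbody rates tracks.tsv --phase growth --response length
tipbody stoich --ref-intensity 912 --sites 16 --copies 17 --query 244
```

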