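# venafit

Constitutive characterization of venous tissue from uniaxial strip tests.

Veins recruited for hemodialysis vascular access (arteriovenous fistulas)
are routinely modelled in computational hemodynamics, but credible
fluid–structure simulations need a nonlinear anisotropic material
description of the venous wall. `venafit` implements the standard
workflow for producing one from planar strip experiments on vessels such
as the basilic and great saphenous vein: forward mechanics of an
incompressible 4-fiber-family hyperelastic model, reduction of raw strip
measurements to per-donor representative stress–stretch curves, global
identification of the constitutive parameters, extraction of initial and
tangent Young's moduli, and a synthetic virtual-experiment generator that
lets the whole pipeline be validated end to end without access to donor
tissue.

## Model

The strain energy density superposes an isotropic neo-Hookean matrix and
four exponentially stiffening fiber families:

```
W = μ/2 (I₁ − 3) + Σⱼ₌₁..₄ k₁ʲ/(4 k₂ʲ) [exp(k₂ʲ (I₄ʲ − 1)²) − 1]
```

with `I₁ = tr C`, `C = FᵀF`, and `I₄ʲ = Mʲ·C Mʲ` the squared stretch of
family *j*. Families lie in the circumferential–longitudinal surface at
angles `βʲ` from the circumferential axis: `β¹ = 0`, `β² = 90°`, and a
symmetric diagonal pair `β³ = −β⁴ = β` sharing one `(k₁, k₂)`, leaving
eight independent parameters `(μ, k₁¹, k₂¹, k₁², k₂², k₁³, k₂³, β)`.

A strip pulled along one in-surface axis is in uniaxial tension:
incompressibility (`det F = 1`) fixes the thickness stretch, the
traction-free thickness face fixes the pressure-like multiplier
(`p = μ λ_R²`, since no fiber has a radial component), and the in-plane
transverse stretch is solved from the zero-transverse-stress condition at
every loading step. Parameters are identified by minimizing

```
Q = Σᵢ₌₁..ₘ [(P_circ^EXP − P_circ^MOD)ᵢ² + (P_long^EXP − P_long^MOD)ᵢ²]
```

over a donor's pair of representative curves (default m = 20 points over
0–200 kPa nominal stress), with a differential-evolution global stage
followed by multistart bound-constrained least squares. Goodness of fit
is reported as R² per direction; stiffness as the initial modulus (OLS
slope over 0–0.5 kPa by default) and the tangent modulus at 100 kPa, both
versus engineering strain.

## Worked example

```python
import numpy as np
from venafit import (FitConfig, FourFiberModel, StripDirection, SyntheticStudy,
                     build_representative, clean_loading_branch, generate_study)

study = generate_study(SyntheticStudy(n_donors=1, seed=3))
donor = next(iter(study.truth))
curves = {}
for d in StripDirection:
    strips = [clean_loading_branch(r) for r in study.records
              if r.donor_id == donor and r.direction is d]
    curves[d] = build_representative(strips, m=20, stress_max=200.0)

model = FourFiberModel.from_curves(curves)
result = model.fit(FitConfig(seed=7, n_multistarts=8))
print(result.summary())
```

prints

```
4-fiber-family fit — donor BV_D01
==============================================
mu (kPa)                 0.001
k1_circ (kPa)          8.55898
k2_circ (-)            732.967
k1_axial (kPa)          87.065
k2_axial (-)           1.51269
k1_diag (kPa)      1.79325e-09
k2_diag (-)            567.432
beta (deg)             35.5768
----------------------------------------------
Q (kPa^2)              126.025
R^2 circ              0.998815
R^2 long              0.999289
evaluations              19146
seed                         7
```

The eight rows are the identified constitutive parameters (stress-like
entries in kPa), `Q` is the residual sum of squares over both 20-point
curves, and the R² values say the fitted model reproduces 99.9% of the
stress variance of this noisy virtual donor in each direction. The
exponential fiber parameters are strongly correlated, so very different
parameter vectors can encode nearly identical curves (here the matrix
term and the diagonal family have collapsed onto other families without
hurting the fit) — recovery is judged on curves, not parameter equality.

The same workflow is available from the shell:

```
venafit synth --n-donors 10 --seed 1 --out data/
venafit run --specimens data/specimens.csv --out results/ --multistarts 8
```

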