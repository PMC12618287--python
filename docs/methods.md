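# Methods

## Constitutive model and its assumptions

The venous wall is treated as hyperelastic and incompressible — standard
for preconditioned blood-vessel tissue — with a strain energy density
combining a neo-Hookean matrix and four exponential fiber families
(circumferential, longitudinal, and a balanced diagonal pair at ±β):

    W = μ/2 (I₁ − 3) + Σⱼ k₁ʲ/(4 k₂ʲ) [exp(k₂ʲ (I₄ʲ − 1)²) − 1].

The model is used phenomenologically: the "fiber families" are a
convenient parameterization of anisotropic stiffening, not a claim about
histological architecture. Nominal (first Piola–Kirchhoff) stress follows
from `P_ii = ∂W/∂λ_i − p/λ_i` in the principal frame.

Assumptions baked into the implementation:

* **Diagonal deformation.** Strip tests are modelled with
  `F = diag(λ_R, λ_T, λ_Z)` in cylindrical axes. Because the diagonal
  families are balanced at ±β, no shear is energetically induced, so this
  is consistent for strips cut along the vessel axes. Arbitrary `F` with
  shear is out of scope.
* **Fibers in the Θ–Z surface.** `I₄ʲ = λ_T² cos²βʲ + λ_Z² sin²βʲ`; no
  family loads the thickness direction, which is what makes the
  multiplier eliminable in closed form (`p = μ λ_R²`).
* **Compressed fibers.** The exponential term is evaluated for all `I₄`,
  including `I₄ < 1`, exactly as the energy is written. A tension-only
  switch (`tension_only=True` throughout) zeroes shortened families; it is
  off by default since the experimental literature for this model family
  fits the full expression, and published parameter tables do not state a
  compressed-fiber exclusion.
* **Loading branch only.** Unloading/hysteresis and rate effects are not
  modelled.

## Parameters

| parameter | units | meaning | admissible |
|---|---|---|---|
| μ | kPa | matrix (small-strain shear-like) stiffness; uniaxial small-strain Young's modulus is 3μ | > 0 |
| k₁ circ/axial/diag | kPa | fiber stiffness scale per family | ≥ 0 |
| k₂ circ/axial/diag | – | exponential stiffening rate per family | > 0 |
| β | deg | diagonal-pair angle from the circumferential axis | [0°, 90°] |

Degrees at every interface, radians internally. Reported magnitudes for
venous tissue span μ ~ 1–10³ kPa, k₁ ~ 1–2·10³ kPa, k₂ ~ 0.5–10⁴, β ~
30°–80°; fitting bounds are set with headroom around these (μ ∈ (10⁻³,
5·10³] kPa, k₁ ∈ [0, 5·10⁴] kPa, k₂ ∈ (10⁻⁶, 5·10⁴], β ∈ [0°, 90°]).

## Numerical choices

* **k₂ → 0 limit.** The fiber term `k₁/(4k₂)(e^{k₂x²} − 1)` switches to
  its series `k₁x²/4 (1 + k₂x²/2)` below k₂ = 10⁻⁸, avoiding 0/0.
* **Overflow.** An exponent `k₂(I₄−1)² > 700` raises a diverged-energy
  error in the scalar API; inside the vectorized solver the exponent is
  clipped (sign-preserving) and non-finite objective values are treated
  as infeasible with a large penalty.
* **Exact family axes.** cos²/sin² of the family angles are snapped to 0
  below 10⁻³⁰, so a family at exactly 0° or 90° contributes exactly
  nothing across its normal. Without this, the rounding residue of
  cos(π/2) (~10⁻¹⁷) multiplies the exponential term and can leak
  arbitrarily large spurious stress into the wrong component.
* **Transverse solve.** Per loading step the in-plane transverse stretch
  is the root of the zero-transverse-stress equation. The bracket starts
  at [1/λ, 1] (between area-preserving in-plane contraction and no
  contraction) and widens once to [0.3, 1.5]. The scalar API uses brentq
  (xtol 10⁻¹⁴); curve sweeps and the fitting objective use a vectorized
  safeguarded Newton with the analytic derivative, bisection fallback, and
  the same bracket policy (tests assert the two paths agree to 10⁻¹²
  absolute in the transverse stretch). Solutions
  must leave a transverse residual below
  10⁻⁹ · max(1, P_load) + 32 eps · |∂P_trans/∂u · u| kPa or an error is
  raised; the second term is the double-precision floor — with the root
  known to ~eps relative, the residual cannot be driven below
  eps × (slope × stretch), which matters only for extremely stiff states
  (k₂ ~ 10³–10⁴) where the slope reaches 10¹⁰ kPa per unit stretch.
* **Constraint handling.** The zero-transverse-stress conditions are
  satisfied exactly by this nested per-point root-finding, rather than by
  penalty terms in the objective; the outer optimization is then purely
  bound-constrained and no constraint weights need tuning.

## Curve processing

Specimens are cleaned by zero-shifting to the first sample (stress offset
removed, stretch renormalised to 1), collapsing duplicate stretches, and
pruning to the strictly increasing stress envelope; fewer than five
surviving points rejects the specimen with a reason. Representative
curves average a donor's specimens **at fixed stress**: m uniform stress
levels on (0, P_max] (default 20 levels, P_max = 200 kPa, giving the grid
10, 20, …, 200 kPa), each specimen's stretch interpolated monotonically
(piecewise-linear in stretch-vs-stress, no overshoot) and averaged
arithmetically. Stress-parameterized averaging is chosen because the
protocol fixes a stress range, not a stretch range; a
stretch-parameterized alternative and a (1, 0) anchor point are config
options. The grid excludes 0 to avoid a degenerate all-zero point. A
specimen that tops out below P_max truncates the grid to the common
maximum by default (logged) or rejects, per configuration. The averaging
scheme is this package's convention; source datasets rarely document
theirs.

## Fitting

`Q` is the unweighted sum of squared stress residuals over both
directions at the experimental stretches (per-direction weights are
available but default to 1, matching the objective as usually printed).
The search runs in a transformed space: log₁₀ for μ and the three k₂
(k₂ magnitudes span four orders in published tables; μ spans three), while
k₁ stays linear so its lower bound 0 — the isotropic limit — is
reachable exactly. The pipeline is: one differential-evolution stage over
the box (latin-hypercube init, pop 8·8, 40 generations, no polish),
then bound-constrained trust-region least squares from the evolutionary
optimum, a data-informed start (μ from the first-grid-point secant / 3,
moderate fibers at 45°), and random restarts — with k₁ drawn
log-uniformly, since a uniform draw over the k₁ box concentrates on huge,
mostly infeasible fiber stiffnesses — up to `n_multistarts`
(default 32, each capped at 2000 objective evaluations). Restarts stop
early once Q < 10⁻¹⁰ × Σ P_exp² — an essentially exact fit that further
restarts cannot improve meaningfully. The best restart is returned and Q
is recomputed at the reported parameters. Everything is a deterministic
function of the seed.

The exponential parameters are strongly correlated (near
non-identifiable): very different parameter vectors can produce nearly
identical curves. Fit quality is therefore judged on reproduced curves
(R² per direction), never on parameter equality.

## Elastic moduli

Both moduli are OLS slopes of nominal stress versus engineering strain
(λ − 1): the initial modulus over a low-stress window (default 0–0.5 kPa,
kept as the conventional definition although it is very narrow — it
requires densely sampled low-load data, and the implementation raises a
clear error when fewer than two points fall inside; the window is fully
configurable) and the tangent modulus in a ±10 kPa window around
100 kPa. A regression window is used instead of a two-point difference
for noise robustness. Reported in MPa.

## Synthetic studies

The generator emulates a strip-test campaign: 10 donors split between
two vein groups, 3–4 strips per direction, curves spanning 0–200 kPa,
~150 sample points per strip (a fixed-rate video extensometer at constant
crosshead speed samples roughly uniformly in stretch), a 7% experiment
failure rate (failure masks redrawn so at least two strips per direction
survive), 5% multiplicative lognormal stress noise (heteroscedastic —
absolute scatter grows with load, as in real tensile data), and 5%
specimen-level rescaling of the strain axis `λ−1 → s(λ−1)`, mimicking
gauge-length/clamping variation while keeping each donor's ground truth
well defined. Ground-truth parameters are drawn log-uniformly (μ 1–10³
kPa, k₁ 1–2·10³ kPa, k₂ 0.5–5·10³, β 30°–80°) and screened for a
monotone, solvable response to 200 kPa; both vein groups share these
ranges since published magnitudes overlap almost completely between
groups. What the generator does **not** emulate: preconditioning cycles,
viscoelastic rate effects, hysteresis, extensometer artifact spikes,
temperature/storage effects. Passing recovery tests therefore shows the
pipeline is correct and well-conditioned under realistic noise — not that
real tissue data meets the generator's statistical assumptions.

## Validation sizes and oracles

The finite-difference stress check draws parameters log-uniformly
(μ 10–10³ kPa, k₁ 1–2·10³ kPa, k₂ 0.5–50) at stretches in [0.8, 1.4] and
screens states to W ≤ 10³ kPa: outside that regime the central-difference
oracle itself loses meaning in double precision (the exponential term
dwarfs the smaller stress components below the rounding granularity of
W). Brute-force verification of the transverse solver scans a 10⁻⁶
stretch grid. End-to-end recovery uses 10 noiseless donors and 10 noisy
single-donor seeds with the multistart count at 8; these sizes keep a
full validation run at a few minutes on one CPU while exercising
every pipeline stage.

## Known limitations

* Biaxial/inflation states, residual stress and shear are not modelled;
  parameters identified from uniaxial strips inherit the usual caveats
  when extrapolated to 2-D stress states.
* Parameter values are not unique (see fitting); uncertainty
  quantification of parameters is out of scope.
* Group-comparison statistics (mixed-effects models on moduli) are out of
  scope; the moduli CSV output is ready for off-the-shelf tools.
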