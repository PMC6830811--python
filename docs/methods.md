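# Methods

## Model

Passive nominal stress (first Piola–Kirchhoff: force per undeformed
area, kPa) is modelled at the sarcomere level; the strain coordinate is
always sarcomere length L (μm), because whole-specimen stretch
overstates sarcomere stretch when clip regions deform non-uniformly.

**Fibre (parallel elastic element).**  P(λ) = A·[exp(λ² − 1) − 1] for
λ = L/L₀ ≥ 1 and 0 below slack — fibres are assumed to have no
compressive stiffness, so every fibre law here is clamped to zero for
λ < 1.  A (kPa) is half the initial tangent modulus (the analytic
derivative dP/dλ → 2A as λ → 1⁺); L₀ (μm) is the slack sarcomere
length.  Two literature alternatives are provided for comparison: the
quadratic law 4P₀(λ − 1)², whose initial stiffness is exactly zero, and
the Zhang exponential law 2P₀aA(λ − 1)·exp[a(λ − 1)²] with initial
modulus 2P₀aA, where P₀ is a maximum isometric stress that can be fixed
to a physiological value (e.g. 137.5 kPa) while a, A are fitted.

**ECM.**  An isotropic hyperelastic law with a volumetric and an
isochoric part,

    P_c = k_v (J² − 1) F⁻ᵀ + β Ī₁ exp(Ī₁ − 3) J^(−2/3) (F − ⅓ I₁ F⁻ᵀ),

with J = det F, I₁ = tr(FFᵀ), Ī₁ = J^(−2/3) I₁.  The bulk modulus k_v
multiplies (J² − 1) and therefore vanishes identically for isochoric
deformation; it is *not identifiable* from uniaxial incompressible
experiments and is carried through unchanged (generator default 0).
β (kPa) sets the nonlinear stress scale.  For uniaxial incompressible
stretch the scalar working form used everywhere in fitting is

    P_ecm(λ) = β I₁ (λ − 1/λ²) exp(λ² + 2/λ − 3),   λ = L/L₀b,

with I₁ = λ² + 2/λ and L₀b the stress-free sarcomere length of the
bundle.  No compression clamp is applied to the ECM: the expression is
evaluated for all λ > 0 and is negative below λ = 1.

**Scalar vs tensor form.**  Reducing the tensor law under
F = diag(λ, λ^(−1/2), λ^(−1/2)) gives a (1,1) component equal to
**2/3** of the scalar form at every stretch: the deviatoric projection
contributes (2/3)(λ − 1/λ²) where the scalar form carries (λ − 1/λ²).
The two printed forms are mutually inconsistent by this constant
factor.  Both are implemented literally as written; the ratio is
exposed as `UNIAXIAL_TENSOR_SCALAR_RATIO` and asserted in tests rather
than silently reconciled.  Fitting uses the scalar form.

**Bundle.**  Rule of mixtures over fast fibres, slow fibres and ECM
with cross-sectional volume fractions α_f + α_s + α_c = 1 (study values
0.425/0.425/0.15):

    P = α_f P_f(λ_f) + α_s P_s(λ_s) + α_c P_ecm(λ)        (scalar)
    P = (α_f P_f + α_s P_s) n ⊗ n₀ + α_c P_c              (tensor)

In the tensor form the fibre stretch is |F·n₀| and n = F·n₀/|F·n₀|.
The bundle reference configuration is its stress-free state, so a
deformation-gradient stretch λ corresponds to sarcomere length λ·L₀b,
which is what each fibre law receives (each converts to its own λ via
its own slack length).  The three scalar addends are returned
separately and sum to the total exactly.

## Fitting

Objective: Ξ = (1/n)·Σ[Pᵢ − P(Lᵢ; θ)]² (kPa²), unweighted.  The
reported residual sum of squares is RSS = Ξ·n (Ξ is already a mean of
squares, so this is the plain Σ residual²); degrees of freedom
ν = n − N with N the number of *free* parameters.  "Multiple fitting"
of a specimen group concatenates all of the group's records into one
objective with a single shared parameter set — the group-average curve.

Optimiser: 64 uniform random starts inside a finite bound box
(A ∈ (0, 10³] kPa, L₀ ∈ [1.5, 3.5] μm, P₀ ∈ (0, 10³] kPa, a ∈ (0, 10],
Zhang A ∈ (0, 10²], β ∈ (0, 10⁶] kPa, L₀b ∈ [1.0, 3.0] μm — spanning
all plausible values with margin), then Nelder–Mead polish of the five
best starts with one simplex restart at each incumbent (the restart
rescues stalls on badly scaled parameters such as β).  Out-of-box
excursions are penalised; parameters landing at a bound raise a
warning and set `at_bounds`.  Everything is driven by one integer seed:
repeated runs are bit-identical, and the result is invariant to record
order up to floating-point summation.

The bundle fit freezes the fibre parameters (from prior fibre fits) and
the volume fractions, leaving β — and by default L₀b as well — free.
With α_c = 0 the ECM term is absent from the model and β is
unidentifiable; this raises `NonIdentifiableError` rather than
returning an arbitrary number.

Time traces (stress relaxation after a stretch step; tension
redevelopment after release–restretch, giving k_tr) are fitted by
y(t) = y∞ + (y₀ − y∞)·e^(−kt) via bounded least squares with a
data-driven initial guess.  On exact data the fit recovers (k, y∞) to
machine-level precision regardless of truncation, which is why a fitted
asymptote is preferred over the last recorded sample when relaxation
recordings are cut short (a 120 s window on a k = 0.01 s⁻¹ decay leaves
the raw value ~30% of the amplitude above the true plateau).

## Model comparison

Extra-sum-of-squares F-test (Motulsky–Ransnas style): fit the two
groups separately (RSS_sep = RSS₁ + RSS₂, ν_sep = ν₁ + ν₂) and pooled
on the union (never assembled from the group fits — the pooled optimum
is recomputed), then

    F = [(RSS_pool − RSS_sep)/(ν_pool − ν_sep)] · [ν_sep/RSS_sep]

against F(ν_pool − ν_sep, ν_sep).  Continuous p-values are reported
(so "p < 0.001" claims are checkable) alongside the critical-value
route; the two decision rules agree by construction.  For nonlinear
regressions the test is approximate: under a simulated null
(5 + 5 specimens, 8 points each, homoscedastic Gaussian noise of SD
1 kPa, 500 replicates) the empirical size at α = 0.05 is ≈ 0.066,
slightly liberal but close to nominal.

## Synthetic data generator

Emulates the study design: 4 fast + 7 slow fibres and 11 bundles, each
measured on an increasing grid of 8 sarcomere lengths (protocol range
5–12) spanning 2.2–4.2 μm — slack to the end of filament overlap.
Specimen-level variability multiplies A lognormally (mean-preserving)
and shifts L₀ by a Gaussian, both with CV 10% by default; bundle volume
fractions are perturbed lognormally and renormalised.  Measurement
noise is additive Gaussian with SD max(0.05·stress, 0.2 kPa) and
stresses are clipped at zero — a simple model chosen because no
residual structure is reported for such experiments; the floor keeps
near-slack points realistically uncertain.

Default truths are the published fitted values (fast 6.64 kPa/2.42 μm,
slow 7.01 kPa/2.44 μm, fractions 0.425/0.425/0.15, L₀b = 1.60 μm).  The
ECM scale is **β = 13.9 kPa**, chosen once so that the α_c-weighted ECM
stress at 2.5 μm is ≈ 18 kPa, matching the measured decomposition's
magnitude at that length.  The published β = 168.55 MPa is *not* usable
here: inserted into the scalar ECM law as printed it yields stresses
many orders of magnitude above the published decomposition, an internal
inconsistency of the source values that cannot be resolved from the
text.  A related consequence: with L₀b = 1.60 μm the exponential ECM
term grows much faster with length than the published ECM column
(thousands of kPa at 4.2 μm), so synthetic bundle data are
substantially stiffer at high stretch than real bundles.  This is a
property of the law with these parameters, not of the generator.

What passing tests on synthetic data do and do not show: they verify
the estimators, the statistics and the pipeline plumbing under the
assumed noise model; they do not validate the constitutive laws against
real tissue, and the generator omits fibre-type misclassification,
length-measurement error, and any viscoelastic residue left by
incomplete relaxation.

## Numerical choices

* Tangent moduli are central differences of nominal stress with respect
  to stretch λ = L/reference_length with relative step 10⁻⁴; the
  reference length is a required explicit argument because a tangent
  "per unit stretch" is meaningless without it.  Where the stencil
  straddles a fibre slack length (a C⁰ kink) a one-sided difference on
  the containing side is used and the point is flagged.
* At exactly λ = 1 the analytic fibre tangent returns the right-limit
  2A (the left derivative is 0).
* RSS/Ξ consistency (RSS = Ξ·n within 1e-9 relative) and ν ≥ 1 are
  enforced on every `FitResult`.
* Degenerate inputs fail loudly: non-positive lengths, singular or
  orientation-reversing deformation gradients, all-equal length data,
  < 4 samples for a time-trace fit.

## Problem sizes used in the statistical tests

Simulation-based checks state their designs explicitly: the null
calibration uses 500 replicates of 5 + 5 specimens × 8 points; the
fibres-vs-bundles detection checks use 40 replicates at full study
scale (11 fibres + 11 bundles × 8 points), where the ECM effect is so
large that every replicate rejects at α = 0.001; the noisy
parameter-recovery study uses 20 replicates of 11 specimens × 20
lengths — denser than the wet protocol, because the strong A–L₀
correlation ridge of the exponential law makes the *parameters* (unlike
the fitted curve) converge slowly with n: at 5% proportional noise the
median relative error on A is ≈ 9% with 88 points and ≈ 4% with 220.

## Known limitations

* The ECM is treated as isotropic although muscle tissue is not; the
  data informing β are uniaxial along the fibre direction only.
* k_v cannot be estimated from these experiments (see above).
* No confidence intervals on fitted parameters; the F-test compares
  groups but does not quantify per-parameter uncertainty.
* The quadratic and Zhang laws are provided for comparison only; the
  Zhang fit with physiological P₀ is known to push L₀ to
  non-physiological values on this kind of data.
* Published bundle tangent-modulus tables cannot be reproduced without
  knowing the stretch reference used for them; tangent curves here
  always state theirs.
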