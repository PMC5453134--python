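# Methods

## Scope and kinematic assumptions

The package models homogeneous, incompressible uniaxial extension and
compression: every state is diagonal in the principal frame with
λ1 = λ, λ2 = λ3 = λ^(−1/2), so J = det F = 1 exactly and I3 = 1. Deformation
tensors are never materialized — all constitutive equations used here depend
only on the principal stretches and the invariants I1, I2, and the strain
intensity m = √(tr B²) = √(I1² − 2I2). This matches how cyclic tissue and
suture tests are actually run and fitted; general triaxial boundary-value
problems, compressibility and viscoelastic rate effects are out of scope.
Compression (λ < 1) is fully supported, since brain-tissue protocols mix
tension and compression.

## Constitutive structure

Total energy by the rule of mixtures, W_T = (1−f) W_iso(I1) + f W_aniso(I1, I3).

The matrix part is the amended non-Gaussian eight-chain energy

W_iso = μ[N(βλr + ln(β/sinh β)) − ln(β/λr)] + c,  λr = √(I1/3N), β = ℒ⁻¹(λr).

The amendment −μ ln(β/λr) corrects the eight-chain average toward the
full-network response; it is what lets fitted N values barely above 1
(tracheal membranes: N ≈ 1.03) reproduce the very sharp strain stiffening
of collagenous tissue, because the material then operates near its locking
stretch √N from the outset. The response function used in all stresses is
the exact derivative, ℵ = 2∂W_iso/∂I1 = μ/(3λr)[β + (1/N)(1/λr − 1/(βℒ′(β)))],
where ℒ′(β) = 1 − λr² − 2λr/β is an algebraic identity on the Langevin
function. Stress–energy consistency (engineering stress = dW_T/dλ) is
enforced by test at 1e−6 relative and is the arbiter for this functional
form. The fiber part is the isotropized eight-chain fiber energy
(A1/3)(I1−3) + (A2/9)(I1−3)² − (2A1/3)ln I3; the log term vanishes on the
incompressible states used here but is kept so the expression stays valid
for near-incompressible extensions. The per-fiber (non-isotropized) energy
with explicit fiber stretches is deliberately not implemented: the
isotropized form is the one actually used for all published fits.

In the stress differences the direction-cosine factor {x_ji² − x_ki²} that
a literal transcription of the stress equations would carry is dropped: it
is identically zero for the eight-chain cosines (all squares equal 1/3) and
would annihilate the fitted fiber constants. The implemented fiber stress
is the derivative of the isotropized energy, (2f/3)(A1 + (2A2/3)(I1−3))
(λj² − λk²), the unique reading consistent with W_T. The literal-zero
variant remains available via `literal_fiber_factor=True` for audit.

## Softening model

τ_j − τ_k = [virgin + (μC/2)(λj f_j − λk f_k)] · F(m, M; b), with
f_k = −2n λk^(n−1)(λmax_k^n − λk^n) and n = 1 by default. Two kernels are
provided because the source typography of the exponential is ambiguous:
`literal` (default) exp[−b(M−m)(m/M)] and `radical`
exp[−b(√M−√m)√(m/M)]. Everything downstream depends only on the kernel
contract — equal to 1 on the primary path, in (0, 1], decreasing as m drops
below M — and fitting works with either. The per-component form of the
residual term (μλk²C f_k) that appears alongside the softened stress in the
source is superseded by the stress-difference form above, which is the one
the published tables were fitted with.

History on a uniaxial path is the running maximum of m, together with the
principal stretches and the stored energy at the point where that maximum
was attained. A sample that sets a new maximum lies on the primary path,
responds with the virgin equation and updates the history (this includes
compression excursions: m measures deformation magnitude regardless of
sign). At the reversal point the kernel is 1 and the residual gradient
vanishes, so loading→unloading is exactly continuous; reloading retraces
the unloading branch and rejoins the virgin curve at λmax. One known
artifact: after a tension cycle, a subsequent compression excursion
re-enters the primary path at a state different from the stored λmax, and
the residual term then makes the softened→virgin hand-off discontinuous.
This is inherent to the history structure of the model, not to this
implementation.

The permanent-set stretch λres solves softened σ(λ) = 0 on the unloading
branch by Brent root-bracketing in (λ_mirror, λmax], where λ_mirror < 1 is
where m re-attains M on the compression side; the residual of the root is
below 1e−9 and λres = 1 exactly when C = 0.

## Pseudo-elastic model

τ_j − τ_k = [virgin + (1−η2)(ν1λj² − ν2λk²)]·η1, with
η1 = 1 − (1/r1)tanh[(Wmax−W_T)/(μ m1)], η2 = tanh[(W_T/Wmax)^α]/(r1 tanh 1),
α = (3 + 8Wmax/(5μ))/10, ν2 = γμ, ν1 = ν2(1 − (1/r2)tanh[10(λmax−1)]).
The bracket groupings are the only dimensionless readings that give η1 = 1
and η2 = 1/r1 at the reversal point, which is what the near-1 fitted r1
values require; η1 multiplies the whole bracket. On the primary path the
virgin equation applies; the reversal-point gap to the virgin curve is
(1 − 1/r1)(ν1λmax² − ν2/λmax) and vanishes linearly as r1 → 1 (verified at
r1 ∈ {1.1, 1.01, 1.001}).

Energies in η1/η2 are measured from the undeformed state, W(λ) − W(1),
with the same parameter set (including c) in both terms. The absolute
reference energy of the amended model, W_iso(I1=3), is negative for several
published parameter sets (male mouse skin: ≈ −0.13 MPa), which would make
the fractional power in η2 undefined; measuring from the unloaded state
keeps W_T/Wmax in [0, 1] on every admissible path while leaving the
c-insensitive difference Wmax − W_T untouched.

## Numerics

- **Inverse Langevin**: safeguarded Newton on coth β − 1/β − y, bracket
  [0, 3/(1−y)+10], Cohen seed y(3−y²)/(1−y²), residual tolerance 1e−12,
  bisection fallback when a Newton step leaves the bracket; vectorized.
  No fixed approximant is used, so approximation error cannot leak into the
  stress–energy consistency checks. ℒ itself uses a 4-term odd series below
  β = 0.05 (cancellation) and 1 − 1/β above β = 30 (coth ≡ 1 in doubles).
- **Locking** (λr ≥ 1, i.e. I1 ≥ 3N) raises a typed `LockingError` instead
  of returning infinities, so fitting can bound N away from locking: the
  lower bound on N is I1max/3·(1+1e−3) computed from the data's stretch
  range.
- **Fitting**: scipy `least_squares` (trust-region reflective, bounds),
  residuals normalized by the peak |stress| and parameters by their initial
  values, which makes the calibration invariant to the stress unit and well
  conditioned across magnitudes (μ ~ 0.1, A2 ~ 10⁴). The objective is
  multimodal in (N, b), so a seeded multi-start (default 8, ±20% around the
  start) is used; results are bitwise reproducible for a fixed seed. Trial
  sets that lock raise no exception — they are rejected with a large
  penalty residual.
- Root finding for λres uses `brentq` with xtol 1e−12.

## Parameters and units

μ (stress), N (>1; √N is the locking stretch), c (energy density, same
pressure unit as μ; printed in J/m³ = Pa by the sources and converted on
load), f ∈ [0,1] (the printed "f (%)" columns are divided by 100; a bare
fraction reading is available via `params(f_as_fraction=True)`), A1, A2
(stress; the tracheal table prints them in MPa against μ in kPa — stored
verbatim and converted at evaluation), b ≥ 0 and C ≥ 0 dimensionless (C is
printed with a pressure unit in the tables, but it enters the stress only
through μC, so dimensionless storage is the consistent choice), n = 1,
m1, r1, r2, γ dimensionless with ν2 = γμ.

Each packaged fixture also records a protocol stretch maximum used by the
simulators and audits. Where the sources state a range it is honored
(tracheal membranes: within 1.048–1.215); elsewhere the value is a typical
cyclic-test range for that material chosen safely below chain locking
(e.g. mouse skin 1.25 against locking ≈ 1.31, brain ±10% strain, rubber 6).

## Synthetic data and what the tests show

`generate_cycle_data` replays a stretch program through the chosen model
and adds seeded zero-mean Gaussian stress noise — it emulates the sampling
and noise level of a cyclic uniaxial test (default recovery experiment: 2%
of peak stress, 100 points/branch), but not instrument drift, preload
uncertainty, specimen-to-specimen variability, or rate effects. Passing
recovery tests therefore show identifiability of the constitutive
parameters under idealized cyclic data, not robustness to every laboratory
artifact.

Identifiability itself is structural: uniaxial data determine the
combinations μ(1−f), fA1, fA2, μC, b, N, so μ and f cannot be separated
when both are free. The recovery experiments accordingly treat the fiber
composition block (f, A1, A2) as known — exactly as the rubber validation
fixes f = 25% from X-ray diffraction — and recover (μ, N, b, C) from noisy
data (worst case over 12 noise seeds: μ within 2.6%, N within 0.2%).
Similarly γ and r2 are collinear through ν1 when a single reversal is
observed, so the γ-recovery experiment fixes r2.

## Known limitations

- Single scalar history (M or Wmax): no independent per-axis damage, no
  anisotropic damage evolution.
- The softened→virgin hand-off after a tension→compression history switch
  is discontinuous (see above).
- No uncertainty quantification on fitted parameters; the multi-start
  least-squares result is a point estimate.
- Cauchy vs engineering stress is metadata on every curve and must be
  correct — the two differ by a factor λ and mixing them silently would
  corrupt fits; file I/O refuses curves without a parseable header only if
  columns are malformed, defaulting to engineering stress otherwise.
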