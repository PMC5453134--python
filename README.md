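# mullinsmix

Rule-of-mixtures constitutive models for **Mullins stress-softening and
residual strains** in soft biological tissues and biocompatible materials,
under uniaxial extension or compression of an incompressible solid.

Cyclically loaded soft tissues (skin, vaginal tissue, tracheal membranes,
brain white matter) and polymeric sutures respond more compliantly on
reloading than on first loading (the Mullins effect) and retain a nonzero
stretch at zero stress after unloading (permanent set). `mullinsmix`
implements, tests and calibrates an equivalent-material description of both
effects for biomechanists who need a small number of interpretable
constants rather than a full microstructural model.

## The model

The total strain energy density splits by the rule of mixtures into a
matrix part and a fiber part weighted by the equivalent anisotropic
volumetric fraction *f*:

    W_T = (1 − f) W_iso(I1) + f W_aniso(I1, I3)

**Matrix**: the amended non-Gaussian (average-stretch eight-chain) network
energy,

    W_iso = μ [ N (β λr + ln(β / sinh β)) − ln(β / λr) ] + c,
    λr = √(I1 / 3N),   β = ℒ⁻¹(λr),   ℒ(β) = coth β − 1/β,

with shear modulus μ, chain link count N (locking stretch √N) and energy
constant c. Its stress response function is

    ℵ = 2 ∂W_iso/∂I1 = μ/(3λr) [ β + (1/N)(1/λr − 1/(β ℒ′(β))) ],

which reduces to the neo-Hookean ℵ = μ in the Gaussian limit N → ∞.

**Fibers**: the isotropized eight-chain fiber energy
`W_aniso = (A1/3)(I1−3) + (A2/9)(I1−3)² − (2A1/3) ln I3`, obtained by
averaging fiber families along the cube diagonals (±1, ±1, 1)/√3 of the
principal frame.

**Virgin stress** (principal Cauchy stress differences, pressure
eliminated):

    T_j − T_k = [ (1−f) ℵ + (2f/3)(A1 + (2A2/3)(I1−3)) ] (λj² − λk²)

**Stress softening with permanent set** multiplies the virgin stress,
augmented by a residual-strain term, with a kernel driven by the strain
intensity m = √(I1² − 2I2) relative to its historical maximum M:

    τ_j − τ_k = [ (T_j − T_k) + (μC/2)(λj f_j − λk f_k) ] · exp[−b (M−m)(m/M)]
    f_k = −2n λk^(n−1) (λmax_k^n − λk^n)

Seven material constants (μ, N, A1, A2, b, C, f) calibrate this law. An
alternative **pseudo-elastic** unloading model (modified Dorfmann–Ogden)
modulates the virgin stress with softening variables η1, η2 driven by the
stored energy relative to its maximum at the reversal point, adding
(m1, r1, r2, γ).

## Worked example

Simulate a load–unload cycle of male mouse skin (published constants
μ = 0.95 MPa, N = 1.082, A2 = 30 MPa, b = 2.8, C = 0.98, f = 9%) to
λ = 1.25 and back:

```python
import mullinsmix as mm

fx = mm.material_fixture("male_mouse_skin")
p = fx.params()                       # parameters in MPa
curve = mm.simulate_cycles([1, 1.25, 1], p, n_per_branch=100,
                           stress_kind="cauchy", stress_unit="MPa")

hist = mm.DeformationHistory.from_uniaxial_reversal(1.25, p.iso, p.fib)
s = mm.uniaxial_state(1.2)
print(f"peak Cauchy stress at lam=1.25 : {curve.stress.max():.4f} MPa")
print(f"virgin stress at lam=1.20      : "
      f"{mm.uniaxial_cauchy_stress(1.2, p.iso, p.fib):.4f} MPa")
print(f"unloading stress at lam=1.20   : "
      f"{mm.softened_stress_diff(s, hist, p.iso, p.fib, p.soft, 1, 2):.4f} MPa")
print(f"permanent-set stretch          : "
      f"{mm.residual_stretch(hist, p.iso, p.fib, p.soft):.4f}")
```

prints

```
peak Cauchy stress at lam=1.25 : 1.6603 MPa
virgin stress at lam=1.20      : 0.8706 MPa
unloading stress at lam=1.20   : 0.6645 MPa
permanent-set stretch          : 1.0811
```

The unloading stress at λ = 1.20 sits 24% below the virgin curve (Mullins
softening), and the unloading branch crosses zero stress at λ ≈ 1.081: the
skin keeps an 8% residual stretch after this cycle.

The same workflow is available from the shell:

```sh
mullinsmix fixtures
mullinsmix simulate --fixture male_mouse_skin --program 1:1.25:1 --out cycle.csv
mullinsmix generate --fixture male_mouse_skin --program 1:1.25:1 --noise 0.02 \
    --seed 42 --out synth.csv
mullinsmix fit --model softened --data synth.csv --init-fixture male_mouse_skin \
    --out report.yaml
```

## Layout

- `mullinsmix.kinematics` — principal-stretch states, invariants, strain intensity
- `mullinsmix.chain_statistics` — Langevin function and its numerical inverse
- `mullinsmix.energy` / `virgin_stress` — energies, response function, virgin stress
- `mullinsmix.softening` — softening kernel, history tracking, cycle simulator,
  residual stretch
- `mullinsmix.pseudoelastic` — modified Dorfmann–Ogden unloading model
- `mullinsmix.fitting` — bounded multi-start least-squares calibration
- `mullinsmix.synthetic_data` — published parameter fixtures, synthetic noisy cycles
- `mullinsmix.curveio` / `cli` — CSV curves and the `mullinsmix` command

See `docs/methods.md` for modelling assumptions, parameter meanings,
numerical choices and known limitations.
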