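"""Material parameter blocks for the rule-of-mixtures constitutive models.

All stress-like parameters (mu, A1, A2, nu2 = gamma*mu) must be expressed in
one consistent pressure unit (MPa or kPa); the energy constant c then carries
the same unit, since an energy density in an incompressible solid is a
pressure.  b, C, n, f, N, m1, r1, r2 and gamma are dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional


@dataclass(frozen=True)
class IsotropicParams:
    """Matrix (isotropic) block of the amended non-Gaussian energy.

    mu : shear modulus (stress units, > 0)
    N  : number of rigid links per chain (> 0); locking stretch is sqrt(N)
    c  : additive energy constant (same pressure unit as mu; any sign)
    """

    mu: float
    N: float
    c: float = 0.0

    def __post_init__(self):
        if not self.mu > 0.0:
            raise ValueError(f"shear modulus mu must be positive, got {self.mu!r}")
        if not self.N > 0.0:
            raise ValueError(f"chain link count N must be positive, got {self.N!r}")


@dataclass(frozen=True)
class FiberParams:
    """Fiber (anisotropic) block, isotropized eight-chain form.

    f  : equivalent anisotropic volumetric fraction, in [0, 1]
    A1 : linear fiber energy constant (stress units, any sign)
    A2 : quadratic fiber energy constant (stress units, any sign)
    """

    f: float = 0.0
    A1: float = 0.0
    A2: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.f <= 1.0:
            raise ValueError(f"fiber fraction f must lie in [0, 1], got {self.f!r}")


@dataclass(frozen=True)
class SofteningParams:
    """Stress-softening / residual-strain block.

    b : dimensionless softening parameter (>= 0); b = 0 disables softening
    C : dimensionless residual-strain constant (>= 0); enters the stress as mu*C
    n : residual exponent (>= 1); in practice fixed at 1
    """

    b: float = 0.0
    C: float = 0.0
    n: float = 1.0

    def __post_init__(self):
        if self.b < 0.0 or self.C < 0.0:
            raise ValueError("softening parameters b and C must be non-negative")
        if self.n < 1.0:
            raise ValueError(f"residual exponent n must be >= 1, got {self.n!r}")


@dataclass(frozen=True)
class PseudoElasticParams:
    """Modified Dorfmann-Ogden unloading block.

    m1    : dimensionless scale of the eta1 softening variable (> 0)
    r1    : dimensionless; eta1 in [1 - 1/r1, 1], eta2 in [0, 1/r1]; r1 -> 1
            makes the unloading branch meet the virgin curve at the reversal
    r2    : dimensionless scale in nu1 (> 0)
    gamma : dimensionless; nu2 = gamma * mu (stress units)
    """

    m1: float
    r1: float
    r2: float
    gamma: float

    def __post_init__(self):
        if not self.m1 > 0.0:
            raise ValueError(f"m1 must be positive, got {self.m1!r}")
        if not self.r1 > 0.0:
            raise ValueError(f"r1 must be positive, got {self.r1!r}")
        if not self.r2 > 0.0:
            raise ValueError(f"r2 must be positive, got {self.r2!r}")

    def nu2(self, mu: float) -> float:
        return self.gamma * mu


@dataclass(frozen=True)
class MaterialParams:
    """Composite parameter set used by simulators and fitting."""

    iso: IsotropicParams
    fib: FiberParams = field(default_factory=FiberParams)
    soft: SofteningParams = field(default_factory=SofteningParams)
    pe: Optional[PseudoElasticParams] = None

    def replace(self, **kwargs) -> "MaterialParams":
        return replace(self, **kwargs)
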