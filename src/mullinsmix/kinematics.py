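"""Principal-stretch kinematics of incompressible finite deformations.

All deformation states handled by the package are isochoric (J = 1) and
diagonal in the principal frame, which is the natural setting for uniaxial
extension/compression of incompressible soft tissue.  A state is described by
its three principal stretches, the invariants I1, I2, I3 of the right
Cauchy-Green tensor C, and the strain intensity

    m = |B| = sqrt(tr B^2) = sqrt(I1^2 - 2 I2),

the magnitude of the left Cauchy-Green tensor B.  In the undeformed state
m = sqrt(3); m grows monotonically with the amount of (uniaxial) deformation
in either tension or compression, which is what makes it a convenient scalar
measure of the worst deformation a material point has seen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import DomainError

SQRT3 = math.sqrt(3.0)


@dataclass(frozen=True)
class DeformationState:
    """One incompressible configuration in its principal frame.

    Attributes
    ----------
    lambda1, lambda2, lambda3:
        Principal stretches (dimensionless, positive).
    I1, I2, I3:
        Principal invariants of C = diag(lambda_i^2).
    m:
        Strain intensity sqrt(I1^2 - 2 I2) >= sqrt(3).
    """

    lambda1: float
    lambda2: float
    lambda3: float
    I1: float
    I2: float
    I3: float
    m: float

    @property
    def stretches(self) -> tuple[float, float, float]:
        return (self.lambda1, self.lambda2, self.lambda3)


def state_from_stretches(lambda1: float, lambda2: float, lambda3: float) -> DeformationState:
    """Build a :class:`DeformationState` from three principal stretches.

    The invariants are computed from the squared stretches and the strain
    intensity from the identity m^2 = I1^2 - 2 I2 = tr(B^2).

    Raises
    ------
    DomainError
        If any stretch is not strictly positive.
    """
    for lam in (lambda1, lambda2, lambda3):
        if not lam > 0.0:
            raise DomainError(f"principal stretches must be positive, got {lam!r}")
    a, b, c = lambda1 * lambda1, lambda2 * lambda2, lambda3 * lambda3
    I1 = a + b + c
    I2 = a * b + a * c + b * c
    I3 = a * b * c
    # m^2 = I1^2 - 2 I2 = a^2 + b^2 + c^2, evaluated in the cancellation-free form
    m = math.sqrt(a * a + b * b + c * c)
    return DeformationState(lambda1, lambda2, lambda3, I1, I2, I3, m)


def uniaxial_state(lam: float) -> DeformationState:
    """Uniaxial incompressible state: lambda1 = lam, lambda2 = lambda3 = lam^(-1/2).

    Covers both extension (lam > 1) and compression (0 < lam < 1).  The strain
    intensity reduces to m = sqrt(lam^4 + 2 lam^-2).
    """
    if not lam > 0.0:
        raise DomainError(f"stretch must be positive, got {lam!r}")
    lat = 1.0 / math.sqrt(lam)
    return state_from_stretches(lam, lat, lat)


def uniaxial_strain_intensity(lam):
    """Vectorized m(lam) = sqrt(lam^4 + 2/lam^2) for uniaxial states."""
    import numpy as np

    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0.0):
        raise DomainError("stretch must be positive")
    return np.sqrt(lam**4 + 2.0 / lam**2)


def uniaxial_first_invariant(lam):
    """Vectorized I1(lam) = lam^2 + 2/lam for uniaxial states."""
    import numpy as np

    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0.0):
        raise DomainError("stretch must be positive")
    return lam**2 + 2.0 / lam
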