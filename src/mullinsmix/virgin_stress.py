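"""Virgin (primary-loading) stress of the equivalent material.

For an incompressible isotropic-plus-isotropized-fiber solid the Cauchy
stress is T = [(1-f) aleph + 2f/3 (A1 + 2A2/3 (I1-3))] B - p 1 in the
principal frame, with the material response function

    aleph = mu/(3 lambda_r) [ beta + (1/N)(1/lambda_r - 1/(beta L'(beta))) ]
          = 2 dW_iso/dI1,      L'(beta) = 1 - lambda_r^2 - 2 lambda_r/beta

The indeterminate pressure p is never solved for: all outputs are principal
stress differences T_j - T_k, or the uniaxial engineering stress obtained by
applying the traction-free lateral boundary condition T_2 = T_3 = 0 and
dividing by the axial stretch (sigma = T_1/lambda).
"""

from __future__ import annotations

import numpy as np

from .chain_statistics import inverse_langevin, langevin_prime
from .errors import DomainError
from .kinematics import DeformationState, uniaxial_first_invariant, uniaxial_state
from .parameters import FiberParams, IsotropicParams

_AXES = (1, 2, 3)


def response_function(lambda_r, mu: float, N: float):
    """Material response function aleph(lambda_r; mu, N) = 2 dW_iso/dI1.

    The amendment term carries a 1/N factor and the combination
    1 - lambda_r^2 - 2 lambda_r/beta, which is exactly L'(beta); the second
    form is used numerically for stability near locking.  In the Gaussian
    limit N -> infinity, beta -> 3 lambda_r and aleph -> mu (neo-Hooke).
    """
    arr = np.asarray(lambda_r, dtype=float)
    if np.any(arr <= 0.0) or np.any(arr >= 1.0):
        raise DomainError("response_function requires 0 < lambda_r < 1")
    beta = inverse_langevin(arr)
    amend = 1.0 / arr - 1.0 / (beta * langevin_prime(beta))
    out = mu / (3.0 * arr) * (beta + amend / N)
    return out if np.ndim(lambda_r) else float(out)


def _fiber_modulus(I1, fib: FiberParams, literal_fiber_factor: bool = False):
    """Coefficient of (lambda_j^2 - lambda_k^2) contributed by the fiber part.

    With `literal_fiber_factor=True` the {x_ji^2 - x_ki^2} direction-cosine
    factor of the printed stress-difference equations is retained; it is
    identically zero for the eight-chain cosines (all squares 1/3), so this
    audit switch annihilates the fiber stress.  The default drops it, which
    is the derivative of the isotropized fiber energy.
    """
    if literal_fiber_factor:
        return np.zeros_like(np.asarray(I1, dtype=float))
    return (2.0 * fib.f / 3.0) * (fib.A1 + (2.0 * fib.A2 / 3.0) * (np.asarray(I1, dtype=float) - 3.0))


def stress_coefficient(I1, iso: IsotropicParams, fib: FiberParams,
                       literal_fiber_factor: bool = False):
    """(1-f) aleph + 2f/3 (A1 + 2A2/3 (I1-3)): multiplies lambda_j^2 - lambda_k^2."""
    arr = np.asarray(I1, dtype=float)
    lam_r = np.sqrt(arr / (3.0 * iso.N))
    if np.any(lam_r >= 1.0):
        from .chain_statistics import relative_chain_stretch

        relative_chain_stretch(float(np.max(arr)), iso.N)
    coeff = (1.0 - fib.f) * response_function(lam_r, iso.mu, iso.N) + _fiber_modulus(
        arr, fib, literal_fiber_factor
    )
    return coeff if np.ndim(I1) else float(coeff)


def virgin_stress_diff(state: DeformationState, iso: IsotropicParams, fib: FiberParams,
                       j: int, k: int, literal_fiber_factor: bool = False) -> float:
    """Principal Cauchy-stress difference T_j - T_k of the virgin material."""
    if j not in _AXES or k not in _AXES or j == k:
        raise ValueError(f"axes must be distinct members of {{1,2,3}}, got {(j, k)}")
    lams = state.stretches
    coeff = stress_coefficient(state.I1, iso, fib, literal_fiber_factor)
    return coeff * (lams[j - 1] ** 2 - lams[k - 1] ** 2)


def uniaxial_engineering_stress(lam, iso: IsotropicParams, fib: FiberParams,
                                literal_fiber_factor: bool = False):
    """Engineering stress sigma(lam) = (T1 - T2)/lam with traction-free sides.

    Vectorized over `lam`; equals dW_T/dlam along uniaxial states, negative
    in compression (lam < 1).
    """
    arr = np.asarray(lam, dtype=float)
    if np.any(arr <= 0.0):
        raise DomainError("stretch must be positive")
    I1 = uniaxial_first_invariant(arr)
    coeff = stress_coefficient(I1, iso, fib, literal_fiber_factor)
    sigma = coeff * (arr**2 - 1.0 / arr) / arr
    return sigma if np.ndim(lam) else float(sigma)


def uniaxial_cauchy_stress(lam, iso: IsotropicParams, fib: FiberParams,
                           literal_fiber_factor: bool = False):
    """Axial Cauchy stress T1 = T1 - T2 under the uniaxial boundary condition."""
    arr = np.asarray(lam, dtype=float)
    if np.any(arr <= 0.0):
        raise DomainError("stretch must be positive")
    I1 = uniaxial_first_invariant(arr)
    coeff = stress_coefficient(I1, iso, fib, literal_fiber_factor)
    T = coeff * (arr**2 - 1.0 / arr)
    return T if np.ndim(lam) else float(T)
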