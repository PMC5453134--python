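"""Strain-energy densities and their rule-of-mixtures combination.

The total energy of the equivalent material is split into a matrix part and
a fiber part weighted by the equivalent anisotropic volumetric fraction f:

    W_T = (1 - f) W_iso(I1) + f W_aniso(I1, I3)

The matrix part is the amended non-Gaussian (average-stretch, eight-chain)
network energy

    W_iso = mu [ N (beta lambda_r + ln(beta/sinh beta)) - ln(beta/lambda_r) ] + c

with lambda_r = sqrt(I1/(3N)) and beta = L^-1(lambda_r); the - mu ln(beta/lambda_r)
amendment corrects the eight-chain average toward the full-network response
and is what allows fitted N values barely above 1 to reproduce the sharp
strain-stiffening of tissues.  The fiber part is the isotropized eight-chain
fiber energy

    W_aniso = (A1/3)(I1 - 3) + (A2/9)(I1 - 3)^2 - (2 A1/3) ln I3

obtained by averaging four fiber families along the cube diagonals
(+-1, +-1, 1)/sqrt(3) of the principal frame, which collapses the per-fiber
invariants onto I1 and I3 of the matrix.  For the incompressible states used
throughout, I3 = 1 and the log term vanishes; it is kept so the formula
remains valid for near-incompressible extensions.
"""

from __future__ import annotations

import numpy as np

from .chain_statistics import inverse_langevin, relative_chain_stretch
from .errors import DomainError
from .kinematics import DeformationState, uniaxial_first_invariant
from .parameters import FiberParams, IsotropicParams


def w_iso(I1, params: IsotropicParams):
    """Amended non-Gaussian isotropic energy density at first invariant I1.

    Accepts a scalar or array I1 (each >= 3 and below the locking value 3N).
    """
    arr = np.asarray(I1, dtype=float)
    if np.any(arr < 3.0 - 1e-12):
        raise DomainError("I1 must be >= 3 for isochoric states")
    # relative_chain_stretch raises LockingError for scalars; replicate for arrays
    lam_r = np.sqrt(arr / (3.0 * params.N))
    if np.any(lam_r >= 1.0):
        relative_chain_stretch(float(np.max(arr)), params.N)  # raises LockingError
    beta = inverse_langevin(lam_r)
    w = (
        params.mu
        * (
            params.N * (beta * lam_r + np.log(beta / np.sinh(beta)))
            - np.log(beta / lam_r)
        )
        + params.c
    )
    return w if np.ndim(I1) else float(w)


def dw_iso_dI1(I1, params: IsotropicParams):
    """Analytic derivative dW_iso/dI1; equals half the response function."""
    from .virgin_stress import response_function

    arr = np.asarray(I1, dtype=float)
    lam_r = np.sqrt(arr / (3.0 * params.N))
    if np.any(lam_r >= 1.0):
        relative_chain_stretch(float(np.max(arr)), params.N)
    out = 0.5 * response_function(lam_r, params.mu, params.N)
    return out if np.ndim(I1) else float(out)


def w_aniso(I1, I3, params: FiberParams):
    """Isotropized fiber energy density (without the leading factor f).

    Zero at the undeformed state (I1, I3) = (3, 1).
    """
    arr1 = np.asarray(I1, dtype=float)
    arr3 = np.asarray(I3, dtype=float)
    if np.any(arr3 <= 0.0):
        raise DomainError("I3 must be positive")
    e = arr1 - 3.0
    w = (params.A1 / 3.0) * e + (params.A2 / 9.0) * e**2 - (2.0 * params.A1 / 3.0) * np.log(arr3)
    return w if (np.ndim(I1) or np.ndim(I3)) else float(w)


def w_total(state: DeformationState, iso: IsotropicParams, fib: FiberParams):
    """Rule-of-mixtures total energy (1-f) W_iso + f W_aniso at a state."""
    return (1.0 - fib.f) * w_iso(state.I1, iso) + fib.f * w_aniso(state.I1, state.I3, fib)


def uniaxial_w_total(lam, iso: IsotropicParams, fib: FiberParams):
    """Vectorized W_T along uniaxial states (I3 = 1)."""
    I1 = uniaxial_first_invariant(lam)
    w = (1.0 - fib.f) * w_iso(I1, iso) + fib.f * w_aniso(I1, 1.0, fib)
    return w if np.ndim(lam) else float(w)
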