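"""Langevin chain statistics for the non-Gaussian network model.

A freely jointed chain of N rigid links has end-to-end stretch governed by
the Langevin function L(beta) = coth(beta) - 1/beta.  The network-average
chain stretch of the eight-chain idealization is lambda_chain = sqrt(I1/3),
the locking stretch is lambda_L = sqrt(N), and the relative chain stretch
lambda_r = lambda_chain/lambda_L must stay below 1.  The chain force involves
beta = L^-1(lambda_r), which has no closed form; here it is computed by a
safeguarded Newton iteration on the residual coth(beta) - 1/beta - y, seeded
with Cohen's rational approximant, so that no approximant error leaks into
stress-energy consistency checks.
"""

from __future__ import annotations

import math

import numpy as np

from .errors import DomainError, LockingError
from .kinematics import DeformationState

# below this argument coth(beta) - 1/beta suffers catastrophic cancellation;
# the odd Taylor series is exact to double precision there
_SERIES_CUTOFF = 0.05
# beyond this coth(beta) == 1 to double precision
_ASYMPTOTE_CUTOFF = 30.0


def langevin(beta):
    """Langevin function L(beta) = coth(beta) - 1/beta, for beta >= 0.

    Accepts scalars or arrays; returns values in [0, 1).  Small arguments use
    the series beta/3 - beta^3/45 + 2 beta^5/945 - beta^7/4725 to avoid
    cancellation; large arguments use the asymptote 1 - 1/beta.
    """
    arr = np.asarray(beta, dtype=float)
    if np.any(arr < 0.0):
        raise DomainError("langevin is only evaluated for beta >= 0")
    out = np.empty_like(arr)
    small = arr < _SERIES_CUTOFF
    large = arr > _ASYMPTOTE_CUTOFF
    mid = ~(small | large)
    b = arr[small]
    b2 = b * b
    out[small] = b * (1.0 / 3.0 + b2 * (-1.0 / 45.0 + b2 * (2.0 / 945.0 - b2 / 4725.0)))
    bm = arr[mid]
    out[mid] = 1.0 / np.tanh(bm) - 1.0 / bm
    bl = arr[large]
    out[large] = 1.0 - 1.0 / bl
    return out if np.ndim(beta) else float(out)


def langevin_prime(beta):
    """Derivative L'(beta) = 1/beta^2 - csch(beta)^2 (series near 0)."""
    arr = np.asarray(beta, dtype=float)
    out = np.empty_like(arr)
    small = arr < _SERIES_CUTOFF
    large = arr > _ASYMPTOTE_CUTOFF
    mid = ~(small | large)
    b2 = arr[small] ** 2
    out[small] = 1.0 / 3.0 + b2 * (-1.0 / 15.0 + b2 * (2.0 / 189.0 - b2 / 675.0))
    bm = arr[mid]
    out[mid] = 1.0 / bm**2 - 1.0 / np.sinh(bm) ** 2
    bl = arr[large]
    out[large] = 1.0 / bl**2
    return out if np.ndim(beta) else float(out)


def inverse_langevin(y, tol: float = 1e-12, max_iter: int = 100):
    """Numerical inverse of the Langevin function on [0, 1).

    Newton iteration on coth(beta) - 1/beta - y with a bisection safeguard on
    the bracket [0, 3/(1-y) + 10], seeded by Cohen's approximant
    beta0 = y (3 - y^2)/(1 - y^2).  Converges to |residual| <= `tol`.

    Raises
    ------
    LockingError
        If y >= 1 (fully extended chain).
    DomainError
        If y < 0.
    """
    arr = np.atleast_1d(np.asarray(y, dtype=float))
    if np.any(arr < 0.0):
        raise DomainError("inverse_langevin requires y >= 0")
    if np.any(arr >= 1.0):
        raise LockingError(
            "relative chain stretch reached 1: chain fully extended "
            f"(max y = {float(np.max(arr)):.6g})"
        )
    beta = arr * (3.0 - arr**2) / (1.0 - arr**2)  # Cohen seed
    lo = np.zeros_like(arr)
    hi = 3.0 / (1.0 - arr) + 10.0
    for _ in range(max_iter):
        res = langevin(beta) - arr
        if np.all(np.abs(res) <= tol):
            break
        # maintain the bracket
        lo = np.where(res < 0.0, beta, lo)
        hi = np.where(res > 0.0, beta, hi)
        step = res / langevin_prime(beta)
        cand = beta - step
        # fall back to bisection when Newton leaves the bracket
        bad = (cand <= lo) | (cand >= hi) | ~np.isfinite(cand)
        beta = np.where(bad, 0.5 * (lo + hi), cand)
    return beta if np.ndim(y) else float(beta[0])


def relative_chain_stretch(state: DeformationState | float, N: float) -> float:
    """Relative chain stretch lambda_r = sqrt(I1/(3N)) of the eight-chain network.

    `state` may be a :class:`DeformationState` or a bare I1 value.  For a
    uniaxial state this equals sqrt((lam^2 + 2/lam)/(3N)).

    Raises
    ------
    LockingError
        If lambda_r >= 1, i.e. I1 >= 3N.
    """
    if not N > 0.0:
        raise DomainError(f"chain link count N must be positive, got {N!r}")
    I1 = state.I1 if isinstance(state, DeformationState) else float(state)
    if I1 < 3.0 - 1e-12:
        raise DomainError(f"I1 must be >= 3 for isochoric states, got {I1!r}")
    lam_r = math.sqrt(I1 / (3.0 * N))
    if lam_r >= 1.0:
        raise LockingError(
            f"chain locking: I1 = {I1:.6g} reaches 3N = {3.0 * N:.6g} "
            f"(lambda_r = {lam_r:.6g} >= 1 for N = {N:.6g})"
        )
    return lam_r
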