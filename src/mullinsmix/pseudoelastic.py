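"""Modified Dorfmann-Ogden pseudo-elastic unloading with permanent set.

Unloading from a primary-path reversal at energy W_max = W_T(lambda_max) is
modelled by modulating the virgin stress with two softening variables and a
residual-stress pair (nu1, nu2):

    tau_j - tau_k = [ (T_j - T_k)_virgin
                      + (1 - eta2)(nu1 lambda_j^2 - nu2 lambda_k^2) ] eta1

    eta1 = 1 - (1/r1) tanh[(W_max - W_T)/(mu m1)]
    eta2 = tanh[(W_T/W_max)^alpha] / (r1 tanh 1)
    nu1  = nu2 (1 - (1/r2) tanh[10 (lambda_max - 1)]),   nu2 = gamma mu
    alpha = (1/10)(3 + 8 W_max/(5 mu))

At the reversal point eta1 = 1 and eta2 = 1/r1, so the gap to the virgin
curve is (1 - 1/r1)(nu1 lambda_j^2 - nu2 lambda_k^2) and vanishes linearly
as r1 -> 1; fitted r1 values sit very close to 1 for exactly that reason.

W_T and W_max are always evaluated with the same parameter set and are
measured from the undeformed state, W(lambda) - W(1).  The difference
W_max - W_T driving eta1 is unaffected by this convention; the ratio
W_T/W_max driving eta2 requires it, because the absolute reference energy
of the amended non-Gaussian model is negative for several published
parameter sets (e.g. mouse skin), which would make the fractional power in
eta2 undefined.
"""

from __future__ import annotations

import math

import numpy as np

from .energy import w_total
from .errors import DomainError, HistoryError
from .kinematics import DeformationState
from .parameters import FiberParams, IsotropicParams, PseudoElasticParams
from .softening import DeformationHistory
from .virgin_stress import virgin_stress_diff

_TANH1 = math.tanh(1.0)


def alpha(W_max: float, mu: float):
    """Exponent alpha = (1/10)(3 + 8 W_max/(5 mu)) of the eta2 variable."""
    if not mu > 0.0:
        raise DomainError("mu must be positive")
    if np.any(np.asarray(W_max) < 0.0):
        raise DomainError("W_max must be non-negative")
    return 0.1 * (3.0 + 8.0 * np.asarray(W_max) / (5.0 * mu)) if np.ndim(W_max) else 0.1 * (
        3.0 + 8.0 * W_max / (5.0 * mu)
    )


def eta1(W_T, W_max: float, mu: float, m1: float, r1: float):
    """Mullins softening variable eta1 in [1 - 1/r1, 1]; 1 at W_T = W_max."""
    arr = np.asarray(W_T, dtype=float)
    if np.any(arr > W_max + 1e-9 * max(1.0, abs(W_max))):
        raise HistoryError("W_T exceeds W_max: the state lies on the primary path")
    out = 1.0 - np.tanh((W_max - np.minimum(arr, W_max)) / (mu * m1)) / r1
    return out if np.ndim(W_T) else float(out)


def eta2(W_T, W_max: float, r1: float, alpha_: float):
    """Residual-set variable eta2 in [0, 1/r1]; equals 1/r1 at W_T = W_max.

    Negative W_T (possible only through a large negative energy constant c)
    is clipped to zero before the fractional power.
    """
    if not W_max > 0.0:
        raise DomainError("W_max must be positive to evaluate eta2")
    arr = np.asarray(W_T, dtype=float)
    ratio = np.clip(arr / W_max, 0.0, 1.0)
    out = np.tanh(ratio**alpha_) / (r1 * _TANH1)
    return out if np.ndim(W_T) else float(out)


def nu1(lambda_max, nu2: float, r2: float):
    """Residual-stress coefficient nu1 = nu2 (1 - tanh[10(lambda_max - 1)]/r2)."""
    arr = np.asarray(lambda_max, dtype=float)
    out = nu2 * (1.0 - np.tanh(10.0 * (arr - 1.0)) / r2)
    return out if np.ndim(lambda_max) else float(out)


def pseudoelastic_stress_diff(state: DeformationState, history: DeformationHistory,
                              iso: IsotropicParams, fib: FiberParams,
                              pe: PseudoElasticParams, j: int, k: int,
                              literal_fiber_factor: bool = False) -> float:
    """Principal stress difference tau_j - tau_k on the unloading branch.

    Energies are measured from the undeformed state, consistent with the
    W_max stored by :meth:`DeformationHistory.from_uniaxial_reversal`.
    """
    from .kinematics import uniaxial_state

    W_T = w_total(state, iso, fib) - w_total(uniaxial_state(1.0), iso, fib)
    if W_T > history.W_max + 1e-9 * max(1.0, abs(history.W_max)):
        raise HistoryError(
            f"W_T = {W_T:.6g} exceeds W_max = {history.W_max:.6g}; "
            "the virgin equation applies on the primary path"
        )
    virgin = virgin_stress_diff(state, iso, fib, j, k, literal_fiber_factor)
    n2 = pe.nu2(iso.mu)
    n1 = nu1(history.lambda_max, n2, pe.r2)
    e1 = eta1(W_T, history.W_max, iso.mu, pe.m1, pe.r1)
    e2 = eta2(W_T, history.W_max, pe.r1, alpha(history.W_max, iso.mu))
    lams = state.stretches
    return (virgin + (1.0 - e2) * (n1 * lams[j - 1] ** 2 - n2 * lams[k - 1] ** 2)) * e1


def _path_stress_pseudoelastic(lams, W, W_max, lam_hist, virgin,
                               iso: IsotropicParams, pe: PseudoElasticParams):
    """Vectorized tau_1 - tau_2 along a uniaxial path with per-sample history."""
    # W_max == 0 only on still-undeformed leading samples, which the caller
    # overrides with the virgin response; clip to keep the ratio well-defined
    W_max = np.maximum(np.asarray(W_max, dtype=float), 1e-300)
    n2 = pe.nu2(iso.mu)
    n1 = n2 * (1.0 - np.tanh(10.0 * (lam_hist - 1.0)) / pe.r2)
    e1 = 1.0 - np.tanh((W_max - np.minimum(W, W_max)) / (iso.mu * pe.m1)) / pe.r1
    a = 0.1 * (3.0 + 8.0 * W_max / (5.0 * iso.mu))
    ratio = np.clip(W / W_max, 0.0, 1.0)
    e2 = np.tanh(ratio**a) / (pe.r1 * _TANH1)
    l2sq = 1.0 / lams
    return (virgin + (1.0 - e2) * (n1 * lams**2 - n2 * l2sq)) * e1


def uniaxial_pseudoelastic_stress(lam, history: DeformationHistory,
                                  iso: IsotropicParams, fib: FiberParams,
                                  pe: PseudoElasticParams,
                                  stress_kind: str = "engineering",
                                  literal_fiber_factor: bool = False):
    """Vectorized uniaxial unloading stress for a frozen history."""
    from .energy import uniaxial_w_total
    from .kinematics import uniaxial_first_invariant
    from .virgin_stress import stress_coefficient

    arr = np.asarray(lam, dtype=float)
    W = uniaxial_w_total(arr, iso, fib) - uniaxial_w_total(1.0, iso, fib)
    if np.any(W > history.W_max + 1e-9 * max(1.0, abs(history.W_max))):
        raise HistoryError("stretch path leaves the recorded energy history")
    I1 = uniaxial_first_invariant(arr)
    virgin = stress_coefficient(I1, iso, fib, literal_fiber_factor) * (arr**2 - 1.0 / arr)
    tau = _path_stress_pseudoelastic(
        arr, W, np.full_like(arr, history.W_max),
        np.full_like(arr, history.lambda_max), virgin, iso, pe,
    )
    if stress_kind == "engineering":
        tau = tau / arr
    elif stress_kind != "cauchy":
        raise ValueError(f"stress_kind must be 'engineering' or 'cauchy', got {stress_kind!r}")
    return tau if np.ndim(lam) else float(tau)
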