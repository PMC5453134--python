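"""Non-monotonous stress softening with residual strains, and the cycle simulator.

The softened material response multiplies the virgin stress difference,
augmented by a residual-strain term, with a softening kernel driven by the
strain intensity m relative to its historical maximum M:

    tau_j - tau_k = [ (T_j - T_k)_virgin
                      + (mu C / 2) (lambda_j f_j - lambda_k f_k) ] * F(m, M; b)

    f_k = d/dlambda_k sum_a (lambda_max_a^n - lambda_a^n)^2
        = -2 n lambda_k^(n-1) (lambda_max_k^n - lambda_k^n)

On the primary loading path m = M and lambda = lambda_max, so the kernel is
1 and the residual gradient vanishes: the softened equation reduces exactly
to the virgin one, which is what makes loading-unloading cycles continuous
at the reversal point.  With C > 0 the residual term drives the unloading
branch through zero stress at a residual stretch lambda_res > 1 (permanent
set).

The kernel F(m, M; b) is a configurable strategy because the source
typography of the exponential is ambiguous:

    'literal' (default):  exp[-b (M - m) (m/M)]
    'radical':            exp[-b (sqrt(M) - sqrt(m)) sqrt(m/M)]

Both satisfy the kernel contract F(M, M) = 1, 0 < F <= 1, F decreasing as m
drops below M; every downstream result depends only on that contract.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .energy import uniaxial_w_total, w_total
from .errors import DomainError, HistoryError, NoResidualError
from .kinematics import (
    SQRT3,
    DeformationState,
    uniaxial_first_invariant,
    uniaxial_state,
    uniaxial_strain_intensity,
)
from .parameters import FiberParams, IsotropicParams, MaterialParams, SofteningParams
from .virgin_stress import stress_coefficient, virgin_stress_diff

KERNELS = ("literal", "radical")

_HIST_TOL = 1e-12


@dataclass(frozen=True)
class DeformationHistory:
    """Frozen record of the worst deformation seen on the primary path.

    M             : maximum strain intensity attained (>= sqrt(3))
    lambda_max    : axial stretch at which M was attained
    lambda_max_a  : per-axis principal stretches at the reversal point
    W_max         : total energy at the reversal point, measured from the
                    undeformed state (W_T(lambda_max) - W_T(1) >= 0)
    """

    M: float
    lambda_max: float
    lambda_max_a: tuple[float, float, float]
    W_max: float

    @classmethod
    def from_uniaxial_reversal(cls, lam_max: float, iso: IsotropicParams,
                               fib: FiberParams) -> "DeformationHistory":
        """History of a single primary excursion reversed at axial stretch lam_max."""
        state = uniaxial_state(lam_max)
        w_ref = w_total(uniaxial_state(1.0), iso, fib)
        return cls(
            M=state.m,
            lambda_max=lam_max,
            lambda_max_a=state.stretches,
            W_max=w_total(state, iso, fib) - w_ref,
        )


def softening_factor(m, M: float, b: float, kernel: str = "literal"):
    """Softening kernel F(m, M; b) in (0, 1]; equals 1 on the primary path m = M."""
    if kernel not in KERNELS:
        raise ValueError(f"unknown softening kernel {kernel!r}; choose from {KERNELS}")
    if b < 0.0:
        raise DomainError("softening parameter b must be non-negative")
    arr = np.asarray(m, dtype=float)
    if np.any(arr < SQRT3 - 1e-9):
        raise DomainError("strain intensity m cannot fall below sqrt(3)")
    if np.any(arr > M + 1e-9):
        raise HistoryError(
            f"m = {float(np.max(arr)):.6g} exceeds recorded maximum M = {M:.6g}; "
            "extend the primary path instead"
        )
    arr = np.minimum(arr, M)
    if kernel == "literal":
        out = np.exp(-b * (M - arr) * (arr / M))
    else:
        out = np.exp(-b * (np.sqrt(M) - np.sqrt(arr)) * np.sqrt(arr / M))
    return out if np.ndim(m) else float(out)


def residual_gradient(lams, lam_maxes, n: float = 1.0):
    """Gradient f_k of the residual-strain potential sum_a (lmax_a^n - l_a^n)^2.

    Returns the three values f_k = -2 n lambda_k^(n-1) (lmax_k^n - lambda_k^n);
    identically zero at lambda = lambda_max (the reversal point).
    """
    lams = np.asarray(lams, dtype=float)
    lam_maxes = np.asarray(lam_maxes, dtype=float)
    if np.any(lams <= 0.0) or np.any(lam_maxes <= 0.0):
        raise DomainError("stretches must be positive")
    return -2.0 * n * lams ** (n - 1.0) * (lam_maxes**n - lams**n)


def _residual_term(lams, lam_maxes, mu: float, soft: SofteningParams, j: int, k: int):
    fk = residual_gradient(lams, lam_maxes, soft.n)
    return 0.5 * mu * soft.C * (lams[j - 1] * fk[j - 1] - lams[k - 1] * fk[k - 1])


def softened_stress_diff(state: DeformationState, history: DeformationHistory,
                         iso: IsotropicParams, fib: FiberParams, soft: SofteningParams,
                         j: int, k: int, kernel: str = "literal",
                         literal_fiber_factor: bool = False) -> float:
    """Principal stress difference tau_j - tau_k of the stress-softened material.

    Requires m(state) <= M of the history; reduces exactly to the virgin
    stress difference at the reversal point.
    """
    if state.m > history.M + 1e-9:
        raise HistoryError(
            f"state intensity m = {state.m:.6g} exceeds history M = {history.M:.6g}"
        )
    virgin = virgin_stress_diff(state, iso, fib, j, k, literal_fiber_factor)
    resid = _residual_term(
        np.asarray(state.stretches), np.asarray(history.lambda_max_a), iso.mu, soft, j, k
    )
    return (virgin + resid) * softening_factor(state.m, history.M, soft.b, kernel)


def uniaxial_softened_stress(lam, history: DeformationHistory, iso: IsotropicParams,
                             fib: FiberParams, soft: SofteningParams,
                             stress_kind: str = "engineering", kernel: str = "literal",
                             literal_fiber_factor: bool = False):
    """Vectorized uniaxial softened stress on the unloading/reloading branch."""
    arr = np.asarray(lam, dtype=float)
    lm = history.lambda_max
    tau = _path_stress_softened(
        arr,
        np.full_like(arr, history.M),
        np.full_like(arr, lm),
        iso, fib, soft, kernel, literal_fiber_factor,
        check_history=True,
    )
    if stress_kind == "engineering":
        tau = tau / arr
    elif stress_kind != "cauchy":
        raise ValueError(f"stress_kind must be 'engineering' or 'cauchy', got {stress_kind!r}")
    return tau if np.ndim(lam) else float(tau)


def _path_stress_softened(lams, M, lam_hist, iso, fib, soft, kernel,
                          literal_fiber_factor, check_history=False):
    """Cauchy stress difference tau_1 - tau_2 along uniaxial stretches with
    per-sample history (M, axial lambda_max)."""
    m = uniaxial_strain_intensity(lams)
    if check_history and np.any(m > M + 1e-9):
        raise HistoryError("stretch path leaves the recorded deformation history")
    I1 = uniaxial_first_invariant(lams)
    coeff = stress_coefficient(I1, iso, fib, literal_fiber_factor)
    virgin = coeff * (lams**2 - 1.0 / lams)
    l2 = 1.0 / np.sqrt(lams)
    lm2 = 1.0 / np.sqrt(lam_hist)
    n = soft.n
    f1 = -2.0 * n * lams ** (n - 1.0) * (lam_hist**n - lams**n)
    f2 = -2.0 * n * l2 ** (n - 1.0) * (lm2**n - l2**n)
    resid = 0.5 * iso.mu * soft.C * (lams * f1 - l2 * f2)
    factor = np.exp(
        -soft.b * (M - np.minimum(m, M)) * (np.minimum(m, M) / M)
        if kernel == "literal"
        else -soft.b * (np.sqrt(M) - np.sqrt(np.minimum(m, M))) * np.sqrt(np.minimum(m, M) / M)
    )
    return (virgin + resid) * factor


def residual_stretch(history: DeformationHistory, iso: IsotropicParams,
                     fib: FiberParams, soft: SofteningParams,
                     kernel: str = "literal") -> float:
    """Residual stretch lambda_res where the unloading stress crosses zero.

    Root of the uniaxial softened stress on the unloading branch, bracketed
    in (1e-3, lambda_max]; returns exactly 1.0 when C = 0 (no permanent set).

    Raises
    ------
    NoResidualError
        If the stress does not change sign inside the admissible bracket.
    """
    if soft.C == 0.0:
        return 1.0

    def sigma(lam):
        return float(
            uniaxial_softened_stress(lam, history, iso, fib, soft, "engineering", kernel)
        )

    lo = 1e-3
    # below the mirror point where m(lam) = M again the history is violated
    m_lo = float(uniaxial_strain_intensity(lo))
    if m_lo > history.M:
        lo = brentq(
            lambda lam: float(uniaxial_strain_intensity(lam)) - history.M,
            1e-3, min(1.0, history.lambda_max), xtol=1e-12,
        ) + 1e-9
    hi = history.lambda_max
    s_lo, s_hi = sigma(lo), sigma(hi)
    if s_lo * s_hi > 0.0:
        raise NoResidualError(
            f"no zero-stress crossing in ({lo:.3g}, {hi:.6g}): "
            f"sigma ranges {s_lo:.3g} to {s_hi:.3g}"
        )
    return float(brentq(sigma, lo, hi, xtol=1e-12, rtol=8.9e-16))


# ---------------------------------------------------------------------------
# cycle simulation
# ---------------------------------------------------------------------------


def _history_indices(metric):
    """Index of the running-maximum location of `metric` at each sample."""
    run = np.maximum.accumulate(metric)
    primary = metric >= run - _HIST_TOL
    idx = np.where(primary, np.arange(metric.size), -1)
    idx = np.maximum.accumulate(idx)
    return run, primary, idx


def uniaxial_stress_path(lams, params: MaterialParams, model: str = "softened",
                         stress_kind: str = "engineering", kernel: str = "literal",
                         literal_fiber_factor: bool = False):
    """Stress along an ordered uniaxial stretch path with evolving history.

    The path itself defines the history: a sample on which the governing
    scalar (strain intensity m for the softened model, energy W_T for the
    pseudo-elastic one) sets a new running maximum lies on the primary path
    and responds with the virgin equation while updating the history; any
    other sample responds with the softened / pseudo-elastic unloading
    equation evaluated against the frozen history.

    Returns (stress, primary_mask).
    """
    lams = np.asarray(lams, dtype=float)
    if lams.size == 0:
        raise ValueError("empty stretch path")
    iso, fib = params.iso, params.fib
    if model == "virgin":
        I1 = uniaxial_first_invariant(lams)
        tau = stress_coefficient(I1, iso, fib, literal_fiber_factor) * (lams**2 - 1.0 / lams)
        primary = np.ones(lams.size, dtype=bool)
    elif model == "softened":
        m = uniaxial_strain_intensity(lams)
        M, primary, idx = _history_indices(m)
        lam_hist = lams[idx]
        tau = _path_stress_softened(
            lams, M, lam_hist, iso, fib, params.soft, kernel, literal_fiber_factor
        )
    elif model == "pseudoelastic":
        if params.pe is None:
            raise ValueError("pseudo-elastic simulation requires MaterialParams.pe")
        from .pseudoelastic import _path_stress_pseudoelastic

        W = uniaxial_w_total(lams, iso, fib) - uniaxial_w_total(1.0, iso, fib)
        W_max, primary, idx = _history_indices(W)
        lam_hist = lams[idx]
        I1 = uniaxial_first_invariant(lams)
        virgin = stress_coefficient(I1, iso, fib, literal_fiber_factor) * (
            lams**2 - 1.0 / lams
        )
        tau = _path_stress_pseudoelastic(
            lams, W, W_max, lam_hist, virgin, iso, params.pe
        )
        tau = np.where(primary, virgin, tau)
    else:
        raise ValueError(f"unknown model {model!r}")
    if stress_kind == "engineering":
        tau = tau / lams
    elif stress_kind != "cauchy":
        raise ValueError(f"stress_kind must be 'engineering' or 'cauchy', got {stress_kind!r}")
    return tau, primary


def expand_program(program, n_per_branch: int = 100) -> np.ndarray:
    """Expand an ordered list of target stretches into a sampled path.

    Each segment between consecutive targets is sampled with `n_per_branch`
    points (endpoint included, start point carried over from the previous
    segment)."""
    program = [float(p) for p in program]
    if len(program) < 2:
        raise ValueError("stretch program needs at least a start and one target")
    if abs(program[0] - 1.0) > 1e-12:
        raise ValueError(f"stretch program must start at lambda = 1, got {program[0]}")
    if any(p <= 0 for p in program):
        raise DomainError("stretch targets must be positive")
    pieces = [np.array([1.0])]
    for a, b in zip(program[:-1], program[1:]):
        pieces.append(np.linspace(a, b, n_per_branch + 1)[1:])
    return np.concatenate(pieces)


def simulate_cycles(program, params: MaterialParams, model: str = "softened",
                    n_per_branch: int = 100, stress_kind: str = "engineering",
                    stress_unit: str = "MPa", kernel: str = "literal",
                    literal_fiber_factor: bool = False):
    """Simulate a loading-unloading stretch program and return the curve.

    Phases are labelled per sample: 'loading' on the primary path,
    'unloading' where the strain intensity is decreasing below its maximum,
    'reloading' where it increases again without exceeding the maximum
    (idealized Mullins behaviour: the reloading branch retraces the
    unloading branch and rejoins the virgin curve at the reversal point).
    The cycle index increments each time a new (re)loading branch follows an
    unloading one.
    """
    from .curveio import StressStretchCurve

    lams = expand_program(program, n_per_branch)
    stress, primary = uniaxial_stress_path(
        lams, params, model, stress_kind, kernel, literal_fiber_factor
    )
    m = uniaxial_strain_intensity(lams)
    phases = np.empty(lams.size, dtype=object)
    cycles = np.empty(lams.size, dtype=int)
    phase, cycle = "loading", 1
    for i in range(lams.size):
        if primary[i]:
            new_phase = "loading"
        elif i > 0 and m[i] < m[i - 1] - _HIST_TOL:
            new_phase = "unloading"
        elif i > 0 and m[i] > m[i - 1] + _HIST_TOL:
            new_phase = "reloading"
        else:
            new_phase = phase
        if phase == "unloading" and new_phase in ("loading", "reloading"):
            cycle += 1
        phase = new_phase
        phases[i] = phase
        cycles[i] = cycle
    return StressStretchCurve(
        stretch=lams, stress=stress, phase=phases, cycle=cycles,
        stress_kind=stress_kind, unit=stress_unit,
    )
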