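"""Published material-parameter fixtures and synthetic cyclic test data.

The registry transcribes, verbatim and with their printed units, the fitted
parameter sets for vaginal tissue, mouse skin, two suture materials, human
tracheal membranes and human brain tissue, plus the vulcanized natural
rubber set used to validate the energy split and the pseudo-elastic sets
quoted alongside the corresponding figures.  Unit oddities in the sources
are preserved rather than silently rescaled: the tracheal table lists A1/A2
in MPa against mu in kPa (converted at evaluation time), C is printed with a
pressure unit although it enters the stress only through the product mu*C
(treated as dimensionless here), and f is printed in percent.

Synthetic loading-unloading curves for testing and parameter-recovery
experiments are produced by :func:`generate_cycle_data`: the exact model
curve for a stretch program, plus additive zero-mean Gaussian noise from a
seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import LockingError
from .kinematics import uniaxial_first_invariant
from .parameters import (
    FiberParams,
    IsotropicParams,
    MaterialParams,
    PseudoElasticParams,
    SofteningParams,
)
from .softening import simulate_cycles

_PA_PER_UNIT = {"MPa": 1e6, "kPa": 1e3}


@dataclass(frozen=True)
class MaterialFixture:
    """One published parameter set, stored exactly as printed."""

    name: str
    provenance: str
    stress_unit: str  # unit of mu (and of evaluated stresses)
    mu: float
    N: float
    A1: float
    A2: float
    A_unit: str  # printed unit of A1/A2 (may differ from stress_unit)
    b: float
    C: float
    f_percent: float
    c_J_per_m3: Optional[float] = None
    pe: Optional[tuple[float, float, float, float]] = None  # (m1, r1, r2, gamma)
    protocol_lambda_max: float = 1.2
    stress_kind: str = "engineering"

    def params(self, f_as_fraction: bool = False) -> MaterialParams:
        """Evaluate to a :class:`MaterialParams` in the fixture's stress unit.

        ``f_as_fraction=True`` reads the printed f value as a bare fraction
        instead of a percentage (alternative reading of the f(%) column).
        """
        a_scale = _PA_PER_UNIT[self.A_unit] / _PA_PER_UNIT[self.stress_unit]
        c = 0.0
        if self.c_J_per_m3 is not None:
            c = self.c_J_per_m3 / _PA_PER_UNIT[self.stress_unit]  # 1 J/m^3 = 1 Pa
        f = self.f_percent if f_as_fraction else self.f_percent / 100.0
        pe = PseudoElasticParams(*self.pe) if self.pe is not None else None
        return MaterialParams(
            iso=IsotropicParams(mu=self.mu, N=self.N, c=c),
            fib=FiberParams(f=f, A1=self.A1 * a_scale, A2=self.A2 * a_scale),
            soft=SofteningParams(b=self.b, C=self.C),
            pe=pe,
        )

    @property
    def locking_first_invariant(self) -> float:
        return 3.0 * self.N


def _fx(*args, **kw) -> MaterialFixture:
    return MaterialFixture(*args, **kw)


FIXTURES: dict[str, MaterialFixture] = {
    f.name: f
    for f in [
        # -- tissue / suture table (mu, A1, A2 in MPa) -----------------------
        _fx("vaginal_longitudinal", "vaginal tissue, longitudinal axis", "MPa",
            mu=0.085, N=3.25, A1=-6.5, A2=70.0, A_unit="MPa", b=1.3, C=0.7,
            f_percent=0.2, c_J_per_m3=-0.0284, pe=(1.8, 1.0001, 0.1, 0.3),
            protocol_lambda_max=1.6, stress_kind="cauchy"),
        _fx("vaginal_transverse", "vaginal tissue, transverse axis", "MPa",
            mu=0.085, N=3.25, A1=-6.5, A2=3.93, A_unit="MPa", b=1.3, C=0.7,
            f_percent=0.2, c_J_per_m3=-0.0284, pe=(1.8, 1.0001, 0.1, 0.3),
            protocol_lambda_max=1.6, stress_kind="cauchy"),
        _fx("male_mouse_skin", "male mouse skin", "MPa",
            mu=0.95, N=1.082, A1=0.0, A2=30.0, A_unit="MPa", b=2.8, C=0.98,
            f_percent=9.0, c_J_per_m3=0.0994, pe=(0.0525, 1.00001, 0.55, 0.55),
            protocol_lambda_max=1.25, stress_kind="cauchy"),
        _fx("female_mouse_skin", "female mouse skin", "MPa",
            mu=0.77, N=1.18, A1=0.0, A2=20.0, A_unit="MPa", b=2.55, C=1.2,
            f_percent=9.0, c_J_per_m3=0.7741, pe=(0.05, 1.001, 0.04, 0.55),
            protocol_lambda_max=1.4, stress_kind="cauchy"),
        _fx("pgc25_suture", "PGC25 3-0 suture material", "MPa",
            mu=100.0, N=2.35, A1=0.0, A2=1300.0, A_unit="MPa", b=0.95, C=0.008,
            f_percent=10.0, c_J_per_m3=-27.5616, pe=(1.65, 1.1, 0.6, 1.0),
            protocol_lambda_max=1.15, stress_kind="engineering"),
        _fx("polypropylene_suture", "polypropylene suture material", "MPa",
            mu=300.0, N=50.5, A1=-7500.0, A2=-2100.0, A_unit="MPa", b=0.6,
            C=0.0024, f_percent=1.35, c_J_per_m3=-78.5996,
            pe=(0.85, 1.0001, 0.35, 0.975),
            protocol_lambda_max=1.12, stress_kind="engineering"),
        # -- tracheal table (mu, C in kPa; A1, A2 printed in MPa) ------------
        _fx("csm_trachea", "circumferential mucosa/submucosa membrane (CSM)", "kPa",
            mu=5.0, N=1.029, A1=0.0, A2=2500.0, A_unit="MPa", b=1.3, C=2.1,
            f_percent=0.8, protocol_lambda_max=1.12, stress_kind="cauchy"),
        _fx("asm_trachea", "axial mucosa/submucosa membrane (ASM)", "kPa",
            mu=5.0, N=1.029, A1=0.0, A2=15.0, A_unit="MPa", b=1.3, C=2.1,
            f_percent=0.8, protocol_lambda_max=1.12, stress_kind="cauchy"),
        _fx("cam_trachea", "circumferential adventitial membrane (CAM)", "kPa",
            mu=10.0, N=1.045, A1=0.0, A2=35000.0, A_unit="MPa", b=1.0, C=3.4,
            f_percent=0.6, protocol_lambda_max=1.16, stress_kind="cauchy"),
        _fx("aam_trachea", "axial adventitial membrane (AAM)", "kPa",
            mu=10.0, N=1.045, A1=0.0, A2=1.5, A_unit="MPa", b=1.0, C=3.4,
            f_percent=0.6, protocol_lambda_max=1.16, stress_kind="cauchy"),
        # -- brain table (all in kPa) ----------------------------------------
        _fx("frontal_tension", "frontal lobe white matter, sagittal direction, tension", "kPa",
            mu=2.6, N=1.065, A1=-150.0, A2=-3000.0, A_unit="kPa", b=2.7, C=4.6,
            f_percent=1.0, c_J_per_m3=-0.8263, pe=(0.095, 1.001, 0.8, 0.1),
            protocol_lambda_max=1.1, stress_kind="engineering"),
        _fx("frontal_compression", "frontal lobe white matter, sagittal direction, compression", "kPa",
            mu=2.6, N=1.065, A1=-150.0, A2=-3000.0, A_unit="kPa", b=2.5, C=0.6,
            f_percent=1.0, c_J_per_m3=-0.8263, pe=(0.095, 1.001, 0.8, 0.1),
            protocol_lambda_max=0.9, stress_kind="engineering"),
        _fx("occipital_tension", "occipital lobe white matter, frontal direction, tension", "kPa",
            mu=2.65, N=2.5, A1=-350.0, A2=650.0, A_unit="kPa", b=2.7, C=3.8,
            f_percent=0.93, c_J_per_m3=-0.0205, pe=(0.006, 2.5, 1.8, 0.1),
            protocol_lambda_max=1.1, stress_kind="engineering"),
        _fx("occipital_compression", "occipital lobe white matter, frontal direction, compression", "kPa",
            mu=2.65, N=2.5, A1=-350.0, A2=650.0, A_unit="kPa", b=2.7, C=3.8,
            f_percent=0.93, c_J_per_m3=-0.0205, pe=(0.006, 2.5, 1.8, 0.1),
            protocol_lambda_max=0.9, stress_kind="engineering"),
        # -- vulcanized natural rubber (energy-split validation set) ---------
        _fx("natural_rubber", "vulcanized natural rubber, WAXD energy split", "MPa",
            mu=0.475, N=28.13, A1=0.0, A2=0.0001, A_unit="MPa", b=0.0, C=0.0,
            f_percent=25.0, c_J_per_m3=-0.188,
            protocol_lambda_max=6.0, stress_kind="engineering"),
    ]
}

TABLE_FIXTURE_NAMES = tuple(n for n in FIXTURES if n != "natural_rubber")


def material_fixture(name: str) -> MaterialFixture:
    """Look up a fixture by name; the error lists the available names."""
    try:
        return FIXTURES[name]
    except KeyError:
        avail = ", ".join(sorted(FIXTURES))
        raise KeyError(f"unknown material fixture {name!r}; available: {avail}") from None


def generate_cycle_data(params: MaterialParams, stretch_program,
                        n_points_per_branch: int = 100, noise_sd: float = 0.0,
                        seed: Optional[int] = None, model: str = "softened",
                        stress_kind: str = "engineering", stress_unit: str = "MPa",
                        kernel: str = "literal"):
    """Simulate a cyclic uniaxial test and add seeded Gaussian stress noise.

    The stretch program is checked against chain locking (I1 < 3N at every
    target) before any sampling.  For ``noise_sd = 0`` the exact model curve
    is returned; for a fixed seed the output is bitwise reproducible.
    """
    if noise_sd < 0.0:
        raise ValueError("noise_sd must be non-negative")
    I1_targets = uniaxial_first_invariant(np.asarray(stretch_program, dtype=float))
    if np.any(I1_targets >= 3.0 * params.iso.N):
        raise LockingError(
            f"stretch program reaches I1 = {float(np.max(I1_targets)):.6g} "
            f">= 3N = {3.0 * params.iso.N:.6g}"
        )
    curve = simulate_cycles(
        stretch_program, params, model=model, n_per_branch=n_points_per_branch,
        stress_kind=stress_kind, stress_unit=stress_unit, kernel=kernel,
    )
    if noise_sd > 0.0:
        rng = np.random.default_rng(seed)
        curve.stress = curve.stress + rng.normal(0.0, noise_sd, size=len(curve))
    return curve
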