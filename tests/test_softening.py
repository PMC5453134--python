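import math

import numpy as np
import pytest

from mullinsmix import (
    DeformationHistory,
    DomainError,
    FiberParams,
    HistoryError,
    IsotropicParams,
    MaterialParams,
    NoResidualError,
    SofteningParams,
    residual_gradient,
    residual_stretch,
    simulate_cycles,
    softened_stress_diff,
    softening_factor,
    uniaxial_engineering_stress,
    uniaxial_softened_stress,
    uniaxial_state,
    virgin_stress_diff,
)
from mullinsmix.kinematics import SQRT3


@pytest.fixture
def mats():
    iso = IsotropicParams(mu=0.95, N=3.25)
    fib = FiberParams(f=0.1, A1=0.5, A2=2.0)
    return iso, fib


class TestSofteningFactor:
    def test_primary_path_identity_any_kernel(self):
        m = uniaxial_state(1.4).m
        for kernel in ("literal", "radical"):
            assert softening_factor(m, m, 2.5, kernel) == 1.0

    def test_disabled_when_b_zero(self):
        M = uniaxial_state(1.6).m
        for lam in (1.0, 1.2, 1.5):
            assert softening_factor(uniaxial_state(lam).m, M, 0.0) == 1.0

    def test_literal_kernel_against_direct_evaluation(self):
        b = 2.8
        M = uniaxial_state(1.6).m
        m = uniaxial_state(1.2).m
        expected = math.exp(-b * (M - m) * (m / M))  # independent re-evaluation
        val = softening_factor(m, M, b, "literal")
        assert val == pytest.approx(expected, rel=1e-14)
        assert 0.0 < val < 1.0

    def test_radical_kernel_against_direct_evaluation(self):
        b, M, m = 1.7, 4.0, 2.5
        expected = math.exp(-b * (math.sqrt(M) - math.sqrt(m)) * math.sqrt(m / M))
        assert softening_factor(m, M, b, "radical") == pytest.approx(expected, rel=1e-14)

    def test_decreasing_as_m_drops(self):
        M = uniaxial_state(1.6).m
        ms = np.linspace(SQRT3, M, 50)
        for kernel in ("literal", "radical"):
            vals = softening_factor(ms, M, 2.0, kernel)
            assert np.all(np.diff(vals) > 0)  # recovers toward 1 as m -> M
            assert np.all((vals > 0) & (vals <= 1))

    def test_history_violation_and_domain(self):
        with pytest.raises(HistoryError):
            softening_factor(2.5, 2.0, 1.0)
        with pytest.raises(DomainError):
            softening_factor(1.0, 2.0, 1.0)  # m below sqrt(3)
        with pytest.raises(ValueError):
            softening_factor(2.0, 2.0, 1.0, kernel="unknown")


class TestResidualGradient:
    def test_zero_at_reversal_point(self):
        lams = (1.3, 1.3**-0.5, 1.3**-0.5)
        assert np.allclose(residual_gradient(lams, lams), 0.0)

    def test_hand_differentiated_values(self):
        # n=1: f_1 = -2 (2 - 1.5) = -1
        f = residual_gradient((1.5, 1.0, 1.0), (2.0, 1.0, 1.0), n=1.0)
        assert f[0] == pytest.approx(-1.0, rel=1e-14)
        # n=2: f_1 = -2*2*1*(4 - 1) = -12
        f = residual_gradient((1.0, 1.0, 1.0), (2.0, 1.0, 1.0), n=2.0)
        assert f[0] == pytest.approx(-12.0, rel=1e-14)

    def test_sign_structure_on_unloading(self):
        lam, lam_max = 1.2, 1.6
        lams = (lam, lam**-0.5, lam**-0.5)
        maxes = (lam_max, lam_max**-0.5, lam_max**-0.5)
        f = residual_gradient(lams, maxes)
        assert f[0] < 0  # axial: below its maximum
        assert f[1] > 0 and f[2] > 0  # lateral: above their (contracted) maxima


class TestSoftenedStressDiff:
    def test_reduces_to_virgin_at_reversal(self, mats, rng):
        iso, fib = mats
        soft = SofteningParams(b=2.0, C=0.8)
        for _ in range(10):
            lam = float(rng.uniform(1.05, 1.7))
            s = uniaxial_state(lam)
            hist = DeformationHistory.from_uniaxial_reversal(lam, iso, fib)
            tau = softened_stress_diff(s, hist, iso, fib, soft, 1, 2)
            T = virgin_stress_diff(s, iso, fib, 1, 2)
            assert abs(tau - T) <= 1e-10 * max(1.0, abs(T))

    def test_ideal_elasticity_when_disabled(self, mats):
        iso, fib = mats
        soft = SofteningParams(b=0.0, C=0.0)
        hist = DeformationHistory.from_uniaxial_reversal(1.6, iso, fib)
        for lam in np.linspace(1.0, 1.6, 20):
            s = uniaxial_state(float(lam))
            assert softened_stress_diff(s, hist, iso, fib, soft, 1, 2) == pytest.approx(
                virgin_stress_diff(s, iso, fib, 1, 2), rel=1e-13, abs=1e-15
            )

    def test_softening_lies_below_virgin(self, mats):
        iso, fib = mats
        soft = SofteningParams(b=2.0, C=0.0)
        hist = DeformationHistory.from_uniaxial_reversal(1.6, iso, fib)
        lam = np.linspace(1.01, 1.59, 50)
        soft_sig = uniaxial_softened_stress(lam, hist, iso, fib, soft)
        virgin_sig = uniaxial_engineering_stress(lam, iso, fib)
        assert np.all(soft_sig < virgin_sig)
        assert np.all(soft_sig > 0)  # no permanent set without C

    def test_residual_compressive_state_near_identity(self, mats):
        iso, fib = mats
        soft = SofteningParams(b=1.0, C=0.7)
        hist = DeformationHistory.from_uniaxial_reversal(1.6, iso, fib)
        s = uniaxial_state(1.0)
        assert softened_stress_diff(s, hist, iso, fib, soft, 1, 2) < 0.0

    def test_history_violation(self, mats):
        iso, fib = mats
        hist = DeformationHistory.from_uniaxial_reversal(1.3, iso, fib)
        with pytest.raises(HistoryError):
            softened_stress_diff(
                uniaxial_state(1.5), hist, iso, fib, SofteningParams(), 1, 2
            )


class TestResidualStretch:
    def test_no_permanent_set_without_C(self, mats):
        iso, fib = mats
        hist = DeformationHistory.from_uniaxial_reversal(1.5, iso, fib)
        assert residual_stretch(hist, iso, fib, SofteningParams(b=1.0, C=0.0)) == 1.0

    def test_root_residual_is_tiny(self, mats):
        iso, fib = mats
        soft = SofteningParams(b=1.5, C=0.5)
        hist = DeformationHistory.from_uniaxial_reversal(1.6, iso, fib)
        lam_res = residual_stretch(hist, iso, fib, soft)
        assert 1.0 < lam_res < 1.6
        sig = uniaxial_softened_stress(lam_res, hist, iso, fib, soft)
        assert abs(sig) <= 1e-9

    def test_male_mouse_skin_has_permanent_set(self):
        from mullinsmix import material_fixture

        p = material_fixture("male_mouse_skin").params()
        hist = DeformationHistory.from_uniaxial_reversal(1.25, p.iso, p.fib)
        lam_res = residual_stretch(hist, p.iso, p.fib, p.soft)
        assert 1.0 < lam_res < 1.25

    def test_monotone_in_C(self, mats):
        iso, fib = mats
        hist = DeformationHistory.from_uniaxial_reversal(1.6, iso, fib)
        res = [
            residual_stretch(hist, iso, fib, SofteningParams(b=1.0, C=C))
            for C in (0.1, 0.5, 1.0)
        ]
        assert res[0] <= res[1] <= res[2]
        assert res[0] > 1.0


class TestSimulateCycles:
    def make_params(self, b=1.5, C=0.5):
        return MaterialParams(
            iso=IsotropicParams(mu=0.95, N=3.25),
            fib=FiberParams(f=0.1, A1=0.5, A2=2.0),
            soft=SofteningParams(b=b, C=C),
        )

    def test_single_loading_is_virgin_curve(self):
        p = self.make_params()
        curve = simulate_cycles([1, 2], p, n_per_branch=50)
        virgin = uniaxial_engineering_stress(curve.stretch, p.iso, p.fib)
        assert np.allclose(curve.stress, virgin, rtol=1e-12, atol=1e-14)
        assert set(curve.phase) == {"loading"}

    def test_reloading_retraces_unloading_branch(self):
        p = self.make_params()
        curve = simulate_cycles([1, 1.5, 1, 1.5], p, n_per_branch=80)
        unload = curve.stress[curve.phase == "unloading"]
        reload_ = curve.stress[curve.phase == "reloading"]
        # identical interior grid traversed in opposite directions with the
        # same frozen history (the final lam_max sample rejoins the virgin
        # path and is labelled 'loading' again)
        assert np.max(np.abs(unload[::-1][1:] - reload_)) <= 1e-10

    def test_second_loading_softened_then_rejoins_virgin(self):
        p = self.make_params(C=0.0)
        curve = simulate_cycles([1, 1.5, 1, 2.0], p, n_per_branch=100)
        virgin = uniaxial_engineering_stress(curve.stretch, p.iso, p.fib)
        last = slice(-101, None)  # final 1 -> 2 branch
        lam, sig, vir = curve.stretch[last], curve.stress[last], virgin[last]
        below = (lam > 1.01) & (lam < 1.499)  # both are zero at lam = 1
        above = lam > 1.501
        assert np.all(sig[below] < vir[below])  # Mullins softening
        assert np.allclose(sig[above], vir[above], rtol=1e-10)  # rejoined

    def test_no_stress_jump_at_reversal(self):
        p = self.make_params()
        curve = simulate_cycles([1, 1.6, 1], p, n_per_branch=200)
        jumps = np.abs(np.diff(curve.stress))
        # the reversal sits where phase flips; local jump must be comparable
        # to the sampling increment, not O(1)
        flip = np.flatnonzero(curve.phase[:-1] != curve.phase[1:])[0]
        assert jumps[flip] <= 5 * np.median(jumps)

    def test_strain_intensity_maximum_never_decreases(self):
        from mullinsmix.kinematics import uniaxial_strain_intensity

        p = self.make_params()
        curve = simulate_cycles([1, 1.4, 1.1, 1.7, 1, 1.2], p, n_per_branch=40)
        m = uniaxial_strain_intensity(curve.stretch)
        M = np.maximum.accumulate(m)
        assert np.all(np.diff(M) >= 0)

    def test_tension_compression_program(self):
        from mullinsmix import material_fixture

        p = material_fixture("occipital_tension").params()
        curve = simulate_cycles([1, 0.9, 1, 1.1, 1], p, n_per_branch=50)
        assert np.all(np.isfinite(curve.stress))
        assert curve.stress[curve.stretch == 0.9].min() < 0  # compressive branch

    def test_invalid_programs(self):
        p = self.make_params()
        with pytest.raises(ValueError):
            simulate_cycles([], p)
        with pytest.raises(ValueError):
            simulate_cycles([1.2, 1.5], p)  # must start at 1
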