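import numpy as np
import pytest

from mullinsmix import (
    FiberParams,
    FitConfig,
    IsotropicParams,
    MaterialParams,
    PseudoElasticParams,
    SofteningParams,
    fit_pseudoelastic,
    fit_softened,
    generate_cycle_data,
    material_fixture,
)
from mullinsmix.fitting import get_param, with_params


@pytest.fixture(scope="module")
def mouse_truth():
    return material_fixture("male_mouse_skin").params()


@pytest.fixture(scope="module")
def mouse_clean(mouse_truth):
    return generate_cycle_data(
        mouse_truth, [1, 1.25, 1], 100, 0.0, model="softened", stress_kind="cauchy"
    )


class TestFitSoftened:
    def test_self_consistency_from_truth(self, mouse_truth, mouse_clean):
        res = fit_softened(mouse_clean, mouse_truth, FitConfig(multistart=1))
        assert res.rss == pytest.approx(0.0, abs=1e-16)
        assert res.success

    def test_noiseless_recovery_from_perturbed_init(self, mouse_truth, mouse_clean):
        """A +-20% perturbed start recovers the exact parameters on clean data."""
        free = ("mu", "N", "A1", "A2", "b", "C")
        rng = np.random.default_rng(123)
        pert = [
            get_param(mouse_truth, n) * (1 + 0.2 * rng.uniform(-1, 1)) for n in free
        ]
        pert[1] = max(pert[1], 1.06)  # keep N above the data's locking bound
        init = with_params(mouse_truth, free, pert)
        res = fit_softened(mouse_clean, init, FitConfig(free=free, multistart=4))
        assert abs(res["mu"] - mouse_truth.iso.mu) / mouse_truth.iso.mu < 0.01
        assert abs(res["b"] - mouse_truth.soft.b) / mouse_truth.soft.b < 0.05
        assert abs(res["N"] - mouse_truth.iso.N) / mouse_truth.iso.N < 0.01

    def test_noisy_recovery_of_modulus_and_links(self, mouse_truth, mouse_clean):
        """2% peak-stress noise: mu within 5%, N within 10% (fiber block known)."""
        sd = 0.02 * float(np.abs(mouse_clean.stress).max())
        noisy = generate_cycle_data(
            mouse_truth, [1, 1.25, 1], 100, sd, seed=7, model="softened",
            stress_kind="cauchy",
        )
        free = ("mu", "N", "b", "C")
        init = with_params(
            mouse_truth, free, [get_param(mouse_truth, n) * 1.15 for n in free]
        )
        res = fit_softened(noisy, init, FitConfig(free=free, multistart=4, seed=1))
        assert abs(res["mu"] - mouse_truth.iso.mu) / mouse_truth.iso.mu < 0.05
        assert abs(res["N"] - mouse_truth.iso.N) / mouse_truth.iso.N < 0.10

    def test_deterministic_given_seed(self, mouse_truth, mouse_clean):
        free = ("mu", "N", "b", "C")
        init = with_params(
            mouse_truth, free, [get_param(mouse_truth, n) * 1.1 for n in free]
        )
        cfg = FitConfig(free=free, multistart=3, seed=11)
        r1 = fit_softened(mouse_clean, init, cfg)
        r2 = fit_softened(mouse_clean, init, cfg)
        assert np.array_equal(r1.x, r2.x)  # bitwise identical

    def test_objective_never_worse_than_start(self, mouse_truth, mouse_clean):
        free = ("mu", "N", "b", "C")
        init = with_params(
            mouse_truth, free, [get_param(mouse_truth, n) * 1.2 for n in free]
        )
        res = fit_softened(mouse_clean, init, FitConfig(free=free, multistart=2))
        assert res.rss <= res.initial_rss

    def test_stress_unit_rescaling_invariance(self, mouse_truth, mouse_clean):
        """Fitting in kPa instead of MPa rescales mu and leaves N, b untouched."""
        free = ("mu", "N", "b", "C")
        init = with_params(
            mouse_truth, free, [get_param(mouse_truth, n) * 1.1 for n in free]
        )
        res_mpa = fit_softened(mouse_clean, init, FitConfig(free=free, multistart=1))

        curve_kpa = generate_cycle_data(
            mouse_truth, [1, 1.25, 1], 100, 0.0, model="softened", stress_kind="cauchy"
        )
        curve_kpa.stress = curve_kpa.stress * 1000.0
        curve_kpa.unit = "kPa"
        # every stress-like parameter moves to kPa, dimensionless ones do not
        init_kpa = with_params(
            init, ("mu", "A1", "A2", "c"),
            [init.iso.mu * 1e3, init.fib.A1 * 1e3, init.fib.A2 * 1e3, init.iso.c * 1e3],
        )
        lo, hi = init.iso.mu / 10 * 1000, init.iso.mu * 10 * 1000
        res_kpa = fit_softened(
            curve_kpa, init_kpa,
            FitConfig(free=free, multistart=1, bounds={"mu": (lo, hi)}),
        )
        assert res_kpa["mu"] == pytest.approx(res_mpa["mu"] * 1000.0, rel=1e-6)
        assert res_kpa["N"] == pytest.approx(res_mpa["N"], rel=1e-6)
        assert res_kpa["b"] == pytest.approx(res_mpa["b"], rel=1e-6)

    def test_requires_loading_and_unloading(self, mouse_truth):
        loading_only = generate_cycle_data(
            mouse_truth, [1, 1.25], 50, 0.0, model="softened", stress_kind="cauchy"
        )
        with pytest.raises(ValueError, match="unloading"):
            fit_softened(loading_only, mouse_truth, FitConfig())


class TestFitPseudoelastic:
    truth = MaterialParams(
        iso=IsotropicParams(mu=1.0, N=4.0),
        fib=FiberParams(f=0.1, A1=0.5, A2=2.0),
        soft=SofteningParams(),
        pe=PseudoElasticParams(m1=0.5, r1=1.5, r2=0.8, gamma=0.5),
    )

    def test_noiseless_self_consistency(self):
        clean = generate_cycle_data(self.truth, [1, 1.8, 1.05], 60, 0.0, model="pseudoelastic")
        res = fit_pseudoelastic(clean, self.truth, FitConfig(multistart=1))
        assert res.rss == pytest.approx(0.0, abs=1e-16)

    def test_gamma_recovery_under_noise(self):
        """Seeded 2%-noise experiment recovers gamma within 10% (r2 known)."""
        clean = generate_cycle_data(self.truth, [1, 1.8, 1.05], 100, 0.0, model="pseudoelastic")
        sd = 0.02 * float(np.abs(clean.stress).max())
        noisy = generate_cycle_data(
            self.truth, [1, 1.8, 1.05], 100, sd, seed=3, model="pseudoelastic"
        )
        free = ("m1", "r1", "gamma")
        init = with_params(self.truth, free, [get_param(self.truth, n) * 1.15 for n in free])
        res = fit_pseudoelastic(noisy, init, FitConfig(free=free, multistart=4, seed=2))
        assert abs(res["gamma"] - self.truth.pe.gamma) / self.truth.pe.gamma < 0.10

    def test_loading_only_curve_rejected(self):
        loading_only = generate_cycle_data(self.truth, [1, 1.8], 50, 0.0, model="pseudoelastic")
        with pytest.raises(ValueError, match="unloading"):
            fit_pseudoelastic(loading_only, self.truth, FitConfig())

    def test_missing_pe_block_rejected(self):
        clean = generate_cycle_data(self.truth, [1, 1.8, 1.05], 30, 0.0, model="pseudoelastic")
        bare = MaterialParams(iso=self.truth.iso, fib=self.truth.fib)
        with pytest.raises(ValueError, match="pseudo-elastic"):
            fit_pseudoelastic(clean, bare, FitConfig())
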