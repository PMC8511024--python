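import numpy as np
import pytest

from quenchbind import (
    HillModel,
    SternVolmerModel,
    TitrationSeries,
    classify_quenching_mechanism,
    displacement_ratio,
    fit_hill,
    fit_stern_volmer,
    read_titration_csv,
    write_titration_csv,
)
from quenchbind.quenching import HillResults, SternVolmerResults
from tests.conftest import Q_GRID_UM, REFERENCE_KSV


def make_series(Ksv=2.773e4, F0=1000.0, n=1.0, temperature=290.0, q_um=Q_GRID_UM):
    """Noiseless titration exactly obeying F = F0/(1 + K·Qⁿ)."""
    Q = np.asarray(q_um) * 1e-6
    F = F0 / (1.0 + Ksv * Q**n)
    return TitrationSeries(temperature=temperature, Q=Q, F=F)


class TestTitrationSeries:
    def test_requires_zero_first_point_and_positive_intensities(self):
        with pytest.raises(ValueError, match="Q = 0"):
            TitrationSeries(290, [1e-6, 2e-6], [10, 9])
        with pytest.raises(ValueError, match="> 0"):
            TitrationSeries(290, [0, 1e-6], [10, 0])
        with pytest.raises(ValueError, match="increasing"):
            TitrationSeries(290, [0, 2e-6, 1e-6], [10, 9, 8])

    def test_csv_round_trip(self, tmp_path):
        s = make_series()
        p = tmp_path / "titr.csv"
        write_titration_csv([s], p)
        (s2,) = read_titration_csv(p)
        assert s2.temperature == s.temperature
        assert np.allclose(s2.Q, s.Q)
        assert np.allclose(s2.F, s.F)


class TestSternVolmer:
    def test_recovers_exact_slope_on_noiseless_data(self):
        res = fit_stern_volmer(make_series(Ksv=2.773e4))
        assert res.Ksv == pytest.approx(2.773e4, rel=1e-9)
        assert res.intercept == pytest.approx(1.0, abs=1e-9)
        assert res.r2 == pytest.approx(1.0, abs=1e-12)

    def test_quenching_rate_constant_identity(self):
        res = fit_stern_volmer(make_series(Ksv=2.773e4), tau0=1e-8)
        assert res.kq == pytest.approx(2.773e12, rel=1e-9)
        assert res.kq == res.Ksv / res.tau0

    def test_constant_intensity_gives_zero_slope(self):
        s = TitrationSeries(290, np.asarray(Q_GRID_UM) * 1e-6, np.full(len(Q_GRID_UM), 500.0))
        assert fit_stern_volmer(s).Ksv == pytest.approx(0.0, abs=1e-12)

    def test_constrained_intercept_fixed_at_one(self):
        rng = np.random.default_rng(5)
        s = make_series()
        s = TitrationSeries(s.temperature, s.Q, s.F * (1 + 0.01 * rng.standard_normal(len(s))))
        res = SternVolmerModel(s).fit(constrain_intercept=True)
        assert res.intercept == 1.0
        assert res.constrained
        assert res.Ksv == pytest.approx(2.773e4, rel=0.1)

    def test_too_few_points_rejected(self):
        s = TitrationSeries(290, [0, 1e-6, 2e-6], [100, 99, 98])
        with pytest.raises(ValueError, match="at least 3"):
            SternVolmerModel(s)

    def test_anti_quenching_flagged(self):
        Q = np.asarray(Q_GRID_UM) * 1e-6
        F = 100.0 * (1 + 0.5 * Q / Q[-1])  # intensity rising well above F0
        res = fit_stern_volmer(TitrationSeries(290, Q, F))
        assert any("anti-quenching" in w for w in res.warnings)


class TestMechanismClassifier:
    @staticmethod
    def _fits(ksv_by_T, tau0=1e-8):
        return [
            SternVolmerResults(k, 0.0, 1.0, 0.0, 0.99, tau0, T, 11, False)
            for T, k in ksv_by_T.items()
        ]

    def test_reference_trend_is_static(self):
        call = classify_quenching_mechanism(self._fits(REFERENCE_KSV))
        assert call.mechanism == "static"

    def test_rising_ksv_with_diffusion_limited_kq_is_dynamic(self):
        call = classify_quenching_mechanism(self._fits({290.0: 1e2, 310.0: 2e2}))
        assert call.mechanism == "dynamic"

    def test_conflicting_evidence_is_indeterminate_with_note(self):
        # Ksv decreasing (static trend) but kq below the diffusion ceiling
        call = classify_quenching_mechanism(self._fits({290.0: 2e2, 310.0: 1e2}))
        assert call.mechanism == "indeterminate"
        assert call.note

    def test_single_temperature_rejected(self):
        with pytest.raises(ValueError):
            classify_quenching_mechanism(self._fits({290.0: 1e4}))


class TestHill:
    def test_noiseless_round_trip_noncooperative(self):
        res = fit_hill(make_series(Ksv=1.195e4))
        assert res.KA == pytest.approx(1.195e4, rel=1e-6)
        assert res.n == pytest.approx(1.0, abs=1e-6)
        assert res.r2 == pytest.approx(1.0, abs=1e-9)

    def test_half_saturation_identity(self):
        KA = 1.195e4
        q_um = tuple(Q_GRID_UM) + (1e6 / KA,)  # add Q = 1/KA
        s = make_series(Ksv=KA, q_um=tuple(sorted(q_um)))
        i = int(np.argmin(np.abs(s.Q - 1.0 / KA)))
        assert (s.F0 - s.F[i]) / s.F0 == pytest.approx(0.5, rel=1e-12)

    def test_linearized_and_nonlinear_agree_on_noiseless_data(self):
        s = make_series(Ksv=2.5e4)
        lin = fit_hill(s, method="linearized")
        non = fit_hill(s, method="nonlinear")
        assert lin.KA == pytest.approx(non.KA, rel=1e-6)
        assert lin.n == pytest.approx(non.n, abs=1e-6)

    def test_cooperative_fit_matches_grid_search_oracle(self):
        KA_true, n_true = 5e7, 2.0
        s = make_series(Ksv=KA_true, n=n_true)
        res = fit_hill(s)
        # brute-force SSR minimization over a 400×400 log-spaced lattice
        Q = s.Q[s.Q > 0]
        y = (s.F0 - s.F[s.Q > 0]) / s.F0
        logKA_grid = np.linspace(np.log10(KA_true) - 2, np.log10(KA_true) + 2, 400)
        n_grid = np.linspace(0.5, 4.0, 400)
        x = 10.0 ** logKA_grid[:, None, None] * Q[None, None, :] ** n_grid[None, :, None]
        ssr = np.sum((x / (1 + x) - y) ** 2, axis=-1)
        xf = res.KA * Q**res.n
        ssr_fit = np.sum((xf / (1 + xf) - y) ** 2)
        # the optimizer must beat every one of the 160 000 lattice candidates
        assert ssr_fit <= ssr.min() + 1e-15
        assert res.KA == pytest.approx(KA_true, rel=1e-5)
        assert res.n == pytest.approx(n_true, abs=1e-4)

    def test_fix_n_holds_coefficient(self):
        rng = np.random.default_rng(7)
        s = make_series(Ksv=1.7e4)
        s = TitrationSeries(s.temperature, s.Q, s.F * (1 + 0.01 * rng.standard_normal(len(s))))
        res = fit_hill(s, fix_n=1.0)
        assert res.n == 1.0
        assert res.n_se == 0.0

    def test_stern_volmer_slope_equals_hill_ka_for_noncooperative_data(self):
        # F0/F = 1 + K·Q is algebraically the n = 1 Hill isotherm
        s = make_series(Ksv=1.706e4)
        sv = fit_stern_volmer(s)
        hill = fit_hill(s)
        assert sv.Ksv == pytest.approx(hill.KA, rel=1e-9)

    def test_too_few_informative_points_rejected(self):
        s = make_series(q_um=(0.0, 10.0, 50.0, 100.0, 170.0))
        fit_hill(s)  # exactly 4 informative points is fine
        with pytest.raises(ValueError, match="at least 4"):
            HillModel(TitrationSeries(290, [0, 1e-6, 2e-6, 3e-6], [100, 99, 98, 97.5]))

    def test_median_recovery_under_realistic_noise(self):
        # 1% multiplicative noise, 11-point design: the free fit pins n,
        # and K_A under the n = 1 convention comes back within a few percent
        from quenchbind import SimulationConfig, simulate_titration_series

        errs, n_errs = [], []
        for seed in range(20):
            cfg = SimulationConfig(temperatures=(310.0,), noise_rel=0.01, seed=seed)
            (s,), truth = simulate_titration_series(cfg)
            n_errs.append(abs(fit_hill(s).n - 1.0))
            errs.append(abs(fit_hill(s, fix_n=1.0).KA / truth["KA_by_T"][310.0] - 1))
        assert np.median(errs) < 0.05
        assert np.median(n_errs) < 0.1


class TestDisplacement:
    @staticmethod
    def _hill(KA, n=1.0):
        return HillResults(KA, 0.0, n, 0.0, 0.99, "nonlinear", 310.0, 10)

    def test_marker_increasing_ka_means_no_direct_competition(self):
        d = displacement_ratio(self._hill(1.195e4), self._hill(2.124e4))
        assert d.ratio == pytest.approx(1.777, abs=5e-4)
        assert d.interpretation == "no direct competition at probed site"

    def test_identical_fits_ratio_one(self):
        ratio, interp = displacement_ratio(self._hill(1e4), self._hill(1e4))
        assert ratio == 1.0
        assert interp == "no direct competition at probed site"

    def test_large_drop_with_unchanged_n_is_direct_competition(self):
        d = displacement_ratio(self._hill(1e4), self._hill(3e3))
        assert d.interpretation == "direct competition"

    def test_changed_cooperativity_is_ambiguous(self):
        d = displacement_ratio(self._hill(1e4, n=1.0), self._hill(2e4, n=1.8))
        assert d.interpretation == "ambiguous"
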