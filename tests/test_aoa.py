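import numpy as np
import pandas as pd
import pytest

import sedpower as sp


class TestRelativeDepth:
    def test_surface_and_boundary(self):
        assert sp.relative_depth(0.0, 0.15) == 0.0
        assert sp.relative_depth(0.15, 0.15) == 1.0
        assert sp.relative_depth(0.075, 0.15) == pytest.approx(0.5)

    def test_nonpositive_opd_rejected(self):
        with pytest.raises(ValueError):
            sp.relative_depth(0.1, 0.0)


class TestExponentialFit:
    def test_noiseless_exact_recovery(self):
        x = np.linspace(0, 1, 12)
        y = 10.0 * np.exp(-1.0 * x)
        fit = sp.fit_exponential_decay(x, y)
        assert fit.a == pytest.approx(10.0, rel=1e-6)
        assert fit.b == pytest.approx(-1.0, rel=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_constant_data_degenerates_to_flat_fit(self):
        x = np.linspace(0, 1, 8)
        fit = sp.fit_exponential_decay(x, np.full(8, 7.5))
        assert fit.a == pytest.approx(7.5)
        assert fit.b == 0.0
        assert fit.r_squared == 0.0

    def test_noisy_simulation_recovers_regime(self, amor):
        # lognormal fraction scatter at the generator defaults, n = 40
        comm = sp.generate_community_observations(amor, 40, seed=7)
        x = sp.relative_depth(comm["depth_m"], comm["opd_m"].iloc[0])
        fit = sp.fit_exponential_decay(x, comm["aoa_fraction_pct"])
        assert 22.3 / 2 <= fit.a <= 22.3 * 2
        assert abs(fit.b - (-2.0)) <= 0.7
        assert 0.3 < fit.r_squared < 0.9

    def test_scaling_equivariance(self):
        rng = np.random.default_rng(11)
        x = rng.uniform(0, 1, 30)
        y = 20.0 * np.exp(-1.5 * x) * np.exp(rng.normal(0, 0.3, 30))
        f1 = sp.fit_exponential_decay(x, y)
        f2 = sp.fit_exponential_decay(x, 3.0 * y)
        assert f2.a == pytest.approx(3.0 * f1.a, rel=1e-4)
        assert f2.b == pytest.approx(f1.b, rel=1e-4, abs=1e-6)
        assert f2.r_squared == pytest.approx(f1.r_squared, rel=1e-6)

    def test_no_depth_contrast_rejected(self):
        with pytest.raises(ValueError):
            sp.fit_exponential_decay(np.zeros(10), np.linspace(1, 5, 10))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            sp.fit_exponential_decay([0.1, 0.9], [5.0, 1.0])


class TestPrediction:
    def printed_fit(self):
        return sp.RegressionFit(
            a=22.3, b=-2.0, covariance=np.zeros((2, 2)),
            r_squared=0.64, n=40, residual_variance=0.0,
        )

    def test_intercept_at_surface(self):
        y, lo, hi = sp.predict_fraction(self.printed_fit(), 0.0)
        assert y == pytest.approx(22.3)

    def test_value_at_oxic_anoxic_boundary(self):
        y, lo, hi = sp.predict_fraction(self.printed_fit(), 1.0)
        assert y == pytest.approx(22.3 * np.exp(-2.0), rel=1e-6)  # ~3.02%

    def test_zero_covariance_gives_zero_width(self):
        y, lo, hi = sp.predict_fraction(self.printed_fit(), 0.5)
        assert lo == pytest.approx(y) and hi == pytest.approx(y)

    def test_extrapolation_below_oxic_zone_refused(self):
        with pytest.raises(ValueError):
            sp.predict_fraction(self.printed_fit(), 1.2)

    def test_monotone_decline_for_negative_decay(self):
        xs = np.linspace(0, 1, 50)
        y, _, _ = sp.predict_fraction(self.printed_fit(), xs)
        assert np.all(np.diff(y) < 0)


class TestAbsoluteAbundance:
    def test_arithmetic_on_printed_intercept(self):
        assert sp.estimate_aoa_absolute(1e8, 22.3) == pytest.approx(2.23e7)

    def test_zero_totals(self):
        assert sp.estimate_aoa_absolute(0.0, 22.3) == 0.0

    def test_fraction_above_hundred_rejected(self):
        with pytest.raises(ValueError):
            sp.estimate_aoa_absolute(1e8, 120.0)

    def test_ci_propagates_multiplicatively(self):
        est, lo, hi = sp.estimate_aoa_absolute(1e6, 10.0, (5.0, 20.0))
        assert (est, lo, hi) == (pytest.approx(1e5), pytest.approx(5e4), pytest.approx(2e5))

    def test_sast_like_surface_abundance_in_reported_band(self, sast):
        surface_totals = sp.total_cells(sast, 0.0)
        est = sp.estimate_aoa_absolute(surface_totals, 22.3)
        assert 1.5e7 <= est <= 1.7e8

    def test_abundance_never_exceeds_totals(self, amor):
        comm = sp.generate_community_observations(amor, 20, seed=3)
        est = sp.estimate_aoa_absolute(
            comm["total_cells_per_cm3"], comm["aoa_fraction_pct"]
        )
        assert np.all(est <= comm["total_cells_per_cm3"])


class TestQpcrComparison:
    def frame(self, depths, est, qpcr):
        return (
            pd.DataFrame({"depth_m": depths, "aoa_cells_per_cm3": est}),
            pd.DataFrame({"depth_m": depths, "amoa_copies_per_cm3": qpcr}),
        )

    def test_identical_series_fold_one(self):
        e, q = self.frame([0.1, 0.2], [1e5, 2e4], [1e5, 2e4])
        out, summary = sp.compare_with_qpcr(e, q)
        np.testing.assert_allclose(out["fold_difference"], 1.0)
        assert summary["max_fold"] == 1.0

    def test_fourfold_difference(self):
        e, q = self.frame([0.1], [2e5], [5e4])
        _, summary = sp.compare_with_qpcr(e, q)
        assert summary["max_fold"] == pytest.approx(4.0)

    def test_zero_qpcr_excluded_with_warning(self):
        e, q = self.frame([0.1, 0.2], [1e5, 1e5], [1e5, 0.0])
        with pytest.warns(UserWarning):
            _, summary = sp.compare_with_qpcr(e, q)
        assert summary["n"] == 1

    def test_generator_scatter_keeps_folds_below_ten(self, amor):
        # sigma_log10 = 0.3 qPCR scatter: <10-fold in >= 95% of depths
        comm = sp.generate_community_observations(
            sp.ScenarioTruth(
                site=amor.site, params=amor.params, grid=amor.grid,
                profiles=amor.profiles, rates=amor.rates,
                community={**amor.community, "sigma_frac": 0.0},
            ),
            60, seed=21,
        )
        est = pd.DataFrame(
            {
                "depth_m": comm["depth_m"],
                "aoa_cells_per_cm3": comm["aoa_fraction_pct"] / 100
                * comm["total_cells_per_cm3"],
            }
        )
        qpcr = comm[["depth_m", "amoa_copies_per_cm3"]]
        out, _ = sp.compare_with_qpcr(est, qpcr)
        assert np.mean(out["fold_difference"] < 10.0) >= 0.95


class TestCoverage:
    def test_confidence_band_covers_truth_in_log_matched_mode(self):
        # a quick 50-run version of the full 200-run coverage audit
        a0, b0, sig = 22.3, -2.0, 0.5
        xs = np.array([0.1, 0.5, 0.9])
        truth = a0 * np.exp(b0 * xs)
        rng_master = np.random.default_rng(99)
        hits = np.zeros(3)
        n_runs = 50
        for _ in range(n_runs):
            rng = np.random.default_rng(int(rng_master.integers(2**31)))
            x = rng.uniform(0, 1, 40)
            y = np.clip(a0 * np.exp(b0 * x) * np.exp(rng.normal(0, sig, 40)), 0, 100)
            fit = sp.fit_exponential_decay(x, y, log_space=True)
            _, lo, hi = sp.predict_fraction(fit, xs)
            hits += (truth >= lo) & (truth <= hi)
        assert np.all(hits / n_runs >= 0.85) and np.all(hits / n_runs <= 1.0)
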