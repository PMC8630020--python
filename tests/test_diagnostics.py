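import numpy as np
import pandas as pd
import pytest

import sedpower as sp
from sedpower.diagnostics import integrated_rate

from conftest import make_profile_set


@pytest.fixture
def grid():
    return sp.build_grid(0.1, 11)


class TestOxygenPenetrationDepth:
    def test_uniform_oxygen_never_crosses_threshold(self, grid):
        prof = make_profile_set(grid, O2=np.full(11, 0.1))
        assert sp.oxygen_penetration_depth(prof) == np.inf

    def test_linear_profile_interpolates_crossing(self, grid):
        # 10 uM at surface declining linearly to 0 at 0.1 m: 1 uM at 0.09 m
        o2 = 1e-2 * (1 - grid.node_depths / 0.1)
        prof = make_profile_set(grid, O2=o2)
        assert sp.oxygen_penetration_depth(prof) == pytest.approx(0.09, rel=1e-12)

    def test_threshold_parameter(self, grid):
        o2 = 1e-2 * (1 - grid.node_depths / 0.1)
        prof = make_profile_set(grid, O2=o2)
        assert sp.oxygen_penetration_depth(prof, threshold=5e-3) == pytest.approx(0.05)

    def test_sast_preset_opd_near_fifteen_centimetres(self, sast):
        opd = sp.oxygen_penetration_depth(sast.profiles)
        assert opd == pytest.approx(0.15, rel=0.20)


class TestRmse:
    def measured(self, depths, values, species="O2"):
        return pd.DataFrame(
            {"depth_m": depths, "species": species, "value": values}
        )

    def test_perfect_match_gives_zero(self, grid):
        prof = make_profile_set(grid, O2=np.linspace(0.2, 0.1, 11))
        m = self.measured(grid.node_depths, np.linspace(0.2, 0.1, 11))
        assert sp.rmse(prof, m, _dummy_site())["O2"] == pytest.approx(0.0, abs=1e-15)

    def test_alternating_unit_residuals_give_one(self, grid):
        prof = make_profile_set(grid, O2=np.full(11, 5.0))
        m = self.measured([0.0, 0.03, 0.06, 0.09], [4.0, 6.0, 4.0, 6.0])
        assert sp.rmse(prof, m, _dummy_site())["O2"] == pytest.approx(1.0)

    def test_single_residual_of_three(self, grid):
        prof = make_profile_set(grid, O2=np.full(11, 5.0))
        m = self.measured([0.05], [8.0])
        assert sp.rmse(prof, m, _dummy_site())["O2"] == pytest.approx(3.0)

    def test_out_of_domain_species_warns_and_skips(self, grid):
        prof = make_profile_set(grid, O2=np.full(11, 5.0))
        m = self.measured([0.5], [4.0], species="NO3")
        with pytest.warns(UserWarning):
            out = sp.rmse(prof, m, _dummy_site())
        assert "NO3" not in out

    def test_censored_records_excluded(self, grid):
        prof = make_profile_set(grid, NH4=np.full(11, 1e-3))
        m = pd.DataFrame(
            {
                "depth_m": [0.02, 0.05],
                "species": "NH4",
                "value": [1e-3, 1e-4],
                "censored": [False, True],
            }
        )
        assert sp.rmse(prof, m, _dummy_site())["NH4"] == pytest.approx(0.0, abs=1e-15)


class TestNitrateOxygenSlope:
    def test_exact_redfield_coupling_recovers_slope(self, grid):
        o2 = np.linspace(0.2, 0.05, 11)
        no3 = 0.094 * (0.2 - o2)
        prof = make_profile_set(grid, O2=o2, NO3=no3)
        assert sp.nitrate_oxygen_slope(prof, (0.0, 0.1)) == pytest.approx(0.094)

    def test_constant_nitrate_gives_zero_slope(self, grid):
        prof = make_profile_set(grid, O2=np.linspace(0.2, 0.05, 11), NO3=np.full(11, 0.03))
        assert sp.nitrate_oxygen_slope(prof, (0.0, 0.1)) == pytest.approx(0.0, abs=1e-12)

    def test_too_few_points_rejected(self, grid):
        prof = make_profile_set(grid, O2=np.linspace(0.2, 0.05, 11), NO3=np.full(11, 0.03))
        with pytest.raises(ValueError):
            sp.nitrate_oxygen_slope(prof, (0.0, 0.015))

    def test_forward_model_slope_near_stoichiometric_expectation(self, np_site):
        # NO3 gained per O2 lost: (1/rCN) C-to-N release over (1 + 2/rCN) O2
        # demand per C -> slope ~ 1/(rCN + 2), within transport distortion
        slope = sp.nitrate_oxygen_slope(np_site.profiles, (0.5, 25.0))
        expected = 1.0 / (np_site.site.cn_ratio + 2.0)
        assert slope == pytest.approx(expected, rel=0.15)


class TestFluxBudget:
    def test_no_reaction_solve_closes_exactly(self, oracle_site, inert_params):
        grid = sp.build_grid(0.2, 40)
        sol = sp.solve_steady_state(oracle_site, inert_params, grid)
        rep = sp.flux_budget(sol, oracle_site, inert_params)
        assert rep.max_closure_error < 1e-6

    def test_amor_preset_closes_below_tolerance(self, amor):
        rep = sp.flux_budget((amor.profiles, amor.rates), amor.site, amor.params)
        assert rep.max_closure_error < 1e-3

    def test_nitrification_bounded_by_nitrogen_supply(self, amor):
        # integrated R4 cannot exceed N mineralisation plus the NH4 influx
        r4 = integrated_rate(amor.rates, amor.grid, "R4")
        n_min = (
            integrated_rate(amor.rates, amor.grid, "R1")
            + integrated_rate(amor.rates, amor.grid, "R2")
            + integrated_rate(amor.rates, amor.grid, "R3")
        ) / amor.site.cn_ratio
        rep = sp.flux_budget((amor.profiles, amor.rates), amor.site, amor.params)
        nh4_influx = rep.elements["N"]["influx"]
        assert r4 <= n_min + max(nh4_influx, 0.0) + 1e-12


class TestSensitivityScan:
    def test_identity_factor_reproduces_base_solution(self, amor):
        res = sp.sensitivity_scan(amor.site, amor.params, amor.grid, "k_nit", [1.0])
        np.testing.assert_allclose(
            res[0].profiles.solutes["O2"], amor.profiles.solutes["O2"], rtol=1e-8
        )

    def test_lower_oxygen_inhibition_shrinks_oxic_zone_denitrification(self, amor):
        res = sp.sensitivity_scan(
            amor.site, amor.params, amor.grid, "k_O2_inhib", [1.0, 0.1, 0.01]
        )
        opd = sp.oxygen_penetration_depth(amor.profiles)
        r2_oxic = [
            integrated_rate(r.rates, amor.grid, "R2", r.profiles.grid.node_depths <= opd)
            for r in res
        ]
        assert r2_oxic[0] > r2_oxic[1] > r2_oxic[2]

    def test_supply_limited_nitrification_insensitive_to_rate_constant(self):
        # with no boundary NH4 source, integrated R4 is pinned by N supply
        site, params = sp.make_site_preset("NP-like")
        site = site.replace(top_concentrations={**site.top_concentrations, "NH4": 0.0})
        grid = sp.build_grid(site.domain_length, 150, 1.04)
        res = sp.sensitivity_scan(site, params, grid, "k_nit", [0.1, 1.0, 10.0])
        r4 = [integrated_rate(r.rates, grid, "R4") for r in res]
        assert (max(r4) - min(r4)) / np.mean(r4) < 0.10
        supply = site.organic_flux * sum(site.g_fractions[:2]) / site.cn_ratio
        assert all(v <= supply for v in r4)

    def test_unknown_parameter_rejected(self, amor):
        with pytest.raises(ValueError):
            sp.sensitivity_scan(amor.site, amor.params, amor.grid, "nope", [1.0])


def _dummy_site():
    return sp.SiteConfig(
        name="d", water_depth=1000.0, temperature=2.0, pH=7.8,
        sedimentation_rate=1e-5, domain_length=1.0,
        top_concentrations={"O2": 0.2, "NO3": 0.03, "NH4": 0.0, "Mn": 0.0, "DIC": 2.3},
        organic_flux=0.0,
    )
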