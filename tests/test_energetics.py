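import numpy as np
import pytest

import sedpower as sp
from sedpower import energetics
from sedpower.units import GAS_CONSTANT

from conftest import make_profile_set


@pytest.fixture(scope="module")
def table():
    return sp.load_thermo_table()


class TestAmmoniaEquilibrium:
    def test_equal_at_pka(self):
        assert sp.nh3_from_nh4(1e-3, pH=9.3) == pytest.approx(1e-3)

    def test_zero_in_zero_out(self):
        assert sp.nh3_from_nh4(0.0, pH=7.0) == 0.0

    def test_typical_deep_sea_ph(self):
        # pH 7.79, pKa 9.3: factor 10^-1.51
        assert sp.nh3_from_nh4(1e-3, pH=7.79) == pytest.approx(1e-3 * 10 ** (-1.51))

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            sp.nh3_from_nh4(-1.0, pH=8.0)


class TestActivityCoefficient:
    def test_neutral_species_ideal(self):
        assert sp.activity_coefficient(0, 0.7, 277.0, 0.0) == pytest.approx(1.0)

    def test_infinite_dilution_ideal(self):
        assert sp.activity_coefficient(1, 0.0, 277.0, 3.0) == pytest.approx(1.0)

    def test_seawater_monovalent_hand_value(self):
        # independent hand evaluation of the extended Debye-Hueckel formula
        # at z=1, I=0.7 molal, T=277 K, ion size 3 A
        assert sp.activity_coefficient(1, 0.7, 277.0, 3.0) == pytest.approx(0.5919, rel=1e-3)

    def test_gamma_approaches_one_as_dilution_increases(self):
        gammas = [sp.activity_coefficient(1, i, 277.0, 3.0) for i in (0.7, 0.1, 1e-3, 1e-10)]
        assert np.all(np.diff(gammas) > 0) and gammas[-1] == pytest.approx(1.0, abs=1e-4)

    def test_negative_ionic_strength_rejected(self):
        with pytest.raises(ValueError):
            sp.activity_coefficient(1, -0.1, 277.0, 3.0)


class TestStandardGibbs:
    def test_reference_state_is_sum_of_formation_energies(self, table):
        nu = sp.NITRIFICATION_NH3.stoichiometry
        expected = sum(v * table.dgf[s] for s, v in nu.items())
        assert sp.standard_gibbs(sp.NITRIFICATION_NH3, table, 298.15, 1.0) == pytest.approx(
            expected
        )
        # brute-force sum over the packaged table: -352.43 kJ/mol
        assert expected == pytest.approx(-352.43, abs=0.01)

    def test_zero_reaction_volume_removes_pressure_dependence(self, table):
        zero_v = energetics.ThermoTable(
            dgf=table.dgf, dhf=table.dhf, charge=table.charge,
            ion_size=table.ion_size, volume={s: 0.0 for s in table.volume},
        )
        g1 = sp.standard_gibbs(sp.NITRIFICATION_NH3, zero_v, 277.0, 1.0)
        g2 = sp.standard_gibbs(sp.NITRIFICATION_NH3, zero_v, 277.0, 500.0)
        assert g1 == pytest.approx(g2)

    def test_pressure_term_sign_and_size(self, table):
        g_surface = sp.standard_gibbs(sp.NITRIFICATION_NH3, table, 277.0, 1.0)
        g_deep = sp.standard_gibbs(sp.NITRIFICATION_NH3, table, 277.0, 443.0)
        # negative reaction volume: pressure favours the reaction, few kJ
        assert g_deep < g_surface
        assert abs(g_deep - g_surface) < 5.0

    def test_missing_species_rejected(self, table):
        bad = energetics.Reaction(stoichiometry={"XYZ": 1}, n_electrons=1)
        with pytest.raises(sp.ConfigurationError):
            sp.standard_gibbs(bad, table, 298.15, 1.0)


class TestGibbsProfile:
    def make_inputs(self, nh4_scale=1.0):
        grid = sp.build_grid(0.1, 11)
        site = sp.SiteConfig(
            name="e", water_depth=2770.0, temperature=3.85, pH=7.79,
            sedimentation_rate=1e-5, domain_length=0.1,
            top_concentrations={"O2": 0.2, "NO3": 0.03, "NH4": 1e-4, "Mn": 0.0, "DIC": 2.3},
            organic_flux=0.0,
        )
        prof = make_profile_set(
            grid,
            O2=np.full(11, 0.1),
            NO3=np.full(11, 0.03),
            NH4=np.full(11, 1e-4 * nh4_scale),
        )
        return site, prof

    def test_tenfold_ammonia_shifts_energy_by_rt_ln10_over_ne(self):
        site, prof1 = self.make_inputs(1.0)
        _, prof10 = self.make_inputs(10.0)
        t1 = sp.gibbs_energy_profile(prof1, site)
        t10 = sp.gibbs_energy_profile(prof10, site)
        expected = GAS_CONSTANT * t1.temperature_k * np.log(10.0) / 8.0 / 1000.0
        np.testing.assert_allclose(t1.dg_per_e - t10.dg_per_e, expected, rtol=1e-10)

    def test_energy_in_plausible_deep_sea_range(self):
        site, prof = self.make_inputs()
        t8 = sp.gibbs_energy_profile(prof, site)
        assert np.all(t8.dg_per_e < -30) and np.all(t8.dg_per_e > -60)
        t4 = sp.gibbs_energy_profile(prof, site, electron_equivalents=4)
        np.testing.assert_allclose(t4.dg_per_e, 2 * t8.dg_per_e)

    def test_anoxic_depths_masked(self, sast):
        thermo = sp.gibbs_energy_profile(sast.profiles, sast.site)
        opd = sp.oxygen_penetration_depth(sast.profiles)
        below = sast.grid.node_depths > opd
        assert np.all(np.isnan(thermo.dg_per_e[below]))
        assert np.all(np.isfinite(thermo.dg_per_e[~below]))

    def test_gibbs_energy_declines_with_depth_in_oxic_zone(self, amor):
        thermo = sp.gibbs_energy_profile(amor.profiles, amor.site)
        dg = thermo.dg_per_e[thermo.oxic_mask]
        # less negative downcore, but within one order of magnitude
        assert dg[-1] > dg[0]
        assert np.nanmax(np.abs(dg)) / np.nanmin(np.abs(dg)) < 10


class TestPowerSupply:
    def test_zero_rate_zero_power(self, amor):
        thermo = sp.gibbs_energy_profile(amor.profiles, amor.site)
        rates = amor.rates
        zeroed = sp.RateProfiles(
            R1=rates.R1, R2=rates.R2, R3=rates.R3, R4=np.zeros_like(rates.R4),
            R5=rates.R5, R6=rates.R6, G1_loss=rates.G1_loss, G2_loss=rates.G2_loss,
            o2_first_order=rates.o2_first_order,
        )
        power = sp.power_supply_profile(thermo, zeroed)
        assert np.all(power.ps[thermo.oxic_mask] == 0.0)

    def test_hand_converted_magnitude(self):
        # |dG| = 50 kJ/mol e- x 8 e- with R4 = 1e-3 mol N m-3 yr-1
        # -> 400 kJ m-3 yr-1 = 4e5 J / 3.1536e7 s = 1.268e-5 W m-3
        ps = 50.0 * 8 * 1e-3 * 1e3 / 3.1536e7
        assert ps == pytest.approx(1.268e-5, rel=1e-3)

    def test_power_linear_in_rate(self, amor):
        thermo = sp.gibbs_energy_profile(amor.profiles, amor.site)
        p1 = sp.power_supply_profile(thermo, amor.rates)
        doubled = sp.RateProfiles(
            R1=amor.rates.R1, R2=amor.rates.R2, R3=amor.rates.R3,
            R4=2 * amor.rates.R4, R5=amor.rates.R5, R6=amor.rates.R6,
            G1_loss=amor.rates.G1_loss, G2_loss=amor.rates.G2_loss,
            o2_first_order=amor.rates.o2_first_order,
        )
        p2 = sp.power_supply_profile(thermo, doubled)
        mask = thermo.oxic_mask
        np.testing.assert_allclose(p2.ps[mask], 2 * p1.ps[mask], rtol=1e-12)

    def test_presets_span_many_orders_of_magnitude(self, scenarios):
        ps_all = []
        for name in ("SAST-like", "AMOR-like", "SPG-like"):
            tr = scenarios(name)
            thermo = sp.gibbs_energy_profile(tr.profiles, tr.site)
            power = sp.power_supply_profile(thermo, tr.rates)
            vals = power.ps[np.isfinite(power.ps) & (power.ps > 0)]
            ps_all.extend([vals.min(), vals.max()])
        assert max(ps_all) / min(ps_all) > 1e5
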