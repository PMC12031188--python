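"""Plume physics: sigma curves, settling, reflection, mass budget, compliance."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from dustrisk import (
    CLASS_D_SCHEME,
    PM10,
    PM25,
    AtmosphericState,
    InvalidParameterError,
    ParticleClass,
    Receptor,
    compliance_distance,
    concentration_profile,
    emission_rate,
    particle_concentration_fn,
    plume_concentration,
    settling_factor,
    sigma,
)
from dustrisk.dispersion import DispersionScheme, PowerLawBand


class TestSigma:
    def test_frozen_class_d_values(self):
        # Direct evaluation of the shipped near-field class-D coefficients:
        # 0.146669 * 1000^0.929418 and 0.104634 * 1000^0.826212.
        sy, sz = sigma(1000.0)
        assert sy == pytest.approx(90.07252364469682, rel=1e-12)
        assert sz == pytest.approx(31.499874830590038, rel=1e-12)

    def test_power_law_ratio_within_band(self):
        sy1, _ = sigma(200.0)
        sy2, _ = sigma(400.0)
        assert sy2 / sy1 == pytest.approx(2.0**0.929418, rel=1e-12)

    def test_vanishes_toward_origin(self):
        sy, sz = sigma(1e-9)
        assert sy < 1e-8 and sz < 1e-7

    def test_nonpositive_distance_rejected(self):
        with pytest.raises(InvalidParameterError):
            sigma(0.0)
        with pytest.raises(InvalidParameterError):
            sigma(-100.0)

    def test_strictly_increasing_across_band_edges(self):
        # Band anchoring keeps the piecewise power law continuous and
        # strictly increasing through the 1000 m break.
        x = np.linspace(10, 5000, 2000)
        assert np.all(np.diff(CLASS_D_SCHEME.sigma_y(x)) > 0)
        assert np.all(np.diff(CLASS_D_SCHEME.sigma_z(x)) > 0)
        left = CLASS_D_SCHEME.sigma_y(1000.0 - 1e-9)
        right = CLASS_D_SCHEME.sigma_y(1000.0 + 1e-9)
        assert right == pytest.approx(left, rel=1e-6)

    def test_invalid_scheme_rejected(self):
        with pytest.raises(InvalidParameterError):
            PowerLawBand(1000.0, -0.5, 0.1)
        with pytest.raises(InvalidParameterError):
            DispersionScheme("X", [], [])


class TestSettling:
    def test_massless_or_neutral_particle_is_undepleted(self, atm):
        zero_d = ParticleClass("z", diameter=1e-30, size_multiplier=1.0)
        assert settling_factor(5000.0, zero_d, 2.0, atm) == pytest.approx(1.0)
        neutral = ParticleClass("n", diameter=1e-5, size_multiplier=1.0,
                                particle_density=atm.air_density + 1e-12)
        assert settling_factor(5000.0, neutral, 2.0, atm) == pytest.approx(1.0)

    def test_frozen_pm10_value(self, atm):
        # Hand evaluation: exponent g*x*(rho-rho_a)*d^2/(18*mu*U)
        # = 9.81*2000*1208.795*1e-10/(18*1.81e-5*2) ~ 3.64.
        f = settling_factor(2000.0, PM10, 2.0, atm)
        assert f == pytest.approx(0.02625912186134303, rel=1e-9)
        assert f == pytest.approx(math.exp(-3.7), rel=0.1)

    def test_monotone_in_distance_and_diameter(self, atm):
        assert settling_factor(2000.0, PM10, 2.0, atm) < settling_factor(1000.0, PM10, 2.0, atm)
        assert settling_factor(1000.0, PM10, 2.0, atm) < settling_factor(1000.0, PM25, 2.0, atm)

    def test_buoyant_particle_needs_override(self):
        # A particle lighter than the surrounding air would amplify the
        # plume through the depletion term; that needs an explicit opt-in.
        light = ParticleClass("l", 1e-5, 1.0, particle_density=1.21)  # kg/m^3, literal
        dense_air = AtmosphericState(air_density=1.3)
        with pytest.raises(InvalidParameterError):
            settling_factor(1000.0, light, 2.0, dense_air)
        assert settling_factor(1000.0, light, 2.0, dense_air, allow_buoyant=True) > 1.0


class TestPlume:
    def test_zero_emission_gives_zero_everywhere(self, scenario, atm, scheme):
        for x in (50.0, 500.0, 5000.0):
            assert plume_concentration(0.0, Receptor(x), scenario, PM10, scheme, atm) == 0.0

    def test_crosswind_symmetry(self, scenario, atm, scheme):
        er = emission_rate(scenario, PM10)
        cpos = plume_concentration(er, Receptor(500.0, y=37.0), scenario, PM10, scheme, atm)
        cneg = plume_concentration(er, Receptor(500.0, y=-37.0), scenario, PM10, scheme, atm)
        assert cpos == pytest.approx(cneg, rel=1e-14)

    def test_frozen_residential_value(self, scenario, atm, scheme):
        # Independent term-by-term evaluation at x=500, y=0, z=1.5, h=15,
        # U=2 m/s with the default PM2.5 emission rate.
        er = emission_rate(scenario, PM25)
        c = plume_concentration(er, Receptor(500.0, 0.0, 1.5), scenario, PM25, scheme, atm)
        assert c == pytest.approx(0.014695191385077837, rel=1e-9)

    def test_ground_level_reflection_doubles_centreline(self, scenario, atm, scheme):
        # At y=0, z=0 the vertical bracket collapses to 2*exp(-h^2/2sz^2).
        er = emission_rate(scenario, PM10)
        x = 800.0
        c = plume_concentration(er, Receptor(x, 0.0, 0.0), scenario, PM10, scheme, atm)
        sy, sz = sigma(x)
        expected = (
            er * 1000.0 / (2 * math.pi * scenario.wind_speed * sy * sz)
            * 2.0 * math.exp(-scenario.stack_height**2 / (2 * sz**2))
            * settling_factor(x, PM10, scenario.wind_speed, atm)
        )
        assert c == pytest.approx(expected, rel=1e-12)

    def test_exactly_linear_in_emission_rate(self, scenario, atm, scheme):
        r = Receptor(640.0)
        c1 = plume_concentration(1.0, r, scenario, PM10, scheme, atm)
        c7 = plume_concentration(7.0, r, scenario, PM10, scheme, atm)
        assert c7 == pytest.approx(7 * c1, rel=1e-14)

    def test_mass_conservation_without_settling(self, scenario, atm, scheme):
        # With settling disabled the crosswind/vertical integral of U*C over
        # the half-space recovers the emission rate: reflection folds the
        # below-ground mass back above ground.
        er = 1.0  # mg/s
        heavy_like = ParticleClass("nd", diameter=1e-30, size_multiplier=1.0)
        x = 500.0
        sy, sz = sigma(x)

        def c_yz(y, z):
            return plume_concentration(
                er, Receptor(x, y, z), scenario, heavy_like, scheme, atm
            ) * 1e-3  # ug -> mg

        inner = lambda z: quad(lambda y: c_yz(y, z), -8 * sy, 8 * sy, limit=200)[0]
        total, _ = quad(inner, 0.0, scenario.stack_height + 10 * sz, limit=200)
        flux = scenario.wind_speed * total
        assert flux == pytest.approx(er, rel=5e-3)


class TestProfileAndCompliance:
    def test_single_distance_matches_plume(self, scenario, atm, scheme):
        df = concentration_profile([500.0], scenario, [PM10], scheme, atm)
        assert len(df) == 1
        er = emission_rate(scenario, PM10)
        direct = plume_concentration(
            er, Receptor(500.0, scenario.crosswind_offset, scenario.receptor_height),
            scenario, PM10, scheme, atm,
        )
        assert df["concentration_ug_m3"].iloc[0] == pytest.approx(direct, rel=1e-12)

    def test_monotone_decay_beyond_the_peak(self, scenario, atm, scheme):
        distances = list(range(100, 2001, 100))
        df = concentration_profile(distances, scenario, [PM25, PM10], scheme, atm)
        for label in ("PM2.5", "PM10"):
            vals = df[df["class"] == label]["concentration_ug_m3"].to_numpy()
            peak = int(np.argmax(vals))
            tail = vals[peak:]
            assert np.all(np.diff(tail) <= 0)
            # beyond the peak the decay is strict: profile(x)/profile(2x) > 1
            for i, x in enumerate(distances):
                if x >= distances[peak] and 2 * x in distances:
                    assert vals[i] / vals[distances.index(2 * x)] > 1

    def test_empty_distance_list_rejected(self, scenario, atm, scheme):
        with pytest.raises(InvalidParameterError):
            concentration_profile([], scenario, [PM10], scheme, atm)

    def test_solver_agrees_with_metre_step_scan(self, scenario, atm, scheme):
        fn = particle_concentration_fn(scenario, PM10, scheme, atm)
        limit = 0.01  # ug/m^3, attained inside the window
        result = compliance_distance(limit, fn)
        assert result.attained and not result.already_compliant
        # Brute-force oracle: 1 m steps from the peak outward.
        xs = np.arange(10.0, 20000.0, 1.0)
        vals = fn(xs)
        beyond = xs[np.argmax(vals):][vals[np.argmax(vals):] <= limit]
        assert abs(result.distance - beyond[0]) <= 1.0

    def test_generous_limit_flags_already_compliant(self, scenario, atm, scheme):
        fn = particle_concentration_fn(scenario, PM10, scheme, atm)
        result = compliance_distance(1e6, fn)
        assert result.already_compliant and result.distance == 10.0

    def test_unattainable_limit_reports_window_bound(self, scenario, atm, scheme):
        fn = particle_concentration_fn(scenario, PM10, scheme, atm)
        result = compliance_distance(1e-30, fn)
        assert not result.attained and result.distance == 20000.0

    def test_doubling_emission_pushes_compliance_outward(self, scenario, atm, scheme):
        er = emission_rate(scenario, PM10)
        fn1 = particle_concentration_fn(scenario, PM10, scheme, atm, er_mg_s=er)
        fn2 = particle_concentration_fn(scenario, PM10, scheme, atm, er_mg_s=2 * er)
        limit = 0.01
        assert compliance_distance(limit, fn2).distance > compliance_distance(limit, fn1).distance
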