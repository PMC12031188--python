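"""Fugitive dust emission from open slag stockpiles.

The source term is the AP-42 style aggregate-handling emission factor: the
mass of dust of a given size fraction released per megagram of material
disturbed scales as a power law in wind speed and inversely in the moisture
content of the pile, attenuated by any dust-suppression (removal) measures,

    EF [kg/Mg] = k * 0.0016 * (U / 2.2)^1.3 / (M / 2)^1.4 * (1 - eta)

Multiplying by the material throughput (disturbance rate * bulk density)
gives the emission rate of the stockpile as a whole.  ``k`` is the
dimensionless size multiplier selecting the fraction of the handled dust
that ends up in a given aerodynamic size class.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .errors import InvalidParameterError

__all__ = [
    "ParticleClass",
    "StockpileScenario",
    "PM25",
    "PM10",
    "TSP",
    "DEFAULT_CLASSES",
    "emission_rate",
]

#: Air density used for the "denser than air" sanity check, kg/m^3.
_AIR_DENSITY = 1.205


@dataclass(frozen=True)
class ParticleClass:
    """One aerodynamic size fraction of the emitted dust.

    Parameters
    ----------
    label:
        Human-readable name, e.g. ``"PM2.5"`` or ``"PM10"``.
    diameter:
        Representative particle diameter in metres.
    size_multiplier:
        Dimensionless aggregate-handling size multiplier ``k``.
    particle_density:
        Particle material density in kg/m^3.  Slag dust is ~1210 kg/m^3
        (1.21 g/cm^3).
    air_quality_limit:
        Ambient air-quality concentration limit for this fraction, ug/m^3.
    """

    label: str
    diameter: float
    size_multiplier: float
    particle_density: float = 1210.0
    air_quality_limit: float = 40.0

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise InvalidParameterError(f"{self.label}: diameter must be > 0")
        if self.size_multiplier <= 0:
            raise InvalidParameterError(f"{self.label}: size multiplier must be > 0")
        if self.particle_density <= _AIR_DENSITY:
            raise InvalidParameterError(
                f"{self.label}: particle density {self.particle_density} kg/m^3 "
                f"must exceed the density of air ({_AIR_DENSITY} kg/m^3)"
            )
        if self.air_quality_limit <= 0:
            raise InvalidParameterError(f"{self.label}: air-quality limit must be > 0")

    def with_density(self, particle_density: float) -> "ParticleClass":
        return replace(self, particle_density=particle_density)


# Default size fractions.  Size multipliers are the standard aggregate
# handling values (PM2.5 0.053, PM10 0.35, TSP 0.74); ambient limits are the
# annual PM2.5 / 24h PM10 / TSP standards used as compliance references,
# ug/m^3.  TSP carries a nominal 30 um diameter; it is used for total dust
# loading outputs, not for settling-sensitive size apportionment.
PM25 = ParticleClass("PM2.5", diameter=2.5e-6, size_multiplier=0.053, air_quality_limit=15.0)
PM10 = ParticleClass("PM10", diameter=1.0e-5, size_multiplier=0.35, air_quality_limit=40.0)
TSP = ParticleClass("TSP", diameter=3.0e-5, size_multiplier=0.74, air_quality_limit=80.0)

DEFAULT_CLASSES = (PM25, PM10, TSP)


@dataclass(frozen=True)
class StockpileScenario:
    """Meteorology, pile geometry and operating parameters of one stockpile.

    Defaults are the central values of the study scenario: ground wind speed
    2 m/s, pile moisture 30 %, suppression efficiency 50 %, disturbance rate
    500 m^3/h, pile height 15 m, receptors at adult breathing height on the
    plume centreline.

    Attributes
    ----------
    wind_speed:
        Mean ground-level wind speed U, m/s.
    moisture:
        Moisture content M as a percent-valued number (30 means 30 %),
        following the emission-factor convention.
    removal_rate:
        Dust removal (suppression) efficiency eta, fraction in [0, 1].
    disturbance_rate:
        Volume of pile material disturbed per unit time V, m^3/s.
    bulk_density:
        Bulk density of the slag converting V to mass throughput, Mg/m^3.
    stack_height:
        Effective release height = stockpile height h, m.
    receptor_height:
        Default receptor height z above ground, m.
    crosswind_offset:
        Default lateral receptor offset y from the plume centreline, m.
    """

    wind_speed: float = 2.0
    moisture: float = 30.0
    removal_rate: float = 0.5
    disturbance_rate: float = 500.0 / 3600.0
    bulk_density: float = 1.0
    stack_height: float = 15.0
    receptor_height: float = 1.5
    crosswind_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.wind_speed <= 0:
            raise InvalidParameterError("wind speed must be > 0")
        if self.moisture <= 0:
            raise InvalidParameterError("moisture content must be > 0")
        if not 0.0 <= self.removal_rate <= 1.0:
            raise InvalidParameterError("removal rate must lie in [0, 1]")
        if self.disturbance_rate <= 0:
            raise InvalidParameterError("disturbance rate must be > 0")
        if self.bulk_density <= 0:
            raise InvalidParameterError("bulk density must be > 0")
        if self.stack_height < 0:
            raise InvalidParameterError("stack height must be >= 0")

    def replace(self, **kwargs) -> "StockpileScenario":
        return replace(self, **kwargs)


def emission_rate(scenario: StockpileScenario, pclass: ParticleClass) -> float:
    """Dust emission rate of the stockpile for one size class, mg/s.

    ER = V * rho_bulk * k * 0.0016 * (U/2.2)^1.3 / (M/2)^1.4 * (1 - eta),
    with V * rho_bulk the material throughput in Mg/s and the factor in
    kg dust per Mg handled, converted to mg/s.

    ER is zero exactly when the removal rate is 1, strictly increasing in
    wind speed and disturbance rate, strictly decreasing in moisture and
    removal rate.
    """
    throughput = scenario.disturbance_rate * scenario.bulk_density  # Mg/s
    factor_kg_per_mg = (
        pclass.size_multiplier
        * 0.0016
        * (scenario.wind_speed / 2.2) ** 1.3
        / (scenario.moisture / 2.0) ** 1.4
        * (1.0 - scenario.removal_rate)
    )
    return throughput * factor_kg_per_mg * 1.0e6  # kg/s -> mg/s
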