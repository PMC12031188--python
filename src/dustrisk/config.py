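"""Run configuration: unit-tagged JSON in, validated objects out.

A run config is a JSON document in which every physical quantity is either
a bare number in the field's canonical unit or a ``{"value": ..., "unit":
...}`` pair in any supported unit.  Unknown keys are rejected with their
key path, so typos fail loudly instead of silently falling back to
defaults.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

from .dispersion import CLASS_D_SCHEME, AtmosphericState, DispersionScheme, PowerLawBand
from .emission import DEFAULT_CLASSES, ParticleClass, StockpileScenario
from .errors import ConfigurationError
from .uncertainty import DEFAULT_DISTRIBUTIONS, ParameterDistribution

__all__ = ["RunConfig", "load_config", "config_hash", "DEFAULT_CONFIG"]

# unit -> (canonical unit, multiplicative factor to canonical)
_UNIT_CONVERSIONS: dict[str, tuple[str, float]] = {
    "m/s": ("m/s", 1.0),
    "m": ("m", 1.0),
    "percent": ("percent", 1.0),
    "fraction": ("fraction", 1.0),
    "m^3/s": ("m^3/s", 1.0),
    "m^3/h": ("m^3/s", 1.0 / 3600.0),
    "Mg/m^3": ("Mg/m^3", 1.0),
    "kg/m^3": ("kg/m^3", 1.0),
    "g/cm^3": ("kg/m^3", 1000.0),
    "ug/m^3": ("ug/m^3", 1.0),
    "mg/kg": ("mg/kg", 1.0),
}


def _quantity(raw: Any, canonical_unit: str, path: str) -> float:
    """Parse a bare number or a {"value", "unit"} pair into the canonical unit."""
    if isinstance(raw, (int, float)) and not isinstance(raw, bool):
        return float(raw)
    if isinstance(raw, Mapping):
        extra = set(raw) - {"value", "unit"}
        if extra:
            raise ConfigurationError(f"{path}: unexpected keys {sorted(extra)}")
        if "value" not in raw or "unit" not in raw:
            raise ConfigurationError(f"{path}: quantity needs both 'value' and 'unit'")
        unit = raw["unit"]
        if unit not in _UNIT_CONVERSIONS:
            raise ConfigurationError(f"{path}: unsupported unit {unit!r}")
        target, factor = _UNIT_CONVERSIONS[unit]
        if target != canonical_unit:
            raise ConfigurationError(
                f"{path}: unit {unit!r} is not convertible to {canonical_unit!r}"
            )
        return float(raw["value"]) * factor
    raise ConfigurationError(f"{path}: expected a number or a value/unit pair")


_SCENARIO_UNITS = {
    "wind_speed": "m/s",
    "moisture": "percent",
    "removal_rate": "fraction",
    "disturbance_rate": "m^3/s",
    "bulk_density": "Mg/m^3",
    "stack_height": "m",
    "receptor_height": "m",
    "crosswind_offset": "m",
}

_PCLASS_UNITS = {
    "diameter": "m",
    "size_multiplier": "fraction",
    "particle_density": "kg/m^3",
    "air_quality_limit": "ug/m^3",
}

_DIST_FIELDS = {"name", "family", "minimum", "maximum", "central"}


def _check_keys(block: Mapping, allowed: set[str], path: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigurationError(f"{path}: unknown keys {sorted(unknown)}")


def _parse_scenario(block: Mapping, path: str) -> StockpileScenario:
    _check_keys(block, set(_SCENARIO_UNITS), path)
    kwargs = {
        name: _quantity(raw, _SCENARIO_UNITS[name], f"{path}.{name}")
        for name, raw in block.items()
    }
    return StockpileScenario(**kwargs)


def _parse_pclasses(blocks: Sequence[Mapping], path: str) -> tuple[ParticleClass, ...]:
    classes = []
    for i, block in enumerate(blocks):
        p = f"{path}[{i}]"
        _check_keys(block, {"label"} | set(_PCLASS_UNITS), p)
        if "label" not in block:
            raise ConfigurationError(f"{p}: particle class needs a label")
        kwargs = {
            name: _quantity(block[name], unit, f"{p}.{name}")
            for name, unit in _PCLASS_UNITS.items()
            if name in block
        }
        classes.append(ParticleClass(label=block["label"], **kwargs))
    return tuple(classes)


def _parse_scheme(block: Mapping, path: str) -> DispersionScheme:
    _check_keys(block, {"stability", "sigma_y", "sigma_z"}, path)
    def bands(raw, p):
        out = []
        for i, b in enumerate(raw):
            _check_keys(b, {"x_upper", "alpha", "gamma"}, f"{p}[{i}]")
            x_upper = float(b["x_upper"]) if b["x_upper"] is not None else float("inf")
            out.append(PowerLawBand(x_upper, float(b["alpha"]), float(b["gamma"])))
        return out
    return DispersionScheme(
        block.get("stability", "custom"),
        bands(block["sigma_y"], f"{path}.sigma_y"),
        bands(block["sigma_z"], f"{path}.sigma_z"),
    )


def _parse_distributions(blocks: Sequence[Mapping], path: str) -> tuple[ParameterDistribution, ...]:
    dists = []
    for i, block in enumerate(blocks):
        p = f"{path}[{i}]"
        _check_keys(block, _DIST_FIELDS, p)
        missing = _DIST_FIELDS - set(block)
        if missing:
            raise ConfigurationError(f"{p}: missing keys {sorted(missing)}")
        dists.append(
            ParameterDistribution(
                block["name"], block["family"],
                float(block["minimum"]), float(block["maximum"]), float(block["central"]),
            )
        )
    return tuple(dists)


@dataclass(frozen=True)
class RunConfig:
    """Validated pipeline configuration."""

    seed: int
    scenario: StockpileScenario = StockpileScenario()
    particle_classes: tuple[ParticleClass, ...] = DEFAULT_CLASSES
    scheme: DispersionScheme = CLASS_D_SCHEME
    atm: AtmosphericState = AtmosphericState()
    distributions: tuple[ParameterDistribution, ...] = DEFAULT_DISTRIBUTIONS
    profile_distances: tuple[float, ...] = tuple(float(x) for x in range(100, 2001, 100))
    residential_distance: float = 500.0
    reference_distance: float = 1000.0
    exceedance_targets: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EXCEEDANCE_TARGETS)
    )
    enrichment: float = 2.0
    n_draws: int = 10000
    metal_contents_csv: str | None = None
    output_dir: str = "dustrisk_out"
    raw: Mapping[str, Any] | None = None


#: Default calibration targets: exceedance multiples at the 1000 m
#: reference point used to back out dust metal contents when no measured
#: content table is supplied.  Hg sits just below its limit; Pb moderately
#: and Cd/As/Cr(VI) strongly above.
DEFAULT_EXCEEDANCE_TARGETS: Mapping[str, float] = {
    "Cr(VI)": 131.5,
    "Cd": 51.8,
    "As": 23.6,
    "Pb": 5.3,
    "Hg": 0.9,
}

_TOP_KEYS = {
    "seed",
    "scenario",
    "particle_classes",
    "dispersion_scheme",
    "distributions",
    "profile_distances",
    "residential_distance",
    "reference_distance",
    "exceedance_targets",
    "enrichment",
    "n_draws",
    "metal_contents_csv",
    "output_dir",
}


def load_config(source: str | Path | Mapping[str, Any]) -> RunConfig:
    """Load and validate a run config from a JSON file or a mapping."""
    if isinstance(source, (str, Path)):
        raw = json.loads(Path(source).read_text())
    else:
        raw = dict(source)
    if not isinstance(raw, Mapping):
        raise ConfigurationError("config root must be a JSON object")
    _check_keys(raw, _TOP_KEYS, "config")
    if "seed" not in raw:
        raise ConfigurationError("config.seed: a seed is required (no hidden randomness)")
    if not isinstance(raw["seed"], int) or isinstance(raw["seed"], bool):
        raise ConfigurationError("config.seed: must be an integer")
    kwargs: dict[str, Any] = {"seed": raw["seed"], "raw": raw}
    if "scenario" in raw:
        kwargs["scenario"] = _parse_scenario(raw["scenario"], "config.scenario")
    if "particle_classes" in raw:
        kwargs["particle_classes"] = _parse_pclasses(
            raw["particle_classes"], "config.particle_classes"
        )
    if "dispersion_scheme" in raw:
        kwargs["scheme"] = _parse_scheme(raw["dispersion_scheme"], "config.dispersion_scheme")
    if "distributions" in raw:
        kwargs["distributions"] = _parse_distributions(
            raw["distributions"], "config.distributions"
        )
    for simple in (
        "residential_distance",
        "reference_distance",
        "enrichment",
        "n_draws",
        "metal_contents_csv",
        "output_dir",
    ):
        if simple in raw:
            kwargs[simple] = raw[simple]
    if "profile_distances" in raw:
        kwargs["profile_distances"] = tuple(float(x) for x in raw["profile_distances"])
    if "exceedance_targets" in raw:
        kwargs["exceedance_targets"] = dict(raw["exceedance_targets"])
    return RunConfig(**kwargs)


def config_hash(config: RunConfig) -> str:
    """Stable short hash identifying the configuration that produced a run.

    The output directory is excluded: it changes where artifacts land, not
    what they contain, and identical science must hash identically.
    """
    raw = dict(config.raw) if config.raw is not None else {"seed": config.seed, "defaults": True}
    raw.pop("output_dir", None)
    canonical = json.dumps(raw, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


DEFAULT_CONFIG: Mapping[str, Any] = {
    "seed": 20250415,
    "scenario": {
        "wind_speed": {"value": 2, "unit": "m/s"},
        "moisture": {"value": 30, "unit": "percent"},
        "removal_rate": {"value": 0.5, "unit": "fraction"},
        "disturbance_rate": {"value": 500, "unit": "m^3/h"},
        "bulk_density": {"value": 1.0, "unit": "Mg/m^3"},
        "stack_height": {"value": 15, "unit": "m"},
        "receptor_height": {"value": 1.5, "unit": "m"},
    },
    "residential_distance": 500.0,
    "reference_distance": 1000.0,
    "n_draws": 10000,
}
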