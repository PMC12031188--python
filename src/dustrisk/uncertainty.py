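"""Monte Carlo uncertainty propagation and one-at-a-time sensitivity.

Each uncertain scenario parameter is described by a bounded distribution
(minimum, maximum, central value).  The study scenario gives only central
values and ranges, so the family is a modelling choice: a truncated
lognormal matched to the stated mean is used when the mean sits off-centre
in the range (wind speed, disturbance rate), a triangular with the central
value as mode when it is interior, and a uniform when only bounds are
meaningful (removal rate).  All families sample by inverse-CDF on a seeded
generator, so ensembles are bit-reproducible.

Sensitivity follows the tornado convention: perturb one parameter to +/-25 %
of its default, re-run the emission -> dispersion chain, and report the
larger-over-smaller ratio of the selected output.  Uncertainty spans do the
same at the extremes of the parameter's full range.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq

from .dispersion import (
    CLASS_D_SCHEME,
    AtmosphericState,
    DispersionScheme,
    Receptor,
    plume_concentration,
)
from .emission import DEFAULT_CLASSES, PM25, ParticleClass, StockpileScenario, emission_rate
from .errors import ConfigurationError, InvalidParameterError
from .risk import MetalProfile, metal_air_concentration

__all__ = [
    "ParameterDistribution",
    "EnsembleResult",
    "DEFAULT_DISTRIBUTIONS",
    "sample_parameters",
    "run_monte_carlo",
    "cumulative_frequency",
    "exceedance_probability",
    "sensitivity_ratio",
    "uncertainty_span",
    "DEFAULT_SENSITIVITY_PARAMETERS",
]

_FAMILIES = ("uniform", "triangular", "truncated-lognormal")

#: Scenario fields a distribution may target, plus the two chain parameters
#: that live outside StockpileScenario.
_SCENARIO_FIELDS = (
    "wind_speed",
    "moisture",
    "removal_rate",
    "disturbance_rate",
    "bulk_density",
    "stack_height",
)
_EXTRA_PARAMETERS = ("particle_density", "distance")


@dataclass(frozen=True)
class ParameterDistribution:
    """Bounded distribution of one scenario parameter.

    ``central`` is the mean for the truncated lognormal, the mode for the
    triangular, and informational for the uniform.  Samples always fall in
    [minimum, maximum].
    """

    name: str
    family: str
    minimum: float
    maximum: float
    central: float

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ConfigurationError(
                f"{self.name}: unknown family {self.family!r}; choose from {_FAMILIES}"
            )
        if not self.minimum < self.maximum:
            raise ConfigurationError(f"{self.name}: require minimum < maximum")
        if self.family in ("triangular", "truncated-lognormal") and not (
            self.minimum <= self.central <= self.maximum
        ):
            raise ConfigurationError(
                f"{self.name}: central value {self.central} outside "
                f"[{self.minimum}, {self.maximum}]"
            )
        if self.family == "truncated-lognormal" and self.minimum <= 0:
            raise ConfigurationError(f"{self.name}: lognormal support requires minimum > 0")

    def _frozen(self):
        a, b, c = self.minimum, self.maximum, self.central
        if self.family == "uniform":
            return stats.uniform(loc=a, scale=b - a)
        if self.family == "triangular":
            return stats.triang(c=(c - a) / (b - a), loc=a, scale=b - a)
        # Truncated lognormal: fixed log-sd, log-mean solved so that the
        # truncated mean equals the stated central value.
        s = 0.5
        la, lb = math.log(a), math.log(b)

        def trunc_mean(mu: float) -> float:
            # E[exp(Y)] for a normal Y(mu, s) truncated to [la, lb]
            alpha, beta = (la - mu) / s, (lb - mu) / s
            num = stats.norm.cdf(beta - s) - stats.norm.cdf(alpha - s)
            den = stats.norm.cdf(beta) - stats.norm.cdf(alpha)
            if den <= 0:
                return math.inf
            return math.exp(mu + s * s / 2.0) * num / den

        lo, hi = la - 6 * s, lb + 6 * s
        try:
            mu = brentq(lambda m: trunc_mean(m) - c, lo, hi, xtol=1e-12)
        except ValueError as exc:  # pragma: no cover - guarded by __post_init__
            raise ConfigurationError(
                f"{self.name}: cannot match truncated-lognormal mean {c} on [{a}, {b}]"
            ) from exc
        alpha, beta = (la - mu) / s, (lb - mu) / s
        base = stats.truncnorm(alpha, beta, loc=mu, scale=s)

        class _TruncLognorm:
            def ppf(self, q):
                return np.exp(base.ppf(q))

        return _TruncLognorm()

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Inverse-CDF draws; clipped to the bounds against roundoff."""
        u = rng.random(n)
        x = self._frozen().ppf(u)
        return np.clip(x, self.minimum, self.maximum)


#: Study-scenario parameter uncertainty: central value and range of each
#: parameter.  Means off-centre in their range (wind speed, disturbance
#: rate) get the truncated lognormal; interior means the triangular;
#: removal rate spans its full physical range and is uniform.  The particle
#: density central/range is in kg/m^3 (1.21 g/cm^3 and its range).
DEFAULT_DISTRIBUTIONS: tuple[ParameterDistribution, ...] = (
    ParameterDistribution("wind_speed", "truncated-lognormal", 1.0, 6.0, 2.0),
    ParameterDistribution("stack_height", "triangular", 5.2, 19.0, 15.0),
    ParameterDistribution("moisture", "triangular", 21.0, 44.0, 30.0),
    ParameterDistribution("removal_rate", "uniform", 0.0, 1.0, 0.5),
    ParameterDistribution(
        "disturbance_rate", "truncated-lognormal", 250.0 / 3600.0, 2500.0 / 3600.0, 500.0 / 3600.0
    ),
    ParameterDistribution("particle_density", "triangular", 1030.0, 1360.0, 1210.0),
)


def sample_parameters(
    spec: Sequence[ParameterDistribution], n: int, seed: int
) -> pd.DataFrame:
    """Draw ``n`` joint parameter vectors (independent marginals), one column each."""
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return pd.DataFrame({dist.name: dist.sample(n, rng) for dist in spec})


@dataclass(frozen=True)
class EnsembleResult:
    """Monte Carlo ensemble: per-draw parameters and chain outputs."""

    parameters: pd.DataFrame
    outputs: pd.DataFrame
    seed: int
    n_draws: int

    def percentiles(self, qs: Sequence[float] = (5, 25, 50, 75, 95)) -> pd.DataFrame:
        return self.outputs.quantile([q / 100 for q in qs])


def _evaluate_chain(
    scenario: StockpileScenario,
    receptor: Receptor,
    pclasses: Sequence[ParticleClass],
    scheme: DispersionScheme,
    atm: AtmosphericState,
    profile: MetalProfile | None,
    density_override: float | None = None,
) -> dict[str, float]:
    out: dict[str, float] = {}
    conc_by_class: dict[str, float] = {}
    for pclass in pclasses:
        if density_override is not None:
            pclass = pclass.with_density(density_override)
        er = emission_rate(scenario, pclass)
        conc = plume_concentration(er, receptor, scenario, pclass, scheme, atm)
        out[f"conc_{pclass.label}"] = conc
        conc_by_class[pclass.label] = conc
    if profile is not None:
        risk_classes = {k: v for k, v in conc_by_class.items() if k in ("PM2.5", "PM10")}
        for metal in profile.metals:
            out[f"metal_{metal}"] = metal_air_concentration(profile, metal, risk_classes)
    return out


def run_monte_carlo(
    scenario: StockpileScenario,
    spec: Sequence[ParameterDistribution] = DEFAULT_DISTRIBUTIONS,
    n: int = 10000,
    seed: int = 0,
    receptor: Receptor | None = None,
    pclasses: Sequence[ParticleClass] = DEFAULT_CLASSES,
    scheme: DispersionScheme = CLASS_D_SCHEME,
    atm: AtmosphericState = AtmosphericState(),
    profile: MetalProfile | None = None,
) -> EnsembleResult:
    """Propagate parameter uncertainty through emission -> dispersion (-> metals).

    Every draw re-runs the full deterministic chain at the receptor (default
    1000 m downwind at the scenario receptor height).  Outputs are dust
    concentrations per size class (ug/m^3) and, when a metal profile is
    given, metal air concentrations.  A draw that fails invalidates the run.
    """
    receptor = receptor or Receptor(x=1000.0, y=scenario.crosswind_offset, z=scenario.receptor_height)
    params = sample_parameters(spec, n, seed)
    rows = []
    scenario_fields = [c for c in params.columns if c in _SCENARIO_FIELDS]
    for i in range(n):
        draw = params.iloc[i]
        try:
            scen_i = scenario.replace(**{f: float(draw[f]) for f in scenario_fields})
            density = float(draw["particle_density"]) if "particle_density" in params else None
            rec_i = (
                Receptor(float(draw["distance"]), receptor.y, receptor.z)
                if "distance" in params
                else receptor
            )
            rows.append(
                _evaluate_chain(scen_i, rec_i, pclasses, scheme, atm, profile, density)
            )
        except Exception as exc:
            raise InvalidParameterError(f"Monte Carlo draw {i} failed: {exc}") from exc
    outputs = pd.DataFrame(rows)
    if not np.isfinite(outputs.to_numpy()).all():
        raise InvalidParameterError("non-finite output in Monte Carlo ensemble")
    return EnsembleResult(parameters=params, outputs=outputs, seed=seed, n_draws=n)


def cumulative_frequency(values: Sequence[float]) -> pd.DataFrame:
    """Empirical CDF table: sorted values and cumulative frequency ending at 1."""
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise InvalidParameterError("no values supplied")
    freq = np.arange(1, v.size + 1) / v.size
    return pd.DataFrame({"value": v, "cumulative_frequency": freq})


def exceedance_probability(values: Sequence[float], limit: float) -> float:
    """Fraction of draws strictly above the limit."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise InvalidParameterError("no values supplied")
    return float(np.mean(v > limit))


#: Parameter -> default value for one-at-a-time perturbation.  Densities in
#: kg/m^3; disturbance rate in m^3/s; distance is the receptor's downwind x.
DEFAULT_SENSITIVITY_PARAMETERS: Mapping[str, float] = {
    "wind_speed": 2.0,
    "moisture": 30.0,
    "removal_rate": 0.5,
    "disturbance_rate": 500.0 / 3600.0,
    "stack_height": 15.0,
    "particle_density": 1210.0,
    "distance": 500.0,
}

#: Physical bounds applied when a +/-delta perturbation leaves the
#: admissible range (the perturbed value is clipped with a warning).
_PHYSICAL_BOUNDS: Mapping[str, tuple[float, float]] = {
    "removal_rate": (0.0, 1.0),
}


def _chain_output(
    parameter: str,
    value: float,
    scenario: StockpileScenario,
    receptor: Receptor,
    pclass: ParticleClass,
    scheme: DispersionScheme,
    atm: AtmosphericState,
) -> float:
    density = None
    if parameter in _SCENARIO_FIELDS:
        scenario = scenario.replace(**{parameter: value})
    elif parameter == "particle_density":
        density = value
    elif parameter == "distance":
        receptor = Receptor(value, receptor.y, receptor.z)
    else:
        raise InvalidParameterError(f"unknown sensitivity parameter: {parameter!r}")
    if density is not None:
        pclass = pclass.with_density(density)
    er = emission_rate(scenario, pclass)
    return plume_concentration(er, receptor, scenario, pclass, scheme, atm)


def sensitivity_ratio(
    parameter: str,
    delta: float = 0.25,
    *,
    scenario: StockpileScenario = StockpileScenario(),
    receptor: Receptor | None = None,
    pclass: ParticleClass = PM25,
    scheme: DispersionScheme = CLASS_D_SCHEME,
    atm: AtmosphericState = AtmosphericState(),
    default: float | None = None,
    output: Callable[[float], float] | None = None,
) -> float:
    """Tornado sensitivity: larger-over-smaller output ratio at +/-delta.

    By default the output is the PM2.5 exposure concentration at the
    residential receptor 500 m downwind; ``output`` may supply any other
    scalar function of the parameter value.  The ratio is >= 1 and equals 1
    when the output is flat in the parameter.
    """
    if default is None:
        default = DEFAULT_SENSITIVITY_PARAMETERS[parameter]
    receptor = receptor or Receptor(
        x=500.0, y=scenario.crosswind_offset, z=scenario.receptor_height
    )
    lo_val, hi_val = (1.0 - delta) * default, (1.0 + delta) * default
    if parameter in _PHYSICAL_BOUNDS:
        bmin, bmax = _PHYSICAL_BOUNDS[parameter]
        clipped = (max(lo_val, bmin), min(hi_val, bmax))
        if clipped != (lo_val, hi_val):
            warnings.warn(
                f"{parameter}: perturbed values clipped to physical bounds [{bmin}, {bmax}]",
                stacklevel=2,
            )
        lo_val, hi_val = clipped
    if output is None:
        output = lambda v: _chain_output(parameter, v, scenario, receptor, pclass, scheme, atm)
    a, b = output(lo_val), output(hi_val)
    if a < 0 or b < 0:
        raise InvalidParameterError("sensitivity output must be non-negative")
    if a == b:
        return 1.0
    if min(a, b) == 0.0:
        # one clipped endpoint shut the source off entirely (eta -> 1)
        return math.inf
    return max(a, b) / min(a, b)


def uncertainty_span(
    parameter: str,
    minimum: float | None = None,
    maximum: float | None = None,
    *,
    scenario: StockpileScenario = StockpileScenario(),
    receptor: Receptor | None = None,
    pclass: ParticleClass = PM25,
    scheme: DispersionScheme = CLASS_D_SCHEME,
    atm: AtmosphericState = AtmosphericState(),
    output: Callable[[float], float] | None = None,
) -> float:
    """Max/min output ratio over a parameter's full range, others at default.

    Bounds default to the study-scenario distribution of the parameter.
    """
    if minimum is None or maximum is None:
        for dist in DEFAULT_DISTRIBUTIONS:
            if dist.name == parameter:
                minimum = dist.minimum if minimum is None else minimum
                maximum = dist.maximum if maximum is None else maximum
                break
        else:
            raise ConfigurationError(f"no default range known for {parameter!r}")
    if minimum > maximum:
        raise InvalidParameterError("minimum must be <= maximum")
    if minimum == maximum:
        return 1.0
    receptor = receptor or Receptor(
        x=500.0, y=scenario.crosswind_offset, z=scenario.receptor_height
    )
    if output is None:
        output = lambda v: _chain_output(parameter, v, scenario, receptor, pclass, scheme, atm)
    a, b = output(minimum), output(maximum)
    if a <= 0 or b <= 0:
        raise InvalidParameterError("span output must be positive at both extremes")
    return max(a, b) / min(a, b)
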