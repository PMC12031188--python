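"""Inhalation exposure and heavy-metal risk characterisation.

Airborne dust carries metals in proportion to their content in the
particulate (mg metal per kg dust).  The chain is:

    intake      Q  = PM_i * DAIR * ED * PIAF * EF * 1e-6 / (BW * AT)
    cancer risk CR = Q * C * SF
    hazard quot HQ = Q * C / (RfD * SAF)

with PM_i the particulate concentration in mg/m^3 and C the metal content
in mg/kg; the 1e-6 factor makes Q a kg-dust per kg-bodyweight per day
quantity so that Q*C is a metal dose in mg/kg-d.

Two screening indices complement the dose-based risk numbers:

* PHI-E (potential environmental hazard index): metal content divided by
  the soil Class II screening value.
* PHI-H (potential health hazard index): the metal air concentration
  implied by dust at the ambient TSP limit, divided by the metal's ambient
  air limit: PHI-H = C * TSP_limit * 1e-6 / air_limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import constants
from .errors import InvalidParameterError, NoSolutionError

__all__ = [
    "ExposureParams",
    "ToxicityValues",
    "MetalProfile",
    "RiskTable",
    "intake",
    "cancer_risk",
    "hazard_quotient",
    "aggregate",
    "risk_table",
    "phi_e",
    "phi_h",
    "exceedance_multiple",
    "metal_air_concentration",
    "size_fraction_contribution",
    "calibrate_contents",
]

CARCINOGENIC = "carcinogenic"
NONCARCINOGENIC = "noncarcinogenic"


@dataclass(frozen=True)
class ExposureParams:
    """Adult inhalation exposure parameters (HJ 25.3-2019 defaults)."""

    DAIR: float = constants.DEFAULT_EXPOSURE["DAIR"]
    ED: float = constants.DEFAULT_EXPOSURE["ED"]
    EF: float = constants.DEFAULT_EXPOSURE["EF"]
    PIAF: float = constants.DEFAULT_EXPOSURE["PIAF"]
    BW: float = constants.DEFAULT_EXPOSURE["BW"]
    AT_carcinogenic: float = constants.DEFAULT_EXPOSURE["AT_carcinogenic"]
    AT_noncarcinogenic: float = constants.DEFAULT_EXPOSURE["AT_noncarcinogenic"]
    SAF: float = constants.DEFAULT_EXPOSURE["SAF"]

    def __post_init__(self) -> None:
        for name in (
            "DAIR",
            "ED",
            "EF",
            "PIAF",
            "BW",
            "AT_carcinogenic",
            "AT_noncarcinogenic",
            "SAF",
        ):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"exposure parameter {name} must be > 0")
        if self.PIAF > 1 or self.SAF > 1:
            raise InvalidParameterError("PIAF and SAF must lie in (0, 1]")


@dataclass(frozen=True)
class ToxicityValues:
    """Per-metal slope factors, reference doses and regulatory limits.

    ``table`` maps metal -> {"sf", "rfd", "air_limit", "soil_screening"};
    sf/rfd may be None for metals without the corresponding toxicity value.
    """

    table: Mapping[str, Mapping[str, float | None]] = field(
        default_factory=lambda: constants.DEFAULT_TOXICITY
    )

    def __post_init__(self) -> None:
        for metal, row in self.table.items():
            for key, value in row.items():
                if value is not None and value <= 0:
                    raise InvalidParameterError(f"{metal}.{key} must be > 0 if present")

    def sf(self, metal: str) -> float | None:
        return self.table[metal].get("sf")

    def rfd(self, metal: str) -> float | None:
        return self.table[metal].get("rfd")

    def air_limit(self, metal: str) -> float:
        return self.table[metal]["air_limit"]

    def soil_screening(self, metal: str) -> float:
        return self.table[metal]["soil_screening"]


@dataclass(frozen=True)
class MetalProfile:
    """Metal contents of the dust, mg metal per kg particulate, per size class.

    ``contents`` maps metal -> {class label -> content}.  This is the
    in-memory form of the measured (or calibrated, or synthesised) sample
    matrix after per-metal aggregation.
    """

    contents: Mapping[str, Mapping[str, float]]

    def __post_init__(self) -> None:
        for metal, per_class in self.contents.items():
            for label, c in per_class.items():
                if c < 0:
                    raise InvalidParameterError(f"{metal}/{label}: content must be >= 0")

    def content(self, metal: str, class_label: str) -> float:
        return self.contents[metal][class_label]

    @property
    def metals(self) -> tuple[str, ...]:
        return tuple(self.contents.keys())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"metal": m, "class": label, "content_mg_kg": c}
            for m, per_class in self.contents.items()
            for label, c in per_class.items()
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MetalProfile":
        contents: dict[str, dict[str, float]] = {}
        for row in df.to_dict("records"):
            contents.setdefault(row["metal"], {})[row["class"]] = float(row["content_mg_kg"])
        return cls(contents)


def intake(pmi_mg_m3: float, params: ExposureParams = ExposureParams(), averaging: str = CARCINOGENIC) -> float:
    """Chronic daily particulate intake per unit body weight, kg-dust/kg-bw/d.

    Linear in the particulate concentration; the averaging label selects the
    lifetime (carcinogenic) or exposure-duration (non-carcinogenic)
    averaging time.
    """
    if pmi_mg_m3 < 0:
        raise InvalidParameterError("particulate concentration must be >= 0")
    if averaging == CARCINOGENIC:
        at = params.AT_carcinogenic
    elif averaging == NONCARCINOGENIC:
        at = params.AT_noncarcinogenic
    else:
        raise InvalidParameterError(f"unknown averaging label: {averaging!r}")
    return pmi_mg_m3 * params.DAIR * params.ED * params.PIAF * params.EF * 1e-6 / (params.BW * at)


def cancer_risk(q: float, content_mg_kg: float, sf: float | None) -> float | None:
    """Lifetime excess cancer risk CR = Q * C * SF; None when SF is absent."""
    if sf is None:
        return None
    if min(q, content_mg_kg, sf) < 0:
        raise InvalidParameterError("Q, C and SF must be >= 0")
    return q * content_mg_kg * sf


def hazard_quotient(
    q: float, content_mg_kg: float, rfd: float | None, saf: float = constants.DEFAULT_EXPOSURE["SAF"]
) -> float | None:
    """Non-carcinogenic hazard quotient HQ = Q * C / (RfD * SAF); None without RfD."""
    if rfd is None:
        return None
    if rfd <= 0 or saf <= 0:
        raise InvalidParameterError("RfD and SAF must be > 0")
    if min(q, content_mg_kg) < 0:
        raise InvalidParameterError("Q and C must be >= 0")
    return q * content_mg_kg / (rfd * saf)


@dataclass(frozen=True)
class RiskTable:
    """Per-metal, per-class CR and HQ with exact column and grand totals."""

    cells: pd.DataFrame  # columns: metal, class, CR, HQ (NaN = absent)
    class_totals: pd.DataFrame  # columns: class, CR_total, HQ_total
    cr_total: float
    hq_total: float

    def cell(self, metal: str, class_label: str, kind: str) -> float:
        sel = self.cells[(self.cells["metal"] == metal) & (self.cells["class"] == class_label)]
        return float(sel[kind].iloc[0])

    def exceeds_limits(
        self, cr_limit: float = constants.CR_LIMIT, hq_limit: float = constants.HQ_LIMIT
    ) -> dict[str, bool]:
        return {"CR": self.cr_total > cr_limit, "HQ": self.hq_total > hq_limit}


def aggregate(cells: Iterable[Mapping]) -> RiskTable:
    """Assemble per-metal/per-class CR and HQ cells into a risk table.

    ``cells`` is an iterable of mappings with keys metal, class, CR, HQ
    (CR/HQ may be None/NaN for absent entries).  Totals are plain sums of
    the present cells, per class and grand.
    """
    df = pd.DataFrame(list(cells))
    if df.empty:
        raise InvalidParameterError("no risk cells supplied")
    for col in ("CR", "HQ"):
        if col not in df:
            df[col] = np.nan
        df[col] = df[col].astype(float)
    totals = (
        df.groupby("class", sort=False)[["CR", "HQ"]]
        .sum(min_count=1)
        .rename(columns={"CR": "CR_total", "HQ": "HQ_total"})
        .reset_index()
    )
    return RiskTable(
        cells=df[["metal", "class", "CR", "HQ"]],
        class_totals=totals,
        cr_total=float(df["CR"].sum(skipna=True)),
        hq_total=float(df["HQ"].sum(skipna=True)),
    )


def risk_table(
    profile: MetalProfile,
    conc_by_class: Mapping[str, float],
    params: ExposureParams = ExposureParams(),
    tox: ToxicityValues = ToxicityValues(),
    metals: Iterable[str] = constants.RISK_METALS,
) -> RiskTable:
    """Full risk table from a metal profile and class concentrations (ug/m^3)."""
    cells = []
    for metal in metals:
        for label, conc_ug_m3 in conc_by_class.items():
            pmi = conc_ug_m3 * 1e-3  # ug/m^3 -> mg/m^3
            c = profile.content(metal, label)
            qc = intake(pmi, params, CARCINOGENIC)
            qn = intake(pmi, params, NONCARCINOGENIC)
            cells.append(
                {
                    "metal": metal,
                    "class": label,
                    "CR": cancer_risk(qc, c, tox.sf(metal)),
                    "HQ": hazard_quotient(qn, c, tox.rfd(metal), params.SAF),
                }
            )
    return aggregate(cells)


def phi_e(content_mg_kg: float, soil_screening_mg_kg: float) -> float:
    """Potential environmental hazard index: content over soil screening value."""
    if soil_screening_mg_kg <= 0:
        raise InvalidParameterError("soil screening value must be > 0")
    if content_mg_kg < 0:
        raise InvalidParameterError("content must be >= 0")
    return content_mg_kg / soil_screening_mg_kg


def phi_h(
    content_mg_kg: float,
    air_limit_ug_m3: float,
    tsp_limit_ug_m3: float = constants.TSP_LIMIT,
) -> float:
    """Potential health hazard index.

    The metal concentration implied by dust at the ambient TSP limit
    (content * TSP_limit * 1e-6, ug/m^3) divided by the metal's ambient air
    limit.  The 1e-6 converts the mg/kg content to a mass fraction.
    """
    if air_limit_ug_m3 <= 0 or tsp_limit_ug_m3 <= 0:
        raise InvalidParameterError("limits must be > 0")
    if content_mg_kg < 0:
        raise InvalidParameterError("content must be >= 0")
    return content_mg_kg * tsp_limit_ug_m3 * 1e-6 / air_limit_ug_m3


def exceedance_multiple(metal_conc_ug_m3: float, air_limit_ug_m3: float) -> float:
    """Ratio of a metal's air concentration to its ambient limit (>1 = exceedance)."""
    if air_limit_ug_m3 <= 0:
        raise InvalidParameterError("air limit must be > 0")
    if metal_conc_ug_m3 < 0:
        raise InvalidParameterError("concentration must be >= 0")
    return metal_conc_ug_m3 / air_limit_ug_m3


def metal_air_concentration(
    profile: MetalProfile, metal: str, conc_by_class: Mapping[str, float]
) -> float:
    """Airborne concentration of one metal, ug/m^3.

    Sum over size classes of dust concentration times the metal's mass
    fraction in that class (content in mg/kg is 1e-6 kg per kg).
    """
    return sum(
        conc * profile.content(metal, label) * 1e-6 for label, conc in conc_by_class.items()
    )


def size_fraction_contribution(
    profile: MetalProfile, metal: str, conc_by_class: Mapping[str, float]
) -> dict[str, float]:
    """Fraction of a metal's airborne concentration carried by each size class."""
    parts = {
        label: conc * profile.content(metal, label) * 1e-6
        for label, conc in conc_by_class.items()
    }
    total = sum(parts.values())
    if total <= 0:
        raise NoSolutionError(f"{metal}: zero airborne concentration in every class")
    return {label: p / total for label, p in parts.items()}


def calibrate_contents(
    target_multiples: Mapping[str, float],
    conc_by_class: Mapping[str, float],
    tox: ToxicityValues = ToxicityValues(),
    *,
    pm25_label: str = "PM2.5",
    pm10_label: str = "PM10",
    enrichment: float = 2.0,
) -> MetalProfile:
    """Back-calculate dust metal contents from target exceedance multiples.

    Given the model's dust concentrations at a reference distance and a
    target exceedance multiple per metal, solve the linear relation
    metal_air_concentration(C) = multiple * air_limit for the contents,
    splitting each metal across size fractions by a fixed PM2.5/PM10
    enrichment ratio.  This supplies a working measurement matrix when the
    underlying sample data are not available.
    """
    if enrichment <= 0:
        raise InvalidParameterError("enrichment ratio must be > 0")
    c25 = conc_by_class.get(pm25_label, 0.0)
    c10 = conc_by_class.get(pm10_label, 0.0)
    denom = (enrichment * c25 + c10) * 1e-6
    if denom <= 0:
        raise NoSolutionError("model dust concentration is zero at the reference point")
    contents: dict[str, dict[str, float]] = {}
    for metal, multiple in target_multiples.items():
        if multiple < 0:
            raise InvalidParameterError(f"{metal}: target multiple must be >= 0")
        pm10_content = multiple * tox.air_limit(metal) / denom
        contents[metal] = {
            pm10_label: pm10_content,
            pm25_label: enrichment * pm10_content,
        }
    return MetalProfile(contents)
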