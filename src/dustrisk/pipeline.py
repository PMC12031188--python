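"""End-to-end pipeline: emission -> dispersion -> risk -> uncertainty.

``run_pipeline`` takes a validated :class:`~dustrisk.config.RunConfig` and
writes the full artifact bundle — concentration profiles, the per-metal
risk table, Monte Carlo summary, tornado sensitivities and a run log — into
the configured output directory.  Outputs are staged in a temporary
directory and moved into place only when every stage has succeeded, so a
failed run never leaves partial artifacts; every file is traceable to the
config hash recorded in the log and summary.
"""

from __future__ import annotations

import json
import shutil
import tempfile
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import constants
from .config import RunConfig, config_hash
from .dispersion import (
    Receptor,
    compliance_distance,
    concentration_profile,
    particle_concentration_fn,
)
from .emission import emission_rate
from .risk import (
    MetalProfile,
    RiskTable,
    ToxicityValues,
    calibrate_contents,
    exceedance_multiple,
    metal_air_concentration,
    risk_table,
    size_fraction_contribution,
)
from .uncertainty import (
    DEFAULT_SENSITIVITY_PARAMETERS,
    exceedance_probability,
    run_monte_carlo,
    sensitivity_ratio,
)

__all__ = ["PipelineResult", "run_pipeline", "resolve_profile", "headline_report"]

try:  # single source of truth for the version string
    from importlib.metadata import version as _pkg_version

    _VERSION = _pkg_version("dustrisk")
except Exception:  # pragma: no cover
    _VERSION = "unknown"


@dataclass(frozen=True)
class PipelineResult:
    """Paths and headline numbers of one pipeline run."""

    output_dir: Path
    files: dict[str, Path]
    risk: RiskTable
    residential_conc: dict[str, float]
    exceedance: dict[str, float]
    compliance: dict[str, float | None]


def resolve_profile(config: RunConfig, tox: ToxicityValues = ToxicityValues()) -> MetalProfile:
    """Metal contents for the run: measured CSV if given, else calibrated.

    Without a measured content table the contents are back-calculated so the
    modelled exceedance multiples at the reference distance match the
    configured targets.
    """
    if config.metal_contents_csv is not None:
        return MetalProfile.from_frame(pd.read_csv(config.metal_contents_csv))
    ref_conc = _class_concentrations(config, config.reference_distance)
    risk_conc = {k: v for k, v in ref_conc.items() if k in ("PM2.5", "PM10")}
    return calibrate_contents(
        dict(config.exceedance_targets), risk_conc, tox, enrichment=config.enrichment
    )


def _class_concentrations(config: RunConfig, x: float) -> dict[str, float]:
    out = {}
    for pclass in config.particle_classes:
        fn = particle_concentration_fn(config.scenario, pclass, config.scheme, config.atm)
        out[pclass.label] = float(fn(x))
    return out


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run every stage and write the artifact bundle atomically."""
    tox = ToxicityValues()
    profile = resolve_profile(config, tox)
    chash = config_hash(config)
    meta = {"config_hash": chash, "seed": config.seed, "package_version": _VERSION}

    # Stage 1: emission rates.
    er_rows = [
        {"class": p.label, "ER_mg_per_s": emission_rate(config.scenario, p)}
        for p in config.particle_classes
    ]

    # Stage 2: concentration profiles and compliance distances.
    profile_df = concentration_profile(
        config.profile_distances, config.scenario, config.particle_classes,
        config.scheme, config.atm,
    )
    compliance: dict[str, float | None] = {}
    for pclass in config.particle_classes:
        fn = particle_concentration_fn(config.scenario, pclass, config.scheme, config.atm)
        res = compliance_distance(pclass.air_quality_limit, fn)
        compliance[pclass.label] = res.distance if res.attained else None
    risk_class_labels = [p.label for p in config.particle_classes if p.label in ("PM2.5", "PM10")]
    for metal in profile.metals:
        fns = {
            p.label: particle_concentration_fn(config.scenario, p, config.scheme, config.atm)
            for p in config.particle_classes
            if p.label in risk_class_labels
        }
        metal_fn = lambda x, fns=fns, metal=metal: metal_air_concentration(
            profile, metal, {label: fn(x) for label, fn in fns.items()}
        )
        res = compliance_distance(tox.air_limit(metal), metal_fn)
        compliance[metal] = res.distance if res.attained else None

    # Stage 3: residential risk table, exceedance and size-fraction shares.
    res_conc = _class_concentrations(config, config.residential_distance)
    risk_conc = {k: v for k, v in res_conc.items() if k in ("PM2.5", "PM10")}
    table = risk_table(profile, risk_conc, tox=tox)
    ref_conc = {
        k: v
        for k, v in _class_concentrations(config, config.reference_distance).items()
        if k in ("PM2.5", "PM10")
    }
    exceed = {
        metal: exceedance_multiple(
            metal_air_concentration(profile, metal, ref_conc), tox.air_limit(metal)
        )
        for metal in profile.metals
    }
    shares = {
        metal: size_fraction_contribution(profile, metal, ref_conc)
        for metal in profile.metals
    }

    # Stage 4: Monte Carlo and sensitivity.
    ensemble = run_monte_carlo(
        config.scenario,
        config.distributions,
        n=config.n_draws,
        seed=config.seed,
        receptor=Receptor(
            config.reference_distance,
            config.scenario.crosswind_offset,
            config.scenario.receptor_height,
        ),
        pclasses=config.particle_classes,
        scheme=config.scheme,
        atm=config.atm,
        profile=profile,
    )
    mc_summary = {
        "meta": meta,
        "n_draws": ensemble.n_draws,
        "percentiles": {
            col: {str(q): float(v) for q, v in ensemble.percentiles()[col].items()}
            for col in ensemble.outputs.columns
        },
        "exceedance_probability": {
            metal: exceedance_probability(
                ensemble.outputs[f"metal_{metal}"], tox.air_limit(metal)
            )
            for metal in profile.metals
            if f"metal_{metal}" in ensemble.outputs
        },
    }
    receptor = Receptor(
        config.residential_distance,
        config.scenario.crosswind_offset,
        config.scenario.receptor_height,
    )
    sens_rows = []
    for name in DEFAULT_SENSITIVITY_PARAMETERS:
        ratio = sensitivity_ratio(name, scenario=config.scenario, receptor=receptor,
                                  scheme=config.scheme, atm=config.atm)
        sens_rows.append({"parameter": name, "ratio": ratio})

    risk_summary = {
        "meta": meta,
        "residential_distance_m": config.residential_distance,
        "residential_concentration_ug_m3": res_conc,
        "CR_total": table.cr_total,
        "HQ_total": table.hq_total,
        "limits_exceeded": table.exceeds_limits(),
        "exceedance_multiples_at_reference": exceed,
        "size_fraction_contribution_at_reference": shares,
        "compliance_distance_m": compliance,
    }

    # Write everything atomically: stage into a temp dir, then move.
    out_dir = Path(config.output_dir)
    staging = Path(tempfile.mkdtemp(prefix="dustrisk_"))
    files: dict[str, Path] = {}
    try:
        def _csv(name: str, df: pd.DataFrame) -> None:
            df.to_csv(staging / name, index=False)
            files[name] = out_dir / name

        def _json(name: str, obj) -> None:
            (staging / name).write_text(json.dumps(obj, indent=2, sort_keys=True))
            files[name] = out_dir / name

        _csv("emission.csv", pd.DataFrame(er_rows))
        _csv("profile.csv", profile_df)
        _csv("metal_contents.csv", profile.to_frame())
        _csv("risk_table.csv", table.cells)
        _csv("sensitivity.csv", pd.DataFrame(sens_rows))
        _csv("mc_draws.csv", pd.concat([ensemble.parameters, ensemble.outputs], axis=1))
        _json("risk_summary.json", risk_summary)
        _json("mc_summary.json", mc_summary)
        log_lines = [
            f"dustrisk {_VERSION}",
            f"config_hash {chash}",
            f"seed {config.seed}",
            f"n_draws {config.n_draws}",
            "stages emission,dispersion,risk,monte_carlo,sensitivity",
        ]
        (staging / "run.log").write_text("\n".join(log_lines) + "\n")
        files["run.log"] = out_dir / "run.log"

        out_dir.mkdir(parents=True, exist_ok=True)
        for name in files:
            shutil.move(str(staging / name), str(files[name]))
    finally:
        shutil.rmtree(staging, ignore_errors=True)

    return PipelineResult(
        output_dir=out_dir,
        files=files,
        risk=table,
        residential_conc=res_conc,
        exceedance=exceed,
        compliance=compliance,
    )


def headline_report(result: PipelineResult) -> str:
    """Human-readable summary of the run's headline numbers."""
    lines = ["Stockpile dust risk summary", "=" * 28]
    lines.append("Residential receptor concentrations (ug/m^3):")
    for label, conc in result.residential_conc.items():
        lines.append(f"  {label:6s} {conc:10.4g}")
    lines.append(
        f"Total carcinogenic risk  CR = {result.risk.cr_total:.3g} "
        f"(limit {constants.CR_LIMIT:g}; {'EXCEEDED' if result.risk.cr_total > constants.CR_LIMIT else 'ok'})"
    )
    lines.append(
        f"Total hazard quotient    HQ = {result.risk.hq_total:.3g} "
        f"(limit {constants.HQ_LIMIT:g}; {'EXCEEDED' if result.risk.hq_total > constants.HQ_LIMIT else 'ok'})"
    )
    lines.append("Exceedance multiples at the reference distance:")
    for metal, mult in sorted(result.exceedance.items(), key=lambda kv: -kv[1]):
        lines.append(f"  {metal:7s} {mult:8.1f}x")
    lines.append("Compliance distances (m):")
    for key, dist in result.compliance.items():
        lines.append(f"  {key:7s} {'not attained in window' if dist is None else f'{dist:8.0f}'}")
    return "\n".join(lines)
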