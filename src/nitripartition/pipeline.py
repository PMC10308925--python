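"""End-to-end orchestration: simulate → partition → sip → qpcr.

`run_experiment` executes the requested stages in order against one output
directory, writing human-readable CSV tables plus a machine JSON report.
Every artifact carries a provenance block (package version, global seed,
config hash), and identical configs yield byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import (
    FRESHWATER_SALINITY,
    SALINE_SALINITY,
    GradientConfig,
    InputError,
    MicrocosmConfig,
    TaxonBand,
    default_gradient_config,
    default_microcosm_config,
)
from .gradient import simulate_gradient
from .io import (
    config_hash,
    read_fraction_table,
    read_timeseries,
    write_csv,
    write_fraction_table,
    write_timeseries,
)
from .microcosm import simulate_microcosm
from .qpcr import StandardCurve, fit_standard_curve, fold_change, quantify, synthetic_cq
from .rates import check_dnra_control, fit_rate, partition_guilds, treatment_par
from .sip import detect_labeling

__all__ = ["RunConfig", "run_experiment", "default_bands", "STAGES"]

log = logging.getLogger("nitripartition")

STAGES = ("simulate", "partition", "sip", "qpcr")

#: GC contents placing unlabeled peaks at fractions 12 (AOA), 11 (AOB) and
#: 10 (comammox) of the default gradient; excess ¹³C per one-fraction shift
#: is 0.0085 / 0.036 ≈ 0.236.
_GC = {"AOA": 0.31122, "AOB": 0.39796, "CMX": 0.48469}
_SHIFT_FRACTIONS = {
    # (condition) → target → peak shift in fractions under 13CO2
    "freshwater": {"AOA": 2, "AOB": 2, "CMX": 1},
    "saline": {"AOA": 2, "AOB": 1, "CMX": 0},
}
_TOTAL_COPIES = {
    "freshwater": {"AOA": 5e6, "AOB": 8e6, "CMX": 1.5e7},
    "saline": {"AOA": 6e6, "AOB": 1.2e7, "CMX": 5e6},
}
_EXCESS_PER_FRACTION = 0.0085 / 0.036


def default_bands(condition: str, isotope: str) -> list[TaxonBand]:
    """Taxon bands emulating the observed fraction profiles per condition."""
    if condition not in _SHIFT_FRACTIONS:
        raise InputError(f"condition must be freshwater or saline, got {condition!r}")
    if isotope not in ("12C", "13C"):
        raise InputError(f"isotope must be 12C or 13C, got {isotope!r}")
    bands = []
    for target, gc in _GC.items():
        shift = _SHIFT_FRACTIONS[condition][target] if isotope == "13C" else 0
        bands.append(
            TaxonBand(
                name=target,
                gc=gc,
                atom13c_excess=shift * _EXCESS_PER_FRACTION,
                total_copies=_TOTAL_COPIES[condition][target],
            )
        )
    return bands


@dataclass(frozen=True)
class RunConfig:
    """Declarative description of one pipeline run."""

    stages: tuple[str, ...] = STAGES
    out_dir: str = "results"
    seed: int = 0
    salinities: tuple[float, ...] = (FRESHWATER_SALINITY, SALINE_SALINITY)
    n_replicates: int = 3
    sample_times: tuple[float, ...] = (0.0, 12.0, 24.0, 36.0, 48.0, 60.0, 72.0)
    saline_exclude_before: float = 12.0
    microcosm: MicrocosmConfig | None = None
    gradient: GradientConfig | None = None
    timeseries_path: str | None = None
    fractions_path: str | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise InputError(f"unknown stage(s) {unknown}; valid stages: {STAGES}")

    @classmethod
    def from_dict(cls, data: Mapping) -> "RunConfig":
        data = dict(data)
        if "microcosm" in data and isinstance(data["microcosm"], Mapping):
            base = dataclasses.asdict(default_microcosm_config())
            base.update(data["microcosm"])
            base["dose_schedule"] = tuple(
                tuple(d) for d in base.get("dose_schedule", ())
            )
            data["microcosm"] = MicrocosmConfig(**base)
        if "gradient" in data and isinstance(data["gradient"], Mapping):
            data["gradient"] = GradientConfig(**data["gradient"])
        for key in ("stages", "salinities", "sample_times"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as handle:
            return cls.from_dict(yaml.safe_load(handle) or {})

    def hash(self) -> str:
        # output location and verbosity do not affect scientific content
        payload = dataclasses.asdict(self)
        payload.pop("out_dir", None)
        payload.pop("log_level", None)
        return config_hash(payload)


def _exclusion_for(config: RunConfig, salinity: float) -> float:
    return config.saline_exclude_before if salinity >= 1.0 else 0.0


def _stage_simulate(config: RunConfig, out: Path, provenance: dict) -> dict:
    mc = (config.microcosm or default_microcosm_config()).with_(seed=config.seed)
    gc = config.gradient or default_gradient_config(seed=config.seed)
    series = [
        simulate_microcosm(mc, treatment, salinity, config.sample_times,
                           replicate_seed=rep)
        for salinity in config.salinities
        for treatment in ("I", "II", "III", "IV")
        for rep in range(1, config.n_replicates + 1)
    ]
    ts_path = write_timeseries(series, out / "timeseries.csv", provenance)

    tables = []
    gradient_seed = config.seed
    for salinity in config.salinities:
        condition = "saline" if salinity >= 1.0 else "freshwater"
        for isotope in ("12C", "13C"):
            for rep in range(1, config.n_replicates + 1):
                gradient_seed += 1
                gcfg = dataclasses.replace(gc, seed=gradient_seed)
                tables.append(
                    simulate_gradient(
                        gcfg,
                        default_bands(condition, isotope),
                        gradient_id=f"{condition}-{isotope}-r{rep}",
                        condition=condition,
                        isotope=isotope,
                        replicate=rep,
                    )
                )
    fr_path = write_fraction_table(
        pd.concat(tables, ignore_index=True), out / "fractions.csv", provenance
    )
    log.info("simulate: wrote %d series and %d gradients", len(series), len(tables))
    return {"timeseries": str(ts_path), "fractions": str(fr_path)}


def _stage_partition(config: RunConfig, out: Path, provenance: dict) -> dict:
    path = config.timeseries_path or out / "timeseries.csv"
    if not Path(path).exists():
        raise InputError(
            f"partition stage needs a time-series file ({path} not found); "
            "run the simulate stage first or set timeseries_path"
        )
    series = read_timeseries(path)
    rows = []
    for salinity in sorted({s.salinity for s in series}):
        exclude = _exclusion_for(config, salinity)
        pars = {}
        for treatment in ("I", "II", "III"):
            fits = [
                fit_rate(s, exclude_before=exclude)
                for s in series
                if s.treatment == treatment and s.salinity == salinity
            ]
            if not fits:
                raise InputError(
                    f"partition needs treatments I–III at salinity {salinity}%"
                )
            pars[treatment] = treatment_par(treatment, salinity, fits)
        result = partition_guilds(pars["I"], pars["II"], pars["III"])
        controls = [s for s in series if s.treatment == "IV" and s.salinity == salinity]
        dnra_ok = all(check_dnra_control(s)[0] for s in controls) if controls else None
        rows.append(
            {
                "salinity": salinity,
                "par_I": pars["I"].par, "par_I_sd": pars["I"].sd,
                "par_II": pars["II"].par, "par_II_sd": pars["II"].sd,
                "par_III": pars["III"].par, "par_III_sd": pars["III"].sd,
                "par_aoa": result.par_aoa, "par_aoa_sd": result.par_aoa_sd,
                "par_aob": result.par_aob, "par_aob_sd": result.par_aob_sd,
                "par_cmx": result.par_cmx, "par_cmx_sd": result.par_cmx_sd,
                "contrib_aoa_pct": result.contrib_aoa,
                "contrib_aob_pct": result.contrib_aob,
                "contrib_cmx_pct": result.contrib_cmx,
                "dnra_control_ok": dnra_ok,
            }
        )
        log.info(
            "partition: salinity %s%% → AOA %.2f, AOB %.2f, comammox %.2f "
            "mg N/day/kg", salinity, result.par_aoa, result.par_aob, result.par_cmx
        )
    path_out = write_csv(pd.DataFrame(rows), out / "partition.csv", provenance)
    return {"partition": str(path_out)}


def _stage_sip(config: RunConfig, out: Path, provenance: dict) -> dict:
    path = config.fractions_path or out / "fractions.csv"
    if not Path(path).exists():
        raise InputError(
            f"sip stage needs a fraction table ({path} not found); "
            "run the simulate stage first or set fractions_path"
        )
    frame = read_fraction_table(path)
    targets = [c for c in frame.columns
               if c not in ("gradient_id", "condition", "isotope", "replicate",
                            "fraction", "density_g_ml", "refractive_index")]
    rows = []
    for condition, group in frame.groupby("condition"):
        for rep, pair in group.groupby("replicate"):
            t12 = pair[pair["isotope"] == "12C"]
            t13 = pair[pair["isotope"] == "13C"]
            if t12.empty or t13.empty:
                raise InputError(
                    f"condition {condition!r} replicate {rep} lacks a 12C/13C pair"
                )
            for target in targets:
                res = detect_labeling(t12, t13, target)
                rows.append(
                    {
                        "condition": condition,
                        "replicate": int(rep),
                        "target": target,
                        "wmd_12c": res.wmd_12c,
                        "wmd_13c": res.wmd_13c,
                        "delta_wmd": res.delta_wmd,
                        "peak_12c": res.peak_12c,
                        "peak_13c": res.peak_13c,
                        "labeled": res.labeled,
                    }
                )
    path_out = write_csv(pd.DataFrame(rows), out / "sip_results.csv", provenance)
    log.info("sip: %d labeling calls written", len(rows))
    return {"sip_results": str(path_out)}


def _stage_qpcr(config: RunConfig, out: Path, provenance: dict) -> dict:
    """Demonstration qPCR stage on synthetic assays.

    Builds a noisy dilution series per target from a plausible true curve,
    fits the standard curve, then quantifies synthetic day-0 / day-18
    comammox samples and reports the abundance fold change.
    """
    rng = np.random.default_rng(int(config.seed) % 2**31 + 17)
    true = StandardCurve("true", slope=-3.55, intercept=38.0, r2=1.0,
                         efficiency=0.0, qc_pass=True)
    curve_rows, abundance_rows = [], []
    for target in ("AOA", "AOB", "CMX"):
        dilutions = [
            (lg, synthetic_cq(10.0**lg, true, noise_sd=0.15, rng=rng))
            for lg in range(1, 8)
        ]
        curve = fit_standard_curve(dilutions, target=target)
        curve_rows.append(
            {"target": target, "slope": curve.slope, "intercept": curve.intercept,
             "r2": curve.r2, "efficiency": curve.efficiency, "qc_pass": curve.qc_pass}
        )
        if target == "CMX":
            for sample, copies_per_g in (("day0", 5e6), ("day18_freshwater", 1.5e7)):
                copies_per_ul = copies_per_g * (1.0 / 30.0) * 0.16 / 30.0
                cq = synthetic_cq(copies_per_ul, curve, noise_sd=0.15, rng=rng)
                abundance_rows.append(
                    {"target": target, "sample": sample,
                     "copies_per_g": quantify(cq, curve)}
                )
    curves_path = write_csv(pd.DataFrame(curve_rows), out / "qpcr_curves.csv", provenance)
    fc = fold_change(abundance_rows[0]["copies_per_g"], abundance_rows[1]["copies_per_g"])
    abund = pd.DataFrame(abundance_rows)
    abund["fold_change_vs_day0"] = [1.0, fc]
    abund_path = write_csv(abund, out / "qpcr_abundance.csv", provenance)
    log.info("qpcr: comammox fold change %.2f", fc)
    return {"qpcr_curves": str(curves_path), "qpcr_abundance": str(abund_path)}


def run_experiment(config: RunConfig) -> dict:
    """Execute the requested stages; returns (and writes) the run report."""
    logging.basicConfig(
        level=getattr(logging, config.log_level.upper(), logging.INFO),
        format="%(name)s %(levelname)s %(message)s",
    )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance = {"seed": config.seed, "config_hash": config.hash()}
    report: dict = {
        "package": f"nitripartition {__version__}",
        "seed": config.seed,
        "config_hash": config.hash(),
        "stages": {},
    }
    runners = {
        "simulate": _stage_simulate,
        "partition": _stage_partition,
        "sip": _stage_sip,
        "qpcr": _stage_qpcr,
    }
    for stage in config.stages:
        log.info("running stage %s", stage)
        report["stages"][stage] = runners[stage](config, out, provenance)
    report_path = out / "run_report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n",
                           encoding="utf-8")
    report["report_path"] = str(report_path)
    return report
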