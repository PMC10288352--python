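"""End-to-end orchestration: simulate or load inputs, run every analysis
stage, and emit one structured, deterministic report.

A run consumes either a simulation *scenario* (JSON dict, schema below) or
a set of CSV input paths — exactly one of the two. The default scenario
regenerates every input with the constants the analyses are expected to
recover, so ``run_pipeline(PipelineConfig())`` doubles as a full
reproduction of the characterization workflow.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import io
from .activity import fit_ic50, reversibility_test
from .fluorescence import (
    DIFFUSION_LIMIT,
    analyze_titration,
    classify_quenching,
    stern_volmer_fit,
)
from .kinetics import fit_primary_lines, fit_secondary, lineweaver_burk_transform
from .params import KineticParams, NoiseModel, QuenchParams, TitrationScheme
from .simulate import (
    DEFAULT_INHIBITOR_GRID,
    DEFAULT_SUBSTRATE_GRID,
    simulate_dose_response,
    simulate_enzyme_series,
    simulate_rate_grid,
    simulate_titration,
)
from .tables import DoseResponse, RateTable, TitrationSeries
from .thermo import binding_thermo

__all__ = [
    "PipelineConfig",
    "default_scenario",
    "simulate_scenario",
    "run_pipeline",
    "export_tables",
    "SCHEMA_VERSION",
]

log = logging.getLogger("inhibkit")

SCHEMA_VERSION = 1


def default_scenario(seed: int = 0, rel_sd: float = 0.0) -> dict[str, Any]:
    """Scenario regenerating every assay with the reference constants.

    Km/Vmax are arbitrary (never reported for this system); Ki/Kis, IC50,
    Ksv, Ka and n per temperature are the constants the downstream fits
    should return.
    """
    return {
        "schema_version": SCHEMA_VERSION,
        "seed": seed,
        "noise_rel_sd": rel_sd,
        "kinetics": {
            "vmax": 1.0,
            "km": 10.0,
            "ki": 10.6,
            "kis": 57.24,
            "substrate_uM": list(DEFAULT_SUBSTRATE_GRID),
            "inhibitor_uM": list(DEFAULT_INHIBITOR_GRID),
        },
        "enzyme_series": {
            "substrate_uM": 100.0,
            "enzyme_scales": [0.5, 1.0, 1.5, 2.0],
        },
        "dose_response": {
            "ic50_uM": 22.97,
            "hill": 1.0,
            "inhibitor_uM": [
                round(c, 4) for c in np.geomspace(2.0, 80.0, 8).tolist()
            ],
        },
        "titration": {
            "scheme": {"v0_mL": 2.0, "va_mL": 0.1, "stock_uM": 100.0, "n_additions": 8},
            "f0": 1000.0,
            "tau0_s": 1e-8,
            "eps_ex_per_uM": 0.012,
            "eps_em_per_uM": 0.004,
            "temperatures": [
                {"T_K": 298.0, "ksv": 1.881e5, "ka": 1.67e4, "n": 1.183},
                {"T_K": 304.0, "ksv": 1.661e5, "ka": 1.21e4, "n": 1.236},
                {"T_K": 310.0, "ksv": 1.455e5, "ka": 1.17e4, "n": 1.308},
            ],
        },
    }


@dataclass
class SimulatedInputs:
    rate_grid: RateTable
    enzyme_series: RateTable
    dose_response: DoseResponse
    titrations_sv: list[TitrationSeries]  # linear-quenching generation law
    titrations_dl: list[TitrationSeries]  # double-log generation law
    tau0: float
    scheme: TitrationScheme | None = None


def simulate_scenario(scenario: dict[str, Any]) -> SimulatedInputs:
    """Generate every input table a scenario describes.

    The two quenching laws are mutually inconsistent forward models, so a
    titration is generated under each: the linear-law series feeds the
    Stern-Volmer fit, the power-law series the double-log binding fit.
    """
    version = scenario.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ValueError(f"unsupported scenario schema_version {version!r}")
    seed = int(scenario.get("seed", 0))
    rel_sd = float(scenario.get("noise_rel_sd", 0.0))

    def noise(offset: int) -> NoiseModel:
        return NoiseModel(rel_sd=rel_sd, seed=seed + offset)

    kin = scenario["kinetics"]
    p = KineticParams(vmax=kin["vmax"], km=kin["km"], ki=kin["ki"], kis=kin["kis"])
    rate_grid = simulate_rate_grid(
        p, kin["substrate_uM"], kin["inhibitor_uM"], noise(1)
    )
    enz = scenario["enzyme_series"]
    enzyme_series = simulate_enzyme_series(
        p, enz["substrate_uM"], kin["inhibitor_uM"], enz["enzyme_scales"], noise(2)
    )
    dr = scenario["dose_response"]
    dose_response = simulate_dose_response(
        dr["ic50_uM"], dr["hill"], dr["inhibitor_uM"], noise(3)
    )
    tit = scenario["titration"]
    scheme = TitrationScheme(
        v0=tit["scheme"]["v0_mL"],
        va=tit["scheme"]["va_mL"],
        c_stock=tit["scheme"]["stock_uM"],
        n_additions=tit["scheme"]["n_additions"],
    )
    titrations_sv, titrations_dl = [], []
    for j, temp in enumerate(tit["temperatures"]):
        q = QuenchParams(
            f0=tit["f0"],
            ksv=temp["ksv"],
            ka=temp["ka"],
            n=temp["n"],
            eps_ex=tit.get("eps_ex_per_uM", 0.0),
            eps_em=tit.get("eps_em_per_uM", 0.0),
            tau0=tit.get("tau0_s", 1e-8),
        )
        titrations_sv.append(
            simulate_titration(q, scheme, temp["T_K"], "stern_volmer", noise(10 + j))
        )
        titrations_dl.append(
            simulate_titration(q, scheme, temp["T_K"], "double_log", noise(20 + j))
        )
    return SimulatedInputs(
        rate_grid=rate_grid,
        enzyme_series=enzyme_series,
        dose_response=dose_response,
        titrations_sv=titrations_sv,
        titrations_dl=titrations_dl,
        tau0=tit.get("tau0_s", 1e-8),
        scheme=scheme,
    )


@dataclass
class PipelineConfig:
    """Configuration for one end-to-end run.

    Exactly one of ``scenario`` (a dict, or a path to a scenario JSON) and
    the CSV input paths may be provided; with neither, the run is invalid.
    """

    scenario: dict[str, Any] | str | Path | None = None
    rates_csv: str | Path | None = None
    dose_response_csv: str | Path | None = None
    titration_csv: str | Path | None = None
    outdir: str | Path | None = None
    seed: int | None = None  # overrides the scenario seed
    origin_tol: float = 0.05
    class_rel_tol: float = 0.10
    force_rules: str = "paper"
    diffusion_limit: float = DIFFUSION_LIMIT
    tau0: float = 1e-8
    dilution_correction: bool = False

    def has_csv_inputs(self) -> bool:
        return any(
            p is not None
            for p in (self.rates_csv, self.dose_response_csv, self.titration_csv)
        )


def _file_sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _rescale(series: TitrationSeries, factors: np.ndarray) -> TitrationSeries:
    return TitrationSeries(
        temperature_K=series.temperature_K,
        quencher_uM=series.quencher_uM,
        f_measured=series.f_measured * factors,
        a_ex=series.a_ex,
        a_em=series.a_em,
    )


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run every analysis stage and return the structured report.

    Stages whose inputs are missing are skipped with a logged reason; the
    report records each skip. Raises ``ValueError`` when no stage can run
    or when both scenario and CSV inputs are given.
    """
    if config.scenario is not None and config.has_csv_inputs():
        raise ValueError("provide either a scenario or CSV inputs, not both")
    if config.scenario is None and not config.has_csv_inputs():
        raise ValueError("no inputs: provide a scenario or CSV paths")

    report: dict[str, Any] = {
        "schema_version": SCHEMA_VERSION,
        "stages": {},
        "skipped": {},
        "provenance": {},
    }

    rate_grid = enzyme_series = dose_response = None
    titrations_sv: list[TitrationSeries] = []
    titrations_dl: list[TitrationSeries] = []
    tau0 = config.tau0

    if config.scenario is not None:
        scenario = config.scenario
        if not isinstance(scenario, dict):
            scenario = io.read_json(scenario)
        if config.seed is not None:
            scenario = {**scenario, "seed": config.seed}
        sim = simulate_scenario(scenario)
        rate_grid = sim.rate_grid
        enzyme_series = sim.enzyme_series
        dose_response = sim.dose_response
        titrations_sv = sim.titrations_sv
        titrations_dl = sim.titrations_dl
        tau0 = sim.tau0
        if config.dilution_correction and sim.scheme is not None:
            # undo fluorophore dilution: scale intensities by cumulative volume
            factors = sim.scheme.volumes() / sim.scheme.v0
            titrations_sv = [_rescale(s, factors) for s in titrations_sv]
            titrations_dl = [_rescale(s, factors) for s in titrations_dl]
        report["provenance"]["scenario"] = io.jsonable(scenario)
    else:
        if config.rates_csv is not None:
            table = io.read_rates(config.rates_csv)
            frame = table.to_frame()
            grid = frame[frame["enzyme_scale"] == 1.0]
            if len(grid):
                rate_grid = RateTable.from_frame(grid)
            if frame["enzyme_scale"].nunique() >= 2:
                enzyme_series = table
            report["provenance"]["rates_csv"] = _file_sha256(config.rates_csv)
        if config.dose_response_csv is not None:
            dose_response = io.read_dose_response(config.dose_response_csv)
            report["provenance"]["dose_response_csv"] = _file_sha256(
                config.dose_response_csv
            )
        if config.titration_csv is not None:
            titrations_sv = io.read_titrations(config.titration_csv)
            titrations_dl = titrations_sv  # one measured series serves both fits
            report["provenance"]["titration_csv"] = _file_sha256(config.titration_csv)

    # --- reversibility -----------------------------------------------------
    if enzyme_series is not None:
        verdict = reversibility_test(enzyme_series, origin_tol=config.origin_tol)
        log.info("reversibility: %s (slopes decreasing: %s)",
                 verdict.verdict, verdict.slopes_decreasing)
        report["stages"]["reversibility"] = io.jsonable(verdict)
    else:
        report["skipped"]["reversibility"] = "no enzyme-series rates provided"
        log.info("skipping reversibility: no enzyme-series rates")

    # --- dose-response / IC50 ---------------------------------------------
    if dose_response is not None:
        ic50 = fit_ic50(dose_response)
        log.info("IC50 = %.4g μmol/L (hill %.3g, R² %.4f)",
                 ic50.ic50, ic50.hill, ic50.r2)
        report["stages"]["ic50"] = io.jsonable(ic50)
    else:
        report["skipped"]["ic50"] = "no dose-response table provided"
        log.info("skipping IC50: no dose-response table")

    # --- inhibition kinetics ----------------------------------------------
    if rate_grid is not None:
        lines = fit_primary_lines(lineweaver_burk_transform(rate_grid))
        fit = fit_secondary(lines, rel_tol=config.class_rel_tol)
        log.info("Ki = %.4g, Kis = %.4g μmol/L -> %s (%s)",
                 fit.ki, fit.kis, fit.inhibition_type, fit.binding_preference)
        report["stages"]["kinetics"] = io.jsonable(fit)
    else:
        report["skipped"]["kinetics"] = "no rate grid provided"
        log.info("skipping kinetics: no rate grid")

    # --- fluorescence quenching -------------------------------------------
    quench_fits = []
    if titrations_sv:
        same_series = titrations_sv is titrations_dl
        for sv_series, dl_series in zip(titrations_sv, titrations_dl):
            if same_series:
                qf = analyze_titration(sv_series, tau0=tau0)
            else:
                sv = stern_volmer_fit(sv_series, tau0=tau0)
                dl = analyze_titration(dl_series, tau0=tau0)
                qf = type(sv)(
                    temperature_K=sv.temperature_K,
                    ksv=sv.ksv, ksv_se=sv.ksv_se, r_sv=sv.r_sv,
                    sv_intercept=sv.sv_intercept, kq=sv.kq,
                    ka=dl.ka, ka_se=dl.ka_se, n=dl.n, n_se=dl.n_se,
                    r_dl=dl.r_dl, tau0=tau0,
                )
            quench_fits.append(qf)
            log.info("T=%g K: Ksv=%.4g L/mol, Kq=%.4g, Ka=%.4g L/mol, n=%.4g",
                     qf.temperature_K, qf.ksv, qf.kq, qf.ka, qf.n)
        mechanism = classify_quenching(quench_fits, config.diffusion_limit)
        log.info("quenching mechanism: %s (%s)",
                 mechanism.verdict, "; ".join(mechanism.reasons))
        report["stages"]["quenching"] = {
            "fits": [io.jsonable(q) for q in quench_fits],
            "mechanism": io.jsonable(mechanism),
        }
    else:
        report["skipped"]["quenching"] = "no titration series provided"
        log.info("skipping quenching: no titration series")

    # --- thermodynamics ----------------------------------------------------
    if len(quench_fits) >= 2:
        pairs = [(q.temperature_K, q.ka) for q in quench_fits]
        thermo = binding_thermo(pairs, rules=config.force_rules)
        log.info("ΔH=%.4g kJ/mol, ΔS=%.4g J/(mol·K), ΔG=%s -> %s%s",
                 thermo.dh, thermo.ds,
                 ["%.4g" % g for g in thermo.dg], thermo.force_verdict,
                 ", spontaneous" if thermo.spontaneous else "")
        report["stages"]["thermodynamics"] = io.jsonable(thermo)
    else:
        report["skipped"]["thermodynamics"] = (
            "need quench fits at >= 2 temperatures"
        )
        log.info("skipping thermodynamics: need >= 2 temperatures")

    if not report["stages"]:
        raise ValueError("all stages skipped: " + repr(report["skipped"]))

    if config.outdir is not None:
        export_tables(report, config.outdir)
    return report


def export_tables(report: dict[str, Any], outdir: str | Path) -> None:
    """Write the report JSON plus a per-temperature summary CSV.

    The CSV has one row per temperature with columns
    ``temperature_K, ksv, r_sv, ka, r_dl, n, dH_kJ_mol, dG_kJ_mol,
    dS_J_mol_K`` (null where a stage was skipped).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_json(report, outdir / "report.json")

    quench = report["stages"].get("quenching", {})
    fits = quench.get("fits", [])
    thermo = report["stages"].get("thermodynamics")
    rows = []
    for j, qf in enumerate(fits):
        row = {
            "temperature_K": qf["temperature_K"],
            "ksv": qf["ksv"],
            "r_sv": qf["r_sv"],
            "ka": qf["ka"],
            "r_dl": qf["r_dl"],
            "n": qf["n"],
            "dH_kJ_mol": thermo["dh"] if thermo else None,
            "dG_kJ_mol": thermo["dg"][j] if thermo else None,
            "dS_J_mol_K": thermo["ds"] if thermo else None,
        }
        rows.append(row)
    columns = [
        "temperature_K", "ksv", "r_sv", "ka", "r_dl", "n",
        "dH_kJ_mol", "dG_kJ_mol", "dS_J_mol_K",
    ]
    pd.DataFrame(rows, columns=columns).to_csv(
        outdir / "binding_summary.csv", index=False
    )
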