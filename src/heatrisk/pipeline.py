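"""End-to-end orchestration: simulate → fit MMTs → indices → ensemble → validate.

Each stage writes its artifact to the run directory so stages can be rerun
and inspected individually; ``run_all`` returns a machine-readable report.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, attribution, composite, dlnm, raster, simulate
from .config import RunConfig

log = logging.getLogger("heatrisk")

REPORT_SCHEMA_VERSION = 1

#: Province population exceeds the summed city populations by this factor
#: (rural residents outside city limits).
RURAL_FACTOR = 1.6


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            log.info("stage %s", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # surface the failing stage
                raise StageError(name, exc) from exc
        wrapped.__name__ = fn.__name__
        return wrapped
    return deco


@_stage("simulate")
def stage_simulate(cfg: RunConfig, outdir: Path):
    zones = simulate.make_zone_map(cfg.sim)
    lst_day = simulate.gen_lst_stack(cfg.sim, "day", zones)
    lst_night = simulate.gen_lst_stack(cfg.sim, "night", zones)
    panel, truth = simulate.gen_mortality_panel(cfg.sim, lst_day, lst_night, zones)
    indicators, ind_truth = simulate.gen_indicator_table(cfg.sim, zones)
    experts, _ = simulate.gen_expert_matrices(cfg.sim)
    if outdir:
        raster.save_stack(outdir / "lst_day.npz", lst_day)
        raster.save_stack(outdir / "lst_night.npz", lst_night)
        raster.save_zones(outdir / "zones.npz", zones)
        panel.to_csv(outdir / "panel.csv", index=False)
        indicators.to_csv(outdir / "indicators.csv", index=False)
        save_experts(outdir / "experts.json", experts)
        np.save(outdir / "density_grid.npy", ind_truth.density_grid)
        with open(outdir / "truth.json", "w") as fh:
            json.dump({"mmt_day": truth.mmt_day, "mmt_night": truth.mmt_night,
                       "weights": {k: np.asarray(v).tolist()
                                   for k, v in truth.weights.items()}}, fh, indent=2)
    return dict(zones=zones, lst_day=lst_day, lst_night=lst_night, panel=panel,
                indicators=indicators, experts=experts, truth=truth,
                density_grid=ind_truth.density_grid)


@_stage("impute")
def stage_impute(cfg: RunConfig, panel: pd.DataFrame, outdir: Path):
    completed = raster.impute_panel(panel, seed=cfg.sim.seed)
    if outdir:
        completed.to_csv(outdir / "panel_imputed.csv", index=False)
    return completed


@_stage("fit-mmt")
def stage_fit_mmt(cfg: RunConfig, panel: pd.DataFrame, outdir: Path):
    if panel is None or panel.empty:
        raise ValueError("mortality panel is missing or empty")
    results = {}
    for phase in ("day", "night"):
        res = dlnm.fit_phase(panel, cfg.crossbasis, phase)
        results[phase] = res
        if outdir:
            res.curve.to_frame().to_csv(outdir / f"rr_{phase}.csv", index=False)
            with open(outdir / f"mmt_{phase}.json", "w") as fh:
                json.dump({"phase": phase, "mmt_c": res.mmt, "flat": res.mmt_flat,
                           "p99_c": res.p99, "rr_p99": res.rr_p99,
                           "dispersion": res.fit.dispersion}, fh, indent=2)
    return results


@_stage("composite")
def stage_composite(cfg: RunConfig, sim_out: dict, mmt_results: dict, outdir: Path):
    zones = sim_out["zones"]
    comp_day = raster.temporal_max_composite(sim_out["lst_day"])
    comp_night = raster.temporal_max_composite(sim_out["lst_night"])
    hazard = composite.hazard_index(comp_day, comp_night,
                                    mmt_results["day"].mmt,
                                    mmt_results["night"].mmt, zones)
    exposure = composite.exposure_index(sim_out["density_grid"], zones)
    if outdir:
        pd.DataFrame({"hazard": hazard, "exposure": exposure}).to_csv(
            outdir / "component_indices.csv", index_label="city")
    return hazard, exposure


@_stage("risk")
def stage_risk(cfg: RunConfig, hazard, exposure, indicators, experts, outdir: Path):
    weight_sets = [composite.weights_from_matrices(e, m)
                   for e, m in enumerate(experts)]
    retained = composite.screen_experts(weight_sets, cfg.cr_threshold)
    table = composite.risk_table(hazard, exposure, indicators, retained)
    if outdir:
        table.to_csv(outdir / "risk.csv", index_label="city")
    return table, retained


@_stage("validate")
def stage_validate(cfg: RunConfig, risk: pd.DataFrame, indicators: pd.DataFrame,
                   panel: pd.DataFrame, mmt_results: dict, outdir: Path):
    prov_mort = panel.groupby("province")["deaths"].mean()
    prov_pop = (indicators.groupby("province")["population"].sum() * RURAL_FACTOR)
    rr_day = mmt_results["day"].rr_p99
    rr_night = mmt_results["night"].rr_p99
    ndah = {}
    for _, row in indicators.iterrows():
        m = attribution.mortality_share(row["population"], prov_pop[row["province"]],
                                        prov_mort[row["province"]])
        x = attribution.attributable_deaths(rr_day, rr_night, m)
        ndah[row["city"]] = attribution.ndah(x, row["area_km2"])
    ndah = pd.Series(ndah, name="ndah")
    result = attribution.validate(risk["hhri"], ndah)
    if outdir:
        result.scatter.to_csv(outdir / "validation_scatter.csv", index=False)
        with open(outdir / "validation.json", "w") as fh:
            json.dump({"pearson_r": result.r, "p_value": result.p_value,
                       "n_used": result.n_used, "n_dropped": result.n_dropped},
                      fh, indent=2)
    return result, ndah


def run_all(cfg: RunConfig, outdir=None) -> dict:
    """Execute every stage and return the run report (also written to disk)."""
    outdir = Path(outdir if outdir is not None else cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    sim_out = stage_simulate(cfg, outdir)
    panel = sim_out["panel"]
    if panel[["temp_day", "temp_night"]].isna().any().any():
        panel = stage_impute(cfg, panel, outdir)
    mmt_results = stage_fit_mmt(cfg, panel, outdir)
    hazard, exposure = stage_composite(cfg, sim_out, mmt_results, outdir)
    risk, retained = stage_risk(cfg, hazard, exposure, sim_out["indicators"],
                                sim_out["experts"], outdir)
    validation, ndah = stage_validate(cfg, risk, sim_out["indicators"], panel,
                                      mmt_results, outdir)

    retained_w = np.stack([ws.risk for ws in retained])
    vuln_w = np.stack([ws.vulnerability for ws in retained])
    top = risk.sort_values("hhri", ascending=False).head(5)
    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "heatrisk_version": __version__,
        "seed": cfg.sim.seed,
        "config": cfg.to_dict(),
        "mmt": {p: {"mmt_c": r.mmt, "rr_p99": r.rr_p99, "p99_c": r.p99,
                    "dispersion": r.fit.dispersion, "flat": r.mmt_flat}
                for p, r in mmt_results.items()},
        "true_mmt": {"day": cfg.sim.true_mmt_day, "night": cfg.sim.true_mmt_night},
        "experts": {"received": cfg.sim.n_experts, "retained": len(retained)},
        "weights_mean": {
            "hazard": float(retained_w[:, 0].mean()),
            "exposure": float(retained_w[:, 1].mean()),
            "vulnerability": float(retained_w[:, 2].mean()),
            "sensitivity": float(vuln_w[:, 0].mean()),
            "capacity": float(vuln_w[:, 1].mean()),
        },
        "top_cities": [
            {"city": int(c), "hhri": round(float(r["hhri"]), 6),
             "ci": [round(float(r["ci_low"]), 6), round(float(r["ci_high"]), 6)],
             "category": r["category"]}
            for c, r in top.iterrows()
        ],
        "validation": {"pearson_r": validation.r, "p_value": validation.p_value,
                       "n_cities": validation.n_used},
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    log.info("run complete: MMT day %.1f °C, night %.1f °C, r=%.3f",
             mmt_results["day"].mmt, mmt_results["night"].mmt, validation.r)
    return report


# ---------------------------------------------------------------------------
# expert matrix persistence
# ---------------------------------------------------------------------------

def save_experts(path, experts) -> None:
    payload = [
        {group: {"items": list(pm.items), "matrix": pm.matrix.tolist()}
         for group, pm in expert.items()}
        for expert in experts
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_experts(path):
    with open(path) as fh:
        payload = json.load(fh)
    return [
        {group: composite.PairwiseMatrix(tuple(d["items"]), np.array(d["matrix"]))
         for group, d in expert.items()}
        for expert in payload
    ]
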