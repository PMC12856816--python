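"""End-to-end orchestration: simulate, fit, map, plan, report.

Each stage is a pure function over the objects produced upstream, so
the CLI subcommands, the tests and ``run_all`` share one code path.
Sub-seeds for the independent random stages are fixed offsets from the
config seed, which makes every stage individually reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import mapping as shp_mapping

from . import grids, mapping, risk, scenarios, simulate, units
from .grids import Grid


@dataclass
class SimulatedInputs:
    """Everything the synthetic generator produces for one study system."""

    config: simulate.SimConfig
    trees: object
    traits: pd.DataFrame
    landscape: dict[str, Grid]
    ranges: dict[str, np.ndarray]
    tenure: Grid
    pa_mask: Grid
    pastoral_overlay: Grid
    boundary: object
    status: pd.DataFrame
    predictors: pd.DataFrame  # standardized design columns
    predictors_raw: pd.DataFrame
    centroids: pd.DataFrame
    transform_log: dict = field(default_factory=dict)
    vif_report: pd.DataFrame | None = None
    beta_true: pd.Series | None = None


def simulate_inputs(config: dict) -> SimulatedInputs:
    """Generate the complete synthetic study system from a config dict."""
    seed = int(config["seed"])
    sim_cfg_in = dict(config.get("simulate", {}))
    notch = sim_cfg_in.pop("boundary_notch", True)
    sim_cfg = simulate.SimConfig(seed=seed, **sim_cfg_in)

    trees = simulate.simulate_phylogenies(sim_cfg.n_species, sim_cfg.n_trees, seed)
    traits = simulate.simulate_traits(trees[0], seed=seed + 1)
    landscape = simulate.simulate_landscape(sim_cfg, seed + 2)
    sizes = simulate.default_range_sizes(sim_cfg, seed + 3)
    ranges = simulate.simulate_ranges(sim_cfg, sizes, seed + 4)
    tenure, pa_mask, pastoral = simulate.simulate_tenure(sim_cfg, seed + 5)
    boundary = simulate.generate_boundary(sim_cfg, notch=notch)

    predictors_raw, centroids = risk.summarize_predictors(ranges, landscape, traits)
    rk = config.get("risk", {})
    X_std, tlog = risk.transform_standardize(
        predictors_raw,
        skew_threshold=rk.get("skew_threshold", 1.0),
        quadratic=("body_mass_g",),
    )
    linear_cols = [c for c in X_std.columns if c != "body_mass_g_sq"]
    retained, vif_report = risk.vif_screen(
        X_std[linear_cols], threshold=rk.get("vif_threshold", 5.0)
    )
    X = X_std[retained + ["body_mass_g_sq"]]

    tm = config.get("true_model", {})
    beta = pd.Series(0.0, index=X.columns)
    for name, val in tm.get("beta", {}).items():
        if name in beta.index:
            beta[name] = float(val)
    true_model = simulate.TrueRiskModel(
        beta_true=beta.to_numpy(),
        w_phylo=tm.get("w_phylo", 0.4),
        w_space=tm.get("w_space", 0.2),
        w_iid=1.0 - tm.get("w_phylo", 0.4) - tm.get("w_space", 0.2),
        sigma2=tm.get("sigma2", 2.0),
        spatial_range=tm.get("spatial_range", 20.0),
        suppression_shift=int(tm.get("suppression_shift", 3)),
    )
    status = simulate.assign_threat_status(
        true_model,
        X,
        trees[0],
        centroids,
        seed + 6,
        suppressed_fraction=sim_cfg.suppressed_fraction,
    )
    return SimulatedInputs(
        config=sim_cfg,
        trees=trees,
        traits=traits,
        landscape=landscape,
        ranges=ranges,
        tenure=tenure,
        pa_mask=pa_mask,
        pastoral_overlay=pastoral,
        boundary=boundary,
        status=status,
        predictors=X,
        predictors_raw=predictors_raw,
        centroids=centroids,
        transform_log=tlog,
        vif_report=vif_report,
        beta_true=beta,
    )


@dataclass
class RiskAnalysis:
    full_fit: risk.GLSResults
    mam_fit: risk.GLSResults
    trace: list[dict]
    latent: pd.DataFrame
    covariance: risk.CovarianceModel


def fit_risk(inputs: SimulatedInputs, config: dict) -> RiskAnalysis:
    """Fit the full model, find the MAM, average latent risk over trees."""
    rk = config.get("risk", {})
    y = inputs.status["status_observed"].astype(float)
    X = inputs.predictors
    species = list(X.index)
    tree0 = inputs.trees[0]
    if rk.get("profile_covariance", False):
        cov, _ = risk.profile_covariance(y, X, tree0, inputs.centroids)
    else:
        cov = risk.build_covariance(
            tree0, species, inputs.centroids,
            w_phylo=rk.get("w_phylo", 0.4),
            w_space=rk.get("w_space", 0.2),
            rho=rk.get("rho", 20.0),
        )
    full_fit = risk.fit_gls(X, y, cov)
    mam_fit, trace = risk.stepwise_mam(
        y.to_numpy(), X, cov, delta_aicc=rk.get("delta_aicc", 2.0)
    )
    mam_predictors = [c for c in mam_fit.params.index if c != "const"]
    latent = risk.latent_risk(
        y, X, mam_predictors, inputs.trees, inputs.centroids,
        w_phylo=cov.w_phylo, w_space=cov.w_space, rho=cov.rho,
    )
    return RiskAnalysis(full_fit=full_fit, mam_fit=mam_fit, trace=trace,
                        latent=latent, covariance=cov)


def region_mask(inputs: SimulatedInputs) -> np.ndarray:
    """Boolean grid of cells whose centres fall inside the boundary."""
    import shapely

    g = inputs.tenure
    xs, ys = g.cell_centers()
    return shapely.contains_xy(inputs.boundary, xs, ys)


def build_risk_maps(inputs: SimulatedInputs, analysis: RiskAnalysis) -> mapping.RiskGrid:
    return mapping.build_risk_grids(
        inputs.ranges,
        inputs.status["status_observed"].astype(float),
        analysis.latent["latent"],
        template=inputs.tenure,
        region_mask=region_mask(inputs),
    )


@dataclass
class PlanningInputs:
    pus: pd.DataFrame
    features: pd.DataFrame
    area_proportion: pd.Series


def build_planning(inputs: SimulatedInputs, config: dict) -> PlanningInputs:
    """Tessellate, classify, cost and build the feature matrix."""
    pl = config.get("planning", {})
    pus = units.build_pu_table(
        inputs.boundary,
        side_km=pl.get("hex_side_km", 4.0),
        tenure=inputs.tenure,
        pastoral_overlay=inputs.pastoral_overlay,
        pa_mask=inputs.pa_mask,
        mei=inputs.landscape["mei"],
        hii=inputs.landscape["hii"],
        w_floor=pl.get("w_floor", 0.01),
    )
    features = units.build_features(pus, inputs.ranges, inputs.tenure)
    lo, hi = config.get("targets", {}).get("area_proportion_range", [0.15, 0.9])
    rng = np.random.default_rng(int(config["seed"]) + 7)
    A = pd.Series(
        rng.uniform(lo, hi, size=len(features.columns)),
        index=features.columns,
        name="area_proportion",
    )
    return PlanningInputs(pus=pus, features=features, area_proportion=A)


def run_scenarios_stage(
    inputs: SimulatedInputs,
    analysis: RiskAnalysis,
    planning: PlanningInputs,
    config: dict,
) -> scenarios.ScenarioSet:
    tg = config.get("targets", {})
    return scenarios.run_scenarios(
        planning.pus,
        planning.features,
        status=inputs.status["status_observed"],
        latent=analysis.latent["latent"],
        area_proportion=planning.area_proportion,
        latent_threshold=tg.get("latent_threshold", 1.50),
        gap=config.get("prioritize", {}).get("gap", 0.0),
    )


def run_all(config: dict, outdir) -> dict:
    """Drive the full pipeline from one config and write the bundle.

    Returns a dict with every intermediate object plus the paths
    written, so callers (CLI, tests, acceptance script) can inspect any
    stage.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = simulate_inputs(config)
    analysis = fit_risk(inputs, config)
    riskmaps = build_risk_maps(inputs, analysis)
    planning = build_planning(inputs, config)
    sset = run_scenarios_stage(inputs, analysis, planning, config)

    paths = write_inputs(inputs, outdir)
    paths.update(write_analysis(analysis, outdir))
    maps_dir = outdir / "maps"
    maps_dir.mkdir(exist_ok=True)
    for name, g in riskmaps.layers().items():
        p = maps_dir / f"{name}.asc"
        grids.write_ascii_grid(g, p)
        paths[f"map_{name}"] = str(p)
    paths.update(write_planning(planning, outdir))
    paths.update(scenarios.write_report(sset, planning.pus, outdir, config, config["seed"]))
    return {
        "inputs": inputs,
        "analysis": analysis,
        "riskmaps": riskmaps,
        "planning": planning,
        "scenarios": sset,
        "paths": paths,
    }


# ---------------------------------------------------------------------------
# Serialization of intermediate artifacts (plain-text formats throughout)
# ---------------------------------------------------------------------------


def write_inputs(inputs: SimulatedInputs, outdir: Path) -> dict[str, str]:
    outdir = Path(outdir)
    paths = {}
    p = outdir / "trees.nwk"
    p.write_text(simulate.trees_to_newick(inputs.trees))
    paths["trees"] = str(p)
    for name, df in (
        ("traits", inputs.traits),
        ("status", inputs.status),
        ("predictors_raw", inputs.predictors_raw),
        ("predictors_std", inputs.predictors),
        ("centroids", inputs.centroids),
    ):
        p = outdir / f"{name}.csv"
        df.to_csv(p)
        paths[name] = str(p)
    rows = []
    for sp, mask in inputs.ranges.items():
        rr, cc = np.nonzero(mask)
        rows.append(pd.DataFrame({"species": sp, "row": rr, "col": cc}))
    p = outdir / "ranges.csv"
    pd.concat(rows, ignore_index=True).to_csv(p, index=False)
    paths["ranges"] = str(p)
    rasters_dir = outdir / "rasters"
    rasters_dir.mkdir(exist_ok=True)
    all_layers = dict(inputs.landscape)
    all_layers.update(
        {"tenure": inputs.tenure, "pa_mask": inputs.pa_mask,
         "pastoral_overlay": inputs.pastoral_overlay}
    )
    for name, g in all_layers.items():
        p = rasters_dir / f"{name}.asc"
        grids.write_ascii_grid(g, p)
        paths[f"raster_{name}"] = str(p)
    p = outdir / "boundary.geojson"
    p.write_text(json.dumps({
        "type": "FeatureCollection",
        "features": [{"type": "Feature", "geometry": shp_mapping(inputs.boundary),
                      "properties": {"name": "study region"}}],
    }))
    paths["boundary"] = str(p)
    return paths


def write_analysis(analysis: RiskAnalysis, outdir: Path) -> dict[str, str]:
    outdir = Path(outdir)
    paths = {}
    coef = pd.concat(
        {
            "full": analysis.full_fit.coefficient_table(),
            "mam": analysis.mam_fit.coefficient_table(),
        },
        names=["model", "predictor"],
    )
    p = outdir / "coefficients.csv"
    coef.to_csv(p)
    paths["coefficients"] = str(p)
    p = outdir / "stepwise_trace.json"
    p.write_text(json.dumps(analysis.trace, indent=2))
    paths["stepwise_trace"] = str(p)
    p = outdir / "latent_risk.csv"
    analysis.latent.to_csv(p)
    paths["latent_risk"] = str(p)
    return paths


def write_planning(planning: PlanningInputs, outdir: Path) -> dict[str, str]:
    outdir = Path(outdir)
    paths = {}
    gj = scenarios.pus_to_geojson(planning.pus)
    p = outdir / "planning_units.geojson"
    p.write_text(json.dumps(gj))
    paths["planning_units"] = str(p)
    trip = planning.features.stack()
    trip = trip[trip > 0].rename("amount_km2").reset_index()
    trip.columns = ["pu_id", "species", "amount_km2"]
    p = outdir / "features.csv"
    trip.to_csv(p, index=False)
    paths["features"] = str(p)
    p = outdir / "area_proportion.csv"
    planning.area_proportion.to_csv(p)
    paths["area_proportion"] = str(p)
    return paths
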