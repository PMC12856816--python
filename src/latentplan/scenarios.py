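"""The 2 x 2 scenario grid and its reporting.

Crosses the two protection criteria (current risk, positive latent
risk) with the two objectives (expand from any tenure; expand by
voluntary declaration of Indigenous-held land) on one shared PU table
and feature matrix, then summarizes per-PU selection frequency (0-4;
frequency 4 defines the high-priority set) and tenure breakdowns.
Selection frequency counts newly selected PUs only — the locked-in
estate would trivially score 4 in every scenario and swamp the signal.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import mapping as shp_mapping

from . import __version__
from .prioritize import Solution, build_problem, solution_metrics, solve_exact
from .targets import build_target_table

CRITERIA = ("current_risk", "positive_latent_risk")
OBJECTIVES = (1, 2)


@dataclass
class ScenarioSet:
    solutions: dict[tuple[str, int], Solution]
    metrics: pd.DataFrame  # one row per scenario
    frequency: pd.Series  # per PU, 0..4, newly selected only
    target_tables: dict[str, pd.DataFrame]

    @property
    def high_priority(self) -> pd.Index:
        return self.frequency.index[self.frequency == len(self.solutions)]


def run_scenarios(
    pus: pd.DataFrame,
    features: pd.DataFrame,
    status: pd.Series,
    latent: pd.Series,
    area_proportion: pd.Series | None = None,
    latent_threshold: float = 1.50,
    gap: float = 0.0,
    include_locked_in_frequency: bool = False,
) -> ScenarioSet:
    """Solve all four scenarios and tabulate selection frequency.

    ``status`` is each species' ordinal current status and ``latent``
    its mean latent risk.  Targets are built per criterion (risk scaled
    to [0.25, 0.75] within each criterion's target set), then each
    objective's lock structure is applied and the ILP solved to
    optimality.  Infeasibility propagates with the scenario label.
    """
    totals = features.sum(axis=0)
    target_tables = {
        "current_risk": build_target_table(
            status.astype(float), totals, "current_risk", area_proportion
        ),
        "positive_latent_risk": build_target_table(
            latent, totals, "positive_latent_risk", area_proportion,
            latent_threshold=latent_threshold,
        ),
    }
    solutions: dict[tuple[str, int], Solution] = {}
    rows = []
    for criterion in CRITERIA:
        tgt = target_tables[criterion]["T_km2"]
        for objective in OBJECTIVES:
            label = f"{criterion}/objective{objective}"
            problem = build_problem(pus, features, tgt, objective, label=label)
            sol = solve_exact(problem, gap=gap)
            solutions[(criterion, objective)] = sol
            m = solution_metrics(sol, pus, features)
            rows.append(
                {
                    "criterion": criterion,
                    "objective": objective,
                    "n_pu_selected": m["n_pu_selected"],
                    "n_pu_new": m["n_pu_new"],
                    "proxy_cost": round(m["proxy_cost_new"], 6),
                    "area_km2": round(m["area_km2"], 6),
                    "boundary_km": round(m["boundary_km"], 6),
                    "mean_coverage_pct": round(m["mean_coverage_pct"], 6),
                    "status": m["status"],
                }
            )
    freq = selection_frequency(solutions, include_locked_in=include_locked_in_frequency)
    return ScenarioSet(
        solutions=solutions,
        metrics=pd.DataFrame(rows),
        frequency=freq,
        target_tables=target_tables,
    )


def selection_frequency(
    solutions: dict[tuple[str, int], Solution], include_locked_in: bool = False
) -> pd.Series:
    """Number of scenarios (0-4) in which each PU is newly selected."""
    any_sol = next(iter(solutions.values()))
    freq = pd.Series(0, index=any_sol.selected.index, dtype=int)
    for sol in solutions.values():
        ids = sol.selected_ids if include_locked_in else sol.new_ids
        freq.loc[ids] += 1
    return freq


def tenure_breakdown(
    sset: ScenarioSet, pus: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tenure x selection-frequency counts, and per-scenario proportions.

    The first frame cross-tabulates newly selected PUs by tenure class
    and frequency level (1-4).  The second gives, per scenario, the
    percentage of newly selected PUs in each tenure class (rows sum to
    100).
    """
    freq = sset.frequency
    picked = freq > 0
    counts = pd.crosstab(pus.loc[picked, "tenure"], freq[picked])
    counts.columns.name = "selection_frequency"
    props = {}
    for (criterion, objective), sol in sset.solutions.items():
        tenures = pus.loc[sol.new_ids, "tenure"]
        props[f"{criterion}/obj{objective}"] = tenures.value_counts(normalize=True) * 100.0
    prop_df = pd.DataFrame(props).T.fillna(0.0)
    prop_df.index.name = "scenario"
    return counts, prop_df


def config_hash(config: dict) -> str:
    """Stable hash of a config mapping (canonical YAML, sha256)."""
    canon = yaml.safe_dump(config, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()


def pus_to_geojson(pus: pd.DataFrame, extra: dict[str, pd.Series] | None = None) -> dict:
    feats = []
    extra = extra or {}
    for pid, pu in pus.iterrows():
        props = {"pu_id": int(pid), "w": float(pu["w"]), "tenure": pu.get("tenure", "")}
        if "cost" in pu:
            props["cost"] = float(pu["cost"])
        for name, series in extra.items():
            v = series.loc[pid]
            props[name] = float(v) if isinstance(v, (int, float, np.floating, np.integer)) else v
        feats.append(
            {
                "type": "Feature",
                "geometry": shp_mapping(pu["geometry"]),
                "properties": props,
            }
        )
    return {"type": "FeatureCollection", "features": feats}


def write_report(
    sset: ScenarioSet,
    pus: pd.DataFrame,
    outdir,
    config: dict,
    seed: int,
) -> dict[str, str]:
    """Write the scenario report bundle.

    Emits ``scenario_metrics.csv`` (one row per scenario),
    ``selection_frequency.geojson`` (PU polygons with frequency),
    ``tenure_frequency.csv`` and ``tenure_proportions.csv``, the four
    target tables, and ``manifest.json`` with the config hash, seed and
    package version.  Returns the paths written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    mpath = outdir / "scenario_metrics.csv"
    sset.metrics.to_csv(mpath, index=False)
    paths["metrics"] = str(mpath)

    gj = pus_to_geojson(pus, extra={"selection_frequency": sset.frequency})
    gpath = outdir / "selection_frequency.geojson"
    gpath.write_text(json.dumps(gj))
    paths["frequency_geojson"] = str(gpath)

    counts, props = tenure_breakdown(sset, pus)
    cpath = outdir / "tenure_frequency.csv"
    counts.to_csv(cpath)
    paths["tenure_frequency"] = str(cpath)
    ppath = outdir / "tenure_proportions.csv"
    props.to_csv(ppath)
    paths["tenure_proportions"] = str(ppath)

    for criterion, table in sset.target_tables.items():
        tpath = outdir / f"targets_{criterion}.csv"
        table.to_csv(tpath)
        paths[f"targets_{criterion}"] = str(tpath)

    manifest = {
        "config_sha256": config_hash(config),
        "seed": int(seed),
        "package": "latentplan",
        "version": __version__,
        "n_scenarios": len(sset.solutions),
        "n_high_priority": int(len(sset.high_priority)),
    }
    mpath2 = outdir / "manifest.json"
    mpath2.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    paths["manifest"] = str(mpath2)
    return paths
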