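"""Stage orchestration: simulate -> clean -> fit -> estimate -> population
-> hia -> report.

Each stage reads its upstream artifacts from the run's output directory,
writes its own artifacts plus a machine-readable manifest (input
checksums, seed, package version), and is re-entrant: rerunning a stage
with the same config and seed reproduces its outputs byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .activity_estimator import (
    CELL_INDEX, FitBundle, TpaMatrix, build_tpa_matrix,
)
from .component_models import (
    fit_duration_gee, fit_from_json, fit_purpose_mnl, fit_zip,
)
from .config import RunConfig
from .designs import PURPOSE_BASE, design_set
from .hia_engine import (
    DeathRates, DoseResponse, EligibilityWindows, Scenario, avoided_mortality,
    monte_carlo_ci, quintile_summary, scenario_transform,
)
from .population_builder import (
    build_population, prepare_block_groups, smooth_labor_force,
)
from .survey_data import (
    derive_trip_counts, drop_missing, remove_atypical, stratify,
)
from .synthetic_data import (
    RegionConfig, SyntheticRegion, default_truth, generate_region,
    generate_survey,
)

STAGES = ("simulate", "clean", "fit", "estimate", "population", "hia", "report")

#: Default counterfactual and scenarios of the hypothetical application:
#: a fixed weekly walking time, a population-wide walking increase, and
#: two commute mode shifts.
DEFAULT_SCENARIOS = [
    {"kind": "scale_walking", "percent": 7.9},
    {"kind": "mode_shift", "from_mode": "private_vehicle", "to_mode": "walk",
     "share": 0.079},
    {"kind": "mode_shift", "from_mode": "private_vehicle",
     "to_mode": "transit", "share": 0.145},
]


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write_manifest(outdir: Path, stage: str, seed, inputs, outputs, t0):
    manifest = {
        "stage": stage,
        "seed": seed,
        "version": __version__,
        "elapsed_s": round(time.time() - t0, 3),
        "inputs": {str(p): _checksum(Path(p)) for p in inputs},
        "outputs": {str(p): _checksum(Path(p)) for p in outputs},
    }
    path = outdir / f"manifest_{stage}.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing upstream artifact {path}; run the {producer!r} stage first"
        )
    return path


def _child_seed(seed: int, label: str) -> int:
    h = hashlib.sha256(f"{seed}:{label}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: RunConfig) -> dict:
    t0 = time.time()
    out = cfg.outpath
    out.mkdir(parents=True, exist_ok=True)
    truth = default_truth(cfg.n_persons)
    persons, trips = generate_survey(truth, seed=_child_seed(cfg.seed, "survey"))
    region = generate_region(
        RegionConfig(**cfg.region), seed=_child_seed(cfg.seed, "region")
    )
    persons.to_csv(out / "persons.csv", index=False)
    trips.to_csv(out / "trips.csv", index=False)
    truth.to_yaml(out / "truth.yaml")
    region_dir = out / "region"
    region.write_csvs(region_dir)
    outputs = [out / "persons.csv", out / "trips.csv", out / "truth.yaml"]
    _write_manifest(out, "simulate", cfg.seed, [], outputs, t0)
    return {"persons": persons, "trips": trips, "region": region}


def stage_clean(cfg: RunConfig) -> dict:
    t0 = time.time()
    out = cfg.outpath
    ppath = _require(out / "persons.csv", "simulate")
    tpath = _require(out / "trips.csv", "simulate")
    persons = pd.read_csv(ppath)
    trips = pd.read_csv(tpath)
    persons, trips, rep1 = remove_atypical(persons, trips)
    persons, trips, rep2 = drop_missing(persons, trips)
    persons = derive_trip_counts(persons, trips)
    strata = stratify(persons)
    strata["working_adults"].to_csv(out / "working_adults.csv", index=False)
    strata["nonworking_adults"].to_csv(out / "nonworking_adults.csv", index=False)
    trips.to_csv(out / "trips_clean.csv", index=False)
    report = {
        "remove_atypical": json.loads(rep1.to_json()),
        "drop_missing": json.loads(rep2.to_json()),
        "final_sizes": {k: len(v) for k, v in strata.items()},
    }
    (out / "cleaning_report.json").write_text(json.dumps(report, indent=2))
    outputs = [out / "working_adults.csv", out / "nonworking_adults.csv",
               out / "trips_clean.csv", out / "cleaning_report.json"]
    _write_manifest(out, "clean", cfg.seed, [ppath, tpath], outputs, t0)
    return {"strata": strata, "trips": trips, "report": report}


_STRATUM_FILE = {"workers": "working_adults.csv",
                 "nonworkers": "nonworking_adults.csv"}


def _load_strata(out: Path) -> dict[str, pd.DataFrame]:
    return {
        s: pd.read_csv(_require(out / f, "clean"))
        for s, f in _STRATUM_FILE.items()
    }


def _stratum_trips(trips: pd.DataFrame, persons: pd.DataFrame,
                   mode: str) -> pd.DataFrame:
    sub = trips.loc[
        (trips["mode"] == mode) & trips["person_id"].isin(persons["person_id"])
    ]
    cov_cols = [c for c in persons.columns if c not in ("walk_trip_count",
                                                        "bike_trip_count")]
    merged = sub.merge(persons[cov_cols], on="person_id", how="left",
                       suffixes=("", "_person"))
    return merged


def fit_all(strata: dict[str, pd.DataFrame], trips: pd.DataFrame,
            models_cfg: dict | None = None) -> dict:
    """Fit the three component models for every (stratum, mode) pair."""
    models_cfg = models_cfg or {}
    bundles = {}
    for stratum in ("workers", "nonworkers"):
        persons = strata[stratum]
        for mode in ("walk", "bike"):
            designs = design_set(stratum, mode)
            mtrips = _stratum_trips(trips, persons, mode)
            zfit = fit_zip(persons, designs["count"])
            mfit = fit_purpose_mnl(mtrips, designs["purpose"],
                                   base=PURPOSE_BASE[stratum])
            dfit = fit_duration_gee(mtrips, designs["duration"])
            bundles[(stratum, mode)] = FitBundle(stratum, mode, zfit, mfit, dfit)
    return bundles


def stage_fit(cfg: RunConfig) -> dict:
    t0 = time.time()
    out = cfg.outpath
    strata_files = {s: _require(out / f, "clean")
                    for s, f in _STRATUM_FILE.items()}
    tpath = _require(out / "trips_clean.csv", "clean")
    strata = {"workers": pd.read_csv(strata_files["workers"]),
              "nonworkers": pd.read_csv(strata_files["nonworkers"])}
    trips = pd.read_csv(tpath)
    bundles = fit_all(strata, trips, cfg.models)
    outputs = []
    for (stratum, mode), b in bundles.items():
        for name, fit in (("count", b.zip_fit), ("purpose", b.mnl_fit),
                          ("duration", b.duration_fit)):
            path = out / f"fit_{stratum}_{mode}_{name}.json"
            path.write_text(fit.to_json())
            outputs.append(path)
    _write_manifest(out, "fit", cfg.seed,
                    list(strata_files.values()) + [tpath], outputs, t0)
    return {"bundles": bundles, "strata": strata, "trips": trips}


def load_bundles(out: Path) -> dict:
    """Rehydrate fitted bundles from the fit stage's JSON artifacts."""
    strata = _load_strata(out)
    trips = pd.read_csv(_require(out / "trips_clean.csv", "clean"))
    bundles = {}
    for stratum in ("workers", "nonworkers"):
        for mode in ("walk", "bike"):
            persons = strata[stratum]
            mtrips = _stratum_trips(trips, persons, mode)
            fits = {}
            for name, ref in (("count", persons), ("purpose", mtrips),
                              ("duration", mtrips)):
                path = _require(out / f"fit_{stratum}_{mode}_{name}.json",
                                "fit")
                fits[name] = fit_from_json(path.read_text(), ref)
            bundles[(stratum, mode)] = FitBundle(
                stratum, mode, fits["count"], fits["purpose"], fits["duration"]
            )
    return bundles


def stage_estimate(cfg: RunConfig, bundles=None) -> dict:
    t0 = time.time()
    out = cfg.outpath
    region = SyntheticRegion.read_csvs(_require(out / "region", "simulate"))
    if bundles is None:
        bundles = load_bundles(out)
    bg, provenance = prepare_block_groups(region)
    est = cfg.estimate
    tpa = build_tpa_matrix(
        bundles,
        bg,
        ages=cfg.ages,
        seed=_child_seed(cfg.seed, "tpa"),
        n_draws=int(est.get("n_draws", 40)),
        exclude_recreational=bool(est.get("exclude_recreational", True)),
        season=est.get("season", "average"),
    )
    tpa.to_csv(out / "tpa.csv")
    provenance.to_csv(out / "ttw_provenance.csv", index=False)
    _write_manifest(out, "estimate", cfg.seed, [], [out / "tpa.csv"], t0)
    return {"tpa": tpa, "block_groups": bg, "region": region}


def stage_population(cfg: RunConfig) -> dict:
    t0 = time.time()
    out = cfg.outpath
    region = SyntheticRegion.read_csvs(_require(out / "region", "simulate"))
    participation = smooth_labor_force(region.labor_force)
    pop = build_population(region, participation, ages=cfg.ages)
    pop.to_csv(out / "population.csv", index=False)
    _write_manifest(out, "population", cfg.seed, [],
                    [out / "population.csv"], t0)
    return {"population": pop, "region": region}


def join_cells(tpa: TpaMatrix, population: pd.DataFrame,
               block_groups: pd.DataFrame) -> pd.DataFrame:
    """Join doses, persons, and county ids into the HIA cell table."""
    cells = tpa.table.merge(population, on=CELL_INDEX, how="left")
    cells["persons"] = cells["persons"].fillna(0.0)
    cells = cells.merge(block_groups[["block_group", "county"]],
                        on="block_group", how="left")
    return cells


def stage_hia(cfg: RunConfig) -> dict:
    t0 = time.time()
    out = cfg.outpath
    region = SyntheticRegion.read_csvs(_require(out / "region", "simulate"))
    tpa = TpaMatrix.read_csv(_require(out / "tpa.csv", "estimate"))
    population = pd.read_csv(_require(out / "population.csv", "population"))
    cells = join_cells(tpa, population, region.block_groups)

    hcfg = cfg.hia
    dr = DoseResponse(
        base_rr=float(hcfg.get("base_rr", 0.90)),
        reference_dose=float(hcfg.get("reference_dose", 11.25)),
    )
    windows = EligibilityWindows()
    rates = DeathRates.from_pooled_counts(region.deaths)
    formula_mode = hcfg.get("formula_mode", "pif")
    minutes = float(hcfg.get("counterfactual_walk_minutes", 37.4))
    n_draws = int(hcfg.get("n_draws", 200))

    baseline_sc = Scenario("fixed_walk_minutes", minutes_per_week=minutes)
    baseline = avoided_mortality(
        scenario_transform(cells, baseline_sc), rates, windows, dr,
        formula_mode,
    )
    baseline_ci = monte_carlo_ci(
        cells, baseline_sc, rates, windows, dr, formula_mode,
        n_draws=n_draws, seed=_child_seed(cfg.seed, "hia_mc"),
    )
    baseline.intervals = baseline_ci

    quintiles = quintile_summary(
        cells, baseline,
        region.block_groups.set_index("block_group")["pop_density_k"],
    )

    scenario_rows = []
    for i, sdict in enumerate(hcfg.get("scenarios", DEFAULT_SCENARIOS)):
        sc = Scenario.from_dict(sdict)
        res = avoided_mortality(
            scenario_transform(cells, sc), rates, windows, dr, formula_mode
        )
        ci = monte_carlo_ci(
            cells, sc, rates, windows, dr, formula_mode,
            n_draws=n_draws, seed=_child_seed(cfg.seed, f"hia_mc_s{i}"),
        )
        paired = scenario_transform(cells, sc)
        pop_total = paired["persons"].sum()
        tpa_cf = (
            (paired["persons"] * (paired["walk_cf"] + paired["bike_cf"])).sum()
            / pop_total if pop_total else 0.0
        )
        scenario_rows.append({
            "scenario": sdict.get("name", f"scenario_{i + 1}"),
            "kind": sc.kind,
            "tpa_met_h_week": tpa_cf,
            "prevented_deaths": res.total_deaths,
            "prevented_deaths_low": ci["total_deaths"]["ci_low"],
            "prevented_deaths_high": ci["total_deaths"]["ci_high"],
            "prevented_per_100k": res.per_100k,
        })
    scenarios_df = pd.DataFrame(scenario_rows)

    baseline.to_json(out / "hia_baseline.json")
    baseline.by("county", "sex").to_csv(out / "hia_by_county_sex.csv",
                                        index=False)
    quintiles.to_csv(out / "hia_quintiles.csv", index=False)
    scenarios_df.to_csv(out / "hia_scenarios.csv", index=False)
    pop_total = cells["persons"].sum()
    mean_tpa = (
        (cells["persons"] * cells["tpa_mean"]).sum() / pop_total
        if pop_total else 0.0
    )
    summary = {
        "regional_mean_tpa_met_h_week": float(mean_tpa),
        "population": float(pop_total),
        "counterfactual_walk_minutes": minutes,
        "baseline_avoided_deaths": baseline.intervals["total_deaths"],
        "baseline_per_100k": baseline.intervals["per_100k"],
    }
    (out / "hia_summary.json").write_text(json.dumps(summary, indent=2))
    outputs = [out / "hia_baseline.json", out / "hia_quintiles.csv",
               out / "hia_scenarios.csv", out / "hia_summary.json"]
    _write_manifest(out, "hia", cfg.seed,
                    [out / "tpa.csv", out / "population.csv"], outputs, t0)
    return {
        "baseline": baseline, "quintiles": quintiles,
        "scenarios": scenarios_df, "summary": summary, "cells": cells,
    }


def stage_report(cfg: RunConfig) -> dict:
    t0 = time.time()
    out = cfg.outpath
    qpath = _require(out / "hia_quintiles.csv", "hia")
    spath = _require(out / "hia_scenarios.csv", "hia")
    summary = json.loads(_require(out / "hia_summary.json", "hia").read_text())
    quintiles = pd.read_csv(qpath)
    scenarios = pd.read_csv(spath)
    quintiles.to_csv(out / "table_density_quintiles.csv", index=False)
    scenarios.to_csv(out / "table_scenarios.csv", index=False)
    lines = [
        "Active transportation physical activity and avoided mortality",
        "=" * 60,
        f"Regional population: {summary['population']:,.0f}",
        "Population-weighted mean dose: "
        f"{summary['regional_mean_tpa_met_h_week']:.2f} MET-h/week",
        "Counterfactual: everyone walks "
        f"{summary['counterfactual_walk_minutes']} min/week",
        "Avoided premature deaths: "
        f"{summary['baseline_avoided_deaths']['point']:.1f} "
        f"(95% CI {summary['baseline_avoided_deaths']['ci_low']:.1f}-"
        f"{summary['baseline_avoided_deaths']['ci_high']:.1f})",
        "",
        "Density quintiles:",
        quintiles.to_string(index=False),
    ]
    if len(scenarios):
        lines += ["", "Scenarios:", scenarios.to_string(index=False)]
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
    outputs = [out / "table_density_quintiles.csv",
               out / "table_scenarios.csv", out / "summary.txt"]
    _write_manifest(out, "report", cfg.seed, [qpath, spath], outputs, t0)
    return {"quintiles": quintiles, "scenarios": scenarios,
            "summary": summary}


_STAGE_FN = {
    "simulate": stage_simulate,
    "clean": stage_clean,
    "fit": stage_fit,
    "estimate": stage_estimate,
    "population": stage_population,
    "hia": stage_hia,
    "report": stage_report,
}


def run_stage(stage: str, cfg: RunConfig) -> dict:
    """Run one named stage; raises if its upstream artifacts are absent."""
    if stage not in _STAGE_FN:
        raise ValueError(f"unknown stage {stage!r}; stages are {STAGES}")
    return _STAGE_FN[stage](cfg)


def run_all(cfg: RunConfig) -> dict:
    """Run the full pipeline in order, passing fits through in memory."""
    artifacts = {}
    artifacts["simulate"] = stage_simulate(cfg)
    artifacts["clean"] = stage_clean(cfg)
    fit_art = stage_fit(cfg)
    artifacts["fit"] = fit_art
    artifacts["estimate"] = stage_estimate(cfg, bundles=fit_art["bundles"])
    artifacts["population"] = stage_population(cfg)
    artifacts["hia"] = stage_hia(cfg)
    artifacts["report"] = stage_report(cfg)
    return artifacts
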