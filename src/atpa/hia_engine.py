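"""Health impact assessment for transportation physical activity.

All-cause mortality relative risk declines log-linearly in the weekly
MET-hour dose, RR(TPA) = 0.90 ** (TPA / 11.25): one reference dose of
11.25 MET-hours per week multiplies risk by 0.90.  Comparing the
estimated dose distribution with a counterfactual distribution yields an
attributable (potential impact) fraction per population cell, which
baseline county age- and sex-specific death rates convert into avoided
premature deaths.  Walking benefits accrue at ages 20-74 and cycling
benefits at ages 20-64; doses carry separate walking and cycling
components so each can be windowed independently.  Uncertainty intervals
come from Monte Carlo perturbation of the dose matrix with its cell SDs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import yaml

from .activity_estimator import BIKE_MET, WALK_MET


@dataclass(frozen=True)
class DoseResponse:
    """Log-linear dose-response for all-cause mortality."""

    base_rr: float = 0.90
    reference_dose: float = 11.25  # MET-hours per week

    def __post_init__(self):
        if not 0.0 < self.base_rr <= 1.0:
            raise ValueError("base relative risk must lie in (0, 1]")
        if self.reference_dose <= 0:
            raise ValueError("reference dose must be positive")


@dataclass(frozen=True)
class EligibilityWindows:
    """Inclusive age ranges over which mode-specific benefits accrue."""

    walk: tuple[int, int] = (20, 74)
    bike: tuple[int, int] = (20, 64)

    def __post_init__(self):
        for lo, hi in (self.walk, self.bike):
            if not lo < hi:
                raise ValueError("window lower bound must be below upper bound")

    def windowed_dose(self, walk_met, bike_met, age) -> np.ndarray:
        """Total eligible dose: each component zeroed outside its window."""
        age = np.asarray(age, dtype=float)
        w = np.where(
            (age >= self.walk[0]) & (age <= self.walk[1]),
            np.asarray(walk_met, dtype=float), 0.0,
        )
        b = np.where(
            (age >= self.bike[0]) & (age <= self.bike[1]),
            np.asarray(bike_met, dtype=float), 0.0,
        )
        return w + b


def relative_risk(tpa, dr: DoseResponse = DoseResponse()):
    """All-cause mortality relative risk at a weekly MET-hour dose."""
    t = np.asarray(tpa, dtype=float)
    if (t < 0).any():
        raise ValueError("dose must be nonnegative")
    out = dr.base_rr ** (t / dr.reference_dose)
    return float(out) if out.ndim == 0 else out


def benefit_integral(doses, weights, dr: DoseResponse = DoseResponse()) -> float:
    """Expected mortality benefit B = sum_k w_k (1 - RR(dose_k)).

    ``weights`` must be a nonnegative probability vector.
    """
    w = np.asarray(weights, dtype=float)
    if (w < 0).any():
        raise ValueError("weights must be nonnegative")
    if abs(w.sum() - 1.0) > 1e-8:
        raise ValueError(f"weights must sum to 1 (got {w.sum():.6g})")
    return float(np.sum(w * (1.0 - relative_risk(doses, dr))))


def attributable_fraction(
    f_est: tuple,
    f_cf: tuple,
    dr: DoseResponse = DoseResponse(),
    formula_mode: str = "pif",
) -> float:
    """Fraction of mortality avoidable by moving from f_est to f_cf.

    Each distribution is (doses, weights).  The default ``pif`` mode uses
    the standard potential-impact-fraction form
    ``(B_cf - B_est) / (1 - B_est)``, positive when the counterfactual is
    more active; ``as_printed`` applies the alternative form
    ``(B_est - B_cf) / (1 + B_est)``.
    """
    b_est = benefit_integral(*f_est, dr=dr)
    b_cf = benefit_integral(*f_cf, dr=dr)
    return _af_from_benefits(b_est, b_cf, formula_mode)


def _af_from_benefits(b_est, b_cf, formula_mode: str):
    b_est = np.asarray(b_est, dtype=float)
    b_cf = np.asarray(b_cf, dtype=float)
    if formula_mode == "pif":
        if np.any(b_est >= 1.0):
            raise ValueError("degenerate denominator: B_est = 1")
        out = (b_cf - b_est) / (1.0 - b_est)
    elif formula_mode == "as_printed":
        out = (b_est - b_cf) / (1.0 + b_est)
    else:
        raise ValueError(f"unknown formula_mode {formula_mode!r}")
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Baseline death rates
# ---------------------------------------------------------------------------

@dataclass
class DeathRates:
    """County x age-group x sex baseline death rates from pooled counts.

    Five calendar years of deaths and person-years are pooled before
    dividing, which stabilizes age groups with few events.
    """

    table: pd.DataFrame  # county, age_lo, age_hi, sex, rate

    @staticmethod
    def from_pooled_counts(deaths: pd.DataFrame) -> "DeathRates":
        t = deaths.copy()
        if (t["deaths"] < 0).any() or (t["person_years"] <= 0).any():
            raise ValueError("need nonnegative deaths and positive person-years")
        t["rate"] = t["deaths"] / t["person_years"]
        return DeathRates(t[["county", "age_lo", "age_hi", "sex", "rate"]])

    def rate(self, county, age, sex) -> np.ndarray:
        """Annual death rate for vectors of county / single age / sex."""
        key = pd.DataFrame({
            "county": np.asarray(county), "age": np.asarray(age),
            "sex": np.asarray(sex),
        })
        t = self.table
        out = np.full(len(key), np.nan)
        for (c, s), grp in t.groupby(["county", "sex"]):
            rows = (key["county"] == c) & (key["sex"] == s)
            if not rows.any():
                continue
            ages = key.loc[rows, "age"].to_numpy(dtype=float)
            vals = np.full(rows.sum(), np.nan)
            for _, r in grp.iterrows():
                inbin = (ages >= r["age_lo"]) & (ages <= r["age_hi"])
                vals[inbin] = r["rate"]
            out[rows.to_numpy()] = vals
        if np.isnan(out).any():
            bad = key.loc[np.isnan(out)].drop_duplicates().head()
            raise ValueError(f"no death rate for strata:\n{bad}")
        return out


# ---------------------------------------------------------------------------
# Scenarios
# ---------------------------------------------------------------------------

@dataclass
class Scenario:
    """Counterfactual definition.

    Kinds: ``fixed_walk_minutes`` (everyone walks a fixed number of
    minutes per week), ``scale_walking`` (walking component scaled by a
    percentage), ``mode_shift`` (a share of one commute category's
    population re-reads its dose from another category), ``elasticity``
    (built-environment elasticities combined into a walking percentage).
    """

    kind: str
    minutes_per_week: float | None = None
    percent: float | None = None
    from_mode: str | None = None
    to_mode: str | None = None
    share: float | None = None
    elasticities: list = field(default_factory=list)
    pct_changes: list = field(default_factory=list)
    combine: str = "additive"

    def __post_init__(self):
        if self.kind not in ("fixed_walk_minutes", "scale_walking",
                             "mode_shift", "elasticity"):
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        if self.share is not None and not 0.0 <= self.share <= 1.0:
            raise ValueError("shifted share must lie in [0, 1]")
        if self.minutes_per_week is not None and self.minutes_per_week < 0:
            raise ValueError("minutes per week must be nonnegative")

    @staticmethod
    def from_dict(d: dict) -> "Scenario":
        return Scenario(**d)

    @staticmethod
    def from_yaml(source) -> "Scenario":
        return Scenario.from_dict(yaml.safe_load(str(source)))


def counterfactual_fixed_walking(minutes_per_week: float) -> float:
    """Weekly MET-hour dose of a fixed weekly walking time."""
    if minutes_per_week < 0:
        raise ValueError("minutes must be nonnegative")
    return minutes_per_week * WALK_MET / 60.0


def combine_elasticities(
    elasticities: Sequence[tuple[str, float]],
    pct_changes: Sequence[float],
    mode: str = "additive",
) -> float:
    """Percent behavior change from built-environment elasticities.

    ``additive``: sum of elasticity x percent-change products.
    ``multiplicative``: 100 * (prod (1 + delta/100)^e - 1).
    """
    values = [v for _, v in elasticities]
    if len(values) != len(pct_changes):
        raise ValueError("need one percent change per elasticity")
    if mode == "additive":
        return float(sum(e * d for e, d in zip(values, pct_changes)))
    if mode == "multiplicative":
        prod = 1.0
        for e, d in zip(values, pct_changes):
            prod *= (1.0 + d / 100.0) ** e
        return 100.0 * (prod - 1.0)
    raise ValueError(f"unknown combination mode {mode!r}")


def scenario_transform(cells: pd.DataFrame, scenario: Scenario) -> pd.DataFrame:
    """Build the paired baseline/counterfactual dose table for a scenario.

    ``cells`` is the joined dose/population table (cell index columns plus
    ``walk_met_wk, bike_met_wk, tpa_sd, persons``).  The result carries
    one row per homogeneous person group with baseline components
    (``walk_est, bike_est``) and counterfactual components
    (``walk_cf, bike_cf``); population totals are conserved.
    """
    out = cells.copy()
    out = out.rename(columns={"walk_met_wk": "walk_est",
                              "bike_met_wk": "bike_est"})
    out["walk_cf"] = out["walk_est"]
    out["bike_cf"] = out["bike_est"]
    out["cf_model_based"] = True

    if scenario.kind == "fixed_walk_minutes":
        out["walk_cf"] = counterfactual_fixed_walking(scenario.minutes_per_week)
        out["bike_cf"] = 0.0
        out["cf_model_based"] = False
        return out

    if scenario.kind in ("scale_walking", "elasticity"):
        pct = (
            scenario.percent
            if scenario.kind == "scale_walking"
            else combine_elasticities(scenario.elasticities,
                                      scenario.pct_changes, scenario.combine)
        )
        out["walk_cf"] = out["walk_est"] * (1.0 + pct / 100.0)
        return out

    # mode_shift: a share of the from-category population re-reads its dose
    # from the to-category cell with the same (age, sex, race, block group)
    if scenario.share is None or scenario.from_mode is None:
        raise ValueError("mode_shift needs from_mode, to_mode, and share")
    key = ["age", "sex", "race_ethnicity", "block_group"]
    from_rows = out["commute_category"] == scenario.from_mode
    to_dose = (
        out.loc[out["commute_category"] == scenario.to_mode]
        .set_index(key)[["walk_est", "bike_est"]]
    )
    shifted = out.loc[from_rows].copy()
    moved = shifted["persons"] * scenario.share
    if (moved - shifted["persons"] > 1e-9).any():
        raise ValueError("cannot shift more than the available population")
    shifted["persons"] = moved
    idx = pd.MultiIndex.from_frame(shifted[key])
    shifted["walk_cf"] = to_dose["walk_est"].reindex(idx).to_numpy()
    shifted["bike_cf"] = to_dose["bike_est"].reindex(idx).to_numpy()
    if shifted[["walk_cf", "bike_cf"]].isna().any().any():
        raise ValueError(
            f"no {scenario.to_mode!r} cells to re-read doses from"
        )
    out.loc[from_rows, "persons"] = out.loc[from_rows, "persons"] - moved.to_numpy()
    return pd.concat([out, shifted], ignore_index=True)


# ---------------------------------------------------------------------------
# Avoided mortality
# ---------------------------------------------------------------------------

@dataclass
class HiaResult:
    """Attributable fractions and avoided deaths with optional intervals."""

    table: pd.DataFrame            # per-stratum AF and avoided deaths
    total_deaths: float
    per_100k: float
    population: float
    formula_mode: str
    intervals: dict = field(default_factory=dict)

    def by(self, *columns) -> pd.DataFrame:
        """Aggregate avoided deaths over any cell margin."""
        return (
            self.table.groupby(list(columns), as_index=False)
            .agg(avoided_deaths=("avoided_deaths", "sum"),
                 persons=("persons", "sum"))
        )

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "total_deaths": self.total_deaths,
                "per_100k": self.per_100k,
                "population": self.population,
                "formula_mode": self.formula_mode,
                "intervals": self.intervals,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


def avoided_mortality(
    paired: pd.DataFrame,
    rates: DeathRates,
    windows: EligibilityWindows = EligibilityWindows(),
    dr: DoseResponse = DoseResponse(),
    formula_mode: str = "pif",
) -> HiaResult:
    """Avoided premature deaths from a paired dose table.

    The attributable fraction is evaluated cell by cell (the dose
    distribution within a cell is a point mass), each component dose
    windowed by age eligibility, then multiplied by the county age/sex
    baseline death rate and the cell's person count.  Totals are sums over
    cells; the per-100,000 rate uses the full table population.
    """
    required = {"county", "age", "sex", "persons",
                "walk_est", "bike_est", "walk_cf", "bike_cf"}
    missing = required - set(paired.columns)
    if missing:
        raise ValueError(f"paired table lacks columns: {sorted(missing)}")
    t = paired.copy()
    dose_est = windows.windowed_dose(t["walk_est"], t["bike_est"], t["age"])
    dose_cf = windows.windowed_dose(t["walk_cf"], t["bike_cf"], t["age"])
    b_est = 1.0 - relative_risk(dose_est, dr)
    b_cf = 1.0 - relative_risk(dose_cf, dr)
    t["af"] = _af_from_benefits(b_est, b_cf, formula_mode)
    t["death_rate"] = rates.rate(t["county"], t["age"], t["sex"])
    t["avoided_deaths"] = t["af"] * t["death_rate"] * t["persons"]
    population = float(t["persons"].sum())
    total = float(t["avoided_deaths"].sum())
    per_100k = 1e5 * total / population if population > 0 else 0.0
    return HiaResult(
        table=t,
        total_deaths=total,
        per_100k=per_100k,
        population=population,
        formula_mode=formula_mode,
    )


def monte_carlo_ci(
    cells: pd.DataFrame,
    scenario: Scenario,
    rates: DeathRates,
    windows: EligibilityWindows = EligibilityWindows(),
    dr: DoseResponse = DoseResponse(),
    formula_mode: str = "pif",
    n_draws: int = 200,
    seed: int | None = 0,
    extra_stats: Callable[[HiaResult], dict] | None = None,
) -> dict:
    """Percentile 95% intervals for avoided deaths under dose uncertainty.

    Each draw perturbs every cell's total dose with independent normal
    noise of its SD (truncated at zero, components rescaled
    proportionally; a zero-dose cell puts perturbed mass into walking),
    re-applies the scenario, and reruns the mortality calculation.
    Deterministic for a fixed seed.
    """
    if n_draws < 100:
        raise ValueError("n_draws must be at least 100")
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    def run(table: pd.DataFrame) -> HiaResult:
        return avoided_mortality(
            scenario_transform(table, scenario), rates, windows, dr,
            formula_mode,
        )

    point = run(cells)
    stats = {"total_deaths": point.total_deaths, "per_100k": point.per_100k}
    if extra_stats is not None:
        stats.update(extra_stats(point))
    draws = {k: np.empty(n_draws) for k in stats}
    sd = cells["tpa_sd"].to_numpy(dtype=float)
    walk = cells["walk_met_wk"].to_numpy(dtype=float)
    bike = cells["bike_met_wk"].to_numpy(dtype=float)
    total = walk + bike
    for j in range(n_draws):
        noise = rng.normal(0.0, 1.0, size=len(cells)) * sd
        new_total = np.clip(total + noise, 0.0, None)
        with np.errstate(invalid="ignore", divide="ignore"):
            factor = np.where(total > 0, new_total / np.where(total > 0, total, 1.0), 0.0)
        pw = np.where(total > 0, walk * factor, new_total)
        pb = np.where(total > 0, bike * factor, 0.0)
        perturbed = cells.assign(walk_met_wk=pw, bike_met_wk=pb)
        res = run(perturbed)
        d = {"total_deaths": res.total_deaths, "per_100k": res.per_100k}
        if extra_stats is not None:
            d.update(extra_stats(res))
        for k in draws:
            draws[k][j] = d[k]
    out = {}
    for k, v in stats.items():
        lo, hi = np.percentile(draws[k], [2.5, 97.5])
        out[k] = {"point": float(v), "ci_low": float(lo), "ci_high": float(hi)}
    return out


def quintile_summary(
    cells: pd.DataFrame,
    result: HiaResult,
    densities: pd.Series,
) -> pd.DataFrame:
    """Density-quintile table: dose, population, and preventable mortality.

    Block groups are ranked by population density and split into five
    equal-count groups; each row reports the population-weighted mean
    weekly dose, total population, preventable deaths, and the per-100,000
    rate, with an ``All`` row for the region.
    """
    if densities.index.nunique() < 5:
        raise ValueError("need at least 5 block groups for quintiles")
    ranks = densities.rank(method="first")
    quint = pd.qcut(ranks, 5, labels=[1, 2, 3, 4, 5])
    per_bg_deaths = (
        result.table.groupby("block_group")["avoided_deaths"].sum()
    )
    per_bg = pd.DataFrame({
        "density": densities,
        "quintile": quint.astype(int),
        "deaths": per_bg_deaths.reindex(densities.index).fillna(0.0),
    })
    cell_bg = cells.groupby("block_group").apply(
        lambda g: pd.Series({
            "population": g["persons"].sum(),
            "dose_weighted": (g["persons"] * (g["walk_met_wk"]
                                              + g["bike_met_wk"])).sum(),
        }),
        include_groups=False,
    )
    per_bg = per_bg.join(cell_bg)
    rows = []
    for q, grp in per_bg.groupby("quintile"):
        pop = grp["population"].sum()
        rows.append({
            "quintile": q,
            "mean_density": grp["density"].mean(),
            "population": pop,
            "tpa_met_h_week": grp["dose_weighted"].sum() / pop if pop else 0.0,
            "preventable_per_100k": 1e5 * grp["deaths"].sum() / pop if pop else 0.0,
            "preventable_deaths": grp["deaths"].sum(),
        })
    pop = per_bg["population"].sum()
    rows.append({
        "quintile": "All",
        "mean_density": per_bg["density"].mean(),
        "population": pop,
        "tpa_met_h_week": per_bg["dose_weighted"].sum() / pop if pop else 0.0,
        "preventable_per_100k": 1e5 * per_bg["deaths"].sum() / pop if pop else 0.0,
        "preventable_deaths": per_bg["deaths"].sum(),
    })
    return pd.DataFrame(rows)
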