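"""Small-area population synthesis from block-group marginal tables.

Block-group marginals (age-by-sex counts, race/ethnicity shares,
commute-mode shares) are combined — under an independence assumption —
into a normalized joint population distribution (NPD) over commute
category x age x sex x race for every block group, then scaled by the
block-group population vector.  Workers are split from non-workers using
county labor-force participation rates smoothed over age with
least-squares cubic splines; missing block-group attributes fall back to
tract and then county values; and the census quirk that cyclists' travel
time to work is pooled with motorcycle/taxi/other modes is handled by
capping it at the private-vehicle time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import LSQUnivariateSpline, interp1d

from .activity_estimator import CELL_INDEX
from .survey_data import MODES, RACE_ETHNICITIES


# ---------------------------------------------------------------------------
# Labor-force smoothing
# ---------------------------------------------------------------------------

class ParticipationSet:
    """Smoothed labor-force participation curves per (county, sex)."""

    def __init__(self, curves: dict[tuple[str, str], object]):
        self._curves = curves

    def rate(self, county: str, sex: str, ages) -> np.ndarray:
        ages = np.asarray(ages, dtype=float)
        try:
            f = self._curves[(county, sex)]
        except KeyError:
            raise KeyError(f"no participation curve for ({county!r}, {sex!r})")
        return np.clip(f(ages), 0.0, 1.0)

    def counties(self):
        return sorted({c for c, _ in self._curves})


def _fit_age_spline(mid: np.ndarray, rates: np.ndarray):
    """Least-squares spline of polynomial order 4 (cubic pieces) with
    interior knots at every other interior age-group midpoint.

    Thinning the knots keeps the least-squares system overdetermined
    (avoiding boundary oscillation); knots are dropped further if the
    Schoenberg-Whitney conditions still reject the fit.
    """
    interior = list(mid[2:-2:2])
    while True:
        try:
            return LSQUnivariateSpline(mid, rates, t=interior, k=3)
        except ValueError:
            if not interior:
                raise
            del interior[len(interior) // 2]


def smooth_labor_force(labor_force: pd.DataFrame) -> ParticipationSet:
    """Smooth binned participation rates into functions of single age.

    Expects columns ``county, sex, age_lo, age_hi, participation`` with
    rates in [0, 1].  Groups with fewer than four age bins fall back to
    step interpolation with a warning.  Evaluations are clamped to [0, 1].
    """
    if ((labor_force["participation"] < 0) | (labor_force["participation"] > 1)).any():
        raise ValueError("participation rates must lie in [0, 1]")
    curves: dict[tuple[str, str], object] = {}
    for (county, sex), grp in labor_force.groupby(["county", "sex"]):
        grp = grp.sort_values("age_lo")
        mid = (grp["age_lo"].to_numpy(float) + grp["age_hi"].to_numpy(float)) / 2.0
        rates = grp["participation"].to_numpy(float)
        if len(grp) < 4:
            warnings.warn(
                f"fewer than 4 age groups for ({county}, {sex}); "
                "using step interpolation"
            )
            curves[(county, sex)] = interp1d(
                mid, rates, kind="previous", bounds_error=False,
                fill_value=(rates[0], rates[-1]),
            )
        else:
            spline = _fit_age_spline(mid, rates)
            lo_m, hi_m = mid[0], mid[-1]
            lo_v, hi_v = float(spline(lo_m)), float(spline(hi_m))

            def f(a, s=spline, lo_m=lo_m, hi_m=hi_m, lo_v=lo_v, hi_v=hi_v):
                a = np.asarray(a, dtype=float)
                out = s(np.clip(a, lo_m, hi_m))
                return np.asarray(out, dtype=float)

            curves[(county, sex)] = f
    return ParticipationSet(curves)


# ---------------------------------------------------------------------------
# Missing-data fallback ladder and the bike-time rule
# ---------------------------------------------------------------------------

def resolve_missing(
    block_groups: pd.DataFrame,
    tracts: pd.DataFrame,
    counties: pd.DataFrame,
    attribute: str,
) -> tuple[pd.Series, pd.Series]:
    """Fill a block-group attribute from tract, then county aggregates.

    Observed block-group values are never overwritten.  Returns the filled
    series and a provenance tag series (``block_group`` / ``tract`` /
    ``county``).  Missing at all three levels raises, naming the attribute
    and county.
    """
    values = block_groups[attribute].copy()
    provenance = pd.Series("block_group", index=block_groups.index)

    tract_vals = block_groups["tract"].map(
        tracts.set_index("tract")[attribute]
    )
    use_tract = values.isna() & tract_vals.notna()
    values[use_tract] = tract_vals[use_tract]
    provenance[use_tract] = "tract"

    county_vals = block_groups["county"].map(
        counties.set_index("county")[attribute]
    )
    use_county = values.isna() & county_vals.notna()
    values[use_county] = county_vals[use_county]
    provenance[use_county] = "county"

    if values.isna().any():
        bad = block_groups.loc[values.isna(), "county"].unique()
        raise ValueError(
            f"attribute {attribute!r} missing at block-group, tract, and "
            f"county level in county(ies) {sorted(bad)}"
        )
    return values, provenance


def bike_time_rule(combined_other_mode_time, private_vehicle_time):
    """Travel time to work for cyclists from the pooled census category.

    Census tables pool bicycle with motorcycle/taxicab/other; when that
    pooled time exceeds the private-vehicle time, the lower (vehicle) value
    is used, otherwise the pooled value stands.
    """
    c = np.asarray(combined_other_mode_time, dtype=float)
    v = np.asarray(private_vehicle_time, dtype=float)
    if (c < 0).any() or (v < 0).any():
        raise ValueError("travel times must be nonnegative")
    out = np.where(c > v, v, c)
    return float(out) if out.ndim == 0 else out


def prepare_block_groups(region) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Resolve travel-time attributes and apply the bike-time rule.

    Returns the block-group table with complete ``ttw_*`` columns
    (including the derived ``ttw_bike``) plus a provenance table recording
    the source level of each filled attribute.
    """
    bg = region.block_groups.copy()
    prov = pd.DataFrame(index=bg.index)
    for col in ("ttw_private_vehicle", "ttw_transit", "ttw_walk",
                "ttw_bike_other"):
        bg[col], prov[col] = resolve_missing(bg, region.tracts,
                                             region.counties, col)
    bg["ttw_bike"] = bike_time_rule(bg["ttw_bike_other"],
                                    bg["ttw_private_vehicle"])
    prov["block_group"] = bg["block_group"]
    return bg, prov


# ---------------------------------------------------------------------------
# Normalized population distributions
# ---------------------------------------------------------------------------

def _expand_ages(age_sex: pd.DataFrame, ages: np.ndarray) -> pd.DataFrame:
    """Uniformly spread binned age-by-sex counts over an age grid.

    Counts are spread uniformly over the single years within each bin,
    then aggregated to the nearest grid age, conserving totals.
    """
    records = []
    grid = np.asarray(sorted(ages))
    for _, row in age_sex.iterrows():
        lo, hi = int(row["age_lo"]), int(row["age_hi"])
        span = np.arange(lo, hi + 1)
        per_age = float(row["count"]) / len(span)
        nearest = grid[np.abs(span[:, None] - grid[None, :]).argmin(axis=1)]
        for g in np.unique(nearest):
            records.append(
                (row["sex"], int(g), per_age * int((nearest == g).sum()))
            )
    out = pd.DataFrame(records, columns=["sex", "age", "count"])
    return out.groupby(["sex", "age"], as_index=False)["count"].sum()


def build_npd(
    profile: pd.Series,
    age_sex: pd.DataFrame,
    participation: ParticipationSet,
    ages=None,
) -> pd.DataFrame:
    """Normalized joint distribution over (commute category, age, sex, race).

    The age-by-sex distribution is normalized, split into workers and
    non-workers by the county participation curve, worker mass is divided
    across the four commute modes by the block group's commute shares, and
    the result is multiplied by the race/ethnicity share vector under
    independence.  Shares sum to 1 (all zero for a zero-population block
    group).
    """
    county = profile["county"]
    if ages is None:
        ages = np.arange(int(age_sex["age_lo"].min()),
                         int(age_sex["age_hi"].max()) + 1)
    expanded = _expand_ages(age_sex, np.asarray(ages))
    total = expanded["count"].sum()
    rows = []
    degenerate = total <= 0 or profile.get("population", total) <= 0
    race_shares = {r: float(profile[f"race_{r}"]) for r in RACE_ETHNICITIES}
    commute_shares = {m: float(profile[f"commute_{m}"]) for m in MODES}
    for _, arow in expanded.iterrows():
        sex, age = arow["sex"], int(arow["age"])
        base = 0.0 if degenerate else float(arow["count"]) / total
        p_work = float(participation.rate(county, sex, [age])[0])
        for race, rs in race_shares.items():
            for mode in MODES:
                rows.append(
                    (mode, age, sex, race,
                     base * p_work * commute_shares[mode] * rs)
                )
            rows.append(
                ("not_in_labor_force", age, sex, race,
                 base * (1.0 - p_work) * rs)
            )
    npd = pd.DataFrame(rows, columns=["commute_category", "age", "sex",
                                      "race_ethnicity", "share"])
    if not degenerate:
        s = npd["share"].sum()
        if abs(s - 1.0) > 1e-6:
            raise AssertionError(f"NPD normalization failed: sum={s}")
        npd["share"] /= s
    return npd


def apply_population(npds: pd.DataFrame, populations: pd.Series) -> pd.DataFrame:
    """Scale per-block-group NPDs by the population vector.

    ``npds`` is long format with a ``block_group`` column and ``share``
    summing to 1 per block group (or all zero for flagged degenerate
    block groups).  The regional person total equals the population sum
    over non-degenerate block groups.
    """
    out = npds.copy()
    out["persons"] = out["share"] * out["block_group"].map(populations)
    return out.drop(columns=["share"])


def build_population(
    region,
    participation: ParticipationSet | None = None,
    ages=None,
) -> pd.DataFrame:
    """NPD x population for every block group in a region.

    Returns a long table over the TPA cell index with a ``persons``
    column; zero-population (special-district) block groups are carried
    with all-zero cells so joins stay aligned.
    """
    if participation is None:
        participation = smooth_labor_force(region.labor_force)
    frames = []
    bg_table = region.block_groups.set_index("block_group")
    for bg_id, profile in bg_table.iterrows():
        age_sex = region.age_sex.loc[region.age_sex["block_group"] == bg_id]
        npd = build_npd(profile, age_sex, participation, ages=ages)
        npd.insert(0, "block_group", bg_id)
        frames.append(npd)
    npds = pd.concat(frames, ignore_index=True)
    pop = apply_population(npds, bg_table["population"])
    return pop[CELL_INDEX + ["persons"]]
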