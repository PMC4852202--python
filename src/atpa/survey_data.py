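"""Reading, harmonizing, cleaning, and stratifying travel-diary survey tables.

Person and trip tables arrive as delimited text shaped like a national
household travel survey release (one diary day per person).  This module
normalizes raw survey codes into the analysis categories, derives the
covariates the regression models use, applies the outlier and missing-data
rules, and splits the sample into working and non-working adults.  Every
removal is accounted for in a :class:`CleaningReport` so that sample-size
deltas reconcile exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

# Collapsed transportation modes. Airplane and "other" survey codes map to
# MODE_OTHER and are dropped as atypical commutes downstream.
MODES = ("private_vehicle", "transit", "walk", "bike")
ACTIVE_MODES = ("walk", "bike")
MODE_OTHER = "other"

# Collapsed roundtrip purposes; vacation-related trips are tagged and removed.
PURPOSES = ("work", "shopping", "social", "recreational", "personal_family")
PURPOSE_VACATION = "vacation"

RACE_ETHNICITIES = ("nh_white", "nh_black", "hispanic", "nh_asian", "nh_other")
SEXES = ("male", "female")
SEASONS = ("winter", "spring", "summer", "fall")
WEEKEND_DAYS = ("saturday", "sunday")
DAYS_OF_WEEK = (
    "monday", "tuesday", "wednesday", "thursday", "friday", "saturday", "sunday"
)

#: Raw mode codes in the style of a national travel survey codebook.  All
#: private vehicle types and carpool collapse to private_vehicle; fixed-route
#: and paratransit services collapse to transit.  Override via the YAML
#: column-mapping config for other codebooks.
DEFAULT_MODE_CODES: dict[int, str] = {
    1: "private_vehicle",   # car
    2: "private_vehicle",   # van
    3: "private_vehicle",   # SUV
    4: "private_vehicle",   # pickup truck
    5: "private_vehicle",   # other truck
    6: "private_vehicle",   # RV
    7: "private_vehicle",   # motorcycle
    8: "private_vehicle",   # carpool / vanpool
    9: "transit",           # local public bus
    10: "transit",          # commuter bus
    11: "transit",          # paratransit / dial-a-ride
    12: "transit",          # commuter rail
    13: "transit",          # subway / elevated
    14: "transit",          # streetcar / trolley
    15: "transit",          # ferry
    16: "bike",
    17: "walk",
    18: MODE_OTHER,         # airplane
    97: MODE_OTHER,         # other
}

#: Negative sentinel codes used for refusals / don't-know / not-ascertained
#: answers in the raw files; normalized to NaN at read time.
DEFAULT_MISSING_CODES = (-1, -7, -8, -9)

#: Month -> season mapping (Dec-Feb winter, Mar-May spring, Jun-Aug summer,
#: Sep-Nov fall).
SEASON_BY_MONTH = {
    12: "winter", 1: "winter", 2: "winter",
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "fall", 10: "fall", 11: "fall",
}


def collapse_modes(raw_mode_code, code_map: Mapping | None = None) -> str:
    """Collapse a raw survey mode code into one of the four analysis modes.

    Returns one of ``private_vehicle``, ``transit``, ``walk``, ``bike`` or the
    sentinel ``other`` (airplane / unclassifiable modes, dropped downstream).

    Raises
    ------
    ValueError
        If the code is absent from the configured code dictionary.
    """
    code_map = DEFAULT_MODE_CODES if code_map is None else code_map
    try:
        return code_map[raw_mode_code]
    except KeyError:
        raise ValueError(
            f"unknown raw mode code {raw_mode_code!r}; "
            "add it to the mode_codes mapping"
        ) from None


def season_from_month(month: int) -> str:
    if not 1 <= int(month) <= 12:
        raise ValueError(f"month must be in 1..12, got {month!r}")
    return SEASON_BY_MONTH[int(month)]


def derive_covariates(
    persons: pd.DataFrame,
    month_col: str = "month",
    travel_day_col: str = "travel_day",
    raw_density_col: str = "raw_density",
) -> pd.DataFrame:
    """Attach season, weekend flag, and density in thousands per square mile.

    ``season`` comes from the calendar month, ``weekend`` is true iff the
    travel day is Saturday or Sunday, and ``pop_density_k`` is the raw
    persons-per-square-mile density divided by 1,000.
    """
    out = persons.copy()
    out["season"] = out[month_col].map(season_from_month)
    days = out[travel_day_col].astype(str).str.lower()
    unknown = set(days.unique()) - set(DAYS_OF_WEEK)
    if unknown:
        raise ValueError(f"unknown travel day values: {sorted(unknown)}")
    out["weekend"] = days.isin(WEEKEND_DAYS)
    density = out[raw_density_col].astype(float)
    if (density < 0).any():
        raise ValueError("population density must be nonnegative")
    out["pop_density_k"] = density / 1000.0
    return out


def derive_trip_counts(persons: pd.DataFrame, trips: pd.DataFrame) -> pd.DataFrame:
    """Sum retained walk and bike trips per person onto the person table.

    Persons with no linked trips get zero counts.  Trips whose ``person_id``
    does not occur in the person table are an error.
    """
    orphans = set(trips["person_id"]) - set(persons["person_id"])
    if orphans:
        raise ValueError(
            f"trips reference person_ids absent from the person table: "
            f"{sorted(orphans)[:10]}"
        )
    out = persons.copy()
    for mode, col in (("walk", "walk_trip_count"), ("bike", "bike_trip_count")):
        counts = (
            trips.loc[trips["mode"] == mode]
            .groupby("person_id")
            .size()
        )
        out[col] = out["person_id"].map(counts).fillna(0).astype(int)
    return out


@dataclass
class CleaningReport:
    """Per-rule removal counts; removals reconcile with table-size deltas."""

    person_rules: dict[str, int] = field(default_factory=dict)
    trip_rules: dict[str, int] = field(default_factory=dict)
    duration_thresholds: dict[str, float] = field(default_factory=dict)
    input_sizes: dict[str, int] = field(default_factory=dict)
    output_sizes: dict[str, int] = field(default_factory=dict)

    def persons_removed(self) -> int:
        return sum(self.person_rules.values())

    def trips_removed(self) -> int:
        return sum(self.trip_rules.values())

    def to_json(self, path=None) -> str:
        payload = json.dumps(self.__dict__, indent=2, default=float)
        if path is not None:
            Path(path).write_text(payload)
        return payload


def _cascade_trips(trips, dropped_ids, rule, trip_rules):
    linked = trips["person_id"].isin(dropped_ids)
    trip_rules[rule] = trip_rules.get(rule, 0) + int(linked.sum())
    return trips.loc[~linked]


def remove_atypical(
    persons: pd.DataFrame,
    trips: pd.DataFrame,
    max_commute_minutes: float = 120.0,
    tail_quantile: float = 0.99,
    duration_thresholds: Mapping[str, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, CleaningReport]:
    """Remove responses that do not reflect routine transportation.

    Person rules: out of town on the travel day; commuting by airplane or
    "other" modes; work commutes strictly longer than ``max_commute_minutes``
    (2 h by default, the boundary value is kept).  Trip rules: trips linked
    to removed persons; non-active trips; vacation-related trips; active
    trips with durations strictly above the mode-specific ``tail_quantile``
    (top 1%) threshold.

    The duration thresholds are estimated once, from the active trips that
    survive the preceding rules, and recorded in the report.  Pass
    ``duration_thresholds`` (e.g. from a previous report) to reuse recorded
    cuts instead of re-estimating them, which makes re-cleaning already
    cleaned data an exact no-op.
    """
    report = CleaningReport(
        input_sizes={"persons": len(persons), "trips": len(trips)}
    )
    p, t = persons, trips

    out = p["out_of_town"].fillna(False).astype(bool)
    report.person_rules["out_of_town"] = int(out.sum())
    dropped = set(p.loc[out, "person_id"])
    p = p.loc[~out]
    t = _cascade_trips(t, dropped, "linked_to_dropped_person", report.trip_rules)

    other = p["commute_mode"].eq(MODE_OTHER).fillna(False)
    report.person_rules["airplane_or_other_commute"] = int(other.sum())
    dropped = set(p.loc[other, "person_id"])
    p = p.loc[~other]
    t = _cascade_trips(t, dropped, "linked_to_dropped_person", report.trip_rules)

    long_commute = p["time_to_work"] > max_commute_minutes
    long_commute = long_commute.fillna(False)
    report.person_rules["commute_over_2h"] = int(long_commute.sum())
    dropped = set(p.loc[long_commute, "person_id"])
    p = p.loc[~long_commute]
    t = _cascade_trips(t, dropped, "linked_to_dropped_person", report.trip_rules)

    if (t["duration"] <= 0).any():
        raise ValueError("trip durations must be strictly positive")

    nonactive = ~t["mode"].isin(ACTIVE_MODES)
    report.trip_rules["non_active"] = int(nonactive.sum())
    t = t.loc[~nonactive]

    vacation = t["purpose"].eq(PURPOSE_VACATION)
    report.trip_rules["vacation"] = int(vacation.sum())
    t = t.loc[~vacation]

    # Mode-specific top-tail cut on the retained active trips; strictly
    # greater than the empirical quantile (linear interpolation), keeping ties.
    thresholds = dict(duration_thresholds) if duration_thresholds else {}
    tail_mask = pd.Series(False, index=t.index)
    for mode in ACTIVE_MODES:
        d = t.loc[t["mode"] == mode, "duration"]
        if mode not in thresholds:
            if len(d) == 0:
                continue
            thresholds[mode] = float(np.quantile(d, tail_quantile))
        tail_mask.loc[d.index] = d > thresholds[mode]
    report.trip_rules["duration_top_tail"] = int(tail_mask.sum())
    report.duration_thresholds = thresholds
    t = t.loc[~tail_mask]

    report.output_sizes = {"persons": len(p), "trips": len(t)}
    return p.copy(), t.copy(), report


#: Person variables whose missingness removes the person (commute mode is
#: conditional on worker status).
MISSING_DROP_VARS = ("race_ethnicity", "education", "medical_condition")


def drop_missing(
    persons: pd.DataFrame, trips: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, CleaningReport]:
    """Drop persons with missing modeling variables, cascading their trips.

    Race/ethnicity, education, and the travel-restricting medical condition
    flag are required for everyone; commute mode to work is required for
    working adults only.
    """
    report = CleaningReport(
        input_sizes={"persons": len(persons), "trips": len(trips)}
    )
    p, t = persons, trips
    for var in MISSING_DROP_VARS:
        miss = p[var].isna()
        report.person_rules[f"missing_{var}"] = int(miss.sum())
        dropped = set(p.loc[miss, "person_id"])
        p = p.loc[~miss]
        t = _cascade_trips(t, dropped, "linked_to_dropped_person", report.trip_rules)

    miss_commute = p["worker"].astype(bool) & p["commute_mode"].isna()
    report.person_rules["missing_commute_mode_workers"] = int(miss_commute.sum())
    dropped = set(p.loc[miss_commute, "person_id"])
    p = p.loc[~miss_commute]
    t = _cascade_trips(t, dropped, "linked_to_dropped_person", report.trip_rules)

    report.output_sizes = {"persons": len(p), "trips": len(t)}
    return p.copy(), t.copy(), report


def stratify(persons: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Partition adults (18+) into working and non-working strata.

    Age 18 is included ("aged 18 and over"); persons under 18 are excluded
    from both strata.
    """
    adults = persons.loc[persons["age"] >= 18]
    worker = adults["worker"].astype(bool)
    return {
        "working_adults": adults.loc[worker].copy(),
        "nonworking_adults": adults.loc[~worker].copy(),
    }


# ---------------------------------------------------------------------------
# Delimited-text ingestion with a column-mapping config
# ---------------------------------------------------------------------------

def default_mapping() -> dict:
    """Column-mapping config for files already using analysis column names."""
    return {
        "missing_codes": list(DEFAULT_MISSING_CODES),
        "mode_codes": None,  # modes already collapsed
        "persons": {"columns": {}},
        "trips": {"columns": {}},
    }


def load_mapping(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _normalize_missing(df, codes):
    return df.replace(list(codes), np.nan) if codes else df


def read_survey(
    person_path,
    trip_path,
    mapping: Mapping | None = None,
    sep: str = ",",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read person and trip tables, renaming columns and normalizing codes.

    ``mapping`` follows :func:`default_mapping`: per-table raw->analysis
    column renames, a raw mode code dictionary (or ``None`` if modes are
    already collapsed), and the sentinel codes that encode missing answers.
    """
    mapping = dict(default_mapping() if mapping is None else mapping)
    persons = pd.read_csv(person_path, sep=sep)
    trips = pd.read_csv(trip_path, sep=sep)
    pcols = mapping.get("persons", {}).get("columns") or {}
    tcols = mapping.get("trips", {}).get("columns") or {}
    persons = persons.rename(columns={v: k for k, v in pcols.items()})
    trips = trips.rename(columns={v: k for k, v in tcols.items()})
    codes = mapping.get("missing_codes") or ()
    persons = _normalize_missing(persons, codes)
    trips = _normalize_missing(trips, codes)
    mode_codes = mapping.get("mode_codes")
    if mode_codes is not None:
        mode_codes = {int(k): v for k, v in mode_codes.items()}
        trips["mode"] = trips["mode"].map(
            lambda c: collapse_modes(int(c), mode_codes) if pd.notna(c) else c
        )
        persons["commute_mode"] = persons["commute_mode"].map(
            lambda c: collapse_modes(int(c), mode_codes) if pd.notna(c) else c
        )
    return persons, trips


def write_cleaned(persons, trips, report: CleaningReport, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    persons.to_csv(outdir / "persons_clean.csv", index=False)
    trips.to_csv(outdir / "trips_clean.csv", index=False)
    report.to_json(outdir / "cleaning_report.json")
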