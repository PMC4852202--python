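"""Seeded synthetic travel surveys and census-style regional inputs.

The generator is the exact statistical inverse of the estimation pipeline:
daily walk/bike trip counts are drawn from a zero-inflated Poisson law whose
inflation probability and rate are logit/log-linear in person covariates,
each trip's purpose is drawn from multinomial-logit probabilities, and trip
durations are lognormal around a log-linear mean with a shared person-level
random effect so trips are correlated within persons (the marginal mean is
offset-corrected to match the log link exactly).

It also builds a nested block-group / tract / county region with
age-by-sex counts, race and commute-mode shares, mean travel times to work
with planted missingness (to exercise the fallback ladder), county death
counts pooled over five years, and smooth age-specific labor-force
participation — the small-area inputs the population builder and health
impact engine consume.

Coefficients are written with friendly keys (``Intercept``,
``pop_density_k``, ``commute_mode=walk``, ``purpose=work:log_ttw``) that
map one-to-one onto the patsy design columns used at fit time, so planted
truth can be compared directly with recovered estimates.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .survey_data import DAYS_OF_WEEK, MODES, PURPOSES, RACE_ETHNICITIES, SEASONS

EDUCATION_LEVELS = ("hs_or_less", "some_college", "college")
STATES = ("s1", "s2", "s3", "s4", "s5", "s6")

#: Adult age bins in the style of small-area census releases.
AGE_BINS = (
    (18, 24), (25, 34), (35, 44), (45, 54),
    (55, 64), (65, 74), (75, 84), (85, 96),
)


# ---------------------------------------------------------------------------
# Friendly-key linear predictors (generator-side; independent of patsy)
# ---------------------------------------------------------------------------

def _factor_values(df: pd.DataFrame, token: str) -> np.ndarray:
    if token == "Intercept":
        return np.ones(len(df))
    if "=" in token:
        var, lev = token.split("=", 1)
        return (df[var].astype(str) == lev).to_numpy(dtype=float)
    return df[token].to_numpy(dtype=float)


def linear_predictor(df: pd.DataFrame, coef: dict[str, float]) -> np.ndarray:
    """Evaluate ``sum_k coef[k] * x_k`` with friendly coefficient keys."""
    lp = np.zeros(len(df))
    for key, value in coef.items():
        x = np.ones(len(df))
        for token in key.split(":"):
            x = x * _factor_values(df, token)
        lp += value * x
    return lp


# ---------------------------------------------------------------------------
# Truth configuration
# ---------------------------------------------------------------------------

@dataclass
class ModeTruth:
    """Generative coefficients for one (stratum, mode) model triple."""

    infl: dict[str, float]
    count: dict[str, float]
    purpose_base: str
    purpose: dict[str, dict[str, float]]
    duration: dict[str, float]


@dataclass
class CovariateConfig:
    """Marginal distributions for synthetic person covariates."""

    n_persons: int = 10_000
    age_mean: float = 47.0
    age_sd: float = 17.0
    age_range: tuple[int, int] = (18, 95)
    p_female: float = 0.51
    race_shares: dict[str, float] = field(
        default_factory=lambda: {
            "nh_white": 0.64, "nh_black": 0.12, "hispanic": 0.16,
            "nh_asian": 0.05, "nh_other": 0.03,
        }
    )
    density_k_log_mean: float = 0.3
    density_k_log_sd: float = 0.9
    pct_rental_beta: tuple[float, float] = (2.0, 4.0)
    commute_shares: dict[str, float] = field(
        default_factory=lambda: {
            "private_vehicle": 0.88, "transit": 0.05, "walk": 0.04, "bike": 0.03,
        }
    )
    ttw_log_mean: float = np.log(20.0)
    ttw_log_sd: float = 0.6
    education_shares: dict[str, float] = field(
        default_factory=lambda: {
            "hs_or_less": 0.35, "some_college": 0.30, "college": 0.35,
        }
    )
    p_heavy_rail: float = 0.25
    p_medical: float = 0.07
    p_proxy: float = 0.10
    p_out_of_town: float = 0.0
    p_missing: float = 0.0


@dataclass
class TruthConfig:
    """Full generative truth: covariate marginals plus model coefficients."""

    covariates: CovariateConfig
    workers: dict[str, ModeTruth]
    nonworkers: dict[str, ModeTruth]
    duration_icc: float = 0.30
    duration_log_sd: float = 0.55

    def __post_init__(self):
        if not 0.0 <= self.duration_icc < 1.0:
            raise ValueError("duration_icc must lie in [0, 1)")
        for shares in (self.covariates.race_shares, self.covariates.commute_shares,
                       self.covariates.education_shares):
            if abs(sum(shares.values()) - 1.0) > 1e-9:
                raise ValueError("covariate shares must sum to 1")

    def mode_truth(self, stratum: str, mode: str) -> ModeTruth:
        table = self.workers if stratum == "workers" else self.nonworkers
        return table[mode]

    def to_yaml(self, path=None) -> str:
        def plain(obj):
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            if isinstance(obj, np.generic):
                return obj.item()
            return obj

        payload = yaml.safe_dump(plain(asdict(self)), sort_keys=False)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @staticmethod
    def from_yaml(source) -> "TruthConfig":
        text = str(source)
        if "\n" not in text and Path(text).exists():
            text = Path(text).read_text()
        d = yaml.safe_load(text)
        cov = CovariateConfig(**{
            k: (tuple(v) if isinstance(v, list) else v)
            for k, v in d["covariates"].items()
        })
        def modes(block):
            return {m: ModeTruth(**mt) for m, mt in block.items()}
        return TruthConfig(
            covariates=cov,
            workers=modes(d["workers"]),
            nonworkers=modes(d["nonworkers"]),
            duration_icc=d["duration_icc"],
            duration_log_sd=d["duration_log_sd"],
        )


def participation_curve(age, sex: str, shift: float = 0.0) -> np.ndarray:
    """Smooth labor-force participation by single age: rise at labor-market
    entry, plateau, decline through retirement."""
    age = np.asarray(age, dtype=float)
    peak = 0.86 if sex == "male" else 0.76
    entry = 1.0 / (1.0 + np.exp(-(age - 19.0) / 1.5))
    exit_ = 1.0 / (1.0 + np.exp((age - 62.0 - shift) / 4.0))
    return np.clip(peak * entry * exit_, 0.0, 1.0)


def default_truth(n_persons: int = 10_000) -> TruthConfig:
    """Study-condition defaults: sparse walk/bike counts with excess zeros,
    strong commute-mode effects on trip-making and purpose mix, and
    durations in the 8-30 minute range with purpose interactions."""
    workers = {
        "walk": ModeTruth(
            infl={
                "Intercept": 1.3, "commute_mode=transit": -1.55,
                "commute_mode=walk": -2.81, "commute_mode=bike": -0.69,
                "pop_density_k": -0.03, "pct_rental": -0.01,
            },
            count={
                "Intercept": -0.25, "commute_mode=transit": 0.086,
                "commute_mode=walk": 0.52, "commute_mode=bike": 0.24,
                "pop_density_k": 0.01, "pct_rental": 0.002,
                "weekend=True": -0.10,
            },
            purpose_base="work",
            purpose={
                "shopping": {
                    "Intercept": 0.9, "commute_mode=walk": -2.5,
                    "commute_mode=transit": -1.2, "commute_mode=bike": -1.0,
                    "pct_rental": 0.005,
                },
                "social": {
                    "Intercept": 0.6, "commute_mode=walk": -2.6,
                    "commute_mode=transit": -1.3, "commute_mode=bike": -1.1,
                    "age": -0.01,
                },
                "recreational": {
                    "Intercept": 0.8, "commute_mode=walk": -2.9,
                    "commute_mode=transit": -1.5, "commute_mode=bike": -1.2,
                    "pop_density_k": -0.03,
                },
                "personal_family": {
                    "Intercept": 1.0, "commute_mode=walk": -2.4,
                    "commute_mode=transit": -1.1, "commute_mode=bike": -1.0,
                },
            },
            duration={
                "Intercept": 0.94,
                "purpose=shopping": 1.02, "purpose=social": 1.07,
                "purpose=recreational": 2.05, "purpose=personal_family": 1.28,
                "purpose=work:log_ttw": 0.54, "purpose=shopping:log_ttw": 0.06,
                "purpose=social:log_ttw": 0.08,
                "purpose=recreational:log_ttw": -0.02,
                "purpose=personal_family:log_ttw": 0.07,
                "purpose=work:commute_mode=transit": -0.40,
                "purpose=work:commute_mode=bike": 0.30,
                "purpose=recreational:pop_density_k": -0.004,
                "purpose=shopping:pct_rental": 0.002,
                "age": 0.002,
            },
        ),
        "bike": ModeTruth(
            infl={
                "Intercept": 3.3, "commute_mode=transit": -1.10,
                "commute_mode=walk": -0.27, "commute_mode=bike": -5.70,
                "pop_density_k": -0.04, "sex=female": 1.24,
            },
            count={
                "Intercept": 0.41, "commute_mode=transit": 0.18,
                "commute_mode=walk": -0.09, "commute_mode=bike": 0.39,
            },
            purpose_base="work",
            purpose={
                "shopping": {"Intercept": 0.5, "commute_mode=bike": -2.8,
                             "commute_mode=transit": -0.9},
                "social": {"Intercept": 0.3, "commute_mode=bike": -2.6,
                           "commute_mode=transit": -1.0},
                "recreational": {"Intercept": 1.1, "commute_mode=bike": -3.3,
                                 "commute_mode=transit": -1.4},
                "personal_family": {"Intercept": 0.6, "commute_mode=bike": -2.7,
                                    "commute_mode=transit": -1.0},
            },
            duration={
                "Intercept": 0.80,
                "purpose=shopping": 0.95, "purpose=social": 1.55,
                "purpose=recreational": 2.45, "purpose=personal_family": 1.25,
                "purpose=work:log_ttw": 0.73, "purpose=shopping:log_ttw": 0.36,
                "purpose=social:log_ttw": 0.18,
                "purpose=personal_family:log_ttw": 0.30,
                "purpose=work:commute_mode=private_vehicle": 0.38,
                "purpose=shopping:pct_rental": -0.005,
                "sex=female": -0.075, "age": 0.004,
            },
        ),
    }
    nonworkers = {
        "walk": ModeTruth(
            infl={
                "Intercept": 0.5, "age": 0.010,
                "pop_density_k": -0.03, "pct_rental": -0.01,
            },
            count={
                "Intercept": -0.24, "pop_density_k": 0.010,
                "pct_rental": 0.004, "age": 0.010, "age_sq": -0.0001,
                "weekend=True": -0.10,
            },
            purpose_base="recreational",
            purpose={
                "shopping": {"Intercept": 0.2, "pct_rental": 0.010,
                             "age": -0.006},
                "social": {"Intercept": -0.1, "age": -0.016},
                "personal_family": {"Intercept": 0.1, "age": -0.016,
                                    "sex=female": 0.26},
            },
            duration={
                "Intercept": 3.05,
                "purpose=shopping": -0.71, "purpose=social": -0.76,
                "purpose=personal_family": -0.46,
                "purpose=social:pop_density_k": 0.011,
                "purpose=shopping:pct_rental": 0.003,
                "age": 0.006, "age_sq": -0.0001, "sex=female": -0.083,
            },
        ),
        "bike": ModeTruth(
            infl={"Intercept": 2.6, "age": 0.020, "sex=female": 1.47},
            count={"Intercept": 0.55, "sex=female": -0.31},
            purpose_base="recreational",
            purpose={
                "shopping": {"Intercept": -0.6, "pop_density_k": 0.10,
                             "age": 0.010},
                "social": {"Intercept": -0.3, "age": -0.005},
                "personal_family": {"Intercept": -0.4, "pct_rental": 0.015,
                                    "age": -0.010},
            },
            duration={
                "Intercept": 3.15,
                "purpose=shopping": -0.58, "purpose=social": -0.45,
                "purpose=personal_family": -0.39,
                "sex=female": -0.19,
            },
        ),
    }
    return TruthConfig(
        covariates=CovariateConfig(n_persons=n_persons),
        workers=workers,
        nonworkers=nonworkers,
    )


# ---------------------------------------------------------------------------
# Survey generation
# ---------------------------------------------------------------------------

def _draw_categorical(rng, shares: dict[str, float], n: int) -> np.ndarray:
    cats = list(shares)
    return rng.choice(cats, size=n, p=[shares[c] for c in cats])


def _draw_persons(truth: TruthConfig, rng, weekday_only: bool = False) -> pd.DataFrame:
    cov = truth.covariates
    n = cov.n_persons
    age = np.clip(
        np.round(rng.normal(cov.age_mean, cov.age_sd, size=n)),
        *cov.age_range,
    ).astype(int)
    sex = np.where(rng.random(n) < cov.p_female, "female", "male")
    p_work = np.where(
        sex == "female",
        participation_curve(age, "female"),
        participation_curve(age, "male"),
    )
    worker = rng.random(n) < p_work
    commute = np.where(
        worker, _draw_categorical(rng, cov.commute_shares, n), None
    )
    ttw = np.where(
        worker, rng.lognormal(cov.ttw_log_mean, cov.ttw_log_sd, size=n), np.nan
    )
    if weekday_only:
        travel_day = rng.choice(DAYS_OF_WEEK[:5], size=n)
    else:
        travel_day = rng.choice(DAYS_OF_WEEK, size=n)
    state = rng.choice(STATES, size=n)
    state_idx = np.array([STATES.index(s) for s in state])
    persons = pd.DataFrame(
        {
            "person_id": np.arange(n),
            "household_id": np.arange(n),
            "age": age,
            "age_sq": (age.astype(float)) ** 2,
            "sex": sex,
            "race_ethnicity": _draw_categorical(rng, cov.race_shares, n),
            "education": _draw_categorical(rng, cov.education_shares, n),
            "worker": worker,
            "commute_mode": commute,
            "time_to_work": ttw,
            "medical_condition": rng.random(n) < cov.p_medical,
            "proxy_interview": rng.random(n) < cov.p_proxy,
            "out_of_town": rng.random(n) < cov.p_out_of_town,
            "travel_day": travel_day,
            "season": rng.choice(SEASONS, size=n),
            "heavy_rail_msa": rng.random(n) < cov.p_heavy_rail,
            "state_id": state,
            "division_id": np.array([f"d{i // 2}" for i in state_idx]),
            "region_id": np.array([f"r{i // 4}" for i in state_idx]),
            "pop_density_k": rng.lognormal(
                cov.density_k_log_mean, cov.density_k_log_sd, size=n
            ),
            "pct_rental": 100.0 * rng.beta(*cov.pct_rental_beta, size=n),
            "survey_weight": rng.lognormal(0.0, 0.5, size=n),
        }
    )
    persons["weekend"] = persons["travel_day"].isin(("saturday", "sunday"))
    persons["log_ttw"] = np.log(persons["time_to_work"]).fillna(0.0)
    return persons


def zip_counts(rng, pi: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """Draw from the zero-inflated Poisson law cellwise."""
    structural = rng.random(len(pi)) < pi
    return np.where(structural, 0, rng.poisson(lam))


def purpose_probabilities_from_truth(
    df: pd.DataFrame, mt: ModeTruth
) -> pd.DataFrame:
    """Closed-form multinomial-logit purpose probabilities under the truth."""
    outcomes = [mt.purpose_base] + list(mt.purpose)
    eta = np.zeros((len(df), len(outcomes)))
    for j, p in enumerate(mt.purpose, start=1):
        eta[:, j] = linear_predictor(df, mt.purpose[p])
    eta -= eta.max(axis=1, keepdims=True)
    w = np.exp(eta)
    return pd.DataFrame(w / w.sum(axis=1, keepdims=True), columns=outcomes,
                        index=df.index)


def _draw_trips_for_mode(
    persons: pd.DataFrame,
    counts: np.ndarray,
    mode: str,
    mt: ModeTruth,
    icc: float,
    log_sd: float,
    rng,
    person_effect: np.ndarray,
) -> pd.DataFrame:
    takers = counts > 0
    if not takers.any():
        return pd.DataFrame(
            columns=["person_id", "mode", "purpose", "duration", "travel_day"]
        )
    rep = np.repeat(np.flatnonzero(takers), counts[takers])
    rows = persons.iloc[rep].reset_index(drop=True)
    probs = purpose_probabilities_from_truth(rows, mt).to_numpy()
    cum = probs.cumsum(axis=1)
    u = rng.random(len(rows))[:, None]
    outcome_idx = (u > cum).sum(axis=1)
    outcomes = [mt.purpose_base] + list(mt.purpose)
    purpose = np.array(outcomes)[outcome_idx]
    rows = rows.assign(purpose=purpose)
    # lognormal duration around the log-link mean: subtract sigma^2/2 so
    # E[duration | x] = exp(x'beta) exactly
    sigma_b = log_sd * np.sqrt(icc)
    sigma_e = log_sd * np.sqrt(1.0 - icc)
    b = person_effect[rep] * sigma_b
    e = rng.normal(0.0, sigma_e, size=len(rows))
    log_mean = linear_predictor(rows, mt.duration)
    duration = np.exp(log_mean - 0.5 * log_sd**2 + b + e)
    return pd.DataFrame(
        {
            "person_id": rows["person_id"].to_numpy(),
            "mode": mode,
            "purpose": purpose,
            "duration": duration,
            "travel_day": rows["travel_day"].to_numpy(),
        }
    )


def generate_survey(
    truth: TruthConfig, seed: int | None = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a person table and linked trip table under the truth.

    Deterministic for a fixed seed.  Counts follow the zero-inflated
    Poisson law, purposes the multinomial logit, durations the log-link
    mean with within-person correlation ``duration_icc``.
    """
    _validate_truth(truth)
    ss = np.random.SeedSequence(seed)
    rng_p, rng_c, rng_t = (np.random.default_rng(s) for s in ss.spawn(3))
    persons = _draw_persons(truth, rng_p)
    person_effect = rng_t.standard_normal(len(persons))

    counts = {}
    for mode in ("walk", "bike"):
        n = len(persons)
        pi = np.zeros(n)
        lam = np.zeros(n)
        for stratum, mask in (
            ("workers", persons["worker"].to_numpy()),
            ("nonworkers", ~persons["worker"].to_numpy()),
        ):
            mt = truth.mode_truth(stratum, mode)
            sub = persons.loc[mask]
            pi[mask] = 1.0 / (1.0 + np.exp(-linear_predictor(sub, mt.infl)))
            lam[mask] = np.exp(linear_predictor(sub, mt.count))
        counts[mode] = zip_counts(rng_c, pi, lam)

    persons["walk_trip_count"] = counts["walk"]
    persons["bike_trip_count"] = counts["bike"]
    persons["trips_on_day"] = (
        counts["walk"] + counts["bike"] + rng_c.poisson(2.5, size=len(persons))
    )

    trip_frames = []
    for mode in ("walk", "bike"):
        for stratum, mask in (
            ("workers", persons["worker"].to_numpy()),
            ("nonworkers", ~persons["worker"].to_numpy()),
        ):
            mt = truth.mode_truth(stratum, mode)
            mode_counts = np.where(mask, counts[mode], 0)
            trip_frames.append(
                _draw_trips_for_mode(
                    persons, mode_counts, mode, mt,
                    truth.duration_icc, truth.duration_log_sd,
                    rng_t, person_effect,
                )
            )
    trips = pd.concat(trip_frames, ignore_index=True)
    trips = trips.sort_values(["person_id", "mode"]).reset_index(drop=True)

    if truth.covariates.p_missing > 0:
        rng_m = np.random.default_rng(ss.spawn(1)[0])
        for col in ("race_ethnicity", "education", "commute_mode"):
            mask = rng_m.random(len(persons)) < truth.covariates.p_missing
            persons.loc[mask, col] = np.nan
    return persons, trips


def _validate_truth(truth: TruthConfig) -> None:
    for stratum in ("workers", "nonworkers"):
        table = truth.workers if stratum == "workers" else truth.nonworkers
        for mode, mt in table.items():
            if mode not in ("walk", "bike"):
                raise ValueError(f"unknown mode block {mode!r}")
            if mt.purpose_base in mt.purpose:
                raise ValueError(
                    f"{stratum}/{mode}: base purpose {mt.purpose_base!r} must "
                    "not appear among the non-base purpose coefficient blocks"
                )
            for p in mt.purpose:
                if p not in PURPOSES:
                    raise ValueError(f"{stratum}/{mode}: unknown purpose {p!r}")


def generate_validation_survey(
    truth: TruthConfig, n: int, seed: int | None = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Single-weekday diaries for banded validation (workers and non-workers).

    Observed MET-hours per person are computable from the trip table with
    the standard walking/cycling MET conversion.
    """
    if n == 0:
        persons, trips = generate_survey(
            TruthConfig(
                covariates=CovariateConfig(n_persons=1),
                workers=truth.workers,
                nonworkers=truth.nonworkers,
                duration_icc=truth.duration_icc,
                duration_log_sd=truth.duration_log_sd,
            ),
            seed,
        )
        return persons.iloc[:0].copy(), trips.iloc[:0].copy()
    cov = CovariateConfig(**{**asdict(truth.covariates), "n_persons": n})
    vt = TruthConfig(
        covariates=cov,
        workers=truth.workers,
        nonworkers=truth.nonworkers,
        duration_icc=truth.duration_icc,
        duration_log_sd=truth.duration_log_sd,
    )
    ss = np.random.SeedSequence(seed)
    rng_p, rng_c, rng_t = (np.random.default_rng(s) for s in ss.spawn(3))
    persons = _draw_persons(vt, rng_p, weekday_only=True)
    person_effect = rng_t.standard_normal(len(persons))
    counts = {}
    for mode in ("walk", "bike"):
        pi = np.zeros(n)
        lam = np.zeros(n)
        for stratum, mask in (
            ("workers", persons["worker"].to_numpy()),
            ("nonworkers", ~persons["worker"].to_numpy()),
        ):
            mt = vt.mode_truth(stratum, mode)
            sub = persons.loc[mask]
            pi[mask] = 1.0 / (1.0 + np.exp(-linear_predictor(sub, mt.infl)))
            lam[mask] = np.exp(linear_predictor(sub, mt.count))
        counts[mode] = zip_counts(rng_c, pi, lam)
    persons["walk_trip_count"] = counts["walk"]
    persons["bike_trip_count"] = counts["bike"]
    persons["trips_on_day"] = (
        counts["walk"] + counts["bike"] + rng_c.poisson(2.5, size=n)
    )
    frames = []
    for mode in ("walk", "bike"):
        for stratum, mask in (
            ("workers", persons["worker"].to_numpy()),
            ("nonworkers", ~persons["worker"].to_numpy()),
        ):
            mt = vt.mode_truth(stratum, mode)
            mode_counts = np.where(mask, counts[mode], 0)
            frames.append(
                _draw_trips_for_mode(
                    persons, mode_counts, mode, mt,
                    vt.duration_icc, vt.duration_log_sd, rng_t, person_effect,
                )
            )
    trips = pd.concat(frames, ignore_index=True)
    return persons, trips


# ---------------------------------------------------------------------------
# Regional (census-style) inputs
# ---------------------------------------------------------------------------

@dataclass
class RegionConfig:
    """Shape and missingness of the synthetic region."""

    n_counties: int = 2
    tracts_per_county: int = 3
    bgs_per_tract: int = 5
    n_block_groups: int | None = None  # overrides the product if set
    missing_bg_rate: float = 0.15
    missing_tract_rate: float = 0.10
    n_zero_population: int = 1
    death_rate_at_20: float = 8e-4
    death_rate_doubling_years: float = 8.0


@dataclass
class SyntheticRegion:
    """Nested geography tables plus vital-statistics and labor-force inputs."""

    block_groups: pd.DataFrame
    tracts: pd.DataFrame
    counties: pd.DataFrame
    age_sex: pd.DataFrame
    deaths: pd.DataFrame
    labor_force: pd.DataFrame

    def write_csvs(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in ("block_groups", "tracts", "counties", "age_sex",
                     "deaths", "labor_force"):
            getattr(self, name).to_csv(outdir / f"{name}.csv", index=False)

    @staticmethod
    def read_csvs(indir) -> "SyntheticRegion":
        indir = Path(indir)
        return SyntheticRegion(
            **{
                name: pd.read_csv(indir / f"{name}.csv")
                for name in ("block_groups", "tracts", "counties", "age_sex",
                             "deaths", "labor_force")
            }
        )


#: Age-group shares for the adult population pyramid (sums to 1).
_AGE_GROUP_SHARES = (0.12, 0.18, 0.17, 0.18, 0.16, 0.11, 0.06, 0.02)

TTW_COLUMNS = ("ttw_private_vehicle", "ttw_transit", "ttw_walk", "ttw_bike_other")


def mortality_rate(age, config: RegionConfig) -> np.ndarray:
    """Age-increasing annual all-cause death rate (exponential in age)."""
    age = np.asarray(age, dtype=float)
    growth = np.log(2.0) / config.death_rate_doubling_years
    return config.death_rate_at_20 * np.exp(growth * (age - 20.0))


def generate_region(
    config: RegionConfig | None = None, seed: int | None = 0
) -> SyntheticRegion:
    """Generate a nested block-group/tract/county region with planted
    missingness in travel-time-to-work attributes, pooled 5-year county
    death counts, and noisy age-binned labor-force participation."""
    config = config or RegionConfig()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if config.n_block_groups is not None:
        n_bg = config.n_block_groups
        per_tract = config.bgs_per_tract
        n_tracts = int(np.ceil(n_bg / per_tract))
        n_counties = max(1, min(config.n_counties, n_tracts))
    else:
        n_counties = config.n_counties
        n_tracts = n_counties * config.tracts_per_county
        n_bg = n_tracts * config.bgs_per_tract
    tract_county = np.sort(np.arange(n_tracts) % n_counties)
    bg_tract = np.sort(np.arange(n_bg) % n_tracts)

    counties = [f"c{j:02d}" for j in range(n_counties)]
    tracts = [f"{counties[tract_county[t]]}_t{t:03d}" for t in range(n_tracts)]
    bgs = [f"{tracts[bg_tract[i]]}_bg{i:04d}" for i in range(n_bg)]

    population = rng.lognormal(np.log(1200.0), 0.4, size=n_bg)
    population = np.round(population).astype(float)
    zero_idx = rng.choice(n_bg, size=min(config.n_zero_population, n_bg),
                          replace=False)
    population[zero_idx] = 0.0

    density_k = rng.lognormal(np.log(1.4), 0.9, size=n_bg)
    pct_rental = 100.0 * rng.beta(2.0, 4.0, size=n_bg)
    race = rng.dirichlet(np.array([12.0, 2.5, 3.0, 1.0, 0.6]), size=n_bg)
    commute = rng.dirichlet(np.array([40.0, 2.5, 2.0, 1.5]), size=n_bg)
    ttw_pv = rng.lognormal(np.log(22.0), 0.25, size=n_bg)
    ttw_tr = ttw_pv * rng.lognormal(np.log(1.7), 0.15, size=n_bg)
    ttw_wk = rng.lognormal(np.log(12.0), 0.3, size=n_bg)
    ttw_bo = ttw_pv * rng.lognormal(np.log(1.1), 0.3, size=n_bg)
    edu = rng.dirichlet(np.array([6.0, 5.0, 6.0]), size=n_bg)

    bg = pd.DataFrame(
        {
            "block_group": bgs,
            "tract": [tracts[t] for t in bg_tract],
            "county": [counties[tract_county[t]] for t in bg_tract],
            "population": population,
            "pop_density_k": density_k,
            "pct_rental": pct_rental,
            **{f"race_{r}": race[:, i] for i, r in enumerate(RACE_ETHNICITIES)},
            **{f"commute_{m}": commute[:, i] for i, m in enumerate(MODES)},
            "ttw_private_vehicle": ttw_pv,
            "ttw_transit": ttw_tr,
            "ttw_walk": ttw_wk,
            "ttw_bike_other": ttw_bo,
            **{f"edu_{e}": edu[:, i] for i, e in enumerate(EDUCATION_LEVELS)},
        }
    )
    # Planted missingness in travel-time attributes (small-sample suppression)
    for col in TTW_COLUMNS:
        mask = rng.random(n_bg) < config.missing_bg_rate
        bg.loc[mask, col] = np.nan

    tract_df = (
        bg.groupby(["tract", "county"], as_index=False)
        .agg(population=("population", "sum"),
             **{c: (c, "mean") for c in TTW_COLUMNS})
    )
    for col in TTW_COLUMNS:
        mask = rng.random(len(tract_df)) < config.missing_tract_rate
        tract_df.loc[mask, col] = np.nan
    county_df = (
        bg.groupby("county", as_index=False)
        .agg(population=("population", "sum"),
             **{c: (c, "mean") for c in TTW_COLUMNS})
    )
    # county level is complete by construction (backstop of the ladder)
    for col in TTW_COLUMNS:
        county_df[col] = county_df[col].fillna(
            float(np.nanmean(bg[col])) if bg[col].notna().any() else 20.0
        )

    # Age-by-sex counts per block group
    shares = np.asarray(_AGE_GROUP_SHARES)
    records = []
    for i, g in enumerate(bgs):
        base = population[i] * shares
        for (lo, hi), tot in zip(AGE_BINS, base):
            f = 0.51 + 0.02 * rng.standard_normal()
            records.append((g, lo, hi, "female", np.round(tot * f)))
            records.append((g, lo, hi, "male", np.round(tot * (1 - f))))
    age_sex = pd.DataFrame(
        records, columns=["block_group", "age_lo", "age_hi", "sex", "count"]
    )
    age_sex["count"] = age_sex["count"].clip(lower=0.0)

    # Pooled 5-year death counts per county x age group x sex
    drecs = []
    for county in counties:
        cpop = float(county_df.loc[county_df["county"] == county, "population"].iloc[0])
        for (lo, hi), share in zip(AGE_BINS, shares):
            mid = 0.5 * (lo + hi)
            rate = float(mortality_rate(mid, config))
            for sex, sex_mult, sex_share in (
                ("male", 1.25, 0.49), ("female", 0.85, 0.51)
            ):
                person_years = max(cpop * share * sex_share, 1.0) * 5.0
                deaths = rng.poisson(rate * sex_mult * person_years)
                drecs.append((county, lo, hi, sex, deaths, person_years))
    deaths = pd.DataFrame(
        drecs,
        columns=["county", "age_lo", "age_hi", "sex", "deaths", "person_years"],
    )

    # Labor-force participation by county x sex x age group (noisy)
    lrecs = []
    for county in counties:
        shift = rng.normal(0.0, 1.5)
        for sex in ("male", "female"):
            for lo, hi in AGE_BINS:
                mid = 0.5 * (lo + hi)
                p = float(participation_curve(np.array([mid]), sex, shift)[0])
                p = float(np.clip(p + rng.normal(0.0, 0.015), 0.0, 1.0))
                lrecs.append((county, sex, lo, hi, p))
    labor_force = pd.DataFrame(
        lrecs, columns=["county", "sex", "age_lo", "age_hi", "participation"]
    )

    return SyntheticRegion(
        block_groups=bg.iloc[:n_bg].reset_index(drop=True),
        tracts=tract_df,
        counties=county_df,
        age_sex=age_sex,
        deaths=deaths,
        labor_force=labor_force,
    )
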