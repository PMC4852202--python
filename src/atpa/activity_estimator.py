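"""Combining the fitted component models into physical-activity doses.

Expected daily minutes of walking or biking for a covariate profile are
the product of the expected daily trip count (zero-inflated Poisson), the
purpose mix (multinomial logit), and purpose-specific durations (log-link
GEE), summed over purposes:

    TT = E(t) * sum_p Pr(p) * d_p

Minutes convert to MET-hours at 3.5 MET (walking) and 6.8 MET (cycling),
and weekly doses weight a typical weekday by five and a typical weekend
day by two.  The regional product is a matrix of mean weekly MET-hours and
Monte Carlo standard deviations over commute category x age x sex x
race/ethnicity x block group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .component_models import DurationFit, MnlFit, ZipFit, predict_matrix
from .survey_data import RACE_ETHNICITIES, SEASONS, SEXES
from .synthetic_data import EDUCATION_LEVELS

WALK_MET = 3.5
BIKE_MET = 6.8

#: Commute categories of the regional application: the four commute modes
#: plus a category for adults not in the labor force.
COMMUTE_CATEGORIES = (
    "private_vehicle", "transit", "walk", "bike", "not_in_labor_force"
)

CELL_INDEX = ["commute_category", "age", "sex", "race_ethnicity", "block_group"]

_TTW_BY_MODE = {
    "private_vehicle": "ttw_private_vehicle",
    "transit": "ttw_transit",
    "walk": "ttw_walk",
    "bike": "ttw_bike",
}


@dataclass
class FitBundle:
    """The three fitted component models for one (stratum, mode) pair."""

    stratum: str
    mode: str
    zip_fit: ZipFit
    mnl_fit: MnlFit
    duration_fit: DurationFit

    def __post_init__(self):
        if self.stratum not in ("workers", "nonworkers"):
            raise ValueError(f"unknown stratum {self.stratum!r}")
        if self.mode not in ("walk", "bike"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not self.zip_fit.design.response.startswith(self.mode):
            raise ValueError(
                f"count model response {self.zip_fit.design.response!r} does "
                f"not match bundle mode {self.mode!r}"
            )
        if self.duration_fit.design.response != "duration":
            raise ValueError("duration model must predict 'duration'")

    @property
    def purposes(self) -> tuple[str, ...]:
        return self.mnl_fit.outcomes


def expected_daily_minutes(
    x: pd.DataFrame, bundle: FitBundle, exclude_recreational: bool = False
) -> np.ndarray:
    """Expected daily minutes of the bundle's mode for each covariate row.

    Implements the count x purpose x duration composition; with
    ``exclude_recreational`` the recreational purpose's duration
    contribution is dropped (purpose-oriented travel only).
    """
    e_t = bundle.zip_fit.expected_count(x)
    probs = bundle.mnl_fit.probabilities(x)
    total = np.zeros(len(x))
    for p in bundle.purposes:
        if exclude_recreational and p == "recreational":
            continue
        d_p = bundle.duration_fit.predict(x.assign(purpose=p))
        total += probs[p].to_numpy() * d_p
    return e_t * total


def met_hours(walk_minutes, bike_minutes):
    """Daily MET-hours from walking and biking minutes (3.5 / 6.8 MET)."""
    w = np.asarray(walk_minutes, dtype=float)
    b = np.asarray(bike_minutes, dtype=float)
    if (w < 0).any() or (b < 0).any():
        raise ValueError("minutes must be nonnegative")
    out = (w * WALK_MET + b * BIKE_MET) / 60.0
    return float(out) if out.ndim == 0 else out


def weekly_tpa(weekday_daily, weekend_daily):
    """Weekly dose: five typical weekdays plus two typical weekend days."""
    wd = np.asarray(weekday_daily, dtype=float)
    we = np.asarray(weekend_daily, dtype=float)
    if (wd < 0).any() or (we < 0).any():
        raise ValueError("daily doses must be nonnegative")
    out = 5.0 * wd + 2.0 * we
    return float(out) if out.ndim == 0 else out


def observed_met_hours(persons: pd.DataFrame, trips: pd.DataFrame) -> pd.Series:
    """Observed daily MET-hours per person from recorded trips."""
    walk = trips.loc[trips["mode"] == "walk"].groupby("person_id")["duration"].sum()
    bike = trips.loc[trips["mode"] == "bike"].groupby("person_id")["duration"].sum()
    w = persons["person_id"].map(walk).fillna(0.0).to_numpy()
    b = persons["person_id"].map(bike).fillna(0.0).to_numpy()
    return pd.Series(met_hours(w, b), index=persons.index)


# ---------------------------------------------------------------------------
# Regional TPA matrix
# ---------------------------------------------------------------------------

@dataclass
class TpaMatrix:
    """Mean weekly MET-hours and Monte Carlo SD per population cell.

    ``table`` is long format over (commute_category, age, sex,
    race_ethnicity, block_group) with separate walking and cycling weekly
    MET-hour components, their total, and the SD of the total.
    """

    table: pd.DataFrame
    exclude_recreational: bool
    n_draws: int
    seed: int | None

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @staticmethod
    def read_csv(path, exclude_recreational=True, n_draws=0, seed=None):
        return TpaMatrix(pd.read_csv(path), exclude_recreational, n_draws, seed)


def _make_cells(block_groups: pd.DataFrame, ages: Sequence[int]) -> pd.DataFrame:
    idx = pd.MultiIndex.from_product(
        [
            COMMUTE_CATEGORIES,
            list(ages),
            SEXES,
            RACE_ETHNICITIES,
            block_groups["block_group"].tolist(),
        ],
        names=CELL_INDEX,
    )
    cells = idx.to_frame(index=False)
    keep = ["block_group", "pop_density_k", "pct_rental"] + list(
        _TTW_BY_MODE.values()
    ) + [f"edu_{e}" for e in EDUCATION_LEVELS]
    missing_cols = [c for c in keep if c not in block_groups.columns]
    if missing_cols:
        raise ValueError(
            f"block-group table lacks required attributes: {missing_cols}"
        )
    cells = cells.merge(block_groups[keep], on="block_group", how="left")
    return cells


def _check_cell_attributes(cells: pd.DataFrame) -> None:
    worker = cells["commute_category"] != "not_in_labor_force"
    for col in ("pop_density_k", "pct_rental"):
        bad = cells.loc[cells[col].isna(), "block_group"].unique()
        if len(bad):
            raise ValueError(
                f"missing {col} after fallback for block group(s) {list(bad)[:5]}"
            )
    for mode, col in _TTW_BY_MODE.items():
        rows = worker & (cells["commute_category"] == mode)
        bad = cells.loc[rows & cells[col].isna(), "block_group"].unique()
        if len(bad):
            raise ValueError(
                f"missing {col} after fallback for block group(s) {list(bad)[:5]}"
            )


_DEFAULT_REFERENCE = {
    "medical_condition": False,
    "proxy_interview": False,
    "heavy_rail_msa": False,
    "state_id": "s1",
    "division_id": "d0",
    "region_id": "r0",
}


def _expansion_frame(
    cells: pd.DataFrame,
    season: str,
    reference_values: Mapping | None,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Expand cells over (weekday/weekend) x education x season with
    weekly weights.

    Education enters by averaging predictions over the block group's
    education distribution; ``season="average"`` averages predictions over
    the four seasons with equal weight; weekday and weekend evaluations
    carry weights 5 and 2.  Returns the frame, the per-row weight, and the
    cell index of each row.
    """
    n = len(cells)
    frames = []
    weights = []
    cell_idx = []
    base_idx = np.arange(n)
    seasons = list(SEASONS) if season == "average" else [season]
    for weekend, mult in ((False, 5.0), (True, 2.0)):
        for edu in EDUCATION_LEVELS:
            for s in seasons:
                f = cells.copy()
                f["weekend"] = weekend
                f["education"] = edu
                f["season"] = s
                frames.append(f)
                weights.append(
                    mult * cells[f"edu_{edu}"].to_numpy(dtype=float)
                    / len(seasons)
                )
                cell_idx.append(base_idx)
    F = pd.concat(frames, ignore_index=True)
    worker = F["commute_category"] != "not_in_labor_force"
    F["commute_mode"] = F["commute_category"].where(worker, None)
    ttw = np.full(len(F), np.nan)
    for mode, col in _TTW_BY_MODE.items():
        rows = (F["commute_category"] == mode).to_numpy()
        ttw[rows] = F.loc[rows, col].to_numpy(dtype=float)
    F["time_to_work"] = ttw
    F["log_ttw"] = np.where(np.isnan(ttw) | (ttw <= 0), 0.0, np.log(
        np.where(np.isnan(ttw) | (ttw <= 0), 1.0, ttw)))
    F["age_sq"] = F["age"].astype(float) ** 2
    F["trips_on_day"] = 0.0
    for k, v in {**_DEFAULT_REFERENCE, **(reference_values or {})}.items():
        F[k] = v
    return F, np.concatenate(weights), np.concatenate(cell_idx)


class _BundleMatrices:
    """Cached design matrices for one bundle on one evaluation chunk."""

    def __init__(self, bundle: FitBundle, chunk: pd.DataFrame,
                 exclude_recreational: bool):
        self.bundle = bundle
        self.exclude = exclude_recreational
        z = bundle.zip_fit

        def mat(di):
            return predict_matrix(di, chunk).to_numpy(dtype=float)

        self.Xc = mat(z._count_di)
        self.Xi = None if z.infl_params is None else mat(z._infl_di)
        self.Xm = mat(bundle.mnl_fit._di)
        self.Xd = {}
        for p in bundle.purposes:
            if self.exclude and p == "recreational":
                continue
            self.Xd[p] = predict_matrix(
                bundle.duration_fit._di, chunk.assign(purpose=p)
            ).to_numpy(dtype=float)

    def minutes(self, zip_vec: np.ndarray, mnl_vec: np.ndarray,
                dur_vec: np.ndarray) -> np.ndarray:
        z = self.bundle.zip_fit
        k = z._n_infl
        if self.Xi is None:
            pi = 0.0
        else:
            pi = expit(self.Xi @ zip_vec[:k])
        lam = np.exp(np.clip(self.Xc @ zip_vec[k:], -700.0, 30.0))
        e_t = (1.0 - pi) * lam
        B = mnl_vec.reshape(self.bundle.mnl_fit.params.shape, order="F")
        eta = self.Xm @ B
        eta = np.column_stack([np.zeros(len(eta)), eta])
        eta -= eta.max(axis=1, keepdims=True)
        w = np.exp(eta)
        probs = w / w.sum(axis=1, keepdims=True)
        total = np.zeros(len(e_t))
        for j, p in enumerate(self.bundle.purposes):
            if p not in self.Xd:
                continue
            total += probs[:, j] * np.exp(
                np.clip(self.Xd[p] @ dur_vec, -700.0, 30.0))
        return e_t * total


def mvn_draws(mean: np.ndarray, cov: np.ndarray, n: int, rng) -> np.ndarray:
    """Draws from N(mean, cov) via a PSD-clipped eigendecomposition."""
    w, V = np.linalg.eigh((cov + cov.T) / 2)
    L = V * np.sqrt(np.clip(w, 0.0, None))
    return mean[None, :] + rng.standard_normal((n, len(mean))) @ L.T


def build_tpa_matrix(
    bundles: Mapping[tuple[str, str], FitBundle],
    block_groups: pd.DataFrame,
    ages: Sequence[int] = tuple(range(18, 97)),
    seed: int | None = 0,
    n_draws: int = 60,
    exclude_recreational: bool = True,
    season: str = "average",
    reference_values: Mapping | None = None,
    chunk_size: int = 50_000,
) -> TpaMatrix:
    """Evaluate weekly MET-hour doses with Monte Carlo uncertainty.

    For every (commute category, age, sex, race, block group) cell the
    composition is evaluated under weekday and weekend settings, averaged
    over the block group's education mix (and the four seasons when
    ``season="average"``), and combined into a weekly dose.  Cell SDs
    propagate coefficient uncertainty: ``n_draws`` joint-normal coefficient
    draws per component model, independent across models, re-evaluating the
    full matrix per draw.  Deterministic for a fixed seed.
    """
    for key in (("workers", "walk"), ("workers", "bike"),
                ("nonworkers", "walk"), ("nonworkers", "bike")):
        if key not in bundles:
            raise ValueError(f"missing fit bundle for {key}")
    cells = _make_cells(block_groups, ages)
    _check_cell_attributes(cells)
    if season != "average" and season not in SEASONS:
        raise ValueError(f"unknown season {season!r}")
    F, weights, cell_idx = _expansion_frame(cells, season, reference_values)
    ncells = len(cells)

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    weekly = {
        "walk": np.zeros((n_draws + 1, ncells)),
        "bike": np.zeros((n_draws + 1, ncells)),
    }
    for mode in ("walk", "bike"):
        for stratum in ("workers", "nonworkers"):
            bundle = bundles[(stratum, mode)]
            if stratum == "workers":
                mask = (F["commute_category"] != "not_in_labor_force").to_numpy()
            else:
                mask = (F["commute_category"] == "not_in_labor_force").to_numpy()
            sub = F.loc[mask].reset_index(drop=True)
            sub_w = weights[mask]
            sub_idx = cell_idx[mask]
            z, m, d = bundle.zip_fit, bundle.mnl_fit, bundle.duration_fit
            param_sets = [(z.all_params, m.all_params, d.all_params)]
            if n_draws > 0:
                zd = mvn_draws(z.all_params, z.cov.to_numpy(), n_draws, rng)
                md = mvn_draws(m.all_params, m.cov.to_numpy(), n_draws, rng)
                dd = mvn_draws(d.all_params, d.cov.to_numpy(), n_draws, rng)
                param_sets += [(zd[j], md[j], dd[j]) for j in range(n_draws)]
            for start in range(0, len(sub), chunk_size):
                chunk = sub.iloc[start:start + chunk_size]
                w_chunk = sub_w[start:start + chunk_size]
                i_chunk = sub_idx[start:start + chunk_size]
                mats = _BundleMatrices(bundle, chunk, exclude_recreational)
                for j, (zv, mv, dv) in enumerate(param_sets):
                    mins = mats.minutes(zv, mv, dv)
                    weekly[mode][j] += np.bincount(
                        i_chunk, weights=w_chunk * mins, minlength=ncells
                    )

    met_factor = {"walk": WALK_MET / 60.0, "bike": BIKE_MET / 60.0}
    tpa_all = (
        weekly["walk"] * met_factor["walk"] + weekly["bike"] * met_factor["bike"]
    )
    table = cells[CELL_INDEX].copy()
    table["walk_met_wk"] = weekly["walk"][0] * met_factor["walk"]
    table["bike_met_wk"] = weekly["bike"][0] * met_factor["bike"]
    table["tpa_mean"] = tpa_all[0]
    table["tpa_sd"] = (
        tpa_all[1:].std(axis=0, ddof=1) if n_draws > 1 else np.zeros(ncells)
    )
    return TpaMatrix(
        table=table,
        exclude_recreational=exclude_recreational,
        n_draws=n_draws,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Combined marginal effects
# ---------------------------------------------------------------------------

@dataclass
class CombinedEffect:
    """Monte Carlo combined marginal effect on expected daily minutes."""

    variable: str
    level: str | None
    effect: float
    ci_low: float
    ci_high: float
    draws: np.ndarray = field(repr=False, default=None)


def _bundle_mentions(bundle: FitBundle, variable: str) -> bool:
    designs = [bundle.zip_fit.design, bundle.mnl_fit.design,
               bundle.duration_fit.design]
    if bundle.zip_fit.infl_design is not None:
        designs.append(bundle.zip_fit.infl_design)
    return any(variable in t.expr for dsg in designs for t in dsg.terms)


def combined_marginal_effect(
    bundle: FitBundle,
    sample: pd.DataFrame,
    variable: str,
    level: str | None = None,
    reference: str | None = None,
    n_draws: int = 500,
    seed: int | None = 0,
    exclude_recreational: bool = False,
) -> CombinedEffect:
    """Average marginal effect of ``variable`` on expected daily minutes.

    Coefficient vectors for the three component models are drawn from
    their estimated joint-normal laws (independently across models); the
    composition's average marginal effect is recomputed per draw and the
    95% interval is the 2.5-97.5 percentile range of the draws.
    """
    if n_draws < 2:
        raise ValueError("n_draws must be at least 2")
    if not _bundle_mentions(bundle, variable):
        return CombinedEffect(variable, level, 0.0, 0.0, 0.0,
                              draws=np.zeros(n_draws))
    is_cat = level is not None
    if is_cat and reference is None:
        raise ValueError("categorical effects need a reference level")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    z, m, d = bundle.zip_fit, bundle.mnl_fit, bundle.duration_fit
    zd = mvn_draws(z.all_params, z.cov.to_numpy(), n_draws, rng)
    md = mvn_draws(m.all_params, m.cov.to_numpy(), n_draws, rng)
    dd = mvn_draws(d.all_params, d.cov.to_numpy(), n_draws, rng)

    if is_cat:
        hi = sample.assign(**{variable: level})
        lo = sample.assign(**{variable: reference})
    else:
        x = sample[variable].to_numpy(dtype=float)
        h = 1e-4 * max(1.0, float(np.std(x)))
        hi = sample.assign(**{variable: x + h})
        lo = sample.assign(**{variable: x - h})

    def ame(b: FitBundle) -> float:
        diff = expected_daily_minutes(hi, b, exclude_recreational) - \
            expected_daily_minutes(lo, b, exclude_recreational)
        val = float(diff.mean())
        return val if is_cat else val / (2 * h)

    from dataclasses import replace as _replace
    point = ame(bundle)
    draws = np.empty(n_draws)
    for j in range(n_draws):
        b = FitBundle(
            bundle.stratum, bundle.mode,
            z.with_params(zd[j]), m.with_params(md[j]), d.with_params(dd[j]),
        )
        draws[j] = ame(b)
    lo_q, hi_q = np.percentile(draws, [2.5, 97.5])
    return CombinedEffect(variable, level, point, float(lo_q), float(hi_q),
                          draws=draws)


# ---------------------------------------------------------------------------
# Banded validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationSummary:
    """Banded agreement between predicted and observed daily MET-hours."""

    proportions: dict[float, float]
    n: int
    group_means: pd.DataFrame | None = None

    def __post_init__(self):
        bands = sorted(self.proportions)
        props = [self.proportions[b] for b in bands]
        if any(not 0.0 <= p <= 1.0 for p in props):
            raise ValueError("proportions must lie in [0, 1]")
        if any(b2 < b1 for b1, b2 in zip(props, props[1:])):
            raise ValueError("proportions must be nondecreasing in band width")


def validate_predictions(
    predicted,
    observed,
    bands: Sequence[float] = (0.5, 1.0, 1.6),
    groups=None,
) -> ValidationSummary:
    """Share of persons whose predicted dose is within each band of observed.

    ``groups`` (e.g. commute mode) adds per-group predicted and observed
    means to the summary.
    """
    pred = np.asarray(predicted, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if pred.shape != obs.shape:
        raise ValueError(
            f"predicted and observed lengths differ: {pred.shape} vs {obs.shape}"
        )
    gap = np.abs(pred - obs)
    props = {float(b): float(np.mean(gap <= b)) for b in bands}
    gm = None
    if groups is not None:
        gm = (
            pd.DataFrame({"group": np.asarray(groups), "predicted": pred,
                          "observed": obs})
            .groupby("group")
            .mean()
        )
    return ValidationSummary(proportions=props, n=len(pred), group_means=gm)
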