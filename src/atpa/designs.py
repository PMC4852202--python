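"""Default model designs for the component regressions.

One design set per (stratum, mode): a count design shared by both stages
of the zero-inflated Poisson model, a purpose design for the multinomial
logit, and a duration design whose built-environment and commute terms
are interacted with trip purpose (workers additionally interact purpose
with the log of travel time to work).  Demographics and built-environment
terms are selection candidates; education, season, weekday/weekend, and
(for the well-populated walk models) medical condition, proxy response,
heavy-rail presence, and geography fixed effects are always-kept
controls.

Bike trips are roughly an order of magnitude scarcer than walk trips, so
the bike designs are deliberately leaner — at desk-scale sample sizes a
full control set would be separated on a few dozen cycling days.
"""

from __future__ import annotations

from .component_models import ModelDesign, Term, cat

PURPOSE_BASE = {"workers": "work", "nonworkers": "recreational"}

_COMMUTE = cat("commute_mode", "private_vehicle")
_SEX = cat("sex", "male")
_RACE = cat("race_ethnicity", "nh_white")
_PURPOSE = {s: cat("purpose", b) for s, b in PURPOSE_BASE.items()}


def _full_controls(fixed_effect: str) -> list[Term]:
    ref = {"state_id": "s1", "division_id": "d0", "region_id": "r0"}
    return [
        Term(cat("education", "hs_or_less"), "control"),
        Term("medical_condition", "control"),
        Term("proxy_interview", "control"),
        Term(cat("season", "winter"), "control"),
        Term("weekend", "control"),
        Term("heavy_rail_msa", "control"),
        Term(cat(fixed_effect, ref[fixed_effect]), "fixed_effect"),
    ]


_SLIM_CONTROLS = [Term("weekend", "control")]


def count_design(stratum: str, mode: str,
                 fixed_effect: str = "state_id") -> ModelDesign:
    """Design for daily walk/bike trip counts (both ZIP stages)."""
    response = f"{mode}_trip_count"
    if mode == "walk":
        terms = [
            Term("pop_density_k"), Term("pct_rental"),
            Term("age"), Term("age_sq"), Term(_SEX), Term(_RACE),
        ]
        if stratum == "workers":
            terms.insert(0, Term(_COMMUTE))
        return ModelDesign(response, terms + _full_controls(fixed_effect))
    if stratum == "workers":
        terms = [Term(_COMMUTE), Term("pop_density_k"), Term("age"),
                 Term(_SEX)]
    else:
        terms = [Term("age"), Term(_SEX)]
    return ModelDesign(response, terms + _SLIM_CONTROLS)


def purpose_design(stratum: str, mode: str = "walk",
                   fixed_effect: str = "division_id") -> ModelDesign:
    """Design for the trip-purpose multinomial logit."""
    if mode == "walk":
        terms = [
            Term("pop_density_k"), Term("pct_rental"), Term("age"),
            Term(_SEX), Term(_RACE),
        ]
        if stratum == "workers":
            terms.insert(0, Term(_COMMUTE))
        return ModelDesign("purpose", terms + _full_controls(fixed_effect))
    if stratum == "workers":
        # scarce bike trips: commute enters as own-mode / transit indicators
        terms = [Term("I(commute_mode == 'bike')"),
                 Term("I(commute_mode == 'transit')"),
                 Term("age"), Term(_SEX)]
    else:
        terms = [Term("pop_density_k"), Term("pct_rental"), Term("age"),
                 Term(_SEX)]
    return ModelDesign("purpose", terms + _SLIM_CONTROLS)


def duration_design(stratum: str, mode: str = "walk",
                    fixed_effect: str = "state_id") -> ModelDesign:
    """Design for log-link trip duration with purpose interactions."""
    purpose = _PURPOSE[stratum]
    if mode == "walk":
        if stratum == "workers":
            terms = [
                Term(f"{purpose} * {_COMMUTE}"),
                Term(f"{purpose}:log_ttw"),
                Term(f"{purpose}:pop_density_k"),
                Term(f"{purpose}:pct_rental"),
            ]
        else:
            terms = [
                Term(purpose),
                Term(f"{purpose}:pop_density_k"),
                Term(f"{purpose}:pct_rental"),
            ]
        terms += [Term("age"), Term("age_sq"), Term(_SEX), Term(_RACE)]
        return ModelDesign("duration", terms + _full_controls(fixed_effect))
    if stratum == "workers":
        terms = [
            Term(purpose),
            Term(f"{purpose}:log_ttw"),
            Term("I(commute_mode == 'private_vehicle')"),
            Term("age"), Term(_SEX),
        ]
    else:
        terms = [Term(purpose), Term("age"), Term(_SEX)]
    return ModelDesign("duration", terms + _SLIM_CONTROLS)


def design_set(stratum: str, mode: str) -> dict[str, ModelDesign]:
    """The three default designs for one (stratum, mode) model triple."""
    return {
        "count": count_design(stratum, mode),
        "purpose": purpose_design(stratum, mode),
        "duration": duration_design(stratum, mode),
    }
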