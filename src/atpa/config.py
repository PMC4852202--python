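"""Run configuration: one YAML file with per-stage sections.

Command-line flags override the config's ``seed`` and ``outdir``; every
source of randomness in a run derives from the single master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

_FORMULA_MODES = ("pif", "as_printed")
_SEASONS = ("average", "winter", "spring", "summer", "fall")


@dataclass
class RunConfig:
    """Validated options for a full pipeline run."""

    seed: int = 0
    outdir: str = "out"
    survey: dict = field(default_factory=dict)
    region: dict = field(default_factory=dict)
    models: dict = field(default_factory=dict)
    estimate: dict = field(default_factory=dict)
    hia: dict = field(default_factory=dict)

    def __post_init__(self):
        if not isinstance(self.seed, int):
            raise ValueError("seed must be an integer")
        est = self.estimate
        if est.get("season", "average") not in _SEASONS:
            raise ValueError(f"estimate.season must be one of {_SEASONS}")
        if self.hia.get("formula_mode", "pif") not in _FORMULA_MODES:
            raise ValueError(f"hia.formula_mode must be one of {_FORMULA_MODES}")
        for key in ("n_draws",):
            if key in est and (not isinstance(est[key], int) or est[key] < 0):
                raise ValueError(f"estimate.{key} must be a nonnegative integer")

    # Section accessors with defaults -------------------------------------
    @property
    def n_persons(self) -> int:
        return int(self.survey.get("n_persons", 10_000))

    @property
    def ages(self) -> range:
        a = self.estimate.get("ages", {})
        return range(int(a.get("start", 18)), int(a.get("stop", 97)),
                     int(a.get("step", 1)))

    @property
    def outpath(self) -> Path:
        return Path(self.outdir)

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in RunConfig.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        return RunConfig(**raw)

    def to_yaml(self, path=None) -> str:
        payload = yaml.safe_dump(
            {
                "seed": self.seed, "outdir": self.outdir,
                "survey": self.survey, "region": self.region,
                "models": self.models, "estimate": self.estimate,
                "hia": self.hia,
            },
            sort_keys=False,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload
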