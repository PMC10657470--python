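"""Run configuration: YAML-backed, schema-checked, with the study constants.

All fixed analysis constants live here rather than inline in the
modules: the PTSD raw-score cut (strictly greater than 31), the
depression t-score cut (>= 60), the FDR level (0.05) and the ten
evaluation seeds.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .outcomes import DEPRESSION_CUT, PTSD_CUT

__all__ = ["RunConfig", "OUTCOME_COLUMNS", "ConfigError"]

#: analysis outcome name -> outcome-panel column
OUTCOME_COLUMNS = {
    "ptsd": "pcl5_raw",
    "depression": "promis_t",
    "somatic": "somatic_count",
}


class ConfigError(ValueError):
    """Raised for invalid run configuration before any computation starts."""


@dataclass
class RunConfig:
    out_dir: str = "gutapns_out"
    outcomes: tuple[str, ...] = ("ptsd", "depression", "somatic")
    ptsd_cut: int = PTSD_CUT
    depression_cut: float = DEPRESSION_CUT
    fdr_level: float = 0.05
    seeds: tuple[int, ...] = tuple(range(10))
    #: overrides forwarded to SimulationConfig (synthetic-input runs)
    simulation: dict = field(default_factory=dict)
    #: overrides forwarded to MERF (n_estimators, max_iter, ...)
    merf: dict = field(default_factory=dict)
    #: diagnosis week used to stratify pathway-contribution groups
    group_week: int = 12
    contribution_rank: str = "genus"
    power_rho: float = 0.5
    power_n: int = 51
    power_alpha: float = 0.05

    def __post_init__(self) -> None:
        self.outcomes = tuple(self.outcomes)
        self.seeds = tuple(int(s) for s in self.seeds)
        unknown = set(self.outcomes) - set(OUTCOME_COLUMNS)
        if unknown:
            raise ConfigError(f"unknown outcomes: {sorted(unknown)}; "
                              f"allowed: {sorted(OUTCOME_COLUMNS)}")
        if not self.outcomes:
            raise ConfigError("at least one outcome is required")
        if not 0.0 < self.fdr_level < 1.0:
            raise ConfigError("fdr_level must be in (0, 1)")
        if not self.seeds:
            raise ConfigError("at least one seed is required")
        if self.contribution_rank not in ("genus", "species"):
            raise ConfigError("contribution_rank must be 'genus' or 'species'")
        if not isinstance(self.simulation, dict) or not isinstance(self.merf, dict):
            raise ConfigError("simulation and merf sections must be mappings")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        allowed = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - allowed
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["outcomes"] = list(self.outcomes)
        d["seeds"] = list(self.seeds)
        return d

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
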