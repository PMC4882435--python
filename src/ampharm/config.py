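"""Pipeline configuration.

All analysis thresholds live here with the published defaults: significance
level 0.05, dlog(RA) FDR 1 %, unambiguous-effect thresholds of 0.5 log units
(potency) and 30 percentage points (Emax), a potency reporting floor of
pEC50 = 6 and a span floor of 10 % of WT for censoring, and an expression
exclusion cutoff (see docs/methods.md for why the default is 25 %).

Config files are flat ``key: value`` YAML mappings; every field can be
overridden.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from .errors import ConfigurationError

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    raw_csv: str | None = None
    summary_csv: str | None = None
    expression_csv: str | None = None
    outdir: str = "ampharm_out"
    receptors: tuple[str, str] = ("AM1", "AM2")
    alpha: float = 0.05
    fdr_q: float = 0.01
    fdr_method: str = "two-stage"  # or "bh"
    anova_variance: str = "summary"  # or "exact"
    delta_pec50_min: float = 0.5
    emax_diff_min: float = 30.0
    expression_exclusion_pct: float = 25.0
    pec50_floor: float = 6.0
    span_floor_frac: float = 0.10
    use_published_edge_rules: bool = True
    seed: int = 0

    def validate(self) -> None:
        for name in ("alpha", "fdr_q"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ConfigurationError(f"{name}: must be in (0, 1), got {v}")
        for name in ("delta_pec50_min", "emax_diff_min", "expression_exclusion_pct",
                     "pec50_floor", "span_floor_frac"):
            v = getattr(self, name)
            if v <= 0:
                raise ConfigurationError(f"{name}: must be positive, got {v}")
        if self.fdr_method not in ("two-stage", "bh"):
            raise ConfigurationError(f"fdr_method: unknown method {self.fdr_method!r}")
        if self.anova_variance not in ("summary", "exact"):
            raise ConfigurationError(
                f"anova_variance: unknown option {self.anova_variance!r}"
            )
        if self.raw_csv and self.summary_csv:
            raise ConfigurationError("raw_csv/summary_csv: give one input mode, not both")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if not isinstance(data, dict):
            raise ConfigurationError("config file must be a flat key-value mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "receptors" in data:
            data["receptors"] = tuple(data["receptors"])
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["receptors"] = list(self.receptors)
        return d
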