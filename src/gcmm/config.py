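"""Analysis configuration: winsorization, caps, bootstrap and classification knobs."""

from __future__ import annotations

from dataclasses import asdict, dataclass

import yaml

from .errors import ConfigError


@dataclass
class AnalysisConfig:
    """Tunable parameters of the full pipeline.

    Defaults reproduce the published analysis choices: spending winsorized at
    the 1st/99th percentile, breadth capped at 7 game types, the outcome
    severity score capped at 6, the propensity outcome defined as score >= 5
    (at least moderate risk), 5000 bootstrap resamples with 95% percentile
    intervals, and a dominance-ratio threshold of 2.0.
    """

    winsor_lower_pct: float = 1.0
    winsor_upper_pct: float = 99.0
    breadth_cap_mode: str = "fixed"  # "fixed" | "percentile99"
    breadth_cap_value: int = 7
    pgsi_cap_mode: str = "fixed"  # "fixed" | "percentile99"
    pgsi_cap_value: int = 6
    propensity_threshold: int = 5
    propensity_score_scale: str = "probability"  # "probability" | "linear"
    impute_before_winsorize: bool = True
    bootstrap_B: int = 5000
    ci_level: float = 0.95
    rng_seed: int = 20211
    dominance_ratio_threshold: float = 2.0
    bonferroni: bool = False

    def __post_init__(self):
        if not (0 <= self.winsor_lower_pct < self.winsor_upper_pct <= 100):
            raise ConfigError(
                "winsor percentiles must satisfy 0 <= lower < upper <= 100"
            )
        if self.bootstrap_B < 1:
            raise ConfigError("bootstrap_B must be >= 1")
        if not (0 < self.ci_level < 1):
            raise ConfigError("ci_level must be in (0, 1)")
        if self.breadth_cap_mode not in ("fixed", "percentile99"):
            raise ConfigError("breadth_cap_mode must be 'fixed' or 'percentile99'")
        if self.pgsi_cap_mode not in ("fixed", "percentile99"):
            raise ConfigError("pgsi_cap_mode must be 'fixed' or 'percentile99'")
        if self.propensity_score_scale not in ("probability", "linear"):
            raise ConfigError("propensity_score_scale must be 'probability' or 'linear'")

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def replace(self, **kwargs) -> "AnalysisConfig":
        data = asdict(self)
        data.update(kwargs)
        return AnalysisConfig(**data)
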