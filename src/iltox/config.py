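"""Run configuration: thresholds and conventions shared across stages."""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Flat configuration of the modelling pipeline.

    Every knob has the package default; a YAML file with matching keys
    overrides fields, and CLI flags override the file.
    """

    p_threshold: float = 0.05  # backward-elimination significance cut
    r2_min: float = 0.6  # coverage screen
    r2_soft: float = 0.55  # low-scatter exemption: minimum R^2 ...
    se_max: float = 0.35  # ... combined with maximum SE
    trim: float = 0.05  # fraction trimmed in MAE validation
    min_onboard_points: int = 5
    seed: int = 0
    se_denominator: str = "n_minus_k"  # or "n"
    eq5_predictor: str = "with_z"  # or "without_z"

    def __post_init__(self) -> None:
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must be in (0, 1)")
        if not 0 <= self.trim < 1:
            raise ValueError("trim must be in [0, 1)")
        if self.se_denominator not in ("n_minus_k", "n"):
            raise ValueError("se_denominator must be 'n_minus_k' or 'n'")
        if self.eq5_predictor not in ("with_z", "without_z"):
            raise ValueError("eq5_predictor must be 'with_z' or 'without_z'")

    @property
    def include_z(self) -> bool:
        return self.eq5_predictor == "with_z"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {', '.join(sorted(unknown))}")
        return cls(**payload)
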