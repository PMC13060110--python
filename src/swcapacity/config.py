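"""Analysis configuration: meta-parameters of the sliding-window pipeline.

Window length and step may be given in seconds (converted through the TR)
or directly in samples.  Capacity units are fixed per run and recorded in
every output file; mixing bases across files is refused downstream.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .model import OrderSelectionConfig
from .sliding import window_length_from_seconds

__all__ = ["AnalysisConfig"]


@dataclass
class AnalysisConfig:
    window_length: float = 50.0
    window_unit: str = "seconds"  # seconds | samples
    step_samples: int = 1
    criterion: str = "BIC"
    k_max: int | None = None
    grid_size: int = 4096
    units: str = "bits"
    cv_threshold: float = 0.30
    q_threshold: float = 0.02
    alpha: float = 0.02
    k_range: list[int] = field(default_factory=lambda: list(range(1, 11)))
    n_init: int = 6
    seed: int = 0
    orientation: str = "roi_rows"
    use_lookback: bool = True

    def __post_init__(self):
        if self.window_unit not in ("seconds", "samples"):
            raise ValueError("window_unit must be 'seconds' or 'samples'")
        if self.units not in ("bits", "nats"):
            raise ValueError("units must be 'bits' or 'nats'")
        if self.step_samples < 1:
            raise ValueError("step_samples must be >= 1")
        if self.grid_size < 2:
            raise ValueError("grid_size must be >= 2")
        if self.orientation not in ("roi_rows", "roi_cols"):
            raise ValueError("orientation must be 'roi_rows' or 'roi_cols'")
        # delegate criterion/k_max validation
        self.order_config()

    def order_config(self) -> OrderSelectionConfig:
        return OrderSelectionConfig(criterion=self.criterion, k_max=self.k_max)

    def window_samples(self, tr_seconds: float) -> int:
        if self.window_unit == "samples":
            return int(self.window_length)
        return window_length_from_seconds(self.window_length, tr_seconds)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))
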