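"""Analysis configuration: every threshold used by the pipeline, in one place.

Defaults follow the conventions of the live-cell twitching assay this package
models: 2 µm net displacement separates non-motile (wobbling/tethered) cells
from motile ones over a 5-minute observation window, and per-track log-log MSD
slopes α near 1 indicate random-walk-like twitching, with α > 1.2 treated as
superdiffusive (directed) and α < 0.5 as strongly subdiffusive (tethered).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import yaml

__all__ = ["AnalysisConfig"]


@dataclass
class AnalysisConfig:
    #: net displacement (µm) below which a track is classified non-motile
    non_motile_threshold: float = 2.0
    #: MSD slope fit restricted to lags <= this fraction of track duration
    msd_max_lag_fraction: float = 0.25
    #: alpha below this -> subdiffusive
    alpha_subdiffusive_max: float = 0.5
    #: alpha above this -> superdiffusive
    alpha_superdiffusive_min: float = 1.2
    #: a track is a "roller" (detached cell dragged by convection flow) when
    #: both its persistence ratio and net displacement are high
    roller_persistence_min: float = 0.5
    roller_displacement_min: float = 10.0
    #: root seed for any stochastic step of an analysis run
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.msd_max_lag_fraction <= 1):
            raise ValueError("msd_max_lag_fraction must be in (0, 1]")
        for name in ("non_motile_threshold", "roller_persistence_min",
                     "roller_displacement_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.alpha_subdiffusive_max >= self.alpha_superdiffusive_min:
            raise ValueError("alpha_subdiffusive_max must be < alpha_superdiffusive_min")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path, "r", encoding="utf-8") as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
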