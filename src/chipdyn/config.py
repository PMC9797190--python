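"""Analysis configuration: the pipeline's named constants in one place.

Defaults are the study constants the stages share: 25-bp bins, the 500-bp
scoring promoter and the -500/+50 peak-annotation promoter, 1-kb TSS and
15-kb origin metagene flanks, 5-kb origin-proximal radius for partitioned
normalization, EdU firing threshold 2, top-1000 residual selection with the
-0.075 minimal-signal floor, gene–origin distance bins at 1/2/5 kb and the
5-kb timing assignment cutoff.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import yaml


@dataclass
class AnalysisConfig:
    bin_width: int = 25
    promoter_upstream: int = 500
    peak_promoter_downstream: int = 50
    tss_flank: int = 1000
    origin_flank: int = 15000
    origin_radius: int = 5000
    pseudocount: float = 1.0
    edu_threshold: float = 2.0
    edu_window: int = 2500
    top_k: int = 1000
    min_signal: float = -0.075
    distance_edges: tuple = (1000, 2000, 5000)
    timing_max_dist: int = 5000
    alpha: float = 0.05
    n_null: int = 10000
    seed: int = 0

    def __post_init__(self):
        self.distance_edges = tuple(self.distance_edges)
        for name in ("bin_width", "promoter_upstream", "tss_flank", "origin_flank",
                     "top_k", "n_null"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)
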