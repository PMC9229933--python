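"""Pipeline configuration: one YAML file shared by both entry points.

The ``simulate`` section holds the synthetic-cohort design, the
``analyze`` section the binning/filter/model parameters. Every field has
a CLI-flag override; paths left null fall back to the packaged defaults
(water-region exclusion list, metabolite annotation map).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .types import ConfigurationError


@dataclass
class SimulateConfig:
    n_per_cell: int = 6
    animal_cv: float = 0.12
    noise_sd: float = 500.0
    baseline_amplitude: float = 50.0
    points_per_bin: int = 64
    seed: int = 0
    null: bool = False  # force all planted ratios to 1


@dataclass
class AnalyzeConfig:
    window_lo: float = 0.0
    window_hi: float = 10.0
    bin_width: float = 0.01
    bin_aggregation: str = "sum"
    exclude_bins_path: Optional[str] = None  # null -> packaged water list
    threshold: float = 100_000.0
    threshold_statistic: str = "max"
    model_mode: str = "per_week"
    transform: str = "log2"
    pseudocount: Optional[float] = None  # null -> auto (half min positive)
    fdr_tiers: tuple[float, float] = (0.05, 0.1)
    annotation_path: Optional[str] = None  # null -> packaged metabolite map
    fdr_aggregation: str = "mean"


@dataclass
class PipelineConfig:
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    analyze: AnalyzeConfig = field(default_factory=AnalyzeConfig)

    def __post_init__(self) -> None:
        t1, t2 = self.analyze.fdr_tiers
        if not (0 < t1 < t2 <= 1):
            raise ConfigurationError(f"fdr_tiers must satisfy 0 < t1 < t2 <= 1, got {t1}, {t2}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        sim = SimulateConfig(**raw.get("simulate", {}))
        ana_raw = dict(raw.get("analyze", {}))
        if "fdr_tiers" in ana_raw:
            ana_raw["fdr_tiers"] = tuple(ana_raw["fdr_tiers"])
        ana = AnalyzeConfig(**ana_raw)
        return cls(simulate=sim, analyze=ana)

    def to_yaml(self, path) -> None:
        data = {"simulate": asdict(self.simulate), "analyze": asdict(self.analyze)}
        data["analyze"]["fdr_tiers"] = list(self.analyze.fdr_tiers)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False), encoding="utf-8")
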