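"""Pipeline configuration: one YAML file, one root seed."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .al import ALConfig


@dataclass
class FilterConfig:
    rmsd_indole_max: float = 5.0
    rmsd_murcko_max: float = 4.0
    score_max: float = -6.0
    clash_max: float = 0.5


@dataclass
class TIConfig:
    init_len_ns: float = 2.5
    increment_ns: float = 0.5
    criterion: float = 0.1
    max_total_ns: float = 10.0
    n_lambda: int = 9

    @classmethod
    def fast(cls) -> "TIConfig":
        """Accelerated preset: shorter initial and extension lengths."""
        return cls(init_len_ns=1.0, increment_ns=0.25)


@dataclass
class BudgetConfig:
    total: int = 75
    greedy: int = 70
    diverse: int = 5

    def __post_init__(self) -> None:
        if self.greedy + self.diverse != self.total:
            raise ValueError("greedy + diverse must equal total budget")


@dataclass
class PipelineConfig:
    """Everything the end-to-end synthetic pipeline needs."""

    seed: int = 0
    library_size: int = 1000
    closest_smarts: str = "NC(=O)C(=O)N"  # oxamide core
    general_smarts: str = "c1ccccc1"
    pre_al_size: int = 60
    docking_pass_fraction: float = 0.8
    oracle_noise_sd: float = 0.5
    anchor_dg: float = -6.0
    filters: FilterConfig = field(default_factory=FilterConfig)
    ti: TIConfig = field(default_factory=TIConfig)
    al: ALConfig = field(default_factory=ALConfig)
    budget: BudgetConfig = field(default_factory=BudgetConfig)
    tsne_perplexity: float = 30.0

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        if "filters" in kwargs and isinstance(kwargs["filters"], dict):
            kwargs["filters"] = FilterConfig(**kwargs["filters"])
        if "ti" in kwargs and isinstance(kwargs["ti"], dict):
            kwargs["ti"] = TIConfig(**kwargs["ti"])
        if "budget" in kwargs and isinstance(kwargs["budget"], dict):
            kwargs["budget"] = BudgetConfig(**kwargs["budget"])
        if "al" in kwargs and isinstance(kwargs["al"], dict):
            al_kwargs = dict(kwargs["al"])
            for key in ("representations", "algorithms", "batch_schedule"):
                if key in al_kwargs and isinstance(al_kwargs[key], list):
                    al_kwargs[key] = tuple(al_kwargs[key])
            kwargs["al"] = ALConfig(**al_kwargs)
        return cls(**kwargs)
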