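"""Run configuration: a single human-readable YAML document.

Defaults encode the study setup (loss weights alpha = beta = 1000, the
nine-parameter uniform prior box, currents 0.0-0.4 nA) so that a minimal
config reproduces the reference pipeline at user-chosen chain/sample
counts. Unknown keys are rejected.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .burst_loss import (DEFAULT_BURST_THRESHOLD, DEFAULT_MERGE_GAP,
                         WORST_CASE_LOSS)
from .diagnostics import DEFAULT_CV_THRESHOLD

__all__ = ["RunConfig", "load_config", "save_config", "ConfigError"]


class ConfigError(ValueError):
    pass


@dataclass
class SolverSection:
    method: str = "BDF"
    rtol: float = 1e-6
    atol: float = 1e-8
    dt_out: float = 0.1


@dataclass
class StimSection:
    t_total: float = 12000.0
    t_discard: float = 4000.0


@dataclass
class LossSection:
    alpha: float = 1000.0
    beta: float = 1000.0
    gamma: float = 0.0
    delta: float = 0.0
    eta: float = 0.0
    threshold: float = DEFAULT_BURST_THRESHOLD
    merge_gap: float = DEFAULT_MERGE_GAP
    sentinel: float = WORST_CASE_LOSS


@dataclass
class PTSection:
    n_chains: int = 24
    n_samples: int = 10000
    gamma_min: float = 1e-3
    swap_interval: int = 1
    adapt_start: int = 100
    adapt_ladder: bool = True
    initial_step_frac: float = 0.05


@dataclass
class DiagnosticsSection:
    cv_threshold: float = DEFAULT_CV_THRESHOLD
    geweke_z_cut: float = 2.0


@dataclass
class AnalysisSection:
    bins: int = 50
    kde_grid: int = 128
    n_projections: int = 200
    point_alpha: float = 1e-3


@dataclass
class PriorSection:
    lower: list = None   # None: model default box
    upper: list = None


@dataclass
class RunConfig:
    model: str = "am8"                  # "am8" | "hh3"
    constraint: str = "individual"      # "individual" | "aggregate"
    current: float = 0.0                # nA, for the individual constraint
    seed: int = 0
    out_dir: str = "runs/out"
    solver: SolverSection = field(default_factory=SolverSection)
    stim: StimSection = field(default_factory=StimSection)
    loss: LossSection = field(default_factory=LossSection)
    pt: PTSection = field(default_factory=PTSection)
    diagnostics: DiagnosticsSection = field(default_factory=DiagnosticsSection)
    analysis: AnalysisSection = field(default_factory=AnalysisSection)
    prior: PriorSection = field(default_factory=PriorSection)

    def __post_init__(self):
        if self.model not in ("am8", "hh3"):
            raise ConfigError(f"unknown model: {self.model!r}")
        if self.constraint not in ("individual", "aggregate"):
            raise ConfigError(f"unknown constraint: {self.constraint!r}")
        if self.model == "am8" and self.constraint == "individual":
            from .ground_truth import DEFAULT_CURRENTS
            if self.current not in DEFAULT_CURRENTS:
                raise ConfigError(
                    f"current {self.current} outside the supported "
                    f"ground-truth set {DEFAULT_CURRENTS}")


_SECTION_TYPES = {
    "solver": SolverSection,
    "stim": StimSection,
    "loss": LossSection,
    "pt": PTSection,
    "diagnostics": DiagnosticsSection,
    "analysis": AnalysisSection,
    "prior": PriorSection,
}


def _build_section(cls, data, path):
    if not isinstance(data, dict):
        raise ConfigError(f"section {path!r} must be a mapping")
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in section {path!r}")
    return cls(**data)


def config_from_dict(data: dict) -> RunConfig:
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    known = {f.name: f for f in fields(RunConfig)}
    unknown = set(data) - set(known)
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        if name in _SECTION_TYPES:
            kwargs[name] = _build_section(_SECTION_TYPES[name], value, name)
        else:
            kwargs[name] = value
    return RunConfig(**kwargs)


def config_to_dict(cfg: RunConfig) -> dict:
    return dataclasses.asdict(cfg)


def load_config(path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text())
    if data is None:
        data = {}
    return config_from_dict(data)


def save_config(path, cfg: RunConfig) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg),
                                         sort_keys=False))
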