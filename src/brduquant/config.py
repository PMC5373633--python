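"""Run configuration: one YAML file describing every stage of the pipeline."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cytometry import GatingParams
from .kinetics import AntibodyKinetics
from .segment import SegmentationParams
from .synthgen import CellCycleParams, ImagingParams, PopulationParams

__all__ = ["WashParams", "FlowParams", "RunConfig", "load_config", "config_hash"]


@dataclass
class WashParams:
    """Post-antibody wash applied to the simulated population (optional)."""

    t_wash: float = 0.0  # minutes
    stabilised: bool = False
    formaldehyde_conc: float = 0.0  # percent


@dataclass
class FlowParams:
    noise_cv: float = 0.05


@dataclass
class RunConfig:
    population: PopulationParams = field(default_factory=PopulationParams)
    cell_cycle: CellCycleParams = field(default_factory=CellCycleParams)
    imaging: ImagingParams = field(default_factory=ImagingParams)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    kinetics: AntibodyKinetics = field(default_factory=AntibodyKinetics)
    gating: GatingParams = field(default_factory=GatingParams)
    wash: WashParams = field(default_factory=WashParams)
    flow: FlowParams = field(default_factory=FlowParams)
    seed: int = 0
    f: float | None = None  # labelled fraction for the R/non-R statistic; None = estimate
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.apply_seed(self.seed)

    def apply_seed(self, seed: int) -> None:
        """Propagate one global seed to every stochastic stage."""
        self.seed = int(seed)
        self.population.seed = self.seed
        self.imaging.seed = self.seed + 1

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["kinetics"]["stab_curve"] = [list(p) for p in d["kinetics"]["stab_curve"]]
        return d


_BLOCKS = {
    "population": PopulationParams,
    "cell_cycle": CellCycleParams,
    "imaging": ImagingParams,
    "segmentation": SegmentationParams,
    "kinetics": AntibodyKinetics,
    "gating": GatingParams,
    "wash": WashParams,
    "flow": FlowParams,
}


def _build_block(cls, data: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    if cls is AntibodyKinetics and "stab_curve" in data:
        data = dict(data, stab_curve=tuple(tuple(p) for p in data["stab_curve"]))
    if cls is ImagingParams and "nucleus_radius_range" in data:
        data = dict(data, nucleus_radius_range=tuple(data["nucleus_radius_range"]))
    return cls(**data)


def load_config(path=None, overrides: dict | None = None, seed: int | None = None) -> RunConfig:
    """Build a :class:`RunConfig` from an optional YAML file plus overrides.

    The YAML file holds one mapping per parameter block (``population``,
    ``imaging``, ...) and top-level ``seed`` / ``f`` / ``log_level`` keys.  A
    ``seed`` argument overrides everything and is propagated to all stages.
    """
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    if overrides:
        data.update(overrides)

    kwargs = {}
    for key, cls in _BLOCKS.items():
        if key in data:
            kwargs[key] = _build_block(cls, dict(data.pop(key)))
    for key in ("seed", "f", "log_level"):
        if key in data:
            kwargs[key] = data.pop(key)
    if data:
        raise ValueError(f"unknown configuration keys: {sorted(data)}")

    cfg = RunConfig(**kwargs)
    if seed is not None:
        cfg.apply_seed(seed)
    return cfg


def config_hash(cfg: RunConfig) -> str:
    """Deterministic sha256 of the canonical JSON form of a config."""
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()
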