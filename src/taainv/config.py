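"""Run configuration: one schema-checked block per pipeline stage."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .exceptions import ParameterError

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Configuration for dataset generation, training and evaluation.

    Serialized verbatim (as JSON) into every artifact the pipeline writes,
    so containers and checkpoints are self-describing.
    """

    # synthetic-data generation
    n_profiles: int = 100
    combos: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0)
    base_seed: int = 0
    target_dmax: float = 1.5
    dmax_tol: float = 0.01
    floor_frac: float = 0.3
    kernel_variance: float = 1.0
    kernel_length_theta: float = 1.0
    kernel_length_z: float = 0.25
    smooth_width: int = 3
    # wall model
    target_distensibility: float = 0.05442
    # maps / split
    n_train: int = 450
    split_seed: int = 1
    d_range: tuple[float, float] = (0.9, 1.8)
    dist_range: tuple[float, float] = (0.0, 0.08)
    # training
    tier: str = "reduced"
    train_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_profiles < 1:
            raise ParameterError("n_profiles must be >= 1")
        if not self.combos:
            raise ParameterError("combos must be nonempty")
        if self.tier not in ("full", "reduced"):
            raise ParameterError(f"unknown tier {self.tier!r}")
        if self.n_train >= self.n_profiles * len(self.combos):
            raise ParameterError("n_train must be below the record count")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        data = dict(data)
        for key in ("combos", "d_range", "dist_range"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        for key in ("combos", "d_range", "dist_range"):
            out[key] = list(out[key])
        return out

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))
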