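"""Pipeline configuration.

A single seed governs every stochastic stage; each stage derives its own
independent stream from it (`PipelineConfig.rng`), so whole-pipeline runs
are bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import tomllib
import zlib
from pathlib import Path

import numpy as np


@dataclasses.dataclass
class PipelineConfig:
    seed: int = 1
    mcl_inflation: float = 1.5
    accumulation_permutations: int = 100
    synteny_min_anchors: int = 5
    synteny_max_gap: int = 25
    mixture_max_iter: int = 2000
    mixture_tol: float = 1e-8
    mixture_restarts: int = 20

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if v <= 0:
                raise ValueError(f"config field {f.name!r} must be positive, got {v}")
        if self.mcl_inflation <= 1:
            raise ValueError("mcl_inflation must be > 1")

    def rng(self, stage: str) -> np.random.Generator:
        """Per-stage random stream derived from the global seed."""
        key = zlib.crc32(stage.encode()) % 2**31  # stable across processes
        ss = np.random.SeedSequence(self.seed, spawn_key=(key,))
        return np.random.default_rng(ss)

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
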