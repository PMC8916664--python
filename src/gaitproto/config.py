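"""Experiment configuration: one YAML-serializable object per study.

Defaults reproduce the reference operating point of the recognition
pipeline: margin alpha = 1.25, loss weight lambda = 1.0, n = 10 shots,
kernel width gamma = 2.2, regularizer nu = 0.06, acceptance threshold
tau = -0.1 and pressure floor delta = 0.01, on a 40-subject x 158-step
dataset split 20/10/10 over 10 repetitions.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .encoder import EncoderConfig
from .recognizer import SplitSpec
from .synthetic import GenerationConfig


def fan_out_seed(seed: int, n: int) -> list[int]:
    """Derive n independent child seeds (< 2^31) from one global seed."""
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] % 2**31) for c in children]


@dataclass
class ExperimentConfig:
    generation: GenerationConfig = field(default_factory=GenerationConfig)
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    split: SplitSpec = field(default_factory=SplitSpec)
    gamma: float = 2.2
    nu: float = 0.06
    tau: float = -0.1
    method: str = "lrp"          # attribution method: "sa" | "lrp"
    epsilon: float = 1e-7        # LRP stabilizer
    delta: float = 0.01          # pressure floor
    common_map_steps_per_subject: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seed is not None:
            self.reseed(self.seed)

    def reseed(self, seed: int) -> None:
        """Fan the global seed out to per-stage child seeds."""
        self.seed = seed
        gen_seed, enc_seed, split_seed = fan_out_seed(seed, 3)
        self.generation.seed = gen_seed
        self.encoder.seed = enc_seed
        self.split.seed = split_seed

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        gen = GenerationConfig(**d.pop("generation", {}))
        enc_d = d.pop("encoder", {})
        for key in ("conv_filters", "dense_widths"):
            if key in enc_d:
                enc_d[key] = tuple(enc_d[key])
        enc = EncoderConfig(**enc_d)
        split = SplitSpec(**d.pop("split", {}))
        cfg = cls.__new__(cls)
        defaults = {f: getattr(cls(), f) for f in
                    ("gamma", "nu", "tau", "method", "epsilon", "delta",
                     "common_map_steps_per_subject", "seed")}
        defaults.update(d)
        object.__setattr__(cfg, "generation", gen)
        object.__setattr__(cfg, "encoder", enc)
        object.__setattr__(cfg, "split", split)
        for key, val in defaults.items():
            object.__setattr__(cfg, key, val)
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
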