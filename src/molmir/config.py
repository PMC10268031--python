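"""Run configuration: one flat record covering representation sizes,
fingerprint radius, attention switch, negative sampling and the optimizer."""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields

import yaml


@dataclass
class ModelConfig:
    r: int = 2              # fingerprint radius
    n: int = 3              # bases per word
    w: int = 5              # words per convolution window
    d: int = 32             # embedding width
    T: int = 2              # GNN update rounds
    L: int = 2              # convolution layers
    attention: bool = True  # attended readout; False falls back to the plain mean
    negative_ratio: float = 1.0  # negatives per positive
    epochs: int = 100
    lr: float = 1e-3
    momentum: float = 0.9
    batch_size: int = 8
    seed: int = 0

    def to_yaml(self, path):
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path):
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**raw)
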