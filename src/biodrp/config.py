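"""Run configuration: one YAML document validated into a typed RunConfig.

Defaults mirror the reference training settings (batch 64, 50 epochs, Adam
learning rate 0.001, 1024 fingerprint bits, pathway significance cutoff
0.05, 5-fold CV). Validation is eager and aggregates every problem into one
error message.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import yaml

from .network import TrainConfig


@dataclass
class RunConfig:
    data_dir: str = "."
    out_dir: str = "out"
    alpha: float = 0.05
    fingerprint_radius: int = 2
    fingerprint_bits: int = 1024
    batch_size: int = 64
    epochs: int = 50
    learning_rate: float = 0.001
    strategy: str = "pair_kfold"
    k: int = 5
    seed: int = 0
    omics_subset: list[str] | None = None
    init_scheme: str = "glorot"
    n_runs: int = 10
    top_k: int = 20
    n_select: int = 10

    def train_config(self) -> TrainConfig:
        return TrainConfig(batch_size=self.batch_size, epochs=self.epochs,
                           learning_rate=self.learning_rate, seed=self.seed,
                           init_scheme=self.init_scheme)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def validate_config(raw: dict | str | Path, check_paths: bool = True) -> RunConfig:
    """Validate a raw config mapping (or a YAML file path) into a RunConfig.

    Unknown keys, out-of-range values and missing paths are collected and
    reported together.
    """
    if isinstance(raw, (str, Path)):
        raw = yaml.safe_load(Path(raw).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config document must be a mapping")

    known = {f.name for f in fields(RunConfig)}
    problems = [f"unknown config key: {k!r}" for k in raw if k not in known]
    cfg = RunConfig(**{k: v for k, v in raw.items() if k in known})

    if not 0.0 <= cfg.alpha <= 1.0:
        problems.append(f"alpha must lie in [0, 1], got {cfg.alpha}")
    if cfg.fingerprint_bits < 1:
        problems.append("fingerprint_bits must be >= 1")
    if cfg.batch_size < 1:
        problems.append("batch_size must be >= 1")
    if cfg.epochs < 1:
        problems.append("epochs must be >= 1")
    if cfg.learning_rate < 0:
        problems.append("learning_rate must be >= 0")
    if cfg.strategy not in ("pair_kfold", "lodo", "loclo", "loco"):
        problems.append(f"unknown split strategy {cfg.strategy!r}")
    if cfg.k < 2:
        problems.append("k must be >= 2")
    if cfg.omics_subset is not None:
        bad = set(cfg.omics_subset) - {"GE", "CNV", "MUT", "PROT"}
        if bad:
            problems.append(f"unknown omics kinds in subset: {sorted(bad)}")
    if check_paths and not Path(cfg.data_dir).exists():
        problems.append(f"data_dir does not exist: {cfg.data_dir}")

    if problems:
        raise ValueError("invalid configuration:\n  " + "\n  ".join(problems))
    return cfg
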