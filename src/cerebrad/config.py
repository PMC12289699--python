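"""Run configuration: YAML with full defaulting, validation, and a config hash.

Every pipeline stage records the hash of the configuration that produced its
outputs; re-running a stage whose outputs already carry the same hash is a
no-op unless forced.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from cerebrad.sparse import SRCSettings

__all__ = ["RunConfig", "load_config", "config_hash"]

TASKS = {
    # task name -> (positive group(s), negative group(s))
    "ci_vs_hc": (["MCI", "AD"], ["HC"]),
    "ad_vs_mci": (["AD"], ["MCI"]),
    "ad_vs_hc": (["AD"], ["HC"]),
}


@dataclass
class RunConfig:
    """All knobs of a pipeline run, with validated defaults."""

    # paths
    out_dir: str = "runs/default"
    manifest: str | None = None

    # cohort simulation
    n_per_group: int = 30
    grid_shape: tuple[int, int, int] = (64, 64, 32)
    n_regions: int = 26
    seed: int = 20240101

    # extraction
    modalities: tuple[str, ...] = ("T1", "T2", "FLAIR")
    n_levels: int = 32
    min_voxels: int = 10

    # model
    n_selected: int = 100
    max_atoms: int = 30
    tol: float = 1e-6
    gamma: float = 0.01

    # evaluation
    task: str = "ci_vs_hc"
    ratio: tuple[int, int] = (2, 1)
    n_folds: int = 10
    repeats: int = 1

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}; expected one of {sorted(TASKS)}")
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if self.ratio[0] <= 0 or self.ratio[1] <= 0:
            raise ValueError("both ratio portions must be positive")

    def src_settings(self) -> SRCSettings:
        return SRCSettings(
            n_selected=self.n_selected, max_atoms=self.max_atoms,
            tol=self.tol, gamma=self.gamma,
        )

    def task_groups(self):
        return TASKS[self.task]


def config_hash(cfg: RunConfig) -> str:
    payload = json.dumps(asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path | None, **overrides) -> RunConfig:
    """Load YAML config (all keys optional) and apply CLI overrides."""
    data: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config {path} must be a mapping")
        data.update(raw)
    data.update({k: v for k, v in overrides.items() if v is not None})
    for key in ("grid_shape", "modalities", "ratio"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    return RunConfig(**data)
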