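"""Run configuration: dataclass + YAML loading and seed substreams."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from .model_eval import DEFAULT_C_GRID


@dataclass
class RunConfig:
    """Everything one experiment needs, mirroring the YAML layout."""

    database: str = ""
    frames: tuple = ("body", "world")     # or a single frame
    window_s: float = 7.0
    window_mode: str = "first"            # 'first' | 'tiled'
    c_grid: tuple = DEFAULT_C_GRID
    folds: int = 5
    repeats: int = 20
    seed: int = 0
    balance: bool = True
    standardize: bool = True
    run_sbs: bool = False
    sbs_stop_size: int = 1
    sbs_cv_repeats: int = 1
    output: str = "results"

    def __post_init__(self):
        if isinstance(self.frames, str):
            self.frames = ("body", "world") if self.frames == "both" else (self.frames,)
        self.frames = tuple(self.frames)
        for f in self.frames:
            if f not in ("body", "world"):
                raise ValueError(f"unknown frame {f!r}")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if self.window_s <= 0:
            raise ValueError("window must be positive")
        self.c_grid = tuple(float(c) for c in self.c_grid)


def load_config(path, **overrides) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    raw.update(overrides)
    return RunConfig(**raw)


#: named randomness substreams, all derived from the single root seed
SUBSTREAMS = ("balance", "grid", "folds", "sbs", "permutation", "simulate")


def substream_seeds(root_seed: int) -> dict:
    """One reproducible child seed (< 2^31) per named pipeline stage."""
    ss = np.random.SeedSequence(root_seed)
    states = ss.generate_state(len(SUBSTREAMS)) % (2 ** 31)
    return dict(zip(SUBSTREAMS, (int(s) for s in states)))
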