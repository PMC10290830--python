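"""Run configuration: one place for every knob the pipeline exposes.

A master seed fans out to every stochastic stage through numpy's
``SeedSequence`` spawning, so a whole run is reproducible from the config
file alone.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .matrices import Background
from .models import Catalog


@dataclass
class RunConfig:
    seed: int = 0
    at_content: float = 0.6
    pseudocount: float = 1.0
    threshold_positions: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0)
    p_value: float = 0.006
    n_scrambles: int = 100
    rz_scrambles: int = 1
    n_trials: int = 50
    train_size: int = 102
    n_null_sets: int = 100_000
    catalog: str = Catalog.FULL64.value
    output_dir: str = "marz-out"

    def background(self) -> Background:
        return Background.from_at_gc(self.at_content, 1.0 - self.at_content)

    def rng(self, stage: str) -> np.random.Generator:
        """A per-stage generator derived from the master seed.

        Distinct stage names give independent streams; the same (seed,
        stage) pair always reproduces the same stream.
        """
        stage_key = int.from_bytes(stage.encode(), "big") % (2**31)
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(stage_key,))
        )

    def to_yaml(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["threshold_positions"] = list(self.threshold_positions)
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text())
        payload["threshold_positions"] = tuple(payload["threshold_positions"])
        return cls(**payload)
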