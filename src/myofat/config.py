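"""Pipeline configuration: one flat record of every tunable, YAML round-trippable."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from .active_contour import SnakeConfig
from .errors import InvalidSpecError


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of the segmentation pipeline.

    Snake weights (0.1, 0.6, 0.3), N = 50 contour points and the 20-middle-
    slice aggregation window are the method's standard operating point.
    """

    # tissue clustering
    kmeans_restarts: int = 8
    closing_radius_px: int = 3
    # active contour
    alpha: float = 0.1
    beta: float = 0.6
    gamma: float = 0.3
    n_points: int = 50
    search_window_px: int = 7
    max_iter: int = 200
    move_tol: float = 0.02
    # compartments / aggregation
    n_middle: int = 20
    min_fascia_fraction: float = 0.2
    boundary_support_radius_px: int = 5
    # run control
    seed: int = 0
    out_dir: str = "myofat_out"
    verbosity: str = "INFO"

    def snake_config(self) -> SnakeConfig:
        return SnakeConfig(
            alpha=self.alpha,
            beta=self.beta,
            gamma=self.gamma,
            n_points=self.n_points,
            search_window_px=self.search_window_px,
            max_iter=self.max_iter,
            move_tol=self.move_tol,
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InvalidSpecError(
                f"unknown configuration keys: {sorted(unknown)}"
            )
        return cls(**data)
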