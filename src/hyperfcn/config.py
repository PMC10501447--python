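"""Pipeline configuration with defaults matching the reference protocol.

Defaults: incidence threshold t = 0.7; hyperparameter grids
p in 0.01..0.10 (step 0.01), lambda in 0.1..0.9 (step 0.1),
gamma in 2^-4..2^4 (integer exponents); threshold sweep 0.10..0.95
(step 0.05).  Every pipeline run writes its resolved configuration next
to its outputs so results are reproducible from config + seed alone.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .classify import DEFAULT_METHODS, METHOD_VIEWS, HyperparameterGrid


def default_sweep_thresholds() -> list[float]:
    """The 18-point threshold grid 0.10, 0.15, ..., 0.95."""
    return [round(0.1 + 0.05 * k, 10) for k in range(18)]


@dataclass
class PipelineConfig:
    threshold: float = 0.7
    abs_threshold: bool = False
    p_grid: list[float] = field(
        default_factory=lambda: [round(0.01 * k, 10) for k in range(1, 11)]
    )
    lambda_grid: list[float] = field(
        default_factory=lambda: [round(0.1 * k, 10) for k in range(1, 10)]
    )
    gamma_grid: list[float] = field(
        default_factory=lambda: [float(2.0**e) for e in range(-4, 5)]
    )
    methods: list[str] = field(default_factory=lambda: list(DEFAULT_METHODS))
    seed: int = 0
    manifest: str | None = None
    output_dir: str = "hyperfcn_out"
    outer_folds: int = 10
    inner_folds: int = 10
    equal_var: bool = False
    sweep_thresholds: list[float] = field(default_factory=default_sweep_thresholds)
    write_matrices: bool = True
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError(f"threshold must lie in [0, 1], got {self.threshold}")
        for t in self.sweep_thresholds:
            if not 0.0 <= t <= 1.0:
                raise ValueError(f"sweep threshold {t} outside [0, 1]")
        for m in self.methods:
            if m not in METHOD_VIEWS:
                raise ValueError(
                    f"unknown method {m!r}; choose from {sorted(METHOD_VIEWS)}"
                )
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("fold counts must be at least 2")
        self.grid()  # validates the three grids

    def grid(self) -> HyperparameterGrid:
        return HyperparameterGrid(
            p_grid=np.asarray(self.p_grid, dtype=float),
            lambda_grid=np.asarray(self.lambda_grid, dtype=float),
            gamma_grid=np.asarray(self.gamma_grid, dtype=float),
        )

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        raw.pop("hyperfcn_version", None)  # provenance stamp, not a setting
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        from . import __version__

        payload = asdict(self)
        payload["hyperfcn_version"] = __version__
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))
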