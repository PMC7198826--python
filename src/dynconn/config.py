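"""Run configuration: one flat YAML file covering every pipeline parameter."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from .classify import HyperGrid

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """All pipeline parameters with their defaults.

    A serialized copy is written into every CLI output directory so each run
    is reproducible from the config and the inputs alone.
    """

    # synthetic-cohort generator
    n_patients: int = 45
    n_controls: int = 47
    n_roi: int = 16
    n_volumes: int = 170
    n_states: int = 2
    within_r: float = 0.6
    noise_sd: float = 0.4
    # network construction / moment extraction (per-level optima as defaults)
    lo_window: int = 60
    lo_step: int = 2
    lo_order: int = 4
    ho_window: int = 40
    ho_step: int = 12
    ho_order: int = 2
    normalization: str = "paper"
    ho_trim: str = "pair_excluded"
    # cross-validation
    outer_folds: int = 6
    inner_folds: int = 5
    repetitions: int = 10
    seed: int = 0
    # hyperparameter grids
    p_thresholds: Sequence[float] = field(
        default_factory=lambda: list(HyperGrid().p_thresholds)
    )
    lambdas: Sequence[float] = field(default_factory=lambda: list(HyperGrid().lambdas))
    svm_tradeoffs: Sequence[float] = field(
        default_factory=lambda: list(HyperGrid().svm_tradeoffs)
    )
    fusion_weights: Sequence[float] = field(
        default_factory=lambda: list(HyperGrid().fusion_weights)
    )
    T_grid: Sequence[int] = field(default_factory=lambda: list(HyperGrid().T_grid))
    S_grid: Sequence[int] = field(default_factory=lambda: list(HyperGrid().S_grid))
    d_grid: Sequence[int] = field(default_factory=lambda: list(HyperGrid().d_grid))

    def hyper_grid(self) -> HyperGrid:
        return HyperGrid(
            p_thresholds=tuple(self.p_thresholds),
            lambdas=tuple(self.lambdas),
            svm_tradeoffs=tuple(self.svm_tradeoffs),
            fusion_weights=tuple(self.fusion_weights),
            T_grid=tuple(self.T_grid),
            S_grid=tuple(self.S_grid),
            d_grid=tuple(self.d_grid),
        )

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
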