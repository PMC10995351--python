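"""Run configuration: one validated YAML drives the whole pipeline.

Every stochastic stage derives its seed from the single top-level seed,
so a run is a pure function of its configuration.  Unknown keys are
rejected (typos fail loudly).  The defaults are desk-scale: they keep a
full simulate -> train -> prune -> retrain -> explain -> report run in
the minutes range on one CPU.  ``paper_scale: true`` swaps in the
original study's search spaces (log-spaced learning rates 1e-07..0.9,
momenta 0.05..1.00 with a finer 0.95..1.00 band, 500 epochs, 50,000
random restarts, retraining grid 1e-09..1e-04 x 0.700..1.000 step
0.025), which are cluster-scale settings.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import snn


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CohortConfig(_Section):
    n_train: int = Field(default=15, ge=1)
    n_test: int = Field(default=7, ge=1)
    n_per_category: int = Field(default=40, ge=1)
    n_volumes: int = Field(default=485, ge=1)
    n_ics: int = Field(default=125, ge=1)
    tr_seconds: float = Field(default=2.5, gt=0)
    noise_sd: float = Field(default=0.5, ge=0)
    effect_size: float = 1.0


class ScreeningConfig(_Section):
    n_stimuli: int = Field(default=200, ge=1)
    n_per_group: int = Field(default=40, ge=1)


class FeatureConfig(_Section):
    volume_offset: int = Field(default=3, ge=1)
    standardize_mode: str = "train_stats"

    @model_validator(mode="after")
    def _check_mode(self):
        if self.standardize_mode not in ("train_stats", "independent"):
            raise ValueError(
                f"standardize_mode must be 'train_stats' or 'independent', "
                f"got {self.standardize_mode!r}"
            )
        return self


class TrainStageConfig(_Section):
    lr_grid: list[float] = Field(default_factory=lambda: [0.01])
    momentum_grid: list[float] = Field(default_factory=lambda: [0.9])
    epochs: int = Field(default=30, ge=1)
    n_restarts: int = Field(default=2, ge=1)
    init_scale: float = Field(default=0.5, ge=0)
    n_hidden: int = Field(default=10, ge=1)


class RetrainStageConfig(_Section):
    lr_grid: list[float] = Field(default_factory=lambda: [1e-9, 1e-3])
    momentum_grid: list[float] = Field(default_factory=lambda: [0.85])
    epochs: int = Field(default=30, ge=1)
    n_restarts: int = Field(default=1, ge=1)


class ExplainConfig(_Section):
    background_n: int = Field(default=100, ge=1)
    n_permutations: int = Field(default=2000, ge=1)
    #: test instances explained at input level; None = all of them
    n_instances: int | None = Field(default=None, ge=1)
    top_n: int = Field(default=20, ge=1)


class RunConfig(_Section):
    seed: int = Field(default=0, ge=0, lt=2**31)
    paper_scale: bool = False
    cohort: CohortConfig = Field(default_factory=CohortConfig)
    screening: ScreeningConfig = Field(default_factory=ScreeningConfig)
    features: FeatureConfig = Field(default_factory=FeatureConfig)
    train: TrainStageConfig = Field(default_factory=TrainStageConfig)
    retrain: RetrainStageConfig = Field(default_factory=RetrainStageConfig)
    explain: ExplainConfig = Field(default_factory=ExplainConfig)

    def effective(self) -> "RunConfig":
        """Resolve ``paper_scale`` into concrete search spaces."""
        if not self.paper_scale:
            return self
        out = self.model_copy(deep=True)
        out.train.lr_grid = snn.training_lr_grid()
        out.train.momentum_grid = snn.training_momentum_grid()
        out.train.epochs = 500
        out.train.n_restarts = 50_000
        out.retrain.lr_grid = snn.retraining_lr_grid()
        out.retrain.momentum_grid = snn.retraining_momentum_grid()
        return out

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.model_validate(raw or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump()))
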