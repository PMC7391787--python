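"""Run configuration shared by the pipeline and the CLI.

Defaults reproduce the published protocol where it is stated: 80/20
stratified split, gaps g = 0..9, the five cluster profiles at their default
peptide orders, and a 20% test-sensitivity threshold for admitting base
models into the stacked ensemble.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .modeling import DEFAULT_C_GRID, DEFAULT_GAMMA_GRID

#: Vote-vector construction policies for final-classifier training.
STACKING_POLICIES = ("out_of_fold", "resubstitution")


@dataclass
class RunConfig:
    """All tunables of a training run."""

    seed: int = 42
    split_fraction: float = 0.8
    sensitivity_threshold: float = 0.2
    gaps: tuple[int, ...] = tuple(range(10))
    profiles: tuple[str, ...] = ("Op5", "Op8", "Op9", "Op11", "Op13")
    c_grid: tuple[float, ...] = DEFAULT_C_GRID
    gamma_grid: tuple[float, ...] = DEFAULT_GAMMA_GRID
    cv_folds: int = 5
    ifs_ggap: bool = True        # ANOVA + IFS on g-gap models
    ifs_raac: bool = False       # RAAC models keep their full feature set
    ifs_max_k: int | None = None  # truncate the IFS curve (None = full)
    ifs_nested_grid: bool = False  # re-run grid search at every IFS subset size
    stacking_policy: str = "out_of_fold"
    stacking_folds: int = 5
    class_weight: str | None = None  # None or "balanced"

    def __post_init__(self) -> None:
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError(f"split_fraction must be in (0, 1), got {self.split_fraction}")
        if not 0.0 <= self.sensitivity_threshold <= 1.0:
            raise ValueError("sensitivity_threshold must be in [0, 1]")
        if self.stacking_policy not in STACKING_POLICIES:
            raise ValueError(
                f"unknown stacking_policy {self.stacking_policy!r}; expected {STACKING_POLICIES}"
            )
        if self.cv_folds < 2 or self.stacking_folds < 2:
            raise ValueError("fold counts must be >= 2")
        self.gaps = tuple(int(g) for g in self.gaps)
        self.profiles = tuple(self.profiles)
        self.c_grid = tuple(float(c) for c in self.c_grid)
        self.gamma_grid = tuple(float(g) for g in self.gamma_grid)

    def as_dict(self) -> dict:
        d = asdict(self)
        d["gaps"] = list(self.gaps)
        d["profiles"] = list(self.profiles)
        d["c_grid"] = list(self.c_grid)
        d["gamma_grid"] = list(self.gamma_grid)
        return d

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.as_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)
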