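"""Run configuration: every tunable of the two-stage pipeline in one place.

A resolved copy of the configuration is written next to each run's outputs
so any result can be reproduced from its directory alone.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .ranker import DEFAULT_C_GRID, DEFAULT_PAIR_CAP, DEFAULT_RELEVANCE_BINS

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # feature windowing
    window: int = 9
    # stage-1 under-sampled ensemble
    ratio: int = 4                       # non-contact : contact
    n_members: int = 3                   # classifiers per range class
    n_trees: int = 500
    # stage-2 ranking SVM
    relevance_bins: tuple = DEFAULT_RELEVANCE_BINS
    pair_cap: int = DEFAULT_PAIR_CAP
    C: float | None = None               # fixed C; None => cross-validate
    C_grid: tuple = DEFAULT_C_GRID
    svm_tol: float = 1e-9
    svm_max_iter: int = 100_000
    # stage-2 features for training targets come from RF ensembles fitted on
    # the other folds (stacking without leakage); 1 disables cross-fitting
    cross_fit_folds: int = 2
    # reproducibility / resources
    seed: int = 0
    n_jobs: int = 1

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["relevance_bins"] = list(self.relevance_bins)
        data["C_grid"] = list(self.C_grid)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "relevance_bins" in data:
            data["relevance_bins"] = tuple(data["relevance_bins"])
        if "C_grid" in data:
            data["C_grid"] = tuple(data["C_grid"])
        return cls(**data)
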