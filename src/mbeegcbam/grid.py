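"""Attention hyperparameter grid search for a single branch.

For every (reduction ratio, spatial kernel) cell, one single-branch model is
trained on the training split and scored on the test split; results come
back as a tidy table sorted by accuracy.  The grid is a pure function of
(data, grid spec, training spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .attention import AttentionConfig
from .containers import TrialSet
from .eegnet import BranchConfig, default_branch_configs
from .evaluation import evaluate
from .model import build_eegcbam
from .pipeline import split_within_subject
from .training import TrainSpec, train

__all__ = ["GridSpec", "run_grid"]


@dataclass(frozen=True)
class GridSpec:
    """Ratio x kernel grid over one branch's attention block."""

    ratios: tuple[int, ...] = (2, 4, 8)
    kernels: tuple[int, ...] = (2, 4, 8)
    branch_under_test: int = 1
    repetitions: int = 1
    seed: int = 0

    def __post_init__(self):
        if not self.ratios or not self.kernels:
            raise ValueError("ratio and kernel sets must be non-empty")
        if not 1 <= self.branch_under_test <= 3:
            raise ValueError("branch_under_test must lie in 1..3")
        if self.repetitions < 1:
            raise ValueError("repetitions must be positive")


def run_grid(data, grid: GridSpec, trainspec: TrainSpec | None = None,
             base_config: BranchConfig | None = None) -> pd.DataFrame:
    """Train one single-branch model per grid cell and tabulate accuracies.

    ``data`` is either a ``(train, test)`` pair of TrialSets or a list of
    session TrialSets (split with the last session held out).  Returns a
    DataFrame with columns ratio, kernel, accuracy, sorted by accuracy
    (descending), averaging over ``grid.repetitions`` differently seeded
    builds per cell.
    """
    if isinstance(data, (tuple, list)) and len(data) == 2 \
            and isinstance(data[0], TrialSet) and isinstance(data[1], TrialSet) \
            and not isinstance(data, TrialSet):
        train_set, test_set = data
    else:
        train_set, test_set = split_within_subject(list(data), 1)
    trainspec = trainspec or TrainSpec()
    if base_config is None:
        base_config = default_branch_configs()[grid.branch_under_test - 1]
    n_classes = int(max(train_set.labels.max(), test_set.labels.max())) + 1
    input_shape = (train_set.n_channels, train_set.n_samples)
    rows = []
    for ratio in grid.ratios:
        for kernel in grid.kernels:
            cfg = replace(base_config,
                          attention=AttentionConfig(ratio=ratio, kernel=kernel))
            accs = []
            for rep in range(grid.repetitions):
                cell_seed = (grid.seed + 10007 * rep) % (2 ** 31)
                model = build_eegcbam(input_shape, n_classes, cfg, seed=cell_seed)
                spec = replace(trainspec, seed=cell_seed)
                train(model, train_set, spec)
                accs.append(evaluate(model, test_set).accuracy)
            rows.append({"ratio": ratio, "kernel": kernel,
                         "accuracy": float(np.mean(accs))})
    table = pd.DataFrame(rows)
    return table.sort_values("accuracy", ascending=False, kind="mergesort",
                             ignore_index=True)
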