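"""Hidden-layer size selection by RMSE sweep.

Candidate sizes come from the rule-of-thumb n = sqrt(i + k) + alpha with
alpha swept over a small integer range: with 6 inputs, 2 outputs and
alpha in 1..10 this enumerates the 11 candidates 3..13.  Each candidate is
trained independently (own seed, derived from the base seed and n, so the
sweep is order-independent) and scored by validation RMSE; the winner
minimizes the sum over outputs of validation RMSE divided by that output's
observed range, which puts the g/L-scale glucose error and the sub-g/L
phenolics error on a common footing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .ann_model import (
    NetworkParams,
    TrainingConfig,
    TrainingHistory,
    init_network,
    train_adam,
)
from .dataset_io import Dataset, OUTPUT_VARS
from .preprocessing import NormalizationSpec


@dataclass(frozen=True)
class ArchitectureSearchConfig:
    n_inputs: int = 6
    n_outputs: int = 2
    alpha_range: tuple[int, int] = (1, 10)
    iterations: int = 500
    seed: int = 0
    training: TrainingConfig = field(default_factory=TrainingConfig)
    candidates_override: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_inputs < 1 or self.n_outputs < 1:
            raise ValueError("n_inputs and n_outputs must be >= 1")
        if self.alpha_range[0] > self.alpha_range[1]:
            raise ValueError("alpha_range is empty")


def candidate_sizes(cfg: ArchitectureSearchConfig) -> list[int]:
    """All integer hidden sizes spanned by sqrt(i+k) + alpha.

    The window runs from floor(sqrt(i+k) + alpha_min) to
    round-half-up(sqrt(i+k) + alpha_max) inclusive, so the default
    configuration enumerates 3..13.
    """
    if cfg.candidates_override is not None:
        sizes = list(cfg.candidates_override)
        if not sizes or sorted(set(sizes)) != sizes or sizes[0] < 1:
            raise ValueError("candidates_override must be strictly increasing ints >= 1")
        return sizes
    base = math.sqrt(cfg.n_inputs + cfg.n_outputs)
    lo = int(math.floor(base + cfg.alpha_range[0]))
    hi = int(math.floor(base + cfg.alpha_range[1] + 0.5))
    return list(range(lo, hi + 1))


def candidate_seed(base_seed: int, n: int) -> int:
    """Per-candidate training seed, a pure function of (base seed, n)."""
    return int(np.random.SeedSequence((base_seed, n)).generate_state(1)[0] % (2**31))


@dataclass
class SweepResult:
    """Train/validation RMSE per candidate hidden size (original scale)."""

    rows: pd.DataFrame  # columns n, rmse_train_glc, rmse_val_glc, rmse_train_phe, rmse_val_phe, seed
    output_ranges: tuple[float, float]  # observed (C_Glc, C_Phe) spans, for scoring

    def to_csv(self, path: str | Path) -> None:
        self.rows.to_csv(path, index=False, float_format="%.10g")


def sweep_neurons(
    train: Dataset,
    validation: Dataset,
    cfg: ArchitectureSearchConfig,
    input_spec: NormalizationSpec | None = None,
    target_spec: NormalizationSpec | None = None,
) -> SweepResult:
    """Train one network per candidate hidden size and record its RMSEs."""
    tcfg = replace(cfg.training, iterations=cfg.iterations)
    records = []
    for n in candidate_sizes(cfg):
        seed = candidate_seed(cfg.seed, n)
        run_cfg = replace(tcfg, seed=seed)
        params = init_network(n, seed)
        _, hist = train_adam(
            params, train, validation, run_cfg,
            input_spec=input_spec, target_spec=target_spec,
            checkpoints=[cfg.iterations],
        )
        (tr_glc, tr_phe) = hist.rmse_train[-1]
        (va_glc, va_phe) = hist.rmse_val[-1]
        records.append(
            {
                "n": n,
                "rmse_train_glc": tr_glc,
                "rmse_val_glc": va_glc,
                "rmse_train_phe": tr_phe,
                "rmse_val_phe": va_phe,
                "seed": seed,
            }
        )
    Y = train.output_matrix()
    ranges = (float(np.ptp(Y[:, 0])), float(np.ptp(Y[:, 1])))
    return SweepResult(rows=pd.DataFrame(records), output_ranges=ranges)


def sweep_iterations(
    train: Dataset,
    validation: Dataset,
    n: int,
    max_iterations: int,
    checkpoints: Sequence[int],
    seed: int = 0,
    training: TrainingConfig | None = None,
    input_spec: NormalizationSpec | None = None,
    target_spec: NormalizationSpec | None = None,
) -> TrainingHistory:
    """One training run of a size-n network with RMSE recorded at checkpoints."""
    marks = list(checkpoints)
    if not marks or any(b <= a for a, b in zip(marks, marks[1:])):
        raise ValueError("checkpoints must be non-empty and strictly increasing")
    if marks[-1] > max_iterations or marks[0] < 1:
        raise ValueError("checkpoints must lie within [1, max_iterations]")
    tcfg = replace(training or TrainingConfig(), iterations=max_iterations, seed=seed)
    params = init_network(n, seed)
    _, hist = train_adam(
        params, train, validation, tcfg,
        input_spec=input_spec, target_spec=target_spec, checkpoints=marks,
    )
    return hist


def select_architecture(sweep: SweepResult) -> int:
    """Best hidden size: lowest range-normalized validation-RMSE sum.

    Score(n) = rmse_val_glc / range(C_Glc) + rmse_val_phe / range(C_Phe);
    ties break toward the smaller n.
    """
    if sweep.rows.empty:
        raise ValueError("sweep result is empty")
    rg, rp = sweep.output_ranges
    df = sweep.rows
    score = df["rmse_val_glc"] / rg + df["rmse_val_phe"] / rp
    best = df.loc[score.idxmin(), "n"]  # idxmin returns first minimum: smaller n wins ties
    # idxmin is positional-first; guarantee the tie rule even for unsorted rows
    minimum = score.min()
    candidates = df.loc[score <= minimum, "n"]
    return int(min(int(best), int(candidates.min())))
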