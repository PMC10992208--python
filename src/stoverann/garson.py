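"""Garson connection-weight relative importance of the network inputs.

For output k, the importance of input i partitions the absolute
input-to-hidden weights, scaled by the absolute hidden-to-output weights:

    I_i = sum_j ( |IW_ji| / sum_i' |IW_ji'| ) * |LW_kj|
          -----------------------------------------------
          sum_i'' sum_j ( |IW_ji''| / sum_i' |IW_ji'| ) * |LW_kj|

Biases play no role and the statistic is independent of the activation
functions, so it can be evaluated directly on a published weight table.
The fractions are non-negative and sum to exactly 1 per output.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .ann_model import NetworkParams
from .dataset_io import CONDITION_VARS, OUTPUT_VARS

#: inputs belonging to the pretreatment step (everything except enzyme dose)
PRETREATMENT_VARS = ("C_IA", "T", "t", "R_SL", "k_IA")


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero-point-five up."""
    return int(np.floor(x + 0.5))


@dataclass(frozen=True)
class ImportanceTable:
    """Relative importance of each input on one output."""

    output: str  # "C_Glc" or "C_Phe"
    fractions: tuple[float, ...]  # per input, in CONDITION_VARS order, sums to 1

    @property
    def percents(self) -> tuple[int, ...]:
        """Integer-percent view (round-half-up); not forced to sum to 100."""
        return tuple(round_half_up(100.0 * f) for f in self.fractions)

    @property
    def ranking(self) -> tuple[str, ...]:
        """Input names from most to least important (ties: input order)."""
        order = sorted(
            range(len(self.fractions)), key=lambda i: (-self.fractions[i], i)
        )
        return tuple(CONDITION_VARS[i] for i in order)

    def fraction_of(self, variable: str) -> float:
        return self.fractions[CONDITION_VARS.index(variable)]

    def percent_of(self, variable: str) -> int:
        return self.percents[CONDITION_VARS.index(variable)]

    def group_fraction(self, variables=PRETREATMENT_VARS) -> float:
        return sum(self.fraction_of(v) for v in variables)

    def group_percent(self, variables=PRETREATMENT_VARS) -> int:
        return round_half_up(100.0 * self.group_fraction(variables))


def garson_importance(params: NetworkParams, k: int) -> ImportanceTable:
    """Garson importance of every input on output ``k`` (1=C_Glc, 2=C_Phe)."""
    if k not in (1, 2):
        raise ValueError(f"output index k must be 1 or 2, got {k}")
    abs_iw = np.abs(params.IW)  # (n, 6)
    row_sums = abs_iw.sum(axis=1)  # per hidden node
    if np.any(row_sums == 0):
        bad = np.nonzero(row_sums == 0)[0] + 1
        raise ValueError(f"hidden node(s) {bad.tolist()} have all-zero input weights")
    share = abs_iw / row_sums[:, None]  # fractional contribution within node
    contrib = (share * np.abs(params.LW[k - 1])[:, None]).sum(axis=0)  # per input
    fractions = contrib / contrib.sum()
    return ImportanceTable(output=OUTPUT_VARS[k - 1], fractions=tuple(fractions))


@dataclass(frozen=True)
class ImportanceReport:
    """Both per-output importance tables plus derived summaries."""

    glucose: ImportanceTable
    phenolics: ImportanceTable

    def tables(self) -> tuple[ImportanceTable, ImportanceTable]:
        return (self.glucose, self.phenolics)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for tab in self.tables():
            ranks = {v: r + 1 for r, v in enumerate(tab.ranking)}
            for i, var in enumerate(CONDITION_VARS):
                rows.append(
                    {
                        "output": tab.output,
                        "input": var,
                        "importance_fraction": tab.fractions[i],
                        "importance_percent_rounded": tab.percents[i],
                        "rank": ranks[var],
                    }
                )
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")

    def summary_text(self) -> str:
        lines = []
        for tab in self.tables():
            lines.append(f"Relative importance on {tab.output}:")
            for var, frac, pct in zip(CONDITION_VARS, tab.fractions, tab.percents):
                lines.append(f"  {var:>5}: {100 * frac:6.2f}%  (~{pct}%)")
            lines.append(
                f"  pretreatment group (C_IA,T,t,R_SL,k_IA): {tab.group_percent()}%"
                f" vs enzyme dose E: {tab.percent_of('E')}%"
            )
            lines.append(f"  ranking: {' > '.join(tab.ranking)}")
        return "\n".join(lines)


def importance_report(params: NetworkParams) -> ImportanceReport:
    """Importance tables for both outputs of a trained (or loaded) network."""
    return ImportanceReport(
        glucose=garson_importance(params, 1),
        phenolics=garson_importance(params, 2),
    )
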