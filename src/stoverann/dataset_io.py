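"""Data model and I/O for pretreatment/hydrolysis experiment tables.

One experimental run couples six operating conditions of a dilute-acid
pretreatment + enzymatic hydrolysis of corn stover (acid kind, acid
concentration, temperature, residence time, solid-to-liquid ratio, enzyme
dose) with two measured outputs: glucose concentration ``C_Glc`` and total
phenolic content ``C_Phe``, both in g/L of hydrolysate.

The canonical CSV schema (header exactly) is::

    run_id, k_IA, C_IA_mol_L, T_C, t_min, R_SL_frac, E_FPU_g, C_Glc_g_L, C_Phe_g_L

UTF-8, '.' decimal separator, comma delimiter.  Output cells may be empty
for runs whose outcomes were not measured (or not published).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

#: condition variables, in the fixed input order of the network
CONDITION_VARS = ("C_IA", "T", "t", "R_SL", "k_IA", "E")
#: measured outputs, in the fixed output order of the network
OUTPUT_VARS = ("C_Glc", "C_Phe")

#: canonical CSV column for each field
CANONICAL_SCHEMA: dict[str, str] = {
    "run_id": "run_id",
    "k_IA": "k_IA",
    "C_IA": "C_IA_mol_L",
    "T": "T_C",
    "t": "t_min",
    "R_SL": "R_SL_frac",
    "E": "E_FPU_g",
    "C_Glc": "C_Glc_g_L",
    "C_Phe": "C_Phe_g_L",
}

ACID_CODES = (1, 2, 3)  # 1=HCl, 2=H2SO4, 3=H3PO4


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class ParseError(ValueError):
    """A cell could not be parsed as a number."""


@dataclass(frozen=True)
class ExperimentRecord:
    """A single pretreatment/hydrolysis run.

    Conditions are strictly positive finite numbers; the acid kind ``k_IA``
    is the ordinal code 1 (HCl), 2 (H2SO4) or 3 (H3PO4).  Outputs may be
    ``None`` for unmeasured runs.
    """

    run_id: str
    k_IA: int
    C_IA: float  # mol/L
    T: float  # degC
    t: float  # min
    R_SL: float  # fraction
    E: float  # FPU/g
    C_Glc: float | None = None  # g/L
    C_Phe: float | None = None  # g/L

    def __post_init__(self) -> None:
        if self.k_IA not in ACID_CODES:
            raise ValueError(f"k_IA must be one of {ACID_CODES}, got {self.k_IA!r}")
        for name in ("C_IA", "T", "t", "R_SL", "E"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")
        for name in OUTPUT_VARS:
            v = getattr(self, name)
            if v is not None and not (math.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")

    def conditions(self) -> np.ndarray:
        """The six condition values in canonical input order."""
        return np.array([getattr(self, v) for v in CONDITION_VARS], dtype=float)

    def outputs(self) -> np.ndarray:
        """The two outputs in canonical order (NaN where unmeasured)."""
        return np.array(
            [math.nan if getattr(self, v) is None else getattr(self, v) for v in OUTPUT_VARS]
        )


@dataclass(frozen=True)
class DesignSpace:
    """Closed intervals of the operating-condition design, plus allowed acids.

    Defaults are the corn-stover design used throughout: acid concentration
    0.05-0.6 mol/L, temperature 120-200 degC, residence time 20-60 min,
    solid-to-liquid ratio 0.10-0.15, enzyme dose 10-20 FPU/g, all three
    inorganic acids allowed.
    """

    C_IA: tuple[float, float] = (0.05, 0.6)
    T: tuple[float, float] = (120.0, 200.0)
    t: tuple[float, float] = (20.0, 60.0)
    R_SL: tuple[float, float] = (0.10, 0.15)
    E: tuple[float, float] = (10.0, 20.0)
    acid_codes: tuple[int, ...] = ACID_CODES

    def __post_init__(self) -> None:
        for name in ("C_IA", "T", "t", "R_SL", "E"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"design interval for {name} must have low < high")

    def interval(self, var: str) -> tuple[float, float]:
        return getattr(self, var)


@dataclass
class Dataset:
    """Ordered collection of runs with a provenance tag."""

    records: list[ExperimentRecord]
    provenance: str = "measured"  # measured | synthetic | fixture

    def __post_init__(self) -> None:
        ids = [r.run_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate run_id values: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ExperimentRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> ExperimentRecord:
        return self.records[i]

    def condition_matrix(self) -> np.ndarray:
        """N x 6 array of conditions in canonical order."""
        return np.array([r.conditions() for r in self.records], dtype=float).reshape(
            len(self), len(CONDITION_VARS)
        )

    def output_matrix(self) -> np.ndarray:
        """N x 2 array of outputs, NaN where unmeasured."""
        return np.array([r.outputs() for r in self.records], dtype=float).reshape(
            len(self), len(OUTPUT_VARS)
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append({col: getattr(r, f) for f, col in CANONICAL_SCHEMA.items()})
        return pd.DataFrame(rows, columns=list(CANONICAL_SCHEMA.values()))


def _coerce_rsl(value: float) -> float:
    # Table prints the ratio as a percentage; store as a fraction.
    return value / 100.0 if value > 1.0 else value


def read_dataset(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    provenance: str = "measured",
) -> Dataset:
    """Read a run table from CSV.

    Parameters
    ----------
    path:
        CSV file with one header row.
    schema:
        Optional map from canonical field names (``run_id``, ``k_IA``,
        ``C_IA`` ...) to the column names actually present; defaults to the
        canonical schema.  Output columns may contain empty cells.

    Raises
    ------
    SchemaError
        if a required column is absent (the message names it).
    ParseError
        if a cell is not numeric (the message carries the row index).
    """
    schema = dict(CANONICAL_SCHEMA if schema is None else schema)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for fld, col in schema.items():
        if col not in df.columns:
            raise SchemaError(f"missing column {col!r} (field {fld})")

    records: list[ExperimentRecord] = []
    for idx, row in df.iterrows():
        kwargs: dict[str, object] = {"run_id": str(row[schema["run_id"]])}
        for fld in ("k_IA", "C_IA", "T", "t", "R_SL", "E", "C_Glc", "C_Phe"):
            cell = str(row[schema[fld]]).strip()
            if fld in OUTPUT_VARS and cell == "":
                kwargs[fld] = None
                continue
            percent = cell.endswith("%")
            try:
                value = float(cell.rstrip("%"))
            except ValueError:
                raise ParseError(
                    f"row {idx}: cannot parse {fld} value {cell!r} as a number"
                ) from None
            if fld == "R_SL":
                value = value / 100.0 if percent else _coerce_rsl(value)
            kwargs[fld] = int(value) if fld == "k_IA" else value
        records.append(ExperimentRecord(**kwargs))  # type: ignore[arg-type]
    return Dataset(records, provenance=provenance)


def write_dataset(data: Dataset, path: str | Path) -> None:
    """Write a dataset in the canonical CSV schema (empty cells for missing outputs)."""
    df = data.to_frame()
    df.to_csv(path, index=False, float_format="%.10g")


def load_fig2_fixture() -> Dataset:
    """The 15 single-variable scan runs bundled as a fixture.

    Conditions: three acids x five acid concentrations at T=160 degC,
    t=60 min, R_SL=0.10, E=20 FPU/g.  Only the four published outcome values
    are populated; the three highest concentrations per acid are a synthetic
    stand-in for the unpublished scan points and carry no outputs.
    """
    with resources.as_file(resources.files("stoverann.data") / "fig2_points.csv") as p:
        return read_dataset(p, provenance="fixture")


@dataclass(frozen=True)
class Violation:
    run_id: str
    variable: str
    value: float
    bounds: tuple[float, float] | tuple[int, ...]


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def counts_by_variable(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for v in self.violations:
            out[v.variable] = out.get(v.variable, 0) + 1
        return out

    def violating_run_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for v in self.violations:
            seen.setdefault(v.run_id)
        return list(seen)


def validate_ranges(data: Dataset, space: DesignSpace | None = None) -> ValidationReport:
    """Flag every condition value outside the design space.

    A record violates iff any continuous condition lies outside its closed
    interval or its acid code is not allowed.  Purely reporting: never raises.
    """
    space = space or DesignSpace()
    report = ValidationReport()
    for r in data:
        if r.k_IA not in space.acid_codes:
            report.violations.append(
                Violation(r.run_id, "k_IA", float(r.k_IA), space.acid_codes)
            )
        for var in ("C_IA", "T", "t", "R_SL", "E"):
            lo, hi = space.interval(var)
            val = getattr(r, var)
            if not (lo <= val <= hi):
                report.violations.append(Violation(r.run_id, var, val, (lo, hi)))
    return report


def split_dataset(
    data: Dataset,
    ratios: Sequence[float] = (0.75, 0.15, 0.10),
    seed: int = 0,
) -> tuple[Dataset, Dataset, Dataset]:
    """Deterministic seeded train/validation/test partition.

    The training set takes ``floor(N * r_train)`` records.  The remainder is
    shared between validation and test in proportion ``r_val : r_test``,
    validation taking the rounded (half-up) share and test the rest.  With
    N=77 and 75:15:10 this yields 57/12/8.  Assignment is a seeded uniform
    shuffle; the same seed always gives the identical partition.
    """
    if len(data) == 0:
        raise ValueError("cannot split an empty dataset")
    r = np.asarray(ratios, dtype=float)
    if r.ndim != 1 or r.size != 3 or (r < 0).any():
        raise ValueError("ratios must be three non-negative numbers")
    if r.sum() <= 0:
        raise ValueError("degenerate ratios: at least one must be positive")
    r = r / r.sum()

    n = len(data)
    n_train = int(math.floor(n * r[0]))
    rest = n - n_train
    denom = r[1] + r[2]
    if denom > 0:
        n_val = int(math.floor(rest * (r[1] / denom) + 0.5))
    else:
        n_val = 0
    n_val = min(n_val, rest)

    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    idx_train = sorted(order[:n_train])
    idx_val = sorted(order[n_train : n_train + n_val])
    idx_test = sorted(order[n_train + n_val :])

    def take(idx: list[int]) -> Dataset:
        return Dataset([data[i] for i in idx], provenance=data.provenance)

    return take(idx_train), take(idx_val), take(idx_test)
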