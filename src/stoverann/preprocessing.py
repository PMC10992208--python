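"""Min-max normalization of condition and output variables to [-1, 1].

Each covered variable V is mapped affinely from its observed bounds
``[V_min, V_max]`` to a target interval (default ``[-1, 1]``)::

    V' = (V - V_min) / (V_max - V_min) * (V'_max - V'_min) + V'_min

Bounds are fitted on the training split only, so validation/test values may
legitimately map slightly outside the target interval; they are transformed,
never clipped.  ``denormalize`` is the exact affine inverse.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .dataset_io import Dataset


@dataclass(frozen=True)
class NormalizationSpec:
    """Per-variable original bounds plus the shared target interval."""

    bounds: dict[str, tuple[float, float]]
    target: tuple[float, float] = (-1.0, 1.0)

    def __post_init__(self) -> None:
        a, b = self.target
        if not a < b:
            raise ValueError("target range must have min < max")
        for var, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValueError(f"bounds for {var!r} must have min < max")

    @property
    def variables(self) -> list[str]:
        return list(self.bounds)

    def _check(self, variable: str) -> tuple[float, float]:
        try:
            return self.bounds[variable]
        except KeyError:
            raise KeyError(f"variable {variable!r} not covered by this spec") from None

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "target": list(self.target),
            "bounds": {v: [float(lo), float(hi)] for v, (lo, hi) in self.bounds.items()},
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "NormalizationSpec":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(
            bounds={v: (float(lo), float(hi)) for v, (lo, hi) in payload["bounds"].items()},
            target=tuple(payload["target"]),  # type: ignore[arg-type]
        )


def fit_normalizer(
    data: Dataset | np.ndarray,
    variables: Sequence[str],
    target_range: tuple[float, float] = (-1.0, 1.0),
) -> NormalizationSpec:
    """Fit per-variable min/max bounds from data.

    ``data`` is either a :class:`Dataset` (variables looked up by field name)
    or an array with one column per entry of ``variables``.  A constant
    column is an error: the affine map would divide by zero.
    """
    if isinstance(data, Dataset):
        cols = {
            v: np.array(
                [getattr(r, v) for r in data if getattr(r, v) is not None], dtype=float
            )
            for v in variables
        }
    else:
        arr = np.asarray(data, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != len(variables):
            raise ValueError("array data must be 2-D with one column per variable")
        cols = {v: arr[:, j] for j, v in enumerate(variables)}

    bounds: dict[str, tuple[float, float]] = {}
    for v, col in cols.items():
        col = col[np.isfinite(col)]
        if col.size < 2:
            raise ValueError(f"variable {v!r} needs at least two values to fit bounds")
        lo, hi = float(col.min()), float(col.max())
        if lo == hi:
            raise ValueError(f"variable {v!r} is constant (zero range)")
        bounds[v] = (lo, hi)
    return NormalizationSpec(bounds=bounds, target=target_range)


def normalize(value, variable: str, spec: NormalizationSpec):
    """Affine map of ``value`` (scalar or array) into the target interval."""
    lo, hi = spec._check(variable)
    a, b = spec.target
    return (np.asarray(value, dtype=float) - lo) / (hi - lo) * (b - a) + a


def denormalize(value, variable: str, spec: NormalizationSpec):
    """Exact inverse of :func:`normalize`."""
    lo, hi = spec._check(variable)
    a, b = spec.target
    return (np.asarray(value, dtype=float) - a) / (b - a) * (hi - lo) + lo


def normalize_matrix(X: np.ndarray, variables: Sequence[str], spec: NormalizationSpec) -> np.ndarray:
    """Column-wise :func:`normalize` of an N x len(variables) array."""
    X = np.asarray(X, dtype=float)
    return np.column_stack([normalize(X[:, j], v, spec) for j, v in enumerate(variables)])


def denormalize_matrix(X: np.ndarray, variables: Sequence[str], spec: NormalizationSpec) -> np.ndarray:
    """Column-wise :func:`denormalize` of an N x len(variables) array."""
    X = np.asarray(X, dtype=float)
    return np.column_stack([denormalize(X[:, j], v, spec) for j, v in enumerate(variables)])
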