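"""Single-hidden-layer feedforward network for hydrolysate prediction.

The model maps the six normalized operating conditions to the two outputs
(glucose and total phenolics) through one hidden layer of ``n`` neurons:

    y_k = f_out( b2_k + sum_j LW_kj * f_hid( b1_j + sum_i IW_ji * x_i ) )

with tanh hidden units and a linear output layer by default.  Training is
plain minibatch Adam on the mean squared error of both outputs jointly, on
the normalized scale; all reported RMSEs are on the original g/L scale.

Weights serialize to a CSV laid out like the published weight table (one row
per hidden node, output biases on the first two rows) and to lossless JSON.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .dataset_io import CONDITION_VARS, OUTPUT_VARS, Dataset
from .preprocessing import (
    NormalizationSpec,
    denormalize_matrix,
    fit_normalizer,
    normalize_matrix,
)

N_INPUTS = len(CONDITION_VARS)  # 6
N_OUTPUTS = len(OUTPUT_VARS)  # 2

_ACTIVATIONS: dict[str, tuple[Callable, Callable]] = {
    # name -> (f, f') with f' expressed in terms of the pre-activation z
    "tanh": (np.tanh, lambda z: 1.0 - np.tanh(z) ** 2),
    "identity": (lambda z: z, lambda z: np.ones_like(z)),
    "logistic": (
        lambda z: 1.0 / (1.0 + np.exp(-z)),
        lambda z: (s := 1.0 / (1.0 + np.exp(-z))) * (1.0 - s),
    ),
}


@dataclass
class NetworkParams:
    """Weights and biases of a 6-n-2 network.

    ``IW[j, i]`` is the weight from input i to hidden node j; ``LW[k, j]``
    the weight from hidden node j to output k; ``b1`` and ``b2`` the hidden
    and output biases.
    """

    IW: np.ndarray  # (n, 6)
    b1: np.ndarray  # (n,)
    LW: np.ndarray  # (2, n)
    b2: np.ndarray  # (2,)
    hidden_activation: str = "tanh"
    output_activation: str = "identity"

    def __post_init__(self) -> None:
        self.IW = np.asarray(self.IW, dtype=float)
        self.b1 = np.asarray(self.b1, dtype=float)
        self.LW = np.asarray(self.LW, dtype=float)
        self.b2 = np.asarray(self.b2, dtype=float)
        n = self.IW.shape[0]
        if self.IW.shape != (n, N_INPUTS):
            raise ValueError(f"IW must be (n, {N_INPUTS}), got {self.IW.shape}")
        if self.b1.shape != (n,):
            raise ValueError(f"b1 must be (n,), got {self.b1.shape}")
        if self.LW.shape != (N_OUTPUTS, n):
            raise ValueError(f"LW must be ({N_OUTPUTS}, n), got {self.LW.shape}")
        if self.b2.shape != (N_OUTPUTS,):
            raise ValueError(f"b2 must be ({N_OUTPUTS},), got {self.b2.shape}")
        for arr, name in ((self.IW, "IW"), (self.b1, "b1"), (self.LW, "LW"), (self.b2, "b2")):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite entries")
        for act in (self.hidden_activation, self.output_activation):
            if act not in _ACTIVATIONS:
                raise ValueError(f"unknown activation {act!r}")

    @property
    def n_hidden(self) -> int:
        return self.IW.shape[0]

    def copy(self) -> "NetworkParams":
        return NetworkParams(
            self.IW.copy(),
            self.b1.copy(),
            self.LW.copy(),
            self.b2.copy(),
            self.hidden_activation,
            self.output_activation,
        )


def init_network(n: int, seed: int) -> NetworkParams:
    """Seeded initial parameters: uniform(-0.5, 0.5) weights, zero biases."""
    if n < 1:
        raise ValueError(f"hidden size must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    return NetworkParams(
        IW=rng.uniform(-0.5, 0.5, size=(n, N_INPUTS)),
        b1=np.zeros(n),
        LW=rng.uniform(-0.5, 0.5, size=(N_OUTPUTS, n)),
        b2=np.zeros(N_OUTPUTS),
    )


def forward(params: NetworkParams, x: np.ndarray) -> np.ndarray:
    """Forward pass for one 6-vector or a batch of shape (N, 6)."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != N_INPUTS:
        raise ValueError(f"expected {N_INPUTS} inputs, got shape {x.shape}")
    if not np.all(np.isfinite(X)):
        raise ValueError("inputs must be finite")
    f_hid = _ACTIVATIONS[params.hidden_activation][0]
    f_out = _ACTIVATIONS[params.output_activation][0]
    H = f_hid(X @ params.IW.T + params.b1)
    Y = f_out(H @ params.LW.T + params.b2)
    return Y[0] if single else Y


def loss_and_grads(
    params: NetworkParams, X: np.ndarray, Y: np.ndarray
) -> tuple[float, dict[str, np.ndarray]]:
    """Mean-squared-error loss over a batch and its analytic gradients.

    The loss is the mean over samples *and* outputs of the squared residual,
    i.e. both outputs are weighted equally on the normalized scale.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have the same number of rows")
    f_hid, d_hid = _ACTIVATIONS[params.hidden_activation]
    f_out, d_out = _ACTIVATIONS[params.output_activation]

    Z1 = X @ params.IW.T + params.b1
    H = f_hid(Z1)
    Z2 = H @ params.LW.T + params.b2
    Yhat = f_out(Z2)

    R = Yhat - Y
    loss = float(np.mean(R**2))
    dZ2 = (2.0 / R.size) * R * d_out(Z2)
    dLW = dZ2.T @ H
    db2 = dZ2.sum(axis=0)
    dZ1 = (dZ2 @ params.LW) * d_hid(Z1)
    dIW = dZ1.T @ X
    db1 = dZ1.sum(axis=0)
    return loss, {"IW": dIW, "b1": db1, "LW": dLW, "b2": db2}


def rmse(pred: Sequence[float], exp: Sequence[float]) -> float:
    """Root-mean-square error between paired predictions and measurements."""
    p = np.asarray(pred, dtype=float).ravel()
    e = np.asarray(exp, dtype=float).ravel()
    if p.size != e.size:
        raise ValueError(f"length mismatch: {p.size} vs {e.size}")
    if p.size == 0:
        raise ValueError("rmse of empty vectors is undefined")
    return float(np.sqrt(np.mean((p - e) ** 2)))


def evaluate_parity(pred: Sequence[float], exp: Sequence[float]) -> tuple[float, float]:
    """Least-squares parity fit of predictions against measurements.

    Fits ``pred = slope * exp + intercept`` by OLS and returns the slope and
    the coefficient of determination of that fit.  Slope and R-squared both
    near 1 indicate an accurate model.
    """
    p = np.asarray(pred, dtype=float).ravel()
    e = np.asarray(exp, dtype=float).ravel()
    if p.size != e.size:
        raise ValueError("pred and exp must have equal length")
    if p.size < 2:
        raise ValueError("parity fit needs at least two points")
    if np.ptp(e) == 0:
        raise ValueError("experimental values are constant; parity fit undefined")
    slope, intercept = np.polyfit(e, p, 1)
    fitted = slope * e + intercept
    ss_res = float(np.sum((p - fitted) ** 2))
    ss_tot = float(np.sum((p - p.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(slope), float(r2)


# ---------------------------------------------------------------------------
# training


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters of the Adam fit (defaults follow the study setup)."""

    learning_rate: float = 0.001
    batch_size: int = 2
    iterations: int = 800  # epochs: full passes over the training set
    seed: int = 0
    split_ratios: tuple[float, float, float] = (0.75, 0.15, 0.10)
    normalize_targets: bool = True
    checkpoint_every: int = 100
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8

    def checkpoints(self) -> list[int]:
        pts = sorted(
            set(range(self.checkpoint_every, self.iterations + 1, self.checkpoint_every))
            | ({self.iterations} if self.iterations > 0 else set())
        )
        return pts


@dataclass
class TrainingHistory:
    """Per-checkpoint RMSE of each output on the original g/L scale."""

    iterations: list[int] = field(default_factory=list)
    rmse_train: list[tuple[float, float]] = field(default_factory=list)  # (C_Glc, C_Phe)
    rmse_val: list[tuple[float, float]] = field(default_factory=list)

    def append(self, it: int, train: tuple[float, float], val: tuple[float, float]) -> None:
        if self.iterations and it <= self.iterations[-1]:
            raise ValueError("checkpoints must be strictly increasing")
        self.iterations.append(it)
        self.rmse_train.append(train)
        self.rmse_val.append(val)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": self.iterations,
                "rmse_train_glc": [r[0] for r in self.rmse_train],
                "rmse_train_phe": [r[1] for r in self.rmse_train],
                "rmse_val_glc": [r[0] for r in self.rmse_val],
                "rmse_val_phe": [r[1] for r in self.rmse_val],
            }
        )


def _dataset_arrays(data: Dataset) -> tuple[np.ndarray, np.ndarray]:
    X = data.condition_matrix()
    Y = data.output_matrix()
    if np.isnan(Y).any():
        raise ValueError("training/validation records must have both outputs measured")
    return X, Y


def _denorm_rmse(
    params: NetworkParams,
    Xn: np.ndarray,
    Y_orig: np.ndarray,
    target_spec: NormalizationSpec | None,
) -> tuple[float, float]:
    Yhat = forward(params, Xn)
    if target_spec is not None:
        Yhat = denormalize_matrix(Yhat, OUTPUT_VARS, target_spec)
    return (
        rmse(Yhat[:, 0], Y_orig[:, 0]),
        rmse(Yhat[:, 1], Y_orig[:, 1]),
    )


def train_adam(
    params: NetworkParams,
    train: Dataset,
    validation: Dataset,
    cfg: TrainingConfig,
    input_spec: NormalizationSpec | None = None,
    target_spec: NormalizationSpec | None = None,
    checkpoints: Sequence[int] | None = None,
) -> tuple[NetworkParams, TrainingHistory]:
    """Fit the network by minibatch Adam; fully reproducible for a fixed seed.

    One iteration is one epoch: a full pass over the seeded-shuffled training
    set in batches of ``cfg.batch_size`` (final short batch kept).  If the
    normalization specs are not supplied they are fitted on the training
    split; pass them explicitly to share a normalizer across runs.  History
    RMSEs are always on the original measurement scale.
    """
    if len(train) == 0:
        raise ValueError("training set is empty")
    if cfg.batch_size < 1 or cfg.batch_size > len(train):
        raise ValueError("batch_size must be in [1, len(train)]")
    X_raw, Y_raw = _dataset_arrays(train)

    if input_spec is None:
        input_spec = fit_normalizer(X_raw, CONDITION_VARS)
    if target_spec is None and cfg.normalize_targets:
        target_spec = fit_normalizer(Y_raw, OUTPUT_VARS)

    Xn = normalize_matrix(X_raw, CONDITION_VARS, input_spec)
    Yn = normalize_matrix(Y_raw, OUTPUT_VARS, target_spec) if target_spec else Y_raw

    have_val = len(validation) > 0
    if have_val:
        Xv_raw, Yv_raw = _dataset_arrays(validation)
        Xvn = normalize_matrix(Xv_raw, CONDITION_VARS, input_spec)

    params = params.copy()
    moments = {
        key: (np.zeros_like(getattr(params, key)), np.zeros_like(getattr(params, key)))
        for key in ("IW", "b1", "LW", "b2")
    }
    rng = np.random.default_rng(cfg.seed)
    step = 0
    marks = sorted(set(checkpoints)) if checkpoints is not None else cfg.checkpoints()
    if marks and (marks[0] < 1 or marks[-1] > cfg.iterations):
        raise ValueError("checkpoints must lie in [1, iterations]")
    history = TrainingHistory()

    n = len(train)
    for epoch in range(1, cfg.iterations + 1):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            _, grads = loss_and_grads(params, Xn[batch], Yn[batch])
            step += 1
            for key, g in grads.items():
                m, v = moments[key]
                m *= cfg.beta1
                m += (1 - cfg.beta1) * g
                v *= cfg.beta2
                v += (1 - cfg.beta2) * g**2
                m_hat = m / (1 - cfg.beta1**step)
                v_hat = v / (1 - cfg.beta2**step)
                getattr(params, key)[...] -= cfg.learning_rate * m_hat / (
                    np.sqrt(v_hat) + cfg.eps
                )
        if epoch in marks:
            tr = _denorm_rmse(params, Xn, Y_raw, target_spec)
            va = _denorm_rmse(params, Xvn, Yv_raw, target_spec) if have_val else tr
            history.append(epoch, tr, va)

    return params, history


def predict_conditions(
    params: NetworkParams,
    X: np.ndarray,
    input_spec: NormalizationSpec,
    target_spec: NormalizationSpec | None = None,
) -> np.ndarray:
    """Predict outputs on the original scale for raw condition rows (N x 6)."""
    Xn = normalize_matrix(np.atleast_2d(np.asarray(X, dtype=float)), CONDITION_VARS, input_spec)
    Y = forward(params, Xn)
    if target_spec is not None:
        Y = denormalize_matrix(Y, OUTPUT_VARS, target_spec)
    return Y


# ---------------------------------------------------------------------------
# weight serialization (published-table CSV layout + lossless JSON)

_CSV_COLUMNS = [f"IW_j{i}" for i in range(1, 7)] + ["b1_j", "LW_1j", "LW_2j", "b2_k"]


def save_weights(params: NetworkParams, path: str | Path) -> None:
    """Write weights as CSV: one row per hidden node j, columns IW_j1..IW_j6,
    b1_j, LW_1j, LW_2j, and b2_k populated on rows j=1,2 only."""
    n = params.n_hidden
    rows = []
    for j in range(n):
        row: dict[str, object] = {"j": j + 1}
        for i in range(6):
            row[f"IW_j{i + 1}"] = repr(float(params.IW[j, i]))
        row["b1_j"] = repr(float(params.b1[j]))
        row["LW_1j"] = repr(float(params.LW[0, j]))
        row["LW_2j"] = repr(float(params.LW[1, j]))
        row["b2_k"] = repr(float(params.b2[j])) if j < 2 else ""
        rows.append(row)
    pd.DataFrame(rows, columns=["j"] + _CSV_COLUMNS).to_csv(path, index=False)


def load_weights(path: str | Path, expected_n: int | None = None) -> NetworkParams:
    """Read a weights CSV in the published-table layout.

    Raises on a malformed row, a wrong column count, or a row count that
    contradicts ``expected_n``.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in ["j"] + _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"weights file missing columns: {missing}")
    extra = [c for c in df.columns if c not in ["j"] + _CSV_COLUMNS]
    if extra:
        raise ValueError(f"weights file has unexpected columns: {extra}")
    n = len(df)
    if expected_n is not None and n != expected_n:
        raise ValueError(f"expected {expected_n} hidden-node rows, file has {n}")
    if n < 2:
        raise ValueError("weights file must have at least 2 rows (output biases)")

    def num(cell: str, where: str) -> float:
        try:
            return float(cell)
        except ValueError:
            raise ValueError(f"malformed numeric cell at {where}: {cell!r}") from None

    IW = np.empty((n, 6))
    b1 = np.empty(n)
    LW = np.empty((2, n))
    b2 = np.empty(2)
    for j in range(n):
        row = df.iloc[j]
        for i in range(6):
            IW[j, i] = num(row[f"IW_j{i + 1}"], f"row {j + 1}, IW_j{i + 1}")
        b1[j] = num(row["b1_j"], f"row {j + 1}, b1_j")
        LW[0, j] = num(row["LW_1j"], f"row {j + 1}, LW_1j")
        LW[1, j] = num(row["LW_2j"], f"row {j + 1}, LW_2j")
        cell = str(row["b2_k"]).strip()
        if j < 2:
            b2[j] = num(cell, f"row {j + 1}, b2_k")
        elif cell:
            raise ValueError(f"unexpected b2_k entry on row {j + 1}")
    return NetworkParams(IW=IW, b1=b1, LW=LW, b2=b2)


def load_reference_weights() -> NetworkParams:
    """The published 6-12-2 weight set bundled with the package."""
    from importlib import resources

    with resources.as_file(resources.files("stoverann.data") / "table3_weights.csv") as p:
        return load_weights(p, expected_n=12)


def params_to_json(params: NetworkParams, path: str | Path) -> None:
    payload = {
        "IW": params.IW.tolist(),
        "b1": params.b1.tolist(),
        "LW": params.LW.tolist(),
        "b2": params.b2.tolist(),
        "hidden_activation": params.hidden_activation,
        "output_activation": params.output_activation,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def params_from_json(path: str | Path) -> NetworkParams:
    payload = json.loads(Path(path).read_text())
    return NetworkParams(
        IW=np.array(payload["IW"]),
        b1=np.array(payload["b1"]),
        LW=np.array(payload["LW"]),
        b2=np.array(payload["b2"]),
        hidden_activation=payload["hidden_activation"],
        output_activation=payload["output_activation"],
    )
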