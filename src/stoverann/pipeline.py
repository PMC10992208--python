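"""End-to-end orchestration of the modelling workflow.

``run_pipeline`` chains the stages: load or generate the run table,
validate it against the design space, split 75:15:10, fit the normalizer on
the training split, sweep hidden-layer sizes, sweep iterations at the
selected size, retrain the final network, evaluate test-set parity, and
compute Garson importances from the final weights.  Every artifact embeds
the config hash and all seeds, and two runs with the same config produce
byte-identical numeric artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import ann_model, architecture_search, dataset_io, garson, preprocessing, synthetic_data
from .ann_model import TrainingConfig
from .architecture_search import ArchitectureSearchConfig
from .dataset_io import CANONICAL_SCHEMA, CONDITION_VARS, OUTPUT_VARS, Dataset, DesignSpace
from .synthetic_data import GeneratorConfig


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of one full run.

    Exactly one of ``dataset_path`` / ``generator`` drives the input stage;
    ``weights_path`` with ``skip_training=True`` bypasses everything except
    the importance report (useful for published weight tables).
    """

    dataset_path: str | None = None
    generator: GeneratorConfig | None = None
    n_runs: int = 77
    replicates: int = 3
    seed: int = 0
    split_ratios: tuple[float, float, float] = (0.75, 0.15, 0.10)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    search: ArchitectureSearchConfig = field(default_factory=ArchitectureSearchConfig)
    iteration_sweep_max: int = 1000
    iteration_checkpoint_every: int = 100
    final_iterations: int = 800
    skip_training: bool = False
    weights_path: str | None = None
    out_dir: str = "stoverann_out"

    def __post_init__(self) -> None:
        if self.skip_training:
            if self.weights_path is None:
                raise ValueError("skip_training requires weights_path")
        elif (self.dataset_path is None) == (self.generator is None):
            raise ValueError("exactly one of dataset_path / generator must be set")

    def config_hash(self) -> str:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {str(k): enc(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [enc(v) for v in obj]
            return obj

        payload = enc(self)
        payload.pop("out_dir", None)  # output location is not part of the run identity
        blob = json.dumps(payload, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


class _Log:
    def __init__(self, path: Path):
        self.path = path
        self.lines: list[str] = []

    def __call__(self, msg: str) -> None:
        self.lines.append(f"[{time.strftime('%Y-%m-%d %H:%M:%S')}] {msg}")
        self.path.write_text("\n".join(self.lines) + "\n")


def _importance_only(cfg: PipelineConfig, out: Path, log: _Log, summary: dict) -> dict:
    params = ann_model.load_weights(cfg.weights_path)
    report = garson.importance_report(params)
    report.to_csv(out / "importance.csv")
    (out / "importance.txt").write_text(report.summary_text() + "\n")
    log(f"importance-only run on {cfg.weights_path} (n={params.n_hidden})")
    summary["mode"] = "importance_only"
    summary["importance_percent"] = {
        tab.output: dict(zip(CONDITION_VARS, tab.percents)) for tab in report.tables()
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the configured workflow; returns the JSON-able run summary."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _Log(out / "run.log")
    summary: dict = {"config_hash": cfg.config_hash(), "seed": cfg.seed}
    log(f"config hash {cfg.config_hash()}")

    if cfg.skip_training:
        return _importance_only(cfg, out, log, summary)

    stage = "load"
    try:
        if cfg.dataset_path is not None:
            data = dataset_io.read_dataset(cfg.dataset_path)
        else:
            data = synthetic_data.generate_dataset(
                cfg.generator, n_runs=cfg.n_runs, seed=cfg.seed, replicates=cfg.replicates
            )
            dataset_io.write_dataset(data, out / "dataset.csv")
        log(f"{stage}: {len(data)} runs ({data.provenance})")

        stage = "validate"
        space = cfg.generator.space if cfg.generator else DesignSpace()
        report = dataset_io.validate_ranges(data, space)
        if not report.ok:
            log(f"{stage}: {len(report.violations)} out-of-range values "
                f"({report.counts_by_variable()})")
        summary["n_range_violations"] = len(report.violations)

        stage = "split"
        train, val, test = dataset_io.split_dataset(data, cfg.split_ratios, cfg.seed)
        log(f"{stage}: {len(train)}/{len(val)}/{len(test)} train/val/test (seed {cfg.seed})")
        summary["split_sizes"] = [len(train), len(val), len(test)]

        stage = "normalize"
        input_spec = preprocessing.fit_normalizer(train.condition_matrix(), CONDITION_VARS)
        target_spec = (
            preprocessing.fit_normalizer(train.output_matrix(), OUTPUT_VARS)
            if cfg.training.normalize_targets
            else None
        )
        input_spec.to_yaml(out / "normalization_inputs.yaml")
        if target_spec:
            target_spec.to_yaml(out / "normalization_targets.yaml")

        stage = "neuron_sweep"
        search_cfg = replace(cfg.search, seed=cfg.seed, training=cfg.training)
        sweep = architecture_search.sweep_neurons(
            train, val, search_cfg, input_spec=input_spec, target_spec=target_spec
        )
        sweep.to_csv(out / "sweep.csv")
        n_best = architecture_search.select_architecture(sweep)
        log(f"{stage}: {len(sweep.rows)} candidates, selected n={n_best}")
        summary["selected_n"] = n_best

        stage = "iteration_sweep"
        marks = list(
            range(
                cfg.iteration_checkpoint_every,
                cfg.iteration_sweep_max + 1,
                cfg.iteration_checkpoint_every,
            )
        )
        hist = architecture_search.sweep_iterations(
            train, val, n_best, cfg.iteration_sweep_max, marks,
            seed=architecture_search.candidate_seed(cfg.seed, n_best),
            training=cfg.training, input_spec=input_spec, target_spec=target_spec,
        )
        hist.to_frame().to_csv(out / "history.csv", index=False, float_format="%.10g")
        log(f"{stage}: {len(marks)} checkpoints up to {cfg.iteration_sweep_max}")

        stage = "final_train"
        final_seed = architecture_search.candidate_seed(cfg.seed, 10_000 + n_best)
        tcfg = replace(cfg.training, iterations=cfg.final_iterations, seed=final_seed)
        params = ann_model.init_network(n_best, final_seed)
        params, final_hist = ann_model.train_adam(
            params, train, val, tcfg,
            input_spec=input_spec, target_spec=target_spec,
            checkpoints=[cfg.final_iterations],
        )
        ann_model.save_weights(params, out / "weights.csv")
        ann_model.params_to_json(params, out / "weights.json")
        tr_glc, tr_phe = final_hist.rmse_train[-1]
        log(f"{stage}: n={n_best}, {cfg.final_iterations} iterations, "
            f"train RMSE {tr_glc:.3f} / {tr_phe:.3f} g/L")
        summary["final_seed"] = final_seed
        summary["rmse_train"] = {"C_Glc": tr_glc, "C_Phe": tr_phe}

        stage = "parity"
        parity: dict[str, dict[str, float]] = {}
        Yhat = ann_model.predict_conditions(params, test.condition_matrix(), input_spec, target_spec)
        Yexp = test.output_matrix()
        for j, name in enumerate(OUTPUT_VARS):
            slope, r2 = ann_model.evaluate_parity(Yhat[:, j], Yexp[:, j])
            parity[name] = {
                "slope": slope,
                "r_squared": r2,
                "rmse": ann_model.rmse(Yhat[:, j], Yexp[:, j]),
            }
        (out / "parity.json").write_text(json.dumps(parity, indent=1, sort_keys=True))
        log(f"{stage}: " + ", ".join(
            f"{k} slope {v['slope']:.3f} R2 {v['r_squared']:.3f}" for k, v in parity.items()
        ))
        summary["parity"] = parity

        stage = "importance"
        report = garson.importance_report(params)
        report.to_csv(out / "importance.csv")
        (out / "importance.txt").write_text(report.summary_text() + "\n")
        summary["importance_percent"] = {
            tab.output: dict(zip(CONDITION_VARS, tab.percents)) for tab in report.tables()
        }
        log(f"{stage}: " + "; ".join(
            f"{tab.output} top input {tab.ranking[0]}" for tab in report.tables()
        ))
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage-tagged re-raise
        (out / "INCOMPLETE").write_text(f"failed at stage {stage}: {exc}\n")
        raise PipelineError(stage, exc) from exc

    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    log("done")
    return summary


def predict(bundle_dir: str | Path, conditions_csv: str | Path, out_csv: str | Path) -> pd.DataFrame:
    """Predict outputs for raw condition rows using a trained-model bundle.

    The bundle directory must contain ``weights.json`` and
    ``normalization_inputs.yaml`` (plus ``normalization_targets.yaml`` when
    targets were normalized).  Rows outside the standard design space are
    still predicted but flagged ``extrapolated``.
    """
    bundle = Path(bundle_dir)
    spec_path = bundle / "normalization_inputs.yaml"
    if not spec_path.exists():
        raise FileNotFoundError(f"bundle lacks normalization spec: {spec_path}")
    params = ann_model.params_from_json(bundle / "weights.json")
    input_spec = preprocessing.NormalizationSpec.from_yaml(spec_path)
    tpath = bundle / "normalization_targets.yaml"
    target_spec = preprocessing.NormalizationSpec.from_yaml(tpath) if tpath.exists() else None

    # conditions CSV may omit the output columns entirely
    raw = pd.read_csv(conditions_csv, dtype=str, keep_default_na=False)
    for fld in OUTPUT_VARS:
        col = CANONICAL_SCHEMA[fld]
        if col not in raw.columns:
            raw[col] = ""
    import io

    buf = io.StringIO()
    raw.to_csv(buf, index=False)
    buf.seek(0)
    data = dataset_io.read_dataset(buf)

    result = pd.DataFrame({"run_id": [r.run_id for r in data]})
    if len(data) > 0:
        Yhat = ann_model.predict_conditions(
            params, data.condition_matrix(), input_spec, target_spec
        )
        flagged = set(dataset_io.validate_ranges(data).violating_run_ids())
        result["C_Glc_pred_g_L"] = Yhat[:, 0]
        result["C_Phe_pred_g_L"] = Yhat[:, 1]
        result["extrapolated"] = [r.run_id in flagged for r in data]
    else:
        result["C_Glc_pred_g_L"] = pd.Series(dtype=float)
        result["C_Phe_pred_g_L"] = pd.Series(dtype=float)
        result["extrapolated"] = pd.Series(dtype=bool)
    result.to_csv(out_csv, index=False, float_format="%.10g")
    return result
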