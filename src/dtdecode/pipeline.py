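"""End-to-end pipeline: simulate -> split -> fit -> predict -> DT -> evaluate.

A :class:`RunConfig` fully determines a run; a single global seed fans out to
per-stage seeds by fixed offsets, so reruns reproduce all numeric outputs
bit-for-bit for the deterministic decoders. Each run directory contains the
design matrices (CSV), predictions with and without distributional
transformation (CSV), the metrics report (JSON + CSV), the method-comparison
report (JSON), a log file and a config snapshot.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import Dataset
from .dt import distributional_transform
from .linear import OLSRegressor
from .nnet import NeuralNetRegressor
from .preprocessing import ColumnZScorer
from .simulate import PopulationConfig, distort_predictions, generate_population, \
    split_train_validation
from .stats import ComparisonResult, empirical_kl, ks_two_sample, \
    prediction_metrics, wilcoxon_ae_comparison
from .svm import SVRDecoder

__all__ = ["RunConfig", "run_pipeline", "make_decoder"]

# per-stage seed offsets fanned out from the global seed
_STAGE_OFFSETS = {"population": 1, "split": 2, "decoder": 3, "distortion": 4}

#: Table-style column headers for the metrics report.
MEASURE_NAMES = {
    "r_squared": "R^2",
    "adj_r_squared": "R^2_adj",
    "pearson_r": "r",
    "spearman_r": "r_SC",
    "mae": "MAE",
    "rmse": "RMSE",
    "objective2": "Obj. 2",
}


@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    out_dir: str
    seed: int = 0
    decoder: str = "glm"  # glm | svr | dnn
    dt: bool = True
    n_subjects: int = 3300
    ratio: float = 4.0
    match_age: bool = True
    population: dict = field(default_factory=dict)  # PopulationConfig overrides
    decoder_params: dict = field(default_factory=dict)
    distortion: dict | None = None  # {"mode": ..., "params": {...}}
    scale_with_train: bool = False
    alpha: float = 0.10
    kl_bin_width: float = 1.0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(**payload)


def make_decoder(name: str, seed: int = 0, **params):
    """Instantiate a decoder by pipeline name (glm, svr or dnn)."""
    if name == "glm":
        return OLSRegressor(**params)
    if name == "svr":
        return SVRDecoder(**params)
    if name == "dnn":
        params.setdefault("seed", seed)
        return NeuralNetRegressor(**params)
    raise ValueError(f"unknown decoder {name!r} (expected glm, svr or dnn)")


def _decoder_inputs(train: Dataset, val: Dataset, name: str,
                    scale_with_train: bool):
    """The DNN consumes z-scored non-indicator columns; by convention each
    matrix is scaled by its own statistics unless scale_with_train is set."""
    if name != "dnn":
        return train.design, val.design
    scorer = ColumnZScorer(indicator_mask=train.indicator_mask)
    X1 = scorer.fit_transform(train.design)
    if scale_with_train:
        X2 = scorer.transform(val.design)
    else:
        X2 = ColumnZScorer(
            indicator_mask=val.indicator_mask).fit_transform(val.design)
    return X1, X2


def _comparison(y_true, y1_ref, pred_raw, pred_dt, kl_bin_width) -> dict:
    z, p = wilcoxon_ae_comparison(y_true, pred_dt, pred_raw)
    out = {
        "wilcoxon_dt_vs_raw": {"z": z, "p": p},
        "kl_actual_vs_raw": empirical_kl(y_true, pred_raw, kl_bin_width),
        "kl_actual_vs_dt": empirical_kl(y_true, pred_dt, kl_bin_width),
        "ks_raw_vs_validation": dict(zip(("D", "p"),
                                         ks_two_sample(pred_raw, y_true))),
        "ks_dt_vs_validation": dict(zip(("D", "p"),
                                        ks_two_sample(pred_dt, y_true))),
        "ks_dt_vs_training": dict(zip(("D", "p"),
                                      ks_two_sample(pred_dt, y1_ref))),
    }
    return out


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full synthetic workflow; returns the run directory."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log = logging.getLogger("dtdecode.pipeline")
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        stage = "config"
        (out_dir / "config.yaml").write_text(yaml.safe_dump(config.to_dict()))

        stage = "simulate"
        pop_kwargs = dict(config.population)
        pop_kwargs.setdefault("n_subjects", config.n_subjects)
        pop_kwargs.setdefault("seed", config.seed + _STAGE_OFFSETS["population"])
        population = generate_population(PopulationConfig(**pop_kwargs))
        log.info("simulated population: n=%d, p=%d", population.n, population.p)

        stage = "split"
        train, val = split_train_validation(
            population, ratio=config.ratio,
            seed=config.seed + _STAGE_OFFSETS["split"],
            match_age=config.match_age)
        train.to_csv(out_dir / "train_design.csv")
        val.to_csv(out_dir / "validation_design.csv")
        log.info("split: %d train / %d validation", train.n, val.n)

        stage = "fit/predict"
        if config.distortion is not None:
            pred_raw = distort_predictions(
                val.ages, config.distortion["mode"],
                config.distortion.get("params", {}),
                seed=config.seed + _STAGE_OFFSETS["distortion"])
            log.info("distortion scenario %s in place of a decoder",
                     config.distortion["mode"])
        else:
            decoder = make_decoder(
                config.decoder, seed=config.seed + _STAGE_OFFSETS["decoder"],
                **config.decoder_params)
            X1, X2 = _decoder_inputs(train, val, config.decoder,
                                     config.scale_with_train)
            decoder.fit(X1, train.ages)
            pred_raw = decoder.predict(X2)
            log.info("decoder %s fitted", config.decoder)

        stage = "transform"
        pred_dt = distributional_transform(pred_raw, train.ages)

        stage = "evaluate"
        predictions = pd.DataFrame({
            "subject_id": val.subject_ids, "y_true": val.ages,
            "y_pred": pred_raw, "y_pred_dt": pred_dt})
        predictions.to_csv(out_dir / "predictions.csv", index=False)
        metrics = {
            "without_dt": prediction_metrics(val.ages, pred_raw,
                                             p_model=val.p).to_dict(),
            "with_dt": prediction_metrics(val.ages, pred_dt,
                                          p_model=val.p).to_dict(),
        }
        (out_dir / "metrics.json").write_text(json.dumps(metrics, indent=2))
        table = pd.DataFrame(metrics).T.rename(columns=MEASURE_NAMES)
        table.to_csv(out_dir / "metrics.csv")
        comparison = _comparison(val.ages, train.ages, pred_raw, pred_dt,
                                 config.kl_bin_width)
        (out_dir / "comparison.json").write_text(json.dumps(comparison, indent=2))
        log.info("MAE without DT %.3f / with DT %.3f",
                 metrics["without_dt"]["mae"], metrics["with_dt"]["mae"])
        return out_dir
    except Exception:
        log.exception("stage %r failed", stage)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
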