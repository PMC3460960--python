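"""Internal cross-validation harnesses and performance accounting.

Leave-one-out (LOOCV) and Monte-Carlo (MCCV, repeated random split)
cross-validation.  Every per-iteration classifier is fitted from the
training samples only — filtering, tuning and calibration never see the
held-out samples — so permuting test-set values leaves the fitted model
bit-identical.  Aggregate LOOCV metrics are computed on the pooled
confusion matrix across the n single-sample tests; MCCV reports
per-iteration metric means, ranges and SDs plus a feature-frequency table
over the generated classifiers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .classify import (
    SvmModel,
    SvmSpec,
    TspModel,
    svm_fit,
    svm_predict,
    tsp_fit,
    tsp_predict,
)
from .errors import ConfigError, ContentError

logger = logging.getLogger(__name__)

METRICS = ("accuracy", "sensitivity", "specificity", "ppv", "npv")


def confusion_counts(
    predictions: Sequence[str], truth: Sequence[str]
) -> Dict[str, int]:
    pred = np.asarray(predictions)
    true = np.asarray(truth)
    if pred.size == 0:
        raise ContentError("cannot score an empty prediction set")
    return {
        "tp": int(np.sum((pred == "case") & (true == "case"))),
        "fn": int(np.sum((pred == "control") & (true == "case"))),
        "tn": int(np.sum((pred == "control") & (true == "control"))),
        "fp": int(np.sum((pred == "case") & (true == "control"))),
    }


def metrics_from_confusion(c: Dict[str, int]) -> Dict[str, float]:
    """Percent-scale metrics; a metric with a zero denominator is NaN."""

    def _ratio(num: int, den: int) -> float:
        return 100.0 * num / den if den > 0 else float("nan")

    total = c["tp"] + c["fn"] + c["tn"] + c["fp"]
    return {
        "accuracy": _ratio(c["tp"] + c["tn"], total),
        "sensitivity": _ratio(c["tp"], c["tp"] + c["fn"]),
        "specificity": _ratio(c["tn"], c["tn"] + c["fp"]),
        "ppv": _ratio(c["tp"], c["tp"] + c["fp"]),
        "npv": _ratio(c["tn"], c["tn"] + c["fn"]),
    }


def performance_metrics(
    predictions: Sequence[str], truth: Sequence[str]
) -> Dict[str, float]:
    """Accuracy, sensitivity, specificity, PPV, NPV in percent.

    Sensitivity is computed on the case class; values are stored at full
    precision (round for display).
    """
    return metrics_from_confusion(confusion_counts(predictions, truth))


@dataclass
class CvIteration:
    train_ids: List[str]
    test_ids: List[str]
    predictions: List[str]
    truth: List[str]
    probabilities: Optional[List[float]] = None


@dataclass
class CvReport:
    method: str
    iterations: List[CvIteration]
    pooled_confusion: Dict[str, int]
    pooled_metrics: Dict[str, float]
    metric_summary: pd.DataFrame  # mean / min / max / sd per metric across iterations
    feature_frequency: pd.Series  # probe -> number of classifiers containing it
    models: List[object] = field(default_factory=list, repr=False)

    def iteration_metrics(self) -> pd.DataFrame:
        rows = [
            metrics_from_confusion(confusion_counts(it.predictions, it.truth))
            for it in self.iterations
        ]
        return pd.DataFrame(rows)


def _fit_model(
    method: str,
    train_matrix: pd.DataFrame,
    train_classes: np.ndarray,
    spec: Optional[SvmSpec],
    seed: int,
):
    if method == "tsp":
        return tsp_fit(train_matrix, train_classes)
    if method == "svm":
        return svm_fit(train_matrix, train_classes, spec, seed=seed)
    raise ConfigError(f"unknown classification method {method!r}")


def _predict_model(method: str, model, test_matrix: pd.DataFrame):
    if method == "tsp":
        return tsp_predict(model, test_matrix), None
    labels, probs = svm_predict(model, test_matrix)
    return labels, probs


def _model_features(method: str, model) -> List[str]:
    if method == "tsp":
        return [model.probe_i, model.probe_j]
    return list(model.features)


def _finalize(
    method: str,
    iterations: List[CvIteration],
    models: List[object],
) -> CvReport:
    pooled = confusion_counts(
        np.concatenate([np.asarray(it.predictions) for it in iterations]),
        np.concatenate([np.asarray(it.truth) for it in iterations]),
    )
    rows = [
        metrics_from_confusion(confusion_counts(it.predictions, it.truth))
        for it in iterations
    ]
    frame = pd.DataFrame(rows)
    summary = pd.DataFrame(
        {
            "mean": frame.mean(),
            "min": frame.min(),
            "max": frame.max(),
            "sd": frame.std(ddof=1),
        }
    )
    freq: Dict[str, int] = {}
    for model in models:
        for feature in _model_features(method, model):
            freq[feature] = freq.get(feature, 0) + 1
    feature_frequency = pd.Series(freq, dtype=int).sort_values(ascending=False)
    return CvReport(
        method=method,
        iterations=iterations,
        pooled_confusion=pooled,
        pooled_metrics=metrics_from_confusion(pooled),
        metric_summary=summary,
        feature_frequency=feature_frequency,
        models=models,
    )


def loocv(
    matrix: pd.DataFrame,
    classes: Sequence[str],
    method: str = "tsp",
    spec: Optional[SvmSpec] = None,
    seed: int = 0,
) -> CvReport:
    """Leave-one-out cross-validation: n iterations, train on n-1, test on 1."""
    classes = np.asarray(classes)
    n = matrix.shape[1]
    if n < 3:
        raise ContentError("LOOCV needs at least 3 samples")
    if len(np.unique(classes)) < 2:
        raise ContentError("both classes must be present")
    iterations, models = [], []
    sample_ids = list(matrix.columns)
    for i in range(n):
        train_idx = [k for k in range(n) if k != i]
        train_matrix = matrix.iloc[:, train_idx]
        model = _fit_model(method, train_matrix, classes[train_idx], spec, seed)
        pred, probs = _predict_model(method, model, matrix.iloc[:, [i]])
        iterations.append(
            CvIteration(
                train_ids=[sample_ids[k] for k in train_idx],
                test_ids=[sample_ids[i]],
                predictions=list(pred),
                truth=[classes[i]],
                probabilities=None if probs is None else [float(probs[0])],
            )
        )
        models.append(model)
    return _finalize(method, iterations, models)


def mccv(
    matrix: pd.DataFrame,
    classes: Sequence[str],
    method: str = "tsp",
    spec: Optional[SvmSpec] = None,
    n_iter: int = 1000,
    n_train: int = 36,
    n_test: int = 9,
    seed: int = 0,
    stratified: bool = False,
) -> CvReport:
    """Monte-Carlo cross-validation with repeated random splits.

    Splits are plain (unstratified) random assignments by default; a
    training draw that misses a class is resampled and logged.
    """
    classes = np.asarray(classes)
    n = matrix.shape[1]
    if n_train + n_test > n:
        raise ContentError("n_train + n_test must not exceed the sample count")
    if n_train < 2 or n_test < 1:
        raise ContentError("invalid split sizes")
    rng = np.random.default_rng(seed)
    sample_ids = list(matrix.columns)
    iterations, models = [], []
    for it in range(n_iter):
        for _ in range(1000):
            if stratified:
                case_idx = np.flatnonzero(classes == "case")
                ctrl_idx = np.flatnonzero(classes == "control")
                n_case_train = round(n_train * len(case_idx) / n)
                train_idx = np.concatenate(
                    [
                        rng.choice(case_idx, n_case_train, replace=False),
                        rng.choice(ctrl_idx, n_train - n_case_train, replace=False),
                    ]
                )
                rest = np.setdiff1d(np.arange(n), train_idx)
                test_idx = rng.choice(rest, n_test, replace=False)
            else:
                perm = rng.permutation(n)
                train_idx = perm[:n_train]
                test_idx = perm[n_train : n_train + n_test]
            if len(np.unique(classes[train_idx])) == 2:
                break
            logger.info("resampling MCCV split %d: single-class training draw", it)
        else:
            raise ContentError("could not draw a two-class training set")
        train_idx = np.sort(train_idx)
        test_idx = np.sort(test_idx)
        train_matrix = matrix.iloc[:, train_idx]
        model = _fit_model(
            method, train_matrix, classes[train_idx], spec, seed=seed + it
        )
        pred, probs = _predict_model(method, model, matrix.iloc[:, test_idx])
        iterations.append(
            CvIteration(
                train_ids=[sample_ids[k] for k in train_idx],
                test_ids=[sample_ids[k] for k in test_idx],
                predictions=list(pred),
                truth=list(classes[test_idx]),
                probabilities=None if probs is None else [float(v) for v in probs],
            )
        )
        models.append(model)
    return _finalize(method, iterations, models)


def training_size_sweep(
    matrix: pd.DataFrame,
    classes: Sequence[str],
    method: str = "tsp",
    spec: Optional[SvmSpec] = None,
    sizes: Sequence[int] = (12, 18, 24, 30, 36, 42),
    n_iter: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """MCCV learning curve: one row per training-set size.

    At each size the test set is the complement of the training draw.
    Reports mean and 95% CI per metric plus the number of distinct features
    used across the generated classifiers.
    """
    n = matrix.shape[1]
    rows = []
    for size in sizes:
        if not 2 <= size <= n - 1:
            raise ConfigError(f"invalid training size {size} for n={n}")
        report = mccv(
            matrix,
            classes,
            method=method,
            spec=spec,
            n_iter=n_iter,
            n_train=size,
            n_test=n - size,
            seed=seed + size,
        )
        frame = report.iteration_metrics()
        row = {"train_size": size, "n_iter": n_iter}
        for metric in METRICS:
            vals = frame[metric].dropna()
            mean = vals.mean()
            half = (
                1.96 * vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else np.nan
            )
            row[f"{metric}_mean"] = mean
            row[f"{metric}_ci_low"] = mean - half
            row[f"{metric}_ci_high"] = mean + half
        row["n_distinct_features"] = int(len(report.feature_frequency))
        rows.append(row)
    return pd.DataFrame(rows)
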