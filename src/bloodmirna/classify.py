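"""Binary classifiers: top-scoring pairs (TSP) and linear soft-margin SVM.

TSP selects the probe pair whose within-sample ordering differs most in
frequency between classes (score Delta, ties broken by the average
rank-difference score gamma, then lexicographically by probe id); prediction
reads off the observed ordering.  Being rank-based, TSP is invariant to any
within-sample monotone transformation of the expression scale.

The SVM route filters probes by moderated-t evidence computed on the
training data only (top 15 by default), tunes the soft-margin cost over a
fixed 9-value grid by stratified inner 3-fold cross-validation, fits the
final linear SVM, and calibrates probabilities by Platt scaling of
out-of-fold decision values.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .diffexp import fit_moderated_prior, moderated_t
from .errors import ConfigError, ContentError

DEFAULT_COST_GRID = (0.1, 0.2, 0.5, 1.0, 2.0, 5.0, 10.0, 20.0, 50.0)


# ---------------------------------------------------------------------------
# Top-scoring pairs


@dataclass
class TspModel:
    """Fitted top-scoring pair.

    ``orientation`` is True when observing probe_i < probe_j votes "case"
    (i.e. the ordering is more frequent among training cases).  Ties in the
    within-sample comparison are resolved to the training majority class.
    """

    probe_i: str
    probe_j: str
    delta: float
    gamma: float
    orientation_i_less_j_is_case: bool
    freq_case: float
    freq_control: float
    majority_class: str

    def to_json(self) -> str:
        return json.dumps(
            {
                "model": "tsp",
                "probe_i": self.probe_i,
                "probe_j": self.probe_j,
                "delta": self.delta,
                "gamma": self.gamma,
                "orientation_i_less_j_is_case": self.orientation_i_less_j_is_case,
                "freq_case": self.freq_case,
                "freq_control": self.freq_control,
                "majority_class": self.majority_class,
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "TspModel":
        d = json.loads(text)
        if d.pop("model", None) != "tsp":
            raise ContentError("not a serialized TSP model")
        return cls(**d)


def tsp_fit(train_matrix: pd.DataFrame, train_classes: Sequence[str]) -> TspModel:
    """Select the top-scoring pair on the training data.

    Delta_ij = |P(X_i < X_j | case) - P(X_i < X_j | control)| with strict
    within-sample comparisons (ties count as "not less-than").  The maximum
    Delta wins; ties are broken by the largest mean within-class
    rank-difference gap gamma, then by lexicographic probe order.
    """
    classes = np.asarray(train_classes)
    case = classes == "case"
    ctrl = classes == "control"
    n_case, n_ctrl = int(case.sum()), int(ctrl.sum())
    if n_case == 0 or n_ctrl == 0:
        raise ContentError("both classes must be present in the training set")
    p = train_matrix.shape[0]
    if p < 2:
        raise ContentError("TSP needs at least two probes")
    x = train_matrix.to_numpy(dtype=float)
    counts_case = np.zeros((p, p), dtype=np.int32)
    counts_ctrl = np.zeros((p, p), dtype=np.int32)
    for s in range(x.shape[1]):
        col = x[:, s]
        less = col[:, None] < col[None, :]
        if case[s]:
            counts_case += less
        else:
            counts_ctrl += less
    p_case = counts_case / n_case
    p_ctrl = counts_ctrl / n_ctrl
    delta = np.abs(p_case - p_ctrl)
    iu, ju = np.triu_indices(p, k=1)
    dvals = delta[iu, ju]
    best = dvals.max()
    cand = np.flatnonzero(dvals >= best - 1e-12)
    # Tie-break 1: rank-difference score gamma.
    ranks = np.apply_along_axis(rankdata, 0, x)
    d_rank = ranks[:, case].mean(axis=1) - ranks[:, ctrl].mean(axis=1)
    gammas = np.abs(d_rank[iu[cand]] - d_rank[ju[cand]])
    gbest = gammas.max()
    cand = cand[gammas >= gbest - 1e-12]
    # Tie-break 2: lexicographic by (probe_i, probe_j) names.
    names = train_matrix.index
    keys = sorted(
        (str(names[iu[c]]), str(names[ju[c]]), c) for c in cand
    )
    _, _, chosen = keys[0]
    i, j = int(iu[chosen]), int(ju[chosen])
    fc = float(p_case[i, j])
    fk = float(p_ctrl[i, j])
    majority = "case" if n_case >= n_ctrl else "control"
    if n_case == n_ctrl:
        majority = "control"
    return TspModel(
        probe_i=str(names[i]),
        probe_j=str(names[j]),
        delta=float(delta[i, j]),
        gamma=float(abs(d_rank[i] - d_rank[j])),
        orientation_i_less_j_is_case=fc > fk,
        freq_case=fc,
        freq_control=fk,
        majority_class=majority,
    )


def tsp_predict(model: TspModel, test_matrix: pd.DataFrame) -> np.ndarray:
    """Predict class labels from the observed within-sample ordering."""
    for probe in (model.probe_i, model.probe_j):
        if probe not in test_matrix.index:
            raise ContentError(f"probe {probe!r} missing from the test matrix")
    xi = test_matrix.loc[model.probe_i].to_numpy(dtype=float)
    xj = test_matrix.loc[model.probe_j].to_numpy(dtype=float)
    labels = np.empty(xi.size, dtype=object)
    i_less_j = xi < xj
    tie = xi == xj
    if model.orientation_i_less_j_is_case:
        labels[:] = np.where(i_less_j, "case", "control")
    else:
        labels[:] = np.where(i_less_j, "control", "case")
    labels[tie] = model.majority_class
    return labels


# ---------------------------------------------------------------------------
# Linear SVM with nested tuning


@dataclass
class SvmSpec:
    cost_grid: Tuple[float, ...] = DEFAULT_COST_GRID
    max_features: int = 15
    inner_folds: int = 3

    def validate(self) -> None:
        if len(self.cost_grid) == 0 or any(c <= 0 for c in self.cost_grid):
            raise ConfigError("cost grid must contain positive values")
        if self.max_features < 1:
            raise ConfigError("max_features must be >= 1")
        if self.inner_folds < 2:
            raise ConfigError("inner_folds must be >= 2")


@dataclass
class SvmModel:
    features: List[str]
    cost: float
    weights: np.ndarray
    intercept: float
    platt_a: float
    platt_b: float
    inner_errors: Dict[float, float] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "model": "svm",
                "features": list(self.features),
                "cost": self.cost,
                "weights": [repr(float(w)) for w in np.asarray(self.weights)],
                "intercept": repr(float(self.intercept)),
                "platt_a": repr(float(self.platt_a)),
                "platt_b": repr(float(self.platt_b)),
                "inner_errors": {repr(k): repr(v) for k, v in self.inner_errors.items()},
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "SvmModel":
        d = json.loads(text)
        if d.pop("model", None) != "svm":
            raise ContentError("not a serialized SVM model")
        return cls(
            features=list(d["features"]),
            cost=float(d["cost"]),
            weights=np.array([float(w) for w in d["weights"]]),
            intercept=float(d["intercept"]),
            platt_a=float(d["platt_a"]),
            platt_b=float(d["platt_b"]),
            inner_errors={float(k): float(v) for k, v in d["inner_errors"].items()},
        )


def _select_features(
    train_matrix: pd.DataFrame, classes: np.ndarray, max_features: int
) -> List[str]:
    mod = moderated_t(train_matrix, classes, prior=None)
    ranked = mod["moderated_t"].abs().sort_values(ascending=False, kind="stable")
    return list(ranked.index[: min(max_features, len(ranked))])


def svm_fit(
    train_matrix: pd.DataFrame,
    train_classes: Sequence[str],
    spec: Optional[SvmSpec] = None,
    seed: int = 0,
) -> SvmModel:
    """Filter, tune, fit and calibrate a linear soft-margin SVM.

    All steps use the training data only: moderated-t probe filtering, a
    stratified inner cross-validation over the cost grid (ties resolved to
    the smaller cost), a final fit at the chosen cost, and Platt scaling of
    the inner out-of-fold decision values.
    """
    spec = spec or SvmSpec()
    spec.validate()
    classes = np.asarray(train_classes)
    y = (classes == "case").astype(int)
    n_case, n_ctrl = int(y.sum()), int((1 - y).sum())
    need = max(4, spec.inner_folds)
    if n_case < need or n_ctrl < need:
        raise ContentError(
            f"svm_fit needs at least {need} samples per class "
            f"(got {n_case} cases, {n_ctrl} controls)"
        )
    features = _select_features(train_matrix, classes, spec.max_features)
    X = train_matrix.loc[features].to_numpy(dtype=float).T  # samples × features

    rng_seed = int(seed) % (2**31 - 1)
    for attempt in range(10):
        skf = StratifiedKFold(
            n_splits=spec.inner_folds, shuffle=True, random_state=rng_seed + attempt
        )
        folds = list(skf.split(X, y))
        if all(len(np.unique(y[tr])) == 2 for tr, _ in folds):
            break
    else:
        raise ContentError("could not build stratified inner folds with both classes")

    inner_errors: Dict[float, float] = {}
    for cost in spec.cost_grid:
        errs = []
        for tr, te in folds:
            clf = SVC(kernel="linear", C=cost)
            clf.fit(X[tr], y[tr])
            errs.append(float(np.mean(clf.predict(X[te]) != y[te])))
        inner_errors[float(cost)] = float(np.mean(errs))
    best_err = min(inner_errors.values())
    chosen_cost = min(c for c, e in inner_errors.items() if e <= best_err + 1e-12)

    final = SVC(kernel="linear", C=chosen_cost)
    final.fit(X, y)
    weights = final.coef_.ravel().copy()
    intercept = float(final.intercept_[0])

    # Platt calibration on inner out-of-fold decision values at the chosen cost.
    dv = np.empty(len(y))
    for tr, te in folds:
        clf = SVC(kernel="linear", C=chosen_cost)
        clf.fit(X[tr], y[tr])
        dv[te] = clf.decision_function(X[te])
    lr = LogisticRegression(C=1.0, solver="lbfgs")
    lr.fit(dv.reshape(-1, 1), y)
    platt_a = float(lr.coef_[0, 0])
    platt_b = float(lr.intercept_[0])

    return SvmModel(
        features=features,
        cost=float(chosen_cost),
        weights=weights,
        intercept=intercept,
        platt_a=platt_a,
        platt_b=platt_b,
        inner_errors=inner_errors,
    )


def svm_decision_values(model: SvmModel, test_matrix: pd.DataFrame) -> np.ndarray:
    missing = [f for f in model.features if f not in test_matrix.index]
    if missing:
        raise ContentError(f"feature(s) missing from the test matrix: {missing[:5]}")
    X = test_matrix.loc[model.features].to_numpy(dtype=float).T
    return X @ np.asarray(model.weights) + model.intercept


def svm_predict(
    model: SvmModel, test_matrix: pd.DataFrame
) -> Tuple[np.ndarray, np.ndarray]:
    """Labels from the hyperplane side; calibrated case-probabilities."""
    dv = svm_decision_values(model, test_matrix)
    labels = np.where(dv > 0, "case", "control").astype(object)
    probs = expit(model.platt_a * dv + model.platt_b)
    return labels, probs
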