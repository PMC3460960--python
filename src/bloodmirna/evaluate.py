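"""ROC/AUC analysis, confounder profiling, clustering, platform concordance.

AUC is the empirical trapezoid area, identical to the Mann–Whitney
probability estimate with ties counted 1/2.  Correlated-AUC comparison uses
the DeLong structural-component variance.  Covariate profiling reports
per-probe Pearson correlations over pairwise-complete samples with a
permutation null for the flagged fraction.  Hierarchical clustering uses
1 - Pearson r distance with average linkage and optimized leaf ordering.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .errors import ContentError


# ---------------------------------------------------------------------------
# ROC / AUC / DeLong


@dataclass
class RocResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    v_case: np.ndarray  # DeLong structural components, one per case
    v_control: np.ndarray  # one per control


def _structural_components(
    scores: np.ndarray, is_case: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    cases = scores[is_case]
    controls = scores[~is_case]
    # V10[i] = P_hat(control < case_i) with ties counted 1/2; V01 analogous.
    v10 = (
        (controls[None, :] < cases[:, None]).sum(axis=1)
        + 0.5 * (controls[None, :] == cases[:, None]).sum(axis=1)
    ) / controls.size
    v01 = (
        (cases[None, :] > controls[:, None]).sum(axis=1)
        + 0.5 * (cases[None, :] == controls[:, None]).sum(axis=1)
    ) / cases.size
    return v10, v01


def roc_auc(scores: Sequence[float], labels: Sequence[str]) -> RocResult:
    """Empirical ROC over all score thresholds; AUC via the Mann–Whitney form."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if not np.all(np.isfinite(scores)):
        raise ContentError("scores must be finite")
    is_case = labels == "case"
    n_case = int(is_case.sum())
    n_ctrl = int((~is_case).sum())
    if n_case == 0 or n_ctrl == 0:
        raise ContentError("both classes must be present for ROC analysis")
    v10, v01 = _structural_components(scores, is_case)
    auc = float(v10.mean())
    order = np.argsort(-scores, kind="stable")
    sorted_labels = is_case[order]
    sorted_scores = scores[order]
    tp = np.cumsum(sorted_labels)
    fp = np.cumsum(~sorted_labels)
    # Collapse tied scores so ties contribute diagonal segments.
    distinct = np.r_[np.diff(sorted_scores) != 0, True]
    tpr = np.r_[0.0, tp[distinct] / n_case]
    fpr = np.r_[0.0, fp[distinct] / n_ctrl]
    thresholds = np.r_[np.inf, sorted_scores[distinct]]
    return RocResult(
        thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc, v_case=v10, v_control=v01
    )


def delong_compare(
    scores_a: Sequence[float], scores_b: Sequence[float], labels: Sequence[str]
) -> Dict[str, float]:
    """DeLong test for two correlated AUCs measured on the same samples."""
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels)
    if scores_a.shape != scores_b.shape or scores_a.shape[0] != labels.shape[0]:
        raise ContentError("paired scores must cover the identical sample set")
    roc_a = roc_auc(scores_a, labels)
    roc_b = roc_auc(scores_b, labels)
    m = roc_a.v_case.size
    n = roc_a.v_control.size
    v10 = np.vstack([roc_a.v_case, roc_b.v_case])
    v01 = np.vstack([roc_a.v_control, roc_b.v_control])
    s10 = np.cov(v10) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(v01) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    delta = roc_a.auc - roc_b.auc
    var = max(float(cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]), 0.0)
    if var > 0:
        z = delta / math.sqrt(var)
        p = 2.0 * stats.norm.sf(abs(z))
    else:
        z = 0.0
        p = 1.0
    half = 1.959963984540054 * math.sqrt(var)
    return {
        "auc_a": roc_a.auc,
        "auc_b": roc_b.auc,
        "delta": delta,
        "z": z,
        "p": p,
        "ci_low": delta - half,
        "ci_high": delta + half,
    }


# ---------------------------------------------------------------------------
# Covariate correlation profiling


@dataclass
class CorrelationProfile:
    r: pd.Series  # per-probe Pearson r vs the covariate
    n_used: int
    threshold: float
    flagged: List[str]

    @property
    def flagged_fraction(self) -> float:
        return len(self.flagged) / len(self.r) if len(self.r) else 0.0


def correlate_covariate(
    matrix_log2: pd.DataFrame,
    covariate: pd.Series,
    threshold: float = 0.4,
) -> CorrelationProfile:
    """Per-probe Pearson r against a covariate over pairwise-complete samples."""
    cov = covariate.reindex(matrix_log2.columns)
    keep = cov.notna().to_numpy()
    n_used = int(keep.sum())
    if n_used < 3:
        raise ContentError("need at least 3 pairwise-complete observations")
    c = cov.to_numpy(dtype=float)[keep]
    if np.ptp(c) == 0.0:
        raise ContentError("covariate is constant; correlation undefined")
    x = matrix_log2.to_numpy(dtype=float)[:, keep]
    xc = x - x.mean(axis=1, keepdims=True)
    cc = c - c.mean()
    denom = np.sqrt((xc**2).sum(axis=1) * (cc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, xc @ cc / denom, 0.0)
    series = pd.Series(r, index=matrix_log2.index, name="pearson_r")
    flagged = list(series.index[np.abs(r) > threshold])
    return CorrelationProfile(r=series, n_used=n_used, threshold=threshold, flagged=flagged)


def analytic_null_flagged_fraction(threshold: float, n: int) -> float:
    """P(|r| > threshold) for a null Pearson correlation at sample size n.

    Uses the exact t-transform of r under bivariate-normal independence:
    t = r sqrt((n-2)/(1-r^2)) follows Student t with n-2 df.
    """
    if n < 4:
        raise ContentError("analytic null needs n >= 4")
    t = threshold * math.sqrt((n - 2) / (1.0 - threshold**2))
    return float(2.0 * stats.t.sf(t, n - 2))


def resample_covariate_null(
    matrix_log2: pd.DataFrame,
    covariate: pd.Series,
    threshold: float = 0.4,
    n_reps: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Null distribution of the flagged fraction from covariate permutation."""
    cov = covariate.reindex(matrix_log2.columns)
    keep = cov.notna().to_numpy()
    values = cov.to_numpy(dtype=float)[keep]
    sub = matrix_log2.iloc[:, np.flatnonzero(keep)]
    rng = np.random.default_rng(seed)
    fractions = np.empty(n_reps)
    for rep in range(n_reps):
        perm = pd.Series(rng.permutation(values), index=sub.columns)
        profile = correlate_covariate(sub, perm, threshold)
        fractions[rep] = profile.flagged_fraction
    return fractions


# ---------------------------------------------------------------------------
# Hierarchical clustering


@dataclass
class Dendrogram:
    labels: List[str]
    linkage: np.ndarray
    leaf_order: List[int]
    distance: np.ndarray  # full square distance matrix

    def leaf_labels(self) -> List[str]:
        return [self.labels[i] for i in self.leaf_order]

    def adjacent_distance_sum(self, order: Optional[Sequence[int]] = None) -> float:
        order = list(self.leaf_order if order is None else order)
        return float(
            sum(self.distance[order[k], order[k + 1]] for k in range(len(order) - 1))
        )

    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2].copy()

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def _walk(node) -> str:
            if node.is_leaf():
                return self.labels[node.id]
            left = _walk(node.left)
            right = _walk(node.right)
            bl_left = max(node.dist - node.left.dist, 0.0)
            bl_right = max(node.dist - node.right.dist, 0.0)
            return f"({left}:{bl_left:.10g},{right}:{bl_right:.10g})"

        return _walk(tree) + ";"


def correlation_distance_matrix(profiles: np.ndarray) -> np.ndarray:
    """1 - Pearson r between item profiles; constant profiles get distance 2."""
    n = profiles.shape[0]
    sd = profiles.std(axis=1)
    constant = sd == 0.0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} item(s) have constant profiles; "
            "assigned maximal correlation distance 2.0"
        )
    centered = profiles - profiles.mean(axis=1, keepdims=True)
    norm = np.sqrt((centered**2).sum(axis=1))
    safe_norm = np.where(norm > 0, norm, 1.0)
    unit = centered / safe_norm[:, None]
    r = unit @ unit.T
    d = 1.0 - r
    d[constant, :] = 2.0
    d[:, constant] = 2.0
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, 2.0)
    return d


def hierarchical_cluster(
    matrix_log2: pd.DataFrame, axis: str = "samples"
) -> Dendrogram:
    """Average-linkage clustering on correlation distance, leaf order optimized.

    ``axis='samples'`` clusters the columns by their probe profiles;
    ``axis='probes'`` clusters the rows by their sample profiles.  The leaf
    order minimizes the sum of adjacent-leaf distances among orders
    consistent with the tree.
    """
    if axis == "samples":
        profiles = matrix_log2.to_numpy(dtype=float).T
        labels = [str(c) for c in matrix_log2.columns]
    elif axis == "probes":
        profiles = matrix_log2.to_numpy(dtype=float)
        labels = [str(i) for i in matrix_log2.index]
    else:
        raise ContentError("axis must be 'samples' or 'probes'")
    if profiles.shape[0] < 2:
        raise ContentError("clustering needs at least 2 items")
    dist = correlation_distance_matrix(profiles)
    condensed = dist[np.triu_indices(dist.shape[0], k=1)]
    linkage = hierarchy.average(condensed)
    linkage = hierarchy.optimal_leaf_ordering(linkage, condensed)
    leaf_order = list(hierarchy.leaves_list(linkage))
    return Dendrogram(labels=labels, linkage=linkage, leaf_order=leaf_order, distance=dist)


# ---------------------------------------------------------------------------
# Cross-platform concordance


def platform_concordance(
    cq_values: Sequence[float], log2_signals: Sequence[float]
) -> Dict[str, float]:
    """Pearson concordance between RT-PCR Cq and log2 array signal.

    Cq is inversely (log-linearly) related to abundance, so good concordance
    shows as strongly negative r.  Returns r with its Fisher-z 95% CI and
    two-sided p, and the range-amplification ratio range(Cq)/range(log2).
    """
    cq = np.asarray(cq_values, dtype=float)
    sig = np.asarray(log2_signals, dtype=float)
    if cq.shape != sig.shape or cq.size < 3:
        raise ContentError("concordance needs >= 3 paired measurements")
    r, p = stats.pearsonr(cq, sig)
    n = cq.size
    if n > 3 and abs(r) < 1.0:
        z = math.atanh(r)
        half = 1.959963984540054 / math.sqrt(n - 3)
        ci_low, ci_high = math.tanh(z - half), math.tanh(z + half)
    else:
        ci_low, ci_high = r, r
    sig_range = float(np.ptp(sig))
    amplification = float(np.ptp(cq)) / sig_range if sig_range > 0 else float("nan")
    return {
        "r": float(r),
        "p": float(p),
        "ci_low": float(ci_low),
        "ci_high": float(ci_high),
        "range_amplification": amplification,
    }
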