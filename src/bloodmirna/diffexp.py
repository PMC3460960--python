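"""Differential expression and cohort-comparison statistics.

The two-group comparison uses empirical-Bayes moderated t-statistics: probe
variances are shrunk toward a common prior via the scaled
inverse-chi-square hierarchy.  The prior (d0, s0^2) is estimated by matching
the first two moments of the log sample variances to the theoretical
scaled-F distribution via digamma/trigamma relations.  Tests run on the
log2 scale; fold-changes are ratios of linear-scale group means, matching
the convention in which printed group means and fold-changes are on the
linear signal scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import special, stats

from .errors import ContentError

LOG_FLOOR = 1e-8  # guard for non-positive signals before log2 (cannot occur
# with a positive normexp offset; retained defensively)


@dataclass
class ModeratedPrior:
    """Hyperparameters of the variance shrinkage prior."""

    d0: float  # prior degrees of freedom; may be +inf
    s0_sq: float  # prior variance

    def __post_init__(self) -> None:
        if not (self.d0 >= 0):
            raise ContentError("prior degrees of freedom must be >= 0")
        if not (self.s0_sq > 0):
            raise ContentError("prior variance must be positive")


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise ContentError("trigamma_inverse needs a positive argument")
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(100):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return x


def fit_moderated_prior(
    sample_variances: np.ndarray, residual_df: int
) -> ModeratedPrior:
    """Estimate (d0, s0^2) from observed per-probe sample variances.

    Moment matching on z = log(s^2): under the hierarchy, z is a scaled
    log-F variable whose mean and variance involve digamma/trigamma of the
    half-degrees of freedom.  When the observed dispersion of z does not
    exceed the sampling floor trigamma(df/2), the prior is degenerate
    (d0 = +inf) and every probe shares the variance s0^2.
    """
    s2 = np.asarray(sample_variances, dtype=float)
    if s2.size < 10:
        raise ContentError("prior estimation needs at least 10 variances")
    if np.any(~np.isfinite(s2)) or np.any(s2 <= 0):
        raise ContentError("sample variances must be positive and finite")
    if residual_df < 1:
        raise ContentError("residual_df must be >= 1")
    half_df = residual_df / 2.0
    e = np.log(s2) - special.digamma(half_df) + math.log(half_df)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(special.polygamma(1, half_df))
    if evar > 0:
        half_d0 = trigamma_inverse(evar)
        d0 = 2.0 * half_d0
        s0_sq = math.exp(emean + special.digamma(half_d0) - math.log(half_d0))
    else:
        d0 = math.inf
        s0_sq = math.exp(emean)
    return ModeratedPrior(d0=d0, s0_sq=s0_sq)


def _group_stats(
    matrix: pd.DataFrame, classes: np.ndarray
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, int, int]:
    classes = np.asarray(classes)
    case = classes == "case"
    ctrl = classes == "control"
    n1, n2 = int(case.sum()), int(ctrl.sum())
    if n1 < 2 or n2 < 2:
        raise ContentError("each class needs at least 2 samples")
    x = matrix.to_numpy(dtype=float)
    m1 = x[:, case].mean(axis=1)
    m2 = x[:, ctrl].mean(axis=1)
    v1 = x[:, case].var(axis=1, ddof=1)
    v2 = x[:, ctrl].var(axis=1, ddof=1)
    return m1, m2, v1, v2, n1, n2


def moderated_t(
    log2_matrix: pd.DataFrame,
    classes: np.ndarray,
    prior: Optional[ModeratedPrior] = None,
) -> pd.DataFrame:
    """Per-probe moderated t, p and BH q for a two-group comparison.

    Pooled residual variance s_g^2 with df = n1+n2-2 is shrunk to
    s~^2 = (d0 s0^2 + df s_g^2) / (d0 + df); the statistic uses the shrunken
    standard error and d0 + df degrees of freedom.  d0 = 0 recovers the
    ordinary pooled t; d0 = +inf fixes the variance at s0^2 (normal tail).
    """
    m1, m2, v1, v2, n1, n2 = _group_stats(log2_matrix, classes)
    df = n1 + n2 - 2
    s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    if prior is None:
        prior = fit_moderated_prior(np.maximum(s2, 1e-300), df)
    d0 = prior.d0
    if math.isinf(d0):
        s2_tilde = np.full_like(s2, prior.s0_sq)
        df_total = math.inf
    else:
        s2_tilde = (d0 * prior.s0_sq + df * s2) / (d0 + df)
        df_total = d0 + df
    se = np.sqrt(s2_tilde * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, (m1 - m2) / se, 0.0)
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return pd.DataFrame(
        {
            "log2_mean_case": m1,
            "log2_mean_control": m2,
            "pooled_variance": s2,
            "moderated_t": t,
            "p": p,
            "q": benjamini_hochberg(p),
        },
        index=log2_matrix.index,
    )


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """Step-up FDR adjustment: monotone, capped at 1."""
    p = np.asarray(p, dtype=float)
    if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ContentError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def wilcoxon_table(matrix: pd.DataFrame, classes: np.ndarray) -> pd.Series:
    """Two-sided rank-sum p per probe.

    Exact enumeration when min(n1, n2) <= 8 and the probe has no ties;
    normal approximation with tie correction otherwise.
    """
    classes = np.asarray(classes)
    case = classes == "case"
    ctrl = classes == "control"
    if case.sum() < 1 or ctrl.sum() < 1:
        raise ContentError("both classes must be present")
    x = matrix.to_numpy(dtype=float)
    small = min(int(case.sum()), int(ctrl.sum())) <= 8
    pvals = np.empty(x.shape[0])
    for g in range(x.shape[0]):
        a, b = x[g, case], x[g, ctrl]
        has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
        method = "exact" if (small and not has_ties) else "asymptotic"
        pvals[g] = stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
    return pd.Series(pvals, index=matrix.index, name="wilcoxon_p")


def fold_changes(matrix_linear: pd.DataFrame, classes: np.ndarray) -> pd.Series:
    """Ratio of case-group mean to control-group mean on the linear scale."""
    classes = np.asarray(classes)
    case = classes == "case"
    ctrl = classes == "control"
    if case.sum() < 1 or ctrl.sum() < 1:
        raise ContentError("both classes must be present")
    x = matrix_linear.to_numpy(dtype=float)
    if np.any(x < 0):
        raise ContentError("linear-scale signals must be non-negative")
    m1 = x[:, case].mean(axis=1)
    m2 = x[:, ctrl].mean(axis=1)
    if np.any(m2 <= 0):
        raise ContentError("control group mean is zero for some probe")
    return pd.Series(m1 / m2, index=matrix_linear.index, name="fold_change")


def display_fold(fold: float) -> float:
    """Fold-change display convention: two decimals."""
    return round(float(fold), 2)


def diffexp_table(
    matrix_linear: pd.DataFrame,
    classes: np.ndarray,
    prior: Optional[ModeratedPrior] = None,
) -> pd.DataFrame:
    """Full differential-expression table on a linear-scale signal matrix."""
    log2_matrix = np.log2(matrix_linear.clip(lower=LOG_FLOOR))
    mod = moderated_t(log2_matrix, classes, prior)
    m1, m2, v1, v2, _, _ = _group_stats(matrix_linear, classes)
    table = pd.DataFrame(
        {
            "mean_case": m1,
            "sd_case": np.sqrt(v1),
            "mean_control": m2,
            "sd_control": np.sqrt(v2),
            "fold_change": fold_changes(matrix_linear, classes),
        },
        index=matrix_linear.index,
    )
    table = table.join(mod)
    table["wilcoxon_p"] = wilcoxon_table(log2_matrix, classes)
    table["wilcoxon_q"] = benjamini_hochberg(table["wilcoxon_p"].to_numpy())
    return table


# ---------------------------------------------------------------------------
# Cohort summary statistics


def pooled_t_from_summaries(
    n1: int, mean1: float, sd1: float, n2: int, mean2: float, sd2: float
) -> Tuple[float, int, float]:
    """Two-sided pooled-variance t-test from per-group n/mean/sd summaries."""
    if n1 < 2 or n2 < 2:
        raise ContentError("pooled t needs at least 2 observations per group")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    se = math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    t = (mean1 - mean2) / se if se > 0 else 0.0
    p = 2.0 * stats.t.sf(abs(t), df) if se > 0 else 1.0
    return t, df, p


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher's exact p: sum of tables at most as probable."""
    arr = np.asarray(table, dtype=int)
    if arr.shape != (2, 2) or np.any(arr < 0):
        raise ContentError("Fisher's exact test needs a non-negative 2x2 table")
    return float(stats.fisher_exact(arr, alternative="two-sided")[1])


def cohort_summary_tests(sheet) -> pd.DataFrame:
    """Case-vs-control cohort comparison table.

    Continuous variables (age, wbc, platelets, hemoglobin): two-sided
    pooled-variance t-tests on the available values.  Categorical variables
    (gender, smoking): Fisher's exact test on the 2x2 contingency table.
    All-missing variables are skipped with a warning row.
    """
    import warnings

    table = sheet.table
    case = table["class"] == "case"
    rows = []
    for var in ("age", "wbc", "platelets", "hemoglobin"):
        a = table.loc[case, var].dropna()
        b = table.loc[~case, var].dropna()
        if len(a) < 2 or len(b) < 2:
            warnings.warn(f"cohort test skipped for {var!r}: insufficient data")
            continue
        t, df, p = pooled_t_from_summaries(
            len(a), a.mean(), a.std(ddof=1), len(b), b.mean(), b.std(ddof=1)
        )
        rows.append(
            {
                "variable": var,
                "test": "pooled_t",
                "case_n": len(a),
                "control_n": len(b),
                "case_mean": a.mean(),
                "control_mean": b.mean(),
                "statistic": t,
                "p": p,
            }
        )
    for var in ("gender", "smoking"):
        vals = table[var]
        levels = sorted(vals.astype(str).unique())
        if len(levels) < 2:
            rows.append(
                {
                    "variable": var,
                    "test": "fisher_exact",
                    "case_n": int(case.sum()),
                    "control_n": int((~case).sum()),
                    "case_mean": np.nan,
                    "control_mean": np.nan,
                    "statistic": np.nan,
                    "p": 1.0,
                }
            )
            continue
        first = levels[0]
        ct = [
            [int(((vals.astype(str) == first) & case).sum()),
             int(((vals.astype(str) != first) & case).sum())],
            [int(((vals.astype(str) == first) & ~case).sum()),
             int(((vals.astype(str) != first) & ~case).sum())],
        ]
        rows.append(
            {
                "variable": var,
                "test": "fisher_exact",
                "case_n": int(case.sum()),
                "control_n": int((~case).sum()),
                "case_mean": np.nan,
                "control_mean": np.nan,
                "statistic": np.nan,
                "p": fisher_exact_2x2(ct),
            }
        )
    return pd.DataFrame(rows)
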