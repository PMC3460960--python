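"""Spot-level pre-processing: background correction, normalization, summarization.

Stage order is fixed: per-array per-channel normexp background correction
(offset 10), within-array global loess of M on A (span 1/3), between-array
quantile normalization of the reference channel, then per-probe replicate
summarization of the sample channel (mean when max < 1.5×min, else median).
Probes are called expressed against the per-array mean summarized empty-spot
signal.

normexp models an observed spot intensity as Normal(mu, sigma^2) background
plus Exponential(alpha) true signal; the corrected value is the conditional
expectation E[signal | observed] plus a positive offset, which keeps every
corrected intensity strictly positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, special
from statsmodels.nonparametric.smoothers_lowess import lowess

from .core import ExpressionMatrix, ProbePanel, SpotTable
from .errors import ConfigError, ContentError, EstimationError


@dataclass
class PreprocessConfig:
    normexp_offset: float = 10.0
    loess_span: float = 1.0 / 3.0
    expressed_fold: float = 3.0
    expressed_fraction: float = 0.25
    summarize_ratio_threshold: float = 1.5
    pooled_empty_reference: bool = False

    def validate(self) -> None:
        if self.normexp_offset < 0:
            raise ConfigError("normexp_offset must be >= 0")
        if not 0.0 < self.loess_span <= 1.0:
            raise ConfigError("loess_span must be in (0, 1]")
        if self.expressed_fold <= 1.0:
            raise ConfigError("expressed_fold must be > 1")
        if not 0.0 < self.expressed_fraction <= 1.0:
            raise ConfigError("expressed_fraction must be in (0, 1]")
        if self.summarize_ratio_threshold <= 1.0:
            raise ConfigError("summarize_ratio_threshold must be > 1")


# ---------------------------------------------------------------------------
# normexp background correction


def _normexp_nll(params: np.ndarray, x: np.ndarray) -> float:
    mu, log_sigma, log_alpha = params
    sigma = math.exp(log_sigma)
    alpha = math.exp(log_alpha)
    if sigma == 0.0 or alpha == 0.0:
        return float("inf")
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        z = (x - mu - sigma * sigma / alpha) / sigma
        ll = (
            -log_alpha
            + (mu - x) / alpha
            + sigma * sigma / (2.0 * alpha * alpha)
            + special.log_ndtr(z)
        )
        total = float(np.sum(ll))
    return float("inf") if math.isnan(total) else -total


def _inv_mills(z: np.ndarray) -> np.ndarray:
    """phi(z)/Phi(z), numerically stable for very negative z."""
    return math.sqrt(2.0 / math.pi) / special.erfcx(-np.asarray(z) / math.sqrt(2.0))


def _normexp_nll_grad(params: np.ndarray, x: np.ndarray) -> Tuple[float, np.ndarray]:
    """Negative log-likelihood and its gradient in (mu, log sigma, log alpha)."""
    mu, log_sigma, log_alpha = params
    sigma = math.exp(log_sigma)
    alpha = math.exp(log_alpha)
    z = (x - mu) / sigma - sigma / alpha
    mills = _inv_mills(z)
    ll = (
        -log_alpha
        + (mu - x) / alpha
        + sigma * sigma / (2.0 * alpha * alpha)
        + special.log_ndtr(z)
    )
    n = x.size
    d_mu = np.sum(1.0 / alpha - mills / sigma)
    d_sigma = np.sum(
        sigma / (alpha * alpha) + mills * (-(x - mu) / (sigma * sigma) - 1.0 / alpha)
    )
    d_alpha = np.sum(
        -1.0 / alpha
        - (mu - x) / (alpha * alpha)
        - sigma * sigma / alpha**3
        + mills * sigma / (alpha * alpha)
    )
    grad = -np.array([d_mu, sigma * d_sigma, alpha * d_alpha])
    return -float(np.sum(ll)), grad


def normexp_fit(x: np.ndarray) -> Tuple[float, float, float]:
    """Maximum-likelihood fit of the Normal+Exponential convolution.

    Returns (mu, sigma, alpha): background mean and sd, and signal mean.
    Raises ``EstimationError`` for degenerate input (fewer than 50 values or
    zero spread).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 50:
        raise EstimationError(
            f"normexp fit needs at least 50 intensities, got {x.size}"
        )
    if not np.all(np.isfinite(x)) or np.any(x < 0):
        raise ContentError("normexp input must be finite and non-negative")
    if np.ptp(x) == 0.0:
        raise EstimationError("normexp fit impossible: all intensities identical")
    # Two moment-based starts: the exponential part carries the skewness,
    # while the lower quantiles pin the background location and spread.  The
    # likelihood surface has a degenerate sigma->0 basin when signal
    # dominates, so both starts are tried and the better optimum kept.
    starts = []
    m3 = float(np.mean((x - x.mean()) ** 3))
    alpha_skew = max((max(m3, 1e-6) / 2.0) ** (1.0 / 3.0), 1e-3)
    var0 = float(np.var(x))
    sigma_skew = math.sqrt(max(var0 - alpha_skew * alpha_skew, 1e-4))
    starts.append(
        np.array([x.mean() - alpha_skew, math.log(sigma_skew), math.log(alpha_skew)])
    )
    mu_bg = float(np.quantile(x, 0.05))
    low = x[x <= np.quantile(x, 0.10)]
    sigma_bg = max(float(low.std()), 1e-2)
    alpha_bg = max(float(x.mean()) - mu_bg, 1e-3)
    starts.append(np.array([mu_bg, math.log(sigma_bg), math.log(alpha_bg)]))
    spread = float(np.ptp(x))
    bounds = [
        (float(x.min()) - 10.0 * spread, float(x.max())),
        (math.log(spread * 1e-6), math.log(spread * 10.0)),
        (math.log(spread * 1e-6), math.log(spread * 10.0)),
    ]
    best = None
    for start in starts:
        start = np.clip(start, [b[0] for b in bounds], [b[1] for b in bounds])
        result = optimize.minimize(
            _normexp_nll_grad, start, args=(x,), jac=True, method="L-BFGS-B",
            bounds=bounds, options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-9},
        )
        if best is None or result.fun < best.fun:
            best = result
    # Derivative-free polish guards against premature line-search stops.
    result = optimize.minimize(
        _normexp_nll, best.x, args=(x,), method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 200},
    )
    if result.fun < best.fun:
        best = result
    mu, log_sigma, log_alpha = best.x
    return float(mu), float(math.exp(log_sigma)), float(math.exp(log_alpha))


def normexp_expected_signal(
    x: np.ndarray, mu: float, sigma: float, alpha: float
) -> np.ndarray:
    """E[signal | observed] under the fitted convolution model.

    Uses the scaled-complementary-error-function form of the inverse Mills
    ratio for numerical stability at low intensities.
    """
    x = np.asarray(x, dtype=float)
    if sigma <= 0.0 or alpha <= 0.0:
        raise EstimationError("normexp parameters must be positive")
    mu_sf = x - mu - sigma * sigma / alpha
    with np.errstate(over="ignore", divide="ignore"):
        t = mu_sf / sigma
        # phi(t) / Phi(t) computed stably for very negative t.
        ratio = math.sqrt(2.0 / math.pi) / special.erfcx(-t / math.sqrt(2.0))
    return mu_sf + sigma * ratio


def normexp_correct(x: np.ndarray, offset: float = 10.0) -> np.ndarray:
    """Background-correct raw intensities; output strictly positive, monotone."""
    mu, sigma, alpha = normexp_fit(np.asarray(x, dtype=float))
    return normexp_expected_signal(x, mu, sigma, alpha) + offset


# ---------------------------------------------------------------------------
# Normalized per-array spot representation


@dataclass
class NormalizedArray:
    """Per-spot (M, A) log-ratio geometry for one hybridization.

    M = log2(sample/reference); A = (log2 sample + log2 reference)/2.
    Channel intensities are recoverable as sample = 2^(A + M/2) and
    reference = 2^(A - M/2).
    """

    array_id: str
    probe_id: np.ndarray
    replicate: np.ndarray
    m: np.ndarray
    a: np.ndarray

    @classmethod
    def from_channels(
        cls,
        array_id: str,
        probe_id: np.ndarray,
        replicate: np.ndarray,
        sample: np.ndarray,
        reference: np.ndarray,
    ) -> "NormalizedArray":
        sample = np.asarray(sample, dtype=float)
        reference = np.asarray(reference, dtype=float)
        if np.any(sample <= 0) or np.any(reference <= 0):
            raise ContentError("channel intensities must be strictly positive")
        ls, lr = np.log2(sample), np.log2(reference)
        return cls(
            array_id=array_id,
            probe_id=np.asarray(probe_id),
            replicate=np.asarray(replicate),
            m=ls - lr,
            a=0.5 * (ls + lr),
        )

    @property
    def sample_channel(self) -> np.ndarray:
        return np.exp2(self.a + self.m / 2.0)

    @property
    def reference_channel(self) -> np.ndarray:
        return np.exp2(self.a - self.m / 2.0)

    @property
    def n_spots(self) -> int:
        return self.m.size


def loess_normalize_within(array: NormalizedArray, span: float = 1.0 / 3.0) -> NormalizedArray:
    """Remove the intensity-dependent dye-bias trend within one array.

    Fits a locally weighted degree-1 regression of M on A over all spots
    jointly (tricube weights, 3 robustness iterations) and subtracts the fit.
    A is unchanged.
    """
    if not 0.0 < span <= 1.0:
        raise ConfigError("loess span must be in (0, 1]")
    if array.n_spots < 10:
        raise ContentError("loess normalization needs at least 10 spots")
    if not np.all(np.isfinite(array.a)):
        raise ContentError("A values must be finite for loess normalization")
    # delta = 1% of the A range: standard lowess interpolation shortcut for
    # dense designs; exact local fits at knots, linear interpolation between.
    trend = lowess(
        array.m,
        array.a,
        frac=span,
        it=3,
        delta=0.01 * float(np.ptp(array.a)),
        return_sorted=False,
    )
    return NormalizedArray(
        array_id=array.array_id,
        probe_id=array.probe_id,
        replicate=array.replicate,
        m=array.m - trend,
        a=array.a.copy(),
    )


def rquantile_between(arrays: Sequence[NormalizedArray]) -> List[NormalizedArray]:
    """Quantile-normalize reference-channel intensities across arrays.

    Every array's reference channel is mapped onto the mean of per-rank
    sorted reference values (ties get the mean of their tied ranks' values);
    per-spot M is unchanged and the sample channel is recomputed from
    (M, new reference).
    """
    if len(arrays) == 0:
        raise ContentError("rquantile_between needs at least one array")
    n_spots = arrays[0].n_spots
    if any(a.n_spots != n_spots for a in arrays):
        raise ContentError("all arrays must have the same number of spots")
    refs = np.column_stack([a.reference_channel for a in arrays])
    mean_sorted = np.sort(refs, axis=0).mean(axis=1)
    ranks_grid = np.arange(1, n_spots + 1, dtype=float)
    out = []
    for idx, arr in enumerate(arrays):
        from scipy.stats import rankdata

        r = rankdata(refs[:, idx], method="average")
        new_ref = np.interp(r, ranks_grid, mean_sorted)
        new_sample = new_ref * np.exp2(arr.m)
        out.append(
            NormalizedArray.from_channels(
                arr.array_id, arr.probe_id, arr.replicate, new_sample, new_ref
            )
        )
    return out


# ---------------------------------------------------------------------------
# Replicate summarization and the expression call


def summarize_probe(values: np.ndarray, ratio_threshold: float = 1.5) -> float:
    """Summarize replicate spot values: mean if max < threshold×min, else median."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ContentError("cannot summarize an empty replicate set")
    if np.any(values <= 0):
        raise ContentError("replicate values must be positive")
    if values.max() < ratio_threshold * values.min():
        return float(values.mean())
    return float(np.median(values))


def _summarize_array(
    arr: NormalizedArray, ratio_threshold: float
) -> pd.Series:
    frame = pd.DataFrame({"probe_id": arr.probe_id, "value": arr.sample_channel})
    grouped = frame.groupby("probe_id", sort=False)["value"]
    mins = grouped.min()
    maxs = grouped.max()
    means = grouped.mean()
    medians = grouped.median()
    use_mean = maxs < ratio_threshold * mins
    return means.where(use_mean, medians)


def normalize_arrays(
    spot_tables: Sequence[SpotTable],
    config: Optional[PreprocessConfig] = None,
) -> List[NormalizedArray]:
    """Background-correct and normalize all arrays (normexp, loess, rquantile)."""
    config = config or PreprocessConfig()
    config.validate()
    normalized = []
    for table in spot_tables:
        data = table.data
        cs = normexp_correct(
            data["sample_signal"].to_numpy(dtype=float), config.normexp_offset
        )
        cr = normexp_correct(
            data["reference_signal"].to_numpy(dtype=float), config.normexp_offset
        )
        arr = NormalizedArray.from_channels(
            table.array_id,
            data["probe_id"].to_numpy(),
            data["replicate"].to_numpy(),
            cs,
            cr,
        )
        normalized.append(loess_normalize_within(arr, config.loess_span))
    return rquantile_between(normalized)


def build_expression_matrix(
    spot_tables: Sequence[SpotTable],
    panel: ProbePanel,
    config: Optional[PreprocessConfig] = None,
) -> Tuple[ExpressionMatrix, pd.Series]:
    """Run the full stage order and summarize per probe per array.

    Returns the probe × sample matrix of summarized sample-channel signals
    (human, non-empty probes only) and the per-array mean summarized
    empty-spot signal.  The expressed-mask is not set here; apply
    ``call_expressed`` (or use ``run_preprocess``).
    """
    config = config or PreprocessConfig()
    config.validate()
    for table in spot_tables:
        table.validate(panel)
    normalized = normalize_arrays(spot_tables, config)
    empty_ids = set(panel.empty_probe_ids)
    human_ids = list(panel.human_probe_ids)
    columns: Dict[str, pd.Series] = {}
    empty_summary: Dict[str, float] = {}
    for arr in normalized:
        summarized = _summarize_array(arr, config.summarize_ratio_threshold)
        is_empty = summarized.index.isin(empty_ids)
        empty_vals = summarized[is_empty]
        if len(empty_vals) == 0:
            raise ContentError(
                f"array {arr.array_id!r} has no empty spots for the expression call"
            )
        empty_summary[arr.array_id] = float(empty_vals.mean())
        columns[arr.array_id] = summarized.reindex(human_ids)
    values = pd.DataFrame(columns, index=pd.Index(human_ids, name="probe_id"))
    if values.isna().any().any():
        raise ContentError("some panel probes were absent from an array")
    matrix = ExpressionMatrix(
        values=values,
        expressed_mask=None,
        provenance={"preprocess": asdict(config), "n_arrays": len(spot_tables)},
    )
    return matrix, pd.Series(empty_summary, name="empty_spot_mean")


def call_expressed(
    matrix: ExpressionMatrix,
    empty_summaries: pd.Series,
    fold: float = 3.0,
    fraction: float = 0.25,
    pooled: bool = False,
) -> pd.Series:
    """Flag probes whose signal beats fold × the empty-spot level often enough.

    A probe is expressed iff its summarized signal exceeds ``fold`` times the
    (per-array, or pooled mean) empty-spot summary on at least
    ``ceil(fraction × n_arrays)`` arrays.
    """
    n_arrays = matrix.values.shape[1]
    required = math.ceil(fraction * n_arrays)
    if required < 1 or required > n_arrays:
        raise ConfigError(
            f"expressed_fraction {fraction} yields invalid required count {required}"
        )
    empty = empty_summaries.reindex(matrix.values.columns)
    if empty.isna().any():
        raise ContentError("empty-spot summary missing for some arrays")
    if pooled:
        thresholds = pd.Series(
            fold * float(empty.mean()), index=matrix.values.columns
        )
    else:
        thresholds = fold * empty
    above = matrix.values.gt(thresholds, axis=1)
    mask = above.sum(axis=1) >= required
    mask.name = None
    return mask


def run_preprocess(
    spot_tables: Sequence[SpotTable],
    panel: ProbePanel,
    config: Optional[PreprocessConfig] = None,
) -> Tuple[ExpressionMatrix, pd.Series]:
    """Full pre-processing: matrix construction plus the expression call."""
    config = config or PreprocessConfig()
    matrix, empty_summaries = build_expression_matrix(spot_tables, panel, config)
    mask = call_expressed(
        matrix,
        empty_summaries,
        fold=config.expressed_fold,
        fraction=config.expressed_fraction,
        pooled=config.pooled_empty_reference,
    )
    matrix.expressed_mask = mask
    return matrix, empty_summaries
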