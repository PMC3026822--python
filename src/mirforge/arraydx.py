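"""Microarray detection calls and two-group differential expression.

A probe is positive on an array when its (triplicate-median) signal
reaches the negative-control mean plus two standard deviations, and is
detected overall when positive on at least two arrays.  Signals are
background-corrected under a Normal-background + Exponential-signal
convolution (posterior-mean correction), quantile-normalised so every
array shares one empirical distribution, and tested per probe with a
pooled-variance two-sample t-test.  P-values receive a
Benjamini-Hochberg adjustment; the differential-expression call is
|log2 fold change| >= 1.5 with p < 0.05, where the call uses the raw
p-value by default (the adjusted one via ``use_adjusted=True``; both
are always reported).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

LOGFC_MIN = 1.5
ALPHA = 0.05
MIN_POSITIVE_ARRAYS = 2


def collapse_replicate_spots(signal: pd.DataFrame) -> pd.DataFrame:
    """Median-collapse replicate spots sharing a probe id (index)."""
    return signal.groupby(level=0).median()


def detection_call(signal: pd.DataFrame, probe_class: pd.Series,
                   min_positive_arrays: int = MIN_POSITIVE_ARRAYS):
    """Per-array positivity and the overall detected flag per probe.

    Returns (positive flags DataFrame, detected Series, thresholds
    Series, degenerate Series).  An array whose negative controls have
    zero variance is flagged degenerate and uses the bare negative mean
    as threshold.
    """
    neg = signal.loc[probe_class == "negative_control"]
    if neg.empty:
        raise ValueError("no negative-control probes present")
    mu = neg.mean(axis=0)
    sd = neg.std(axis=0, ddof=1).fillna(0.0)
    degenerate = sd == 0
    thresholds = mu + 2.0 * sd
    thresholds[degenerate] = mu[degenerate]
    positive = signal.ge(thresholds, axis=1)
    detected = positive.sum(axis=1) >= min_positive_arrays
    return positive, detected, thresholds, degenerate


def positive_rate(n_detected: int, n_probes: int) -> float:
    """Detection rate in percent, rounded to one decimal."""
    if n_probes <= 0:
        return 0.0
    return round(100.0 * n_detected / n_probes, 1)


def normexp_posterior_mean(x, mu: float, sigma: float, alpha: float):
    """E[signal | observed] for Normal(mu, sigma) + Exponential(alpha).

    The posterior of the exponential signal given the observation is a
    normal truncated to s > 0, giving
    E[S|X=x] = m + sigma * phi(m/sigma) / Phi(m/sigma)
    with m = x - mu - sigma^2/alpha; computed in log space for
    stability and strictly positive.
    """
    if sigma <= 0 or alpha <= 0:
        raise ValueError("sigma and alpha must be positive")
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite input signal")
    m = x - mu - sigma ** 2 / alpha
    z = m / sigma
    out = m + sigma * np.exp(stats.norm.logpdf(z) - stats.norm.logcdf(z))
    return np.maximum(out, np.finfo(float).tiny)


def estimate_normexp_params(col: pd.Series, neg_values: np.ndarray):
    mu = float(np.mean(neg_values))
    sigma = float(np.std(neg_values, ddof=1))
    if sigma <= 0:
        sigma = max(1e-6, 0.01 * max(abs(mu), 1.0))
    alpha = float(np.mean(col) - mu)
    alpha = max(alpha, sigma)
    return mu, sigma, alpha


def background_correct(signal: pd.DataFrame,
                       probe_class: pd.Series) -> pd.DataFrame:
    """Per-array normexp posterior-mean correction.

    Background parameters come from the negative-control probes of each
    array; the exponential mean from the non-control signal excess.
    Output is strictly positive and order-preserving within an array.
    """
    neg = signal.loc[probe_class == "negative_control"]
    if neg.empty:
        raise ValueError("no negative-control probes present")
    out = {}
    mirna = probe_class != "negative_control"
    for col in signal.columns:
        mu, sigma, alpha = estimate_normexp_params(
            signal.loc[mirna, col], neg[col].to_numpy())
        out[col] = normexp_posterior_mean(signal[col].to_numpy(),
                                          mu, sigma, alpha)
    return pd.DataFrame(out, index=signal.index)


def quantile_normalize(signal: pd.DataFrame) -> pd.DataFrame:
    """Force one empirical distribution on every array (column).

    Each column's values map to the row-sorted mean profile at their
    within-column ranks; ties receive the average of the tied profile
    values.  Idempotent.
    """
    if signal.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 arrays")
    vals = signal.to_numpy(dtype=float)
    profile = np.sort(vals, axis=0).mean(axis=1)
    n = vals.shape[0]
    out = np.empty_like(vals)
    for j in range(vals.shape[1]):
        ranks = stats.rankdata(vals[:, j], method="average")
        out[:, j] = np.interp(ranks - 1.0, np.arange(n), profile)
    return pd.DataFrame(out, index=signal.index, columns=signal.columns)


def de_test(signal: pd.DataFrame, groups: pd.Series,
            logfc_min: float = LOGFC_MIN, alpha: float = ALPHA,
            use_adjusted: bool = False,
            detected: pd.Series | None = None) -> pd.DataFrame:
    """Per-probe pooled-variance t-test with BH adjustment and DE calls.

    The t statistic and the fold change are computed on log2 signals:
    log_fc is the difference of group means on the log2 scale, i.e.
    log2 of the ratio of geometric means (the linear-model "logFC"
    convention of array analysis).  Zero
    within-group variance in both groups with equal means yields p = 1
    by convention.  The DE call requires |log_fc| >= ``logfc_min``
    (inclusive) and p < ``alpha`` using raw p by default, BH-adjusted p
    when ``use_adjusted`` is set, and the detection flag when supplied.
    """
    a_cols = groups.index[groups == "A"]
    b_cols = groups.index[groups == "B"]
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValueError("each group needs at least 2 arrays")
    A = np.log2(signal[a_cols].to_numpy(dtype=float))
    B = np.log2(signal[b_cols].to_numpy(dtype=float))
    log_fc = A.mean(axis=1) - B.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat, p_raw = stats.ttest_ind(A, B, axis=1, equal_var=True)
    flat = (np.nanvar(A, axis=1) == 0) & (np.nanvar(B, axis=1) == 0)
    same = flat & np.isclose(A.mean(axis=1), B.mean(axis=1))
    p_raw = np.where(same, 1.0, p_raw)
    t_stat = np.where(same, 0.0, t_stat)
    p_raw = np.where(np.isnan(p_raw) & flat & ~same, 0.0, p_raw)
    p_raw = np.nan_to_num(p_raw, nan=1.0)
    p_adj = multipletests(p_raw, method="fdr_bh")[1]
    p_used = p_adj if use_adjusted else p_raw
    det = detected.reindex(signal.index).fillna(True).to_numpy() \
        if detected is not None else np.ones(len(signal), dtype=bool)
    de_call = (np.abs(log_fc) >= logfc_min) & (p_used < alpha) & det
    return pd.DataFrame({
        "log_fc": log_fc, "t_stat": t_stat, "p_raw": p_raw,
        "p_adj": p_adj, "detected": det, "de_call": de_call,
    }, index=signal.index)


def platform_concordance(array_values, qpcr_values) -> float:
    """Pearson correlation between paired platform measurements."""
    x = np.asarray(array_values, dtype=float)
    y = np.asarray(qpcr_values, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("paired vectors of length >= 3 required")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("undefined correlation: zero variance")
    return float(stats.pearsonr(x, y)[0])


def analyze(signal: pd.DataFrame, probe_class: pd.Series, groups: pd.Series,
            logfc_min: float = LOGFC_MIN, alpha: float = ALPHA,
            use_adjusted: bool = False,
            min_positive_arrays: int = MIN_POSITIVE_ARRAYS):
    """Full array stage: detection -> normexp -> quantile -> DE.

    Control spots are removed before testing.  Returns (results
    DataFrame restricted to miRNA probes, detection summary dict).
    """
    signal = collapse_replicate_spots(signal)
    _pos, detected, _thr, _deg = detection_call(signal, probe_class,
                                                min_positive_arrays)
    corrected = background_correct(signal, probe_class)
    normalized = quantile_normalize(corrected)
    mirna = probe_class == "miRNA"
    results = de_test(normalized.loc[mirna], groups, logfc_min, alpha,
                      use_adjusted, detected.loc[mirna])
    n_mirna = int(mirna.sum())
    n_det = int(detected.loc[mirna].sum())
    summary = {
        "n_probes": n_mirna,
        "n_detected": n_det,
        "positive_rate": positive_rate(n_det, n_mirna),
        "n_de": int(results["de_call"].sum()),
    }
    return results, summary
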