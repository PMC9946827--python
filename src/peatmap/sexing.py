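"""Competitive-mapping U/V sex assignment.

In a haploid-dominant moss each gametophyte carries either the female U or
the male V chromosome. Reads are competitively mapped to a shared homologous
region present on both the V chromosome and the U scaffold; the per-sample
ratio count_V / (count_V + count_U) is bimodal at ~0 and ~1, so sex can be
called from the ratio with an autosomal null distribution quantifying
mapping bias, a bimodal chromosome-coverage classifier, and an exact
binomial test for the 1:1 expected sex ratio.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import binom
from sklearn.cluster import KMeans


def classify_sex(
    count_v: np.ndarray, count_u: np.ndarray, tau: float = 0.9, min_total: int = 20
) -> np.ndarray:
    """Call V (male) / U (female) / NA from a competitive count pair.

    V when ratio >= tau, U when ratio <= 1 - tau, NA otherwise or when
    total coverage < min_total.
    """
    count_v = np.asarray(count_v, dtype=float)
    count_u = np.asarray(count_u, dtype=float)
    total = count_v + count_u
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(total > 0, count_v / total, np.nan)
    call = np.full(count_v.shape, "NA", dtype=object)
    ok = total >= min_total
    call[ok & (ratio >= tau)] = "V"
    call[ok & (ratio <= 1.0 - tau)] = "U"
    return call


def call_table(
    counts: pd.DataFrame, tau: float = 0.9, min_total: int = 20
) -> pd.DataFrame:
    """Annotate a count table with ratio and sex call."""
    out = counts.copy()
    total = out["count_V"] + out["count_U"]
    out["ratio"] = np.where(total > 0, out["count_V"] / total.replace(0, np.nan), np.nan)
    out["call"] = classify_sex(
        out["count_V"].to_numpy(), out["count_U"].to_numpy(), tau, min_total
    )
    return out


def autosomal_null(
    window_counts: np.ndarray,
    n_pairs: int = 10_000,
    seed: int = 0,
) -> np.ndarray:
    """Null count ratios from random pairs of equal-length autosomal windows."""
    counts = np.asarray(window_counts, dtype=float)
    if counts.size < 2:
        raise ValueError("need >= 2 autosomal windows")
    rng = np.random.default_rng(seed)
    i = rng.integers(0, counts.size, n_pairs)
    j = rng.integers(0, counts.size - 1, n_pairs)
    j = np.where(j >= i, j + 1, j)  # distinct windows
    tot = counts[i] + counts[j]
    return np.where(tot > 0, counts[i] / np.maximum(tot, 1), 0.5)


def null_tail(null_ratios: np.ndarray, observed_ratio: float) -> float:
    """Fraction of null ratios at least as extreme (two-sided) as observed.

    Extremeness of a ratio r is max(r, 1 - r), so an unbiased observation
    (r = 0.5) has tail ~1 and a strongly one-sided one a tiny tail.
    """
    thr = max(observed_ratio, 1.0 - observed_ratio)
    extreme = np.maximum(null_ratios, 1.0 - null_ratios)
    return float(np.mean(extreme >= thr))


def bimodal_coverage(coverage: np.ndarray, min_mean_ratio: float = 2.0) -> np.ndarray:
    """Split normalized chromosome-wide coverages into low/high mapping modes.

    1-D two-means with deterministic initialisation at the min and max; the
    split is only declared when the high-cluster mean is at least
    ``min_mean_ratio`` times the low one, otherwise every sample is labelled
    'high' (single mode).
    """
    cov = np.asarray(coverage, dtype=float)
    if cov.size < 4:
        raise ValueError("need >= 4 samples")
    import warnings

    init = np.array([[cov.min()], [cov.max()]])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # identical points trip k=2 convergence noise
        km = KMeans(n_clusters=2, init=init, n_init=1).fit(cov[:, None])
    means = km.cluster_centers_.ravel()
    lo = int(np.argmin(means))
    if means[1 - lo] < min_mean_ratio * max(means[lo], 1e-12):
        return np.full(cov.shape, "high", dtype=object)
    return np.where(km.labels_ == lo, "low", "high").astype(object)


def sex_ratio_test(n_female: int, n_male: int) -> float:
    """Two-sided exact binomial test of a 1:1 sex ratio.

    Symmetric form: 2 * min(lower tail, upper tail) capped at 1.
    """
    n = n_female + n_male
    if n <= 0:
        raise ValueError("no individuals")
    # evaluating the lower tail at the minority count is exactly symmetric
    k = min(n_female, n_male)
    return float(min(2.0 * binom.cdf(k, n, 0.5), 1.0))
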