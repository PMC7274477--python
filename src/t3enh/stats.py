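"""Statistical kernel: size factors, NB differential test, BH, exact tests.

The differential test is a deliberately lean negative-binomial Wald
test in the DESeq2 tradition (median-ratio size factors, per-unit
dispersion, log2 fold change with pseudocount): no LFC shrinkage, no
independent filtering, no outlier replacement.  Downstream stages only
consume (log2FC, FDR) thresholds, so the simplifications do not change
the decision rules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import stats as sps

DIFF_COLUMNS = ["unit_id", "base_mean", "log2fc", "p_value", "q_value", "degenerate"]


def median_ratio_size_factors(counts: pd.DataFrame | np.ndarray) -> np.ndarray:
    """DESeq-style size factors: per-column median ratio to the row geometric mean.

    Rows containing any zero are excluded from the reference.  Factors
    are returned as-is (no renormalisation to product one).
    """
    mat = np.asarray(counts, dtype=float)
    all_pos = (mat > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError("no reference rows: every row contains a zero count")
    ref = mat[all_pos]
    log_geomean = np.log(ref).mean(axis=1)
    ratios = np.log(ref) - log_geomean[:, None]
    return np.exp(np.median(ratios, axis=0))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved.

    NaN entries propagate as NaN and do not count toward m.
    """
    p = np.asarray(p_values, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    qv = np.empty(m)
    qv[order] = np.minimum(ranked, 1.0)
    q[ok] = qv
    return q


def _moment_dispersion(norm_counts: np.ndarray, groups: list[np.ndarray],
                       inv_s_mean: float, floor: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-unit method-of-moments dispersion from within-group variability.

    Var(k/s) = mu * mean(1/s) + alpha * mu^2 under NB(mu, alpha), so
    alpha_hat = (within-group variance - mu * mean(1/s)) / mu^2.
    """
    m = norm_counts.mean(axis=1)
    var_w = np.zeros(norm_counts.shape[0])
    n_groups = 0
    for cols in groups:
        if len(cols) >= 2:
            var_w += norm_counts[:, cols].var(axis=1, ddof=1)
            n_groups += 1
    var_w /= max(n_groups, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (var_w - m * inv_s_mean) / np.maximum(m, 1e-12) ** 2
    return np.maximum(alpha, floor), m


def _trend_dispersion(alpha: np.ndarray, mean: np.ndarray, n_bins: int = 20) -> np.ndarray:
    """Mean dispersion per abundance bin, to moderate the noisy per-unit MoM."""
    trend = np.empty_like(alpha)
    order = np.argsort(mean, kind="mergesort")
    for idx in np.array_split(order, min(n_bins, max(len(alpha), 1))):
        if len(idx):
            trend[idx] = alpha[idx].mean()
    return trend


def nb_differential_test(counts: pd.DataFrame,
                         ref_cols: list[str],
                         trt_cols: list[str],
                         size_factors: np.ndarray | None = None,
                         pseudocount: float = 0.5,
                         dispersion_floor: float = 1e-8,
                         moderate_dispersion: bool = True,
                         moderation_cap: float = 2.0,
                         n_trend_bins: int = 20) -> pd.DataFrame:
    """Two-group NB Wald test on log2 fold change (treatment over reference).

    Dispersion is method-of-moments per unit, pooled across the two
    groups after size-factor normalisation, floored at
    ``dispersion_floor``.  With ``moderate_dispersion`` the per-unit
    estimate is clamped to [trend, moderation_cap * trend], where the
    trend is the bin-mean of the per-unit values along abundance: with
    two replicates per group the raw moment estimate carries so little
    information that a plug-in Wald test is badly anti-conservative,
    while the trend alone would ignore genuinely overdispersed units;
    the clamped estimate restores nominal type-I error at minimal cost
    in power.

    Groups with zero total counts are handled via the pseudocount and
    flagged ``degenerate``.
    """
    if len(ref_cols) < 2 or len(trt_cols) < 2:
        raise ValueError("need >= 2 samples per group for dispersion estimation")
    cols = list(ref_cols) + list(trt_cols)
    mat = counts[cols].to_numpy(dtype=float)
    if (mat < 0).any():
        raise ValueError("counts must be nonnegative")
    if size_factors is None:
        size_factors = median_ratio_size_factors(counts[cols])
    s = np.asarray(size_factors, dtype=float)
    y = mat / s
    i_ref = np.arange(len(ref_cols))
    i_trt = np.arange(len(ref_cols), len(cols))
    inv_s_mean = float((1.0 / s).mean())
    alpha, base_mean = _moment_dispersion(y, [i_ref, i_trt], inv_s_mean, dispersion_floor)
    if moderate_dispersion:
        trend = _trend_dispersion(alpha, base_mean, n_trend_bins)
        alpha = np.clip(alpha, trend, moderation_cap * trend)
    m_ref = y[:, i_ref].mean(axis=1)
    m_trt = y[:, i_trt].mean(axis=1)
    log2fc = np.log2(m_trt + pseudocount) - np.log2(m_ref + pseudocount)
    ln2 = math.log(2.0)

    def var_log2_mean(m_g: np.ndarray, idx: np.ndarray) -> np.ndarray:
        # Var of the normalized group mean under NB, then delta method to log2.
        var = (m_g[:, None] / s[None, idx] + alpha[:, None] * m_g[:, None] ** 2).sum(axis=1)
        var /= len(idx) ** 2
        return var / ((m_g + pseudocount) * ln2) ** 2

    se = np.sqrt(var_log2_mean(m_ref, i_ref) + var_log2_mean(m_trt, i_trt))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / np.where(se > 0, se, 1.0), 0.0)
    p = 2.0 * sps.norm.sf(np.abs(z))
    degenerate = (mat[:, i_ref].sum(axis=1) == 0) | (mat[:, i_trt].sum(axis=1) == 0)
    out = pd.DataFrame({
        "unit_id": counts.index.astype(str),
        "base_mean": base_mean,
        "log2fc": log2fc,
        "p_value": p,
        "q_value": bh_adjust(p),
        "degenerate": degenerate,
    }).reset_index(drop=True)
    return out


@dataclass(frozen=True)
class FisherResult:
    odds_ratio: float
    p_value: float
    extreme: bool = False  # odds ratio hit 0 or infinity


def fisher_exact_2x2(table) -> FisherResult:
    """Conditional two-sided Fisher exact test on a 2x2 table.

    The p-value sums the hypergeometric probabilities of all tables
    with the observed margins whose probability does not exceed that of
    the observed table.  Probabilities are compared as exact integers
    (numerators over the common denominator C(n, c1)), so ties are
    handled without floating-point ambiguity.
    """
    (a, b), (c, d) = [[int(x) for x in row] for row in table]
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be nonnegative")
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if n == 0:
        return FisherResult(odds_ratio=float("nan"), p_value=1.0, extreme=True)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = [math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(lo, hi + 1)]
    obs = weights[a - lo]
    num = sum(w for w in weights if w <= obs)
    p = float(Fraction(num, math.comb(n, c1)))
    if b * c == 0:
        if a * d == 0:
            return FisherResult(odds_ratio=float("nan"), p_value=min(p, 1.0), extreme=True)
        return FisherResult(odds_ratio=float("inf"), p_value=min(p, 1.0), extreme=True)
    return FisherResult(odds_ratio=(a * d) / (b * c), p_value=min(p, 1.0),
                        extreme=(a * d == 0))


@dataclass(frozen=True)
class SignedRankResult:
    statistic: float  # sum of ranks of positive differences
    p_value: float
    n_used: int  # pairs remaining after dropping zero differences
    all_zero: bool = False


def wilcoxon_signed_rank(paired_a, paired_b, exact_below: int = 25) -> SignedRankResult:
    """Paired two-sided Wilcoxon signed-rank test.

    Zero differences are dropped; tied absolute differences receive
    midranks.  Below ``exact_below`` remaining pairs the null
    distribution is enumerated exactly over all sign assignments (a
    convolution over the doubled, hence integral, ranks); from there a
    tie-corrected normal approximation with continuity correction is
    used.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    d = a - b
    d = d[d != 0]
    n = d.size
    if n == 0:
        return SignedRankResult(statistic=0.0, p_value=1.0, n_used=0, all_zero=True)
    ranks = sps.rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())
    mu = ranks.sum() / 2.0
    if n < exact_below:
        # Null distribution of 2W by convolution; midranks double to integers.
        r2 = np.rint(2 * ranks).astype(np.int64)
        dist = np.zeros(int(r2.sum()) + 1)
        dist[0] = 1.0
        for r in r2:
            shifted = np.zeros_like(dist)
            shifted[r:] = dist[: dist.size - r]
            dist = dist + shifted
        dist /= 2.0 ** n
        support = np.arange(dist.size)
        dev = abs(2 * w - 2 * mu)
        p = float(dist[np.abs(support - 2 * mu) >= dev - 1e-9].sum())
    else:
        _, counts = np.unique(ranks, return_counts=True)
        tie_term = ((counts ** 3 - counts).sum()) / 48.0
        sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        z = (abs(w - mu) - 0.5) / math.sqrt(sigma2)
        p = float(2.0 * sps.norm.sf(z))
    return SignedRankResult(statistic=w, p_value=min(p, 1.0), n_used=n)


def zscore_rows(matrix) -> np.ndarray:
    """Row-wise z-score with population standard deviation.

    Constant rows come back as all zeros.
    """
    mat = np.asarray(matrix, dtype=float)
    mean = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, keepdims=True)
    safe = np.where(sd == 0, 1.0, sd)
    out = (mat - mean) / safe
    out[np.broadcast_to(sd == 0, out.shape)] = 0.0
    return out
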