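"""Cohort-level statistics for strategy comparisons.

Friedman tests (with Kendall W concordance effect sizes) compare repeated
measures -- one row per shoulder, one column per implantation strategy --
followed by pairwise Wilcoxon signed-rank tests.  Pearson correlations
with conventional strength bands and univariate R^2 quantify how head size
predicts lateralization and muscle length, and group summaries report
graft thickness by head-size group.  Two-tailed alpha 0.05 throughout.

Strength bands for |r|: 0.1-0.3 weak, 0.3-0.5 moderate, 0.5-0.7 strong,
0.7-0.9 very strong, > 0.9 excellent; boundary values fall to the lower
band.  Kendall W classes: >= 0.1 small, >= 0.3 moderate, >= 0.5 large.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .errors import ValidationError

ALPHA = 0.05


@dataclass
class FriedmanResult:
    chi_square: float
    df: int
    p_value: float
    kendall_w: float
    n: int
    k: int


@dataclass
class PairwiseWilcoxonResult:
    pairs: list                    # (i, j) column index pairs
    p_values: list
    degenerate: list               # flag: all paired differences were zero
    holm_adjusted: Optional[list] = None


@dataclass
class PearsonResult:
    r: float
    r_squared: float
    p_value: float
    strength_band: str
    power: float
    n: int


@dataclass
class GroupSummary:
    group_label: str
    n: int
    median: float
    iqr: tuple                     # (q25, q75), linear-interpolation quantiles


def _check_matrix(matrix: np.ndarray) -> np.ndarray:
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValidationError("need an n x k matrix with n >= 2 subjects and k >= 2 conditions")
    if not np.all(np.isfinite(m)):
        raise ValidationError("matrix contains missing or non-finite cells")
    return m


def friedman_test(matrix: np.ndarray) -> FriedmanResult:
    """Friedman rank test across the k columns of an n x k matrix,
    average-rank tie corrected, chi-square approximation."""
    m = _check_matrix(matrix)
    n, k = m.shape
    chi2, p = stats.friedmanchisquare(*(m[:, j] for j in range(k)))
    return FriedmanResult(chi_square=float(chi2), df=k - 1, p_value=float(p),
                          kendall_w=kendall_w(float(chi2), n, k), n=n, k=k)


def kendall_w(chi_square: float, n: int, k: int) -> float:
    """Kendall's coefficient of concordance from the Friedman statistic:
    W = chi^2 / (n (k - 1))."""
    if n < 2 or k < 2:
        raise ValidationError("need n >= 2 and k >= 2")
    return float(chi_square) / (n * (k - 1))


def kendall_w_from_ranks(matrix: np.ndarray) -> float:
    """W computed directly from within-row ranks (tie-corrected); agrees
    with the chi-square form on tie-free data."""
    m = _check_matrix(matrix)
    n, k = m.shape
    ranks = np.apply_along_axis(stats.rankdata, 1, m)
    col_sums = ranks.sum(axis=0)
    s = float(np.sum((col_sums - n * (k + 1) / 2.0) ** 2))
    tie_term = 0.0
    for row in m:
        _, counts = np.unique(row, return_counts=True)
        tie_term += float(np.sum(counts ** 3 - counts))
    denom = n ** 2 * (k ** 3 - k) - n * tie_term
    if denom <= 0:
        raise ValidationError("degenerate rank matrix (all cells tied)")
    return 12.0 * s / denom


def kendall_w_class(w: float) -> str:
    if w >= 0.5:
        return "large"
    if w >= 0.3:
        return "moderate"
    if w >= 0.1:
        return "small"
    return "negligible"


def pairwise_wilcoxon(matrix: np.ndarray, pairs: Optional[Sequence] = None,
                      holm: bool = False) -> PairwiseWilcoxonResult:
    """Wilcoxon signed-rank p-values for paired columns; zero differences
    dropped, exact null distribution for n <= 25 effective pairs."""
    m = _check_matrix(matrix)
    k = m.shape[1]
    pairs = list(pairs) if pairs is not None else list(combinations(range(k), 2))
    p_values, degenerate = [], []
    for i, j in pairs:
        diffs = m[:, i] - m[:, j]
        nonzero = diffs[diffs != 0]
        if len(nonzero) == 0:
            p_values.append(np.nan)
            degenerate.append(True)
            continue
        method = "exact" if len(nonzero) <= 25 else "approx"
        res = stats.wilcoxon(m[:, i], m[:, j], zero_method="wilcox", method=method)
        p_values.append(float(res.pvalue))
        degenerate.append(False)
    out = PairwiseWilcoxonResult(pairs=pairs, p_values=p_values, degenerate=degenerate)
    if holm:
        finite = [(idx, p) for idx, p in enumerate(p_values) if np.isfinite(p)]
        adj = [np.nan] * len(p_values)
        order = sorted(finite, key=lambda t: t[1])
        running = 0.0
        for rank, (idx, p) in enumerate(order):
            running = max(running, min(1.0, (len(order) - rank) * p))
            adj[idx] = running
        out.holm_adjusted = adj
    return out


def strength_band(r: float) -> str:
    """|r| strength band; boundary values assigned to the lower band."""
    a = abs(r)
    if a > 0.9:
        return "excellent"
    if a > 0.7:
        return "very_strong"
    if a > 0.5:
        return "strong"
    if a > 0.3:
        return "moderate"
    return "weak"


def correlation_power(r: float, n: int, alpha: float = ALPHA) -> float:
    """Post-hoc two-tailed power of the Pearson test at the observed r,
    Fisher-z normal approximation."""
    if n <= 3 or abs(r) >= 1.0:
        return 1.0 if abs(r) >= 1.0 else 0.0
    z = np.arctanh(r) * np.sqrt(n - 3)
    z_crit = stats.norm.ppf(1 - alpha / 2)
    return float(stats.norm.cdf(abs(z) - z_crit) + stats.norm.cdf(-abs(z) - z_crit))


def pearson_with_band(x: np.ndarray, y: np.ndarray) -> PearsonResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValidationError("need paired samples with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("non-finite values in correlation input")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("zero variance in correlation input")
    r, p = stats.pearsonr(x, y)
    r = float(r)
    return PearsonResult(r=r, r_squared=r * r, p_value=float(p),
                         strength_band=strength_band(r),
                         power=correlation_power(r, len(x)), n=len(x))


def hhs_group_summary(central_graft_mm: np.ndarray, osteotomy_hhs_mm: np.ndarray,
                      cut_mm: float = 47.0) -> dict:
    """Median and IQR of central graft thickness for small
    (osteotomy HHS < cut) vs. large (>= cut) head groups."""
    graft = np.asarray(central_graft_mm, dtype=float)
    hhs = np.asarray(osteotomy_hhs_mm, dtype=float)
    if len(graft) != len(hhs) or len(graft) == 0:
        raise ValidationError("graft and HHS arrays must be nonempty and matched")
    out = {}
    for label, mask in (("small", hhs < cut_mm), ("large", hhs >= cut_mm)):
        if not mask.any():
            out[label] = None  # empty group: summary missing
            continue
        vals = graft[mask]
        out[label] = GroupSummary(
            group_label=label, n=int(mask.sum()), median=float(np.median(vals)),
            iqr=(float(np.quantile(vals, 0.25)), float(np.quantile(vals, 0.75))))
    return out
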