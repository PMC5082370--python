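"""Small inferential utilities shared across the analysis.

Thin, explicitly-named wrappers over :mod:`scipy.stats` so that every figure-
or table-level statistic in the package goes through one audited code path:
Pearson/Fisher-z correlations, Spearman rank correlation, the chi-square
survival function used for goodness of fit, and the two-sample
Kolmogorov-Smirnov test used to compare phase distributions.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

__all__ = [
    "CorrelationReport",
    "correlation_report",
    "fisher_z",
    "spearman",
    "chi2_sf",
    "ks_2sample",
]


@dataclass(frozen=True)
class CorrelationReport:
    """Pearson and Spearman association between two cell-level summaries.

    Attributes
    ----------
    r : float
        Pearson correlation coefficient.
    z : float
        Fisher z transform, ``atanh(r)``; approximately normal with
        SE = 1/sqrt(n-3) under bivariate normality.
    r_s : float
        Spearman rank correlation (midranks for ties).
    p_r, p_rs : float
        Two-sided p-values for ``r`` and ``r_s``.
    n : int
        Number of paired observations.
    """

    r: float
    z: float
    r_s: float
    p_r: float
    p_rs: float
    n: int

    @property
    def z_se(self) -> float:
        return 1.0 / math.sqrt(self.n - 3) if self.n > 3 else math.nan


def fisher_z(r: float, n: int | None = None) -> float | tuple[float, float]:
    """Fisher z transform of a correlation coefficient.

    Returns ``atanh(r)``; if the sample size ``n`` is supplied, returns the
    pair ``(z, se)`` with the large-sample standard error ``1/sqrt(n-3)``.
    """
    r = float(r)
    if abs(r) >= 1.0:
        raise ValueError(f"fisher_z requires |r| < 1, got r={r}")
    z = math.atanh(r)
    if n is None:
        return z
    if n <= 3:
        raise ValueError("n must exceed 3 for the Fisher z standard error")
    return z, 1.0 / math.sqrt(n - 3)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    Ties are handled with midranks. For n <= 8 and tie-free data the p-value
    is computed by exact enumeration of rank permutations; otherwise the
    asymptotic t approximation from scipy is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("spearman undefined for a constant input")
    res = _sps.spearmanr(x, y)
    rs = float(res.statistic)
    tie_free = len(set(x)) == n and len(set(y)) == n
    if n <= 8 and tie_free:
        p = _exact_spearman_p(x, y, rs)
    else:
        p = float(res.pvalue)
    return rs, p


def _exact_spearman_p(x, y, rs_obs) -> float:
    rx = _sps.rankdata(x)
    ry = _sps.rankdata(y)
    n = len(rx)
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        rp = ry[list(perm)]
        rs = np.corrcoef(rx, rp)[0, 1]
        total += 1
        if abs(rs) >= abs(rs_obs) - 1e-12:
            count += 1
    return count / total


def chi2_sf(x: float, df: int) -> float:
    """Upper-tail probability of the chi-square distribution."""
    if x < 0:
        raise ValueError("chi-square statistic must be nonnegative")
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(_sps.chi2.sf(x, df))


def ks_2sample(x, y) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov statistic and asymptotic p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 5 or y.size < 5:
        raise ValueError("each sample needs at least 5 values")
    res = _sps.ks_2samp(x, y, method="asymp")
    return float(res.statistic), float(res.pvalue)


def correlation_report(x, y) -> CorrelationReport:
    """Full Pearson + Spearman report for two paired summaries."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    pr = _sps.pearsonr(x, y)
    rs, p_rs = spearman(x, y)
    r = float(pr.statistic)
    return CorrelationReport(
        r=r, z=math.atanh(r), r_s=rs, p_r=float(pr.pvalue), p_rs=p_rs, n=n
    )
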