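"""Agreement and comparison statistics for paired respiration-rate series.

Covers the statistics conventionally reported for method-agreement studies of
per-minute respiration counts:

* Pearson product-moment correlation;
* the two-sample Wilcoxon rank-sum statistic with pooled midranks, the
  tie-corrected normal approximation and a 0.5 continuity correction
  (W = sum of group-A ranks);
* the one-sample Wilcoxon signed-rank test on paired differences (exact
  enumeration for small n, tie-corrected normal approximation otherwise);
* Bland–Altman bias and 95% limits of agreement (mean ± 1.96 sample SD of
  the differences);
* five-number summaries with 1.5·IQR whiskers (the numbers behind skeletal
  box plots).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations, product

import numpy as np
from scipy import stats as sstats

from .errors import DataError, DegeneracyError

__all__ = [
    "RRComparison",
    "RankSumResult",
    "BlandAltmanResult",
    "pearson_r",
    "rank_sum",
    "signed_rank",
    "bland_altman",
    "five_number",
]


@dataclass
class RRComparison:
    """Paired per-subject breaths/min from two methods (b - a differences)."""

    labels: list
    rr_a: np.ndarray
    rr_b: np.ndarray

    def __post_init__(self) -> None:
        self.rr_a = np.asarray(self.rr_a, dtype=float)
        self.rr_b = np.asarray(self.rr_b, dtype=float)
        if self.rr_a.size != self.rr_b.size or len(self.labels) != self.rr_a.size:
            raise DataError("labels, rr_a and rr_b must have equal lengths")
        if self.rr_a.size < 2:
            raise DataError("need at least 2 paired observations")

    @property
    def differences(self) -> np.ndarray:
        return self.rr_b - self.rr_a

    @property
    def n(self) -> int:
        return self.rr_a.size


@dataclass
class RankSumResult:
    """W (midrank sum of group A), tie-corrected z, two-sided p."""

    W: float
    z: float
    p: float


@dataclass
class BlandAltmanResult:
    """Bias and 95% limits of agreement of paired differences."""

    mean_diff: float
    sd_diff: float
    loa_lo: float
    loa_hi: float


def pearson_r(a, b) -> float:
    """Product-moment correlation; errors on zero variance."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise DataError("inputs must have equal lengths")
    if a.size < 3:
        raise DataError("need at least 3 observations")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise DegeneracyError("correlation undefined for constant input")
    return float(np.corrcoef(a, b)[0, 1])


def rank_sum(a, b, continuity: bool = True, method: str = "auto") -> RankSumResult:
    """Two-sample Wilcoxon rank-sum test with midranks and tie correction.

    W is the sum of the pooled midranks of group ``a``.  The normal deviate
    uses the tie-corrected variance

        var = n_a n_b / 12 * (N + 1 - sum(t^3 - t) / (N (N - 1)))

    and, when ``continuity`` is set, a 0.5 correction toward the null mean
    n_a (N + 1) / 2.  p is two-sided.

    ``method``: ``"normal"`` always uses the approximation; ``"exact"``
    enumerates all group-A subsets; ``"auto"`` (default) uses the exact
    distribution for small untied samples (N <= 12), as is conventional —
    at those sizes the normal tail approximation can be off by several
    hundredths.  z is always reported on the normal scale.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DataError("each group needs at least 2 observations")
    if method not in ("auto", "exact", "normal"):
        raise DataError(f"unknown method {method!r}")
    n_a, n_b = a.size, b.size
    N = n_a + n_b
    pooled = np.concatenate([a, b])
    ranks = sstats.rankdata(pooled)
    W = float(ranks[:n_a].sum())
    mu = n_a * (N + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie = float(np.sum(counts**3 - counts))
    var = n_a * n_b / 12.0 * ((N + 1) - tie / (N * (N - 1)))
    if var <= 0:
        return RankSumResult(W=W, z=0.0, p=1.0)
    cc = 0.5 if continuity else 0.0
    delta = W - mu
    if delta > 0:
        z = (delta - cc) / math.sqrt(var)
    elif delta < 0:
        z = (delta + cc) / math.sqrt(var)
    else:
        z = 0.0

    exact = method == "exact" or (method == "auto" and N <= 12 and tie == 0)
    if exact:
        obs = abs(W - mu)
        Ws = np.fromiter(
            (sum(c) for c in combinations(ranks, n_a)), dtype=float
        )
        p = float(np.mean(np.abs(Ws - mu) >= obs - 1e-12))
    else:
        p = min(1.0, 2.0 * sstats.norm.sf(abs(z)))
    return RankSumResult(W=W, z=float(z), p=float(p))


def signed_rank(
    paired_a, paired_b, method: str = "auto", continuity: bool = True
) -> RankSumResult:
    """Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped; |d| receives midranks; W is the sum of
    ranks of positive differences.  ``method='exact'`` enumerates all 2^n
    sign assignments (default for n <= 12), otherwise the tie-corrected
    normal approximation with continuity correction is used.

    Raises
    ------
    DegeneracyError
        If every difference is zero.
    """
    d = np.asarray(paired_a, dtype=float) - np.asarray(paired_b, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        raise DegeneracyError("all paired differences are zero")
    n = d.size
    r = sstats.rankdata(np.abs(d))
    W = float(r[d > 0].sum())
    mu = n * (n + 1) / 4.0

    if method not in ("auto", "exact", "normal"):
        raise DataError(f"unknown method {method!r}")
    exact = method == "exact" or (method == "auto" and n <= 12)
    if exact:
        # Enumerate every sign pattern on the observed midranks; two-sided p
        # by symmetry of |W - mu| under the null.
        obs = abs(W - mu)
        count = 0
        for signs in product((0.0, 1.0), repeat=n):
            w = float(np.dot(signs, r))
            if abs(w - mu) >= obs - 1e-12:
                count += 1
        p = count / 2.0**n
        # Report z on the same normal scale for consistency.
        var = n * (n + 1) * (2 * n + 1) / 24.0
        z = 0.0 if var == 0 else (W - mu) / math.sqrt(var)
        return RankSumResult(W=W, z=float(z), p=float(min(p, 1.0)))

    _, counts = np.unique(np.abs(d), return_counts=True)
    tie = float(np.sum(counts**3 - counts))
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie / 48.0
    if var <= 0:
        return RankSumResult(W=W, z=0.0, p=1.0)
    cc = 0.5 if continuity else 0.0
    delta = W - mu
    if delta > 0:
        z = (delta - cc) / math.sqrt(var)
    elif delta < 0:
        z = (delta + cc) / math.sqrt(var)
    else:
        z = 0.0
    p = min(1.0, 2.0 * sstats.norm.sf(abs(z)))
    return RankSumResult(W=W, z=float(z), p=float(p))


def bland_altman(cmp: RRComparison) -> BlandAltmanResult:
    """Bias (mean of b - a) and 95% limits of agreement (±1.96 sample SD)."""
    d = cmp.differences
    if d.size < 2:
        raise DataError("Bland-Altman needs at least 2 pairs")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        mean_diff=mean,
        sd_diff=sd,
        loa_lo=mean - 1.96 * sd,
        loa_hi=mean + 1.96 * sd,
    )


def five_number(values) -> tuple[float, float, float, float, float]:
    """(lower whisker, Q1, median, Q3, upper whisker) with 1.5·IQR fences.

    Quartiles use linear interpolation; whiskers are the most extreme data
    points within 1.5·IQR of the nearer quartile (outliers excluded).
    """
    v = np.sort(np.asarray(values, dtype=float))
    if v.size < 5:
        raise DataError("five-number summary needs at least 5 values")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    return float(inside[0]), float(q1), float(med), float(q3), float(inside[-1])
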