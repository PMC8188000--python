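"""Statistical comparison of virtual and observed samples.

Mann-Whitney / Wilcoxon rank-sum for two independent samples (the test used
to compare virtual and wild pairwise home-range overlaps), plus the summary
statistics reported alongside distribution plots: n, mean, median,
inter-quartile range and the sign of skewness.

Conventions, fixed and documented because they cannot be recovered from a
printed statistic alone:

* ``W`` is reported in the smaller-rank-sum convention: the lesser of the
  two samples' rank sums (midranks for ties);
* the p-value is exact (enumeration over rank arrangements) when
  ``m + n <= 20`` and there are no ties, otherwise the normal approximation
  with tie correction and continuity correction;
* quartiles use linear interpolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class MannWhitneyResult:
    W: float  # smaller rank sum
    U: float  # smaller of the two U statistics
    p_value: float
    method: str  # "exact" or "asymptotic"
    n_a: int
    n_b: int


@dataclass
class SummaryStats:
    n: int
    mean: float
    median: float
    iqr: float
    skew_sign: int  # sign of (mean - median): +1 right-skew, -1 left, 0 symmetric


def mann_whitney(sample_a, sample_b) -> MannWhitneyResult:
    """Two-tailed Mann-Whitney U test of two independent samples.

    Returns the smaller rank sum W, the smaller U, and the two-tailed
    p-value (exact for small untied samples, normal approximation with tie
    and continuity corrections otherwise).  Identical constant samples give
    p = 1 with a warning.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)  # midranks
    r_a = float(ranks[: a.size].sum())
    r_b = float(ranks[a.size :].sum())
    u_a = r_a - a.size * (a.size + 1) / 2.0
    u_b = r_b - b.size * (b.size + 1) / 2.0
    has_ties = np.unique(pooled).size < pooled.size
    if np.ptp(pooled) == 0:
        warnings.warn("all values identical in both samples; p = 1", stacklevel=2)
        return MannWhitneyResult(min(r_a, r_b), min(u_a, u_b), 1.0, "degenerate", a.size, b.size)
    small = a.size + b.size <= 20 and not has_ties
    method = "exact" if small else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    return MannWhitneyResult(
        W=min(r_a, r_b),
        U=float(min(u_a, u_b)),
        p_value=float(min(res.pvalue, 1.0)),
        method=method,
        n_a=int(a.size),
        n_b=int(b.size),
    )


def permutation_pvalue(sample_a, sample_b, n_perm: int = 10_000, seed: int = 0) -> float:
    """Two-tailed permutation p-value on the rank-sum statistic (cross-check)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    mu = a.size * (pooled.size + 1) / 2.0
    observed = abs(ranks[: a.size].sum() - mu)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(ranks)
        if abs(perm[: a.size].sum() - mu) >= observed - 1e-12:
            count += 1
    return (count + 1) / (n_perm + 1)


def summarize(values) -> SummaryStats:
    """n, mean, median, IQR (linear-interpolation quartiles) and skewness sign."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot summarize an empty sample")
    q1, q3 = np.percentile(v, [25, 75])
    mean = float(v.mean())
    median = float(np.median(v))
    return SummaryStats(
        n=int(v.size),
        mean=mean,
        median=median,
        iqr=float(q3 - q1),
        skew_sign=int(np.sign(round(mean - median, 12))),
    )
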