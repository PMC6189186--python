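"""Formula-level inferential statistics used in the cohort analysis.

Wilson score intervals for small-count proportions, the classical
two-proportion sample-size formula, Fisher's exact test by hypergeometric
enumeration, the chi-square rate comparison with Yates continuity
correction, the normal-approximation VAF confidence interval, and a
two-group VAF comparison.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "ProportionCI",
    "wilson_interval",
    "required_sample_size",
    "fisher_exact_2x2",
    "chi2_yates_rate_comparison",
    "vaf_confidence_interval",
    "compare_vaf_groups",
]


@dataclass(frozen=True)
class ProportionCI:
    k: int
    n: int
    level: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.lower <= self.k / self.n <= self.upper <= 1.0):
            raise ValueError("interval does not bracket the point estimate")


def wilson_interval(k: int, n: int, level: float = 0.95) -> ProportionCI:
    """Wilson score interval for a binomial proportion.

    Well-behaved at small counts (k = 0 gives a zero lower bound rather than
    a degenerate interval).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0 <= k <= n):
        raise ValueError("k must be in [0, n]")
    lower, upper = proportion_confint(k, n, alpha=1.0 - level, method="wilson")
    return ProportionCI(k=k, n=n, level=level,
                        lower=float(lower), upper=float(upper))


def required_sample_size(p_a: float, p_b: float, k: float = 1.0,
                         alpha: float = 0.05, power: float = 0.90,
                         ) -> tuple[int, int]:
    """Two-proportion sample sizes for a case:control matching ratio ``k``.

    ``n_B = (p_A(1-p_A)/k + p_B(1-p_B)) * ((z_{1-a/2} + z_{1-b}) / (p_A - p_B))**2``
    rounded up, with ``n_A = k * n_B``.  Returns ``(n_A, n_B)``.
    """
    if not (0.0 < p_b < p_a < 1.0):
        raise ValueError("need 0 < p_B < p_A < 1")
    if k <= 0:
        raise ValueError("matching ratio k must be positive")
    z_a = stats.norm.ppf(1.0 - alpha / 2.0)
    z_b = stats.norm.ppf(power)
    n_b = ((p_a * (1.0 - p_a) / k + p_b * (1.0 - p_b))
           * ((z_a + z_b) / (p_a - p_b)) ** 2)
    n_b = math.ceil(n_b - 1e-9)
    n_a = math.ceil(k * n_b - 1e-9)
    return n_a, n_b


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table ``[[a, b], [c, d]]``.

    Enumerates all tables with the observed margins under the hypergeometric
    null and sums the probabilities of tables no more likely than the
    observed one (the minimum-likelihood two-sided rule).
    """
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValueError("cell counts must be nonnegative integers")
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    dist = stats.hypergeom(n, row1, col1)
    support = np.arange(max(0, col1 - (c + d)), min(row1, col1) + 1)
    probs = dist.pmf(support)
    total = float(np.sum(probs))
    if abs(total - 1.0) > 1e-9:
        raise AssertionError("hypergeometric enumeration does not sum to 1")
    p_obs = float(dist.pmf(a))
    # tolerance guards ties against floating-point noise
    p = float(np.sum(probs[probs <= p_obs * (1.0 + 1e-9)]))
    return min(p, 1.0)


def chi2_yates_rate_comparison(k1: int, l1: int, k2: int, l2: int) -> float:
    """Chi-square test (1 df, Yates-corrected) for equal per-base mutation rates.

    Compares ``k1`` events over ``l1`` bases with ``k2`` over ``l2`` as the
    2x2 table of mutated vs non-mutated bases.  Warns when an expected cell
    falls below 1.
    """
    if l1 <= 0 or l2 <= 0:
        raise ValueError("base counts must be positive")
    table = np.array([[k1, l1 - k1], [k2, l2 - k2]], dtype=float)
    if np.any(table < 0):
        raise ValueError("event counts cannot exceed base counts")
    res = stats.chi2_contingency(table, correction=True)
    if np.any(res.expected_freq < 1.0):
        warnings.warn("expected cell count < 1; chi-square approximation is "
                      "unreliable", stacklevel=2)
    return float(res.pvalue)


def vaf_confidence_interval(n_total_reads: int, n_alt_reads: int,
                            level: float = 0.95) -> tuple[float, float]:
    """Normal-approximation confidence interval for an observed VAF.

    ``(1/n) * (n_s +- z * sqrt(n_s * n_f / n))`` with ``n_s`` variant reads
    and ``n_f`` reference reads, algebraically the Wald binomial interval on
    ``n_s / n``; the lower bound is clipped at 0.
    """
    n = n_total_reads
    if n < 1:
        raise ValueError("n_total_reads must be >= 1")
    if not (0 <= n_alt_reads <= n):
        raise ValueError("n_alt_reads must be in [0, n_total_reads]")
    z = stats.norm.ppf(0.5 + level / 2.0)
    n_s = n_alt_reads
    n_f = n - n_s
    half = z * math.sqrt(n_s * n_f / n)
    return (max(0.0, (n_s - half) / n), (n_s + half) / n)


def _logit(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 1e-6, 1.0 - 1e-6)
    return np.log(x / (1.0 - x))


def compare_vaf_groups(vafs_a, vafs_b, method: str = "welch-logit",
                       ) -> dict[str, float | str]:
    """Compare VAF distributions of two variant groups.

    Default is a Welch t-test on logit-transformed VAFs (the logit
    stabilises proportions near 0); ``method='mannwhitney'`` gives the
    rank-based alternative.  Returns the p-value, group means and the method
    used.
    """
    a = np.asarray(vafs_a, dtype=float)
    b = np.asarray(vafs_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 values per group")
    if method == "welch-logit":
        res = stats.ttest_ind(_logit(a), _logit(b), equal_var=False)
        p = float(res.pvalue)
    elif method == "mannwhitney":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        p = float(res.pvalue)
    else:
        raise ValueError(f"unknown method {method!r}")
    return {
        "p_value": p,
        "mean_a": float(np.mean(a)),
        "mean_b": float(np.mean(b)),
        "method": method,
    }
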