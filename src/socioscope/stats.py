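"""Shared statistics: coefficient of variation and permutation-test results."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


def coefficient_of_variation(values, ddof: int = 1) -> float:
    """Standard deviation divided by the mean (sample sd by default).

    Returns NaN (with a warning) when fewer than two values are supplied or
    the mean is not positive, since the CV is undefined there.
    """
    v = np.asarray(list(values), dtype=float)
    if v.size < 2:
        warnings.warn("CV undefined for fewer than two values", stacklevel=2)
        return float("nan")
    m = v.mean()
    if m <= 0:
        warnings.warn("CV undefined for non-positive mean", stacklevel=2)
        return float("nan")
    return float(v.std(ddof=ddof) / m)


@dataclass
class PermutationResult:
    """Outcome of a resampling null-model test.

    ``p_value`` follows the count-over-n convention: the fraction of null
    values at least as extreme as the observed statistic in the stated tail
    (ties count toward the tail).  For two-sided percentile tests the
    decision uses the 0.025/0.975 percentiles of the null; ``significant``
    is then "greater", "less", or None, with ties resolved conservatively.
    """

    observed: float
    null_values: np.ndarray
    p_value: float
    n_perm: int
    seed: int | None
    tail: str = "upper"
    method: str = ""
    statistic: str = ""
    significant: str | None = None
    lower_cut: float | None = None
    upper_cut: float | None = None
    extras: dict = field(default_factory=dict)

    @property
    def prop_greater(self) -> float:
        return float(np.mean(self.null_values > self.observed))

    @property
    def prop_less(self) -> float:
        return float(np.mean(self.null_values < self.observed))


def upper_tail_p(observed: float, null_values: np.ndarray,
                 convention: str = "count_over_n") -> float:
    """Fraction of null values >= observed (ties count toward the tail).

    ``convention="plus_one"`` uses (count+1)/(n+1), which cannot return 0.
    """
    count = int(np.sum(null_values >= observed))
    n = len(null_values)
    if convention == "plus_one":
        return (count + 1) / (n + 1)
    return count / n


def two_sided_percentile_decision(observed: float, null_values: np.ndarray,
                                  alpha: float = 0.05):
    """Two-tailed percentile rule: significant-greater above the 1-alpha/2
    percentile of the null, significant-less below the alpha/2 percentile;
    exact ties with a cutoff are non-significant.

    Cutoffs are the k-th extreme order statistics of the null with
    k = floor(alpha/2 * (n+1)), the exact permutation construction: for an
    observed value exchangeable with the n null values, each tail rejects
    with probability k/(n+1) <= alpha/2 (with equality for continuous
    statistics), independent of n.  Interpolated quantiles round outward
    for discrete statistics (e.g. diversity counts) and would make the rule
    needlessly conservative.
    """
    n = len(null_values)
    k = max(1, int(np.floor(alpha / 2 * (n + 1))))
    snull = np.sort(null_values)
    lower = float(snull[k - 1])
    upper = float(snull[n - k])
    if observed > upper:
        sig = "greater"
    elif observed < lower:
        sig = "less"
    else:
        sig = None
    return sig, lower, upper
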