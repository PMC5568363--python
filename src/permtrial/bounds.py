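"""Berry-Esseen machinery: bounds on the Kolmogorov-Smirnov distance
between standardized arm means and the standard normal, p-value
uncertainty intervals, guaranteed-digit and minimal-n calculators, and
Monte-Carlo KS-distance verification.

The iid bound is ``be_constant * C / sqrt(n)`` with default constant 0.5;
the two-arm combined error is the sum of the per-arm bounds (the KS
distance is sub-additive under convolution with an independent summand, so
the sum is a valid upper bound for the error of the difference statistic).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .distributions import ConfigurationError, ResponseDistribution, moment_ratio

__all__ = [
    "BerryEsseenBound",
    "PValueInterval",
    "berry_esseen_epsilon",
    "bound_for_arms",
    "combined_pvalue_uncertainty",
    "min_n_for_tolerance",
    "guaranteed_decimal_digits",
    "generalized_be_epsilon",
    "empirical_ks_distance",
]

DEFAULT_BE_CONSTANT = 0.5
# the non-iid (generalized) constant is not printed in the source material;
# 0.56 is the best published value for the non-identically-distributed case
DEFAULT_GENERALIZED_CONSTANT = 0.56


def berry_esseen_epsilon(n: int, C: float, be_constant: float = DEFAULT_BE_CONSTANT) -> float:
    """KS-distance bound ``be_constant * C / sqrt(n)`` for an iid mean."""
    if n < 1:
        raise ConfigurationError("sample size n must be >= 1")
    if C < 1.0:
        raise ConfigurationError(
            f"moment ratio C = {C} is impossible: C >= 1 for every distribution"
        )
    if be_constant <= 0:
        raise ConfigurationError("Berry-Esseen constant must be > 0")
    return be_constant * C / math.sqrt(n)


@dataclass
class BerryEsseenBound:
    """Per-arm KS bounds and their combined (summed) value."""

    per_arm: List[dict]
    be_constant: float = DEFAULT_BE_CONSTANT
    generalized: bool = False
    combined_epsilon: float = field(init=False)

    def __post_init__(self) -> None:
        self.combined_epsilon = float(sum(a["epsilon"] for a in self.per_arm))


def bound_for_arms(
    n1: int, n0: int, C1: float, C0: float, be_constant: float = DEFAULT_BE_CONSTANT
) -> BerryEsseenBound:
    return BerryEsseenBound(
        per_arm=[
            {"arm": 1, "n": n1, "C": C1, "epsilon": berry_esseen_epsilon(n1, C1, be_constant)},
            {"arm": 0, "n": n0, "C": C0, "epsilon": berry_esseen_epsilon(n0, C0, be_constant)},
        ],
        be_constant=be_constant,
    )


@dataclass
class PValueInterval:
    """Uncertainty interval around a nominal parametric p-value."""

    p_nominal: float
    p_lo: float
    p_hi: float
    threshold: Optional[float] = None
    significance_guaranteed: Optional[bool] = None


def combined_pvalue_uncertainty(
    p: float, bounds: BerryEsseenBound, threshold: Optional[float] = 0.05
) -> PValueInterval:
    """Interval ``p +/- combined_epsilon`` clipped to [0, 1].

    When a significance threshold is given, the interval is checked against
    it: significance is guaranteed only if ``p_hi`` stays below the
    threshold.
    """
    if not 0.0 <= p <= 1.0:
        raise ConfigurationError("p must lie in [0, 1]")
    eps = bounds.combined_epsilon
    lo = max(0.0, p - eps)
    hi = min(1.0, p + eps)
    guaranteed = None
    if threshold is not None:
        guaranteed = bool(hi <= threshold)
    return PValueInterval(
        p_nominal=p, p_lo=lo, p_hi=hi, threshold=threshold, significance_guaranteed=guaranteed
    )


def _combined_epsilon_at(n: int, C1: float, C0: float, be_constant: float) -> float:
    return berry_esseen_epsilon(n, C1, be_constant) + berry_esseen_epsilon(n, C0, be_constant)


def min_n_for_tolerance(
    tolerance: float, C1: float = 1.0, C0: float = 1.0,
    be_constant: float = DEFAULT_BE_CONSTANT,
) -> int:
    """Smallest equal per-arm n with combined KS error <= tolerance.

    Exact by construction: the bound holds at the returned n and fails at
    n - 1 (unless n = 1 already satisfies it).
    """
    if tolerance <= 0.0 or tolerance > 1.0:
        raise ConfigurationError("tolerance must lie in (0, 1]")
    if _combined_epsilon_at(1, C1, C0, be_constant) <= tolerance:
        return 1
    # combined epsilon = be_constant*(C1+C0)/sqrt(n) <= tol
    n = math.ceil((be_constant * (C1 + C0) / tolerance) ** 2)
    while n > 1 and _combined_epsilon_at(n - 1, C1, C0, be_constant) <= tolerance:
        n -= 1
    while _combined_epsilon_at(n, C1, C0, be_constant) > tolerance:
        n += 1
    return n


def guaranteed_decimal_digits(
    n1: int, n0: int, C1: float = 1.0, C0: float = 1.0,
    be_constant: float = DEFAULT_BE_CONSTANT,
) -> dict:
    """Largest k with combined error <= 0.5 * 10^-k (half-ulp rounding
    correctness of the k-th decimal digit of the p-value)."""
    eps = berry_esseen_epsilon(n1, C1, be_constant) + berry_esseen_epsilon(n0, C0, be_constant)
    k = 0
    while eps <= 0.5 * 10.0 ** (-(k + 1)):
        k += 1
    return {
        "digits": k,
        "combined_epsilon": eps,
        "criterion": f"combined_epsilon <= 0.5e-{k} (rounding-correct k-th decimal)",
    }


def generalized_be_epsilon(
    summand_moments: Sequence[dict], constant: float = DEFAULT_GENERALIZED_CONSTANT
) -> float:
    """Non-identically-distributed independent-summand bound:
    ``constant * sum(rho3) / sum(sigma2)^(3/2)``.

    Reduces to the iid formula ``constant * C / sqrt(n)`` when all summands
    are identical.
    """
    if len(summand_moments) == 0:
        raise ConfigurationError("need at least one summand")
    sigma2 = np.array([m["sigma2"] for m in summand_moments], dtype=float)
    rho3 = np.array([m["rho3"] for m in summand_moments], dtype=float)
    if np.any(sigma2 <= 0):
        raise ConfigurationError("every summand needs sigma2 > 0")
    if not np.all(np.isfinite(rho3)):
        raise ConfigurationError("third absolute central moments must be finite")
    return float(constant * rho3.sum() / sigma2.sum() ** 1.5)


def empirical_ks_distance(
    dist: ResponseDistribution,
    n: int,
    reps: int,
    seed,
    chunk: int = 20_000_000,
) -> float:
    """Monte-Carlo KS distance between the standardized n-sample mean and
    the standard normal.

    Draws ``reps`` independent means of ``n`` samples, standardizes by the
    true mean and SD, and returns the sup-distance of the empirical CDF
    from the standard normal CDF.
    """
    if reps < 1000:
        raise ConfigurationError("reps must be >= 1000 for a usable estimate")
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    if dist.is_degenerate():
        raise ConfigurationError("KS distance undefined for a degenerate distribution")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    mu = dist.mean()
    sd = dist.std()
    zs = np.empty(reps, dtype=float)
    rows_per_chunk = max(1, chunk // max(n, 1))
    done = 0
    while done < reps:
        take = min(rows_per_chunk, reps - done)
        draws = dist.sample(rng, (take, n))
        zs[done : done + take] = (draws.mean(axis=1) - mu) * math.sqrt(n) / sd
        done += take
    return float(stats.kstest(zs, "norm").statistic)
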