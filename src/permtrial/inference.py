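"""P-values four ways: parametric tail, exact permutation, Monte-Carlo
permutation, and the permutation-averaged parametric p-value.

All permutation methods operate under the strong null: each subject's
observed response is held fixed across every re-allocation, and the test
statistic is recomputed for each admissible allocation of the randomization
scheme actually used.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .distributions import ConfigurationError
from .engine import (
    DEFAULT_ENUMERATION_LIMIT,
    AllocationEnsemble,
    TrialDesign,
    TrialResult,
    _rng,
    _unit_index,
    count_allocations,
    enumerate_allocations,
    sample_label_matrix,
)
from .population import Cohort

__all__ = [
    "PValueReport",
    "parametric_pvalue",
    "permutation_pvalue",
    "perm_averaged_parametric_pvalue",
]

_SIDES = {"right", "left", "two-sided"}
_TIE_TOL = 1e-12


@dataclass
class PValueReport:
    """One inference result.

    ``uncertainty`` is an optional ``(p_lo, p_hi)`` Berry-Esseen interval
    attached by the bounds module; ``fallback`` flags an exact request that
    exceeded the enumeration limit and was answered by Monte Carlo.
    """

    method: str
    statistic: str
    statistic_value: float
    sidedness: str
    p: float
    n_allocations_used: int = 0
    exact: bool = False
    total_allocations: Optional[int] = None
    n_extreme: Optional[int] = None
    n_degenerate: int = 0
    fallback: bool = False
    uncertainty: Optional[Tuple[float, float]] = None

    def to_frame(self) -> pd.DataFrame:
        d = {
            "method": self.method,
            "statistic": self.statistic,
            "statistic_value": self.statistic_value,
            "sidedness": self.sidedness,
            "p": self.p,
            "n_allocations_used": self.n_allocations_used,
            "exact": self.exact,
            "total_allocations": self.total_allocations,
            "n_extreme": self.n_extreme,
            "n_degenerate": self.n_degenerate,
            "fallback": self.fallback,
            "p_lo": self.uncertainty[0] if self.uncertainty else None,
            "p_hi": self.uncertainty[1] if self.uncertainty else None,
        }
        return pd.DataFrame([d])


def parametric_pvalue(z: Optional[float], sidedness: str = "two-sided") -> float:
    """Standard-normal tail probability of the normalized difference."""
    if z is None or not np.isfinite(z):
        raise ConfigurationError(
            "z is unavailable (degenerate arm); use a permutation method instead"
        )
    if sidedness not in _SIDES:
        raise ConfigurationError(f"sidedness must be one of {sorted(_SIDES)}")
    if sidedness == "right":
        return float(stats.norm.sf(z))
    if sidedness == "left":
        return float(stats.norm.cdf(z))
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def _matrix_stats(y: np.ndarray, labels: np.ndarray, statistic: str) -> np.ndarray:
    """Vectorized delta or z for each allocation row in ``labels``.

    Rows whose z is undefined (an arm with < 2 subjects or zero variance)
    come back as NaN.
    """
    labels = labels.astype(np.float64)
    n = y.size
    n1 = labels.sum(axis=1)
    n0 = n - n1
    with np.errstate(divide="ignore", invalid="ignore"):
        sum1 = labels @ y
        total = y.sum()
        a1 = sum1 / n1
        a0 = (total - sum1) / n0
        delta = a1 - a0
        if statistic == "delta":
            delta[(n1 == 0) | (n0 == 0)] = np.nan
            return delta
        sq1 = labels @ (y * y)
        sq_total = float((y * y).sum())
        var1 = (sq1 - n1 * a1**2) / (n1 - 1)
        var0 = ((sq_total - sq1) - n0 * a0**2) / (n0 - 1)
        var1 = np.clip(var1, 0.0, None)
        var0 = np.clip(var0, 0.0, None)
        se = np.sqrt(var1 / n1 + var0 / n0)
        z = delta / se
    bad = (n1 < 2) | (n0 < 2) | (se <= 0) | ~np.isfinite(z)
    z[bad] = np.nan
    return z


def _null_cohort(trial: TrialResult) -> Cohort:
    """The strong-null cohort: observed responses fixed regardless of arm."""
    return Cohort(
        subject_id=trial.subject_id,
        cluster_id=trial.cluster_id,
        category=np.zeros(trial.subject_id.size, dtype=object),
        y0=trial.observed,
        y1=trial.observed,
    )


def _extreme_mask(values: np.ndarray, observed: float, sidedness: str, rule: str) -> np.ndarray:
    tol = _TIE_TOL * (1.0 + abs(observed))
    if sidedness == "right":
        return values >= observed - tol
    if sidedness == "left":
        return values <= observed + tol
    if rule == "absolute":
        return np.abs(values) >= abs(observed) - tol
    raise ConfigurationError(f"unknown two-sided rule {rule!r}")


def permutation_pvalue(
    trial: TrialResult,
    design: TrialDesign,
    mode: str = "exact",
    m: int = 9999,
    seed=None,
    statistic: str = "delta",
    sidedness: str = "two-sided",
    two_sided_rule: str = "absolute",
    limit: int = DEFAULT_ENUMERATION_LIMIT,
) -> PValueReport:
    """Randomization p-value under the strong null.

    Exact mode counts allocations whose statistic is at least as extreme as
    the observed one (ties count as extreme) over every admissible
    allocation; when their number exceeds ``limit`` the call falls back to
    Monte Carlo with ``m`` draws and sets the ``fallback`` flag. Monte-Carlo
    mode uses the add-one estimator p = (b + 1)/(m + 1), which can never be
    zero and keeps the test valid.
    """
    if sidedness not in _SIDES:
        raise ConfigurationError(f"sidedness must be one of {sorted(_SIDES)}")
    if statistic not in {"delta", "z"}:
        raise ConfigurationError("statistic must be 'delta' or 'z'")
    if mode not in {"exact", "mc"}:
        raise ConfigurationError("mode must be 'exact' or 'mc'")
    if mode == "mc" and m < 1:
        raise ConfigurationError("Monte-Carlo permutation needs m >= 1 draws")

    cohort = _null_cohort(trial)
    y = trial.observed.astype(np.float64)
    unit_index, n_units = _unit_index(cohort, design)
    total = count_allocations(design, n_units)

    fallback = False
    if mode == "exact" and total > limit:
        mode = "mc"
        fallback = True

    if mode == "exact":
        ensemble = enumerate_allocations(cohort, design, limit=limit, seed=seed)
        labels = ensemble.subject_matrix()
    else:
        rng = _rng(seed)
        unit_labels = sample_label_matrix(
            n_units, m, design.allocation_scheme, design.block_length, rng
        )
        labels = unit_labels[:, unit_index]

    values = _matrix_stats(y, labels, statistic)
    obs_row = trial.arms.astype(np.int8)[None, :]
    observed = float(_matrix_stats(y, obs_row, statistic)[0])
    if not np.isfinite(observed):
        raise ConfigurationError(
            "observed statistic is undefined (degenerate arm); use statistic='delta'"
        )

    finite = np.isfinite(values)
    n_degenerate = int((~finite).sum())
    extreme = _extreme_mask(values[finite], observed, sidedness, two_sided_rule)
    b = int(extreme.sum())
    used = int(finite.sum())

    if mode == "exact":
        if used == 0:
            raise ConfigurationError("no allocation yields a defined statistic")
        p = b / used
    else:
        p = (b + 1) / (used + 1)

    return PValueReport(
        method="permutation-exact" if mode == "exact" else "permutation-mc",
        statistic=statistic,
        statistic_value=observed,
        sidedness=sidedness,
        p=float(p),
        n_allocations_used=used,
        exact=(mode == "exact"),
        total_allocations=total,
        n_extreme=b,
        n_degenerate=n_degenerate,
        fallback=fallback,
    )


def perm_averaged_parametric_pvalue(
    trial: TrialResult,
    design: TrialDesign,
    limit: int = DEFAULT_ENUMERATION_LIMIT,
    seed=None,
    sidedness: str = "two-sided",
    degenerate: str = "drop",
) -> PValueReport:
    """Average of parametric p-values over all admissible allocations.

    Each subject's observed response is held fixed; every enumerated (or,
    beyond ``limit``, sampled) allocation contributes the standard-normal
    tail probability of its own normalized difference. Allocations with a
    degenerate arm are dropped by default (``degenerate='impute-one'``
    counts them as p = 1 instead).
    """
    if sidedness not in _SIDES:
        raise ConfigurationError(f"sidedness must be one of {sorted(_SIDES)}")
    if degenerate not in {"drop", "impute-one"}:
        raise ConfigurationError("degenerate must be 'drop' or 'impute-one'")
    cohort = _null_cohort(trial)
    y = trial.observed.astype(np.float64)
    ensemble = enumerate_allocations(cohort, design, limit=limit, seed=seed)
    z = _matrix_stats(y, ensemble.subject_matrix(), "z")
    finite = np.isfinite(z)
    n_degenerate = int((~finite).sum())
    if not finite.any():
        raise ConfigurationError(
            "every allocation has a degenerate arm; the averaged parametric "
            "p-value is undefined (responses are constant)"
        )
    zf = z[finite]
    if sidedness == "right":
        ps = stats.norm.sf(zf)
    elif sidedness == "left":
        ps = stats.norm.cdf(zf)
    else:
        ps = np.minimum(1.0, 2.0 * stats.norm.sf(np.abs(zf)))
    if degenerate == "impute-one":
        p = float((ps.sum() + n_degenerate) / z.size)
        used = int(z.size)
    else:
        p = float(ps.mean())
        used = int(zf.size)
    obs = trial.z if trial.z_available else trial.delta
    return PValueReport(
        method="perm-averaged-parametric",
        statistic="z",
        statistic_value=float(obs),
        sidedness=sidedness,
        p=p,
        n_allocations_used=used,
        exact=ensemble.exact,
        total_allocations=ensemble.total_count,
        n_degenerate=n_degenerate,
    )
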