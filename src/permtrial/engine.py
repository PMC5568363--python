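"""Two-arm trial mechanics: randomization schemes, sample-size regimes,
outcome realization and enumeration of admissible allocations.

Allocations are represented as 0/1 arm-label vectors aligned with the
cohort; ensembles of allocations are (m, n) label matrices so that
randomization inference can evaluate thousands of re-allocations with
vectorized arithmetic.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterator, Optional, Tuple

import numpy as np
import pandas as pd

from .distributions import ConfigurationError
from .population import Cohort

__all__ = [
    "TrialDesign",
    "Allocation",
    "TrialResult",
    "AllocationEnsemble",
    "randomize",
    "apply_sample_size_regime",
    "realize_trial",
    "enumerate_allocations",
    "count_allocations",
    "trial_from_table",
]

DEFAULT_ENUMERATION_LIMIT = 1_000_000

_SCHEMES = {"simple-coin", "complete-balanced", "permuted-block"}
_REGIMES = {"fixed", "poisson-total", "dropout", "event-driven"}


@dataclass(frozen=True)
class TrialDesign:
    """Design of a two-arm randomized trial.

    ``randomize_clusters=True`` assigns whole clusters to an arm (the unit of
    randomization becomes the cluster), which is how within-cluster
    dependence propagates into the variance of the arm means.
    """

    allocation_scheme: str = "complete-balanced"
    block_length: Optional[int] = None
    sample_size_regime: str = "fixed"
    poisson_mean: Optional[float] = None
    retention: Optional[float] = None
    event_threshold: Optional[float] = None
    event_target: Optional[int] = None
    randomize_clusters: bool = False
    arm_labels: Tuple[str, str] = ("0", "1")

    def __post_init__(self) -> None:
        if self.allocation_scheme not in _SCHEMES:
            raise ConfigurationError(
                f"unknown allocation scheme {self.allocation_scheme!r}"
            )
        if self.allocation_scheme == "permuted-block":
            b = self.block_length
            if b is None or b < 2 or b % 2 != 0:
                raise ConfigurationError("permuted-block needs an even block length >= 2")
        if self.sample_size_regime not in _REGIMES:
            raise ConfigurationError(
                f"unknown sample-size regime {self.sample_size_regime!r}"
            )
        if self.sample_size_regime == "poisson-total":
            if self.poisson_mean is None or self.poisson_mean <= 0:
                raise ConfigurationError("poisson-total regime needs mean > 0")
        if self.sample_size_regime == "dropout":
            q = self.retention
            if q is None or not 0.0 < q <= 1.0:
                raise ConfigurationError("dropout retention must lie in (0, 1]")
        if self.sample_size_regime == "event-driven":
            if self.event_threshold is None or self.event_target is None or self.event_target < 1:
                raise ConfigurationError(
                    "event-driven regime needs an event threshold and target count >= 1"
                )
        if len(self.arm_labels) != 2:
            raise ConfigurationError("exactly two arms supported")


@dataclass(frozen=True)
class Allocation:
    """Assignment of every enrolled subject to arm 0 or arm 1."""

    subject_id: np.ndarray
    arms: np.ndarray  # int8 vector of 0/1, aligned with subject_id

    def __post_init__(self) -> None:
        if self.subject_id.shape != self.arms.shape:
            raise ConfigurationError("subject_id and arms must be aligned")

    @property
    def assignment(self) -> dict:
        return {int(s): int(a) for s, a in zip(self.subject_id, self.arms)}

    def arm_sizes(self) -> Tuple[int, int]:
        n1 = int(self.arms.sum())
        return (self.arms.size - n1, n1)


@dataclass
class TrialResult:
    """Realized trial: observed responses, arm summaries and statistics.

    ``z`` is the normalized difference (unpooled by default); it is ``None``
    with ``z_available=False`` whenever an arm has fewer than two subjects
    or zero sample variance -- delta is always reported.
    """

    subject_id: np.ndarray
    cluster_id: np.ndarray
    arms: np.ndarray
    observed: np.ndarray
    n1: int
    n0: int
    a1: float
    a0: float
    delta: float
    z: Optional[float]
    z_available: bool
    s1: float
    s0: float
    pooled: bool = False

    @property
    def allocation(self) -> Allocation:
        return Allocation(self.subject_id, self.arms)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "cluster_id": self.cluster_id,
                "arm": self.arms,
                "response": self.observed,
            }
        )


# --- randomization -------------------------------------------------------


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _balanced_rows(m: int, u: int, rng: np.random.Generator) -> np.ndarray:
    """m random complete-balanced 0/1 rows of length u (arm sizes differ by <= 1)."""
    k = np.full(m, u // 2, dtype=np.int64)
    if u % 2 == 1:
        k = k + rng.integers(0, 2, m)
    order = np.argsort(rng.random((m, u)), axis=1)
    mask = np.arange(u)[None, :] < k[:, None]
    labels = np.zeros((m, u), dtype=np.int8)
    np.put_along_axis(labels, order, mask.astype(np.int8), axis=1)
    return labels

def _block_slices(u: int, b: int):
    return [(lo, min(lo + b, u)) for lo in range(0, u, b)]


def sample_label_matrix(
    u: int, m: int, scheme: str, block_length: Optional[int], rng: np.random.Generator
) -> np.ndarray:
    """Draw m iid arm-label vectors over u randomization units."""
    if scheme == "simple-coin":
        return rng.integers(0, 2, (m, u), dtype=np.int8)
    if scheme == "complete-balanced":
        return _balanced_rows(m, u, rng)
    # permuted-block: each block (final one possibly truncated) balanced
    out = np.empty((m, u), dtype=np.int8)
    for lo, hi in _block_slices(u, block_length):
        out[:, lo:hi] = _balanced_rows(m, hi - lo, rng)
    return out


def randomize(cohort: Cohort, design: TrialDesign, seed) -> Allocation:
    """Draw one allocation from the scheme's exact distribution.

    With ``randomize_clusters`` the scheme acts on clusters in order of first
    appearance and every member of a cluster gets the cluster's arm.
    """
    if len(cohort) == 0:
        raise ConfigurationError("cannot randomize an empty cohort")
    rng = _rng(seed)
    unit_index, n_units = _unit_index(cohort, design)
    row = sample_label_matrix(n_units, 1, design.allocation_scheme, design.block_length, rng)[0]
    return Allocation(subject_id=cohort.subject_id.copy(), arms=row[unit_index])


def _unit_index(cohort: Cohort, design: TrialDesign) -> Tuple[np.ndarray, int]:
    """Map each subject to its randomization unit (itself, or its cluster)."""
    if not design.randomize_clusters:
        return np.arange(len(cohort)), len(cohort)
    uniq, first_idx, inverse = np.unique(
        cohort.cluster_id, return_index=True, return_inverse=True
    )
    # renumber units by order of first appearance so block schemes follow enrollment
    rank = np.empty(uniq.size, dtype=np.int64)
    rank[np.argsort(first_idx, kind="stable")] = np.arange(uniq.size)
    return rank[inverse], uniq.size


# --- sample-size regimes -------------------------------------------------


def apply_sample_size_regime(
    cohort: Cohort, design: TrialDesign, seed, cohort_factory=None
) -> Cohort:
    """Return the retained cohort under the design's sample-size regime.

    ``poisson-total`` draws N ~ Poisson(mean) and truncates the enrollment
    sequence, or extends it through ``cohort_factory(extra_n, rng)`` (the
    cohort-generating process) when N exceeds the available pool.
    ``event-driven`` retains subjects in enrollment order until the target
    number of events (control-arm potential outcome exceeding the threshold)
    has accrued. Dropout is non-informative: each subject is kept
    independently with the retention probability.
    """
    rng = _rng(seed)
    regime = design.sample_size_regime
    if regime == "fixed":
        return cohort
    if regime == "dropout":
        keep = rng.random(len(cohort)) < design.retention
        if not keep.any():
            raise ConfigurationError("dropout removed every subject; lower the dropout rate")
        return cohort.subset(np.flatnonzero(keep))
    if regime == "poisson-total":
        n_drawn = int(rng.poisson(design.poisson_mean))
        if n_drawn < 1:
            raise ConfigurationError("poisson-total regime drew N = 0 subjects")
        if n_drawn <= len(cohort):
            return cohort.subset(np.arange(n_drawn))
        if cohort_factory is None:
            raise ConfigurationError(
                f"poisson-total drew N = {n_drawn} > available {len(cohort)}; "
                "provide a cohort_factory to extend the cohort"
            )
        extra = cohort_factory(n_drawn - len(cohort), rng)
        return _concat_cohorts(cohort, extra)
    # event-driven
    events = cohort.y0 > design.event_threshold
    cum = np.cumsum(events)
    total = int(cum[-1]) if len(cohort) else 0
    if total < design.event_target:
        raise ConfigurationError(
            f"event-driven regime needs {design.event_target} events but the "
            f"cohort only produced {total}"
        )
    cutoff = int(np.searchsorted(cum, design.event_target))
    return cohort.subset(np.arange(cutoff + 1))


def _concat_cohorts(a: Cohort, b: Cohort) -> Cohort:
    offset_id = a.subject_id.max() + 1 if len(a) else 0
    offset_cl = a.cluster_id.max() + 1 if len(a) else 0
    return Cohort(
        subject_id=np.concatenate([a.subject_id, b.subject_id + offset_id]),
        cluster_id=np.concatenate([a.cluster_id, b.cluster_id + offset_cl]),
        category=np.concatenate([a.category, b.category]),
        y0=np.concatenate([a.y0, b.y0]),
        y1=np.concatenate([a.y1, b.y1]),
    )


# --- realization ---------------------------------------------------------


def realize_trial(cohort: Cohort, allocation: Allocation, pooled: bool = False) -> TrialResult:
    """Observe each subject's potential outcome for its assigned arm and
    compute arm means, delta and the normalized difference z."""
    if not np.array_equal(cohort.subject_id, allocation.subject_id):
        raise ConfigurationError("allocation does not cover the retained cohort")
    arms = allocation.arms.astype(np.int8)
    y = np.where(arms == 1, cohort.y1, cohort.y0)
    n1 = int(arms.sum())
    n0 = int(arms.size - n1)
    if n1 == 0 or n0 == 0:
        raise ConfigurationError("both arms need at least one subject")
    y1 = y[arms == 1]
    y0 = y[arms == 0]
    a1 = float(y1.mean())
    a0 = float(y0.mean())
    delta = a1 - a0
    s1 = float(y1.std(ddof=1)) if n1 > 1 else float("nan")
    s0 = float(y0.std(ddof=1)) if n0 > 1 else float("nan")
    z, available = _normalized_difference(delta, s1, s0, n1, n0, pooled)
    return TrialResult(
        subject_id=cohort.subject_id.copy(),
        cluster_id=cohort.cluster_id.copy(),
        arms=arms,
        observed=y,
        n1=n1,
        n0=n0,
        a1=a1,
        a0=a0,
        delta=delta,
        z=z,
        z_available=available,
        s1=s1,
        s0=s0,
        pooled=pooled,
    )


def _normalized_difference(delta, s1, s0, n1, n0, pooled):
    if n1 < 2 or n0 < 2 or not np.isfinite(s1) or not np.isfinite(s0):
        return None, False
    if pooled:
        sp2 = ((n1 - 1) * s1**2 + (n0 - 1) * s0**2) / (n1 + n0 - 2)
        se = math.sqrt(sp2 * (1.0 / n1 + 1.0 / n0))
    else:
        se = math.sqrt(s1**2 / n1 + s0**2 / n0)
    if se <= 0.0:
        return None, False
    return delta / se, True


def trial_from_table(df: pd.DataFrame, pooled: bool = False) -> TrialResult:
    """Build a TrialResult from a subject-level table with columns
    subject_id, [cluster_id], arm, response."""
    subject_id = df["subject_id"].to_numpy()
    cluster_id = (
        df["cluster_id"].to_numpy()
        if "cluster_id" in df.columns
        else np.arange(len(df), dtype=np.int64)
    )
    arms = df["arm"].to_numpy().astype(np.int8)
    y = df["response"].to_numpy(dtype=float)
    cohort = Cohort(subject_id, cluster_id, np.zeros(len(df), dtype=object), y, y)
    return realize_trial(cohort, Allocation(subject_id, arms), pooled=pooled)


# --- allocation enumeration ---------------------------------------------


@dataclass
class AllocationEnsemble:
    """A set of allocations as a (m, n_units) label matrix.

    ``exact=True`` means every admissible allocation appears exactly once;
    otherwise the rows are iid draws from the scheme. ``subject_matrix()``
    broadcasts unit labels to per-subject labels.
    """

    unit_labels: np.ndarray
    unit_index: np.ndarray
    subject_id: np.ndarray
    exact: bool
    total_count: int

    @property
    def n_allocations(self) -> int:
        return self.unit_labels.shape[0]

    def subject_matrix(self) -> np.ndarray:
        return self.unit_labels[:, self.unit_index]

    def allocations(self) -> Iterator[Allocation]:
        for row in self.subject_matrix():
            yield Allocation(self.subject_id, row)


def _balanced_count(u: int) -> int:
    if u % 2 == 0:
        return math.comb(u, u // 2)
    return math.comb(u, u // 2) + math.comb(u, u // 2 + 1)


def count_allocations(design: TrialDesign, n_units: int) -> int:
    """Number of distinct label vectors the scheme can produce."""
    scheme = design.allocation_scheme
    if scheme == "simple-coin":
        return 2**n_units
    if scheme == "complete-balanced":
        return _balanced_count(n_units)
    total = 1
    for lo, hi in _block_slices(n_units, design.block_length):
        total *= _balanced_count(hi - lo)
    return total


def _enumerate_balanced(u: int) -> np.ndarray:
    ks = [u // 2] if u % 2 == 0 else [u // 2, u // 2 + 1]
    rows = []
    for k in ks:
        for combo in itertools.combinations(range(u), k):
            row = np.zeros(u, dtype=np.int8)
            row[list(combo)] = 1
            rows.append(row)
    return np.array(rows, dtype=np.int8)


def _enumerate_labels(design: TrialDesign, u: int) -> np.ndarray:
    scheme = design.allocation_scheme
    if scheme == "simple-coin":
        bits = (np.arange(2**u, dtype=np.int64)[:, None] >> np.arange(u)) & 1
        return bits.astype(np.int8)
    if scheme == "complete-balanced":
        return _enumerate_balanced(u)
    blocks = [_enumerate_balanced(hi - lo) for lo, hi in _block_slices(u, design.block_length)]
    total = 1
    for b in blocks:
        total *= b.shape[0]
    out = np.empty((total, u), dtype=np.int8)
    reps = total
    col = 0
    for b in blocks:
        nb, width = b.shape
        reps //= nb
        tile = total // (nb * reps)
        block_rows = np.repeat(np.tile(np.arange(nb), tile), reps)
        out[:, col : col + width] = b[block_rows]
        col += width
    return out


def enumerate_allocations(
    cohort: Cohort,
    design: TrialDesign,
    limit: int = DEFAULT_ENUMERATION_LIMIT,
    seed=None,
) -> AllocationEnsemble:
    """All admissible allocations if there are at most ``limit`` of them
    (exact), otherwise ``limit`` iid draws from the scheme (Monte Carlo)."""
    if limit < 1:
        raise ConfigurationError("enumeration limit must be >= 1")
    unit_index, n_units = _unit_index(cohort, design)
    total = count_allocations(design, n_units)
    if total <= limit:
        labels = _enumerate_labels(design, n_units)
        exact = True
    else:
        rng = _rng(seed)
        labels = sample_label_matrix(
            n_units, limit, design.allocation_scheme, design.block_length, rng
        )
        exact = False
    return AllocationEnsemble(
        unit_labels=labels,
        unit_index=unit_index,
        subject_id=cohort.subject_id.copy(),
        exact=exact,
        total_count=total,
    )
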