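"""Heterogeneous population models: category mixtures, clustered dependence,
and vectorized cohort sampling with per-subject potential outcomes.

A subject's potential outcomes under both arms are drawn exactly once at
sampling time, so re-randomizing a cohort never changes any response --
the invariance the strong-null permutation machinery relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .distributions import (
    ConfigurationError,
    IntegerLaw,
    ResponseDistribution,
    constant,
    normal,
)

__all__ = [
    "ResponseCategory",
    "DependenceSpec",
    "CategoryLawSpec",
    "PopulationModel",
    "Cohort",
    "sample_category_composition",
    "sample_subjects",
]

_WEIGHT_TOL = 1e-12

ArmLaw = Union[ResponseDistribution, float, int]


def _as_distribution(law: ArmLaw) -> ResponseDistribution:
    if isinstance(law, ResponseDistribution):
        return law
    return constant(float(law))


@dataclass(frozen=True)
class ResponseCategory:
    """A latent population stratum with arm-specific response laws.

    ``arm_laws`` is ``(law_arm0, law_arm1)``; plain numbers are promoted to
    degenerate constant distributions, so deterministic and stochastic
    categories coexist in one representation.
    """

    label: str
    arm_laws: tuple
    weight: float

    def __post_init__(self) -> None:
        if not 0.0 < self.weight <= 1.0:
            raise ConfigurationError(f"category weight {self.weight} must lie in (0, 1]")
        if len(self.arm_laws) != 2:
            raise ConfigurationError("exactly two arm laws required")
        object.__setattr__(
            self, "arm_laws", tuple(_as_distribution(law) for law in self.arm_laws)
        )


@dataclass(frozen=True)
class DependenceSpec:
    """Within-cluster equicorrelation induced by a shared additive latent effect."""

    mode: str = "independent"
    cluster_size_law: Optional[IntegerLaw] = None
    intra_cluster_correlation: float = 0.0
    allow_cross_category_clusters: bool = False

    def __post_init__(self) -> None:
        if self.mode not in {"independent", "clustered"}:
            raise ConfigurationError(f"unknown dependence mode {self.mode!r}")
        r = self.intra_cluster_correlation
        if not 0.0 <= r < 1.0:
            raise ConfigurationError("intra_cluster_correlation must lie in [0, 1)")
        if self.mode == "independent" and r != 0.0:
            raise ConfigurationError("independent mode requires r = 0")
        if self.mode == "clustered":
            if self.cluster_size_law is None:
                raise ConfigurationError("clustered mode requires a cluster_size_law")
            if self.cluster_size_law.min_support() < 1:
                raise ConfigurationError("cluster sizes must be positive integers")


@dataclass(frozen=True)
class CategoryLawSpec:
    """Generating law for a random category composition.

    The number of categories K is drawn from ``k_law`` (support must exclude
    0), weights from a symmetric Dirichlet with the given concentration.
    Each realized category gets normal arm laws with a category-specific
    mean drawn from N(base_mean, between_sd); arm 1 additionally receives
    ``arm1_shift`` plus a category-specific effect drawn from
    N(0, effect_sd) -- set both to 0 for a null composition.
    """

    k_law: IntegerLaw = field(default_factory=lambda: IntegerLaw("poisson", {"mean": 5.0, "shift": 1}))
    concentration: float = 1.0
    base_mean: float = 0.0
    between_sd: float = 1.0
    within_sd: float = 1.0
    arm1_shift: float = 0.0
    effect_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise ConfigurationError("Dirichlet concentration must be > 0")
        if self.k_law.min_support() < 1:
            raise ConfigurationError(
                "category-count law must have support >= 1 (shift a poisson law by 1)"
            )
        if self.within_sd <= 0:
            raise ConfigurationError("within_sd must be > 0")


@dataclass(frozen=True)
class PopulationModel:
    """Mixture of response categories, fixed or generated, plus dependence."""

    categories: Optional[Sequence[ResponseCategory]] = None
    category_law: Optional[CategoryLawSpec] = None
    dependence: DependenceSpec = field(default_factory=DependenceSpec)

    def __post_init__(self) -> None:
        if self.categories is None and self.category_law is None:
            raise ConfigurationError("need fixed categories or a category-generating law")
        if self.categories is not None:
            cats = tuple(self.categories)
            if len(cats) == 0:
                raise ConfigurationError("at least one category required")
            total = sum(c.weight for c in cats)
            if abs(total - 1.0) > _WEIGHT_TOL:
                # renormalize, preserving proportions
                cats = tuple(
                    ResponseCategory(c.label, c.arm_laws, c.weight / total) for c in cats
                )
            object.__setattr__(self, "categories", cats)

    def resolve_categories(self, rng: np.random.Generator) -> List[ResponseCategory]:
        if self.categories is not None:
            return list(self.categories)
        return sample_category_composition(self, rng)


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_category_composition(model: PopulationModel, seed) -> List[ResponseCategory]:
    """Draw a realized category list (K categories with Dirichlet weights)."""
    if model.category_law is None:
        raise ConfigurationError("model has no category-generating law")
    law = model.category_law
    rng = _rng(seed)
    k = int(law.k_law.sample(rng))
    if k < 1:
        raise ConfigurationError("category-count law produced K < 1")
    weights = rng.dirichlet(np.full(k, law.concentration))
    weights = weights / weights.sum()
    mus = rng.normal(law.base_mean, law.between_sd, k)
    effects = rng.normal(0.0, law.effect_sd, k) if law.effect_sd > 0 else np.zeros(k)
    cats = []
    for j in range(k):
        cats.append(
            ResponseCategory(
                label=f"cat{j}",
                arm_laws=(
                    normal(mus[j], law.within_sd),
                    normal(mus[j] + law.arm1_shift + effects[j], law.within_sd),
                ),
                weight=float(weights[j]),
            )
        )
    return cats


@dataclass
class Cohort:
    """A sampled cohort stored as aligned column arrays.

    ``y0``/``y1`` hold each subject's potential outcome under arm 0/arm 1;
    both are drawn once at sampling time and never redrawn.
    """

    subject_id: np.ndarray
    cluster_id: np.ndarray
    category: np.ndarray
    y0: np.ndarray
    y1: np.ndarray

    def __len__(self) -> int:
        return self.subject_id.size

    @property
    def n(self) -> int:
        return len(self)

    def subset(self, index: np.ndarray) -> "Cohort":
        return Cohort(
            self.subject_id[index],
            self.cluster_id[index],
            self.category[index],
            self.y0[index],
            self.y1[index],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "cluster_id": self.cluster_id,
                "category": self.category,
                "y_arm0": self.y0,
                "y_arm1": self.y1,
            }
        )

    def write_table(self, path, sep: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Cohort":
        return cls(
            subject_id=df["subject_id"].to_numpy(),
            cluster_id=df["cluster_id"].to_numpy(),
            category=df["category"].to_numpy(),
            y0=df["y_arm0"].to_numpy(dtype=float),
            y1=df["y_arm1"].to_numpy(dtype=float),
        )

    @classmethod
    def read_table(cls, path, sep: str = "\t") -> "Cohort":
        return cls.from_frame(pd.read_csv(path, sep=sep))


_CORRELATABLE = {"normal"}


def _draw_outcomes(
    law: ResponseDistribution,
    idx: np.ndarray,
    cluster_effect: Optional[np.ndarray],
    r: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw outcomes for the subjects at ``idx`` from one arm law.

    With a shared cluster effect G ~ N(0,1) per cluster and correlation r,
    normal responses decompose as mu + sd*(sqrt(r)*G + sqrt(1-r)*E), which
    has the marginal law intact and exact within-cluster correlation r.
    """
    m = idx.size
    if r > 0.0 and cluster_effect is not None:
        if law.family not in _CORRELATABLE:
            raise ConfigurationError(
                f"intra-cluster correlation r={r} is not supported for the "
                f"{law.family!r} family; use a normal response law"
            )
        mu = float(law.params["mean"])
        sd = float(law.params["sd"])
        eps = rng.normal(0.0, 1.0, m)
        return mu + sd * (np.sqrt(r) * cluster_effect[idx] + np.sqrt(1.0 - r) * eps)
    return law.sample(rng, m)


def sample_subjects(model: PopulationModel, n: int, seed) -> Cohort:
    """Sample ``n`` subjects: category labels, cluster ids and per-arm
    potential outcomes (drawn once).

    Clusters are filled within each category (never across categories unless
    the dependence spec allows it); one latent effect per cluster is shared
    by both arms' outcomes so that any two responses in a cluster correlate
    at exactly ``r``.
    """
    if n < 1:
        raise ConfigurationError(f"cohort size must be >= 1, got {n}")
    rng = _rng(seed)
    cats = model.resolve_categories(rng)
    weights = np.array([c.weight for c in cats], dtype=float)
    weights = weights / weights.sum()
    cat_idx = rng.choice(len(cats), size=n, p=weights)

    dep = model.dependence
    cluster_id = np.arange(n, dtype=np.int64)
    if dep.mode == "clustered":
        cluster_id = np.empty(n, dtype=np.int64)
        next_cluster = 0
        if dep.allow_cross_category_clusters:
            groups = [np.arange(n)]
        else:
            groups = [np.flatnonzero(cat_idx == j) for j in range(len(cats))]
        for members in groups:
            pos = 0
            while pos < members.size:
                size = int(dep.cluster_size_law.sample(rng))
                take = members[pos : pos + size]
                cluster_id[take] = next_cluster
                next_cluster += 1
                pos += size

    r = dep.intra_cluster_correlation
    cluster_effect = None
    if r > 0.0:
        n_clusters = int(cluster_id.max()) + 1
        effects = rng.normal(0.0, 1.0, n_clusters)
        cluster_effect = effects[cluster_id]

    y0 = np.empty(n, dtype=float)
    y1 = np.empty(n, dtype=float)
    for j, cat in enumerate(cats):
        idx = np.flatnonzero(cat_idx == j)
        if idx.size == 0:
            continue
        y0[idx] = _draw_outcomes(cat.arm_laws[0], idx, cluster_effect, r, rng)
        y1[idx] = _draw_outcomes(cat.arm_laws[1], idx, cluster_effect, r, rng)

    labels = np.array([cats[j].label for j in cat_idx], dtype=object)
    return Cohort(
        subject_id=np.arange(n, dtype=np.int64),
        cluster_id=cluster_id,
        category=labels,
        y0=y0,
        y1=y1,
    )
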