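"""Response distributions and integer laws used by the population sampler.

Every distribution knows its mean, variance, third absolute central moment
and how to draw vectorized samples from a :class:`numpy.random.Generator`.
Deterministic responses are represented as the degenerate ``constant``
family so that fully deterministic cohorts share the stochastic code path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import integrate, stats

__all__ = [
    "ResponseDistribution",
    "IntegerLaw",
    "moment_ratio",
    "normal",
    "bernoulli",
    "truncated_normal",
    "two_point",
    "uniform",
    "tabulated",
    "constant",
]

_FAMILIES = {
    "normal",
    "bernoulli",
    "truncated-normal",
    "two-point",
    "uniform",
    "tabulated",
    "constant",
}

_PROB_TOL = 1e-12


class ConfigurationError(ValueError):
    """Raised when a distribution or law specification is invalid."""


@dataclass(frozen=True)
class ResponseDistribution:
    """A response law for one trial arm.

    Parameters
    ----------
    family:
        One of ``normal``, ``bernoulli``, ``truncated-normal``, ``two-point``,
        ``uniform``, ``tabulated`` or the degenerate ``constant``.
    params:
        Family-specific parameters (see the module-level constructors).
    support_bounds:
        Optional ``(lo, hi)`` interval that must contain all mass.
    """

    family: str
    params: Mapping[str, object] = field(default_factory=dict)
    support_bounds: Optional[Tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ConfigurationError(
                f"unknown family {self.family!r}; choose from {sorted(_FAMILIES)}"
            )
        p = dict(self.params)
        if self.family == "normal":
            if p.get("sd", 1.0) <= 0:
                raise ConfigurationError("normal sd must be > 0")
        elif self.family == "bernoulli":
            prob = p["p"]
            if not 0.0 <= prob <= 1.0:
                raise ConfigurationError("bernoulli p must lie in [0, 1]")
        elif self.family == "truncated-normal":
            if p.get("sd", 1.0) <= 0:
                raise ConfigurationError("truncated-normal sd must be > 0")
            if p["lo"] >= p["hi"]:
                raise ConfigurationError("truncated-normal requires lo < hi")
        elif self.family == "two-point":
            prob = p.get("p", 0.5)
            if not 0.0 <= prob <= 1.0:
                raise ConfigurationError("two-point p must lie in [0, 1]")
        elif self.family == "uniform":
            if p["lo"] >= p["hi"]:
                raise ConfigurationError("uniform requires lo < hi")
        elif self.family == "tabulated":
            probs = np.asarray(p["probs"], dtype=float)
            values = np.asarray(p["values"], dtype=float)
            if probs.shape != values.shape or probs.ndim != 1 or probs.size == 0:
                raise ConfigurationError("tabulated values/probs must be matching 1-d arrays")
            if np.any(probs < 0):
                raise ConfigurationError("tabulated probabilities must be nonnegative")
            if abs(probs.sum() - 1.0) > _PROB_TOL:
                raise ConfigurationError(
                    f"tabulated probabilities sum to {probs.sum()!r}, not 1 within {_PROB_TOL}"
                )
        if self.support_bounds is not None:
            lo, hi = self.support_bounds
            if lo >= hi:
                raise ConfigurationError("support_bounds must satisfy lo < hi")
            slo, shi = self._natural_support()
            if slo < lo - _PROB_TOL or shi > hi + _PROB_TOL:
                raise ConfigurationError(
                    f"{self.family} places mass on [{slo}, {shi}] outside "
                    f"support_bounds [{lo}, {hi}]"
                )

    # -- moments -----------------------------------------------------------

    def mean(self) -> float:
        f, p = self.family, self.params
        if f == "normal":
            return float(p["mean"])
        if f == "bernoulli":
            return float(p["p"])
        if f == "truncated-normal":
            return float(self._frozen().mean())
        if f == "two-point":
            prob = float(p.get("p", 0.5))
            return prob * float(p["a"]) + (1 - prob) * float(p["b"])
        if f == "uniform":
            return 0.5 * (float(p["lo"]) + float(p["hi"]))
        if f == "tabulated":
            v = np.asarray(p["values"], dtype=float)
            w = np.asarray(p["probs"], dtype=float)
            return float(v @ w)
        return float(p["value"])  # constant

    def var(self) -> float:
        f, p = self.family, self.params
        if f == "normal":
            return float(p["sd"]) ** 2
        if f == "bernoulli":
            prob = float(p["p"])
            return prob * (1 - prob)
        if f == "truncated-normal":
            return float(self._frozen().var())
        if f == "two-point":
            prob = float(p.get("p", 0.5))
            return prob * (1 - prob) * (float(p["a"]) - float(p["b"])) ** 2
        if f == "uniform":
            return (float(p["hi"]) - float(p["lo"])) ** 2 / 12.0
        if f == "tabulated":
            v = np.asarray(p["values"], dtype=float)
            w = np.asarray(p["probs"], dtype=float)
            mu = float(v @ w)
            return float(((v - mu) ** 2) @ w)
        return 0.0  # constant

    def std(self) -> float:
        return math.sqrt(self.var())

    def third_abs_central_moment(self) -> float:
        """E|X - mu|^3, closed form where available, quadrature otherwise."""
        f, p = self.family, self.params
        if f == "normal":
            # E|Z|^3 = 2 * sqrt(2/pi) for standard normal
            return 2.0 * math.sqrt(2.0 / math.pi) * float(p["sd"]) ** 3
        if f == "bernoulli":
            prob = float(p["p"])
            return prob * (1 - prob) * (prob**2 + (1 - prob) ** 2)
        if f == "two-point":
            prob = float(p.get("p", 0.5))
            a, b = float(p["a"]), float(p["b"])
            mu = prob * a + (1 - prob) * b
            return prob * abs(a - mu) ** 3 + (1 - prob) * abs(b - mu) ** 3
        if f == "uniform":
            half = 0.5 * (float(p["hi"]) - float(p["lo"]))
            return half**3 / 4.0
        if f == "tabulated":
            v = np.asarray(p["values"], dtype=float)
            w = np.asarray(p["probs"], dtype=float)
            mu = float(v @ w)
            return float((np.abs(v - mu) ** 3) @ w)
        if f == "truncated-normal":
            frozen = self._frozen()
            mu = float(frozen.mean())
            lo, hi = float(p["lo"]), float(p["hi"])
            val, _ = integrate.quad(
                lambda x: abs(x - mu) ** 3 * frozen.pdf(x),
                lo,
                hi,
                points=[mu],
                epsabs=1e-12,
                epsrel=1e-12,
                limit=200,
            )
            return float(val)
        return 0.0  # constant

    # -- sampling ----------------------------------------------------------

    def sample(self, rng: np.random.Generator, size: int | tuple) -> np.ndarray:
        f, p = self.family, self.params
        if f == "normal":
            return rng.normal(float(p["mean"]), float(p["sd"]), size)
        if f == "bernoulli":
            return rng.binomial(1, float(p["p"]), size).astype(float)
        if f == "truncated-normal":
            # inverse-CDF sampling: much faster than truncnorm.rvs for big draws
            mean, sd = float(p["mean"]), float(p["sd"])
            lo = stats.norm.cdf((float(p["lo"]) - mean) / sd)
            hi = stats.norm.cdf((float(p["hi"]) - mean) / sd)
            u = rng.uniform(lo, hi, size)
            from scipy.special import ndtri

            return mean + sd * ndtri(u)
        if f == "two-point":
            prob = float(p.get("p", 0.5))
            picks = rng.random(size) < prob
            return np.where(picks, float(p["a"]), float(p["b"]))
        if f == "uniform":
            return rng.uniform(float(p["lo"]), float(p["hi"]), size)
        if f == "tabulated":
            v = np.asarray(p["values"], dtype=float)
            w = np.asarray(p["probs"], dtype=float)
            idx = rng.choice(v.size, size=size, p=w)
            return v[idx]
        return np.full(size, float(p["value"]))  # constant

    # -- helpers -----------------------------------------------------------

    def is_degenerate(self) -> bool:
        return self.var() <= 0.0

    def _frozen(self):
        p = self.params
        if self.family == "truncated-normal":
            mean, sd = float(p["mean"]), float(p["sd"])
            a = (float(p["lo"]) - mean) / sd
            b = (float(p["hi"]) - mean) / sd
            return stats.truncnorm(a, b, loc=mean, scale=sd)
        raise NotImplementedError(self.family)

    def _natural_support(self) -> Tuple[float, float]:
        f, p = self.family, self.params
        if f == "normal":
            return (-math.inf, math.inf)
        if f == "bernoulli":
            return (0.0, 1.0)
        if f == "truncated-normal":
            return (float(p["lo"]), float(p["hi"]))
        if f == "two-point":
            a, b = float(p["a"]), float(p["b"])
            return (min(a, b), max(a, b))
        if f == "uniform":
            return (float(p["lo"]), float(p["hi"]))
        if f == "tabulated":
            v = np.asarray(p["values"], dtype=float)
            return (float(v.min()), float(v.max()))
        val = float(p["value"])
        return (val, val)

    def to_dict(self) -> dict:
        out = {"family": self.family, "params": dict(self.params)}
        if self.support_bounds is not None:
            out["support_bounds"] = list(self.support_bounds)
        return out

    @classmethod
    def from_dict(cls, d: Mapping) -> "ResponseDistribution":
        bounds = d.get("support_bounds")
        return cls(
            family=d["family"],
            params=dict(d.get("params", {})),
            support_bounds=tuple(bounds) if bounds is not None else None,
        )


# convenience constructors ------------------------------------------------


def normal(mean: float, sd: float, support_bounds=None) -> ResponseDistribution:
    return ResponseDistribution("normal", {"mean": mean, "sd": sd}, support_bounds)


def bernoulli(p: float) -> ResponseDistribution:
    return ResponseDistribution("bernoulli", {"p": p}, (0.0, 1.0))


def truncated_normal(mean: float, sd: float, lo: float, hi: float) -> ResponseDistribution:
    return ResponseDistribution(
        "truncated-normal", {"mean": mean, "sd": sd, "lo": lo, "hi": hi}, (lo, hi)
    )


def two_point(a: float, b: float, p: float = 0.5) -> ResponseDistribution:
    return ResponseDistribution("two-point", {"a": a, "b": b, "p": p})


def uniform(lo: float, hi: float) -> ResponseDistribution:
    return ResponseDistribution("uniform", {"lo": lo, "hi": hi}, (lo, hi))


def tabulated(values: Sequence[float], probs: Sequence[float]) -> ResponseDistribution:
    return ResponseDistribution("tabulated", {"values": list(values), "probs": list(probs)})


def constant(value: float) -> ResponseDistribution:
    return ResponseDistribution("constant", {"value": float(value)})


def moment_ratio(dist: ResponseDistribution) -> float:
    """Ratio C of the third absolute central moment to the cubed SD.

    ``C >= 1`` for every non-degenerate distribution; a zero-variance
    distribution has no C and is rejected.
    """
    var = dist.var()
    if var <= 0.0:
        raise ConfigurationError(
            "moment ratio undefined for a degenerate (zero-variance) distribution"
        )
    return dist.third_abs_central_moment() / var**1.5


@dataclass(frozen=True)
class IntegerLaw:
    """Distribution over nonnegative integers (category counts, cluster sizes,
    random sample sizes).

    Kinds: ``constant`` (value k), ``poisson`` (mean, optional shift added to
    every draw), ``geometric`` (mean of the number-of-trials law, support >= 1).
    """

    kind: str
    params: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in {"constant", "poisson", "geometric"}:
            raise ConfigurationError(f"unknown integer law {self.kind!r}")
        p = dict(self.params)
        if self.kind == "constant" and int(p["value"]) < 0:
            raise ConfigurationError("constant law value must be >= 0")
        if self.kind == "poisson" and p["mean"] <= 0:
            raise ConfigurationError("poisson mean must be > 0")
        if self.kind == "geometric" and p["mean"] < 1:
            raise ConfigurationError("geometric mean must be >= 1")

    def min_support(self) -> int:
        if self.kind == "constant":
            return int(self.params["value"])
        if self.kind == "poisson":
            return int(self.params.get("shift", 0))
        return 1  # geometric (number of trials)

    def mean(self) -> float:
        if self.kind == "constant":
            return float(self.params["value"])
        if self.kind == "poisson":
            return float(self.params["mean"]) + float(self.params.get("shift", 0))
        return float(self.params["mean"])

    def var(self) -> float:
        if self.kind == "constant":
            return 0.0
        if self.kind == "poisson":
            return float(self.params["mean"])
        m = float(self.params["mean"])
        p = 1.0 / m
        return (1.0 - p) / p**2

    def sample(self, rng: np.random.Generator, size: int | tuple = ()) -> np.ndarray:
        if self.kind == "constant":
            return np.full(size, int(self.params["value"]), dtype=np.int64)
        if self.kind == "poisson":
            shift = int(self.params.get("shift", 0))
            return rng.poisson(float(self.params["mean"]), size) + shift
        p = 1.0 / float(self.params["mean"])
        return rng.geometric(p, size).astype(np.int64)

    def to_dict(self) -> dict:
        return {"kind": self.kind, "params": dict(self.params)}

    @classmethod
    def from_dict(cls, d: Mapping) -> "IntegerLaw":
        return cls(kind=d["kind"], params=dict(d.get("params", {})))
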