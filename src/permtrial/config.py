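"""Structured-configuration loading (JSON or YAML) and builders that turn
plain dictionaries into population models, trial designs and scenarios.

Schema (all keys optional unless noted)::

    population:
      categories:                 # either this ...
        - label: responders
          weight: 0.5
          arm_laws:               # two entries: arm 0 then arm 1; a bare
            - {family: normal, params: {mean: 0, sd: 1}}
            - 2.0                 # number means a deterministic response
      category_law:               # ... or this
        k_law: {kind: poisson, params: {mean: 5, shift: 1}}
        concentration: 1.0
        between_sd: 1.0
        within_sd: 1.0
        arm1_shift: 0.0
        effect_sd: 0.0
      dependence:
        mode: clustered
        cluster_size_law: {kind: constant, params: {value: 2}}
        intra_cluster_correlation: 0.5
    design:
      allocation_scheme: complete-balanced   # simple-coin | permuted-block
      block_length: 4
      sample_size_regime: fixed   # poisson-total | dropout | event-driven
      poisson_mean: 50
      retention: 0.8
      event_threshold: 1.0
      event_target: 20
      randomize_clusters: false
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Union

import yaml

from .distributions import ConfigurationError, IntegerLaw, ResponseDistribution
from .engine import TrialDesign
from .population import (
    CategoryLawSpec,
    DependenceSpec,
    PopulationModel,
    ResponseCategory,
)

__all__ = [
    "load_config",
    "population_from_dict",
    "design_from_dict",
]


def load_config(path: Union[str, Path]) -> dict:
    """Load a JSON or YAML configuration file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def _law_from(entry) -> ResponseDistribution:
    if isinstance(entry, (int, float)):
        return entry  # promoted to a constant distribution by ResponseCategory
    if isinstance(entry, Mapping):
        return ResponseDistribution.from_dict(entry)
    raise ConfigurationError(f"cannot interpret arm law {entry!r}")


def population_from_dict(d: Mapping) -> PopulationModel:
    categories = None
    if "categories" in d:
        categories = [
            ResponseCategory(
                label=c.get("label", f"cat{i}"),
                arm_laws=tuple(_law_from(x) for x in c["arm_laws"]),
                weight=float(c["weight"]),
            )
            for i, c in enumerate(d["categories"])
        ]
    category_law = None
    if "category_law" in d:
        cl = dict(d["category_law"])
        if "k_law" in cl:
            cl["k_law"] = IntegerLaw.from_dict(cl["k_law"])
        category_law = CategoryLawSpec(**cl)
    dependence = DependenceSpec()
    if "dependence" in d:
        dep = dict(d["dependence"])
        if "cluster_size_law" in dep:
            dep["cluster_size_law"] = IntegerLaw.from_dict(dep["cluster_size_law"])
        dependence = DependenceSpec(**dep)
    return PopulationModel(
        categories=categories, category_law=category_law, dependence=dependence
    )


def design_from_dict(d: Mapping) -> TrialDesign:
    allowed = {
        "allocation_scheme",
        "block_length",
        "sample_size_regime",
        "poisson_mean",
        "retention",
        "event_threshold",
        "event_target",
        "randomize_clusters",
    }
    unknown = set(d) - allowed
    if unknown:
        raise ConfigurationError(f"unknown design keys: {sorted(unknown)}")
    return TrialDesign(**{k: d[k] for k in d})
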