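"""Operating-characteristic experiments and worked-example demos.

Everything here is replayable: a scenario plus a seed determines every
number bit-exactly, and :func:`run_report` writes a manifest capturing the
configuration hash and all derived seeds.
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .distributions import ConfigurationError, IntegerLaw, ResponseDistribution, normal
from .engine import (
    DEFAULT_ENUMERATION_LIMIT,
    TrialDesign,
    apply_sample_size_regime,
    randomize,
    realize_trial,
)
from .inference import (
    parametric_pvalue,
    perm_averaged_parametric_pvalue,
    permutation_pvalue,
)
from .population import (
    CategoryLawSpec,
    Cohort,
    DependenceSpec,
    PopulationModel,
    ResponseCategory,
    sample_subjects,
)

__all__ = [
    "ScenarioConfig",
    "OperatingCharacteristics",
    "AveragingFallacyTable",
    "run_operating_characteristics",
    "averaging_fallacy_demo",
    "random_sample_size_demo",
    "run_report",
    "scenario_preset",
    "SCENARIO_PRESETS",
]

_METHODS = {"parametric", "permutation-exact", "permutation-mc", "perm-averaged-parametric"}
_HYPOTHESES = {"strong-null", "shift", "model"}


@dataclass(frozen=True)
class ScenarioConfig:
    """A named data-generating scenario plus the analysis applied to it.

    ``hypothesis`` controls the potential outcomes after cohort sampling:
    ``strong-null`` copies the arm-0 outcome to arm 1 (every subject
    responds identically under either assignment), ``shift`` adds a
    constant treatment effect to the arm-0 outcome, and ``model`` keeps the
    outcomes exactly as the population model drew them.
    """

    name: str
    population: PopulationModel
    design: TrialDesign
    n_subjects: int
    method: str = "parametric"
    statistic: str = "delta"
    sidedness: str = "two-sided"
    alpha: float = 0.05
    hypothesis: str = "strong-null"
    shift: float = 0.0
    mc_draws: int = 999
    enumeration_limit: int = DEFAULT_ENUMERATION_LIMIT
    # realize the random category composition once per experiment instead of
    # once per replicate: different experiments then query visibly different
    # populations, which is the irreproducibility mechanism under study
    freeze_composition: bool = False

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ConfigurationError(f"unknown method {self.method!r}")
        if self.hypothesis not in _HYPOTHESES:
            raise ConfigurationError(f"unknown hypothesis {self.hypothesis!r}")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError("alpha must lie in (0, 1)")
        if self.n_subjects < 2:
            raise ConfigurationError("scenario needs at least two subjects")


@dataclass
class OperatingCharacteristics:
    scenario_id: str
    nominal_alpha: float
    method: str
    n_reps: int
    rejection_rate: float
    mc_standard_error: float
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def _apply_hypothesis(cohort: Cohort, scenario: ScenarioConfig) -> Cohort:
    if scenario.hypothesis == "strong-null":
        cohort.y1 = cohort.y0.copy()
    elif scenario.hypothesis == "shift":
        cohort.y1 = cohort.y0 + scenario.shift
    return cohort


def _one_pvalue(trial, scenario: ScenarioConfig, rng) -> float:
    method = scenario.method
    if method == "parametric":
        if not trial.z_available:
            return 1.0
        return parametric_pvalue(trial.z, scenario.sidedness)
    if method == "permutation-exact":
        return permutation_pvalue(
            trial, scenario.design, mode="exact", seed=rng,
            statistic=scenario.statistic, sidedness=scenario.sidedness,
            limit=scenario.enumeration_limit,
        ).p
    if method == "permutation-mc":
        return permutation_pvalue(
            trial, scenario.design, mode="mc", m=scenario.mc_draws, seed=rng,
            statistic=scenario.statistic, sidedness=scenario.sidedness,
        ).p
    return perm_averaged_parametric_pvalue(
        trial, scenario.design, limit=scenario.enumeration_limit, seed=rng,
        sidedness=scenario.sidedness,
    ).p


def run_operating_characteristics(
    scenario: ScenarioConfig, n_reps: int, seed: int
) -> OperatingCharacteristics:
    """Monte-Carlo rejection rate of the scenario's method at its nominal
    alpha, with the binomial MC standard error."""
    if n_reps < 100:
        warnings.warn(
            f"n_reps = {n_reps} is small; rejection-rate estimates will be noisy",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    population = scenario.population
    if scenario.freeze_composition and population.category_law is not None:
        from .population import sample_category_composition

        population = PopulationModel(
            categories=sample_category_composition(population, rng),
            dependence=population.dependence,
        )
    rejections = 0
    for _ in range(n_reps):
        cohort = sample_subjects(population, scenario.n_subjects, rng)
        cohort = _apply_hypothesis(cohort, scenario)
        cohort = apply_sample_size_regime(cohort, scenario.design, rng)
        allocation = randomize(cohort, scenario.design, rng)
        trial = realize_trial(cohort, allocation)
        p = _one_pvalue(trial, scenario, rng)
        if p <= scenario.alpha:
            rejections += 1
    rate = rejections / n_reps
    return OperatingCharacteristics(
        scenario_id=scenario.name,
        nominal_alpha=scenario.alpha,
        method=scenario.method,
        n_reps=n_reps,
        rejection_rate=rate,
        mc_standard_error=math.sqrt(rate * (1.0 - rate) / n_reps),
        seed=seed,
    )


# --- worked example ------------------------------------------------------


@dataclass
class AveragingFallacyTable:
    """Three-drug example: the drug that wins on average loses for every
    single patient against the per-patient best of the other two."""

    average_efficacy: Dict[str, float]
    per_patient_best_efficacy: float
    best_on_average: str
    best_for_each_patient_ratio: float
    n_patients: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"quantity": f"average_efficacy_{d}", "value": v}
            for d, v in sorted(self.average_efficacy.items())
        ]
        rows.append(
            {"quantity": "per_patient_best_of_AB", "value": self.per_patient_best_efficacy}
        )
        rows.append(
            {"quantity": "per_patient_to_C_ratio", "value": self.best_for_each_patient_ratio}
        )
        return pd.DataFrame(rows)


def averaging_fallacy_demo(n_patients: int = 1000) -> AveragingFallacyTable:
    """Build the two-subpopulation, three-drug example and compute per-drug
    population averages and the per-patient best of drugs A and B.

    Half the population responds to drug A with 2 units and to B with 0;
    the other half is the reverse; drug C delivers 1.1 units to everyone.
    """
    if n_patients < 2 or n_patients % 2 != 0:
        raise ConfigurationError("n_patients must be an even number >= 2")
    half = n_patients // 2
    eff_a = np.concatenate([np.full(half, 2.0), np.full(half, 0.0)])
    eff_b = np.concatenate([np.full(half, 0.0), np.full(half, 2.0)])
    eff_c = np.full(n_patients, 1.1)
    # two equal subpopulations with constant response in each: the population
    # average is the half-weighted mean of the two subpopulation values
    # (exact in floating point, unlike a naive running sum over patients)
    averages = {
        "A": 0.5 * eff_a[0] + 0.5 * eff_a[-1],
        "B": 0.5 * eff_b[0] + 0.5 * eff_b[-1],
        "C": 0.5 * eff_c[0] + 0.5 * eff_c[-1],
    }
    for drug, eff in (("A", eff_a), ("B", eff_b), ("C", eff_c)):
        assert abs(averages[drug] - eff.mean()) < 1e-12
    per_patient_best = float(np.minimum.reduce([np.maximum(eff_a, eff_b)]).min())
    best_on_average = max(averages, key=averages.get)
    if best_on_average != "C":
        raise AssertionError("drug C must win on average in this fixture")
    if not np.all(np.maximum(eff_a, eff_b) > eff_c):
        raise AssertionError("the per-patient best must beat C for every patient")
    return AveragingFallacyTable(
        average_efficacy=averages,
        per_patient_best_efficacy=per_patient_best,
        best_on_average=best_on_average,
        best_for_each_patient_ratio=per_patient_best / averages["C"],
        n_patients=n_patients,
    )


def averaging_fallacy_population() -> Dict[str, PopulationModel]:
    """The same example expressed as population models, one per drug arm 1
    (arm 0 is no treatment, efficacy 0)."""
    def model(first_half: float, second_half: float) -> PopulationModel:
        return PopulationModel(
            categories=[
                ResponseCategory("responders-A", (0.0, first_half), 0.5),
                ResponseCategory("responders-B", (0.0, second_half), 0.5),
            ]
        )

    return {
        "A": model(2.0, 0.0),
        "B": model(0.0, 2.0),
        "C": PopulationModel(categories=[ResponseCategory("all", (0.0, 1.1), 1.0)]),
    }


# --- random sample size --------------------------------------------------


def random_sample_size_demo(
    laws: Sequence[IntegerLaw],
    summand: ResponseDistribution,
    reps: int,
    seed,
) -> pd.DataFrame:
    """KS distance between the standardized random-sum mean and the
    standard normal, one row per sample-size law.

    The sum S_N of N iid summands is standardized by its exact first two
    moments, ``(S_N - mu*E[N]) / sqrt(E[N]*sigma^2 + Var(N)*mu^2)``.
    Fixed and Poisson sample sizes stay close to normal; geometric sample
    sizes converge to a heavy-tailed (Laplace-type) limit instead.
    """
    if reps < 1000:
        raise ConfigurationError("reps must be >= 1000")
    if summand.is_degenerate():
        raise ConfigurationError("summand distribution must be non-degenerate")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    mu = summand.mean()
    sigma2 = summand.var()
    rows = []
    for law in laws:
        sizes = law.sample(rng, reps).astype(np.int64)
        flat = summand.sample(rng, int(sizes.sum()))
        csum = np.concatenate([[0.0], np.cumsum(flat)])
        ends = np.cumsum(sizes)
        sums = csum[ends] - csum[ends - sizes]
        denom = math.sqrt(law.mean() * sigma2 + law.var() * mu**2)
        z = (sums - mu * law.mean()) / denom
        rows.append(
            {
                "law": law.kind,
                "expected_n": law.mean(),
                "ks_distance": float(stats.kstest(z, "norm").statistic),
                "reps": reps,
            }
        )
    return pd.DataFrame(rows)


# --- scenario presets and reports ---------------------------------------


def _iid_normal_population() -> PopulationModel:
    return PopulationModel(
        categories=[ResponseCategory("all", (normal(0.0, 1.0), normal(0.0, 1.0)), 1.0)]
    )


def _clustered_population(r: float = 0.5, cluster_size: int = 2) -> PopulationModel:
    return PopulationModel(
        categories=[ResponseCategory("all", (normal(0.0, 1.0), normal(0.0, 1.0)), 1.0)],
        dependence=DependenceSpec(
            mode="clustered",
            cluster_size_law=IntegerLaw("constant", {"value": cluster_size}),
            intra_cluster_correlation=r,
        ),
    )


def _heterogeneous_population(effect_sd: float = 0.0) -> PopulationModel:
    return PopulationModel(
        category_law=CategoryLawSpec(
            k_law=IntegerLaw("poisson", {"mean": 5.0, "shift": 1}),
            concentration=1.0,
            between_sd=1.0,
            within_sd=1.0,
            effect_sd=effect_sd,
        )
    )


SCENARIO_PRESETS = {
    "iid-normal-null": lambda: ScenarioConfig(
        name="iid-normal-null",
        population=_iid_normal_population(),
        design=TrialDesign(),
        n_subjects=200,
        method="parametric",
    ),
    "iid-normal-null-permutation": lambda: ScenarioConfig(
        name="iid-normal-null-permutation",
        population=_iid_normal_population(),
        design=TrialDesign(),
        n_subjects=200,
        method="permutation-mc",
        mc_draws=499,
    ),
    "iid-normal-shift": lambda: ScenarioConfig(
        name="iid-normal-shift",
        population=_iid_normal_population(),
        design=TrialDesign(),
        n_subjects=200,
        method="parametric",
        hypothesis="shift",
        shift=0.4,
    ),
    "clustered-null-parametric": lambda: ScenarioConfig(
        name="clustered-null-parametric",
        population=_clustered_population(),
        design=TrialDesign(randomize_clusters=True),
        n_subjects=200,
        method="parametric",
    ),
    "clustered-null-permutation": lambda: ScenarioConfig(
        name="clustered-null-permutation",
        population=_clustered_population(),
        design=TrialDesign(randomize_clusters=True),
        n_subjects=200,
        method="permutation-mc",
        mc_draws=499,
    ),
    "heterogeneous-null": lambda: ScenarioConfig(
        name="heterogeneous-null",
        population=_heterogeneous_population(),
        design=TrialDesign(),
        n_subjects=200,
        method="parametric",
    ),
}


def scenario_preset(name: str, **overrides) -> ScenarioConfig:
    if name not in SCENARIO_PRESETS:
        raise ConfigurationError(
            f"unknown scenario {name!r}; available: {sorted(SCENARIO_PRESETS)}"
        )
    scenario = SCENARIO_PRESETS[name]()
    return replace(scenario, **overrides) if overrides else scenario


def _config_hash(config: dict) -> str:
    canonical = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()


def run_report(config: dict, out_dir, seed: int) -> dict:
    """Execute every scenario named in the config and write one table per
    scenario plus a JSON manifest; same config + seed replays bit-exactly.

    Config keys: ``scenarios`` (list of preset names), ``n_reps``
    (default 1000), and optional per-run overrides under ``overrides``
    keyed by scenario name.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    names = list(config.get("scenarios", []))
    n_reps = int(config.get("n_reps", 1000))
    overrides = config.get("overrides", {})
    root = np.random.SeedSequence(seed)
    scenario_seeds = [int(s.generate_state(1)[0]) for s in root.spawn(max(len(names), 1))]
    manifest = {
        "config_hash": _config_hash(config),
        "seed": seed,
        "package_version": __version__,
        "numpy_version": np.__version__,
        "scenarios": {},
        "tables": [],
    }
    import scipy

    manifest["scipy_version"] = scipy.__version__
    for name, sc_seed in zip(names, scenario_seeds):
        scenario = scenario_preset(name, **overrides.get(name, {}))
        oc = run_operating_characteristics(scenario, n_reps, sc_seed)
        table_path = out / f"oc_{name}.tsv"
        oc.to_frame().to_csv(table_path, sep="\t", index=False)
        manifest["scenarios"][name] = {"seed": sc_seed, "n_reps": n_reps}
        manifest["tables"].append(table_path.name)
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
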