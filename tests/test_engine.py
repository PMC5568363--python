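import itertools
import math

import numpy as np
import pytest
from scipy import stats

import permtrial as pt
from permtrial.distributions import ConfigurationError
from permtrial.engine import enumerate_allocations, sample_label_matrix


class TestRandomize:
    def test_complete_balanced_even(self, fixed_cohort_factory):
        cohort = fixed_cohort_factory([1.0, 2.0, 3.0, 4.0])
        for seed in range(10):
            allocation = pt.randomize(cohort, pt.TrialDesign(), seed)
            assert allocation.arm_sizes() == (2, 2)

    def test_complete_balanced_odd_differs_by_one(self, fixed_cohort_factory):
        cohort = fixed_cohort_factory([1.0, 2.0, 3.0, 4.0, 5.0])
        for seed in range(10):
            n0, n1 = pt.randomize(cohort, pt.TrialDesign(), seed).arm_sizes()
            assert abs(n1 - n0) == 1

    def test_simple_coin_fraction(self, fixed_cohort_factory):
        cohort = fixed_cohort_factory(np.zeros(10_000))
        design = pt.TrialDesign(allocation_scheme="simple-coin")
        allocation = pt.randomize(cohort, design, 3)
        frac = allocation.arms.mean()
        assert abs(frac - 0.5) < 3 * math.sqrt(0.25 / 10_000)

    def test_permuted_block_balance(self, fixed_cohort_factory):
        cohort = fixed_cohort_factory(np.zeros(8))
        design = pt.TrialDesign(allocation_scheme="permuted-block", block_length=4)
        for seed in range(10):
            arms = pt.randomize(cohort, design, seed).arms
            for lo in range(0, 8, 4):
                assert arms[lo : lo + 4].sum() == 2

    def test_partial_final_block_truncated_balanced(self, fixed_cohort_factory):
        cohort = fixed_cohort_factory(np.zeros(10))
        design = pt.TrialDesign(allocation_scheme="permuted-block", block_length=4)
        for seed in range(10):
            arms = pt.randomize(cohort, design, seed).arms
            assert arms[8:].sum() == 1  # 2-subject tail split 1/1

    def test_cluster_randomization_keeps_clusters_together(self, iid_normal_model):
        from permtrial.distributions import IntegerLaw

        model = pt.PopulationModel(
            categories=iid_normal_model.categories,
            dependence=pt.DependenceSpec(
                mode="clustered",
                cluster_size_law=IntegerLaw("constant", {"value": 2}),
                intra_cluster_correlation=0.0,
            ),
        )
        cohort = pt.sample_subjects(model, 40, 0)
        design = pt.TrialDesign(randomize_clusters=True)
        allocation = pt.randomize(cohort, design, 1)
        for cl in np.unique(cohort.cluster_id):
            arms = allocation.arms[cohort.cluster_id == cl]
            assert len(set(arms.tolist())) == 1

    def test_empty_cohort_rejected(self, fixed_cohort_factory):
        cohort = fixed_cohort_factory([1.0]).subset(np.array([], dtype=int))
        with pytest.raises(ConfigurationError):
            pt.randomize(cohort, pt.TrialDesign(), 0)


class TestSampleSizeRegimes:
    def test_full_retention_is_identity(self, fixed_cohort_factory):
        cohort = fixed_cohort_factory(np.arange(20.0))
        design = pt.TrialDesign(sample_size_regime="dropout", retention=1.0)
        retained = pt.apply_sample_size_regime(cohort, design, 0)
        assert np.array_equal(retained.subject_id, cohort.subject_id)

    def test_dropout_binomial_count(self, fixed_cohort_factory):
        cohort = fixed_cohort_factory(np.zeros(10_000))
        design = pt.TrialDesign(sample_size_regime="dropout", retention=0.8)
        retained = pt.apply_sample_size_regime(cohort, design, 5)
        se = math.sqrt(10_000 * 0.8 * 0.2)
        assert abs(len(retained) - 8_000) < 3 * se

    def test_poisson_total_mean(self, fixed_cohort_factory):
        cohort = fixed_cohort_factory(np.zeros(200))
        design = pt.TrialDesign(sample_size_regime="poisson-total", poisson_mean=50.0)
        rng = np.random.default_rng(9)
        sizes = [
            len(pt.apply_sample_size_regime(cohort, design, rng)) for _ in range(10_000)
        ]
        se = math.sqrt(50.0 / 10_000)
        assert abs(np.mean(sizes) - 50.0) < 3 * se

    def test_poisson_total_pads_through_factory(self, fixed_cohort_factory):
        cohort = fixed_cohort_factory(np.zeros(10))
        design = pt.TrialDesign(sample_size_regime="poisson-total", poisson_mean=40.0)

        def factory(extra_n, rng):
            return fixed_cohort_factory(np.ones(extra_n))

        retained = pt.apply_sample_size_regime(cohort, design, 2, cohort_factory=factory)
        assert len(retained) > 10
        assert len(np.unique(retained.subject_id)) == len(retained)

    def test_poisson_total_overflow_without_factory(self, fixed_cohort_factory):
        cohort = fixed_cohort_factory(np.zeros(5))
        design = pt.TrialDesign(sample_size_regime="poisson-total", poisson_mean=50.0)
        with pytest.raises(ConfigurationError, match="cohort_factory"):
            pt.apply_sample_size_regime(cohort, design, 0)

    def test_invalid_poisson_mean_rejected(self):
        with pytest.raises(ConfigurationError):
            pt.TrialDesign(sample_size_regime="poisson-total", poisson_mean=0.0)

    def test_event_driven_retains_until_target(self, fixed_cohort_factory):
        cohort = fixed_cohort_factory([0.0, 2.0, 0.0, 2.0, 2.0, 0.0])
        design = pt.TrialDesign(
            sample_size_regime="event-driven", event_threshold=1.0, event_target=2
        )
        retained = pt.apply_sample_size_regime(cohort, design, 0)
        assert len(retained) == 4  # subjects up to and including the 2nd event

    def test_event_driven_insufficient_events(self, fixed_cohort_factory):
        cohort = fixed_cohort_factory([0.0, 0.0, 2.0])
        design = pt.TrialDesign(
            sample_size_regime="event-driven", event_threshold=1.0, event_target=5
        )
        with pytest.raises(ConfigurationError, match="events"):
            pt.apply_sample_size_regime(cohort, design, 0)


class TestRealizeTrial:
    def _trial(self, y1_vals, y0_vals):
        y = np.array(list(y1_vals) + list(y0_vals), dtype=float)
        n = y.size
        cohort = pt.Cohort(
            subject_id=np.arange(n),
            cluster_id=np.arange(n),
            category=np.zeros(n, dtype=object),
            y0=y,
            y1=y,
        )
        arms = np.array([1] * len(y1_vals) + [0] * len(y0_vals), dtype=np.int8)
        return pt.realize_trial(cohort, pt.Allocation(cohort.subject_id, arms))

    def test_zero_delta(self):
        trial = self._trial([2.0, 0.0], [1.0, 1.0])
        assert trial.delta == pytest.approx(0.0, abs=1e-12)
        assert trial.a1 == pytest.approx(1.0) and trial.a0 == pytest.approx(1.0)

    def test_unit_delta(self):
        trial = self._trial([3.0, 1.0], [2.0, 0.0])
        assert trial.delta == pytest.approx(1.0, abs=1e-12)

    def test_uniform_drug_arm_mean(self):
        # every patient responds 1.1 to the across-the-board drug
        trial = self._trial([1.1] * 10, [0.0] * 10)
        assert trial.a1 == pytest.approx(1.1, abs=1e-12)

    def test_delta_consistency_invariant(self, iid_normal_model):
        cohort = pt.sample_subjects(iid_normal_model, 30, 2)
        trial = pt.realize_trial(cohort, pt.randomize(cohort, pt.TrialDesign(), 3))
        y1 = trial.observed[trial.arms == 1]
        y0 = trial.observed[trial.arms == 0]
        assert trial.delta == pytest.approx(y1.mean() - y0.mean(), abs=1e-12)
        assert trial.n1 + trial.n0 == len(cohort)

    def test_degenerate_arm_flags_z(self):
        trial = self._trial([1.0, 1.0], [0.0, 0.0])
        assert not trial.z_available and trial.z is None
        assert trial.delta == pytest.approx(1.0)

    def test_single_subject_arm_flags_z(self):
        trial = self._trial([3.0], [1.0, 2.0, 0.0])
        assert not trial.z_available
        assert trial.delta == pytest.approx(2.0)

    def test_welch_z_value(self):
        trial = self._trial([3.0, 1.0], [2.0, 0.0])
        s2 = np.var([3.0, 1.0], ddof=1)
        expected = 1.0 / math.sqrt(s2 / 2 + s2 / 2)
        assert trial.z == pytest.approx(expected, abs=1e-12)

    def test_pooled_option(self):
        trial_w = self._trial([3.0, 1.0, 2.0], [2.0, 0.0])
        trial_p = pt.realize_trial(
            pt.Cohort(
                trial_w.subject_id, trial_w.cluster_id,
                np.zeros(5, dtype=object), trial_w.observed, trial_w.observed,
            ),
            pt.Allocation(trial_w.subject_id, trial_w.arms),
            pooled=True,
        )
        assert trial_p.pooled and trial_p.z != pytest.approx(trial_w.z)

    def test_bit_identical_re_realization(self, iid_normal_model):
        cohort = pt.sample_subjects(iid_normal_model, 20, 4)
        allocation = pt.randomize(cohort, pt.TrialDesign(), 5)
        a = pt.realize_trial(cohort, allocation)
        b = pt.realize_trial(cohort, allocation)
        assert a.delta == b.delta and a.z == b.z
        assert np.array_equal(a.observed, b.observed)


class TestEnumeration:
    def test_complete_balanced_count(self, fixed_cohort_factory):
        cohort = fixed_cohort_factory(np.zeros(4))
        ensemble = enumerate_allocations(cohort, pt.TrialDesign())
        assert ensemble.exact and ensemble.total_count == 6
        assert ensemble.unit_labels.shape == (6, 4)

    def test_permuted_block_count(self, fixed_cohort_factory):
        cohort = fixed_cohort_factory(np.zeros(4))
        design = pt.TrialDesign(allocation_scheme="permuted-block", block_length=2)
        ensemble = enumerate_allocations(cohort, design)
        assert ensemble.total_count == 4
        rows = {tuple(r) for r in ensemble.unit_labels}
        # oracle: brute-force product of balanced 2-blocks
        oracle = {
            (a, 1 - a, b, 1 - b) for a in (0, 1) for b in (0, 1)
        }
        assert rows == oracle

    def test_simple_coin_count(self, fixed_cohort_factory):
        cohort = fixed_cohort_factory(np.zeros(3))
        design = pt.TrialDesign(allocation_scheme="simple-coin")
        ensemble = enumerate_allocations(cohort, design)
        assert ensemble.total_count == 8
        assert len({tuple(r) for r in ensemble.unit_labels}) == 8

    @pytest.mark.parametrize("n", [4, 6, 8, 10, 12, 5, 7])
    def test_balanced_enumeration_matches_oracle(
        self, n, fixed_cohort_factory, balanced_splits_oracle
    ):
        cohort = fixed_cohort_factory(np.zeros(n))
        ensemble = enumerate_allocations(cohort, pt.TrialDesign())
        rows = sorted(tuple(int(x) for x in r) for r in ensemble.unit_labels)
        assert rows == sorted(balanced_splits_oracle(n))

    def test_coin_enumeration_matches_oracle(self, fixed_cohort_factory):
        cohort = fixed_cohort_factory(np.zeros(6))
        design = pt.TrialDesign(allocation_scheme="simple-coin")
        ensemble = enumerate_allocations(cohort, design)
        rows = sorted(tuple(int(x) for x in r) for r in ensemble.unit_labels)
        assert rows == sorted(itertools.product((0, 1), repeat=6))

    def test_block_enumeration_matches_oracle(self, fixed_cohort_factory):
        cohort = fixed_cohort_factory(np.zeros(10))
        design = pt.TrialDesign(allocation_scheme="permuted-block", block_length=4)
        ensemble = enumerate_allocations(cohort, design)

        def balanced(k):
            out = []
            ks = [k // 2] if k % 2 == 0 else [k // 2, k // 2 + 1]
            for kk in ks:
                for combo in itertools.combinations(range(k), kk):
                    row = [0] * k
                    for i in combo:
                        row[i] = 1
                    out.append(tuple(row))
            return out

        oracle = sorted(
            a + b + c
            for a in balanced(4)
            for b in balanced(4)
            for c in balanced(2)
        )
        rows = sorted(tuple(int(x) for x in r) for r in ensemble.unit_labels)
        assert rows == oracle
        assert ensemble.total_count == 6 * 6 * 2

    def test_fallback_to_sampling_beyond_limit(self, fixed_cohort_factory):
        cohort = fixed_cohort_factory(np.zeros(30))
        ensemble = enumerate_allocations(cohort, pt.TrialDesign(), limit=1000, seed=0)
        assert not ensemble.exact
        assert ensemble.n_allocations == 1000
        assert ensemble.total_count == math.comb(30, 15)

    def test_sampled_allocations_uniform_over_exact_set(self):
        # chi-square uniformity of complete-balanced draws over C(4,2) cells
        rng = np.random.default_rng(17)
        labels = sample_label_matrix(4, 100_000, "complete-balanced", None, rng)
        keys = labels @ np.array([8, 4, 2, 1])
        _, counts = np.unique(keys, return_counts=True)
        assert counts.size == 6
        assert stats.chisquare(counts).pvalue > 1e-3

    def test_cluster_level_enumeration(self, iid_normal_model):
        from permtrial.distributions import IntegerLaw

        model = pt.PopulationModel(
            categories=iid_normal_model.categories,
            dependence=pt.DependenceSpec(
                mode="clustered",
                cluster_size_law=IntegerLaw("constant", {"value": 2}),
                intra_cluster_correlation=0.0,
            ),
        )
        cohort = pt.sample_subjects(model, 8, 0)
        design = pt.TrialDesign(randomize_clusters=True)
        ensemble = enumerate_allocations(cohort, design)
        assert ensemble.total_count == 6  # C(4, 2) over the 4 clusters
        subject_labels = ensemble.subject_matrix()
        assert subject_labels.shape == (6, 8)
        for row in subject_labels:
            for cl in np.unique(cohort.cluster_id):
                assert len(set(row[cohort.cluster_id == cl].tolist())) == 1


class TestDesignValidation:
    def test_odd_block_length_rejected(self):
        with pytest.raises(ConfigurationError):
            pt.TrialDesign(allocation_scheme="permuted-block", block_length=3)

    def test_bad_retention_rejected(self):
        with pytest.raises(ConfigurationError):
            pt.TrialDesign(sample_size_regime="dropout", retention=0.0)

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ConfigurationError):
            pt.TrialDesign(allocation_scheme="minimization")


class TestTrialFromTable:
    def test_roundtrip(self):
        import pandas as pd

        df = pd.DataFrame(
            {
                "subject_id": [0, 1, 2, 3],
                "arm": [1, 1, 0, 0],
                "response": [3.0, 1.0, 2.0, 0.0],
            }
        )
        trial = pt.trial_from_table(df)
        assert trial.delta == pytest.approx(1.0)
        assert trial.n1 == 2 and trial.n0 == 2
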