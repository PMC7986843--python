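"""Bootstrap resampling and Jaccard co-membership stability."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netstab import (
    BootstrapEnsemble,
    ModuleSet,
    bootstrap_modules,
    bootstrap_resample,
    module_stability,
    node_jaccard,
    node_stability,
    overall_stability,
    partition_agreement,
    stability_report,
    unconditional_observed_stability,
)

from conftest import random_partition


def brute_force_node_jaccard(a: ModuleSet, b: ModuleSet, node: str) -> float:
    sa = {n for n in a.nodes if a.module_id_of(n) == a.module_id_of(node)}
    sb = {n for n in b.nodes if b.module_id_of(n) == b.module_id_of(node)}
    return len(sa & sb) / len(sa | sb)


class TestBootstrapResample:
    def test_seeded_determinism(self, toy_data):
        a = bootstrap_resample(toy_data, seed=5)
        b = bootstrap_resample(toy_data, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_same_columns_and_shape(self, toy_data):
        out = bootstrap_resample(toy_data, seed=0)
        assert out.shape == toy_data.shape
        assert list(out.columns) == list(toy_data.columns)

    def test_row_inclusion_frequency_matches_closed_form(self):
        # P(row included in a bootstrap of n=5) = 1 - (1 - 1/5)^5
        n, reps = 5, 10_000
        data = pd.DataFrame({"a": np.arange(n, dtype=float), "b": np.arange(n) ** 2.0})
        rng = np.random.default_rng(123)
        included = 0
        for _ in range(reps):
            included += 0 in set(bootstrap_resample(data, rng).index)
        expected = 1 - (1 - 1 / n) ** n
        se = (expected * (1 - expected) / reps) ** 0.5
        assert abs(included / reps - expected) < 3 * se


class TestJaccardAndAgreement:
    def test_identical_partitions_score_one(self, pair_partitions):
        a, _ = pair_partitions
        assert node_jaccard(a, a, "1") == 1.0
        assert partition_agreement(a, a) == 1.0

    def test_forced_quarter_example(self):
        a = ModuleSet.from_modules([{"n", "x", "y"}, {"z"}])
        b = ModuleSet.from_modules([{"n", "z"}, {"x"}, {"y"}])
        assert node_jaccard(a, b, "n") == pytest.approx(1 / 4)

    def test_worked_four_node_agreement(self, pair_partitions):
        a, b = pair_partitions
        # node-wise: 2/3, 2/3, 1/4, 1/2 -> mean 25/48
        assert partition_agreement(a, b) == pytest.approx(25 / 48)
        assert partition_agreement(b, a) == pytest.approx(25 / 48)

    def test_singletons_agree_perfectly(self):
        a = ModuleSet(list("abcd"), [0, 1, 2, 3])
        b = ModuleSet(list("abcd"), [3, 2, 1, 0])
        assert partition_agreement(a, b) == 1.0

    def test_mismatched_node_sets_error(self, pair_partitions):
        a, _ = pair_partitions
        other = ModuleSet.from_modules([{"x", "y"}])
        with pytest.raises(ValueError, match="node set"):
            partition_agreement(a, other)
        with pytest.raises(KeyError):
            node_jaccard(a, a, "zzz")

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), p=st.integers(2, 12))
    def test_agreement_matches_set_arithmetic_oracle(self, seed, p):
        rng = np.random.default_rng(seed)
        nodes = [f"n{i}" for i in range(p)]
        a = random_partition(rng, nodes)
        b = random_partition(rng, nodes)
        expected = np.mean([brute_force_node_jaccard(a, b, n) for n in nodes])
        assert partition_agreement(a, b) == pytest.approx(expected, abs=1e-12)
        assert partition_agreement(a, b) == pytest.approx(partition_agreement(b, a))
        for n in nodes:
            assert node_jaccard(a, b, n) == pytest.approx(
                brute_force_node_jaccard(a, b, n)
            )


class TestStabilityLevels:
    @pytest.fixture
    def mixed_ensemble(self, pair_partitions):
        a, b = pair_partitions
        return BootstrapEnsemble(reference=a, replicates=(b, a))

    def test_all_identical_replicates_give_unit_stability(self, pair_partitions):
        a, _ = pair_partitions
        ens = BootstrapEnsemble(reference=a, replicates=(a, a, a))
        report = stability_report(ens)
        assert report.overall == 1.0
        assert all(v == 1.0 for v in report.node_stability.values())
        assert all(v == 1.0 for v in report.module_stability.values())

    def test_two_replicate_node_average(self, mixed_ensemble):
        # node "3": Jaccard vs replicate b is 1/4, vs copy of reference 1
        assert node_stability(mixed_ensemble, "3") == pytest.approx((1 / 4 + 1) / 2)

    def test_module_stability_is_mean_of_member_nodes(self, mixed_ensemble):
        report = stability_report(mixed_ensemble)
        ref = mixed_ensemble.reference
        for mid, val in report.module_stability.items():
            members = [n for n in ref.nodes if ref.module_id_of(n) == mid]
            expected = np.mean([report.node_stability[n] for n in members])
            assert val == pytest.approx(expected, abs=1e-12)
            assert module_stability(mixed_ensemble, mid) == pytest.approx(val)

    def test_overall_equals_mean_node_stability(self, mixed_ensemble):
        report = stability_report(mixed_ensemble)
        assert report.overall == pytest.approx(
            np.mean(list(report.node_stability.values())), abs=1e-12
        )
        assert overall_stability(mixed_ensemble) == pytest.approx(report.overall)

    def test_single_replicate_overall_is_pair_agreement(self, pair_partitions):
        a, b = pair_partitions
        ens = BootstrapEnsemble(reference=a, replicates=(b,))
        assert overall_stability(ens) == pytest.approx(25 / 48)

    def test_copying_reference_into_a_replicate_never_decreases_stability(
        self, pair_partitions
    ):
        a, b = pair_partitions
        before = stability_report(BootstrapEnsemble(a, (b, b)))
        after = stability_report(BootstrapEnsemble(a, (b, a)))
        for n in a.nodes:
            assert after.node_stability[n] >= before.node_stability[n]

    def test_values_lie_in_unit_interval(self, mixed_ensemble):
        report = stability_report(mixed_ensemble)
        values = [report.overall, *report.node_stability.values(), *report.module_stability.values()]
        assert all(0 < v <= 1 for v in values)

    def test_unknown_labels_are_rejected(self, mixed_ensemble):
        with pytest.raises(KeyError):
            node_stability(mixed_ensemble, "nope")
        with pytest.raises(ValueError):
            module_stability(mixed_ensemble, 99)


class TestUnconditionalObservedStability:
    def test_all_identical_sets_score_one(self, pair_partitions):
        a, _ = pair_partitions
        assert unconditional_observed_stability([a, a, a]) == 1.0

    def test_three_set_enumeration(self, pair_partitions):
        a, b = pair_partitions
        expected = (1 + 25 / 48 + 25 / 48) / 3
        assert unconditional_observed_stability([a, a, b]) == pytest.approx(expected)

    def test_matches_mean_of_per_set_means(self, pair_partitions):
        # the unordered-pair mean equals (1/(B+1)) sum_i mean_{j != i} A(Mi, Mj)
        rng = np.random.default_rng(9)
        nodes = [f"n{i}" for i in range(8)]
        sets = [random_partition(rng, nodes) for _ in range(5)]
        direct = unconditional_observed_stability(sets)
        per_set = [
            np.mean([partition_agreement(si, sj) for j, sj in enumerate(sets) if j != i])
            for i, si in enumerate(sets)
        ]
        assert direct == pytest.approx(np.mean(per_set), abs=1e-12)

    def test_requires_at_least_two_sets(self, pair_partitions):
        with pytest.raises(ValueError):
            unconditional_observed_stability([pair_partitions[0]])


class TestBootstrapPipeline:
    def test_fixed_seed_reproducible_ensemble(self, toy_data):
        e1 = bootstrap_modules(toy_data, t=0.4, B=5, seed=11)
        e2 = bootstrap_modules(toy_data, t=0.4, B=5, seed=11)
        assert e1.reference == e2.reference
        assert e1.replicates == e2.replicates

    def test_degenerate_replicate_is_redrawn(self):
        # two distinct rows: a resample drawing one row N times is constant
        data = pd.DataFrame(
            {"a": [0.0, 1.0, 2.0, 0.5], "b": [1.0, 0.0, 1.5, 2.0], "c": [2.0, 1.0, 0.0, 1.0]}
        )
        small = data.iloc[:3]
        with pytest.warns(UserWarning, match="redrawn"):
            # with N=3 the all-same-row draw has probability 3*(1/27) per
            # replicate; 300 replicates make at least one near-certain
            ens = bootstrap_modules(small, t=0.5, B=300, seed=2)
        assert ens.B == 300
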