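"""Subsampling distances, CDF interpolation, agreement and correlation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from percept import cohort, evaluation
from percept.cohort import FeatureTable


def _ratio_table(values: np.ndarray) -> FeatureTable:
    data = pd.DataFrame(
        values,
        index=[f"f{i}" for i in range(values.shape[0])],
        columns=[f"d{j}" for j in range(values.shape[1])],
    )
    return FeatureTable(data=data, value_space="log2_ratio")


class TestDistance:
    def test_identical_vectors(self):
        assert evaluation.distance_to_population([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_constant_offset(self):
        v = np.array([0.3, -1.2, 4.0])
        assert evaluation.distance_to_population(v + 0.7, v) == pytest.approx(0.7)

    def test_hand_arithmetic(self):
        assert evaluation.distance_to_population([1.0, 2.0], [0.0, 0.0]) == 1.5

    def test_aligned_on_index_with_nulls(self):
        a = pd.Series({"x": 1.0, "y": np.nan, "z": 2.0})
        b = pd.Series({"y": 5.0, "z": 1.0, "x": 1.0, "w": 9.0})
        assert evaluation.distance_to_population(a, b) == pytest.approx(0.5)

    def test_no_overlap_errors(self):
        a = pd.Series({"x": 1.0})
        b = pd.Series({"y": 1.0})
        with pytest.raises(ValueError, match="overlap"):
            evaluation.distance_to_population(a, b)

    def test_pseudometric_on_fixed_features(self, rng):
        a, b, c = rng.normal(0, 1, (3, 30))
        d = evaluation.distance_to_population
        assert d(a, b) == pytest.approx(d(b, a))
        assert d(a, c) <= d(a, b) + d(b, c) + 1e-12


class TestSubsampleDonors:
    def test_full_draw_recovers_population(self, rng):
        table = _ratio_table(rng.normal(0, 0.5, (20, 6)))
        trials = evaluation.subsample_donors(table, k=5, trials=1, seed=0, F=20)
        # k < donors is required; with k = n-1 distances stay small but > 0
        assert trials[0].raw_distance > 0
        with pytest.raises(ValueError):
            evaluation.subsample_donors(table, k=6, trials=1, seed=0)

    def test_population_default_is_the_table_mean(self, rng):
        values = rng.normal(0, 0.5, (10, 8))
        table = _ratio_table(values)
        pop = table.data.mean(axis=1)
        [trial] = evaluation.subsample_donors(table, k=4, trials=1, seed=3, F=20)
        expected = evaluation.distance_to_population(trial.raw_means, pop)
        assert trial.raw_distance == pytest.approx(expected)

    def test_deterministic_under_seed(self, rng):
        table = _ratio_table(rng.normal(0, 0.5, (10, 9)))
        a = evaluation.subsample_donors(table, k=5, trials=4, seed=11, F=20)
        b = evaluation.subsample_donors(table, k=5, trials=4, seed=11, F=20)
        assert [t.donor_ids for t in a] == [t.donor_ids for t in b]
        assert [t.scaled_distance for t in a] == [t.scaled_distance for t in b]


class TestNormalizeDistances:
    def test_single_trial(self):
        t = evaluation.SubsampleTrial(0, ("d0",), pd.Series(), pd.Series(), 2.0, 1.0)
        [out] = evaluation.normalize_distances([t])
        assert (out.raw_distance, out.scaled_distance) == (1.0, 0.5)

    def test_hand_arithmetic_and_unit_mean(self):
        mk = lambda i, r, s: evaluation.SubsampleTrial(
            i, ("d0",), pd.Series(), pd.Series(), r, s
        )
        out = evaluation.normalize_distances([mk(0, 2.0, 1.0), mk(1, 4.0, 2.0)])
        assert [t.raw_distance for t in out] == pytest.approx([2 / 3, 4 / 3])
        assert [t.scaled_distance for t in out] == pytest.approx([1 / 3, 2 / 3])
        assert np.mean([t.raw_distance for t in out]) == pytest.approx(1.0)

    def test_idempotent_after_first_application(self):
        mk = lambda i, r, s: evaluation.SubsampleTrial(
            i, ("d0",), pd.Series(), pd.Series(), r, s
        )
        once = evaluation.normalize_distances([mk(0, 3.0, 2.0), mk(1, 1.0, 0.5)])
        twice = evaluation.normalize_distances(once)
        assert [t.raw_distance for t in twice] == pytest.approx(
            [t.raw_distance for t in once]
        )


class TestInterpolateCdf:
    def test_constant_input(self):
        out = evaluation.interpolate_cdf([3.0, 3.0, 3.0])
        assert (out == 3.0).all()
        assert len(out) == 101

    def test_nearest_with_lower_tie_break(self):
        out = evaluation.interpolate_cdf([1.0, 2.0, 3.0, 4.0], increments=101)
        # positions are 0.25, 0.5, 0.75, 1.0; 0.6 is nearest to 0.5
        assert out.loc[0.6] == 2.0
        # 0.625 is equidistant between 0.5 and 0.75: lower wins
        exact = evaluation.interpolate_cdf([1.0, 2.0, 3.0, 4.0], increments=9)
        assert exact.loc[0.625] == 2.0

    @given(st.lists(st.floats(-100, 100), min_size=1, max_size=40))
    def test_monotone_and_bounded(self, values):
        out = evaluation.interpolate_cdf(values)
        arr = out.to_numpy()
        assert np.all(np.diff(arr) >= 0)
        assert arr.min() >= min(values) and arr.max() <= max(values)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            evaluation.interpolate_cdf([np.nan])

    def test_mean_cdf_grid(self, rng):
        samples = [rng.normal(0, 1, 50) for _ in range(5)]
        out = evaluation.mean_cdf(samples)
        assert list(out.columns) == ["mean", "sd"]
        assert len(out) == 101 and (out["sd"] >= 0).all()


class TestBlandAltman:
    def test_perfect_agreement(self):
        out = evaluation.bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (out.mean_difference, out.loa_low, out.loa_high) == (0.0, 0.0, 0.0)

    def test_symmetric_differences(self):
        # d = {-1, +1}: mean 0, sd sqrt(2), limits +/- 1.96*sqrt(2)
        out = evaluation.bland_altman([0.0, 1.0], [1.0, 0.0])
        assert out.mean_difference == 0.0
        assert out.loa_high == pytest.approx(1.96 * np.sqrt(2), abs=1e-9)
        assert out.loa_high == pytest.approx(2.772, abs=1e-3)
        assert out.loa_low == pytest.approx(-out.loa_high)

    @given(st.lists(st.tuples(st.floats(-50, 50), st.floats(-50, 50)),
                    min_size=2, max_size=30))
    def test_limits_bracket_the_mean(self, pairs):
        a, b = zip(*pairs)
        out = evaluation.bland_altman(list(a), list(b))
        assert out.loa_low <= out.mean_difference <= out.loa_high

    def test_needs_two_pairs(self):
        with pytest.raises(ValueError):
            evaluation.bland_altman([1.0], [2.0])


class TestPairwiseCorrelation:
    def test_self_pair_is_perfect(self, rng):
        v = pd.Series(rng.normal(0, 1, 50), index=[f"f{i}" for i in range(50)])
        pairs = evaluation.pairwise_correlation(
            {"a": v, "b": v.copy()}, {"a": "AD", "b": "AD"}
        )
        assert pairs.loc[0, "r"] == pytest.approx(1.0)
        assert pairs.loc[0, "relation"] == "inside"

    def test_independent_noise_is_null(self):
        rng = np.random.default_rng(123)
        idx = [f"f{i}" for i in range(1000)]
        a = pd.Series(rng.normal(0, 1, 1000), index=idx)
        b = pd.Series(rng.normal(0, 1, 1000), index=idx)
        pairs = evaluation.pairwise_correlation({"a": a, "b": b}, {"a": "AD", "b": "ALS"})
        assert abs(pairs.loc[0, "r"]) < 3 / np.sqrt(1000)
        assert pairs.loc[0, "relation"] == "outside"

    def test_too_few_shared_features_flags_null(self):
        a = pd.Series({"x": 1.0, "y": 2.0})
        b = pd.Series({"x": 1.0, "y": 3.0, "z": 0.0})
        pairs = evaluation.pairwise_correlation({"a": a, "b": b}, {"a": "d", "b": "d"})
        assert np.isnan(pairs.loc[0, "r"]) and pairs.loc[0, "n_shared"] == 2

    def test_shared_truth_correlates_stronger_after_scaling(self):
        # two studies of the same disease share true effects; scaling
        # suppresses the noise-dominated features, boosting cross-study R
        from percept.synthetic import CohortSpec, generate_cohort

        base = CohortSpec(n_features=300, n_control=6, n_case=5,
                          affected_fraction=0.3, effect_log2=1.0,
                          noise_sd_log2=0.5, seed=0)
        rng = np.random.default_rng(77)
        affected = rng.random(base.n_features) < base.affected_fraction
        truth = np.where(affected, rng.choice([-1.0, 1.0], base.n_features), 0.0)

        raw_rs, scaled_rs = [], []
        for seed in range(8):
            summaries = {}
            for name, s in (("s1", seed * 2 + 100), ("s2", seed * 2 + 101)):
                import dataclasses as dc

                table, _ = generate_cohort(dc.replace(base, seed=s), effects=truth)
                ratios = cohort.abundance_ratios(table)
                summaries[name] = cohort.scale_table(ratios, m0=0.0, F=20.0)
            raw = evaluation.pairwise_correlation(
                {k: v["m1"] for k, v in summaries.items()}, {"s1": "x", "s2": "x"}
            )
            scl = evaluation.pairwise_correlation(
                {k: v["V"] for k, v in summaries.items()}, {"s1": "x", "s2": "x"}
            )
            raw_rs.append(raw.loc[0, "r"])
            scaled_rs.append(scl.loc[0, "r"])
        assert np.mean(scaled_rs) > np.mean(raw_rs)


class TestCorrelationSummary:
    def test_groups_means_by_relation(self):
        pairs = pd.DataFrame(
            {
                "dataset_a": ["a", "a", "b"],
                "dataset_b": ["b", "c", "c"],
                "n_shared": [10, 10, 10],
                "r": [0.9, 0.1, 0.2],
                "relation": ["inside", "outside", "outside"],
            }
        )
        out = evaluation.correlation_summary(pairs)
        row = out[(out["dataset"] == "a") & (out["relation"] == "inside")]
        assert row["mean_r"].iloc[0] == pytest.approx(0.9)
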