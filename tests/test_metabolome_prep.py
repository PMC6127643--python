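import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from omicsconcord.concordance import icc_oneway
from omicsconcord.io_model import FeatureTable, ValidationError, pair_by_subject
from omicsconcord.metabolome_prep import (
    detectability,
    detectability_table,
    filter_by_detectability,
    half_min_impute,
    log10_transform,
    metabolite_icc_profile,
    min_detected_count,
    overlap_with_gold,
    preprocess_method,
    quantile_normalize,
)
from omicsconcord.synthetic_data import generate_metabolome
from conftest import make_design


def intensity_table(values: dict, features) -> FeatureTable:
    return FeatureTable(pd.DataFrame(values, index=features), "intensity")


@pytest.fixture
def two_method_table():
    design = make_design(3, methods=("gold", "alt"))
    data = {
        "S001.gold": [2.0, 10.0], "S002.gold": [4.0, np.nan], "S003.gold": [np.nan, 30.0],
        "S001.alt": [8.0, 100.0], "S002.alt": [6.0, np.nan], "S003.alt": [np.nan, 300.0],
    }
    return intensity_table(data, ["f1", "f2"]), design


class TestDetectability:
    def test_six_of_eight(self):
        design = make_design(8, methods=("gold", "alt"))
        cols = {s: [1.0] for s in design.samples_for_method("alt")}
        for s in list(cols)[:2]:
            cols[s] = [np.nan]
        cols.update({s: [1.0] for s in design.samples_for_method("gold")})
        table = intensity_table(cols, ["f1"])
        assert detectability(table, design, "alt")["f1"] == pytest.approx(0.75)

    def test_all_missing_and_none_missing(self, two_method_table):
        table, design = two_method_table
        frac = detectability(table, design, "gold")
        assert frac["f1"] == pytest.approx(2 / 3)
        assert frac["f2"] == pytest.approx(2 / 3)

    def test_unknown_method_is_error(self, two_method_table):
        table, design = two_method_table
        with pytest.raises(ValidationError):
            detectability(table, design, "nope")


class TestMinDetectedCount:
    def test_paper_value(self):
        assert min_detected_count(0.75, 8) == 6

    def test_full_detection(self):
        assert min_detected_count(1.0, 8) == 8

    def test_ceiling(self):
        assert min_detected_count(0.5, 7) == 4

    def test_invalid_level(self):
        for level in (0, -0.1, 1.1):
            with pytest.raises(ValidationError):
                min_detected_count(level, 8)

    @given(st.floats(0.01, 1.0), st.integers(1, 50))
    @settings(max_examples=100, deadline=None)
    def test_smallest_integer_satisfying_level(self, level, n):
        c = min_detected_count(level, n)
        assert c / n >= level - 1e-9
        if c > 0:
            assert (c - 1) / n < level


class TestFilterByDetectability:
    def test_level_zero_keeps_everything(self, two_method_table):
        table, design = two_method_table
        out = filter_by_detectability(table, design, "gold", 0.0)
        assert out.feature_ids == table.feature_ids

    def test_level_one_keeps_fully_detected(self, two_method_table):
        table, design = two_method_table
        out = filter_by_detectability(table, design, "gold", 1.0)
        assert out.feature_ids == []

    def test_matches_brute_force_recount(self):
        design = make_design(8, methods=("gold", "alt"))
        table, design_syn, _ = generate_metabolome(
            n_subjects=8, methods=("gold", "alt"), n_features=50,
            censor_quantile=0.3, seed=17,
        )
        for level in (0.5, 0.75, 1.0):
            kept = set(
                filter_by_detectability(table, design_syn, "alt", level).feature_ids
            )
            expected = set()
            samples = design_syn.samples_for_method("alt")
            for fid in table.feature_ids:
                n_det = int(table.data.loc[fid, samples].notna().sum())
                if n_det / len(samples) >= level - 1e-12:
                    expected.add(fid)
            assert kept == expected


class TestOverlapWithGold:
    def test_paper_overlap(self):
        gold = {f"m{i}" for i in range(621)}
        method = {f"m{i}" for i in range(213)} | {f"x{i}" for i in range(32)}
        shared, pct = overlap_with_gold(gold, method)
        assert shared == 213
        assert pct == 34.3

    def test_identical_sets(self):
        shared, pct = overlap_with_gold({"a", "b"}, {"a", "b"})
        assert (shared, pct) == (2, 100.0)

    def test_disjoint_sets(self):
        assert overlap_with_gold({"a"}, {"b"}) == (0, 0.0)

    def test_empty_gold_is_error(self):
        with pytest.raises(ValidationError):
            overlap_with_gold(set(), {"a"})


class TestHalfMinImpute:
    def test_half_minimum(self):
        design = make_design(3, methods=("gold",))
        table = intensity_table(
            {"S001.gold": [2.0], "S002.gold": [4.0], "S003.gold": [np.nan]}, ["f1"]
        )
        out = half_min_impute(table, design, "gold")
        assert out.data.loc["f1", "S003.gold"] == 1.0

    def test_no_missing_is_noop(self, two_method_table):
        table, design = two_method_table
        full = intensity_table(
            {s: [1.0, 2.0] for s in design.assignments}, ["f1", "f2"]
        )
        out = half_min_impute(full, design, "gold")
        pd.testing.assert_frame_equal(out.data, full.data)

    def test_each_method_uses_its_own_minimum(self, two_method_table):
        table, design = two_method_table
        out = half_min_impute(
            half_min_impute(table, design, "gold"), design, "alt"
        )
        # gold f1 min = 2 -> 1 ; alt f1 min = 6 -> 3
        assert out.data.loc["f1", "S003.gold"] == 1.0
        assert out.data.loc["f1", "S003.alt"] == 3.0
        # detected cells untouched
        assert out.data.loc["f1", "S001.alt"] == 8.0

    def test_feature_never_detected_is_error(self):
        design = make_design(3, methods=("gold",))
        table = intensity_table(
            {s: [np.nan] for s in design.assignments}, ["f1"]
        )
        with pytest.raises(ValidationError, match="no detected value"):
            half_min_impute(table, design, "gold")

    def test_imputation_never_changes_detectability(self, two_method_table):
        table, design = two_method_table
        before = detectability(table, design, "gold")
        # detectability is computed on raw data; imputing the *other* method
        # must not leak into gold detectability either
        imputed = half_min_impute(table, design, "alt")
        sub = imputed.data[design.samples_for_method("gold")]
        after = sub.notna().sum(axis=1) / sub.shape[1]
        pd.testing.assert_series_equal(before, after, check_names=False)


class TestQuantileNormalize:
    def test_worked_example(self):
        table = intensity_table(
            {"s1": [1.0, 2.0, 3.0], "s2": [4.0, 5.0, 6.0]}, ["a", "b", "c"]
        )
        out = quantile_normalize(table)
        np.testing.assert_allclose(out.data["s1"], [2.5, 3.5, 4.5])
        np.testing.assert_allclose(out.data["s2"], [2.5, 3.5, 4.5])

    def test_identical_samples_fixed_point(self):
        table = intensity_table({"s1": [1.0, 5.0], "s2": [1.0, 5.0]}, ["a", "b"])
        out = quantile_normalize(table)
        pd.testing.assert_frame_equal(out.data, table.data)

    def test_ties_get_mean_of_spanned_reference(self):
        table = intensity_table(
            {"s1": [1.0, 1.0, 10.0], "s2": [2.0, 4.0, 6.0]}, ["a", "b", "c"]
        )
        out = quantile_normalize(table)
        ref = np.sort(table.data.to_numpy(), axis=0).mean(axis=1)
        assert out.data.loc["a", "s1"] == pytest.approx((ref[0] + ref[1]) / 2)
        assert out.data.loc["b", "s1"] == pytest.approx((ref[0] + ref[1]) / 2)

    @given(st.integers(0, 2**31 - 1), st.integers(2, 6), st.integers(2, 30))
    @settings(max_examples=30, deadline=None)
    def test_postcondition_identical_sorted_columns(self, seed, n_samples, n_features):
        rng = np.random.default_rng(seed)
        X = rng.gamma(2.0, 5.0, size=(n_features, n_samples))
        table = intensity_table(
            {f"s{j}": X[:, j] for j in range(n_samples)},
            [f"f{i}" for i in range(n_features)],
        )
        out = quantile_normalize(table).data.to_numpy()
        sorted_cols = np.sort(out, axis=0)
        for j in range(1, n_samples):
            np.testing.assert_allclose(sorted_cols[:, j], sorted_cols[:, 0])

    def test_missing_values_rejected(self, two_method_table):
        table, _ = two_method_table
        with pytest.raises(ValidationError, match="complete"):
            quantile_normalize(table)


class TestLog10:
    def test_values(self):
        table = intensity_table({"s1": [100.0, 1.0]}, ["a", "b"])
        out = log10_transform(table)
        assert out.data.loc["a", "s1"] == 2.0
        assert out.data.loc["b", "s1"] == 0.0

    def test_zero_is_error(self):
        table = intensity_table({"s1": [0.0]}, ["a"])
        with pytest.raises(ValidationError, match="positive"):
            log10_transform(table)


class TestMetaboliteIccProfile:
    def make_tables(self, gold_vals, alt_vals, features):
        design = make_design(gold_vals.shape[1], methods=("gold", "alt"))
        g = FeatureTable(
            pd.DataFrame(gold_vals, index=features,
                         columns=design.samples_for_method("gold")),
            "transformed",
        )
        a = FeatureTable(
            pd.DataFrame(alt_vals, index=features,
                         columns=design.samples_for_method("alt")),
            "transformed",
        )
        return g, a, design

    def test_duplicated_features_give_median_one_iqr_zero(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(5, 6))
        g, a, design = self.make_tables(vals, vals, [f"f{i}" for i in range(5)])
        summary, estimates = metabolite_icc_profile(g, a, design, "alt")
        assert summary.median == pytest.approx(1.0)
        assert summary.q3 - summary.q1 == pytest.approx(0.0)
        assert summary.n_features == 5

    def test_per_feature_equals_direct_icc_calls(self):
        rng = np.random.default_rng(4)
        g_vals = rng.normal(size=(6, 10))
        a_vals = g_vals + rng.normal(scale=0.5, size=(6, 10))
        feats = [f"f{i}" for i in range(6)]
        g, a, design = self.make_tables(g_vals, a_vals, feats)
        _, estimates = metabolite_icc_profile(g, a, design, "alt")
        for i, fid in enumerate(feats):
            values = dict(
                zip(design.samples_for_method("gold"), g_vals[i])
            ) | dict(zip(design.samples_for_method("alt"), a_vals[i]))
            direct = icc_oneway(pair_by_subject(values, design, "alt"))
            assert estimates[fid].estimate == pytest.approx(direct.estimate)

    def test_median_recovery_from_known_truth(self):
        table, design, truth = generate_metabolome(
            n_subjects=100, methods=("gold", "alt"), n_features=100,
            icc_range=(0.2, 0.9), censor_quantile=0.0, seed=55,
        )
        gold = preprocess_method(table, design, "gold")
        alt = preprocess_method(table, design, "alt")
        summary, _ = metabolite_icc_profile(gold, alt, design, "alt")
        assert summary.median == pytest.approx(
            float(np.median(truth.true_icc)), abs=0.07
        )

    def test_no_shared_features_is_error(self):
        rng = np.random.default_rng(5)
        g, a, design = self.make_tables(
            rng.normal(size=(2, 4)), rng.normal(size=(2, 4)), ["f1", "f2"]
        )
        with pytest.raises(ValidationError, match="shared"):
            metabolite_icc_profile(g, a, design, "alt", features=[])


class TestDetectabilityTable:
    def test_monotone_counts_down_levels(self):
        table, design, _ = generate_metabolome(
            n_subjects=8, methods=("gold", "alt", "other"), n_features=120,
            censor_quantile=0.2, seed=9,
            method_censor_shift={"alt": 0.2, "other": 0.1},
        )
        rows = detectability_table(table, design, levels=(0.0, 0.5, 0.75, 1.0))
        by_method: dict[str, list[int]] = {}
        for row in rows:
            by_method.setdefault(row.method, []).append(row.n_features)
        for counts in by_method.values():
            assert counts == sorted(counts, reverse=True)

    def test_shared_bounded_by_both_sets(self):
        table, design, truth = generate_metabolome(
            n_subjects=8, methods=("gold", "alt"), n_features=80,
            censor_quantile=0.3, seed=10,
        )
        rows = detectability_table(table, design, known_features=truth.known_features)
        gold_counts = {r.level: r.n_features for r in rows if r.method == "gold"}
        for row in rows:
            if row.method == "gold":
                continue
            assert row.n_shared <= min(gold_counts[row.level], row.n_features)
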