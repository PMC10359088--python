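"""Oracle assignment, delta responses, CV harness, rank-sum validation."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from oncoassign import (
    Assignment,
    MethodSpec,
    SensitivityMatrix,
    compare_methods,
    cross_validate,
    delta_ic50,
    intragroup_test,
    make_folds,
    oracle_assign,
    rank_sum_test,
)
from oncoassign.exceptions import AlignmentError, ConfigError, EvaluationError
from tests.conftest import random_sensitivity


def enumeration_p(x, y):
    """Oracle: exhaustive two-sided permutation p over all label splits."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1 = len(x)
    mu = n1 * len(y) / 2.0
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    hits = total = 0
    for idx in combinations(range(len(pooled)), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0
        hits += abs(u - mu) >= abs(u_obs - mu) - 1e-12
        total += 1
    return hits / total


class TestOracle:
    def test_row_argmin(self):
        y = SensitivityMatrix(
            np.array([[0.5, -1.2, 0.3]]), ["p1"], ["a", "b", "c"], scale="log_ic50"
        )
        a = oracle_assign(y)
        assert a.assigned_drug == ["b"]
        assert a.achieved_value[0] == pytest.approx(-1.2)

    def test_tie_goes_to_lower_index(self):
        y = SensitivityMatrix(np.array([[1.0, 1.0, 2.0]]), ["p1"], ["a", "b", "c"])
        assert oracle_assign(y).assigned_drug == ["a"]

    def test_matches_independent_row_minima(self, rng):
        y = random_sensitivity(rng, p=50, d=8, missing_rate=0.15)
        a = oracle_assign(y)
        for i in range(50):
            row = y.values[i]
            want = np.min(row[~np.isnan(row)])
            assert a.achieved_value[i] == pytest.approx(want)

    def test_benefit_scale_takes_argmax(self):
        y = SensitivityMatrix(np.array([[1.0, 3.0]]), ["p1"], ["a", "b"], scale="benefit")
        assert oracle_assign(y).assigned_drug == ["b"]

    def test_all_missing_patient_named(self):
        vals = np.array([[1.0, 2.0], [np.nan, np.nan]])
        y = SensitivityMatrix(vals, ["ok", "ghost"], ["a", "b"])
        with pytest.raises(EvaluationError, match="ghost"):
            oracle_assign(y)


class TestDelta:
    def test_oracle_delta_is_zero(self, rng):
        y = random_sensitivity(rng, p=20, d=5)
        np.testing.assert_allclose(delta_ic50(oracle_assign(y), y), 0.0, atol=1e-12)

    def test_arithmetic(self):
        y = SensitivityMatrix(np.array([[1.0, 3.0]]), ["p1"], ["a", "b"])
        a = Assignment(["p1"], ["b"])
        assert delta_ic50(a, y)[0] == pytest.approx(2.0)

    def test_always_nonnegative(self, rng):
        y = random_sensitivity(rng, p=30, d=4)
        drugs = [y.drug_names[j] for j in rng.integers(0, 4, size=30)]
        d = delta_ic50(Assignment(list(y.patient_ids), drugs), y)
        assert np.all(d >= 0)

    def test_unmeasured_assignment_reported_missing(self):
        vals = np.array([[1.0, np.nan]])
        y = SensitivityMatrix(vals, ["p1"], ["a", "b"])
        d = delta_ic50(Assignment(["p1"], ["b"]), y)
        assert np.isnan(d[0])


class TestFolds:
    def test_balanced_sizes(self):
        plan = make_folds([f"p{i}" for i in range(10)], 5, seed=0)
        sizes = [len(plan.test_indices(f)) for f in range(1, 6)]
        assert sizes == [2] * 5

    def test_deterministic(self):
        ids = [f"p{i}" for i in range(23)]
        a = make_folds(ids, 4, seed=9)
        b = make_folds(ids, 4, seed=9)
        np.testing.assert_array_equal(a.fold_labels, b.fold_labels)

    def test_permutation_stable(self, rng):
        ids = [f"p{i}" for i in range(17)]
        plan = make_folds(ids, 3, seed=5)
        perm = rng.permutation(17)
        plan2 = make_folds([ids[i] for i in perm], 3, seed=5)
        for i, p in enumerate(ids):
            j = list(perm).index(i)
            assert plan.fold_labels[i] == plan2.fold_labels[j]

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(4, 60), st.integers(2, 6), st.integers(0, 10_000))
    def test_partition_property(self, p, k, seed):
        k = min(k, p)
        plan = make_folds([f"p{i}" for i in range(p)], k, seed)
        all_idx = np.concatenate([plan.test_indices(f) for f in range(1, k + 1)])
        assert sorted(all_idx) == list(range(p))
        sizes = [len(plan.test_indices(f)) for f in range(1, k + 1)]
        assert max(sizes) - min(sizes) <= 1

    def test_invalid_k(self):
        with pytest.raises(ConfigError):
            make_folds(["a", "b", "c"], 1, seed=0)
        with pytest.raises(ConfigError):
            make_folds(["a", "b"], 3, seed=0)


def constant_spec(drug):
    return MethodSpec(
        name=f"always {drug}",
        fit=lambda y, x: drug,
        predict=lambda d, x: Assignment(list(x.patient_ids), [d] * x.n_patients),
    )


class TestCrossValidate:
    def test_cheating_oracle_has_zero_delta(self, rng):
        from oncoassign import BiomarkerMatrix

        y = random_sensitivity(rng, p=24, d=4)
        x = BiomarkerMatrix(
            rng.binomial(1, 0.5, (24, 3)).astype(float),
            list(y.patient_ids), ["g0", "g1", "g2"],
        )
        full = y

        def cheat_predict(_state, x_test):
            idx = [full.patient_ids.index(p) for p in x_test.patient_ids]
            return oracle_assign(full.take_patients(idx))

        spec = MethodSpec(name="cheat", fit=lambda y_, x_: None, predict=cheat_predict)
        report = cross_validate(y, x, spec, make_folds(y.patient_ids, 4, seed=1))
        np.testing.assert_allclose(report.delta, 0.0, atol=1e-12)

    def test_constant_method_forced_values(self, rng):
        from oncoassign import BiomarkerMatrix

        y = random_sensitivity(rng, p=20, d=3)
        x = BiomarkerMatrix(
            rng.binomial(1, 0.5, (20, 2)).astype(float), list(y.patient_ids), ["g0", "g1"]
        )
        report = cross_validate(y, x, constant_spec("d1"), make_folds(y.patient_ids, 5, 3))
        np.testing.assert_allclose(report.achieved, y.values[:, 1], atol=1e-12)
        assert report.n_excluded == 0

    def test_no_train_test_leakage(self, rng):
        """Instrumented stub: the fold's training cohort must never
        contain a patient later presented for prediction."""
        from oncoassign import BiomarkerMatrix

        y = random_sensitivity(rng, p=30, d=3)
        x = BiomarkerMatrix(
            rng.binomial(1, 0.5, (30, 2)).astype(float), list(y.patient_ids), ["g0", "g1"]
        )
        seen = []

        def fit(y_train, x_train):
            assert y_train.patient_ids == x_train.patient_ids
            return set(y_train.patient_ids)

        def predict(train_ids, x_test):
            assert not (train_ids & set(x_test.patient_ids))
            seen.append(list(x_test.patient_ids))
            return Assignment(list(x_test.patient_ids), ["d0"] * x_test.n_patients)

        plan = make_folds(y.patient_ids, 5, seed=7)
        cross_validate(y, x, MethodSpec("stub", fit, predict), plan)
        flat = [p for fold in seen for p in fold]
        assert sorted(flat) == sorted(y.patient_ids)  # each patient tested once

    def test_method_failure_recorded_as_partial(self, rng):
        from oncoassign import BiomarkerMatrix

        y = random_sensitivity(rng, p=12, d=3)
        x = BiomarkerMatrix(
            rng.binomial(1, 0.5, (12, 2)).astype(float), list(y.patient_ids), ["g0", "g1"]
        )
        calls = {"n": 0}

        def flaky_fit(y_, x_):
            calls["n"] += 1
            if calls["n"] == 2:
                raise RuntimeError("boom")
            return "d0"

        spec = MethodSpec(
            "flaky", flaky_fit,
            lambda d, x_: Assignment(list(x_.patient_ids), [d] * x_.n_patients),
        )
        report = cross_validate(y, x, spec, make_folds(y.patient_ids, 3, 0))
        assert report.partial and 2 in report.fold_errors
        assert np.isnan(report.achieved).sum() == len(report.fold_labels) // 3


class TestRankSum:
    def test_identical_multisets_give_p_one(self):
        res = rank_sum_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == pytest.approx(1.0)

    def test_exact_matches_enumeration_on_example(self):
        x, y = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0, 7.0]
        res = rank_sum_test(x, y)
        assert res.method == "exact"
        assert res.statistic == pytest.approx(0.0)  # complete separation
        assert res.p_value == pytest.approx(enumeration_p(x, y), abs=1e-12)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 5), st.integers(2, 5))
    def test_exact_p_equals_enumeration_tie_free(self, seed, n1, n2):
        rng = np.random.default_rng(seed)
        vals = rng.permutation(np.arange(1.0, n1 + n2 + 1.0))
        res = rank_sum_test(vals[:n1], vals[n1:])
        assert res.p_value == pytest.approx(enumeration_p(vals[:n1], vals[n1:]), abs=1e-12)

    def test_tied_small_samples_use_enumeration(self):
        x, y = [1.0, 1.0, 2.0], [1.0, 2.0, 2.0, 3.0]
        res = rank_sum_test(x, y)
        assert res.method == "permutation"
        assert res.p_value == pytest.approx(enumeration_p(x, y), abs=1e-12)

    def test_large_samples_use_asymptotic(self, rng):
        res = rank_sum_test(rng.standard_normal(30), rng.standard_normal(40))
        assert res.method == "asymptotic"
        assert 0 <= res.p_value <= 1


class TestIntragroup:
    def test_recommended_group_separates(self, rng):
        p = 40
        vals = rng.standard_normal((p, 2))
        rec = np.arange(p) < 15
        vals[rec, 0] -= 3.0  # recommended patients really are more sensitive
        y = SensitivityMatrix(vals, [f"p{i}" for i in range(p)], ["a", "b"])
        a = Assignment(list(y.patient_ids), ["a" if r else "b" for r in rec])
        res = intragroup_test(a, y, "a")
        assert res.n_recommended == 15 and res.n_other == 25
        assert res.p_value < 0.01

    def test_degenerate_group_skipped(self, rng):
        y = random_sensitivity(rng, p=6, d=2)
        a = Assignment(list(y.patient_ids), ["d0"] * 6)
        res = intragroup_test(a, y, "d1")
        assert res.skipped is not None

    def test_raw_metric_option(self, rng):
        y = random_sensitivity(rng, p=20, d=3)
        drugs = [y.drug_names[j] for j in rng.integers(0, 3, size=20)]
        a = Assignment(list(y.patient_ids), drugs)
        res = intragroup_test(a, y, "d0", metric="raw")
        assert res.n_recommended + res.n_other == 20


class TestCompareMethods:
    def test_single_report_recomputed_median(self, rng):
        from oncoassign import BiomarkerMatrix

        y = random_sensitivity(rng, p=20, d=3)
        x = BiomarkerMatrix(
            rng.binomial(1, 0.5, (20, 2)).astype(float), list(y.patient_ids), ["g0", "g1"]
        )
        report = cross_validate(y, x, constant_spec("d0"), make_folds(y.patient_ids, 4, 0))
        table = compare_methods([report])
        assert table.loc["always d0", "median_achieved"] == pytest.approx(
            np.median(y.values[:, 0])
        )

    def test_identical_reports_identical_rows(self, rng):
        from oncoassign import BiomarkerMatrix

        y = random_sensitivity(rng, p=16, d=3)
        x = BiomarkerMatrix(
            rng.binomial(1, 0.5, (16, 2)).astype(float), list(y.patient_ids), ["g0", "g1"]
        )
        plan = make_folds(y.patient_ids, 4, 0)
        r1 = cross_validate(y, x, constant_spec("d1"), plan)
        r2 = cross_validate(y, x, constant_spec("d1"), plan)
        t = compare_methods([r1, r2])
        assert t.iloc[0].equals(t.iloc[1])

    def test_cohort_mismatch_rejected(self, rng):
        from oncoassign import BiomarkerMatrix

        y1 = random_sensitivity(rng, p=10, d=2)
        y2 = random_sensitivity(rng, p=8, d=2)
        x1 = BiomarkerMatrix(np.zeros((10, 1)) + 1, list(y1.patient_ids), ["g"], ["binary"])
        x2 = BiomarkerMatrix(np.zeros((8, 1)) + 1, list(y2.patient_ids), ["g"], ["binary"])
        r1 = cross_validate(y1, x1, constant_spec("d0"), make_folds(y1.patient_ids, 2, 0))
        r2 = cross_validate(y2, x2, constant_spec("d0"), make_folds(y2.patient_ids, 2, 0))
        with pytest.raises(AlignmentError):
            compare_methods([r1, r2])
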