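"""Tree and forest tests: split criteria, method dispatch, growing, prediction."""

import itertools

import numpy as np
import pandas as pd
import pytest

from catsplitrf import (
    ForestConfig,
    NominalVar,
    PartitionLimitError,
    SurvivalOutcome,
    best_split_for_variable,
    gini_decrease,
    logrank_split_statistic,
    tree_node_counts,
    variance_decrease,
)
from catsplitrf import forest as rf
from catsplitrf.forest import Forest, fit
from catsplitrf.scenarios import ScenarioConfig, simulate


# ---------------------------------------------------------------------------
# split criteria
# ---------------------------------------------------------------------------


class TestGiniDecrease:
    def test_pure_parent_zero(self):
        assert gini_decrease([4, 0], [2, 0], [2, 0]) == pytest.approx(0.0)

    def test_perfect_separation(self):
        assert gini_decrease([2, 2], [2, 0], [0, 2]) == pytest.approx(0.5)

    def test_binary_gini_picks_same_split_as_variance(self):
        """For a 0/1 outcome, Gini splitting is equivalent to variance
        splitting on the 0/1 coding: the selected split agrees."""
        rng = np.random.default_rng(0)
        for _ in range(30):
            n, k = 24, 4
            codes = rng.integers(0, k, n)
            y = rng.integers(0, 2, n)
            var = NominalVar(codes=codes, labels=tuple(str(i) for i in range(k)))
            by_gini = best_split_for_variable(var, y, "classification", "partition", c=2)
            by_var = best_split_for_variable(var, y.astype(float), "regression", "partition")
            if by_gini is None or by_var is None:
                assert by_gini is None and by_var is None
                continue
            assert by_gini[0].left_mask == by_var[0].left_mask


class TestVarianceDecrease:
    def test_constant_outcome_zero(self):
        assert variance_decrease(8.0, 16.0, 4, 4.0, 8.0, 2) == pytest.approx(0.0)

    def test_hand_case(self):
        # y = (0, 0, 10, 10): SS = 100; split by value -> 0 + 0
        y = np.array([0.0, 0.0, 10.0, 10.0])
        dec = variance_decrease(y.sum(), (y**2).sum(), 4, 0.0, 0.0, 2)
        assert dec == pytest.approx(100.0)

    def test_translation_invariance(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=10)
        nl = 4
        d1 = variance_decrease(y.sum(), (y**2).sum(), 10, y[:nl].sum(), (y[:nl]**2).sum(), nl)
        z = y + 7.5
        d2 = variance_decrease(z.sum(), (z**2).sum(), 10, z[:nl].sum(), (z[:nl]**2).sum(), nl)
        assert d1 == pytest.approx(d2, abs=1e-9)


def brute_force_logrank(time, status, group):
    """Independent O/E/V tabulation over distinct event times."""
    o_minus_e, v = 0.0, 0.0
    for t in sorted(set(time[status == 1])):
        at_risk = time >= t
        y_tot = at_risk.sum()
        y1 = (at_risk & (group == 0)).sum()
        d_tot = ((time == t) & (status == 1)).sum()
        d1 = ((time == t) & (status == 1) & (group == 0)).sum()
        o_minus_e += d1 - d_tot * y1 / y_tot
        if y_tot > 1:
            v += d_tot * (y1 / y_tot) * (1 - y1 / y_tot) * (y_tot - d_tot) / (y_tot - 1)
    return 0.0 if v == 0 else o_minus_e**2 / v


class TestLogrankStatistic:
    def test_identical_children_near_zero(self):
        left = SurvivalOutcome(time=[1, 2, 3], status=[1, 1, 1])
        right = SurvivalOutcome(time=[1, 2, 3], status=[1, 1, 1])
        assert logrank_split_statistic(left, right) == pytest.approx(0.0, abs=1e-12)

    def test_complete_separation_matches_brute_force(self):
        left = SurvivalOutcome(time=[1, 2, 3], status=[1, 1, 1])
        right = SurvivalOutcome(time=[10, 11, 12], status=[1, 1, 1])
        time = np.array([1, 2, 3, 10, 11, 12], dtype=float)
        status = np.ones(6, dtype=int)
        group = np.array([0, 0, 0, 1, 1, 1])
        expected = brute_force_logrank(time, status, group)
        assert logrank_split_statistic(left, right) == pytest.approx(expected, abs=1e-12)

    def test_random_samples_match_brute_force(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            n = int(rng.integers(4, 30))
            time = rng.exponential(2, n) + 0.01
            status = rng.integers(0, 2, n)
            if status.sum() == 0:
                status[0] = 1
            group = rng.integers(0, 2, n)
            if group.min() == group.max():
                group[0] = 1 - group[0]
            left = SurvivalOutcome(time=time[group == 0], status=status[group == 0])
            right = SurvivalOutcome(time=time[group == 1], status=status[group == 1])
            expected = brute_force_logrank(time, status, group)
            assert logrank_split_statistic(left, right) == pytest.approx(expected, abs=1e-10)

    def test_symmetry(self):
        left = SurvivalOutcome(time=[1, 5, 9], status=[1, 0, 1])
        right = SurvivalOutcome(time=[2, 3], status=[1, 1])
        assert logrank_split_statistic(left, right) == \
            pytest.approx(logrank_split_statistic(right, left), abs=1e-12)


# ---------------------------------------------------------------------------
# best split per variable; the split-equivalence theorem
# ---------------------------------------------------------------------------


def exhaustive_best_partition(codes, y, impurity="ss"):
    """Independent oracle: scan every 2-partition of the present categories,
    recomputing the impurity decrease from first principles."""
    present = sorted(set(codes.tolist()))
    best_gain, best_sets = -np.inf, None
    n = len(y)
    y = np.asarray(y, dtype=float)

    def ss(v):
        return ((v - v.mean()) ** 2).sum() if v.size else 0.0

    def gini_imp(v):
        _, cnt = np.unique(v, return_counts=True)
        f = cnt / v.size
        return 1 - (f**2).sum()

    for r in range(1, len(present)):
        for combo in itertools.combinations(present, r):
            left = np.isin(codes, combo)
            if not left.any() or left.all():
                continue
            if impurity == "ss":
                gain = ss(y) - ss(y[left]) - ss(y[~left])
            else:
                gain = gini_imp(y) - (left.sum() / n) * gini_imp(y[left]) \
                    - ((~left).sum() / n) * gini_imp(y[~left])
            if gain > best_gain + 1e-12:
                best_gain, best_sets = gain, {frozenset(combo),
                                              frozenset(set(present) - set(combo))}
            elif abs(gain - best_gain) <= 1e-12 and best_sets is not None:
                best_sets |= {frozenset(combo), frozenset(set(present) - set(combo))}
    return best_gain, best_sets


def split_sets(rule, k):
    left = frozenset(c for c in range(k) if rule.left_mask >> c & 1)
    present = frozenset(c for c in range(k) if rule.present_mask >> c & 1)
    return left, present - left


class TestEquivalenceTheorem:
    """Ordering by outcome mean reproduces the exhaustive-partition optimum
    for regression and binary classification."""

    @pytest.mark.parametrize("outcome", ["regression", "binary"])
    def test_200_random_nodes(self, outcome):
        rng = np.random.default_rng(17)
        for _ in range(200):
            n = int(rng.integers(4, 31))
            k = int(rng.integers(2, 7))
            codes = rng.integers(0, k, n)
            if outcome == "regression":
                y = rng.normal(size=n)
                oracle_gain, oracle_sets = exhaustive_best_partition(codes, y, "ss")
                kind = "regression"
            else:
                y = rng.integers(0, 2, n)
                oracle_gain, oracle_sets = exhaustive_best_partition(codes, y, "gini")
                kind = "classification"
            var = NominalVar(codes=codes, labels=tuple(str(i) for i in range(k)))
            args = (var, y, kind)
            kw = {"c": 2} if kind == "classification" else {}
            res_ord = best_split_for_variable(*args, "order_split", **kw)
            res_par = best_split_for_variable(*args, "partition", **kw)
            if oracle_gain <= 1e-12:
                continue
            assert res_ord is not None and res_par is not None
            assert res_ord[1] == pytest.approx(oracle_gain, abs=1e-9)
            assert res_par[1] == res_ord[1]  # shared kernel: bit-identical
            lo, ro = split_sets(res_ord[0], k)
            lp, rp = split_sets(res_par[0], k)
            assert {lo, ro} == {lp, rp}
            assert lo in oracle_sets
            # identical induced observation split
            assert np.array_equal(np.isin(codes, list(lo)), np.isin(codes, list(lp)))

    def test_partition_counts_candidates_exhaustively(self):
        rng = np.random.default_rng(5)
        codes = rng.integers(0, 5, 40)
        y = rng.normal(size=40)
        var = NominalVar(codes=codes, labels=tuple("abcde"))
        res = best_split_for_variable(var, y, "regression", "partition")
        assert res[2] == 2**4 - 1
        res_ord = best_split_for_variable(var, y, "regression", "order_split")
        assert res_ord[2] == 4  # k - 1 candidates


class TestFig1DigitParity:
    """Four categories, parity outcome: Partition needs 7 trials, ordering 3,
    and treating codes as ordinal cannot express the interleaved split."""

    def setup_method(self):
        codes = np.array([0, 1, 2, 3] * 5)
        self.var = NominalVar(codes=codes, labels=("1", "2", "3", "4"))
        self.y = codes % 2  # odd/even of the digit labels 1..4 -> 1,0,1,0

    def test_partition_finds_parity_with_seven_trials(self):
        rule, gain, n_cand = best_split_for_variable(self.var, 1 - self.y,
                                                     "classification", "partition", c=2)
        assert n_cand == 7
        left, right = split_sets(rule, 4)
        assert {left, right} == {frozenset({0, 2}), frozenset({1, 3})}
        assert gain == pytest.approx(0.5)

    def test_order_split_finds_parity_with_three_trials(self):
        rule, gain, n_cand = best_split_for_variable(self.var, 1 - self.y,
                                                     "classification", "order_split", c=2)
        assert n_cand == 3
        left, right = split_sets(rule, 4)
        assert {left, right} == {frozenset({0, 2}), frozenset({1, 3})}
        assert gain == pytest.approx(0.5)

    def test_ignore_cannot_separate(self):
        res = best_split_for_variable(self.var, 1 - self.y, "classification",
                                      "ignore", c=2)
        # the best ordinal threshold is strictly worse than the parity split
        assert res is None or res[1] < 0.5 - 1e-12

    def test_pure_node_returns_none(self):
        assert best_split_for_variable(self.var, np.zeros(20, dtype=int),
                                       "classification", "partition", c=2) is None


# ---------------------------------------------------------------------------
# growing, fitting, predicting
# ---------------------------------------------------------------------------


def digit_data(outcome, n=80, seed=0, **kw):
    return simulate(ScenarioConfig(predictor_type="digit", outcome_type=outcome,
                                   n=n, seed=seed, **kw))


class TestFit:
    def test_reproducible(self):
        data = digit_data("binary")
        cfg = ForestConfig(n_trees=5, mtry=2, seed=11, nominal_method="order_once")
        f1, f2 = fit(data.train, data.schema, cfg), fit(data.train, data.schema, cfg)
        assert np.array_equal(f1.predict(data.valid), f2.predict(data.valid))
        for t1, t2 in zip(f1.trees, f2.trees):
            assert len(t1.nodes) == len(t2.nodes)
            assert np.array_equal(t1.bootstrap, t2.bootstrap)

    def test_node_counts_odd_and_single_observation(self):
        data = digit_data("binary", n=60)
        f = fit(data.train, data.schema, ForestConfig(n_trees=10, mtry=2, seed=0))
        counts = tree_node_counts(f)
        assert np.all(counts % 2 == 1)
        one = data.train.head(2)  # n=2, min node 1: may split once or not at all
        f1 = fit(one, data.schema, ForestConfig(n_trees=3, mtry=1, seed=0))
        assert np.all(tree_node_counts(f1) >= 1)

    def test_separable_data_zero_training_error_full_mtry(self):
        df = pd.DataFrame({"x1": ["a"] * 10 + ["b"] * 10, "y": [0] * 10 + [1] * 10})
        schema = {"x1": "nominal", "y": "outcome_classification"}
        f = fit(df, schema, ForestConfig(n_trees=5, mtry=1, seed=2,
                                         nominal_method="partition"))
        assert np.array_equal(f.predict(df), df.y.to_numpy())

    def test_order_once_binary_uses_full_data_proportion_order(self):
        from catsplitrf import order_by_mean
        from catsplitrf.data import from_dataframe
        data = digit_data("binary", n=120, seed=3)
        f = fit(data.train, data.schema,
                ForestConfig(n_trees=1, mtry=1, seed=0, nominal_method="order_once"))
        train = from_dataframe(data.train, data.schema)
        for col, pred in zip(f.design.columns, train.predictors):
            expected = order_by_mean(pred.var, train.y.astype(float))
            assert col.ordering.permutation.tolist() == expected.permutation.tolist()

    def test_partition_category_limit(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"x1": [f"c{i}" for i in rng.integers(0, 60, 200)],
                           "y": rng.normal(size=200)})
        schema = {"x1": "nominal", "y": "outcome_regression"}
        with pytest.raises(PartitionLimitError):
            fit(df, schema, ForestConfig(n_trees=1, mtry=1, nominal_method="partition"))

    def test_mtry_validation(self):
        data = digit_data("binary")
        with pytest.raises(ValueError):
            fit(data.train, data.schema, ForestConfig(n_trees=1, mtry=9))


class TestPredict:
    def test_single_tree_forest_returns_tree_payload(self):
        df = pd.DataFrame({"x1": ["a", "a", "b", "b"], "y": [1.0, 1.0, 5.0, 5.0]})
        schema = {"x1": "nominal", "y": "outcome_regression"}
        f = fit(df, schema, ForestConfig(n_trees=1, mtry=1, min_node_size=1, seed=4,
                                         nominal_method="partition"))
        pred = f.predict(df)
        leaves = [nd.payload for t in f.trees for nd in t.nodes if nd.is_terminal]
        assert set(np.round(pred, 12)) <= set(np.round(leaves, 12))

    def test_regression_within_training_range(self):
        data = digit_data("regression", n=100, seed=5)
        f = fit(data.train, data.schema, ForestConfig(n_trees=10, mtry=2, seed=0))
        pred = f.predict(data.valid)
        assert pred.min() >= data.train.y.min() - 1e-9
        assert pred.max() <= data.train.y.max() + 1e-9

    def test_survival_chf_nondecreasing(self):
        data = digit_data("survival", n=60, seed=6)
        f = fit(data.train, data.schema, ForestConfig(n_trees=10, mtry=2, seed=0))
        pred = f.predict(data.valid)
        chf = -np.log(np.clip(pred.surv, 1e-300, None))
        assert np.all(np.diff(chf, axis=1) >= -1e-12)

    def test_absent_level_policy_reproducible(self):
        df = pd.DataFrame({"x1": list("aabbccdd") * 8,
                           "y": np.tile([0, 1], 32)})
        schema = {"x1": "nominal", "y": "outcome_classification"}
        f = fit(df, schema, ForestConfig(n_trees=10, mtry=1, seed=1,
                                         nominal_method="order_split"))
        new = pd.DataFrame({"x1": ["zz"] * 6})  # entirely new category
        p1, p2 = f.predict(new), f.predict(new)
        assert np.array_equal(p1, p2)

    def test_absent_level_policy_none_raises(self):
        df = pd.DataFrame({"x1": list("aabb"), "y": [0, 0, 1, 1]})
        schema = {"x1": "nominal", "y": "outcome_classification"}
        f = fit(df, schema, ForestConfig(n_trees=2, mtry=1, seed=1,
                                         absent_level_policy=None))
        with pytest.raises(ValueError, match="zz"):
            f.predict(pd.DataFrame({"x1": ["zz", "a"]}))

    def test_json_roundtrip_predictions(self, tmp_path):
        for outcome in ("binary", "regression", "survival"):
            data = digit_data(outcome, n=50, seed=7)
            f = fit(data.train, data.schema,
                    ForestConfig(n_trees=5, mtry=2, seed=2, nominal_method="order_once"))
            path = tmp_path / f"model-{outcome}.json"
            f.to_json(path)
            g = Forest.from_json(path)
            if outcome == "survival":
                a, b = f.predict(data.valid), g.predict(data.valid)
                assert np.array_equal(a.times, b.times)
                assert np.allclose(a.surv, b.surv)
            else:
                assert np.array_equal(f.predict(data.valid), g.predict(data.valid))


class TestMethodInvariants:
    def test_partition_equals_order_split_trees(self):
        """Split-equivalence: same seeds give identical trees (regression &
        binary), compared by the induced partitions of bootstrap indices."""
        for outcome in ("regression", "binary"):
            for seed in range(3):
                data = digit_data(outcome, n=70, seed=seed)
                cfgs = [ForestConfig(n_trees=5, mtry=3, seed=seed, nominal_method=m,
                                     record_node_indices=True)
                        for m in ("partition", "order_split")]
                fa, fb = (fit(data.train, data.schema, c) for c in cfgs)
                for ta, tb in zip(fa.trees, fb.trees):
                    assert len(ta.nodes) == len(tb.nodes)
                    for na, nb in zip(ta.nodes, tb.nodes):
                        assert np.array_equal(na.indices, nb.indices)

    def test_partition_gain_dominates_orderings(self):
        """Exhaustive search over a superset of candidates: partition's best
        gain is at least order_split's at every audited node."""
        data = simulate(ScenarioConfig(predictor_type="digit", outcome_type="multiclass",
                                       n=60, seed=9))
        cfg = ForestConfig(n_trees=3, mtry=4, seed=0, nominal_method="order_split",
                           record_node_indices=True)
        f = fit(data.train, data.schema, cfg)
        from catsplitrf.data import from_dataframe
        train = from_dataframe(data.train, data.schema)
        audited = 0
        for tree in f.trees:
            for node in tree.nodes:
                if node.is_terminal or audited >= 40:
                    continue
                idx = node.indices
                j = node.split.var_index
                pred = train.predictors[j]
                sub = NominalVar(codes=pred.var.codes[idx], labels=pred.var.labels)
                y_sub = train.y[idx]
                res_par = best_split_for_variable(sub, y_sub, "classification",
                                                  "partition", c=train.n_classes)
                assert res_par is not None
                assert res_par[1] >= node.gain - 1e-9
                audited += 1
        assert audited > 10

    def test_candidate_economy_counters(self):
        """Instrumented counters: ordering methods evaluate k-1 candidates
        per nominal variable, partition 2**(k-1) - 1."""
        data = digit_data("regression", n=100, seed=1)
        for method, expect in (("order_split", lambda m: m - 1),
                               ("partition", lambda m: 2 ** (m - 1) - 1)):
            from catsplitrf.forest import fit_training_data
            from catsplitrf.data import from_dataframe
            train = from_dataframe(data.train, data.schema)
            f = fit_training_data(train, ForestConfig(n_trees=2, mtry=4, seed=0,
                                                      nominal_method=method), audit=True)
            root_records = [r for r in f.audit if r["n_node"] == 100]
            assert root_records, "no root-node audit records"
            for r in root_records:
                # m = number of categories present in the bootstrap sample
                assert r["n_candidates"] >= expect(2)
                if method == "order_split":
                    assert r["n_candidates"] <= 9
                else:
                    assert r["n_candidates"] in {2 ** (m - 1) - 1 for m in range(2, 11)}


class TestNodeStatistics:
    def test_stump_and_one_split_counts(self):
        df = pd.DataFrame({"x1": ["a", "b"] * 8, "y": [0, 1] * 8})
        schema = {"x1": "nominal", "y": "outcome_classification"}
        f = fit(df, schema, ForestConfig(n_trees=5, mtry=1, seed=0))
        assert set(tree_node_counts(f)) <= {1, 3}

    def test_available_categories_by_depth(self):
        data = simulate(ScenarioConfig(predictor_type="digit", outcome_type="multiclass",
                                       n=100, seed=2))
        f = fit(data.train, data.schema,
                ForestConfig(n_trees=20, mtry=4, seed=0, nominal_method="ignore",
                             record_node_categories=True))
        avail = rf.available_categories_by_depth(f, "x1")
        assert avail.loc[0] <= 10
        deep = avail.index.max()
        assert avail.loc[deep] < avail.loc[0]  # categories vanish with depth
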