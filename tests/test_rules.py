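"""Discretization, feature selection, mining, fuzzification and relevance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import phenomap as pm
from phenomap.rules import (
    CrispRule,
    FuzzyCondition,
    discretize,
    fuzzify,
    mine_rules,
    parse_rule_text,
    possibility,
    render_rule,
    rule_relevance,
    rules_from_json,
    rules_to_json,
    select_features,
    semantic_relevance,
)

from _oracles import brute_force_rules


class TestDiscretize:
    def test_equal_width_hand_example(self):
        X = pd.DataFrame({"f": [0, 0.25, 0.5, 0.75, 1.0]})
        disc = discretize(X, n_bins=4)
        assert disc.codes[:, 0].tolist() == [0, 1, 2, 3, 3]

    def test_equal_frequency_balances_counts(self):
        X = pd.DataFrame({"f": np.arange(8) / 7})
        disc = discretize(X, n_bins=4, scheme="equal_frequency")
        counts = np.bincount(disc.codes[:, 0], minlength=4)
        assert counts.tolist() == [2, 2, 2, 2]

    def test_constant_feature_warns_under_equal_frequency(self):
        X = pd.DataFrame({"f": np.ones(5)})
        with pytest.warns(UserWarning, match="constant"):
            disc = discretize(X, n_bins=4, scheme="equal_frequency")
        assert len(disc.edges[0]) == 2

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=2, max_size=40),
        st.integers(2, 8),
    )
    def test_every_value_lies_inside_its_assigned_interval(self, vals, n_bins):
        X = pd.DataFrame({"f": vals})
        disc = discretize(X, n_bins=n_bins)
        last = disc.edges[0][-1]
        for v, code in zip(vals, disc.codes[:, 0]):
            lo, hi = disc.interval(0, code, code)
            assert lo <= v < hi or (v == hi == last)

    def test_rejects_bad_inputs(self):
        X = pd.DataFrame({"f": [0.0, 1.0]})
        with pytest.raises(ValueError):
            discretize(X, n_bins=1)
        with pytest.raises(ValueError):
            discretize(X, scheme="magic")
        with pytest.raises(ValueError, match="missing"):
            discretize(pd.DataFrame({"f": [0.0, np.nan]}))


class TestSelectFeatures:
    def _table(self, rng, n=40):
        y = np.asarray(["a"] * (n // 2) + ["b"] * (n // 2), object)
        f1 = np.r_[rng.uniform(0, 0.4, n // 2), rng.uniform(0.6, 1, n // 2)]
        return y, f1

    def test_duplicated_feature_selected_once(self):
        rng = np.random.default_rng(0)
        y, f1 = self._table(rng)
        X = pd.DataFrame({"f1": f1, "f2": f1.copy()})
        chosen = select_features(X, y)
        assert len([c for c in chosen if c in ("f1", "f2")]) == 1

    def test_noise_features_rarely_selected(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y, f1 = self._table(rng)
            X = pd.DataFrame({"sig": f1})
            for j in range(4):
                X[f"noise{j}"] = rng.uniform(0, 1, len(y))
            chosen = select_features(X, y)
            if not any(c.startswith("noise") for c in chosen):
                hits += 1
        assert hits >= 19  # >= 95% of 20 seeded trials

    def test_greedy_merit_close_to_exhaustive_optimum(self):
        from phenomap.rules import cfs_merit, _safe_corr

        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            n = 30
            y = np.asarray(["a"] * 15 + ["b"] * 15, object)
            X = pd.DataFrame(
                rng.uniform(0, 1, (n, 6)), columns=[f"f{j}" for j in range(6)]
            )
            X["f0"] += (y == "a") * rng.uniform(0.3, 0.6)

            def merit_of(cols):
                Xv = X.to_numpy(float)
                onehot = [np.asarray(y == t, float) for t in ("a", "b")]
                rcf = np.array(
                    [
                        np.mean([abs(_safe_corr(Xv[:, j], oh)) for oh in onehot])
                        for j in range(6)
                    ]
                )
                idx = [list(X.columns).index(c) for c in cols]
                return cfs_merit(Xv, rcf, idx, {})

            greedy = merit_of(select_features(X, y, "greedy_stepwise"))
            best = merit_of(select_features(X, y, "exhaustive"))
            if greedy >= 0.9 * best:
                wins += 1
        assert wins == 20

    def test_exhaustive_limited_to_15_features(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.uniform(0, 1, (10, 16)))
        y = np.asarray(["a", "b"] * 5, object)
        with pytest.raises(ValueError, match="15"):
            select_features(X, y, "exhaustive")

    def test_missing_class_is_an_error(self):
        X = pd.DataFrame({"f": [0.1, 0.9]})
        with pytest.raises(ValueError, match="no labeled terms"):
            select_features(X, np.asarray([None, None], object))


class TestMiner:
    def test_single_split_rule_matches_hand_computation(self):
        rng = np.random.default_rng(3)
        f1 = np.r_[rng.uniform(0, 0.49, 5), rng.uniform(0.51, 1, 5)]
        X = pd.DataFrame({"F1": f1})
        y = np.asarray(["A"] * 5 + ["B"] * 5, object)
        disc = discretize(X, n_bins=2)
        rules = mine_rules(disc, y, min_support=0.5, min_confidence=1.0, max_len=1)
        top_a = [r for r in rules if r.consequent == "A"][0]
        assert top_a.support == pytest.approx(0.5)
        assert top_a.confidence == 1.0
        lo, hi = top_a.antecedent[0][1:]
        assert lo == pytest.approx(f1.min())
        assert all(lo <= v < hi for v in f1[:5])

    def test_high_support_on_balanced_classes_yields_nothing(self):
        X = pd.DataFrame({"F1": np.linspace(0, 1, 10)})
        y = np.asarray(["A", "B"] * 5, object)
        rules = mine_rules(discretize(X, 4), y, min_support=0.9, min_confidence=0.5)
        assert rules == []

    @pytest.mark.parametrize("seed", range(10))
    def test_miner_equals_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 31))
        m = int(rng.integers(1, 5))
        n_bins = int(rng.integers(2, 5))
        X = pd.DataFrame(
            rng.uniform(0, 1, (n, m)), columns=[f"F{j + 1:03d}" for j in range(m)]
        )
        y = np.asarray(rng.choice(["A", "B", None], size=n, p=[0.4, 0.4, 0.2]), object)
        min_support = float(rng.uniform(0.05, 0.3))
        min_confidence = float(rng.uniform(0.5, 1.0))
        disc = discretize(X, n_bins=n_bins)
        mined = {
            (r.consequent, r.antecedent, round(r.support, 12), round(r.confidence, 12))
            for r in mine_rules(disc, y, min_support, min_confidence, max_len=3)
        }
        oracle = brute_force_rules(
            disc.codes, disc.edges, disc.feature_names, list(y),
            min_support, min_confidence, max_len=3,
        )
        assert mined == oracle

    def test_pruned_mining_is_a_subset_led_by_the_same_top_rule(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.uniform(0, 1, (40, 3)), columns=["F1", "F2", "F3"])
        y = np.asarray(["A" if v < 0.5 else "B" for v in X["F1"]], object)
        disc = discretize(X, 5)
        full = mine_rules(disc, y, 0.1, 0.9, 2)
        pruned = mine_rules(disc, y, 0.1, 0.9, 2, prune_specializations=True)
        assert {r.key() for r in pruned} <= {r.key() for r in full}
        assert pruned[0] == full[0]

    def test_threshold_validation(self):
        X = pd.DataFrame({"F1": [0.1, 0.9]})
        y = np.asarray(["A", "B"], object)
        with pytest.raises(ValueError):
            mine_rules(discretize(X, 2), y, min_support=0.0)


class TestSerialization:
    def _worked_rule(self):
        return CrispRule(
            antecedent=(("F006", 0.09, 0.16), ("F399", 0.12, 0.21)),
            consequent="elliptical_lesions",
            support=0.2,
            confidence=0.95,
        )

    def test_worked_rule_renders_and_parses_back(self):
        rule = self._worked_rule()
        text = render_rule(rule)
        assert text == "{F006 ∈ [0.09, 0.16] ∧ F399 ∈ [0.12, 0.21]} → elliptical_lesions"
        back = parse_rule_text(text, support=0.2, confidence=0.95)
        assert back == rule

    def test_fuzzy_rules_roundtrip_through_json(self):
        fr = fuzzify(self._worked_rule())
        back = rules_from_json(rules_to_json([fr]))[0]
        assert back.consequent == fr.consequent
        assert back.support == fr.support
        for a, b in zip(back.conditions, fr.conditions):
            assert a.feature == b.feature
            assert a.lam1 == pytest.approx(b.lam1)
            assert a.lam3 == pytest.approx(b.lam3)


class TestFuzzification:
    def test_interval_maps_to_center_and_width(self):
        fr = fuzzify(self._rule([("F1", 0.09, 0.16)]))
        c = fr.conditions[0]
        assert c.lam1 == pytest.approx(0.125, abs=1e-6)
        assert c.lam2 == pytest.approx(0.07, abs=1e-6)

    def _rule(self, conds, term="t"):
        return CrispRule(tuple(conds), term, 0.1, 1.0)

    def test_slope_doubles_with_slope_scale(self):
        r = self._rule([("F1", 0.2, 0.4)])
        assert fuzzify(r, 2.0).conditions[0].lam3 == pytest.approx(
            2 * fuzzify(r, 1.0).conditions[0].lam3
        )

    def test_rule_count_preserved_and_zero_width_rejected(self):
        rules = [self._rule([("F1", 0.0, 0.5)]), self._rule([("F2", 0.5, 1.0)])]
        assert len([fuzzify(r) for r in rules]) == 2
        with pytest.raises(ValueError, match="zero-width"):
            fuzzify(self._rule([("F1", 0.3, 0.3)]))

    def test_open_upper_edge_scores_strictly_below_closed_lower_edge(self):
        r = self._rule([("F1", 0.2, 0.4)])
        fr = fuzzify(r, upper_open=[True])
        c = fr.conditions[0]
        assert possibility(0.4, c) < possibility(0.2, c)


class TestPossibility:
    def test_center_is_exactly_one(self):
        c = FuzzyCondition("F", lam1=0.3, lam2=0.2, lam3=5.0)
        assert possibility(0.3, c) == 1.0

    def test_large_slope_approximates_crisp_indicator(self):
        c = FuzzyCondition("F", lam1=0.5, lam2=0.4, lam3=1e4)
        inside = np.array([0.31, 0.5, 0.69])
        outside = np.array([0.29, 0.71, 0.0, 1.0])
        assert np.all(np.abs(possibility(inside, c) - 1) < 1e-3)
        assert np.all(possibility(outside, c) < 1e-3)

    def test_far_value_has_very_low_relevance_for_fitted_interval(self):
        # condition fitted to the size-histogram feature interval of the
        # worked elliptical-lesion rule
        fr = fuzzify(CrispRule((("F399", 0.12, 0.21),), "elliptical_lesions", 0.1, 1.0))
        assert possibility(0.96, fr.conditions[0]) < 0.05
        fig_cond = fuzzify(
            CrispRule((("F399", 0.107, 0.196),), "elliptical_lesions", 0.1, 1.0)
        ).conditions[0]
        assert possibility(0.96, fig_cond) < 0.05

    @settings(derandomize=True, max_examples=60)
    @given(
        st.floats(-2, 3, allow_nan=False),
        st.floats(0.05, 1.0),
        st.floats(0.5, 50.0),
    )
    def test_bounded_and_monotone_away_from_center(self, x, lam2, lam3):
        c = FuzzyCondition("F", lam1=0.4, lam2=lam2, lam3=lam3)
        p = possibility(x, c)
        assert 0.0 <= p <= 1.0
        farther = 0.4 + 1.5 * (x - 0.4)
        assert possibility(farther, c) <= p + 1e-12

    def test_inside_points_dominate_the_edges(self):
        c = fuzzify(CrispRule((("F", 0.3, 0.7),), "t", 0.1, 1.0)).conditions[0]
        edge = possibility(0.3, c)
        for x in np.linspace(0.31, 0.69, 20):
            assert possibility(x, c) >= edge


class TestRelevance:
    def _fuzzy(self, intervals, term="t"):
        return fuzzify(
            CrispRule(tuple(("F%d" % i, lo, hi) for i, (lo, hi) in enumerate(intervals)),
                      term, 0.1, 1.0)
        )

    def test_all_conditions_at_centers_give_one(self):
        fr = self._fuzzy([(0.2, 0.4), (0.6, 0.8)])
        v = {"F0": 0.3, "F1": 0.7}
        assert rule_relevance(v, fr) == pytest.approx(1.0)

    def test_one_far_condition_dominates_under_min(self):
        fr = self._fuzzy([(0.2, 0.4), (0.6, 0.8)])
        v = {"F0": 0.3, "F1": 5.0}
        assert rule_relevance(v, fr) < 1e-6

    def test_min_tnorm_dominates_product(self):
        rng = np.random.default_rng(2)
        fr = self._fuzzy([(0.1, 0.5), (0.4, 0.9), (0.0, 0.3)])
        for _ in range(50):
            v = {f"F{i}": float(x) for i, x in enumerate(rng.uniform(-0.5, 1.5, 3))}
            assert rule_relevance(v, fr, "min") >= rule_relevance(v, fr, "product")

    def test_missing_feature_is_an_error(self):
        fr = self._fuzzy([(0.2, 0.4)])
        with pytest.raises(ValueError, match="missing"):
            rule_relevance({"other": 0.3}, fr)

    def test_semantic_relevance_max_aggregation(self):
        r1 = self._fuzzy([(0.2, 0.4)])
        r2 = self._fuzzy([(0.6, 0.8)])
        v = {"F0": 0.3}
        assert semantic_relevance(v, []) == 0.0
        assert semantic_relevance(v, [r1]) == rule_relevance(v, r1)
        assert semantic_relevance(v, [r1, r2]) >= semantic_relevance(v, [r1])


class TestEstimator:
    def _data(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        y = np.asarray(["lo"] * (n // 2) + ["hi"] * (n // 2), object)
        X = pd.DataFrame(
            {
                "F001": np.r_[rng.uniform(0, 0.4, n // 2), rng.uniform(0.6, 1, n // 2)],
                "F002": rng.uniform(0, 1, n),
            }
        )
        return X, y

    def test_fit_recovers_separable_terms(self):
        X, y = self._data()
        miner = pm.SemanticRuleMiner(min_confidence=1.0).fit(X, y)
        assert set(miner.terms_) == {"lo", "hi"}
        assert len(miner.rules_) > 0
        pred = miner.predict(X)
        assert (pred == y).mean() == 1.0
        rel = miner.relevance(X)
        assert rel.shape == (len(X), 2)
        assert np.all((rel.values >= 0) & (rel.values <= 1))

    def test_single_term_class_skips_mining_with_warning(self):
        X, y = self._data()
        y[:] = "only"
        with pytest.warns(UserWarning, match="2 terms"):
            miner = pm.SemanticRuleMiner().fit(X, y)
        assert miner.rules_ == []

    def test_sklearn_clone_roundtrip(self):
        from sklearn.base import clone

        miner = pm.SemanticRuleMiner(min_support=0.1, n_bins=6)
        cloned = clone(miner)
        assert cloned.get_params() == miner.get_params()
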