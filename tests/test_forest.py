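"""Random survival forest: Nelson-Aalen, log-rank splits, trees, ensemble
predictions, Harrell's C and permutation importance."""

import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test
from lifelines.utils import concordance_index

import survscreen as ss
from survscreen import (ForestConfig, SurvivalForestModel, fit_forest,
                        grow_tree, harrell_c, logrank_split_statistic,
                        nelson_aalen)
from conftest import make_noise, make_single_effect


class TestNelsonAalen:
    def test_all_events_hand_value(self):
        na = nelson_aalen([1.0, 2.0, 3.0], [1, 1, 1])
        assert na(3.0) == pytest.approx(11 / 6)
        assert na(0.5) == 0.0

    def test_all_censored_flat_zero(self):
        na = nelson_aalen([1.0, 2.0], [0, 0])
        assert na(10.0) == 0.0

    def test_tied_events(self):
        na = nelson_aalen([1.0, 1.0, 2.0], [1, 1, 1])
        assert na(1.0) == pytest.approx(2 / 3)
        assert na(2.0) == pytest.approx(2 / 3 + 1.0)

    def test_nondecreasing(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(1, 30)
        d = (rng.random(30) < 0.7).astype(int)
        d[0] = 1
        na = nelson_aalen(t, d)
        vals = na(np.sort(t))
        assert np.all(np.diff(vals) >= 0)


class TestLogrankSplit:
    def test_identical_groups_zero(self):
        t = np.array([1.0, 2, 3, 1, 2, 3])
        d = np.array([1, 1, 0, 1, 1, 0])
        x = np.array([0.0, 0, 0, 1, 1, 1])
        data = ss.SurvivalDataset(t, d, x[:, None])
        assert logrank_split_statistic(data, 0, 0.5) == pytest.approx(0.0)

    def test_matches_lifelines_oracle(self):
        # separated groups: early events left, late events right
        t = np.array([1.0, 2, 3, 4, 5, 10, 11, 12, 13, 14])
        d = np.ones(10)
        x = np.array([0.0] * 5 + [1.0] * 5)
        data = ss.SurvivalDataset(t, d, x[:, None])
        stat = logrank_split_statistic(data, 0, 0.5)
        oracle = logrank_test(t[x == 0], t[x == 1], d[:5], d[5:])
        assert stat**2 == pytest.approx(oracle.test_statistic, rel=1e-10)

    def test_symmetry_under_relabeling(self, random_dataset):
        X = random_dataset.covariates
        c = float(np.median(X[:, 0]))
        a = logrank_split_statistic(random_dataset, 0, c)
        flipped = random_dataset.with_covariates(-X)
        b = logrank_split_statistic(flipped, 0, -c - 1e-12)
        assert a == pytest.approx(b, abs=1e-9)

    def test_empty_daughter_rejected(self, random_dataset):
        hi = random_dataset.covariates[:, 0].max()
        with pytest.raises(ValueError):
            logrank_split_statistic(random_dataset, 0, hi + 1)


class TestGrowTree:
    def test_identical_rows_single_leaf(self):
        d = ss.SurvivalDataset([1.0, 2, 3, 4], [1, 1, 1, 0], np.ones((4, 2)))
        tree = grow_tree(d, np.arange(4), ForestConfig(ntree=1, min_node_events=1), seed=0)
        assert np.all(tree.feature < 0)

    def test_perfect_binary_separator_is_root_split(self):
        rng = np.random.default_rng(0)
        n = 30
        x0 = np.repeat([0.0, 1.0], n // 2)
        t = np.where(x0 == 0, rng.uniform(0.1, 1, n), rng.uniform(10, 20, n))
        noise = rng.standard_normal((n, 1)) * 0.01
        X = np.column_stack([x0, noise])
        d = ss.SurvivalDataset(t, np.ones(n), X)
        tree = grow_tree(d, np.arange(n), ForestConfig(mtry=2), seed=1)
        assert tree.feature[0] == 0

    def test_seeded_determinism(self, random_dataset):
        cfg = ForestConfig(mtry=2)
        a = grow_tree(random_dataset, np.arange(10), cfg, seed=7)
        b = grow_tree(random_dataset, np.arange(10), cfg, seed=7)
        np.testing.assert_array_equal(a.feature, b.feature)
        np.testing.assert_array_equal(a.threshold, b.threshold)
        np.testing.assert_allclose(a.chf, b.chf)

    def test_terminal_chfs_nondecreasing(self):
        d = make_single_effect(n=40, beta=2.0, p=3, seed=1)
        tree = grow_tree(d, np.arange(40), ForestConfig(mtry=3), seed=2)
        assert np.all(np.diff(tree.chf, axis=1) >= 0)


class TestForest:
    def test_single_tree_forest_equals_tree(self):
        d = make_single_effect(n=40, beta=2.0, p=3, seed=1)
        forest = fit_forest(d, ntree=1, seed=5)
        tree = forest.trees[0]
        X = d.covariates[:5]
        np.testing.assert_allclose(forest.ensemble_mortality(X),
                                   tree.predict_mortality(X))

    def test_duplicated_tree_leaves_ensemble_unchanged(self):
        d = make_single_effect(n=30, beta=1.0, p=3, seed=2)
        forest = fit_forest(d, ntree=1, seed=5)
        chf1 = forest.ensemble_chf(d.covariates[:4])
        forest.trees.append(forest.trees[0])
        chf2 = forest.ensemble_chf(d.covariates[:4])
        np.testing.assert_allclose(chf1, chf2)

    def test_ensemble_chf_nondecreasing(self):
        d = make_single_effect(n=40, beta=1.5, p=4, seed=3)
        forest = fit_forest(d, ntree=20, seed=1)
        chf = forest.ensemble_chf(d.covariates[:6])
        assert np.all(np.diff(chf, axis=1) >= -1e-12)

    def test_monotone_transform_invariance(self):
        # splits depend only on the ordering of covariate values, so a tree
        # grown after a strictly monotone transform routes the cases it was
        # grown on identically (midpoints move, but not across those cases)
        d = make_single_effect(n=40, beta=2.0, p=3, seed=4)
        cfg = ForestConfig(mtry=3)
        tree_a = grow_tree(d, np.arange(40), cfg, seed=9)
        transformed = d.with_covariates(np.exp(d.covariates))
        tree_b = grow_tree(transformed, np.arange(40), cfg, seed=9)
        np.testing.assert_array_equal(tree_a.feature, tree_b.feature)
        np.testing.assert_allclose(
            tree_a.predict_mortality(d.covariates),
            tree_b.predict_mortality(np.exp(d.covariates)))

    def test_oob_concordance_noise_near_half_signal_above(self):
        noise_c = [fit_forest(make_noise(n=100, p=20, seed=s),
                              ntree=100, seed=s).oob_concordance()
                   for s in range(5)]
        assert all(0.4 <= c <= 0.6 for c in noise_c)
        signal_c = fit_forest(make_single_effect(n=100, beta=3.0, p=20, seed=0),
                              ntree=100, seed=0).oob_concordance()
        assert signal_c > 0.6


class TestHarrellC:
    def test_pure_ties_half(self):
        assert harrell_c(np.ones(5), [1, 2, 3, 4, 5.0], [1, 1, 1, 0, 1]) == 0.5

    def test_perfect_discrimination(self):
        t = np.array([5.0, 4, 3, 2, 1])
        assert harrell_c(np.array([1.0, 2, 3, 4, 5]), t, np.ones(5)) == 1.0

    def test_brute_force_oracle_mixed_censoring(self):
        rng = np.random.default_rng(8)
        r = rng.standard_normal(5)
        t = np.array([2.0, 1.0, 3.0, 2.0, 5.0])
        d = np.array([1, 1, 0, 0, 1])
        conc = usable = 0.0
        for i in range(5):
            for j in range(5):
                if i == j:
                    continue
                if (t[i] < t[j] and d[i] == 1) or (t[i] == t[j] and d[i] == 1 and d[j] == 0):
                    usable += 1
                    conc += 1.0 if r[i] > r[j] else (0.5 if r[i] == r[j] else 0.0)
        assert harrell_c(r, t, d) == pytest.approx(conc / usable)

    def test_matches_lifelines_without_time_ties(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(1.0, 30)
        d = (rng.random(30) < 0.7).astype(int)
        d[0] = 1
        r = rng.standard_normal(30)
        ours = harrell_c(r, t, d)
        theirs = concordance_index(t, -r, d)
        assert ours == pytest.approx(theirs, abs=1e-12)

    def test_no_usable_pairs_raises(self):
        with pytest.raises(ValueError):
            harrell_c([1.0, 2.0], [1.0, 1.0], [1, 1])


class TestPermutationImportance:
    def test_unused_covariate_exactly_zero(self):
        d = make_single_effect(n=40, beta=3.0, p=2, seed=1)
        # append a constant covariate: it can never split
        X = np.column_stack([d.covariates, np.zeros(40)])
        d2 = ss.SurvivalDataset(d.times, d.events, X)
        forest = fit_forest(d2, ntree=20, mtry=3, seed=2)
        assert forest.permutation_importance(2, seed=0) == 0.0

    def test_null_importances_center_on_zero(self):
        vals = []
        for s in range(5):
            forest = fit_forest(make_noise(n=60, p=10, seed=s), ntree=60, seed=s)
            vals.extend(forest.permutation_importance(seed=s).to_numpy())
        assert abs(np.mean(vals)) < 0.02
        # many variables have nonpositive importance on null data
        assert np.mean(np.asarray(vals) <= 0) >= 0.4

    def test_strong_effect_ranks_first(self):
        wins = 0
        for s in range(10):
            d = make_single_effect(n=80, beta=3.0, p=10, seed=s)
            forest = fit_forest(d, ntree=80, seed=s)
            pam = forest.permutation_importance(seed=s).to_numpy()
            wins += int(np.argmax(pam) == 0)
        assert wins >= 9
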