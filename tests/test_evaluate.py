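import numpy as np
import pandas as pd
import pytest

from gutapns.evaluate import (SeedRunResult, aggregate_importance,
                              build_feature_matrix, compute_directions,
                              feature_direction, permutation_importance,
                              run_seeds, time_split)
from gutapns.merf import MERF
from gutapns.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="module")
def fast_cohort():
    cfg = SimulationConfig(n_subjects=30, n_species=20, n_effectors=2,
                           gamma=(3.0, 0.0), sigma_b=1.0, seed=13)
    return simulate_cohort(cfg)


class TestTimeSplit:
    def test_full_panel_partitions_by_week(self, fast_cohort):
        train, test = time_split(fast_cohort.outcomes)
        assert len(train) == 2 * 30 and len(test) == 30
        assert set(train["week"]) == {2, 8} and set(test["week"]) == {12}
        key = lambda df: set(zip(df["subject_id"], df["week"]))
        assert not key(train) & key(test)  # a true partition

    def test_missing_week_contributes_partial_rows(self, fast_cohort):
        panel = fast_cohort.outcomes
        drop = (panel["subject_id"] == "SUBJ000") & (panel["week"] == 8)
        train, test = time_split(panel[~drop])
        assert (train["subject_id"] == "SUBJ000").sum() == 1
        assert (test["subject_id"] == "SUBJ000").sum() == 1

    def test_no_test_week_errors(self, fast_cohort):
        panel = fast_cohort.outcomes
        with pytest.raises(ValueError, match="week-12"):
            time_split(panel[panel["week"] != 12])


class TestPermutationImportance:
    @pytest.fixture()
    def fitted(self, fast_cohort):
        features = build_feature_matrix(fast_cohort.species, fast_cohort.cohort)
        train, test = time_split(fast_cohort.outcomes)
        X = features.loc[train["subject_id"].to_numpy()].reset_index(drop=True)
        res = MERF(train["promis_t"].to_numpy(), X,
                   train["subject_id"].to_numpy(),
                   n_estimators=100, max_iter=5, random_state=0).fit()
        X_te = features.loc[test["subject_id"].to_numpy()].reset_index(drop=True)
        return res, X_te, test["subject_id"].to_numpy(), test["promis_t"].to_numpy()

    def test_constant_feature_scores_exactly_zero(self, fitted):
        res, X, groups, y = fitted
        X = X.copy()
        X["sex_male"] = 1.0  # make a column constant; permuting is the identity
        imp = permutation_importance(res, X, groups, y,
                                     rng=np.random.default_rng(0))
        assert imp["sex_male"] == 0.0

    def test_planted_effector_dominates(self, fitted, fast_cohort):
        res, X, groups, y = fitted
        imp = permutation_importance(res, X, groups, y,
                                     rng=np.random.default_rng(0))
        dominant = fast_cohort.truth.effectors[
            int(np.argmax(fast_cohort.truth.gamma))]
        assert imp.idxmax() == dominant

    def test_duplicated_feature_importance_splits(self, fast_cohort):
        features = build_feature_matrix(fast_cohort.species, fast_cohort.cohort)
        dominant = fast_cohort.truth.effectors[
            int(np.argmax(fast_cohort.truth.gamma))]
        train, test = time_split(fast_cohort.outcomes)

        def importance_of(feats):
            X = feats.loc[train["subject_id"].to_numpy()].reset_index(drop=True)
            res = MERF(train["promis_t"].to_numpy(), X,
                       train["subject_id"].to_numpy(),
                       n_estimators=200, max_iter=5, random_state=0).fit()
            X_te = feats.loc[test["subject_id"].to_numpy()].reset_index(drop=True)
            return permutation_importance(res, X_te,
                                          test["subject_id"].to_numpy(),
                                          test["promis_t"].to_numpy(),
                                          rng=np.random.default_rng(0))
        solo = importance_of(features)[dominant]
        dup_features = features.copy()
        dup_features["dup_of_dominant"] = features[dominant]
        dup = importance_of(dup_features)
        assert dup[dominant] <= solo * 1.05
        assert dup["dup_of_dominant"] <= solo * 1.05


class TestRunSeeds:
    def test_near_deterministic_outcome_predicted_accurately(self):
        # outcome almost a pure function of the microbiome: tiny noise floor
        cfg = SimulationConfig(n_subjects=30, n_species=20, n_effectors=2,
                               gamma=(4.0, 0.0), sigma_b=0.0, sigma_e=0.02,
                               time_slope=0.0, covariate_effects=(0, 0, 0), seed=17)
        cohort = simulate_cohort(cfg)
        features = build_feature_matrix(cohort.species, cohort.cohort)
        runs = run_seeds(cohort.outcomes, features, "promis_t", seeds=range(3),
                         n_estimators=200)
        sd = cohort.outcomes["promis_t"].std()
        rmses = [r.rmse_test for r in runs]
        assert np.median(rmses) <= 0.35 * sd  # forest bias floors the error
        assert all(r.corr_test > 0.9 for r in runs)

    def test_pure_noise_outcome_gives_weak_correlation(self):
        cfg = SimulationConfig(n_subjects=30, n_species=20, n_effectors=2,
                               gamma=(0.0, 0.0), sigma_b=0.0,
                               covariate_effects=(0, 0, 0), seed=19)
        cohort = simulate_cohort(cfg)
        features = build_feature_matrix(cohort.species, cohort.cohort)
        runs = run_seeds(cohort.outcomes, features, "promis_t", seeds=range(5),
                         n_estimators=100, max_iter=10)
        mean_corr = np.nanmean([r.corr_test for r in runs])
        assert abs(mean_corr) <= 0.3

    def test_single_seed_aggregates_gracefully(self, fast_cohort):
        features = build_feature_matrix(fast_cohort.species, fast_cohort.cohort)
        runs = run_seeds(fast_cohort.outcomes, features, "promis_t", seeds=[0],
                         n_estimators=50, max_iter=3)
        table = aggregate_importance(runs)
        assert (table["n_seeds"] == 1).all()
        assert list(table["rank"]) == list(range(1, len(table) + 1))


class TestAggregation:
    def _fake_runs(self):
        imp_a = pd.Series({"f1": 3.0, "f2": 1.0, "f3": 0.5})
        imp_b = pd.Series({"f1": 1.0, "f2": 3.0, "f3": -0.5})
        return [SeedRunResult(seed=0, importance=imp_a),
                SeedRunResult(seed=1, importance=imp_b)]

    def test_identical_importances_average_to_themselves(self):
        imp = pd.Series({"a": 2.0, "b": 1.0})
        runs = [SeedRunResult(seed=s, importance=imp.copy()) for s in range(3)]
        table = aggregate_importance(runs)
        assert table.loc["a", "mean_importance"] == 2.0
        assert table.loc["a", "rank"] == 1

    def test_order_invariance(self):
        runs = self._fake_runs()
        t1 = aggregate_importance(runs)
        t2 = aggregate_importance(list(reversed(runs)))
        pd.testing.assert_frame_equal(t1, t2)

    def test_missing_seed_feature_counts_available_runs(self):
        runs = self._fake_runs()
        runs[1].importance = runs[1].importance.drop("f3")
        table = aggregate_importance(runs)
        assert table.loc["f3", "n_seeds"] == 1
        assert table.loc["f3", "mean_importance"] == 0.5

    def test_nonpositive_importance_features_dropped(self):
        runs = [SeedRunResult(seed=0, importance=pd.Series({"a": 1.0, "b": -0.2,
                                                            "c": 0.0}))]
        table = aggregate_importance(runs)
        assert list(table.index) == ["a"]

    def test_failed_seed_recorded_not_raised(self, fast_cohort):
        features = build_feature_matrix(fast_cohort.species, fast_cohort.cohort)
        bad = features.copy()
        runs = run_seeds(fast_cohort.outcomes.assign(promis_t=np.nan), bad,
                         "promis_t", seeds=[0], n_estimators=10, max_iter=2)
        assert runs[0].error is not None


class TestFeatureDirection:
    def test_monotone_pairs(self):
        assert feature_direction([1, 2, 3, 4], [10, 20, 30, 40]) == 1.0
        assert feature_direction([1, 2, 3, 4], [4, 3, 2, 1]) == -1.0

    def test_hand_computed_rank_correlation(self):
        # ranks differ by (1,1,1,1,0): rho = 1 - 6*4/(5*24) = 0.8
        assert feature_direction([1, 2, 3, 4, 5], [2, 1, 4, 3, 5]) == pytest.approx(0.8)

    def test_degenerate_inputs(self):
        assert np.isnan(feature_direction([1, 1, 1], [1, 2, 3]))
        with pytest.raises(ValueError):
            feature_direction([1, 2], [1, 2])

    def test_directions_attach_to_aggregate(self, fast_cohort):
        features = build_feature_matrix(fast_cohort.species, fast_cohort.cohort)
        directions = compute_directions(fast_cohort.outcomes, features, "promis_t")
        runs = run_seeds(fast_cohort.outcomes, features, "promis_t", seeds=[0],
                         n_estimators=50, max_iter=3)
        table = aggregate_importance(runs, directions=directions)
        assert "direction_rho" in table.columns
        dominant = fast_cohort.truth.effectors[
            int(np.argmax(fast_cohort.truth.gamma))]
        assert table.loc[dominant, "direction_rho"] > 0
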