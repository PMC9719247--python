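import numpy as np
import pandas as pd
import pytest
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

import cfpromoter as cf
from cfpromoter.classify import ClassifierError, _as_binary
from conftest import brute_force_auc


def gene_matrix(values: np.ndarray, prefix="f") -> cf.PromoterProfileMatrix:
    values = np.asarray(values, float)
    df = pd.DataFrame(
        values,
        index=[f"s{i}" for i in range(values.shape[0])],
        columns=[f"{prefix}{j}" for j in range(values.shape[1])],
    )
    return cf.PromoterProfileMatrix(df, level="gene")


def shifted_cohort(n_per_class=60, n_noise=98, n_inform=2, shift=3.0, seed=0):
    """Two informative features with a class mean shift, the rest noise."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    X = rng.normal(1000.0, 1.0, size=(n, n_noise + n_inform))
    y = np.array([1] * n_per_class + [0] * n_per_class)
    X[: n_per_class, :n_inform] += shift
    return gene_matrix(X), y


class TestRocWithDelong:
    def test_half_concordant_pairs(self):
        ev = cf.roc_with_delong([3, 2, 1, 4], [1, 1, 0, 0])
        assert ev.auc == pytest.approx(0.5)

    def test_perfect_separation(self):
        ev = cf.roc_with_delong([4, 3, 2, 1], [1, 1, 0, 0])
        assert ev.auc == 1.0
        assert ev.sensitivity == ev.specificity == ev.accuracy == 1.0

    def test_single_cross_class_tie(self):
        # pairs: 3 fully concordant, one tied -> (3 + 0.5)/4
        ev = cf.roc_with_delong([4, 2, 2, 1], [1, 1, 0, 0])
        assert ev.auc == pytest.approx(0.875)

    def test_auc_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            n = int(rng.integers(4, 31))
            y = np.zeros(n, int)
            y[: max(1, n // 3)] = 1
            rng.shuffle(y)
            scores = np.round(rng.normal(size=n) + y, 1)  # rounding induces ties
            ev = cf.roc_with_delong(scores, y)
            assert ev.auc == pytest.approx(brute_force_auc(scores, y), abs=1e-12)

    def test_delong_se_positive_with_distinct_scores(self):
        ev = cf.roc_with_delong([0.1, 0.9, 0.7, 0.6, 0.2, 0.8], [0, 1, 0, 1, 0, 1])
        assert ev.delong_se > 0
        lo, hi = ev.ci95
        assert 0 <= lo <= ev.auc <= hi <= 1

    def test_one_class_rejected(self):
        with pytest.raises(ClassifierError):
            cf.roc_with_delong([1, 2], [1, 1])


class TestDelongComparison:
    def test_self_comparison_p_one(self):
        scores = np.random.default_rng(3).normal(size=20)
        y = np.tile([0, 1], 10)
        z, p = cf.compare_auc_delong(scores, scores, y)
        assert z == 0.0 and p == 1.0

    def test_antisymmetry(self):
        rng = np.random.default_rng(4)
        y = np.tile([0, 1], 30)
        a = rng.normal(size=60) + y
        b = rng.normal(size=60)
        za, pa = cf.compare_auc_delong(a, b, y)
        zb, pb = cf.compare_auc_delong(b, a, y)
        assert za == pytest.approx(-zb)
        assert pa == pytest.approx(pb)

    def test_informative_beats_noise(self):
        rng = np.random.default_rng(5)
        y = np.array([1] * 100 + [0] * 100)
        good = y * 2.0 + rng.normal(size=200)
        noise = rng.normal(size=200)
        _, p = cf.compare_auc_delong(good, noise, y)
        assert p < 0.01

    def test_unpaired_lengths_rejected(self):
        with pytest.raises(ClassifierError):
            cf.compare_auc_delong([1, 2, 3], [1, 2], [1, 0, 1])


class TestFeatureRanking:
    def test_single_feature_is_rank_one(self):
        mat, y = shifted_cohort(n_per_class=10, n_noise=0, n_inform=1)
        ranking = cf.rank_features(mat, y)
        assert ranking.features == ["f0"]

    @pytest.mark.parametrize("method", ["rfe", "weight"])
    def test_informative_features_reach_top_ranks(self, method):
        hits = 0
        for seed in range(10):
            mat, y = shifted_cohort(seed=seed)
            ranking = cf.rank_features(mat, y, method=method)
            hits += {"f0", "f1"} <= set(ranking.top(10))
        assert hits == 10

    def test_duplicated_informative_feature_also_ranks_high(self):
        mat, y = shifted_cohort(n_noise=48, seed=3)
        vals = mat.values.copy()
        vals["dup"] = vals["f0"]
        ranking = cf.rank_features(cf.PromoterProfileMatrix(vals, level="gene"), y)
        top = set(ranking.top(10))
        assert "f0" in top and "dup" in top

    def test_constant_feature_ranked_last_with_warning(self):
        mat, y = shifted_cohort(n_per_class=10, n_noise=5, seed=4)
        vals = mat.values.copy()
        vals["const"] = 7.0
        with pytest.warns(UserWarning, match="constant"):
            ranking = cf.rank_features(cf.PromoterProfileMatrix(vals, level="gene"), y)
        assert ranking.features[-1] == "const"

    def test_ranking_deterministic(self):
        mat, y = shifted_cohort(seed=6)
        a = cf.rank_features(mat, y).features
        b = cf.rank_features(mat, y).features
        assert a == b and sorted(a) == sorted(mat.feature_ids)


class TestLoocv:
    def test_perfectly_separated_feature_gives_auc_one(self):
        X = np.concatenate([np.linspace(10, 11, 8), np.linspace(2, 3, 8)])[:, None]
        y = np.array([1] * 8 + [0] * 8)
        scores = cf.loocv_scores(gene_matrix(X), y, ["f0"], "svm")
        assert cf.auc_mann_whitney(scores, y) == 1.0

    def test_label_permutation_yields_chance_auc(self):
        rng = np.random.default_rng(7)
        X = rng.normal(5, 1, size=(40, 3))
        aucs = []
        for _ in range(20):
            y = np.array([1] * 20 + [0] * 20)
            rng.shuffle(y)
            scores = cf.loocv_scores(gene_matrix(X), y, ["f0", "f1", "f2"], "lda")
            aucs.append(cf.auc_mann_whitney(scores, y))
        assert abs(np.mean(aucs) - 0.5) < 0.08

    def test_tiny_case_matches_manual_folds(self):
        X = np.array([[1.0, 0.5], [2.0, 1.5], [3.0, 0.2], [4.0, 1.1]])
        y = np.array([0, 0, 1, 1])
        got = cf.loocv_scores(gene_matrix(X), y, ["f0", "f1"], "svm")
        for i in range(4):
            mask = np.ones(4, bool)
            mask[i] = False
            sc = StandardScaler().fit(X[mask])
            est = SVC(kernel="linear", C=1.0).fit(sc.transform(X[mask]), y[mask])
            want = est.decision_function(sc.transform(X[i : i + 1]))[0]
            assert got.iloc[i] == pytest.approx(want)

    @pytest.mark.parametrize("model_type", ["svm", "lr", "lda"])
    def test_all_model_types_produce_finite_scores(self, model_type):
        mat, y = shifted_cohort(n_per_class=15, n_noise=4, seed=8)
        scores = cf.loocv_scores(mat, y, mat.feature_ids[:3], model_type)
        assert np.isfinite(scores).all() and len(scores) == 30

    def test_degenerate_fold_rejected(self):
        X = np.random.default_rng(0).normal(5, 1, size=(4, 2))
        with pytest.raises(ClassifierError):
            cf.loocv_scores(gene_matrix(X), [1, 0, 0, 0], ["f0"], "svm")


class TestBackwardSelect:
    def test_k_top_one_returns_that_feature(self):
        mat, y = shifted_cohort(n_per_class=10, n_noise=3, seed=9)
        ranking = cf.rank_features(mat, y)
        subset, path = cf.backward_select(mat, y, ranking, k_top=1)
        assert subset == [ranking.features[0]] and len(path) == 1

    def test_informative_feature_retained_and_auc_maximal(self):
        mat, y = shifted_cohort(n_per_class=20, n_noise=8, n_inform=1, seed=10)
        ranking = cf.rank_features(mat, y)
        subset, path = cf.backward_select(mat, y, ranking, k_top=9)
        assert "f0" in subset
        assert path["auc"].max() == pytest.approx(
            cf.auc_mann_whitney(cf.loocv_scores(mat, y, subset, "svm"), y)
        )

    def test_pure_noise_flagged_non_informative(self):
        rng = np.random.default_rng(11)
        mat = gene_matrix(rng.normal(3, 1, size=(30, 10)))
        y = np.array([1] * 15 + [0] * 15)
        clf = cf.AlnClassifier(mat, y, model_type="svm")
        res = clf.fit(k_top=5, ranking_method="weight")
        assert abs(res.auc - 0.5) < 0.35
        assert not res.informative or res.auc < 0.75

    def test_greedy_mode_never_worse_than_start(self):
        mat, y = shifted_cohort(n_per_class=12, n_noise=4, seed=12)
        ranking = cf.rank_features(mat, y)
        subset, path = cf.backward_select(mat, y, ranking, k_top=6, mode="greedy")
        assert path["auc"].iloc[-1] >= path["auc"].iloc[0]
        assert subset


class TestValidationEvaluation:
    def test_validation_identical_to_training_matches_refit_scores(self):
        mat, y = shifted_cohort(n_per_class=15, n_noise=3, seed=13)
        frozen = cf.fit_frozen(mat, y, mat.feature_ids, "svm")
        ev = cf.evaluate_on_validation(frozen, mat, y)
        sc = StandardScaler().fit(mat.values.to_numpy())
        est = SVC(kernel="linear", C=1.0).fit(sc.transform(mat.values.to_numpy()), _as_binary(y))
        want = est.decision_function(sc.transform(mat.values.to_numpy()))
        np.testing.assert_allclose(ev.scores.to_numpy(), want, rtol=1e-8)

    def test_permuted_validation_labels_give_chance_auc(self):
        mat, y = shifted_cohort(n_per_class=50, n_noise=10, seed=14)
        frozen = cf.fit_frozen(mat, y, mat.feature_ids, "svm")
        rng = np.random.default_rng(14)
        aucs = []
        for _ in range(20):
            yp = rng.permutation(y)
            aucs.append(cf.evaluate_on_validation(frozen, mat, yp).auc)
        assert abs(np.mean(aucs) - 0.5) < 0.08

    def test_missing_feature_columns_listed(self):
        mat, y = shifted_cohort(n_per_class=5, n_noise=2, seed=15)
        frozen = cf.fit_frozen(mat, y, mat.feature_ids, "lr")
        small = cf.PromoterProfileMatrix(mat.values[["f0"]], level="gene")
        with pytest.raises(ClassifierError, match="f1"):
            frozen.decision(small)

    def test_frozen_model_json_round_trip(self, tmp_path):
        mat, y = shifted_cohort(n_per_class=5, n_noise=2, seed=16)
        frozen = cf.fit_frozen(mat, y, mat.feature_ids, "lda")
        frozen.to_json(tmp_path / "m.json")
        back = cf.FittedClassifier.from_json(tmp_path / "m.json")
        np.testing.assert_allclose(back.decision(mat), frozen.decision(mat))


class TestStratifiedEvaluation:
    def test_constant_covariate_equals_pooled(self):
        rng = np.random.default_rng(17)
        y = np.tile([0, 1], 30)
        scores = y + rng.normal(size=60)
        rows, pvals = cf.stratified_evaluation(scores, y, np.full(60, "all"))
        pooled = cf.roc_with_delong(scores, y)
        assert len(rows) == 1 and not pvals
        assert rows["auc"].iloc[0] == pytest.approx(pooled.auc)

    def test_independent_covariate_strata_similar(self):
        rng = np.random.default_rng(18)
        non_sig = 0
        for _ in range(20):
            y = np.tile([0, 1], 50)
            scores = y * 1.5 + rng.normal(size=100)
            cov = rng.choice(["lo", "hi"], 100)
            _, pvals = cf.stratified_evaluation(scores, y, cov)
            non_sig += all(p > 0.05 for p in pvals.values())
        assert non_sig >= 16

    def test_degenerate_stratum_excluded_with_warning(self):
        y = np.array([1, 1, 0, 0, 1, 1])
        scores = np.array([0.9, 0.8, 0.2, 0.1, 0.7, 0.6])
        cov = np.array(["a", "a", "a", "a", "b", "b"])
        with pytest.warns(UserWarning, match="lacks both classes"):
            rows, _ = cf.stratified_evaluation(scores, y, cov)
        assert list(rows["cohort"]) == ["a"]

    def test_tumor_fraction_tertiles_similar_when_signal_independent(self):
        truth = cf.generate_cohort_truth(90, 90, n_genes=10, seed=19)
        rng = np.random.default_rng(19)
        y = _as_binary(truth.labels.to_numpy())
        scores = y * 1.8 + rng.normal(size=180)
        tert = pd.qcut(truth.samples["tumor_fraction"], 3, labels=["low", "mid", "high"])
        rows, pvals = cf.stratified_evaluation(scores, y, tert.to_numpy())
        assert len(rows) == 3
        assert rows["auc"].max() - rows["auc"].min() < 0.2
        assert all(p > 0.01 for p in pvals.values())


class TestCovariateCombinations:
    def test_four_covariates_give_fifteen_rows_plus_baseline(self):
        mat, y = shifted_cohort(n_per_class=10, n_noise=2, seed=20)
        rng = np.random.default_rng(20)
        cov = pd.DataFrame(
            {c: rng.integers(0, 2, 20) for c in ["ER", "PR", "Her2", "Ki67"]}, dtype=float
        )
        out = cf.combine_with_covariates(mat, ["f0", "f1"], cov, y)
        assert len(out) == 16
        assert (out["covariates"] == "(baseline)").sum() == 1

    def test_label_leak_covariate_reaches_auc_one(self):
        mat, y = shifted_cohort(n_per_class=10, n_noise=2, n_inform=0, shift=0, seed=21)
        cov = pd.DataFrame({"leak": np.asarray(y, float)})
        out = cf.combine_with_covariates(mat, ["f0"], cov, y)
        assert out.set_index("covariates").loc["leak", "auc"] == 1.0

    def test_missing_covariate_values_rejected(self):
        mat, y = shifted_cohort(n_per_class=5, n_noise=2, seed=22)
        cov = pd.DataFrame({"ER": [1.0, np.nan] + [0.0] * 8})
        with pytest.raises(ClassifierError, match="no imputation"):
            cf.combine_with_covariates(mat, ["f0"], cov, y)


class TestModelResultsFacade:
    def test_fit_selects_informative_features_and_summarizes(self):
        mat, y = shifted_cohort(n_per_class=25, n_noise=10, seed=23)
        res = cf.AlnClassifier(mat, y, model_type="svm").fit(k_top=12)
        assert {"f0", "f1"} & set(res.selected_features)
        assert res.auc > 0.9
        text = res.summary()
        assert "LOOCV AUC" in text and "svm" in text

    def test_from_dataframe_constructor(self):
        mat, y = shifted_cohort(n_per_class=10, n_noise=3, seed=24)
        df = mat.values.copy()
        df["label"] = y
        res = cf.AlnClassifier.from_dataframe(df).fit(k_top=5, ranking_method="weight")
        assert res.train_eval.auc > 0.8

    def test_training_artifacts_independent_of_validation_labels(self):
        """Scrambling validation labels changes nothing fitted on training."""
        mat, y = shifted_cohort(n_per_class=20, n_noise=8, seed=25)
        val_mat, val_y = shifted_cohort(n_per_class=10, n_noise=8, seed=26)
        res1 = cf.AlnClassifier(mat, y).fit(k_top=10)
        res1.evaluate(val_mat, val_y)
        res2 = cf.AlnClassifier(mat, y).fit(k_top=10)
        res2.evaluate(val_mat, np.random.default_rng(0).permutation(val_y))
        assert res1.selected_features == res2.selected_features
        pd.testing.assert_series_equal(res1.loocv_scores_, res2.loocv_scores_)
        np.testing.assert_array_equal(res1.fitted.coef, res2.fitted.coef)

    def test_pooled_evaluation_combines_cohorts(self):
        mat, y = shifted_cohort(n_per_class=15, n_noise=4, seed=27)
        val_mat, val_y = shifted_cohort(n_per_class=8, n_noise=4, seed=28)
        res = cf.AlnClassifier(mat, y).fit(k_top=6, ranking_method="weight")
        pooled = res.pooled_evaluation(val_mat, val_y)
        assert len(pooled.scores) == 46
        assert pooled.cohort == "pooled"


def test_enrichment_pvalue_detects_overrepresentation():
    universe = [f"g{i}" for i in range(100)]
    truth = universe[:10]
    assert cf.enrichment_pvalue(universe[:8], truth, universe) < 1e-6
    assert cf.enrichment_pvalue(universe[50:58], truth, universe) > 0.5
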