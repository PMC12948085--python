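"""Gene-level benchmark machinery: splits, scaling, ROC, importances,
concordance selection, resampling stability."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from scresponse import models, simulate as sim
from scresponse.errors import ValidationError

from oracles import pair_counting_auc


def _meta(labels, patients=None):
    df = pd.DataFrame({"response": labels})
    df["patient_id"] = patients if patients is not None else [f"p{i}" for i in range(len(df))]
    return df


class TestStratifiedSplit:
    def test_cell_split_sizes_and_proportions(self):
        labels = ["responder"] * 40 + ["non-responder"] * 60
        spec = models.SplitSpec(test_fraction=0.2, seed=0)
        tr, te = models.stratified_split(_meta(labels), spec)
        assert len(te) == 20
        assert len(tr) == 80
        te_labels = np.asarray(labels)[te]
        assert (te_labels == "responder").sum() == 8  # class proportion preserved

    def test_seeded_determinism(self):
        labels = ["responder"] * 30 + ["non-responder"] * 30
        spec = models.SplitSpec(seed=5)
        a = models.stratified_split(_meta(labels), spec)
        b = models.stratified_split(_meta(labels), spec)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_patient_split_keeps_patients_whole(self, small_cohort):
        meta = small_cohort["meta"]
        spec = models.SplitSpec(unit="patient", test_fraction=0.3, seed=1)
        tr, te = models.stratified_split(meta, spec)
        tr_patients = set(meta["patient_id"].iloc[tr])
        te_patients = set(meta["patient_id"].iloc[te])
        assert not tr_patients & te_patients
        for part in (tr, te):
            assert meta["response"].iloc[part].nunique() == 2

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            models.stratified_split(_meta(["responder"] * 10), models.SplitSpec())


class TestStandardize:
    def test_train_statistics_and_constant_feature(self, rng):
        X = rng.normal(2.0, 3.0, size=(50, 3))
        X[:, 2] = 7.0  # constant feature
        Xs, _, _ = models.standardize(X)
        assert np.abs(Xs[:, :2].mean(axis=0)).max() < 1e-9
        np.testing.assert_allclose(Xs[:, :2].std(axis=0), 1.0, atol=1e-9)
        np.testing.assert_allclose(Xs[:, 2], 0.0)

    def test_train_only_scaling_differs_from_pooled(self):
        train = np.array([[0.0, 1.0], [2.0, 3.0]])
        test = np.array([[10.0, 11.0]])
        _, applied_train_only, _ = models.standardize(train, test)
        _, applied_pooled, _ = models.standardize(train, test, pooled=True)
        assert not np.allclose(applied_train_only, applied_pooled)


class TestRocAuc:
    def test_hand_enumerated_example(self):
        # 4 positive-negative pairs, 3 concordant -> 0.75
        _, a = models.roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert a == pytest.approx(0.75)

    def test_boundary_cases(self):
        _, perfect = models.roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert perfect == 1.0
        _, ties = models.roc_auc([0.5] * 6, [0, 1, 0, 1, 0, 1])
        assert ties == 0.5
        with pytest.raises(ValidationError):
            models.roc_auc([0.1, 0.2], [1, 1])

    @given(st.integers(0, 500))
    def test_matches_pair_counting_oracle_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 50)
        scores = rng.choice(np.linspace(0, 1, 7), size=n)  # heavy ties
        labels = np.zeros(n, dtype=int)
        labels[rng.choice(n, size=max(1, n // 3), replace=False)] = 1
        if labels.sum() in (0, n):
            labels[0] = 1 - labels[0]
        roc, a = models.roc_auc(scores, labels)
        assert a == pytest.approx(pair_counting_auc(scores, labels), abs=1e-12)
        # stored curve is monotone and its trapezoid equals the auc
        assert (np.diff(roc["fpr"]) >= 0).all() and (np.diff(roc["tpr"]) >= 0).all()
        assert np.trapezoid(roc["tpr"], roc["fpr"]) == pytest.approx(a, abs=1e-9)

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        _, a1 = models.roc_auc(scores, labels)
        _, a2 = models.roc_auc(np.exp(3 * scores) + 5, labels)
        assert a1 == pytest.approx(a2)


class TestTuneAndTrain:
    def test_size_one_search_space_returns_that_candidate(self, rng):
        X = rng.normal(size=(60, 5))
        y = rng.integers(0, 2, 60)
        y[:10] = 1
        y[10:20] = 0
        space = {"n_estimators": [13], "max_depth": [2]}
        _, params = models.tune_and_train("xgboost", X, y, n_iter=5, search_space=space, cv_folds=3)
        assert params == {"n_estimators": 13, "max_depth": 2}

    def test_class_too_small_for_folds_rejected(self, rng):
        X = rng.normal(size=(20, 3))
        y = np.zeros(20, dtype=int)
        y[:3] = 1
        with pytest.raises(ValidationError):
            models.tune_and_train("svm", X, y, cv_folds=5)

    def test_permuted_labels_give_chance_auc(self, rng):
        X = rng.normal(size=(2000, 10))
        y = rng.integers(0, 2, 2000)
        model, _ = models.tune_and_train("logistic_regression", X[:1600], y[:1600])
        _, a = models.roc_auc(models.model_scores(model, X[1600:]), y[1600:])
        assert 0.4 <= a <= 0.6


class TestTreeImportances:
    def test_planted_signals_rank_above_noise(self, rng):
        n = 800
        X = rng.normal(size=(n, 30))
        signal = X[:, :5].sum(axis=1)
        y = (signal + rng.normal(0, 0.5, n) > 0).astype(int)
        est = models.default_estimator("random_forest", seed=0)
        est.fit(X, y)
        ranking = models.tree_importances(est, [f"g{i}" for i in range(30)])
        planted_rank = ranking.ranks[[f"g{i}" for i in range(5)]].mean()
        noise_rank = ranking.ranks[[f"g{i}" for i in range(5, 30)]].mean()
        assert planted_rank < noise_rank
        # ranks are a permutation of 1..m up to average-rank ties
        assert ranking.ranks.sum() == pytest.approx(30 * 31 / 2)

    def test_unsupported_model_rejected(self, rng):
        est = models.default_estimator("logistic_regression")
        est.fit(rng.normal(size=(20, 3)), rng.integers(0, 2, 20))
        with pytest.raises(ValidationError):
            models.tree_importances(est, ["a", "b", "c"])


class TestConcordantSelection:
    def test_identical_and_reversed_rankings(self):
        genes = [f"g{i}" for i in range(30)]
        ranks = pd.Series(np.arange(1.0, 31.0), index=genes)
        sel, rho, _ = models.concordant_gene_selection(ranks, ranks, top_n=10)
        assert len(sel) == 10 and rho == pytest.approx(1.0)
        rev = pd.Series(ranks.to_numpy()[::-1], index=genes)
        sel_r, rho_r, _ = models.concordant_gene_selection(ranks, rev, top_n=10)
        assert rho_r == pytest.approx(-1.0)
        assert sel_r == []

    def test_random_rankings_match_hypergeometric_expectation(self):
        # E[|top50 A intersect top50 B|] = 50^2/210 ~ 11.9 for independent rankings
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(210)]
        sizes = []
        for _ in range(200):
            ra = pd.Series(rng.permutation(210) + 1.0, index=genes)
            rb = pd.Series(rng.permutation(210) + 1.0, index=genes)
            sel, _, _ = models.concordant_gene_selection(ra, rb, top_n=50)
            sizes.append(len(sel))
        assert np.mean(sizes) == pytest.approx(50 * 50 / 210, abs=0.6)

    def test_mismatched_universes_rejected(self):
        ra = pd.Series([1.0, 2.0], index=["a", "b"])
        rb = pd.Series([1.0, 2.0], index=["a", "c"])
        with pytest.raises(ValidationError, match="c"):
            models.concordant_gene_selection(ra, rb)


class TestResamplingStability:
    def test_perfect_classifier_has_degenerate_ci(self, rng):
        X = rng.normal(size=(120, 2))
        y = (X[:, 0] > 0).astype(int)
        X[:, 0] += 4 * y  # fully separable
        out = models.resampling_stability(
            X, y, {"logistic_regression": models.default_estimator("logistic_regression")},
            n_splits=10, base_seed=0,
        )
        assert out["ci95"]["logistic_regression"] == (1.0, 1.0)

    def test_distinct_base_seeds_give_distinct_split_sequences(self, rng):
        X = rng.normal(size=(100, 3))
        y = rng.integers(0, 2, 100)
        y[:5], y[5:10] = 1, 0
        est = {"logistic_regression": models.default_estimator("logistic_regression")}
        a = models.resampling_stability(X, y, est, n_splits=5, base_seed=0)
        b = models.resampling_stability(X, y, est, n_splits=5, base_seed=1000)
        assert not np.array_equal(a["aucs"]["logistic_regression"], b["aucs"]["logistic_regression"])

    def test_too_few_splits_rejected(self, rng):
        with pytest.raises(ValidationError):
            models.resampling_stability(rng.normal(size=(10, 2)), np.array([0, 1] * 5), {}, n_splits=1)


class TestPseudoreplication:
    def test_patient_split_auc_not_above_cell_split_auc(self):
        # with per-sample intercepts and no class effect beyond them, a
        # cell-level split lets models memorize samples; the patient-level
        # split removes that leakage, so its AUC should not exceed the
        # cell-level one (checked in expectation over a few seeds)
        diffs = []
        for seed in range(3):
            cfg = sim.SimConfig(
                seed=seed, n_samples_responder=6, n_samples_nonresponder=6,
                cells_per_sample=30, n_genes=60, n_deg_up_responder=3,
                n_deg_up_nonresponder=3, deg_log2fc=0.4, sample_effect_sd=0.6,
                pathway_spec=None,
            )
            X, meta, _ = sim.simulate_single_cell_cohort(cfg)
            aucs = {}
            for unit in ("cell", "patient"):
                spec = models.SplitSpec(unit=unit, seed=seed)
                tr, te = models.stratified_split(meta, spec)
                Xtr, Xte, _ = models.standardize(X.values[tr], X.values[te])
                y = models.response_to_binary(meta["response"])
                est = models.default_estimator("random_forest", seed=0)
                est.fit(Xtr, y[tr])
                _, aucs[unit] = models.roc_auc(models.model_scores(est, Xte), y[te])
            diffs.append(aucs["cell"] - aucs["patient"])
        assert np.mean(diffs) > 0
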