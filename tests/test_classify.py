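"""Base classifiers, majority voting, and the MMRF probability stack."""

import numpy as np
import pytest

from cystct.classify import (
    BaseClassifierConfig,
    RandomForestConfig,
    SingleClassError,
    fit_base,
    fit_meta,
    fit_mmrf,
    majority_vote,
    positive_proba,
    predict_mmrf,
    predict_proba,
)
from cystct.evaluate import roc_auc


def blobs(n_per_class=50, sep=4.0, dim=3, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack(
        [rng.normal(0, 1, (n_per_class, dim)), rng.normal(sep, 1, (n_per_class, dim))]
    )
    y = np.array(["SCN"] * n_per_class + ["MCN"] * n_per_class)
    perm = rng.permutation(len(y))
    return X[perm], y[perm]


class TestFitBase:
    def test_knn_k1_memorizes_training_point(self):
        X, y = blobs()
        model = fit_base("knn", X, y, BaseClassifierConfig(kind="knn", k=1))
        assert positive_proba(model, X[y == "MCN"][:5]).min() == 1.0

    def test_softmax_separates_disjoint_blobs(self):
        X, y = blobs(sep=6.0)
        model = fit_base("softmax", X, y)
        assert (model.predict(X) == y).mean() == 1.0

    def test_bayes_uninformative_features_near_chance(self):
        """Equal class-conditional means: held-out accuracy ~ 0.5."""
        rng = np.random.default_rng(1)
        X = rng.normal(size=(1000, 4))
        y = np.array(["SCN", "MCN"] * 500)
        model = fit_base("bayes", X[:500], y[:500])
        acc = (model.predict(X[500:]) == y[500:]).mean()
        assert abs(acc - 0.5) < 0.1

    @pytest.mark.parametrize("kind", ["knn", "softmax", "bayes", "svm"])
    def test_proba_rows_normalized(self, kind):
        X, y = blobs(seed=2)
        model = fit_base(kind, X, y)
        proba = predict_proba(model, X[:10])
        assert np.allclose(proba.sum(axis=1), 1.0)
        assert proba.min() >= 0 and proba.max() <= 1

    def test_single_class_rejected(self):
        X = np.zeros((10, 2))
        with pytest.raises(SingleClassError):
            fit_base("knn", X, np.array(["SCN"] * 10))

    def test_nan_rejected(self):
        X, y = blobs()
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            fit_base("bayes", X, y)

    def test_dimension_mismatch_rejected(self):
        X, y = blobs()
        model = fit_base("softmax", X, y)
        with pytest.raises(ValueError):
            predict_proba(model, X[:, :2])

    def test_even_k_rejected(self):
        with pytest.raises(ValueError):
            BaseClassifierConfig(kind="knn", k=4)

    def test_bayes_symmetric_posterior_at_midpoint(self):
        """1-D two-Gaussian toy, means +-1, equal priors: posterior at 0 is (.5, .5)."""
        rng = np.random.default_rng(3)
        X = np.concatenate([rng.normal(-1, 1, 5000), rng.normal(1, 1, 5000)])[:, None]
        y = np.array(["SCN"] * 5000 + ["MCN"] * 5000)
        model = fit_base("bayes", X, y)
        p = predict_proba(model, np.array([[0.0]]))
        assert np.allclose(p, [[0.5, 0.5]], atol=0.02)


class TestMajorityVote:
    @pytest.mark.parametrize(
        "votes,winner",
        [
            (["SCN", "SCN", "MCN"], "SCN"),
            (["MCN", "MCN", "MCN"], "MCN"),
            (["MCN", "SCN", "MCN"], "MCN"),
        ],
    )
    def test_modal_label(self, votes, winner):
        assert majority_vote(votes) == winner

    @pytest.mark.parametrize("votes", [["SCN", "MCN"], ["SCN"] * 4, []])
    def test_non_three_voters_rejected(self, votes):
        with pytest.raises(ValueError):
            majority_vote(votes)


class TestMMRF:
    def test_meta_learner_discovers_informative_base(self):
        """One base's probability equals the label, two are noise: the stack
        must recover near-perfect accuracy and dominate the noise bases."""
        rng = np.random.default_rng(4)
        n = 400
        y = np.array(["SCN", "MCN"] * (n // 2))[rng.permutation(n)]
        meta_X = np.column_stack(
            [(y == "MCN").astype(float), rng.random(n), rng.random(n)]
        )
        tr = rng.permutation(n)[:300]
        te = np.setdiff1d(np.arange(n), tr)
        rf = fit_meta(meta_X[tr], y[tr], RandomForestConfig(seed=0))
        pred = rf.predict(meta_X[te])
        assert (pred == y[te]).mean() >= 0.95
        pos = list(rf.classes_).index("MCN")
        fused = rf.predict_proba(meta_X[te])[:, pos]
        fused_auc = roc_auc(y[te], fused)
        assert fused_auc >= roc_auc(y[te], meta_X[te, 1])
        assert fused_auc >= roc_auc(y[te], meta_X[te, 2])

    def test_identical_bases_agree_with_shared_base(self):
        X, y = blobs(sep=6.0, seed=5)
        configs = tuple(BaseClassifierConfig(kind="softmax") for _ in range(3))
        model = fit_mmrf(X, y, base_configs=configs, seed=1)
        _, fused_labels = predict_mmrf(model, X)
        base_labels = model.base_models[0].predict(X)
        assert (fused_labels == base_labels).mean() == 1.0

    def test_seeded_refit_reproduces_predictions(self):
        X, y = blobs(seed=6)
        p1, l1 = predict_mmrf(fit_mmrf(X, y, seed=9), X)
        p2, l2 = predict_mmrf(fit_mmrf(X, y, seed=9), X)
        assert np.array_equal(p1, p2) and np.array_equal(l1, l2)

    def test_oof_matrix_is_out_of_fold(self):
        """A memorizing base (knn k=1) emits probability 1 for its own label
        in-fold; the stored meta-training matrix must not show that."""
        X, y = blobs(n_per_class=30, sep=0.5, seed=7)  # overlapping classes
        configs = (BaseClassifierConfig(kind="knn", k=1),) * 3
        model = fit_mmrf(X, y, base_configs=configs, seed=2)
        in_fold = (y == "MCN").astype(float)
        assert not np.array_equal(model.oof_probabilities[:, 0], in_fold)

    def test_oof_matrix_matches_manual_fold_loop(self):
        from sklearn.model_selection import StratifiedKFold

        from cystct.classify import _make_estimator

        X, y = blobs(seed=8)
        cfg = BaseClassifierConfig(kind="softmax")
        model = fit_mmrf(X, y, base_configs=(cfg,) * 3, cv_folds=4, seed=3)
        skf = StratifiedKFold(n_splits=4, shuffle=True, random_state=3)
        manual = np.empty(len(y))
        for tr, te in skf.split(X, y):
            est = _make_estimator(cfg).fit(X[tr], y[tr])
            pos = list(est.classes_).index("MCN")
            manual[te] = est.predict_proba(X[te])[:, pos]
        assert np.allclose(model.oof_probabilities[:, 0], manual)

    def test_unanimous_confident_bases_match_majority_vote(self):
        X, y = blobs(sep=8.0, seed=10)
        model = fit_mmrf(X, y, seed=4)
        probs = np.column_stack(
            [positive_proba(m, X) for m in model.base_models]
        )
        confident = np.all(probs > 0.99, axis=1) | np.all(probs < 0.01, axis=1)
        assert confident.any()
        _, fused = predict_mmrf(model, X[confident])
        votes = np.where(probs[confident] >= 0.5, "MCN", "SCN")
        voted = [majority_vote(list(row)) for row in votes]
        assert np.array_equal(fused, voted)

    def test_fused_probability_in_unit_interval(self):
        X, y = blobs(seed=11)
        model = fit_mmrf(X, y, seed=5)
        fused, labels = predict_mmrf(model, X)
        assert fused.min() >= 0 and fused.max() <= 1
        assert set(labels) <= {"SCN", "MCN"}

    def test_small_class_vs_folds_rejected(self):
        X = np.random.default_rng(0).normal(size=(8, 2))
        y = np.array(["SCN"] * 5 + ["MCN"] * 3)
        with pytest.raises(SingleClassError):
            fit_mmrf(X, y, cv_folds=5)

    def test_cv_folds_below_two_rejected(self):
        X, y = blobs()
        with pytest.raises(ValueError):
            fit_mmrf(X, y, cv_folds=1)
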