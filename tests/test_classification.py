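"""GSVM cross-validation, feature selection, ROC/AUC and Youden point."""

import numpy as np
import pandas as pd
import pytest

from hs27pipe.classification import (
    KernelConfig,
    LabeledFeatureSet,
    ROCResult,
    cv_scores,
    roc_auc,
    run_task,
    select_features,
    standardize,
    youden_optimum,
)
from hs27pipe.features import FEATURE_NAMES


def make_set(X, y, names=None):
    X = np.asarray(X, dtype=float)
    names = tuple(names or [f"f{i}" for i in range(X.shape[1])])
    ids = tuple(f"b{i}" for i in range(len(y)))
    return LabeledFeatureSet(X=X, y=np.asarray(y), feature_names=names, biopsy_ids=ids)


def concordance_auc(scores, labels):
    """Brute-force pairwise concordance with ties counted 1/2."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestStandardize:
    def test_two_point_z_score(self):
        train = np.array([[0.0], [2.0]])
        z, _, _, _ = standardize(train, train)
        np.testing.assert_allclose(z.ravel(), [-np.sqrt(0.5), np.sqrt(0.5)])

    def test_apply_equals_train_when_identical(self, rng):
        X = rng.normal(size=(10, 3))
        z_train, z_apply, _, _ = standardize(X, X)
        np.testing.assert_array_equal(z_train, z_apply)

    def test_held_out_row_uses_train_parameters_only(self, rng):
        train = rng.normal(2, 3, size=(20, 2))
        held = rng.normal(0, 1, size=(1, 2))
        _, z, mu, sd = standardize(train, held)
        np.testing.assert_allclose(z, (held - train.mean(0)) / train.std(0, ddof=1))

    def test_zero_variance_column_named(self):
        X = np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]])
        with pytest.raises(ValueError, match="1"):
            standardize(X, X)


class TestCVScores:
    def test_separable_feature_ranks_positives_first(self, rng):
        X = np.concatenate([rng.normal(10, 0.1, 15), rng.normal(0, 0.1, 15)])[:, None]
        y = np.array([1] * 15 + [0] * 15)
        data = make_set(X, y)
        scores = cv_scores(data, ("f0",), k=5, seed=0)
        assert scores[y == 1].min() > scores[y == 0].max()

    def test_determinism(self, rng):
        data = make_set(rng.normal(size=(20, 2)), np.array([0, 1] * 10))
        s1 = cv_scores(data, ("f0", "f1"), k=4, seed=3)
        s2 = cv_scores(data, ("f0", "f1"), k=4, seed=3)
        np.testing.assert_array_equal(s1, s2)

    def test_no_leakage_between_held_out_biopsies(self, rng):
        X = rng.normal(size=(24, 2))
        y = np.array([0, 1] * 12)
        data = make_set(X, y)
        base = cv_scores(data, ("f0", "f1"), k=4, seed=1)
        # perturb one biopsy's features: only biopsies sharing its fold's
        # training membership may change -- its own fold-mates' scores are
        # computed from a model that never saw it
        X2 = X.copy()
        X2[0] += 100.0
        pert = cv_scores(make_set(X2, y), ("f0", "f1"), k=4, seed=1)
        from sklearn.model_selection import StratifiedKFold
        skf = StratifiedKFold(n_splits=4, shuffle=True, random_state=1)
        fold_of_0 = next(
            test for _, test in skf.split(X, y) if 0 in test
        )
        np.testing.assert_array_equal(base[fold_of_0[fold_of_0 != 0]],
                                      pert[fold_of_0[fold_of_0 != 0]])

    def test_fold_reduction_for_small_minority(self, rng):
        X = rng.normal(size=(12, 1))
        y = np.array([1] * 9 + [0] * 3)
        scores = cv_scores(make_set(X, y), ("f0",), k=10, seed=0)  # k drops to 3
        assert len(scores) == 12


class TestROCAndYouden:
    def test_perfect_separation(self):
        roc = roc_auc(np.array([0.9, 0.8, 0.1, 0.2]), np.array([1, 1, 0, 0]))
        assert roc.auc == 1.0
        op = youden_optimum(roc)
        assert (op.sensitivity, op.specificity, op.youden_j) == (1.0, 1.0, 1.0)

    def test_all_tied_scores_give_half(self):
        roc = roc_auc(np.zeros(10), np.array([1] * 5 + [0] * 5))
        assert roc.auc == 0.5

    def test_trapezoid_equals_concordance_oracle(self, rng):
        scores = np.round(rng.normal(size=60), 1)  # rounding forces ties
        labels = rng.integers(0, 2, 60)
        if labels.sum() in (0, 60):
            labels[0] = 1 - labels[0]
        roc = roc_auc(scores, labels)
        assert roc.auc == pytest.approx(concordance_auc(scores, labels), abs=1e-12)

    def test_complement_and_monotone_invariance(self, rng):
        scores = rng.normal(size=40)
        labels = np.array([0, 1] * 20)
        a1 = roc_auc(scores, labels).auc
        assert roc_auc(-scores, labels).auc == pytest.approx(1 - a1, abs=1e-12)
        assert roc_auc(np.exp(scores), labels).auc == pytest.approx(a1, abs=1e-12)

    def test_endpoints_present(self, rng):
        roc = roc_auc(rng.normal(size=20), np.array([0, 1] * 10))
        assert roc.sens[0] == 0 and roc.spec[0] == 1
        assert roc.sens[-1] == 1 and roc.spec[-1] == 0

    def test_youden_matches_exhaustive_scan(self, rng):
        scores = np.round(rng.normal(size=25), 1)
        labels = rng.integers(0, 2, 25)
        labels[:2] = [0, 1]
        roc = roc_auc(scores, labels)
        op = youden_optimum(roc)
        brute = max(
            (scores >= t)[labels == 1].mean() + (scores < t)[labels == 0].mean() - 1
            for t in np.concatenate(([np.inf], np.unique(scores)))
        )
        assert op.youden_j == pytest.approx(brute, abs=1e-12)

    def test_diagonal_roc_tie_breaks_to_high_specificity(self):
        # scores identical within class patterns -> J = 0 everywhere
        roc = roc_auc(np.array([1.0, 2.0, 1.0, 2.0]), np.array([1, 1, 0, 0]))
        op = youden_optimum(roc)
        assert op.youden_j == pytest.approx(0.0)
        assert op.specificity == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.array([1.0, 2.0]), np.array([1, 1]))


class TestSelectFeatures:
    def test_candidate_count_is_n_plus_pairs(self, rng):
        X = rng.normal(size=(30, 12))
        y = np.array([1] * 20 + [0] * 10)
        report = select_features(make_set(X, y, FEATURE_NAMES), k=3, seed=0)
        assert len(report.candidate_sets) == 78  # 12 + C(12,2)
        assert report.best_auc == max(a for _, a in report.candidate_sets)
        assert len(report.best_set) in (1, 2)

    def test_planted_singleton_recovered(self, rng):
        X = rng.normal(size=(37, 6))
        y = np.array([1] * 27 + [0] * 10)
        X[:, 2] += 3.0 * y  # informative feature f2
        report = select_features(make_set(X, y), k=5, seed=0)
        assert "f2" in report.best_set

    def test_xor_pair_recovered_by_gaussian_kernel(self, rng):
        n = 48
        y = np.array([0, 1] * (n // 2))
        x1 = rng.choice([-1.0, 1.0], n)
        x2 = x1 * (2 * y - 1) + rng.normal(0, 0.2, n)
        x1 = x1 + rng.normal(0, 0.2, n)
        X = np.column_stack([x1, x2, rng.normal(size=(n, 3))])
        report = select_features(make_set(X, y), k=4, seed=0)
        assert set(report.best_set) == {"f0", "f1"}


class TestRunTask:
    @staticmethod
    def feature_frame(rng, n_pos=12, n_neg=8, gap=6.0, neg_class="mammoplasty"):
        rows = []
        for i in range(n_pos + n_neg):
            pos = i < n_pos
            base = {n: rng.normal(gap if pos else 0.0, 1.0) for n in FEATURE_NAMES}
            base.update(
                biopsy_id=f"b{i}",
                tissue_class="tumor" if pos else neg_class,
                subtype="TNBC" if pos else "none",
            )
            rows.append(base)
        return pd.DataFrame(rows)

    def test_strong_signal_end_to_end(self, rng):
        df = self.feature_frame(rng)
        rep = run_task(df, "tumor_vs_mammoplasty", k=4, seed=0)
        assert rep.roc.auc > 0.95
        assert rep.operating_point.specificity == 1.0
        assert set(rep.block_aucs) == {"cdf_all", "cdf_top1", "summary_all", "summary_top1"}

    def test_null_pipeline_auc_centred_on_half(self, rng):
        aucs = []
        for seed in range(20):
            df = self.feature_frame(rng, gap=0.0)
            rep_scores = cv_scores(
                LabeledFeatureSet(
                    X=df[list(FEATURE_NAMES)].to_numpy(),
                    y=(df["tissue_class"] == "tumor").astype(int).to_numpy(),
                    feature_names=FEATURE_NAMES,
                    biopsy_ids=tuple(df["biopsy_id"]),
                ),
                ("cdf_A_all", "mean_all"), k=4, seed=seed,
            )
            aucs.append(roc_auc(rep_scores, (df["tissue_class"] == "tumor").astype(int).to_numpy()).auc)
        assert 0.35 < np.mean(aucs) < 0.65

    def test_missing_class_rejected(self, rng):
        df = self.feature_frame(rng, neg_class="benign")
        with pytest.raises(ValueError, match="missing"):
            run_task(df, "tumor_vs_mammoplasty")
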