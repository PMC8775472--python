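"""Feature ranking, subset selection, the one-vs-rest SVM stager and
subject-grouped cross-validation.

These tests run on small constructed feature matrices; the full
EEG-to-hypnogram staging performance is exercised in the acceptance suite.
"""

import numpy as np
import pandas as pd
import pytest

from somnostage import (STAGES, cross_validate, predict_stage,
                        rank_features_gini, select_subset, train_ovr_svm)
from somnostage.staging import StagingModel
from somnostage.exceptions import ConfigurationError, DataError
from sklearn.preprocessing import StandardScaler


def make_fm(n_per_class=30, n_noise=18, informative_scale=0.01, seed=0,
            classes=STAGES):
    """Synthetic matrix: feature f0 = class index + tiny noise (perfectly
    separating), f1 weakly informative, the rest pure noise."""
    rng = np.random.default_rng(seed)
    rows = []
    for ci, stage in enumerate(classes):
        for _ in range(n_per_class):
            row = {"f0": ci + rng.normal(0, informative_scale),
                   "f1": ci + rng.normal(0, 1.5)}
            for j in range(n_noise):
                row[f"noise{j}"] = rng.normal()
            row["stage"] = stage
            rows.append(row)
    return pd.DataFrame(rows)


class TestRanking:
    def test_separating_feature_ranks_first(self):
        ranking = rank_features_gini(make_fm(seed=1), seed=1)
        assert ranking.iloc[0]["feature"] == "f0"

    def test_duplicated_feature_shares_importance(self):
        fm = make_fm(seed=2, informative_scale=0.5)
        base = rank_features_gini(fm, seed=2).set_index("feature")
        orig = base.loc["f0", "importance"]
        fm2 = fm.copy()
        fm2["f0_copy"] = fm2["f0"]
        dup = rank_features_gini(fm2, seed=2).set_index("feature")
        combined = dup.loc["f0", "importance"] + dup.loc["f0_copy", "importance"]
        assert combined == pytest.approx(orig, rel=0.2)

    def test_single_class_rejected(self):
        fm = make_fm(classes=("N2",))
        with pytest.raises(DataError):
            rank_features_gini(fm)


class TestSubset:
    def test_identity_and_top1(self):
        ranking = rank_features_gini(make_fm(seed=3), seed=3)
        assert select_subset(ranking, k=len(ranking)) == \
            ranking["feature"].tolist()
        assert select_subset(ranking, k=1) == [ranking.iloc[0]["feature"]]

    def test_default_k_is_eight(self):
        ranking = rank_features_gini(make_fm(seed=3), seed=3)
        assert len(select_subset(ranking)) == 8

    def test_bad_k(self):
        ranking = rank_features_gini(make_fm(seed=3), seed=3)
        with pytest.raises(ConfigurationError):
            select_subset(ranking, k=0)


class TestOvRSVM:
    def test_separable_training_is_perfect(self):
        fm = make_fm(seed=4)
        model = train_ovr_svm(fm, ["f0", "f1"], seed=4)
        pred, probs = predict_stage(model, fm)
        assert np.mean(pred == fm["stage"].to_numpy()) == 1.0
        assert (probs >= 0).all() and (probs <= 1).all()

    def test_deterministic_training(self):
        fm = make_fm(seed=5)
        held = make_fm(seed=55)
        p1, _ = predict_stage(train_ovr_svm(fm, ["f0", "f1"], seed=7), held)
        p2, _ = predict_stage(train_ovr_svm(fm, ["f0", "f1"], seed=7), held)
        assert np.array_equal(p1, p2)

    def test_duplicating_training_data_changes_nothing(self):
        fm = make_fm(seed=6)
        held = make_fm(seed=66)
        p1, _ = predict_stage(train_ovr_svm(fm, ["f0", "f1"], seed=1), held)
        doubled = pd.concat([fm, fm], ignore_index=True)
        p2, _ = predict_stage(train_ovr_svm(doubled, ["f0", "f1"], seed=1),
                              held)
        assert np.mean(p1 == p2) > 0.98

    def test_absent_stage_warns_and_scores_low(self):
        fm = make_fm(classes=("N0", "N1", "N2", "N3"), seed=7)
        with pytest.warns(UserWarning, match="REM"):
            model = train_ovr_svm(fm, ["f0", "f1"], seed=7)
        pred, probs = predict_stage(model, fm)
        assert probs[:, STAGES.index("REM")].max() < 1e-6
        assert "REM" not in pred

    def test_model_bundle_roundtrip(self, tmp_path):
        fm = make_fm(seed=9)
        model = train_ovr_svm(fm, ["f0", "f1"], seed=9)
        path = tmp_path / "model.bundle"
        model.save(path)
        back = StagingModel.load(path)
        p1, _ = predict_stage(model, fm)
        p2, _ = predict_stage(back, fm)
        assert np.array_equal(p1, p2)
        assert back.manifest()["subset"] == ["f0", "f1"]

    def test_argmax_tie_goes_to_earlier_stage(self):
        class Flat:
            classes_ = np.array([0, 1])

            def __init__(self, p):
                self.p = p

            def predict_proba(self, X):
                return np.column_stack([np.full(len(X), 1 - self.p),
                                        np.full(len(X), self.p)])

        X = pd.DataFrame({"f0": [0.0], "f1": [0.0]})
        scaler = StandardScaler().fit([[0, 0], [1, 1]])
        model = StagingModel(subset=["f0", "f1"], scaler=scaler,
                             scorers={"N0": Flat(0.2), "N1": Flat(0.7),
                                      "N2": Flat(0.7), "N3": Flat(0.1),
                                      "REM": Flat(0.7)})
        pred, _ = predict_stage(model, X)
        assert pred[0] == "N1"  # earliest of the tied maxima


class TestCrossValidation:
    def _grouped_fm(self, n_subjects=12, seed=8):
        frames = []
        for s in range(n_subjects):
            df = make_fm(n_per_class=6, seed=seed + s)
            df["subject"] = f"S{s}"
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def test_every_subject_in_exactly_one_test_fold(self):
        fm = self._grouped_fm()
        cv = cross_validate(fm, folds=6, k=4, seed=0)
        seen = [s for fold in cv.folds for s in fold["test_subjects"]]
        assert sorted(seen) == sorted(fm["subject"].unique())

    def test_selection_refit_inside_each_fold(self):
        """The per-fold selected subsets are computed on the training folds:
        they must match a ranking re-fit on exactly those subjects."""
        fm = self._grouped_fm()
        cv = cross_validate(fm, folds=6, k=4, seed=0)
        fold0 = cv.folds[0]
        train = fm[~fm["subject"].isin(fold0["test_subjects"])]
        expected = select_subset(rank_features_gini(train, seed=0), k=4)
        assert fold0["subset"] == expected

    def test_confusion_rows_sum_to_stage_counts(self):
        fm = self._grouped_fm()
        cv = cross_validate(fm, folds=6, k=4, seed=0)
        counts = fm["stage"].value_counts()
        for s in STAGES:
            assert cv.confusion.loc[s].sum() == counts.get(s, 0)

    def test_separable_cohort_high_accuracy(self):
        cv = cross_validate(self._grouped_fm(), folds=6, k=4, seed=0)
        assert cv.mean_accuracy > 0.95

    def test_more_folds_than_subjects_rejected(self):
        with pytest.raises(ConfigurationError):
            cross_validate(self._grouped_fm(n_subjects=4), folds=6)
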