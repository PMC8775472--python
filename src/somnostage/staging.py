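"""Epoch-level sleep staging: Gini feature selection + one-vs-rest SVM.

The staging model is a pipeline of three fitted parts, all learned on
training data only:

1. a CART tree ranks the 20 features by total Gini-impurity decrease;
2. the top-k features (k = 8 by default) are z-scored with training
   location/scale;
3. five binary RBF-SVM scorers (one per stage, stage-vs-rest) with Platt
   probability calibration produce per-stage probability estimates; the
   predicted stage is the argmax, ties resolved to the earlier stage in the
   fixed order (N0, N1, N2, N3, REM).

Cross-validation is subject-grouped: no subject contributes epochs to both
the training and test side of a fold, and selection/standardisation/
calibration are re-fit inside each training fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.model_selection import GroupKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .exceptions import ConfigurationError, DataError
from .features import FEATURE_NAMES, FeatureConfig, extract_features
from .preprocess import epoch_record
from .types import Hypnogram, STAGES

__all__ = ["StagingModel", "CVResult", "rank_features_gini", "select_subset",
           "train_ovr_svm", "predict_proba", "predict_stage",
           "cross_validate", "stage_recording", "median_smooth"]


#: Non-feature columns of a feature matrix.
RESERVED_COLUMNS = {"epoch_index", "stage", "subject", "group", "night"}


def _xy(fm: pd.DataFrame, feature_names=None):
    if feature_names is None:
        feature_names = [c for c in fm.columns
                         if c not in RESERVED_COLUMNS
                         and pd.api.types.is_numeric_dtype(fm[c])]
    names = list(feature_names)
    X = fm[names].to_numpy(float)
    if not np.isfinite(X).all():
        raise DataError("feature matrix contains non-finite entries")
    return X, names


def rank_features_gini(fm: pd.DataFrame, label_col: str = "stage",
                       seed: int = 0, **tree_kw) -> pd.DataFrame:
    """Rank features by total Gini-impurity decrease of a CART tree.

    Returns a DataFrame (feature, importance) sorted descending;
    deterministic under a fixed seed.
    """
    if label_col not in fm.columns:
        raise DataError(f"label column {label_col!r} missing")
    y = fm[label_col].to_numpy()
    if len(np.unique(y)) < 2:
        raise DataError("feature ranking needs at least 2 classes")
    X, names = _xy(fm)
    tree = DecisionTreeClassifier(criterion="gini", random_state=seed,
                                  **tree_kw)
    tree.fit(X, y)
    order = np.argsort(-tree.feature_importances_, kind="stable")
    return pd.DataFrame({
        "feature": [names[i] for i in order],
        "importance": tree.feature_importances_[order],
    })


def select_subset(ranking: pd.DataFrame, k: int = 8) -> list[str]:
    """Top-k features of a ranking."""
    if not (1 <= k <= len(ranking)):
        raise ConfigurationError(f"k must be in 1..{len(ranking)}")
    return ranking["feature"].head(k).tolist()


@dataclass
class StagingModel:
    subset: list[str]
    scaler: StandardScaler
    scorers: dict  # stage -> fitted SVC or None (stage absent in training)
    seed: int = 0
    hyper: dict = field(default_factory=dict)

    def manifest(self) -> dict:
        """JSON-serialisable description of the fitted model."""
        return {
            "format_version": 1,
            "subset": self.subset,
            "standardization": {
                "mean": self.scaler.mean_.tolist(),
                "scale": self.scaler.scale_.tolist(),
            },
            "stages": [s for s in STAGES],
            "missing_stages": [s for s, f in self.scorers.items() if f is None],
            "seed": self.seed,
            "hyperparameters": self.hyper,
        }

    def save(self, path) -> None:
        """Single-file bundle: the fitted estimators plus the manifest."""
        import joblib
        joblib.dump({"manifest": self.manifest(), "model": self}, path)

    @classmethod
    def load(cls, path) -> "StagingModel":
        import joblib
        bundle = joblib.load(path)
        model = bundle["model"]
        if bundle["manifest"]["format_version"] != 1:
            raise DataError("unsupported model bundle format")
        return model


def train_ovr_svm(fm: pd.DataFrame, subset: list[str] | None = None,
                  label_col: str = "stage", C: float = 1.0,
                  gamma="scale", class_weight="balanced",
                  seed: int = 0) -> StagingModel:
    """Fit the five stage-vs-rest scorers on standardised selected features.

    Each scorer is an RBF SVC with Platt-calibrated probabilities. A stage
    absent from the training labels gets a None scorer that emits a constant
    low probability at prediction time (with a warning here).
    """
    if subset is None:
        subset = [c for c in FEATURE_NAMES if c in fm.columns]
    if not subset:
        raise DataError("empty feature subset")
    y = fm[label_col].to_numpy()
    if len(np.unique(y)) < 2:
        raise DataError("training needs at least 2 classes")
    X, _ = _xy(fm, subset)
    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)
    scorers = {}
    hyper = {"C": C, "gamma": gamma, "kernel": "rbf",
             "class_weight": class_weight}
    for stage in STAGES:
        mask = (y == stage)
        n_pos = int(mask.sum())
        if n_pos < 2 or mask.all():
            warnings.warn(f"stage {stage} missing (or the only stage) in the "
                          "training data; its scorer will emit a constant "
                          "low probability")
            scorers[stage] = None
            continue
        svc = SVC(kernel="rbf", C=C, gamma=gamma, class_weight=class_weight,
                  random_state=seed)
        cv = min(5, n_pos, int((~mask).sum()))
        clf = CalibratedClassifierCV(svc, method="sigmoid", cv=cv,
                                     ensemble=False)
        clf.fit(Xs, mask.astype(int))
        scorers[stage] = clf
    return StagingModel(subset=list(subset), scaler=scaler, scorers=scorers,
                        seed=seed, hyper=hyper)


def predict_proba(model: StagingModel, fm: pd.DataFrame) -> np.ndarray:
    """(n_epochs, 5) per-stage probability estimates in stage order."""
    X, _ = _xy(fm, model.subset)
    Xs = model.scaler.transform(X)
    probs = np.empty((Xs.shape[0], len(STAGES)))
    for j, stage in enumerate(STAGES):
        clf = model.scorers[stage]
        if clf is None:
            probs[:, j] = 1e-9
        else:
            pos = list(clf.classes_).index(1)
            probs[:, j] = clf.predict_proba(Xs)[:, pos]
    return probs


def predict_stage(model: StagingModel, fm: pd.DataFrame):
    """Predicted stage labels and the 5-column probability matrix.

    The stage with the maximum estimate wins; an exact tie goes to the
    stage earlier in the fixed order.
    """
    probs = predict_proba(model, fm)
    winners = np.argmax(probs, axis=1)  # first maximum -> earlier stage
    return np.array([STAGES[i] for i in winners]), probs


@dataclass
class CVResult:
    fold_accuracy: list
    mean_accuracy: float
    sd_accuracy: float
    per_stage_recall: dict
    confusion: pd.DataFrame  # rows = true stage, cols = predicted
    folds: list  # per-fold dicts: test_subjects, subset, n_test


def cross_validate(fm: pd.DataFrame, folds: int = 10, k: int = 8,
                   label_col: str = "stage", subject_col: str = "subject",
                   C: float = 1.0, class_weight="balanced",
                   seed: int = 0) -> CVResult:
    """Subject-grouped k-fold cross-validation of the full staging pipeline.

    Feature ranking, subset selection, standardisation and the SVM scorers
    are re-fit inside each training fold, so no information from a test
    subject leaks into the model that stages it.
    """
    subjects = fm[subject_col].to_numpy()
    n_subjects = len(np.unique(subjects))
    if folds > n_subjects:
        raise ConfigurationError(
            f"{folds} folds but only {n_subjects} subjects")
    y = fm[label_col].to_numpy()
    accs, fold_info = [], []
    conf = pd.DataFrame(0, index=list(STAGES), columns=list(STAGES))
    for tr, te in GroupKFold(n_splits=folds).split(fm, y, groups=subjects):
        train = fm.iloc[tr]
        test = fm.iloc[te]
        ranking = rank_features_gini(train, label_col=label_col, seed=seed)
        subset = select_subset(ranking, k=min(k, len(ranking)))
        model = train_ovr_svm(train, subset, label_col=label_col, C=C,
                              class_weight=class_weight, seed=seed)
        pred, _ = predict_stage(model, test)
        truth = y[te]
        accs.append(float(np.mean(pred == truth)))
        for t, p in zip(truth, pred):
            conf.loc[t, p] += 1
        fold_info.append({"test_subjects": sorted(set(subjects[te])),
                          "subset": subset, "n_test": len(te)})
    recall = {}
    for s in STAGES:
        row = conf.loc[s]
        recall[s] = float(row[s] / row.sum()) if row.sum() else float("nan")
    accs_arr = np.array(accs)
    return CVResult(fold_accuracy=accs, mean_accuracy=float(accs_arr.mean()),
                    sd_accuracy=float(accs_arr.std(ddof=1)),
                    per_stage_recall=recall, confusion=conf, folds=fold_info)


def median_smooth(labels: np.ndarray, width: int = 3) -> np.ndarray:
    """Optional temporal smoothing: per-epoch majority over a centred window
    (off by default in the pipeline)."""
    out = labels.copy()
    half = width // 2
    for i in range(len(labels)):
        lo, hi = max(0, i - half), min(len(labels), i + half + 1)
        vals, counts = np.unique(labels[lo:hi], return_counts=True)
        out[i] = vals[np.argmax(counts)]
    return out


def stage_recording(model: StagingModel, rec, channel: str,
                    cfg: FeatureConfig | None = None,
                    smooth: bool = False) -> Hypnogram:
    """Stage a preprocessed recording epoch by epoch on one channel."""
    epochs = epoch_record(rec, channel)
    fm = extract_features(epochs, cfg)
    pred, _ = predict_stage(model, fm)
    if smooth:
        pred = median_smooth(pred)
    return Hypnogram.from_labels(pred)
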