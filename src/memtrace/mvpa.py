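"""Cross-task MVPA: localizer-trained face/house decoding with calibrated
probabilities.

A balanced, L2-regularized linear SVM (C = 1) is trained on localizer
betaseries within the face-selective ROI, after per-fold standardization
and ANOVA feature selection keeping the 14 voxels with the strongest
face-preferring F statistics.  Leave-one-run-out cross-validation reports
balanced accuracies; the full model (all runs) is Platt-calibrated and
applied to association-task epochs to yield a per-trial face-processing
probability — the representation-strength measure fed to the
brain-behavior linkage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.calibration import CalibratedClassifierCV
from sklearn.feature_selection import f_classif
from sklearn.metrics import balanced_accuracy_score, recall_score
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .lss import BetaSeries

__all__ = [
    "MvpaConfig",
    "FaceEvidenceModel",
    "select_face_features",
    "cross_validate",
    "fit_full_model",
    "predict_evidence",
    "validate_probability_measure",
]


@dataclass(frozen=True)
class MvpaConfig:
    n_features: int = 14
    svm_cost: float = 1.0
    seed: int = 0
    label_column: str = "category"      # 'face' / 'house'
    run_column: str = "run"


def select_face_features(X: np.ndarray, y: np.ndarray,
                         n_features: int) -> np.ndarray:
    """Indices of the strongest face-preferring voxels by one-way F.

    Only voxels whose face-class mean exceeds the house-class mean are
    candidates ("positive ANOVA effects" — the FFA-like population);
    within those, the ``n_features`` largest F statistics are kept.  If
    fewer positive voxels exist, all of them are returned; if none exist
    (possible under label permutation), the top-F voxels are used
    regardless of sign so the classifier remains fittable.
    """
    f_stat, _ = f_classif(X, y)
    f_stat = np.nan_to_num(f_stat)
    face_mean = X[y == "face"].mean(axis=0)
    house_mean = X[y == "house"].mean(axis=0)
    positive = np.flatnonzero(face_mean > house_mean)
    if len(positive) == 0:
        positive = np.arange(X.shape[1])
    order = positive[np.argsort(f_stat[positive])[::-1]]
    return np.sort(order[:n_features])


def _check_series(series: BetaSeries, config: MvpaConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    X = series.matrix
    y = series.trial_meta[config.label_column].to_numpy()
    runs = series.trial_meta[config.run_column].to_numpy()
    return X, y, runs


def cross_validate(series: BetaSeries, config: MvpaConfig = MvpaConfig()) -> dict:
    """Leave-one-run-out cross-validation of the face/house classifier.

    Per fold: standardize on the training runs only, select features on the
    training runs only, fit a balanced linear SVM, and score the held-out
    run with balanced accuracy (mean of per-class recalls).  Folds whose
    training set lacks a class are skipped with an error record.
    """
    X, y, runs = _check_series(series, config)
    run_ids = np.unique(runs)
    if len(run_ids) < 2:
        raise ValueError("cross-validation needs at least 2 runs")
    folds = []
    for held in run_ids:
        train = runs != held
        if len(np.unique(y[train])) < 2:
            folds.append(dict(run=held, error="training set missing a class"))
            continue
        scaler = StandardScaler().fit(X[train])
        Xtr = scaler.transform(X[train])
        Xte = scaler.transform(X[~train])
        feat = select_face_features(Xtr, y[train], config.n_features)
        clf = SVC(kernel="linear", C=config.svm_cost, class_weight="balanced",
                  random_state=config.seed)
        clf.fit(Xtr[:, feat], y[train])
        pred = clf.predict(Xte[:, feat])
        folds.append(dict(
            run=held,
            balanced_accuracy=balanced_accuracy_score(y[~train], pred),
            face_accuracy=recall_score(y[~train], pred, pos_label="face",
                                       zero_division=np.nan),
            house_accuracy=recall_score(y[~train], pred, pos_label="house",
                                        zero_division=np.nan),
        ))
    scored = [f for f in folds if "balanced_accuracy" in f]
    accs = np.array([f["balanced_accuracy"] for f in scored])
    face = np.array([f["face_accuracy"] for f in scored], float)
    house = np.array([f["house_accuracy"] for f in scored], float)
    return dict(
        folds=folds,
        mean_balanced_accuracy=float(accs.mean()) if len(accs) else np.nan,
        mean_face_accuracy=float(np.nanmean(face)) if len(face) else np.nan,
        mean_house_accuracy=float(np.nanmean(house)) if len(house) else np.nan,
        class_accuracy_difference=(float(np.nanmean(face - house))
                                   if len(face) else np.nan),
    )


@dataclass
class FaceEvidenceModel:
    """Frozen decoding chain: scaler -> feature subset -> Platt-scaled SVM."""

    scaler: StandardScaler
    feature_idx: np.ndarray
    classifier: CalibratedClassifierCV
    config: MvpaConfig
    n_voxels: int

    def predict_proba_face(self, X: np.ndarray) -> np.ndarray:
        if X.shape[1] != self.n_voxels:
            raise ValueError(
                f"feature-space mismatch: model expects {self.n_voxels} "
                f"voxels, got {X.shape[1]}")
        Xs = self.scaler.transform(X)[:, self.feature_idx]
        proba = self.classifier.predict_proba(Xs)
        face_col = list(self.classifier.classes_).index("face")
        return proba[:, face_col]

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "FaceEvidenceModel":
        return joblib.load(path)


def fit_full_model(series: BetaSeries,
                   config: MvpaConfig = MvpaConfig()) -> FaceEvidenceModel:
    """Fit the cross-classification model on all localizer runs.

    Scaling and feature selection use every training trial (there is no
    held-out run at this stage); Platt calibration of the decision values
    is fit by the SVM's internal cross-validation, seeded for
    reproducibility.
    """
    X, y, _ = _check_series(series, config)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to fit the model")
    if config.n_features > len(y):
        raise ValueError("n_features exceeds the number of training trials")
    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)
    feat = select_face_features(Xs, y, config.n_features)
    base = SVC(kernel="linear", C=config.svm_cost, class_weight="balanced",
               random_state=config.seed)
    clf = CalibratedClassifierCV(base, method="sigmoid", cv=5, ensemble=False)
    clf.fit(Xs[:, feat], y)
    return FaceEvidenceModel(scaler=scaler, feature_idx=feat, classifier=clf,
                             config=config, n_voxels=X.shape[1])


def predict_evidence(model: FaceEvidenceModel, series: BetaSeries,
                     epoch: str, participant_id=None) -> pd.DataFrame:
    """Calibrated face-probability per trial of an association-task epoch.

    ``predicted_class`` is face whenever ``face_probability >= 0.5`` (ties
    go to face).
    """
    proba = model.predict_proba_face(series.matrix)
    out = series.trial_meta.copy()
    out["epoch"] = epoch
    out["face_probability"] = proba
    out["predicted_class"] = np.where(proba >= 0.5, "face", "house")
    if participant_id is not None:
        out["participant_id"] = participant_id
    return out


def validate_probability_measure(evidence: pd.DataFrame) -> pd.DataFrame:
    """Spearman check that mean face probability tracks face-prediction rate.

    Groups by participant within each epoch and correlates the mean
    calibrated probability with the fraction of face predictions — the two
    should agree in rank if the probability scale is meaningful.
    """
    rows = []
    for epoch, grp in evidence.groupby("epoch"):
        per = grp.groupby("participant_id").agg(
            mean_probability=("face_probability", "mean"),
            face_fraction=("predicted_class", lambda s: (s == "face").mean()),
        )
        if len(per) < 5:
            raise ValueError("validation needs at least 5 participants")
        if per["mean_probability"].nunique() == 1 or per["face_fraction"].nunique() == 1:
            import warnings

            warnings.warn(f"constant values in epoch {epoch!r}; "
                          "correlation undefined")
            rho, p = np.nan, np.nan
        else:
            rho, p = spearmanr(per["mean_probability"], per["face_fraction"])
        rows.append(dict(epoch=epoch, rho=rho, p=p, n=len(per)))
    return pd.DataFrame(rows)
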