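"""Leave-one-subject-out machine-learning evaluation.

Classification of impairment (binary or 0-4) and support-vector
regression of the impairment score from HRV features.  Folds are split by
subject so no subject contributes to both training and testing;
standardization, SMOTE balancing and hyperparameter tuning all see
training rows only.  SMOTE is implemented here (interpolation between
nearest minority neighbours) so its randomness and neighbour policy are
fully specified and seedable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import accuracy_score, f1_score, mean_squared_error, r2_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier, NearestNeighbors
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, SVR

__all__ = [
    "LosoSplit",
    "SmoteConfig",
    "CvReport",
    "MODEL_GRIDS",
    "make_model",
    "make_loso",
    "smote",
    "tune_first_fold",
    "evaluate_classifiers",
    "svr_regression_eval",
]

#: hyperparameter grids: SVM C spans 0.001..1000 by factors of 10 (7
#: values); KNN k in 2..5; random forest over the stated size/depth ranges.
MODEL_GRIDS = {
    "kernel_svm": {"C": [10.0**e for e in range(-3, 4)]},
    "linear_svm": {"C": [10.0**e for e in range(-3, 4)]},
    "knn": {"n_neighbors": [2, 3, 4, 5]},
    "random_forest": {
        "n_estimators": [20, 30, 50, 70, 100],
        "max_depth": [3, 5, 10, 15, 20],
    },
}


def make_model(name: str, params: dict | None = None, seed: int = 0):
    params = params or {}
    if name == "random_forest":
        return RandomForestClassifier(random_state=seed, **params)
    if name == "kernel_svm":
        return SVC(kernel="rbf", random_state=seed, **params)
    if name == "linear_svm":
        return SVC(kernel="linear", random_state=seed, **params)
    if name == "knn":
        return KNeighborsClassifier(**params)
    raise ValueError(f"unknown model {name!r}")


@dataclass
class LosoSplit:
    """One fold per subject: (training subject ids, test subject id)."""

    folds: list

    def __len__(self) -> int:
        return len(self.folds)


@dataclass
class SmoteConfig:
    k_neighbors: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")


@dataclass
class CvReport:
    model: str
    stratum: str
    fold_accuracy: list
    fold_f1: list
    chosen_params: dict = field(default_factory=dict)

    @property
    def accuracy_mean(self) -> float:
        return float(np.mean(self.fold_accuracy))

    @property
    def accuracy_sd(self) -> float:
        return float(np.std(self.fold_accuracy, ddof=1))

    @property
    def f1_mean(self) -> float:
        return float(np.mean(self.fold_f1))

    @property
    def f1_sd(self) -> float:
        return float(np.std(self.fold_f1, ddof=1))


def make_loso(data: pd.DataFrame) -> LosoSplit:
    """Leave-one-subject-out folds, ordered by subject id."""
    counts = data.groupby("subject_id").size()
    subjects = sorted(counts[counts > 0].index)
    empty = sorted(set(data["subject_id"].unique()) - set(subjects))
    if empty:
        warnings.warn(f"subjects without stages excluded: {empty}")
    if len(subjects) < 3:
        raise ValueError("need at least 3 subjects for LOSO")
    folds = [([s for s in subjects if s != t], t) for t in subjects]
    return LosoSplit(folds=folds)


def smote(
    X: np.ndarray, y: np.ndarray, cfg: SmoteConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic minority oversampling.

    Each synthetic sample is x_i + u * (x_nn - x_i) with u ~ U(0,1) and
    x_nn one of the k nearest minority neighbours (Euclidean distance on
    z-scored features, interpolation in the original feature space).
    Originals are preserved verbatim; output classes are balanced to the
    majority count.
    """
    cfg = cfg or SmoteConfig()
    X = np.asarray(X, float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("SMOTE requires at least 2 classes")
    n_maj = counts.max()
    rng = np.random.default_rng(cfg.seed)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xz = (X - X.mean(axis=0)) / sd
    X_out = [X]
    y_out = [y]
    for cls, cnt in zip(classes, counts):
        need = n_maj - cnt
        if need == 0:
            continue
        if cnt < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 samples")
        idx = np.flatnonzero(y == cls)
        k = cfg.k_neighbors
        if k >= cnt:
            warnings.warn(f"k_neighbors lowered to {cnt - 1} for class {cls!r}")
            k = cnt - 1
        nn = NearestNeighbors(n_neighbors=k + 1).fit(Xz[idx])
        _, nbrs = nn.kneighbors(Xz[idx])  # column 0 is the point itself
        picks = rng.integers(0, cnt, size=need)
        nbr_col = rng.integers(1, k + 1, size=need)
        u = rng.uniform(0.0, 1.0, size=need)
        xi = X[idx[picks]]
        xn = X[idx[nbrs[picks, nbr_col]]]
        X_out.append(xi + u[:, None] * (xn - xi))
        y_out.append(np.full(need, cls, dtype=y.dtype))
    return np.vstack(X_out), np.concatenate(y_out)


def tune_first_fold(
    X: np.ndarray, y: np.ndarray, model: str, seed: int = 0, cv: int = 10
) -> dict:
    """Grid search with stratified k-fold CV, maximizing F1.

    Run on the first LOSO training fold only; the chosen parameters are
    reused for all subsequent folds.
    """
    binary = len(np.unique(y)) == 2
    scoring = "f1" if binary else "f1_macro"
    n_min = np.unique(y, return_counts=True)[1].min()
    splitter = StratifiedKFold(
        n_splits=min(cv, int(n_min)), shuffle=True, random_state=seed
    )
    gs = GridSearchCV(
        make_model(model, seed=seed),
        MODEL_GRIDS[model],
        scoring=scoring,
        cv=splitter,
        n_jobs=1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gs.fit(X, y)
    return dict(gs.best_params_)


def _fold_arrays(data, labels, feature_cols, train_subj, test_subj):
    tr = data["subject_id"].isin(train_subj).to_numpy()
    te = (data["subject_id"] == test_subj).to_numpy()
    X = data[feature_cols].to_numpy(float)
    y = np.asarray(labels)
    return X[tr], y[tr], X[te], y[te]


def evaluate_classifiers(
    data: pd.DataFrame,
    labels: np.ndarray,
    feature_cols: list[str],
    split: LosoSplit | None = None,
    smote_cfg: SmoteConfig | None = None,
    models: tuple[str, ...] = ("random_forest", "kernel_svm", "linear_svm", "knn"),
    stratum: str = "all",
    seed: int = 0,
    tune: bool = True,
    params: dict | None = None,
) -> list[CvReport]:
    """LOSO evaluation of the four classifiers.

    Per fold: z-score standardization fitted on training rows, SMOTE on
    the training rows only, fit, predict the held-out subject.  F1 uses
    the impaired class for binary labels and macro averaging otherwise;
    single-class test folds are excluded from the F1 mean (accuracy is
    still counted).
    """
    split = split or make_loso(data)
    smote_cfg = smote_cfg or SmoteConfig(seed=seed)
    data = data.reset_index(drop=True)
    labels = np.asarray(labels)
    binary = len(np.unique(labels)) == 2
    reports = []
    for model in models:
        chosen = dict(params.get(model, {})) if params else {}
        accs, f1s = [], []
        for i, (train_subj, test_subj) in enumerate(split.folds):
            Xtr, ytr, Xte, yte = _fold_arrays(
                data, labels, feature_cols, train_subj, test_subj
            )
            if len(np.unique(ytr)) < 2 or len(Xte) == 0:
                continue
            scaler = StandardScaler().fit(Xtr)
            Xtr_s, Xte_s = scaler.transform(Xtr), scaler.transform(Xte)
            if i == 0 and tune and not chosen:
                chosen = tune_first_fold(Xtr_s, ytr, model, seed=seed)
            Xb, yb = smote(Xtr_s, ytr, smote_cfg)
            clf = make_model(model, chosen, seed=seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                clf.fit(Xb, yb)
                pred = clf.predict(Xte_s)
            accs.append(accuracy_score(yte, pred))
            if len(np.unique(yte)) > 1 or not binary:
                avg = "binary" if binary else "macro"
                f1s.append(f1_score(yte, pred, average=avg, zero_division=0))
        reports.append(
            CvReport(
                model=model,
                stratum=stratum,
                fold_accuracy=accs,
                fold_f1=f1s,
                chosen_params=chosen,
            )
        )
    return reports


def svr_regression_eval(
    data: pd.DataFrame,
    scores: np.ndarray,
    feature_cols: list[str],
    split: LosoSplit | None = None,
    C: float = 1.0,
) -> tuple[float, float]:
    """RBF support-vector regression of the 0-4 score; (mean R^2, mean RMSE).

    R^2 is computed on the pooled held-out predictions per fold; folds
    with fewer than 2 test samples or zero test variance contribute RMSE
    only.
    """
    split = split or make_loso(data)
    data = data.reset_index(drop=True)
    scores = np.asarray(scores, float)
    r2s, rmses = [], []
    for train_subj, test_subj in split.folds:
        Xtr, ytr, Xte, yte = _fold_arrays(
            data, scores, feature_cols, train_subj, test_subj
        )
        if len(Xte) == 0:
            continue
        scaler = StandardScaler().fit(Xtr)
        reg = SVR(kernel="rbf", C=C)
        reg.fit(scaler.transform(Xtr), ytr)
        pred = reg.predict(scaler.transform(Xte))
        rmses.append(float(np.sqrt(mean_squared_error(yte, pred))))
        if len(yte) >= 2 and np.std(yte) > 0:
            r2s.append(float(r2_score(yte, pred)))
    return float(np.mean(r2s)), float(np.mean(rmses))
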