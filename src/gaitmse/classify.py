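"""Classifiers and cross-validated experiments.

The 1-NN classifier uses the weighted per-feature distance
d(q, x) = Σ_f w_f · |q_f − x_f| (all 72 features are continuous, so the
per-feature term is the absolute difference; unit weights by default). The
SVM is deliberately delegated to a standard maximum-margin solver
(sklearn's SVC, one-vs-one for multi-class). Evaluation is stratified
k-fold cross-validation with two grouping modes: ``window_level`` lets
overlapping windows of one subject span folds (the optimistic but common
setting for this pipeline) and ``subject_level`` keeps each subject's
windows inside a single fold. SMOTE and feature selection run inside each
training fold by default; ``global`` modes applying them once before the
split are provided for comparability with augment-then-validate protocols.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.svm import SVC

from gaitmse.features import MSEParams, extract_features
from gaitmse.io import GaitRecord
from gaitmse.preprocess import ArtifactRules, prepare_windows
from gaitmse.selection import SelectionResult, sbs, sfs
from gaitmse.smote import SmoteConfig, balance_classes

logger = logging.getLogger(__name__)


@dataclass
class SVMSettings:
    """Settings passed through to the delegated SVM solver."""

    kernel: str = "rbf"
    C: float = 1.0
    gamma: str | float = "scale"


@dataclass
class ExperimentConfig:
    """One cell of the experiment grid.

    ``task`` is a tuple of class labels (``None`` = all present classes).
    ``grouping`` selects window-level (default) or subject-level folds.
    SMOTE/selection modes are ``fold_internal`` (default, leakage-safe) or
    ``global``.
    """

    task: tuple[str, ...] | None = None
    tw_s: float = 10.0
    overlap_fraction: float = 0.5
    trim_s: float = 20.0
    max_s: float = 300.0
    normalization: str = "zscore"
    smote_enabled: bool = False
    smote: SmoteConfig = field(default_factory=SmoteConfig)
    smote_mode: str = "fold_internal"
    selection: str = "none"
    selection_mode: str = "fold_internal"
    selection_p: int | None = None
    selection_folds: int = 3
    classifier: str = "knn"
    knn_k: int = 1
    svm: SVMSettings = field(default_factory=SVMSettings)
    cv_folds: int = 10
    grouping: str = "window_level"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.classifier not in ("knn", "svm"):
            raise ValueError("classifier must be 'knn' or 'svm'")
        if self.grouping not in ("window_level", "subject_level"):
            raise ValueError("grouping must be 'window_level' or 'subject_level'")
        if self.selection not in ("none", "sfs", "sbs"):
            raise ValueError("selection must be 'none', 'sfs' or 'sbs'")


@dataclass
class CVResult:
    """Per-fold and pooled evaluation outputs of one experiment."""

    fold_accuracies: list[float]
    confusion: np.ndarray
    labels: list[str]
    selected_per_fold: list[list[str]]
    n_before_smote: dict[str, int]
    n_after_smote: dict[str, int]
    config: ExperimentConfig
    predictions: pd.DataFrame | None = None
    """Per-validation-row outcomes: columns fold, subject_id, label, pred."""

    @property
    def mean_accuracy(self) -> float:
        """Average of per-fold accuracies."""
        return float(np.mean(self.fold_accuracies))

    @property
    def pooled_accuracy(self) -> float:
        """Correct / total over all validation rows (confusion-matrix trace)."""
        return float(np.trace(self.confusion) / self.confusion.sum())

    def confusion_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.confusion, index=self.labels, columns=self.labels)


def knn_distance(
    q: Sequence[float], x: Sequence[float], weights: Sequence[float] | None = None
) -> float:
    """Weighted per-feature distance Σ_f w_f · |q_f − x_f|."""
    q = np.asarray(q, dtype=float)
    x = np.asarray(x, dtype=float)
    if q.shape != x.shape:
        raise ValueError(f"length mismatch: {q.shape} vs {x.shape}")
    w = np.ones_like(q) if weights is None else np.asarray(weights, dtype=float)
    return float(np.sum(w * np.abs(q - x)))


def _knn_predict(
    train_X: np.ndarray,
    train_y: np.ndarray,
    test_X: np.ndarray,
    k: int = 1,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Vectorized k-NN under the weighted absolute-difference distance.

    Distance ties are broken by training-row order (stable sort); vote ties
    by the lowest class index in sorted label order.
    """
    classes = np.array(sorted(set(train_y.tolist())))
    if weights is not None:
        train_X = train_X * weights
        test_X = test_X * weights
    dist = cdist(test_X, train_X, metric="cityblock")
    order = np.argsort(dist, axis=1, kind="stable")[:, :k]
    neighbor_labels = train_y[order]
    if k == 1:
        return neighbor_labels[:, 0]
    preds = np.empty(len(test_X), dtype=train_y.dtype)
    class_index = {c: i for i, c in enumerate(classes)}
    for row in range(len(test_X)):
        votes = np.zeros(len(classes), dtype=int)
        for lab in neighbor_labels[row]:
            votes[class_index[lab]] += 1
        winners = np.flatnonzero(votes == votes.max())
        if len(winners) > 1:
            logger.debug("k-NN vote tie resolved toward lowest class index")
        preds[row] = classes[winners[0]]
    return preds


def knn_classify(
    train: pd.DataFrame | np.ndarray,
    query: Sequence[float],
    k: int = 1,
    train_y: np.ndarray | None = None,
    weights: Sequence[float] | None = None,
) -> str:
    """Classify one query vector by majority vote of its k nearest training
    rows (k=1: the nearest neighbor's label)."""
    if isinstance(train, pd.DataFrame):
        cols = [c for c in train.columns if c.startswith("F")]
        X = train[cols].to_numpy(dtype=float)
        y = train["label"].to_numpy()
    else:
        X = np.asarray(train, dtype=float)
        y = np.asarray(train_y)
    if len(X) == 0:
        raise ValueError("empty training set")
    w = None if weights is None else np.asarray(weights, dtype=float)
    pred = _knn_predict(X, y, np.asarray(query, dtype=float)[None, :], k=k, weights=w)
    return pred[0]


def svm_train_predict(
    train_X: np.ndarray,
    train_y: np.ndarray,
    test_X: np.ndarray,
    settings: SVMSettings | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Train the delegated SVM (one-vs-one multi-class) and predict."""
    if settings is None:
        settings = SVMSettings()
    if len(set(train_y.tolist())) < 2:
        raise ValueError("SVM training needs at least two classes")
    clf = SVC(
        kernel=settings.kernel,
        C=settings.C,
        gamma=settings.gamma,
        decision_function_shape="ovo",
        random_state=seed,
    )
    clf.fit(train_X, train_y)
    return clf.predict(test_X)


def make_cv_criterion(
    classifier: str = "knn",
    folds: int = 3,
    seed: int = 0,
    knn_k: int = 1,
    svm: SVMSettings | None = None,
):
    """Wrapper criterion for feature selection: mean stratified CV accuracy
    of the configured classifier, evaluated on training data only."""

    def criterion(X: np.ndarray, y: np.ndarray) -> float:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        accs = []
        for tr, te in splitter.split(X, y):
            if classifier == "knn":
                pred = _knn_predict(X[tr], y[tr], X[te], k=knn_k)
            else:
                pred = svm_train_predict(X[tr], y[tr], X[te], svm, seed=seed)
            accs.append(float(np.mean(pred == y[te])))
        return float(np.mean(accs))

    criterion.description = f"mean {folds}-fold stratified CV accuracy of {classifier}"
    return criterion


def _feature_cols(features: pd.DataFrame) -> list[str]:
    return [c for c in features.columns if c.startswith("F")]


def _standardize(train: np.ndarray, test: np.ndarray):
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (train - mu) / sd, (test - mu) / sd


def _impute(train: np.ndarray, test: np.ndarray):
    """Fill NaN with the training-fold column median (logged)."""
    n_bad = int(np.isnan(train).sum() + np.isnan(test).sum())
    if n_bad == 0:
        return train, test
    med = np.nanmedian(train, axis=0)
    med = np.where(np.isnan(med), 0.0, med)
    idx = np.where(np.isnan(train))
    train = train.copy()
    train[idx] = med[idx[1]]
    idx = np.where(np.isnan(test))
    test = test.copy()
    test[idx] = med[idx[1]]
    logger.info("imputed %d undefined feature value(s) with training-fold medians", n_bad)
    return train, test


def kfold_cv(features: pd.DataFrame, config: ExperimentConfig) -> CVResult:
    """Stratified k-fold cross-validation of one experiment configuration.

    Imputation, standardization, SMOTE and feature selection are fit on each
    training fold and applied to its validation fold, unless the respective
    ``global`` mode is configured.
    """
    df = features
    if config.task is not None:
        df = df[df["label"].isin(config.task)].reset_index(drop=True)
        missing = set(config.task) - set(df["label"])
        if missing:
            raise ValueError(f"task classes absent from data: {sorted(missing)}")
    labels_sorted = sorted(df["label"].unique())
    if len(labels_sorted) < 2:
        raise ValueError("need at least two classes")
    n_before = df["label"].value_counts().to_dict()
    n_after = dict(n_before)

    if config.smote_enabled and config.smote_mode == "global":
        if config.grouping == "subject_level":
            raise ValueError("global SMOTE is incompatible with subject-level grouping")
        cols = _feature_cols(df)
        X_all = df[cols].to_numpy(dtype=float)
        if np.isnan(X_all).any():
            med = np.nanmedian(X_all, axis=0)
            idx = np.where(np.isnan(X_all))
            X_all[idx] = med[idx[1]]
            df = df.copy()
            df[cols] = X_all
        df = balance_classes(df, config.smote)
        n_after = df["label"].value_counts().to_dict()

    cols = _feature_cols(df)
    X = df[cols].to_numpy(dtype=float)
    y = df["label"].to_numpy()
    groups = df["subject_id"].to_numpy()
    counts = df["label"].value_counts()
    if counts.min() < config.cv_folds:
        raise ValueError(
            f"smallest class has {counts.min()} rows < cv_folds={config.cv_folds}"
        )

    global_selection: list[str] | None = None
    if config.selection != "none" and config.selection_mode == "global":
        global_selection = _run_selection(X, y, cols, config)

    if config.grouping == "subject_level":
        splitter = StratifiedGroupKFold(
            n_splits=config.cv_folds, shuffle=True, random_state=config.seed
        )
        splits = splitter.split(X, y, groups=groups)
    else:
        splitter = StratifiedKFold(
            n_splits=config.cv_folds, shuffle=True, random_state=config.seed
        )
        splits = splitter.split(X, y)

    label_index = {lab: i for i, lab in enumerate(labels_sorted)}
    confusion = np.zeros((len(labels_sorted), len(labels_sorted)), dtype=int)
    fold_accuracies: list[float] = []
    selected_per_fold: list[list[str]] = []
    prediction_rows: list[dict] = []

    for fold, (tr, te) in enumerate(splits):
        X_tr, X_te = _impute(X[tr], X[te])
        X_tr, X_te = _standardize(X_tr, X_te)
        y_tr, y_te = y[tr], y[te]

        if config.smote_enabled and config.smote_mode == "fold_internal":
            frame = pd.DataFrame(X_tr, columns=cols)
            frame["label"] = y_tr
            frame["subject_id"] = groups[tr]
            frame["window_id"] = -1
            fold_cfg = SmoteConfig(
                k_neighbors=config.smote.k_neighbors,
                target=config.smote.target,
                seed=config.smote.seed + fold,
            )
            balanced = balance_classes(frame, fold_cfg)
            X_tr = balanced[cols].to_numpy(dtype=float)
            y_tr = balanced["label"].to_numpy()
            if fold == 0:
                n_after = balanced["label"].value_counts().to_dict()

        if global_selection is not None:
            keep = [cols.index(c) for c in global_selection]
            selected_per_fold.append(list(global_selection))
        elif config.selection != "none":
            names = _run_selection(X_tr, y_tr, cols, config)
            keep = [cols.index(c) for c in names]
            selected_per_fold.append(names)
        else:
            keep = list(range(len(cols)))
            selected_per_fold.append(list(cols))

        X_tr_k, X_te_k = X_tr[:, keep], X_te[:, keep]
        if config.classifier == "knn":
            pred = _knn_predict(X_tr_k, y_tr, X_te_k, k=config.knn_k)
        else:
            pred = svm_train_predict(X_tr_k, y_tr, X_te_k, config.svm, seed=config.seed)
        fold_accuracies.append(float(np.mean(pred == y_te)))
        for row, truth, guess in zip(te, y_te, pred):
            confusion[label_index[truth], label_index[guess]] += 1
            prediction_rows.append(
                {"fold": fold, "subject_id": groups[row], "label": truth, "pred": guess}
            )

    return CVResult(
        fold_accuracies=fold_accuracies,
        confusion=confusion,
        labels=labels_sorted,
        selected_per_fold=selected_per_fold,
        n_before_smote={k: int(v) for k, v in n_before.items()},
        n_after_smote={k: int(v) for k, v in n_after.items()},
        config=config,
        predictions=pd.DataFrame(prediction_rows),
    )


def _run_selection(X: np.ndarray, y: np.ndarray, cols: list[str], config: ExperimentConfig):
    criterion = make_cv_criterion(
        classifier=config.classifier,
        folds=config.selection_folds,
        seed=config.seed,
        knn_k=config.knn_k,
        svm=config.svm,
    )
    search = sfs if config.selection == "sfs" else sbs
    result: SelectionResult = search(X, criterion, p=config.selection_p, y=y)
    # map positional names back onto the real column names
    return [cols[int(name[1:]) - 1] for name in result.selected]


def cohort_features(
    records: Iterable[GaitRecord],
    tw_s: float,
    overlap_fraction: float = 0.5,
    trim_s: float = 20.0,
    max_s: float = 300.0,
    normalization: str = "zscore",
    params: MSEParams | None = None,
    rules: ArtifactRules | None = None,
) -> pd.DataFrame:
    """Preprocess and featurize every record of a cohort into one matrix."""
    frames = []
    for record in records:
        wset = prepare_windows(
            record,
            tw_s=tw_s,
            overlap_fraction=overlap_fraction,
            trim_s=trim_s,
            max_s=max_s,
            normalization=normalization,
            rules=rules,
        )
        frames.append(extract_features(wset, params))
    return pd.concat(frames, ignore_index=True)


def run_experiment(
    records: Iterable[GaitRecord] | None,
    config: ExperimentConfig,
    features: pd.DataFrame | None = None,
    params: MSEParams | None = None,
) -> CVResult:
    """Execute one experiment cell end to end: preprocessing, feature
    extraction, optional SMOTE/selection, classification, k-fold CV.

    Precomputed ``features`` (from :func:`cohort_features`) may be passed to
    avoid re-extracting when sweeping variants at one window length.
    """
    if features is None:
        if records is None:
            raise ValueError("provide records or a precomputed feature matrix")
        try:
            features = cohort_features(
                records,
                tw_s=config.tw_s,
                overlap_fraction=config.overlap_fraction,
                trim_s=config.trim_s,
                max_s=config.max_s,
                normalization=config.normalization,
                params=params,
            )
        except Exception as exc:
            raise RuntimeError(f"feature-extraction stage failed: {exc}") from exc
    try:
        return kfold_cv(features, config)
    except Exception as exc:
        raise RuntimeError(f"cross-validation stage failed: {exc}") from exc


def run_grid(
    records: list[GaitRecord],
    tasks: list[tuple[str, ...] | None],
    tw_list: Sequence[float] = (10.0, 20.0, 30.0, 60.0),
    variants: Sequence[dict] | None = None,
    base_config: ExperimentConfig | None = None,
    params: MSEParams | None = None,
) -> pd.DataFrame:
    """Sweep tasks × window lengths × pipeline variants.

    ``variants`` are dicts of ExperimentConfig overrides, e.g.
    ``{"classifier": "svm", "smote_enabled": True, "selection": "sfs"}``.
    Features are extracted once per window length and shared across cells.
    Returns one row per cell with mean/pooled accuracy and sample counts.
    """
    if base_config is None:
        base_config = ExperimentConfig()
    if variants is None:
        variants = [{}]
    rows = []
    for tw in tw_list:
        feats = cohort_features(
            records,
            tw_s=tw,
            overlap_fraction=base_config.overlap_fraction,
            trim_s=base_config.trim_s,
            max_s=base_config.max_s,
            normalization=base_config.normalization,
            params=params,
        )
        for task in tasks:
            for variant in variants:
                cfg_kwargs = {**asdict(base_config), **variant, "task": task, "tw_s": tw}
                cfg_kwargs["smote"] = SmoteConfig(**cfg_kwargs["smote"]) if isinstance(
                    cfg_kwargs["smote"], dict
                ) else cfg_kwargs["smote"]
                cfg_kwargs["svm"] = SVMSettings(**cfg_kwargs["svm"]) if isinstance(
                    cfg_kwargs["svm"], dict
                ) else cfg_kwargs["svm"]
                cfg = ExperimentConfig(**cfg_kwargs)
                result = run_experiment(None, cfg, features=feats)
                rows.append(
                    {
                        "task": "all" if task is None else ":".join(task),
                        "tw_s": tw,
                        "classifier": cfg.classifier,
                        "smote": cfg.smote_enabled,
                        "selection": cfg.selection,
                        "grouping": cfg.grouping,
                        "mean_accuracy": result.mean_accuracy,
                        "pooled_accuracy": result.pooled_accuracy,
                        "folds": cfg.cv_folds,
                        "n_rows": int(result.confusion.sum()),
                    }
                )
    return pd.DataFrame(rows)
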