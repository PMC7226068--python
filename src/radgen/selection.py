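"""Class balancing and bootstrap-LASSO stability selection of the signature.

The discovery cohort is heavily imbalanced (46 metastasis-free vs 12
metastatic), so the minority class is first oversampled with ADASYN.  The
prognostic signature is then the set of features whose L1-logistic
coefficient is nonzero in at least ``frequency_threshold`` (default 95%) of
bootstrap replicates, where each replicate fits a logistic LASSO with
cross-validated penalty on a stratified 80% split and holds out 20%.
Three classifiers (regularized logistic, linear SVM, 50-tree random forest)
quantify the prognostic power of the selected signature on the same
resampling scheme.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import LinearSVC

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelectionConfig:
    """Stability-selection settings (defaults follow the emulated protocol)."""

    n_bootstrap: int = 10_000
    holdout_ratio: float = 0.2
    cv_folds: int = 5
    frequency_threshold: float = 0.95
    adasyn_k: int = 5
    adasyn_mode: str = "global"  # "global" (balance once) or "per_bootstrap"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.holdout_ratio < 1.0:
            raise ValueError("holdout_ratio must lie strictly between 0 and 1")
        if not 0.0 < self.frequency_threshold <= 1.0:
            raise ValueError("frequency_threshold must lie in (0, 1]")
        if self.adasyn_mode not in ("global", "per_bootstrap"):
            raise ValueError("adasyn_mode must be 'global' or 'per_bootstrap'")


@dataclass
class SelectionResult:
    """Per-feature selection frequencies and the stable signature."""

    frequencies: pd.Series
    signature: list[str]
    n_bootstrap: int
    threshold: float
    selected_sets: list[list[str]] | None = None


def adasyn_balance(
    features: pd.DataFrame, labels: np.ndarray, k: int = 5, seed: int = 0
) -> tuple[pd.DataFrame, np.ndarray]:
    """Adaptive synthetic oversampling of the minority class (He et al.).

    Minority points are weighted by the fraction of majority points among
    their ``k`` nearest neighbors in the full data; synthetic points are
    convex combinations of a minority point and one of its ``k`` nearest
    *minority* neighbors.  Original rows are returned unchanged as a prefix
    of the output; the minority count is raised to (approximately) the
    majority count.
    """
    labels = np.asarray(labels).astype(int)
    X = features.to_numpy(dtype=float)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) != 2:
        raise ValueError("adasyn_balance needs exactly two classes present")
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    if n_min == n_maj:
        return features.copy(), labels.copy()
    if n_min < k + 1:
        raise ValueError(
            f"minority class has {n_min} samples; needs at least k+1={k + 1} "
            "(lower k to proceed)"
        )

    rng = np.random.default_rng(seed)
    X_min = X[labels == minority]

    # neighbor search in the full data for the density ratios
    nn_all = NearestNeighbors(n_neighbors=k + 1).fit(X)
    _, idx = nn_all.kneighbors(X_min)
    neigh_labels = labels[idx[:, 1:]]  # drop self
    ratio = (neigh_labels != minority).mean(axis=1)
    if ratio.sum() == 0:
        ratio = np.ones_like(ratio)  # uniform when no majority neighbors anywhere
    weights = ratio / ratio.sum()

    n_new = int(n_maj - n_min)
    per_point = np.floor(weights * n_new).astype(int)
    # distribute the rounding remainder to the highest-weight points
    remainder = n_new - per_point.sum()
    if remainder > 0:
        order = np.argsort(-weights)
        per_point[order[:remainder]] += 1

    nn_min = NearestNeighbors(n_neighbors=min(k + 1, len(X_min))).fit(X_min)
    _, min_idx = nn_min.kneighbors(X_min)

    synthetic = []
    for i, g in enumerate(per_point):
        neighbors = min_idx[i, 1:]
        for _ in range(int(g)):
            j = int(rng.choice(neighbors)) if len(neighbors) else i
            lam = rng.uniform()
            synthetic.append(X_min[i] + lam * (X_min[j] - X_min[i]))

    if not synthetic:
        return features.copy(), labels.copy()
    syn = np.asarray(synthetic)
    syn_index = [f"SYN{i:04d}" for i in range(len(syn))]
    out = pd.concat(
        [features, pd.DataFrame(syn, columns=features.columns, index=syn_index)]
    )
    out.index.name = features.index.name
    out_labels = np.concatenate([labels, np.full(len(syn), minority, dtype=int)])
    return out, out_labels


def _stratified_split(labels: np.ndarray, holdout_ratio: float, rng: np.random.Generator):
    """Indices of a class-stratified train/holdout split (without replacement)."""
    train, test = [], []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        idx = rng.permutation(idx)
        n_test = max(1, int(round(len(idx) * holdout_ratio)))
        test.append(idx[:n_test])
        train.append(idx[n_test:])
    return np.concatenate(train), np.concatenate(test)


def _zscore_train_apply(train: np.ndarray, *others: np.ndarray):
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return tuple((a - mu) / sd for a in (train, *others))


def bootstrap_lasso_selection(
    features: pd.DataFrame,
    labels: np.ndarray,
    config: SelectionConfig,
    keep_sets: bool = False,
) -> SelectionResult:
    """Selection frequency of every feature over bootstrapped LASSO fits.

    Per replicate: draw a stratified ``1 - holdout_ratio`` training split,
    z-score its columns, fit an L1-penalized logistic regression with the
    penalty chosen by ``cv_folds``-fold cross-validation on the split, and
    record the features with nonzero coefficients.  The signature is every
    feature selected in at least ``frequency_threshold`` of replicates.
    """
    labels = np.asarray(labels).astype(int)
    if min(np.bincount(labels)) < 2:
        raise ValueError("need at least 2 patients per class")

    keep = features.std(axis=0) > 0
    if not keep.all():
        logger.warning("dropping %d constant feature column(s)", int((~keep).sum()))
        features = features.loc[:, keep]
    names = list(features.columns)
    X_all = features.to_numpy(dtype=float)

    rng = np.random.default_rng(config.seed)
    counts = np.zeros(len(names))
    sets: list[list[str]] = []
    for _ in range(config.n_bootstrap):
        tr, _te = _stratified_split(labels, config.holdout_ratio, rng)
        Xtr_raw, ytr = X_all[tr], labels[tr]
        if config.adasyn_mode == "per_bootstrap":
            # balance inside the replicate so synthetic neighbors never leak
            # across the train/holdout boundary
            k_rep = min(config.adasyn_k, int(np.bincount(ytr).min()) - 1)
            if k_rep >= 1:
                bal, ytr = adasyn_balance(
                    pd.DataFrame(Xtr_raw, columns=names),
                    ytr,
                    k=k_rep,
                    seed=int(rng.integers(2**31 - 1)),
                )
                Xtr_raw = bal.to_numpy(dtype=float)
        Xtr, = _zscore_train_apply(Xtr_raw)
        # L1 path from the data-driven lambda_max down two decades (the
        # glmnet convention for n < p), expressed as liblinear C values
        n_tr = len(ytr)
        lam_max = np.abs(Xtr.T @ (ytr - ytr.mean())).max() / n_tr
        lams = np.geomspace(lam_max, 0.01 * lam_max, 10)
        model = LogisticRegressionCV(
            Cs=1.0 / (n_tr * lams),
            cv=StratifiedKFold(
                config.cv_folds, shuffle=True, random_state=int(rng.integers(2**31 - 1))
            ),
            penalty="l1",
            solver="liblinear",
            scoring="neg_log_loss",
            max_iter=200,
            random_state=0,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            model.fit(Xtr, ytr)
        nonzero = np.abs(model.coef_.ravel()) > 1e-10
        counts += nonzero
        if keep_sets:
            sets.append([n for n, nz in zip(names, nonzero) if nz])

    freq = pd.Series(counts / config.n_bootstrap, index=names, name="selection_frequency")
    signature = [n for n in names if freq[n] >= config.frequency_threshold]
    return SelectionResult(
        frequencies=freq,
        signature=signature,
        n_bootstrap=config.n_bootstrap,
        threshold=config.frequency_threshold,
        selected_sets=sets if keep_sets else None,
    )


def _metrics(y_true: np.ndarray, y_pred: np.ndarray, score: np.ndarray) -> dict[str, float]:
    tp = int(np.sum((y_pred == 1) & (y_true == 1)))
    tn = int(np.sum((y_pred == 0) & (y_true == 0)))
    fp = int(np.sum((y_pred == 1) & (y_true == 0)))
    fn = int(np.sum((y_pred == 0) & (y_true == 1)))
    return {
        "auc": float(roc_auc_score(y_true, score)),
        "sensitivity": tp / (tp + fn) if tp + fn else 0.0,
        "specificity": tn / (tn + fp) if tn + fp else 0.0,
        "accuracy": (tp + tn) / len(y_true),
    }


def _classifiers(seed: int):
    return {
        "logistic": LogisticRegression(max_iter=1000),
        "svm_linear": LinearSVC(),
        "random_forest": RandomForestClassifier(n_estimators=50, random_state=seed),
    }


def evaluate_classifiers(
    features: pd.DataFrame, labels: np.ndarray, config: SelectionConfig
) -> pd.DataFrame:
    """Bootstrap-mean train/test metrics of the three signature classifiers.

    Returns a tidy frame indexed by (classifier, split) with columns
    auc / sensitivity / specificity / accuracy, each averaged over
    ``config.n_bootstrap`` stratified resampling replicates.
    """
    labels = np.asarray(labels).astype(int)
    if features.shape[1] == 0:
        raise ValueError("empty signature")
    X_all = features.to_numpy(dtype=float)
    rng = np.random.default_rng(config.seed)

    acc: dict[tuple[str, str], list[dict[str, float]]] = {}
    done = 0
    while done < config.n_bootstrap:
        tr, te = _stratified_split(labels, config.holdout_ratio, rng)
        if len(np.unique(labels[te])) < 2 or len(np.unique(labels[tr])) < 2:
            logger.info("single-class split; replicate resampled")
            continue
        Xtr, Xte = _zscore_train_apply(X_all[tr], X_all[te])
        ytr, yte = labels[tr], labels[te]
        for name, clf in _classifiers(int(rng.integers(2**31 - 1))).items():
            clf.fit(Xtr, ytr)
            if hasattr(clf, "predict_proba"):
                str_, ste = clf.predict_proba(Xtr)[:, 1], clf.predict_proba(Xte)[:, 1]
            else:
                str_, ste = clf.decision_function(Xtr), clf.decision_function(Xte)
            for split, Xs, ys, sc in (("train", Xtr, ytr, str_), ("test", Xte, yte, ste)):
                acc.setdefault((name, split), []).append(
                    _metrics(ys, clf.predict(Xs), sc)
                )
        done += 1

    rows = {
        key: pd.DataFrame(vals).mean().to_dict() for key, vals in acc.items()
    }
    report = pd.DataFrame.from_dict(rows, orient="index")
    report.index = pd.MultiIndex.from_tuples(report.index, names=["classifier", "split"])
    return report.sort_index()


def logistic_importance(
    features: pd.DataFrame, labels: np.ndarray
) -> pd.DataFrame:
    """Unpenalized multivariate logistic weights and odds ratios per feature.

    Fit by statsmodels-free Newton iterations via sklearn with a vanishingly
    small penalty; under perfect separation the weights are capped by that
    penalty and a warning is logged.
    """
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) != 2:
        raise ValueError("both classes must be present")
    if features.shape[1] == 0:
        raise ValueError("empty signature")
    X = features.to_numpy(dtype=float)
    clf = LogisticRegression(C=1e8, max_iter=5000).fit(X, labels)
    weights = clf.coef_.ravel()
    if np.abs(weights).max() > 50:
        logger.warning("near-perfect separation; logistic weights capped by the ridge")
    out = pd.DataFrame(
        {"weight": weights, "odds_ratio": np.exp(weights)}, index=features.columns
    )
    out.index.name = "feature"
    return out
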