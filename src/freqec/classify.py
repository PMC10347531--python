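"""Linear-SVM discrimination of groups from band-specific EC features.

Features are the vectorised off-diagonal entries of each subject's directed
connectivity matrix, one table per frequency band (optionally concatenated
across bands). Classification uses a linear soft-margin SVM inside repeated
stratified k-fold cross-validation with a two-step nested feature selection
performed on the training folds only:

1. MRMR (max-relevance min-redundancy on mutual information over 3
   equal-frequency bins) prunes weakly discriminative features;
2. SVM-RFE (recursive elimination of the smallest-|weight| feature, 10% chunks
   while more than 50 remain) refines to a final subset, with the subset size
   and SVM C chosen by inner cross-validation on the training data.

Per test fold we record accuracy, sensitivity (patients positive),
specificity and AUC; the reported metrics are means over folds x repeats,
with pooled-prediction accuracy reported alongside. The per-feature selection
frequency over all folds x repeats ranks the most recognizable features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

__all__ = [
    "FeatureTable",
    "CVConfig",
    "CVResult",
    "ec_feature_table",
    "combine_band_features",
    "mrmr_select",
    "svmrfe_select",
    "nested_cv",
    "roc_curve",
]


@dataclass
class FeatureTable:
    """Subjects x features matrix with (band, source, target) feature ids."""

    X: np.ndarray
    feature_ids: list[tuple[str, int, int]]
    labels: np.ndarray  # 1 = patient, 0 = control
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if self.X.shape[1] != len(self.feature_ids):
            raise ValueError("feature_ids must match X columns")
        if self.X.shape[0] != len(self.labels):
            raise ValueError("labels must match X rows")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("feature matrix contains non-finite values")
        if not self.subject_ids:
            self.subject_ids = [f"sub-{i:03d}" for i in range(self.X.shape[0])]


def ec_feature_table(
    ec_array: np.ndarray,
    band: str,
    labels: np.ndarray,
    subject_ids: list[str] | None = None,
) -> FeatureTable:
    """Vectorise the off-diagonal EC entries of one band into a feature table."""
    ec_array = np.nan_to_num(np.asarray(ec_array, dtype=float))
    n = ec_array.shape[1]
    off = ~np.eye(n, dtype=bool)
    src, tgt = np.where(off)
    X = ec_array[:, src, tgt]
    ids = [(band, int(s), int(t)) for s, t in zip(src, tgt)]
    return FeatureTable(X=X, feature_ids=ids, labels=labels, subject_ids=subject_ids or [])


def combine_band_features(tables: list[FeatureTable]) -> FeatureTable:
    """Column-wise concatenation of per-band tables (subjects must match)."""
    if not tables:
        raise ValueError("no tables to combine")
    base = tables[0]
    for t in tables[1:]:
        if t.subject_ids != base.subject_ids or not np.array_equal(t.labels, base.labels):
            raise ValueError("subject ordering/labels differ across band tables")
    X = np.hstack([t.X for t in tables])
    ids = [fid for t in tables for fid in t.feature_ids]
    if len(set(ids)) != len(ids):
        raise ValueError("combined feature ids are not unique")
    return FeatureTable(X=X, feature_ids=ids, labels=base.labels, subject_ids=base.subject_ids)


# ---------------------------------------------------------------------------
# feature selection
# ---------------------------------------------------------------------------


def _discretize(X: np.ndarray, n_bins: int = 3) -> np.ndarray:
    """Equal-frequency binning per feature into integer codes."""
    n, f = X.shape
    codes = np.zeros((n, f), dtype=np.int64)
    qs = np.quantile(X, np.linspace(0, 1, n_bins + 1)[1:-1], axis=0)
    for j in range(f):
        codes[:, j] = np.searchsorted(np.unique(qs[:, j]), X[:, j], side="right")
    return codes


def _mi_with(codes_a: np.ndarray, code_b: np.ndarray, ka: int, kb: int) -> np.ndarray:
    """Mutual information (nats) of each column of codes_a with code_b."""
    n, f = codes_a.shape
    joint = codes_a * kb + code_b[:, None]
    offsets = np.arange(f) * (ka * kb)
    counts = np.bincount((joint + offsets[None, :]).ravel(), minlength=f * ka * kb)
    counts = counts.reshape(f, ka, kb).astype(float) / n
    pa = counts.sum(axis=2, keepdims=True)
    pb = counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = counts * (np.log(counts) - np.log(pa) - np.log(pb))
    return np.nansum(term, axis=(1, 2))


def mrmr_select(X: np.ndarray, y: np.ndarray, k: int, n_bins: int = 3) -> list[int]:
    """Greedy max-relevance min-redundancy ranking of ``k`` features.

    Relevance and redundancy are mutual information on features discretized
    into ``n_bins`` equal-frequency bins; the first pick maximises MI with the
    label, each next pick maximises MI(label) minus the mean MI with already
    selected features. Deterministic; ties break toward the lower index.
    Constant features carry zero MI but never block selection.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(np.int64)
    n, f = X.shape
    if k > f:
        raise ValueError("k exceeds the feature count")
    if k == 0:
        return []
    codes = _discretize(X, n_bins)
    ka = n_bins + 1  # searchsorted can emit n_bins distinct codes; +1 headroom
    kb = int(y.max()) + 1
    relevance = _mi_with(codes, y, ka, kb)
    selected: list[int] = []
    redundancy = np.zeros(f)
    remaining = np.ones(f, dtype=bool)
    for step in range(k):
        if step == 0:
            score = relevance.copy()
        else:
            score = relevance - redundancy / step
        score[~remaining] = -np.inf
        pick = int(np.argmax(score))  # argmax takes the first (lowest) index on ties
        selected.append(pick)
        remaining[pick] = False
        if step < k - 1:
            redundancy += _mi_with(codes, codes[:, pick], ka, ka)
    return selected


def _standardizer(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return mu, sd


def _rfe_order(X: np.ndarray, y: np.ndarray, c: float, min_k: int = 1) -> list[int]:
    """Elimination order (first-removed first) of SVM-RFE down to ``min_k``.

    Removes the feature with the smallest |weight| each round (a 10% chunk
    while more than 50 remain); among tied weights the highest index is
    removed first, so the lowest index survives.
    """
    active = list(range(X.shape[1]))
    removed: list[int] = []
    while len(active) > min_k:
        clf = SVC(kernel="linear", C=c)
        clf.fit(X[:, active], y)
        w = np.abs(np.asarray(clf.coef_).ravel())
        n_drop = max(1, int(0.1 * len(active))) if len(active) > 50 else 1
        n_drop = min(n_drop, len(active) - min_k)
        # sort by (|w| ascending, index descending) so ties drop high indices first
        order = sorted(range(len(active)), key=lambda i: (w[i], -active[i]))
        drop = sorted((active[i] for i in order[:n_drop]), reverse=True)
        for d in drop:
            removed.append(d)
            active.remove(d)
    return removed


def svmrfe_select(X: np.ndarray, y: np.ndarray, target_k: int, c: float = 1.0) -> list[int]:
    """Indices of the ``target_k`` features surviving SVM-RFE.

    The feature matrix is standardized on the provided (training) data before
    fitting. Rejects single-class input.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("SVM-RFE requires both classes")
    if target_k > X.shape[1]:
        raise ValueError("target_k exceeds the feature count")
    if target_k == X.shape[1]:
        return list(range(X.shape[1]))
    mu, sd = _standardizer(X)
    Xs = (X - mu) / sd
    removed = _rfe_order(Xs, y, c, min_k=target_k)
    keep = [i for i in range(X.shape[1]) if i not in set(removed)]
    return keep


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------


def roc_curve(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC points (fpr, tpr) over unique score thresholds and trapezoidal AUC.

    The trapezoidal integral with tied scores grouped equals the normalised
    Mann-Whitney pair count with ties counted half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC undefined with a single class")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    # group ties: keep the last point of each run of equal scores
    distinct = np.r_[np.diff(s) != 0, True]
    tp = np.cumsum(y)[distinct]
    fp = np.cumsum(1 - y)[distinct]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


# ---------------------------------------------------------------------------
# nested cross-validation
# ---------------------------------------------------------------------------


@dataclass
class CVConfig:
    """Cross-validation and nested feature-selection settings.

    Defaults follow the repeated 10-fold scheme (10 repeats, mean of the 100
    fold results). MRMR keeps the top ``mrmr_frac`` of features (at least
    ``mrmr_floor``); the final subset size and SVM C are chosen by
    ``inner_folds``-fold CV on the training data over ``k_grid`` x ``c_grid``.
    """

    folds: int = 10
    repeats: int = 10
    mrmr_frac: float = 0.3
    mrmr_floor: int = 20
    k_grid: tuple = (10, 20, 40, "all")
    c_grid: tuple = (0.01, 0.1, 1.0, 10.0, 100.0)
    inner_folds: int = 5


@dataclass
class CVResult:
    """Aggregated nested-CV performance and bookkeeping for reproducibility."""

    accuracy: float  # percent, mean over folds x repeats
    sensitivity: float  # percent
    specificity: float  # percent
    auc: float
    pooled_accuracy: float  # percent, pooled predictions
    roc_points: tuple[np.ndarray, np.ndarray]
    selection_frequency: pd.DataFrame
    fold_assignments: list[np.ndarray]
    fold_details: list[dict]

    def metrics(self) -> dict:
        return {
            "accuracy_pct": self.accuracy,
            "sensitivity_pct": self.sensitivity,
            "specificity_pct": self.specificity,
            "auc": self.auc,
            "pooled_accuracy_pct": self.pooled_accuracy,
        }

    def top_features(self, k: int = 10) -> pd.DataFrame:
        return self.selection_frequency.head(k).reset_index(drop=True)


def _fit_fold(
    X_tr: np.ndarray, y_tr: np.ndarray, config: CVConfig, rng_seed: int
) -> tuple[list[int], float, np.ndarray, np.ndarray, SVC]:
    """Training-fold pipeline: standardize, MRMR, RFE path + inner CV choice."""
    mu, sd = _standardizer(X_tr)
    Xs = (X_tr - mu) / sd
    f = Xs.shape[1]
    m = min(f, max(config.mrmr_floor, int(np.ceil(config.mrmr_frac * f))))
    ranked = mrmr_select(X_tr, y_tr, m)
    k_options = sorted(
        {m if k == "all" else int(k) for k in config.k_grid if k == "all" or int(k) <= m}
    )
    if not k_options:
        k_options = [m]
    best = (-np.inf, None, None)
    min_k = min(k_options)
    removed_local = _rfe_order(Xs[:, ranked], y_tr, c=1.0, min_k=min_k)
    surviving = {len(ranked): list(ranked)}
    active = list(ranked)
    for d in removed_local:
        orig = ranked[d]
        active = [i for i in active if i != orig]
        surviving[len(active)] = list(active)
    inner = StratifiedKFold(n_splits=config.inner_folds, shuffle=True, random_state=rng_seed)
    n_tr = len(y_tr)
    for k in k_options:
        feats = surviving[k]
        for c in config.c_grid:
            correct = 0
            for itr, ival in inner.split(Xs, y_tr):
                mu_i, sd_i = _standardizer(X_tr[itr][:, feats])
                Xi = (X_tr[itr][:, feats] - mu_i) / sd_i
                Xv = (X_tr[ival][:, feats] - mu_i) / sd_i
                clf = SVC(kernel="linear", C=c)
                clf.fit(Xi, y_tr[itr])
                correct += int((clf.predict(Xv) == y_tr[ival]).sum())
            acc = correct / n_tr
            if acc > best[0] + 1e-12:
                best = (acc, k, c)
    _, k_best, c_best = best
    feats = surviving[k_best]
    clf = SVC(kernel="linear", C=c_best)
    clf.fit(Xs[:, feats], y_tr)
    return feats, c_best, mu, sd, clf


def nested_cv(table: FeatureTable, config: CVConfig | None = None, seed: int = 0) -> CVResult:
    """Repeated stratified k-fold CV with nested MRMR -> SVM-RFE selection.

    All feature selection, standardization and hyperparameter tuning are fit
    on the training folds only; test folds contribute held-out predictions.
    Deterministic given ``seed``.
    """
    config = config or CVConfig()
    X, y = table.X, table.labels.astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    n, f = X.shape
    sel_counts = np.zeros(f)
    fold_metrics = []
    fold_assignments: list[np.ndarray] = []
    fold_details: list[dict] = []
    pooled_scores = np.empty(0)
    pooled_true = np.empty(0, dtype=int)
    pooled_pred = np.empty(0, dtype=int)
    n_folds_total = 0
    for rep in range(config.repeats):
        rep_seed = int(np.random.SeedSequence([seed, rep]).generate_state(1)[0] % (2**31))
        skf = StratifiedKFold(n_splits=config.folds, shuffle=True, random_state=rep_seed)
        for fold, (tr, te) in enumerate(skf.split(X, y)):
            fold_assignments.append(te)
            inner_seed = int(
                np.random.SeedSequence([seed, rep, fold, 1]).generate_state(1)[0] % (2**31)
            )
            feats, c_best, mu, sd, clf = _fit_fold(X[tr], y[tr], config, rng_seed=inner_seed)
            Xt = (X[te] - mu) / sd
            scores = clf.decision_function(Xt[:, feats])
            pred = (scores > 0).astype(int)
            yt = y[te]
            tp = int(((pred == 1) & (yt == 1)).sum())
            tn = int(((pred == 0) & (yt == 0)).sum())
            fp_ = int(((pred == 1) & (yt == 0)).sum())
            fn = int(((pred == 0) & (yt == 1)).sum())
            acc = (tp + tn) / len(yt)
            sens = tp / (tp + fn) if tp + fn else np.nan
            spec = tn / (tn + fp_) if tn + fp_ else np.nan
            try:
                _, _, fold_auc = roc_curve(scores, yt)
            except ValueError:
                fold_auc = np.nan
            fold_metrics.append((acc, sens, spec, fold_auc))
            sel_counts[feats] += 1
            n_folds_total += 1
            pooled_scores = np.r_[pooled_scores, scores]
            pooled_true = np.r_[pooled_true, yt]
            pooled_pred = np.r_[pooled_pred, pred]
            fold_details.append(
                {
                    "repeat": rep,
                    "fold": fold,
                    "selected": tuple(feats),
                    "c": c_best,
                    "scaler_mean": mu,
                    "scaler_sd": sd,
                }
            )
    fm = np.asarray(fold_metrics, dtype=float)
    fpr, tpr, _ = roc_curve(pooled_scores, pooled_true)
    freq = pd.DataFrame(
        {
            "feature": [str(fid) for fid in table.feature_ids],
            "band": [fid[0] for fid in table.feature_ids],
            "source": [fid[1] for fid in table.feature_ids],
            "target": [fid[2] for fid in table.feature_ids],
            "selection_frequency": sel_counts / n_folds_total,
        }
    ).sort_values("selection_frequency", ascending=False, kind="stable")
    return CVResult(
        accuracy=100.0 * float(np.nanmean(fm[:, 0])),
        sensitivity=100.0 * float(np.nanmean(fm[:, 1])),
        specificity=100.0 * float(np.nanmean(fm[:, 2])),
        auc=float(np.nanmean(fm[:, 3])),
        pooled_accuracy=100.0 * float((pooled_pred == pooled_true).mean()),
        roc_points=(fpr, tpr),
        selection_frequency=freq,
        fold_assignments=fold_assignments,
        fold_details=fold_details,
    )
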