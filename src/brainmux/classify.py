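"""Diagnostic classification: p-ranked features, Mahalanobis classifier,
repeated cross-validation, ROC/AUC, and the two-family feature grid.

The classifier assigns a subject to the class whose mean is closer in
Mahalanobis distance under the pooled within-class covariance; the ROC score
of a subject is d(negative class) - d(positive class), so larger means more
positive-like. Performance is averaged over repeated stratified 80/20 splits
(a 5-fold-sized test set); a classical 5-fold mode is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .stats import StatResult

__all__ = [
    "ClassifierPerformance",
    "MahalanobisClassifier",
    "rank_features",
    "repeated_cv",
    "roc_auc",
    "feature_grid_search",
]

POSITIVE = "AD"
NEGATIVE = "HC"


@dataclass
class ClassifierPerformance:
    """Acc/Sens/Spec in percent, AUC in [0, 1], and the pooled ROC points."""

    acc: float
    sens: float
    spec: float
    auc: float
    roc_points: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    n_iterations: int = 0

    def as_dict(self) -> dict:
        return {
            "acc": self.acc,
            "sens": self.sens,
            "spec": self.spec,
            "auc": self.auc,
            "n_iterations": self.n_iterations,
        }


def rank_features(local_stats: list[StatResult]) -> list[int]:
    """Indices of features ordered by ascending p, ties by |Z| descending
    then original index."""
    keyed = [
        (r.p, -abs(r.z), i) for i, r in enumerate(local_stats)
    ]
    return [i for _, _, i in sorted(keyed)]


class MahalanobisClassifier:
    """Nearest-class-mean classifier under pooled within-class covariance.

    Ridge shrinkage ``lambda * I`` with ``lambda = 1e-6 * trace / dim`` is
    applied automatically when the pooled covariance is ill-conditioned;
    without it a singular covariance raises with advice to regularize.
    """

    def __init__(self, shrinkage: str = "auto"):
        if shrinkage not in ("auto", "never"):
            raise ValueError("shrinkage must be 'auto' or 'never'")
        self.shrinkage = shrinkage
        self.classes_: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "MahalanobisClassifier":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("exactly 2 classes required")
        means, pooled, n_total = [], np.zeros((X.shape[1], X.shape[1])), 0
        for c in self.classes_:
            Xc = X[y == c]
            if len(Xc) < 2:
                raise ValueError(f"class {c!r} needs >= 2 training subjects")
            means.append(Xc.mean(axis=0))
            pooled += (len(Xc) - 1) * np.cov(Xc, rowvar=False).reshape(X.shape[1], -1)
            n_total += len(Xc)
        pooled /= n_total - 2
        self.means_ = np.array(means)
        cond = np.linalg.cond(pooled) if pooled.size else np.inf
        if not np.isfinite(cond) or cond > 1e8:
            if self.shrinkage == "never":
                raise np.linalg.LinAlgError(
                    "pooled within-class covariance is singular or ill-conditioned; "
                    "enable ridge shrinkage (shrinkage='auto')"
                )
            lam = 1e-6 * np.trace(pooled) / pooled.shape[0]
            if lam <= 0:
                lam = 1e-6
            pooled = pooled + lam * np.eye(pooled.shape[0])
        self.cov_inv_ = np.linalg.inv(pooled)
        return self

    def distances(self, X: np.ndarray) -> np.ndarray:
        """Mahalanobis distance of each row to each class mean, (n, 2)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        d = np.empty((X.shape[0], len(self.classes_)))
        for j, mu in enumerate(self.means_):
            diff = X - mu
            d[:, j] = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", diff, self.cov_inv_, diff), 0))
        return d

    def predict(self, X: np.ndarray) -> np.ndarray:
        d = self.distances(X)
        return self.classes_[np.argmin(d, axis=1)]

    def scores(self, X: np.ndarray, positive: str = POSITIVE) -> np.ndarray:
        """d(negative) - d(positive): larger = more positive-like."""
        d = self.distances(X)
        pos = int(np.flatnonzero(self.classes_ == positive)[0])
        neg = 1 - pos
        return d[:, neg] - d[:, pos]


def roc_auc(scores: np.ndarray, labels: np.ndarray, positive: str = POSITIVE) -> tuple[np.ndarray, float]:
    """ROC points by threshold sweep and AUC by the trapezoid rule.

    Equivalent to the normalized count of correctly ordered class pairs with
    ties counted 1/2 (Mann-Whitney).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    is_pos = labels == positive
    if is_pos.all() or not is_pos.any():
        raise ValueError("both classes must be present to compute a ROC curve")
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    pos_sorted = is_pos[order].astype(float)
    tp = np.cumsum(pos_sorted)
    fp = np.cumsum(1.0 - pos_sorted)
    # collapse tied thresholds: keep the last index of each distinct score
    distinct = np.r_[np.flatnonzero(np.diff(s_sorted) != 0), len(s_sorted) - 1]
    tpr = np.r_[0.0, tp[distinct] / is_pos.sum()]
    fpr = np.r_[0.0, fp[distinct] / (~is_pos).sum()]
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


def _stratified_split(
    y: np.ndarray, train_frac: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    train_idx, test_idx = [], []
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        rng.shuffle(idx)
        n_train = int(round(train_frac * len(idx)))
        n_train = min(max(n_train, 2), len(idx) - 1)  # both sides nonempty, >=2 train
        train_idx.append(idx[:n_train])
        test_idx.append(idx[n_train:])
    return np.concatenate(train_idx), np.concatenate(test_idx)


def repeated_cv(
    features: np.ndarray,
    labels: np.ndarray,
    n_iter: int = 1000,
    train_frac: float = 0.8,
    seed: int = 0,
    mode: str = "shuffle",
    positive: str = POSITIVE,
    selector=None,
) -> ClassifierPerformance:
    """Average Acc/Sens/Spec over repeated stratified splits; ROC/AUC from
    the pooled held-out scores.

    ``mode="shuffle"`` (default) draws ``n_iter`` stratified random
    train_frac/(1-train_frac) splits; ``mode="kfold"`` runs ``n_iter``
    repetitions of stratified 5-fold. ``selector(X_train, y_train)`` may
    return column indices to use for this split (leakage-free in-fold
    feature selection).
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(labels)
    if mode not in ("shuffle", "kfold"):
        raise ValueError("mode must be 'shuffle' or 'kfold'")
    rng = np.random.default_rng(seed)
    accs, senss, specs = [], [], []
    pooled_scores, pooled_labels = [], []

    def _one_split(tr, te):
        cols = selector(X[tr], y[tr]) if selector is not None else slice(None)
        clf = MahalanobisClassifier().fit(X[tr][:, cols], y[tr])
        pred = clf.predict(X[te][:, cols])
        actual_pos = y[te] == positive
        accs.append(100.0 * np.mean(pred == y[te]))
        if actual_pos.any():
            senss.append(100.0 * np.mean(pred[actual_pos] == positive))
        if (~actual_pos).any():
            specs.append(100.0 * np.mean(pred[~actual_pos] != positive))
        pooled_scores.append(clf.scores(X[te][:, cols], positive=positive))
        pooled_labels.append(y[te])

    if mode == "shuffle":
        for _ in range(n_iter):
            tr, te = _stratified_split(y, train_frac, rng)
            _one_split(tr, te)
    else:
        for _ in range(n_iter):
            folds = _stratified_kfold(y, 5, rng)
            for te in folds:
                tr = np.setdiff1d(np.arange(len(y)), te)
                _one_split(tr, te)

    roc, auc = roc_auc(
        np.concatenate(pooled_scores), np.concatenate(pooled_labels), positive=positive
    )
    return ClassifierPerformance(
        acc=float(np.mean(accs)),
        sens=float(np.mean(senss)),
        spec=float(np.mean(specs)),
        auc=auc,
        roc_points=roc,
        n_iterations=n_iter,
    )


def _stratified_kfold(y: np.ndarray, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    per_fold: list[list[int]] = [[] for _ in range(k)]
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        rng.shuffle(idx)
        for j, i in enumerate(idx):
            per_fold[j % k].append(i)
    return [np.array(f) for f in per_fold]


def t_abs_selector(k: int):
    """In-fold selector: top-``k`` columns by train-only |t| statistic."""

    def _select(Xtr: np.ndarray, ytr: np.ndarray) -> np.ndarray:
        from .stats import _nodewise_t

        groups = np.unique(ytr)
        t = _nodewise_t(Xtr, (ytr == groups[0])[None, :])[0]
        t = np.where(np.isfinite(t), np.abs(t), -np.inf)
        return np.argsort(-t, kind="stable")[:k]

    return _select


def feature_grid_search(
    pc_features: np.ndarray,
    mpc_features: np.ndarray,
    labels: np.ndarray,
    max_k_each: int = 3,
    n_iter: int = 200,
    seed: int = 0,
    rank_in_fold: bool = True,
    pc_order: list[int] | None = None,
    mpc_order: list[int] | None = None,
) -> dict:
    """Evaluate every (k_PC, k_MPC) combination of top-ranked features.

    For each cell, the top-``k_PC`` single-layer features are concatenated
    with the top-``k_MPC`` multiplex features and scored by
    :func:`repeated_cv`. With ``rank_in_fold=True`` (default) ranking uses
    train-only |t| within each family inside every split; otherwise
    ``pc_order``/``mpc_order`` (e.g. from :func:`rank_features` on the full
    sample) fix the order up front.

    Returns a dict with Acc/Sens/Spec/AUC matrices of shape
    (max_k_each + 1, max_k_each + 1) — cell (0, 0) is NaN — and the
    argmax-accuracy cell.
    """
    pc = np.atleast_2d(np.asarray(pc_features, dtype=float))
    mpc = np.atleast_2d(np.asarray(mpc_features, dtype=float))
    y = np.asarray(labels)
    if max_k_each < 1:
        raise ValueError("grid is empty: max_k_each must be >= 1")
    if not rank_in_fold:
        pc_order = pc_order if pc_order is not None else list(range(pc.shape[1]))
        mpc_order = mpc_order if mpc_order is not None else list(range(mpc.shape[1]))

    shape = (max_k_each + 1, max_k_each + 1)
    mats = {m: np.full(shape, np.nan) for m in ("acc", "sens", "spec", "auc")}
    for k_pc in range(max_k_each + 1):
        for k_mpc in range(max_k_each + 1):
            if k_pc == 0 and k_mpc == 0:
                continue
            if rank_in_fold:
                n_pc_cols = pc.shape[1]
                X = np.hstack([pc, mpc])

                def selector(Xtr, ytr, k_pc=k_pc, k_mpc=k_mpc, n_pc=n_pc_cols):
                    cols = []
                    if k_pc:
                        cols.append(t_abs_selector(k_pc)(Xtr[:, :n_pc], ytr))
                    if k_mpc:
                        cols.append(t_abs_selector(k_mpc)(Xtr[:, n_pc:], ytr) + n_pc)
                    return np.concatenate(cols)

                perf = repeated_cv(X, y, n_iter=n_iter, seed=seed, selector=selector)
            else:
                blocks = []
                if k_pc:
                    blocks.append(pc[:, pc_order[:k_pc]])
                if k_mpc:
                    blocks.append(mpc[:, mpc_order[:k_mpc]])
                perf = repeated_cv(np.hstack(blocks), y, n_iter=n_iter, seed=seed)
            for m in mats:
                mats[m][k_pc, k_mpc] = getattr(perf, m)
    best = np.unravel_index(np.nanargmax(mats["acc"]), shape)
    return {
        "acc": mats["acc"],
        "sens": mats["sens"],
        "spec": mats["spec"],
        "auc": mats["auc"],
        "best_cell": (int(best[0]), int(best[1])),
        "best_acc": float(mats["acc"][best]),
    }
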