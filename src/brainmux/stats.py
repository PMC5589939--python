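"""Group statistics: permutation t-tests, FDR, Spearman, Kruskal-Wallis,
and the hierarchical global-then-local testing scheme.

Permutation tests draw B label permutations; the two-sided p-value uses the
+1 correction, p = (1 + #{|t*| >= |t|}) / (B + 1), so p is never 0 and is
bounded below by 1/(B+1). Z-scores are taken against the permutation null's
mean and sd. Node-wise tests share one seeded permutation schedule across
nodes within a call.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

__all__ = [
    "StatResult",
    "permutation_ttest",
    "nodewise_group_test",
    "fdr_adjust",
    "spearman_correlation",
    "kruskal_wallis",
    "hierarchical_test",
]


@dataclass(frozen=True)
class StatResult:
    """Outcome of one permutation test on a single feature."""

    feature_id: str
    statistic: float
    z: float
    p: float
    n_permutations: int
    significant: bool | None = None
    p_adjusted: float | None = None


def _tstat(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sample pooled-variance t statistic (NaN if both groups constant)."""
    nx, ny = len(x), len(y)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    sp2 = ((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2)
    denom = np.sqrt(sp2 * (1.0 / nx + 1.0 / ny))
    if denom == 0:
        return np.nan
    return float((x.mean() - y.mean()) / denom)


def _perm_matrix(n: int, B: int, rng: np.random.Generator) -> np.ndarray:
    """B row permutations of arange(n), shape (B, n)."""
    return rng.permuted(np.tile(np.arange(n), (B, 1)), axis=1)


def _nodewise_t(data: np.ndarray, is_x: np.ndarray) -> np.ndarray:
    """Vectorized pooled t for columns of data, group masks rows of is_x.

    data: (n_subjects, n_features); is_x: (B, n_subjects) boolean.
    Returns (B, n_features) t statistics (NaN where pooled sd is 0).
    """
    nx = is_x.sum(axis=1, keepdims=True).astype(float)
    ny = is_x.shape[1] - nx
    fx = is_x.astype(float)
    fy = 1.0 - fx
    sum_x = fx @ data
    sum_y = fy @ data
    sumsq_x = fx @ (data**2)
    sumsq_y = fy @ (data**2)
    mean_x = sum_x / nx
    mean_y = sum_y / ny
    ss_x = sumsq_x - nx * mean_x**2
    ss_y = sumsq_y - ny * mean_y**2
    sp2 = (ss_x + ss_y) / (nx + ny - 2)
    sp2 = np.maximum(sp2, 0.0)  # numerical floor
    denom = np.sqrt(sp2 * (1.0 / nx + 1.0 / ny))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (mean_x - mean_y) / denom
    return t


def permutation_ttest(
    x: np.ndarray,
    y: np.ndarray,
    B: int = 10000,
    seed: int = 0,
    feature_id: str = "",
) -> StatResult:
    """Two-sided permutation t-test for a group difference in means.

    Both groups must have size >= 2. If pooled variance is zero under every
    labeling (all values identical), the result is p = 1, Z = 0 with a
    warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.ptp(np.concatenate([x, y])) == 0:
        warnings.warn("zero variance in both groups: p=1, Z=0", stacklevel=2)
        return StatResult(feature_id, 0.0, 0.0, 1.0, B)
    res = nodewise_group_test(
        np.concatenate([x, y])[:, None],
        np.array([0] * len(x) + [1] * len(y)),
        B=B,
        seed=seed,
        feature_ids=[feature_id],
    )[0]
    return res


def nodewise_group_test(
    features: np.ndarray,
    labels: np.ndarray,
    B: int = 10000,
    seed: int = 0,
    feature_ids: list[str] | None = None,
) -> list[StatResult]:
    """Permutation t-test per column of ``features`` (group 0 minus group 1).

    One shared permutation schedule, seeded, is used for all columns.
    Columns that are constant across all subjects get p = 1, Z = 0 and a
    warning.
    """
    features = np.asarray(features, dtype=float)
    if features.ndim == 1:
        features = features[:, None]
    if not np.isfinite(features).all():
        raise ValueError("features contain missing or non-finite values")
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, got {list(groups)}")
    mask_x = labels == groups[0]
    if mask_x.sum() < 2 or (~mask_x).sum() < 2:
        raise ValueError("each group needs at least 2 subjects")
    n, n_feat = features.shape
    ids = feature_ids if feature_ids is not None else [str(j) for j in range(n_feat)]
    if len(ids) != n_feat:
        raise ValueError("feature_ids length mismatch")

    rng = np.random.default_rng(seed)
    t_obs = _nodewise_t(features, mask_x[None, :])[0]

    perms = _perm_matrix(n, B, rng)
    is_x_perm = np.zeros((B, n), dtype=bool)
    nx = int(mask_x.sum())
    rowed = np.arange(B)[:, None]
    is_x_perm[rowed, perms[:, :nx]] = True
    t_null = _nodewise_t(features, is_x_perm)  # (B, n_feat)

    results = []
    for j in range(n_feat):
        if np.isnan(t_obs[j]):
            warnings.warn(
                f"feature {ids[j]!r} is constant: flagged non-significant", stacklevel=2
            )
            results.append(StatResult(ids[j], 0.0, 0.0, 1.0, B))
            continue
        null_j = t_null[:, j]
        finite = np.isfinite(null_j)
        exceed = np.abs(null_j[finite]) >= abs(t_obs[j]) - 1e-12
        p = (1.0 + exceed.sum()) / (B + 1.0)
        sd = null_j[finite].std(ddof=1)
        z = (t_obs[j] - null_j[finite].mean()) / sd if sd > 0 else 0.0
        results.append(StatResult(ids[j], float(t_obs[j]), float(z), float(p), B))
    return results


def fdr_adjust(
    p: np.ndarray, q: float = 0.05, method: str = "bh"
) -> tuple[np.ndarray, np.ndarray]:
    """Step-up FDR control at level ``q``.

    Parameters
    ----------
    p : array of raw p-values in (0, 1].
    method : "bh" (Benjamini-Hochberg, default) or "by"
        (Benjamini-Yekutieli, with the harmonic-sum penalty).

    Returns
    -------
    reject : boolean mask of rejected hypotheses.
    p_adj : adjusted p-values, monotone in the raw p-values.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in (0, 1]")
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    c_m = np.sum(1.0 / np.arange(1, m + 1)) if method == "by" else 1.0
    if method not in ("bh", "by"):
        raise ValueError(f"unknown FDR method {method!r}")
    ranks = np.arange(1, m + 1)
    adj = ranked * m * c_m / ranks
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    p_adj = np.empty(m)
    p_adj[order] = adj
    # step-up rejection: largest i with p_(i) <= i*q/(m*c_m), reject all smaller
    thresh_ok = ranked <= ranks * q / (m * c_m)
    reject = np.zeros(m, dtype=bool)
    if thresh_ok.any():
        cutoff = np.max(np.flatnonzero(thresh_ok))
        reject[order[: cutoff + 1]] = True
    return reject, p_adj


def spearman_correlation(
    feature: np.ndarray, score: np.ndarray, B: int = 10000, seed: int = 0
) -> tuple[float, float]:
    """Spearman R (midranks for ties) with a permutation p-value.

    p is two-sided, from B random permutations of the score order with the
    +1 correction. Constant inputs have undefined R and raise.
    """
    feature = np.asarray(feature, dtype=float)
    score = np.asarray(score, dtype=float)
    if feature.shape != score.shape or feature.ndim != 1:
        raise ValueError("feature and score must be paired 1-D vectors")
    if len(feature) < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(feature) == 0 or np.ptp(score) == 0:
        raise ValueError("Spearman R is undefined for constant input")
    rf = _sps.rankdata(feature)
    rs = _sps.rankdata(score)
    r_obs = float(np.corrcoef(rf, rs)[0, 1])
    rng = np.random.default_rng(seed)
    perms = _perm_matrix(len(score), B, rng)
    rs_perm = rs[perms]  # (B, n)
    rf_c = rf - rf.mean()
    rs_c = rs_perm - rs_perm.mean(axis=1, keepdims=True)
    num = rs_c @ rf_c
    denom = np.sqrt((rf_c**2).sum() * (rs_c**2).sum(axis=1))
    r_null = num / denom
    p = float((1.0 + np.sum(np.abs(r_null) >= abs(r_obs) - 1e-12)) / (B + 1.0))
    return r_obs, p


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Kruskal-Wallis H with tie correction; p from the chi-square
    approximation on len(groups) - 1 degrees of freedom."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) == 0 for g in groups):
        raise ValueError("every group needs at least 1 value")
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = _sps.rankdata(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    if tie_term == 0:  # all values identical
        return 0.0, 1.0
    h /= tie_term
    h = max(h, 0.0)
    df = len(groups) - 1
    p = float(_sps.chi2.sf(h, df))
    return float(h), p


def hierarchical_test(
    global_features: dict[str, tuple[np.ndarray, np.ndarray]],
    local_features: dict[str, tuple[np.ndarray, np.ndarray]],
    B: int = 10000,
    q: float = 0.05,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict[str, dict]:
    """Global-then-local testing with an FDR-corrected local stage.

    ``global_features[name] = (x_group, y_group)`` scalars per subject;
    ``local_features[name] = (features, labels)`` with subjects x nodes.
    Local tests run only for features whose global p < ``alpha``; otherwise
    the feature is marked ``"not pursued"``.
    """
    out: dict[str, dict] = {}
    for name, (gx, gy) in global_features.items():
        g = permutation_ttest(gx, gy, B=B, seed=seed, feature_id=name)
        entry: dict = {"global": g}
        if g.p < alpha and name in local_features:
            feats, labels = local_features[name]
            locs = nodewise_group_test(feats, labels, B=B, seed=seed)
            reject, p_adj = fdr_adjust(np.array([r.p for r in locs]), q=q)
            entry["local"] = [
                StatResult(
                    r.feature_id, r.statistic, r.z, r.p, r.n_permutations,
                    significant=bool(rej), p_adjusted=float(pa),
                )
                for r, rej, pa in zip(locs, reject, p_adj)
            ]
            entry["status"] = "pursued"
        else:
            entry["status"] = "not pursued"
        out[name] = entry
    return out
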