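"""Differential expression, multi-group tests, clustering and ordination.

Fold changes are computed by subtraction of group means on log2 abundances,
significance by the pooled-variance (Student) two-sample t-test (Welch is
available), multiplicity control by Benjamini–Hochberg.  Clustering follows
the Cluster 3.0 conventions: optional median centering of protein rows,
uncentered-correlation distance, complete linkage, with a deterministic
smallest-index tie-break.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass
class DeThresholds:
    """Volcano / significance cutoffs on log2 data."""

    min_abs_log2fc: float = 1.0
    max_p: float = 0.05
    strict_p: float = 0.01     # volcano highlight line
    max_q: float = 0.1

    def validate(self) -> None:
        for name in ("min_abs_log2fc", "max_p", "strict_p", "max_q"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name}: must be positive")
        if self.max_p > 1:
            raise ValueError("max_p: must be <= 1")


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    arr = np.asarray(pvalues, dtype=float)
    if arr.size == 0:
        return arr.copy()
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ValueError("p-values must be in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def _group_stats(values: np.ndarray):
    """nan-aware per-row count, mean and ddof-1 variance."""
    n = np.isfinite(values).sum(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(values, axis=1)
        var = np.nanvar(values, axis=1, ddof=1)
    return n, mean, var


def differential_expression(matrix: pd.DataFrame, group_a, group_b,
                            equal_var: bool = True,
                            min_per_group: int = 2) -> pd.DataFrame:
    """Two-group differential expression per protein.

    ``log2fc = mean(group_a) - mean(group_b)``; two-sided p from the
    pooled-variance t-test (or Welch with ``equal_var=False``); BH q over
    tested proteins.  Proteins with fewer than ``min_per_group`` observed
    values in either group are reported untested (NaN statistics).
    """
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    na, ma, va = _group_stats(matrix[group_a].values.astype(float))
    nb, mb, vb = _group_stats(matrix[group_b].values.astype(float))
    diff = ma - mb
    tested = (na >= min_per_group) & (nb >= min_per_group)
    t = np.full(len(matrix), np.nan)
    p = np.full(len(matrix), np.nan)
    df = np.full(len(matrix), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        if equal_var:
            sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
            se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
            dfv = na + nb - 2.0
        else:
            se = np.sqrt(va / na + vb / nb)
            dfv = (va / na + vb / nb) ** 2 / (
                (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        tv = diff / se
    zero_se = tested & (se == 0)
    t[tested] = tv[tested]
    df[tested] = dfv[tested]
    p[tested] = 2.0 * sps.t.sf(np.abs(tv[tested]), dfv[tested])
    # degenerate zero-variance groups: identical data -> p = 1, else certain
    t[zero_se & (diff == 0)] = 0.0
    p[zero_se & (diff == 0)] = 1.0
    t[zero_se & (diff != 0)] = np.sign(diff[zero_se & (diff != 0)]) * np.inf
    p[zero_se & (diff != 0)] = 0.0
    q = np.full(len(matrix), np.nan)
    if tested.any():
        q[tested] = bh_adjust(p[tested])
    return pd.DataFrame(
        {"log2fc": np.where(tested, diff, np.nan), "t": t, "p": p, "q": q,
         "n_a": na, "n_b": nb, "tested": tested},
        index=matrix.index,
    )


def differential_expression_pooled(matrices: list, group_a, group_b
                                   ) -> pd.DataFrame:
    """Differential expression over multiply imputed matrices.

    Runs the group-mean contrast on each completed matrix and pools the
    per-imputation estimates and their squared standard errors with Rubin's
    rules (Barnard–Rubin df with complete-data df ``n_a + n_b - 2``); BH q
    over the pooled p-values.
    """
    from .impute import _rubin_arrays

    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    na, nb = len(group_a), len(group_b)
    ests, variances = [], []
    index = matrices[0].index
    for mat in matrices:
        if not mat.index.equals(index):
            raise ValueError("imputed matrices must share their protein index")
        a = mat[group_a].values.astype(float)
        b = mat[group_b].values.astype(float)
        ma, mb = a.mean(axis=1), b.mean(axis=1)
        va = a.var(axis=1, ddof=1)
        vb = b.var(axis=1, ddof=1)
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        ests.append(ma - mb)
        variances.append(sp2 * (1.0 / na + 1.0 / nb))
    est = np.vstack(ests)
    var = np.vstack(variances)
    point, W, B, T, df, t, p = _rubin_arrays(
        est, var, np.full(est.shape[1], na + nb - 2.0))
    return pd.DataFrame(
        {"log2fc": point, "t": t, "p": p, "q": bh_adjust(p),
         "within_var": W, "between_var": B, "total_var": T, "df": df,
         "n_a": na, "n_b": nb},
        index=index,
    )


def anova_oneway(matrix: pd.DataFrame, groups) -> pd.DataFrame:
    """Classical one-way ANOVA F-test per protein across >= 3 groups.

    ``groups`` maps sample id to group label.  Rows where any group has
    fewer than 2 observed values are untested (NaN).  Degenerate rows with
    zero within- and between-group variance get p = 1 with a warning.
    """
    groups = pd.Series(groups)
    labels = [g for g in groups.unique()]
    if len(labels) < 3:
        raise ValueError("need >= 3 groups (use the t-test for 2)")
    parts = []
    for g in labels:
        cols = [s for s in matrix.columns if groups.get(s) == g]
        parts.append(_group_stats(matrix[cols].values.astype(float)))
    k = len(labels)
    ns = np.vstack([p[0] for p in parts])
    means = np.vstack([p[1] for p in parts])
    vars_ = np.vstack([p[2] for p in parts])
    tested = (ns >= 2).all(axis=0)
    N = ns.sum(axis=0)
    grand = (ns * means).sum(axis=0) / N
    ssb = (ns * (means - grand) ** 2).sum(axis=0)
    ssw = ((ns - 1) * vars_).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / (k - 1)) / (ssw / (N - k))
    p = np.full(len(matrix), np.nan)
    Fout = np.full(len(matrix), np.nan)
    ok = tested & (ssw > 0)
    Fout[ok] = F[ok]
    p[ok] = sps.f.sf(F[ok], k - 1, (N - k)[ok])
    degen = tested & (ssw == 0)
    if degen.any():
        both_zero = degen & (ssb == 0)
        if both_zero.any():
            warnings.warn(
                f"{int(both_zero.sum())} proteins with zero variance "
                "everywhere: p set to 1")
        Fout[both_zero] = 0.0
        p[both_zero] = 1.0
        sep = degen & (ssb > 0)
        Fout[sep] = np.inf
        p[sep] = 0.0
    return pd.DataFrame({"F": Fout, "p": p, "tested": tested},
                        index=matrix.index)


def uncentered_correlation_distance(x, y) -> float:
    """``1 - sum(x*y) / (||x|| * ||y||)`` over pairwise-complete positions.

    The cosine-type distance of Cluster 3.0 (no mean subtraction); range
    [0, 2].  Raises on zero-norm vectors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have the same length")
    shared = np.isfinite(x) & np.isfinite(y)
    xs, ys = x[shared], y[shared]
    nx = np.sqrt(np.sum(xs ** 2))
    ny = np.sqrt(np.sum(ys ** 2))
    if nx == 0 or ny == 0:
        raise ValueError("zero-norm vector over shared positions")
    return float(1.0 - np.dot(xs, ys) / (nx * ny))


def uncentered_distance_matrix(items: np.ndarray, min_shared: int = 3
                               ) -> np.ndarray:
    """Pairwise uncentered-correlation distances between the rows of
    ``items`` over pairwise-complete positions.

    Pairs sharing fewer than ``min_shared`` positions (or with a degenerate
    zero norm) get the maximum observed distance, with a warning.
    """
    X = np.asarray(items, dtype=float)
    M = np.isfinite(X)
    Xz = np.where(M, X, 0.0)
    dot = Xz @ Xz.T
    sq = Xz ** 2
    norm2 = sq @ M.T          # ||x||^2 over positions shared with y
    shared = M.astype(int) @ M.T.astype(int)
    with np.errstate(divide="ignore", invalid="ignore"):
        D = 1.0 - dot / np.sqrt(norm2 * norm2.T)
    bad = (shared < min_shared) | ~np.isfinite(D)
    np.fill_diagonal(bad, False)
    np.fill_diagonal(D, 0.0)
    if bad.any():
        warnings.warn(
            f"{int(bad.sum() // 2)} item pairs with < {min_shared} shared "
            "positions or zero norm set to the maximum observed distance")
        finite = D[np.isfinite(D) & ~bad]
        fallback = float(finite.max()) if finite.size else 2.0
        D[bad] = fallback
    return D


@dataclass
class ClusterResult:
    """Agglomeration record of a hierarchical clustering."""

    linkage: np.ndarray     # (n-1, 4): id_a, id_b, height, size (scipy layout)
    labels: list            # leaf labels, original order
    leaf_order: list        # labels in dendrogram order
    newick: str


def hierarchical_cluster(matrix: pd.DataFrame, axis: str = "samples",
                         median_center: bool = True,
                         min_shared: int = 3) -> ClusterResult:
    """Complete-linkage agglomeration under uncentered-correlation distance.

    Protein rows are median-centered first when ``median_center`` is set
    (the Cluster 3.0 convention).  At every step the closest pair is merged;
    ties are broken deterministically by the smaller item index pair.  Items
    that are entirely missing are dropped with a warning.
    """
    if axis not in ("samples", "proteins"):
        raise ValueError("axis: must be 'samples' or 'proteins'")
    X = matrix.values.astype(float)
    if median_center:
        X = X - np.nanmedian(X, axis=1, keepdims=True)
    if axis == "samples":
        X = X.T
        labels = list(matrix.columns)
    else:
        labels = list(matrix.index)
    all_missing = ~np.isfinite(X).any(axis=1)
    if all_missing.any():
        warnings.warn(
            f"dropping all-missing items: "
            f"{[l for l, m in zip(labels, all_missing) if m]}")
        X = X[~all_missing]
        labels = [l for l, m in zip(labels, all_missing) if m == False]  # noqa: E712
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 items to cluster")
    D = uncentered_distance_matrix(X, min_shared=min_shared)

    work = D.copy()
    np.fill_diagonal(work, np.inf)
    active = list(range(n))            # row slots still alive
    cluster_id = list(range(n))        # scipy-style ids of those slots
    sizes = {i: 1 for i in range(n)}
    children: dict = {}
    heights = {}
    linkage = np.zeros((n - 1, 4))
    alive = np.ones(n, bool)
    for step in range(n - 1):
        sub = work[np.ix_(alive.nonzero()[0], alive.nonzero()[0])]
        flat = np.argmin(sub)          # row-major: smallest index pair on ties
        ii, jj = np.unravel_index(flat, sub.shape)
        rows = alive.nonzero()[0]
        i, j = int(rows[min(ii, jj)]), int(rows[max(ii, jj)])
        h = work[i, j]
        new_id = n + step
        ca, cb = cluster_id[i], cluster_id[j]
        linkage[step] = [min(ca, cb), max(ca, cb),
                         h, sizes[ca] + sizes[cb]]
        children[new_id] = (min(ca, cb), max(ca, cb))
        heights[new_id] = h
        sizes[new_id] = sizes[ca] + sizes[cb]
        # complete linkage: merged cluster at slot i
        merged = np.maximum(work[i], work[j])
        work[i, :] = merged
        work[:, i] = merged
        work[i, i] = np.inf
        alive[j] = False
        cluster_id[i] = new_id

    def leaves(cid):
        if cid < n:
            return [cid]
        a, b = children[cid]
        return leaves(a) + leaves(b)

    def newick(cid, parent_h):
        h = heights.get(cid, 0.0)
        if cid < n:
            return f"{labels[cid]}:{parent_h - h:g}"
        a, b = children[cid]
        return (f"({newick(a, h)},{newick(b, h)}):{parent_h - h:g}")

    root = 2 * n - 2
    order = [labels[i] for i in leaves(root)]
    nwk = newick(root, heights[root])
    # strip the root's zero-length branch
    nwk = nwk.rsplit(":", 1)[0] + ";"
    return ClusterResult(linkage, labels, order, nwk)


def pca_scores(matrix: pd.DataFrame, n_components: int = 2):
    """Sample scores and explained-variance fractions by SVD of the
    feature-centered data.

    Samples (columns of ``matrix``) are the observations; each protein
    feature is mean-centered.  Requires a complete matrix — impute first.
    """
    X = matrix.values.astype(float).T      # samples x proteins
    if not np.isfinite(X).all():
        raise ValueError("matrix contains missing values; run imputation first")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign: largest-magnitude loading positive
    for k in range(len(S)):
        lead = np.argmax(np.abs(Vt[k]))
        if Vt[k, lead] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    k = min(n_components, len(S))
    scores = pd.DataFrame(U[:, :k] * S[:k], index=matrix.columns,
                          columns=[f"PC{i + 1}" for i in range(k)])
    total = np.sum(S ** 2)
    evr = (S[:k] ** 2 / total) if total > 0 else np.zeros(k)
    return scores, evr


def resolve_contrast(annotation: pd.DataFrame, contrast: str):
    """Parse ``"a+b:c"`` into two sample lists using the annotation table."""
    try:
        left, right = contrast.split(":")
    except ValueError:
        raise ValueError(f"contrast must be 'groupA:groupB', got {contrast!r}")
    known = set(annotation["group"])

    def side(expr):
        groups = expr.split("+")
        missing = [g for g in groups if g not in known]
        if missing:
            raise ValueError(f"unknown groups in contrast: {missing}")
        return list(annotation.loc[annotation["group"].isin(groups),
                                   "sample_id"])

    return side(left), side(right)
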