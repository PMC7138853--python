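"""Multiple imputation by chained equations with predictive mean matching,
Rubin's-rules pooling, and cross-plex batch correction.

The imputation model treats each sample (column) of the proteins x samples
abundance matrix as a regression target on all other samples: proteins are
the observations, and missing cells are filled by predictive mean matching
(PMM) — the imputed value is an *observed* value of the same column, drawn
from the donors whose predicted means are nearest the missing cell's
prediction.  Columns are visited in order of descending missingness, the
sweep is repeated ``maxit`` times, and ``m`` independent chains yield ``m``
completed matrices whose analyses are pooled with Rubin's rules:

    point = mean(estimates)
    W     = mean(variances)            (within-imputation)
    B     = var(estimates, ddof=1)     (between-imputation)
    T     = W + (1 + 1/m) * B
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class ImputeConfig:
    m: int = 5          # number of imputed data sets
    maxit: int = 50     # chained-equation sweeps
    donors: int = 5     # PMM donor-pool size
    seed: int = 0

    def validate(self) -> None:
        if self.m < 1:
            raise ValueError("m: must be >= 1")
        if self.maxit < 1:
            raise ValueError("maxit: must be >= 1")
        if self.donors < 1:
            raise ValueError("donors: must be >= 1")


def pmm_impute(matrix: pd.DataFrame, config: ImputeConfig | None = None,
               min_observed: int = 3) -> list:
    """Impute missing cells of a proteins x samples matrix; returns ``m``
    completed copies.

    Rows with fewer than ``min_observed`` observed values are dropped with a
    warning before imputation (their regressions are hopeless).  Observed
    cells are never altered, and every imputed value is an observed value of
    its own column (the PMM property).  Columns without missing values still
    serve as predictors.  A rank-deficient regression falls back to
    column-median prediction with a warning.
    """
    config = config or ImputeConfig()
    config.validate()
    obs_per_row = matrix.notna().sum(axis=1)
    drop = obs_per_row < min_observed
    if drop.any():
        warnings.warn(
            f"dropping {int(drop.sum())} rows with < {min_observed} observed values")
        matrix = matrix.loc[~drop]
    X0 = matrix.values.astype(float)
    miss = ~np.isfinite(X0)
    if miss.all(axis=0).any():
        bad = list(matrix.columns[miss.all(axis=0)])
        raise ValueError(f"columns entirely missing: {bad}")
    if not miss.any():
        return [matrix.copy() for _ in range(config.m)]

    n, p = X0.shape
    # visit order: descending missingness, ties by column position
    n_miss = miss.sum(axis=0)
    visit = sorted(np.flatnonzero(n_miss > 0),
                   key=lambda j: (-n_miss[j], j))
    ss = np.random.SeedSequence(config.seed)
    completed = []
    warned_rank = False
    for chain_seed in ss.spawn(config.m):
        rng = np.random.default_rng(chain_seed)
        X = X0.copy()
        for j in range(p):
            mj = miss[:, j]
            if mj.any():
                obs_vals = X0[~mj, j]
                X[mj, j] = rng.choice(obs_vals, size=mj.sum(), replace=True)
        for _ in range(config.maxit):
            for j in visit:
                mj = miss[:, j]
                others = np.delete(np.arange(p), j)
                A = np.column_stack([np.ones(n), X[:, others]])
                y_obs = X0[~mj, j]
                coef, _, rank, _ = np.linalg.lstsq(A[~mj], y_obs, rcond=None)
                if rank < A.shape[1]:
                    if not warned_rank:
                        warnings.warn(
                            "rank-deficient regression; falling back to "
                            "column-median prediction")
                        warned_rank = True
                    pred = np.full(n, np.median(y_obs))
                else:
                    pred = A @ coef
                yhat_obs = pred[~mj]
                yhat_mis = pred[mj]
                k = min(config.donors, len(y_obs))
                d = np.abs(yhat_mis[:, None] - yhat_obs[None, :])
                pool = np.argpartition(d, k - 1, axis=1)[:, :k]
                pick = pool[np.arange(len(yhat_mis)),
                            rng.integers(0, k, size=len(yhat_mis))]
                X[mj, j] = y_obs[pick]
        completed.append(pd.DataFrame(X, index=matrix.index,
                                      columns=matrix.columns))
    return completed


@dataclass
class PooledEstimate:
    """Rubin's-rules pooled estimate for one scalar quantity."""

    estimate: float
    within: float       # W
    between: float      # B
    total: float        # T = W + (1 + 1/m) * B
    df: float
    statistic: float
    p: float
    m: int


def _rubin_arrays(estimates: np.ndarray, variances: np.ndarray,
                  df_complete=None):
    """Vectorized Rubin's rules along axis 0 (the imputation axis)."""
    m = estimates.shape[0]
    point = estimates.mean(axis=0)
    W = variances.mean(axis=0)
    B = estimates.var(axis=0, ddof=1) if m > 1 else np.zeros_like(point)
    T = W + (1.0 + 1.0 / m) * B
    with np.errstate(divide="ignore", invalid="ignore"):
        lam = np.where(T > 0, (1.0 + 1.0 / m) * B / T, 0.0)
        df_old = np.where(lam > 0, (m - 1) / lam ** 2, np.inf)
        if df_complete is not None:
            nu_com = np.asarray(df_complete, dtype=float)
            nu_obs = ((nu_com + 1.0) / (nu_com + 3.0)) * nu_com * (1.0 - lam)
            df = 1.0 / (1.0 / df_old + 1.0 / nu_obs)
        else:
            df = df_old
        t = np.where(T > 0, point / np.sqrt(T),
                     np.where(point == 0, 0.0, np.inf * np.sign(point)))
    p = np.where(np.isinf(df), 2.0 * sps.norm.sf(np.abs(t)),
                 2.0 * sps.t.sf(np.abs(t), np.maximum(df, 1e-12)))
    p = np.where(np.isinf(np.abs(t)), 0.0, p)
    p = np.where((T == 0) & (point == 0), 1.0, p)
    return point, W, B, T, df, t, p


def pool_rubin(estimates, variances, df_complete: float | None = None
               ) -> PooledEstimate:
    """Pool per-imputation estimates and variances by Rubin's rules.

    Degrees of freedom follow the Barnard–Rubin small-sample formula when
    the complete-data df is supplied, else the classic large-sample form;
    with ``m = 1`` or identical estimates, B = 0 and T = W.
    """
    est = np.asarray(estimates, dtype=float)
    var = np.asarray(variances, dtype=float)
    if est.shape != var.shape:
        raise ValueError("estimates and variances must have the same length")
    point, W, B, T, df, t, p = _rubin_arrays(
        est[:, None], var[:, None],
        None if df_complete is None else np.array([df_complete]))
    return PooledEstimate(float(point[0]), float(W[0]), float(B[0]),
                          float(T[0]), float(df[0]), float(t[0]),
                          float(p[0]), len(est))


def median_pooled_pvalue(pvalues) -> float:
    """Median of per-imputation p-values (even counts: mean of the two
    central values)."""
    arr = np.asarray(pvalues, dtype=float)
    if arr.size == 0:
        raise ValueError("empty p-value list")
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("p-values must be in [0, 1]")
    return float(np.median(arr))


def batch_correct(matrix: pd.DataFrame, batches) -> pd.DataFrame:
    """Remove per-protein batch means: subtract the batch mean and add back
    the grand mean, per protein.

    Within-batch contrasts are preserved exactly.  Proteins with an entirely
    missing batch are left uncorrected with a warning.
    """
    batches = pd.Series(batches)
    unknown = [s for s in matrix.columns if s not in batches.index]
    if unknown:
        raise ValueError(f"samples missing from batch map: {unknown}")
    batches = batches[matrix.columns]
    labels = batches.unique()
    for b in labels:
        if (batches == b).sum() < 2:
            raise ValueError(f"batch {b!r} has fewer than 2 samples")
    grand = matrix.mean(axis=1, skipna=True)
    out = matrix.copy()
    batch_means = {}
    uncorrectable = pd.Series(False, index=matrix.index)
    for b in labels:
        cols = matrix.columns[(batches == b).values]
        bm = matrix[cols].mean(axis=1, skipna=True)
        batch_means[b] = bm
        uncorrectable |= bm.isna()
    if uncorrectable.any():
        warnings.warn(
            f"{int(uncorrectable.sum())} proteins with an all-missing batch "
            "left uncorrected")
    for b in labels:
        cols = matrix.columns[(batches == b).values]
        ok = ~uncorrectable
        out.loc[ok, cols] = (matrix.loc[ok, cols]
                             .sub(batch_means[b][ok], axis=0)
                             .add(grand[ok], axis=0))
    return out
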