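"""Differential statistics: Welch tests, volcano classification, PCA.

The study's headline rule is deliberately simple: features with an
uncorrected Welch p < 0.05 are called differential, up or down by the sign
of the log2 fold change (WD minus control).  A Benjamini-Hochberg column is
emitted alongside for transparency but never drives classification.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .core_io import AbundanceMatrix, SampleDesign, ValidationError, design_samples

__all__ = ["WelchResult", "welch_test", "differential_table", "PcaSummary", "pca_scores"]


@dataclass(frozen=True)
class WelchResult:
    t_stat: float
    df: float
    p_value: float
    degenerate: bool = False


def welch_test(x: Sequence[float], y: Sequence[float]) -> WelchResult:
    """Two-sided unequal-variance t test with Welch-Satterthwaite df.

    Degenerate zero-variance inputs are resolved explicitly rather than
    left to 0/0 arithmetic: two constant groups with equal means are a
    perfect null (t=0, p=1); with unequal means they are flagged
    degenerate with p -> 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("welch_test needs >= 2 non-missing values per group")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        pooled_df = float(len(x) + len(y) - 2)
        if x.mean() == y.mean():
            return WelchResult(0.0, pooled_df, 1.0, degenerate=False)
        t = np.inf if x.mean() > y.mean() else -np.inf
        return WelchResult(t, pooled_df, 0.0, degenerate=True)
    res = sps.ttest_ind(x, y, equal_var=False)
    return WelchResult(float(res.statistic), float(res.df), float(res.pvalue))


def _welch_vectorized(xs: np.ndarray, ys: np.ndarray) -> tuple[np.ndarray, ...]:
    """Row-wise Welch test on two feature x sample blocks (NaN-aware).

    Returns (t, df, p, n_x, n_y, mean_x, mean_y, degenerate, testable).
    """
    import warnings

    nx = np.sum(~np.isnan(xs), axis=1)
    ny = np.sum(~np.isnan(ys), axis=1)
    testable = (nx >= 2) & (ny >= 2)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # rows with < 2 values are dropped afterwards; their dof warnings are noise
        warnings.filterwarnings("ignore", message="Degrees of freedom")
        warnings.filterwarnings("ignore", message="Mean of empty slice")
        mx = np.nanmean(xs, axis=1)
        my = np.nanmean(ys, axis=1)
        vx = np.nanvar(xs, axis=1, ddof=1)
        vy = np.nanvar(ys, axis=1, ddof=1)
        sx, sy = vx / nx, vy / ny
        se2 = sx + sy
        t = (mx - my) / np.sqrt(se2)
        df = se2**2 / (sx**2 / (nx - 1) + sy**2 / (ny - 1))
        p = 2.0 * sps.t.sf(np.abs(t), df)
    degenerate = np.zeros(len(t), dtype=bool)
    both_const = testable & (vx == 0) & (vy == 0)
    equal_means = both_const & (mx == my)
    diff_means = both_const & (mx != my)
    pooled_df = (nx + ny - 2).astype(float)
    t[equal_means], df[equal_means], p[equal_means] = 0.0, pooled_df[equal_means], 1.0
    t[diff_means] = np.where(mx[diff_means] > my[diff_means], np.inf, -np.inf)
    df[diff_means], p[diff_means] = pooled_df[diff_means], 0.0
    degenerate[diff_means] = True
    return t, df, p, nx, ny, mx, my, degenerate, testable


def differential_table(
    log2_table: AbundanceMatrix,
    design: Sequence[SampleDesign],
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-feature Welch differential table for one tissue, WD vs control.

    Returns ``(table, skipped)``.  ``table`` has one row per feature with
    at least two non-missing values in each condition: mean_control,
    mean_wd, log2fc (WD - control), t, df, p, p_adj_bh, class
    (up / down / ns at the uncorrected alpha, strict inequality), n_control,
    n_wd, degenerate.  ``skipped`` lists excluded features with a reason
    code — no imputation is done anywhere.
    """
    if log2_table.scale not in ("log2", "log2_adjusted"):
        raise ValidationError(f"differential_table expects log2 scale, got {log2_table.scale!r}")
    ctrl = design_samples(design, "control")
    wd = design_samples(design, "WD")
    if not ctrl or not wd:
        raise ValidationError("design must contain both conditions")
    missing = [s for s in ctrl + wd if s not in log2_table.sample_ids]
    if missing:
        raise ValidationError(f"design sample(s) absent from table: {missing}")
    tissues = {d.tissue for d in design}
    if len(tissues) != 1:
        raise ValidationError(f"design spans multiple tissues: {sorted(tissues)}")

    xs = log2_table.data.loc[:, wd].to_numpy(dtype=float)
    ys = log2_table.data.loc[:, ctrl].to_numpy(dtype=float)
    t, df, p, n_wd, n_ctrl, mean_wd, mean_ctrl, degenerate, testable = _welch_vectorized(xs, ys)

    feats = np.asarray(log2_table.feature_ids)
    skipped = pd.DataFrame(
        {"feature_id": feats[~testable], "reason": "fewer_than_2_values_per_group"}
    )

    idx = testable
    log2fc = mean_wd[idx] - mean_ctrl[idx]
    pvals = p[idx]
    p_adj = multipletests(pvals, method="fdr_bh")[1] if idx.any() else np.array([])
    volcano = np.where(
        (pvals < alpha) & (log2fc > 0), "up", np.where((pvals < alpha) & (log2fc < 0), "down", "ns")
    )
    table = pd.DataFrame(
        {
            "feature_id": feats[idx],
            "mean_control": mean_ctrl[idx],
            "mean_wd": mean_wd[idx],
            "log2fc": log2fc,
            "t": t[idx],
            "df": df[idx],
            "p": pvals,
            "p_adj_bh": p_adj,
            "class": volcano,
            "n_control": n_ctrl[idx],
            "n_wd": n_wd[idx],
            "degenerate": degenerate[idx],
        }
    ).reset_index(drop=True)
    return table, skipped


@dataclass
class PcaSummary:
    """Sample scores and variance fractions from a feature-centered PCA."""

    scores: pd.DataFrame  # samples x components
    variance_explained: np.ndarray
    n_features_used: int
    n_features_excluded: int


def pca_scores(log2_table: AbundanceMatrix, n_components: int | None = None) -> PcaSummary:
    """PCA of samples using all features with complete data.

    Features (variables) are mean-centered; scores come from the SVD of the
    samples x features matrix.  Sign convention: each component is flipped
    so its largest-magnitude feature loading is positive, making output
    deterministic across SVD implementations.
    """
    complete = log2_table.data.dropna(axis=0)
    n_excluded = len(log2_table.data) - len(complete)
    if len(complete) < 2:
        raise ValidationError("PCA needs at least 2 features with complete data")
    if complete.shape[1] < 2:
        raise ValidationError("PCA needs at least 2 samples")
    X = complete.to_numpy(dtype=float).T  # samples x features
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign: largest-|loading| entry of each component positive
    for k in range(len(S)):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    total_var = float((S**2).sum())
    var_frac = S**2 / total_var if total_var > 0 else np.zeros_like(S)
    k = len(S) if n_components is None else min(n_components, len(S))
    scores = pd.DataFrame(
        (U[:, :k] * S[:k]),
        index=log2_table.sample_ids,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    return PcaSummary(scores, var_frac[:k], len(complete), n_excluded)
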