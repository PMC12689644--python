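"""Mass-univariate voxelwise / parcelwise group comparison."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .grids import FeatureGrid, ParcelAtlas, parcel_means
from .stats import bh_adjust

__all__ = ["groupwise_glm", "voxelwise_glm", "parcelwise_glm", "StatMapResult"]


@dataclass
class StatMapResult:
    table: pd.DataFrame  # feature, t_value, p_raw, p_adjusted, significant flags, ok
    alpha: float
    covariates: tuple[str, ...]
    n_per_group: dict


def groupwise_glm(values, group_labels, covars: pd.DataFrame | None = None,
                  alpha: float = 0.05, feature_names=None) -> StatMapResult:
    """OLS t-test of the group coefficient per feature, with BH adjustment.

    ``values`` is (n_subjects, n_features); ``group_labels`` a two-level
    vector (the coefficient is for the second level in sorted order, so
    positive t means higher values in that level). Covariates enter the
    design unchanged. Features whose model is degenerate are flagged
    ``ok = False`` with NaN statistics rather than raising.
    """
    Y = np.asarray(values, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    labels = np.asarray(group_labels)
    levels = sorted(pd.unique(labels))
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {levels}")
    n0 = int(np.sum(labels == levels[0]))
    n1 = int(np.sum(labels == levels[1]))
    if min(n0, n1) < 3:
        raise ValueError("each group needs at least 3 subjects")
    ind = (labels == levels[1]).astype(float)

    columns = [np.ones(Y.shape[0]), ind]
    names = ["intercept", f"group[{levels[1]}]"]
    cov_names: tuple[str, ...] = ()
    if covars is not None and len(covars.columns):
        for c in covars.columns:
            col = covars[c]
            if col.dtype == object:
                col = pd.Categorical(col).codes
            columns.append(np.asarray(col, dtype=float))
            names.append(c)
        cov_names = tuple(covars.columns)
    X = np.column_stack(columns)
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    deficient = rank < p

    if feature_names is None:
        feature_names = [f"f{j}" for j in range(Y.shape[1])]

    t_vals = np.full(Y.shape[1], np.nan)
    p_vals = np.full(Y.shape[1], np.nan)
    ok = np.zeros(Y.shape[1], dtype=bool)
    if not deficient and n > p:
        XtX_inv = np.linalg.inv(X.T @ X)
        beta = XtX_inv @ (X.T @ Y)
        resid = Y - X @ beta
        dof = n - p
        sigma2 = np.sum(resid**2, axis=0) / dof
        se = np.sqrt(sigma2 * XtX_inv[1, 1])
        good = se > 0
        t_vals[good] = beta[1, good] / se[good]
        p_vals[good] = 2.0 * sps.t.sf(np.abs(t_vals[good]), dof)
        t_vals[~good & (sigma2 == 0)] = 0.0
        p_vals[~good & (sigma2 == 0)] = 1.0
        ok = np.isfinite(p_vals)

    p_adj = np.full_like(p_vals, np.nan)
    if ok.any():
        p_adj[ok] = bh_adjust(p_vals[ok])
    table = pd.DataFrame({
        "feature": list(feature_names),
        "t_value": t_vals,
        "p_raw": p_vals,
        "p_adjusted": p_adj,
        "significant_raw": p_vals < alpha,
        "significant_adjusted": p_adj < alpha,
        "ok": ok,
    })
    return StatMapResult(
        table=table,
        alpha=alpha,
        covariates=cov_names,
        n_per_group={str(levels[0]): n0, str(levels[1]): n1},
    )


def _covar_frame(index: pd.DataFrame, covariate_columns) -> pd.DataFrame:
    cov = pd.DataFrame(index=index.index)
    for c in covariate_columns:
        cov[c] = index[c]
    return cov


def voxelwise_glm(grid: FeatureGrid, group_column: str = "subtype",
                  covariate_columns=("age", "sex", "tiv", "latent_time"),
                  alpha: float = 0.05) -> StatMapResult:
    """Per-voxel subtype GLM restricted to brain-mask voxels.

    One scan per subject is expected (e.g. baseline scans only); group
    and covariates are read off the grid index.
    """
    idx = grid.index.reset_index(drop=True)
    available = [c for c in covariate_columns if c in idx.columns]
    mask_flat = np.flatnonzero(grid.geometry.brain_mask.ravel())
    Y = grid.data.reshape(grid.n_scans, -1)[:, mask_flat]
    res = groupwise_glm(
        Y, idx[group_column].to_numpy(), _covar_frame(idx, available),
        alpha=alpha, feature_names=[f"voxel{v}" for v in mask_flat],
    )
    return res


def parcelwise_glm(grid: FeatureGrid, atlas: ParcelAtlas,
                   group_column: str = "subtype",
                   covariate_columns=("age", "sex", "tiv", "latent_time"),
                   alpha: float = 0.05) -> StatMapResult:
    """Subtype GLM on parcel-mean features; BH within this parcellation."""
    idx = grid.index.reset_index(drop=True)
    available = [c for c in covariate_columns if c in idx.columns]
    means = parcel_means(grid, atlas)
    names = [atlas.names[pid] for pid in atlas.parcel_ids]
    Y = means[names].to_numpy(dtype=float)
    return groupwise_glm(
        Y, idx[group_column].to_numpy(), _covar_frame(idx, available),
        alpha=alpha, feature_names=names,
    )
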