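"""Normalization, missing-value handling, batch adjustment, PCA diagnostics.

The normalization chain is the standard two-step used for untargeted
relative abundances: a generalized logarithm (variance stabilization,
finite at zero) followed by per-feature auto-scaling to zero mean and
unit standard deviation. Fitted scaling parameters are recorded so a
replication cohort can either be scaled with its own parameters or with
the discovery cohort's.

Batch adjustment is a transparent per-feature location-scale correction
on the glog scale: within each batch, a shared feature is re-centred and
re-scaled to the pooled grand mean and pooled standard deviation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import FeatureTable


@dataclass
class TransformParams:
    """Fitted normalization parameters (for reuse on held-out data)."""

    glog_a: float
    scale_means: pd.Series | None = None
    scale_sds: pd.Series | None = None


def glog_transform(table: FeatureTable, a: float = 1.0) -> FeatureTable:
    """Generalized log: x -> log2((x + sqrt(x^2 + a^2)) / 2).

    Strictly increasing, defined at zero (glog(0) = log2(a/2)), and
    asymptotically equal to log2(x) for x >> a.
    """
    if a <= 0:
        raise ValueError("glog offset a must be positive")
    if table.transform_state != "raw":
        raise ValueError(f"glog expects a raw table, got {table.transform_state!r}")
    x = table.abundances.to_numpy(dtype=float)
    out = np.log2((x + np.sqrt(x * x + a * a)) / 2.0)
    return table.with_abundances(
        pd.DataFrame(out, index=table.abundances.index, columns=table.abundances.columns),
        transform_state="glog",
    )


def autoscale(table: FeatureTable, params: TransformParams | None = None) -> tuple[FeatureTable, TransformParams]:
    """Per-feature standardization to mean 0, sd 1 (sample sd, n-1).

    Zero-variance features cannot be scaled and are dropped with a
    warning. Pass fitted ``params`` to apply a previous cohort's
    centring/scaling instead of refitting.
    """
    if table.transform_state != "glog":
        raise ValueError(f"autoscale expects a glog table, got {table.transform_state!r}")
    if table.n_samples < 2:
        raise ValueError("autoscaling needs at least 2 samples")
    X = table.abundances
    if params is not None and params.scale_means is not None:
        means = params.scale_means.reindex(X.columns)
        sds = params.scale_sds.reindex(X.columns)
        if means.isna().any():
            missing = means.index[means.isna()].tolist()
            raise KeyError(f"fitted parameters missing for feature(s): {missing}")
    else:
        means = X.mean(axis=0)
        sds = X.std(axis=0, ddof=1)
    keep = sds > 0
    if not keep.all():
        dropped = sds.index[~keep].tolist()
        warnings.warn(f"dropping {len(dropped)} zero-variance feature(s): {dropped}")
    X = X.loc[:, keep]
    scaled = (X - means[keep]) / sds[keep]
    out = table.with_abundances(scaled).with_transform_state("autoscaled")
    return out, TransformParams(glog_a=np.nan, scale_means=means[keep], scale_sds=sds[keep])


def impute_missing(table: FeatureTable) -> FeatureTable:
    """Half-minimum imputation of non-detects in a raw table.

    Zeros (and NaNs) are replaced by half the feature's minimum positive
    abundance; features with no positive value at all are dropped.
    """
    if table.transform_state != "raw":
        raise ValueError("imputation applies to raw tables")
    X = table.abundances.copy()
    vals = X.to_numpy(dtype=float)
    vals[~np.isfinite(vals)] = 0.0
    pos = np.where(vals > 0, vals, np.inf)
    col_min = pos.min(axis=0)
    all_zero = ~np.isfinite(col_min)
    if all_zero.any():
        dropped = X.columns[all_zero].tolist()
        warnings.warn(f"dropping {len(dropped)} all-zero feature(s): {dropped}")
    fill = np.where(np.isfinite(col_min), col_min / 2.0, 0.0)
    vals = np.where(vals > 0, vals, fill[None, :])
    out = pd.DataFrame(vals, index=X.index, columns=X.columns).loc[:, ~all_zero]
    return table.with_abundances(out)


def batch_correct(tables: list[FeatureTable]) -> list[FeatureTable]:
    """Location-scale batch adjustment of shared features.

    All tables must be on the same (glog) scale. For every feature label
    present in two or more tables, each batch's values are mapped to the
    pooled grand mean and pooled standard deviation:

        x -> (x - mean_batch) / sd_batch * sd_pooled + mean_pooled

    Per-batch feature means are therefore exactly equal afterwards.
    Features unique to one table pass through unchanged with a warning.
    """
    if len(tables) < 2:
        raise ValueError("batch correction needs at least 2 tables")
    states = {t.transform_state for t in tables}
    if len(states) != 1:
        raise ValueError(f"tables are on different scales: {states}")
    shared = set(tables[0].features.index)
    union = set(tables[0].features.index)
    for t in tables[1:]:
        shared &= set(t.features.index)
        union |= set(t.features.index)
    if not shared:
        raise ValueError("no shared features across batches; nothing to correct")
    unshared = union - shared
    if unshared:
        warnings.warn(f"{len(unshared)} feature(s) not shared across batches pass through unchanged")

    shared_order = [f for f in tables[0].features.index if f in shared]
    pooled = pd.concat([t.abundances[shared_order] for t in tables], axis=0)
    grand_mean = pooled.mean(axis=0)
    # population sds: identical batches are then an exact fixed point
    grand_sd = pooled.std(axis=0, ddof=0)
    out = []
    for t in tables:
        X = t.abundances.copy()
        bm = X[shared_order].mean(axis=0)
        bs = X[shared_order].std(axis=0, ddof=0)
        bs = bs.where(bs > 0, 1.0)  # constant-within-batch: shift only
        gs = grand_sd.where(grand_sd > 0, 1.0)
        X[shared_order] = (X[shared_order] - bm) / bs * gs + grand_mean
        out.append(t.with_abundances(X))
    return out


def pca_scores(table: FeatureTable, n_components: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """SVD-based PCA sample scores and component variance fractions.

    Used as a before/after batch-correction diagnostic. The sign of each
    component is fixed so its largest-magnitude loading is positive.
    Returns ``(scores, variance_fractions)`` with ``scores`` of shape
    ``(n_samples, n_components)``.
    """
    if table.transform_state != "autoscaled":
        raise ValueError("PCA diagnostic expects an autoscaled table")
    X = table.abundances.to_numpy(dtype=float)
    max_rank = min(X.shape)
    if n_components > max_rank:
        raise ValueError(f"n_components={n_components} exceeds min(n_samples, n_features)={max_rank}")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign: largest-|loading| entry of each component positive
    for k in range(n_components):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    scores = U[:, :n_components] * s[:n_components]
    var = s**2
    frac = var[:n_components] / var.sum() if var.sum() > 0 else np.zeros(n_components)
    return scores, frac
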