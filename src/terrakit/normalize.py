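"""Cross-sample normalization of merged gene + TERRA count tables.

TERRA expression is compared across tissues and cell types by merging the
TERRA region counts with ordinary gene counts into one expression table,
dropping genes below an expression floor, and applying smooth quantile
normalization. Smooth quantile normalization interpolates, rank by rank,
between the classical quantile-normalization reference (the cross-sample
mean of the sorted values) and group-specific references, weighting by
how much of the variance at that rank lies between groups: ranks where
groups genuinely differ keep their group reference, ranks where they do
not are pulled to the global one.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd


@dataclass
class ExpressionMatrix:
    """Features x samples expression values with per-sample group labels."""

    values: pd.DataFrame
    groups: pd.Series
    stage: str = "raw"
    terra_features: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.groups = pd.Series(self.groups)
        missing = set(self.values.columns) - set(self.groups.index)
        if missing:
            raise ValueError(f"samples without group labels: {sorted(missing)}")
        self.groups = self.groups[self.values.columns]
        if self.groups.isna().any() or (self.groups == "").any():
            raise ValueError("group labels must be non-empty")

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


def filter_low_expression(
    m: ExpressionMatrix,
    cpm_threshold: float = 1.0,
    library_sizes: pd.Series | None = None,
    aggregator: str = "mean",
) -> ExpressionMatrix:
    """Drop features below the expression floor in every group.

    A feature is retained iff its group-aggregated CPM (mean by default)
    reaches ``cpm_threshold`` in at least one group. TERRA features (the
    analyte) are always retained. Library sizes default to per-sample
    column sums of the raw counts.
    """
    if aggregator not in ("mean", "median"):
        raise ValueError("aggregator must be 'mean' or 'median'")
    if library_sizes is None:
        library_sizes = m.values.sum(axis=0)
    library_sizes = pd.Series(library_sizes)[m.samples].astype(float)
    if (library_sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    cpm = m.values * 1e6 / library_sizes
    agg = cpm.T.groupby(m.groups).mean() if aggregator == "mean" else \
        cpm.T.groupby(m.groups).median()
    keep = (agg >= cpm_threshold).any(axis=0)
    keep |= m.values.index.to_series().isin(m.terra_features)
    return replace(m, values=m.values.loc[keep])


def _running_median(x: np.ndarray, window: int) -> np.ndarray:
    """Centered running median; window ends copy the nearest fully
    computed value."""
    n = len(x)
    window = max(1, min(window, n))
    if window == 1:
        return x.copy()
    half = window // 2
    out = np.empty(n)
    lo = half
    hi = n - (window - 1 - half)
    for i in range(lo, hi):
        out[i] = np.median(x[i - half : i - half + window])
    if hi <= lo:  # window covers everything
        out[:] = np.median(x)
        return out
    out[:lo] = out[lo]
    out[hi:] = out[hi - 1]
    return out


def qsmooth_normalize(
    m: ExpressionMatrix, window_frac: float = 0.05
) -> ExpressionMatrix:
    """Smooth quantile normalization.

    Per rank u over the sorted per-sample value vectors: the global
    reference is the cross-sample mean Q̄_u and each group's reference is
    its group mean Q̄_{g,u}. The raw weight 1 - SSB_u/SST_u (between-group
    over total sum of squares across samples at rank u; 1 when SST_u = 0)
    is smoothed by a running median over ``ceil(window_frac * n_ranks)``
    ranks and clamped to [0, 1]; the normalized sorted value for a sample
    in group g is w_u * Q̄_u + (1 - w_u) * Q̄_{g,u}. Values are mapped
    back to each sample's original feature order, ties receiving the mean
    of their tied normalized values. Within each sample the ordering of
    values is preserved.
    """
    if not 0 < window_frac <= 1:
        raise ValueError("window_frac must be in (0, 1]")
    X = m.values.to_numpy(dtype=float)
    n_feat, n_samp = X.shape
    if n_samp < 2:
        raise ValueError("need at least 2 samples")
    groups = m.groups.to_numpy()
    uniq = pd.unique(groups)

    order = np.argsort(X, axis=0, kind="stable")
    Q = np.take_along_axis(X, order, axis=0)  # sorted columns

    qbar = Q.mean(axis=1)
    group_means = np.empty((n_feat, len(uniq)))
    group_idx = {g: np.flatnonzero(groups == g) for g in uniq}
    for j, g in enumerate(uniq):
        group_means[:, j] = Q[:, group_idx[g]].mean(axis=1)

    sst = ((Q - qbar[:, None]) ** 2).sum(axis=1)
    ssb = np.zeros(n_feat)
    for j, g in enumerate(uniq):
        n_g = len(group_idx[g])
        ssb += n_g * (group_means[:, j] - qbar) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        w_raw = np.where(sst > 0, 1.0 - ssb / sst, 1.0)
    window = int(np.ceil(window_frac * n_feat))
    w = np.clip(_running_median(w_raw, window), 0.0, 1.0)

    norm_sorted = np.empty_like(Q)
    for j, g in enumerate(uniq):
        cols = group_idx[g]
        target = w * qbar + (1 - w) * group_means[:, j]
        norm_sorted[:, cols] = target[:, None]

    out = np.empty_like(X)
    rows = np.arange(n_feat)
    for s in range(n_samp):
        col = np.empty(n_feat)
        col[order[:, s]] = norm_sorted[:, s]
        # ties in the input receive the mean of their tied normalized values
        vals = X[:, s]
        if len(np.unique(vals)) != n_feat:
            df = pd.DataFrame({"v": vals, "n": col})
            col = df.groupby("v")["n"].transform("mean").to_numpy()
        out[:, s] = col
    values = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    return replace(m, values=values, stage="normalized")
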