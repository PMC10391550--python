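"""Per-cell feature matrix, correlation filtering, PCA, and CRH trajectories.

The cohort workflow condenses each cell into twelve excitability parameters.
Before PCA, redundant parameters are removed: any pair correlating at or
above 0.8 flags the member with the highest overall mean absolute
correlation for removal (greedily, until no pair exceeds the cutoff), or a
named set can be removed directly.  PCA standardizes the remaining columns
and eigendecomposes their correlation structure; a deterministic sign
convention (the largest-magnitude loading of each component is positive)
makes scores reproducible across platforms.  Basal-to-stimulated
trajectories are per-cell displacements in the joint PC plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FeatureMatrix",
    "PCAResult",
    "transform_features",
    "correlation_filter",
    "run_pca",
    "trajectories",
]


@dataclass
class FeatureMatrix:
    """Cells-by-features numeric table with per-cell labels."""

    data: pd.DataFrame                  # numeric feature columns only
    labels: pd.DataFrame | None = None  # sex/condition/etc., same index
    log_columns: tuple[str, ...] = ()
    removal_log: tuple[str, ...] = ()
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.columns.duplicated().any():
            raise ValueError("feature names must be unique")
        if not all(np.issubdtype(dt, np.number) for dt in self.data.dtypes):
            raise ValueError("feature columns must be numeric")

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)


def transform_features(matrix: FeatureMatrix,
                       log_columns: Sequence[str]) -> FeatureMatrix:
    """Natural-log transform the named columns.

    Columns containing zeros use log(x + eps) with eps set to half the
    smallest positive observed value in that column; the offsets used are
    recorded in the output metadata.  Negative values are rejected.
    """
    data = matrix.data.copy()
    offsets: dict[str, float] = {}
    for col in log_columns:
        x = data[col].to_numpy(dtype=float)
        if (x < 0).any():
            raise ValueError(f"column {col!r} contains negative values; "
                             "cannot log-transform")
        eps = 0.0
        if (x == 0).any():
            positive = x[x > 0]
            if positive.size == 0:
                raise ValueError(f"column {col!r} is all zeros")
            eps = float(positive.min()) / 2.0
        data[col] = np.log(x + eps)
        offsets[col] = eps
    meta = dict(matrix.meta)
    meta["log_offsets"] = offsets
    return FeatureMatrix(data=data, labels=matrix.labels,
                         log_columns=tuple(log_columns),
                         removal_log=matrix.removal_log, meta=meta)


def correlation_filter(matrix: FeatureMatrix, cutoff: float = 0.8,
                       remove: Sequence[str] | None = None) -> FeatureMatrix:
    """Drop highly correlated features.

    With ``remove`` given, drops exactly that named set (replication mode).
    Otherwise, greedily: while some pair has |Pearson r| >= cutoff, drop the
    member of an offending pair with the largest mean absolute correlation
    against all remaining columns.  Constant columns have undefined
    correlations, which are treated as zero (with a warning).
    """
    if remove is not None:
        missing = set(remove) - set(matrix.columns)
        if missing:
            raise KeyError(f"columns not present: {sorted(missing)}")
        data = matrix.data.drop(columns=list(remove))
        return FeatureMatrix(data=data, labels=matrix.labels,
                             log_columns=matrix.log_columns,
                             removal_log=matrix.removal_log + tuple(remove),
                             meta=matrix.meta)
    if len(matrix.columns) < 2 or len(matrix.data) < 3:
        raise ValueError("need at least 2 features and 3 cells")

    data = matrix.data.copy()
    removed: list[str] = []
    while True:
        corr = data.corr().to_numpy()
        if np.isnan(corr).any():
            import warnings
            warnings.warn("constant column: undefined correlations treated as 0")
            corr = np.nan_to_num(corr)
        np.fill_diagonal(corr, 0.0)
        acorr = np.abs(corr)
        over = acorr >= cutoff
        if not over.any():
            break
        involved = np.flatnonzero(over.any(axis=0))
        # Primary score: mean |r| over a column's over-cutoff partners.
        # Ties (e.g. the two members of an isolated pair) break toward the
        # column with the larger mean |r| against everything else, then
        # toward the later column, keeping removal deterministic.
        pair_score = np.array([acorr[i, over[i]].mean() for i in involved])
        overall = acorr.mean(axis=1)[involved]
        order = pair_score + 1e-6 * overall + 1e-12 * involved
        worst = involved[int(np.argmax(order))]
        removed.append(data.columns[worst])
        data = data.drop(columns=[data.columns[worst]])
    return FeatureMatrix(data=data, labels=matrix.labels,
                         log_columns=matrix.log_columns,
                         removal_log=matrix.removal_log + tuple(removed),
                         meta=matrix.meta)


@dataclass
class PCAResult:
    scores: pd.DataFrame              # cells x components
    loadings: pd.DataFrame            # features x components
    variance_explained: np.ndarray    # fraction per component
    mean: pd.Series
    scale: pd.Series

    def project(self, data: pd.DataFrame) -> pd.DataFrame:
        """Project new rows using the fitted centering/scaling/loadings."""
        z = (data[self.mean.index] - self.mean) / self.scale
        s = z.to_numpy() @ self.loadings.to_numpy()
        return pd.DataFrame(s, index=data.index, columns=self.scores.columns)


def run_pca(matrix: FeatureMatrix, n_components: int | None = None) -> PCAResult:
    """PCA on standardized features via SVD.

    Columns are centred and scaled to unit variance (features carry
    incommensurate units), so this is an eigendecomposition of the
    correlation matrix.  Components are ordered by variance; each loading
    vector is flipped so its largest-magnitude entry is positive.
    """
    X = matrix.data.to_numpy(dtype=float)
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least 2 rows")
    sd = X.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        names = [matrix.columns[i] for i in zero]
        raise ValueError(f"zero-variance feature(s): {names}")
    if n < p:
        import warnings
        warnings.warn(f"fewer cells ({n}) than features ({p}); "
                      "components beyond rank are degenerate")
    mu = X.mean(axis=0)
    Z = (X - mu) / sd
    _, s, Vt = np.linalg.svd(Z, full_matrices=False)
    var = s ** 2 / (n - 1)
    frac = var / Z.var(axis=0, ddof=1).sum()
    k = min(n_components or p, Vt.shape[0])
    V = Vt[:k].T
    # Sign convention: largest-|loading| entry of each component positive.
    for j in range(k):
        i = int(np.argmax(np.abs(V[:, j])))
        if V[i, j] < 0:
            V[:, j] = -V[:, j]
    comps = [f"PC{i + 1}" for i in range(k)]
    scores = pd.DataFrame(Z @ V, index=matrix.data.index, columns=comps)
    loadings = pd.DataFrame(V, index=matrix.columns, columns=comps)
    return PCAResult(scores=scores, loadings=loadings,
                     variance_explained=frac[:k],
                     mean=pd.Series(mu, index=matrix.columns),
                     scale=pd.Series(sd, index=matrix.columns))


def trajectories(basal_scores: pd.DataFrame, stim_scores: pd.DataFrame,
                 labels: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-cell displacement in PC space from basal to stimulated state.

    Both score tables must be indexed by cell id, one row per cell.  Returns
    a table of delta-PC columns, joined with labels when given.
    """
    missing = set(basal_scores.index) ^ set(stim_scores.index)
    if missing:
        raise ValueError(f"unmatched cell ids: {sorted(missing)[:5]}")
    stim = stim_scores.loc[basal_scores.index]
    disp = stim - basal_scores
    disp.columns = [f"d{c}" for c in disp.columns]
    if labels is not None:
        disp = disp.join(labels)
    return disp
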