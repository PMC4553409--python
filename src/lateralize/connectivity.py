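"""ROI time series, nuisance regression and Fisher-z functional connectivity."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .images import BoldImage, Parcellation

__all__ = [
    "RoiTimeseries",
    "ConnectivityMatrix",
    "extract_roi_timeseries",
    "regress_nuisance",
    "fc_matrix",
    "candidate_fc_filter",
    "CLIP_R",
]

# Degenerate correlations are clipped here before atanh so Fisher z stays finite.
CLIP_R = 1.0 - 1e-7


@dataclass
class RoiTimeseries:
    """Region-mean time courses: a T x R matrix plus the ROI id per column."""

    data: np.ndarray
    roi_ids: list[int]
    tr: float
    missing: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("RoiTimeseries.data must be T x R")
        if self.data.shape[1] != len(self.roi_ids):
            raise ValueError("number of columns must match roi_ids")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]


@dataclass
class ConnectivityMatrix:
    """Symmetric R x R Fisher-z connectivity; the diagonal is excluded (0)."""

    z: np.ndarray
    roi_ids: list[int]

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)

    @property
    def r(self) -> np.ndarray:
        """Back-transformed Pearson correlations, tanh(z)."""
        return np.tanh(self.z)

    def to_frame(self, names: dict[int, str] | None = None) -> pd.DataFrame:
        labels = [names.get(i, f"R{i}") if names else f"R{i}" for i in self.roi_ids]
        return pd.DataFrame(self.z, index=labels, columns=labels)


def extract_roi_timeseries(bold: BoldImage, parcellation: Parcellation) -> RoiTimeseries:
    """Average the BOLD signal over each atlas region.

    Regions with no in-mask voxels produce an all-NaN column, recorded in
    ``missing``. Raises if the mask overlaps no region at all.
    """
    if bold.grid != parcellation.labels.shape:
        raise ValueError("BOLD and parcellation grids differ")
    roi_ids = [int(r) for r in parcellation.region_ids]
    T = bold.n_timepoints
    data = np.full((T, len(roi_ids)), np.nan)
    missing = []
    for col, roi in enumerate(roi_ids):
        vox = (parcellation.labels == roi) & bold.mask
        if vox.any():
            data[:, col] = bold.data[vox].mean(axis=0)
        else:
            missing.append(roi)
    if len(missing) == len(roi_ids):
        raise ValueError("brain mask overlaps no atlas region")
    return RoiTimeseries(data=data, roi_ids=roi_ids, tr=bold.tr, missing=missing)


def _with_intercept(confounds: np.ndarray) -> np.ndarray:
    has_const = np.any(np.all(confounds == confounds[0:1, :], axis=0) &
                       np.any(confounds != 0, axis=0))
    if has_const:
        return confounds
    return np.column_stack([np.ones(confounds.shape[0]), confounds])


def regress_nuisance(ts: RoiTimeseries, confounds) -> RoiTimeseries:
    """Replace each ROI column by its OLS residual against the confounds.

    An intercept is added if absent. Collinear confound columns are dropped
    with a warning. Residuals are orthogonal to every retained confound.
    """
    X = np.asarray(confounds, dtype=float)
    if isinstance(confounds, pd.DataFrame):
        X = confounds.to_numpy(dtype=float)
    if X.ndim != 2 or X.shape[0] != ts.n_timepoints:
        raise ValueError("confounds must be T x C with T matching the time series")
    X = _with_intercept(X)
    if X.shape[1] >= ts.n_timepoints:
        raise ValueError("more confound columns than timepoints")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # Greedy rank-preserving column drop.
        keep: list[int] = []
        for j in range(X.shape[1]):
            trial = X[:, keep + [j]]
            if np.linalg.matrix_rank(trial) > len(keep):
                keep.append(j)
        warnings.warn(
            f"dropping {X.shape[1] - len(keep)} collinear confound column(s)",
            stacklevel=2,
        )
        X = X[:, keep]
    Y = ts.data
    finite_cols = ~np.isnan(Y).any(axis=0)
    resid = np.full_like(Y, np.nan)
    if finite_cols.any():
        beta, *_ = np.linalg.lstsq(X, Y[:, finite_cols], rcond=None)
        resid[:, finite_cols] = Y[:, finite_cols] - X @ beta
    return RoiTimeseries(data=resid, roi_ids=list(ts.roi_ids), tr=ts.tr,
                         missing=list(ts.missing))


def fc_matrix(ts: RoiTimeseries) -> ConnectivityMatrix:
    """Pearson correlation of ROI columns, Fisher z transformed.

    |r| is clipped to ``CLIP_R`` before atanh. Zero-variance or missing
    columns yield NaN rows/columns (recorded as missing connectivity).
    """
    if ts.n_timepoints < 3:
        raise ValueError("need at least 3 timepoints for correlation")
    Y = ts.data
    sd = np.nanstd(Y, axis=0)
    ok = np.isfinite(sd) & (sd > 0) & ~np.isnan(Y).any(axis=0)
    R = ts.n_regions
    z = np.full((R, R), np.nan)
    if ok.sum() >= 2:
        r = np.corrcoef(Y[:, ok], rowvar=False)
        r = np.clip(r, -CLIP_R, CLIP_R)
        zi = np.arctanh(r)
        idx = np.flatnonzero(ok)
        z[np.ix_(idx, idx)] = zi
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(z=z, roi_ids=list(ts.roi_ids))


def one_sample_t_mask(values: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Two-sided one-sample t-test of each column against 0; True where p < alpha.

    Degenerate columns: zero variance with nonzero mean is significant
    (infinite t), zero variance with zero mean is not. ``values`` is
    n_observations x n_features.
    """
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    if n < 3:
        raise ValueError("need at least 3 observations for the candidate t-test")
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    sig = p < alpha
    zero_var = sd == 0
    sig[zero_var] = mean[zero_var] != 0
    sig[np.isnan(values).any(axis=0)] = False
    return sig


def candidate_fc_filter(train_z: list[ConnectivityMatrix], alpha: float = 0.05) -> np.ndarray:
    """Boolean R x R candidate mask: connections whose training-subject
    z-values differ from 0 by a two-sided one-sample t-test at ``alpha``.

    Computed from training subjects only (call per cross-validation fold).
    The mask is symmetric with a False diagonal; upper-triangle True entries
    enumerate the candidate bivariate features.
    """
    if len(train_z) < 3:
        raise ValueError("need at least 3 training subjects")
    stack = np.stack([m.z for m in train_z])  # n x R x R
    n, R, _ = stack.shape
    sig = one_sample_t_mask(stack.reshape(n, R * R), alpha).reshape(R, R)
    sig = sig & sig.T
    np.fill_diagonal(sig, False)
    return sig
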