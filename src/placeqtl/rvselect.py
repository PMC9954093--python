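"""Per-gene normalization, covariate regression, and residual-variance gene
set construction.

Residual variance (RV) of a gene is the fraction of its rank/quantile
normalized expression variance left unexplained by the covariate-only OLS fit
(RV = RSS/TSS = 1 - R^2, computed on the normalized response).  Genes with
high RV retain room for genetic effects; the incremental RV thresholds define
the nested input gene sets of the cis scan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy.special import ndtri
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

RV_GRID = tuple(np.round(np.arange(0.50, 0.951, 0.05), 2))


def rank_quantile_normalize(x) -> np.ndarray:
    """Map a vector to normal quantiles by average-tied ranks:
    z_i = Phi^-1(rank_i / (n + 1)).  A constant vector maps to all zeros
    (flagged unusable)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 values")
    if np.ptp(x) == 0:
        logger.warning("constant vector in rank_quantile_normalize; returning zeros")
        return np.zeros(n)
    ranks = rankdata(x, method="average")
    return ndtri(ranks / (n + 1))


def normalize_expression(values: pd.DataFrame) -> pd.DataFrame:
    """Row-wise rank/quantile normalization of a genes x samples matrix."""
    out = np.vstack([rank_quantile_normalize(row) for row in values.to_numpy(dtype=float)])
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def _check_full_rank(x: np.ndarray, names: list) -> None:
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # name the offending columns via QR pivoting
        _, r, piv = sla.qr(x, pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(x.shape) * np.finfo(float).eps
        bad = [names[j] for j in piv[rank:]] if diag.size else names
        raise ValueError(f"design matrix is rank-deficient; collinear columns: {bad}")


def covariate_regress(e_norm: pd.DataFrame, design: pd.DataFrame):
    """Per-gene OLS of normalized expression on [1 | covariates].

    Returns (residuals genes x samples, rv Series).  Errors if the design is
    rank-deficient, naming the collinear columns.
    """
    y = e_norm.to_numpy(dtype=float)  # genes x samples
    c = design.loc[e_norm.columns].to_numpy(dtype=float)
    x = np.column_stack([np.ones(c.shape[0]), c])
    _check_full_rank(x, ["(intercept)"] + list(design.columns))
    coef, *_ = np.linalg.lstsq(x, y.T, rcond=None)
    resid = (y.T - x @ coef).T  # genes x samples
    rss = np.sum(resid**2, axis=1)
    tss = np.sum((y - y.mean(axis=1, keepdims=True)) ** 2, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rv = np.where(tss > 0, rss / tss, np.nan)
    if np.isnan(rv).any():
        logger.warning("%d constant gene(s): rv undefined", int(np.isnan(rv).sum()))
    residuals = pd.DataFrame(resid, index=e_norm.index, columns=e_norm.columns)
    return residuals, pd.Series(rv, index=e_norm.index, name="rv")


@dataclass
class RvTable:
    """Per-gene residual variance with nested threshold memberships."""

    rv: pd.Series
    membership: pd.DataFrame  # genes x thresholds, boolean

    def gene_set(self, tau: float) -> list:
        col = self._col(tau)
        return list(self.membership.index[self.membership[col]])

    def counts(self) -> pd.Series:
        return self.membership.sum(axis=0)

    def _col(self, tau: float) -> str:
        col = f"RV{tau:.2f}"
        if col not in self.membership.columns:
            raise KeyError(f"threshold {tau} not in grid")
        return col


def rv_gene_sets(rv: pd.Series, grid=RV_GRID) -> RvTable:
    """Membership flags rv >= tau for each threshold; sets are nested."""
    member = pd.DataFrame(
        {f"RV{t:.2f}": rv >= t for t in grid}, index=rv.index
    )
    return RvTable(rv=rv, membership=member)
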