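"""Expression preprocessing and covariate discovery.

Covers probe filtering by mean log2 intensity, within-group covariate
imputation, expression PCA (centred genes, optional unit scaling), the
PC-vs-covariate Pearson correlation report, surrogate-variable estimation by
permutation parallel analysis + residual SVD, and greedy collinearity pruning
of the covariate set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import CLINICAL_COLUMNS, CovariateTable, ExpressionMatrix

logger = logging.getLogger(__name__)


def filter_probes(e: ExpressionMatrix, min_mean: float = 4.5) -> ExpressionMatrix:
    """Keep genes whose mean log2 intensity across samples is >= ``min_mean``
    (inclusive boundary); input order preserved; idempotent."""
    if e.values.shape[0] == 0:
        raise ValueError("empty expression matrix")
    keep = e.values.mean(axis=1) >= min_mean
    return e.subset_genes(e.values.index[keep])


def impute_covariates(c: CovariateTable, group_column: str = "Group") -> CovariateTable:
    """Replace missing values with the within-group mean (numeric) or mode
    (categorical; ties broken by the smallest code).  Falls back to the global
    statistic when a group's column is entirely missing."""
    if c.data[group_column].isna().any():
        raise ValueError("group column must be complete")
    data = c.data.copy()
    categorical = set(c.encodings)
    for col in data.columns:
        if not data[col].isna().any():
            continue
        for grp, sub in data.groupby(group_column):
            idx = sub.index[sub[col].isna()]
            if len(idx) == 0:
                continue
            observed = sub[col].dropna()
            if len(observed) == 0:
                observed = data[col].dropna()
                logger.warning("group %s has no observed %s; using global statistic", grp, col)
            if col in categorical:
                counts = observed.value_counts()
                top = counts.max()
                fill = min(v for v, n in counts.items() if n == top)
            else:
                fill = observed.mean()
            data.loc[idx, col] = fill
    return CovariateTable(data, dict(c.encodings))


def _fix_signs(u: np.ndarray, vt: np.ndarray, k: int) -> None:
    for j in range(k):
        if vt[j, np.argmax(np.abs(vt[j]))] < 0:
            u[:, j] *= -1
            vt[j] *= -1


def expression_pca(e: ExpressionMatrix, n_pcs: int = 10, scale: bool = False):
    """Sample-space PCA of the expression matrix.

    Genes are centred (and optionally unit-scaled); scores are per-sample with
    a deterministic sign convention (largest-|loading| gene positive).
    """
    x = e.values.to_numpy(dtype=float).T  # samples x genes
    n = x.shape[0]
    if n < 3:
        raise ValueError("expression PCA requires at least 3 samples")
    x = x - x.mean(axis=0)
    if scale:
        sd = x.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        x = x / sd
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    k = min(n_pcs, n - 1, x.shape[1])
    _fix_signs(u, vt, k)
    scores = pd.DataFrame(
        u[:, :k] * s[:k],
        index=e.values.columns,
        columns=[f"ExprPC{i + 1}" for i in range(k)],
    )
    varexp = pd.Series(s[:k] ** 2 / np.sum(s**2), index=scores.columns, name="variance_explained")
    return scores, varexp


@dataclass
class CorrelationReport:
    r: pd.DataFrame
    p: pd.DataFrame
    stars: pd.DataFrame
    removed: list


def _pearson_rp(x: np.ndarray, y: np.ndarray):
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan, np.nan
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(min(r, 1.0), -1.0)
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1 - r * r))
    return r, float(2 * stats.t.sf(abs(t), df=n - 2))


def _star(p: float) -> str:
    if np.isnan(p):
        return ""
    return "***" if p <= 0.001 else "**" if p <= 0.01 else "*" if p <= 0.05 else ""


def eigencor(scores: pd.DataFrame, c: CovariateTable | pd.DataFrame) -> CorrelationReport:
    """Pearson r and two-sided p between every PC score and covariate column
    (plus all within-set pairs), with 0.05/0.01/0.001 significance stars."""
    cov = c.data if isinstance(c, CovariateTable) else c
    cols = list(scores.columns) + list(cov.columns)
    joined = scores.join(cov, how="inner")
    m = len(cols)
    r = np.ones((m, m))
    p = np.zeros((m, m))
    arr = joined[cols].to_numpy(dtype=float)
    for a in range(m):
        for b in range(a + 1, m):
            r[a, b], p[a, b] = _pearson_rp(arr[:, a], arr[:, b])
            r[b, a], p[b, a] = r[a, b], p[a, b]
    rr = pd.DataFrame(r, index=cols, columns=cols)
    pp = pd.DataFrame(p, index=cols, columns=cols)
    ss = pp.map(_star)
    return CorrelationReport(rr, pp, ss, [])


def estimate_svs(
    e: ExpressionMatrix,
    primary: pd.Series,
    n_perm: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    max_svs: int | None = None,
):
    """Surrogate variables by the two-step construction.

    1. The number of SVs comes from permutation parallel analysis on the
       singular values of the residual matrix after removing the primary
       variable fit (``n_perm`` within-gene permutations, level ``alpha``).
    2. The SVs are the corresponding top right-singular vectors of that
       residual matrix (mutually orthogonal by construction).

    The iteratively reweighted refinement of the reference procedure is not
    applied; this is the plain parallel-analysis + residual-SVD estimator.
    """
    y = e.values.to_numpy(dtype=float)  # genes x samples
    samples = list(e.values.columns)
    x = np.column_stack([np.ones(len(samples)), primary.loc[samples].to_numpy(dtype=float)])
    coef, *_ = np.linalg.lstsq(x, y.T, rcond=None)
    resid = y.T - x @ coef  # samples x genes
    rank_mod = np.linalg.matrix_rank(x)
    cap = resid.shape[0] - rank_mod
    if max_svs is not None:
        cap = min(cap, max_svs)

    scale = max(np.abs(y).max(), 1.0)
    if np.abs(resid).max() <= 1e-10 * scale:  # primary variable explains everything
        return pd.DataFrame(index=samples)
    s_obs = np.linalg.svd(resid, compute_uv=False)
    d_obs = s_obs**2 / np.sum(s_obs**2)
    rng = np.random.default_rng(seed)
    d_perm = np.zeros((n_perm, len(d_obs)))
    for b in range(n_perm):
        perm = np.empty_like(resid)
        for gj in range(resid.shape[1]):
            perm[:, gj] = rng.permutation(resid[:, gj])
        coef_b, *_ = np.linalg.lstsq(x, perm, rcond=None)
        s_b = np.linalg.svd(perm - x @ coef_b, compute_uv=False)
        d_perm[b] = s_b**2 / np.sum(s_b**2)

    n_sv = 0
    for j in range(min(cap, len(d_obs))):
        thresh = np.quantile(d_perm[:, j], 1 - alpha)
        if d_obs[j] > thresh:
            n_sv += 1
        else:
            break
    if n_sv == 0:
        return pd.DataFrame(index=samples)
    u, s, vt = np.linalg.svd(resid, full_matrices=False)
    _fix_signs(u, vt, n_sv)
    return pd.DataFrame(u[:, :n_sv], index=samples, columns=[f"SV{i + 1}" for i in range(n_sv)])


def collinearity_filter(c: CovariateTable, cutoff: float = 0.9, priority: list | None = None):
    """Greedy removal of collinear covariates at |r| >= ``cutoff``.

    Columns are visited in priority order (clinical variables before
    expression PCs before SVs; earlier-listed wins within a class); a column
    is dropped when it correlates at |r| >= cutoff with any already-kept one.
    """
    cols = list(c.data.columns)
    if priority is None:
        clinical = [x for x in CLINICAL_COLUMNS if x in cols]
        pcs = sorted(
            [x for x in cols if x.startswith("ExprPC")], key=lambda s: int(s.removeprefix("ExprPC"))
        )
        svs = sorted([x for x in cols if x.startswith("SV")], key=lambda s: int(s.removeprefix("SV")))
        rest = [x for x in cols if x not in set(clinical + pcs + svs)]
        priority = clinical + pcs + svs + rest
    kept, removed = [], []
    arr = c.data
    for col in priority:
        if np.ptp(arr[col].to_numpy(dtype=float)) == 0:
            logger.info("collinearity: dropping constant column %s", col)
            removed.append(col)
            continue
        drop = False
        for k in kept:
            r, _ = _pearson_rp(arr[col].to_numpy(dtype=float), arr[k].to_numpy(dtype=float))
            if not np.isnan(r) and abs(r) >= cutoff:
                logger.info("collinearity: dropping %s (|r|=%.3f with %s)", col, abs(r), k)
                removed.append(col)
                drop = True
                break
        if not drop:
            kept.append(col)
    out = CovariateTable(c.data[kept].copy(), {k: v for k, v in c.encodings.items() if k in kept})
    return out, removed


def discover_covariates(
    e_filtered: ExpressionMatrix,
    clinical: CovariateTable,
    geno_pcs: pd.DataFrame,
    n_expr_pcs: int = 5,
    collinearity_cutoff: float = 0.9,
    run_sva: bool = False,
    seed: int = 0,
    pca_scale: bool = True,
):
    """Assemble the scan covariate table: imputed clinical variables +
    expression PCs + genotype PCs, collinearity-pruned on the transcriptomic
    side (clinical + expression PCs [+ SVs in the report only]).

    Returns (covariate_table, correlation_report, sv_frame).
    """
    imputed = impute_covariates(clinical)
    scores, _ = expression_pca(e_filtered, n_pcs=max(10, n_expr_pcs), scale=pca_scale)
    svs = (
        estimate_svs(e_filtered, imputed.data["Group"], seed=seed)
        if run_sva
        else pd.DataFrame(index=scores.index)
    )
    report = eigencor(scores, CovariateTable(imputed.data.join(svs), imputed.encodings))
    transcriptomic = CovariateTable(imputed.data.join(scores), imputed.encodings)
    pruned, removed = collinearity_filter(transcriptomic, cutoff=collinearity_cutoff)
    report.removed.extend(removed)
    design_cols = [c for c in pruned.data.columns if not c.startswith("ExprPC")] + [
        f"ExprPC{i + 1}" for i in range(n_expr_pcs) if f"ExprPC{i + 1}" in pruned.data.columns
    ]
    table = CovariateTable(
        pruned.data[design_cols].join(geno_pcs, how="inner"), pruned.encodings
    )
    return table, report, svs
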