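"""Covariate-adjusted cis-eQTL scan.

The scan tests, for every (gene, SNP) pair within a cis window, the genotype
slope in ``expr ~ 1 + covariates + dosage`` on rank/quantile normalized
expression.  It is implemented by residualizing both expression and dosage
against the covariate design and converting the partial correlation to a
t statistic with df = n - k - 2; this is numerically identical to per-pair
OLS.  Benjamini-Hochberg q-values are computed once across all tested pairs.

Organized as a statsmodels-style model: build a :class:`CisEqtlModel` from
the aligned matrices, ``fit()`` returns a :class:`CisEqtlResults`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def build_cis_pairs(gene_meta: pd.DataFrame, snp_meta: pd.DataFrame, window: int = 100_000) -> pd.DataFrame:
    """All (gene, SNP) pairs with SNP pos in [start - window, end + window]
    (1-based inclusive on both ends); distance 0 for SNPs inside the gene."""
    rows = []
    for chrom, snps in snp_meta.groupby("chrom", sort=False):
        genes = gene_meta[gene_meta["chrom"] == chrom]
        pos = snps["pos"].to_numpy()
        order = np.argsort(pos, kind="stable")
        pos_sorted = pos[order]
        ids_sorted = snps.index.to_numpy()[order]
        for gene in genes.itertuples():
            lo = np.searchsorted(pos_sorted, gene.start - window, side="left")
            hi = np.searchsorted(pos_sorted, gene.end + window, side="right")
            for j in range(lo, hi):
                p = int(pos_sorted[j])
                dist = 0 if gene.start <= p <= gene.end else min(abs(p - gene.start), abs(p - gene.end))
                rows.append((gene.Index, ids_sorted[j], dist))
    return pd.DataFrame(rows, columns=["gene", "snp", "distance"])


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values: q_(i) = min_{j>=i} p_(j) m / j,
    capped at 1, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _residualize(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Residuals of each column of y against the column space of x."""
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    return y - x @ coef


class CisEqtlModel:
    """Mass linear model for cis gene-SNP pairs.

    Parameters
    ----------
    expr_norm : DataFrame
        Rank/quantile normalized expression, genes x samples.
    dosage : DataFrame
        Samples x SNPs ALT-allele dosages (NaN = missing call).
    covariates : DataFrame
        Samples x covariates numeric design block (no intercept column).
    pairs : DataFrame
        Output of :func:`build_cis_pairs` (columns gene, snp, distance).
    maf_min : float
        SNPs below this minor allele frequency are excluded from testing.
    missing : {"complete", "mean"}
        Complete-case per pair (default) or mean imputation of missing
        dosages (enables the fast matrix path throughout).
    """

    def __init__(self, expr_norm, dosage, covariates, pairs, maf_min=0.15, missing="complete"):
        if missing not in ("complete", "mean"):
            raise ValueError("missing must be 'complete' or 'mean'")
        samples = list(expr_norm.columns)
        if list(dosage.index) != samples or list(covariates.index) != samples:
            raise ValueError("samples are not aligned across inputs")
        self.expr_norm = expr_norm
        self.dosage = dosage
        self.covariates = covariates
        self.maf_min = maf_min
        self.missing = missing
        self.n_covariates = covariates.shape[1]

        d = dosage.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            f = np.nansum(d, axis=0) / (2.0 * np.sum(~np.isnan(d), axis=0))
        snp_maf = pd.Series(np.minimum(f, 1 - f), index=dosage.columns)
        ok_snps = set(snp_maf.index[snp_maf >= maf_min])
        usable = pairs["snp"].isin(ok_snps) & pairs["gene"].isin(set(expr_norm.index))
        self.pairs = pairs[usable].reset_index(drop=True)
        if len(self.pairs) < len(pairs):
            logger.info(
                "excluded %d pairs (MAF < %g or gene not in input set)",
                len(pairs) - len(self.pairs), maf_min,
            )

    def fit(self) -> "CisEqtlResults":
        y_all = self.expr_norm.to_numpy(dtype=float)
        d_all = self.dosage.to_numpy(dtype=float)
        n = y_all.shape[1]
        k = self.n_covariates
        df = n - k - 2
        if df < 1:
            raise ValueError("not enough samples for the covariate design")
        x = np.column_stack([np.ones(n), self.covariates.to_numpy(dtype=float)])
        gene_row = {g: i for i, g in enumerate(self.expr_norm.index)}
        snp_col = {s: j for j, s in enumerate(self.dosage.columns)}

        if self.missing == "mean":
            mu = np.nanmean(d_all, axis=0)
            d_all = np.where(np.isnan(d_all), mu, d_all)

        ry = _residualize(y_all.T, x)  # samples x genes
        snp_has_na = np.isnan(d_all).any(axis=0)
        rd = _residualize(np.where(np.isnan(d_all), 0.0, d_all), x)  # valid where no NA

        gi = self.pairs["gene"].map(gene_row).to_numpy()
        sj = self.pairs["snp"].map(snp_col).to_numpy()

        beta = np.full(len(self.pairs), np.nan)
        tstat = np.full(len(self.pairs), np.nan)
        pval = np.full(len(self.pairs), np.nan)
        dfs = np.full(len(self.pairs), df, dtype=float)

        fast = ~snp_has_na[sj] if self.missing == "complete" else np.ones(len(self.pairs), bool)
        if fast.any():
            yv = ry[:, gi[fast]]
            dv = rd[:, sj[fast]]
            dd = np.sum(dv * dv, axis=0)
            yy = np.sum(yv * yv, axis=0)
            yd = np.sum(yv * dv, axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                ok = dd > 1e-12
                b = np.where(ok, yd / dd, np.nan)
                r = np.where(ok, yd / np.sqrt(dd * yy), np.nan)
                r = np.clip(r, -1.0, 1.0)
                t = r * np.sqrt(df / np.maximum(1 - r * r, 1e-300))
            beta[fast], tstat[fast] = b, t
            pval[fast] = 2 * stats.t.sf(np.abs(t), df=df)
            if (~ok).any():
                logger.info("%d pairs skipped: constant dosage after residualization", int((~ok).sum()))

        for idx in np.nonzero(~fast)[0]:  # complete-case per pair
            dcol = d_all[:, sj[idx]]
            keep = ~np.isnan(dcol)
            nn = int(keep.sum())
            dfi = nn - k - 2
            if dfi < 1 or np.ptp(dcol[keep]) == 0:
                logger.info("pair %d skipped (insufficient complete cases)", idx)
                continue
            xi = x[keep]
            ryi = _residualize(y_all[gi[idx], keep][:, None], xi)[:, 0]
            rdi = _residualize(dcol[keep][:, None], xi)[:, 0]
            dd = float(rdi @ rdi)
            if dd <= 1e-12:
                continue
            b = float(ryi @ rdi) / dd
            r = float(ryi @ rdi) / np.sqrt(dd * float(ryi @ ryi))
            r = max(min(r, 1.0), -1.0)
            t = r * np.sqrt(dfi / max(1 - r * r, 1e-300))
            beta[idx], tstat[idx], dfs[idx] = b, t, dfi
            pval[idx] = 2 * stats.t.sf(abs(t), df=dfi)

        frame = self.pairs.copy()
        frame["beta"] = beta
        frame["t"] = tstat
        frame["p"] = pval
        tested = ~np.isnan(pval)
        q = np.full(len(frame), np.nan)
        if tested.any():
            q[tested] = bh_fdr(pval[tested])
        frame["q"] = q
        frame = frame[tested].reset_index(drop=True)
        return CisEqtlResults(frame, self, df=df)


def summarize_egenes(results_frame: pd.DataFrame, snp_meta: pd.DataFrame, fdr: float = 0.05):
    """Per-eGene summary: eSNP count, best eSNP (min q, ties min p then
    smallest position), and the overall enrichment (significant pairs per
    eGene; NaN when there is no eGene)."""
    sig = results_frame[results_frame["q"] <= fdr].copy()
    if len(sig) == 0:
        return pd.DataFrame(
            columns=["gene", "n_esnps", "best_esnp", "best_p", "best_q", "best_beta"]
        ), float("nan")
    sig["pos"] = sig["snp"].map(snp_meta["pos"])
    rows = []
    for gene, sub in sig.groupby("gene", sort=False):
        best = sub.sort_values(["q", "p", "pos"], kind="stable").iloc[0]
        rows.append(
            {
                "gene": gene,
                "n_esnps": len(sub),
                "best_esnp": best["snp"],
                "best_p": best["p"],
                "best_q": best["q"],
                "best_beta": best["beta"],
            }
        )
    summary = pd.DataFrame(rows).sort_values("best_q", kind="stable").reset_index(drop=True)
    enrichment = len(sig) / len(summary)
    return summary, enrichment


@dataclass
class CisEqtlResults:
    """Fitted scan results: one row per tested pair with beta, t, p, q."""

    frame: pd.DataFrame
    model: CisEqtlModel
    df: int

    def egenes(self, fdr: float = 0.05) -> list:
        sig = self.frame[self.frame["q"] <= fdr]
        return sorted(sig["gene"].unique())

    def significant_pairs(self, fdr: float = 0.05) -> pd.DataFrame:
        return self.frame[self.frame["q"] <= fdr].reset_index(drop=True)

    def egene_summary(self, snp_meta: pd.DataFrame, fdr: float = 0.05):
        return summarize_egenes(self.frame, snp_meta, fdr=fdr)

    def manhattan_data(self, snp_meta: pd.DataFrame) -> pd.DataFrame:
        out = self.frame[["gene", "snp", "p"]].copy()
        out["chrom"] = out["snp"].map(snp_meta["chrom"])
        out["pos"] = out["snp"].map(snp_meta["pos"])
        out["neg_log10_p"] = -np.log10(out["p"])
        return out[["chrom", "pos", "gene", "snp", "p", "neg_log10_p"]]

    def summary(self, fdr: float = 0.05) -> str:
        sig = self.frame[self.frame["q"] <= fdr]
        n_eg = sig["gene"].nunique()
        lines = [
            "Cis-eQTL scan results",
            "=" * 40,
            f"tested pairs:        {len(self.frame)}",
            f"genes tested:        {self.frame['gene'].nunique()}",
            f"residual df:         {self.df}",
            f"significant pairs:   {len(sig)} (FDR <= {fdr})",
            f"eGenes:              {n_eg}",
        ]
        if n_eg:
            lines.append(f"enrichment (eSNP/eGene): {len(sig) / n_eg:.2f}")
        return "\n".join(lines)
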