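"""Genotype quality control and population-structure summarization.

Filters mirror a standard PLINK-style array QC: per-sample missingness,
contamination screening by excess heterozygosity (F statistic on an LD-pruned
SNP set), per-SNP missingness, and an exact Hardy-Weinberg test.  Principal
components of the standardized, LD-pruned dosage matrix summarize population
stratification for use as scan covariates.

Dosage counts the ALT allele as written in the input; MAF folds to the minor
allele.  Beta signs downstream therefore depend on input allele orientation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .datatypes import GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class QcThresholds:
    sample_miss: float = 0.02  # remove samples with missing fraction >= this
    f_min: float = -0.05       # remove samples with F < this (het excess)
    snp_miss: float = 0.01     # remove SNPs with missing fraction >= this
    hwe_p: float = 1e-6        # remove SNPs with exact HWE p < this
    prune_window: int = 50
    prune_step: int = 5
    prune_r2: float = 0.2


@dataclass
class QcReport:
    samples_removed: pd.DataFrame  # index sample, column reason
    snps_removed: pd.DataFrame     # index snp, column reason
    sample_stats: pd.DataFrame     # call_rate, F
    snp_stats: pd.DataFrame        # call_rate, maf, hwe_p
    thresholds: QcThresholds = field(default_factory=QcThresholds)


def call_rates(g: GenotypeMatrix):
    """Per-sample and per-SNP missing fraction (denominator = row/col length)."""
    if g.n_samples == 0 or g.n_snps == 0:
        raise ValueError("empty genotype matrix")
    isna = g.dosage.isna()
    return isna.mean(axis=1), isna.mean(axis=0)


def maf(g: GenotypeMatrix) -> pd.Series:
    """Minor allele frequency per SNP; NaN for all-missing SNPs (flagged)."""
    d = g.dosage.to_numpy(dtype=float)
    n_called = np.sum(~np.isnan(d), axis=0)
    with np.errstate(invalid="ignore"):
        f = np.nansum(d, axis=0) / (2.0 * n_called)
    f = np.where(n_called == 0, np.nan, f)
    if np.any(n_called == 0):
        logger.warning("%d SNP(s) with no non-missing calls: MAF undefined", int((n_called == 0).sum()))
    return pd.Series(np.minimum(f, 1 - f), index=g.dosage.columns, name="maf")


def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Two-sided exact Hardy-Weinberg test (Wigginton-style).

    Conditions on the allele counts and sums the probabilities of all
    heterozygote counts whose conditional probability does not exceed that of
    the observed count.  Returns p in (0, 1].
    """
    counts = (int(n_aa), int(n_ab), int(n_bb))
    if any(c < 0 for c in counts) or sum(counts) < 1:
        raise ValueError("genotype counts must be non-negative with sum >= 1")
    n = sum(counts)
    n_minor = min(2 * counts[0] + counts[1], 2 * counts[2] + counts[1])
    # attainable heterozygote counts share the parity of the minor allele count
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    hom_minor = (n_minor - hets) // 2
    hom_major = n - hets - hom_minor
    # P(het = h | allele counts) via log-multinomial / log-binomial
    logp = (
        gammaln(n + 1)
        - gammaln(hom_minor + 1)
        - gammaln(hets + 1)
        - gammaln(hom_major + 1)
        + hets * np.log(2.0)
        + gammaln(n_minor + 1)
        + gammaln(2 * n - n_minor + 1)
        - gammaln(2 * n + 1)
    )
    prob = np.exp(logp - logp.max())
    prob /= prob.sum()
    p_obs = prob[hets == counts[1]][0]
    return float(min(1.0, prob[prob <= p_obs * (1 + 1e-12)].sum()))


def hwe_chi2_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """1-df chi-square HWE test (available behind a flag; exact is default)."""
    from scipy.stats import chi2

    n = n_aa + n_ab + n_bb
    p = (2 * n_aa + n_ab) / (2 * n)
    exp = np.array([n * p**2, 2 * n * p * (1 - p), n * (1 - p) ** 2])
    obs = np.array([n_aa, n_ab, n_bb], dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.nansum(np.where(exp > 0, (obs - exp) ** 2 / exp, 0.0))
    return float(chi2.sf(stat, df=1))


def hwe_pvalues(g: GenotypeMatrix, exact: bool = True) -> pd.Series:
    d = g.dosage.to_numpy(dtype=float)
    out = np.ones(g.n_snps)
    for j in range(g.n_snps):
        col = d[:, j]
        col = col[~np.isnan(col)]
        if col.size == 0:
            out[j] = np.nan
            continue
        n_bb = int((col == 2).sum())
        n_ab = int((col == 1).sum())
        n_aa = int((col == 0).sum())
        out[j] = hwe_exact_test(n_aa, n_ab, n_bb) if exact else hwe_chi2_test(n_aa, n_ab, n_bb)
    return pd.Series(out, index=g.dosage.columns, name="hwe_p")


def ld_r2(g1: np.ndarray, g2: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors on their shared
    non-missing samples; NaN if either is constant there (pair not prunable)."""
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    ok = ~(np.isnan(g1) | np.isnan(g2))
    x, y = g1[ok], g2[ok]
    if x.size < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.debug("zero-variance pair in ld_r2; treated as not prunable")
        return np.nan
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def ld_prune(g: GenotypeMatrix, window: int = 50, step: int = 5, r2_max: float = 0.2) -> list:
    """Greedy windowed LD pruning; the LATER SNP of an offending pair is
    removed.  Windows are taken over the currently kept, position-sorted SNPs
    of each chromosome and the sweep repeats until no removal occurs, so no
    kept pair within a window exceeds the threshold."""
    meta = g.snp_meta
    dosage = g.dosage.to_numpy(dtype=float)
    col_of = {s: j for j, s in enumerate(g.snp_ids)}
    any_missing = bool(np.isnan(dosage).any())

    def window_r2(ids: list) -> np.ndarray:
        cols = [col_of[s] for s in ids]
        if any_missing:
            m = len(ids)
            r2 = np.full((m, m), np.nan)
            for a in range(m):
                for b in range(a + 1, m):
                    r2[a, b] = ld_r2(dosage[:, cols[a]], dosage[:, cols[b]])
            return r2
        block = dosage[:, cols]
        sd = block.std(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.corrcoef(block, rowvar=False)
        r2 = np.asarray(c, dtype=float) ** 2
        r2[sd == 0, :] = np.nan
        r2[:, sd == 0] = np.nan
        return np.triu(r2, k=1) + np.tril(np.full_like(r2, np.nan))

    kept_all = []
    for chrom in pd.unique(meta["chrom"]):
        ids = list(meta.index[meta["chrom"] == chrom])
        ids.sort(key=lambda s: int(meta.at[s, "pos"]))
        kept = ids
        changed = True
        while changed:
            changed = False
            removed = set()
            start = 0
            while start < len(kept):
                win = [s for s in kept[start : start + window] if s not in removed]
                if len(win) > 1:
                    r2 = window_r2(win)
                    for a_i in range(len(win)):
                        if win[a_i] in removed:
                            continue
                        for b_i in range(a_i + 1, len(win)):
                            if win[b_i] in removed:
                                continue
                            v = r2[a_i, b_i]
                            if not np.isnan(v) and v >= r2_max:
                                removed.add(win[b_i])
                start += step
            if removed:
                changed = True
                kept = [s for s in kept if s not in removed]
        kept_all.extend(kept)
    return [s for s in g.snp_ids if s in set(kept_all)]


def heterozygosity_f(g_pruned: GenotypeMatrix) -> pd.Series:
    """PLINK-style per-sample F = (O_hom - E_hom) / (L - E_hom).

    E_hom uses cohort allele frequencies with the n/(n-1) small-sample
    correction of expected heterozygosity.  Samples where L == E_hom are
    returned NaN and flagged for manual review.
    """
    d = g_pruned.dosage.to_numpy(dtype=float)
    if d.shape[1] == 0:
        raise ValueError("pruned SNP set is empty")
    n_called = np.sum(~np.isnan(d), axis=0).astype(float)
    with np.errstate(invalid="ignore"):
        p = np.nansum(d, axis=0) / (2.0 * n_called)
    usable = (n_called > 1) & (p > 0) & (p < 1)
    corr = np.where(n_called > 1, n_called / np.maximum(n_called - 1, 1), 1.0)
    e_het_snp = 2.0 * p * (1 - p) * corr

    out = np.empty(d.shape[0])
    for i in range(d.shape[0]):
        row = d[i]
        ok = ~np.isnan(row) & usable
        L = float(ok.sum())
        if L == 0:
            out[i] = np.nan
            continue
        o_hom = float(np.sum(row[ok] != 1))
        e_hom = float(np.sum(1.0 - e_het_snp[ok]))
        if abs(L - e_hom) < 1e-12:
            logger.warning("sample %s: degenerate F (L == E_hom); flagged", g_pruned.sample_ids[i])
            out[i] = np.nan
            continue
        out[i] = (o_hom - e_hom) / (L - e_hom)
    return pd.Series(out, index=g_pruned.dosage.index, name="F")


def run_qc(g: GenotypeMatrix, thresholds: QcThresholds | None = None):
    """Full QC: sample missingness -> pruning -> F -> SNP missingness -> HWE.

    Returns the filtered matrix and a report accounting for every removal.
    Idempotent: re-running on the output removes nothing.
    """
    thr = thresholds or QcThresholds()
    sample_cr, _ = call_rates(g)
    bad_miss = sample_cr.index[sample_cr >= thr.sample_miss]
    g1 = g.subset(samples=[s for s in g.sample_ids if s not in set(bad_miss)])
    if g1.n_samples == 0:
        raise RuntimeError("all samples removed by missingness filter")

    pruned_ids = ld_prune(g1, thr.prune_window, thr.prune_step, thr.prune_r2)
    f_stat = heterozygosity_f(g1.subset(snps=pruned_ids))
    bad_f = f_stat.index[f_stat < thr.f_min]
    g2 = g1.subset(samples=[s for s in g1.sample_ids if s not in set(bad_f)])
    if g2.n_samples == 0:
        raise RuntimeError("all samples removed by heterozygosity filter")

    # SNP statistics are per-SNP on the final cohort, so one pass suffices
    _, snp_cr = call_rates(g2)
    bad_snp_miss = snp_cr.index[snp_cr >= thr.snp_miss]
    g3 = g2.subset(snps=[s for s in g2.snp_ids if s not in set(bad_snp_miss)])

    hwe = hwe_pvalues(g3)
    bad_hwe = hwe.index[hwe < thr.hwe_p]
    g4 = g3.subset(snps=[s for s in g3.snp_ids if s not in set(bad_hwe)])

    sample_rows = [(s, "missingness") for s in bad_miss] + [(s, "heterozygosity") for s in bad_f]
    snp_rows = [(s, "missingness") for s in bad_snp_miss] + [(s, "hwe") for s in bad_hwe]
    report = QcReport(
        samples_removed=pd.DataFrame(sample_rows, columns=["id", "reason"]).set_index("id"),
        snps_removed=pd.DataFrame(snp_rows, columns=["id", "reason"]).set_index("id"),
        sample_stats=pd.DataFrame({"missing_rate": sample_cr, "F": f_stat.reindex(sample_cr.index)}),
        snp_stats=pd.DataFrame(
            {
                "missing_rate": snp_cr.reindex(g.snp_ids),
                "maf": maf(g),
                "hwe_p": hwe.reindex(g.snp_ids),
            }
        ),
        thresholds=thr,
    )
    logger.info(
        "QC: %d/%d samples and %d/%d SNPs passed",
        g4.n_samples, g.n_samples, g4.n_snps, g.n_snps,
    )
    return g4, report


def genotype_pca(g: GenotypeMatrix, n_pcs: int = 10, pruned_ids: list | None = None):
    """PCA of the standardized dosage matrix (on the LD-pruned subset).

    Each SNP is centred by 2p and scaled by sqrt(2p(1-p)); missing dosages are
    mean-imputed for the PCA only.  Score signs are fixed so the largest-|loading|
    element of each component is positive.
    """
    sub = g.subset(snps=pruned_ids) if pruned_ids is not None else g
    d = sub.dosage.to_numpy(dtype=float)
    p = np.nansum(d, axis=0) / (2.0 * np.sum(~np.isnan(d), axis=0))
    keep = (p > 0) & (p < 1)
    d = d[:, keep]
    p = p[keep]
    x = (np.where(np.isnan(d), 2 * p, d) - 2 * p) / np.sqrt(2 * p * (1 - p))
    n = x.shape[0]
    k = min(n_pcs, n - 1, x.shape[1])
    if k < n_pcs:
        logger.warning("returning %d PCs (requested %d)", k, n_pcs)
    u, s, vt = np.linalg.svd(x - x.mean(axis=0), full_matrices=False)
    for j in range(k):
        if vt[j, np.argmax(np.abs(vt[j]))] < 0:
            u[:, j] *= -1
            vt[j] *= -1
    scores = pd.DataFrame(
        u[:, :k] * s[:k],
        index=sub.dosage.index,
        columns=[f"GenoPC{i + 1}" for i in range(k)],
    )
    varexp = pd.Series(s[:k] ** 2 / np.sum(s**2), index=scores.columns, name="variance_explained")
    return scores, varexp
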