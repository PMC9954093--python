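"""The two-pass "subtraction" strategy.

The same covariate-adjusted cis scan is run twice: once with the full
covariate set (disease group included) and once with the disease group and
the disease-correlated expression PC(s) removed.  Because disease status
explains a large share of expression variance for disease-dysregulated genes,
those genes only clear the residual-variance gate in the second pass; eGenes
specific to the MINUS DISEASE pass are therefore candidates for
disease-related genetic regulation, and a genotype x disease interaction test
on their best eSNPs probes for conditional eQTLs.

Organized as a statsmodels-style model: :class:`SubtractionAnalysis` is built
from the prepared dataset, ``fit()`` returns :class:`SubtractionResults`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cisscan import CisEqtlModel, CisEqtlResults, bh_fdr, build_cis_pairs, summarize_egenes
from .datatypes import CovariateTable, ExpressionMatrix, GenotypeMatrix
from .exprcov import _pearson_rp
from .rvselect import RV_GRID, RvTable, covariate_regress, normalize_expression, rv_gene_sets

logger = logging.getLogger(__name__)

ALL_COVARIATES = "ALL_COVARIATES"
MINUS_DISEASE = "MINUS_DISEASE"


@dataclass
class DesignSpec:
    """A named covariate design: which columns enter the scan regression."""

    name: str
    columns: list


def make_designs(
    cov: CovariateTable,
    group_column: str = "Group",
    pc_prefix: str = "ExprPC",
    pc_corr_cutoff: float = 0.4,
    minus_drop: list | None = None,
):
    """Build the ALL COVARIATES and MINUS DISEASE designs.

    MINUS DISEASE removes the disease group column plus every included
    expression PC that is disease-associated: either its scores correlate
    with the binary disease indicator at |Pearson r| >= ``pc_corr_cutoff``
    (a disease mean-shift PC, the rule the study design applied, which
    removed exactly one PC), or its score dispersion does (|r| between
    |score - median| and the indicator, a disease-dispersion PC: disease
    heterogeneity spreads scores without shifting their mean).  An explicit
    ``minus_drop`` list overrides the data-driven rule.
    """
    all_cols = list(cov.data.columns)
    if group_column not in all_cols:
        raise ValueError(f"{group_column!r} not among covariates")
    if minus_drop is None:
        z = (cov.data[group_column].to_numpy(dtype=float) > 0).astype(float)
        minus_drop = [group_column]
        for col in all_cols:
            if col.startswith(pc_prefix):
                sc = cov.data[col].to_numpy(dtype=float)
                r_mean, _ = _pearson_rp(sc, z)
                r_disp, _ = _pearson_rp(np.abs(sc - np.median(sc)), z)
                r = np.nanmax([abs(r_mean), abs(r_disp)])
                if not np.isnan(r) and r >= pc_corr_cutoff:
                    logger.info(
                        "MINUS DISEASE drops %s (disease |r| = %.2f mean / %.2f dispersion)",
                        col, abs(r_mean), abs(r_disp),
                    )
                    minus_drop.append(col)
    else:
        minus_drop = list(minus_drop)
        if group_column not in minus_drop:
            minus_drop = [group_column] + minus_drop
    minus_cols = [c for c in all_cols if c not in set(minus_drop)]
    return (
        DesignSpec(ALL_COVARIATES, all_cols),
        DesignSpec(MINUS_DISEASE, minus_cols),
    )


@dataclass
class VennComparison:
    """Exact set arithmetic between the two passes, at gene and pair level."""

    egenes_a_only: set
    egenes_shared: set
    egenes_b_only: set
    esnps_a_only: set
    esnps_shared: set
    esnps_b_only: set
    pairs_a_only: set
    pairs_shared: set
    pairs_b_only: set

    def counts(self) -> dict:
        return {
            "egenes_a": len(self.egenes_a_only) + len(self.egenes_shared),
            "egenes_b": len(self.egenes_b_only) + len(self.egenes_shared),
            "egenes_a_only": len(self.egenes_a_only),
            "egenes_shared": len(self.egenes_shared),
            "egenes_b_only": len(self.egenes_b_only),
            "esnps_a_only": len(self.esnps_a_only),
            "esnps_shared": len(self.esnps_shared),
            "esnps_b_only": len(self.esnps_b_only),
            "pairs_a_only": len(self.pairs_a_only),
            "pairs_shared": len(self.pairs_shared),
            "pairs_b_only": len(self.pairs_b_only),
        }


def venn(results_a: pd.DataFrame, results_b: pd.DataFrame, fdr: float = 0.05) -> VennComparison:
    """Set differences of eGenes, eSNPs and (gene, SNP) pairs at a common FDR."""
    def _sets(frame):
        sig = frame[frame["q"] <= fdr]
        return (
            set(sig["gene"]),
            set(sig["snp"]),
            set(zip(sig["gene"], sig["snp"])),
        )

    ga, sa, pa = _sets(results_a)
    gb, sb, pb = _sets(results_b)
    return VennComparison(
        egenes_a_only=ga - gb, egenes_shared=ga & gb, egenes_b_only=gb - ga,
        esnps_a_only=sa - sb, esnps_shared=sa & sb, esnps_b_only=sb - sa,
        pairs_a_only=pa - pb, pairs_shared=pa & pb, pairs_b_only=pb - pa,
    )


def venn_sets(a: set, b: set) -> dict:
    """Plain set arithmetic helper (|A only|, |shared|, |B only|)."""
    a, b = set(a), set(b)
    return {"a_only": a - b, "shared": a & b, "b_only": b - a}


def select_rv_threshold(enrichment_table: pd.DataFrame, default: float = 0.85):
    """Report the configured threshold plus an advisory score per threshold
    (enrichment gain per eGene lost, relative to the previous grid point)."""
    tab = enrichment_table.sort_values("tau", kind="stable")
    taus = tab["tau"].to_numpy(dtype=float)
    enr = tab["enrichment"].to_numpy(dtype=float)
    ngenes = tab["n_egenes"].to_numpy(dtype=float)
    score = np.zeros(len(tab))
    for i in range(1, len(tab)):
        gain = enr[i] - enr[i - 1] if np.isfinite(enr[i]) and np.isfinite(enr[i - 1]) else 0.0
        lost = max(ngenes[i - 1] - ngenes[i], 1.0)
        score[i] = gain / lost
    scores = pd.Series(score, index=taus, name="advisory_score")
    advisory = float(taus[int(np.argmax(score))]) if score.max() > 0 else float(taus[0])
    return default, scores, advisory


@dataclass
class InteractionResult:
    """Genotype x disease interaction fit for one eGene's best eSNP."""

    gene_id: str
    snp_id: str
    coef_interaction: float
    p_snp: float
    p_group: float
    p_interaction: float
    p_model: float
    conditional: bool
    warning: str | None = None


def interaction_test(
    residual_expr: np.ndarray,
    dosage: np.ndarray,
    disease: np.ndarray,
    gene_id: str = "",
    snp_id: str = "",
    alpha: float = 0.05,
) -> InteractionResult:
    """OLS of covariate residuals on eSNP + disease + eSNP:disease.

    ``residual_expr`` are the MINUS DISEASE covariate residuals of the
    normalized expression; ``disease`` is the binary control-vs-disease
    indicator; ``dosage`` is the 0/1/2 genotype.  Per-coefficient two-sided t
    p-values, the model F p-value, and the conditional flag
    (interaction p <= alpha) are returned.
    """
    y = np.asarray(residual_expr, dtype=float)
    d = np.asarray(dosage, dtype=float)
    z = np.asarray(disease, dtype=float)
    ok = ~(np.isnan(y) | np.isnan(d) | np.isnan(z))
    y, d, z = y[ok], d[ok], z[ok]
    x = np.column_stack([np.ones(y.size), d, z, d * z])
    warning = None
    rank = np.linalg.matrix_rank(x)
    if rank < 4:
        if np.ptp(d) == 0 or np.ptp(z) == 0:
            raise ValueError("perfect collinearity: constant dosage or disease indicator")
        warning = "rank-deficient interaction design (empty genotype x disease stratum)"
        logger.warning("%s/%s: %s", gene_id, snp_id, warning)
    fit = sm.OLS(y, x).fit()
    p = fit.pvalues
    return InteractionResult(
        gene_id=gene_id,
        snp_id=snp_id,
        coef_interaction=float(fit.params[3]),
        p_snp=float(p[1]),
        p_group=float(p[2]),
        p_interaction=float(p[3]),
        p_model=float(fit.f_pvalue),
        conditional=bool(p[3] <= alpha),
        warning=warning,
    )


def stratified_export(
    expr_raw: pd.Series, dosage: pd.Series, group: pd.Series
) -> pd.DataFrame:
    """Long-format (sample, genotype, group, raw expression) table for
    boxplotting; samples with a missing genotype are dropped with a log entry."""
    joined = pd.DataFrame(
        {"genotype": dosage, "group": group, "expression": expr_raw}
    ).dropna(subset=["genotype"])
    n_dropped = len(dosage) - len(joined)
    if n_dropped:
        logger.info("stratified_export: dropped %d sample(s) with missing genotype", n_dropped)
    joined["genotype"] = joined["genotype"].astype(int)
    joined.index.name = "sample"
    return joined.reset_index()


@dataclass
class _DesignFit:
    design: DesignSpec
    rv_table: RvTable
    residuals: pd.DataFrame
    scan: CisEqtlResults
    enrichment: pd.DataFrame  # per-tau table


class SubtractionAnalysis:
    """Two-pass covariate-adjusted cis-eQTL analysis on a prepared dataset.

    Parameters
    ----------
    expression : ExpressionMatrix
        Filtered (expressed) genes x samples log2 matrix; normalization is
        applied internally.
    genotypes : GenotypeMatrix
        QC-passed genotypes.
    covariates : CovariateTable
        Full numeric covariate table (clinical + expression PCs + genotype PCs).
    designs : (DesignSpec, DesignSpec), optional
        The (ALL COVARIATES, MINUS DISEASE) pair; built by
        :func:`make_designs` when omitted.
    """

    def __init__(
        self,
        expression: ExpressionMatrix,
        genotypes: GenotypeMatrix,
        covariates: CovariateTable,
        designs=None,
        grid=RV_GRID,
        tau: float = 0.85,
        window: int = 100_000,
        fdr: float = 0.05,
        maf_min: float = 0.15,
        interaction_alpha: float = 0.05,
        group_column: str = "Group",
    ):
        samples = expression.sample_ids
        if genotypes.sample_ids != samples or covariates.sample_ids != samples:
            raise ValueError("inputs are not sample-aligned")
        self.expression = expression
        self.genotypes = genotypes
        self.covariates = covariates
        self.designs = designs or make_designs(covariates, group_column=group_column)
        for d in self.designs:
            missing = [c for c in d.columns if c not in covariates.data.columns]
            if missing:
                raise ValueError(f"design {d.name}: columns absent from covariate table: {missing}")
        self.grid = tuple(grid)
        self.tau = tau
        self.window = window
        self.fdr = fdr
        self.maf_min = maf_min
        self.interaction_alpha = interaction_alpha
        self.group_column = group_column

    def fit(self) -> "SubtractionResults":
        expr_norm = normalize_expression(self.expression.values)
        pairs = build_cis_pairs(self.expression.gene_meta, self.genotypes.snp_meta, self.window)
        fits = {}
        for design in self.designs:
            residuals, rv = covariate_regress(expr_norm, self.covariates.data[design.columns])
            rv_table = rv_gene_sets(rv, self.grid)
            scan = CisEqtlModel(
                expr_norm,
                self.genotypes.dosage,
                self.covariates.data[design.columns],
                pairs,
                maf_min=self.maf_min,
            ).fit()
            enrichment = self._enrichment_table(scan.frame, rv_table)
            fits[design.name] = _DesignFit(design, rv_table, residuals, scan, enrichment)
        return SubtractionResults(self, fits, expr_norm)

    def _enrichment_table(self, frame: pd.DataFrame, rv_table: RvTable) -> pd.DataFrame:
        rows = []
        for tau in self.grid:
            genes = set(rv_table.gene_set(tau))
            sub = frame[frame["gene"].isin(genes)].copy()
            if len(sub):
                sub["q"] = bh_fdr(sub["p"].to_numpy())
            sig = sub[sub["q"] <= self.fdr] if len(sub) else sub
            n_eg = sig["gene"].nunique() if len(sig) else 0
            rows.append(
                {
                    "tau": tau,
                    "n_input_genes": len(genes),
                    "n_pairs": len(sub),
                    "n_sig_pairs": len(sig),
                    "n_egenes": n_eg,
                    "n_esnps": sig["snp"].nunique() if len(sig) else 0,
                    "enrichment": (len(sig) / n_eg) if n_eg else np.nan,
                }
            )
        return pd.DataFrame(rows)

    def scan_at_tau(self, fit: _DesignFit, tau: float) -> pd.DataFrame:
        """Scan results restricted to the RV >= tau gene set, with q-values
        recomputed over the restricted pair set (FDR is per analysis run)."""
        genes = set(fit.rv_table.gene_set(tau))
        sub = fit.scan.frame[fit.scan.frame["gene"].isin(genes)].copy()
        if len(sub):
            sub["q"] = bh_fdr(sub["p"].to_numpy())
        return sub.reset_index(drop=True)


class SubtractionResults:
    """Results of the two-pass analysis: per-design RV tables, enrichment
    grids, the subtraction Venn at the chosen threshold, and the interaction
    tests on best eSNPs."""

    def __init__(self, model: SubtractionAnalysis, fits: dict, expr_norm: pd.DataFrame):
        self.model = model
        self.fits = fits
        self.expr_norm = expr_norm
        self._scan_a = model.scan_at_tau(fits[ALL_COVARIATES], model.tau)
        self._scan_b = model.scan_at_tau(fits[MINUS_DISEASE], model.tau)
        self.venn = venn(self._scan_a, self._scan_b, fdr=model.fdr)
        self._interactions = None

    @property
    def enrichment_tables(self) -> dict:
        return {name: f.enrichment for name, f in self.fits.items()}

    def scan_frame(self, design_name: str) -> pd.DataFrame:
        return {ALL_COVARIATES: self._scan_a, MINUS_DISEASE: self._scan_b}[design_name]

    def egenes(self, design_name: str) -> set:
        frame = self.scan_frame(design_name)
        return set(frame[frame["q"] <= self.model.fdr]["gene"])

    def disease_specific_egenes(self) -> set:
        """eGenes found only when disease is NOT corrected for."""
        return set(self.venn.egenes_b_only)

    def interactions(self, egene_set: str = MINUS_DISEASE, all_pairs: bool = False) -> pd.DataFrame:
        """Genotype x disease interaction tests on eGene best eSNPs.

        Response: MINUS DISEASE covariate residuals of the normalized
        expression.  ``egene_set`` picks whose eGenes are tested; with
        ``all_pairs`` every significant pair is tested, not just the best eSNP.
        """
        m = self.model
        frame = self.scan_frame(egene_set)
        summary, _ = summarize_egenes(frame, m.genotypes.snp_meta, fdr=m.fdr)
        if all_pairs:
            sig = frame[frame["q"] <= m.fdr]
            tested = list(zip(sig["gene"], sig["snp"]))
        else:
            tested = list(zip(summary["gene"], summary["best_esnp"]))
        residuals = self.fits[MINUS_DISEASE].residuals
        z = (m.covariates.data[m.group_column].to_numpy(dtype=float) > 0).astype(float)
        rows = []
        for gene, snp in tested:
            res = interaction_test(
                residuals.loc[gene].to_numpy(),
                m.genotypes.dosage[snp].to_numpy(dtype=float),
                z,
                gene_id=gene,
                snp_id=snp,
                alpha=m.interaction_alpha,
            )
            rows.append(res.__dict__)
        return pd.DataFrame(
            rows,
            columns=[
                "gene_id", "snp_id", "coef_interaction", "p_snp", "p_group",
                "p_interaction", "p_model", "conditional", "warning",
            ],
        )

    def summary(self) -> str:
        c = self.venn.counts()
        ta = self.fits[ALL_COVARIATES].enrichment
        tb = self.fits[MINUS_DISEASE].enrichment
        row_a = ta[ta["tau"] == self.model.tau].iloc[0]
        row_b = tb[tb["tau"] == self.model.tau].iloc[0]
        return "\n".join(
            [
                "Two-pass subtraction analysis",
                "=" * 46,
                f"RV threshold (tau*):           {self.model.tau}",
                f"FDR threshold:                 {self.model.fdr}",
                f"[A] {ALL_COVARIATES}: {int(row_a['n_input_genes'])} input genes, "
                f"{int(row_a['n_sig_pairs'])} significant pairs, {int(row_a['n_egenes'])} eGenes",
                f"[B] {MINUS_DISEASE}:  {int(row_b['n_input_genes'])} input genes, "
                f"{int(row_b['n_sig_pairs'])} significant pairs, {int(row_b['n_egenes'])} eGenes",
                f"eGenes A only / shared / B only: "
                f"{c['egenes_a_only']} / {c['egenes_shared']} / {c['egenes_b_only']}",
                f"disease-specific eGenes (B only): {sorted(self.disease_specific_egenes())}",
            ]
        )
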