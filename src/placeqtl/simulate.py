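"""Synthetic placental eQTL datasets with the confounding structure the
analysis is built to untangle.

The generator emulates a small case/control placental study: four clinical
groups (CTRL, PE, IUGR, PE+IUGR) whose gestational age at delivery is strongly
group-dependent (disease placentas are delivered weeks earlier), batch/cohort
structure, two-population ancestry stratification under a Balding-Nichols
model, and three gene classes:

* ``null``         -- covariate effects + noise only;
* ``constitutive`` -- a cis SNP shifts expression by ``beta_g`` per ALT allele
  in every sample;
* ``conditional``  -- the cis effect (``beta_c``) exists only in disease
  samples, and the gene is additionally disease-dysregulated through a shared
  disease-severity factor s_i = z_i * u_i (z = disease indicator,
  u ~ N(1, severity_sd^2)).  The severity factor is what makes conditional
  genes behave like disease genes: strongly captured by a disease-correlated
  expression PC, yet only weakly predictable from gestational age, so the
  with/without-disease covariate designs genuinely differ for them.

The generative model per gene g and sample i is

    y_gi = mu_g + sum_j gamma_gj * cov_ji + lambda_g * s_i
           + beta_g * d_gi + beta_c * d_gi * z_i + eps_gi

with eps ~ N(0, noise_sd^2) and d the dosage at the gene's causal SNP.
All randomness flows from one seed through numpy's SeedSequence spawning.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import io as pio
from .datatypes import CLINICAL_COLUMNS, GROUP_LABELS, CovariateTable, ExpressionMatrix, GenotypeMatrix

logger = logging.getLogger(__name__)

#: gestational age mean +/- sd (weeks) per group, order (CTRL, PE, IUGR, PE+IUGR)
GA_MEANS_SDS = ((39.2, 1.2), (34.9, 2.6), (31.0, 2.8), (30.0, 2.5))
#: maternal age mean +/- sd (years) per group
MATERNAL_AGE = ((34.0, 3.9), (34.2, 6.0), (32.1, 6.6), (35.3, 2.4))
#: parity mean +/- sd per group
PARITY = ((1.9, 1.5), (1.2, 1.1), (1.2, 0.4), (2.0, 1.4))
#: caesarean fraction per group (disease deliveries are essentially all C-section)
CAESAREAN_FRAC = (23 / 35, 1.0, 1.0, 1.0)


@dataclass
class SimConfig:
    """Generator configuration; defaults are the emulated study's conditions."""

    n_samples: int = 57
    n_snps: int = 600
    n_genes: int = 150
    n_pops: int = 2
    fst: float = 0.1
    maf_range: tuple = (0.25, 0.5)
    group_proportions: tuple = (35 / 57, 9 / 57, 10 / 57, 3 / 57)
    ga_means_sds: tuple = GA_MEANS_SDS
    n_batches: int = 3
    frac_constitutive_eqtl: float = 0.2
    frac_conditional_eqtl: float = 0.1
    beta_g: float = 1.5
    beta_c: float = 4.5
    noise_sd: float = 1.0
    covariate_effect_sds: dict = field(
        default_factory=lambda: {
            "GestationalAge": 0.06,
            "MaternalAge": 0.02,
            "Batch": 0.15,
            "Sex": 0.15,
            "Delivery": 0.10,
            "Parity": 0.05,
            "Ethnicity": 0.10,
        }
    )
    disease_factor_loading: float = 2.5
    disease_severity_sd: float = 1.5
    pop_proportions: tuple = (0.85, 0.15)
    cis_window: int = 100_000
    gene_length: int = 10_000
    gene_spacing: int = 250_000
    n_chroms: int = 3
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (self.frac_constitutive_eqtl, self.frac_conditional_eqtl)
        if any(f < 0 or f > 1 for f in fracs) or sum(fracs) > 1:
            raise ValueError("eQTL fractions must lie in [0,1] and sum to <= 1")
        if abs(sum(self.group_proportions) - 1.0) > 1e-8:
            raise ValueError("group_proportions must sum to 1")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.n_pops < 1:
            raise ValueError("n_pops must be >= 1")
        if not (0 <= self.fst < 1):
            raise ValueError("fst must lie in [0, 1)")


@dataclass
class TruthTable:
    """Planted-effect record: the recovery-testing oracle.

    ``genes`` is indexed by gene id with columns ``gene_class`` in
    {null, constitutive, conditional}, ``causal_snp``, ``beta_g``, ``beta_c``;
    ``samples`` is indexed by sample id with ``population`` and ``group``.
    """

    genes: pd.DataFrame
    samples: pd.DataFrame


@dataclass
class SimulatedDataset:
    genotypes: GenotypeMatrix
    expression: ExpressionMatrix
    covariates: CovariateTable
    truth: TruthTable
    config: SimConfig


def _gene_layout(cfg: SimConfig) -> pd.DataFrame:
    """Genes evenly spaced so that cis windows of neighbours never overlap."""
    idx = np.arange(cfg.n_genes)
    chrom = (idx % cfg.n_chroms) + 1
    rank = idx // cfg.n_chroms
    start = cfg.cis_window + 1 + rank * cfg.gene_spacing
    return pd.DataFrame(
        {
            "chrom": [f"chr{c}" for c in chrom],
            "start": start,
            "end": start + cfg.gene_length - 1,
            "strand": "+",
        },
        index=pd.Index([f"G{i:04d}" for i in idx], name="gene"),
    )


def simulate_genotypes(cfg: SimConfig, rng: np.random.Generator):
    """Balding-Nichols genotypes with per-chromosome sorted 1-based positions.

    Returns the genotype matrix and the per-sample population labels.
    """
    n, m = cfg.n_samples, cfg.n_snps
    pops = rng.choice(cfg.n_pops, size=n, p=np.asarray(cfg.pop_proportions[: cfg.n_pops]) / sum(cfg.pop_proportions[: cfg.n_pops]))
    lo, hi = cfg.maf_range
    p_anc = rng.uniform(lo, hi, size=m)
    if cfg.n_pops > 1 and cfg.fst > 0:
        a = p_anc * (1 - cfg.fst) / cfg.fst
        b = (1 - p_anc) * (1 - cfg.fst) / cfg.fst
        p_pop = rng.beta(a[None, :], b[None, :], size=(cfg.n_pops, m))
    else:
        if cfg.n_pops > 1:
            logger.info("fst = 0 with n_pops > 1: degenerate Beta, using p_subpop = p")
        p_pop = np.tile(p_anc, (cfg.n_pops, 1))
    dosage = rng.binomial(2, p_pop[pops, :]).astype(float)
    if cfg.missing_rate > 0:
        mask = rng.random(dosage.shape) < cfg.missing_rate
        dosage[mask] = np.nan

    # SNP positions: uniform over the gene-bearing span of each chromosome
    genes = _gene_layout(cfg)
    chrom_names = [f"chr{c + 1}" for c in range(cfg.n_chroms)]
    spans = {}
    for c in chrom_names:
        sub = genes[genes["chrom"] == c]
        spans[c] = int(sub["end"].max() + cfg.cis_window) if len(sub) else cfg.gene_spacing
    snp_chrom = np.array([chrom_names[j % cfg.n_chroms] for j in range(m)])
    pos = np.zeros(m, dtype=int)
    for c in chrom_names:
        sel = snp_chrom == c
        k = int(sel.sum())
        if k == 0:
            continue
        p = np.unique(rng.integers(1, spans[c] + 1, size=k))
        while len(p) < k:  # resample the rare collisions
            p = np.unique(np.concatenate([p, rng.integers(1, spans[c] + 1, size=k - len(p))]))
        pos[sel] = np.sort(p)
    order = np.lexsort((pos, snp_chrom))
    snp_ids = [f"rs{j:05d}" for j in range(m)]
    meta = pd.DataFrame(
        {"chrom": snp_chrom[order], "pos": pos[order], "ref": "A", "alt": "B"},
        index=pd.Index(np.array(snp_ids), name="snp"),
    )
    samples = pd.Index([f"S{i:03d}" for i in range(n)], name="sample")
    g = GenotypeMatrix(pd.DataFrame(dosage[:, order], index=samples, columns=meta.index), meta)
    return g, pd.Series(pops, index=samples, name="population")


def simulate_covariates(cfg: SimConfig, rng: np.random.Generator, populations: pd.Series):
    """Clinical covariate table; gestational age is group-dependent (the
    central confounder).  Cohort is generated as a relabelling of Batch so the
    collinearity filter has a genuine |r| >= 0.9 pair to remove.
    """
    n = cfg.n_samples
    samples = list(populations.index)
    group = rng.choice(4, size=n, p=np.asarray(cfg.group_proportions))
    ga = np.array([rng.normal(*cfg.ga_means_sds[g]) for g in group])
    mat_age = np.array([rng.normal(*MATERNAL_AGE[g]) for g in group])
    parity = np.clip(np.round([rng.normal(*PARITY[g]) for g in group]), 0, None)
    caesarean = (rng.random(n) < np.array(CAESAREAN_FRAC)[group]).astype(int)
    batch = rng.choice(cfg.n_batches, size=n)
    cohort = (cfg.n_batches - 1) - batch  # one hospital per batch, relabelled
    sex = rng.choice(2, size=n)
    ethnicity = populations.to_numpy().astype(int)

    data = pd.DataFrame(
        {
            "Batch": batch,
            "Cohort": cohort,
            "Group": group,
            "Delivery": caesarean,
            "MaternalAge": mat_age,
            "Ethnicity": ethnicity,
            "GestationalAge": ga,
            "Sex": sex,
            "Parity": parity.astype(float),
        },
        index=pd.Index(samples, name="sample"),
    )[CLINICAL_COLUMNS]
    encodings = {
        "Group": {lab: i for i, lab in enumerate(GROUP_LABELS)},
        "Delivery": {"Natural": 0, "Caesarean": 1},
        "Sex": {"M": 0, "F": 1},
        "Batch": {f"B{i}": i for i in range(cfg.n_batches)},
        "Cohort": {f"C{i}": i for i in range(cfg.n_batches)},
        "Ethnicity": {f"POP{i}": i for i in range(cfg.n_pops)},
    }
    groups = pd.Series([GROUP_LABELS[g] for g in group], index=samples, name="group")
    return CovariateTable(data, encodings), groups


def simulate_expression(cfg: SimConfig, g: GenotypeMatrix, cov: CovariateTable, rng: np.random.Generator):
    """Expression matrix plus the planted-effect truth table."""
    if g.sample_ids != cov.sample_ids:
        raise ValueError("genotypes and covariates are not sample-aligned")
    n, n_genes = cfg.n_samples, cfg.n_genes
    genes = _gene_layout(cfg)

    n_const = int(round(cfg.frac_constitutive_eqtl * n_genes))
    n_cond = int(round(cfg.frac_conditional_eqtl * n_genes))
    perm = rng.permutation(n_genes)
    classes = np.array(["null"] * n_genes, dtype=object)
    classes[perm[:n_const]] = "constitutive"
    classes[perm[n_const : n_const + n_cond]] = "conditional"

    # cis SNP lookup per gene
    snp_meta = g.snp_meta
    dosage = g.dosage.to_numpy(dtype=float)
    causal = np.array([None] * n_genes, dtype=object)
    for gi, row in enumerate(genes.itertuples()):
        if classes[gi] == "null":
            continue
        sel = (
            (snp_meta["chrom"] == row.chrom)
            & (snp_meta["pos"] >= row.start - cfg.cis_window)
            & (snp_meta["pos"] <= row.end + cfg.cis_window)
        )
        ids = snp_meta.index[sel]
        if len(ids) == 0:
            logger.warning("gene %s has no SNP in its cis window; class forced to null", row.Index)
            classes[gi] = "null"
            continue
        causal[gi] = ids[rng.integers(len(ids))]

    z = (cov.data["Group"].to_numpy() > 0).astype(float)  # disease indicator
    severity = z * rng.normal(1.0, cfg.disease_severity_sd, size=n)

    # covariate effects act on centred values so gene means stay at mu
    cov_cols = {}
    for c in cfg.covariate_effect_sds:
        v = cov.data[c].to_numpy(dtype=float)
        cov_cols[c] = v - v.mean()
    mu = rng.uniform(5.0, 9.0, size=n_genes)
    loadings = rng.choice([-1.0, 1.0], size=n_genes) * cfg.disease_factor_loading

    values = np.zeros((n_genes, n))
    beta_g_arr = np.zeros(n_genes)
    beta_c_arr = np.zeros(n_genes)
    snp_pos = {s: j for j, s in enumerate(g.snp_ids)}
    for gi in range(n_genes):
        y = np.full(n, mu[gi])
        for c, sd in cfg.covariate_effect_sds.items():
            if sd > 0:
                y = y + rng.normal(0, sd) * cov_cols[c]
        if classes[gi] == "conditional":
            y = y + loadings[gi] * severity
        if causal[gi] is not None:
            d = dosage[:, snp_pos[causal[gi]]]
            d = np.where(np.isnan(d), np.nanmean(d), d)
            if classes[gi] == "constitutive":
                beta_g_arr[gi] = cfg.beta_g
                y = y + cfg.beta_g * d
            elif classes[gi] == "conditional":
                beta_c_arr[gi] = cfg.beta_c
                y = y + cfg.beta_c * d * z
        values[gi] = y + rng.normal(0, cfg.noise_sd, size=n)

    expr = ExpressionMatrix(
        pd.DataFrame(values, index=genes.index, columns=g.sample_ids), genes
    )
    truth_genes = pd.DataFrame(
        {
            "gene_class": classes,
            "causal_snp": causal,
            "beta_g": beta_g_arr,
            "beta_c": beta_c_arr,
        },
        index=genes.index,
    )
    return expr, truth_genes


def simulate_dataset(cfg: SimConfig) -> SimulatedDataset:
    """Generate a full dataset from a single seed (byte-deterministic)."""
    ss = np.random.SeedSequence(cfg.seed)
    sub = ss.spawn(3)
    logger.debug("sub-seeds: %s", [s.entropy for s in sub])
    rng_g, rng_c, rng_e = (np.random.default_rng(s) for s in sub)
    geno, pops = simulate_genotypes(cfg, rng_g)
    cov, groups = simulate_covariates(cfg, rng_c, pops)
    expr, truth_genes = simulate_expression(cfg, geno, cov, rng_e)
    truth = TruthTable(
        genes=truth_genes,
        samples=pd.DataFrame({"population": pops, "group": groups}),
    )
    return SimulatedDataset(geno, expr, cov, truth, cfg)


def null_config(cfg: SimConfig | None = None, **overrides) -> SimConfig:
    """A complete-null variant of a configuration: no planted eQTLs, no
    disease factor.  Covariate effects are retained (they are corrected for)."""
    base = cfg or SimConfig()
    return replace(
        base,
        frac_constitutive_eqtl=0.0,
        frac_conditional_eqtl=0.0,
        disease_factor_loading=0.0,
        **overrides,
    )


def write_dataset(ds: SimulatedDataset, out_dir: str) -> dict:
    """Write all components as plain text; returns the path map."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "vcf": os.path.join(out_dir, "genotypes.vcf"),
        "dosage": os.path.join(out_dir, "dosage.tsv"),
        "snp_meta": os.path.join(out_dir, "snps.tsv"),
        "expression": os.path.join(out_dir, "expression.tsv"),
        "genes_bed": os.path.join(out_dir, "genes.bed"),
        "covariates": os.path.join(out_dir, "covariates.tsv"),
        "truth_genes": os.path.join(out_dir, "truth_genes.tsv"),
        "truth_samples": os.path.join(out_dir, "truth_samples.tsv"),
    }
    pio.write_vcf(ds.genotypes, paths["vcf"])
    pio.write_dosage_tsv(ds.genotypes, paths["dosage"])
    pio.write_snp_meta(ds.genotypes, paths["snp_meta"])
    pio.write_expression_tsv(ds.expression, paths["expression"])
    pio.write_gene_bed(ds.expression, paths["genes_bed"])
    pio.write_covariates(ds.covariates, paths["covariates"])
    ds.truth.genes.to_csv(paths["truth_genes"], sep="\t", na_rep="NA", index_label="gene")
    ds.truth.samples.to_csv(paths["truth_samples"], sep="\t", na_rep="NA", index_label="sample")
    return paths


def read_dataset(out_dir: str, use_vcf: bool = False):
    """Read a written dataset back (dosage TSV by default, VCF optionally)."""
    snp_meta = pio.read_snp_meta(os.path.join(out_dir, "snps.tsv"))
    if use_vcf:
        geno = pio.read_vcf(os.path.join(out_dir, "genotypes.vcf"))
    else:
        geno = pio.read_dosage_tsv(os.path.join(out_dir, "dosage.tsv"), snp_meta)
    expr = pio.read_expression(
        os.path.join(out_dir, "expression.tsv"), os.path.join(out_dir, "genes.bed")
    )
    cov = pio.read_covariates(os.path.join(out_dir, "covariates.tsv"))
    truth_genes = pd.read_csv(os.path.join(out_dir, "truth_genes.tsv"), sep="\t", index_col="gene")
    truth_samples = pd.read_csv(os.path.join(out_dir, "truth_samples.tsv"), sep="\t", index_col="sample")
    return geno, expr, cov, TruthTable(truth_genes, truth_samples)
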