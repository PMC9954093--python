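"""End-to-end pipeline orchestration.

Stage order: genotype QC -> covariate discovery -> normalization / residual
variance -> two-pass cis scan -> subtraction -> interaction testing ->
(optional) reference-list overlap.  Every filter step logs its counts, the
configuration fully determines the outputs, and a manifest with file hashes
is written alongside them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field

import pandas as pd
import yaml

from . import exprcov, genoqc, overlap as overlap_mod, simulate
from .datatypes import CovariateTable, align_samples
from .rvselect import RV_GRID
from .subtract import MINUS_DISEASE, SubtractionAnalysis, make_designs

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All thresholds of the analysis; defaults are the study's values."""

    maf_min: float = 0.15
    hwe_p: float = 1e-6
    sample_miss: float = 0.02
    snp_miss: float = 0.01
    f_min: float = -0.05
    probe_mean_min: float = 4.5
    window: int = 100_000
    fdr: float = 0.05
    rv_grid: tuple = RV_GRID
    tau: float = 0.85
    collinearity_cutoff: float = 0.9
    interaction_alpha: float = 0.05
    n_expr_pcs: int = 5
    n_geno_pcs: int = 10
    pc_corr_cutoff: float = 0.4
    pca_scale: bool = True
    run_sva: bool = False
    background_n: int = 30818
    seed: int = 0
    sim: simulate.SimConfig = field(default_factory=simulate.SimConfig)

    def to_yaml(self, path: str) -> None:
        d = asdict(self)
        d["rv_grid"] = [float(t) for t in d["rv_grid"]]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        sim_d = d.pop("sim", {})
        for key in ("maf_range", "group_proportions", "pop_proportions"):
            if key in sim_d:
                sim_d[key] = tuple(sim_d[key])
        if "ga_means_sds" in sim_d:
            sim_d["ga_means_sds"] = tuple(tuple(x) for x in sim_d["ga_means_sds"])
        if "rv_grid" in d:
            d["rv_grid"] = tuple(d["rv_grid"])
        return cls(sim=simulate.SimConfig(**sim_d), **d)


@dataclass
class PipelineOutput:
    dataset: simulate.SimulatedDataset
    qc_report: genoqc.QcReport
    covariates: CovariateTable
    results: object  # SubtractionResults
    overlap: pd.DataFrame | None


def prepare(config: PipelineConfig, dataset: simulate.SimulatedDataset):
    """QC + covariate discovery; returns aligned (expression, genotypes,
    covariate table, qc report)."""
    geno_qc, report = genoqc.run_qc(
        dataset.genotypes,
        genoqc.QcThresholds(
            sample_miss=config.sample_miss,
            f_min=config.f_min,
            snp_miss=config.snp_miss,
            hwe_p=config.hwe_p,
        ),
    )
    expr = exprcov.filter_probes(dataset.expression, min_mean=config.probe_mean_min)
    logger.info("probe filter: %d/%d genes expressed", len(expr.gene_ids), len(dataset.expression.gene_ids))
    pruned = genoqc.ld_prune(geno_qc)
    geno_pcs, _ = genoqc.genotype_pca(geno_qc, n_pcs=config.n_geno_pcs, pruned_ids=pruned)
    expr_aln, clin_aln = align_samples(expr, dataset.covariates)[0:2]
    # restrict to QC-passing samples present everywhere
    common = [s for s in geno_qc.sample_ids if s in set(expr_aln.sample_ids)]
    expr_aln = expr_aln.subset_samples(common)
    geno_aln = geno_qc.subset(samples=common)
    clin_aln = CovariateTable(dataset.covariates.data.loc[common].copy(), dict(dataset.covariates.encodings))
    cov_table, corr_report, svs = exprcov.discover_covariates(
        expr_aln,
        clin_aln,
        geno_pcs.loc[common],
        n_expr_pcs=config.n_expr_pcs,
        collinearity_cutoff=config.collinearity_cutoff,
        run_sva=config.run_sva,
        seed=config.seed,
        pca_scale=config.pca_scale,
    )
    return expr_aln, geno_aln, cov_table, report, corr_report


def run_pipeline(
    config: PipelineConfig,
    dataset: simulate.SimulatedDataset | None = None,
    reference_lists: dict | None = None,
    out_dir: str | None = None,
) -> PipelineOutput:
    """Run every stage on a provided or freshly simulated dataset."""
    if dataset is None:
        sim_cfg = dataclasses.replace(config.sim, seed=config.seed)
        dataset = simulate.simulate_dataset(sim_cfg)
    expr, geno, cov_table, qc_report, _ = prepare(config, dataset)
    designs = make_designs(cov_table, pc_corr_cutoff=config.pc_corr_cutoff)
    analysis = SubtractionAnalysis(
        expr,
        geno,
        cov_table,
        designs=designs,
        grid=config.rv_grid,
        tau=config.tau,
        window=config.window,
        fdr=config.fdr,
        maf_min=config.maf_min,
        interaction_alpha=config.interaction_alpha,
    )
    results = analysis.fit()
    ov = None
    if reference_lists:
        query = results.egenes(MINUS_DISEASE)
        ov = overlap_mod.overlap_report(query, reference_lists, N=config.background_n)
    if out_dir is not None:
        _write_outputs(out_dir, config, results, qc_report, ov)
    return PipelineOutput(dataset, qc_report, cov_table, results, ov)


def _write_outputs(out_dir, config, results, qc_report, ov) -> None:
    os.makedirs(out_dir, exist_ok=True)
    paths = {}

    def _save(name, frame):
        path = os.path.join(out_dir, name)
        frame.to_csv(path, sep="\t", index=False, na_rep="NA")
        paths[name] = path

    for name, fit in results.fits.items():
        _save(f"enrichment_{name}.tsv", fit.enrichment)
        _save(f"scan_{name}.tsv", results.scan_frame(name))
        rv = fit.rv_table.rv.reset_index()
        rv.columns = ["gene", "rv"]
        _save(f"rv_{name}.tsv", rv)
    _save("interactions.tsv", results.interactions())
    venn_counts = pd.DataFrame([results.venn.counts()])
    _save("venn.tsv", venn_counts)
    with open(os.path.join(out_dir, "venn.json"), "w") as fh:
        json.dump(results.venn.counts(), fh, indent=1)
    _save(
        "qc_samples_removed.tsv",
        qc_report.samples_removed.reset_index().rename(columns={"index": "sample"}),
    )
    if ov is not None:
        _save("overlap.tsv", ov)
    config.to_yaml(os.path.join(out_dir, "config.yaml"))
    manifest = {}
    for name, path in paths.items():
        with open(path, "rb") as fh:
            manifest[name] = hashlib.sha256(fh.read()).hexdigest()
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)
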