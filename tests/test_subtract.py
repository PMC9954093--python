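"""Design construction, Venn arithmetic, the interaction test, and the
two-pass machinery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from placeqtl import subtract
from placeqtl.datatypes import CovariateTable
from placeqtl.subtract import (
    ALL_COVARIATES,
    MINUS_DISEASE,
    interaction_test,
    make_designs,
    select_rv_threshold,
    stratified_export,
    venn,
    venn_sets,
)


def _cov_table(rng, n=57):
    idx = [f"S{i}" for i in range(n)]
    data = {
        "Batch": rng.integers(0, 3, n).astype(float),
        "Group": rng.choice(4, n, p=[0.6, 0.2, 0.15, 0.05]).astype(float),
        "GestationalAge": rng.normal(36, 3, n),
        "Sex": rng.integers(0, 2, n).astype(float),
    }
    for i in range(1, 6):
        data[f"ExprPC{i}"] = rng.normal(size=n)
    for i in range(1, 11):
        data[f"GenoPC{i}"] = rng.normal(size=n)
    return CovariateTable(pd.DataFrame(data, index=idx))


class TestMakeDesigns:
    def test_explicit_drop_list_reproduces_two_column_difference(self, rng):
        cov = _cov_table(rng)
        a, b = make_designs(cov, minus_drop=["ExprPC5"])
        assert len(a.columns) == len(cov.columns())
        assert set(a.columns) - set(b.columns) == {"Group", "ExprPC5"}
        assert len(b.columns) == len(a.columns) - 2

    def test_data_driven_rule_drops_disease_correlated_pc(self, rng):
        cov = _cov_table(rng)
        z = (cov.data["Group"] > 0).astype(float)
        cov.data["ExprPC3"] = 0.8 * (z - z.mean()) + 0.2 * rng.normal(size=len(z))
        a, b = make_designs(cov)
        assert "ExprPC3" not in b.columns and "Group" not in b.columns

    def test_dispersion_only_disease_pc_is_dropped(self, rng):
        cov = _cov_table(rng, n=200)
        z = (cov.data["Group"] > 0).to_numpy()
        # disease-dispersion PC: zero mean shift, inflated spread in disease
        sc = rng.normal(size=200)
        sc[z] *= 4.0
        cov.data["ExprPC2"] = sc
        assert abs(np.corrcoef(sc, z.astype(float))[0, 1]) < 0.4
        _, b = make_designs(cov)
        assert "ExprPC2" not in b.columns

    def test_missing_group_column_rejected(self, rng):
        cov = _cov_table(rng)
        cov.data.drop(columns=["Group"], inplace=True)
        with pytest.raises(ValueError):
            make_designs(cov)


class TestVenn:
    def test_study_worked_example_counts(self):
        # |A| = 43, |B| = 54, shared = 38 -> A-only 5, B-only 16
        a = {f"g{i}" for i in range(43)}
        b = {f"g{i}" for i in range(5, 5 + 54)}
        out = venn_sets(a, b)
        assert len(out["shared"]) == 38
        assert len(out["a_only"]) == 5
        assert len(out["b_only"]) == 16

    def test_identical_results_have_empty_only_sets(self):
        frame = pd.DataFrame({"gene": ["g1"], "snp": ["rs1"], "q": [0.01], "p": [1e-5], "beta": [1.0]})
        v = venn(frame, frame.copy())
        assert v.egenes_a_only == set() == v.egenes_b_only
        assert v.egenes_shared == {"g1"}

    def test_random_sets_match_brute_force(self, rng):
        def frame(genes):
            return pd.DataFrame({
                "gene": genes, "snp": [f"rs{g}" for g in genes],
                "q": [0.01] * len(genes), "p": [1e-4] * len(genes), "beta": [1.0] * len(genes),
            })

        ga = [f"g{i}" for i in rng.choice(50, 20, replace=False)]
        gb = [f"g{i}" for i in rng.choice(50, 25, replace=False)]
        v = venn(frame(ga), frame(gb))
        assert v.egenes_shared == set(ga) & set(gb)
        assert v.egenes_a_only == set(ga) - set(gb)
        assert v.egenes_b_only == set(gb) - set(ga)
        c = v.counts()
        assert c["egenes_a"] == len(set(ga)) and c["egenes_b"] == len(set(gb))


class TestSelectRvThreshold:
    def _table(self, taus, enr, negenes):
        return pd.DataFrame({"tau": taus, "enrichment": enr, "n_egenes": negenes})

    def test_default_is_085(self):
        tab = self._table([0.5, 0.85, 0.95], [4.0, 6.5, 8.9], [153, 43, 22])
        tau, scores, _ = select_rv_threshold(tab)
        assert tau == 0.85

    def test_flat_enrichment_flags_smallest_threshold(self):
        tab = self._table([0.5, 0.7, 0.9], [3.0, 3.0, 3.0], [100, 80, 60])
        _, _, advisory = select_rv_threshold(tab)
        assert advisory == 0.5

    def test_advisory_score_matches_hand_computation(self):
        tab = self._table([0.5, 0.7, 0.9], [4.0, 5.0, 8.0], [100, 90, 50])
        _, scores, advisory = select_rv_threshold(tab)
        assert scores.loc[0.7] == pytest.approx((5.0 - 4.0) / 10)
        assert scores.loc[0.9] == pytest.approx((8.0 - 5.0) / 40)
        assert advisory == 0.7


class TestInteractionTest:
    def _data(self, rng, n=300, beta_int=0.5):
        z = (rng.random(n) < 0.4).astype(float)
        d = rng.binomial(2, 0.35, n).astype(float)
        y = 0.2 * d + 0.3 * z + beta_int * d * z + rng.normal(size=n)
        return y, d, z

    def test_planted_interaction_recovered(self, rng):
        y, d, z = self._data(rng)
        res = interaction_test(y, d, z, gene_id="g", snp_id="rs")
        x = np.column_stack([np.ones_like(y), d, z, d * z])
        h = np.linalg.inv(x.T @ x)
        resid = y - x @ (h @ x.T @ y)
        se = np.sqrt(resid @ resid / (len(y) - 4) * h[3, 3])
        assert abs(res.coef_interaction - 0.5) < 2 * se
        assert res.conditional

    def test_matches_closed_form_ols_and_f_oracle(self, rng):
        y, d, z = self._data(rng, n=80)
        res = interaction_test(y, d, z)
        x = np.column_stack([np.ones_like(y), d, z, d * z])
        xtx_inv = np.linalg.inv(x.T @ x)
        beta = xtx_inv @ x.T @ y
        resid = y - x @ beta
        df = len(y) - 4
        s2 = resid @ resid / df
        t_stats = beta / np.sqrt(s2 * np.diag(xtx_inv))
        p_coef = 2 * stats.t.sf(np.abs(t_stats), df)
        tss = np.sum((y - y.mean()) ** 2)
        f = ((tss - resid @ resid) / 3) / s2
        p_f = stats.f.sf(f, 3, df)
        assert res.p_snp == pytest.approx(p_coef[1], abs=1e-10)
        assert res.p_group == pytest.approx(p_coef[2], abs=1e-10)
        assert res.p_interaction == pytest.approx(p_coef[3], abs=1e-10)
        assert res.p_model == pytest.approx(p_f, abs=1e-10)
        assert res.coef_interaction == pytest.approx(beta[3], abs=1e-10)

    def test_null_interaction_p_uniform(self, rng):
        pvals = []
        for _ in range(400):
            y, d, z = self._data(rng, n=60, beta_int=0.0)
            pvals.append(interaction_test(y, d, z).p_interaction)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_empty_stratum_warns_but_returns(self, rng):
        # no disease sample carries the alt allele: d*z is identically zero
        z = np.array([0.0] * 20 + [1.0] * 20)
        d = np.concatenate([np.tile([0.0, 1, 2], 7)[:20], np.zeros(20)])
        res = interaction_test(rng.normal(size=40), d, z)
        assert res.warning is not None

    def test_constant_dosage_is_an_error(self, rng):
        with pytest.raises(ValueError):
            interaction_test(rng.normal(size=20), np.ones(20), (rng.random(20) < 0.5).astype(float))


class TestStratifiedExport:
    def test_small_join(self):
        idx = ["a", "b", "c", "d"]
        out = stratified_export(
            pd.Series([5.0, 6, 7, 8], index=idx),
            pd.Series([0.0, 1, 2, 1], index=idx),
            pd.Series(["CTRL", "PE", "CTRL", "IUGR"], index=idx),
        )
        assert len(out) == 4
        assert list(out.columns) == ["sample", "genotype", "group", "expression"]
        assert out.loc[out["sample"] == "b", "genotype"].iloc[0] == 1

    def test_missing_genotype_dropped(self):
        idx = ["a", "b", "c"]
        out = stratified_export(
            pd.Series([5.0, 6, 7], index=idx),
            pd.Series([0.0, np.nan, 2], index=idx),
            pd.Series(["CTRL", "PE", "CTRL"], index=idx),
        )
        assert list(out["sample"]) == ["a", "c"]

    def test_group_counts_preserved(self, rng):
        n = 30
        idx = [f"S{i}" for i in range(n)]
        group = pd.Series(rng.choice(["CTRL", "PE"], n), index=idx)
        out = stratified_export(
            pd.Series(rng.normal(size=n), index=idx),
            pd.Series(rng.binomial(2, 0.4, n).astype(float), index=idx),
            group,
        )
        assert out["group"].value_counts().to_dict() == group.value_counts().to_dict()


@pytest.fixture(scope="module")
def fitted(small_dataset):
    from placeqtl.pipeline import PipelineConfig, run_pipeline

    return run_pipeline(PipelineConfig(tau=0.5, seed=11), dataset=small_dataset)


class TestTwoPass:

    def test_minus_disease_input_counts_dominate(self, fitted):
        counts_a = fitted.results.fits[ALL_COVARIATES].rv_table.counts()
        counts_b = fitted.results.fits[MINUS_DISEASE].rv_table.counts()
        assert (counts_b >= counts_a).all()

    def test_enrichment_table_covers_full_grid(self, fitted):
        for name in (ALL_COVARIATES, MINUS_DISEASE):
            tab = fitted.results.fits[name].enrichment
            assert len(tab) == 10
            assert (np.diff(tab["n_input_genes"]) <= 0).all()  # nested gene sets

    def test_design_columns_differ_by_group_and_disease_pcs(self, fitted):
        a = fitted.results.fits[ALL_COVARIATES].design.columns
        b = fitted.results.fits[MINUS_DISEASE].design.columns
        diff = set(a) - set(b)
        assert "Group" in diff
        assert all(c == "Group" or c.startswith("ExprPC") for c in diff)

    def test_summary_renders(self, fitted):
        text = fitted.results.summary()
        assert "Two-pass subtraction" in text and "eGenes" in text
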