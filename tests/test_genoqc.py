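"""Genotype QC: call rates, MAF, the exact HWE test, LD pruning, the
heterozygosity F statistic, the full filter chain, and genotype PCA."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from placeqtl import genoqc
from placeqtl.datatypes import GenotypeMatrix


def _gm(dosage_rows, positions=None, chrom="chr1"):
    """Build a GenotypeMatrix from a samples x snps array."""
    arr = np.asarray(dosage_rows, dtype=float)
    n, m = arr.shape
    pos = positions if positions is not None else np.arange(1, m + 1) * 1000
    ids = [f"rs{j}" for j in range(m)]
    meta = pd.DataFrame(
        {"chrom": chrom, "pos": pos, "ref": "A", "alt": "B"},
        index=pd.Index(ids, name="snp"),
    )
    dosage = pd.DataFrame(arr, index=[f"S{i}" for i in range(n)], columns=ids)
    return GenotypeMatrix(dosage, meta)


def hwe_enumeration_oracle(naa, nab, nbb):
    """Exact-rational enumeration of the conditional heterozygote-count
    distribution; independent of the log-space implementation."""
    n = naa + nab + nbb
    minor = min(2 * naa + nab, 2 * nbb + nab)
    probs = {}
    den = Fraction(math.factorial(2 * n), math.factorial(minor) * math.factorial(2 * n - minor))
    for h in range(minor % 2, minor + 1, 2):
        hom_min = (minor - h) // 2
        hom_maj = n - h - hom_min
        num = Fraction(
            math.factorial(n),
            math.factorial(hom_min) * math.factorial(h) * math.factorial(hom_maj),
        ) * Fraction(2) ** h
        probs[h] = num / den
    pobs = probs[nab]
    return float(sum(p for p in probs.values() if p <= pobs))


class TestCallRatesAndMaf:
    def test_no_missing_gives_zero_rates(self):
        g = _gm([[0, 1], [2, 1]])
        s, m = genoqc.call_rates(g)
        assert (s == 0).all() and (m == 0).all()

    def test_single_missing_fraction(self):
        arr = np.zeros((5, 2))
        arr[0, 0] = np.nan
        s, m = genoqc.call_rates(_gm(arr))
        assert s.iloc[0] == 0.5 and m.iloc[0] == 0.2

    def test_random_mask_mean_rate(self, rng):
        arr = rng.binomial(2, 0.4, (100, 100)).astype(float)
        mask = rng.random((100, 100)) < 0.05
        arr[mask] = np.nan
        _, m = genoqc.call_rates(_gm(arr))
        assert abs(m.mean() - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 10_000)

    @pytest.mark.parametrize(
        "col,expected",
        [([0, 0, 1, 2], 0.375), ([2, 2, 2, 2], 0.0), ([1, 1, 1, 1], 0.5)],
    )
    def test_maf_examples(self, col, expected):
        assert genoqc.maf(_gm(np.array(col)[:, None])).iloc[0] == pytest.approx(expected)

    def test_maf_converges_to_generating_frequency(self, rng):
        arr = rng.binomial(2, 0.3, (10_000, 1)).astype(float)
        m = genoqc.maf(_gm(arr)).iloc[0]
        assert abs(m - 0.3) < 3 * np.sqrt(0.3 * 0.7 / 20_000)

    def test_stats_invariant_to_sample_order(self, rng):
        arr = rng.binomial(2, 0.3, (30, 10)).astype(float)
        arr[rng.random((30, 10)) < 0.1] = np.nan
        g = _gm(arr)
        perm = rng.permutation(30)
        gp = GenotypeMatrix(g.dosage.iloc[perm], g.snp_meta)
        pd.testing.assert_series_equal(genoqc.maf(g), genoqc.maf(gp))
        pd.testing.assert_series_equal(genoqc.call_rates(g)[1], genoqc.call_rates(gp)[1])


class TestHweExact:
    def test_monomorphic_probability_one(self):
        assert genoqc.hwe_exact_test(25, 0, 0) == 1.0

    @pytest.mark.parametrize("counts", [(20, 30, 7), (0, 50, 0), (5, 5, 5), (1, 0, 1)])
    def test_matches_exact_rational_enumeration(self, counts):
        assert genoqc.hwe_exact_test(*counts) == pytest.approx(
            hwe_enumeration_oracle(*counts), rel=1e-10
        )

    def test_extreme_het_excess_below_qc_threshold(self):
        assert genoqc.hwe_exact_test(0, 50, 0) < 1e-6

    @given(
        st.integers(min_value=0, max_value=20),
        st.integers(min_value=0, max_value=20),
        st.integers(min_value=0, max_value=20),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_allele_label_symmetry_and_range(self, a, b, c):
        if a + b + c == 0:
            return
        p = genoqc.hwe_exact_test(a, b, c)
        assert 0 < p <= 1
        assert p == pytest.approx(genoqc.hwe_exact_test(c, b, a), rel=1e-12)


class TestLd:
    def test_identical_snps_r2_one(self):
        g = np.array([0.0, 1, 2, 1, 0, 2])
        assert genoqc.ld_r2(g, g) == pytest.approx(1.0)

    def test_orthogonal_dosages_r2_zero(self):
        g1 = np.array([0.0, 0, 1, 1, 2, 2])
        g2 = np.array([0.0, 2, 1, 1, 2, 0])  # zero covariance with g1
        assert genoqc.ld_r2(g1, g2) == pytest.approx(0.0, abs=1e-12)

    def test_matches_pearson_formula(self, rng):
        g1 = rng.binomial(2, 0.4, 6).astype(float)
        g2 = rng.binomial(2, 0.4, 6).astype(float)
        x, y = g1 - g1.mean(), g2 - g2.mean()
        expected = (x @ y) ** 2 / ((x @ x) * (y @ y))
        assert genoqc.ld_r2(g1, g2) == pytest.approx(expected, rel=1e-12)

    def test_constant_snp_not_prunable(self):
        assert np.isnan(genoqc.ld_r2(np.ones(6), np.array([0.0, 1, 2, 0, 1, 2])))

    def test_independent_snps_mostly_kept(self, rng):
        arr = rng.binomial(2, 0.4, (200, 60)).astype(float)
        kept = genoqc.ld_prune(_gm(arr))
        assert len(kept) >= 55

    def test_duplicated_column_later_copy_removed(self, rng):
        arr = rng.binomial(2, 0.4, (50, 10)).astype(float)
        arr[:, 7] = arr[:, 2]  # duplicate; rs7 is the later copy
        kept = genoqc.ld_prune(_gm(arr))
        assert "rs2" in kept and "rs7" not in kept

    def test_small_fixture_matches_hand_greedy_oracle(self, rng):
        arr = rng.binomial(2, 0.4, (40, 8)).astype(float)
        arr[:, 3] = arr[:, 0]
        arr[:, 6] = np.clip(arr[:, 1] + (rng.random(40) < 0.05), 0, 2)
        g = _gm(arr)
        kept = genoqc.ld_prune(g, window=8, step=2, r2_max=0.2)
        # hand-simulated single window pass (all 8 SNPs fit in one window)
        removed = set()
        for a in range(8):
            if f"rs{a}" in removed:
                continue
            for b in range(a + 1, 8):
                if f"rs{b}" in removed:
                    continue
                r2 = genoqc.ld_r2(arr[:, a], arr[:, b])
                if not np.isnan(r2) and r2 >= 0.2:
                    removed.add(f"rs{b}")
        assert set(kept) == {f"rs{j}" for j in range(8)} - removed

    def test_no_offending_pair_survives(self, rng):
        arr = rng.binomial(2, 0.4, (60, 30)).astype(float)
        for j in range(0, 30, 4):  # plant heavy local LD
            arr[:, j + 1] = np.clip(arr[:, j] + (rng.random(60) < 0.1), 0, 2)
        g = _gm(arr)
        kept = genoqc.ld_prune(g, window=10, step=2, r2_max=0.2)
        idx = {s: j for j, s in enumerate(g.snp_ids)}
        for a_i, a in enumerate(kept):
            for b in kept[a_i + 1 : a_i + 10]:
                r2 = genoqc.ld_r2(arr[:, idx[a]], arr[:, idx[b]])
                assert np.isnan(r2) or r2 < 0.2


class TestHeterozygosityF:
    def test_hwe_sample_has_f_near_zero(self, rng):
        arr = rng.binomial(2, 0.5, (200, 2000)).astype(float)
        f = genoqc.heterozygosity_f(_gm(arr))
        assert abs(f.mean()) < 0.02

    def test_fully_heterozygous_sample_flagged(self, rng):
        arr = rng.binomial(2, 0.5, (100, 1000)).astype(float)
        arr[0, :] = 1.0  # heterozygous everywhere: contamination-like
        f = genoqc.heterozygosity_f(_gm(arr))
        assert f.iloc[0] < -0.8 and f.iloc[0] < -0.05

    def test_fully_homozygous_sample_positive_f(self, rng):
        arr = rng.binomial(2, 0.5, (100, 1000)).astype(float)
        arr[0, :] = np.where(rng.random(1000) < 0.5, 0.0, 2.0)
        f = genoqc.heterozygosity_f(_gm(arr))
        assert f.iloc[0] > 0.8


class TestRunQc:
    def test_clean_data_nothing_removed(self, rng):
        # enough SNPs that the per-sample F statistic is tight around zero
        arr = rng.binomial(2, rng.uniform(0.2, 0.5, 5000), (60, 5000)).astype(float)
        g = _gm(arr)
        clean, report = genoqc.run_qc(g)
        assert clean.n_samples == 60
        assert len(report.samples_removed) == 0
        # hwe removals possible but should be rare on HWE draws
        assert len(report.snps_removed) <= 2

    def test_high_missingness_sample_removed_with_reason(self, rng):
        arr = rng.binomial(2, 0.4, (60, 200)).astype(float)
        arr[0, rng.random(200) < 0.05] = np.nan
        clean, report = genoqc.run_qc(_gm(arr))
        assert "S0" not in clean.sample_ids
        assert report.samples_removed.at["S0", "reason"] == "missingness"

    def test_all_het_snp_removed_for_hwe(self, rng):
        arr = rng.binomial(2, 0.4, (60, 100)).astype(float)
        arr[:, 10] = 1.0
        clean, report = genoqc.run_qc(_gm(arr))
        assert "rs10" not in clean.snp_ids
        assert report.snps_removed.at["rs10", "reason"] == "hwe"

    def test_idempotent(self, rng):
        # idempotence needs the F statistic well resolved, hence many SNPs
        arr = rng.binomial(2, 0.4, (60, 5000)).astype(float)
        arr[0, rng.random(5000) < 0.05] = np.nan
        arr[:, 5] = 1.0
        clean, _ = genoqc.run_qc(_gm(arr))
        again, report2 = genoqc.run_qc(clean)
        assert again.sample_ids == clean.sample_ids
        assert again.snp_ids == clean.snp_ids
        assert len(report2.samples_removed) == 0 and len(report2.snps_removed) == 0


class TestGenotypePca:
    def test_scores_orthogonal(self, rng):
        arr = rng.binomial(2, rng.uniform(0.2, 0.5, 100), (40, 100)).astype(float)
        scores, varexp = genoqc.genotype_pca(_gm(arr), n_pcs=5)
        s = scores.to_numpy()
        off = s.T @ s - np.diag(np.diag(s.T @ s))
        assert np.abs(off).max() < 1e-8
        assert (np.diff(varexp.to_numpy()) <= 1e-12).all()

    def test_eigenvalues_match_dense_svd_oracle(self, rng):
        arr = rng.binomial(2, rng.uniform(0.2, 0.5, 50), (20, 50)).astype(float)
        scores, varexp = genoqc.genotype_pca(_gm(arr), n_pcs=5)
        p = arr.mean(axis=0) / 2
        keep = (p > 0) & (p < 1)
        x = (arr[:, keep] - 2 * p[keep]) / np.sqrt(2 * p[keep] * (1 - p[keep]))
        x = x - x.mean(axis=0)
        sv = np.linalg.svd(x, compute_uv=False)
        np.testing.assert_allclose(
            (scores.to_numpy() ** 2).sum(axis=0), sv[:5] ** 2, rtol=1e-8
        )

    def test_fewer_samples_than_requested_pcs(self, rng):
        arr = rng.binomial(2, 0.4, (4, 30)).astype(float)
        scores, _ = genoqc.genotype_pca(_gm(arr), n_pcs=10)
        assert scores.shape[1] == 3
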