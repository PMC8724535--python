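"""Genotype QC: sample filters, kinship, HWE, PCA, variant filters."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ppdprs.qc import (
    GenotypeMatrix,
    QCReport,
    QCThresholds,
    VariantInfo,
    estimate_kinship,
    hwe_test,
    kinship_filter,
    pca_project,
    run_qc,
    sample_qc,
    variant_qc,
)
from ppdprs.simulate import SimulationConfig, simulate_genotypes


def make_matrix(dosages, chrom="1", alleles=None, positions=None):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    alleles = alleles or [("A", "G")] * m
    positions = positions or [1000 * (j + 1) for j in range(m)]
    variants = [
        VariantInfo(chrom=chrom, pos=positions[j], ref_allele=alleles[j][0], alt_allele=alleles[j][1])
        for j in range(m)
    ]
    mat = GenotypeMatrix([f"s{i:03d}" for i in range(n)], variants, dosages)
    mat.refresh_metadata()
    return mat


class TestHweTest:
    def test_exact_hwe_proportions_give_p_one(self):
        assert hwe_test(25, 50, 25) == pytest.approx(1.0)

    def test_all_heterozygous_fails_hard(self):
        assert hwe_test(0, 1000, 0) < 5e-8

    def test_matches_closed_form_oracle_on_random_triples(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            n_aa, n_ab, n_bb = rng.integers(1, 500, size=3)
            n = n_aa + n_ab + n_bb
            p = (2 * n_aa + n_ab) / (2 * n)
            expected = n * np.array([p**2, 2 * p * (1 - p), (1 - p) ** 2])
            chi2 = (((np.array([n_aa, n_ab, n_bb]) - expected) ** 2) / expected).sum()
            oracle = float(stats.chi2.sf(chi2, 1))
            ours = hwe_test(int(n_aa), int(n_ab), int(n_bb))
            assert ours == pytest.approx(oracle, rel=1e-10)

    def test_monomorphic_fits_trivially(self):
        assert hwe_test(100, 0, 0) == 1.0

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_test(0, 0, 0)


class TestSampleQC:
    def test_high_missingness_sample_excluded(self, rng):
        dosages = rng.binomial(2, 0.3, size=(50, 200)).astype(float)
        dosages[0, : int(200 * 0.06)] = np.nan  # 6% missing
        report = sample_qc(make_matrix(dosages), QCThresholds())
        assert report.excluded_samples.get("s000") == "missingness"
        assert "s001" not in report.excluded_samples

    def test_all_het_sample_excluded_for_heterozygosity(self, rng):
        dosages = rng.binomial(2, 0.3, size=(500, 300)).astype(float)
        dosages[7, :] = 1.0
        report = sample_qc(make_matrix(dosages), QCThresholds())
        assert report.excluded_samples.get("s007") == "heterozygosity"

    def test_sex_check_logged_as_skipped(self, rng):
        report = sample_qc(make_matrix(rng.binomial(2, 0.3, (20, 50))), QCThresholds())
        assert any("sex-check skipped" in note for note in report.notes)

    def test_result_independent_of_row_order(self, rng):
        dosages = rng.binomial(2, 0.3, size=(60, 200)).astype(float)
        dosages[3, :15] = np.nan
        mat = make_matrix(dosages)
        rep1 = sample_qc(mat, QCThresholds())
        perm = rng.permutation(60)
        mat2 = GenotypeMatrix([mat.individual_ids[i] for i in perm], mat.variants, dosages[perm])
        rep2 = sample_qc(mat2, QCThresholds())
        assert rep1.excluded_samples == rep2.excluded_samples


class TestKinship:
    def test_duplicate_pair_near_one(self, rng):
        dosages = rng.binomial(2, rng.uniform(0.1, 0.5, 800), size=(40, 800)).astype(float)
        dosages[1] = dosages[0]
        flip = rng.random(800) < 0.01
        dosages[1, flip] = 2 - dosages[1, flip]
        K = estimate_kinship(make_matrix(dosages))
        assert K.iloc[0, 1] > 0.9

    def test_independent_pair_near_zero(self, rng):
        dosages = rng.binomial(2, rng.uniform(0.1, 0.5, 5000), size=(2, 5000)).astype(float)
        K = estimate_kinship(make_matrix(dosages))
        assert K.iloc[0, 1] < 0.05

    def test_self_kinship_is_one(self, rng):
        K = estimate_kinship(make_matrix(rng.binomial(2, 0.3, (5, 100))))
        assert (np.diag(K) == 1.0).all()

    def test_requires_two_samples(self, rng):
        with pytest.raises(ValueError):
            estimate_kinship(make_matrix(rng.binomial(2, 0.3, (1, 50))))


class TestKinshipFilter:
    @staticmethod
    def kframe(ids, entries):
        K = pd.DataFrame(0.0, index=ids, columns=ids)
        np.fill_diagonal(K.values, 1.0)
        for a, b, v in entries:
            K.loc[a, b] = K.loc[b, a] = v
        return K

    def test_single_pair_one_member_removed(self):
        K = self.kframe(["a", "b", "c"], [("a", "b", 0.9)])
        removed = kinship_filter(K)
        assert removed == ["b"]  # equal missingness: lexicographically larger goes

    def test_higher_missingness_member_removed(self):
        K = self.kframe(["a", "b"], [("a", "b", 0.9)])
        miss = pd.Series({"a": 0.04, "b": 0.01})
        assert kinship_filter(K, sample_missingness=miss) == ["a"]

    def test_no_pairs_no_removals(self):
        K = self.kframe(["a", "b"], [])
        assert kinship_filter(K) == []

    def test_triangle_leaves_no_flagged_pair(self):
        K = self.kframe(["a", "b", "c"], [("a", "b", 0.3), ("a", "c", 0.3), ("b", "c", 0.3)])
        removed = kinship_filter(K)
        assert len(removed) <= 2
        kept = [i for i in K.index if i not in removed]
        sub = K.loc[kept, kept].to_numpy()
        assert (sub[~np.eye(len(kept), dtype=bool)] <= 0.125).all()

    def test_skip_set_pairs_ignored(self):
        K = self.kframe(["a", "b"], [("a", "b", 0.9)])
        assert kinship_filter(K, skip=frozenset({"a"})) == []


class TestPca:
    def test_two_subpopulations_separate_on_pc1(self, rng):
        freqs_a = rng.uniform(0.1, 0.5, 300)
        shift = np.where(rng.random(300) < 0.5, 0.3, -0.08)
        freqs_b = np.clip(freqs_a + shift, 0.02, 0.95)
        dos = np.vstack(
            [rng.binomial(2, freqs_a, (60, 300)), rng.binomial(2, freqs_b, (60, 300))]
        ).astype(float)
        pcs, _ = pca_project(make_matrix(dos), k=2)
        label = np.array([0] * 60 + [1] * 60)
        r = np.corrcoef(pcs["PC1"], label)[0, 1]
        assert abs(r) > 0.9

    def test_components_are_orthonormal(self, rng):
        pcs, _ = pca_project(make_matrix(rng.binomial(2, 0.3, (50, 200))), k=4)
        U = pcs.to_numpy()
        assert np.allclose(U.T @ U, np.eye(4), atol=1e-8)

    def test_homogeneous_cohort_has_no_outliers(self, rng):
        _, outliers = pca_project(make_matrix(rng.binomial(2, 0.3, (100, 400))), k=2)
        assert outliers == []

    def test_k_beyond_rank_rejected(self, rng):
        with pytest.raises(ValueError, match="rank"):
            pca_project(make_matrix(rng.binomial(2, 0.3, (4, 100))), k=5)


class TestVariantQC:
    def test_ambiguous_high_maf_excluded_low_maf_kept(self, rng):
        high = rng.binomial(2, 0.45, 400)
        low = rng.binomial(2, 0.10, 400)
        mat = make_matrix(np.column_stack([high, low]), alleles=[("A", "T"), ("C", "G")])
        report = variant_qc(mat, QCThresholds())
        reasons = {k.split("#")[0]: v for k, v in report.excluded_variants.items()}
        assert reasons.get(mat.variants[0].key) == "ambiguous"
        assert mat.variants[1].key not in reasons

    def test_duplicate_keeps_lowest_missingness(self, rng):
        base = rng.binomial(2, 0.3, 200).astype(float)
        a = base.copy()
        b = base.copy()
        b[:6] = np.nan  # 3% missing vs 0%
        mat = make_matrix(np.column_stack([b, a]), positions=[500, 500])
        report = variant_qc(mat, QCThresholds())
        assert report.excluded_variants == {mat.variants[0].key + "#0": "duplicate"}

    def test_batchwise_missingness_rule(self, rng):
        dosages = rng.binomial(2, 0.3, size=(100, 2)).astype(float)
        # 8% missing but only within batch B (50 samples -> 8 missing calls)
        dosages[50:58, 0] = np.nan
        labels = ["A"] * 50 + ["B"] * 50
        report = variant_qc(make_matrix(dosages), QCThresholds(), batch_labels=labels)
        reasons = {k.split("#")[0]: v for k, v in report.excluded_variants.items()}
        assert reasons.get("1:1000:A:G") == "missingness"

    def test_differential_missingness_detected(self, rng):
        dosages = rng.binomial(2, 0.3, size=(2000, 1)).astype(float)
        # batch B missing 4.5% vs batch A 0%: under both per-batch bound, clearly differential
        miss_idx = 1000 + rng.choice(1000, size=45, replace=False)
        dosages[miss_idx, 0] = np.nan
        labels = ["A"] * 1000 + ["B"] * 1000
        report = variant_qc(make_matrix(dosages), QCThresholds(), batch_labels=labels)
        assert list(report.excluded_variants.values()) == ["differential_missingness"]

    def test_bad_batch_labels_rejected(self, rng):
        with pytest.raises(ValueError, match="batch_labels"):
            variant_qc(make_matrix(rng.binomial(2, 0.3, (10, 2))), QCThresholds(), batch_labels=["A"] * 3)


class TestRunQC:
    def test_idempotent_on_clean_cohort(self):
        # enough variants that pairwise kinship noise sits far below the cut-off
        mat = simulate_genotypes(SimulationConfig(n_individuals=100, n_variants=2000, seed=21))
        clean1, _ = run_qc(mat)
        clean2, _ = run_qc(clean1)
        assert clean2.individual_ids == clean1.individual_ids
        assert [v.key for v in clean2.variants] == [v.key for v in clean1.variants]

    def test_report_exports_mdsc_covariates(self):
        mat = simulate_genotypes(SimulationConfig(n_individuals=80, n_variants=1500, seed=22))
        clean, report = run_qc(mat)
        mdsc = report.mdsc
        assert list(mdsc.columns) == ["MDSC1", "MDSC2"]
        assert set(mdsc.index) == set(clean.individual_ids)

    def test_exclusions_have_single_primary_reason(self):
        report = QCReport()
        report.exclude_sample("x", "missingness")
        report.exclude_sample("x", "heterozygosity")
        assert report.excluded_samples == {"x": "missingness"}
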