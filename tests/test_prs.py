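"""C+T PRS engine: harmonization, clumping, thresholding, scoring, quartiles."""

import numpy as np
import pandas as pd
import pytest

from ppdprs.prs import (
    ClumpParams,
    SummaryStatRecord,
    ThresholdSet,
    build_prs,
    clump,
    filter_target,
    harmonize,
    quartilize,
    score,
    select_by_threshold,
)
from ppdprs.qc import GenotypeMatrix, VariantInfo


def make_matrix(dosages, positions=None, chrom="1", alleles=None):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    positions = positions or [1000 * (j + 1) for j in range(m)]
    alleles = alleles or [("A", "G")] * m
    variants = [
        VariantInfo(chrom=chrom, pos=positions[j], ref_allele=alleles[j][0], alt_allele=alleles[j][1])
        for j in range(m)
    ]
    mat = GenotypeMatrix([f"s{i}" for i in range(n)], variants, dosages)
    mat.refresh_metadata()
    return mat


def vframe(matrix):
    return pd.DataFrame(
        {
            "chrom": [v.chrom for v in matrix.variants],
            "pos": [v.pos for v in matrix.variants],
            "ref_allele": [v.ref_allele for v in matrix.variants],
            "alt_allele": [v.alt_allele for v in matrix.variants],
            "maf": [v.maf for v in matrix.variants],
            "call_rate": [v.call_rate for v in matrix.variants],
            "info_score": [v.info_score for v in matrix.variants],
            "var_idx": np.arange(matrix.n_variants),
        }
    )


def sumstat(pos, ea="G", oa="A", beta=0.3, p=1e-4, chrom="1"):
    return SummaryStatRecord(chrom=chrom, pos=pos, effect_allele=ea, other_allele=oa, beta=beta, pvalue=p)


class TestHarmonize:
    def test_direct_match_keeps_beta(self):
        mat = make_matrix([[0, 1], [2, 1]])
        matched, counts = harmonize(vframe(mat), [sumstat(1000, ea="G", oa="A", beta=0.3)])
        assert counts["matched"] == 1
        assert matched["beta"].iloc[0] == 0.3

    def test_swapped_alleles_negate_beta(self):
        mat = make_matrix([[0, 1], [2, 1]])
        matched, counts = harmonize(vframe(mat), [sumstat(1000, ea="A", oa="G", beta=0.3)])
        assert counts["allele_swap"] == 1
        assert matched["beta"].iloc[0] == -0.3

    def test_strand_flip_resolves(self):
        # target A/G; sumstat T/C is the complement strand for (A, G) swapped order
        mat = make_matrix([[0, 1], [2, 1]])
        matched, counts = harmonize(vframe(mat), [sumstat(1000, ea="C", oa="T", beta=0.3)])
        assert counts["strand_flip"] == 1
        assert matched["beta"].iloc[0] == 0.3
        matched, _ = harmonize(vframe(mat), [sumstat(1000, ea="T", oa="C", beta=0.3)])
        assert matched["beta"].iloc[0] == -0.3

    def test_ambiguous_needing_flip_dropped(self):
        mat = make_matrix([[0, 1], [2, 1]], alleles=[("A", "T"), ("A", "G")])
        # sumstat G/C at an A/T target: only a flip could match — dropped
        matched, counts = harmonize(vframe(mat), [sumstat(1000, ea="G", oa="C", beta=0.3)])
        assert counts["ambiguous_dropped"] == 1
        assert matched.empty

    def test_unmatched_position_dropped(self):
        mat = make_matrix([[0, 1], [2, 1]])
        _, counts = harmonize(vframe(mat), [sumstat(999_999)])
        assert counts["unmatched"] == 1

    def test_duplicate_target_positions_rejected(self):
        mat = make_matrix([[0, 1], [2, 1]], positions=[1000, 1000])
        with pytest.raises(ValueError, match="duplicate"):
            harmonize(vframe(mat), [sumstat(1000)])


class TestFilterTarget:
    def test_boundaries_are_strict(self):
        frame = pd.DataFrame(
            {
                "maf": [0.05, 0.051, 0.3],
                "call_rate": [0.99, 0.95, 0.99],
                "info_score": [0.9, 0.9, 0.4],
            }
        )
        kept = filter_target(frame)
        # maf == 0.05 excluded, call_rate == 0.95 excluded, info == 0.4 excluded
        assert kept.empty

    def test_passing_variant_kept_and_missing_info_defaults(self):
        frame = pd.DataFrame({"maf": [0.30], "call_rate": [0.99], "info_score": [np.nan]})
        assert len(filter_target(frame)) == 1


def brute_force_clump(df, r2, params):
    """Independent reference: literal restatement of greedy clumping on a dict of r2."""
    remaining = df.sort_values(["pvalue", "chrom", "pos"], kind="mergesort").reset_index(drop=True)
    remaining = remaining[
        ~remaining.apply(
            lambda r: any(
                str(c) == str(r.chrom) and lo <= r.pos <= hi for c, lo, hi in params.excluded_regions
            ),
            axis=1,
        )
    ].reset_index(drop=True)
    alive = list(remaining.index)
    picked = []
    while alive:
        best = alive[0]
        picked.append(best)
        survivors = []
        for i in alive[1:]:
            same_chrom = remaining.chrom[i] == remaining.chrom[best]
            near = abs(remaining.pos[i] - remaining.pos[best]) <= params.window_kb * 1000
            key = tuple(sorted((remaining.var_idx[best], remaining.var_idx[i])))
            if same_chrom and near and r2.get(key, 0.0) > params.r2_max:
                continue
            survivors.append(i)
        alive = survivors
    return remaining.loc[picked].reset_index(drop=True)


def pairwise_r2(matrix):
    X = matrix.dosages.astype(float)
    mean = np.nanmean(X, axis=0)
    X = np.where(np.isnan(X), mean, X)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(X.T)
    corr = np.nan_to_num(corr)
    return {
        (i, j): corr[i, j] ** 2
        for i in range(matrix.n_variants)
        for j in range(i + 1, matrix.n_variants)
    }


class TestClump:
    def test_single_snp_is_its_own_index(self):
        mat = make_matrix(np.random.default_rng(0).integers(0, 3, (30, 1)))
        matched, _ = harmonize(vframe(mat), [sumstat(1000)])
        out = clump(matched, mat)
        assert len(out) == 1

    def test_correlated_neighbour_removed(self, rng):
        base = rng.integers(0, 3, (200, 1)).astype(float)
        dosages = np.hstack([base, base])  # r2 = 1
        mat = make_matrix(dosages, positions=[10_000, 20_000])
        matched, _ = harmonize(
            vframe(mat), [sumstat(10_000, p=1e-10), sumstat(20_000, p=1e-4)]
        )
        out = clump(matched, mat)
        assert out["pos"].tolist() == [10_000]

    def test_far_apart_snps_both_kept(self, rng):
        base = rng.integers(0, 3, (200, 1)).astype(float)
        dosages = np.hstack([base, base])
        mat = make_matrix(dosages, positions=[10_000, 310_000])  # 300 kb apart
        matched, _ = harmonize(
            vframe(mat), [sumstat(10_000, p=1e-10), sumstat(310_000, p=1e-4)]
        )
        out = clump(matched, mat)
        assert len(out) == 2

    def test_mhc_region_removed(self, rng):
        dosages = rng.integers(0, 3, (50, 2)).astype(float)
        mat = make_matrix(dosages, positions=[28_000_000, 40_000_000], chrom="6")
        matched, _ = harmonize(
            vframe(mat),
            [sumstat(28_000_000, p=1e-12, chrom="6"), sumstat(40_000_000, p=1e-4, chrom="6")],
        )
        out = clump(matched, mat)
        assert out["pos"].tolist() == [40_000_000]

    def test_empty_input_gives_empty_output(self):
        mat = make_matrix([[0.0], [1.0]])
        out = clump(pd.DataFrame(columns=["chrom", "pos", "var_idx", "beta", "pvalue"]), mat)
        assert out.empty

    def test_matches_brute_force_on_random_fixtures(self):
        rng = np.random.default_rng(77)
        params = ClumpParams()
        for _ in range(25):
            m = int(rng.integers(2, 30))
            n = 120
            dosages = rng.binomial(2, rng.uniform(0.1, 0.5, m), size=(n, m)).astype(float)
            positions = np.sort(rng.integers(1, 2_000_000, m)).tolist()
            mat = make_matrix(dosages, positions=positions)
            stats_list = [
                sumstat(positions[j], p=float(rng.uniform(1e-12, 1)), beta=float(rng.normal()))
                for j in range(m)
            ]
            matched, _ = harmonize(vframe(mat), stats_list)
            ours = clump(matched, mat, params)
            ref = brute_force_clump(matched, pairwise_r2(mat), params)
            pd.testing.assert_frame_equal(ours, ref)


class TestSelectByThreshold:
    def test_nested_and_counts(self):
        clumped = pd.DataFrame(
            {"chrom": "1", "pos": range(5), "var_idx": range(5), "beta": 0.1, "pvalue": [1e-9, 1e-5, 0.01, 0.2, 0.6]}
        )
        assert len(select_by_threshold(clumped, 1.0)) == 5
        strict = set(select_by_threshold(clumped, 1e-4)["pos"])
        loose = set(select_by_threshold(clumped, 0.05)["pos"])
        assert strict <= loose
        assert len(select_by_threshold(clumped, 5e-8)) == 1


class TestScore:
    def test_hand_computed_weighted_sum(self):
        mat = make_matrix([[2, 0], [1, 1]])
        snps = pd.DataFrame({"var_idx": [0, 1], "beta": [0.5, -1.0]})
        s = score(mat, snps)
        assert s["s0"] == pytest.approx(1.0, abs=1e-12)
        assert s["s1"] == pytest.approx(-0.5, abs=1e-12)

    def test_zero_betas_zero_scores(self):
        mat = make_matrix([[2, 0], [1, 1]])
        snps = pd.DataFrame({"var_idx": [0, 1], "beta": [0.0, 0.0]})
        assert (score(mat, snps) == 0).all()

    def test_doubling_betas_doubles_scores(self, small_cohort):
        mat = small_cohort.genotypes
        rng = np.random.default_rng(5)
        snps = pd.DataFrame({"var_idx": np.arange(20), "beta": rng.normal(size=20)})
        doubled = snps.assign(beta=2 * snps.beta)
        assert np.allclose(2 * score(mat, snps), score(mat, doubled))

    def test_missing_dosage_mean_imputed(self):
        # alt freq among observed = 0.2 -> missing contributes 2*0.2*beta = 0.4
        col = np.array([[np.nan], [1], [1], [1], [1], [0], [0], [0], [0], [0], [0]])
        mat = make_matrix(col)
        snps = pd.DataFrame({"var_idx": [0], "beta": [1.0]})
        assert score(mat, snps)["s0"] == pytest.approx(0.4, abs=1e-12)

    def test_snp_outside_matrix_rejected(self):
        mat = make_matrix([[0.0], [1.0]])
        with pytest.raises(IndexError):
            score(mat, pd.DataFrame({"var_idx": [5], "beta": [1.0]}))


class TestQuartilize:
    def test_rank_partition_one_to_eight(self):
        s = pd.Series(np.arange(1.0, 9.0), index=list("abcdefgh"))
        q = quartilize(s)
        assert list(q) == ["Q1", "Q1", "Q2", "Q2", "Q3", "Q3", "Q4", "Q4"]

    def test_degenerate_ties_all_q1_with_warning(self):
        s = pd.Series([3.0] * 6)
        with pytest.warns(UserWarning, match="degenerate"):
            q = quartilize(s)
        assert (q == "Q1").all()

    def test_balanced_labels_without_boundary_ties(self, rng):
        s = pd.Series(rng.normal(size=101))
        counts = quartilize(s).value_counts()
        assert counts.max() - counts.min() <= 1

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            quartilize(pd.Series([1.0, 2.0, 3.0]))


class TestBuildPrs:
    def test_thresholdset_validation(self):
        with pytest.raises(ValueError):
            ThresholdSet((0.5, 0.1))
        with pytest.raises(ValueError):
            ThresholdSet((0.0, 0.5))

    def test_n_snps_monotone_and_scores_finite(self, small_cohort):
        res = build_prs(small_cohort.genotypes, small_cohort.sumstats)
        ns = [res.n_snps[t] for t in sorted(res.n_snps)]
        assert ns == sorted(ns)
        assert np.isfinite(res.scores.to_numpy()).all()

    def test_prs_recovers_true_liability(self, small_cohort):
        res = build_prs(small_cohort.genotypes, small_cohort.sumstats, ThresholdSet((5e-8,)))
        s = res.scores[5e-8]
        r = np.corrcoef(s, small_cohort.true_scores[s.index])[0, 1]
        assert r > 0.3

    def test_no_retained_snp_in_mhc(self, rng):
        # variants spanning chr6 including the 27-33 Mb exclusion zone
        m = 40
        positions = np.linspace(26_000_000, 34_000_000, m).astype(int).tolist()
        dosages = rng.binomial(2, 0.3, size=(100, m)).astype(float)
        mat = make_matrix(dosages, positions=positions, chrom="6")
        stats_list = [sumstat(p, p=1e-9, chrom="6") for p in positions]
        res = build_prs(mat, stats_list, ThresholdSet((0.5,)))
        matched, _ = harmonize(vframe(mat), stats_list)
        clumped = clump(matched, mat)
        assert not ((clumped.pos >= 27_000_000) & (clumped.pos <= 33_000_000)).any()
        assert res.n_snps[0.5] == len(clumped)
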