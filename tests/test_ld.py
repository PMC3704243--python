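import dataclasses
import math
from fractions import Fraction

import numpy as np
import pytest

from invpopgen.ld import (
    SiteTable,
    arrangement_association,
    build_site_table,
    fisher_exact_2x2,
    homogeneity_chisq,
    ld_scan,
    min_attainable_p,
    qvalue_fdr,
    subset_combined_scan,
)
from invpopgen.io import LocusAlignment


def exact_two_tailed_p(a, b, c, d):
    """Oracle: exhaustive hypergeometric enumeration in exact arithmetic."""
    r1, c1, n = a + b, a + c, a + b + c + d
    if min(r1, n - r1, c1, n - c1) == 0:
        return 1.0
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    denom = math.comb(n, c1)
    pmf = {
        k: Fraction(math.comb(r1, k) * math.comb(n - r1, c1 - k), denom)
        for k in range(lo, hi + 1)
    }
    p_obs = pmf[a]
    tol = Fraction(1, 10**7)
    total = sum(p for p in pmf.values() if p <= p_obs * (1 + tol))
    return float(min(total, 1))


def _table_from_alleles(alleles, labels, loci=None):
    n_sites, n_strains = alleles.shape
    return SiteTable(
        loci=np.array(loci if loci is not None else ["locus1"] * n_sites),
        positions=np.arange(n_sites),
        alleles=alleles.astype(np.int8),
        major=np.array(["A"] * n_sites),
        minor=np.array(["T"] * n_sites),
        strain_ids=[f"s{i}" for i in range(n_strains)],
        arrangement_labels=np.array(labels),
    )


class TestFisher:
    def test_balanced_table(self):
        assert fisher_exact_2x2([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_diagonal_table(self):
        assert fisher_exact_2x2([[10, 0], [0, 10]]) == pytest.approx(
            2 / math.comb(20, 10), rel=1e-12
        )

    def test_matches_exact_enumeration(self, rng):
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(0, 16, size=4))
            assert fisher_exact_2x2([[a, b], [c, d]]) == pytest.approx(
                exact_two_tailed_p(a, b, c, d), abs=1e-10
            )

    def test_symmetry_invariance(self, rng):
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(0, 12, size=4))
            p = fisher_exact_2x2([[a, b], [c, d]])
            assert fisher_exact_2x2([[c, d], [a, b]]) == pytest.approx(p, rel=1e-9)
            assert fisher_exact_2x2([[b, a], [d, c]]) == pytest.approx(p, rel=1e-9)
            assert fisher_exact_2x2([[a, c], [b, d]]) == pytest.approx(p, rel=1e-9)

    def test_zero_margin_convention(self):
        assert fisher_exact_2x2([[0, 0], [3, 7]]) == 1.0


class TestMinAttainable:
    def test_singleton_margins_cannot_reach_one_percent(self):
        # doubly-singleton margins in 76 strains: best case p = 1/76 > 0.01
        p = min_attainable_p((1, 75, 1, 75))
        assert p == pytest.approx(1 / 76, rel=1e-9)
        assert p > 0.01

    def test_balanced_margins_reach_diagonal_p(self):
        assert min_attainable_p((10, 10, 10, 10)) == pytest.approx(
            2 / math.comb(20, 10), rel=1e-12
        )

    def test_monomorphic_margin_invalid(self):
        assert min_attainable_p((0, 20, 10, 10)) == 1.0

    def test_never_exceeds_observed_p(self, rng):
        for _ in range(100):
            a, b, c, d = (int(x) for x in rng.integers(0, 12, size=4))
            margins = (a + b, c + d, a + c, b + d)
            if min(margins) == 0:
                continue
            assert min_attainable_p(margins) <= fisher_exact_2x2(
                [[a, b], [c, d]]
            ) + 1e-12


class TestQValues:
    def test_all_null_saturated(self):
        q, cutoff, pi0 = qvalue_fdr(np.ones(50), 0.01)
        assert (q == 1.0).all()
        assert cutoff is None

    def test_pi0_one_equals_benjamini_hochberg(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.random(300)
        q, _, _ = qvalue_fdr(p, 0.05, pi0=1.0)
        q_bh = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(q, q_bh)

    def test_monotone_in_p_rank(self, rng):
        p = rng.random(100) ** 3
        q, _, _ = qvalue_fdr(p, 0.01)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_few_tests_warns_and_uses_bh(self):
        with pytest.warns(UserWarning, match="fewer than 20"):
            _, _, pi0 = qvalue_fdr([0.001, 0.5, 0.9], 0.05)
        assert pi0 == 1.0

    def test_rejects_invalid_p(self):
        with pytest.raises(ValueError):
            qvalue_fdr([0.5, 1.5], 0.05)


class TestLDScan:
    def test_perfect_association_significant(self, rng):
        # two perfectly correlated balanced sites among 76 strains, plus
        # noise sites to give the q analysis some mass
        n = 76
        s1 = np.array([1] * 38 + [0] * 38)
        noise = (rng.random((30, n)) < 0.3).astype(np.int8)
        alleles = np.vstack([s1, s1, noise])
        ok = (noise.sum(axis=1) > 0) & (noise.sum(axis=1) < n)
        alleles = np.vstack([s1, s1, noise[ok]])
        table = _table_from_alleles(alleles, ["ST"] * 38 + ["AR"] * 38)
        res = ld_scan(table, fdr=0.01)
        top = res.pairs[(res.pairs.pos_a == 0) & (res.pairs.pos_b == 1)]
        assert bool(top.significant.iloc[0])

    def test_locus_pair_matrix_matches_direct_grouping(self, site_table):
        small = dataclasses.replace(
            site_table,
            loci=site_table.loci[:80],
            positions=site_table.positions[:80],
            alleles=site_table.alleles[:80],
            major=site_table.major[:80],
            minor=site_table.minor[:80],
            outgroup_allele=site_table.outgroup_allele[:80],
        )
        res = ld_scan(small, fdr=0.01)
        matrix = res.locus_pair_matrix()
        # oracle: group the flat pair list directly
        for _, row in matrix.iterrows():
            mask = [
                tuple(sorted((la, lb))) == (row.locus_a, row.locus_b)
                for la, lb in zip(res.pairs.locus_a, res.pairs.locus_b)
            ]
            assert row.valid == sum(mask)
            assert row.significant == int(res.pairs.significant[mask].sum())
        assert matrix.significant.sum() == res.n_significant
        assert matrix.valid.sum() == res.valid_pairs

    def test_validity_filter_never_hides_significance(self, site_table):
        # every pair that would test below the validity threshold is kept:
        # min attainable <= observed always, checked via the scan output
        res = ld_scan(site_table.subset_strains(["AR"]), fdr=0.01,
                      validity_alpha=0.05)
        assert (res.pairs.p >= 0).all()
        assert res.valid_pairs <= res.total_pairs


class TestAssociation:
    def test_enumeration_count(self, rng):
        alleles = (rng.random((12, 40)) < 0.4).astype(np.int8)
        labels = ["CH"] * 10 + ["AR"] * 10 + ["PP"] * 10 + ["ST"] * 10
        table = _table_from_alleles(alleles, labels)
        res = arrangement_association(table, ["CH", "AR", "PP", "ST"])
        assert res.n_enumerated == 12 * 4

    def test_perfect_marker_flagged(self, rng):
        n = 60
        labels = ["CH"] * 30 + ["AR"] * 30
        marker = np.array([1] * 30 + [0] * 30)
        noise = (rng.random((25, n)) < 0.4).astype(np.int8)
        alleles = np.vstack([marker, noise])
        table = _table_from_alleles(alleles, labels)
        res = arrangement_association(table, ["CH", "AR"])
        hit = res.table[(res.table.position == 0) & (res.table.arrangement == "CH")]
        assert bool(hit.significant.iloc[0])

    def test_absent_arrangement_rejected(self, rng):
        alleles = (rng.random((5, 10)) < 0.5).astype(np.int8)
        table = _table_from_alleles(alleles, ["CH"] * 5 + ["AR"] * 5)
        with pytest.raises(ValueError, match="absent"):
            arrangement_association(table, ["CH", "TL"])

    def test_permuted_labels_calibrate(self, site_table, rng):
        # shuffling arrangement labels destroys association: the
        # significant fraction stays at or below the FDR
        table = dataclasses.replace(
            site_table,
            arrangement_labels=rng.permutation(site_table.arrangement_labels),
        )
        res = arrangement_association(table, fdr=0.01)
        frac = res.table.significant.sum() / max(res.valid_tests, 1)
        se = math.sqrt(0.01 * 0.99 / max(res.valid_tests, 1))
        assert frac <= 0.01 + 3 * se


class TestHomogeneity:
    def test_proportional_counts(self):
        res = homogeneity_chisq([10, 20, 30], [100, 200, 300])
        assert res.chi2 == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_hand_computed_three_cells(self):
        # totals: 60 significant over 600 valid -> rate 0.1
        obs, valid = [30, 20, 10], [200, 200, 200]
        res = homogeneity_chisq(obs, valid)
        expected = 20.0
        chi2_hand = sum((o - expected) ** 2 / expected for o in obs)
        assert res.chi2 == pytest.approx(chi2_hand, rel=1e-12)
        assert res.df == 2

    def test_zero_valid_cell_pooled(self):
        res = homogeneity_chisq([5, 0, 10], [50, 0, 50])
        assert res.pooled_cells == 1
        assert res.df == 1
        assert res.flags[1] == ""

    def test_flags_mark_extreme_cells(self):
        res = homogeneity_chisq([95, 5, 50], [100, 100, 100])
        assert res.flags[0] == "above"
        assert res.flags[1] == "below"


class TestCombinedScan:
    def test_identical_subsets_identical_flags(self, site_table):
        r1, r2 = subset_combined_scan(
            site_table, [["ST", "AR"], ["ST", "AR"]], fdr=0.01
        )
        assert r1.pairs.significant.tolist() == r2.pairs.significant.tolist()
        assert r1.q_cutoff_p == r2.q_cutoff_p

    def test_pooled_cutoff_brackets_subset_cutoffs(self, site_table):
        separate = [
            ld_scan(site_table, s, fdr=0.01) for s in (["ST", "AR"], ["ST", "PP"])
        ]
        combined = subset_combined_scan(
            site_table, [["ST", "AR"], ["ST", "PP"]], fdr=0.01
        )
        cuts = [r.q_cutoff_p for r in separate if r.q_cutoff_p is not None]
        pooled_cut = combined[0].q_cutoff_p
        if cuts and pooled_cut is not None:
            assert min(cuts) - 1e-12 <= pooled_cut <= max(cuts) + 1e-12

    def test_empty_subset_rejected(self, site_table):
        with pytest.raises(ValueError, match="empty"):
            subset_combined_scan(site_table, [["ST"], []])


def test_build_site_table_biallelic_only():
    aln = LocusAlignment(
        "loc",
        ["AAAA", "ATCA", "ATGA", "AACA"],
        ["a", "b", "c", "d"],
        ["ST", "ST", "AR", "AR"],
        outgroup_sequence="AAAA",
    )
    table = build_site_table([aln])
    # column 1 (A/T biallelic) kept; column 2 has three alleles (A,C,G): dropped
    assert table.n_sites == 1
    assert table.positions.tolist() == [1]
    assert table.major[0] == "T" or table.minor[0] == "T"
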