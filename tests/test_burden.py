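"""Collapsing burden tests: carriers, cMAF, CMAT, Fisher, chi-squared, OR."""

import math
from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from poolburden.burden import (
    CmatCounts,
    bonferroni_threshold,
    carriers,
    cmaf,
    cmat_counts_for_region,
    cmat_permutation_p,
    cmat_statistic,
    fisher_exact_2x2,
    odds_ratio_carriers,
    pearson_chi2_2x2,
    run_burden_analysis,
    subset_analysis,
)
from poolburden.containers import RegionSpec
from poolburden.synth import default_config, simulate_cohort

from conftest import make_matrix


# ---------------------------------------------------------------------------
# independent oracles


def _chi2_by_summation(table):
    """Direct sum of (O-E)^2/E over the four cells."""
    table = np.asarray(table, dtype=float)
    rows = table.sum(axis=1, keepdims=True)
    cols = table.sum(axis=0, keepdims=True)
    expected = rows @ cols / table.sum()
    return float(((table - expected) ** 2 / expected).sum())


def _fisher_by_enumeration(a, b, c, d):
    """Two-sided Fisher p by full enumeration over tables with fixed margins."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    obs = stats.hypergeom.pmf(a, n, r1, c1)
    p = 0.0
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        pk = stats.hypergeom.pmf(k, n, r1, c1)
        if pk <= obs * (1 + 1e-7):
            p += pk
    return min(p, 1.0)


# ---------------------------------------------------------------------------


class TestCarriersAndCmaf:
    def test_study_fixture_purinergic_region(self, study_matrix, study_regions):
        vids = study_regions["P2RY1/P2RY12"]
        assert carriers(study_matrix, vids, "control") == 1
        assert carriers(study_matrix, vids, "case") == 10

    def test_all_zero_matrix(self):
        g = make_matrix([[0, 0]] * 6, ["control"] * 3 + ["case"] * 3)
        assert carriers(g, ["v0", "v1"], "case") == 0

    def test_unknown_region_variant_raises(self, study_matrix):
        with pytest.raises(KeyError):
            carriers(study_matrix, ["nope:1:A>C"], "control")

    def test_multi_variant_carrier_counted_once(self):
        g = make_matrix([[1, 1], [0, 0]], ["case", "case"] )
        assert carriers(g, ["v0", "v1"], "case") == 1

    def test_missing_genotypes_count_as_reference(self):
        g = make_matrix([[-1], [1]], ["case", "case"])
        assert carriers(g, ["v0"], "case") == 1

    @pytest.mark.parametrize(
        "count,n,expected", [(10, 500, 0.02), (32, 500, 0.064), (1, 500, 0.002), (0, 500, 0.0)]
    )
    def test_carrier_based_cmaf(self, count, n, expected):
        assert cmaf(count, n) == pytest.approx(expected)

    def test_allele_based_convention_flag(self):
        assert cmaf(10, 500, allele_based=True) == pytest.approx(0.01)


class TestPearsonChi2:
    def test_total_carrier_table_p(self):
        _, p = pearson_chi2_2x2(10, 490, 32, 468)
        assert round(p, 4) == 0.0005

    def test_identical_groups(self):
        x2, p = pearson_chi2_2x2(5, 495, 5, 495)
        assert x2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("table", [(10, 490, 32, 468), (3, 7, 2, 8), (50, 50, 25, 75)])
    def test_matches_direct_summation_oracle(self, table):
        x2, _ = pearson_chi2_2x2(*table)
        a, b, c, d = table
        assert x2 == pytest.approx(_chi2_by_summation([[a, b], [c, d]]), abs=1e-9)

    def test_zero_margin_directs_to_fisher(self):
        with pytest.raises(ValueError, match="[Ff]isher"):
            pearson_chi2_2x2(0, 500, 0, 500)


class TestFisherExact:
    def test_single_case_carrier_table(self):
        assert fisher_exact_2x2(0, 500, 1, 499) == pytest.approx(1.0)

    def test_identical_rows(self):
        assert fisher_exact_2x2(5, 5, 5, 5) == pytest.approx(1.0)

    def test_against_enumeration_oracle_on_spec_table(self):
        assert fisher_exact_2x2(0, 500, 2, 498) == pytest.approx(
            _fisher_by_enumeration(0, 500, 2, 498), abs=1e-9
        )

    def test_against_enumeration_oracle_exhaustive_small_tables(self):
        for a, b, c, d in (
            (a, b, c, d)
            for a in range(7) for b in range(7) for c in range(7) for d in range(7)
        ):
            if a + b == 0 or c + d == 0:
                continue
            assert fisher_exact_2x2(a, b, c, d) == pytest.approx(
                _fisher_by_enumeration(a, b, c, d), abs=1e-9
            ), (a, b, c, d)


class TestCmatStatistic:
    def test_symmetric_counts_give_zero(self):
        assert cmat_statistic(CmatCounts(5, 95, 5, 95)) == 0.0

    def test_equals_pearson_chi2_of_allele_table(self):
        counts = CmatCounts(10, 990, 1, 999)
        x2, _ = pearson_chi2_2x2(10, 990, 1, 999)
        assert cmat_statistic(counts) == pytest.approx(x2, abs=1e-9)

    def test_doubling_counts_doubles_statistic(self):
        c1 = CmatCounts(10, 990, 1, 999)
        c2 = CmatCounts(20, 1980, 2, 1998)
        assert cmat_statistic(c2) == pytest.approx(2 * cmat_statistic(c1))

    def test_degenerate_all_reference_is_zero(self):
        assert cmat_statistic(CmatCounts(0, 100, 0, 100)) == 0.0

    def test_counts_collapse_from_genotypes(self):
        g = make_matrix([[1, 0], [0, 2], [0, 0], [0, 0]], ["case", "case", "control", "control"])
        counts = cmat_counts_for_region(g, ["v0", "v1"])
        assert (counts.m_case, counts.M_case) == (3.0, 5.0)
        assert (counts.m_ctrl, counts.M_ctrl) == (0.0, 8.0)


class TestCmatPermutation:
    def test_same_seed_reproduces_p(self, study_matrix, study_regions):
        vids = study_regions["P2RY1/P2RY12"]
        p1, _ = cmat_permutation_p(study_matrix, vids, n_perm=500, seed=3)
        p2, _ = cmat_permutation_p(study_matrix, vids, n_perm=500, seed=3)
        assert p1 == p2

    def test_identical_cohorts_are_null_centered(self):
        rows = [[1]] * 2 + [[0]] * 498 + [[1]] * 2 + [[0]] * 498
        g = make_matrix(rows, ["control"] * 500 + ["case"] * 500)
        p, _ = cmat_permutation_p(g, ["v0"], n_perm=400, seed=1)
        assert p > 0.5

    @pytest.mark.parametrize(
        "case_geno,ctrl_geno",
        [
            ([1, 0, 0, 0], [0, 0, 0, 0]),  # one carrier
            ([1, 1, 1, 0], [1, 0, 0, 0]),  # asymmetric burden
            ([2, 1, 0, 0], [0, 0, 0, 0]),  # homozygote in cases
        ],
    )
    def test_matches_exhaustive_enumeration_small_cohorts(self, case_geno, ctrl_geno):
        geno = [[v] for v in case_geno + ctrl_geno]
        g = make_matrix(geno, ["case"] * 4 + ["control"] * 4)
        m = np.array(case_geno + ctrl_geno, dtype=float)

        def stat(case_idx):
            mc = m[list(case_idx)].sum()
            return cmat_statistic(
                CmatCounts(mc, 8 - mc, m.sum() - mc, 8 - (m.sum() - mc))
            )

        obs = stat(range(4))
        splits = [stat(ix) for ix in combinations(range(8), 4)]
        exact = sum(s >= obs - 1e-12 for s in splits) / len(splits)
        n_perm = 20_000
        p_mc, _ = cmat_permutation_p(g, ["v0"], n_perm=n_perm, seed=5)
        se = math.sqrt(max(exact * (1 - exact), 1e-12) / n_perm)
        assert abs(p_mc - (1 + exact * n_perm) / (1 + n_perm)) <= 3 * se + 2 / n_perm

    def test_zero_minor_alleles_rejected(self):
        g = make_matrix([[0], [0]], ["case", "control"])
        with pytest.raises(ValueError, match="minor"):
            cmat_permutation_p(g, ["v0"], n_perm=200, seed=0)

    def test_null_p_distribution_super_uniform(self):
        """Under label exchangeability P(p <= t) <= t (conservative add-one)."""
        pvals = []
        rng = np.random.default_rng(17)
        for i in range(200):
            geno = (rng.random((100, 3)) < 0.05).astype(int)
            g = make_matrix(geno.tolist(), ["control"] * 50 + ["case"] * 50)
            if geno.sum() == 0:
                continue
            p, _ = cmat_permutation_p(g, ["v0", "v1", "v2"], n_perm=199, seed=1000 + i)
            pvals.append(p)
        pvals = np.array(pvals)
        n = len(pvals)
        for t in (0.01, 0.05, 0.1, 0.25, 0.5):
            assert (pvals <= t).mean() <= t + 3 * math.sqrt(t * (1 - t) / n)

    def test_single_variant_agrees_with_exact_and_asymptotic_null(self):
        """For one variant the permutation p matches the exact
        hypergeometric permutation null within Monte-Carlo error, and the
        allele-table chi-squared p agrees to leading order (the asymptotic
        approximation is coarser in the discrete tail)."""
        n, ncar_case, ncar_ctrl = 500, 40, 20
        rows = [[1]] * ncar_case + [[0]] * (n - ncar_case)
        rows += [[1]] * ncar_ctrl + [[0]] * (n - ncar_ctrl)
        g = make_matrix(rows, ["case"] * n + ["control"] * n)
        x2_obs, p_asym = pearson_chi2_2x2(
            ncar_case, 2 * n - ncar_case, ncar_ctrl, 2 * n - ncar_ctrl
        )
        # exact null: k of the K carrier individuals land among the n cases
        K = ncar_case + ncar_ctrl
        exact = 0.0
        for k in range(K + 1):
            x2k, _ = pearson_chi2_2x2(k, 2 * n - k, K - k, 2 * n - (K - k))
            if x2k >= x2_obs - 1e-12:
                exact += stats.hypergeom.pmf(k, 2 * n, K, n)
        n_perm = 100_000
        p_perm, _ = cmat_permutation_p(g, ["v0"], n_perm=n_perm, seed=9)
        se = math.sqrt(exact * (1 - exact) / n_perm)
        assert abs(p_perm - exact) < 3 * se + 2 / n_perm
        assert p_asym == pytest.approx(p_perm, rel=0.35)


class TestOddsRatio:
    def test_total_carrier_or_rounds_to_published_value(self):
        orr, _, _ = odds_ratio_carriers(32, 468, 10, 490)
        assert round(orr, 1) == 3.4

    def test_balanced_table_gives_unity(self):
        orr, _, _ = odds_ratio_carriers(1, 9, 1, 9)
        assert orr == pytest.approx(1.0)

    def test_woolf_interval_matches_independent_formula(self):
        a, b, c, d = 32, 468, 10, 490
        orr, lo, hi = odds_ratio_carriers(a, b, c, d)
        se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        assert lo == pytest.approx(orr * math.exp(-1.959964 * se), abs=1e-4)
        assert hi == pytest.approx(orr * math.exp(1.959964 * se), abs=1e-4)

    def test_haldane_anscombe_applied_on_zero_cell(self):
        orr, lo, hi = odds_ratio_carriers(1, 499, 0, 500)
        expected = (1.5 * 500.5) / (499.5 * 0.5)
        assert orr == pytest.approx(expected)
        assert 0 < lo < orr < hi < math.inf


class TestBonferroni:
    @pytest.mark.parametrize(
        "alpha,m,expected", [(0.05, 24, 0.0021), (0.05, 1, 0.05), (0.05, 10, 0.005)]
    )
    def test_threshold(self, alpha, m, expected):
        assert bonferroni_threshold(alpha, m) == pytest.approx(expected, rel=0.05)


class TestRunBurdenAnalysis:
    def test_fixture_method_routing_and_totals(self, study_matrix, study_regions):
        res = run_burden_analysis(study_matrix, study_regions, n_perm=300, seed=2)
        by_region = {r.region: r for r in res.rows}
        assert by_region["GP6"].method == "CMAT"  # carriers in both cohorts
        assert by_region["SELP"].method == "Fisher"  # carriers in one cohort
        assert (res.total.carriers_ctrl, res.total.carriers_case) == (10, 32)
        assert res.total.p_value == pytest.approx(0.000524, abs=5e-5)
        assert res.bonferroni_alpha == pytest.approx(0.005)

    def test_no_carriers_anywhere(self):
        g = make_matrix([[0, 0]] * 10, ["control"] * 5 + ["case"] * 5)
        res = run_burden_analysis(g, {"r1": ["v0"], "r2": ["v1"]}, n_perm=200, seed=0)
        assert all(r.method == "NA" for r in res.rows)
        assert res.total.p_value == pytest.approx(1.0)

    def test_empty_region_set_rejected(self, study_matrix):
        with pytest.raises(ValueError):
            run_burden_analysis(study_matrix, {})

    def test_deterministic_given_seed(self, study_matrix, study_regions):
        r1 = run_burden_analysis(study_matrix, study_regions, n_perm=300, seed=5)
        r2 = run_burden_analysis(study_matrix, study_regions, n_perm=300, seed=5)
        assert [r.p_value for r in r1.rows] == [r.p_value for r in r2.rows]


class TestSubsetAnalysis:
    def test_no_flags_matches_full_analysis(self, study_regions):
        cfg = default_config(
            seed=4, comorbidity_prev_ctrl=0.0, comorbidity_prev_case=0.0
        )
        g, _ = simulate_cohort(cfg)
        from poolburden.synth import region_variant_map

        regions = region_variant_map(cfg)
        full = run_burden_analysis(g, regions, n_perm=200, seed=1)
        sub = subset_analysis(g, regions, n_perm=200, seed=1)
        assert [r.p_value for r in full.rows] == [r.p_value for r in sub.rows]

    def test_emptied_cohort_rejected(self):
        g = make_matrix(
            [[1], [0], [0], [1]],
            ["case", "case", "control", "control"],
            comorbid=[True, True, False, False],
        )
        with pytest.raises(ValueError, match="emptied"):
            subset_analysis(g, {"r": ["v0"]}, n_perm=200, seed=0)

    def test_fixture_subset_reproduces_published_carriers(self, study_matrix, study_regions):
        res = subset_analysis(study_matrix, study_regions, n_perm=200, seed=3)
        assert (res.n_ctrl, res.n_case) == (400, 205)
        assert (res.total.carriers_ctrl, res.total.carriers_case) == (5, 27)

    def test_genotype_independent_flags_leave_or_inside_full_ci(self):
        """Comorbidity exclusion at random should not shift the carrier OR."""
        inside = 0
        n_rep = 100
        for s in range(n_rep):
            cfg = default_config(
                seed=6000 + s, causal_region="R00", carrier_or=3.0,
                comorbidity_prev_ctrl=0.3, comorbidity_prev_case=0.3,
            )
            g, _ = simulate_cohort(cfg)
            from poolburden.synth import region_variant_map

            vids = [v for vs in region_variant_map(cfg).values() for v in vs]
            a = carriers(g, vids, "case")
            c = carriers(g, vids, "control")
            _, lo, hi = odds_ratio_carriers(a, 500 - a, c, 500 - c)
            keep = ~g.samples["comorbid"].astype(bool)
            gs = g.subset_samples(g.samples.index[keep])
            na, nc = gs.n_in_cohort("case"), gs.n_in_cohort("control")
            a2, c2 = carriers(gs, vids, "case"), carriers(gs, vids, "control")
            orr2, _, _ = odds_ratio_carriers(a2, na - a2, c2, nc - c2)
            inside += lo <= orr2 <= hi
        assert inside / n_rep >= 0.9
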