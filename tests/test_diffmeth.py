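"""Unit and property tests for strand merging, the beta-binomial model,
the per-site LRT, neighbor combination, BH adjustment and labeling."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.stats import beta as beta_dist
from scipy.stats import binom, norm

from dmrkit.diffmeth import (
    MergedCpGSite,
    SiteTestResult,
    adjust_bh,
    assemble_sites,
    betabinom_loglik,
    combine_neighbors,
    direction_summary,
    fit_betabinom,
    label_sites,
    lrt_site_test,
    merge_strands,
)
from dmrkit.errors import DuplicateRecordError, NotFittableError, ValidationError
from dmrkit.meth_io import CytosineCount


def _cc(chrom, pos, strand, k, n):
    return CytosineCount(chrom, pos, strand, "CpG", k, n)


def _result(chrom, pos, p_raw, delta=0.0):
    site = MergedCpGSite(chrom, pos, [0], [1], ["wt"])
    return SiteTestResult(site=site, pi_group={}, delta=delta, p_raw=p_raw)


# ---------------------------------------------------------------------------
# strand merging
# ---------------------------------------------------------------------------

class TestMergeStrands:
    def test_paired_strands_are_summed_at_forward_position(self):
        out = merge_strands([_cc("chr1", 100, "+", 3, 10), _cc("chr1", 101, "-", 2, 5)])
        assert out == [("chr1", 100, 5, 15)]

    def test_unpaired_forward_passes_through(self):
        assert merge_strands([_cc("chr1", 100, "+", 3, 10)]) == [("chr1", 100, 3, 10)]

    def test_reverse_only_keyed_at_forward_position(self):
        assert merge_strands([_cc("chr1", 101, "-", 2, 5)]) == [("chr1", 100, 2, 5)]

    def test_duplicate_forward_record_rejected(self):
        with pytest.raises(DuplicateRecordError):
            merge_strands([_cc("chr1", 100, "+", 1, 2), _cc("chr1", 100, "+", 0, 3)])

    def test_matches_brute_force_pairing_oracle(self, rng):
        # oracle: exhaustive O(n^2) search for (+ at p, - at p+1) pairs
        for _ in range(30):
            n = int(rng.integers(1, 400))
            recs, used = [], set()
            while len(recs) < n:
                pos = int(rng.integers(1, 2000))
                strand = "+" if rng.random() < 0.5 else "-"
                if (pos, strand) in used:
                    continue
                used.add((pos, strand))
                tot = int(rng.integers(1, 40))
                recs.append(_cc("chr1", pos, strand, int(rng.integers(0, tot + 1)), tot))
            expected = {}
            for r in recs:
                key = r.pos if r.strand == "+" else r.pos - 1
                k, t = expected.get(key, (0, 0))
                expected[key] = (k + r.meth_reads, t + r.total_reads)
            oracle = sorted(("chr1", p, k, t) for p, (k, t) in expected.items())
            assert merge_strands(recs) == oracle


class TestAssembleSites:
    DESIGN = {"wt_1": "wt", "wt_2": "wt", "mut_1": "mut"}

    def test_site_covered_everywhere_is_testable(self):
        merged = {s: [("chr1", 100, 2, 8)] for s in self.DESIGN}
        (site,) = assemble_sites(merged, self.DESIGN)
        assert site.testable and site.total.sum() == 24

    def test_site_covered_in_one_group_flagged_not_testable(self):
        merged = {"wt_1": [("chr1", 100, 2, 8)], "wt_2": [("chr1", 100, 1, 5)],
                  "mut_1": []}
        (site,) = assemble_sites(merged, self.DESIGN)
        assert not site.testable

    def test_missing_sample_gets_zero_counts(self):
        merged = {"wt_1": [("chr1", 100, 2, 8)], "wt_2": [],
                  "mut_1": [("chr1", 100, 1, 5)]}
        (site,) = assemble_sites(merged, self.DESIGN)
        assert site.total.tolist() == [8, 0, 5]

    def test_unknown_sample_in_design_rejected(self):
        with pytest.raises(ValidationError, match="unknown sample"):
            assemble_sites({"wt_1": []}, self.DESIGN)

    def test_site_count_equals_distinct_keys(self, rng):
        merged = {}
        all_keys = set()
        for s in self.DESIGN:
            keys = {("chr1", int(p) * 2) for p in rng.integers(0, 500, size=60)}
            all_keys |= keys
            merged[s] = sorted((c, p, 1, 3) for c, p in keys)
        sites = assemble_sites(merged, self.DESIGN)
        assert len(sites) == len(all_keys)


# ---------------------------------------------------------------------------
# beta-binomial likelihood and MLE
# ---------------------------------------------------------------------------

class TestBetaBinomLoglik:
    def test_empty_observation_contributes_zero(self):
        assert betabinom_loglik(0, 0, 2.0, 3.0) == 0.0

    def test_concentration_limit_approaches_binomial(self):
        # alpha = pi*c, beta = (1-pi)*c with c -> infinity is Binomial(N, pi)
        c, pi = 1e6, 0.3
        got = betabinom_loglik(3, 10, pi * c, (1 - pi) * c)
        assert got == pytest.approx(binom.logpmf(3, 10, pi), abs=1e-3)

    def test_matches_quadrature_over_p(self):
        # oracle: integrate C(6,2) p^2 (1-p)^4 against the Beta(2,3) density
        val, _ = quad(lambda p: binom.pmf(2, 6, p) * beta_dist.pdf(p, 2, 3), 0, 1)
        assert betabinom_loglik(2, 6, 2.0, 3.0) == pytest.approx(math.log(val), abs=1e-9)

    def test_rejects_nonpositive_shapes(self):
        with pytest.raises(ValueError):
            betabinom_loglik(1, 2, 0.0, 1.0)

    @given(
        st.integers(0, 60), st.integers(0, 60),
        st.floats(0.01, 100.0), st.floats(0.01, 100.0),
    )
    def test_is_log_of_a_pmf(self, k, extra, alpha, beta_):
        # log pmf of discrete data is never positive
        assert betabinom_loglik(k, k + extra, alpha, beta_) <= 1e-12


class TestFitBetaBinom:
    def test_symmetric_single_sample_has_mean_half(self):
        fit = fit_betabinom([5], [10])
        assert fit.mean == pytest.approx(0.5, abs=1e-3)

    def test_all_zero_counts_hit_lower_mean_bound(self):
        fit = fit_betabinom([0, 0, 0], [10, 12, 9])
        assert fit.mean <= 1e-5

    def test_all_uncovered_not_fittable(self):
        with pytest.raises(NotFittableError):
            fit_betabinom([0, 0], [0, 0])

    def test_pooled_mean_recovery_at_high_coverage(self, rng):
        # parameter recovery: >= 2000 total reads pin the mean within 0.02
        # (at replicate-level dispersion phi = 100; with very strong biological
        # dispersion the precision is limited by the number of samples instead)
        alpha, beta_ = 40.0, 60.0
        N = np.full(24, 100)
        p = rng.beta(alpha, beta_, size=24)
        k = rng.binomial(N, p)
        fit = fit_betabinom(k, N)
        assert fit.mean == pytest.approx(alpha / (alpha + beta_), abs=0.02)


# ---------------------------------------------------------------------------
# per-site LRT
# ---------------------------------------------------------------------------

def _site(k, n, groups):
    return MergedCpGSite("chr1", 100, k, n, groups)


class TestLrtSiteTest:
    GROUPS = ["wt"] * 3 + ["mut"] * 3

    def test_identical_groups_give_p_near_one(self):
        site = _site([5] * 6, [10] * 6, self.GROUPS)
        res = lrt_site_test(site, "wt", "mut")
        assert res.p_raw > 0.95
        assert abs(res.delta) < 0.05

    def test_maximal_separation_is_strongest_detectable_signal(self):
        # complete 0/30 vs 30/30 separation: the per-group fits are perfect
        # (log-likelihood 0) while the pooled null salvages at best a bimodal
        # Beta with mass ~1/2 on each extreme, i.e. log-likelihood ~ 6*ln(1/2).
        # The LRT statistic is therefore ~8.6 and the free-dispersion test
        # cannot push p below chi2.sf(8.6, 2) ~ 0.014 however clean the split.
        site = _site([0, 0, 0, 30, 30, 30], [30] * 6, self.GROUPS)
        res = lrt_site_test(site, "wt", "mut")
        assert res.p_raw < 0.02
        assert res.delta == pytest.approx(1.0, abs=0.01)
        # intermediate counts cannot hide in the bimodal null, so a milder
        # but interior split is actually detected far more strongly
        milder = lrt_site_test(_site([3, 2, 4, 20, 22, 19], [30] * 6, self.GROUPS),
                               "wt", "mut")
        assert milder.p_raw < 1e-3

    @pytest.mark.parametrize("df_mode", ["full", "shared"])
    def test_statistic_nonnegative_on_random_sites(self, rng, df_mode):
        # the alternative nests the null, so the LRT statistic cannot be negative;
        # p_raw = 1 corresponds to lambda = 0
        from scipy.stats import chi2

        for _ in range(25):
            n = rng.integers(5, 40, size=6)
            k = rng.binomial(n, rng.beta(2, 5, size=6))
            res = lrt_site_test(_site(k, n, self.GROUPS), "wt", "mut", df_mode=df_mode)
            assert np.isfinite(res.p_raw)
            assert 0.0 <= res.p_raw <= 1.0

    def test_untestable_site_rejected(self):
        site = _site([1, 1, 1, 0, 0, 0], [5, 5, 5, 0, 0, 0], self.GROUPS)
        assert not assemble_sites(
            {f"s{i}": ([("chr1", 100, 1, 5)] if g == "wt" else [])
             for i, g in enumerate(self.GROUPS)},
            {f"s{i}": g for i, g in enumerate(self.GROUPS)},
        )[0].testable
        site.testable = False
        with pytest.raises(ValidationError):
            lrt_site_test(site, "wt", "mut")


# ---------------------------------------------------------------------------
# neighbor combination
# ---------------------------------------------------------------------------

class TestPowerAtImplantedSites:
    def test_per_site_power_at_moderate_fdr(self, standard_truth, standard_results):
        """With a 0.4 methylation shift at ~30x coverage (3v3), at least 60%
        of truly affected CpGs reach fdr < 0.05."""
        affected = {
            (c, int(p))
            for c in standard_truth.chroms
            for p, m in zip(standard_truth.cpg_positions[c],
                            standard_truth.affected_mask(c)) if m
        }
        hits = [r.fdr < 0.05 for r in standard_results
                if (r.chrom, r.pos) in affected and math.isfinite(r.fdr)]
        assert len(hits) > 100
        assert np.mean(hits) >= 0.6


class TestCombineNeighbors:
    def test_isolated_site_keeps_raw_p(self):
        res = [_result("chr1", 100, 0.03), _result("chr1", 10_000, 0.6)]
        combine_neighbors(res, window_bp=200)
        assert res[0].p_comb == pytest.approx(0.03, abs=1e-12)
        assert res[1].p_comb == pytest.approx(0.6, abs=1e-12)

    def test_two_adjacent_sites_follow_stouffer_arithmetic(self):
        res = [_result("chr1", 100, 0.05), _result("chr1", 150, 0.05)]
        combine_neighbors(res, window_bp=200)
        # Z = 2 * 1.6449 / sqrt(2) = 2.3263 -> p ~ 0.0100
        assert res[0].p_comb == pytest.approx(0.0100, abs=5e-4)

    def test_missing_p_excluded_from_all_windows(self):
        res = [_result("chr1", 100, 0.05), _result("chr1", 120, math.nan),
               _result("chr1", 140, 0.05)]
        combine_neighbors(res, window_bp=200)
        assert math.isnan(res[1].p_comb)
        assert res[0].p_comb == pytest.approx(0.0100, abs=5e-4)

    def test_unsorted_input_rejected(self):
        res = [_result("chr1", 200, 0.5), _result("chr1", 100, 0.5)]
        with pytest.raises(ValidationError):
            combine_neighbors(res)

    def test_matches_all_pairs_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(1, 200))
            pos = np.sort(rng.choice(20_000, size=n, replace=False))
            res = [
                _result("chr1", int(p), float(rng.random())) for p in pos
            ]
            combine_neighbors(res, window_bp=300)
            for i, r in enumerate(res):
                zs = [
                    norm.isf(np.clip(o.p_raw, 1e-300, 1 - 1e-16))
                    for o in res if abs(o.pos - r.pos) <= 300
                ]
                expected = norm.sf(sum(zs) / math.sqrt(len(zs)))
                assert r.p_comb == pytest.approx(expected, abs=1e-12)


# ---------------------------------------------------------------------------
# BH adjustment and labels
# ---------------------------------------------------------------------------

class TestAdjustBH:
    def test_single_value_unchanged(self):
        assert adjust_bh([0.04]).tolist() == [0.04]

    def test_hand_worked_step_up(self):
        np.testing.assert_allclose(
            adjust_bh([0.01, 0.04, 0.03, 0.02]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_bh([0.1, 1.2])

    def test_missing_values_ignored_and_returned_missing(self):
        out = adjust_bh([0.02, math.nan, 0.04])
        assert math.isnan(out[1])
        np.testing.assert_allclose(out[[0, 2]], [0.04, 0.04])

    def test_matches_direct_formula_and_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(20):
            p = rng.random(int(rng.integers(1, 200)))
            got = adjust_bh(p)
            m = p.size
            order = np.argsort(p, kind="stable")
            # oracle: min over j >= i of m * p_(j) / j in sorted order
            expected = np.empty(m)
            for rank, idx in enumerate(order, start=1):
                tail = [m * p[order[j]] / (j + 1) for j in range(rank - 1, m)]
                expected[idx] = min(1.0, min(tail))
            np.testing.assert_allclose(got, expected, atol=1e-12)
            np.testing.assert_allclose(
                got, multipletests(p, method="fdr_bh")[1], atol=1e-12
            )


class TestLabelsAndSummary:
    def _labeled(self, fdr, delta):
        r = _result("chr1", 100, 0.001, delta=delta)
        r.fdr = fdr
        return r

    @pytest.mark.parametrize(
        "fdr,delta,expected",
        [
            (0.001, 0.3, "hyper"),
            (0.001, -0.3, "hypo"),
            (0.5, 0.9, "ns"),
            (0.001, 0.05, "ns"),      # effect-size gate
            (0.001, -0.05, "ns"),
            (math.nan, 0.9, "ns"),
        ],
    )
    def test_labeling_rule(self, fdr, delta, expected):
        (r,) = label_sites([self._labeled(fdr, delta)], fdr_threshold=0.01,
                           min_delta=0.1)
        assert r.label == expected

    def test_summary_counts_and_fraction(self):
        results = [self._labeled(f, d) for f, d in
                   [(0.001, 0.3), (0.001, 0.4), (0.001, -0.2), (0.9, 0.0)]]
        label_sites(results, 0.01, 0.1)
        s = direction_summary(results)
        assert (s.n_hyper, s.n_hypo, s.n_ns) == (2, 1, 1)
        assert s.frac_hyper_among_sig == pytest.approx(2 / 3)

    def test_no_significant_sites_gives_missing_fraction(self):
        results = label_sites([self._labeled(0.9, 0.0)], 0.01, 0.1)
        s = direction_summary(results)
        assert (s.n_hyper, s.n_hypo, s.n_ns) == (0, 0, 1)
        assert math.isnan(s.frac_hyper_among_sig)

    def test_summary_invariant_under_permutation(self, rng):
        results = [self._labeled(float(f), float(d))
                   for f, d in zip(rng.random(40), rng.uniform(-1, 1, 40))]
        label_sites(results, 0.05, 0.1)
        s1 = direction_summary(results)
        perm = [results[i] for i in rng.permutation(40)]
        assert direction_summary(perm) == s1
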