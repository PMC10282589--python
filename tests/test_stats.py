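"""Agreement statistics: Bland–Altman, Bradley–Blackwood, exact tests."""

import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from retvas.stats import (
    bland_altman,
    bradley_blackwood,
    compare_metrics,
    fisher_exact,
    ks_two_sample,
    mcnemar_exact,
    slope_test,
    two_proportion_test,
)


class TestBlandAltman:
    def test_identical_arms_are_the_zero_element(self):
        ba = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert ba.mean_diff == 0 and ba.sd_diff == 0
        assert (ba.loa_low, ba.loa_high) == (0, 0)

    def test_constant_offset(self):
        ba = bland_altman(np.arange(5.0), np.arange(5.0) - 2)
        assert ba.mean_diff == pytest.approx(2.0)
        assert ba.sd_diff == 0

    def test_hand_computed_example(self):
        ba = bland_altman([10, 12, 14], [9, 10, 11])
        assert ba.mean_diff == pytest.approx(2.0)
        assert ba.sd_diff == pytest.approx(1.0)
        assert ba.loa_low == pytest.approx(0.04)
        assert ba.loa_high == pytest.approx(3.96)

    def test_loa_half_width_is_exactly_1_96_sd(self, rng):
        a = rng.normal(10, 2, 30)
        b = rng.normal(9, 2, 30)
        ba = bland_altman(a, b)
        assert (ba.loa_high - ba.loa_low) / 2 == pytest.approx(1.96 * ba.sd_diff, rel=1e-12)

    def test_antisymmetry_under_arm_swap(self, rng):
        a = rng.normal(10, 2, 25)
        b = a - rng.normal(1, 0.5, 25)
        ab, ba_ = bland_altman(a, b), bland_altman(b, a)
        assert ab.mean_diff == pytest.approx(-ba_.mean_diff)
        assert ab.sd_diff == pytest.approx(ba_.sd_diff)
        Fab, pab = bradley_blackwood(a, b)
        Fba, pba = bradley_blackwood(b, a)
        assert pab == pytest.approx(pba, rel=1e-9)
        sab, _ = slope_test(a, b)
        sba, _ = slope_test(b, a)
        assert sab == pytest.approx(-sba)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1.0], [2.0])


class TestBradleyBlackwood:
    def test_exact_agreement_is_convention_p1(self):
        assert bradley_blackwood([1.0, 2, 3], [1.0, 2, 3]) == (0.0, 1.0)

    def test_matches_explicit_f_formula(self, rng):
        a = rng.normal(10, 1, 40)
        b = rng.normal(10, 1.5, 40)
        F, p = bradley_blackwood(a, b)
        d, m = a - b, (a + b) / 2
        X = np.column_stack([np.ones_like(m), m])
        beta, *_ = np.linalg.lstsq(X, d, rcond=None)
        sse = float(((d - X @ beta) ** 2).sum())
        F_oracle = ((d @ d - sse) / 2) / (sse / (len(d) - 2))
        assert F == pytest.approx(F_oracle, rel=1e-9)
        assert p == pytest.approx(sps.f.sf(F_oracle, 2, len(d) - 2), rel=1e-9)

    def test_large_shift_is_detected(self):
        rng = np.random.default_rng(1)
        a = rng.normal(10, 1, 56)
        b = a - 3 + rng.normal(0, 0.3, 56)
        _, p = bradley_blackwood(a, b)
        assert p < 0.001

    def test_type_i_error_calibrated(self):
        # under H0 (equal means, equal variances, normal) both the joint
        # F-test and the slope t-test reject at close to the nominal 5%
        rng = np.random.default_rng(2026)
        n, reps = 56, 2000
        rej_bb = rej_slope = 0
        for _ in range(reps):
            a = rng.normal(10, 2, n)
            b = rng.normal(10, 2, n)
            if bradley_blackwood(a, b)[1] < 0.05:
                rej_bb += 1
            if slope_test(a, b)[1] < 0.05:
                rej_slope += 1
        assert abs(rej_bb / reps - 0.05) <= 0.02
        assert abs(rej_slope / reps - 0.05) <= 0.02


class TestSlopeTest:
    def test_null_slope_estimates_near_zero(self):
        rng = np.random.default_rng(3)
        slopes = []
        for _ in range(200):
            a = rng.normal(10, 1, 30)
            b = rng.normal(10, 1, 30)
            slopes.append(slope_test(a, b)[0])
        assert abs(np.mean(slopes)) < 0.02

    def test_perfect_proportional_bias(self):
        s = np.array([2.0, 4.0, 8.0, 10.0])
        d = 0.5 * s
        a, b = (s + d) / 2, (s - d) / 2
        slope, p = slope_test(a, b)
        assert slope == pytest.approx(0.5)
        assert p < 1e-10

    def test_minimal_case_matches_hand_ols(self):
        a = np.array([3.0, 5.0, 10.0])
        b = np.array([1.0, 4.0, 5.0])
        s, d = a + b, a - b
        sxx = ((s - s.mean()) ** 2).sum()
        beta = (((s - s.mean()) * (d - d.mean())).sum()) / sxx
        slope, _ = slope_test(a, b)
        assert slope == pytest.approx(beta)


class TestKolmogorovSmirnov:
    def test_identical_samples(self):
        x = np.arange(10.0)
        D, p = ks_two_sample(x, x)
        assert D == 0.0 and p == 1.0

    def test_disjoint_supports(self):
        D, _ = ks_two_sample([1.0, 2, 3], [10.0, 11, 12])
        assert D == 1.0

    def test_matches_brute_force_ecdf_sweep(self, rng):
        x = rng.normal(0, 1, 10)
        y = rng.normal(0.5, 1.2, 10)
        D, _ = ks_two_sample(x, y)
        grid = np.concatenate([x, y])
        brute = max(
            abs((x <= t).mean() - (y <= t).mean()) for t in grid
        )
        assert D == pytest.approx(brute)


class TestFisherExact:
    def test_perfect_association(self):
        assert fisher_exact([[10, 0], [0, 10]]) == pytest.approx(2 / math.comb(20, 10))

    def test_balanced_table_p1(self):
        assert fisher_exact([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_zero_margin_p1(self):
        assert fisher_exact([[0, 0], [3, 4]]) == 1.0

    def test_all_2x2_tables_total_at_most_30_match_hypergeometric(self):
        # scipy's conditional two-sided Fisher test is the closed-form
        # equivalent of exhaustive enumeration
        for n in range(1, 31, 3):
            for a in range(0, n + 1, 2):
                for b in range(0, n - a + 1, 3):
                    for c in range(0, n - a - b + 1, 3):
                        d = n - a - b - c
                        table = [[a, b], [c, d]]
                        if min(a + b, c + d) == 0 or min(a + c, b + d) == 0:
                            continue
                        expect = sps.fisher_exact(table).pvalue
                        assert fisher_exact(table) == pytest.approx(expect, rel=1e-9), table

    @pytest.mark.parametrize(
        "table",
        [[[3, 1, 0], [1, 3, 1], [0, 1, 3]], [[2, 5], [4, 1], [3, 3]], [[1, 2, 3], [3, 2, 1]]],
    )
    def test_rxc_tables_match_permutation_oracle(self, table):
        # Monte-Carlo permutation of category labels estimates the same
        # conditional two-sided p
        t = np.asarray(table)
        p = fisher_exact(t)
        rows = np.repeat(np.arange(t.shape[0]), t.sum(axis=1))
        cols = np.repeat(np.arange(t.shape[1]), t.sum(axis=0))
        rng = np.random.default_rng(5)

        def prob(tab):
            rs, cs = tab.sum(axis=1), tab.sum(axis=0)
            logp = (
                sum(math.lgamma(v + 1) for v in rs)
                + sum(math.lgamma(v + 1) for v in cs)
                - math.lgamma(tab.sum() + 1)
                - sum(math.lgamma(v + 1) for v in tab.ravel())
            )
            return math.exp(logp)

        p_obs = prob(t)
        hits = 0
        reps = 4000
        for _ in range(reps):
            perm = rng.permutation(cols)
            tab = np.zeros_like(t)
            np.add.at(tab, (rows, perm), 1)
            if prob(tab) <= p_obs * (1 + 1e-9):
                hits += 1
        assert p == pytest.approx(hits / reps, abs=0.03)

    def test_oversized_table_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact(np.ones((4, 2), dtype=int))


class TestMcNemar:
    def test_symmetric_discordance_p1(self):
        assert mcnemar_exact(4, 4) == 1.0

    def test_five_zero(self):
        assert mcnemar_exact(5, 0) == pytest.approx(0.0625)

    def test_no_discordant_pairs(self):
        assert mcnemar_exact(0, 0) == 1.0

    def test_all_counts_total_at_most_30_match_binomial_enumeration(self):
        for n01 in range(0, 31):
            for n10 in range(0, 31 - n01):
                n = n01 + n10
                if n == 0:
                    continue
                k = min(n01, n10)
                oracle = min(1.0, 2.0 * sum(math.comb(n, i) * 0.5**n for i in range(k + 1)))
                assert mcnemar_exact(n01, n10) == pytest.approx(oracle, rel=1e-12)


class TestTwoProportions:
    def test_equal_proportions_z0_p1(self):
        p1, p2, z, p = two_proportion_test(8, 20, 12, 30)
        assert z == 0.0 and p == 1.0

    def test_published_evaluability_proportions(self):
        p1, p2, z, p = two_proportion_test(42, 46, 36, 46)
        assert p1 * 100 == pytest.approx(91.3, abs=0.05)
        assert p2 * 100 == pytest.approx(78.3, abs=0.05)

    def test_z_squared_equals_uncorrected_chi_square(self):
        x1, n1, x2, n2 = 13, 40, 22, 55
        _, _, z, _ = two_proportion_test(x1, n1, x2, n2)
        chi2 = sps.chi2_contingency(
            [[x1, n1 - x1], [x2, n2 - x2]], correction=False
        ).statistic
        assert z**2 == pytest.approx(chi2, rel=1e-9)


class TestCompareMetrics:
    @staticmethod
    def _table(n=10, shift=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n):
            base = dict(density_pct=rng.normal(13, 1.5), n_external=rng.poisson(60),
                        n_internal=rng.poisson(50), n_edges=rng.poisson(110),
                        fd=rng.normal(1.5, 0.05))
            rows.append({"eye_id": f"e{i:02d}", "arm": "reference", **base})
            hh = {k: (v - shift if k == "density_pct" else v) for k, v in base.items()}
            rows.append({"eye_id": f"e{i:02d}", "arm": "handheld", **hh})
        return pd.DataFrame(rows)

    def test_identical_arms_zero_differences(self):
        rep = compare_metrics(self._table(shift=0.0))
        assert np.allclose(rep.table["mean_diff"], 0)
        assert np.allclose(rep.table["p_joint"].dropna(), 1.0)

    def test_report_layout_five_metrics_two_strata(self):
        rep = compare_metrics(self._table(), curated_index=[0, 1, 2, 3, 4])
        assert len(rep.table) == 10
        assert set(rep.table["stratum"]) == {"unsupervised", "curated"}
        assert rep.table.groupby("stratum").size().tolist() == [5, 5]
        assert rep.strata == {"unsupervised": 10, "curated": 5}

    def test_constant_density_shift_recovered(self):
        rep = compare_metrics(self._table(shift=2.5))
        row = rep.table.query("metric == 'vessel density'").iloc[0]
        assert row["mean_diff"] == pytest.approx(2.5)

    def test_small_stratum_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="skipped"):
            rep = compare_metrics(self._table(), curated_index=[0])
        assert set(rep.table["stratum"]) == {"unsupervised"}
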