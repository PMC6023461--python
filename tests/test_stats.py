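"""Welch ANOVA, Games-Howell, studentized range, variance tests."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from spotscreen import (
    GroupSummary,
    bartlett_test,
    games_howell,
    intra_plate_variance,
    pearson_between_replicates,
    replicates_needed,
    studentized_range_cdf,
    variance_f_test,
    welch_anova,
)


class TestWelchAnova:
    def test_equal_means_give_zero_F_unit_p(self):
        g = {
            "a": [1.0, 2.0, 3.0],
            "b": [1.0, 2.0, 3.0],
            "c": [0.0, 2.0, 4.0],
        }
        res = welch_anova(g)
        assert res.F == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_k2_equals_squared_welch_t(self, rng):
        a = rng.normal(0, 1, 8)
        b = rng.normal(1, 3, 14)
        res = welch_anova({"a": a, "b": b})
        t, p = sps.ttest_ind(a, b, equal_var=False)
        assert res.F == pytest.approx(t**2, rel=1e-10)
        assert res.p == pytest.approx(p, rel=1e-10)

    def test_hand_computed_three_group_example(self):
        """Step-by-step evaluation of the Welch formula on a fixed dataset,
        performed independently below, must agree to 1e-10."""
        data = {"a": [1.0, 2, 3], "b": [2.0, 3, 4], "c": [10.0, 11, 12]}
        res = welch_anova(data)
        # independent evaluation
        n = np.array([3.0, 3, 3])
        m = np.array([2.0, 3.0, 11.0])
        v = np.array([1.0, 1.0, 1.0])
        w = n / v
        xw = np.sum(w * m) / np.sum(w)
        num = np.sum(w * (m - xw) ** 2) / 2.0
        lam = np.sum((1 - w / w.sum()) ** 2 / (n - 1))
        F = num / (1 + 2 * 1 / 8 * lam)
        df2 = 8 / (3 * lam)
        assert res.F == pytest.approx(F, rel=1e-10)
        assert res.df1 == 2
        assert res.df2 == pytest.approx(df2, rel=1e-10)
        assert res.p == pytest.approx(sps.f.sf(F, 2, df2), rel=1e-10)

    def test_matches_pingouin(self, rng):
        import pingouin as pg

        vals, labs = [], []
        for i, (mu, sd, n) in enumerate([(0, 1, 9), (0.8, 2, 12), (2, 0.5, 7)]):
            x = rng.normal(mu, sd, n)
            vals.extend(x)
            labs.extend([f"g{i}"] * n)
        df = pd.DataFrame({"y": vals, "g": labs})
        ref = pg.welch_anova(data=df, dv="y", between="g")
        res = welch_anova({g: grp["y"].to_numpy() for g, grp in df.groupby("g")})
        assert res.F == pytest.approx(float(ref["F"].iloc[0]), rel=1e-9)
        assert res.p == pytest.approx(float(ref["p_unc"].iloc[0]), rel=1e-6)

    def test_homoscedastic_balanced_matches_classical_anova(self, rng):
        """With two balanced groups of equal sample variance the Welch
        statistic equals the classical one-way F exactly; for k > 2 the
        two differ by Welch's small-sample correction factor, an exact
        algebraic relation verified here."""
        base = rng.normal(0, 1, 10)
        groups2 = {"a": base, "b": base + 1.3}
        res2 = welch_anova(groups2)
        F2, _ = sps.f_oneway(*groups2.values())
        assert res2.F == pytest.approx(F2, rel=1e-10)

        groups3 = {f"g{i}": base + i for i in range(3)}  # identical variances
        res3 = welch_anova(groups3)
        F3, _ = sps.f_oneway(*groups3.values())
        k, n = 3, 10
        lam = (1 - 1 / k) ** 2 * k / (n - 1)
        assert res3.F * (1 + 2 * (k - 2) / (k**2 - 1) * lam) == pytest.approx(
            F3, rel=1e-10
        )

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError):
            welch_anova({"a": [1.0, 2.0]})
        with pytest.raises(ValueError):
            welch_anova({"a": [1.0, 1.0], "b": [1.0, 2.0]})


class TestStudentizedRangeCDF:
    def test_zero_is_zero(self):
        assert studentized_range_cdf(0.0, 3, 10) == 0.0

    def test_k2_reduces_to_t_identity(self):
        """For k=2, P(Q <= q) = P(|t_df| <= q / sqrt(2))."""
        for df in (2.0, 5.0, 10.0, 40.0):
            for q in (0.3, 1.0, 2.0, 3.5, 6.0):
                mine = studentized_range_cdf(q, 2, df)
                ref = sps.t.cdf(q / math.sqrt(2), df) - sps.t.cdf(-q / math.sqrt(2), df)
                assert mine == pytest.approx(ref, abs=1e-6)

    def test_matches_scipy_reference(self):
        for k in (2, 3, 5, 8):
            for df in (3.0, 10.0, 60.0):
                for q in (1.0, 2.5, 4.0, 7.0):
                    assert studentized_range_cdf(q, k, df) == pytest.approx(
                        sps.studentized_range.cdf(q, k, df), abs=1e-6
                    )

    def test_monotone_in_q_and_k(self):
        qs = [0.5, 1.0, 2.0, 3.0, 5.0, 8.0]
        vals = [studentized_range_cdf(q, 4, 12) for q in qs]
        assert all(b >= a for a, b in zip(vals, vals[1:]))
        ks = [2, 3, 5, 9]
        vals_k = [studentized_range_cdf(3.0, k, 12) for k in ks]
        assert all(b <= a for a, b in zip(vals_k, vals_k[1:]))
        assert studentized_range_cdf(40.0, 3, 10) > 0.9999

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            studentized_range_cdf(-1.0, 3, 10)
        with pytest.raises(ValueError):
            studentized_range_cdf(1.0, 1, 10)
        with pytest.raises(ValueError):
            studentized_range_cdf(1.0, 3, 0.0)


class TestGamesHowell:
    def test_identical_groups_p_one(self):
        g = {"a": [1.0, 2, 3, 4], "b": [1.0, 2, 3, 4]}
        res = games_howell(g)[0]
        assert res.q == 0.0
        assert res.p == pytest.approx(1.0)

    def test_k2_equals_welch_t_pvalue(self, rng):
        a = rng.normal(0, 1, 9)
        b = rng.normal(1.2, 2.5, 13)
        res = games_howell({"a": a, "b": b})[0]
        _, p = sps.ttest_ind(a, b, equal_var=False)
        assert res.p == pytest.approx(p, abs=1e-6)

    def test_matches_pingouin_reference(self, rng):
        import pingouin as pg

        vals, labs = [], []
        for i, (mu, sd, n) in enumerate([(0, 1, 8), (1, 2, 10), (3, 0.7, 6), (0.5, 1.5, 12)]):
            x = rng.normal(mu, sd, n)
            vals.extend(x)
            labs.extend([f"g{i}"] * n)
        df = pd.DataFrame({"y": vals, "g": labs})
        ref = pg.pairwise_gameshowell(data=df, dv="y", between="g")
        mine = games_howell({g: grp["y"].to_numpy() for g, grp in df.groupby("g")})
        ref = ref.sort_values(["A", "B"]).reset_index(drop=True)
        for i, cmp_ in enumerate(sorted(mine, key=lambda c: (c.group1, c.group2))):
            assert cmp_.df == pytest.approx(float(ref.loc[i, "df"]), rel=1e-9)
            assert cmp_.p == pytest.approx(float(ref.loc[i, "pval"]), abs=1e-5)

    def test_relabeling_and_shift_invariance(self, rng):
        groups = {f"g{i}": rng.normal(i, 1 + i, 10) for i in range(3)}
        base = {(c.group1, c.group2): c.p for c in games_howell(groups)}
        shifted = {k: v + 42.0 for k, v in groups.items()}
        for c in games_howell(shifted):
            assert c.p == pytest.approx(base[(c.group1, c.group2)], abs=1e-12)
        renamed = {"z_" + k: v for k, v in groups.items()}
        ps = sorted(c.p for c in games_howell(renamed))
        assert ps == pytest.approx(sorted(base.values()), abs=1e-12)

    def test_power_monotonicity(self, rng):
        """Growing mean separation drives every pairwise p to zero."""
        a = rng.normal(0, 1, 10)
        b = rng.normal(0, 2, 10)
        prev = 1.1
        for shift in (0.0, 2.0, 5.0, 10.0):
            p = games_howell({"a": a, "b": b + shift})[0].p
            assert p <= prev + 1e-9
            prev = p
        assert prev < 1e-6


class TestPearsonReplicates:
    def _table(self, v1, v2, v3=None):
        rows = []
        for rep, v in enumerate([v1, v2] + ([v3] if v3 is not None else []), start=1):
            for i, x in enumerate(v):
                rows.append(
                    {"replicate": rep, "condition": "NC", "position": f"p{i}",
                     "frac_spindle": x}
                )
        return pd.DataFrame(rows)

    def test_identical_replicates_r_one(self):
        t = self._table([0.1, 0.2, 0.3, 0.4], [0.1, 0.2, 0.3, 0.4])
        assert pearson_between_replicates(t).mean_r == pytest.approx(1.0)

    def test_negated_around_mean_r_minus_one(self):
        v = np.array([0.1, 0.2, 0.3, 0.4])
        t = self._table(list(v), list(2 * v.mean() - v))
        assert pearson_between_replicates(t).mean_r == pytest.approx(-1.0)

    def test_three_replicates_mean_of_pairs(self, rng):
        v1, v2, v3 = rng.normal(0, 1, (3, 6))
        t = self._table(list(v1), list(v2), list(v3))
        out = pearson_between_replicates(t)
        direct = np.mean(
            [np.corrcoef(a, b)[0, 1] for a, b in ((v1, v2), (v1, v3), (v2, v3))]
        )
        assert out.mean_r == pytest.approx(direct, abs=1e-12)
        assert len(out.pairwise) == 3

    def test_covariance_formula_oracle(self, rng):
        x, y = rng.normal(0, 1, (2, 20))
        t = self._table(list(x), list(y))
        r = pearson_between_replicates(t).mean_r
        direct = ((x - x.mean()) * (y - y.mean())).sum() / math.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert r == pytest.approx(direct, abs=1e-12)

    def test_zero_variance_raises(self):
        t = self._table([0.1, 0.1, 0.1], [0.1, 0.2, 0.3])
        with pytest.raises(ValueError, match="variance"):
            pearson_between_replicates(t)


class TestVarianceTests:
    def test_bartlett_identical_samples(self):
        g = {"a": [1.0, 2, 3, 4, 5], "b": [2.0, 3, 4, 5, 6]}
        stat, df, p = bartlett_test(g)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_bartlett_matches_scipy_and_hand_formula(self, rng):
        xs = [rng.normal(0, s, 5) for s in (1.0, 2.0, 0.5)]
        stat, df, p = bartlett_test({f"g{i}": x for i, x in enumerate(xs)})
        ref_stat, ref_p = sps.bartlett(*xs)
        assert stat == pytest.approx(ref_stat, rel=1e-10)
        assert p == pytest.approx(ref_p, rel=1e-9)
        # direct evaluation of the chi-square formula
        n = np.array([len(x) for x in xs], float)
        v = np.array([x.var(ddof=1) for x in xs])
        N, k = n.sum(), 3
        sp2 = ((n - 1) * v).sum() / (N - k)
        num = (N - k) * np.log(sp2) - ((n - 1) * np.log(v)).sum()
        C = 1 + (np.sum(1 / (n - 1)) - 1 / (N - k)) / (3 * (k - 1))
        assert stat == pytest.approx(num / C, rel=1e-10)

    def test_f_test_of_sample_against_itself(self):
        x = [1.0, 2.0, 4.0, 8.0]
        F, (d1, d2), p = variance_f_test(x, x)
        assert F == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_f_test_two_sided_tail_doubling(self, rng):
        a = rng.normal(0, 3, 10)
        b = rng.normal(0, 1, 15)
        F, (d1, d2), p = variance_f_test(a, b)
        tail = 1 - sps.f.cdf(F, d1, d2)
        assert p == pytest.approx(2 * min(tail, 1 - tail))


class TestIntraPlateVariance:
    def _table(self, values):
        rows = []
        for rep, vals in enumerate(values, start=1):
            for i, v in enumerate(vals):
                rows.append(
                    {"replicate": rep, "condition": "NC", "position": f"p{i}",
                     "frac_spindle": v}
                )
        return pd.DataFrame(rows)

    def test_identical_positions_zero(self):
        t = self._table([[0.3, 0.3, 0.3], [0.4, 0.4, 0.4]])
        out = intra_plate_variance(t)
        assert out["mean_intra_variance"].iloc[0] == pytest.approx(0.0)

    def test_doubling_quadruples(self, rng):
        vals = rng.normal(0.3, 0.05, (3, 8))
        t1 = self._table([list(v) for v in vals])
        t2 = self._table([list(2 * v) for v in vals])
        v1 = intra_plate_variance(t1)["mean_intra_variance"].iloc[0]
        v2 = intra_plate_variance(t2)["mean_intra_variance"].iloc[0]
        assert v2 == pytest.approx(4 * v1, rel=1e-10)

    def test_two_pass_oracle(self, rng):
        vals = rng.normal(0.3, 0.05, (3, 6))
        t = self._table([list(v) for v in vals])
        out = intra_plate_variance(t)["mean_intra_variance"].iloc[0]
        direct = np.mean([v.var(ddof=1) for v in vals])
        assert out == pytest.approx(direct, rel=1e-12)

    def test_single_position_replicate_excluded(self):
        t = self._table([[0.3], [0.1, 0.2, 0.3]])
        with pytest.warns(UserWarning):
            out = intra_plate_variance(t)
        assert out["n_replicates"].iloc[0] == 1


class TestReplicatesNeeded:
    def test_equal_variances_identity(self):
        out = replicates_needed(2.0, 2.0, 3)
        assert out.n_exact == 3.0 and out.n_ceiling == 3

    def test_published_spindle_sds(self):
        """Array vs plate spindle SDs 7.4 and 5.3 with three plate
        replicates require 7.4^2/5.3^2*3 = 5.85 array replicates."""
        out = replicates_needed(7.4**2, 5.3**2, 3)
        assert out.n_exact == pytest.approx(5.8485, abs=5e-4)
        assert out.n_ceiling == 6

    def test_zero_array_variance_limit(self):
        out = replicates_needed(0.0, 1.0, 4)
        assert out.n_exact == 0.0 and out.n_ceiling == 0

    def test_zero_well_variance_raises(self):
        with pytest.raises(ValueError):
            replicates_needed(1.0, 0.0, 3)

    def test_summary_input(self):
        gs = [GroupSummary("a", 5, 0.0, 2.0), GroupSummary("b", 7, 1.0, 3.0)]
        res = welch_anova(gs)
        assert res.df1 == 1
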