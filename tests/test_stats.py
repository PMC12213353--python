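"""Statistics layer, each statistic cross-checked against closed-form recomputation."""

import numpy as np
import pandas as pd
import pytest

from eegage.stats import (
    correlation_metrics,
    independent_gap_test,
    matched_control_sample,
    paired_gap_test,
    paired_gap_test_from_summary,
    regional_anova,
)


class TestCorrelationMetrics:
    def test_perfect_prediction(self, rng):
        ca = rng.uniform(3, 14, size=30)
        m = correlation_metrics(ca, ca)
        assert m.r == pytest.approx(1.0)
        assert m.r2 == pytest.approx(1.0)
        assert m.mae_years == 0.0

    def test_perfect_anticorrelation(self, rng):
        ca = rng.uniform(3, 14, size=30)
        m = correlation_metrics(-ca + 17.0, ca)
        assert m.r == pytest.approx(-1.0)

    def test_r_matches_covariance_formula(self, rng):
        ba = rng.uniform(2, 15, size=50)
        ca = rng.uniform(3, 14, size=50)
        m = correlation_metrics(ba, ca)
        # independent recomputation from raw sums
        bc, cc = ba - ba.mean(), ca - ca.mean()
        r_oracle = (bc * cc).sum() / np.sqrt((bc**2).sum() * (cc**2).sum())
        assert abs(m.r - r_oracle) < 1e-12
        assert m.r2 == pytest.approx(r_oracle**2, abs=1e-12)
        assert m.mae_years == pytest.approx(np.abs(ba - ca).mean())

    def test_explained_variance_variant(self, rng):
        ca = rng.uniform(3, 14, size=40)
        ba = ca + rng.normal(0, 1, size=40)
        m = correlation_metrics(ba, ca, r2_definition="explained_variance")
        sst = ((ca - ca.mean()) ** 2).sum()
        assert m.r2 == pytest.approx(1 - ((ba - ca) ** 2).sum() / sst)

    def test_degenerate_inputs_refused(self):
        with pytest.raises(ValueError):
            correlation_metrics([5.0, 5.0, 5.0], [3.0, 4.0, 5.0])
        with pytest.raises(ValueError):
            correlation_metrics([1.0, 2.0], [1.0, 2.0])


class TestPairedTest:
    def test_matches_closed_form_on_raw_gaps(self, rng):
        gaps = rng.normal(0.8, 1.2, size=40)
        rep = paired_gap_test(gaps)
        t_oracle = gaps.mean() / (gaps.std(ddof=1) / np.sqrt(40))
        assert rep.t == pytest.approx(t_oracle, abs=1e-10)
        assert rep.d == pytest.approx(gaps.mean() / gaps.std(ddof=1))
        assert rep.n == 40

    def test_summary_route_agrees_with_raw_route(self, rng):
        gaps = rng.normal(1.0, 1.5, size=98)
        raw = paired_gap_test(gaps)
        summ = paired_gap_test_from_summary(gaps.mean(), gaps.std(ddof=1), 98)
        assert summ.t == pytest.approx(raw.t, abs=1e-10)
        assert summ.p == pytest.approx(raw.p, abs=1e-12)

    @pytest.mark.parametrize(
        "mean,sd,printed_t",
        [(1.18, 1.49, 7.81), (0.64, 1.46, 4.33)],
    )
    def test_published_group_summaries_recompute(self, mean, sd, printed_t):
        rep = paired_gap_test_from_summary(mean, sd, n=98)
        assert rep.t == pytest.approx(printed_t, abs=0.05)

    def test_zero_variance_refused(self):
        with pytest.raises(ValueError):
            paired_gap_test(np.full(10, 0.5))


class TestIndependentTest:
    def test_identical_groups(self, rng):
        g = rng.normal(size=20)
        t, p = independent_gap_test(g, g.copy())
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_shift_gives_positive_t(self, rng):
        g = rng.normal(0, 1, size=200)
        t, p = independent_gap_test(g + 1.0, g)
        assert t > 0 and p < 1e-6

    def test_pooled_variant_matches_textbook_formula(self, rng):
        a = rng.normal(1.0, 1.0, size=25)
        b = rng.normal(0.2, 1.3, size=30)
        t, _ = independent_gap_test(a, b, equal_var=True)
        sp2 = ((24 * a.var(ddof=1)) + (29 * b.var(ddof=1))) / (25 + 30 - 2)
        t_oracle = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 25 + 1 / 30))
        assert t == pytest.approx(t_oracle, abs=1e-10)

    def test_degenerate_refused(self):
        with pytest.raises(ValueError):
            independent_gap_test([1.0, 1.0], [1.0, 1.0])
        with pytest.raises(ValueError):
            independent_gap_test([1.0], [1.0, 2.0])


def rm_anova_oracle(g):
    """Textbook sums-of-squares for a one-way within-subject design."""
    n, k = g.shape
    grand = g.mean()
    ss_effect = n * ((g.mean(axis=0) - grand) ** 2).sum()
    ss_subject = k * ((g.mean(axis=1) - grand) ** 2).sum()
    ss_total = ((g - grand) ** 2).sum()
    ss_error = ss_total - ss_effect - ss_subject
    df1, df2 = k - 1, (k - 1) * (n - 1)
    f = (ss_effect / df1) / (ss_error / df2)
    return f, df1, df2, ss_effect / (ss_effect + ss_error)


class TestRegionalAnova:
    def test_df_arithmetic_for_98_by_5(self, rng):
        g = rng.normal(size=(98, 5))
        res = regional_anova(g)
        assert (res.df1, res.df2) == (4, 388)

    def test_matches_sums_of_squares_oracle(self, rng):
        g = rng.normal(size=(20, 5)) + np.array([0.0, 0.3, 0.1, 0.5, 0.2])
        res = regional_anova(g)
        f, df1, df2, eta = rm_anova_oracle(g)
        assert res.f == pytest.approx(f, rel=1e-10)
        assert (res.df1, res.df2) == (df1, df2)
        assert res.partial_eta_sq == pytest.approx(eta, rel=1e-10)

    def test_identical_regions_give_zero_f(self, rng):
        col = rng.normal(size=20)
        res = regional_anova(np.tile(col[:, None], (1, 5)))
        assert res.f == 0.0 and res.p == 1.0

    def test_posthoc_bonferroni_multiplies_and_caps(self, rng):
        g = rng.normal(size=(15, 5))
        res = regional_anova(g)
        assert len(res.posthoc) == 10
        for row in res.posthoc.itertuples():
            assert row.p_bonferroni == pytest.approx(min(1.0, row.p_uncorrected * 10))

    def test_missing_cells_refused(self, rng):
        g = rng.normal(size=(10, 5))
        g[3, 2] = np.nan
        with pytest.raises(ValueError):
            regional_anova(g)


class TestMatchedControls:
    def make_pool(self, rng, n, ages=None):
        return pd.DataFrame(
            {
                "subject_id": [f"h{i}" for i in range(n)],
                "ca_years": ages if ages is not None else rng.uniform(3, 14, size=n),
                "sex": rng.choice(["M", "F"], size=n),
            }
        )

    def test_self_match_recovers_age_distribution(self, rng):
        pool = self.make_pool(rng, 200)
        cases = pool.sample(40, random_state=1).reset_index(drop=True)
        matched = matched_control_sample(pool, cases, seed=0)
        assert len(matched) == 40
        assert abs(matched["ca_years"].mean() - cases["ca_years"].mean()) < 0.5

    def test_seeded_determinism(self, rng):
        pool = self.make_pool(rng, 100)
        cases = self.make_pool(rng, 30)
        a = matched_control_sample(pool, cases, seed=7)
        b = matched_control_sample(pool, cases, seed=7)
        assert a.equals(b)

    def test_pool_smaller_than_cases_refused(self, rng):
        pool = self.make_pool(rng, 10)
        cases = self.make_pool(rng, 11)
        with pytest.raises(ValueError):
            matched_control_sample(pool, cases, seed=0)

    def test_sex_stratum_exhaustion_raises(self):
        pool = pd.DataFrame({"ca_years": [5.0, 6.0], "sex": ["M", "M"]})
        cases = pd.DataFrame({"ca_years": [5.5, 6.5], "sex": ["F", "F"]})
        with pytest.raises(ValueError, match="stratum"):
            matched_control_sample(pool, cases, seed=0)
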