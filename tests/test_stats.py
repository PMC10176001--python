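"""Statistical battery tests: mixed ANOVA, pooled t, Sidak, correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mapresponder.stats import (
    correlation_band,
    gg_epsilon,
    mauchly_test,
    mixed_anova,
    pearson_with_band,
    pooled_t_from_samples,
    pooled_two_sample_t,
    responder_stratified_anova,
    sidak_posthoc,
)

from conftest import mixed_anova_closed_form


def _long_table(y1, y2, groups, outcome="y"):
    rows = []
    for i, (a, b, g) in enumerate(zip(y1, y2, groups)):
        rows.append({"participant": f"p{i}", "group": g, "time": "baseline",
                     "outcome": outcome, "value": a})
        rows.append({"participant": f"p{i}", "group": g, "time": "day2",
                     "outcome": outcome, "value": b})
    return pd.DataFrame(rows)


def _random_design(rng, n1, n2):
    groups = np.array(["exp"] * n1 + ["ctl"] * n2)
    y1 = rng.normal(10, 3, n1 + n2)
    y2 = y1 * rng.uniform(0.5, 1.0) + rng.normal(1, 2, n1 + n2)
    return y1, y2, groups


class TestMixedAnova:
    def test_matches_closed_form_oracle_balanced_and_unbalanced(self, rng):
        for _ in range(20):
            n1, n2 = int(rng.integers(3, 12)), int(rng.integers(3, 12))
            y1, y2, groups = _random_design(rng, n1, n2)
            res = mixed_anova(_long_table(y1, y2, groups))
            oracle = mixed_anova_closed_form(y1, y2, groups)
            for effect in ("group", "time", "interaction"):
                key = effect if effect != "group" else "group"
                assert res.effects[key].F == pytest.approx(oracle[effect], abs=1e-8)

    def test_matches_pingouin_on_balanced_designs(self, rng):
        pg = pytest.importorskip("pingouin")
        for _ in range(5):
            n = int(rng.integers(4, 10))
            y1, y2, groups = _random_design(rng, n, n)
            table = _long_table(y1, y2, groups)
            res = mixed_anova(table)
            ref = pg.mixed_anova(table, dv="value", within="time",
                                 between="group", subject="participant")
            ref = dict(zip(ref["Source"], ref["F"]))
            assert res.effects["group"].F == pytest.approx(ref["group"], rel=1e-9)
            assert res.effects["time"].F == pytest.approx(ref["time"], rel=1e-9)
            assert res.effects["interaction"].F == pytest.approx(ref["Interaction"], rel=1e-9)

    def test_constant_data_gives_zero_f(self):
        y = np.full(8, 5.0)
        res = mixed_anova(_long_table(y, y, ["a"] * 4 + ["b"] * 4))
        for e in res.effects.values():
            assert e.F == 0.0

    def test_interaction_equals_squared_change_score_t(self, rng):
        y1, y2, groups = _random_design(rng, 9, 5)
        res = mixed_anova(_long_table(y1, y2, groups))
        d = y2 - y1
        t = pooled_t_from_samples(d[groups == "ctl"], d[groups == "exp"]).t
        assert res.effects["interaction"].F == pytest.approx(t**2, rel=1e-10)

    def test_two_level_epsilon_is_one_and_mauchly_trivial(self, rng):
        y1, y2, groups = _random_design(rng, 6, 6)
        res = mixed_anova(_long_table(y1, y2, groups))
        assert res.epsilon_gg == pytest.approx(1.0)
        assert res.mauchly == (1.0, 1.0)
        assert res.shapiro  # per-cell normality checks ran

    def test_degrees_of_freedom(self, rng):
        y1, y2, groups = _random_design(rng, 26, 10)
        res = mixed_anova(_long_table(y1, y2, groups))
        for e in res.effects.values():
            assert (e.df_num, e.df_den) == (1, 34)

    def test_incomplete_participants_dropped(self, rng):
        y1, y2, groups = _random_design(rng, 5, 5)
        table = _long_table(y1, y2, groups)
        table = table.drop(table.index[-1])  # one participant loses day2
        res = mixed_anova(table)
        assert res.n_used == 9 and res.n_dropped == 1

    def test_too_small_group_raises(self):
        table = _long_table([1.0, 2.0, 3.0], [2.0, 3.0, 4.0], ["a", "a", "b"])
        with pytest.raises(ValueError):
            mixed_anova(table)


class TestGreenhouseGeisser:
    def test_spherical_covariance_gives_epsilon_one(self):
        assert gg_epsilon(np.eye(4)) == pytest.approx(1.0)

    def test_epsilon_bounds(self, rng):
        for k in (3, 4, 5):
            a = rng.normal(size=(20, k))
            cov = np.cov(a.T)
            eps = gg_epsilon(cov)
            assert 1.0 / (k - 1) - 1e-12 <= eps <= 1.0 + 1e-12

    def test_mauchly_two_levels_vacuous(self):
        assert mauchly_test(np.eye(2), 20) == (1.0, 1.0)

    def test_mauchly_detects_nonsphericity(self, rng):
        cov = np.diag([1.0, 5.0, 25.0])
        w, p = mauchly_test(cov, 40)
        assert w < 0.5 and p < 0.01


class TestPooledT:
    def test_identical_summaries_zero_t(self):
        res = pooled_two_sample_t(5.0, 2.0, 10, 5.0, 2.0, 10)
        assert res.t == 0.0 and res.mean_difference == 0.0

    @pytest.mark.parametrize(
        "m1, s1, m2, s2, md",
        [(1.3, 1.2, 0.0, 0.0, 1.3),
         (5.4, 2.5, 0.2, 0.4, 5.2),
         (3.4, 2.1, 0.0, 0.0, 3.4),
         (4.5, 1.8, 0.2, 0.4, 4.3),
         (25.9, 16.6, 0.2, 0.4, 25.7)],
    )
    def test_day2_group_differences(self, m1, s1, m2, s2, md):
        res = pooled_two_sample_t(m1, s1, 26, m2, s2, 10)
        assert res.mean_difference == pytest.approx(md)
        assert res.df == 34
        assert res.ci95[0] < md < res.ci95[1]

    def test_pain_area_t_statistic(self):
        res = pooled_two_sample_t(25.9, 16.6, 26, 0.2, 0.4, 10)
        assert res.t == pytest.approx(4.85, abs=0.01)

    def test_agrees_with_scipy_on_random_summaries(self, rng):
        for _ in range(50):
            m1, m2 = rng.normal(0, 10, 2)
            s1, s2 = rng.uniform(0.5, 8, 2)
            n1, n2 = rng.integers(2, 40, 2)
            res = pooled_two_sample_t(m1, s1, int(n1), m2, s2, int(n2))
            ref = sps.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=True)
            assert res.t == pytest.approx(ref.statistic, abs=1e-10)
            assert res.p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_zero_variance_nonzero_md_warns_inf(self):
        with pytest.warns(UserWarning):
            res = pooled_two_sample_t(2.0, 0.0, 5, 1.0, 0.0, 5)
        assert np.isinf(res.t)

    def test_raw_sample_form(self, rng):
        x, y = rng.normal(0, 1, 20), rng.normal(0.5, 1, 15)
        res = pooled_t_from_samples(x, y)
        ref = sps.ttest_ind(x, y, equal_var=True)
        assert res.t == pytest.approx(ref.statistic)


class TestSidak:
    @pytest.mark.parametrize(
        "p, m, expected",
        [(0.0, 5, 0.0), (0.05, 1, 0.05), (0.02, 2, 0.0396), (1.0, 3, 1.0)],
    )
    def test_formula(self, p, m, expected):
        assert sidak_posthoc([p], m)[0] == pytest.approx(expected)

    def test_adjustment_never_decreases(self, rng):
        p = rng.uniform(0, 1, 50)
        for m in (1, 2, 5):
            adj = sidak_posthoc(p, m)
            assert np.all(adj >= p - 1e-15)
            assert np.all(adj <= 1.0)

    def test_invalid_p_raises(self):
        with pytest.raises(ValueError):
            sidak_posthoc([1.5])


class TestPearson:
    def test_perfect_linear_strong(self):
        x = np.arange(10.0)
        res = pearson_with_band(x, 2 * x)
        assert res.r == pytest.approx(1.0)
        assert res.band == "strong"

    @pytest.mark.parametrize(
        "r, band",
        [(-0.56, "strong"), (-0.46, "moderate"), (0.29, "weak"),
         (0.3, "moderate"), (0.5, "moderate"), (0.51, "strong")],
    )
    def test_band_boundaries(self, r, band):
        assert correlation_band(r) == band

    def test_affine_invariance_and_sign_flip(self, rng):
        x, y = rng.normal(0, 1, 30), rng.normal(0, 1, 30)
        r0 = pearson_with_band(x, y).r
        assert pearson_with_band(3 * x + 2, 0.5 * y - 7).r == pytest.approx(r0)
        assert pearson_with_band(-x, y).r == pytest.approx(-r0)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            pearson_with_band([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestResponderStratified:
    def _tables(self, rng, d_fac, d_dep, sd=80.0, n=12):
        rows, labels = [], []
        for j in range(2 * n):
            stratum = "facilitator" if j < n else "depressor"
            delta = rng.normal(d_fac if stratum == "facilitator" else d_dep, sd)
            base = rng.normal(600, 150)
            pid = f"p{j}"
            rows += [
                {"participant": pid, "group": "experimental", "time": "baseline",
                 "outcome": "ppt_kpa", "value": base},
                {"participant": pid, "group": "experimental", "time": "day2",
                 "outcome": "ppt_kpa", "value": base + delta},
            ]
            labels.append({"participant": pid, "metric": "volume", "label": stratum})
        return pd.DataFrame(rows), pd.DataFrame(labels)

    def test_identical_strata_zero_f(self):
        rows, labels = [], []
        for j in range(6):
            stratum = "facilitator" if j < 3 else "depressor"
            pid = f"p{j}"
            rows += [
                {"participant": pid, "group": "experimental", "time": "baseline",
                 "outcome": "ppt_kpa", "value": 600.0},
                {"participant": pid, "group": "experimental", "time": "day2",
                 "outcome": "ppt_kpa", "value": 600.0},
            ]
            labels.append({"participant": pid, "metric": "volume", "label": stratum})
        res = responder_stratified_anova(pd.DataFrame(rows), pd.DataFrame(labels), "ppt_kpa")
        assert all(e.F == 0.0 for e in res.effects.values())

    def test_power_at_programmed_effect(self, rng):
        # PPT falls for facilitators, rises for depressors: dV +130 % vs -60 %
        # through slope -0.6 kPa/% with 80 kPa noise gives d ~ 1.4, for which
        # the analytic power of the interaction test at n = 12+12 is ~0.9
        rejections = 0
        n_rep = 300
        for _ in range(n_rep):
            table, labels = self._tables(rng, -0.6 * 130, -0.6 * -60)
            res = responder_stratified_anova(table, labels, "ppt_kpa")
            rejections += res.effects["interaction"].p < 0.05
        assert rejections / n_rep >= 0.80

    def test_nonresponders_excluded(self, rng):
        table, labels = self._tables(rng, -60, 60, n=5)
        labels.loc[len(labels)] = {"participant": "p0", "metric": "volume",
                                   "label": "nonresponder"}
        extra = pd.DataFrame(labels.iloc[-1:]).assign(participant="px")
        res = responder_stratified_anova(table, pd.concat([labels, extra]), "ppt_kpa")
        assert res.n_used == 10

    def test_single_member_stratum_raises(self, rng):
        table, labels = self._tables(rng, -60, 60, n=5)
        labels.loc[labels["participant"] != "p0", "label"] = "depressor"
        with pytest.raises(ValueError):
            responder_stratified_anova(table, labels, "ppt_kpa")
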