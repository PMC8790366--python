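"""Statistical layer against brute-force and hand-computed oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from morus import stats


def brute_mwu(a, b):
    """Exact two-sided Mann-Whitney p by full enumeration of group labels."""
    pooled = np.concatenate([a, b])
    n, na = len(pooled), len(a)
    order = pooled.argsort()
    ranks = np.empty(n)
    ranks[order] = np.arange(1, n + 1)
    us = np.array([ranks[list(c)].sum() - na * (na + 1) / 2
                   for c in itertools.combinations(range(n), na)])
    u_obs = ranks[:na].sum() - na * (na + 1) / 2
    p = min(1.0, 2 * min((us <= u_obs).mean(), (us >= u_obs).mean()))
    return u_obs, p


class TestRankTest:
    def test_exact_matches_enumeration(self, rng):
        for na, nb in [(2, 3), (3, 3), (4, 4), (3, 6), (5, 5)]:
            a = rng.normal(size=na)
            b = rng.normal(0.5, 1.0, size=nb)
            res = stats.rank_test(a, b)
            u, p = brute_mwu(a, b)
            assert res.method == "exact"
            assert res.statistic == pytest.approx(u)
            assert res.p_value == pytest.approx(p, abs=1e-12)

    def test_rank_biserial_hand_case(self):
        # complete separation: U = 0 -> r = 1
        res = stats.rank_test([1.0, 2.0], [3.0, 4.0, 5.0])
        assert res.statistic == 0.0
        assert res.effect_size_r == pytest.approx(1.0)
        # reversed: U = n_a n_b -> r = -1
        res = stats.rank_test([3.0, 4.0, 5.0], [1.0, 2.0])
        assert res.effect_size_r == pytest.approx(-1.0)

    def test_ties_fall_back_to_asymptotic(self):
        res = stats.rank_test([1.0, 2.0, 2.0], [2.0, 3.0])
        assert res.method == "asymptotic"

    def test_large_samples_asymptotic(self, rng):
        res = stats.rank_test(rng.normal(size=30), rng.normal(size=30))
        assert res.method == "asymptotic"
        assert 0.0 <= res.p_value <= 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            stats.rank_test([], [1.0])


class TestWelchT:
    def test_hand_computed_case(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([2.0, 4.0, 6.0])
        va, vb = a.var(ddof=1) / 4, b.var(ddof=1) / 3
        t = (a.mean() - b.mean()) / math.sqrt(va + vb)
        df = (va + vb) ** 2 / (va ** 2 / 3 + vb ** 2 / 2)
        res = stats.two_sample_t(a, b)
        assert res.statistic == pytest.approx(t)
        assert res.df == pytest.approx(df)

    def test_df_fractional_for_unequal_variances(self, rng):
        res = stats.two_sample_t(rng.normal(0, 1, 20), rng.normal(0, 5, 12))
        assert res.df != int(res.df)
        assert res.df < 30  # Welch df below pooled df

    def test_tiny_sample_rejected(self):
        with pytest.raises(ValueError):
            stats.two_sample_t([1.0], [2.0, 3.0])


class TestCandidateTermSets:
    def test_marginality_respected(self):
        sets = stats.candidate_term_sets()
        for terms in sets:
            for t in terms:
                if ":" in t:
                    a, b = t.split(":")
                    assert a in terms and b in terms

    def test_counts(self):
        # 4 mains -> 16 subsets; interaction allowed only when sex and type
        # are both present: 2^2 = 4 extra candidates
        sets = stats.candidate_term_sets()
        assert len(sets) == 16 + 4
        assert () in sets
        assert stats.FULL_TERMS in [tuple(s) for s in sets]


class TestAkaikeWeights:
    def test_sum_to_one(self):
        w = stats.akaike_weights([10.0, 12.0, 30.0])
        assert w.sum() == pytest.approx(1.0)

    def test_invariant_to_constant_shift(self):
        a = np.array([100.0, 103.0, 101.5])
        np.testing.assert_allclose(stats.akaike_weights(a),
                                   stats.akaike_weights(a + 57.3))

    def test_known_ratio(self):
        w = stats.akaike_weights([0.0, 2.0])
        assert w[0] / w[1] == pytest.approx(math.exp(1.0))


def _fake_fit(terms, aic, coef=None, se=None):
    coef = coef or {"Intercept": 1.0}
    se = se or {k: 0.1 for k in coef}
    return stats.FittedModel(terms=tuple(terms), coef=coef, se=se,
                             aic=aic, llf=-aic / 2)


class TestModelAveraging:
    def test_window_boundary(self):
        fits = [_fake_fit(("a",), 100.0, {"Intercept": 1.0, "a": 2.0},
                          {"Intercept": 0.1, "a": 0.2}),
                _fake_fit((), 106.0),
                _fake_fit(("b",), 106.01, {"Intercept": 1.0, "b": 3.0},
                          {"Intercept": 0.1, "b": 0.3})]
        avg = stats.aic_model_average(fits)
        assert len(avg.retained) == 2  # delta 6.0 kept, 6.01 excluded
        assert "b" not in set(avg.table["term"])

    def test_retained_weights_sum_to_one(self):
        fits = [_fake_fit((), 10.0), _fake_fit(("a",), 11.0,
                                               {"Intercept": 1.0, "a": 1.0},
                                               {"Intercept": 0.1, "a": 0.1})]
        avg = stats.aic_model_average(fits)
        assert avg.retained["weight"].sum() == pytest.approx(1.0)

    def test_common_term_is_convex_combination(self):
        fits = [_fake_fit(("a",), 10.0, {"Intercept": 2.0, "a": 1.0},
                          {"Intercept": 0.1, "a": 0.1}),
                _fake_fit(("a", "b"), 11.0,
                          {"Intercept": 4.0, "a": 1.5, "b": 0.2},
                          {"Intercept": 0.1, "a": 0.1, "b": 0.1})]
        avg = stats.aic_model_average(fits)
        inter = avg.table.set_index("term").loc["Intercept", "coefficient"]
        assert 2.0 <= inter <= 4.0

    def test_adjusted_se_exceeds_mean_se_under_disagreement(self):
        fits = [_fake_fit(("a",), 10.0, {"a": 1.0}, {"a": 0.1}),
                _fake_fit(("a",), 10.5, {"a": 3.0}, {"a": 0.1})]
        avg = stats.aic_model_average(fits)
        row = avg.table.set_index("term").loc["a"]
        assert row["adjusted_se"] > row["se"]

    def test_full_mode_shrinks_toward_zero(self):
        fits = [_fake_fit(("a",), 10.0, {"a": 2.0}, {"a": 0.1}),
                _fake_fit((), 10.0, {"Intercept": 0.0}, {"Intercept": 0.1})]
        cond = stats.aic_model_average(fits, mode="conditional")
        full = stats.aic_model_average(fits, mode="full")
        a_cond = cond.table.set_index("term").loc["a", "coefficient"]
        a_full = full.table.set_index("term").loc["a", "coefficient"]
        assert a_cond == pytest.approx(2.0)
        assert a_full == pytest.approx(1.0)  # half weight on a zero model

    def test_no_fits_rejected(self):
        with pytest.raises(ValueError):
            stats.aic_model_average([])


def _cost_data(rng, n_birds=8, per_bird=30):
    rows = []
    for b in range(n_birds):
        sex = "female" if b % 2 else "male"
        mass = 2.9 if sex == "female" else 2.7
        intercept = rng.normal(2.0, 0.2)
        for _ in range(per_bird):
            dive_type = "plunge" if rng.random() < 0.7 else "pursuit"
            cost = intercept + (0.8 if dive_type == "pursuit" else 0.0) \
                + (0.2 if sex == "female" else 0.0) + rng.normal(0, 0.3)
            rows.append({"bird_id": f"B{b}", "sex": sex, "mass": mass,
                         "year": 2017 + b % 2, "type": dive_type,
                         "cost_kj": cost})
    return pd.DataFrame(rows)


class TestMixedModel:
    def test_fits_and_detects_type_effect(self, rng):
        data = _cost_data(rng)
        fit = stats.fit_dive_cost_model(data, ("sex", "type"))
        assert fit.converged
        type_terms = [k for k in fit.coef if k.startswith("type")]
        assert len(type_terms) == 1
        assert fit.coef[type_terms[0]] == pytest.approx(0.8, abs=0.25)

    def test_aic_is_ml_based(self, rng):
        data = _cost_data(rng)
        fit = stats.fit_dive_cost_model(data, ())
        # AIC = -2 llf + 2 (1 fixed + RE variance + residual)
        assert fit.aic == pytest.approx(-2 * fit.llf + 2 * 3)

    def test_richer_model_has_higher_loglik(self, rng):
        data = _cost_data(rng)
        f0 = stats.fit_dive_cost_model(data, ())
        f1 = stats.fit_dive_cost_model(data, ("sex", "type"))
        assert f1.llf >= f0.llf

    def test_single_bird_rejected(self, rng):
        data = _cost_data(rng).query("bird_id == 'B0'")
        with pytest.raises(ValueError, match="two birds"):
            stats.fit_dive_cost_model(data, ())


class TestDiveRateModel:
    def test_matches_one_way_anova(self, rng):
        from scipy import stats as sps
        rates = np.concatenate([rng.normal(26, 5, 6), rng.normal(17, 5, 8)])
        sexes = np.array(["female"] * 6 + ["male"] * 8)
        res = stats.dive_rate_model(rates, sexes)
        f, p = sps.f_oneway(rates[:6], rates[6:])
        assert res.f_statistic == pytest.approx(f)
        assert res.p_value == pytest.approx(p)
        assert (res.df_num, res.df_den) == (1, 12)

    def test_one_sex_rejected(self):
        with pytest.raises(ValueError, match="two sexes"):
            stats.dive_rate_model([1.0, 2.0], ["female", "female"])

    def test_single_bird_in_a_sex_rejected(self):
        with pytest.raises(ValueError, match="at least two"):
            stats.dive_rate_model([1.0, 2.0, 3.0],
                                  ["female", "male", "male"])
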