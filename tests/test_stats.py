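"""Feature screening, stepwise OLS, LMG importance and habitat tests."""

import itertools
import logging

import numpy as np
import pandas as pd
import pytest

from reefaes import synthgen
from reefaes.stats import (
    backward_stepwise,
    correlation_filter,
    fit_habitat_model,
    importance_shares,
    respondent_effects,
    tukey_posthoc,
)


class TestCorrelationFilter:
    def test_near_duplicate_pair_keeps_higher_target_correlation(self, rng):
        z = rng.normal(0, 1, 400)
        df = pd.DataFrame({
            "strong": z + rng.normal(0, 0.1, 400),
            "weak": z + rng.normal(0, 0.12, 400),
        })
        target = pd.Series(df["strong"] + rng.normal(0, 0.5, 400))
        retained, log = correlation_filter(df, target)
        assert retained == ["strong"]
        assert log[0]["removed"] == "weak"
        assert log[0]["kept"] == "strong"

    def test_uncorrelated_features_pass_unchanged(self, rng):
        df = pd.DataFrame(rng.normal(0, 1, (300, 4)), columns=list("abcd"))
        target = pd.Series(rng.normal(0, 1, 300))
        retained, log = correlation_filter(df, target)
        assert retained == ["a", "b", "c", "d"]
        assert log == []

    def test_three_feature_chain_matches_hand_trace(self):
        # engineered chain with clear margins: r(A,B) ~ 0.92 (the worst
        # pair, examined first), r(B,C) ~ 0.85, r(A,C) ~ 0.80; the target
        # follows A.  Tracing the stated rule by hand: drop B (lower
        # target correlation than A), then the (A, C) pair still exceeds
        # 0.7 so C is dropped too, leaving {A}.
        rng = np.random.default_rng(77)
        b = rng.normal(0, 1, 500)
        df = pd.DataFrame({
            "A": 0.92 * b + np.sqrt(1 - 0.92**2) * rng.normal(0, 1, 500),
            "B": b,
            "C": 0.85 * b + np.sqrt(1 - 0.85**2) * rng.normal(0, 1, 500),
        })
        target = pd.Series(df["A"] + rng.normal(0, 0.3, 500))
        corr = df.corr().abs()
        assert corr.loc["A", "B"] > corr.loc["B", "C"] > corr.loc["A", "C"] > 0.7
        retained, log = correlation_filter(df, target)
        assert retained == ["A"]
        assert [e["removed"] for e in log] == ["B", "C"]

    def test_no_surviving_pair_above_threshold(self, quadrat_batch):
        feats = quadrat_batch["features"]
        target = feats["pct_live_coral"] * 2.0
        retained, _ = correlation_filter(feats, target)
        corr = feats[retained].corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        assert corr.max() <= 0.7

    def test_constant_feature_dropped_with_warning(self, rng, caplog):
        df = pd.DataFrame({"flat": np.ones(50), "ok": rng.normal(0, 1, 50), "ok2": rng.normal(0, 1, 50)})
        with caplog.at_level(logging.WARNING):
            retained, log = correlation_filter(df, pd.Series(rng.normal(0, 1, 50)))
        assert "flat" not in retained
        assert "constant" in caplog.text


class TestBackwardStepwise:
    def test_signal_features_survive_noise_features(self):
        rng = np.random.default_rng(3)
        n = 500
        df = pd.DataFrame(rng.normal(0, 1, (n, 6)), columns=[f"f{k}" for k in range(6)])
        y = pd.Series(3 * df.f0 - 2 * df.f1 + 1.5 * df.f2 + rng.normal(0, 0.1, n))
        res = backward_stepwise(df, y)
        assert set(res.retained) == {"f0", "f1", "f2"}
        assert res.r_squared >= 0.99

    def test_single_significant_feature_is_kept(self, rng):
        df = pd.DataFrame({"x": rng.normal(0, 1, 100)})
        y = pd.Series(2 * df.x + rng.normal(0, 0.5, 100))
        res = backward_stepwise(df, y)
        assert res.retained == ("x",)
        assert res.importance["x"] == pytest.approx(100.0)

    def test_pure_noise_spurious_retention_near_nominal(self):
        # with alpha = 0.05 and 4 independent noise features, at least one
        # spuriously survives in roughly 1 - 0.95^4 ~ 18% of datasets
        rng = np.random.default_rng(11)
        n_keep = 0
        reps = 150
        for _ in range(reps):
            df = pd.DataFrame(rng.normal(0, 1, (120, 4)), columns=list("abcd"))
            y = pd.Series(rng.normal(0, 1, 120))
            res = backward_stepwise(df, y)
            n_keep += bool(res.retained)
        rate = n_keep / reps
        assert 0.05 < rate < 0.35

    def test_no_survivor_returns_empty_model(self, rng, caplog):
        df = pd.DataFrame({"x": rng.normal(0, 1, 2000)})
        y = pd.Series(rng.normal(0, 1, 2000))
        with caplog.at_level(logging.WARNING):
            res = backward_stepwise(df, y)
        if not res.retained:  # overwhelmingly likely at n=2000
            assert np.isnan(res.r_squared)
            assert "no feature survived" in caplog.text


class TestImportanceShares:
    def test_single_feature_gets_everything(self, rng):
        df = pd.DataFrame({"x": rng.normal(0, 1, 50)})
        y = pd.Series(df.x * 2 + rng.normal(0, 0.1, 50))
        assert importance_shares(df, y)["x"] == pytest.approx(100.0)

    def test_orthogonal_features_split_by_squared_correlation(self):
        # exactly orthogonal design: shares must be proportional to r^2
        n = 64
        t = np.arange(n)
        x1 = np.where(t % 2 == 0, 1.0, -1.0)
        x2 = np.where((t // 2) % 2 == 0, 1.0, -1.0)
        df = pd.DataFrame({"x1": x1, "x2": x2})
        y = pd.Series(3.0 * x1 + 1.0 * x2)
        shares = importance_shares(df, y)
        assert shares["x1"] == pytest.approx(90.0, abs=1e-6)
        assert shares["x2"] == pytest.approx(10.0, abs=1e-6)

    def test_matches_exhaustive_ordering_enumeration(self, rng):
        # independent oracle: average sequential R^2 gains over all k!
        # orderings, computed directly
        n, k = 200, 4
        base = rng.normal(0, 1, (n, k))
        x = base @ np.array(
            [[1, 0.5, 0.2, 0], [0, 1, 0.4, 0.1], [0, 0, 1, 0.3], [0, 0, 0, 1]]
        )
        df = pd.DataFrame(x, columns=list("wxyz"))
        y = pd.Series(x @ np.array([1.0, -0.5, 0.8, 0.3]) + rng.normal(0, 1, n))

        def r2(cols):
            if not cols:
                return 0.0
            xs = np.column_stack([np.ones(n), df[list(cols)].to_numpy()])
            beta, *_ = np.linalg.lstsq(xs, y.to_numpy(), rcond=None)
            resid = y.to_numpy() - xs @ beta
            return 1 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))

        raw = dict.fromkeys(df.columns, 0.0)
        orderings = list(itertools.permutations(df.columns))
        for order in orderings:
            so_far = []
            for feat in order:
                gain = r2(so_far + [feat]) - r2(so_far)
                raw[feat] += gain / len(orderings)
                so_far.append(feat)
        expected = pd.Series(raw) / sum(raw.values()) * 100
        shares = importance_shares(df, y)
        for c in df.columns:
            assert shares[c] == pytest.approx(expected[c], abs=1e-8)

    def test_shares_sum_to_100_and_ignore_column_order(self, rng):
        df = pd.DataFrame(rng.normal(0, 1, (100, 3)), columns=list("abc"))
        y = pd.Series(df.a + 0.5 * df.b + rng.normal(0, 1, 100))
        s1 = importance_shares(df, y)
        s2 = importance_shares(df[["c", "a", "b"]], y)
        assert s1.sum() == pytest.approx(100.0)
        for c in "abc":
            assert s1[c] == pytest.approx(s2[c])

    def test_refuses_more_than_ten_features(self, rng):
        df = pd.DataFrame(rng.normal(0, 1, (30, 11)))
        df.columns = [f"f{k}" for k in range(11)]
        with pytest.raises(ValueError, match="2\\^k"):
            importance_shares(df, pd.Series(rng.normal(0, 1, 30)))


def _habitat_data(effect=(0.0, 0.0, 0.0), n_sites=4, n_img=15, seed=0,
                  site_sd=1.0, noise_sd=1.0, transform=None):
    rng = np.random.default_rng(seed)
    habs = ("degraded", "healthy", "restored")
    rows = []
    for h, eff in zip(habs, effect):
        for s in range(n_sites):
            u = rng.normal(0, site_sd)
            for _ in range(n_img):
                v = eff + u + rng.normal(0, noise_sd)
                rows.append({"value": v if transform is None else transform(v),
                             "habitat": h, "site_id": f"{h}-s{s}"})
    return pd.DataFrame(rows)


class TestHabitatModel:
    def test_identical_groups_give_null_result(self):
        df = _habitat_data()
        df["value"] = 5.0
        res = fit_habitat_model(df, "gaussian")
        assert res.chi2 == pytest.approx(0.0, abs=1e-6)
        assert res.p == pytest.approx(1.0, abs=1e-6)
        assert len(set(res.letters.values())) == 1

    def test_strong_two_vs_one_pattern_yields_a_a_b(self):
        df = _habitat_data(effect=(0.0, 6.0, 6.0), seed=1)
        res = fit_habitat_model(df, "gaussian")
        assert res.p < 0.001
        assert res.letters["healthy"] == res.letters["restored"]
        assert res.letters["degraded"] != res.letters["healthy"]

    def test_adjusted_p_at_least_raw_p(self):
        df = _habitat_data(effect=(0.0, 1.0, 2.0), seed=2)
        res = fit_habitat_model(df, "gaussian")
        assert (res.contrasts["p_adj"] >= res.contrasts["p_raw"] - 1e-12).all()

    def test_single_site_per_habitat_rejected(self):
        df = _habitat_data(n_sites=1)
        with pytest.raises(ValueError, match="2 sites"):
            fit_habitat_model(df, "gaussian")

    def test_gamma_nudges_zero_values_and_notes_it(self):
        df = _habitat_data(effect=(1.0, 3.0, 3.0), seed=3, transform=lambda v: max(np.exp(v / 2), 0.0))
        df.loc[df.index[:3], "value"] = 0.0
        res = fit_habitat_model(df, "gamma")
        assert any("nudged" in n for n in res.notes)
        assert np.isfinite(res.chi2)

    def test_poisson_family_on_counts(self):
        rng = np.random.default_rng(4)
        rows = []
        for h, eff in zip(("degraded", "healthy", "restored"), (0.5, 1.5, 1.5)):
            for s in range(4):
                u = rng.normal(0, 0.3)
                for _ in range(15):
                    rows.append({
                        "value": float(rng.poisson(np.exp(eff + u))),
                        "habitat": h, "site_id": f"{h}-s{s}",
                    })
        df = pd.DataFrame(rows)
        res = fit_habitat_model(df, "poisson")
        assert res.family == "poisson"
        assert res.df == 2
        assert 0.0 <= res.p <= 1.0

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="unknown family"):
            fit_habitat_model(_habitat_data(), "lognormal")

    def test_posthoc_requires_covariance(self):
        from reefaes.stats import HabitatTestResult

        res = HabitatTestResult(
            response="x", family="gaussian", chi2=1.0, df=2, p=0.5,
            letters={}, contrasts=pd.DataFrame(), group_estimates={},
        )
        with pytest.raises(ValueError, match="covariance"):
            tukey_posthoc(res)


class TestRespondentEffects:
    @staticmethod
    def _records(attr_effects=None, seed=0, n_resp=50, n_img=25):
        rng = np.random.default_rng(seed)
        scores = {f"p{k}": float(rng.normal(0, 300)) for k in range(n_img)}
        return synthgen.simulate_choices(
            scores, n_respondents=n_resp, pairs_each=20,
            attr_effects=attr_effects, seed=seed,
        )

    def test_null_attributes_mostly_non_significant(self):
        tab = respondent_effects(self._records(seed=1))
        assert set(tab.columns) == {"attribute", "chi2", "df", "p"}
        assert (tab["p"] < 0.05).sum() <= 1  # at most one false positive

    def test_injected_country_effect_is_detected(self):
        recs = self._records(attr_effects={"country": {"Indonesia": 500.0}}, seed=2)
        tab = respondent_effects(recs).set_index("attribute")
        assert tab.loc["country", "p"] < 0.01

    def test_no_attributes_rejected(self):
        with pytest.raises(ValueError, match="no respondent attributes"):
            respondent_effects(self._records(seed=3), attributes=[])

    def test_single_level_attribute_dropped_with_warning(self, caplog):
        df = synthgen.records_to_frame(self._records(seed=4))
        df["gender"] = "female"
        with caplog.at_level(logging.WARNING):
            tab = respondent_effects(df)
        assert "gender" not in set(tab["attribute"])
        assert "single level" in caplog.text
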