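"""Survival machinery: endpoints, subgroups, log-rank, Cox, enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from hervscape import survival
from hervscape.synthetic import simulate_survival


class TestSurvivalTimes:
    def _frame(self, diag, surg, end, death=1, relapse=1, pid="P1"):
        return pd.DataFrame({"date_diagnosis": [diag],
                             "date_surgery": [surg],
                             "date_endpoint": [end],
                             "death_event": [death],
                             "relapse_event": [relapse]}, index=[pid])

    def test_same_day_gives_zero_os(self):
        out = survival.compute_survival_times(self._frame(0, 0, 0))
        assert out.loc["P1", "os_months"] == 0.0

    def test_month_conversion(self):
        out = survival.compute_survival_times(self._frame(0, 0, 609))
        assert round(out.loc["P1", "rfs_months"], 1) == 20.0

    def test_missing_surgery_column_error(self):
        frame = self._frame(0, 0, 100).drop(columns=["date_surgery"])
        with pytest.raises(ValueError, match="date_surgery"):
            survival.compute_survival_times(frame)

    def test_negative_duration_names_patient(self):
        with pytest.raises(ValueError, match="P1"):
            survival.compute_survival_times(self._frame(0, 200, 100))


class TestWtsGroups:
    def test_exhaustive_truth_table(self):
        # 10 patients: quantile thresholds put the top-3 of each marker high
        cd8 = pd.Series([1, 2, 3, 4, 5, 6, 7, 8, 9, 10],
                        index=[f"P{i}" for i in range(10)], dtype=float)
        hrv = pd.Series([10, 9, 8, 7, 6, 5, 4, 3, 2, 1],
                        index=cd8.index, dtype=float)
        out = survival.assign_wts_group(cd8, hrv)
        for p in cd8.index:
            expected = "WTS-" if (not out.loc[p, "cd8_high"]
                                  and out.loc[p, "herv_high"]) else "WTS+"
            assert out.loc[p, "wts_group"] == expected
        assert (out["wts_group"] == "WTS-").any()
        assert (out["wts_group"] == "WTS+").any()

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        idx = [f"P{i}" for i in range(30)]
        cd8 = pd.Series(rng.normal(size=30), index=idx)
        hrv = pd.Series(rng.normal(size=30), index=idx)
        base = survival.assign_wts_group(cd8, hrv)
        perm = rng.permutation(idx)
        shuffled = survival.assign_wts_group(cd8[perm], hrv[perm])
        pd.testing.assert_frame_equal(shuffled.sort_index(),
                                      base.sort_index())

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="aligned"):
            survival.assign_wts_group(pd.Series([1.0, 2.0]),
                                      pd.Series([1.0]))


class TestCpGroups:
    def test_definitions(self):
        age = pd.Series([50, 50, 50, 85], index=list("abcd"), dtype=float)
        stage = pd.Series(["II", "II", "III", "III"], index=list("abcd"))
        side = pd.Series(["left", "right", "left", "right"],
                         index=list("abcd"))
        out = survival.assign_cp_group(age, stage, side)
        assert out["a"] == "CP+"          # young, stage II, left
        assert out["b"] == "CP-"          # right-sided
        assert out["c"] == "CP-"          # stage III
        assert out["d"] == "CP-"          # all three unfavourable

    def test_missing_covariate_is_na_with_warning(self):
        age = pd.Series([50.0, np.nan, 60.0])
        stage = pd.Series(["II", "II", "II"])
        side = pd.Series(["left", "left", "left"])
        with pytest.warns(UserWarning, match="missing"):
            out = survival.assign_cp_group(age, stage, side)
        assert pd.isna(out.iloc[1])


def two_group_logrank_oracle(times, events, groups):
    """Hand risk-table log-rank chi-square for two groups."""
    df = pd.DataFrame({"t": times, "e": events, "g": groups})
    ga, gb = sorted(df["g"].unique())
    o_minus_e, var = 0.0, 0.0
    for t in sorted(df.loc[df["e"] == 1, "t"].unique()):
        at_risk = df[df["t"] >= t]
        n = len(at_risk)
        na = (at_risk["g"] == ga).sum()
        d = ((df["t"] == t) & (df["e"] == 1)).sum()
        da = ((df["t"] == t) & (df["e"] == 1) & (df["g"] == ga)).sum()
        o_minus_e += da - d * na / n
        if n > 1:
            var += d * (na / n) * (1 - na / n) * (n - d) / (n - 1)
    return o_minus_e ** 2 / var


class TestKmLogrank:
    def test_identical_groups_p_is_one(self):
        times = pd.Series([3.0, 5.0, 7.0, 3.0, 5.0, 7.0])
        events = pd.Series([1, 0, 1, 1, 0, 1])
        groups = pd.Series(["a"] * 3 + ["b"] * 3)
        fit = survival.km_logrank(times, events, groups)
        assert fit.logrank_stat == pytest.approx(0.0, abs=1e-12)
        assert fit.logrank_p == 1.0

    def test_six_patient_hand_fixture(self):
        times = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        events = pd.Series([1] * 6)
        groups = pd.Series(list("ababab"))
        fit = survival.km_logrank(times, events, groups)
        expected = two_group_logrank_oracle(times, events, groups)
        assert fit.logrank_stat == pytest.approx(expected, rel=1e-9)

    def test_km_equals_empirical_survivor_without_censoring(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(1)
        t = rng.exponential(10, 40)
        kmf = KaplanMeierFitter().fit(t, np.ones(40))
        for q in (np.quantile(t, 0.25), np.quantile(t, 0.6)):
            emp = (t > q).mean()
            km = kmf.predict(q)
            assert km == pytest.approx(emp, abs=1 / 40 + 1e-9)

    def test_group_medians_and_counts(self):
        times = pd.Series([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        events = pd.Series([1, 1, 1, 0, 0, 0])
        groups = pd.Series(["a"] * 3 + ["b"] * 3)
        fit = survival.km_logrank(times, events, groups)
        by = {g.name: g for g in fit.groups}
        assert by["a"].n == 3 and by["a"].events == 3
        assert by["a"].median_months == 2.0
        assert by["b"].median_months is None   # never crosses 0.5

    def test_single_group_error(self):
        with pytest.raises(ValueError, match="two"):
            survival.km_logrank(pd.Series([1.0, 2.0]), pd.Series([1, 1]),
                                pd.Series(["a", "a"]))


def cox_newton_oracle(times, events, x, iters=60):
    """Newton solution of the partial likelihood, one binary covariate."""
    order = np.argsort(times)
    t, e, x = np.asarray(times)[order], np.asarray(events)[order], \
        np.asarray(x)[order]
    beta = 0.0
    for _ in range(iters):
        u = 0.0
        info = 0.0
        for i in range(len(t)):
            if not e[i]:
                continue
            risk = t >= t[i]
            w = np.exp(beta * x[risk])
            xbar = (w * x[risk]).sum() / w.sum()
            x2bar = (w * x[risk] ** 2).sum() / w.sum()
            u += x[i] - xbar
            info += x2bar - xbar ** 2
        beta += u / info
    return beta


class TestCox:
    def test_four_patient_hand_fixture(self):
        times = [1.0, 2.0, 3.0, 4.0]
        events = [1, 1, 1, 1]
        x = [1, 0, 1, 0]
        fit = survival.cox_fit(pd.Series(times), pd.Series(events),
                               pd.DataFrame({"x": x}), mode="univariate")
        expected = cox_newton_oracle(times, events, x)
        assert fit.hazard_ratios.loc["x", "coef"] == \
            pytest.approx(expected, abs=1e-4)

    def test_recovers_hr_two(self):
        hrs = []
        for rep in range(20):
            labels = pd.Series(["b"] * 500 + ["a"] * 500)
            out = simulate_survival(labels, {"a": 2.0},
                                    censoring_rate=0.2, seed=100 + rep)
            fit = survival.cox_fit(
                out["rfs_months"], out["rfs_event"],
                pd.DataFrame({"a": (labels == "a").astype(int)}),
                mode="univariate")
            hrs.append(fit.hazard_ratios.loc["a", "hr"])
        assert 1.8 <= np.mean(hrs) <= 2.2

    def test_null_covariate_ci_coverage(self):
        rng = np.random.default_rng(7)
        covered, n_sims = 0, 150
        for rep in range(n_sims):
            labels = pd.Series(["x"] * 100)
            out = simulate_survival(labels, {}, censoring_rate=0.2,
                                    seed=2000 + rep)
            noise = pd.DataFrame({"z": rng.normal(size=100)})
            fit = survival.cox_fit(out["rfs_months"], out["rfs_event"],
                                   noise, mode="univariate")
            lo = fit.hazard_ratios.loc["z", "hr_ci_low"]
            hi = fit.hazard_ratios.loc["z", "hr_ci_high"]
            covered += lo <= 1.0 <= hi
        assert covered / n_sims >= 0.90

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            survival.cox_fit(pd.Series([1.0, 2.0, 3.0]),
                             pd.Series([1, 1, 1]),
                             pd.DataFrame({"c": [1, 1, 1]}))

    def test_separation_reports_nonconvergence(self):
        # perfectly separating covariate: lifelines raises internally
        times = pd.Series([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        events = pd.Series([1, 1, 1, 1, 1, 1])
        cov = pd.DataFrame({"sep": [1, 1, 1, 0, 0, 0]})
        try:
            fit = survival.cox_fit(times, events, cov, mode="univariate")
        except Exception as exc:  # noqa: BLE001
            pytest.fail(f"non-convergence must not raise: {exc}")
        if not fit.converged:
            assert np.isnan(fit.hazard_ratios.loc["sep", "hr"])


class TestEnrichment:
    def test_identical_proportions_p_one(self):
        p, method = survival.two_by_two_test([[10, 40], [10, 40]])
        assert p == 1.0

    def test_fisher_matches_hypergeometric_tails(self):
        table = np.array([[9, 1], [1, 9]])
        p, method = survival.two_by_two_test(table)
        assert method == "fisher"
        # two-sided Fisher: sum of hypergeometric probabilities <= p(obs)
        M, n, N = 20, 10, 10
        probs = [hypergeom.pmf(k, M, n, N) for k in range(0, 11)]
        p_obs = hypergeom.pmf(9, M, n, N)
        expected = sum(pk for pk in probs if pk <= p_obs + 1e-12)
        assert p == pytest.approx(expected, rel=1e-9)

    def test_symmetric_under_group_swap(self):
        a = pd.Series(["x"] * 12 + ["y"] * 18)
        b = pd.Series(["u"] * 7 + ["v"] * 5 + ["u"] * 3 + ["v"] * 15)
        p1 = survival.enrichment_test(a, b)
        p2 = survival.enrichment_test(b, a)
        ps1 = sorted(p1.dropna()["p"].round(12).unique())
        ps2 = sorted(p2.dropna()["p"].round(12).unique())
        assert ps1 == ps2

    def test_empty_category_is_na(self):
        a = pd.Series(["x", "x"])
        b = pd.Series(["u", "v"])
        out = survival.enrichment_test(a, b)
        assert out["p"].notna().any() or out["p"].isna().all()
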