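import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from resectquant.phantom import CohortSpec, make_cohort
from resectquant.survival import (
    bh_adjust,
    combined_model,
    cox_fit,
    dichotomize_os,
    km_logrank,
    mrmr_select,
    normalize_features,
    roc_youden,
    split_cohort,
    stepwise_logistic,
    subgroup_analysis,
)

from _oracles import bf_auc, bf_bh, bf_km, bf_logrank


def _toy_table():
    return pd.DataFrame(
        {
            "os_days": [5, 10, 15, 2, 4, 6],
            "os_event": [0, 1, 1, 1, 1, 1],
            "group_high": [0, 0, 0, 1, 1, 1],
        }
    )


class TestDichotomize:
    def test_censored_before_endpoint_excluded(self):
        tab = pd.DataFrame(
            {
                "os_days": [800.0, 400.0, 400.0, 900.0],
                "os_event": [1, 0, 1, 0],
            }
        )
        out = dichotomize_os(tab)
        assert out["long_survivor"].tolist() == [1, 0, 0, 1]
        assert out["endpoint_excluded"].tolist() == [0, 1, 0, 0]


class TestSplit:
    def _records(self, n=100, n_long=28, seed=0):
        rng = np.random.default_rng(seed)
        tab = pd.DataFrame(
            {
                "id": range(n),
                "os_days": np.where(np.arange(n) < n_long, 900.0, 300.0),
                "os_event": 1,
                "x": rng.normal(size=n),
            }
        )
        return dichotomize_os(tab)

    def test_stratification_arithmetic(self):
        train, test = split_cohort(self._records(), train_frac=0.7, seed=0)
        assert len(train) + len(test) == 100
        assert abs(len(train) - 70) <= 1
        assert abs(train["long_survivor"].sum() - 20) <= 1
        assert abs(test["long_survivor"].sum() - 8) <= 1

    def test_deterministic(self):
        a = split_cohort(self._records(), seed=5)
        b = split_cohort(self._records(), seed=5)
        pd.testing.assert_frame_equal(a[0], b[0])

    def test_disjoint_union(self):
        train, test = split_cohort(self._records(), seed=1)
        assert set(train["id"]).isdisjoint(test["id"])
        assert set(train["id"]) | set(test["id"]) == set(range(100))

    def test_small_class_rejected(self):
        with pytest.raises(ValueError):
            split_cohort(self._records(n=10, n_long=1))


class TestNormalize:
    def test_train_standardized(self, rng):
        train = pd.DataFrame(rng.normal(5, 2, size=(50, 3)), columns=list("abc"))
        test = pd.DataFrame(rng.normal(5, 2, size=(20, 3)), columns=list("abc"))
        tr, te, scaler = normalize_features(train, test, list("abc"))
        assert np.allclose(tr.mean(), 0.0, atol=1e-12)
        assert np.allclose(tr.std(ddof=0), 1.0, atol=1e-12)

    def test_test_uses_train_stats(self, rng):
        train = pd.DataFrame({"a": rng.normal(0, 1, 50)})
        test = pd.DataFrame({"a": rng.normal(3, 1, 50)})
        _, te, _ = normalize_features(train, test, ["a"])
        assert te["a"].mean() > 1.0  # not re-centered on its own mean

    def test_constant_feature_dropped(self, rng):
        train = pd.DataFrame({"a": rng.normal(size=20), "b": 7.0})
        test = train.copy()
        with pytest.warns(UserWarning, match="zero-variance"):
            tr, te, scaler = normalize_features(train, test, ["a", "b"])
        assert "b" not in tr.columns
        assert scaler["features"] == ["a"]


class TestMrmr:
    def test_outcome_copy_selected_first(self, rng):
        y = rng.integers(0, 2, size=60)
        feats = pd.DataFrame(
            {
                "noise1": rng.normal(size=60),
                "oracle": y.astype(float),
                "noise2": rng.normal(size=60),
            }
        )
        assert mrmr_select(feats, y, k=1)[0] == "oracle"

    def test_duplicate_never_second(self, rng):
        y = rng.integers(0, 2, size=80)
        signal = y + rng.normal(0, 0.1, 80)
        feats = pd.DataFrame(
            {
                "a_signal": signal,
                "b_duplicate": signal.copy(),
                "c_noise": rng.normal(size=80),
            }
        )
        order = mrmr_select(feats, y, k=2)
        assert order[0] == "a_signal"
        assert order[1] == "c_noise"  # redundancy penalty blocks the duplicate

    def test_k_all_is_permutation(self, rng):
        y = rng.integers(0, 2, size=40)
        feats = pd.DataFrame(rng.normal(size=(40, 5)),
                             columns=[f"f{i}" for i in range(5)])
        order = mrmr_select(feats, y, k=5)
        assert sorted(order) == sorted(feats.columns)

    def test_k_too_large_rejected(self, rng):
        feats = pd.DataFrame({"a": rng.normal(size=10)})
        with pytest.raises(ValueError):
            mrmr_select(feats, np.zeros(10, dtype=int), k=2)


class TestStepwise:
    def test_predictive_feature_retained(self):
        kept_signal = 0
        noise_dropped = []
        for seed in range(25):
            rng = np.random.default_rng(seed)
            n = 200
            x = rng.normal(size=n)
            logit = 2.5 * x
            y = rng.random(n) < 1 / (1 + np.exp(-logit))
            train = pd.DataFrame(
                {
                    "signal": x,
                    "n1": rng.normal(size=n),
                    "n2": rng.normal(size=n),
                    "n3": rng.normal(size=n),
                    "long_survivor": y.astype(int),
                }
            )
            res = stepwise_logistic(train, ["signal", "n1", "n2", "n3"])
            kept_signal += "signal" in res.selected
            noise_dropped.append(
                sum(1 for c in ("n1", "n2", "n3") if c not in res.selected) / 3)
        assert kept_signal == 25
        assert np.mean(noise_dropped) >= 0.8

    def test_pure_noise_gives_interceptish_model(self, rng):
        n = 150
        train = pd.DataFrame(
            {
                "n1": rng.normal(size=n),
                "long_survivor": rng.integers(0, 2, size=n),
            }
        )
        res = stepwise_logistic(train, ["n1"])
        assert res.aic <= _full_model_aic(train, ["n1"]) + 1e-9

    def test_aic_not_worse_than_extremes(self, rng):
        n = 120
        x = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-x))).astype(int)
        train = pd.DataFrame({"x": x, "junk": rng.normal(size=n),
                              "long_survivor": y})
        res = stepwise_logistic(train, ["x", "junk"])
        assert res.aic <= _full_model_aic(train, ["x", "junk"]) + 1e-9
        assert res.aic <= _full_model_aic(train, []) + 1e-9


def _full_model_aic(train, cols):
    import statsmodels.api as sm

    design = sm.add_constant(train[cols], has_constant="add")
    model = sm.Logit(train["long_survivor"], design).fit(disp=0)
    return float(2 * (len(cols) + 1) - 2 * model.llf)


class TestCox:
    def test_parameter_recovery(self):
        table, truth = make_cohort(
            CohortSpec(n_patients=500, censor_rate=0.2, seed=3))
        res = cox_fit(table, "mean_thickness_mm")
        assert 1.7 <= res.hazard_ratio <= 2.35
        assert res.ci_low < res.hazard_ratio < res.ci_high

    def test_null_covariate_ci_coverage(self):
        covered = 0
        for seed in range(40):
            table, _ = make_cohort(CohortSpec(n_patients=150, seed=seed))
            rng = np.random.default_rng(seed + 9999)
            table["null_cov"] = rng.normal(size=len(table))
            res = cox_fit(table, "null_cov")
            covered += res.ci_low <= 1.0 <= res.ci_high
        assert covered >= 36  # ~95% nominal coverage

    def test_multivariate_supported(self):
        table, _ = make_cohort(CohortSpec(n_patients=300, seed=4))
        results = cox_fit(table, ["mean_thickness_mm", "age_years"])
        assert len(results) == 2
        assert results[0].covariate == "mean_thickness_mm"

    def test_no_events_rejected(self):
        tab = pd.DataFrame({"os_days": [10.0, 20.0], "os_event": [0, 0],
                            "x": [1.0, 2.0]})
        with pytest.raises(ValueError):
            cox_fit(tab, "x")

    def test_large_sample_log_hr_bias(self):
        table, truth = make_cohort(
            CohortSpec(n_patients=2000, censor_rate=0.1, seed=5))
        res = cox_fit(table, "mean_thickness_mm")
        assert abs(res.log_hr - truth.log_hr_per_mm) < 3 * res.log_hr_se
        assert abs(res.log_hr - truth.log_hr_per_mm) < 0.1


class TestKmLogrank:
    def test_toy_matches_hand_computation(self):
        # A {5+, 10, 15} vs B {2, 4, 6}: chi2 = 4.3822, KM steps as computed
        tab = _toy_table()
        res = km_logrank(tab, "group_high", threshold=0.5)
        assert res.logrank_statistic == pytest.approx(4.382215288611544)
        assert res.p_value == pytest.approx(0.03631576905230853)
        bf_t, bf_s = bf_km([2, 4, 6], [1, 1, 1])
        got = dict(zip(res.times["high"], res.survival["high"]))
        for t, s in zip(bf_t, bf_s):
            assert got[t] == pytest.approx(s)
        assert res.logrank_statistic == pytest.approx(
            bf_logrank([5, 10, 15], [0, 1, 1], [2, 4, 6], [1, 1, 1]))

    def test_identical_strata_p_one(self):
        tab = pd.DataFrame(
            {
                "os_days": [3.0, 6.0, 9.0, 3.0, 6.0, 9.0],
                "os_event": [1, 1, 1, 1, 1, 1],
                "x": [0, 0, 0, 1, 1, 1],
            }
        )
        res = km_logrank(tab, "x", threshold=0.5)
        assert res.logrank_statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_km_curve_properties(self):
        table, _ = make_cohort(CohortSpec(n_patients=80, seed=6))
        res = km_logrank(table, "mean_thickness_mm",
                         table["mean_thickness_mm"].median())
        for name in ("low", "high"):
            s = res.survival[name]
            assert s[0] <= 1.0 + 1e-12
            assert np.all(np.diff(s) <= 1e-12)  # nonincreasing

    def test_empty_stratum_rejected(self):
        tab = _toy_table()
        with pytest.raises(ValueError):
            km_logrank(tab, "group_high", threshold=5.0)


class TestRocYouden:
    def test_perfect_separation(self):
        res = roc_youden([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert res.auc == 1.0
        assert 0.2 < res.youden_threshold <= 0.8
        assert res.sensitivity == 1.0 and res.specificity == 1.0

    def test_spec_worked_example(self):
        res = roc_youden([0.1, 0.4, 0.35, 0.8], [0, 1, 0, 1])
        assert res.auc == pytest.approx(1.0)
        assert res.auc == pytest.approx(bf_auc([0.1, 0.4, 0.35, 0.8], [0, 1, 0, 1]))

    def test_symmetry(self, rng):
        scores = rng.normal(size=30)
        y = rng.integers(0, 2, size=30)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        assert (roc_youden(scores, y).auc
                + roc_youden(-scores, y).auc) == pytest.approx(1.0)

    @settings(max_examples=50, deadline=None)
    @given(
        n=st.integers(4, 50),
        seed=st.integers(0, 10_000),
    )
    def test_auc_equals_concordant_pairs(self, n, seed):
        rng = np.random.default_rng(seed)
        scores = np.round(rng.normal(size=n), 2)  # induce ties
        y = rng.integers(0, 2, size=n)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        assert roc_youden(scores, y).auc == pytest.approx(bf_auc(scores, y))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_youden([0.1, 0.5], [1, 1])


class TestBh:
    def test_spec_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), 0.04)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.123])[0] == pytest.approx(0.123)

    def test_matches_bruteforce_stepup(self, rng):
        for _ in range(20):
            p = rng.random(rng.integers(1, 12))
            assert np.allclose(bh_adjust(p), bf_bh(p))

    def test_monotone_never_below_raw(self, rng):
        p = rng.random(10)
        adj = bh_adjust(p)
        assert np.all(adj >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_idempotent_on_flat_adjusted_list(self):
        # re-adjusting an all-equal adjusted list is a fixed point; general
        # idempotency does not hold for the step-up procedure
        adj = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(bh_adjust(adj), adj)


class TestSubgroup:
    def test_windows_and_adjustment(self):
        table, _ = make_cohort(CohortSpec(n_patients=400, seed=7))
        out = subgroup_analysis(table, "mean_thickness_mm")
        windows = set(out["window"])
        assert "all" in windows and len(windows) == 5
        sub = out[out["window"] != "all"]
        assert np.all(sub["p_adj"].to_numpy() >= sub["p_raw"].to_numpy() - 1e-15)
        assert np.allclose(
            np.sort(sub["p_adj"].to_numpy()),
            np.sort(bf_bh(sub["p_raw"].to_numpy())),
        )

    def test_significance_only_in_middle_windows(self):
        spec = CohortSpec(
            n_patients=420, seed=11, censor_rate=0.15,
            window_log_hr={"lt24": 0.0, "24to48": np.log(2.5),
                           "48to72": np.log(2.5), "ge72": 0.0},
        )
        table, _ = make_cohort(spec)
        out = subgroup_analysis(table, "mean_thickness_mm")
        sig = out[(out["window"] != "all") & out["significant"]]["window"].tolist()
        assert "24to48" in sig and "48to72" in sig

    def test_unstable_flag(self):
        table, _ = make_cohort(CohortSpec(n_patients=40, seed=8))
        out = subgroup_analysis(table, "mean_thickness_mm", min_events=10)
        small = out[out["n_events"] < 10]
        assert small["unstable"].all()


class TestCombinedModel:
    def _cohort_frame(self, seed, n=240, signal=True, b_thick=1.2, b_rad=1.0):
        rng = np.random.default_rng(seed)
        thickness = rng.normal(2, 0.8, n)
        rad = rng.normal(0, 1, n)
        if signal:
            logit = b_thick * (thickness - 2) + b_rad * rad
        else:
            logit = np.zeros(n)
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
        frame = pd.DataFrame(
            {
                "mean_thickness_mm": thickness,
                "rcbv99": rng.normal(3, 1, n),
                "psr_max_percent": rng.normal(90, 15, n),
                "radiomics_score": rad,
                "age_years": rng.normal(60, 10, n),
                "kps_ge90": rng.integers(0, 2, n),
                "long_survivor": y,
            }
        )
        train = frame.iloc[: int(0.7 * n)]
        test = frame.iloc[int(0.7 * n):]
        return train, test

    def test_null_outcome_auc_near_half(self):
        aucs = []
        for seed in range(15):
            train, test = self._cohort_frame(seed, signal=False)
            res = combined_model(train, test)
            aucs.append(res["combined"].auc)
        assert abs(np.mean(aucs) - 0.5) < 0.1

    def test_combined_beats_single_families(self):
        wins = 0
        trials = 20
        for seed in range(trials):
            train, test = self._cohort_frame(seed)
            res = combined_model(train, test)
            ok = all(
                res["combined"].auc >= res[f].auc - 0.05
                for f in ("clinical", "perfusion", "thickness", "radiomics")
                if f in res
            )
            wins += ok
        assert wins >= 0.8 * trials

    def test_permuted_labels_destroy_auc(self):
        # note the permuted-fit AUC is scale-free in the coefficients: what
        # remains is a random direction in feature space, so the check needs a
        # modest true signal and a large test set to be sharp
        low = 0
        trials = 20
        for seed in range(trials):
            train, test = self._cohort_frame(seed, n=1500, b_thick=0.35, b_rad=0.3)
            rng = np.random.default_rng(seed + 777)
            train = train.copy()
            train["long_survivor"] = rng.permutation(
                train["long_survivor"].to_numpy())
            res = combined_model(train, test)
            low += res["combined"].auc <= 0.6
        assert low >= 0.9 * trials
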