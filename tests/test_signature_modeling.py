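"""ICC closed form, PCA surrogates, logistic screen, backward AIC, AUC/DeLong, CV."""

import numpy as np
import pandas as pd
import pytest

from radiomap.signature_modeling import (
    auc_mann_whitney,
    backward_aic,
    cross_validate,
    delong_ci,
    evaluate,
    icc_2_1,
    icc_filter,
    pca_surrogates,
    univariate_screen,
)

from oracles import brute_auc


class TestICC:
    def test_hand_computable_table_matches_anova_closed_form(self):
        # classic 4 targets x 2 raters example
        table = np.array([[9.0, 10.0], [6.0, 5.0], [8.0, 7.0], [2.0, 3.0]])
        n, k = table.shape
        grand = table.mean()
        msr = k * ((table.mean(axis=1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((table.mean(axis=0) - grand) ** 2).sum() / (k - 1)
        mse = (
            ((table - grand) ** 2).sum()
            - (n - 1) * msr
            - (k - 1) * msc
        ) / ((n - 1) * (k - 1))
        expected = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        assert icc_2_1(table) == pytest.approx(expected, abs=1e-9)

    def test_matches_pingouin_icc2(self, rng):
        pingouin = pytest.importorskip("pingouin")
        vals = rng.normal(size=(8, 3)) + rng.normal(size=(8, 1)) * 2.0
        df = pd.DataFrame(
            {
                "targets": np.repeat(np.arange(8), 3),
                "raters": np.tile(np.arange(3), 8),
                "ratings": vals.ravel(),
            }
        )
        ref = pingouin.intraclass_corr(df, targets="targets", raters="raters",
                                       ratings="ratings")
        # ICC(A,1): two-way random, absolute agreement, single rater
        icc2 = float(ref.loc[ref["Type"] == "ICC(A,1)", "ICC"].iloc[0])
        assert icc_2_1(vals) == pytest.approx(icc2, abs=1e-9)

    def test_perfect_agreement_is_one_and_stable(self, rng):
        base = rng.normal(size=20)
        tables = [pd.DataFrame({"f": base}) for _ in range(3)]
        res = icc_filter(tables)[0]
        assert res.icc == pytest.approx(1.0)
        assert res.stable

    def test_independent_observers_unstable(self, rng):
        tables = [pd.DataFrame({"f": rng.normal(size=50)}) for _ in range(2)]
        res = icc_filter(tables)[0]
        assert abs(res.icc) < 0.3
        assert not res.stable

    def test_constant_feature_undefined_unstable(self):
        tables = [pd.DataFrame({"f": np.ones(10)}) for _ in range(2)]
        res = icc_filter(tables)[0]
        assert np.isnan(res.icc) and not res.stable

    def test_misaligned_tables_rejected(self, rng):
        a = pd.DataFrame({"f": rng.normal(size=5)})
        b = pd.DataFrame({"g": rng.normal(size=5)})
        with pytest.raises(ValueError, match="misaligned"):
            icc_filter([a, b])


class TestPCASurrogates:
    def test_perfectly_correlated_pair_collapses_to_one(self, rng):
        x = rng.normal(size=30)
        df = pd.DataFrame({"f1": x, "f2": 2.0 * x + 5.0})
        assert pca_surrogates(df, ["f1", "f2"]) == ["f1"]

    def test_orthogonal_equal_variance_needs_both_components(self, rng):
        n = 2000
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        y = y - np.polyfit(x, y, 1)[0] * x  # decorrelate
        df = pd.DataFrame({"f1": x, "f2": y})
        # each component explains ~50% < 95% -> two surrogates
        assert len(pca_surrogates(df, ["f1", "f2"])) == 2

    def test_component_count_is_minimal(self, rng):
        X = rng.normal(size=(60, 6))
        df = pd.DataFrame(X, columns=[f"f{i}" for i in range(6)])
        feats = list(df.columns)
        from sklearn.decomposition import PCA

        Xz = (X - X.mean(0)) / X.std(0)
        cum = np.cumsum(PCA(svd_solver="full").fit(Xz).explained_variance_ratio_)
        k_min = int(np.searchsorted(cum, 0.95 - 1e-12) + 1)
        # surrogates may collapse duplicates but never exceed the minimal k
        sur = pca_surrogates(df, feats)
        assert len(sur) <= k_min
        assert k_min == np.argmax(cum >= 0.95) + 1  # k-1 fails the bound

    def test_zero_variance_feature_dropped(self, rng):
        df = pd.DataFrame({"f1": rng.normal(size=20), "f2": np.ones(20)})
        assert pca_surrogates(df, ["f1", "f2"]) == ["f1"]


class TestScreen:
    def test_perfect_predictor_kept_with_auc_one(self, rng):
        y = np.array([0] * 20 + [1] * 20)
        df = pd.DataFrame({"label": y, "f": y.astype(float)})
        res = univariate_screen(df, ["f"])
        assert res["auc"].iloc[0] == 1.0
        assert bool(res["keep"].iloc[0])

    def test_null_feature_usually_dropped(self, rng):
        dropped = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            y = np.array([0] * 100 + [1] * 100)
            df = pd.DataFrame({"label": y, "f": r.normal(size=200)})
            res = univariate_screen(df, ["f"])
            assert 0.35 <= res["auc"].iloc[0] <= 0.65
            dropped += int(not res["keep"].iloc[0])
        assert dropped >= 9

    def test_constant_feature_dropped_with_warning(self, rng):
        y = np.array([0, 1] * 10)
        df = pd.DataFrame({"label": y, "f": np.ones(20)})
        assert univariate_screen(df, ["f"]).empty

    def test_single_class_rejected(self):
        df = pd.DataFrame({"label": np.zeros(10), "f": np.arange(10.0)})
        with pytest.raises(ValueError, match="both classes"):
            univariate_screen(df, ["f"])


class TestBackwardAIC:
    def _simulated(self, seed, n=150, beta=2.0):
        r = np.random.default_rng(seed)
        x_true = r.normal(size=n)
        x_noise = r.normal(size=n)
        p = 1 / (1 + np.exp(-(beta * x_true)))
        y = (r.random(n) < p).astype(float)
        return pd.DataFrame({"label": y, "signal": x_true, "noise": x_noise})

    def test_noise_eliminated_signal_retained(self):
        # under AIC a pure-noise covariate survives with asymptotic probability
        # P(chi2_1 > 2) ~ 0.157, so elimination is expected in ~84% of seeds
        signal_kept = noise_dropped = 0
        for seed in range(20):
            df = self._simulated(seed)
            model = backward_aic(df, ["signal", "noise"])
            signal_kept += int("signal" in model.coefficients)
            noise_dropped += int("noise" not in model.coefficients)
        assert signal_kept == 20
        assert noise_dropped >= 14

    def test_aic_never_worse_than_full_model(self, rng):
        df = self._simulated(3)
        df["noise2"] = rng.normal(size=len(df))
        model = backward_aic(df, ["signal", "noise", "noise2"])
        full_aic = model.trace[0]["aic"]
        assert model.trace[-1]["aic"] <= full_aic + 1e-9

    def test_single_informative_candidate_retained(self):
        df = self._simulated(7)
        model = backward_aic(df, ["signal"])
        assert model.features == ["signal"]


class TestAUC:
    def test_matches_pairwise_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(6, 20))
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                continue
            score = np.round(rng.normal(size=n), 1)  # ties likely
            assert auc_mann_whitney(y, score) == pytest.approx(brute_auc(y, score))

    def test_perfect_separation_auc_one(self):
        y = np.array([0, 0, 1, 1])
        assert auc_mann_whitney(y, np.array([0.0, 0.1, 5.0, 6.0])) == 1.0

    def test_delong_null_covers_half(self):
        covered = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            y = np.array([0] * 250 + [1] * 250)
            auc, lo, hi = delong_ci(y, r.normal(size=500))
            assert 0.40 <= auc <= 0.60
            covered += int(lo <= 0.5 <= hi)
        assert covered >= 9

    def test_evaluate_flags_failed_validation(self, rng):
        from radiomap.signature_modeling import ModelSpec

        y = rng.integers(0, 2, 400)
        df = pd.DataFrame({"label": y, "f": rng.normal(size=400)})
        model = ModelSpec(intercept=0.0, coefficients={"f": 1.0})
        res = evaluate(model, df)
        assert res["validated"] is False


class TestCrossValidation:
    def _cohort(self, seed, n=100, beta=2.5):
        r = np.random.default_rng(seed)
        x = r.normal(size=n)
        y = (r.random(n) < 1 / (1 + np.exp(-beta * x))).astype(float)
        return pd.DataFrame({"label": y, "f": x, "g": r.normal(size=n)})

    def test_folds_partition_cohort(self):
        df = self._cohort(0)
        res = cross_validate(df, ["f", "g"], k=5, seed=1)
        assert len(res["fold_aucs"]) == 5

    def test_same_seed_identical_results(self):
        df = self._cohort(1)
        a = cross_validate(df, ["f", "g"], k=5, seed=4)
        b = cross_validate(df, ["f", "g"], k=5, seed=4)
        assert a["fold_aucs"] == b["fold_aucs"]

    def test_strong_signal_high_mean_auc(self):
        df = self._cohort(2, n=150, beta=3.0)
        res = cross_validate(df, ["f", "g"], k=5, seed=0)
        assert res["mean_auc"] > 0.8
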