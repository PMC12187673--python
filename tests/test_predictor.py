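"""Elastic-net prediction, validation schemes, feature ranking, associations."""

import numpy as np
import pandas as pd
import pytest

from scsweep.errors import InvalidInputError
from scsweep.metrics import METRIC_NAMES
from scsweep.predictor import (
    ElasticNetFit,
    fit_elasticnet_cv,
    linearity_deviation,
    metric_association,
    predict,
    rank_consistent_features,
    validate_cross,
    validate_intra,
)


def _table(rng, n=60, n_units=6, signal="silhouette", noise=0.0):
    """Feature table whose accuracy is (optionally noisy) linear in one feature."""
    df = pd.DataFrame(rng.normal(size=(n, len(METRIC_NAMES))), columns=list(METRIC_NAMES))
    df["replicate"] = np.arange(n) % n_units
    df["dataset_id"] = "d0"
    y = 0.5 + 0.2 * df[signal] if signal else pd.Series(0.0, index=df.index)
    df["accuracy"] = y + (rng.normal(scale=noise, size=n) if noise else 0.0)
    return df


class TestFitElasticNet:
    def test_zero_response_gives_zero_coefficients(self):
        rng = np.random.default_rng(0)
        df = _table(rng, signal=None)
        fit = fit_elasticnet_cv(df, seed=0)
        assert (fit.coefficients == 0).all()

    def test_vanishing_penalty_recovers_least_squares(self):
        rng = np.random.default_rng(1)
        df = _table(rng)
        fit = fit_elasticnet_cv(df, alpha_grid=np.array([1e-9]), seed=0)
        Z = (df[list(METRIC_NAMES)] - fit.feature_means) / fit.feature_sds
        beta = np.linalg.lstsq(
            np.column_stack([np.ones(len(df)), Z.to_numpy()]), df["accuracy"].to_numpy(), rcond=None
        )[0]
        np.testing.assert_allclose(fit.coefficients.to_numpy(), beta[1:], atol=1e-6)

    def test_zero_variance_feature_dropped_with_zero_coefficient(self):
        rng = np.random.default_rng(2)
        df = _table(rng)
        df["tss"] = 5.0
        fit = fit_elasticnet_cv(df, seed=0)
        assert "tss" in fit.dropped
        assert fit.coefficients["tss"] == 0.0

    def test_standardization_frozen_for_prediction(self):
        rng = np.random.default_rng(3)
        train, test = _table(rng), _table(rng)
        fit = fit_elasticnet_cv(train, seed=0)
        direct = predict(fit, test)
        # shifting the test features must shift predictions through the
        # *training* scaler, proving test statistics are never re-estimated
        shifted = test.copy()
        shifted[list(METRIC_NAMES)] += 1.0
        expected = direct + (fit.coefficients / fit.feature_sds.replace(0, 1)).sum()
        np.testing.assert_allclose(predict(fit, shifted), expected, rtol=1e-9)


class TestValidateIntra:
    def test_exact_linear_signal_gives_perfect_holdout(self):
        rng = np.random.default_rng(4)
        rep = validate_intra(_table(rng, n=100, n_units=5), seed=0)
        assert len(rep.per_unit) == 5
        assert rep.r2_mean == pytest.approx(1.0, abs=1e-6)
        assert rep.rmse_mean == pytest.approx(0.0, abs=1e-4)

    def test_pure_noise_has_no_holdout_skill(self):
        r2s = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            df = _table(rng, n=60, n_units=4, signal=None)
            df["accuracy"] = rng.normal(size=len(df))
            r2s.append(validate_intra(df, seed=0).r2_mean)
        assert np.mean(r2s) <= 0.05

    def test_needs_at_least_three_units(self):
        rng = np.random.default_rng(5)
        with pytest.raises(InvalidInputError):
            validate_intra(_table(rng, n_units=2), seed=0)


class TestValidateCross:
    def _three_datasets(self, rng, shift=0.0):
        parts = []
        for i, d in enumerate("abc"):
            df = _table(rng, n=40, n_units=4)
            df["dataset_id"] = d
            parts.append(df)
        out = pd.concat(parts, ignore_index=True)
        out.loc[out.dataset_id == "c", "accuracy"] += shift
        return out

    def test_one_report_per_held_out_dataset(self):
        rng = np.random.default_rng(6)
        reports, fits = validate_cross(self._three_datasets(rng), seed=0)
        assert len(reports) == 3 and set(fits) == {"a", "b", "c"}
        assert all(r.scheme == "cross_dataset" for r in reports)

    def test_shifted_test_response_inflates_rmse_not_coefficients(self):
        rng = np.random.default_rng(7)
        base = self._three_datasets(rng)
        shifted = base.copy()
        shifted.loc[shifted.dataset_id == "c", "accuracy"] += 0.5
        rep0, fits0 = validate_cross(base, seed=0)
        rep1, fits1 = validate_cross(shifted, seed=0)
        np.testing.assert_allclose(
            fits0["c"].coefficients, fits1["c"].coefficients, atol=1e-12
        )
        assert rep1[2].rmse_mean >= rep0[2].rmse_mean + 0.4

    def test_single_dataset_rejected(self):
        rng = np.random.default_rng(8)
        with pytest.raises(InvalidInputError):
            validate_cross(_table(rng), seed=0)


def _fit_with(coefs):
    s = pd.Series(0.0, index=list(METRIC_NAMES))
    for k, v in coefs.items():
        s[k] = v
    return ElasticNetFit(
        coefficients=s, intercept=0.0, alpha=0.1, l1_ratio=0.5,
        feature_means=pd.Series(0.0, index=list(METRIC_NAMES)),
        feature_sds=pd.Series(1.0, index=list(METRIC_NAMES)),
    )


class TestRankConsistentFeatures:
    def test_always_selected_ranks_above_half_selected(self):
        fits = [
            _fit_with({"wc_dispersion": -0.5, "dunn": 0.2}),
            _fit_with({"wc_dispersion": -0.4}),
            _fit_with({"wc_dispersion": -0.6, "dunn": -0.1}),
            _fit_with({"wc_dispersion": -0.3}),
        ]
        ranked = rank_consistent_features(fits)
        assert ranked.feature.iloc[0] == "wc_dispersion"
        assert ranked[ranked.feature == "wc_dispersion"].sign.iloc[0] == -1

    def test_all_zero_fits_empty_selection(self):
        assert len(rank_consistent_features([_fit_with({}), _fit_with({})])) == 0

    def test_matches_explicit_sort_oracle(self):
        fits = [
            _fit_with({"dunn": 0.3, "tss": 0.1, "silhouette": -0.2}),
            _fit_with({"dunn": 0.2, "tss": -0.4, "silhouette": -0.2}),
            _fit_with({"dunn": 0.5, "silhouette": 0.9}),
        ]
        ranked = rank_consistent_features(fits)
        rows = {
            "dunn": (3, 1.0, (0.3 + 0.2 + 0.5) / 3),
            "silhouette": (3, 2 / 3, (0.2 + 0.2 + 0.9) / 3),
            "tss": (2, 0.5, 0.25),
        }
        expected = sorted(rows, key=lambda f: rows[f], reverse=True)
        assert ranked.feature.tolist() == expected


class TestMetricAssociation:
    def _assoc_table(self, cols):
        df = pd.DataFrame(0.0, index=range(len(next(iter(cols.values())))), columns=list(METRIC_NAMES))
        rng = np.random.default_rng(9)
        for c in METRIC_NAMES:
            df[c] = cols.get(c, rng.normal(size=len(df)))
        df["accuracy"] = 0.5
        return df

    def test_monotone_features_perfectly_correlated(self):
        t = np.arange(10.0)
        df = self._assoc_table({"tss": t, "wc_dispersion": t**3, "dunn": -t})
        rho, _, _ = metric_association(df)
        assert rho.loc["tss", "wc_dispersion"] == pytest.approx(1.0)
        assert rho.loc["tss", "dunn"] == pytest.approx(-1.0)

    def test_first_merge_joins_strongest_pair(self):
        rng = np.random.default_rng(10)
        n = 40
        a = rng.normal(size=n)
        df = self._assoc_table({"tss": a, "wc_dispersion": a + 0.1 * rng.normal(size=n)})
        rho, Z, usable = metric_association(df)
        i, j = int(Z[0, 0]), int(Z[0, 1])
        assert {usable[i], usable[j]} == {"tss", "wc_dispersion"}

    def test_zero_variance_feature_flagged_out(self):
        df = self._assoc_table({"tss": np.zeros(10)})
        rho, _, usable = metric_association(df)
        assert "tss" not in usable
        assert rho["tss"].drop("tss").isna().all()


class TestLinearityDeviation:
    def test_affine_measure_has_zero_residual_sd(self):
        acc = np.linspace(0.2, 0.9, 50)
        df = pd.DataFrame({"accuracy": acc, "m1": 3.0 - 2.0 * acc})
        out = linearity_deviation(df, measures=("m1",))
        assert out.residual_sd.iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_quadratic_measure_deviates_with_u_shape(self):
        acc = np.linspace(0.0, 1.0, 101)
        df = pd.DataFrame({"accuracy": acc, "m1": (acc - 0.5) ** 2})
        out = linearity_deviation(df, measures=("m1",))
        assert out.residual_sd.iloc[0] > 0.05
        # residuals of a line fit to a centered parabola are U-shaped:
        # positive at the ends, negative in the middle
        vn = (df.m1 - df.m1.min()) / (df.m1.max() - df.m1.min())
        fit = np.polyfit(acc, vn, 1)
        resid = vn - np.polyval(fit, acc)
        assert resid.iloc[0] > 0 and resid.iloc[-1] > 0 and resid.iloc[50] < 0

    def test_noisy_measure_deviates_more_than_affine(self):
        rng = np.random.default_rng(11)
        acc = np.linspace(0.2, 0.9, 80)
        df = pd.DataFrame(
            {"accuracy": acc, "clean": 1.0 + acc, "noisy": 1.0 + acc + rng.normal(0, 0.2, 80)}
        )
        out = linearity_deviation(df, measures=("clean", "noisy")).set_index("measure")
        assert out.loc["clean", "residual_sd"] < out.loc["noisy", "residual_sd"]

    def test_constant_measure_flagged(self):
        df = pd.DataFrame({"accuracy": np.linspace(0, 1, 10), "m1": 2.0})
        out = linearity_deviation(df, measures=("m1",))
        assert out.flag.iloc[0] == "constant"
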