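"""Design construction, robust fitting, group comparison, extreme configs."""

import numpy as np
import pandas as pd
import pytest

from scsweep.effects import (
    DesignSpec,
    build_design,
    compare_groups,
    default_design_spec,
    extract_extreme_configs,
    fit_robust_effects,
)
from scsweep.errors import InvalidInputError, RankDeficiencyError
from scsweep.sweep import SweepConfig, enumerate_grid


def _full_records(cfg=None, n_rep=3):
    cfg = cfg or SweepConfig(pcs=(10,), methods=("gauss", "umap"), metrics=("cosine", "euclidean"))
    rows = []
    for r in range(n_rep):
        for c in enumerate_grid(cfg):
            rows.append(
                {"replicate": r, "pc": c.pc, "nn": c.nn, "res": c.res,
                 "method": c.method, "metric": c.metric, "accuracy": 0.0}
            )
    return pd.DataFrame(rows)


class TestBuildDesign:
    def test_main_effect_column_count(self):
        # factors with 2,4,4,3,2 levels: 1 intercept + 1+3+3+2+1 dummies
        rows = []
        levels = {"f1": [0, 1], "f2": [0, 1, 2, 3], "f3": [0, 1, 2, 3], "f4": [0, 1, 2], "f5": [0, 1]}
        import itertools

        for combo in itertools.product(*levels.values()):
            rows.append(dict(zip(levels, combo), accuracy=0.0))
        df = pd.DataFrame(rows)
        spec = DesignSpec(
            factors=[(k, v, v[0]) for k, v in levels.items()],
            include_interactions=False,
            block_factor="",
        )
        X, _ = build_design(df, spec)
        assert X.shape[1] == 11

    def test_two_binary_factors_single_interaction(self):
        df = pd.DataFrame(
            {"a": [0, 0, 1, 1], "b": [0, 1, 0, 1], "accuracy": 0.0}
        )
        spec = DesignSpec(factors=[("a", [0, 1], 0), ("b", [0, 1], 0)], block_factor="")
        X, _ = build_design(df, spec)
        inter = [c for c in X.columns if "×" in c]
        assert inter == ["a:1×b:1"]

    def test_reference_row_is_all_zero(self):
        records = _full_records()
        spec = default_design_spec(records)
        X, _ = build_design(records, spec)
        ref = (
            (records.method == "gauss") & (records.metric == "cosine")
            & (records.nn == 10) & (records.res == 0.5) & (records.replicate == 0)
        )
        i = records.index[ref][0]
        non_block = [c for c in X.columns if c != "intercept" and not c.startswith("block:")]
        assert (X.loc[i, non_block] == 0).all()

    def test_unseen_level_rejected(self):
        df = pd.DataFrame({"a": [0, 2], "accuracy": 0.0})
        spec = DesignSpec(factors=[("a", [0, 1], 0)], block_factor="")
        with pytest.raises(InvalidInputError):
            build_design(df, spec)

    def test_block_coding_sums_to_zero(self):
        records = _full_records(n_rep=4)
        X, _ = build_design(records, default_design_spec(records))
        blocks = [c for c in X.columns if c.startswith("block:")]
        assert len(blocks) == 3
        assert np.allclose(X[blocks].sum(axis=0), 0.0)


class TestFitRobustEffects:
    def test_noiseless_recovery(self):
        records = _full_records()
        records["accuracy"] = 0.6 + 0.1 * (records.res == 2.0)
        X, y = build_design(records, default_design_spec(records))
        fit = fit_robust_effects(X, y)
        assert fit.coefficients["res:2.0"] == pytest.approx(0.1, abs=1e-8)
        assert fit.r2 == pytest.approx(1.0, abs=1e-10)
        assert fit.bias == pytest.approx(0.0, abs=1e-10)

    def test_constant_response_zero_effects(self):
        records = _full_records()
        records["accuracy"] = 0.7
        X, y = build_design(records, default_design_spec(records))
        fit = fit_robust_effects(X, y)
        non_intercept = fit.coefficients.drop("intercept")
        np.testing.assert_allclose(non_intercept, 0.0, atol=1e-10)
        assert fit.coefficients["intercept"] == pytest.approx(0.7)

    def test_without_outliers_equals_ols(self):
        # +-a noise has normalized MAD 1.48a, so every residual sits inside
        # the Huber threshold: weights must all be 1 and the fit must be OLS
        rng = np.random.default_rng(0)
        records = _full_records(n_rep=4)
        records["accuracy"] = (
            0.5 + 0.05 * (records.res == 2.0) + 0.01 * rng.choice([-1.0, 1.0], len(records))
        )
        # main effects only: residuals stay essentially at the +-0.01 noise
        X, y = build_design(records, default_design_spec(records, include_interactions=False))
        fit = fit_robust_effects(X, y)
        ols = np.linalg.lstsq(X.to_numpy(), y.to_numpy(), rcond=None)[0]
        np.testing.assert_allclose(fit.coefficients.to_numpy(), ols, atol=1e-6)
        np.testing.assert_allclose(fit.robust_weights, 1.0)

    def test_r2_matches_independent_recomputation(self):
        rng = np.random.default_rng(1)
        records = _full_records(n_rep=4)
        records["accuracy"] = 0.5 + 0.1 * (records.res == 2.0) + rng.normal(0, 0.02, len(records))
        X, y = build_design(records, default_design_spec(records))
        fit = fit_robust_effects(X, y)
        sse = float((fit.residuals**2).sum())
        sst = float(((y - y.mean()) ** 2).sum())
        assert fit.r2 == pytest.approx(1 - sse / sst, rel=1e-12)

    def test_rank_deficiency_names_columns(self):
        records = _full_records()
        X, y = build_design(records, default_design_spec(records))
        X["dup"] = X["res:2.0"]
        with pytest.raises(RankDeficiencyError, match="dup|res:2.0"):
            fit_robust_effects(X, y)

    def test_downweights_gross_outliers(self):
        rng = np.random.default_rng(2)
        records = _full_records(n_rep=5)
        records["accuracy"] = 0.6 + 0.1 * (records.res == 2.0) + rng.normal(0, 0.01, len(records))
        out = rng.choice(len(records), size=len(records) // 20, replace=False)
        records.loc[out, "accuracy"] += 0.3
        X, y = build_design(records, default_design_spec(records))
        fit = fit_robust_effects(X, y)
        assert fit.robust_weights[out].mean() < 0.5
        assert fit.coefficients["res:2.0"] == pytest.approx(0.1, abs=0.02)


class TestCompareGroups:
    def test_identical_groups_degenerate_convention(self):
        rep = compare_groups({"a": np.ones(5), "b": np.ones(5), "c": np.ones(5)})
        assert rep.kw_statistic == 0.0
        assert all(p_adj == 1.0 for _, _, _, p_adj in rep.pairwise)

    def test_strongly_shifted_groups(self):
        rng = np.random.default_rng(3)
        groups = {f"g{i}": rng.normal(10 * i, 1.0, 100) for i in range(3)}
        rep = compare_groups(groups)
        assert rep.kw_p < 1e-6
        assert all(p_adj < 1e-6 for _, _, _, p_adj in rep.pairwise)

    def test_three_groups_three_pairs(self):
        rng = np.random.default_rng(4)
        rep = compare_groups({g: rng.normal(size=5) for g in "abc"})
        assert len(rep.pairwise) == 3
        assert all(pa >= pu for _, _, pu, pa in rep.pairwise)

    def test_dunn_z_hand_value(self):
        # groups {1,2} vs {3,4}: mean ranks 1.5 and 3.5, se = sqrt(5/3)
        rep = compare_groups({"a": np.array([1.0, 2.0]), "b": np.array([3.0, 4.0])})
        (_, z, _, _), = rep.pairwise
        assert z == pytest.approx(-2.0 / np.sqrt(5.0 / 3.0), rel=1e-12)


class TestExtremeConfigs:
    def test_only_res2_effect_selects_reference_elsewhere(self):
        records = _full_records()
        records["accuracy"] = 0.6 + 0.1 * (records.res == 2.0)
        spec = default_design_spec(records)
        X, y = build_design(records, spec)
        fit = fit_robust_effects(X, y)
        grid = enumerate_grid(SweepConfig(pcs=(10,), methods=("gauss", "umap"), metrics=("cosine", "euclidean")))
        out = extract_extreme_configs(fit, grid, spec)
        best, worst = out["best"]["configuration"], out["worst"]["configuration"]
        assert best.res == 2.0 and (best.method, best.metric, best.nn) == ("gauss", "cosine", 10)
        assert worst.res == 0.5
        assert len(out["predictions"]) == len(grid)

    def test_tie_breaks_by_grid_order(self):
        records = _full_records()
        records["accuracy"] = 0.5
        spec = default_design_spec(records)
        X, y = build_design(records, spec)
        fit = fit_robust_effects(X, y)
        grid = enumerate_grid(SweepConfig(pcs=(10,), methods=("gauss", "umap"), metrics=("cosine", "euclidean")))
        out = extract_extreme_configs(fit, grid, spec)
        assert out["best"]["configuration"] == grid[0]
        assert out["worst"]["configuration"] == grid[0]

    def test_full_reference_grid_gives_192_predictions(self):
        records = _full_records(cfg=SweepConfig(), n_rep=2)
        rng = np.random.default_rng(5)
        records["accuracy"] = rng.uniform(0.4, 0.9, len(records))
        spec = default_design_spec(records)
        X, y = build_design(records, spec)
        fit = fit_robust_effects(X, y)
        out = extract_extreme_configs(fit, enumerate_grid(SweepConfig()), spec)
        assert len(out["predictions"]) == 192
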