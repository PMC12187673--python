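"""Predicting clustering accuracy from the 15 intrinsic indices.

An elastic net (l1_ratio 0.5, alpha chosen by 5-fold cross-validation on a
log-spaced grid) is fit on z-scored indices.  Validation follows two
schemes: intra-dataset leave-one-replicate-out (all configurations of one
subsample replicate held out together, so configurations never leak across
folds) and cross-dataset (train on the pooled other datasets, evaluate on
the held-out one, with standardization statistics frozen from the training
split).  Features that are selected with a consistent sign across fits are
ranked as candidate accuracy proxies, and each candidate's deviation from
a linear relation with accuracy is quantified by the residual spread of a
simple line fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from sklearn.linear_model import ElasticNetCV
from sklearn.metrics import r2_score
from sklearn.model_selection import KFold

from .errors import InvalidInputError
from .metrics import METRIC_NAMES

logger = logging.getLogger(__name__)

__all__ = [
    "ElasticNetFit",
    "ValidationReport",
    "clean_feature_table",
    "fit_elasticnet_cv",
    "predict",
    "validate_intra",
    "validate_cross",
    "rank_consistent_features",
    "metric_association",
    "linearity_deviation",
]

DEFAULT_ALPHA_GRID = np.logspace(-4, 1, 50)


@dataclass
class ElasticNetFit:
    coefficients: pd.Series  # one per feature (dropped features = 0)
    intercept: float
    alpha: float
    l1_ratio: float
    feature_means: pd.Series
    feature_sds: pd.Series
    dropped: list[str] = field(default_factory=list)


@dataclass
class ValidationReport:
    scheme: str  # "intra_loo" or "cross_dataset"
    per_unit: pd.DataFrame  # columns: unit, r2, rmse
    r2_mean: float
    r2_sd: float
    rmse_mean: float
    rmse_sd: float


def clean_feature_table(records: pd.DataFrame, features: tuple[str, ...] = METRIC_NAMES) -> pd.DataFrame:
    """Rows usable for fitting: error-free and with all features finite."""
    df = records
    if "error" in df.columns:
        df = df[df["error"].fillna("") == ""]
    ok = np.isfinite(df[list(features)].to_numpy()).all(axis=1)
    dropped = len(df) - int(ok.sum())
    if dropped:
        logger.warning("excluding %d record(s) with missing feature values", dropped)
    return df[ok]


def fit_elasticnet_cv(
    table: pd.DataFrame,
    l1_ratio: float = 0.5,
    alpha_grid: np.ndarray | None = None,
    folds: int = 5,
    seed: int = 0,
    features: tuple[str, ...] = METRIC_NAMES,
    response: str = "accuracy",
) -> ElasticNetFit:
    """Elastic net on z-scored features; alpha by minimal mean CV error.

    Standardization statistics come from the fitting data only and are
    stored on the fit, so later predictions reuse frozen (mean, sd).
    """
    alphas = DEFAULT_ALPHA_GRID if alpha_grid is None else np.asarray(alpha_grid)
    if not 0 <= l1_ratio <= 1:
        raise InvalidInputError("l1_ratio must be in [0, 1]")
    if len(table) < folds:
        raise InvalidInputError(f"need at least {folds} rows, got {len(table)}")
    X = table[list(features)].astype(float)
    y = table[response].astype(float).to_numpy()
    means = X.mean()
    sds = X.std(ddof=0)
    dropped = [f for f in features if sds[f] == 0]
    if dropped:
        logger.warning("dropping zero-variance feature(s): %s", dropped)
    kept = [f for f in features if f not in dropped]
    coef = pd.Series(0.0, index=list(features))
    if y.std() == 0 or not kept:
        logger.warning("constant response or no usable features; intercept-only fit")
        return ElasticNetFit(
            coefficients=coef,
            intercept=float(y.mean()),
            alpha=float(alphas[0]),
            l1_ratio=l1_ratio,
            feature_means=means,
            feature_sds=sds,
            dropped=dropped,
        )
    Z = (X[kept] - means[kept]) / sds[kept]
    model = ElasticNetCV(
        l1_ratio=l1_ratio,
        alphas=alphas,
        cv=KFold(n_splits=folds, shuffle=True, random_state=seed),
        max_iter=50_000,
        tol=1e-6,
    )
    model.fit(Z.to_numpy(), y)
    coef[kept] = model.coef_
    return ElasticNetFit(
        coefficients=coef,
        intercept=float(model.intercept_),
        alpha=float(model.alpha_),
        l1_ratio=l1_ratio,
        feature_means=means,
        feature_sds=sds,
        dropped=dropped,
    )


def predict(fit: ElasticNetFit, table: pd.DataFrame) -> np.ndarray:
    """Apply a fit to new records using its frozen standardization."""
    feats = list(fit.coefficients.index)
    X = table[feats].astype(float)
    sds = fit.feature_sds.replace(0.0, 1.0)
    Z = (X - fit.feature_means) / sds
    return Z.to_numpy() @ fit.coefficients.to_numpy() + fit.intercept


def _evaluate(fit: ElasticNetFit, table: pd.DataFrame, response: str = "accuracy") -> tuple[float, float]:
    y = table[response].astype(float).to_numpy()
    yhat = predict(fit, table)
    return float(r2_score(y, yhat)), float(np.sqrt(np.mean((y - yhat) ** 2)))


def validate_intra(
    table: pd.DataFrame,
    unit: str = "replicate",
    seed: int = 0,
    l1_ratio: float = 0.5,
    folds: int = 5,
) -> ValidationReport:
    """Leave-one-unit-out validation within one dataset.

    The unit is a subsample replicate: all configurations of the held-out
    replicate are predicted by a model trained on the other replicates.
    """
    units = sorted(table[unit].unique().tolist())
    if len(units) < 3:
        raise InvalidInputError("need at least 3 units for leave-one-out")
    rows = []
    for u in units:
        test = table[table[unit] == u]
        train = table[table[unit] != u]
        if len(test) < 2:
            logger.warning("unit %r has < 2 records; skipped", u)
            continue
        fit = fit_elasticnet_cv(train, l1_ratio=l1_ratio, folds=folds, seed=seed)
        r2, rmse = _evaluate(fit, test)
        rows.append({"unit": u, "r2": r2, "rmse": rmse})
    per_unit = pd.DataFrame(rows)
    return ValidationReport(
        scheme="intra_loo",
        per_unit=per_unit,
        r2_mean=float(per_unit["r2"].mean()),
        r2_sd=float(per_unit["r2"].std(ddof=1)),
        rmse_mean=float(per_unit["rmse"].mean()),
        rmse_sd=float(per_unit["rmse"].std(ddof=1)),
    )


def validate_cross(
    table: pd.DataFrame,
    dataset_col: str = "dataset_id",
    seed: int = 0,
    l1_ratio: float = 0.5,
    folds: int = 5,
) -> tuple[list[ValidationReport], dict[str, ElasticNetFit]]:
    """Cross-dataset validation: for each dataset, train on the pooled others.

    Returns one single-value report per held-out dataset plus the fits
    (keyed by held-out dataset) for feature-consistency ranking.
    """
    datasets = sorted(table[dataset_col].unique().tolist())
    if len(datasets) < 2:
        raise InvalidInputError("cross-dataset validation needs >= 2 datasets")
    reports, fits = [], {}
    for d in datasets:
        train = table[table[dataset_col] != d]
        test = table[table[dataset_col] == d]
        fit = fit_elasticnet_cv(train, l1_ratio=l1_ratio, folds=folds, seed=seed)
        r2, rmse = _evaluate(fit, test)
        per_unit = pd.DataFrame([{"unit": d, "r2": r2, "rmse": rmse}])
        reports.append(
            ValidationReport(
                scheme="cross_dataset",
                per_unit=per_unit,
                r2_mean=r2,
                r2_sd=float("nan"),
                rmse_mean=rmse,
                rmse_sd=float("nan"),
            )
        )
        fits[d] = fit
    return reports, fits


def rank_consistent_features(fits: list[ElasticNetFit]) -> pd.DataFrame:
    """Rank features by selection frequency, sign consistency, mean |coef|.

    A feature ranks higher the more fits select it (nonzero coefficient),
    the more consistent its sign across those fits, and the larger its mean
    absolute coefficient.  Features never selected are excluded.
    """
    if len(fits) < 2:
        raise InvalidInputError("need at least 2 fits to assess consistency")
    coefs = pd.DataFrame([f.coefficients for f in fits]).reset_index(drop=True)
    rows = []
    for feat in coefs.columns:
        c = coefs[feat].to_numpy()
        nz = c[c != 0]
        if len(nz) == 0:
            continue
        sign_consistency = max((nz > 0).sum(), (nz < 0).sum()) / len(nz)
        rows.append(
            {
                "feature": feat,
                "n_selected": len(nz),
                "sign_consistency": float(sign_consistency),
                "mean_abs_coef": float(np.abs(nz).mean()),
                "sign": int(np.sign(nz.mean())),
            }
        )
    ranked = pd.DataFrame(rows, columns=["feature", "n_selected", "sign_consistency", "mean_abs_coef", "sign"])
    if len(ranked):
        ranked = ranked.sort_values(
            ["n_selected", "sign_consistency", "mean_abs_coef"],
            ascending=[False, False, False],
            kind="stable",
        ).reset_index(drop=True)
    return ranked


def metric_association(
    table: pd.DataFrame, features: tuple[str, ...] = METRIC_NAMES
) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Spearman correlation matrix of the indices plus an average-linkage
    dendrogram on distance 1 - |rho|.

    Returns (rho matrix over all features, linkage over usable features,
    usable feature names).  Zero-variance features have undefined
    correlations; they stay as NaN columns and are excluded from the tree.
    """
    if len(table) < 3:
        raise InvalidInputError("need at least 3 records")
    X = table[list(features)].astype(float)
    usable = [f for f in features if X[f].std(ddof=0) > 0]
    excluded = [f for f in features if f not in usable]
    if excluded:
        logger.warning("zero-variance feature(s) excluded from clustering: %s", excluded)
    rho_full = pd.DataFrame(np.nan, index=list(features), columns=list(features))
    rho, _ = stats.spearmanr(X[usable].to_numpy())
    rho = np.atleast_2d(rho)
    rho_full.loc[usable, usable] = rho
    dist = 1.0 - np.abs(rho)
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    return rho_full, Z, usable


def linearity_deviation(
    table: pd.DataFrame,
    measures: tuple[str, ...] = ("banfield_raftery", "wc_dispersion", "silhouette", "ari", "nmi"),
    response: str = "accuracy",
) -> pd.DataFrame:
    """Residual spread of each measure's linear relation with accuracy.

    Each measure is min-max normalized to [0, 1] and regressed linearly on
    accuracy; the residual standard deviation is the linearity-deviation
    score (0 = perfectly affine in accuracy).  Constant measures are
    flagged with NaN.
    """
    if not measures:
        raise InvalidInputError("measures must be non-empty")
    acc = table[response].astype(float).to_numpy()
    rows = []
    for m in measures:
        v = table[m].astype(float).to_numpy()
        rng_ = v.max() - v.min()
        if rng_ == 0 or acc.std() == 0:
            rows.append({"measure": m, "slope": np.nan, "intercept": np.nan, "residual_sd": np.nan, "flag": "constant"})
            continue
        vn = (v - v.min()) / rng_
        fit = stats.linregress(acc, vn)
        resid = vn - (fit.intercept + fit.slope * acc)
        rows.append(
            {
                "measure": m,
                "slope": float(fit.slope),
                "intercept": float(fit.intercept),
                "residual_sd": float(resid.std(ddof=1)),
                "flag": "",
            }
        )
    return pd.DataFrame(rows)
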