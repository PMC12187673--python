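"""Robust regression of clustering accuracy on the sweep factors.

Accuracy is modelled on the categorical sweep parameters (method, metric,
neighbors, components, resolution) with treatment coding against fixed
reference levels, all pairwise first-order interactions, and the subsample
replicate as a sum-to-zero block factor.  Outlying accuracy values are
down-weighted by Huber M-estimation (iteratively reweighted least squares
with MAD scale, tuning constant 1.345), which approximates a robust
random-intercept model with fixed block effects: the coefficient table and
its robustness to gross outliers are preserved, while variance components
are out of scope.

Also provided: Kruskal-Wallis with Dunn's post-hoc z tests (Bonferroni
corrected) for comparing accuracy distributions across datasets, and
extraction of the best/worst parameter configuration from a fitted model.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import InvalidInputError, RankDeficiencyError
from .sweep import Configuration

__all__ = [
    "DesignSpec",
    "EffectFit",
    "ComparisonReport",
    "default_design_spec",
    "build_design",
    "fit_robust_effects",
    "compare_groups",
    "extract_extreme_configs",
    "residual_normality",
]

#: Reference levels for the treatment coding of the five sweep factors.
DEFAULT_REFERENCES = {
    "method": "gauss",
    "res": 0.5,
    "pc": 10,
    "nn": 10,
    "metric": "cosine",
}

FACTOR_ORDER = ("method", "metric", "nn", "pc", "res")


@dataclass
class DesignSpec:
    """Factors (name, levels, reference), interaction switch, block factor."""

    factors: list[tuple[str, list, object]]
    include_interactions: bool = True
    block_factor: str = "replicate"

    def __post_init__(self) -> None:
        for name, levels, ref in self.factors:
            if ref not in levels:
                raise InvalidInputError(f"reference {ref!r} not in levels of {name!r}")


@dataclass
class EffectFit:
    coefficients: pd.Series
    robust_weights: np.ndarray
    bias: float
    rmse: float
    r2: float
    converged: bool
    n_iter: int
    std_errors: pd.Series = None
    p_values: pd.Series = None
    design_spec: DesignSpec = None
    residuals: np.ndarray = None


@dataclass
class ComparisonReport:
    kw_statistic: float
    kw_p: float
    pairwise: list[tuple[tuple, float, float, float]]  # (pair, z, p_unadj, p_adj)


def default_design_spec(records: pd.DataFrame, include_interactions: bool = True) -> DesignSpec:
    """Design over whichever of the five sweep factors vary in ``records``.

    Factors with a single observed level carry no information and are
    dropped; reference levels follow :data:`DEFAULT_REFERENCES`.
    """
    factors = []
    for name in FACTOR_ORDER:
        levels = sorted(records[name].unique().tolist())
        if len(levels) > 1:
            ref = DEFAULT_REFERENCES[name]
            if ref not in levels:
                ref = levels[0]
            factors.append((name, levels, ref))
    return DesignSpec(factors=factors, include_interactions=include_interactions)


def _dummy_columns(records: pd.DataFrame, name: str, levels: list, ref) -> dict[str, np.ndarray]:
    observed = set(records[name].unique().tolist())
    unseen = observed - set(levels)
    if unseen:
        raise InvalidInputError(f"unseen level(s) {unseen} for factor {name!r}")
    return {
        f"{name}:{lvl}": (records[name] == lvl).to_numpy(dtype=float)
        for lvl in levels
        if lvl != ref
    }


def build_design(
    records: pd.DataFrame, spec: DesignSpec, response: str = "accuracy"
) -> tuple[pd.DataFrame, pd.Series]:
    """Treatment-coded design matrix with pairwise interactions and a
    sum-to-zero block factor; deterministic column names and order."""
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(records))}
    per_factor: list[dict[str, np.ndarray]] = []
    for name, levels, ref in spec.factors:
        d = _dummy_columns(records, name, levels, ref)
        per_factor.append(d)
        cols.update(d)
    if spec.include_interactions:
        for da, db in itertools.combinations(per_factor, 2):
            for (na, va), (nb, vb) in itertools.product(da.items(), db.items()):
                cols[f"{na}×{nb}"] = va * vb
    if spec.block_factor and spec.block_factor in records.columns:
        blocks = sorted(records[spec.block_factor].unique().tolist())
        if len(blocks) > 1:
            last = blocks[-1]
            in_last = (records[spec.block_factor] == last).to_numpy(dtype=float)
            for b in blocks[:-1]:
                cols[f"block:{b}"] = (
                    (records[spec.block_factor] == b).to_numpy(dtype=float) - in_last
                )
    X = pd.DataFrame(cols, index=records.index)
    y = records[response].astype(float)
    return X, y


def _collinear_columns(X: pd.DataFrame) -> list[str]:
    _, R = np.linalg.qr(X.to_numpy())
    diag = np.abs(np.diag(R))
    tol = diag.max() * 1e-10
    return [c for c, d in zip(X.columns, diag) if d < tol]


def fit_robust_effects(
    X: pd.DataFrame,
    y: pd.Series,
    tuning: float = 1.345,
    maxiter: int = 100,
    tol: float = 1e-8,
) -> EffectFit:
    """Huber IRLS fit (statsmodels RLM, MAD scale) with diagnostics.

    Diagnostics are computed on the final fit's residuals: bias is the mean
    residual, rmse the root-mean-square residual, and r2 = 1 - SSE/SST.
    """
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise RankDeficiencyError(
            f"design is rank deficient; collinear columns: {_collinear_columns(X)}"
        )
    model = sm.RLM(y.to_numpy(), X.to_numpy(), M=sm.robust.norms.HuberT(t=tuning))
    res = model.fit(conv="coefs", tol=tol, maxiter=maxiter)
    n_iter = len(res.fit_history.get("params", [])) or maxiter
    resid = y.to_numpy() - X.to_numpy() @ res.params
    sse = float((resid**2).sum())
    sst = float(((y - y.mean()) ** 2).sum())
    return EffectFit(
        coefficients=pd.Series(res.params, index=X.columns),
        robust_weights=np.asarray(res.weights),
        bias=float(resid.mean()),
        rmse=float(np.sqrt((resid**2).mean())),
        r2=1.0 - sse / sst if sst > 0 else float("nan"),
        converged=n_iter < maxiter,
        n_iter=n_iter,
        std_errors=pd.Series(res.bse, index=X.columns),
        p_values=pd.Series(res.pvalues, index=X.columns),
        residuals=resid,
    )


def fit_effects_for_records(
    records: pd.DataFrame, include_interactions: bool = True
) -> tuple[EffectFit, DesignSpec]:
    """Convenience: design from the records' varying factors, then robust fit.

    Records with a missing response (a failed clustering stage) are
    excluded; records whose intrinsic indices failed but whose accuracy is
    defined (e.g. single-cluster partitions) stay in.
    """
    ok = records[np.isfinite(records["accuracy"].astype(float))]
    spec = default_design_spec(ok, include_interactions)
    X, y = build_design(ok, spec)
    fit = fit_robust_effects(X, y)
    fit.design_spec = spec
    return fit, spec


def compare_groups(values_by_group: dict[str, np.ndarray]) -> ComparisonReport:
    """Kruskal-Wallis H test plus all pairwise Dunn z tests with Bonferroni
    correction (tie-corrected pooled-rank variance)."""
    names = sorted(values_by_group)
    if len(names) < 2:
        raise InvalidInputError("need at least 2 groups")
    groups = [np.asarray(values_by_group[g], dtype=float) for g in names]
    if any(len(g) < 2 for g in groups):
        raise InvalidInputError("each group needs at least 2 values")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:  # everything tied: no evidence of any difference
        pairwise = [((a, b), 0.0, 1.0, 1.0) for a, b in itertools.combinations(names, 2)]
        return ComparisonReport(kw_statistic=0.0, kw_p=1.0, pairwise=pairwise)
    h, p = stats.kruskal(*groups)
    ranks = stats.rankdata(pooled)
    n_total = len(pooled)
    mean_ranks, sizes = {}, {}
    start = 0
    for g, vals in zip(names, groups):
        mean_ranks[g] = ranks[start : start + len(vals)].mean()
        sizes[g] = len(vals)
        start += len(vals)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float((tie_counts**3 - tie_counts).sum()) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    pairs = list(itertools.combinations(names, 2))
    pairwise = []
    for a, b in pairs:
        se = np.sqrt(base_var * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p_unadj = 2.0 * stats.norm.sf(abs(z))
        pairwise.append(((a, b), float(z), float(p_unadj), float(min(1.0, p_unadj * len(pairs)))))
    return ComparisonReport(kw_statistic=float(h), kw_p=float(p), pairwise=pairwise)


def _config_frame(grid: list[Configuration]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"pc": c.pc, "nn": c.nn, "res": c.res, "method": c.method, "metric": c.metric}
            for c in grid
        ]
    )


def extract_extreme_configs(
    fit: EffectFit, grid: list[Configuration], spec: DesignSpec | None = None
) -> dict:
    """Predicted accuracy over the whole grid (block effect at zero);
    returns argmax/argmin configurations with prediction +- residual sd.

    Ties break toward the earlier configuration in grid order.
    """
    spec = spec or fit.design_spec
    if spec is None:
        raise InvalidInputError("need the DesignSpec used for the fit")
    frame = _config_frame(grid)
    no_block = DesignSpec(
        factors=spec.factors,
        include_interactions=spec.include_interactions,
        block_factor="",
    )
    frame["accuracy"] = 0.0
    X, _ = build_design(frame, no_block)
    coef = fit.coefficients.reindex(X.columns).fillna(0.0)
    pred = X.to_numpy() @ coef.to_numpy()
    sd = float(fit.residuals.std(ddof=1)) if fit.residuals is not None else float("nan")
    # first-in-grid-order among predictions tied with the extremum (ties
    # include numerical noise at the fit's convergence tolerance)
    eps = 1e-8 * max(1.0, float(np.ptp(pred)))
    best_i = int(np.flatnonzero(pred >= pred.max() - eps)[0])
    worst_i = int(np.flatnonzero(pred <= pred.min() + eps)[0])
    return {
        "best": {"configuration": grid[best_i], "predicted": float(pred[best_i]), "sd": sd},
        "worst": {"configuration": grid[worst_i], "predicted": float(pred[worst_i]), "sd": sd},
        "predictions": pred,
    }


def residual_normality(residuals: np.ndarray) -> dict[str, float]:
    """Kolmogorov-Smirnov (against fitted normal) and Anderson-Darling
    statistics for the fit residuals; diagnostics only."""
    resid = np.asarray(residuals, dtype=float)
    ks = stats.kstest(resid, "norm", args=(resid.mean(), resid.std(ddof=1)))
    try:
        ad = stats.anderson(resid, dist="norm", method="interpolate")
        ad_p = float(ad.pvalue)
    except TypeError:  # older scipy without `method`
        ad = stats.anderson(resid, dist="norm")
        ad_p = float("nan")
    return {
        "ks_statistic": float(ks.statistic),
        "ks_p": float(ks.pvalue),
        "ad_statistic": float(ad.statistic),
        "ad_p": ad_p,
    }
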