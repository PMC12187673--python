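"""Fifteen intrinsic cluster-validity indices.

All indices are computed on one embedding (rows = cells) and one hard
partition, with Euclidean distances throughout, split into two families:

* dispersion-based - derived from within-cluster scatter around cluster
  barycenters and total scatter around the global barycenter (TSS,
  within-cluster dispersion, Ball-Hall, Banfield-Raftery, PBM,
  Wemmert-Gancarski, Xie-Beni, Ray-Turi);
* pairwise-based - derived from intra- vs inter-cluster pairwise distances
  (McClain-Rao, C-index, Dunn, Silhouette, Point-Biserial, and the two SD
  components: average scattering and separation).

Degenerate situations (a zero-scatter cluster for Banfield-Raftery, an
all-singleton partition for the pairwise sums, zero distance variance for
Point-Biserial) raise typed errors rather than returning imputed values, so
the sweep driver can tag the record.

Sign conventions follow the definitions: Point-Biserial is the plain
Pearson correlation between the pairwise distances and the same-cluster
indicator (1 = same cluster), hence negative for good clusterings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import DegenerateClusterError, DegeneratePartitionError, InvalidInputError

__all__ = [
    "METRIC_NAMES",
    "ScatterSummary",
    "PairwiseSummary",
    "scatter_stats",
    "pairwise_stats",
    "dispersion_indices",
    "pairwise_indices",
    "compute_metric_vector",
]

#: Fixed column order; the interface contract for all sweep outputs and the
#: accuracy predictor.
METRIC_NAMES: tuple[str, ...] = (
    "tss",
    "wc_dispersion",
    "ball_hall",
    "banfield_raftery",
    "pbm",
    "wemmert_gancarski",
    "xie_beni",
    "ray_turi",
    "mclain_rao",
    "c_index",
    "dunn",
    "silhouette",
    "point_biserial",
    "sd_scattering",
    "sd_separation",
)


@dataclass
class ScatterSummary:
    """Scatter statistics: barycenter, centroids and the sums the
    dispersion indices are built from."""

    barycenter: np.ndarray
    centroids: np.ndarray  # K x d
    sizes: np.ndarray  # K
    T_k: np.ndarray  # per-cluster within-scatter trace sum ||x_i - c_k||^2
    tss: float  # sum ||x_i - xbar||^2
    E_T: float  # sum ||x_i - xbar||
    E_W: float  # sum_k sum_{i in C_k} ||x_i - c_k||


@dataclass
class PairwiseSummary:
    S_W: float  # sum of within-cluster pair distances
    S_B: float  # sum of between-cluster pair distances
    N_W: int
    N_B: int
    S_min: float  # sum of the N_W smallest pairwise distances
    S_max: float  # sum of the N_W largest pairwise distances
    d_min_between: float  # minimal inter-cluster point distance
    d_max_within: float  # maximal intra-cluster diameter


def _validate(X: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    labels = np.asarray(labels)
    if X.shape[0] != labels.shape[0]:
        raise InvalidInputError("X and labels must have equal length")
    _, codes = np.unique(labels, return_inverse=True)
    if codes.max() < 1:
        raise DegeneratePartitionError("validity indices need at least 2 clusters")
    return X, labels, codes


def scatter_stats(X: np.ndarray, labels: np.ndarray) -> ScatterSummary:
    X, _, codes = _validate(X, labels)
    k = codes.max() + 1
    sizes = np.bincount(codes, minlength=k)
    centroids = np.vstack([X[codes == c].mean(axis=0) for c in range(k)])
    barycenter = X.mean(axis=0)
    dev_global = np.linalg.norm(X - barycenter, axis=1)
    dev_own = np.linalg.norm(X - centroids[codes], axis=1)
    T_k = np.bincount(codes, weights=dev_own**2, minlength=k)
    return ScatterSummary(
        barycenter=barycenter,
        centroids=centroids,
        sizes=sizes,
        T_k=T_k,
        tss=float((dev_global**2).sum()),
        E_T=float(dev_global.sum()),
        E_W=float(dev_own.sum()),
    )


def _same_mask(codes: np.ndarray) -> np.ndarray:
    """Condensed (pdist-ordered) boolean vector: pair in the same cluster."""
    iu = np.triu_indices(len(codes), 1)
    return (codes[iu[0]] == codes[iu[1]])


def pairwise_stats(X: np.ndarray, labels: np.ndarray) -> PairwiseSummary:
    X, _, codes = _validate(X, labels)
    d = pdist(X)
    same = _same_mask(codes)
    n_w = int(same.sum())
    n_b = int(d.size - n_w)
    if n_w == 0:
        raise DegeneratePartitionError("all clusters are singletons; no within pairs")
    d_sorted = np.sort(d)
    return PairwiseSummary(
        S_W=float(d[same].sum()),
        S_B=float(d[~same].sum()),
        N_W=n_w,
        N_B=n_b,
        S_min=float(d_sorted[:n_w].sum()),
        S_max=float(d_sorted[-n_w:].sum()),
        d_min_between=float(d[~same].min()) if n_b else float("nan"),
        d_max_within=float(d[same].max()),
    )


def dispersion_indices(X: np.ndarray, labels: np.ndarray) -> dict[str, float]:
    """The eight scatter-based indices."""
    X, _, codes = _validate(X, labels)
    s = scatter_stats(X, labels)
    k = len(s.sizes)
    n = int(s.sizes.sum())
    wc = float(s.T_k.sum())
    out: dict[str, float] = {"tss": s.tss, "wc_dispersion": wc}
    out["ball_hall"] = float((s.T_k / s.sizes).sum() / k)
    if (s.T_k == 0).any():
        raise DegenerateClusterError(
            "banfield_raftery undefined: a cluster has zero within-scatter"
        )
    out["banfield_raftery"] = float((s.sizes * np.log(s.T_k / s.sizes)).sum())
    if s.E_W == 0:
        raise DegenerateClusterError("pbm undefined: zero within-cluster deviation sum")
    cd = pdist(s.centroids)
    out["pbm"] = float(((1.0 / k) * (s.E_T / s.E_W) * cd.max()) ** 2)
    # Wemmert-Gancarski: ratio of own-centroid to nearest-other-centroid distance
    d_to_centroids = np.linalg.norm(X[:, None, :] - s.centroids[None, :, :], axis=2)
    own = d_to_centroids[np.arange(len(codes)), codes]
    d_other = d_to_centroids.copy()
    d_other[np.arange(len(codes)), codes] = np.inf
    ratio = own / d_other.min(axis=1)
    mean_ratio = np.bincount(codes, weights=ratio, minlength=k) / s.sizes
    out["wemmert_gancarski"] = float(
        (s.sizes * np.maximum(0.0, 1.0 - mean_ratio)).sum() / n
    )
    pw = pairwise_stats(X, labels)
    out["xie_beni"] = float((wc / n) / pw.d_min_between**2)
    out["ray_turi"] = float((wc / n) / (cd.min() ** 2))
    return out


def pairwise_indices(X: np.ndarray, labels: np.ndarray) -> dict[str, float]:
    """The seven pairwise-distance-based indices."""
    X, _, codes = _validate(X, labels)
    pw = pairwise_stats(X, labels)
    s = scatter_stats(X, labels)
    k = len(s.sizes)
    out: dict[str, float] = {}
    out["mclain_rao"] = float((pw.S_W / pw.N_W) / (pw.S_B / pw.N_B))
    denom = pw.S_max - pw.S_min
    out["c_index"] = float((pw.S_W - pw.S_min) / denom) if denom > 0 else 0.0
    if pw.d_max_within == 0:
        raise DegenerateClusterError("dunn undefined: zero intra-cluster diameter")
    out["dunn"] = float(pw.d_min_between / pw.d_max_within)
    out["silhouette"] = _silhouette(X, codes, s.sizes)
    d = pdist(X)
    same = _same_mask(codes).astype(float)
    if d.std() == 0 or same.std() == 0:
        raise DegeneratePartitionError("point_biserial undefined: zero variance")
    out["point_biserial"] = float(np.corrcoef(d, same)[0, 1])
    # SD components: per-dimension population variances, Euclidean norms
    var_total = np.linalg.norm(X.var(axis=0, ddof=0))
    var_cluster = np.array(
        [np.linalg.norm(X[codes == c].var(axis=0, ddof=0)) for c in range(k)]
    )
    out["sd_scattering"] = float(var_cluster.mean() / var_total)
    cd = squareform(pdist(s.centroids))
    row_sums = cd.sum(axis=1)
    off = cd[np.triu_indices(k, 1)]
    out["sd_separation"] = float((off.max() / off.min()) * (1.0 / row_sums).sum())
    return out


def _silhouette(X: np.ndarray, codes: np.ndarray, sizes: np.ndarray) -> float:
    """Global silhouette: mean over clusters of the per-cluster mean s_i.

    s_i = (b_i - a_i) / max(a_i, b_i) with a_i the mean distance to the
    cell's own cluster (excluding itself) and b_i the smallest mean distance
    to another cluster; singleton cells get s_i = 0.
    """
    D = squareform(pdist(X))
    k = len(sizes)
    n = len(codes)
    sums = np.zeros((n, k))
    for c in range(k):
        sums[:, c] = D[:, codes == c].sum(axis=1)
    s_i = np.zeros(n)
    for i in range(n):
        c = codes[i]
        if sizes[c] > 1:
            a = sums[i, c] / (sizes[c] - 1)
            b = np.inf
            for c2 in range(k):
                if c2 != c:
                    b = min(b, sums[i, c2] / sizes[c2])
            s_i[i] = (b - a) / max(a, b)
    per_cluster = np.bincount(codes, weights=s_i, minlength=k) / sizes
    return float(per_cluster.mean())


def compute_metric_vector(X: np.ndarray, labels: np.ndarray) -> dict[str, float]:
    """All 15 indices, keyed and ordered by :data:`METRIC_NAMES`."""
    values = {**dispersion_indices(X, labels), **pairwise_indices(X, labels)}
    return {name: values[name] for name in METRIC_NAMES}
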