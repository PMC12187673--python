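"""Standard scRNA-seq preprocessing chain and neighbor-graph construction.

The chain mirrors the conventional single-cell workflow: filter genes seen
in too few cells, normalize each cell to a common library size, log1p
transform, keep the most variable genes (binned normalized dispersion, as
in the Seurat procedure), embed with PCA, and build a weighted k-nearest-
neighbor graph in the PCA space under either a Gaussian kernel with
adaptive bandwidth or the UMAP fuzzy-simplicial-set connectivities, with
cosine or Euclidean distances.

Every step is deterministic given its input and parameters: PCA uses a full
SVD with a fixed sign convention, variable-gene ties break by gene id, and
the exact kNN search has no random component.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from sklearn.neighbors import NearestNeighbors

from .errors import DegenerateInputError, InvalidInputError, RankDeficiencyError

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "Embedding",
    "NeighborGraph",
    "filter_genes",
    "normalize_log",
    "select_hvg",
    "pca_embed",
    "build_knn_graph",
]


@dataclass
class ExpressionMatrix:
    """Dense cells x genes matrix tagged with its processing layer."""

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    layer_tag: str = "counts"  # "counts" or "lognorm"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise InvalidInputError(
                f"matrix shape {self.values.shape} does not match id lists "
                f"({len(self.cell_ids)} cells, {len(self.gene_ids)} genes)"
            )
        if self.layer_tag == "counts" and (self.values < 0).any():
            raise InvalidInputError("counts layer must be non-negative")


@dataclass
class Embedding:
    """PCA scores with explained variance per component (non-increasing)."""

    coords: np.ndarray
    n_pc: int
    explained_variance: np.ndarray


@dataclass
class NeighborGraph:
    """Symmetric weighted kNN graph with zero diagonal."""

    adjacency: sparse.csr_matrix
    n_neighbors: int
    method: str  # "gauss" or "umap"
    metric: str  # "cosine" or "euclidean"


def _require_layer(X: ExpressionMatrix, tag: str, op: str) -> None:
    if X.layer_tag != tag:
        raise InvalidInputError(f"{op} expects layer '{tag}', got '{X.layer_tag}'")


def filter_genes(X: ExpressionMatrix, min_cells: int = 3) -> ExpressionMatrix:
    """Keep genes with a nonzero count in at least ``min_cells`` cells."""
    _require_layer(X, "counts", "filter_genes")
    keep = (X.values > 0).sum(axis=0) >= min_cells
    if not keep.any():
        raise DegenerateInputError("gene filter removed every gene")
    return ExpressionMatrix(
        values=X.values[:, keep],
        gene_ids=[g for g, k in zip(X.gene_ids, keep) if k],
        cell_ids=list(X.cell_ids),
        layer_tag="counts",
    )


def normalize_log(X: ExpressionMatrix, target_sum: float = 1e4) -> ExpressionMatrix:
    """Scale each cell to ``target_sum`` total counts, then natural log1p."""
    _require_layer(X, "counts", "normalize_log")
    totals = X.values.sum(axis=1)
    if (totals == 0).any():
        raise DegenerateInputError("cannot normalize cells with zero total count")
    vals = np.log1p(X.values / totals[:, None] * target_sum)
    return ExpressionMatrix(
        values=vals, gene_ids=list(X.gene_ids), cell_ids=list(X.cell_ids), layer_tag="lognorm"
    )


def select_hvg(X: ExpressionMatrix, n_top: int = 2000, n_bins: int = 20) -> ExpressionMatrix:
    """Keep the ``n_top`` most variable genes by binned normalized dispersion.

    Dispersion = var/mean of the expm1-transformed log values; genes are
    binned by mean expression and dispersions z-scored within each bin, so
    variability is judged relative to genes of similar abundance.  Ties (and
    zero-expression genes, which get -inf) break by gene id order.
    """
    _require_layer(X, "lognorm", "select_hvg")
    n_genes = X.values.shape[1]
    if n_top > n_genes:
        logger.warning("n_top=%d exceeds gene count %d; clamping", n_top, n_genes)
        n_top = n_genes
    expm = np.expm1(X.values)
    mean = expm.mean(axis=0)
    var = expm.var(axis=0, ddof=1) if expm.shape[0] > 1 else np.zeros(n_genes)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, np.nan)
    norm_disp = np.full(n_genes, -np.inf)
    expressed = mean > 0
    if expressed.any():
        # quantile bins over expressed genes; degenerate bins fall back to raw dispersion
        edges = np.quantile(mean[expressed], np.linspace(0, 1, n_bins + 1))
        edges = np.unique(edges)
        bin_of = np.clip(np.searchsorted(edges, mean, side="right") - 1, 0, len(edges) - 2)
        for b in np.unique(bin_of[expressed]):
            members = expressed & (bin_of == b)
            d = disp[members]
            sd = d.std(ddof=0)
            norm_disp[members] = (d - d.mean()) / sd if sd > 0 else 0.0
    # raw dispersion as secondary key keeps zero-dispersion genes last even
    # when a bin degenerates to a single gene (z-score 0); then gene id
    raw = np.where(np.isfinite(disp), disp, -np.inf)
    order = sorted(range(n_genes), key=lambda j: (-norm_disp[j], -raw[j], X.gene_ids[j]))
    keep = sorted(order[:n_top])
    return ExpressionMatrix(
        values=X.values[:, keep],
        gene_ids=[X.gene_ids[j] for j in keep],
        cell_ids=list(X.cell_ids),
        layer_tag="lognorm",
    )


def pca_embed(X: ExpressionMatrix, n_pc: int) -> Embedding:
    """Top-``n_pc`` principal-component scores of the column-centered matrix.

    Uses a full SVD; for each component the loading of largest magnitude is
    made positive, which pins the otherwise arbitrary sign.  ``n_pc`` may
    not exceed the structural rank ``min(cells - 1, genes)``; numerically
    rank-deficient data simply yields trailing components with (near-)zero
    explained variance.
    """
    _require_layer(X, "lognorm", "pca_embed")
    vals = X.values - X.values.mean(axis=0)
    n = vals.shape[0]
    max_pc = min(n - 1, vals.shape[1])
    if n_pc > max_pc:
        raise RankDeficiencyError(
            f"requested {n_pc} components but at most {max_pc} exist "
            f"for {n} cells x {vals.shape[1]} genes"
        )
    u, s, vt = np.linalg.svd(vals, full_matrices=False)
    u, s, vt = u[:, :n_pc], s[:n_pc], vt[:n_pc]
    # sign convention: largest-magnitude loading per component is positive
    flip = np.sign(vt[np.arange(n_pc), np.argmax(np.abs(vt), axis=1)])
    flip[flip == 0] = 1.0
    coords = u * s * flip
    explained = s**2 / (n - 1)
    return Embedding(coords=coords, n_pc=n_pc, explained_variance=explained)


def _knn(coords: np.ndarray, n_neighbors: int, metric: str) -> tuple[np.ndarray, np.ndarray]:
    """Exact kNN (self excluded): (indices, distances), each n_cells x k."""
    nn = NearestNeighbors(n_neighbors=n_neighbors + 1, metric=metric, algorithm="brute")
    nn.fit(coords)
    dists, idx = nn.kneighbors(coords)
    # drop the self column wherever it appears (ties can displace it from col 0)
    n = coords.shape[0]
    out_idx = np.empty((n, n_neighbors), dtype=np.int64)
    out_d = np.empty((n, n_neighbors), dtype=np.float64)
    for i in range(n):
        mask = idx[i] != i
        if mask.sum() == n_neighbors + 1:  # self not returned at all
            mask[-1] = False
        out_idx[i] = idx[i, mask][:n_neighbors]
        out_d[i] = dists[i, mask][:n_neighbors]
    return out_idx, out_d


def build_knn_graph(
    E: Embedding,
    n_neighbors: int,
    method: str = "umap",
    metric: str = "euclidean",
    seed: int = 0,
) -> NeighborGraph:
    """Weighted kNN graph over embedding cells.

    gauss
        Adaptive Gaussian kernel ``w_ij = exp(-d_ij^2 / (sigma_i sigma_j))``
        with ``sigma_i`` the distance from cell i to its ``n_neighbors``-th
        neighbor, symmetrized by the elementwise maximum.
    umap
        Fuzzy simplicial-set connectivities (smooth-kNN calibration of the
        per-point ``rho_i``/``sigma_i`` and fuzzy union ``a + b - ab``),
        delegated to umap-learn on the exact kNN computed here; weights lie
        in [0, 1] and the matrix is symmetric.
    """
    n_cells = E.coords.shape[0]
    if n_neighbors >= n_cells:
        raise InvalidInputError(f"n_neighbors={n_neighbors} must be < n_cells={n_cells}")
    if method not in ("gauss", "umap"):
        raise InvalidInputError(f"unknown method '{method}'")
    if metric not in ("cosine", "euclidean"):
        raise InvalidInputError(f"unknown metric '{metric}'")
    knn_idx, knn_d = _knn(E.coords, n_neighbors, metric)
    rows = np.repeat(np.arange(n_cells), n_neighbors)
    cols = knn_idx.ravel()
    if method == "gauss":
        sigma = knn_d[:, -1]
        sigma = np.where(sigma > 0, sigma, 1e-12)
        w = np.exp(-(knn_d.ravel() ** 2) / (sigma[rows] * sigma[cols]))
        W = sparse.csr_matrix((w, (rows, cols)), shape=(n_cells, n_cells))
        W = W.maximum(W.T)
    else:
        from umap.umap_ import fuzzy_simplicial_set

        W, _, _ = fuzzy_simplicial_set(
            X=sparse.csr_matrix((n_cells, 1)),  # ignored when knn is precomputed
            n_neighbors=n_neighbors,
            random_state=np.random.RandomState(seed),
            metric=metric,
            knn_indices=np.hstack([np.arange(n_cells)[:, None], knn_idx]),
            knn_dists=np.hstack([np.zeros((n_cells, 1)), knn_d]),
        )
        W = sparse.csr_matrix(W)
    W.setdiag(0)
    W.eliminate_zeros()
    if (np.asarray(W.sum(axis=1)).ravel() == 0).any():
        logger.warning("neighbor graph contains isolated nodes")
    return NeighborGraph(adjacency=W, n_neighbors=n_neighbors, method=method, metric=metric)


def preprocess_counts(
    counts: np.ndarray,
    gene_ids: list[str] | None = None,
    cell_ids: list[str] | None = None,
    min_cells: int = 3,
    target_sum: float = 1e4,
    n_hvg: int = 2000,
) -> ExpressionMatrix:
    """Convenience chain: counts -> filter -> normalize/log -> HVG."""
    n_cells, n_genes = counts.shape
    X = ExpressionMatrix(
        values=counts,
        gene_ids=gene_ids or [f"gene{j:05d}" for j in range(n_genes)],
        cell_ids=cell_ids or [f"cell{i:05d}" for i in range(n_cells)],
        layer_tag="counts",
    )
    return select_hvg(normalize_log(filter_genes(X, min_cells), target_sum), n_hvg)
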