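"""Synthetic labeled scRNA-seq count matrices and stratified subsampling.

The generator produces a cell-by-gene matrix of negative-binomial counts for
K cell populations of known (unequal) sizes.  Each population over-expresses
a disjoint block of marker genes by a configurable log fold change; every
cell carries a lognormal library-size factor, so counts show the
overdispersion and depth variation that the downstream validity indices and
regression models must tolerate.  The model deliberately omits batch
effects, doublets, ambient RNA and continuum structure: it is a labeled
stand-in for curated atlas data, not an emulation of any specific tissue.

Stratified subsampling mirrors the resampling design used throughout the
pipeline: a fixed fraction of cells is drawn per population (stratum) so
that subsample composition matches the parent dataset, repeated R times
with independently derived seeds.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import io as scipy_io
from scipy import sparse

from .errors import InvalidInputError, InvalidSpecError

__all__ = [
    "PopulationSpec",
    "SyntheticDataset",
    "SubsampleSet",
    "generate_dataset",
    "stratified_subsample",
    "default_desk_specs",
    "write_dataset",
    "read_dataset",
    "write_dataset_csv",
    "read_dataset_csv",
]


@dataclass(frozen=True)
class PopulationSpec:
    """Generative parameters for one synthetic dataset.

    Parameters
    ----------
    n_cells_per_cluster
        Size of each of the K populations; K = ``len(n_cells_per_cluster)``.
    n_genes
        Total number of genes.
    n_marker_genes_per_cluster
        Number of genes over-expressed in each population (disjoint blocks).
    log_fold_change
        Natural-log elevation of marker-gene means in their own population.
    dispersion
        Negative-binomial shape parameter; variance = mu + mu^2 / dispersion,
        so larger values approach the Poisson limit.
    library_size_log_mean, library_size_log_sd
        Parameters of the lognormal per-cell library-size factor.
    seed
        Master seed; identical specs generate bit-identical datasets.
    """

    n_cells_per_cluster: tuple[int, ...]
    n_genes: int = 500
    n_marker_genes_per_cluster: int = 15
    log_fold_change: float = 2.0
    dispersion: float = 1.5
    library_size_log_mean: float = 0.0
    library_size_log_sd: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "n_cells_per_cluster", tuple(int(n) for n in self.n_cells_per_cluster)
        )
        k = len(self.n_cells_per_cluster)
        if k < 2:
            raise InvalidSpecError(f"need at least 2 populations, got {k}")
        if any(n < 2 for n in self.n_cells_per_cluster):
            raise InvalidSpecError("every population must have at least 2 cells")
        if self.n_genes < 1:
            raise InvalidSpecError("n_genes must be positive")
        if self.n_marker_genes_per_cluster < 0:
            raise InvalidSpecError("n_marker_genes_per_cluster must be >= 0")
        if k * self.n_marker_genes_per_cluster > self.n_genes:
            raise InvalidSpecError("total marker genes exceed n_genes")
        if self.dispersion <= 0:
            raise InvalidSpecError("dispersion must be > 0")
        if self.log_fold_change < 0:
            raise InvalidSpecError("log_fold_change must be >= 0")
        if self.library_size_log_sd < 0:
            raise InvalidSpecError("library_size_log_sd must be >= 0")

    @property
    def n_clusters(self) -> int:
        return len(self.n_cells_per_cluster)

    @property
    def n_cells(self) -> int:
        return int(sum(self.n_cells_per_cluster))


@dataclass
class SyntheticDataset:
    """Counts (cells x genes), per-cell population labels and their spec."""

    counts: np.ndarray
    labels: np.ndarray
    spec: PopulationSpec
    dataset_id: str = "synthetic"
    gene_ids: list[str] = field(default_factory=list)
    cell_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.gene_ids:
            self.gene_ids = [f"gene{j:05d}" for j in range(self.counts.shape[1])]
        if not self.cell_ids:
            self.cell_ids = [f"cell{i:05d}" for i in range(self.counts.shape[0])]


@dataclass
class SubsampleSet:
    """Replicated stratified subsamples of one parent dataset.

    ``replicate_indices[r]`` are duplicate-free cell indices into the parent;
    each stratum contributes its largest-remainder share of ``fraction``,
    never fewer than one cell.
    """

    parent_id: str
    replicate_indices: list[np.ndarray]
    fraction: float
    seed: int


def _cluster_mean_matrix(spec: PopulationSpec, rng: np.random.Generator) -> np.ndarray:
    """K x G matrix of population-level gene means (before library size)."""
    base = rng.lognormal(mean=-1.0, sigma=1.0, size=spec.n_genes)
    means = np.tile(base, (spec.n_clusters, 1))
    m = spec.n_marker_genes_per_cluster
    for k in range(spec.n_clusters):
        means[k, k * m : (k + 1) * m] *= np.exp(spec.log_fold_change)
    return means


def generate_dataset(spec: PopulationSpec, dataset_id: str = "synthetic") -> SyntheticDataset:
    """Draw a labeled count matrix from the negative-binomial population model.

    Marker block k (genes ``[k*m, (k+1)*m)``) has its mean elevated by
    ``exp(log_fold_change)`` in population k only.  Cell i in population k
    draws ``counts[i, g] ~ NB(mean = s_i * mu[k, g], shape = dispersion)``
    with ``s_i ~ lognormal``.  Any all-zero cell is redrawn (deterministic
    continuation of the same stream) so downstream normalization is defined.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    means = _cluster_mean_matrix(spec, rng)
    labels = np.repeat(
        [f"pop{k:02d}" for k in range(spec.n_clusters)], spec.n_cells_per_cluster
    )
    sizes = rng.lognormal(
        mean=spec.library_size_log_mean, sigma=spec.library_size_log_sd, size=spec.n_cells
    )
    cluster_idx = np.repeat(np.arange(spec.n_clusters), spec.n_cells_per_cluster)
    mu = sizes[:, None] * means[cluster_idx, :]
    shape = spec.dispersion
    p = shape / (shape + mu)
    counts = rng.negative_binomial(shape, p).astype(np.int64)
    # all-zero cells break library-size normalization; redraw them
    for _ in range(100):
        zero = counts.sum(axis=1) == 0
        if not zero.any():
            break
        counts[zero] = rng.negative_binomial(shape, p[zero]).astype(np.int64)
    else:  # pragma: no cover - means are far too small to be usable
        raise InvalidSpecError("could not draw non-empty cells; means too small")
    return SyntheticDataset(counts=counts, labels=np.asarray(labels), spec=spec, dataset_id=dataset_id)


def _largest_remainder_shares(sizes: np.ndarray, fraction: float) -> np.ndarray:
    """Per-stratum subsample counts: largest-remainder rounding, floor of 1.

    The total is ``round(fraction * N)``; fractional seats go to the largest
    remainders (ties to the earlier stratum).  Every stratum keeps at least
    one cell so rare populations are never dropped.
    """
    quotas = fraction * sizes
    shares = np.floor(quotas).astype(int)
    total = int(np.floor(fraction * sizes.sum() + 0.5))
    remainders = quotas - shares
    order = np.lexsort((np.arange(len(sizes)), -remainders))
    deficit = total - shares.sum()
    for i in order[:max(deficit, 0)]:
        shares[i] += 1
    shares = np.minimum(np.maximum(shares, 1), sizes)
    return shares


def stratified_subsample(
    labels: np.ndarray,
    fraction: float,
    n_replicates: int,
    seed: int,
    parent_id: str = "synthetic",
) -> SubsampleSet:
    """Draw ``n_replicates`` stratified subsamples of ``fraction`` of the cells.

    Each stratum (unique label) contributes its largest-remainder share of
    the target total independently per replicate.  Replicate r uses a seed
    derived from ``(seed, r)`` via :class:`numpy.random.SeedSequence`, so
    replicates are mutually independent yet jointly reproducible.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise InvalidInputError("labels must be non-empty")
    if not (0 < fraction <= 1):
        raise InvalidInputError(f"fraction must be in (0, 1], got {fraction}")
    if n_replicates < 1:
        raise InvalidInputError("n_replicates must be >= 1")
    strata, stratum_codes = np.unique(labels, return_inverse=True)
    sizes = np.bincount(stratum_codes)
    shares = _largest_remainder_shares(sizes, fraction)
    replicate_indices: list[np.ndarray] = []
    for r in range(n_replicates):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(r,)))
        picked = []
        for s in range(len(strata)):
            members = np.flatnonzero(stratum_codes == s)
            picked.append(rng.choice(members, size=shares[s], replace=False))
        replicate_indices.append(np.sort(np.concatenate(picked)))
    return SubsampleSet(
        parent_id=parent_id,
        replicate_indices=replicate_indices,
        fraction=float(fraction),
        seed=int(seed),
    )


def default_desk_specs(seed: int = 0) -> dict[str, PopulationSpec]:
    """Three desk-scale synthetic datasets with distinct population structure.

    They differ in the number of populations (5, 8 and 10), size imbalance
    and marker strength, standing in for tissues of increasing annotation
    granularity.  Sizes (~600 cells each) keep a 20% subsample above 100
    cells while leaving even the rarest population with >= 5 cells per
    subsample.
    """
    ss = np.random.SeedSequence(seed)
    s1, s2, s3 = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(3))
    return {
        "alpha": PopulationSpec(
            n_cells_per_cluster=(200, 150, 100, 80, 70),
            n_genes=500,
            n_marker_genes_per_cluster=14,
            log_fold_change=2.2,
            dispersion=1.5,
            seed=s1,
        ),
        "beta": PopulationSpec(
            n_cells_per_cluster=(150, 120, 90, 70, 60, 50, 40, 30),
            n_genes=500,
            n_marker_genes_per_cluster=12,
            log_fold_change=2.0,
            dispersion=1.5,
            seed=s2,
        ),
        "gamma": PopulationSpec(
            n_cells_per_cluster=(120, 100, 80, 70, 60, 50, 40, 35, 30, 25),
            n_genes=500,
            n_marker_genes_per_cluster=10,
            log_fold_change=1.8,
            dispersion=1.2,
            seed=s3,
        ),
    }


# ---------------------------------------------------------------------------
# I/O: Matrix Market triplet (10x-style, genes x cells) plus TSV sidecars,
# and a dense CSV form for tiny fixtures.
# ---------------------------------------------------------------------------

def write_dataset(ds: SyntheticDataset, out_dir: str | Path) -> None:
    """Write matrix.mtx (genes x cells) + genes.tsv + barcodes.tsv + labels.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scipy_io.mmwrite(str(out / "matrix.mtx"), sparse.csr_matrix(ds.counts.T))
    (out / "genes.tsv").write_text("\n".join(ds.gene_ids) + "\n")
    (out / "barcodes.tsv").write_text("\n".join(ds.cell_ids) + "\n")
    with open(out / "labels.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["barcode", "label"])
        for bc, lab in zip(ds.cell_ids, ds.labels):
            w.writerow([bc, lab])


def read_dataset(in_dir: str | Path, dataset_id: str | None = None) -> SyntheticDataset:
    """Read the :func:`write_dataset` layout back into a dataset object."""
    d = Path(in_dir)
    counts = np.asarray(scipy_io.mmread(str(d / "matrix.mtx")).todense()).T.astype(np.int64)
    gene_ids = d.joinpath("genes.tsv").read_text().split()
    cell_ids = d.joinpath("barcodes.tsv").read_text().split()
    label_map: dict[str, str] = {}
    with open(d / "labels.tsv") as fh:
        reader = csv.reader(fh, delimiter="\t")
        next(reader)
        for bc, lab in reader:
            label_map[bc] = lab
    labels = np.asarray([label_map[bc] for bc in cell_ids])
    sizes = tuple(int(n) for n in np.unique(labels, return_counts=True)[1])
    spec = PopulationSpec(
        n_cells_per_cluster=sizes, n_genes=counts.shape[1], n_marker_genes_per_cluster=0
    )
    return SyntheticDataset(
        counts=counts,
        labels=labels,
        spec=spec,
        dataset_id=dataset_id or d.name,
        gene_ids=gene_ids,
        cell_ids=cell_ids,
    )


def write_dataset_csv(ds: SyntheticDataset, counts_csv: str | Path, labels_tsv: str | Path) -> None:
    """Dense CSV (cells x genes, with headers) plus a label TSV; for tiny fixtures."""
    with open(counts_csv, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["cell_id", *ds.gene_ids])
        for cid, row in zip(ds.cell_ids, ds.counts):
            w.writerow([cid, *row.tolist()])
    with open(labels_tsv, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["barcode", "label"])
        for bc, lab in zip(ds.cell_ids, ds.labels):
            w.writerow([bc, lab])


def read_dataset_csv(
    counts_csv: str | Path, labels_tsv: str | Path, dataset_id: str = "csv"
) -> SyntheticDataset:
    import pandas as pd

    df = pd.read_csv(counts_csv, index_col=0)
    lab = pd.read_csv(labels_tsv, sep="\t", index_col=0)["label"]
    labels = lab.loc[df.index].to_numpy()
    sizes = tuple(int(n) for n in np.unique(labels, return_counts=True)[1])
    spec = PopulationSpec(
        n_cells_per_cluster=sizes, n_genes=df.shape[1], n_marker_genes_per_cluster=0
    )
    return SyntheticDataset(
        counts=df.to_numpy(dtype=np.int64),
        labels=labels,
        spec=spec,
        dataset_id=dataset_id,
        gene_ids=[str(g) for g in df.columns],
        cell_ids=[str(c) for c in df.index],
    )
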