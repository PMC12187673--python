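import numpy as np
import pytest

from scsweep.synthetic import PopulationSpec, generate_dataset


@pytest.fixture
def p4():
    """Four 1-D points in two tight, well-separated pairs; every validity
    index on this instance has a closed-form hand value."""
    coords = np.array([0.0, 1.0, 10.0, 11.0])[:, None]
    labels = np.array(["A", "A", "B", "B"])
    return coords, labels


@pytest.fixture
def small_dataset():
    """Well-separated 3-population dataset, small enough for fast sweeps."""
    spec = PopulationSpec(
        n_cells_per_cluster=(60, 40, 30),
        n_genes=200,
        n_marker_genes_per_cluster=12,
        log_fold_change=3.0,
        dispersion=2.0,
        seed=42,
    )
    return generate_dataset(spec, dataset_id="small")


def random_instance(rng):
    """Random small clustered instance for oracle comparisons."""
    n = int(rng.integers(6, 31))
    d = int(rng.integers(1, 6))
    k = int(rng.integers(2, min(4, n // 2) + 1))
    centers = rng.normal(scale=4.0, size=(k, d))
    # every cluster gets >= 2 members so all indices are defined
    labels = np.concatenate([np.repeat(np.arange(k), 2), rng.integers(0, k, size=n - 2 * k)])
    rng.shuffle(labels)
    X = centers[labels] + rng.normal(scale=1.0, size=(n, d))
    return X, labels
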