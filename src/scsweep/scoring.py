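"""Extrinsic clustering scores against known cell labels.

With synthetic data the true partition is known, so annotating a clustering
reduces to mapping each cluster to the modal true label of its members
(majority vote, ties broken by lexicographic label order) and measuring the
fraction of cells whose mapped label matches their true one.  ARI and NMI
delegate to scikit-learn: ARI is the Hubert-Arabie adjusted index from the
contingency table, NMI normalizes mutual information by the arithmetic mean
of the two partition entropies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score

from .errors import InvalidInputError

__all__ = [
    "LabelMapping",
    "map_clusters_to_labels",
    "accuracy",
    "adjusted_rand_index",
    "normalized_mutual_information",
    "score_all",
]


@dataclass
class LabelMapping:
    cluster_to_label: dict[int, str]
    method_tag: str = "majority_vote"


def _check(assignment: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    assignment = np.asarray(assignment)
    truth = np.asarray(truth)
    if assignment.size == 0 or truth.size == 0:
        raise InvalidInputError("empty partition")
    if assignment.shape != truth.shape:
        raise InvalidInputError("assignment and truth must have equal length")
    return assignment, truth


def map_clusters_to_labels(assignment: np.ndarray, truth: np.ndarray) -> LabelMapping:
    """Map each cluster id to the modal true label of its members."""
    assignment, truth = _check(assignment, truth)
    mapping: dict[int, str] = {}
    for c in np.unique(assignment):
        members = truth[assignment == c]
        labels, counts = np.unique(members, return_counts=True)  # labels sorted
        mapping[int(c)] = str(labels[np.argmax(counts)])  # first max = lexicographic tie-break
    return LabelMapping(cluster_to_label=mapping)


def accuracy(assignment: np.ndarray, truth: np.ndarray) -> float:
    """Fraction of cells whose majority-vote cluster label equals the truth."""
    assignment, truth = _check(assignment, truth)
    mapping = map_clusters_to_labels(assignment, truth).cluster_to_label
    predicted = np.asarray([mapping[int(c)] for c in assignment])
    return float((predicted == truth.astype(str)).mean())


def adjusted_rand_index(p: np.ndarray, q: np.ndarray) -> float:
    p, q = _check(p, q)
    return float(adjusted_rand_score(p, q))


def normalized_mutual_information(p: np.ndarray, q: np.ndarray) -> float:
    p, q = _check(p, q)
    return float(normalized_mutual_info_score(p, q, average_method="arithmetic"))


def score_all(assignment: np.ndarray, truth: np.ndarray) -> dict[str, float]:
    """accuracy / ari / nmi in one call (one row of the sweep table)."""
    return {
        "accuracy": accuracy(assignment, truth),
        "ari": adjusted_rand_index(assignment, truth),
        "nmi": normalized_mutual_information(assignment, truth),
    }
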