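"""Aggregate one patient community's concordance matrices into a network.

The community concordance network is the elementwise sum S of the member
patients' rank-1 concordance matrices, normalized off the diagonal by

    w_ij = S_ij / sqrt(S_ii * S_jj)          (0 when either diagonal is 0).

S_ii counts patients endorsing symptom i and S_ij counts patients endorsing
both i and j, so w_ij lies in [0, 1] by Cauchy–Schwarz and reaches 1 exactly
when i and j co-occur in every patient who has either. (This normalization is
the Ochiai / binary cosine coefficient of the two symptoms' patient sets — an
interpretation aid, not a different quantity.) Raw endorsement counts are kept
separately as ``counts_diagonal``; the weight matrix's own diagonal is held at
0 so downstream graph algorithms see no self-loops.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .concordance import ConcordanceMatrix
from .errors import ValidationError
from .graph_community import CommunityPartition, WeightedGraph

__all__ = [
    "CommunityConcordanceNetwork",
    "aggregate_community",
    "aggregate_cohort",
]


@dataclass(frozen=True)
class CommunityConcordanceNetwork:
    """Normalized k x k symptom network for one patient community.

    Attributes
    ----------
    symptom_labels : tuple of str
    counts_diagonal : ndarray (k,)
        Within-community endorsement count per symptom (diag of the raw sum).
    normalized_weights : ndarray (k, k)
        Symmetric, off-diagonal in [0, 1], zero diagonal. Symptoms endorsed by
        nobody stay isolate nodes with all-zero weights.
    community_id : int
    n_patients : int
    """

    symptom_labels: tuple
    counts_diagonal: np.ndarray
    normalized_weights: np.ndarray
    community_id: int
    n_patients: int

    def __post_init__(self):
        labels = tuple(str(s) for s in self.symptom_labels)
        counts = np.asarray(self.counts_diagonal, dtype=np.int64)
        w = np.asarray(self.normalized_weights, dtype=np.float64)
        k = len(labels)
        if counts.shape != (k,):
            raise ValidationError("counts_diagonal must have one entry per symptom")
        if w.shape != (k, k):
            raise ValidationError(f"weights shape {w.shape}, expected ({k}, {k})")
        if not np.allclose(w, w.T):
            raise ValidationError("normalized weights must be symmetric")
        if not np.allclose(np.diagonal(w), 0.0):
            raise ValidationError("normalized weight diagonal must be 0")
        if w.min() < -1e-12 or w.max() > 1 + 1e-12:
            raise ValidationError("normalized weights must lie in [0, 1]")
        object.__setattr__(self, "symptom_labels", labels)
        object.__setattr__(self, "counts_diagonal", counts)
        object.__setattr__(self, "normalized_weights", np.clip(w, 0.0, 1.0))

    @property
    def k(self) -> int:
        return len(self.symptom_labels)

    def to_graph(self) -> WeightedGraph:
        return WeightedGraph(self.symptom_labels, self.normalized_weights)

    def counts_to_csv(self, path) -> None:
        pd.DataFrame(
            {"symptom": list(self.symptom_labels), "endorsements": self.counts_diagonal}
        ).to_csv(path, index=False)


def _aggregate_binary(values: np.ndarray):
    """Raw sum and normalized weights from an (n_members, k) binary block."""
    values = np.asarray(values, dtype=np.float64)
    s = values.T @ values  # sum of rank-1 outer products
    d = np.diagonal(s).copy()
    denom = np.sqrt(np.outer(d, d))
    w = np.divide(s, denom, out=np.zeros_like(s), where=denom > 0)
    np.fill_diagonal(w, 0.0)
    return d, w


def aggregate_community(matrices, community_id: int = 0) -> CommunityConcordanceNetwork:
    """Sum a community's concordance matrices and normalize off-diagonals.

    Parameters
    ----------
    matrices : sequence of ConcordanceMatrix
        At least one; all must share the same symptom vocabulary. Order is
        irrelevant (summation commutes).
    community_id : int
        Carried through to outputs.

    Raises
    ------
    ValidationError
        On an empty community or mismatched symptom labels.
    """
    matrices = list(matrices)
    if not matrices:
        raise ValidationError(f"community {community_id} has no members")
    labels = matrices[0].labels
    for m in matrices:
        if not isinstance(m, ConcordanceMatrix):
            raise ValidationError("expected ConcordanceMatrix instances")
        if m.labels != labels:
            raise ValidationError("all matrices must share the symptom vocabulary")
    values = np.stack([m.diagonal for m in matrices])
    counts, weights = _aggregate_binary(values)
    return CommunityConcordanceNetwork(labels, counts, weights, community_id, len(matrices))


def aggregate_cohort(table, partition: CommunityPartition) -> dict:
    """Aggregate every patient community of a cohort.

    Fast path over :func:`aggregate_community` working directly on the binary
    symptom table (each row is the diagonal of that patient's rank-1
    concordance matrix, so S = B^T B).

    Returns
    -------
    dict mapping community id -> CommunityConcordanceNetwork
    """
    if partition.labels.shape != (table.n,):
        raise ValidationError("partition does not match table rows")
    out = {}
    for c in range(partition.n_communities):
        rows = table.values[partition.members(c)]
        counts, weights = _aggregate_binary(rows)
        out[c] = CommunityConcordanceNetwork(
            table.symptom_labels, counts, weights, c, rows.shape[0]
        )
    return out
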