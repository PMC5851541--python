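"""Per-patient concordance matrices and their unique-entry vectorizations.

A concordance matrix is the outer product X X^T of a patient's binary symptom
vector X with itself: the diagonal records symptom presence, the off-diagonal
entries record pairwise co-occurrence. The matrix is rank-1 over {0, 1} and
carries exactly the same information as X, but re-weights it: a pair of
patients sharing s symptoms agree on s raw-vector entries yet on s(s+1)/2
unique concordance entries, so co-occurrence is emphasized quadratically.

Because of the rank-1 structure, matrices are stored sparsely as the *support
set* (the indices of endorsed symptoms) and materialized densely on demand.

The *unique entries* of the symmetric matrix are its diagonal followed by the
strict upper triangle in row-major order — k(k+1)/2 binary values. This is the
vectorization on which between-patient similarity is computed; including the
diagonal is the only reading under which two patients sharing three symptoms
agree on 6 co-present entries (3 presences + 3 pairs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

__all__ = [
    "ConcordanceMatrix",
    "build_concordance",
    "unique_entries",
    "unique_entry_length",
    "unique_entry_matrix",
    "from_unique_entries",
    "agreement_count",
]


@dataclass(frozen=True)
class ConcordanceMatrix:
    """One patient's k x k symmetric binary co-occurrence matrix, stored by support.

    Attributes
    ----------
    labels : tuple of str
        Symptom names, defining row/column order.
    support : tuple of int
        Sorted indices of endorsed symptoms; entry (i, j) of the dense matrix
        is 1 iff both i and j are in the support.
    """

    labels: tuple
    support: tuple = field(default=())

    def __post_init__(self):
        labels = tuple(self.labels)
        support = tuple(sorted(set(int(i) for i in self.support)))
        if support and (support[0] < 0 or support[-1] >= len(labels)):
            raise ValidationError("support index out of range")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "support", support)

    @property
    def k(self) -> int:
        return len(self.labels)

    @property
    def diagonal(self) -> np.ndarray:
        """The patient's binary symptom vector."""
        x = np.zeros(self.k, dtype=np.uint8)
        x[list(self.support)] = 1
        return x

    def dense(self) -> np.ndarray:
        """Materialize the full k x k matrix (outer product of the diagonal)."""
        x = self.diagonal
        return np.outer(x, x)


def build_concordance(x, labels) -> ConcordanceMatrix:
    """Build a patient's concordance matrix from their binary symptom vector.

    ``M[i, j] = x[i] * x[j]``; the diagonal equals ``x``.

    Raises
    ------
    ValidationError
        If ``x`` has a non-binary entry or its length differs from ``labels``.
    """
    x = np.asarray(x)
    labels = tuple(labels)
    if x.ndim != 1 or len(x) != len(labels):
        raise ValidationError(
            f"symptom vector length {x.shape} does not match {len(labels)} labels"
        )
    if not np.isin(x, (0, 1)).all():
        raise ValidationError("symptom vector entries must be exactly 0 or 1")
    return ConcordanceMatrix(labels, tuple(np.flatnonzero(x).tolist()))


def unique_entry_length(k: int) -> int:
    """Number of unique entries of a symmetric k x k matrix: k(k+1)/2."""
    return k * (k + 1) // 2


def unique_entries(m: ConcordanceMatrix) -> np.ndarray:
    """Vectorize a concordance matrix into its k(k+1)/2 unique entries.

    Order: diagonal entries 0..k-1 first, then the strict upper triangle in
    row-major order ((0,1), (0,2), ..., (k-2,k-1)). The map is invertible; see
    :func:`from_unique_entries`.
    """
    dense = m.dense()
    iu = np.triu_indices(m.k, 1)
    return np.concatenate([np.diagonal(dense), dense[iu]]).astype(np.uint8)


def unique_entry_matrix(values) -> np.ndarray:
    """Stack unique-entry vectors for all patients of a binary n x k matrix.

    Vectorized fast path equivalent to calling :func:`build_concordance` and
    :func:`unique_entries` per row; returns an (n, k(k+1)/2) uint8 array.
    """
    values = np.asarray(values, dtype=np.uint8)
    if values.ndim != 2:
        raise ValidationError("expected an n x k binary matrix")
    if not np.isin(values, (0, 1)).all():
        raise ValidationError("matrix entries must be exactly 0 or 1")
    iu, ju = np.triu_indices(values.shape[1], 1)
    pairs = values[:, iu] * values[:, ju]
    return np.concatenate([values, pairs], axis=1)


def from_unique_entries(vec, labels) -> ConcordanceMatrix:
    """Reconstruct a concordance matrix from its unique-entry vector.

    The inverse of :func:`unique_entries`. Rejects vectors that are not the
    vectorization of a rank-1 binary outer product (the off-diagonal part must
    be consistent with the diagonal).
    """
    labels = tuple(labels)
    k = len(labels)
    vec = np.asarray(vec)
    if vec.shape != (unique_entry_length(k),):
        raise ValidationError(
            f"expected {unique_entry_length(k)} unique entries for k={k}, "
            f"got shape {vec.shape}"
        )
    if not np.isin(vec, (0, 1)).all():
        raise ValidationError("unique entries must be exactly 0 or 1")
    diag = vec[:k]
    m = build_concordance(diag, labels)
    if not np.array_equal(unique_entries(m), vec.astype(np.uint8)):
        raise ValidationError(
            "unique-entry vector is not consistent with a rank-1 concordance matrix"
        )
    return m


def agreement_count(a, b) -> int:
    """Count positions where both unique-entry vectors equal 1.

    For two patients sharing s symptoms this equals s(s+1)/2 — the concordance
    representation's quadratic emphasis on co-occurrence (e.g. 6 for three
    shared symptoms, versus raw-vector agreement 3).
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValidationError(f"length mismatch: {a.shape} vs {b.shape}")
    return int(np.sum((a == 1) & (b == 1)))
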