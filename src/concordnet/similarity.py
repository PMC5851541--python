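"""Between-patient similarity: pairwise Adjusted Rand Index with clamping.

Concordance matrices are high-dimensional binary objects; raw distances
between them concentrate, which defeats clustering. The similarity used here
is the Hubert–Arabie Adjusted Rand Index (ARI) between two patients'
unique-entry vectors, treating each binary vector as a labeling of the
L = k(k+1)/2 entry positions. The ARI corrects agreement for chance:

    ARI = (sum_ij C(n_ij,2) - E) / (0.5*[sum_i C(a_i,2) + sum_j C(b_j,2)] - E),
    E   = sum_i C(a_i,2) * sum_j C(b_j,2) / C(L,2),

computed from the 2x2 contingency table of the two vectors (n_ij = positions
valued i in one vector and j in the other; a_i, b_j its margins).

Negative ARI values — agreement worse than chance, a finite-sample effect —
are clamped to 0 in the similarity matrix: worse-than-chance agreement is
read as complete lack of agreement. The diagonal is fixed at 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "SimilarityMatrix",
    "pairwise_ari",
    "adjusted_rand_index",
    "build_similarity_matrix",
]


def _comb2(x):
    """C(x, 2), elementwise, in float to avoid integer overflow at large L."""
    x = np.asarray(x, dtype=np.float64)
    return x * (x - 1.0) / 2.0


def pairwise_ari(a, b) -> float:
    """Hubert–Arabie ARI between two binary vectors of equal length L >= 2.

    Degenerate case: when both vectors are constant every pair of positions is
    co-labeled in both, the chance correction cancels the denominator, and the
    formula is 0/0. By convention identical constant vectors score 1 (the
    limit of perfect agreement) and differing constant vectors score 0.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValidationError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.ndim != 1 or len(a) < 2:
        raise ValidationError("vectors must be one-dimensional with length >= 2")
    for v in (a, b):
        if not np.isin(v, (0, 1)).all():
            raise ValidationError("vectors must be binary (0/1)")

    L = len(a)
    n11 = float(np.sum((a == 1) & (b == 1)))
    n10 = float(np.sum((a == 1) & (b == 0)))
    n01 = float(np.sum((a == 0) & (b == 1)))
    n00 = float(L) - n11 - n10 - n01

    sum_cells = _comb2(n11) + _comb2(n10) + _comb2(n01) + _comb2(n00)
    sum_a = _comb2(n11 + n10) + _comb2(n01 + n00)
    sum_b = _comb2(n11 + n01) + _comb2(n10 + n00)
    expected = sum_a * sum_b / _comb2(L)
    denom = 0.5 * (sum_a + sum_b) - expected
    if denom == 0.0:
        return 1.0 if np.array_equal(a, b) else 0.0
    return float((sum_cells - expected) / denom)


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Hubert–Arabie ARI between two categorical labelings of the same items.

    The multi-class generalization of :func:`pairwise_ari`, computed from the
    full contingency table. Used to score recovered community partitions
    against planted ones; invariant to label renaming. If both labelings are
    trivial (a single class each) the partitions coincide and the score is 1.
    """
    labels_a = np.asarray(labels_a).ravel()
    labels_b = np.asarray(labels_b).ravel()
    if labels_a.shape != labels_b.shape:
        raise ValidationError(
            f"length mismatch: {labels_a.shape} vs {labels_b.shape}"
        )
    n = len(labels_a)
    if n < 2:
        raise ValidationError("need at least 2 items")

    _, ia = np.unique(labels_a, return_inverse=True)
    _, ib = np.unique(labels_b, return_inverse=True)
    table = np.zeros((ia.max() + 1, ib.max() + 1), dtype=np.int64)
    np.add.at(table, (ia, ib), 1)

    sum_cells = _comb2(table).sum()
    sum_a = _comb2(table.sum(axis=1)).sum()
    sum_b = _comb2(table.sum(axis=0)).sum()
    expected = sum_a * sum_b / _comb2(n)
    denom = 0.5 * (sum_a + sum_b) - expected
    if denom == 0.0:
        # both labelings constant: identical trivial partitions
        return 1.0
    return float((sum_cells - expected) / denom)


@dataclass(frozen=True)
class SimilarityMatrix:
    """n x n symmetric patient similarity; entries in [0, 1], diagonal 1."""

    patient_ids: tuple
    values: np.ndarray

    def __post_init__(self):
        ids = tuple(str(p) for p in self.patient_ids)
        values = np.asarray(self.values, dtype=np.float64)
        n = len(ids)
        if len(set(ids)) != n:
            raise ValidationError("duplicate patient IDs")
        if values.shape != (n, n):
            raise ValidationError(f"values shape {values.shape}, expected ({n}, {n})")
        if not np.allclose(values, values.T):
            raise ValidationError("similarity matrix must be symmetric")
        if not np.allclose(np.diagonal(values), 1.0):
            raise ValidationError("similarity diagonal must be 1")
        if values.min() < 0 or values.max() > 1 + 1e-12:
            raise ValidationError("similarity entries must lie in [0, 1]")
        object.__setattr__(self, "patient_ids", ids)
        object.__setattr__(self, "values", values)

    @property
    def n(self) -> int:
        return len(self.patient_ids)

    def to_csv(self, path) -> None:
        """Write as CSV with patient-ID header row/column, full precision."""
        pd.DataFrame(
            self.values, index=list(self.patient_ids), columns=list(self.patient_ids)
        ).to_csv(path, index_label="patient_id")

    @classmethod
    def from_csv(cls, path) -> "SimilarityMatrix":
        frame = pd.read_csv(path, index_col=0, float_precision="round_trip")
        return cls(tuple(str(c) for c in frame.columns), frame.to_numpy(dtype=np.float64))


def build_similarity_matrix(vectors, patient_ids) -> SimilarityMatrix:
    """Pairwise clamped ARI over unique-entry vectors, vectorized over all pairs.

    Entry (i, j) = max(0, ARI(v_i, v_j)) for i != j; the diagonal is 1. The
    all-pairs 2x2 contingency tables are obtained from one matrix product, so
    the result is identical to looping :func:`pairwise_ari` over pairs but
    orders of magnitude faster; equality of the two routes is exercised in the
    test suite.

    Parameters
    ----------
    vectors : sequence of binary vectors, or (n, L) binary array
    patient_ids : sequence of n identifiers
    """
    V = np.asarray(vectors, dtype=np.float64)
    if V.ndim != 2:
        raise ValidationError("expected an (n, L) array of unique-entry vectors")
    n, L = V.shape
    if n < 2:
        raise ValidationError("need at least 2 patients")
    if L < 2:
        raise ValidationError("unique-entry vectors must have length >= 2")
    if not np.isin(V, (0, 1)).all():
        raise ValidationError("unique-entry vectors must be binary (0/1)")
    if len(patient_ids) != n:
        raise ValidationError("patient_ids length does not match vectors")

    ones = V.sum(axis=1)
    n11 = V @ V.T
    n10 = ones[:, None] - n11
    n01 = ones[None, :] - n11
    n00 = L - n11 - n10 - n01

    sum_cells = _comb2(n11) + _comb2(n10) + _comb2(n01) + _comb2(n00)
    sum_a = _comb2(ones) + _comb2(L - ones)
    expected = sum_a[:, None] * sum_a[None, :] / _comb2(L)
    denom = 0.5 * (sum_a[:, None] + sum_a[None, :]) - expected

    with np.errstate(invalid="ignore", divide="ignore"):
        ari = (sum_cells - expected) / denom
    # degenerate pairs (both vectors constant): identical -> 1, differing -> 0
    degenerate = denom == 0.0
    if degenerate.any():
        identical = (n10 + n01) == 0
        ari = np.where(degenerate, np.where(identical, 1.0, 0.0), ari)

    sim = np.clip(ari, 0.0, 1.0)
    sim = (sim + sim.T) / 2.0  # symmetrize away float round-off
    np.fill_diagonal(sim, 1.0)
    return SimilarityMatrix(tuple(patient_ids), sim)
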