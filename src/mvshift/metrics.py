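"""Pair-counting partition agreement: Fowlkes–Mallows and adjusted Rand.

Both indices are computed from an R×C contingency table with exact
integer pair counts (no floating binomials), so small printed tables
reproduce bit-stably.  The Fowlkes–Mallows index,

    FM = T₂ / √(P₂·Q₂),   T₂ = Σ_ij C(n_ij,2),  P₂ = Σ_i C(a_i,2),
                          Q₂ = Σ_j C(b_j,2),

is the geometric mean of pairwise precision and recall and remains
informative when one of the partitions has a single group — the reason
it is preferred for benchmarking against single-cluster truths, where
the adjusted Rand index pins at its minimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ContingencyTable", "MetricReport", "contingency", "fm_index", "ari"]


def _pairs(x: np.ndarray) -> int:
    """Σ C(x_i, 2) with exact integer arithmetic."""
    return int(sum(int(v) * (int(v) - 1) // 2 for v in np.asarray(x).ravel()))


@dataclass(frozen=True)
class ContingencyTable:
    """Cross-tabulation n_ij of two labelings of the same n observations."""

    counts: np.ndarray  # (R, C), nonnegative ints

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D table")
        if not np.issubdtype(counts.dtype, np.integer):
            as_int = counts.astype(int)
            if not np.array_equal(as_int, counts):
                raise ValueError("counts must be integers")
            counts = as_int
        if (counts < 0).any():
            raise ValueError("counts must be nonnegative")
        object.__setattr__(self, "counts", counts)

    @property
    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def n(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class MetricReport:
    fm: float
    ari: float


def contingency(labels_a, labels_b) -> ContingencyTable:
    """Cross-tabulate two label vectors; categories in order of first appearance."""
    a = np.asarray(labels_a).ravel()
    b = np.asarray(labels_b).ravel()
    if a.shape != b.shape or a.size < 1:
        raise ValueError("label vectors must have equal positive length")
    cat_a = {v: i for i, v in enumerate(dict.fromkeys(a.tolist()))}
    cat_b = {v: i for i, v in enumerate(dict.fromkeys(b.tolist()))}
    counts = np.zeros((len(cat_a), len(cat_b)), dtype=int)
    for va, vb in zip(a.tolist(), b.tolist()):
        counts[cat_a[va], cat_b[vb]] += 1
    return ContingencyTable(counts)


def fm_index(t: ContingencyTable) -> float:
    """Fowlkes–Mallows index of a contingency table."""
    if t.n < 2:
        raise ValueError("FM needs at least two observations")
    t2 = _pairs(t.counts)
    p2 = _pairs(t.row_sums)
    q2 = _pairs(t.col_sums)
    if p2 == 0 or q2 == 0:
        raise ValueError("FM undefined for all-singleton partition")
    if t2 * t2 == p2 * q2:  # identical partitions: exactly 1
        return float(t2 > 0)
    return t2 / np.sqrt(float(p2) * float(q2))


def ari(t: ContingencyTable) -> float:
    """Adjusted Rand index of a contingency table."""
    if t.n < 2:
        raise ValueError("ARI needs at least two observations")
    t2 = _pairs(t.counts)
    p2 = _pairs(t.row_sums)
    q2 = _pairs(t.col_sums)
    tot = t.n * (t.n - 1) // 2
    expected = p2 * q2 / tot
    denom = 0.5 * (p2 + q2) - expected
    if denom == 0:
        # both partitions put everything in one cluster: identical partitions
        if t.counts.shape == (1, 1):
            return 1.0
        raise ValueError("ARI undefined: degenerate denominator")
    return (t2 - expected) / denom


def report(labels_a, labels_b) -> MetricReport:
    """FM and ARI between two label vectors."""
    t = contingency(labels_a, labels_b)
    return MetricReport(fm=fm_index(t), ari=ari(t))
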