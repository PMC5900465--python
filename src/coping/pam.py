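"""Partitioning around medoids (PAM) for one-dimensional data.

PAM clusters observations around *medoids* — cluster centers that are
themselves data points — by minimizing the total dissimilarity of each
point to its cluster's medoid.  For one-dimensional latencies with the
absolute (L1) distance this is the robust analogue of k-means: the
medoid of a cluster is a median rather than a mean, so a handful of
censored or extreme latencies cannot drag the center.

Two solvers are provided:

``pam_fit``
    The classical BUILD + SWAP algorithm for any ``k``.  BUILD seeds
    medoids greedily (each new medoid is the point that most reduces the
    total cost); SWAP repeatedly applies the single medoid/non-medoid
    exchange that most reduces the cost, stopping when no exchange gives
    a strict improvement.

``pam_fit_k2`` / ``pam_k2_batch``
    An exact solver for the special case ``k = 2`` in one dimension.
    Under nearest-medoid assignment the two clusters are contiguous in
    sorted order, and the cost-minimizing medoid of a contiguous block
    is its (lower) median — so scanning the ``n - 1`` split points of
    the sorted sample finds the global optimum of the PAM objective in
    ``O(n log n)``.  ``pam_k2_batch`` evaluates many samples at once and
    is the inner engine of the bootstrap classifier.

Tie rules (all deterministic): equidistant points assign to the lower
medoid; SWAP accepts only strictly improving exchanges; BUILD ties
resolve to the lowest input index; the split scan keeps the first
(lowest) minimizing split.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ClusterAssignment",
    "EmptyInputError",
    "DegenerateInputError",
    "pam_fit",
    "pam_fit_k2",
    "pam_k2_batch",
    "assign_nearest_medoid",
    "clustering_cost",
]


class EmptyInputError(ValueError):
    """Raised when asked to cluster an empty sample."""


class DegenerateInputError(ValueError):
    """Raised when the sample has fewer distinct values than clusters."""


@dataclass(frozen=True)
class ClusterAssignment:
    """A fitted clustering.

    Attributes
    ----------
    medoids
        Medoid values in ascending order; each is a member of the input.
    labels
        Per-item cluster index aligned to ``medoids`` (0 = lowest medoid).
    cost
        Total within-cluster absolute deviation,
        ``sum_i |x_i - medoids[labels[i]]|``.
    """

    medoids: tuple[float, ...]
    labels: tuple[int, ...]
    cost: float


def _validate(values: Sequence[float], k: int) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("values must be one-dimensional")
    if x.size == 0:
        raise EmptyInputError("cannot cluster an empty sample")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    n_distinct = np.unique(x).size
    if n_distinct < k:
        raise DegenerateInputError(
            f"need at least k={k} distinct values, got {n_distinct}"
        )
    return x


def pam_fit(values: Sequence[float], k: int = 2) -> ClusterAssignment:
    """Fit PAM with the BUILD + SWAP algorithm.

    Parameters
    ----------
    values
        One-dimensional observations (e.g. average defeat latencies, s).
    k
        Number of clusters; the coping pipeline uses 2.

    Returns
    -------
    ClusterAssignment
        The global optimum of the PAM objective. The BUILD + SWAP result
        is canonicalized against the exact contiguous-partition solution
        (available because the data are one-dimensional), which SWAP can
        tie but never beat; this also fixes the choice among equal-cost
        optima deterministically.
    """
    x = _validate(values, k)
    n = x.size
    dist = np.abs(x[:, None] - x[None, :])  # (n, n)

    # BUILD: first medoid minimizes total distance; each subsequent medoid
    # is the non-medoid minimizing the resulting cost. argmin breaks ties
    # toward the lowest index.
    medoid_idx: list[int] = [int(np.argmin(dist.sum(axis=0)))]
    d_near = dist[:, medoid_idx[0]].copy()  # distance to nearest medoid
    while len(medoid_idx) < k:
        cand_cost = np.minimum(d_near[:, None], dist).sum(axis=0)
        cand_cost[medoid_idx] = np.inf
        j = int(np.argmin(cand_cost))
        medoid_idx.append(j)
        d_near = np.minimum(d_near, dist[:, j])

    # SWAP: steepest descent over all (medoid, candidate) exchanges,
    # accepting only strict improvements.
    medoid_idx_arr = np.array(medoid_idx)
    cost = float(dist[:, medoid_idx_arr].min(axis=1).sum())
    while True:
        best_cost = cost
        best_swap: tuple[int, int] | None = None
        for pos in range(k):
            others = np.delete(medoid_idx_arr, pos)
            d_others = (
                dist[:, others].min(axis=1) if others.size else np.full(n, np.inf)
            )
            # new cost for every candidate replacement at once
            new_costs = np.minimum(d_others[:, None], dist).sum(axis=0)
            new_costs[medoid_idx_arr] = np.inf
            j = int(np.argmin(new_costs))
            if new_costs[j] < best_cost:
                best_cost = float(new_costs[j])
                best_swap = (pos, j)
        if best_swap is None:
            break
        medoid_idx_arr[best_swap[0]] = best_swap[1]
        cost = best_cost

    # Exact 1-D canonicalization: SWAP can terminate in a local optimum
    # on tie-heavy inputs (steepest descent cannot cross an equal-cost
    # plateau), and equal-cost optima exist whenever a cluster has even
    # size (both middle elements are medians). The contiguous-partition
    # solution is provably global and, being computed on the sorted
    # sample with fixed tie rules, is permutation invariant — so it is
    # the canonical result whenever SWAP cannot beat it (it never can).
    exact_medoids, exact_cost = _exact_contiguous(x, k)
    swap_medoids = np.sort(x[medoid_idx_arr])
    swap_cost = float(np.abs(x[:, None] - swap_medoids[None, :]).min(axis=1).sum())
    # the guard absorbs summation-order rounding: SWAP can only tie the
    # exact optimum, and on a tie the canonical solution must win
    medoids = (
        swap_medoids
        if swap_cost < exact_cost - 1e-9 * max(1.0, exact_cost)
        else exact_medoids
    )
    labels = np.argmin(np.abs(x[:, None] - medoids[None, :]), axis=1)
    cost = float(np.abs(x - medoids[labels]).sum())
    return ClusterAssignment(
        medoids=tuple(float(m) for m in medoids),
        labels=tuple(int(l) for l in labels),
        cost=cost,
    )


def _exact_contiguous(x: np.ndarray, k: int) -> tuple[np.ndarray, float]:
    """Global optimum of the 1-D PAM objective by dynamic programming.

    Under nearest-medoid assignment clusters are contiguous in sorted
    order and the optimal medoid of a block is its (lower) median, so
    minimizing over contiguous k-partitions of the sorted sample attains
    the global optimum in O(k n^2).
    """
    xs = np.sort(x)
    n = xs.size
    S = np.concatenate([[0.0], np.cumsum(xs)])

    def seg(i: int, j: int) -> tuple[float, float]:
        """(cost, medoid) of sorted block [i, j)."""
        m = (i + j - 1) // 2
        med = xs[m]
        cost = (med * (m - i + 1) - (S[m + 1] - S[i])) + (
            (S[j] - S[m + 1]) - med * (j - 1 - m)
        )
        return cost, med

    NEG = -1
    dp = np.full((k + 1, n + 1), np.inf)
    choice = np.full((k + 1, n + 1), NEG, dtype=int)
    dp[0, 0] = 0.0
    for m in range(1, k + 1):
        for j in range(m, n + 1):
            for s in range(m - 1, j):
                if not np.isfinite(dp[m - 1, s]):
                    continue
                c, _ = seg(s, j)
                total = dp[m - 1, s] + c
                if total < dp[m, j]:
                    dp[m, j] = total
                    choice[m, j] = s
    medoids = []
    j = n
    for m in range(k, 0, -1):
        s = choice[m, j]
        medoids.append(seg(s, j)[1])
        j = s
    return np.array(sorted(medoids)), float(dp[k, n])


def _split_costs(sorted_rows: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cost and medoids of every contiguous 2-split of each sorted row.

    ``sorted_rows`` has shape ``(B, n)``; returns ``(cost, m1, m2)`` each of
    shape ``(B, n - 1)`` where split ``s`` puts the first ``s`` values in
    the lower cluster.  The medoid of a block is its lower median.
    """
    B, n = sorted_rows.shape
    S = np.concatenate(
        [np.zeros((B, 1)), np.cumsum(sorted_rows, axis=1)], axis=1
    )  # S[:, j] = sum of first j values
    s = np.arange(1, n)  # lower cluster sizes
    i1 = (s - 1) // 2  # lower-median index of block [0, s)
    i2 = s + (n - s - 1) // 2  # lower-median index of block [s, n)
    m1 = sorted_rows[:, i1]
    m2 = sorted_rows[:, i2]
    # L1 deviation of a sorted block [a, b) around element at index m:
    #   m_val*(m - a + 1) - sum(a..m)  +  sum(m+1..b-1) - m_val*(b - 1 - m)
    c1 = (m1 * (i1 + 1) - (S[:, i1 + 1] - S[:, 0][:, None])) + (
        (S[:, s] - S[:, i1 + 1]) - m1 * (s - i1 - 1)
    )
    c2 = (m2 * (i2 - s + 1) - (S[:, i2 + 1] - S[:, s])) + (
        (S[:, n][:, None] - S[:, i2 + 1]) - m2 * (n - 1 - i2)
    )
    return c1 + c2, m1, m2


def pam_k2_batch(samples: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact PAM (k = 2, 1-D) for a batch of samples.

    Parameters
    ----------
    samples
        Array of shape ``(B, n)``; each row is one sample (need not be
        sorted). Every row must contain at least two distinct values.

    Returns
    -------
    (m_low, m_high, cost)
        Arrays of shape ``(B,)``: the two medoids (ascending) and the
        optimal total cost of each row.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim == 1:
        samples = samples[None, :]
    sorted_rows = np.sort(samples, axis=1)
    cost, m1, m2 = _split_costs(sorted_rows)
    best = np.argmin(cost, axis=1)  # first minimum: lowest split wins ties
    rows = np.arange(samples.shape[0])
    return m1[rows, best], m2[rows, best], cost[rows, best]


def pam_fit_k2(values: Sequence[float]) -> ClusterAssignment:
    """Exact two-cluster PAM fit for one-dimensional data."""
    x = _validate(values, 2)
    m_low, m_high, _ = pam_k2_batch(x[None, :])
    medoids = np.array([m_low[0], m_high[0]])
    labels = np.argmin(np.abs(x[:, None] - medoids[None, :]), axis=1)
    cost = float(np.abs(x - medoids[labels]).sum())
    return ClusterAssignment(
        medoids=(float(medoids[0]), float(medoids[1])),
        labels=tuple(int(l) for l in labels),
        cost=cost,
    )


def assign_nearest_medoid(value: float, medoids: Sequence[float]) -> int:
    """Index of the medoid nearest to ``value``; exact ties go to the lower.

    ``medoids`` must be nonempty and ascending.
    """
    m = np.asarray(medoids, dtype=float)
    if m.size == 0:
        raise EmptyInputError("medoids must be nonempty")
    return int(np.argmin(np.abs(value - m)))


def clustering_cost(
    values: Sequence[float], labels: Sequence[int], medoids: Sequence[float]
) -> float:
    """Total within-cluster absolute deviation ``sum |x_i - medoid(label_i)|``."""
    x = np.asarray(values, dtype=float)
    lab = np.asarray(labels, dtype=int)
    m = np.asarray(medoids, dtype=float)
    if x.shape != lab.shape:
        raise ValueError("values and labels must have the same length")
    if lab.size and (lab.min() < 0 or lab.max() >= m.size):
        raise IndexError("label out of range of medoids")
    return float(np.abs(x - m[lab]).sum())
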