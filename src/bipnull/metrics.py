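"""Nestedness (NODF) and bipartite modularity (Barber Q) with optimization.

NODF ("nested overlap and decreasing fill", Almeida-Neto et al. 2008) scores
a binary matrix between 0 and 100 by averaging, over all row pairs and all
column pairs, the percentage overlap of the lower-fill member with the
higher-fill member — counting 0 whenever the two fills are equal (the
"decreasing fill" requirement) or the lower fill is zero.  The paired term
depends only on fills and overlaps, so no pre-sorting of the matrix is
needed even though the metric is usually illustrated on a sorted matrix.

Barber modularity generalizes Newman's Q to bipartite graphs:

    Q = (1/E) * sum_ij (a_ij - k_i d_j / E) * delta(g_i, h_j)

where the sum runs over plant-fungus pairs in the same module and
k_i d_j / E is the configuration-model expectation of the link.  The
optimizer searches partitions by alternating best-label sweeps (each row
node adopts the module with the largest Q gain given the column labels,
then vice versa — equivalent to a sequence of single-node moves because
moves within one layer do not interact), followed by greedy module merges,
repeated over seeded restarts.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .incidence import BipartiteIncidence, CoverageError, IncidenceError

__all__ = [
    "NestednessValue",
    "ModulePartition",
    "UndefinedMetricError",
    "nodf",
    "barber_q",
    "optimize_modularity",
]


class UndefinedMetricError(IncidenceError):
    """The metric is undefined for this matrix shape."""


# ---------------------------------------------------------------------------
# NODF
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class NestednessValue:
    """NODF score with its per-layer components.

    ``nodf`` equals ``(row_component * n_row_pairs + col_component *
    n_col_pairs) / (n_row_pairs + n_col_pairs)``; components are the mean
    paired terms within each layer (0 when a layer has fewer than 2 nodes).
    """

    nodf: float
    row_component: float
    col_component: float
    n_row_pairs: int
    n_col_pairs: int

    def __float__(self) -> float:
        return self.nodf


def _paired_sum(entries: np.ndarray) -> tuple[float, int]:
    """Sum of paired NODF terms over all unordered row pairs of ``entries``."""
    n = entries.shape[0]
    if n < 2:
        return 0.0, 0
    fills = entries.sum(axis=1, dtype=np.int64)
    overlap = entries @ entries.T  # shared 1-columns for each row pair
    iu, ju = np.triu_indices(n, k=1)
    fi, fj = fills[iu], fills[ju]
    lower = np.minimum(fi, fj)
    valid = (fi != fj) & (lower > 0)  # decreasing-fill rule; no 0/0
    terms = np.zeros(iu.shape[0])
    terms[valid] = 100.0 * overlap[iu, ju][valid] / lower[valid]
    return float(terms.sum()), n * (n - 1) // 2


def nodf(inc: BipartiteIncidence) -> NestednessValue:
    """Compute NODF nestedness of a binary incidence matrix.

    Raises
    ------
    UndefinedMetricError
        For a 1x1 matrix, where no pair exists in either layer.
    """
    if inc.n_rows < 2 and inc.n_cols < 2:
        raise UndefinedMetricError("NODF undefined for a single row and single column")
    entries = np.asarray(inc.entries, dtype=np.int64)
    row_sum, n_row_pairs = _paired_sum(entries)
    col_sum, n_col_pairs = _paired_sum(entries.T)
    total_pairs = n_row_pairs + n_col_pairs
    return NestednessValue(
        nodf=(row_sum + col_sum) / total_pairs,
        row_component=row_sum / n_row_pairs if n_row_pairs else 0.0,
        col_component=col_sum / n_col_pairs if n_col_pairs else 0.0,
        n_row_pairs=n_row_pairs,
        n_col_pairs=n_col_pairs,
    )


# ---------------------------------------------------------------------------
# Barber modularity
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class ModulePartition:
    """Assignment of every plant and fungal node to a module.

    ``row_modules`` / ``col_modules`` hold one integer module id per node,
    aligned with the incidence matrix the partition was built for.  ``q``
    is the Barber modularity of this partition on that matrix and
    ``n_modules`` the number of distinct non-empty modules.
    """

    row_modules: tuple[int, ...]
    col_modules: tuple[int, ...]
    q: float
    n_modules: int

    @classmethod
    def from_labels(
        cls,
        inc: BipartiteIncidence,
        row_modules: Sequence[int],
        col_modules: Sequence[int],
    ) -> "ModulePartition":
        """Build a partition from raw labels, computing Q on ``inc``."""
        rows, cols = _canonical_labels(np.asarray(row_modules), np.asarray(col_modules))
        q = _q_from_labels(inc, rows, cols)
        n_modules = len(set(rows.tolist()) | set(cols.tolist()))
        return cls(tuple(rows.tolist()), tuple(cols.tolist()), q, n_modules)

    @classmethod
    def single_module(cls, inc: BipartiteIncidence) -> "ModulePartition":
        return cls((0,) * inc.n_rows, (0,) * inc.n_cols, 0.0, 1)


def _canonical_labels(rows: np.ndarray, cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Relabel modules 0..M-1 by first appearance over rows then columns."""
    order: dict[int, int] = {}
    for lab in np.concatenate([rows, cols]).tolist():
        if lab not in order:
            order[lab] = len(order)
    remap = np.vectorize(order.__getitem__, otypes=[np.int64])
    return remap(rows), remap(cols)


def _q_from_labels(inc: BipartiteIncidence, rows: np.ndarray, cols: np.ndarray) -> float:
    """Barber Q via exact integer accumulation, divided once by E^2."""
    if len(rows) != inc.n_rows or len(cols) != inc.n_cols:
        raise CoverageError("partition does not cover every node")
    e = inc.n_links
    if e == 0:
        return 0.0
    entries = np.asarray(inc.entries, dtype=np.int64)
    k, d = inc.row_degrees, inc.col_degrees
    labels = sorted(set(rows.tolist()) | set(cols.tolist()))
    within = 0
    expect = 0
    for m in labels:
        rmask, cmask = rows == m, cols == m
        if rmask.any() and cmask.any():
            within += int(entries[np.ix_(rmask, cmask)].sum())
            expect += int(k[rmask].sum()) * int(d[cmask].sum())
    return float(within * e - expect) / float(e * e)


def barber_q(
    inc: BipartiteIncidence,
    partition: ModulePartition | tuple[Sequence[int], Sequence[int]],
) -> float:
    """Barber bipartite modularity of ``partition`` on ``inc``.

    Accepts a :class:`ModulePartition` or a raw ``(row_labels,
    col_labels)`` pair; invariant under relabeling of module ids.
    """
    if isinstance(partition, ModulePartition):
        rows = np.asarray(partition.row_modules)
        cols = np.asarray(partition.col_modules)
    else:
        rows, cols = (np.asarray(p) for p in partition)
    if inc.n_links == 0:
        raise IncidenceError("modularity requires at least one link")
    return _q_from_labels(inc, rows, cols)


# -- optimization -----------------------------------------------------------


def _sweep(
    entries: np.ndarray,
    k: np.ndarray,
    d: np.ndarray,
    e: int,
    rows: np.ndarray,
    cols: np.ndarray,
    n_slots: int,
) -> tuple[np.ndarray, np.ndarray]:
    """One alternating best-label pass: columns given rows, then rows."""
    onehot_r = np.zeros((len(rows), n_slots))
    onehot_r[np.arange(len(rows)), rows] = 1.0
    km = k @ onehot_r  # per-module row-degree mass
    score_c = entries.T @ onehot_r - np.outer(d, km) / e
    cols = np.argmax(score_c, axis=1)  # argmax tie-break: lowest module id

    onehot_c = np.zeros((len(cols), n_slots))
    onehot_c[np.arange(len(cols)), cols] = 1.0
    dm = d @ onehot_c
    score_r = entries @ onehot_c - np.outer(k, dm) / e
    rows = np.argmax(score_r, axis=1)
    return rows, cols


def _merge_modules(
    entries: np.ndarray,
    k: np.ndarray,
    d: np.ndarray,
    e: int,
    rows: np.ndarray,
    cols: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Greedily merge module pairs while Q strictly increases."""
    while True:
        labels = np.array(sorted(set(rows.tolist()) | set(cols.tolist())))
        m = len(labels)
        if m < 2:
            return rows, cols
        pos = {lab: i for i, lab in enumerate(labels)}
        ridx = np.array([pos[l] for l in rows.tolist()])
        cidx = np.array([pos[l] for l in cols.tolist()])
        oh_r = np.zeros((len(rows), m))
        oh_r[np.arange(len(rows)), ridx] = 1.0
        oh_c = np.zeros((len(cols), m))
        oh_c[np.arange(len(cols)), cidx] = 1.0
        link = oh_r.T @ entries @ oh_c  # links between rows(a) and cols(b)
        kr = k @ oh_r
        kc = d @ oh_c
        # gain of merging modules a and b (cross terms only)
        expect = np.outer(kr, kc)
        gain = (link + link.T - (expect + expect.T) / e) / e
        np.fill_diagonal(gain, -np.inf)
        a, b = np.unravel_index(np.argmax(gain), gain.shape)
        if gain[a, b] <= 1e-15:
            return rows, cols
        keep, drop = sorted((labels[a], labels[b]))
        rows = np.where(rows == drop, keep, rows)
        cols = np.where(cols == drop, keep, cols)


def _optimize_once(
    inc: BipartiteIncidence,
    rows0: np.ndarray,
    max_sweeps: int = 200,
) -> tuple[np.ndarray, np.ndarray, float]:
    entries = np.asarray(inc.entries, dtype=float)
    k = inc.row_degrees.astype(float)
    d = inc.col_degrees.astype(float)
    e = inc.n_links
    n_slots = int(rows0.max()) + 1
    rows = rows0.copy()
    cols = np.zeros(inc.n_cols, dtype=np.int64)
    best_q = -np.inf
    while True:
        for _ in range(max_sweeps):
            rows_new, cols_new = _sweep(entries, k, d, e, rows, cols, n_slots)
            if np.array_equal(rows_new, rows) and np.array_equal(cols_new, cols):
                break
            rows, cols = rows_new, cols_new
        q = _q_from_labels(inc, rows, cols)
        if q <= best_q + 1e-14:
            return rows, cols, best_q if best_q > -np.inf else q
        best_q = q
        rows, cols = _merge_modules(entries.astype(np.int64), k, d, e, rows, cols)
        q_merged = _q_from_labels(inc, rows, cols)
        if q_merged <= best_q + 1e-14:
            return rows, cols, best_q
        best_q = q_merged
        # re-relax after merging; slots shrink to current label range
        n_slots = int(max(rows.max(), cols.max())) + 1


def optimize_modularity(
    inc: BipartiteIncidence, n_restarts: int = 20, seed: int = 0
) -> ModulePartition:
    """Search for the partition maximizing Barber Q.

    Restart 0 starts from one module per plant node; subsequent restarts
    draw a random initial assignment of the plant layer into a random
    number of modules from a stream derived from ``(seed, restart)``.  The
    best partition over restarts is returned (ties keep the earliest),
    never with Q below the single-module baseline of 0.  Deterministic for
    fixed ``(inc, n_restarts, seed)``.
    """
    if inc.n_links == 0:
        return ModulePartition.single_module(inc)
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for restart in range(max(1, n_restarts)):
        if restart == 0:
            rows0 = np.arange(inc.n_rows, dtype=np.int64)
        else:
            rng = np.random.default_rng([seed, restart])
            n_mod = int(rng.integers(1, max(2, min(inc.n_rows, inc.n_cols) + 1)))
            rows0 = rng.integers(0, n_mod, size=inc.n_rows)
        rows, cols, q = _optimize_once(inc, rows0)
        if best is None or q > best[0] + 1e-14:
            best = (q, rows, cols)
    q, rows, cols = best
    if q < 0.0:
        return ModulePartition.single_module(inc)
    # degree-0 isolates carry no Q weight; give them singleton modules
    next_id = int(max(rows.max(), cols.max())) + 1
    for i in np.flatnonzero(inc.row_degrees == 0):
        rows[i] = next_id
        next_id += 1
    for j in np.flatnonzero(inc.col_degrees == 0):
        cols[j] = next_id
        next_id += 1
    return ModulePartition.from_labels(inc, rows, cols)
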