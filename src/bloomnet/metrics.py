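"""Structural metrics for weighted plant-visitor networks.

Implements the per-plot attribute set used throughout the pipeline:
visitor abundance and richness, unweighted/weighted degree, experiment-wide
connectance, NODF nestedness, size-corrected NODFc, and Barber's weighted
bipartite modularity Q.

NODF (nestedness based on overlap and decreasing fill) averages, over all
row pairs and all column pairs, the percentage overlap of the sparser
vector with the denser one, counting a pair only when its fills strictly
decrease.  NODFc divides the observed NODF by the maximum NODF achievable
at the same dimensions and link count and normalizes by fill and network
size, making nestedness comparable across networks of different sizes:

    NODFc = (NODF / max_NODF) / (C_fill * ln(sqrt(m * n)))

with C_fill = L / (m * n).  The max-NODF search is a greedy nested seed
followed by single-link relocation hill climbing, with exhaustive
enumeration on tiny matrices.

Modularity uses Barber's bipartite Q,

    Q = (1/F) * sum_ij (A_ij - k_i d_j / F) * delta(g_i, g_j),

maximized by weighted label propagation with module agglomeration and
seeded restarts (in the style of the DIRTLPAwb+ optimizer).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, asdict
from functools import lru_cache

import numpy as np

from .io import PlotNetwork

__all__ = [
    "PlotMetrics",
    "connectance_experiment_wide",
    "degrees",
    "nodf",
    "max_nodf",
    "nodfc",
    "bipartite_modularity",
    "barber_q",
    "compute_all",
]


@dataclass
class PlotMetrics:
    """One row of the per-network attribute table."""

    plot_id: str
    abundance: int
    plant_richness: int        # plants that bloomed in the plot (metadata)
    insect_richness: int       # insect species observed in the plot
    species_total: int         # plants + insects present in the network
    links: int
    unweighted_degree: float
    weighted_degree: float
    connectance: float
    nodf: float
    nodfc: float
    modularity: float
    i_total: int               # experiment-wide insect species richness

    def as_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# connectance and degrees
# ---------------------------------------------------------------------------

def connectance_experiment_wide(network: PlotNetwork, i_total: int) -> float:
    """Realized fraction of all potential interactions in a plot.

    The denominator is (plant species that *bloomed* in the plot) times the
    experiment-wide insect species pool, so a plot can realize links with
    species it never received and with plants that bloomed but were not
    visited.
    """
    p = network.meta.plants_bloomed
    if p == 0:
        raise ValueError(
            f"plot {network.meta.plot_id}: connectance undefined with 0 bloomed plants"
        )
    if i_total < len(network.insects):
        raise ValueError("i_total smaller than insects observed in the plot")
    if p < network.shape[0]:
        raise ValueError("plants_bloomed smaller than plants in the network")
    return network.n_links / (p * i_total)


def degrees(network: PlotNetwork) -> tuple[float, float]:
    """(unweighted degree, weighted degree) = (L/S, N_v/S).

    S counts plants plus insects actually present in the network.
    """
    s = sum(network.shape)
    return network.n_links / s, network.total_weight / s


# ---------------------------------------------------------------------------
# NODF
# ---------------------------------------------------------------------------

def _nodf_axis(b: np.ndarray) -> tuple[float, int]:
    """Sum of paired nestedness percentages over row pairs, and pair count."""
    fills = b.sum(axis=1)
    m = b.shape[0]
    if m < 2:
        return 0.0, 0
    overlap = b @ b.T  # shared presences for every row pair
    lo = np.minimum.outer(fills, fills).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        paired = np.where(lo > 0, 100.0 * overlap / lo, 0.0)
    distinct = fills[:, None] != fills[None, :]
    total = float((paired * distinct)[np.triu_indices(m, k=1)].sum())
    return total, m * (m - 1) // 2


def nodf(matrix: np.ndarray) -> float:
    """NODF of a presence/absence matrix, in [0, 100].

    Weighted matrices are binarized (A_ij > 0).  Pairs with equal fill
    contribute zero (strict decreasing-fill rule).
    """
    b = (np.asarray(matrix) > 0).astype(int)
    if b.ndim != 2:
        raise ValueError("matrix must be 2-D")
    if b.sum() == 0:
        raise ValueError("NODF undefined for an all-zero matrix")
    m, n = b.shape
    if m < 2 and n < 2:
        raise ValueError("NODF needs at least 2 rows or 2 columns")
    row_sum, row_pairs = _nodf_axis(b)
    col_sum, col_pairs = _nodf_axis(b.T)
    return (row_sum + col_sum) / (row_pairs + col_pairs)


# ---------------------------------------------------------------------------
# max-NODF
# ---------------------------------------------------------------------------

def _feasible(m: int, n: int, links: int) -> bool:
    return max(m, n) <= links <= m * n


def _greedy_nested_seed(m: int, n: int, links: int) -> np.ndarray:
    """A feasible starting matrix with exactly ``links`` ones, grown greedily
    toward nestedness.

    When the budget covers the maximally nested minimal cover (full first
    row and first column, m+n-1 links) the remaining links are added on the
    staircase frontier, which is where nested optima put them.  For smaller
    budgets the seed is a minimal cover (every row and column exactly once)
    and additions consider every empty cell.
    """
    b = np.zeros((m, n), dtype=int)
    if links >= m + n - 1:
        b[0, :] = 1
        b[:, 0] = 1
        frontier_only = True
    else:
        # minimal cover: one link per column, rows cycled so none is empty
        if n >= m:
            for j in range(n):
                b[min(j, m - 1) if j < m else 0, j] = 1
            for i in range(1, m):
                b[i, min(i, n - 1)] = 1
        else:
            for i in range(m):
                b[i, min(i, n - 1)] = 1
            for j in range(1, n):
                b[min(j, m - 1), j] = 1
        frontier_only = False
    placed = int(b.sum())
    while placed < links:
        if frontier_only:
            cand = [
                (i, j)
                for i in range(1, m)
                for j in range(1, n)
                if b[i, j] == 0 and b[i - 1, j] == 1 and b[i, j - 1] == 1
            ]
            if not cand:
                cand = [tuple(x) for x in np.argwhere(b == 0)]
        else:
            cand = [tuple(x) for x in np.argwhere(b == 0)]
        best, best_val = None, -1.0
        for (i, j) in cand:
            b[i, j] = 1
            val = nodf(b)
            b[i, j] = 0
            if val > best_val:
                best, best_val = (i, j), val
        b[best] = 1
        placed += 1
    while placed > links:  # minimal cover can overshoot tiny budgets
        removable = [
            (i, j)
            for (i, j) in map(tuple, np.argwhere(b == 1))
            if b[i].sum() > 1 and b[:, j].sum() > 1
        ]
        b[removable[-1]] = 0
        placed -= 1
    return b


def _hill_climb(b: np.ndarray, max_moves: int = 10_000) -> np.ndarray:
    """First-improvement single-link relocation until no improvement."""
    b = b.copy()
    current = nodf(b)
    moves = 0
    improved = True
    while improved and moves < max_moves:
        improved = False
        row_fill = b.sum(axis=1)
        col_fill = b.sum(axis=0)
        ones = [tuple(x) for x in np.argwhere(b == 1)]
        zeros = [tuple(x) for x in np.argwhere(b == 0)]
        for (i, j) in ones:
            for (p, q) in zeros:
                # the move must not leave the source row/column empty unless
                # the destination refills it
                if (row_fill[i] <= 1 and p != i) or (
                    col_fill[j] <= 1 and q != j
                ):
                    continue
                moves += 1
                b[i, j] = 0
                b[p, q] = 1
                val = nodf(b)
                if val > current + 1e-12:
                    current = val
                    improved = True
                    break
                b[p, q] = 0
                b[i, j] = 1
                if moves >= max_moves:
                    return b
            if improved:
                break
    return b


def _exhaustive_max_nodf(m: int, n: int, links: int) -> float:
    best = -1.0
    cells = list(itertools.product(range(m), range(n)))
    for combo in itertools.combinations(cells, links):
        b = np.zeros((m, n), dtype=int)
        for (i, j) in combo:
            b[i, j] = 1
        if (b.sum(axis=1) == 0).any() or (b.sum(axis=0) == 0).any():
            continue
        best = max(best, nodf(b))
    if best < 0:
        raise ValueError("no feasible matrix")
    return best


@lru_cache(maxsize=4096)
def max_nodf(n_rows: int, n_cols: int, n_links: int, exhaustive: bool | None = None) -> float:
    """Largest NODF achievable by any binary matrix of the given shape and
    link count in which every row and column has at least one link.

    Exhaustive enumeration when ``n_rows * n_cols <= 12`` (or forced via
    ``exhaustive=True``); otherwise greedy nested fill plus hill climbing.
    Deterministic: the heuristic uses no randomness.
    """
    if not _feasible(n_rows, n_cols, n_links):
        raise ValueError(
            f"infeasible: need max(m,n) <= L <= m*n, got "
            f"m={n_rows}, n={n_cols}, L={n_links}"
        )
    if n_rows < 2 and n_cols < 2:
        raise ValueError("max_nodf needs at least 2 rows or 2 columns")
    if exhaustive is None:
        exhaustive = n_rows * n_cols <= 12
    if exhaustive:
        return _exhaustive_max_nodf(n_rows, n_cols, n_links)
    b = _greedy_nested_seed(n_rows, n_cols, n_links)
    b = _hill_climb(b)
    return nodf(b)


def nodfc(network: PlotNetwork | np.ndarray) -> float:
    """Size- and fill-corrected nestedness.

    NODFc = (NODF / max_NODF) / (C_fill * ln(sqrt(m*n))) where C_fill is
    the within-matrix fill L/(m*n).  Invariant under transposition.
    """
    b = network.binary() if isinstance(network, PlotNetwork) else (
        (np.asarray(network) > 0).astype(int)
    )
    m, n = b.shape
    links = int(b.sum())
    s_geom = np.sqrt(m * n)
    if s_geom <= 1:
        raise ValueError("NODFc undefined for networks with sqrt(m*n) <= 1")
    c_fill = links / (m * n)
    best = max_nodf(m, n, links)
    # a zero maximum (e.g. permutation-matrix fills) forces NODF = 0 too
    ratio = nodf(b) / best if best > 0 else 0.0
    return ratio / (c_fill * np.log(s_geom))


# ---------------------------------------------------------------------------
# Barber bipartite modularity
# ---------------------------------------------------------------------------

def barber_q(
    matrix: np.ndarray, row_labels: np.ndarray, col_labels: np.ndarray
) -> float:
    """Evaluate Barber's bipartite modularity for a given partition."""
    a = np.asarray(matrix, dtype=float)
    f = a.sum()
    if f <= 0:
        raise ValueError("empty network")
    k = a.sum(axis=1)
    d = a.sum(axis=0)
    bbar = a - np.outer(k, d) / f
    same = row_labels[:, None] == col_labels[None, :]
    return float(bbar[same].sum() / f)


def _propagate(bbar: np.ndarray, row_lab, col_lab, rng, max_sweeps: int = 200):
    """Alternating best-label sweeps; each move cannot decrease Q."""
    m, n = bbar.shape
    for _ in range(max_sweeps):
        changed = False
        labels = np.unique(np.concatenate([row_lab, col_lab]))
        # score of row i joining label l = sum of bbar[i, j] over cols with label l
        col_mask = col_lab[None, :] == labels[:, None]          # (L, n)
        row_scores = bbar @ col_mask.T                          # (m, L)
        for i in rng.permutation(m):
            best = labels[int(np.argmax(row_scores[i]))]
            if row_scores[i, int(np.argmax(row_scores[i]))] > row_scores[
                i, int(np.where(labels == row_lab[i])[0][0])
            ] + 1e-12:
                row_lab[i] = best
                changed = True
        row_mask = row_lab[None, :] == labels[:, None]          # (L, m)
        col_scores = bbar.T @ row_mask.T                        # (n, L)
        for j in rng.permutation(n):
            best = labels[int(np.argmax(col_scores[j]))]
            if col_scores[j, int(np.argmax(col_scores[j]))] > col_scores[
                j, int(np.where(labels == col_lab[j])[0][0])
            ] + 1e-12:
                col_lab[j] = best
                changed = True
        if not changed:
            break
    return row_lab, col_lab


def _agglomerate(bbar: np.ndarray, row_lab, col_lab):
    """Merge module pairs while any merge increases Q."""
    while True:
        labels = np.unique(np.concatenate([row_lab, col_lab]))
        if len(labels) < 2:
            return row_lab, col_lab
        # cross-module Barber weight: gain of merging la and lb
        best_gain, best_pair = 0.0, None
        for ia, la in enumerate(labels):
            ra = row_lab == la
            ca = col_lab == la
            for lb in labels[ia + 1:]:
                rb = row_lab == lb
                cb = col_lab == lb
                gain = bbar[np.ix_(ra, cb)].sum() + bbar[np.ix_(rb, ca)].sum()
                if gain > best_gain + 1e-12:
                    best_gain, best_pair = gain, (la, lb)
        if best_pair is None:
            return row_lab, col_lab
        la, lb = best_pair
        row_lab[row_lab == lb] = la
        col_lab[col_lab == lb] = la


def bipartite_modularity(
    network: PlotNetwork | np.ndarray, seed: int = 0, restarts: int = 20
) -> tuple[float, tuple[np.ndarray, np.ndarray]]:
    """Maximize Barber's weighted bipartite modularity.

    Weighted label propagation with module agglomeration, repeated from
    ``restarts`` seeded initial states; returns the best (Q, partition).
    Ties in Q break toward the partition with fewer modules.  Deterministic
    for a given seed.
    """
    a = np.asarray(
        network.matrix if isinstance(network, PlotNetwork) else network, dtype=float
    )
    if a.size == 0 or a.sum() <= 0:
        raise ValueError("empty network")
    m, n = a.shape
    f = a.sum()
    k = a.sum(axis=1)
    d = a.sum(axis=0)
    bbar = a - np.outer(k, d) / f

    master = np.random.default_rng(seed)
    best_q, best_part, best_nmod = -np.inf, None, np.inf
    for _ in range(max(1, restarts)):
        rng = np.random.default_rng(master.integers(2**31))
        row_lab = np.arange(m)
        # each column adopts the row label with the largest Barber affinity
        col_lab = np.argmax(bbar, axis=0).astype(int)
        row_lab, col_lab = _propagate(bbar, row_lab, col_lab, rng)
        row_lab, col_lab = _agglomerate(bbar, row_lab, col_lab)
        row_lab, col_lab = _propagate(bbar, row_lab, col_lab, rng)
        q = barber_q(a, row_lab, col_lab)
        nmod = len(np.unique(np.concatenate([row_lab, col_lab])))
        if q > best_q + 1e-12 or (abs(q - best_q) <= 1e-12 and nmod < best_nmod):
            best_q, best_part, best_nmod = q, (row_lab.copy(), col_lab.copy()), nmod
    # the single-module partition (Q = 0) is always admissible
    if best_q < 0:
        best_q = 0.0
        best_part = (np.zeros(m, dtype=int), np.zeros(n, dtype=int))
    return float(best_q), best_part


# ---------------------------------------------------------------------------
# one-call summary
# ---------------------------------------------------------------------------

def compute_all(
    network: PlotNetwork,
    i_total: int,
    seed: int = 0,
    restarts: int = 20,
    include_nodfc: bool = True,
) -> PlotMetrics:
    """All structural metrics for one plot network, as a table row."""
    uw, w = degrees(network)
    q, _ = bipartite_modularity(network, seed=seed, restarts=restarts)
    return PlotMetrics(
        plot_id=network.meta.plot_id,
        abundance=network.total_weight,
        plant_richness=network.meta.plants_bloomed,
        insect_richness=len(network.insects),
        species_total=sum(network.shape),
        links=network.n_links,
        unweighted_degree=uw,
        weighted_degree=w,
        connectance=connectance_experiment_wide(network, i_total),
        nodf=nodf(network.matrix),
        nodfc=nodfc(network) if include_nodfc else float("nan"),
        modularity=q,
        i_total=i_total,
    )
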