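"""Overlap-weighted tick-host networks: nestedness, modularity, significance.

A directed bipartite network (tick -> host) is built from a Jaccard overlap
matrix: an edge exists wherever the overlap exceeds a threshold, and its
weight is the overlap percentage.

Nestedness uses the NODF family: for each ordered pair of rows (and of
columns) with strictly decreasing marginal totals, the paired overlap is
the percentage of the sparser line's interactions also present in the
denser line; pairs with equal totals contribute zero, and NODF is the mean
paired overlap over all row and column pairs.  The weighted variant
(WNODF) additionally requires the sparser line's weights to be strictly
smaller cell-wise.

Modularity is Barber's bipartite Q, maximized by seeded label propagation
with restarts.  Statistical significance of a metric comes from a
proportional-fill null model; a classical Mantel permutation test is
provided for comparing two distance matrices.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .niche import OverlapMatrix


@dataclass
class TickHostNetwork:
    """Directed weighted bipartite graph plus its incidence-matrix view."""

    ecosystem_id: int
    incidence: pd.DataFrame  # ticks x hosts, weight or 0 (undefined -> 0)
    edge_threshold: float = 0.0
    graph: nx.DiGraph = field(default=None)

    def __post_init__(self) -> None:
        if self.graph is None:
            g = nx.DiGraph()
            g.add_nodes_from(self.incidence.index, bipartite="tick")
            g.add_nodes_from(self.incidence.columns, bipartite="host")
            for t in self.incidence.index:
                for h in self.incidence.columns:
                    w = self.incidence.loc[t, h]
                    if w > 0:
                        g.add_edge(t, h, weight=float(w))
            self.graph = g

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def weight_matrix(self) -> np.ndarray:
        return self.incidence.to_numpy(dtype=float)


@dataclass
class NetworkStats:
    """Observed metric with its null distribution summary."""

    metric: str
    observed: float
    null_mean: float
    null_sd: float
    z: float
    p_value: float
    n_null: int
    seed: int


def build_network(matrix: OverlapMatrix, edge_threshold: float = 0.0) -> TickHostNetwork:
    """Edges for every defined overlap strictly above the threshold.

    Isolated nodes are retained so network size reflects the community.
    """
    if matrix.values.size == 0:
        raise ValueError("empty overlap matrix")
    weights = matrix.values.where(matrix.defined, 0.0).fillna(0.0)
    weights = weights.where(weights > edge_threshold, 0.0)
    return TickHostNetwork(
        ecosystem_id=matrix.ecosystem_id,
        incidence=weights,
        edge_threshold=edge_threshold,
    )


# ---------------------------------------------------------------------------
# Nestedness
# ---------------------------------------------------------------------------


def _binary_pair_sums(M: np.ndarray) -> tuple[float, int]:
    """Sum of paired NODF row terms and the number of row pairs.

    For the ordered pair (denser, sparser) with strictly decreasing totals
    the paired term is 100 * shared / total(sparser); equal totals give 0.
    """
    T = M @ M.T  # shared interactions per row pair
    tot = M.sum(axis=1)
    decreasing = tot[:, None] > tot[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(decreasing, 100.0 * T / tot[None, :], 0.0)
    n = M.shape[0]
    return float(terms[~np.eye(n, dtype=bool)].sum()), n * (n - 1) // 2


def nodf(matrix: np.ndarray) -> float:
    """NODF nestedness of a binary incidence matrix, in [0, 100].

    Rows and columns that are entirely zero are removed first.  Because a
    pair only contributes when its marginal totals strictly decrease, the
    result is equivalent to pre-sorting by decreasing totals and invariant
    to row/column permutations of the input.  An all-zero matrix is
    undefined (NaN).
    """
    M = (np.asarray(matrix, dtype=float) > 0).astype(float)
    M = M[M.sum(axis=1) > 0][:, M.sum(axis=0) > 0]
    if M.size == 0:
        return float("nan")
    if M.shape[0] < 2 or M.shape[1] < 2:
        raise ValueError("need at least 2 non-empty rows and columns")
    rs, rn = _binary_pair_sums(M)
    cs, cn = _binary_pair_sums(M.T)
    return float((rs + cs) / (rn + cn))


def _weighted_pair_sums(W: np.ndarray) -> tuple[float, int]:
    A = W > 0
    fills = A.sum(axis=1)
    # qualifying[i, j] = cells where sparser row j is nonzero and strictly
    # smaller than denser row i (strict inequality already implies W[i] > 0)
    qual = ((W[:, None, :] > W[None, :, :]) & A[None, :, :]).sum(axis=2)
    decreasing = fills[:, None] > fills[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(decreasing, 100.0 * qual / fills[None, :], 0.0)
    n = W.shape[0]
    return float(terms[~np.eye(n, dtype=bool)].sum()), n * (n - 1) // 2


def wnodf(matrix: np.ndarray) -> float:
    """Weighted NODF: paired terms require presence and strictly smaller weights.

    A cell of the sparser line qualifies when the denser line's cell is
    nonzero *and* strictly larger; ties never qualify, so a uniform-weight
    matrix scores 0.
    """
    W = np.asarray(matrix, dtype=float)
    W = W[(W > 0).sum(axis=1) > 0][:, (W > 0).sum(axis=0) > 0]
    if W.size == 0:
        return float("nan")
    if W.shape[0] < 2 or W.shape[1] < 2:
        raise ValueError("need at least 2 non-empty rows and columns")
    rs, rn = _weighted_pair_sums(W)
    cs, cn = _weighted_pair_sums(W.T)
    return float((rs + cs) / (rn + cn))


# ---------------------------------------------------------------------------
# Barber bipartite modularity
# ---------------------------------------------------------------------------


def barber_q(W: np.ndarray, row_labels: np.ndarray, col_labels: np.ndarray) -> float:
    """Barber's bipartite modularity Q of a given module assignment.

    Q = (1/m) sum_ij (A_ij - k_i d_j / m) delta(g_i, g_j) with m the total
    edge weight, k and d the row/column strengths.
    """
    W = np.asarray(W, dtype=float)
    m = W.sum()
    if m <= 0:
        raise ValueError("network has no edges")
    B = W - np.outer(W.sum(axis=1), W.sum(axis=0)) / m
    same = row_labels[:, None] == col_labels[None, :]
    return float((B * same).sum() / m)


def bipartite_modularity(
    net: TickHostNetwork | np.ndarray, seed: int = 0, n_restarts: int = 20
) -> tuple[float, dict[str, int]]:
    """Maximize Barber Q by label propagation with seeded random restarts.

    Each restart assigns random initial modules, then alternately moves each
    row and column node to the module maximizing its modularity
    contribution (ties to the lowest label, fixed iteration order) until no
    move improves.  The best restart wins; reproducibility is preferred over
    global optimality.
    """
    if isinstance(net, TickHostNetwork):
        W = net.weight_matrix()
        row_names = list(net.incidence.index)
        col_names = list(net.incidence.columns)
    else:
        W = np.asarray(net, dtype=float)
        row_names = [f"r{i}" for i in range(W.shape[0])]
        col_names = [f"c{j}" for j in range(W.shape[1])]
    m = W.sum()
    if m <= 0:
        raise ValueError("network has no edges")
    nr, nc = W.shape
    B = W - np.outer(W.sum(axis=1), W.sum(axis=0)) / m
    n_modules = min(nr, nc)
    rng = np.random.default_rng(seed)
    best_q, best_rows, best_cols = -np.inf, None, None
    for _ in range(max(1, n_restarts)):
        rows = rng.integers(n_modules, size=nr)
        cols = rng.integers(n_modules, size=nc)
        for _ in range(200):
            changed = False
            for i in range(nr):
                gains = np.zeros(n_modules)
                for lab in range(n_modules):
                    gains[lab] = B[i, cols == lab].sum()
                new = int(np.argmax(gains))  # argmax takes the lowest on ties
                if new != rows[i] and gains[new] > gains[rows[i]]:
                    rows[i] = new
                    changed = True
            for j in range(nc):
                gains = np.zeros(n_modules)
                for lab in range(n_modules):
                    gains[lab] = B[rows == lab, j].sum()
                new = int(np.argmax(gains))
                if new != cols[j] and gains[new] > gains[cols[j]]:
                    cols[j] = new
                    changed = True
            if not changed:
                break
        q = barber_q(W, rows, cols)
        if q > best_q:
            best_q, best_rows, best_cols = q, rows.copy(), cols.copy()
    partition = {name: int(lab) for name, lab in zip(row_names, best_rows)}
    partition.update({name: int(lab) for name, lab in zip(col_names, best_cols)})
    return best_q, partition


def brute_force_modularity(W: np.ndarray, max_modules: int | None = None) -> float:
    """Exhaustive Barber-Q maximum over all module assignments (tiny networks)."""
    W = np.asarray(W, dtype=float)
    nr, nc = W.shape
    k = max_modules or min(nr, nc)
    best = -np.inf
    for rows in itertools.product(range(k), repeat=nr):
        for cols in itertools.product(range(k), repeat=nc):
            q = barber_q(W, np.array(rows), np.array(cols))
            best = max(best, q)
    return best


# ---------------------------------------------------------------------------
# Null-model significance
# ---------------------------------------------------------------------------


def proportional_probabilities(M: np.ndarray) -> np.ndarray:
    """Cell probabilities p_ij = (r_i/C + c_j/R)/2 of the proportional null.

    r_i and c_j are the row and column incidence counts of M; R and C the
    matrix dimensions (the Bascompte proportional-fill null).
    """
    B = (np.asarray(M) > 0).astype(float)
    R, C = B.shape
    return (B.sum(axis=1)[:, None] / C + B.sum(axis=0)[None, :] / R) / 2.0


def proportional_null(
    M: np.ndarray, rng: np.random.Generator, probabilities: np.ndarray | None = None
) -> np.ndarray:
    """One binary null matrix drawn cell-wise from the proportional model."""
    p = proportional_probabilities(M) if probabilities is None else probabilities
    return (rng.random(p.shape) < p).astype(float)


def _metric_value(M: np.ndarray, metric: str, seed: int) -> float:
    if metric == "nodf":
        return nodf(M)
    if metric == "wnodf":
        return wnodf(M)
    if metric == "modularity":
        q, _ = bipartite_modularity(M, seed=seed, n_restarts=5)
        return q
    raise ValueError(f"unknown metric {metric!r}")


def null_significance(
    matrix: np.ndarray,
    metric: str = "nodf",
    n_null: int = 999,
    model: str = "proportional",
    seed: int = 0,
    probabilities: np.ndarray | None = None,
) -> NetworkStats:
    """Permutation-style significance of a network metric under the null.

    By default the null's cell probabilities are estimated from the
    observed matrix's margins (a plug-in null, slightly conservative
    because margin noise inflates null nestedness); passing
    ``probabilities`` tests against a fully specified proportional null
    instead, under which the Monte-Carlo p-value is exactly uniform.

    Weighted metrics keep the observed positive weights: each null draws a
    binary structure from the proportional model and fills its cells by
    resampling the observed weights with replacement.  The p-value uses the
    add-one correction p = (1 + #{null >= observed}) / (n_null + 1), so it
    can never be exactly zero.
    """
    if n_null < 99:
        raise ValueError("need at least 99 null replicates")
    if model != "proportional":
        raise ValueError(f"unknown null model {model!r}")
    M = np.asarray(matrix, dtype=float)
    observed = _metric_value(M, metric, seed)
    rng = np.random.default_rng(seed)
    weights = M[M > 0]
    nulls = np.empty(n_null)
    for b in range(n_null):
        N = proportional_null(M, rng, probabilities=probabilities)
        if metric in ("wnodf", "modularity") and weights.size:
            fill = N > 0
            N = N.copy()
            N[fill] = rng.choice(weights, size=int(fill.sum()), replace=True)
        try:
            nulls[b] = _metric_value(N, metric, seed=seed + b + 1)
        except (ValueError, FloatingPointError):
            nulls[b] = np.nan
    ok = ~np.isnan(nulls)
    null_mean = float(np.mean(nulls[ok])) if ok.any() else float("nan")
    null_sd = float(np.std(nulls[ok], ddof=1)) if ok.sum() > 1 else float("nan")
    z = (observed - null_mean) / null_sd if null_sd and null_sd > 0 else float("nan")
    p = (1 + np.sum(nulls[ok] >= observed)) / (ok.sum() + 1)
    return NetworkStats(
        metric=metric,
        observed=float(observed),
        null_mean=null_mean,
        null_sd=null_sd,
        z=float(z),
        p_value=float(p),
        n_null=n_null,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------


def _upper(d: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(d.shape[0], k=1)
    return d[iu]


def mantel(
    d1: np.ndarray,
    d2: np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
    alternative: str = "two-sided",
    exact: bool = False,
) -> tuple[float, float]:
    """Mantel permutation test between two distance matrices.

    r is the Pearson correlation of the upper-triangle entries; the null
    distribution permutes rows and columns of d2 simultaneously.  With
    ``exact=True`` all n! relabelings are enumerated (small n only) and the
    p-value is the exact permutation tail; otherwise ``n_perm`` random
    permutations with the add-one correction.
    """
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    n = d1.shape[0]
    if d1.shape != (n, n) or d2.shape != (n, n):
        raise ValueError("distance matrices must be square and equal-sized")
    if n < 4:
        raise ValueError("need at least 4 objects")
    for d in (d1, d2):
        if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0):
            raise ValueError("matrices must be symmetric with zero diagonals")
    x = _upper(d1)
    y = _upper(d2)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant off-diagonal entries: r undefined")
    r_obs = float(np.corrcoef(x, y)[0, 1])

    def perm_r(perm: np.ndarray) -> float:
        return float(np.corrcoef(x, _upper(d2[np.ix_(perm, perm)]))[0, 1])

    def tail(r_perm: float) -> bool:
        if alternative == "two-sided":
            return abs(r_perm) >= abs(r_obs) - 1e-12
        if alternative == "greater":
            return r_perm >= r_obs - 1e-12
        if alternative == "less":
            return r_perm <= r_obs + 1e-12
        raise ValueError(f"unknown alternative {alternative!r}")

    if exact:
        perms = list(itertools.permutations(range(n)))
        hits = sum(tail(perm_r(np.array(p))) for p in perms)
        return r_obs, hits / len(perms)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        hits += tail(perm_r(rng.permutation(n)))
    return r_obs, (1 + hits) / (n_perm + 1)
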