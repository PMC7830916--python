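"""Graph-theory metrics on binary brain networks.

Efficiency metrics follow the standard formalism for possibly disconnected
graphs: unreachable pairs contribute an inverse distance of zero.

- global efficiency: mean of 1/d(i,j) over ordered node pairs;
- local efficiency: mean over nodes of the global efficiency of the
  subgraph induced by the node's neighbors (nodes with fewer than two
  neighbors contribute 0);
- nodal efficiency: per node, the mean of 1/d(i,j) over all other nodes
  (harmonic form, finite on disconnected graphs);
- nodal degree: row sums of the adjacency;
- betweenness centrality (optional, not in the default pipeline): Brandes
  accumulation, counted in unordered source-target pairs.

Global metrics are normalized against the mean of an ensemble of
degree-preserving random networks obtained by double-edge swaps, and every
metric curve over the sparsity grid is summarized by its trapezoidal area
under the curve (AUC).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit

from .connectivity import BinaryNetworkStack

#: Default size of the degree-preserving null ensemble.
N_NULL_DEFAULT = 100


def _as_adj(adj: np.ndarray) -> np.ndarray:
    a = np.asarray(adj)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    return a.astype(bool)


def shortest_paths(adj: np.ndarray) -> np.ndarray:
    """Hop-count distance matrix via level-synchronous BFS from all nodes.

    Implemented as repeated boolean matrix products: after k products the
    reachability matrix covers all paths of length ≤ k, and each newly
    reached pair gets distance k. Unreachable pairs are inf.
    """
    a = _as_adj(adj)
    n = a.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    if not a.any():
        return d
    a8 = a.astype(np.uint8)
    reach = np.eye(n, dtype=bool)
    frontier = a & ~reach
    k = 1
    while frontier.any():
        d[frontier] = k
        reach |= frontier
        nxt = (reach.astype(np.uint8) @ a8) > 0
        frontier = nxt & ~reach
        k += 1
    return d


def _efficiency_from_distances(d: np.ndarray) -> float:
    n = d.shape[0]
    if n < 2:
        return 0.0
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def global_efficiency(adj: np.ndarray) -> float:
    """Mean inverse shortest-path length over ordered node pairs, in [0, 1]."""
    return _efficiency_from_distances(shortest_paths(adj))


def local_efficiency(adj: np.ndarray) -> float:
    """Mean over nodes of the neighbor-subgraph global efficiency."""
    a = _as_adj(adj)
    n = a.shape[0]
    if n < 2:
        return 0.0
    total = 0.0
    for i in range(n):
        nbrs = np.flatnonzero(a[i])
        if nbrs.size < 2:
            continue
        total += global_efficiency(a[np.ix_(nbrs, nbrs)])
    return total / n


def nodal_degree(adj: np.ndarray) -> np.ndarray:
    """Number of links attached to each node."""
    return _as_adj(adj).sum(axis=1).astype(int)


def nodal_efficiency(adj: np.ndarray) -> np.ndarray:
    """Per node, mean inverse distance to every other node (1/inf = 0)."""
    a = _as_adj(adj)
    n = a.shape[0]
    if n < 2:
        return np.zeros(n)
    d = shortest_paths(a)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return inv.sum(axis=1) / (n - 1)


def betweenness_centrality(adj: np.ndarray) -> np.ndarray:
    """Shortest-path betweenness (Brandes), in unordered pair units.

    Excluded from the default pipeline; exposed as an optional metric.
    """
    a = _as_adj(adj)
    n = a.shape[0]
    neighbors = [np.flatnonzero(a[i]) for i in range(n)]
    bc = np.zeros(n)
    for s in range(n):
        sigma = np.zeros(n)
        sigma[s] = 1.0
        dist = np.full(n, -1)
        dist[s] = 0
        preds: list[list[int]] = [[] for _ in range(n)]
        order = [s]
        queue = [s]
        while queue:
            nxt: list[int] = []
            for v in queue:
                for w in neighbors[v]:
                    if dist[w] == -1:
                        dist[w] = dist[v] + 1
                        nxt.append(w)
                    if dist[w] == dist[v] + 1:
                        sigma[w] += sigma[v]
                        preds[w].append(v)
            order.extend(nxt)
            queue = nxt
        delta = np.zeros(n)
        for w in reversed(order):
            for v in preds[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    return bc / 2.0  # each unordered pair counted from both endpoints


@njit(cache=False)
def _swap_kernel(adj, edges, pairs, flips, target):  # pragma: no cover - jitted
    swaps = 0
    for k in range(pairs.shape[0]):
        if swaps >= target:
            break
        e1 = pairs[k, 0]
        e2 = pairs[k, 1]
        if e1 == e2:
            continue
        x1, y1 = edges[e1, 0], edges[e1, 1]
        x2, y2 = edges[e2, 0], edges[e2, 1]
        if flips[k]:
            x2, y2 = y2, x2
        # propose (x1, y2) and (x2, y1)
        if x1 == y2 or x2 == y1 or x1 == x2 or y1 == y2:
            continue
        if adj[x1, y2] or adj[x2, y1]:
            continue
        adj[x1, y1] = adj[y1, x1] = False
        adj[x2, y2] = adj[y2, x2] = False
        adj[x1, y2] = adj[y2, x1] = True
        adj[x2, y1] = adj[y1, x2] = True
        edges[e1, 0], edges[e1, 1] = x1, y2
        edges[e2, 0], edges[e2, 1] = x2, y1
        swaps += 1
    return swaps


def rewire_preserving_degree(
    adj: np.ndarray,
    n_swaps: int | None = None,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Degree-preserving randomization by repeated double-edge swaps.

    Picks two edges (a, b), (c, d) and rewires them to (a, d), (c, b) when
    that creates neither self-loops nor multi-edges. Defaults to
    10 × edge-count attempted successful swaps; if no valid swap can be
    found the input is returned unchanged with a warning.
    """
    a = _as_adj(adj)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    iu, ju = np.nonzero(np.triu(a, k=1))
    m = iu.size
    if m < 2:
        warnings.warn("fewer than 2 edges; cannot rewire", RuntimeWarning)
        return a.copy()
    edges = np.column_stack([iu, ju]).astype(np.int64)
    adj_out = a.copy()
    target = 10 * m if n_swaps is None else int(n_swaps)
    max_attempts = max(100, 20 * target)
    # randomness is drawn up front so the jitted kernel stays deterministic
    pairs = rng.integers(0, m, size=(max_attempts, 2))
    flips = rng.random(max_attempts) < 0.5
    swaps = _swap_kernel(adj_out, edges, pairs, flips, target)
    if swaps == 0:
        warnings.warn("no valid double-edge swap found; returning input", RuntimeWarning)
        return a.copy()
    return adj_out


@dataclass
class MetricCurve:
    """A metric's values over the sparsity grid; NaN marks missing points."""

    name: str
    grid: np.ndarray
    values: np.ndarray

    @property
    def auc(self) -> float:
        return auc_over_sparsity(self.values, self.grid)


@dataclass
class NullEnsemble:
    """Global-metric values of degree-preserving random networks."""

    e_glob: np.ndarray  # (n_sparsity, n_null)
    e_loc: np.ndarray  # (n_sparsity, n_null)


def auc_over_sparsity(values: np.ndarray, grid: np.ndarray) -> float:
    """Trapezoidal integral of a metric curve over the non-missing grid."""
    values = np.asarray(values, dtype=float)
    grid = np.asarray(grid, dtype=float)
    ok = np.isfinite(values)
    if ok.sum() < 2:
        return float("nan")
    return float(np.trapezoid(values[ok], grid[ok]))


def normalize_global(real: np.ndarray, null_values: np.ndarray) -> np.ndarray:
    """real / mean(null) per grid point; zero null mean → NaN (missing)."""
    null_mean = np.asarray(null_values, dtype=float).mean(axis=-1)
    real = np.asarray(real, dtype=float)
    out = np.full_like(real, np.nan)
    ok = null_mean != 0
    out[ok] = real[ok] / null_mean[ok]
    return out


def build_null_ensemble(
    stack: BinaryNetworkStack,
    n_null: int = N_NULL_DEFAULT,
    seed: int = 0,
) -> NullEnsemble:
    """Rewired-network global metrics at every sparsity point."""
    n_s = len(stack.grid)
    e_glob = np.zeros((n_s, n_null))
    e_loc = np.zeros((n_s, n_null))
    for k in range(n_s):
        adj = stack.adjacency[k]
        for j in range(n_null):
            rng = np.random.default_rng(np.random.SeedSequence([seed, k, j]))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                null = rewire_preserving_degree(adj, seed=rng)
            e_glob[k, j] = global_efficiency(null)
            e_loc[k, j] = local_efficiency(null)
    return NullEnsemble(e_glob=e_glob, e_loc=e_loc)


@dataclass
class SubjectMetrics:
    """All metric curves (and AUCs) for one subject/chromophore stack."""

    grid: np.ndarray
    e_glob: MetricCurve
    e_loc: MetricCurve
    e_glob_norm: MetricCurve | None
    e_loc_norm: MetricCurve | None
    degree: np.ndarray  # (n_channels, n_sparsity)
    nodal_eff: np.ndarray  # (n_channels, n_sparsity)
    betweenness: np.ndarray | None = None

    def nodal_auc(self, which: str) -> np.ndarray:
        curves = {"degree": self.degree, "nodal_efficiency": self.nodal_eff}[which]
        return np.array([auc_over_sparsity(row, self.grid) for row in curves])


def compute_subject_metrics(
    stack: BinaryNetworkStack,
    n_null: int = N_NULL_DEFAULT,
    seed: int = 0,
    include_betweenness: bool = False,
) -> SubjectMetrics:
    """Raw + null-normalized global curves and nodal curves for one stack.

    ``n_null=0`` skips the null ensemble (normalized curves are None).
    Nodal degree and efficiency enter downstream statistics as raw AUC
    values; only the global metrics are null-normalized.
    """
    n_s = len(stack.grid)
    n = stack.n_nodes
    eg = np.zeros(n_s)
    el = np.zeros(n_s)
    deg = np.zeros((n, n_s))
    neff = np.zeros((n, n_s))
    btw = np.zeros((n, n_s)) if include_betweenness else None
    for k in range(n_s):
        adj = stack.adjacency[k]
        eg[k] = global_efficiency(adj)
        el[k] = local_efficiency(adj)
        deg[:, k] = nodal_degree(adj)
        neff[:, k] = nodal_efficiency(adj)
        if btw is not None:
            btw[:, k] = betweenness_centrality(adj)
    grid = stack.grid
    e_glob_norm = e_loc_norm = None
    if n_null > 0:
        nulls = build_null_ensemble(stack, n_null=n_null, seed=seed)
        e_glob_norm = MetricCurve("E_glob_norm", grid, normalize_global(eg, nulls.e_glob))
        e_loc_norm = MetricCurve("E_loc_norm", grid, normalize_global(el, nulls.e_loc))
    return SubjectMetrics(
        grid=grid,
        e_glob=MetricCurve("E_glob", grid, eg),
        e_loc=MetricCurve("E_loc", grid, el),
        e_glob_norm=e_glob_norm,
        e_loc_norm=e_loc_norm,
        degree=deg,
        nodal_eff=neff,
        betweenness=btw,
    )
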