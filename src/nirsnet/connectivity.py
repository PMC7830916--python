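"""Functional connectivity matrices and sparsity-thresholded binary networks.

Channel-pair Pearson correlations are Fisher z-transformed; only positive
z values can become edges. A proportional (sparsity) threshold sweep from
1% to 50% of the 48·47/2 = 1128 possible edges, in 1% steps, converts each
z matrix into a nested stack of binary adjacency matrices: at sparsity S
the strongest round(S · 1128) positive edges are kept, with z ties broken
deterministically by the lower (channel_i, channel_j) pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .series import HemoglobinSeries

#: Default proportional-threshold grid: 1%..50% in 1% steps.
SPARSITY_GRID = np.round(np.arange(1, 51) * 0.01, 2)


@dataclass
class ConnectivityMatrix:
    r: np.ndarray  # 48×48 symmetric Pearson r
    z: np.ndarray  # Fisher z = atanh(r), zero diagonal
    chromophore: str = ""


@dataclass
class BinaryNetworkStack:
    grid: np.ndarray  # sparsity values, ascending
    adjacency: np.ndarray  # (len(grid), n, n) boolean, symmetric, zero diag
    achieved: np.ndarray  # realized sparsity per grid point

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[1]


def correlation_matrix(
    series: HemoglobinSeries | np.ndarray, chromophore: str = ""
) -> ConnectivityMatrix:
    """Pearson correlation between all channel pairs.

    Zero-variance channels are flagged with a warning and their edges set
    to r = 0.
    """
    if isinstance(series, HemoglobinSeries):
        data = series.chromophore(chromophore or "HbO")
    else:
        data = np.asarray(series, dtype=float)
    if data.shape[1] < 3:
        raise ValueError("need at least 3 time points")
    sd = data.std(axis=1)
    dead = sd == 0
    if dead.any():
        warnings.warn(
            f"{int(dead.sum())} zero-variance channel(s); their correlations set to 0",
            RuntimeWarning,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(data)
    r[np.isnan(r)] = 0.0
    r[dead, :] = 0.0
    r[:, dead] = 0.0
    np.fill_diagonal(r, 1.0)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    return ConnectivityMatrix(r=r, z=_fisher(r), chromophore=chromophore)


def _fisher(r: np.ndarray) -> np.ndarray:
    z = np.arctanh(np.clip(r, -1 + 1e-7, 1 - 1e-7))
    np.fill_diagonal(z, 0.0)
    return z


def fisher_z(conn: ConnectivityMatrix | np.ndarray) -> np.ndarray:
    """Fisher z-transform, elementwise off-diagonal (clipped near ±1)."""
    r = conn.r if isinstance(conn, ConnectivityMatrix) else np.asarray(conn, float)
    return _fisher(r)


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5))


def threshold_by_sparsity(
    conn: ConnectivityMatrix | np.ndarray,
    grid: np.ndarray = SPARSITY_GRID,
) -> BinaryNetworkStack:
    """Binary adjacency stack over the sparsity grid (positive z only)."""
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty sparsity grid")
    z = conn.z if isinstance(conn, ConnectivityMatrix) else np.asarray(conn, float)
    n = z.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    vals = z[iu, ju]
    positive = vals > 0
    order = np.lexsort((ju, iu, -vals))  # z desc, then (i, j) asc
    order = order[positive[order]]
    n_pairs = iu.size
    n_pos = order.size

    adjacency = np.zeros((grid.size, n, n), dtype=bool)
    achieved = np.zeros(grid.size)
    for k, s in enumerate(np.sort(grid)):
        want = _round_half_away(s * n_pairs)
        take = min(want, n_pos)
        sel = order[:take]
        adjacency[k, iu[sel], ju[sel]] = True
        adjacency[k] |= adjacency[k].T
        achieved[k] = take / n_pairs
    return BinaryNetworkStack(grid=np.sort(grid), adjacency=adjacency, achieved=achieved)
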