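import numpy as np
import pytest

import nirsnet as nn


@pytest.fixture(scope="session")
def montage():
    return nn.make_montage()


@pytest.fixture(scope="session")
def mini_cohort(montage):
    """A small but complete cohort with artifacts, shared across tests."""
    config = nn.CohortConfig(n_asd=4, n_td=3, duration=120.0, seed=7)
    subjects, truth = nn.simulate_cohort(config, montage)
    return config, subjects, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def floyd_warshall_oracle(adj: np.ndarray) -> np.ndarray:
    """Brute-force all-pairs hop distances, independent of the package."""
    a = np.asarray(adj, dtype=bool)
    n = a.shape[0]
    d = np.where(a, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        d = np.minimum(d, d[:, k][:, None] + d[k, :][None, :])
    return d


def global_efficiency_oracle(adj) -> float:
    d = floyd_warshall_oracle(adj)
    n = d.shape[0]
    if n < 2:
        return 0.0
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def local_efficiency_oracle(adj) -> float:
    a = np.asarray(adj, dtype=bool)
    n = a.shape[0]
    total = 0.0
    for i in range(n):
        nbrs = np.flatnonzero(a[i])
        if nbrs.size < 2:
            continue
        total += global_efficiency_oracle(a[np.ix_(nbrs, nbrs)])
    return total / n


def nodal_efficiency_oracle(adj) -> np.ndarray:
    d = floyd_warshall_oracle(adj)
    n = d.shape[0]
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return inv.sum(axis=1) / (n - 1)


def betweenness_oracle(adj) -> np.ndarray:
    """Betweenness by shortest-path counting over the distance matrix.

    sigma(s, t) is accumulated by dynamic programming in order of distance,
    a route entirely different from Brandes' dependency accumulation.
    """
    a = np.asarray(adj, dtype=bool)
    n = a.shape[0]
    d = floyd_warshall_oracle(a)
    sigma = np.zeros((n, n))
    for s in range(n):
        sigma[s, s] = 1.0
        reachable = np.flatnonzero(np.isfinite(d[s]))
        for t in sorted(reachable, key=lambda t: d[s, t]):
            if t == s:
                continue
            preds = [u for u in range(n) if a[u, t] and d[s, u] == d[s, t] - 1]
            sigma[s, t] = sum(sigma[s, u] for u in preds)
    bc = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            if not np.isfinite(d[s, t]) or sigma[s, t] == 0:
                continue
            for v in range(n):
                if v in (s, t):
                    continue
                if d[s, v] + d[v, t] == d[s, t]:
                    bc[v] += sigma[s, v] * sigma[v, t] / sigma[s, t]
    return bc
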