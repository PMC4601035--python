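"""Independent brute-force / closed-form oracles used by the test suite.

Everything here is deliberately naive and independent of the package's own
implementations: shortest paths by exhaustive simple-path enumeration,
clustering by triple loops, the P3 template window mean in closed form, and
Pearson significance by permutation.
"""

from __future__ import annotations

import itertools

import numpy as np


# ---------------------------------------------------------------------------
# graph metrics by exhaustive enumeration (feasible for N <= 8)
# ---------------------------------------------------------------------------


def brute_path_lengths(w: np.ndarray) -> np.ndarray:
    """All-pairs shortest 1/w path lengths by enumerating simple paths."""
    import networkx as nx

    n = w.shape[0]
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if w[i, j] > 0:
                g.add_edge(i, j, length=1.0 / w[i, j])
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(i + 1, n):
            best = np.inf
            for path in nx.all_simple_paths(g, i, j):
                cost = sum(g[a][b]["length"]
                           for a, b in zip(path[:-1], path[1:]))
                best = min(best, cost)
            d[i, j] = d[j, i] = best
    return d


def brute_global_efficiency(w: np.ndarray) -> float:
    d = brute_path_lengths(w)
    n = d.shape[0]
    if n < 2:
        return 0.0
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]):
                total += 1.0 / d[i, j]
    return total / (n * (n - 1))


def brute_char_path_length(w: np.ndarray) -> float:
    d = brute_path_lengths(w)
    n = d.shape[0]
    vals = [d[i, j] for i in range(n) for j in range(n) if i != j]
    return float(np.mean(vals))


def brute_clustering(w: np.ndarray) -> tuple[float, np.ndarray]:
    n = w.shape[0]
    per = np.zeros(n)
    for i in range(n):
        nb = [j for j in range(n) if w[i, j] > 0]
        k = len(nb)
        if k < 2:
            continue
        s = 0.0
        for j, h in itertools.combinations(nb, 2):
            s += (w[i, j] * w[j, h] * w[h, i]) ** (1.0 / 3.0)
        per[i] = 2.0 * s / (k * (k - 1))
    return float(per.mean()), per


def brute_local_efficiency(w: np.ndarray) -> tuple[float, np.ndarray]:
    n = w.shape[0]
    per = np.zeros(n)
    for i in range(n):
        nb = [j for j in range(n) if w[i, j] > 0]
        if len(nb) < 2:
            continue
        sub = w[np.ix_(nb, nb)]
        per[i] = brute_global_efficiency(sub)
    return float(per.mean()), per


def random_weighted_graph(rng: np.random.Generator, n: int,
                          density: float = 0.7) -> np.ndarray:
    """Random symmetric weight matrix in [0,1], zero diagonal."""
    w = rng.uniform(0.05, 1.0, size=(n, n))
    mask = rng.random((n, n)) < density
    w = np.where(mask, w, 0.0)
    w = np.triu(w, k=1)
    return w + w.T


# ---------------------------------------------------------------------------
# P3 template window mean, closed form
# ---------------------------------------------------------------------------


def template_window_mean(amp: float, width_ms: float, fs: float = 500.0,
                         half_width_ms: float = 50.0) -> float:
    """Discrete mean of the half-cosine bump over peak +/- half_width.

    The template is ``amp * cos(pi * u / (2 * width))`` at offsets
    ``u = k / fs`` around the peak; the sum of ``cos(k * theta)`` over
    ``k = -m..m`` is the Dirichlet kernel ``sin((2m+1) theta / 2) /
    sin(theta / 2)``.
    """
    dt_ms = 1000.0 / fs
    m = int(round(half_width_ms / dt_ms))
    theta = np.pi * dt_ms / (2.0 * width_ms)
    count = 2 * m + 1
    dirichlet = np.sin(count * theta / 2.0) / np.sin(theta / 2.0)
    return amp * dirichlet / count


# ---------------------------------------------------------------------------
# permutation test for Pearson correlation
# ---------------------------------------------------------------------------


def permutation_pearson(x: np.ndarray, y: np.ndarray,
                        exact_max_n: int = 7,
                        n_resamples: int = 20000,
                        rng: np.random.Generator | None = None
                        ) -> tuple[float, float]:
    """Two-sided permutation p-value for the Pearson r (exact for small n)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)

    def corr(a, b):
        a = a - a.mean()
        b = b - b.mean()
        return float(a @ b / np.sqrt((a @ a) * (b @ b)))

    r_obs = corr(x, y)
    if n <= exact_max_n:
        perms = itertools.permutations(range(n))
        stats = np.array([corr(x, y[list(p)]) for p in perms])
    else:
        rng = rng or np.random.default_rng(0)
        stats = np.array([corr(x, y[rng.permutation(n)])
                          for _ in range(n_resamples)])
    p = float(np.mean(np.abs(stats) >= abs(r_obs) - 1e-12))
    return r_obs, p
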