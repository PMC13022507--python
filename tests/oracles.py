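"""Independent reference implementations used only to check the package.

Everything here is written deliberately plainly (scalar loops, exhaustive
enumeration) and independently of the library code paths it validates.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np


def wc_fst_site(dosages_by_pop):
    """Scalar transcription of the Weir-Cockerham (1984) a, b, c components.

    ``dosages_by_pop``: one dosage array (0/1/2/nan) per population.
    Returns (a, b, c, theta); nan's when the estimator is undefined.
    """
    pops = []
    for d in dosages_by_pop:
        d = np.asarray(d, dtype=float)
        d = d[~np.isnan(d)]
        if len(d) > 0:
            pops.append(d)
    r = len(pops)
    if r < 2:
        return (np.nan,) * 4
    n = np.array([len(d) for d in pops], dtype=float)
    p = np.array([d.sum() / (2 * len(d)) for d in pops])
    h = np.array([np.mean(d == 1.0) for d in pops])

    nbar = n.sum() / r
    if nbar <= 1.0:
        return (np.nan,) * 4
    nc = (n.sum() - (n**2).sum() / n.sum()) / (r - 1)
    if nc <= 0:
        return (np.nan,) * 4
    pbar = (n * p).sum() / (r * nbar)
    s2 = (n * (p - pbar) ** 2).sum() / ((r - 1) * nbar)
    hbar = (n * h).sum() / (r * nbar)

    a = (nbar / nc) * (
        s2 - (1.0 / (nbar - 1.0)) * (pbar * (1 - pbar) - ((r - 1.0) / r) * s2 - hbar / 4.0)
    )
    b = (nbar / (nbar - 1.0)) * (
        pbar * (1 - pbar) - ((r - 1.0) / r) * s2 - ((2 * nbar - 1.0) / (4 * nbar)) * hbar
    )
    c = hbar / 2.0
    denom = a + b + c
    theta = a / denom if denom > 0 else np.nan
    return a, b, c, theta


def r2_plain(x, y):
    """Squared Pearson correlation over shared called samples (0 conventions)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~np.isnan(x) & ~np.isnan(y)
    if ok.sum() < 2:
        return 0.0
    x, y = x[ok], y[ok]
    if np.all(x == x[0]) or np.all(y == y[0]):
        return 0.0
    return float(np.corrcoef(x, y)[0, 1] ** 2)


def ld_prune_bruteforce(dosages, chroms, pos, window_kb, window_ct, r2_max, step_ct=1):
    """Plain restatement of the greedy windowed pruning rule.

    Windows of ``window_ct`` consecutive sites start every ``step_ct``
    sites per chromosome; inside a window the first surviving pair (in
    genomic order) within ``window_kb`` kb with r^2 > ``r2_max`` loses its
    lower-MAF member (tie: later position), until no such pair remains.
    """
    dosages = np.asarray(dosages, dtype=float)
    n_sites = dosages.shape[1]
    maf = []
    for m in range(n_sites):
        col = dosages[:, m]
        col = col[~np.isnan(col)]
        if len(col) == 0:
            maf.append(-1.0)
        else:
            f = col.sum() / (2 * len(col))
            maf.append(min(f, 1 - f))
    alive = [True] * n_sites

    for c in dict.fromkeys(chroms):
        idx = [m for m in range(n_sites) if chroms[m] == c]
        starts = []
        s = 0
        while True:
            starts.append(s)
            if s + window_ct >= len(idx):
                break
            s += step_ct
        for s in starts:
            window = idx[s : s + window_ct]
            while True:
                hit = None
                for i, j in itertools.combinations(window, 2):
                    if not (alive[i] and alive[j]):
                        continue
                    if pos[j] - pos[i] > window_kb * 1000:
                        continue
                    if r2_plain(dosages[:, i], dosages[:, j]) > r2_max:
                        hit = (i, j)
                        break
                if hit is None:
                    break
                i, j = hit
                victim = i if maf[i] < maf[j] else j
                alive[victim] = False

    return [m for m in range(n_sites) if alive[m]]


def simplex_grid(K, resolution=0.01):
    """All simplex points with coordinates that are multiples of resolution."""
    steps = round(1.0 / resolution)
    if K == 2:
        for i in range(steps + 1):
            yield np.array([i, steps - i]) / steps
    elif K == 3:
        for i in range(steps + 1):
            for j in range(steps + 1 - i):
                yield np.array([i, j, steps - i - j]) / steps
    else:
        raise ValueError("grid oracle supports K <= 3")


def best_grid_objective(P, x, resolution=0.01):
    """Exhaustive minimum of ||P q - x||^2 over the simplex grid."""
    best = np.inf
    for q in simplex_grid(P.shape[1], resolution):
        obj = float(((P @ q - x) ** 2).sum())
        if obj < best:
            best = obj
    return best


def grm_naive(dosages):
    """Elementwise standardized-relationship evaluation (double loop)."""
    dosages = np.asarray(dosages, dtype=float)
    n, M = dosages.shape
    freqs = np.empty(M)
    for m in range(M):
        col = dosages[:, m]
        col = col[~np.isnan(col)]
        freqs[m] = col.sum() / (2 * len(col)) if len(col) else np.nan
    R = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            total, count = 0.0, 0
            for m in range(M):
                f = freqs[m]
                if not np.isfinite(f) or f <= 0.0 or f >= 1.0:
                    continue
                gi, gj = dosages[i, m], dosages[j, m]
                if np.isnan(gi) or np.isnan(gj):
                    continue
                total += (gi - 2 * f) * (gj - 2 * f) / (2 * f * (1 - f))
                count += 1
            R[i, j] = total / count if count else 0.0
    return R


def hamming_naive(dosages):
    dosages = np.asarray(dosages, dtype=float)
    n, M = dosages.shape
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            s = 0.0
            for m in range(M):
                gi, gj = dosages[i, m], dosages[j, m]
                if np.isnan(gi) or np.isnan(gj):
                    continue
                s += abs(gi - gj)
            D[i, j] = s
    return D


def random_additive_tree(n_leaves, rng):
    """Random unrooted binary tree; returns (leaf names, path-length matrix).

    Built by attaching each new leaf to a uniformly random existing edge;
    branch lengths uniform on [0.1, 1.0]. Path lengths are computed with a
    graph shortest-path routine, independent of any NJ code.
    """
    g = nx.Graph()
    leaves = [f"L{i}" for i in range(n_leaves)]
    g.add_edge(leaves[0], "I0", weight=rng.uniform(0.1, 1.0))
    g.add_edge(leaves[1], "I0", weight=rng.uniform(0.1, 1.0))
    g.add_edge(leaves[2], "I0", weight=rng.uniform(0.1, 1.0))
    next_internal = 1
    for leaf in leaves[3:]:
        u, v = list(g.edges())[rng.integers(len(g.edges()))]
        w = g[u][v]["weight"]
        g.remove_edge(u, v)
        node = f"I{next_internal}"
        next_internal += 1
        split = rng.uniform(0.2, 0.8)
        g.add_edge(u, node, weight=w * split)
        g.add_edge(node, v, weight=w * (1 - split))
        g.add_edge(node, leaf, weight=rng.uniform(0.1, 1.0))
    D = np.zeros((n_leaves, n_leaves))
    paths = dict(nx.all_pairs_dijkstra_path_length(g))
    for i, a in enumerate(leaves):
        for j, b in enumerate(leaves):
            D[i, j] = paths[a][b]
    return leaves, D
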